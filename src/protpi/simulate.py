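"""Synthetic proteome generator with a planted-truth manifest.

Emulates the statistical shape of downloaded plant proteomes so the
whole pipeline is testable without external data:

* lengths are log-normal with a heavy right tail (default mean 424.34
  residues, the plant-kingdom average, truncated to [4, 25000]);
* residue frequencies default to the published kingdom-wide averages
  (Leu most abundant at 9.62%, Trp least at 1.28%), renormalized;
* each lineage applies a small log-fold compositional shift, and each
  proteome jitters its composition via a Dirichlet draw around the
  shifted frequencies;
* rare/ambiguous codes (X, B, Z, J) are injected at low per-residue
  rates, never at position 1 and never inside planted sequences;
* extreme proteins are planted with known properties (a giant
  polyketide-synthase-scale chain, a tetrapeptide, an Asp-rich acidic
  repeat, a Lys/Arg-rich basic repeat, selenoproteins with exact Sec
  counts) and recorded in a machine-readable manifest.

Every sequence begins with Met.  Output is deterministic given the
seed, byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import json
import numpy as np
import pandas as pd

from .sequence_io import AMBIGUOUS_RESIDUES, STANDARD_RESIDUES, ProteinRecord, Proteome

# Kingdom-wide average amino-acid abundance (%), used as default base
# frequencies after renormalization.
KINGDOM_AVG_PCT = {
    "L": 9.62, "S": 8.71, "A": 7.68, "G": 6.80, "R": 6.68, "V": 6.55,
    "E": 6.43, "K": 5.73, "D": 5.32, "P": 5.10, "I": 4.94, "T": 4.90,
    "N": 4.13, "F": 3.97, "Q": 3.74, "Y": 2.67, "M": 2.40, "H": 2.40,
    "C": 1.85, "W": 1.28,
}

AVG_PROTEIN_LENGTH = 424.34

# Log-fold shifts per lineage.  The four lineages form two opposed
# pairs along two compositional axes built from abundant residues, so
# the between-lineage structure spans a plane that the leading two
# principal components can capture; per-feature magnitudes are several
# times the Dirichlet(2000) within-lineage spread.
DEFAULT_LINEAGE_SHIFT = {
    "algae": {"A": 0.30, "G": 0.25, "R": 0.25, "V": 0.20,
              "L": -0.30, "S": -0.25, "T": -0.20},
    "bryophyte": {"A": -0.30, "G": -0.25, "R": -0.25, "V": -0.20,
                  "L": 0.30, "S": 0.25, "T": 0.20},
    "monocot": {"E": 0.30, "D": 0.25, "K": 0.25, "P": 0.20,
                "I": -0.30, "F": -0.25, "Q": -0.20},
    "eudicot": {"E": -0.30, "D": -0.25, "K": -0.25, "P": -0.20,
                "I": 0.30, "F": 0.25, "Q": 0.20},
}

DEFAULT_AMBIGUOUS_RATES = {"U": 0.0, "O": 0.0, "B": 5e-6, "Z": 3e-6,
                           "J": 3e-6, "X": 2e-5}

_AA = np.frombuffer(STANDARD_RESIDUES.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class PlantedFeature:
    """One engineered extreme protein with its expected recovery property."""

    kind: str                     # acidic_repeat | basic_repeat | giant | tiny | selenoprotein
    species: str
    params: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)

    _KINDS = ("acidic_repeat", "basic_repeat", "giant", "tiny", "selenoprotein")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown planted kind {self.kind!r}")


def default_planted() -> list[PlantedFeature]:
    """Planted set mirroring the published extremes under default lineages."""
    return [
        PlantedFeature("giant", "algae_01", {"length": 22244},
                       {"size_rank": 1, "length": 22244}),
        PlantedFeature("selenoprotein", "algae_01", {"length": 300, "u_count": 9},
                       {"u_count": 9}),
        PlantedFeature("selenoprotein", "algae_02", {"length": 300, "u_count": 16},
                       {"u_count": 16}),
        PlantedFeature("selenoprotein", "algae_03", {"length": 300, "u_count": 11},
                       {"u_count": 11}),
        PlantedFeature("tiny", "eudicot_01", {"sequence": "MIMF"},
                       {"smallest_rank": 1, "pi_2dp": 5.98, "mw_kda": 0.54}),
        PlantedFeature("acidic_repeat", "eudicot_02", {"unit": "GWID", "copies": 67},
                       {"pi_below": 3.0}),
        PlantedFeature("basic_repeat", "eudicot_03",
                       {"units": [["QKLKSGLT", 64], ["TRRGLTAV", 31]]},
                       {"pi_above": 11.0}),
    ]


@dataclass
class SyntheticSpec:
    """Full parameterization of the generator."""

    seed: int = 0
    lineages: list[tuple[str, int]] = field(
        default_factory=lambda: [("algae", 3), ("bryophyte", 3),
                                 ("monocot", 3), ("eudicot", 3)]
    )
    n_proteins: int = 2000
    length_mean: float = AVG_PROTEIN_LENGTH
    length_sigma: float = 0.75      # log-space
    length_min: int = 4
    length_max: int = 25000
    base_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(KINGDOM_AVG_PCT)
    )
    lineage_shift: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LINEAGE_SHIFT.items()}
    )
    dirichlet_concentration: float | None = 2000.0
    ambiguous_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMBIGUOUS_RATES)
    )
    planted: list[PlantedFeature] = field(default_factory=default_planted)

    def species_names(self) -> list[tuple[str, str]]:
        """All (species, lineage) pairs in generation order."""
        out = []
        for lineage, n in self.lineages:
            for i in range(n):
                out.append((f"{lineage}_{i + 1:02d}", lineage))
        return out

    def validate(self) -> None:
        freqs = np.array([self.base_frequencies.get(r, 0.0) for r in STANDARD_RESIDUES])
        if (freqs <= 0).any() or not math.isfinite(freqs.sum()) or freqs.sum() <= 0:
            raise ValueError("base frequencies must be positive and renormalizable")
        known = {s for s, _ in self.species_names()}
        for f in self.planted:
            if f.species not in known:
                raise ValueError(
                    f"planted feature {f.kind!r} targets unknown species {f.species!r}"
                )
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        for code, rate in self.ambiguous_rates.items():
            if code not in AMBIGUOUS_RESIDUES or rate < 0 or rate >= 1:
                raise ValueError(f"bad ambiguous rate {code}={rate}")


@dataclass
class SyntheticResult:
    proteomes: list[Proteome]
    manifest: pd.DataFrame   # species, protein_id, kind, params, expected
    census: pd.DataFrame     # species x {U,O,B,Z,J,X} realized totals


def _planted_ids(spec: SyntheticSpec) -> list[str]:
    """Deterministic planted protein ids, aligned with spec.planted order."""
    counters: dict[tuple[str, str], int] = {}
    ids = []
    for f in spec.planted:
        key = (f.species, f.kind)
        counters[key] = counters.get(key, 0) + 1
        suffix = f"_{counters[key]}" if counters[key] > 1 else ""
        ids.append(f"{f.species}_planted_{f.kind}{suffix}")
    return ids


def planted_truth(spec: SyntheticSpec) -> pd.DataFrame:
    """Machine-readable manifest of planted features (consumed by recovery tests)."""
    ids = _planted_ids(spec)
    rows = [
        {
            "species": f.species,
            "protein_id": pid,
            "kind": f.kind,
            "params": json.dumps(f.params, sort_keys=True),
            "expected": json.dumps(f.expected, sort_keys=True),
        }
        for f, pid in zip(spec.planted, ids)
    ]
    return pd.DataFrame(rows, columns=["species", "protein_id", "kind", "params", "expected"])


def _sample_lengths(rng: np.random.Generator, spec: SyntheticSpec, n: int) -> np.ndarray:
    """Truncated log-normal lengths; out-of-range draws are resampled."""
    mu = math.log(spec.length_mean) - 0.5 * spec.length_sigma**2
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = np.rint(rng.lognormal(mu, spec.length_sigma, size=n - filled)).astype(np.int64)
        ok = draw[(draw >= spec.length_min) & (draw <= spec.length_max)]
        out[filled:filled + ok.size] = ok
        filled += ok.size
    return out


def _draw_background(rng: np.random.Generator, fractions: np.ndarray, length: int) -> str:
    """One background sequence of the given total length, starting with Met."""
    body = _AA[rng.choice(len(_AA), size=length - 1, p=fractions)]
    return "M" + body.tobytes().decode()


def _build_planted(rng: np.random.Generator, f: PlantedFeature,
                   fractions: np.ndarray) -> str:
    if f.kind == "tiny":
        return f.params["sequence"]
    if f.kind == "acidic_repeat":
        return "M" + f.params["unit"] * int(f.params["copies"])
    if f.kind == "basic_repeat":
        return "M" + "".join(u * int(c) for u, c in f.params["units"])
    if f.kind == "giant":
        return _draw_background(rng, fractions, int(f.params["length"]))
    if f.kind == "selenoprotein":
        length = int(f.params.get("length", 300))
        u = int(f.params["u_count"])
        seq = bytearray(_draw_background(rng, fractions, length).encode())
        pos = rng.choice(np.arange(1, length), size=u, replace=False)
        for p in pos:
            seq[p] = ord("U")
        return seq.decode()
    raise AssertionError(f.kind)


def generate(spec: SyntheticSpec) -> SyntheticResult:
    """Generate all proteomes plus the planted manifest and residue census."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = np.array([spec.base_frequencies[r] for r in STANDARD_RESIDUES], dtype=float)
    base = base / base.sum()

    planted_by_species: dict[str, list[tuple[PlantedFeature, str]]] = {}
    for f, pid in zip(spec.planted, _planted_ids(spec)):
        planted_by_species.setdefault(f.species, []).append((f, pid))

    proteomes = []
    census_rows = []
    for species, lineage in spec.species_names():
        shift = spec.lineage_shift.get(lineage, {})
        shifted = base * np.exp([shift.get(r, 0.0) for r in STANDARD_RESIDUES])
        shifted = shifted / shifted.sum()
        if spec.dirichlet_concentration is not None:
            fractions = rng.dirichlet(spec.dirichlet_concentration * shifted)
        else:
            fractions = shifted

        lengths = _sample_lengths(rng, spec, spec.n_proteins)
        body_lengths = lengths - 1
        flat = _AA[rng.choice(len(_AA), size=int(body_lengths.sum()), p=fractions)]

        # ambiguity codes go into body positions only (never the leading Met)
        for code in AMBIGUOUS_RESIDUES:
            rate = spec.ambiguous_rates.get(code, 0.0)
            if rate > 0 and flat.size > 0:
                k = rng.binomial(flat.size, rate)
                if k > 0:
                    pos = rng.choice(flat.size, size=k, replace=False)
                    flat[pos] = ord(code)

        starts = np.concatenate([[0], np.cumsum(body_lengths)])
        records = []
        for j in range(spec.n_proteins):
            body = flat[starts[j]:starts[j + 1]].tobytes().decode()
            records.append(ProteinRecord(f"{species}_{j + 1:06d}", "synthetic", "M" + body))

        for f, pid in planted_by_species.get(species, []):
            slot = int(rng.integers(0, spec.n_proteins))
            while records[slot].id.endswith("planted") or "_planted_" in records[slot].id:
                slot = (slot + 1) % spec.n_proteins
            seq = _build_planted(rng, f, fractions)
            records[slot] = ProteinRecord(pid, f"planted {f.kind}", seq)

        proteomes.append(Proteome(species=species, lineage=lineage, records=records))
        joined = "".join(r.sequence for r in records)
        census_rows.append(
            {"species": species, **{c: joined.count(c) for c in AMBIGUOUS_RESIDUES}}
        )

    census = pd.DataFrame(census_rows).set_index("species")
    return SyntheticResult(proteomes=proteomes, manifest=planted_truth(spec), census=census)


def spec_from_dict(data: dict) -> SyntheticSpec:
    """Build a spec from a plain dict (e.g. parsed YAML config)."""
    kwargs = dict(data)
    if "lineages" in kwargs:
        kwargs["lineages"] = [tuple(x) for x in kwargs["lineages"]]
    if "planted" in kwargs:
        kwargs["planted"] = [
            PlantedFeature(p["kind"], p["species"], p.get("params", {}),
                           p.get("expected", {}))
            for p in kwargs["planted"]
        ]
    return SyntheticSpec(**kwargs)


def spec_to_dict(spec: SyntheticSpec) -> dict:
    """Echo a spec as plain data (for provenance alongside generated FASTA)."""
    data = asdict(spec)
    data["lineages"] = [list(x) for x in spec.lineages]
    data["planted"] = [
        {"kind": f.kind, "species": f.species, "params": f.params,
         "expected": f.expected}
        for f in spec.planted
    ]
    return data
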