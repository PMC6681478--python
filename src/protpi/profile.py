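"""Per-species aggregation of protein profiles.

Classification follows the presentation convention: a protein is acidic,
neutral or basic according to its pI rounded to two decimals being
below, equal to, or above 7.00.  The neutral class is therefore a
narrow band (width 0.005 either side of 7), which is why real proteomes
show a tiny but nonzero neutral percentage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .physchem import PhysChemProfile, round_pi, truncate_kda
from .sequence_io import AMBIGUOUS_RESIDUES, STANDARD_RESIDUES, Proteome

KDA_100_DA = 100_000.0


@dataclass
class ProteomeSummary:
    """One species' aggregate physicochemical summary (one table row)."""

    species: str
    lineage: str
    n_proteins: int
    pct_acidic: float
    pct_basic: float
    pct_neutral: float
    avg_acidic_pi: float | None
    avg_basic_pi: float | None
    avg_length: float
    avg_mw_kda: float
    gross_mw_kda: float
    pct_ge_100kda: float
    min_pi_record: tuple[str, float]
    max_pi_record: tuple[str, float]
    min_mw_record: tuple[str, float]
    max_mw_record: tuple[str, float]
    rare_counts: dict[str, int] = field(default_factory=dict)
    sec_protein_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=list)


def classify_pi(pi: float) -> str:
    """acidic / neutral / basic by pI rounded to 2 decimals vs 7.00."""
    r = round_pi(pi)
    if r < 7.0:
        return "acidic"
    if r > 7.0:
        return "basic"
    return "neutral"


def summarize(
    profiles: Sequence[PhysChemProfile],
    species: str,
    lineage: str = "other",
) -> ProteomeSummary:
    """Aggregate per-protein profiles into a per-species summary.

    Percentages sum to 100 exactly (up to float addition); the >=100 kDa
    share uses an inclusive threshold on the raw mass in Da.
    """
    if not profiles:
        raise ValueError(f"cannot summarize an empty profile set for {species!r}")
    n = len(profiles)
    classes = [classify_pi(p.pi) for p in profiles]
    n_acidic = classes.count("acidic")
    n_basic = classes.count("basic")
    n_neutral = n - n_acidic - n_basic
    acidic_pis = [p.pi for p, c in zip(profiles, classes) if c == "acidic"]
    basic_pis = [p.pi for p, c in zip(profiles, classes) if c == "basic"]

    # ties on value break by lexicographically smaller id
    by_pi = sorted(profiles, key=lambda p: (p.pi, p.id))
    by_mw = sorted(profiles, key=lambda p: (p.mw_da, p.id))

    rare = {res: sum(p.ambiguous_counts.get(res, 0) for p in profiles)
            for res in AMBIGUOUS_RESIDUES}
    sec_ids = sorted(p.id for p in profiles if p.ambiguous_counts.get("U", 0) > 0)

    gross_da = sum(p.mw_da for p in profiles)
    return ProteomeSummary(
        species=species,
        lineage=lineage,
        n_proteins=n,
        pct_acidic=100.0 * n_acidic / n,
        pct_basic=100.0 * n_basic / n,
        pct_neutral=100.0 * n_neutral / n,
        avg_acidic_pi=(sum(acidic_pis) / len(acidic_pis)) if acidic_pis else None,
        avg_basic_pi=(sum(basic_pis) / len(basic_pis)) if basic_pis else None,
        avg_length=sum(p.length for p in profiles) / n,
        avg_mw_kda=truncate_kda(gross_da / n),
        gross_mw_kda=gross_da / 1000.0,
        pct_ge_100kda=100.0 * sum(p.mw_da >= KDA_100_DA for p in profiles) / n,
        min_pi_record=(by_pi[0].id, by_pi[0].pi),
        max_pi_record=(by_pi[-1].id, by_pi[-1].pi),
        min_mw_record=(by_mw[0].id, by_mw[0].mw_da),
        max_mw_record=(by_mw[-1].id, by_mw[-1].mw_da),
        rare_counts=rare,
        sec_protein_ids=sec_ids,
    )


def find_extremes(
    profiles: Sequence[PhysChemProfile], k: int = 1
) -> dict[str, list[tuple[str, float]]]:
    """Top-k extreme proteins: largest/smallest by mass, highest/lowest by pI.

    Ordering is deterministic; ties on the value break by lexicographic
    id.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    by_mw_asc = sorted(profiles, key=lambda p: (p.mw_da, p.id))
    by_mw_desc = sorted(profiles, key=lambda p: (-p.mw_da, p.id))
    by_pi_asc = sorted(profiles, key=lambda p: (p.pi, p.id))
    by_pi_desc = sorted(profiles, key=lambda p: (-p.pi, p.id))
    return {
        "largest": [(p.id, p.mw_da) for p in by_mw_desc[:k]],
        "smallest": [(p.id, p.mw_da) for p in by_mw_asc[:k]],
        "highest_pi": [(p.id, p.pi) for p in by_pi_desc[:k]],
        "lowest_pi": [(p.id, p.pi) for p in by_pi_asc[:k]],
    }


def rare_residue_census(
    profiles: Sequence[PhysChemProfile],
) -> tuple[dict[str, int], dict[str, dict[str, int]]]:
    """Totals of U, O, B, Z, J, X plus per-protein nonzero occurrences.

    Proteins containing U are candidate selenoproteins.
    """
    totals = {res: 0 for res in AMBIGUOUS_RESIDUES}
    per_protein: dict[str, dict[str, int]] = {}
    for p in profiles:
        found = {res: c for res, c in p.ambiguous_counts.items() if c > 0}
        for res, c in found.items():
            totals[res] += c
        if found:
            per_protein[p.id] = found
    return totals, per_protein


def proteome_composition(profiles: Sequence[PhysChemProfile]) -> dict[str, float]:
    """Aggregate residue fractions over the 20 standard residues.

    Counts are pooled over all proteins and renormalized over the
    standard alphabet (ambiguity codes are censused separately).
    """
    totals = {res: 0 for res in STANDARD_RESIDUES}
    for p in profiles:
        for res in STANDARD_RESIDUES:
            totals[res] += p.counts.get(res, 0)
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("no standard residues in profile set")
    return {res: c / grand for res, c in totals.items()}
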