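"""Shipped pKa scales and residue mass/element tables.

Both are plain TSV files under ``protpi/data`` so users can supply their
own tables in the same format.  The default pKa scale is the IPC protein
scale; EMBOSS and Sillero scales are shipped as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

ELEMENTS = ("C", "H", "N", "O", "S", "Se")

# CIAAW standard atomic weights, used to verify table self-consistency.
_ATOMIC_WEIGHT = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999,
                  "S": 32.06, "Se": 78.971}

DEFAULT_PKA_SET = "ipc_protein"


@dataclass(frozen=True)
class PKaSet:
    """A named table of dissociation constants for ionizable groups.

    ``side_chain`` maps a residue letter to ``(pKa, polarity)`` with
    polarity ``"acidic"`` or ``"basic"``; the chain termini carry their
    own constants.
    """

    name: str
    side_chain: dict[str, tuple[float, str]]
    n_term: float
    c_term: float

    def __post_init__(self) -> None:
        for group, pka in [("n_term", self.n_term), ("c_term", self.c_term)] + [
            (r, v[0]) for r, v in self.side_chain.items()
        ]:
            if not 0.0 < pka < 14.0:
                raise ValueError(f"pKa for {group} out of (0, 14): {pka}")
        for res, (_, pol) in self.side_chain.items():
            if pol not in ("acidic", "basic"):
                raise ValueError(f"polarity for {res} must be acidic|basic, got {pol}")


@dataclass(frozen=True)
class ResidueMassTable:
    """Average residue masses (Da) and element counts of the residue unit.

    A residue unit is the amino acid minus one water; a chain's mass is
    the sum of its residue masses plus one water.
    """

    masses: dict[str, float]
    elements: dict[str, dict[str, int]]
    water_mass: float
    water_elements: dict[str, int]

    def __post_init__(self) -> None:
        for res, mass in self.masses.items():
            if mass <= 0:
                raise ValueError(f"non-positive mass for residue {res}")
            calc = sum(self.elements[res][e] * _ATOMIC_WEIGHT[e] for e in ELEMENTS)
            if abs(calc - mass) > 0.01:
                raise ValueError(
                    f"residue {res}: stored mass {mass} disagrees with element "
                    f"composition ({calc:.4f}) by more than 0.01 Da"
                )


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("protpi").joinpath("data", filename)))


def load_pka_sets(path: str | Path | None = None) -> dict[str, PKaSet]:
    """Load all pKa scales from a TSV (default: the shipped table)."""
    path = Path(path) if path is not None else _data_path("pka_sets.tsv")
    raw: dict[str, dict[str, tuple[float, str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("set\t"):
                continue
            name, group, pka, polarity = line.split("\t")
            raw.setdefault(name, {})[group] = (float(pka), polarity)
    sets = {}
    for name, groups in raw.items():
        n_term = groups.pop("n_term")
        c_term = groups.pop("c_term")
        sets[name] = PKaSet(name=name, side_chain=groups,
                            n_term=n_term[0], c_term=c_term[0])
    return sets


def get_pka_set(name: str = DEFAULT_PKA_SET) -> PKaSet:
    sets = load_pka_sets()
    try:
        return sets[name]
    except KeyError:
        raise KeyError(f"unknown pKa set {name!r}; available: {sorted(sets)}") from None


def load_mass_table(path: str | Path | None = None) -> ResidueMassTable:
    """Load the residue mass/element table from a TSV (default: shipped)."""
    path = Path(path) if path is not None else _data_path("residue_masses.tsv")
    masses: dict[str, float] = {}
    elements: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("residue\t"):
                continue
            fields = line.split("\t")
            res, mass = fields[0], float(fields[1])
            counts = dict(zip(ELEMENTS, (int(x) for x in fields[2:8])))
            if res == "water":
                water_mass, water_elements = mass, counts
            else:
                masses[res] = mass
                elements[res] = counts
    return ResidueMassTable(masses=masses, elements=elements,
                            water_mass=water_mass, water_elements=water_elements)
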