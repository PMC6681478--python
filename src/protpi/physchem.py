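"""Per-protein physicochemical computations.

The isoelectric point is the root of the Henderson-Hasselbalch net
charge

    Q(pH) = sum_basic N_g / (1 + 10^(pH - pKa_g))
          - sum_acidic N_g / (1 + 10^(pKa_g - pH))

over ionizable side chains plus exactly one free N- and one free
C-terminal group per chain.  Q is strictly decreasing in pH, so the root
is unique and found by bisection.  Molecular mass uses average residue
masses plus one water; the elemental formula sums residue units plus
H2O.

Ambiguity codes follow their translation products: B contributes as Asp,
Z as Glu, J as Leu; X is non-ionizable, contributes no atoms to the
formula and (by default) zero mass, with the skipped count recorded on
the profile.  Selenocysteine (U) is non-ionizable by default; an
optional acidic group can be enabled via ``sec_pka``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .sequence_io import ALPHABET, AMBIGUOUS_RESIDUES, Proteome
from .tables import (
    ELEMENTS,
    PKaSet,
    ResidueMassTable,
    get_pka_set,
    load_mass_table,
)

# B/Z/J behave as their translation products in charge, mass and formula.
TRANSLATION_ALIAS = {"B": "D", "Z": "E", "J": "L"}

_MAX_BRACKET = (-5.0, 19.0)


def _ionizable_groups(
    counts: Mapping[str, int],
    pka: PKaSet,
    sec_pka: float | None,
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Collect (pKa, multiplicity) for basic and acidic groups, termini included."""
    basic: list[tuple[float, float]] = [(pka.n_term, 1.0)]
    acidic: list[tuple[float, float]] = [(pka.c_term, 1.0)]
    for res, n in counts.items():
        if res not in ALPHABET:
            raise KeyError(f"unknown residue key {res!r}")
        if n < 0:
            raise ValueError(f"negative count for residue {res!r}")
        if n == 0:
            continue
        if res == "U" and sec_pka is not None:
            acidic.append((sec_pka, float(n)))
            continue
        entry = pka.side_chain.get(TRANSLATION_ALIAS.get(res, res))
        if entry is None:
            continue
        value, polarity = entry
        (basic if polarity == "basic" else acidic).append((value, float(n)))
    return basic, acidic


def net_charge(
    counts: Mapping[str, int],
    pH: float,
    pka: PKaSet | None = None,
    sec_pka: float | None = None,
) -> float:
    """Net charge (elementary charges) of a chain with the given composition.

    ``counts`` maps residue letters to occurrences; one free N- and one
    free C-terminus are always included.  Evaluation outside [0, 14] is
    permitted (used for bracketing).
    """
    pka = pka or get_pka_set()
    basic, acidic = _ionizable_groups(counts, pka, sec_pka)
    q = 0.0
    for value, n in basic:
        q += n / (1.0 + 10.0 ** (pH - value))
    for value, n in acidic:
        q -= n / (1.0 + 10.0 ** (value - pH))
    return q


def isoelectric_point(
    sequence_or_counts: str | Mapping[str, int],
    pka: PKaSet | None = None,
    tol: float = 1e-3,
    sec_pka: float | None = None,
) -> float:
    """Isoelectric point: the pH at which the net charge is zero.

    Bisection on [0, 14]; if the root is not bracketed the bracket is
    widened in 1 pH-unit steps (the termini guarantee a sign change for
    any valid chain).  The returned value is accurate to ``tol`` pH
    units.
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    pka = pka or get_pka_set()
    if isinstance(sequence_or_counts, str):
        counts: Mapping[str, int] = Counter(sequence_or_counts)
    else:
        counts = sequence_or_counts
    basic, acidic = _ionizable_groups(counts, pka, sec_pka)

    def q(pH: float) -> float:
        total = 0.0
        for value, n in basic:
            total += n / (1.0 + 10.0 ** (pH - value))
        for value, n in acidic:
            total -= n / (1.0 + 10.0 ** (value - pH))
        return total

    lo, hi = 0.0, 14.0
    qlo, qhi = q(lo), q(hi)
    while qlo < 0.0 or qhi > 0.0:
        if lo <= _MAX_BRACKET[0] and hi >= _MAX_BRACKET[1]:
            raise ValueError("net charge does not change sign on the widened bracket")
        lo = max(lo - 1.0, _MAX_BRACKET[0])
        hi = min(hi + 1.0, _MAX_BRACKET[1])
        qlo, qhi = q(lo), q(hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if q(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def composition(sequence: str) -> tuple[dict[str, int], dict[str, float]]:
    """Residue counts and fractions (fractions over the full length)."""
    counts = dict(Counter(sequence))
    n = len(sequence)
    fractions = {res: c / n for res, c in counts.items()}
    return counts, fractions


def molecular_weight(
    sequence_or_counts: str | Mapping[str, int],
    masses: ResidueMassTable | None = None,
    policy: str = "lenient",
    x_mass: float = 0.0,
) -> float:
    """Average molecular mass in Da: residue masses plus one water.

    Under ``strict`` policy any residue without its own mass entry
    (B, Z, J, X) is an error; under ``lenient`` (default) B/Z/J use
    their translation products' masses and X uses ``x_mass``.
    """
    masses = masses or load_mass_table()
    if isinstance(sequence_or_counts, str):
        counts: Mapping[str, int] = Counter(sequence_or_counts)
    else:
        counts = sequence_or_counts
    total = masses.water_mass
    for res, n in counts.items():
        if res not in ALPHABET:
            raise KeyError(f"unknown residue key {res!r}")
        if res in masses.masses:
            total += n * masses.masses[res]
        elif policy == "strict":
            raise ValueError(f"no mass entry for residue {res!r} under strict policy")
        elif res == "X":
            total += n * x_mass
        else:
            total += n * masses.masses[TRANSLATION_ALIAS[res]]
    return total


def chemical_formula(
    sequence_or_counts: str | Mapping[str, int],
    masses: ResidueMassTable | None = None,
    policy: str = "lenient",
) -> dict[str, int]:
    """Elemental formula (C, H, N, O, S, Se counts) of the intact chain.

    Sum of residue element counts plus one water.  Strict policy rejects
    ambiguity codes; lenient maps B->D, Z->E, J->L and skips X entirely
    (the skipped count is tracked by :func:`profile_sequence`).
    """
    masses = masses or load_mass_table()
    if isinstance(sequence_or_counts, str):
        counts: Mapping[str, int] = Counter(sequence_or_counts)
    else:
        counts = sequence_or_counts
    formula = dict(masses.water_elements)
    for el in ELEMENTS:
        formula.setdefault(el, 0)
    for res, n in counts.items():
        if res not in ALPHABET:
            raise KeyError(f"unknown residue key {res!r}")
        if res in masses.elements:
            res_el = masses.elements[res]
        elif policy == "strict":
            raise ValueError(f"ambiguous residue {res!r} under strict policy")
        elif res == "X":
            continue
        else:
            res_el = masses.elements[TRANSLATION_ALIAS[res]]
        for el in ELEMENTS:
            formula[el] += n * res_el[el]
    return formula


def truncate_kda(mw_da: float, decimals: int = 2) -> float:
    """Report Da as kDa truncated (not rounded) to ``decimals`` places."""
    scale = 10.0 ** decimals
    return math.floor(mw_da / 1000.0 * scale + 1e-9) / scale


def round_pi(pi: float, decimals: int = 2) -> float:
    """Presentation rounding of pI (half away from zero, deterministic)."""
    scale = 10.0 ** decimals
    return math.floor(pi * scale + 0.5) / scale


@dataclass
class PhysChemProfile:
    """Per-protein physicochemical summary (one row of the profile table)."""

    id: str
    length: int
    mw_da: float
    pi: float
    formula: dict[str, int]
    counts: dict[str, int]
    ambiguous_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.length:
            raise ValueError("residue counts do not sum to sequence length")
        if self.mw_da <= 0:
            raise ValueError("non-positive molecular mass")
        if not 0.0 < self.pi < 14.0:
            raise ValueError(f"pI out of range: {self.pi}")

    @property
    def mw_kda(self) -> float:
        return truncate_kda(self.mw_da)

    @property
    def pi_2dp(self) -> float:
        return round_pi(self.pi)


def profile_sequence(
    rec_id: str,
    sequence: str,
    pka: PKaSet | None = None,
    masses: ResidueMassTable | None = None,
    tol: float = 1e-3,
    sec_pka: float | None = None,
) -> PhysChemProfile:
    """Compute the full physicochemical profile of one sequence."""
    pka = pka or get_pka_set()
    masses = masses or load_mass_table()
    counts = dict(Counter(sequence))
    ambiguous = {res: counts.get(res, 0) for res in AMBIGUOUS_RESIDUES}
    return PhysChemProfile(
        id=rec_id,
        length=len(sequence),
        mw_da=molecular_weight(counts, masses),
        pi=isoelectric_point(counts, pka, tol=tol, sec_pka=sec_pka),
        formula=chemical_formula(counts, masses),
        counts=counts,
        ambiguous_counts=ambiguous,
    )


def profile_proteome(
    proteome: Proteome,
    pka: PKaSet | None = None,
    masses: ResidueMassTable | None = None,
    tol: float = 1e-3,
    sec_pka: float | None = None,
) -> list[PhysChemProfile]:
    """Profile every record of a proteome (order preserved)."""
    pka = pka or get_pka_set()
    masses = masses or load_mass_table()
    return [
        profile_sequence(rec.id, rec.sequence, pka, masses, tol=tol, sec_pka=sec_pka)
        for rec in proteome
    ]


def format_formula(formula: Mapping[str, int]) -> str:
    """Render element counts as e.g. ``C25H40N4O5S2``."""
    parts = []
    for el in ELEMENTS:
        n = formula.get(el, 0)
        if n == 1:
            parts.append(el)
        elif n > 0:
            parts.append(f"{el}{n}")
    return "".join(parts)
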