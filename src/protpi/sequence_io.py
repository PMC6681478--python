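"""Protein FASTA reading, validation and writing.

Sequences are plain amino-acid strings over the extended one-letter
alphabet: the 20 standard residues, selenocysteine (U), pyrrolysine (O)
and the ambiguity codes B (Asn/Asp), Z (Gln/Glu), J (Leu/Ile), X
(unknown).  A single trailing translation stop ('*') is tolerated and
stripped; internal stops are rejected as annotation errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYUOBZJX")
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_RESIDUES = "UOBZJX"

LINEAGES = (
    "algae",
    "bryophyte",
    "pteridophyte",
    "gymnosperm",
    "monocot",
    "eudicot",
    "other",
)


class FastaParseError(ValueError):
    """Malformed FASTA input (e.g. sequence data before any header)."""


class SequenceAlphabetError(ValueError):
    """Sequence contains characters outside the accepted alphabet."""


def validate_sequence(raw: str) -> str:
    """Normalize and validate a raw amino-acid string.

    Whitespace is removed, case is folded to upper, and exactly one
    trailing stop character ('*') is silently stripped.  Raises
    :class:`SequenceAlphabetError` for internal stops or any character
    outside the alphabet (positions reported 1-based on the normalized
    string).
    """
    seq = "".join(raw.split()).upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if not seq:
        raise SequenceAlphabetError("empty sequence")
    if "*" in seq:
        raise SequenceAlphabetError(
            f"internal stop character at position {seq.index('*') + 1}"
        )
    bad = [(i + 1, c) for i, c in enumerate(seq) if c not in ALPHABET]
    if bad:
        desc = ", ".join(f"{c!r} at position {i}" for i, c in bad[:10])
        raise SequenceAlphabetError(f"invalid characters: {desc}")
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """One validated protein sequence with its FASTA identity."""

    id: str
    description: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """An ordered collection of proteins from one species."""

    species: str
    lineage: str = "other"
    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise ValueError(
                f"unknown lineage {self.lineage!r}; expected one of {LINEAGES}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def read_fasta(path: str | Path, species: str = "", lineage: str = "other") -> Proteome:
    """Read a multi-record protein FASTA file into a :class:`Proteome`.

    Record order is preserved.  The id is the first whitespace-delimited
    token of the header; the description is everything after it.  Errors:
    sequence data before the first header (parse error naming the line),
    duplicate ids, and invalid sequences (via :func:`validate_sequence`).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: tuple[str, str] | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        rid, desc = header
        if not chunks:
            raise FastaParseError(
                f"{path.name}: record {rid!r} (line {header_line}) has no sequence"
            )
        try:
            seq = validate_sequence("".join(chunks))
        except SequenceAlphabetError as exc:
            raise SequenceAlphabetError(f"record {rid!r}: {exc}") from exc
        if rid in seen:
            raise FastaParseError(f"{path.name}: duplicate record id {rid!r}")
        seen.add(rid)
        records.append(ProteinRecord(rid, desc, seq))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                chunks = []
                tokens = line[1:].split(None, 1)
                if not tokens:
                    raise FastaParseError(f"{path.name}: empty header at line {lineno}")
                rid = tokens[0]
                desc = tokens[1].strip() if len(tokens) > 1 else ""
                header = (rid, desc)
                header_line = lineno
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path.name}: sequence data before first header at line {lineno}"
                    )
                chunks.append(line.strip())
        flush()
    return Proteome(species=species or path.stem, lineage=lineage, records=records)


def write_fasta(proteome: Proteome | Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``.

    Deterministic byte-for-byte for identical input, and round-trip safe:
    ``read_fasta(write_fasta(p))`` reproduces ids, descriptions and
    sequences exactly.
    """
    records = proteome.records if isinstance(proteome, Proteome) else list(proteome)
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_manifest(path: str | Path) -> list[tuple[Path, str, str]]:
    """Read a TSV manifest with columns ``path``, ``species``, ``lineage``.

    Relative FASTA paths are resolved against the manifest's directory.
    """
    path = Path(path)
    entries: list[tuple[Path, str, str]] = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                expected = ["path", "species", "lineage"]
                if [h.strip() for h in header[:3]] != expected:
                    raise ValueError(
                        f"manifest must start with columns {expected}, got {header[:3]}"
                    )
                continue
            fasta, species, lineage = (f.strip() for f in fields[:3])
            fasta_path = Path(fasta)
            if not fasta_path.is_absolute():
                fasta_path = path.parent / fasta_path
            entries.append((fasta_path, species, lineage))
    return entries
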