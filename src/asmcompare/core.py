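"""Shared data types, coordinate conventions, and threshold configuration.

Coordinates are 0-based half-open internally.  Every emitted report converts
to 1-based inclusive, which is the convention used in cytogenetic and
genome-browser position strings (e.g. ``chr15:15,926,700-16,243,800``).

Soft-masking (lowercase) and ``N`` both count as "masked": the gap/repeat
filter treats assembly gaps and annotated repeats alike.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = frozenset("ACGTNacgtn")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

CHROMOSOME = "chromosome"
UNASSIGNED = "unassigned-scaffold"


class AlphabetError(ValueError):
    """A sequence contains characters outside A/C/G/T/N (either case)."""


class CoordinateError(ValueError):
    """An interval does not fit inside its sequence."""


def reverse_complement(s: str) -> str:
    """Reverse-complement ``s``, preserving per-character case.

    Case is meaningful here: lowercase marks soft-masked (repetitive)
    sequence and must travel with the base when a segment is inverted.
    """
    bad = set(s) - NUCLEOTIDES
    if bad:
        raise AlphabetError(f"non-nucleotide characters: {sorted(bad)!r}")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Interval:
    """A located, stranded segment: 0-based half-open ``[start, end)``."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise CoordinateError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_report(self) -> tuple[str, int, int]:
        """Convert to 1-based inclusive (seq, start, end) for reports."""
        return (self.seq_id, self.start + 1, self.end)

    @classmethod
    def from_report(cls, seq_id: str, start1: int, end1: int, strand: str = "+") -> "Interval":
        """Build from 1-based inclusive report coordinates."""
        return cls(seq_id, start1 - 1, end1, strand)

    def overlap(self, other: "Interval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "Interval") -> float:
        """min(ov/len(self), ov/len(other)); 0 when on different sequences."""
        ov = self.overlap(other)
        if ov == 0:
            return 0.0
        return min(ov / len(self), ov / len(other))


class Assembly:
    """A named genome draft: sequences partitioned into chromosomes and
    unassigned scaffolds.

    Sequences are plain Python strings over ``{A,C,G,T,N,a,c,g,t,n}``;
    lowercase is soft-masked.  Insertion order of sequences is preserved.
    """

    def __init__(
        self,
        name: str,
        sequences: Mapping[str, str],
        roles: Mapping[str, str] | None = None,
    ) -> None:
        self.name = name
        self.sequences: dict[str, str] = dict(sequences)
        if roles is None:
            roles = {sid: CHROMOSOME for sid in self.sequences}
        self.roles: dict[str, str] = dict(roles)
        if set(self.roles) != set(self.sequences):
            raise ValueError("roles must cover exactly the sequence ids")
        for sid, seq in self.sequences.items():
            bad = set(seq) - NUCLEOTIDES
            if bad:
                raise AlphabetError(f"{sid}: non-nucleotide characters {sorted(bad)!r}")
        for sid, role in self.roles.items():
            if role not in (CHROMOSOME, UNASSIGNED):
                raise ValueError(f"{sid}: unknown role {role!r}")

    @property
    def chromosomes(self) -> list[str]:
        return [s for s in self.sequences if self.roles[s] == CHROMOSOME]

    @property
    def scaffolds(self) -> list[str]:
        return [s for s in self.sequences if self.roles[s] == UNASSIGNED]

    def length(self, seq_id: str) -> int:
        return len(self.sequences[seq_id])

    def fetch(self, iv: Interval) -> str:
        """Sequence of ``iv``; reverse-complemented when strand is '-'."""
        seq = self.sequences.get(iv.seq_id)
        if seq is None:
            raise CoordinateError(f"unknown sequence {iv.seq_id!r}")
        if iv.end > len(seq):
            raise CoordinateError(
                f"interval {iv.seq_id}:{iv.start}-{iv.end} exceeds length {len(seq)}"
            )
        sub = seq[iv.start : iv.end]
        return reverse_complement(sub) if iv.strand == "-" else sub

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Assembly({self.name!r}, {len(self.chromosomes)} chromosomes, "
            f"{len(self.scaffolds)} scaffolds)"
        )


def masked_fraction(iv: Interval, asm: Assembly) -> float:
    """Fraction of ``iv`` that is soft-masked (lowercase) or N.

    Operationalizes the "almost completely composed of gaps and/or repeats"
    exclusion: both assembly gaps (N) and repeats (lowercase) count.
    """
    sub = asm.fetch(replace_strand(iv, "+"))
    masked = sum(1 for c in sub if c.islower() or c in "Nn")
    return masked / len(sub)


def replace_strand(iv: Interval, strand: str) -> Interval:
    return Interval(iv.seq_id, iv.start, iv.end, strand)


@dataclass(frozen=True)
class Thresholds:
    """Every numeric constant of the comparison/validation protocol.

    Sizes are in bp.  An inconsistency is *reportable* when strictly larger
    than ``report_min`` and *test-eligible* when strictly larger than the
    category's test minimum (MDP/DCM/ODS: ``test_min_mdp_dcm``; inversions:
    ``test_min_inv``, since disentangling an inversion needs a triplet of
    non-overlapping BAC probes).  ``bes_span_*`` bound the plausible BAC
    insert size implied by a BAC-end-sequence pair.  ``fish_visibility_min``
    is the smallest contiguous homology a FISH probe can light up.
    ``masked_frac_max`` is the gap/repeat exclusion cutoff (strictly greater
    excludes).  ``pcr_amplicon_max`` bounds a long-range PCR product.
    """

    report_min: int = 100_000
    test_min_mdp_dcm: int = 200_000
    test_min_inv: int = 500_000
    bes_span_min: int = 50_000
    bes_span_max: int = 300_000
    fish_visibility_min: int = 5_000
    metaphase_cells: int = 10
    interphase_nuclei: int = 50
    masked_frac_max: float = 0.75
    pcr_amplicon_max: int = 12_000

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        if not self.bes_span_min < self.bes_span_max:
            raise ValueError("bes_span_min must be < bes_span_max")
        if not self.report_min <= self.test_min_mdp_dcm <= self.test_min_inv:
            raise ValueError("require report_min <= test_min_mdp_dcm <= test_min_inv")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "Thresholds":
        """Read a flat ``key = value`` config file; unknown keys rejected."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict[str, float | int] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown threshold {key!r}")
            kwargs[key] = float(val) if key == "masked_frac_max" else int(float(val))
        return cls(**kwargs)

    def with_overrides(self, **kwargs) -> "Thresholds":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


# --------------------------------------------------------------------------
# FASTA I/O (case-preserving)

def read_fasta(path: str | os.PathLike, name: str | None = None,
               scaffold_prefixes: tuple[str, ...] = ("scaffold", "ChrUn", "chrUn", "004.")) -> Assembly:
    """Read a soft-masked FASTA into an :class:`Assembly`.

    Records whose id starts with one of ``scaffold_prefixes`` are classed as
    unassigned scaffolds; everything else is a chromosome.
    """
    sequences: dict[str, str] = {}
    roles: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA record id {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq)
        roles[rec.id] = (
            UNASSIGNED if rec.id.startswith(scaffold_prefixes) else CHROMOSOME
        )
    if name is None:
        name = Path(path).stem
    return Assembly(name, sequences, roles)


def write_fasta(asm: Assembly, path: str | os.PathLike, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description=asm.roles[sid])
        for sid, seq in asm.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
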