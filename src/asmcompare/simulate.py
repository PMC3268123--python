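"""Synthetic genomes: one "true" genome and two assemblies derived from it.

The generator emulates the situation where two drafts were assembled from
the same raw data and disagree: each planted event perturbs exactly one of
the two derived assemblies, so the other assembly remains identical to the
true genome over the event footprint.  Event kinds cover the discrepancy
classes seen between alternate drafts of one genome:

* ``inversion`` — segment reversed in one draft.
* ``relocation`` — segment moved to a distinct position on the same
  chromosome (an MDP when the drafts are compared).
* ``unplace-to-scaffold`` — segment dropped from its chromosome in one
  draft and emitted as an unassigned scaffold (a ChrUn).
* ``cross-chromosome-move`` — segment placed on different chromosomes by
  the two drafts (a DCM when compared).
* ``duplication-insert`` — one draft reports a spurious second copy.
* ``duplication-collapse`` — the true genome carries k >= 2 near-identical
  copies but one draft collapses them into a single copy.
* ``deletion`` — segment missing from one draft altogether.

Background sequence is i.i.d. uniform over A/C/G/T, which makes long
anchors unique with overwhelming probability at the megabase scale used
here.  Repeat copies are planted lowercase (soft-masked); interspersed
family copies carry per-copy substitution noise so that "unique match"
filters have something to reject, while the shared pericentromeric /
subtelomeric low-copy segments are exact copies, the way recent segmental
duplications are near-identical in real genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CHROMOSOME,
    UNASSIGNED,
    Assembly,
    Interval,
    reverse_complement,
)

EVENT_KINDS = (
    "inversion",
    "relocation",
    "unplace-to-scaffold",
    "cross-chromosome-move",
    "duplication-insert",
    "duplication-collapse",
    "deletion",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ParameterError(ValueError):
    """Simulation parameters are infeasible."""


class SpecificationError(ValueError):
    """An event list violates the event invariants."""


@dataclass(frozen=True)
class EventSpec:
    """One planted discrepancy between the two derived assemblies."""

    kind: str
    target: Interval  # on the true genome
    applies_to: str  # "A" or "B": the assembly that carries the event
    destination: Interval | str | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise SpecificationError(f"unknown event kind {self.kind!r}")
        if self.applies_to not in ("A", "B"):
            raise SpecificationError("applies_to must be 'A' or 'B'")
        needs_dest = {
            "relocation": Interval,
            "cross-chromosome-move": Interval,
            "duplication-insert": Interval,
            "unplace-to-scaffold": str,
        }
        want = needs_dest.get(self.kind)
        if want is not None and not isinstance(self.destination, want):
            raise SpecificationError(
                f"{self.kind} requires a destination of type {want.__name__}"
            )

    @property
    def correct_assembly(self) -> str:
        """The derived assembly that agrees with the true genome here."""
        return "B" if self.applies_to == "A" else "A"


@dataclass
class TruthRow:
    """Realized coordinates of one event in both derived assemblies."""

    event: EventSpec
    a_locus: Interval | None
    b_locus: Interval | None
    scaffold_id: str | None = None
    extra: dict = field(default_factory=dict)

    @property
    def correct_assembly(self) -> str:
        return self.event.correct_assembly


class TruthTable(list):
    """List of :class:`TruthRow` with a tabular export."""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self:
            ev = r.event

            def fmt(iv: Interval | None) -> tuple[str, int, int]:
                if iv is None:
                    return ("-", 0, 0)
                sid, s1, e1 = iv.to_report()
                return (sid, s1, e1)

            ta = fmt(r.a_locus)
            tb = fmt(r.b_locus)
            rows.append(
                (
                    ev.kind,
                    ev.applies_to,
                    ev.correct_assembly,
                    *ev.target.to_report(),
                    *ta,
                    *tb,
                    r.scaffold_id or "-",
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "kind", "assembly", "correct",
                "true_seq", "true_start", "true_end",
                "a_seq", "a_start", "a_end",
                "b_seq", "b_start", "b_end",
                "scaffold",
            ],
        )


# --------------------------------------------------------------------------
# True genome

def _plant_copy(arr: np.ndarray, pos: int, copy: np.ndarray) -> None:
    arr[pos : pos + copy.size] = copy | 0x20  # lowercase = soft-masked


def generate_true_genome(
    n_chrom: int,
    chrom_lengths: Sequence[int],
    repeat_family_count: int = 2,
    repeat_copies: int = 40,
    seed: int = 0,
    repeat_len_range: tuple[int, int] = (2_000, 6_000),
    repeat_noise: float = 0.01,
    segdup_families: int = 1,
    segdup_copies: int = 6,
    segdup_len: int = 30_000,
) -> Assembly:
    """Generate a soft-masked "true" genome.

    ``repeat_family_count`` interspersed families are planted with
    ``repeat_copies`` total copies, each carrying ``repeat_noise`` per-base
    substitution noise.  ``segdup_families`` low-copy segments are planted
    as *exact* lowercase copies near chromosome ends (pericentromeric /
    subtelomeric in an acrocentric karyotype), which is what makes
    multi-signal FISH patterns reproducible.  At least 60% of every
    chromosome stays unique uppercase sequence.
    """
    if len(chrom_lengths) != n_chrom:
        raise ParameterError("chrom_lengths must have n_chrom entries")
    if any(l < 200_000 for l in chrom_lengths):
        raise ParameterError("chromosome lengths must be >= 200 kbp")
    rng = np.random.default_rng(seed)
    chroms = {
        f"chr{i + 1}": _BASES[rng.integers(0, 4, size=int(length))]
        for i, length in enumerate(chrom_lengths)
    }
    names = list(chroms)
    planted: dict[str, list[tuple[int, int]]] = {n: [] for n in names}

    def reserve(name: str, pos: int, length: int) -> bool:
        for s, e in planted[name]:
            if pos < e + 1_000 and s < pos + length + 1_000:
                return False
        planted[name].append((pos, pos + length))
        return True

    # budget check: keep >= 60% of each chromosome unique
    total_rep = 0
    if repeat_family_count > 0 and repeat_copies > 0:
        total_rep += repeat_copies * repeat_len_range[1]
    total_rep += segdup_families * segdup_copies * segdup_len
    if total_rep > 0.4 * sum(chrom_lengths):
        raise ParameterError("repeat content would exceed 40% of the genome")

    # interspersed repeat families with per-copy substitution noise
    if repeat_family_count > 0 and repeat_copies > 0:
        masters = [
            _BASES[rng.integers(0, 4, size=int(rng.integers(*repeat_len_range)))]
            for _ in range(repeat_family_count)
        ]
        weights = np.array([len(chroms[n]) for n in names], dtype=float)
        weights /= weights.sum()
        for i in range(repeat_copies):
            master = masters[i % repeat_family_count]
            for _attempt in range(200):
                name = names[rng.choice(len(names), p=weights)]
                pos = int(rng.integers(50_000, len(chroms[name]) - master.size - 50_000))
                if reserve(name, pos, master.size):
                    break
            else:  # pragma: no cover - only hit with absurd densities
                raise ParameterError("could not place repeat copy without overlap")
            copy = master.copy()
            n_sub = rng.binomial(master.size, repeat_noise)
            if n_sub:
                sites = rng.choice(master.size, size=n_sub, replace=False)
                copy[sites] = _BASES[(np.searchsorted(_BASES, copy[sites]) + rng.integers(1, 4, n_sub)) % 4]
            _plant_copy(chroms[name], pos, copy)

    # shared low-copy segments at chromosome extremities (exact copies)
    for fam in range(segdup_families):
        master = _BASES[rng.integers(0, 4, size=segdup_len)]
        for c in range(segdup_copies):
            for _attempt in range(200):
                name = names[int(rng.integers(0, len(names)))]
                length = len(chroms[name])
                near_start = bool(rng.integers(0, 2))
                if near_start:
                    pos = int(rng.integers(10_000, 40_000))
                else:
                    pos = int(rng.integers(length - 40_000 - segdup_len, length - 10_000 - segdup_len))
                if reserve(name, pos, segdup_len):
                    break
            else:  # pragma: no cover
                raise ParameterError("could not place low-copy segment")
            _plant_copy(chroms[name], pos, master)

    sequences = {n: arr.tobytes().decode("ascii") for n, arr in chroms.items()}
    for n, seq in sequences.items():
        upper = sum(1 for c in seq if c.isupper())
        if upper < 0.6 * len(seq):  # pragma: no cover - guarded by budget check
            raise ParameterError(f"{n}: unique fraction below 60%")
    return Assembly("true", sequences)


# --------------------------------------------------------------------------
# Deriving the two assemblies

@dataclass
class _Piece:
    """A contiguous stretch of a derived chromosome, with provenance."""

    src_seq: str | None  # source chromosome on the true genome
    src_start: int
    src_end: int
    orient: str  # '+' or '-'
    content: str
    event_idx: int | None = None  # event that created/modified this piece


def _find_exact_copies(true: Assembly, segment: str) -> list[Interval]:
    """All exact (case-insensitive) occurrences of ``segment`` in the genome."""
    needle = segment.upper()
    out = []
    for sid, seq in true.sequences.items():
        if true.roles[sid] != CHROMOSOME:
            continue
        hay = seq.upper()
        start = 0
        while True:
            p = hay.find(needle, start)
            if p < 0:
                break
            out.append(Interval(sid, p, p + len(needle)))
            start = p + 1
    return out


def _validate_events(events: Sequence[EventSpec], true: Assembly) -> None:
    for side in ("A", "B"):
        ivs: list[Interval] = []
        for ev in events:
            if ev.applies_to != side:
                continue
            t = ev.target
            if t.seq_id not in true.sequences:
                raise SpecificationError(f"target on unknown sequence {t.seq_id!r}")
            if t.end > true.length(t.seq_id):
                raise SpecificationError(f"target {t} exceeds chromosome length")
            for other in ivs:
                if t.overlap(other) > 0:
                    raise SpecificationError(
                        f"overlapping events on assembly {side}: {t} vs {other}"
                    )
            ivs.append(t)
        # destinations must not fall inside a modified region of the same side
        for ev in events:
            if ev.applies_to != side or not isinstance(ev.destination, Interval):
                continue
            d = ev.destination
            if d.seq_id not in true.sequences:
                raise SpecificationError(f"destination on unknown sequence {d.seq_id!r}")
            for t in ivs:
                if t.seq_id == d.seq_id and t.start < d.start < t.end:
                    raise SpecificationError(
                        f"destination {d} falls inside modified region {t}"
                    )


def _apply_side(
    true: Assembly,
    events: Sequence[tuple[int, EventSpec]],
    side: str,
) -> tuple[dict[str, str], dict[str, str], dict[str, list[_Piece]], dict[int, list[Interval]]]:
    """Apply this side's events; return (chromosomes, scaffolds, piece tables,
    collapse-copy loci per event index)."""
    excise: dict[str, list[tuple[int, int, int | None]]] = {c: [] for c in true.chromosomes}
    invert: dict[str, list[tuple[int, int, int]]] = {c: [] for c in true.chromosomes}
    insert: dict[str, list[tuple[int, str, str, int, int, int]]] = {c: [] for c in true.chromosomes}
    scaffolds: dict[str, str] = {}
    collapse_copies: dict[int, list[Interval]] = {}

    for idx, ev in events:
        t = ev.target
        if ev.kind == "inversion":
            invert[t.seq_id].append((t.start, t.end, idx))
        elif ev.kind in ("relocation", "cross-chromosome-move"):
            excise[t.seq_id].append((t.start, t.end, None))
            d = ev.destination
            insert[d.seq_id].append((d.start, t.seq_id, "+", t.start, t.end, idx))
        elif ev.kind == "unplace-to-scaffold":
            excise[t.seq_id].append((t.start, t.end, None))
            scaffolds[str(ev.destination)] = true.fetch(t)
        elif ev.kind == "duplication-insert":
            d = ev.destination
            insert[d.seq_id].append((d.start, t.seq_id, "+", t.start, t.end, idx))
        elif ev.kind == "deletion":
            excise[t.seq_id].append((t.start, t.end, None))
        elif ev.kind == "duplication-collapse":
            copies = _find_exact_copies(true, true.fetch(t))
            if len(copies) < 2:
                raise SpecificationError(
                    f"duplication-collapse target {t} has no additional copies"
                )
            collapse_copies[idx] = copies
            kept = Interval(t.seq_id, t.start, t.end)
            for cp in copies:
                if (cp.seq_id, cp.start, cp.end) != (kept.seq_id, kept.start, kept.end):
                    excise[cp.seq_id].append((cp.start, cp.end, None))

    pieces_by_chrom: dict[str, list[_Piece]] = {}
    new_seqs: dict[str, str] = {}
    for chrom in true.chromosomes:
        seq = true.sequences[chrom]
        # breakpoints: excisions and inversions partition the chromosome
        marks: list[tuple[int, int, str, int | None]] = []  # (start, end, op, event)
        for s, e, _idx in excise[chrom]:
            marks.append((s, e, "excise", None))
        for s, e, idx in invert[chrom]:
            marks.append((s, e, "invert", idx))
        marks.sort()
        pieces: list[_Piece] = []
        pos = 0
        for s, e, op, idx in marks:
            if s > pos:
                pieces.append(_Piece(chrom, pos, s, "+", seq[pos:s]))
            if op == "invert":
                pieces.append(_Piece(chrom, s, e, "-", reverse_complement(seq[s:e]), idx))
            pos = e
        if pos < len(seq):
            pieces.append(_Piece(chrom, pos, len(seq), "+", seq[pos:]))
        # splice insertions at their truth-coordinate positions
        for d_pos, src_chrom, orient, s, e, idx in sorted(insert[chrom], key=lambda x: x[0]):
            content = true.sequences[src_chrom][s:e]
            ins = _Piece(src_chrom, s, e, orient, content, idx)
            placed = False
            for pi, piece in enumerate(pieces):
                if piece.src_seq == chrom and piece.orient == "+" and piece.event_idx is None \
                        and piece.src_start <= d_pos <= piece.src_end:
                    if d_pos == piece.src_start:
                        pieces.insert(pi, ins)
                    elif d_pos == piece.src_end:
                        pieces.insert(pi + 1, ins)
                    else:
                        off = d_pos - piece.src_start
                        left = _Piece(chrom, piece.src_start, d_pos, "+", piece.content[:off])
                        right = _Piece(chrom, d_pos, piece.src_end, "+", piece.content[off:])
                        pieces[pi : pi + 1] = [left, ins, right]
                    placed = True
                    break
            if not placed:
                raise SpecificationError(
                    f"insertion point {chrom}:{d_pos} lies in a removed region"
                )
        pieces_by_chrom[chrom] = pieces
        new_seqs[chrom] = "".join(p.content for p in pieces)
    return new_seqs, scaffolds, pieces_by_chrom, collapse_copies


def _piece_offsets(pieces: list[_Piece]) -> list[int]:
    offs = [0]
    for p in pieces:
        offs.append(offs[-1] + len(p.content))
    return offs


def _locate_event_piece(
    pieces_by_chrom: dict[str, list[_Piece]], idx: int
) -> Interval | None:
    for chrom, pieces in pieces_by_chrom.items():
        offs = _piece_offsets(pieces)
        for pi, p in enumerate(pieces):
            if p.event_idx == idx:
                return Interval(chrom, offs[pi], offs[pi + 1])
    return None


def _map_truth_interval(
    pieces_by_chrom: dict[str, list[_Piece]], iv: Interval
) -> Interval | None:
    """Map a truth-genome interval into derived coordinates (None if the
    region was removed or split on this side)."""
    pieces = pieces_by_chrom.get(iv.seq_id)
    if pieces is None:
        return None
    offs = _piece_offsets(pieces)
    for pi, p in enumerate(pieces):
        if p.src_seq == iv.seq_id and p.orient == "+" and p.event_idx is None \
                and p.src_start <= iv.start and iv.end <= p.src_end:
            delta = offs[pi] - p.src_start
            return Interval(iv.seq_id, iv.start + delta, iv.end + delta)
    return None


def derive_assemblies(
    true: Assembly,
    events: Sequence[EventSpec],
    seed: int = 0,
) -> tuple[Assembly, Assembly, TruthTable]:
    """Apply the planted events, returning assemblies A and B plus the truth
    table of realized per-assembly coordinates.

    The assembly *not* named by an event's ``applies_to`` is byte-identical
    to the true genome across the event footprint.
    """
    _validate_events(events, true)
    indexed = list(enumerate(events))
    built = {}
    for side in ("A", "B"):
        side_events = [(i, e) for i, e in indexed if e.applies_to == side]
        built[side] = _apply_side(true, side_events, side)

    truth = TruthTable()
    for idx, ev in indexed:
        side = ev.applies_to
        other = ev.correct_assembly
        seqs_s, scaf_s, pieces_s, collapse_s = built[side]
        _, _, pieces_o, _ = built[other]
        loc_side: Interval | None
        scaffold_id = None
        extra: dict = {}
        if ev.kind == "inversion":
            loc_side = _locate_event_piece(pieces_s, idx)
        elif ev.kind in ("relocation", "cross-chromosome-move", "duplication-insert"):
            loc_side = _locate_event_piece(pieces_s, idx)
        elif ev.kind == "unplace-to-scaffold":
            scaffold_id = str(ev.destination)
            loc_side = Interval(scaffold_id, 0, len(ev.target))
        elif ev.kind == "deletion":
            loc_side = None
        elif ev.kind == "duplication-collapse":
            loc_side = _map_truth_interval(pieces_s, ev.target)
            copies = built[side][3][idx]
            extra["true_copies"] = copies
            extra["other_copies"] = [
                m for m in (_map_truth_interval(pieces_o, cp) for cp in copies) if m
            ]
        loc_other = _map_truth_interval(pieces_o, ev.target)
        if ev.kind == "duplication-insert":
            extra["source_in_carrier"] = _map_truth_interval(pieces_s, ev.target)
        a_locus = loc_side if side == "A" else loc_other
        b_locus = loc_side if side == "B" else loc_other
        truth.append(TruthRow(ev, a_locus, b_locus, scaffold_id, extra))

    assemblies = {}
    for side in ("A", "B"):
        seqs, scaffolds, _, _ = built[side]
        all_seqs = dict(seqs)
        roles = {c: CHROMOSOME for c in seqs}
        for sid, content in scaffolds.items():
            all_seqs[sid] = content
            roles[sid] = UNASSIGNED
        assemblies[side] = Assembly(side, all_seqs, roles)
    return assemblies["A"], assemblies["B"], truth


# --------------------------------------------------------------------------
# BAC end-sequence library

@dataclass(frozen=True)
class BESClone:
    clone_id: str
    end1: str  # forward strand at the left extremity of the insert
    end2: str  # reverse strand at the right extremity, facing inward
    insert: Interval  # on the true genome


@dataclass
class BESLibrary:
    clones: list[BESClone]

    def __iter__(self):
        return iter(self.clones)

    def __len__(self):
        return len(self.clones)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c.clone_id, *c.insert.to_report(), len(c.insert), c.end1, c.end2)
            for c in self.clones
        ]
        return pd.DataFrame(
            rows,
            columns=["clone_id", "true_seq", "true_start", "true_end", "insert_len", "end1", "end2"],
        )


def generate_bes_library(
    true: Assembly,
    n_clones: int = 600,
    insert_range: tuple[int, int] = (60_000, 250_000),
    end_len: int = 500,
    seed: int = 0,
) -> BESLibrary:
    """Simulate a BAC end-sequence library from the true genome.

    Each clone is a uniform-random insert whose two end sequences face
    inward on opposite strands: end1 reads the forward strand at the left
    extremity, end2 the reverse strand at the right extremity.
    """
    if end_len < 100:
        raise ParameterError("end_len must be >= 100 bp")
    lo, hi = insert_range
    if not (0 < lo <= hi):
        raise ParameterError("invalid insert_range")
    chroms = [c for c in true.chromosomes if true.length(c) > hi + 2]
    if not chroms:
        raise ParameterError("insert_range exceeds every chromosome length")
    rng = np.random.default_rng(seed)
    weights = np.array([true.length(c) for c in chroms], dtype=float)
    weights /= weights.sum()
    clones = []
    width = len(str(n_clones))
    for i in range(n_clones):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        ins_len = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, true.length(chrom) - ins_len))
        iv = Interval(chrom, start, start + ins_len)
        seq = true.sequences[chrom]
        end1 = seq[start : start + end_len]
        end2 = reverse_complement(seq[start + ins_len - end_len : start + ins_len])
        clones.append(BESClone(f"BAC{i + 1:0{width}d}", end1, end2, iv))
    return BESLibrary(clones)


# --------------------------------------------------------------------------
# Standard event suite

def standard_event_suite(
    true: Assembly,
    seed: int = 0,
    margin: int | None = None,
) -> list[EventSpec]:
    """A 12-event mix spanning every event kind, sized above the reporting
    and testing thresholds, planted in unique (uppercase) sequence.

    Relocation displacements exceed twice the segment length so that the
    off-position block is unambiguous, and every footprint keeps ``margin``
    bp clear of other events and chromosome ends.  Event sizes are stated
    for 2-Mbp chromosomes (the standard study scale) and shrink
    proportionally on smaller genomes.
    """
    rng = np.random.default_rng(seed)
    chroms = list(true.chromosomes)
    scale = min(1.0, min(true.length(c) for c in chroms) / 2_000_000)
    if margin is None:
        margin = max(20_000, int(120_000 * scale))
    reserved: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def is_unique(chrom: str, start: int, end: int) -> bool:
        """Breakpoints in unmasked sequence; footprint mostly unique."""
        seq = true.sequences[chrom]
        if not (seq[max(0, start - 200) : start + 200].isupper()
                and seq[end - 200 : end + 200].isupper()):
            return False
        seg = seq[start:end]
        masked = sum(1 for c in seg if c.islower())
        return masked <= 0.3 * len(seg)

    def reserve(chrom: str, start: int, end: int) -> bool:
        for s, e in reserved[chrom]:
            if start < e + margin and s < end + margin:
                return False
        reserved[chrom].append((start, end))
        return True

    def sample_interval(length: int, unique: bool = True,
                        chrom_pool: list[str] | None = None) -> Interval:
        pool = chrom_pool or chroms
        for _attempt in range(500):
            chrom = pool[int(rng.integers(0, len(pool)))]
            n = true.length(chrom)
            if n < length + 2 * margin:
                continue
            start = int(rng.integers(margin, n - length - margin))
            if unique and not is_unique(chrom, start, start + length):
                continue
            if not reserve(chrom, start, start + length):
                continue
            return Interval(chrom, start, start + length)
        raise ParameterError("could not place event in unique sequence")

    def sample_point(exclude_chrom: str | None = None, same_chrom: str | None = None,
                     min_dist_from: Interval | None = None) -> Interval:
        for _attempt in range(500):
            if same_chrom is not None:
                chrom = same_chrom
            else:
                pool = [c for c in chroms if c != exclude_chrom]
                chrom = pool[int(rng.integers(0, len(pool)))]
            n = true.length(chrom)
            pos = int(rng.integers(margin, n - margin))
            if not is_unique(chrom, max(0, pos - 100), pos + 100):
                continue
            if min_dist_from is not None and chrom == min_dist_from.seq_id:
                if abs(pos - min_dist_from.start) < 2 * len(min_dist_from) \
                        or abs(pos - min_dist_from.end) < 2 * len(min_dist_from):
                    continue
            if not reserve(chrom, pos, pos + 1):
                continue
            return Interval(chrom, pos, pos + 1)
        raise ParameterError("could not place destination point")

    def size(lo: int, hi: int) -> int:
        lo = max(10_000, int(lo * scale))
        hi = max(lo, int(hi * scale))
        return int(rng.integers(lo, hi + 1))

    def unreserve(iv: Interval) -> None:
        reserved[iv.seq_id].remove((iv.start, iv.end))

    def sample_with_destination(lo: int, hi: int, same_chrom: bool) -> tuple[Interval, Interval]:
        """A target plus a destination point; the target is resampled when
        no destination can be placed around it (e.g. a relocation target so
        central that no position on its chromosome is far enough away)."""
        for _try in range(30):
            t = sample_interval(size(lo, hi))
            try:
                if same_chrom:
                    d = sample_point(same_chrom=t.seq_id, min_dist_from=t)
                else:
                    d = sample_point(exclude_chrom=t.seq_id)
            except ParameterError:
                unreserve(t)
                continue
            return t, d
        raise ParameterError("could not place event target with destination")

    events: list[EventSpec] = []
    # inversions, one per assembly, above the 500 kbp triplet-test floor
    for side in ("A", "B"):
        events.append(EventSpec("inversion", sample_interval(size(550_000, 900_000)), side))
    # relocations (MDPs), above the 200 kbp test floor, displaced > 2x length
    for side in ("A", "B"):
        t, d = sample_with_destination(210_000, 300_000, same_chrom=True)
        events.append(EventSpec("relocation", t, side, d))
    # unassigned scaffolds (ChrUn-style), demoted from assembly A
    for i in (1, 2):
        t = sample_interval(size(500_000, 900_000))
        events.append(EventSpec("unplace-to-scaffold", t, "A", f"004.{i}"))
    # cross-chromosome moves (DCMs), one per assembly
    for side in ("A", "B"):
        t, d = sample_with_destination(300_000, 450_000, same_chrom=False)
        events.append(EventSpec("cross-chromosome-move", t, side, d))
    # a spurious duplicate copy in A (one-sided DCM pattern)
    t, d = sample_with_destination(210_000, 300_000, same_chrom=False)
    events.append(EventSpec("duplication-insert", t, "A", d))
    # deletions, one per assembly
    for side in ("A", "B"):
        events.append(EventSpec("deletion", sample_interval(size(120_000, 200_000)), side))
    # collapse of the shared low-copy segment family in B, if present
    seg = _first_segdup_copy(true)
    if seg is not None:
        events.append(EventSpec("duplication-collapse", seg, "B"))
    return events


def _first_segdup_copy(true: Assembly) -> Interval | None:
    """Locate one copy of a multi-copy exact lowercase segment, if any."""
    for chrom in true.chromosomes:
        seq = true.sequences[chrom]
        i = 0
        n = len(seq)
        while i < n:
            if seq[i].islower():
                j = i
                while j < n and seq[j].islower():
                    j += 1
                if j - i >= 10_000:
                    iv = Interval(chrom, i, j)
                    if len(_find_exact_copies(true, true.fetch(iv))) >= 2:
                        return iv
                i = j
            else:
                i += 1
    return None
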