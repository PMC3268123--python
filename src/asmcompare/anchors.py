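"""Exact-match anchor discovery and colinear chaining between two genomes.

The comparison engine finds all *maximal exact matches* of at least
``min_anchor`` bp between two sequences, on both strands, and chains
colinear anchors into synteny blocks.  This is the same information a
dot-plot viewer draws as match lines: inversions appear as anti-diagonal
blocks, relocations as off-diagonal blocks, and one-draft-only sequence as
uncovered stretches.

Anchor discovery is a k-mer seed index (k = ``min_anchor``) with maximal
bidirectional extension, vectorized with a rolling polynomial hash over
numpy arrays.  Soft-masking policy: seeds may not *start* in sequence that
is masked in both genomes, but extension runs straight through masked
stretches.  An anchor is therefore kept iff its start is unmasked on at
least one genome — repeats never seed repeat-vs-repeat noise, yet a unique
match interrupted by a repeat is still recovered in one piece.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .core import Assembly, Interval

SAME = "same"
INVERTED = "inverted"

_HASH_BASE = np.uint64(0x100000001B3)  # FNV prime; odd, so invertible mod 2**64
_HASH_BASE_INV = np.uint64(pow(0x100000001B3, -1, 2**64))

_COMP_LUT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_LUT[_a] = _b


def _encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (uppercase byte array, masked-position boolean array)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    upper = raw & np.uint8(0xDF)  # clear the lowercase bit
    mask = (raw >= 97) | (upper == ord("N"))
    return upper, mask


def _window_hashes(upper: np.ndarray, k: int) -> np.ndarray:
    """Polynomial hash of every k-length window, mod 2**64 (wrapping)."""
    n = upper.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    m = n - k + 1
    with np.errstate(over="ignore"):
        pw = np.ones(n, dtype=np.uint64)
        pw[1:] = _HASH_BASE
        np.cumprod(pw, out=pw)  # pw[j] = BASE**j
        pwinv = np.ones(m, dtype=np.uint64)
        pwinv[1:] = _HASH_BASE_INV
        np.cumprod(pwinv, out=pwinv)  # pwinv[i] = BASE**-i
        terms = upper.astype(np.uint64) * pw
        prefix = np.zeros(n + 1, dtype=np.uint64)
        np.cumsum(terms, out=prefix[1:])
        return (prefix[k:] - prefix[:m]) * pwinv


class SeqHash:
    """Per-sequence encoded arrays plus lazily-built k-mer hash indexes."""

    def __init__(self, seq_id: str, seq: str) -> None:
        if not seq:
            raise ValueError(f"empty sequence {seq_id!r}")
        self.seq_id = seq_id
        self.n = len(seq)
        self.upper, self.mask = _encode(seq)
        self._hashes: dict[tuple[int, bool], np.ndarray] = {}
        self._sorted: dict[tuple[int, bool], tuple[np.ndarray, np.ndarray]] = {}

    @cached_property
    def rc_upper(self) -> np.ndarray:
        return _COMP_LUT[self.upper][::-1].copy()

    @cached_property
    def rc_mask(self) -> np.ndarray:
        return self.mask[::-1].copy()

    def hashes(self, k: int, rc: bool = False) -> np.ndarray:
        key = (k, rc)
        if key not in self._hashes:
            arr = self.rc_upper if rc else self.upper
            self._hashes[key] = _window_hashes(arr, k)
        return self._hashes[key]

    def sorted_index(self, k: int, rc: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """(sorted window hashes, original window positions)."""
        key = (k, rc)
        if key not in self._sorted:
            h = self.hashes(k, rc)
            order = np.argsort(h, kind="stable")
            self._sorted[key] = (h[order], order)
            self._hashes.pop(key, None)  # the raw array is no longer needed
        return self._sorted[key]

    def sorted_query(
        self, k: int, rc: bool = False, unmasked_only: bool = False, stride: int = 1
    ) -> tuple[np.ndarray, np.ndarray]:
        """Window hashes in sorted order with their positions, optionally
        restricted to windows starting at unmasked bases.  Sorted queries
        keep the binary search in :func:`_seed_pairs` cache-friendly.

        ``stride`` > 1 keeps only every stride-th window position: any
        match of at least ``k + stride - 1`` bp still contains a seed and
        is recovered in full by maximal extension, so strided seeding is a
        cheap exact search when only multi-kb matches matter."""
        h_sorted, order = self.sorted_index(k, rc)
        keep = None
        if unmasked_only:
            mask = self.rc_mask if rc else self.mask
            keep = ~mask[order]
        if stride > 1:
            sel = (order % stride) == 0
            keep = sel if keep is None else (keep & sel)
        if keep is None:
            return h_sorted, order
        return h_sorted[keep], order[keep]

    def sorted_query_rc_as_fwd(
        self, k: int, unmasked_only: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """The reverse-strand window hashes, reported at their *forward*
        window start positions.  Reuses the already-sorted reverse index:
        the reverse-complement window starting at reverse coordinate ``j``
        covers forward coordinates ``[n-k-j, n-j)``."""
        h_sorted, order = self.sorted_index(k, rc=True)
        fwd_pos = self.n - k - order
        if not unmasked_only:
            return h_sorted, fwd_pos
        keep = ~self.mask[fwd_pos]
        return h_sorted[keep], fwd_pos[keep]


@dataclass(frozen=True)
class MatchSegment:
    """A maximal exact match between two genomes.

    ``b.strand`` is '-' when the match is to the reverse strand of B;
    ``orientation`` mirrors that as 'same'/'inverted'.
    """

    a: Interval
    b: Interval
    orientation: str

    @property
    def length(self) -> int:
        return len(self.a)

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("anchor intervals must have equal length")
        if self.orientation not in (SAME, INVERTED):
            raise ValueError(f"bad orientation {self.orientation!r}")


def _match_sorted(
    qh: np.ndarray,
    qpos: np.ndarray,
    target: SeqHash,
    k: int,
    t_rc: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """(query position, target position) pairs with equal k-mer hash, given
    sorted query hashes.  One binary search; multiplicities are expanded
    incrementally (repeat hits beyond the first are rare)."""
    if qpos.size == 0:
        return (np.empty(0, np.int64),) * 2
    sorted_h, positions = target.sorted_index(k, t_rc)
    m = sorted_h.size
    if m == 0:
        return (np.empty(0, np.int64),) * 2
    idx = np.searchsorted(sorted_h, qh, side="left")
    cur_q, cur_h = qpos, qh
    out_q: list[np.ndarray] = []
    out_t: list[np.ndarray] = []
    while idx.size:
        valid = idx < m
        if not valid.all():
            idx, cur_q, cur_h = idx[valid], cur_q[valid], cur_h[valid]
        if idx.size == 0:
            break
        eq = sorted_h[idx] == cur_h
        idx, cur_q, cur_h = idx[eq], cur_q[eq], cur_h[eq]
        if idx.size == 0:
            break
        out_q.append(cur_q)
        out_t.append(positions[idx])
        idx = idx + 1
    if not out_q:
        return (np.empty(0, np.int64),) * 2
    return (
        np.concatenate(out_q).astype(np.int64, copy=False),
        np.concatenate(out_t).astype(np.int64, copy=False),
    )


def _seed_pairs(
    query: SeqHash,
    target: SeqHash,
    k: int,
    q_rc: bool = False,
    t_rc: bool = False,
    q_unmasked_only: bool = True,
    q_stride: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """All (query position, target position) pairs with equal k-mer hash."""
    qh, qpos = query.sorted_query(k, q_rc, q_unmasked_only, q_stride)
    return _match_sorted(qh, qpos, target, k, t_rc)


def _extend_equal(x: np.ndarray, y: np.ndarray) -> int:
    """Length of the common prefix of two equal-length byte arrays."""
    n = x.size
    step, t = 8192, 0
    while t < n:
        c = min(step, n - t)
        neq = np.flatnonzero(x[t : t + c] != y[t : t + c])
        if neq.size:
            return t + int(neq[0])
        t += c
    return n


def _runs_to_anchors(
    qi: np.ndarray,
    tj: np.ndarray,
    qa: SeqHash,
    tb_upper: np.ndarray,
    k: int,
) -> set[tuple[int, int, int]]:
    """Group seed pairs into diagonal runs and extend each maximally.

    Coordinates are in the (query, oriented-target) frame; inverted matches
    are handled by the caller passing the reverse-complemented target array.
    Returns a set of (q_start, t_start, length) maximal matches.
    """
    if qi.size == 0:
        return set()
    # duplicate pairs from the two seeding passes are harmless: they land
    # adjacent after the lexsort and stay within one diagonal run
    diag = qi - tj
    order = np.lexsort((qi, diag))
    qi, tj, diag = qi[order], tj[order], diag[order]
    # split runs where the diagonal changes or the seed spacing exceeds k
    # (windows <= k apart on one diagonal cover a contiguous exact match)
    breaks = np.flatnonzero((np.diff(diag) != 0) | (np.diff(qi) > k))
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [qi.size - 1]))

    ua, ub = qa.upper, tb_upper
    anchors: set[tuple[int, int, int]] = set()
    for s, e in zip(starts, ends):
        a0, b0 = int(qi[s]), int(tj[s])
        a1 = int(qi[e]) + k
        length = a1 - a0
        if not np.array_equal(ua[a0:a1], ub[b0 : b0 + length]):
            continue  # hash collision; discard spurious seed run
        # extend left
        lmax = min(a0, b0)
        lext = _extend_equal(ua[a0 - lmax : a0][::-1], ub[b0 - lmax : b0][::-1])
        # extend right
        rmax = min(ua.size - a1, ub.size - (b0 + length))
        rext = _extend_equal(ua[a1 : a1 + rmax], ub[b0 + length : b0 + length + rmax])
        anchors.add((a0 - lext, b0 - lext, length + lext + rext))
    return anchors


def anchors_between(
    qa: SeqHash,
    tb: SeqHash,
    min_anchor: int = 50,
    respect_mask: bool = True,
    orientations: tuple[str, ...] = (SAME, INVERTED),
    q_stride: int = 1,
) -> list[MatchSegment]:
    """All maximal exact matches >= ``min_anchor`` bp between two sequences.

    With ``respect_mask`` (the default), an anchor is kept iff its start is
    unmasked on at least one genome; seeding is arranged so that every such
    anchor is discovered.  With ``respect_mask=False`` all anchors are kept
    (used when probing repeats on purpose, e.g. FISH signal prediction).
    ``q_stride`` > 1 trades exhaustiveness for speed: only matches of at
    least ``min_anchor + q_stride - 1`` bp are guaranteed to be found.
    """
    if min_anchor < 20:
        raise ValueError("min_anchor must be >= 20")
    if q_stride > 1 and respect_mask:
        raise ValueError("strided seeding is only supported mask-blind")
    k = min_anchor
    out: list[MatchSegment] = []
    need_pass2 = respect_mask and bool(qa.mask.any())

    # ---- forward orientation, (A, B) frame
    fwd: set[tuple[int, int, int]] = set()
    if SAME in orientations:
        qi, tj = _seed_pairs(qa, tb, k, q_unmasked_only=respect_mask, q_stride=q_stride)
        if need_pass2:
            # second pass, only for anchors whose A start is masked but whose
            # B start is unmasked: seed from unmasked B against the A index
            bi, aj = _seed_pairs(tb, qa, k, q_unmasked_only=True)
            keep = qa.mask[aj]
            qi = np.concatenate([qi, aj[keep]])
            tj = np.concatenate([tj, bi[keep]])
        fwd = _runs_to_anchors(qi, tj, qa, tb.upper, k)

    # ---- inverted orientation, (A, revcomp(B)) frame
    inv: set[tuple[int, int, int]] = set()
    if INVERTED in orientations:
        qi, tj = _seed_pairs(qa, tb, k, t_rc=True, q_unmasked_only=respect_mask,
                             q_stride=q_stride)
        if need_pass2:
            # second pass: unmasked forward-B positions, matched through B's
            # reverse-strand hashes against the forward A index, so an
            # inverted anchor with unmasked B start is found even when its A
            # footprint is fully masked; transform to the (A, revcomp(B)) frame
            bh, bpos = tb.sorted_query_rc_as_fwd(k, unmasked_only=True)
            bj, ai = _match_sorted(bh, bpos, qa, k)  # (B fwd pos, A pos)
            keep = qa.mask[ai] if ai.size else np.empty(0, bool)
            qi = np.concatenate([qi, ai[keep]])
            tj = np.concatenate([tj, tb.n - bj[keep] - k])
        inv = _runs_to_anchors(qi, tj, qa, tb.rc_upper, k)

    nb = tb.n
    for a0, b0, length in fwd:
        if length < min_anchor:
            continue
        if respect_mask and qa.mask[a0] and tb.mask[b0]:
            continue
        out.append(
            MatchSegment(
                Interval(qa.seq_id, a0, a0 + length, "+"),
                Interval(tb.seq_id, b0, b0 + length, "+"),
                SAME,
            )
        )
    for a0, j0, length in inv:
        if length < min_anchor:
            continue
        b_start = nb - (j0 + length)
        if respect_mask and qa.mask[a0] and tb.mask[b_start]:
            continue
        out.append(
            MatchSegment(
                Interval(qa.seq_id, a0, a0 + length, "+"),
                Interval(tb.seq_id, b_start, b_start + length, "-"),
                INVERTED,
            )
        )
    out.sort(key=lambda m: (m.a.start, m.a.end, m.b.start, m.orientation))
    return out


def find_anchors(
    seq_a: str,
    seq_b: str,
    min_anchor: int = 50,
    respect_mask: bool = True,
    seq_a_id: str = "A",
    seq_b_id: str = "B",
) -> list[MatchSegment]:
    """Convenience wrapper over :func:`anchors_between` for two raw strings."""
    if not seq_a or not seq_b:
        raise ValueError("cannot compare empty sequences")
    return anchors_between(
        SeqHash(seq_a_id, seq_a), SeqHash(seq_b_id, seq_b), min_anchor, respect_mask
    )


class AssemblyIndex:
    """Cached per-sequence hash indexes of one assembly for repeated queries.

    Mapping hundreds of BAC end sequences, scaffolds or FISH probes against
    the same assembly reuses one :class:`SeqHash` per target sequence, so
    each target is hashed and sorted exactly once per process.  Queries are
    matched mask-blind, like an alignment of the full (unmasked) sequence:
    repeats are *meant* to produce multiple hits here — that is what the
    uniqueness filters and the FISH multi-signal logic feed on.  A cache
    built elsewhere (e.g. by the whole-chromosome comparison stage) can be
    handed in to avoid re-indexing.
    """

    def __init__(self, assembly: Assembly, cache: dict[str, SeqHash] | None = None) -> None:
        self.assembly = assembly
        self._cache: dict[str, SeqHash] = cache if cache is not None else {}

    def seq_hash(self, seq_id: str) -> SeqHash:
        if seq_id not in self._cache:
            self._cache[seq_id] = SeqHash(seq_id, self.assembly.sequences[seq_id])
        return self._cache[seq_id]

    def query(
        self,
        query_seq: str,
        min_anchor: int = 50,
        seq_ids: list[str] | None = None,
        query_id: str = "query",
        stride: int = 1,
    ) -> list[MatchSegment]:
        """All maximal exact matches of ``query_seq`` (both strands) against
        every (or selected) assembly sequence, with ``a`` in query
        coordinates and ``b`` in target coordinates."""
        if not query_seq:
            raise ValueError("empty query sequence")
        from .core import reverse_complement

        qa = SeqHash(query_id, query_seq)
        qrc = SeqHash(query_id, reverse_complement(query_seq))
        nq = len(query_seq)
        targets = seq_ids if seq_ids is not None else list(self.assembly.sequences)
        out: list[MatchSegment] = []
        # inverted matches come from the reverse-complemented query against
        # the forward target index, so targets never need a reverse index
        for sid in targets:
            if len(self.assembly.sequences[sid]) < min_anchor:
                continue
            tb = self.seq_hash(sid)
            out.extend(
                anchors_between(qa, tb, min_anchor, respect_mask=False,
                                orientations=(SAME,), q_stride=stride)
            )
            for m in anchors_between(qrc, tb, min_anchor, respect_mask=False,
                                     orientations=(SAME,), q_stride=stride):
                a = Interval(query_id, nq - m.a.end, nq - m.a.start, "+")
                b = Interval(sid, m.b.start, m.b.end, "-")
                out.append(MatchSegment(a, b, INVERTED))
        out.sort(key=lambda m: (m.a.start, m.a.end, m.b.seq_id, m.b.start, m.orientation))
        return out


# --------------------------------------------------------------------------
# Chaining

@dataclass
class SyntenyBlock:
    """A chained colinear run of same-orientation anchors."""

    anchors: list[MatchSegment]
    orientation: str

    @property
    def a_span(self) -> Interval:
        return Interval(
            self.anchors[0].a.seq_id,
            min(m.a.start for m in self.anchors),
            max(m.a.end for m in self.anchors),
        )

    @property
    def b_span(self) -> Interval:
        return Interval(
            self.anchors[0].b.seq_id,
            min(m.b.start for m in self.anchors),
            max(m.b.end for m in self.anchors),
            "-" if self.orientation == INVERTED else "+",
        )

    @property
    def anchor_bp(self) -> int:
        return sum(m.length for m in self.anchors)


def _chainable(prev: MatchSegment, nxt: MatchSegment, max_gap: int, max_drift: int) -> bool:
    """Joining predicate: same orientation, colinear, bounded gaps and drift."""
    if prev.orientation != nxt.orientation:
        return False
    if prev.a.seq_id != nxt.a.seq_id or prev.b.seq_id != nxt.b.seq_id:
        return False
    gap_a = nxt.a.start - prev.a.end
    if not (0 <= gap_a <= max_gap):
        return False
    if prev.orientation == SAME:
        gap_b = nxt.b.start - prev.b.end
        drift = abs((nxt.b.start - nxt.a.start) - (prev.b.start - prev.a.start))
    else:
        gap_b = prev.b.start - nxt.b.end
        drift = abs((nxt.a.start + nxt.b.end) - (prev.a.start + prev.b.end))
    return 0 <= gap_b <= max_gap and drift <= max_drift


def _drift(prev: MatchSegment, nxt: MatchSegment) -> int:
    if prev.orientation == SAME:
        return abs((nxt.b.start - nxt.a.start) - (prev.b.start - prev.a.start))
    return abs((nxt.a.start + nxt.b.end) - (prev.a.start + prev.b.end))


def chain_anchors(
    anchors: list[MatchSegment],
    max_gap: int = 50_000,
    max_drift: int = 20_000,
) -> list[SyntenyBlock]:
    """Partition anchors into colinear synteny blocks.

    Greedy left-to-right sweep over anchors sorted by A position: each
    anchor joins the open block whose tail it can follow under the joining
    predicate (same orientation, both-genome gap in [0, max_gap], diagonal
    drift <= max_drift), preferring the block with the smallest drift and
    breaking ties toward the earlier-starting block.  Every anchor ends up
    in exactly one block; blocks are returned sorted by A span.
    """
    if not anchors:
        return []
    pending = sorted(anchors, key=lambda m: (m.a.seq_id, m.a.start, m.a.end, m.b.start))
    blocks: list[list[MatchSegment]] = []
    for m in pending:
        best: int | None = None
        best_key: tuple[int, int] | None = None
        for bi, chain in enumerate(blocks):
            tail = chain[-1]
            if _chainable(tail, m, max_gap, max_drift):
                key = (_drift(tail, m), chain[0].a.start)
                if best_key is None or key < best_key:
                    best, best_key = bi, key
        if best is None:
            blocks.append([m])
        else:
            blocks[best].append(m)
    out = [SyntenyBlock(chain, chain[0].orientation) for chain in blocks]
    out.sort(key=lambda b: (b.a_span.seq_id, b.a_span.start, b.a_span.end))
    return out


# --------------------------------------------------------------------------
# Tabular output

def anchors_table(anchors: list[MatchSegment]):
    """Anchors as a DataFrame with 1-based inclusive report coordinates."""
    import pandas as pd

    rows = []
    for m in anchors:
        (sa, a1, a2), (sb, b1, b2) = m.a.to_report(), m.b.to_report()
        rows.append((sa, a1, a2, sb, b1, b2, m.orientation, m.length))
    return pd.DataFrame(
        rows,
        columns=["seqA", "startA", "endA", "seqB", "startB", "endB", "orient", "len"],
    )


def anchors_to_paf(anchors: list[MatchSegment], len_a: int, len_b: int) -> str:
    """PAF-like records (0-based half-open, as PAF specifies) for dot-plot viewers."""
    lines = []
    for m in anchors:
        strand = "+" if m.orientation == SAME else "-"
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    m.a.seq_id, len_a, m.a.start, m.a.end, strand,
                    m.b.seq_id, len_b, m.b.start, m.b.end,
                    m.length, m.length, 255,
                )
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
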