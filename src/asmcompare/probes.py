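"""BAC probe selection and junction-PCR design.

A BAC clone is usable as a FISH probe for a discordant region when its two
end sequences map to unique positions, in opposite orientation facing
inward, at a plausible insert distance (50-300 kb).  Disentangling an
inversion takes three pairwise non-overlapping clones: one inside the
inverted segment and two outside, close to the opposite borders, so the
interphase signal order discriminates the two orientations.  Discordances
whose alternative positions are too close for FISH resolution are tested
instead by long-range PCR across the predicted junction: each draft
hypothesis predicts a junction; only the junction actually present in the
genome yields an amplicon.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import pandas as pd

from .anchors import AssemblyIndex, MatchSegment
from .classify import INV, MDP, Discordance
from .core import Assembly, Interval, Thresholds, reverse_complement
from .simulate import BESClone


@dataclass
class EndHit:
    """Best mapping of one BAC end sequence."""

    locus: Interval | None  # None when unmappable
    strand: str | None
    unique: bool
    n_hits: int
    edit_distance: int | None


@dataclass
class BACPlacement:
    clone_id: str
    end1: EndHit
    end2: EndHit
    insert: Interval | None  # implied insert; only when both ends on one sequence
    orientation_ok: bool

    @property
    def span(self) -> int | None:
        return None if self.insert is None else len(self.insert)

    def meets_criteria(self, thresholds: Thresholds) -> bool:
        """Both ends unique, opposite orientation facing inward, plausible span."""
        return (
            self.end1.unique
            and self.end2.unique
            and self.orientation_ok
            and self.span is not None
            and thresholds.bes_span_min <= self.span <= thresholds.bes_span_max
        )


def _map_end(
    end_seq: str,
    index: AssemblyIndex,
    min_anchor: int,
    mismatch_per_100: float,
    anchors: list[MatchSegment] | None = None,
) -> EndHit:
    """Map one end sequence: candidate loci from exact anchors, then each
    candidate verified with a banded edit-distance alignment.  A locus
    counts as a hit when its distance is within ``mismatch_per_100``
    mismatches per 100 bp, so near-identical repeat copies make an end
    ambiguous even without an exact second match."""
    n = len(end_seq)
    tol = int(mismatch_per_100 * n / 100)
    if anchors is None:
        anchors = index.query(end_seq, min_anchor)
    # cluster anchor hits into candidate loci per (sequence, strand)
    groups: dict[tuple[str, str], list[MatchSegment]] = {}
    for m in anchors:
        strand = "+" if m.orientation == "same" else "-"
        groups.setdefault((m.b.seq_id, strand), []).append(m)
    clusters: list[tuple[str, str, list[MatchSegment]]] = []
    for (sid, strand), ms in groups.items():
        ms.sort(key=lambda m: m.b.start)
        cur = [ms[0]]
        for m in ms[1:]:
            if m.b.start - cur[-1].b.end <= n:
                cur.append(m)
            else:
                clusters.append((sid, strand, cur))
                cur = [m]
        clusters.append((sid, strand, cur))

    hits: list[tuple[int, Interval, str]] = []
    for sid, strand, ms in clusters:
        lo = min(m.b.start for m in ms)
        hi = max(m.b.end for m in ms)
        pad = n
        seq = index.assembly.sequences[sid]
        window = seq[max(0, lo - pad) : hi + pad].upper()
        query = end_seq.upper() if strand == "+" else reverse_complement(end_seq).upper()
        res = edlib.align(query, window, mode="HW", task="locations", k=tol)
        if res["editDistance"] < 0:
            continue
        s, e = res["locations"][0]
        off = max(0, lo - pad)
        hits.append((res["editDistance"], Interval(sid, off + s, off + e + 1), strand))
    if not hits:
        return EndHit(None, None, False, 0, None)
    hits.sort(key=lambda h: (h[0], h[1].seq_id, h[1].start))
    dist, locus, strand = hits[0]
    return EndHit(locus, strand, unique=len(hits) == 1, n_hits=len(hits), edit_distance=dist)


def map_bes(
    clone: BESClone,
    index: AssemblyIndex,
    min_anchor: int = 50,
    mismatch_per_100: float = 2.0,
) -> BACPlacement:
    """Map both end sequences of a clone onto one draft.

    The implied insert exists only when both ends land on the same
    sequence; ``orientation_ok`` requires the ends on opposite strands
    facing inward (the forward-strand end upstream of the reverse-strand
    end)."""
    h1 = _map_end(clone.end1, index, min_anchor, mismatch_per_100)
    h2 = _map_end(clone.end2, index, min_anchor, mismatch_per_100)
    return _pair_placement(clone.clone_id, h1, h2)


def _pair_placement(clone_id: str, h1: EndHit, h2: EndHit) -> BACPlacement:
    insert = None
    orientation_ok = False
    if h1.locus is not None and h2.locus is not None and h1.locus.seq_id == h2.locus.seq_id:
        if h1.strand != h2.strand and h1.strand is not None:
            fwd, rev = (h1, h2) if h1.strand == "+" else (h2, h1)
            if fwd.locus.start < rev.locus.end:
                orientation_ok = True
                insert = Interval(
                    h1.locus.seq_id,
                    min(h1.locus.start, h2.locus.start),
                    max(h1.locus.end, h2.locus.end),
                )
    return BACPlacement(clone_id, h1, h2, insert, orientation_ok)


def map_library(
    clones, index: AssemblyIndex, min_anchor: int = 50, mismatch_per_100: float = 2.0
) -> dict[str, BACPlacement]:
    """Map a whole BES library on one draft.

    All end sequences are concatenated (separated by runs of N, which an
    ACGT end sequence can never match through) and searched in one pass,
    then each end's hits are verified individually as in :func:`map_bes`.
    """
    from bisect import bisect_right

    sep = "N" * max(50, min_anchor)
    ends: list[tuple[str, int, str, int]] = []  # (clone_id, end no., seq, offset)
    parts: list[str] = []
    off = 0
    for c in clones:
        for which, seq in ((1, c.end1), (2, c.end2)):
            ends.append((c.clone_id, which, seq, off))
            parts.append(seq)
            off += len(seq) + len(sep)
    if not ends:
        return {}
    concat = sep.join(parts)
    anchors = index.query(concat, min_anchor)
    offsets = [e[3] for e in ends]
    per_end: dict[tuple[str, int], list[MatchSegment]] = {}
    for m in anchors:
        i = bisect_right(offsets, m.a.start) - 1
        cid, which, seq, eoff = ends[i]
        if m.a.end > eoff + len(seq):
            continue  # spans a separator (possible only for N-containing targets)
        a = Interval("end", m.a.start - eoff, m.a.end - eoff, m.a.strand)
        per_end.setdefault((cid, which), []).append(
            MatchSegment(a, m.b, m.orientation)
        )
    out: dict[str, BACPlacement] = {}
    for c in clones:
        h1 = _map_end(c.end1, index, min_anchor, mismatch_per_100,
                      per_end.get((c.clone_id, 1), []))
        h2 = _map_end(c.end2, index, min_anchor, mismatch_per_100,
                      per_end.get((c.clone_id, 2), []))
        out[c.clone_id] = _pair_placement(c.clone_id, h1, h2)
    return out


def select_probes_for_region(
    region: Interval,
    placements: dict[str, BACPlacement] | list[BACPlacement],
    thresholds: Thresholds,
    min_overlap: float = 0.5,
) -> list[BACPlacement]:
    """Clones usable as probes for ``region``: both ends unique, opposite
    orientation, span within the plausible insert range, insert overlapping
    the region by >= ``min_overlap`` of the insert; sorted by centrality of
    the insert midpoint."""
    pls = placements.values() if isinstance(placements, dict) else placements
    center = (region.start + region.end) / 2
    out = []
    for p in pls:
        if not p.meets_criteria(thresholds):
            continue
        ins = p.insert
        if ins.seq_id != region.seq_id:
            continue
        if ins.overlap(region) < min_overlap * len(ins):
            continue
        out.append(p)
    out.sort(key=lambda p: (abs((p.insert.start + p.insert.end) / 2 - center), p.clone_id))
    return out


# --------------------------------------------------------------------------
# Inversion triplets

@dataclass
class ProbePlan:
    """Probes assigned to test one discordance."""

    target_code: str
    assay: str  # FISH-interphase | FISH-metaphase | PCR
    probes: list[tuple[str, BACPlacement]]  # (role, placement)
    feasible: bool
    note: str = ""
    draft: str = "A"  # the draft whose coordinates the placements use


def _non_overlapping(*placements: BACPlacement) -> bool:
    ivs = [p.insert for p in placements]
    return all(
        ivs[i].overlap(ivs[j]) == 0 for i in range(len(ivs)) for j in range(i + 1, len(ivs))
    )


def plan_flanked_triplet(
    target: Discordance,
    placements: dict[str, BACPlacement],
    thresholds: Thresholds,
    flank_max: int = 1_000_000,
    inside_pref: str = "central",
    exclude: set[str] | None = None,
    avoid: list[Interval] | None = None,
) -> ProbePlan:
    """Triplet plan for an interphase arrangement test: one probe inside
    the segment's A-side locus, two outside within ``flank_max`` of the
    opposite borders, all pairwise non-overlapping.

    ``inside_pref`` orders the inside candidates: ``central`` (order tests,
    e.g. relocations) or ``off-center`` (inversion tests, where the inside
    signal must sit visibly nearer one flank so that inverting the segment
    changes the arrangement).  ``exclude`` drops specific clones so a
    caller can re-plan when a triplet turns out uninformative.  ``avoid``
    lists other discordant loci on this chromosome: a flank is rejected
    when such a locus falls between it and the target, because the
    inter-signal distance across a draft disagreement is not comparable
    between the drafts."""
    region = target.a_locus
    code = target.code or "?"
    exclude = exclude or set()
    avoid = avoid or []
    eligible = [
        p for p in placements.values()
        if p.meets_criteria(thresholds) and p.insert.seq_id == region.seq_id
        and p.clone_id not in exclude
    ]

    def clear_gap(lo: int, hi: int) -> bool:
        if lo >= hi:
            return True
        gap = Interval(region.seq_id, lo, hi)
        return all(gap.overlap(iv) == 0 for iv in avoid)

    inside = [
        p for p in eligible
        if region.start <= p.insert.start and p.insert.end <= region.end
    ]
    left = [
        p for p in eligible
        if p.insert.end <= region.start and p.insert.start >= region.start - flank_max
        and clear_gap(p.insert.start, region.start)
    ]
    right = [
        p for p in eligible
        if p.insert.start >= region.end and p.insert.end <= region.end + flank_max
        and clear_gap(region.end, p.insert.end)
    ]
    center = (region.start + region.end) / 2

    def asym(p: BACPlacement) -> float:
        return abs((p.insert.start + p.insert.end) / 2 - center)

    if inside_pref == "off-center":
        inside.sort(key=lambda p: (-asym(p), p.clone_id))
    else:
        inside.sort(key=lambda p: (asym(p), p.clone_id))
    left.sort(key=lambda p: (region.start - p.insert.end, p.clone_id))
    right.sort(key=lambda p: (p.insert.start - region.end, p.clone_id))
    for pi in inside:
        for pl in left:
            for pr in right:
                if _non_overlapping(pi, pl, pr):
                    return ProbePlan(
                        code,
                        "FISH-interphase",
                        [("flank-left", pl), ("inside", pi), ("flank-right", pr)],
                        feasible=True,
                    )
    return ProbePlan(code, "FISH-interphase", [], feasible=False,
                     note="no qualifying non-overlapping triplet")


def plan_inversion_test(
    inv: Discordance,
    placements: dict[str, BACPlacement],
    thresholds: Thresholds,
    flank_max: int = 1_000_000,
    exclude: set[str] | None = None,
    avoid: list[Interval] | None = None,
) -> ProbePlan:
    """Probe triplet for a test-eligible inversion (see module docstring)."""
    if inv.category != INV:
        raise ValueError("plan_inversion_test requires an INV discordance")
    if inv.eligibility != "test-eligible":
        raise ValueError(
            f"inversion {inv.code or ''} is not test-eligible "
            f"(size {inv.size} <= {thresholds.test_min_inv})"
        )
    return plan_flanked_triplet(inv, placements, thresholds, flank_max,
                                inside_pref="off-center", exclude=exclude,
                                avoid=avoid)


# --------------------------------------------------------------------------
# Reference panel

def build_reference_panel(
    blocks_by_chrom: dict,
    placements: dict[str, BACPlacement],
    thresholds: Thresholds,
    min_agreement: float = 0.99,
) -> dict[str, BACPlacement | None]:
    """One chromosome-specific reference clone per chromosome, picked from
    highly concordant regions: the insert must lie wholly inside a
    same-orientation block whose two spans agree positionally by
    >= ``min_agreement`` reciprocal overlap.  Chromosomes with no
    qualifying clone map to None."""
    panel: dict[str, BACPlacement | None] = {}
    for chrom, blocks in blocks_by_chrom.items():
        concordant = [
            b for b in blocks
            if b.orientation == "same"
            and Interval(chrom, b.a_span.start, b.a_span.end).reciprocal_overlap(
                Interval(chrom, b.b_span.start, b.b_span.end)
            ) >= min_agreement
        ]
        concordant.sort(key=lambda b: -len(b.a_span))
        chosen = None
        for b in concordant:
            cands = [
                p for p in placements.values()
                if p.meets_criteria(thresholds)
                and p.insert.seq_id == chrom
                and b.a_span.start <= p.insert.start
                and p.insert.end <= b.a_span.end
            ]
            if cands:
                center = (b.a_span.start + b.a_span.end) / 2
                cands.sort(key=lambda p: (abs((p.insert.start + p.insert.end) / 2 - center),
                                          p.clone_id))
                chosen = cands[0]
                break
        panel[chrom] = chosen
    return panel


# --------------------------------------------------------------------------
# Junction PCR

PRIMER_LEN = 25


@dataclass
class PCRAssay:
    """A primer pair across the junction predicted by one draft hypothesis."""

    hypothesis: str  # assembly name
    fwd_primer: str | None
    rev_primer: str | None  # given 5'->3' on the reverse strand
    fwd_site: Interval | None
    rev_site: Interval | None
    predicted_amplicon: int | None
    feasible: bool
    note: str = ""


def _occurrences(primer: str, assembly: Assembly) -> list[tuple[str, int, str]]:
    """All exact occurrences of a primer site on either strand."""
    out = []
    fwd = primer.upper()
    rev = reverse_complement(primer).upper()
    for sid, seq in assembly.sequences.items():
        hay = seq.upper()
        for needle, strand in ((fwd, "+"), (rev, "-")):
            start = 0
            while True:
                p = hay.find(needle, start)
                if p < 0:
                    break
                out.append((sid, p, strand))
                start = p + 1
    return out


def _unique_primer(
    assembly: Assembly, chrom: str, pos: int, direction: int, max_slide: int = 2_000
) -> tuple[str, Interval] | None:
    """A 25-bp primer site unique in ``assembly``, at or sliding outward
    from ``pos`` (direction -1: site ends at pos, walking left; +1: site
    starts at pos, walking right)."""
    seq = assembly.sequences[chrom]
    for off in range(0, max_slide, 50):
        if direction < 0:
            s = pos - PRIMER_LEN - off
            if s < 0:
                return None
        else:
            s = pos + off
            if s + PRIMER_LEN > len(seq):
                return None
        site = seq[s : s + PRIMER_LEN]
        if not site.isupper():
            continue
        if len(_occurrences(site, assembly)) == 1:
            return site, Interval(chrom, s, s + PRIMER_LEN)
    return None


def design_junction_pcr(
    mdp: Discordance,
    asm_a: Assembly,
    asm_b: Assembly,
    thresholds: Thresholds,
    primer_offset: int = 100,
) -> dict[str, PCRAssay]:
    """One junction assay per draft hypothesis for an MDP.

    Each draft predicts a junction at the upstream boundary of where it
    places the segment; a primer pair flanking that junction (forward
    primer upstream, reverse primer inside the segment) amplifies only if
    the genome really joins those two sequences within the long-PCR limit.
    """
    if mdp.category != MDP:
        raise ValueError("design_junction_pcr requires an MDP discordance")
    out: dict[str, PCRAssay] = {}
    for name, asm, locus in (
        (asm_a.name, asm_a, mdp.a_locus),
        (asm_b.name, asm_b, mdp.b_locus),
    ):
        if locus is None:
            out[name] = PCRAssay(name, None, None, None, None, None, False, "no locus")
            continue
        j = locus.start
        fwd = _unique_primer(asm, locus.seq_id, j - primer_offset, direction=-1)
        rev_site = _unique_primer(asm, locus.seq_id, j + primer_offset, direction=+1)
        if fwd is None or rev_site is None:
            out[name] = PCRAssay(name, None, None, None, None, None, False,
                                 "no unique primer site")
            continue
        fwd_seq, fwd_iv = fwd
        site_seq, rev_iv = rev_site
        amplicon = rev_iv.end - fwd_iv.start
        feasible = amplicon <= thresholds.pcr_amplicon_max
        out[name] = PCRAssay(
            name,
            fwd_seq,
            reverse_complement(site_seq),
            fwd_iv,
            rev_iv,
            amplicon,
            feasible,
            "" if feasible else f"amplicon {amplicon} exceeds long-PCR limit",
        )
    return out


def in_silico_pcr(
    assay: PCRAssay, genome: Assembly, max_len: int
) -> list[tuple[str, int, int]]:
    """Amplicons the assay would produce on ``genome``: a forward-primer
    site and a reverse-primer site on the same molecule, facing inward,
    within ``max_len``."""
    if not assay.feasible or assay.fwd_primer is None:
        return []
    fwd_hits = _occurrences(assay.fwd_primer, genome)
    # the reverse primer anneals where its reverse complement appears on '+'
    rev_hits = _occurrences(reverse_complement(assay.rev_primer), genome)
    out = []
    for sid_f, pf, strand_f in fwd_hits:
        for sid_r, pr, strand_r in rev_hits:
            if sid_f != sid_r:
                continue
            if strand_f == "+" and strand_r == "+" and pr >= pf:
                length = pr + PRIMER_LEN - pf
                if length <= max_len:
                    out.append((sid_f, pf, pr + PRIMER_LEN))
            elif strand_f == "-" and strand_r == "-" and pf >= pr:
                length = pf + PRIMER_LEN - pr
                if length <= max_len:
                    out.append((sid_f, pr, pf + PRIMER_LEN))
    return sorted(set(out))


def probe_table(plans: list[ProbePlan]) -> pd.DataFrame:
    rows = []
    for plan in plans:
        if not plan.probes:
            rows.append((plan.target_code, plan.assay, "-", "-", "-", 0, 0,
                         int(plan.feasible), plan.note))
        for role, p in plan.probes:
            sid, s, e = p.insert.to_report() if p.insert else ("-", 0, 0)
            rows.append((plan.target_code, plan.assay, role, p.clone_id, sid, s, e,
                         int(plan.feasible), plan.note))
    return pd.DataFrame(
        rows,
        columns=["target", "assay", "role", "clone", "seq", "start", "end",
                 "feasible", "note"],
    )
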