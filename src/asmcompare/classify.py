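"""Classify synteny blocks into the discordance taxonomy.

Comparing the like-named chromosomes of two drafts yields synteny blocks;
their geometry sorts every inconsistency into four categories:

* **INV** — a block in inverted orientation whose two spans occupy (almost)
  the same chromosomal position once projected through the flanking
  colinear blocks.
* **MDP** — a same-orientation block *M*apped to a *D*istinct *P*osition
  along the chromosome: its position violates the dominant colinear order.
* **ODS** — *O*ne-*D*raft-only *S*equence: a maximal chromosome region of
  one draft covered by no block at all.
* **DCM** — *D*iscordant *C*hromosome *M*apping: a pair of ODSs, one per
  draft, that match each other but sit on differently-named chromosomes;
  a one-sided variant covers the case where one draft carries a duplicate
  second copy and the other a single placement.

Reportability and test eligibility are strict-inequality rules on segment
size (> ``report_min`` to be reported; > ``test_min_inv`` for an inversion
to be FISH-testable with a probe triplet, > ``test_min_mdp_dcm`` for the
other categories), and segments almost completely composed of gaps and/or
repeats are excluded from testing but retained in the reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .anchors import INVERTED, SAME, MatchSegment, SyntenyBlock
from .core import Assembly, Interval, Thresholds, masked_fraction

INV = "INV"
MDP = "MDP"
ODS = "ODS"
DCM = "DCM"

SUB_THRESHOLD = "sub-threshold"
REPORTABLE = "reportable"
TEST_ELIGIBLE = "test-eligible"


@dataclass
class Discordance:
    """A classified inconsistency between the two drafts."""

    category: str
    a_locus: Interval | None
    b_locus: Interval | None
    size: int
    source_assembly: str | None = None  # for ODS: the draft that has the sequence
    eligibility: str = REPORTABLE
    gap_repeat_flag: bool = False
    code: str | None = None
    dcm_partner: "Discordance | None" = field(default=None, repr=False)
    duplicated_in: str | None = None  # one-sided DCM: draft carrying the duplicate

    @property
    def defining_locus(self) -> Interval:
        """The locus that defines the discordance (used for masking and codes)."""
        if self.category == ODS:
            locus = self.a_locus if self.source_assembly == "A" else self.b_locus
        else:
            locus = self.a_locus if self.a_locus is not None else self.b_locus
        if locus is None:
            raise ValueError(f"{self.category} discordance has no locus")
        return locus


def _eligibility(category: str, size: int, thresholds: Thresholds) -> str:
    if size <= thresholds.report_min:
        return SUB_THRESHOLD
    test_min = (
        thresholds.test_min_inv if category == INV else thresholds.test_min_mdp_dcm
    )
    return TEST_ELIGIBLE if size > test_min else REPORTABLE


def _weighted_lis(blocks: list[SyntenyBlock]) -> list[SyntenyBlock]:
    """Backbone: the anchor-bp-heaviest subsequence of same-orientation
    blocks whose B positions increase with A position."""
    if not blocks:
        return []
    n = len(blocks)
    best = [b.anchor_bp for b in blocks]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if blocks[j].b_span.start <= blocks[i].b_span.start:
                cand = best[j] + blocks[i].anchor_bp
                if cand > best[i]:
                    best[i], prev[i] = cand, j
    i = max(range(n), key=lambda x: best[x])
    chain = []
    while i >= 0:
        chain.append(blocks[i])
        i = prev[i]
    return chain[::-1]


def _local_offset(backbone: list[SyntenyBlock], s: int, e: int, slack: int = 1_000) -> int:
    """Estimated B-minus-A offset at A interval [s, e), interpolated from the
    nearest flanking backbone blocks (0 when there is no backbone).

    ``slack`` tolerates the few bp by which a maximal anchor can overrun a
    breakpoint by chance, which would otherwise disqualify the true flank.
    """
    left = None
    right = None
    for b in backbone:
        if b.a_span.end <= s + slack:
            left = b
        elif b.a_span.start >= e - slack and right is None:
            right = b
    offs = []
    if left is not None:
        offs.append(left.b_span.end - left.a_span.end)
    if right is not None:
        offs.append(right.b_span.start - right.a_span.start)
    if not offs:
        # fall back to any backbone block (or zero offset)
        if backbone:
            b = backbone[0]
            return b.b_span.start - b.a_span.start
        return 0
    return round(sum(offs) / len(offs))


def _uncovered(length: int, covered: list[tuple[int, int]], min_len: int) -> list[tuple[int, int]]:
    """Maximal gaps of [0, length) not covered by any interval."""
    out = []
    pos = 0
    for s, e in sorted(covered):
        if s > pos and s - pos >= min_len:
            out.append((pos, s))
        pos = max(pos, e)
    if length - pos >= min_len:
        out.append((pos, length))
    return out


def classify_chromosome_pair(
    chrom: str,
    blocks: list[SyntenyBlock],
    len_a: int,
    len_b: int,
    thresholds: Thresholds,
    min_inv_overlap: float = 0.8,
    min_block_bp: int = 5_000,
) -> list[Discordance]:
    """Classify the blocks of one homologous chromosome pair.

    INV requires >= ``min_inv_overlap`` reciprocal overlap between the
    block's B span and its A span projected through the flanking colinear
    blocks ("almost coincidental mapping").  MDP requires the B center to be
    displaced from the colinear prediction by more than the block's own
    length.  ODS regions are the maximal uncovered stretches of either
    chromosome, trimmed to the nearest unmatched base.

    Blocks with fewer than ``min_block_bp`` matched bp are treated as noise
    (short cross-matches between diverged repeat copies): they enter
    neither the backbone, nor the INV/MDP candidates, nor the coverage used
    for ODS detection.  The floor sits far below the reporting threshold,
    so no reportable discordance can consist of noise alone.
    """
    for b in blocks:
        if b.a_span.seq_id != chrom or b.b_span.seq_id != chrom:
            raise ValueError(
                f"block {b.a_span.seq_id}/{b.b_span.seq_id} does not belong to pair {chrom}"
            )
    blocks = [b for b in blocks if b.anchor_bp >= min_block_bp]
    same = sorted((b for b in blocks if b.orientation == SAME),
                  key=lambda b: b.a_span.start)
    inverted = [b for b in blocks if b.orientation == INVERTED]
    backbone = _weighted_lis(same)
    backbone_set = {id(b) for b in backbone}

    out: list[Discordance] = []
    for b in inverted:
        a, bs = b.a_span, b.b_span
        off = _local_offset(backbone, a.start, a.end)
        lo = a.start + off
        proj = Interval(chrom, max(0, lo), max(0, lo) + len(a))
        if proj.reciprocal_overlap(Interval(chrom, bs.start, bs.end)) >= min_inv_overlap:
            size = len(a)
            out.append(Discordance(INV, a, Interval(chrom, bs.start, bs.end), size,
                                   eligibility=_eligibility(INV, size, thresholds)))
    for b in same:
        if id(b) in backbone_set:
            continue
        a, bs = b.a_span, b.b_span
        off = _local_offset(backbone, a.start, a.end)
        pred_center = (a.start + a.end) / 2 + off
        center = (bs.start + bs.end) / 2
        if abs(center - pred_center) > len(a):
            size = len(a)
            out.append(Discordance(MDP, a, Interval(chrom, bs.start, bs.end), size,
                                   eligibility=_eligibility(MDP, size, thresholds)))
    cov_a = [(b.a_span.start, b.a_span.end) for b in blocks]
    cov_b = [(b.b_span.start, b.b_span.end) for b in blocks]
    for s, e in _uncovered(len_a, cov_a, thresholds.report_min):
        out.append(Discordance(ODS, Interval(chrom, s, e), None, e - s,
                               source_assembly="A",
                               eligibility=_eligibility(ODS, e - s, thresholds)))
    for s, e in _uncovered(len_b, cov_b, thresholds.report_min):
        out.append(Discordance(ODS, None, Interval(chrom, s, e), e - s,
                               source_assembly="B",
                               eligibility=_eligibility(ODS, e - s, thresholds)))
    return out


def classify_discordances(
    blocks_by_chrom: dict[str, list[SyntenyBlock]],
    asm_a: Assembly,
    asm_b: Assembly,
    thresholds: Thresholds,
) -> list[Discordance]:
    """Classify every homologous chromosome pair of the two drafts."""
    out: list[Discordance] = []
    for chrom, blocks in blocks_by_chrom.items():
        out.extend(
            classify_chromosome_pair(
                chrom, blocks, asm_a.length(chrom), asm_b.length(chrom), thresholds
            )
        )
    return out


# --------------------------------------------------------------------------
# DCM pairing

def _coverage_against(
    placements: list[MatchSegment], ods_len: int, target_locus: Interval | None,
    target_chrom: str | None = None,
) -> float:
    """Fraction of an ODS sequence covered by anchors that land in
    ``target_locus`` (or anywhere on ``target_chrom``)."""
    ivs = []
    for m in placements:
        if target_locus is not None:
            if m.b.seq_id != target_locus.seq_id or m.b.overlap(target_locus) == 0:
                continue
        elif target_chrom is not None and m.b.seq_id != target_chrom:
            continue
        ivs.append((m.a.start, m.a.end))
    covered = 0
    pos = 0
    for s, e in sorted(ivs):
        if e > pos:
            covered += e - max(pos, s)
            pos = e
    return covered / ods_len


def pair_odss(
    ods_a: list[Discordance],
    ods_b: list[Discordance],
    placements_a: dict[int, list[MatchSegment]],
    placements_b: dict[int, list[MatchSegment]],
    target_roles_a: dict[str, str] | None = None,
    target_roles_b: dict[str, str] | None = None,
    min_recip: float = 0.5,
) -> list[Discordance]:
    """Pair ODSs across drafts into DCMs.

    ``placements_a[i]`` holds the anchor matches of the i-th A-side ODS
    sequence against the whole B draft (anchor ``a`` coordinates are within
    the ODS sequence, ``b`` on the target draft); symmetrically for
    ``placements_b``.  A DCM is emitted when two ODSs cover each other
    reciprocally >= ``min_recip`` and sit on differently-named chromosomes.
    An unpaired ODS that still maps to a different chromosome of the other
    draft is emitted as a one-sided DCM flagged as duplicated in its source
    draft (the other draft holds a single copy where the source holds two).
    """
    roles_a = target_roles_a or {}
    roles_b = target_roles_b or {}
    dcms: list[Discordance] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    candidates = []
    for i, da in enumerate(ods_a):
        la = da.defining_locus
        for j, db in enumerate(ods_b):
            lb = db.defining_locus
            if la.seq_id == lb.seq_id:
                continue
            cov_ab = _coverage_against(placements_a.get(i, []), len(la), lb)
            cov_ba = _coverage_against(placements_b.get(j, []), len(lb), la)
            if cov_ab >= min_recip and cov_ba >= min_recip:
                candidates.append((min(cov_ab, cov_ba), i, j))
    for _cov, i, j in sorted(candidates, reverse=True):
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        da, db = ods_a[i], ods_b[j]
        la, lb = da.defining_locus, db.defining_locus
        size = max(len(la), len(lb))
        d = Discordance(DCM, la, lb, size)
        da.dcm_partner = d
        db.dcm_partner = d
        dcms.append(d)

    # one-sided DCMs: the source draft duplicates a sequence that the other
    # draft places once, on a different chromosome
    for src, ods_list, placements, roles, used in (
        ("A", ods_a, placements_a, roles_b, used_a),
        ("B", ods_b, placements_b, roles_a, used_b),
    ):
        for i, d in enumerate(ods_list):
            if i in used:
                continue
            locus = d.defining_locus
            hits = [
                m for m in placements.get(i, [])
                if m.b.seq_id != locus.seq_id and roles.get(m.b.seq_id, "chromosome") == "chromosome"
            ]
            best_cluster = None
            best_cov = 0.0
            for chrom in {m.b.seq_id for m in hits}:
                for cluster in _position_clusters(
                    [m for m in hits if m.b.seq_id == chrom]
                ):
                    cov = _coverage_against(cluster, len(locus), None, chrom)
                    if cov > best_cov:
                        best_cov, best_cluster = cov, cluster
            if best_cluster is None or best_cov < min_recip:
                continue
            partner_span = _hull_on_chrom(best_cluster, best_cluster[0].b.seq_id)
            a_locus = locus if src == "A" else partner_span
            b_locus = partner_span if src == "A" else locus
            dcm = Discordance(DCM, a_locus, b_locus, len(locus), duplicated_in=src)
            d.dcm_partner = dcm
            dcms.append(dcm)
    return dcms


def _position_clusters(
    hits: list[MatchSegment], merge_gap: int = 100_000
) -> list[list[MatchSegment]]:
    """Group hits on one target sequence into loci separated by > merge_gap."""
    clusters: list[list[MatchSegment]] = []
    for m in sorted(hits, key=lambda m: m.b.start):
        if clusters and m.b.start - clusters[-1][-1].b.end <= merge_gap:
            clusters[-1].append(m)
        else:
            clusters.append([m])
    return clusters


def _hull_on_chrom(placements: list[MatchSegment], chrom: str) -> Interval:
    xs = [m.b for m in placements if m.b.seq_id == chrom]
    return Interval(chrom, min(x.start for x in xs), max(x.end for x in xs))


def finalize_eligibility(dcms: list[Discordance], thresholds: Thresholds) -> None:
    for d in dcms:
        d.eligibility = _eligibility(DCM, d.size, thresholds)


# --------------------------------------------------------------------------
# Gap/repeat exclusion

def filter_gap_repeat(
    discordances: list[Discordance],
    asm_a: Assembly,
    asm_b: Assembly,
    thresholds: Thresholds,
) -> tuple[list[Discordance], list[Discordance]]:
    """Split discordances into (kept, excluded) by masked fraction.

    A discordance is excluded when the masked (lowercase or N) fraction of
    its defining locus strictly exceeds ``masked_frac_max``; excluded items
    are retained for reporting, only dropped from testing.
    """
    kept, excluded = [], []
    for d in discordances:
        locus = d.defining_locus
        if d.category == ODS:
            asm = asm_a if d.source_assembly == "A" else asm_b
        else:
            asm = asm_a if d.a_locus is not None else asm_b
        frac = masked_fraction(locus, asm)
        d.gap_repeat_flag = frac > thresholds.masked_frac_max
        (excluded if d.gap_repeat_flag else kept).append(d)
    return kept, excluded


# --------------------------------------------------------------------------
# Codes

def _chrom_number(seq_id: str) -> str:
    return seq_id[3:] if seq_id.lower().startswith("chr") else seq_id


def _mbp(pos0: int) -> str:
    """Position in Mbp, one decimal, trailing '.0' stripped (INV_20_0 style)."""
    s = f"{pos0 / 1e6:.1f}"
    return s[:-2] if s.endswith(".0") else s


def assign_code(d: Discordance) -> str:
    """The category code: ``<CAT>_<chrom>_<Mbp position>`` for INV/MDP/ODS,
    ``DCM_<chromA>-<chromB>`` for DCMs."""
    if d.category == DCM:
        if d.a_locus is None or d.b_locus is None:
            raise ValueError("DCM without both loci cannot be coded")
        return f"DCM_{_chrom_number(d.a_locus.seq_id)}-{_chrom_number(d.b_locus.seq_id)}"
    locus = d.defining_locus
    return f"{d.category}_{_chrom_number(locus.seq_id)}_{_mbp(locus.start)}"


def assign_codes(discordances: list[Discordance]) -> None:
    """Assign codes to all discordances, de-duplicating with .2/.3 suffixes."""
    seen: dict[str, int] = {}
    for d in discordances:
        base = assign_code(d)
        n = seen.get(base, 0) + 1
        seen[base] = n
        d.code = base if n == 1 else f"{base}.{n}"


# --------------------------------------------------------------------------
# Report

def discordance_table(discordances: list[Discordance]) -> pd.DataFrame:
    """Report table, 1-based inclusive coordinates."""
    rows = []
    for d in discordances:
        def fmt(iv: Interval | None):
            return iv.to_report() if iv is not None else ("-", 0, 0)

        a = fmt(d.a_locus)
        b = fmt(d.b_locus)
        rows.append(
            (
                d.code or "-", d.category, *a, *b, d.size,
                d.source_assembly or "-", d.eligibility,
                int(d.gap_repeat_flag),
                (d.dcm_partner.code or "linked") if d.dcm_partner is not None else "-",
                d.duplicated_in or "-",
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "code", "category", "chromA", "startA", "endA",
            "chromB", "startB", "endB", "size", "source",
            "eligibility", "gap_repeat_flag", "dcm_partner", "duplicated_in",
        ],
    )
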