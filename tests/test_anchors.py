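import random
from collections import defaultdict

import networkx as nx
import pytest

from asmcompare.anchors import (
    INVERTED,
    SAME,
    MatchSegment,
    _chainable,
    chain_anchors,
    find_anchors,
)
from asmcompare.core import Interval, reverse_complement

from conftest import random_seq


# ---------------------------------------------------------------------------
# Independent brute-force oracle: k-mer scan + maximal extension

def _is_masked(seq: str, i: int) -> bool:
    c = seq[i]
    return c.islower() or c in "Nn"


def _brute_strand(seq_a: str, seq_b: str, k: int) -> set[tuple[int, int, int]]:
    ua, ub = seq_a.upper(), seq_b.upper()
    kmers = defaultdict(list)
    for j in range(len(ub) - k + 1):
        kmers[ub[j : j + k]].append(j)
    found = set()
    for i in range(len(ua) - k + 1):
        for j in kmers.get(ua[i : i + k], ()):
            sa, sb = i, j
            while sa > 0 and sb > 0 and ua[sa - 1] == ub[sb - 1]:
                sa -= 1
                sb -= 1
            ea, eb = i + k, j + k
            while ea < len(ua) and eb < len(ub) and ua[ea] == ub[eb]:
                ea += 1
                eb += 1
            found.add((sa, sb, ea - sa))
    return found


def brute_force_anchors(seq_a: str, seq_b: str, k: int):
    """All maximal exact matches >= k bp on both strands, kept iff the start
    is unmasked on at least one genome (the comparison's masking rule)."""
    out = set()
    for sa, sb, length in _brute_strand(seq_a, seq_b, k):
        if not _is_masked(seq_a, sa) or not _is_masked(seq_b, sb):
            out.add((sa, sb, length, SAME))
    rc = reverse_complement(seq_b)
    for sa, srb, length in _brute_strand(seq_a, rc, k):
        b_start = len(seq_b) - srb - length
        if not _is_masked(seq_a, sa) or not _is_masked(seq_b, b_start):
            out.add((sa, b_start, length, INVERTED))
    return out


def as_tuples(anchors):
    return {(m.a.start, m.b.start, m.length, m.orientation) for m in anchors}


def _plant(seq: str, insert: str, pos: int) -> str:
    return seq[:pos] + insert + seq[pos + len(insert):]


def _random_pair(rng: random.Random):
    """A random sequence pair with planted shared segments in assorted
    orientations and masking states."""
    na, nb = rng.randint(300, 9_000), rng.randint(300, 9_000)
    a, b = random_seq(rng, na), random_seq(rng, nb)
    for _ in range(rng.randint(0, 3)):
        seg_len = rng.randint(40, min(600, na // 2, nb // 2))
        seg = random_seq(rng, seg_len)
        if rng.random() < 0.3:
            seg = seg.lower()
        pa = rng.randint(0, na - seg_len)
        pb = rng.randint(0, nb - seg_len)
        sa = seg if rng.random() < 0.5 else seg.swapcase()
        sb = seg if rng.random() < 0.7 else reverse_complement(seg)
        if rng.random() < 0.3:
            sb = sb.swapcase()
        a = _plant(a, sa, pa)
        b = _plant(b, sb, pb)
    return a, b


class TestFindAnchors:
    def test_identity_single_full_anchor(self, rng):
        s = random_seq(rng, 5_000)
        (m,) = find_anchors(s, s, 50)
        assert (m.a.start, m.a.end) == (0, 5_000)
        assert (m.b.start, m.b.end) == (0, 5_000)
        assert m.orientation == SAME

    def test_reverse_complement_single_inverted_anchor(self, rng):
        s = random_seq(rng, 5_000)
        (m,) = find_anchors(s, reverse_complement(s), 50)
        assert m.orientation == INVERTED
        assert (m.b.start, m.b.end, m.b.strand) == (0, 5_000, "-")

    def test_rejects_empty_and_small_k(self):
        with pytest.raises(ValueError):
            find_anchors("", "ACGT" * 100)
        with pytest.raises(ValueError):
            find_anchors("ACGT" * 100, "ACGT" * 100, min_anchor=10)

    @pytest.mark.parametrize("k", [20, 35, 50])
    def test_matches_brute_force_oracle(self, k):
        rng = random.Random(1_234 + k)
        for _case in range(40):
            a, b = _random_pair(rng)
            got = as_tuples(find_anchors(a, b, k))
            want = brute_force_anchors(a, b, k)
            assert got == want

    def test_soundness_and_maximality(self, rng):
        a, b = _random_pair(rng)
        ua, ub = a.upper(), b.upper()
        for m in find_anchors(a, b, 30):
            sub_a = ua[m.a.start : m.a.end]
            if m.orientation == SAME:
                sub_b = ub[m.b.start : m.b.end]
                assert sub_a == sub_b
                # maximality: one-bp extension breaks the match
                if m.a.start > 0 and m.b.start > 0:
                    assert ua[m.a.start - 1] != ub[m.b.start - 1]
                if m.a.end < len(a) and m.b.end < len(b):
                    assert ua[m.a.end] != ub[m.b.end]
            else:
                sub_b = reverse_complement(b[m.b.start : m.b.end]).upper()
                assert sub_a == sub_b
                if m.a.start > 0 and m.b.end < len(b):
                    assert ua[m.a.start - 1] != reverse_complement(b[m.b.end]).upper()
                if m.a.end < len(a) and m.b.start > 0:
                    assert ua[m.a.end] != reverse_complement(b[m.b.start - 1]).upper()

    def test_symmetry_under_swap(self):
        rng = random.Random(77)
        for _case in range(15):
            a, b = _random_pair(rng)
            fwd = {
                (m.a.start, m.b.start, m.length, m.orientation)
                for m in find_anchors(a, b, 30)
            }
            swapped = {
                (m.b.start, m.a.start, m.length, m.orientation)
                for m in find_anchors(b, a, 30)
            }
            assert fwd == swapped


# ---------------------------------------------------------------------------
# Chaining

def _anchor(a0, b0, length, orientation=SAME):
    if orientation == SAME:
        b = Interval("B", b0, b0 + length, "+")
    else:
        b = Interval("B", b0, b0 + length, "-")
    return MatchSegment(Interval("A", a0, a0 + length, "+"), b, orientation)


def _min_path_cover(anchors, max_gap, max_drift) -> int:
    """Exact minimum number of chains covering all anchors, via maximum
    bipartite matching on the chainability DAG (independent of the greedy
    implementation under test)."""
    n = len(anchors)
    g = nx.Graph()
    g.add_nodes_from((f"u{i}" for i in range(n)))
    g.add_nodes_from((f"v{i}" for i in range(n)))
    order = sorted(range(n), key=lambda i: (anchors[i].a.start, anchors[i].b.start))
    for xi, i in enumerate(order):
        for j in order[xi + 1 :]:
            if _chainable(anchors[i], anchors[j], max_gap, max_drift):
                g.add_edge(f"u{i}", f"v{j}")
    matching = nx.bipartite.maximum_matching(
        g, top_nodes=[f"u{i}" for i in range(n)]
    )
    return n - len(matching) // 2


def _random_anchor_set(rng: random.Random):
    """Colinear runs (separated by oversize gaps or drifts) plus strays."""
    anchors = []
    a_pos = rng.randint(0, 1000)
    for _run in range(rng.randint(1, 4)):
        orientation = rng.choice([SAME, INVERTED])
        diag = rng.randint(-5_000, 5_000)
        b_pos = a_pos + diag + 60_000 if orientation == SAME else None
        n_in_run = rng.randint(1, 6)
        if orientation == INVERTED:
            b_hi = rng.randint(a_pos + 400_000, a_pos + 800_000)
        for _i in range(n_in_run):
            length = rng.randint(60, 4_000)
            if orientation == SAME:
                anchors.append(_anchor(a_pos, b_pos, length, SAME))
                gap = rng.randint(0, 30_000)
                drift = rng.randint(-8_000, 8_000)
                a_pos += length + gap
                b_pos += length + gap + drift
            else:
                b_hi -= length
                anchors.append(_anchor(a_pos, b_hi, length, INVERTED))
                gap = rng.randint(0, 30_000)
                a_pos += length + gap
                b_hi -= gap + rng.randint(-8_000, 8_000)
        # force a break before the next run
        a_pos += rng.choice([60_000, 120_000])
    for _stray in range(rng.randint(0, 3)):
        anchors.append(
            _anchor(rng.randint(0, a_pos), rng.randint(800_000, 2_000_000),
                    rng.randint(60, 300), rng.choice([SAME, INVERTED]))
        )
    return anchors[:30]


class TestChainAnchors:
    def test_empty(self):
        assert chain_anchors([]) == []

    def test_colinear_run_single_block(self):
        anchors = [_anchor(0, 0, 100), _anchor(150, 150, 100), _anchor(300, 300, 50)]
        (block,) = chain_anchors(anchors, max_gap=1_000, max_drift=500)
        assert block.anchor_bp == 250
        assert (block.a_span.start, block.a_span.end) == (0, 350)

    def test_oversize_gap_splits(self):
        anchors = [_anchor(0, 0, 100), _anchor(2_100, 2_100, 100)]
        blocks = chain_anchors(anchors, max_gap=1_000, max_drift=500)
        assert len(blocks) == 2

    def test_drift_splits(self):
        anchors = [_anchor(0, 0, 100), _anchor(200, 900, 100)]
        blocks = chain_anchors(anchors, max_gap=1_000, max_drift=500)
        assert len(blocks) == 2

    def test_partition_and_optimality_against_path_cover(self):
        rng = random.Random(4242)
        max_gap, max_drift = 50_000, 20_000
        for _case in range(60):
            anchors = _random_anchor_set(rng)
            blocks = chain_anchors(anchors, max_gap, max_drift)
            # partition: every anchor in exactly one block
            seen = [m for b in blocks for m in b.anchors]
            assert sorted(id(m) for m in seen) == sorted(id(m) for m in anchors)
            # validity: consecutive anchors satisfy the joining predicate
            for b in blocks:
                for prev, nxt in zip(b.anchors, b.anchors[1:]):
                    assert _chainable(prev, nxt, max_gap, max_drift)
                assert len({m.orientation for m in b.anchors}) == 1
            # optimality: as few blocks as any valid partition allows
            assert len(blocks) == _min_path_cover(anchors, max_gap, max_drift)

    def test_tabular_and_paf_export(self, rng):
        from asmcompare.anchors import anchors_table, anchors_to_paf

        s = random_seq(rng, 2_000)
        anchors = find_anchors(s, reverse_complement(s), 50)
        table = anchors_table(anchors)
        assert list(table.loc[0, ["startA", "endA"]]) == [1, 2_000]  # 1-based
        paf = anchors_to_paf(anchors, len(s), len(s))
        fields = paf.strip().split("\t")
        assert fields[4] == "-" and fields[2] == "0"  # PAF stays 0-based

    def test_blocks_sorted_by_a_span(self):
        rng = random.Random(7)
        anchors = _random_anchor_set(rng)
        blocks = chain_anchors(anchors)
        starts = [(b.a_span.seq_id, b.a_span.start, b.a_span.end) for b in blocks]
        assert starts == sorted(starts)
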