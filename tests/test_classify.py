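import pytest

from asmcompare.anchors import INVERTED, SAME, MatchSegment, SyntenyBlock
from asmcompare.classify import (
    DCM,
    INV,
    MDP,
    ODS,
    REPORTABLE,
    SUB_THRESHOLD,
    TEST_ELIGIBLE,
    Discordance,
    _eligibility,
    assign_code,
    assign_codes,
    classify_chromosome_pair,
    filter_gap_repeat,
    pair_odss,
)
from asmcompare.core import Assembly, Interval, Thresholds


def block(a0, a1, b0, b1, orientation=SAME):
    """A one-anchor synteny block covering [a0,a1) vs [b0,b1)."""
    strand = "+" if orientation == SAME else "-"
    m = MatchSegment(
        Interval("chr1", a0, a1, "+"), Interval("chr1", b0, b1, strand), orientation
    )
    return SyntenyBlock([m], orientation)


LEN = 3_000_000


class TestClassifyChromosomePair:
    def classify(self, blocks, **kw):
        return classify_chromosome_pair("chr1", blocks, LEN, LEN, Thresholds(), **kw)

    def test_clean_inversion(self):
        blocks = [
            block(0, 1_000_000, 0, 1_000_000),
            block(1_000_000, 1_600_000, 1_000_000, 1_600_000, INVERTED),
            block(1_600_000, LEN, 1_600_000, LEN),
        ]
        inv = [d for d in self.classify(blocks) if d.category == INV]
        assert len(inv) == 1
        assert inv[0].size == 600_000
        assert inv[0].eligibility == TEST_ELIGIBLE

    def test_displaced_block_is_mdp(self):
        blocks = [
            block(0, 1_000_000, 0, 1_000_000),
            # 250 kb block placed 1.2 Mb downstream on the B draft
            block(1_000_000, 1_250_000, 2_200_000, 2_450_000),
            block(1_250_000, 2_200_000, 1_000_000, 1_950_000),
        ]
        got = self.classify(blocks)
        mdp = [d for d in got if d.category == MDP]
        assert len(mdp) == 1
        assert mdp[0].size == 250_000
        assert mdp[0].eligibility == TEST_ELIGIBLE

    def test_small_offset_block_is_not_mdp(self):
        # displaced by less than its own length: still colinear slack
        blocks = [
            block(0, 1_000_000, 0, 1_000_000),
            block(1_000_000, 1_400_000, 1_100_000, 1_500_000),
            block(1_400_000, LEN, 1_500_000, LEN + 100_000),
        ]
        assert [d for d in self.classify(blocks) if d.category == MDP] == []

    def test_uncovered_region_is_ods_on_each_side(self):
        blocks = [
            block(0, 1_000_000, 0, 1_000_000),
            block(1_800_000, LEN, 1_400_000, LEN - 400_000),
        ]
        got = self.classify(blocks)
        ods_a = [d for d in got if d.category == ODS and d.source_assembly == "A"]
        ods_b = [d for d in got if d.category == ODS and d.source_assembly == "B"]
        assert [(d.a_locus.start, d.a_locus.end) for d in ods_a] == [(1_000_000, 1_800_000)]
        # the shorter B draft is uncovered both in the middle and at the tail
        assert [(d.b_locus.start, d.b_locus.end) for d in ods_b] == [
            (1_000_000, 1_400_000), (2_600_000, 3_000_000)]

    def test_noise_blocks_do_not_split_ods(self):
        blocks = [
            block(0, 1_000_000, 0, 1_000_000),
            block(1_200_000, 1_200_200, 2_500_000, 2_500_200),  # diverged-repeat noise
            block(1_800_000, LEN, 1_400_000, LEN - 400_000),
        ]
        ods_a = [d for d in self.classify(blocks)
                 if d.category == ODS and d.source_assembly == "A"]
        assert [(d.a_locus.start, d.a_locus.end) for d in ods_a] == [(1_000_000, 1_800_000)]

    def test_mismatched_pair_rejected(self):
        b = block(0, 1000, 0, 1000)
        with pytest.raises(ValueError):
            classify_chromosome_pair("chr2", [b], LEN, LEN, Thresholds())


class TestEligibilityBoundaries:
    """Strict size rules: reported when larger than 100 kbp, testable when
    larger than 200 kbp (MDP/DCM/ODS) or 500 kbp (INV)."""

    @pytest.mark.parametrize(
        "category,size,expected",
        [
            (INV, 90_000, SUB_THRESHOLD),
            (INV, 100_000, SUB_THRESHOLD),
            (INV, 101_000, REPORTABLE),
            (MDP, 199_000, REPORTABLE),
            (MDP, 200_000, REPORTABLE),
            (MDP, 201_000, TEST_ELIGIBLE),
            (DCM, 200_000, REPORTABLE),
            (DCM, 200_001, TEST_ELIGIBLE),
            (ODS, 100_001, REPORTABLE),
            (ODS, 200_001, TEST_ELIGIBLE),
            (INV, 499_000, REPORTABLE),
            (INV, 500_000, REPORTABLE),
            (INV, 501_000, TEST_ELIGIBLE),
        ],
    )
    def test_boundary(self, category, size, expected):
        assert _eligibility(category, size, Thresholds()) == expected

    def test_classified_events_land_in_bands(self):
        """Planted blocks of boundary sizes classify per the thresholds."""
        for size, expected in [(90_000, SUB_THRESHOLD), (101_000, REPORTABLE),
                               (501_000, TEST_ELIGIBLE)]:
            blocks = [
                block(0, 1_000_000, 0, 1_000_000),
                block(1_000_000, 1_000_000 + size, 1_000_000, 1_000_000 + size, INVERTED),
                block(1_000_000 + size, LEN, 1_000_000 + size, LEN),
            ]
            got = classify_chromosome_pair("chr1", blocks, LEN, LEN, Thresholds())
            (inv,) = [d for d in got if d.category == INV]
            assert inv.eligibility == expected, size


class TestCodes:
    def make(self, category, chrom, start, size=600_000):
        iv = Interval(chrom, start, start + size)
        if category == ODS:
            return Discordance(ODS, iv, None, size, source_assembly="A")
        return Discordance(category, iv, iv, size)

    @pytest.mark.parametrize(
        "category,chrom,start,expected",
        [
            (INV, "chr27", 42_300_000, "INV_27_42.3"),
            (MDP, "chr5", 9_600_000, "MDP_5_9.6"),
            (MDP, "chr28", 700_000, "MDP_28_0.7"),
            (INV, "chr20", 0 + 40_000, "INV_20_0"),  # sub-100-kb rounding
            (INV, "chr1", 53_300_000, "INV_1_53.3"),
            (ODS, "chr15", 15_900_000, "ODS_15_15.9"),
        ],
    )
    def test_code_strings(self, category, chrom, start, expected):
        assert assign_code(self.make(category, chrom, start)) == expected

    def test_dcm_code_reports_both_chromosomes(self):
        d = Discordance(
            DCM,
            Interval("chr3", 1_000_000, 1_400_000),
            Interval("chr13", 2_000_000, 2_400_000),
            400_000,
        )
        assert assign_code(d) == "DCM_3-13"

    def test_collision_suffixes(self):
        ds = [self.make(INV, "chr2", 1_010_000) for _ in range(3)]
        assign_codes(ds)
        assert [d.code for d in ds] == ["INV_2_1", "INV_2_1.2", "INV_2_1.3"]


class TestGapRepeatFilter:
    def assemble(self, seq):
        return Assembly("x", {"chr1": seq})

    def run(self, seq_a, locus):
        asm = self.assemble(seq_a)
        d = Discordance(ODS, locus, None, len(locus), source_assembly="A")
        kept, excluded = filter_gap_repeat([d], asm, asm, Thresholds())
        return kept, excluded, d

    def test_mostly_masked_excluded(self):
        seq = "a" * 900 + "G" * 100
        kept, excluded, d = self.run(seq, Interval("chr1", 0, 1000))
        assert excluded == [d] and d.gap_repeat_flag

    def test_clean_kept(self):
        kept, excluded, d = self.run("G" * 1000, Interval("chr1", 0, 1000))
        assert kept == [d] and not d.gap_repeat_flag

    def test_exactly_at_cutoff_kept(self):
        # strictly-greater rule: 75% masked is retained
        seq = "a" * 750 + "G" * 250
        kept, excluded, d = self.run(seq, Interval("chr1", 0, 1000))
        assert kept == [d]


def _seg(q0, q1, t_chrom, t0, t1):
    return MatchSegment(
        Interval("q", q0, q1, "+"), Interval(t_chrom, t0, t1, "+"), SAME
    )


class TestPairOdss:
    def ods(self, source, chrom, start, end):
        iv = Interval(chrom, start, end)
        if source == "A":
            return Discordance(ODS, iv, None, end - start, source_assembly="A")
        return Discordance(ODS, None, iv, end - start, source_assembly="B")

    def test_reciprocal_match_on_different_chromosomes_is_dcm(self):
        da = self.ods("A", "chr3", 0, 400_000)
        db = self.ods("B", "chr13", 100_000, 500_000)
        pa = {0: [_seg(0, 390_000, "chr13", 100_000, 490_000)]}
        pb = {0: [_seg(0, 390_000, "chr3", 0, 390_000)]}
        (dcm,) = pair_odss([da], [db], pa, pb)
        assert dcm.category == DCM
        assert da.dcm_partner is dcm and db.dcm_partner is dcm
        assert (dcm.a_locus.seq_id, dcm.b_locus.seq_id) == ("chr3", "chr13")

    def test_same_chromosome_never_pairs(self):
        da = self.ods("A", "chr3", 0, 400_000)
        db = self.ods("B", "chr3", 100_000, 500_000)
        pa = {0: [_seg(0, 390_000, "chr3", 100_000, 490_000)]}
        pb = {0: [_seg(0, 390_000, "chr3", 0, 390_000)]}
        assert pair_odss([da], [db], pa, pb) == []

    def test_disjoint_sets_give_no_dcm(self):
        da = self.ods("A", "chr3", 0, 400_000)
        db = self.ods("B", "chr13", 0, 400_000)
        assert pair_odss([da], [db], {0: []}, {0: []}) == []

    def test_one_sided_duplication_pattern(self):
        """An A-only ODS whose sequence maps to a different B chromosome
        (single copy there) becomes a one-sided DCM flagged duplicated-in-A."""
        da = self.ods("A", "chr3", 0, 300_000)
        pa = {0: [_seg(0, 295_000, "chr13", 1_000_000, 1_295_000)]}
        (dcm,) = pair_odss([da], [], pa, {})
        assert dcm.duplicated_in == "A"
        assert dcm.b_locus.seq_id == "chr13"
        assert da.dcm_partner is dcm

    def test_one_sided_requires_chromosome_target(self):
        da = self.ods("A", "chr3", 0, 300_000)
        pa = {0: [_seg(0, 295_000, "004.1", 0, 295_000)]}
        roles = {"004.1": "unassigned-scaffold"}
        assert pair_odss([da], [], pa, {}, target_roles_b=roles) == []
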