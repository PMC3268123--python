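import pytest

from asmcompare.anchors import AssemblyIndex
from asmcompare.classify import Discordance, INV, MDP
from asmcompare.core import Assembly, Interval, Thresholds, reverse_complement
from asmcompare.probes import (
    BACPlacement,
    EndHit,
    design_junction_pcr,
    in_silico_pcr,
    map_bes,
    plan_flanked_triplet,
    plan_inversion_test,
    select_probes_for_region,
)
from asmcompare.simulate import (
    BESClone,
    EventSpec,
    derive_assemblies,
    generate_bes_library,
    generate_true_genome,
)

from conftest import random_seq


def placement(clone_id, chrom, start, end, unique=(True, True), orientation_ok=True):
    h1 = EndHit(Interval(chrom, start, start + 500), "+", unique[0], 1, 0)
    h2 = EndHit(Interval(chrom, end - 500, end), "-", unique[1], 1, 0)
    insert = Interval(chrom, start, end) if orientation_ok else None
    return BACPlacement(clone_id, h1, h2, insert, orientation_ok)


class TestSelectionCriteria:
    """Every returned clone must satisfy the probe criteria: both ends
    unique, opposite orientation facing inward, span within 50-300 kb."""

    region = Interval("chr1", 1_000_000, 1_400_000)

    def run(self, cands):
        return select_probes_for_region(self.region, cands, Thresholds())

    @pytest.mark.parametrize(
        "span,accepted",
        [(49_999, False), (50_000, True), (120_000, True),
         (300_000, True), (300_001, False)],
    )
    def test_span_boundaries(self, span, accepted):
        p = placement("c", "chr1", 1_100_000, 1_100_000 + span)
        got = self.run([p])
        assert (p in got) == accepted

    def test_non_unique_end_rejected(self):
        p = placement("c", "chr1", 1_100_000, 1_250_000, unique=(True, False))
        assert self.run([p]) == []

    def test_wrong_orientation_rejected(self):
        p = placement("c", "chr1", 1_100_000, 1_250_000, orientation_ok=False)
        assert self.run([p]) == []

    def test_low_region_overlap_rejected(self):
        p = placement("c", "chr1", 1_380_000, 1_520_000)  # < 50% inside region
        assert self.run([p]) == []

    def test_sorted_by_centrality(self):
        near = placement("near", "chr1", 1_130_000, 1_270_000)
        far = placement("far", "chr1", 1_000_000, 1_140_000)
        assert self.run([far, near]) == [near, far]

    def test_all_returned_meet_criteria(self):
        cands = [
            placement("a", "chr1", 1_050_000, 1_200_000),
            placement("b", "chr1", 1_100_000, 1_140_000),  # span 40 kb
            placement("c", "chr1", 1_000_000, 1_450_000),  # span 450 kb
            placement("d", "chr1", 1_150_000, 1_300_000, unique=(False, True)),
        ]
        got = self.run(cands)
        assert [p.clone_id for p in got] == ["a"]
        assert all(p.meets_criteria(Thresholds()) for p in got)


@pytest.fixture(scope="module")
def bes_genome():
    g = generate_true_genome(
        2, [500_000, 500_000], repeat_family_count=1, repeat_copies=10,
        seed=31, repeat_noise=0.01, segdup_families=0,
    )
    return g, AssemblyIndex(g)


class TestMapBes:
    @pytest.fixture()
    def genome(self, bes_genome):
        return bes_genome

    def test_unique_clone_maps_with_span(self, genome):
        g, idx = genome
        seq = g.sequences["chr1"]
        # a window whose two 500-bp extremities are clean unique sequence
        start = next(
            s for s in range(50_000, 400_000, 5_000)
            if seq[s : s + 500].isupper() and seq[s + 59_500 : s + 60_000].isupper()
        )
        clone = BESClone(
            "c1",
            seq[start : start + 500],
            reverse_complement(seq[start + 59_500 : start + 60_000]),
            Interval("chr1", start, start + 60_000),
        )
        p = map_bes(clone, idx)
        assert p.end1.unique and p.end2.unique and p.orientation_ok
        assert p.span == 60_000
        assert p.meets_criteria(Thresholds())

    def test_end_in_repeat_family_not_unique(self, genome):
        g, idx = genome
        import re

        runs = [
            (c, m.start(), m.end())
            for c in g.chromosomes
            for m in re.finditer(r"[a-z]{1000,}", g.sequences[c])
        ]
        assert len(runs) >= 2
        c, s, _e = runs[0]
        end1 = g.sequences[c][s : s + 500]  # inside a 10-copy repeat family
        end2 = reverse_complement(g.sequences[c][s + 100_000 : s + 100_500])
        p = map_bes(BESClone("c2", end1, end2, Interval(c, s, s + 100_500)), idx)
        assert not p.end1.unique
        assert p.end1.n_hits >= 2

    def test_ends_on_different_chromosomes_give_no_insert(self, genome):
        g, idx = genome
        end1 = g.sequences["chr1"][200_000 : 200_500]
        end2 = reverse_complement(g.sequences["chr2"][200_000 : 200_500]).upper()
        p = map_bes(BESClone("c3", end1, end2, Interval("chr1", 0, 1)), idx)
        assert p.insert is None and not p.orientation_ok
        assert p.end1.locus.seq_id != p.end2.locus.seq_id

    def test_unmappable_end(self, genome, rng):
        g, idx = genome
        end1 = g.sequences["chr1"][100_000 : 100_500]
        p = map_bes(BESClone("c4", end1, random_seq(rng, 500), Interval("chr1", 0, 1)), idx)
        assert p.end2.locus is None


class TestTriplets:
    def make_inv(self, eligibility="test-eligible"):
        iv = Interval("chr1", 1_000_000, 1_600_000)
        return Discordance(INV, iv, iv, 600_000, eligibility=eligibility, code="INV_1_1")

    def library(self):
        # inside probes at varying asymmetry plus flanks
        return {
            p.clone_id: p
            for p in [
                placement("in_center", "chr1", 1_220_000, 1_380_000),
                placement("in_left", "chr1", 1_020_000, 1_170_000),
                placement("fl", "chr1", 830_000, 990_000),
                placement("fr", "chr1", 1_620_000, 1_790_000),
            ]
        }

    def test_geometry_and_off_center_preference(self):
        inv = self.make_inv()
        plan = plan_inversion_test(inv, self.library(), Thresholds())
        assert plan.feasible
        roles = dict((r, p.clone_id) for r, p in plan.probes)
        assert roles["inside"] == "in_left"  # off-center preferred
        inserts = [p.insert for _r, p in plan.probes]
        for i in range(3):
            for j in range(i + 1, 3):
                assert inserts[i].overlap(inserts[j]) == 0
        inside = next(p for r, p in plan.probes if r == "inside")
        assert inv.a_locus.start <= inside.insert.start
        assert inside.insert.end <= inv.a_locus.end

    def test_not_eligible_rejected(self):
        inv = self.make_inv()
        inv.eligibility = "reportable"
        inv.size = 450_000
        with pytest.raises(ValueError):
            plan_inversion_test(inv, self.library(), Thresholds())

    def test_empty_library_infeasible(self):
        plan = plan_inversion_test(self.make_inv(), {}, Thresholds())
        assert not plan.feasible and plan.probes == []

    def test_avoid_zone_rejects_bridging_flank(self):
        inv = self.make_inv()
        avoid = [Interval("chr1", 995_000, 999_000)]  # discordance in the left gap
        plan = plan_inversion_test(inv, self.library(), Thresholds(), avoid=avoid)
        assert not plan.feasible  # only left flank candidate bridges the zone


class TestReferencePanel:
    def blocks(self):
        from asmcompare.anchors import INVERTED, SAME, MatchSegment, SyntenyBlock
        from asmcompare.core import Interval as Iv

        def blk(chrom, a0, a1, b0, b1, orientation=SAME):
            strand = "+" if orientation == SAME else "-"
            m = MatchSegment(Iv(chrom, a0, a1, "+"), Iv(chrom, b0, b1, strand),
                             orientation)
            return SyntenyBlock([m], orientation)

        return {
            # chr1: large concordant block (identical positions in both drafts)
            "chr1": [blk("chr1", 0, 900_000, 0, 900_000)],
            # chr2: same orientation but offset beyond the 99% agreement rule
            "chr2": [blk("chr2", 0, 900_000, 300_000, 1_200_000)],
            # chr3: fully inverted
            "chr3": [blk("chr3", 0, 900_000, 0, 900_000, INVERTED)],
        }

    def test_one_concordant_clone_per_chromosome(self):
        from asmcompare.probes import build_reference_panel

        placements = {
            p.clone_id: p
            for p in [
                placement("r1", "chr1", 300_000, 450_000),
                placement("r2", "chr2", 300_000, 450_000),
                placement("r3", "chr3", 300_000, 450_000),
            ]
        }
        panel = build_reference_panel(self.blocks(), placements, Thresholds())
        assert panel["chr1"].clone_id == "r1"
        # offset and inverted chromosomes have no concordant candidate
        assert panel["chr2"] is None and panel["chr3"] is None
        chosen = [p for p in panel.values() if p is not None]
        assert len({p.insert.seq_id for p in chosen}) == len(chosen)


@pytest.fixture(scope="module")
def mdp_case():
    true = generate_true_genome(1, [600_000], 0, 0, seed=41, segdup_families=0)
    ev = [EventSpec("relocation", Interval("chr1", 100_000, 160_000), "A",
                    Interval("chr1", 400_000, 400_001))]
    a, b, truth = derive_assemblies(true, ev)
    a.name, b.name = "A", "B"
    row = truth[0]
    mdp = Discordance(MDP, row.a_locus, row.b_locus, 60_000, code="MDP_1_0.3")
    return true, a, b, mdp


class TestJunctionPCR:

    def test_correct_draft_amplifies(self, mdp_case):
        true, a, b, mdp = mdp_case
        assays = design_junction_pcr(mdp, a, b, Thresholds())
        assert set(assays) == {"A", "B"}
        assert all(x.feasible for x in assays.values())
        hits = {
            name: in_silico_pcr(x, true, Thresholds().pcr_amplicon_max)
            for name, x in assays.items()
        }
        # the relocation was applied to A, so the true genome matches B
        assert hits["B"] and not hits["A"]
        # each assay amplifies on its own draft by construction
        assert in_silico_pcr(assays["A"], a, Thresholds().pcr_amplicon_max)

    def test_truth_matching_neither_draft_is_double_negative(self):
        """The same segment placed at three different positions: in the true
        genome, in draft A, and in draft B; both junction assays must fail."""
        true = generate_true_genome(1, [600_000], 0, 0, seed=43, segdup_families=0)
        seg = Interval("chr1", 100_000, 160_000)
        ev_a = EventSpec("relocation", seg, "A", Interval("chr1", 400_000, 400_001))
        ev_b = EventSpec("relocation", seg, "B", Interval("chr1", 500_000, 500_001))
        a, b, truth = derive_assemblies(true, [ev_a, ev_b])
        a.name, b.name = "A", "B"
        mdp = Discordance(MDP, truth[0].a_locus, truth[1].b_locus, 60_000)
        assays = design_junction_pcr(mdp, a, b, Thresholds())
        for x in assays.values():
            assert x.feasible
            assert in_silico_pcr(x, true, Thresholds().pcr_amplicon_max) == []

    def test_oversize_amplicon_infeasible(self, mdp_case):
        _true, a, b, mdp = mdp_case
        tight = Thresholds(pcr_amplicon_max=100)
        assays = design_junction_pcr(mdp, a, b, tight)
        assert not any(x.feasible for x in assays.values())
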