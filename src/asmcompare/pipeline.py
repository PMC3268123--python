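"""End-to-end orchestration: compare two drafts, design probes, simulate
FISH/PCR, and decide which draft each discordance supports.

The programmatic entry points are :func:`compare_assemblies` (in-memory)
and :func:`run_compare` / :func:`run_simulate` (file-based, used by the
command line).  Homologous chromosomes are paired by identical sequence id;
a name mismatch is an error listing the unpaired names, never a silent
drop.  All emitted tables are deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .anchors import AssemblyIndex, SeqHash, anchors_between, anchors_table, chain_anchors
from .classify import (
    DCM,
    INV,
    MDP,
    ODS,
    Discordance,
    assign_codes,
    classify_discordances,
    discordance_table,
    filter_gap_repeat,
    finalize_eligibility,
    pair_odss,
)
from .core import Assembly, Interval, Thresholds, read_fasta, write_fasta
from .fish import (
    Hypothesis,
    Verdict,
    decide,
    probe_loci,
    simulate_interphase_triplet,
    simulate_metaphase,
)
from .placement import PlacementReport, place_scaffold, placement_table
from .probes import (
    BACPlacement,
    PCRAssay,
    ProbePlan,
    design_junction_pcr,
    in_silico_pcr,
    map_library,
    build_reference_panel,
    plan_flanked_triplet,
    plan_inversion_test,
    probe_table,
    select_probes_for_region,
)
from .simulate import (
    BESClone,
    BESLibrary,
    derive_assemblies,
    generate_bes_library,
    generate_true_genome,
    standard_event_suite,
)

log = logging.getLogger("asmcompare")

TEST_ELIGIBLE = "test-eligible"


class PairingError(ValueError):
    """The chromosome name sets of the two drafts differ."""


@dataclass
class AnchorParams:
    min_anchor: int = 50
    max_gap: int = 50_000
    max_drift: int = 20_000


@dataclass
class SimParams:
    disorder_p: float = 0.15
    p_drop: float = 0.05


@dataclass
class TestRecord:
    """One row of the disambiguation summary (Table-1 layout)."""

    code: str
    category: str
    test: str  # FISH/int | FISH/met | PCR | -
    verdict: Verdict | None
    note: str = ""

    @property
    def supported(self) -> str:
        return self.verdict.formatted() if self.verdict is not None else "-"


@dataclass
class ComparisonResult:
    asm_a: Assembly
    asm_b: Assembly
    anchors_by_chrom: dict
    blocks_by_chrom: dict
    discordances: list[Discordance]
    kept: list[Discordance]
    excluded: list[Discordance]
    scaffold_reports: list[PlacementReport]
    ods_crosslinks: dict[str, list[str]]  # ODS code -> scaffold ids ([] = NS)
    bes_a: dict[str, BACPlacement]
    bes_b: dict[str, BACPlacement]
    probe_plans: list[ProbePlan]
    reference_panel: dict[str, BACPlacement | None]
    pcr_assays: dict[str, dict[str, PCRAssay]]
    tests: list[TestRecord]

    def category_counts(self) -> dict[str, int]:
        """Reportable discordances per category; DCM member ODSs are counted
        once, under DCM."""
        counts = {INV: 0, MDP: 0, ODS: 0, DCM: 0}
        for d in self.discordances:
            if d.eligibility == "sub-threshold":
                continue
            if d.category == ODS and d.dcm_partner is not None:
                continue
            counts[d.category] += 1
        return counts


def _paired_chromosomes(asm_a: Assembly, asm_b: Assembly) -> list[str]:
    ca, cb = set(asm_a.chromosomes), set(asm_b.chromosomes)
    if ca != cb:
        raise PairingError(
            f"unpaired chromosomes: only in {asm_a.name}: {sorted(ca - cb)}; "
            f"only in {asm_b.name}: {sorted(cb - ca)}"
        )
    return list(asm_a.chromosomes)


def compare_assemblies(
    asm_a: Assembly,
    asm_b: Assembly,
    bes_library: BESLibrary | None = None,
    true_genome: Assembly | None = None,
    thresholds: Thresholds | None = None,
    anchor: AnchorParams | None = None,
    sim: SimParams | None = None,
    seed: int = 0,
) -> ComparisonResult:
    """Run the full comparison pipeline in memory.

    ``true_genome`` plays the role of the assembly-independent experiment
    (FISH on real chromosomes / PCR on genomic DNA): without it the
    pipeline stops after probe design and the summary carries no verdicts.
    """
    thresholds = thresholds or Thresholds()
    anchor = anchor or AnchorParams()
    sim = sim or SimParams()
    log.info("thresholds: %s", thresholds)
    log.info("simulation parameters: %s; seed=%d", sim, seed)
    chroms = _paired_chromosomes(asm_a, asm_b)

    # --- stage 1: anchors and synteny blocks per homologous pair
    log.info("anchoring %d chromosome pairs (min_anchor=%d, max_gap=%d, max_drift=%d)",
             len(chroms), anchor.min_anchor, anchor.max_gap, anchor.max_drift)
    cache_a: dict[str, SeqHash] = {}
    cache_b: dict[str, SeqHash] = {}
    anchors_by = {}
    blocks_by = {}
    for chrom in chroms:
        cache_a[chrom] = SeqHash(chrom, asm_a.sequences[chrom])
        cache_b[chrom] = SeqHash(chrom, asm_b.sequences[chrom])
        ms = anchors_between(cache_a[chrom], cache_b[chrom], anchor.min_anchor)
        anchors_by[chrom] = ms
        blocks_by[chrom] = chain_anchors(ms, anchor.max_gap, anchor.max_drift)

    index_a = AssemblyIndex(asm_a, cache_a)
    index_b = AssemblyIndex(asm_b, cache_b)

    # --- stage 2: classification and DCM pairing
    discordances = classify_discordances(blocks_by, asm_a, asm_b, thresholds)
    ods_a = [d for d in discordances if d.category == ODS and d.source_assembly == "A"]
    ods_b = [d for d in discordances if d.category == ODS and d.source_assembly == "B"]
    # cross-placement of each ODS sequence on the other draft (stride: only
    # multi-kb matches are relevant to the 50% reciprocal-coverage rule)
    pl_a = {
        i: index_b.query(asm_a.fetch(d.defining_locus), anchor.min_anchor, stride=256)
        for i, d in enumerate(ods_a)
    }
    pl_b = {
        i: index_a.query(asm_b.fetch(d.defining_locus), anchor.min_anchor, stride=256)
        for i, d in enumerate(ods_b)
    }
    dcms = pair_odss(
        ods_a, ods_b, pl_a, pl_b,
        {s: asm_a.roles[s] for s in asm_a.sequences},
        {s: asm_b.roles[s] for s in asm_b.sequences},
    )
    finalize_eligibility(dcms, thresholds)
    discordances = discordances + dcms
    assign_codes(discordances)
    kept, excluded = filter_gap_repeat(discordances, asm_a, asm_b, thresholds)

    # --- stage 3: scaffold placement and ODS/ChrUn crosslinks
    scaffold_reports = []
    for sid in asm_a.scaffolds:
        scaffold_reports.append(
            place_scaffold(sid, asm_a.sequences[sid], index_b, thresholds,
                           anchor.min_anchor, anchor.max_gap, anchor.max_drift)
        )
    for sid in asm_b.scaffolds:
        scaffold_reports.append(
            place_scaffold(sid, asm_b.sequences[sid], index_a, thresholds,
                           anchor.min_anchor, anchor.max_gap, anchor.max_drift)
        )
    from .placement import crosslink_ods_chrun

    crosslinks: dict[str, list[str]] = {}
    for ods_list, source_asm, other_asm in ((ods_a, asm_a, asm_b), (ods_b, asm_b, asm_a)):
        seqs = [source_asm.fetch(d.defining_locus) for d in ods_list]
        scaffolds = {sid: other_asm.sequences[sid] for sid in other_asm.scaffolds}
        links = crosslink_ods_chrun(ods_list, seqs, scaffolds, anchor.min_anchor)
        for i, d in enumerate(ods_list):
            crosslinks[d.code] = links[i]

    # --- stage 4: BES mapping and probe plans
    bes_pa: dict[str, BACPlacement] = {}
    bes_pb: dict[str, BACPlacement] = {}
    plans: list[ProbePlan] = []
    panel: dict[str, BACPlacement | None] = {}
    assays: dict[str, dict[str, PCRAssay]] = {}
    if bes_library is not None:
        log.info("mapping %d BES pairs on both drafts", len(bes_library))
        bes_pa = map_library(bes_library, index_a, anchor.min_anchor)
        bes_pb = map_library(bes_library, index_b, anchor.min_anchor)
        panel = build_reference_panel(blocks_by, bes_pa, thresholds)
        avoid_by_chrom = _discordant_loci_in_a(discordances, blocks_by)
        for d in kept:
            if d.eligibility != TEST_ELIGIBLE:
                continue
            if d.category == INV:
                avoid = _avoid_for(d, avoid_by_chrom)
                plans.append(_informative_triplet(
                    lambda ex, d=d, avoid=avoid: plan_inversion_test(
                        d, bes_pa, thresholds, exclude=ex, avoid=avoid),
                    asm_a, index_a, index_b, thresholds,
                ))
            elif d.category == MDP:
                disp = abs(
                    (d.b_locus.start + d.b_locus.end) / 2
                    - (d.a_locus.start + d.a_locus.end) / 2
                )
                if disp >= 1_000_000:
                    avoid = _avoid_for(d, avoid_by_chrom)
                    plans.append(_informative_triplet(
                        lambda ex, d=d, avoid=avoid: plan_flanked_triplet(
                            d, bes_pa, thresholds, exclude=ex, avoid=avoid),
                        asm_a, index_a, index_b, thresholds,
                    ))
                else:
                    assays[d.code] = design_junction_pcr(d, asm_a, asm_b, thresholds)
                    plans.append(ProbePlan(d.code, "PCR", [], feasible=all(
                        a.feasible for a in assays[d.code].values()
                    )))
            elif d.category == DCM:
                probes = select_probes_for_region(d.a_locus, bes_pa, thresholds)
                if probes:
                    plans.append(ProbePlan(d.code, "FISH-metaphase",
                                           [("inside", probes[0])], feasible=True))
                else:
                    probes = select_probes_for_region(d.b_locus, bes_pb, thresholds)
                    if probes:
                        plans.append(ProbePlan(d.code, "FISH-metaphase",
                                               [("inside", probes[0])], feasible=True,
                                               note="probe selected on draft B",
                                               draft="B"))
                    else:
                        plans.append(ProbePlan(d.code, "FISH-metaphase", [],
                                               feasible=False, note="no qualifying clone"))
        # scaffold validation probes (the ChrUn protocol)
        for rep in scaffold_reports:
            sid = rep.scaffold_id
            owner, own_pl, own_draft = (
                (asm_a, bes_pa, "A") if sid in asm_a.sequences else (asm_b, bes_pb, "B")
            )
            if owner.length(sid) <= thresholds.test_min_mdp_dcm:
                continue
            region = Interval(sid, 0, owner.length(sid))
            probes = select_probes_for_region(region, own_pl, thresholds)
            if probes:
                plans.append(ProbePlan(f"ChrUn_{sid}", "FISH-metaphase",
                                       [("inside", probes[0])], feasible=True,
                                       draft=own_draft))
            else:
                plans.append(ProbePlan(f"ChrUn_{sid}", "FISH-metaphase", [],
                                       feasible=False, note="no qualifying clone"))

    # --- stage 5: simulated FISH / PCR and verdicts
    tests: list[TestRecord] = []
    if true_genome is not None and bes_library is not None:
        true_index = AssemblyIndex(true_genome)
        rng = np.random.SeedSequence(seed)
        children = iter(rng.spawn(len(plans) + 1))
        by_code = {d.code: d for d in discordances}
        for plan in sorted(plans, key=lambda p: p.target_code):
            child_seed = int(next(children).generate_state(1)[0] % (2**31))
            tests.append(
                _run_test(
                    plan, by_code.get(plan.target_code), asm_a, asm_b,
                    index_a, index_b, true_index, assays,
                    thresholds, sim, child_seed, scaffold_reports,
                )
            )
    return ComparisonResult(
        asm_a, asm_b, anchors_by, blocks_by, discordances, kept, excluded,
        scaffold_reports, crosslinks, bes_pa, bes_pb, plans, panel, assays, tests,
    )


def _probe_seq(asm: Assembly, placement: BACPlacement) -> str:
    return asm.fetch(placement.insert)


def _discordant_loci_in_a(
    discordances: list[Discordance], blocks_by_chrom: dict
) -> dict[str, list[tuple[Interval, Discordance]]]:
    """Every discordant locus expressed in draft-A chromosome coordinates.

    A B-only ODS (sequence missing from A) is projected to its A insertion
    point: the end of the last colinear block upstream of the B locus.
    Inter-probe distances across any of these loci differ between drafts,
    so probe planning must not bridge them."""
    out: dict[str, list[tuple[Interval, Discordance]]] = {}
    for d in discordances:
        if d.a_locus is not None and not d.a_locus.seq_id.startswith(("004.", "scaffold")):
            out.setdefault(d.a_locus.seq_id, []).append((d.a_locus, d))
        elif d.b_locus is not None:
            chrom = d.b_locus.seq_id
            point = None
            for blk in blocks_by_chrom.get(chrom, []):
                if blk.orientation == "same" and blk.b_span.end <= d.b_locus.start + 1_000:
                    if point is None or blk.a_span.end > point:
                        point = blk.a_span.end
            if point is not None:
                out.setdefault(chrom, []).append(
                    (Interval(chrom, max(0, point - 2), point + 2), d)
                )
    return out


def _avoid_for(
    d: Discordance, avoid_by_chrom: dict[str, list[tuple[Interval, Discordance]]]
) -> list[Interval]:
    chrom = d.a_locus.seq_id if d.a_locus is not None else None
    if chrom is None:
        return []
    return [iv for iv, other in avoid_by_chrom.get(chrom, []) if other is not d]


def _informative_triplet(
    build,
    asm_a: Assembly,
    index_a: AssemblyIndex,
    index_b: AssemblyIndex,
    thresholds: Thresholds,
    max_retries: int = 5,
) -> ProbePlan:
    """Build a triplet plan whose predicted arrangements differ between the
    two drafts, re-planning with the inside probe excluded when a candidate
    triplet happens to be uninformative (e.g. the inside probe sits at the
    exact center of an inversion)."""
    exclude: set[str] = set()
    plan = build(exclude)
    for _ in range(max_retries):
        if not plan.feasible:
            return plan
        triplet = [(role, _probe_seq(asm_a, p)) for role, p in plan.probes]
        oa = _order_from_seqs(triplet, index_a, thresholds)
        ob = _order_from_seqs(triplet, index_b, thresholds)
        if oa is None or ob is None or oa != ob:
            return plan
        inside = next(p for role, p in plan.probes if role == "inside")
        exclude.add(inside.clone_id)
        plan = build(exclude)
    if plan.feasible:
        plan.note = (plan.note + "; predictions coincide").strip("; ")
    return plan


def _chrom_prediction(
    probe_seq: str, index: AssemblyIndex, thresholds: Thresholds, min_anchor: int = 50
) -> tuple[str, ...]:
    """Chromosome multiset a draft predicts for a probe (scaffold loci do
    not produce chromosome signals)."""
    asm = index.assembly
    loci = probe_loci(probe_seq, index, thresholds, min_anchor)
    return tuple(sorted(sid for sid, _s, _e in loci if asm.roles[sid] == "chromosome"))


def _run_test(
    plan: ProbePlan,
    disc: Discordance | None,
    asm_a: Assembly,
    asm_b: Assembly,
    index_a: AssemblyIndex,
    index_b: AssemblyIndex,
    true_index: AssemblyIndex,
    assays: dict[str, dict[str, PCRAssay]],
    thresholds: Thresholds,
    sim: SimParams,
    seed: int,
    scaffold_reports: list[PlacementReport],
) -> TestRecord:
    category = disc.category if disc is not None else "ChrUn"
    if plan.assay == "PCR":
        pair = assays.get(plan.target_code, {})
        if not pair or not any(a.feasible for a in pair.values()):
            return TestRecord(plan.target_code, category, "PCR", None, "assay infeasible")
        results = {
            name: bool(in_silico_pcr(a, true_index.assembly, thresholds.pcr_amplicon_max))
            for name, a in pair.items()
        }
        names = list(results)
        pos = [n for n, hit in results.items() if hit]
        if len(pos) == 1:
            verdict = Verdict(pos[0], 1.0, 1)
        elif len(pos) == 2:
            verdict = Verdict("both-consistent", 1.0, 1)
        else:
            verdict = Verdict("neither", 0.0, 1)
        return TestRecord(plan.target_code, category, "PCR", verdict)

    short = {"FISH-interphase": "FISH/int", "FISH-metaphase": "FISH/met"}
    if not plan.feasible:
        return TestRecord(plan.target_code, category, short.get(plan.assay, plan.assay),
                          None, plan.note or "no probes")

    if plan.assay == "FISH-interphase":
        # probe DNA is physical: fetch it from the draft the plan was
        # selected on (A), then locate it independently on each draft
        triplet = [(role, _probe_seq(asm_a, p)) for role, p in plan.probes]
        order_a = _order_from_seqs(triplet, index_a, thresholds)
        order_b = _order_from_seqs(triplet, index_b, thresholds)
        if order_a is None or order_b is None:
            return TestRecord(plan.target_code, category, "FISH/int", None,
                              "probe unmappable on one draft")
        counts = simulate_interphase_triplet(
            triplet, true_index, thresholds.interphase_nuclei,
            disorder_p=sim.disorder_p, seed=seed, thresholds=thresholds,
        )
        verdict = decide(counts, Hypothesis(asm_a.name, order_a), Hypothesis(asm_b.name, order_b))
        return TestRecord(plan.target_code, category, "FISH/int", verdict)

    # metaphase
    role, probe = plan.probes[0]
    owner = asm_a if plan.draft == "A" else asm_b
    seq = _probe_seq(owner, probe)
    pred_a = _chrom_prediction(seq, index_a, thresholds)
    pred_b = _chrom_prediction(seq, index_b, thresholds)
    obs = simulate_metaphase(
        [(plan.target_code, seq)], true_index, thresholds.metaphase_cells,
        thresholds, seed=seed, p_drop=sim.p_drop,
    )
    verdict = decide(obs, Hypothesis(asm_a.name, pred_a), Hypothesis(asm_b.name, pred_b))
    # collapsed-duplication surveillance: more true loci than either draft predicts
    n_true = len(probe_loci(seq, true_index, thresholds))
    if plan.target_code.startswith("ChrUn_"):
        sid = plan.target_code[len("ChrUn_"):]
        for rep in scaffold_reports:
            if rep.scaffold_id == sid and n_true > max(len(pred_a), len(pred_b), 1):
                rep.collapse_suspect = True
    return TestRecord(plan.target_code, category, "FISH/met", verdict)


def _order_from_seqs(
    probe_seqs: list[tuple[str, str]],
    index: AssemblyIndex,
    thresholds: Thresholds,
) -> tuple[str, ...] | None:
    """Predicted interphase signal arrangement on one draft: each probe
    sequence is located on the draft by homology, then the canonical
    arrangement of the three midpoints is taken.  None when a probe is
    unmappable or the probes span several chromosomes."""
    from .fish import arrangement

    positions = {}
    chroms = set()
    asm = index.assembly
    for label, seq in probe_seqs:
        loci = [
            l for l in probe_loci(seq, index, thresholds)
            if asm.roles[l[0]] == "chromosome"
        ]
        if not loci:
            return None
        sid, s, e = max(loci, key=lambda l: l[2] - l[1])
        chroms.add(sid)
        positions[label] = (s + e) // 2
    if len(chroms) != 1:
        return None
    return arrangement(positions)


# --------------------------------------------------------------------------
# File-based pipeline

@dataclass
class SimConfig:
    """Parameters of a synthetic study (``simulate`` subcommand)."""

    n_chrom: int = 8
    chrom_length: int = 2_000_000
    repeat_families: int = 2
    repeat_copies: int = 40
    repeat_noise: float = 0.01
    segdup_families: int = 1
    segdup_copies: int = 6
    segdup_len: int = 30_000
    n_clones: int = 300
    bes_end_len: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunConfig:
    """Paths and parameters of a comparison run (``compare`` subcommand)."""

    assembly_a: str
    assembly_b: str
    bes_tsv: str | None = None
    truth_fasta: str | None = None
    out_dir: str = "asmcompare_out"
    thresholds: Thresholds = field(default_factory=Thresholds)
    anchor: AnchorParams = field(default_factory=AnchorParams)
    sim: SimParams = field(default_factory=SimParams)
    seed: int = 0


def read_bes_tsv(path) -> BESLibrary:
    df = pd.read_csv(path, sep="\t")
    clones = [
        BESClone(
            str(r.clone_id),
            str(r.end1),
            str(r.end2),
            Interval.from_report(str(r.true_seq), int(r.true_start), int(r.true_end)),
        )
        for r in df.itertuples()
    ]
    return BESLibrary(clones)


def run_simulate(config: SimConfig, out_dir) -> tuple[Assembly, Assembly, Assembly, object, BESLibrary]:
    """Generate a synthetic study bundle and write it under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    true = generate_true_genome(
        config.n_chrom,
        [config.chrom_length] * config.n_chrom,
        config.repeat_families,
        config.repeat_copies,
        seed=config.seed,
        repeat_noise=config.repeat_noise,
        segdup_families=config.segdup_families,
        segdup_copies=config.segdup_copies,
        segdup_len=config.segdup_len,
    )
    events = standard_event_suite(true, seed=config.seed)
    asm_a, asm_b, truth = derive_assemblies(true, events, seed=config.seed)
    asm_a.name, asm_b.name = "A", "B"
    library = generate_bes_library(
        true, config.n_clones, end_len=config.bes_end_len, seed=config.seed
    )
    write_fasta(true, out / "true.fa")
    write_fasta(asm_a, out / "assemblyA.fa")
    write_fasta(asm_b, out / "assemblyB.fa")
    truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    library.to_frame().to_csv(out / "bes.tsv", sep="\t", index=False)
    with open(out / "bes.fa", "w") as fh:
        for c in library:
            fh.write(f">{c.clone_id}.1\n{c.end1}\n>{c.clone_id}.2\n{c.end2}\n")
    log.info("simulated bundle with %d events written to %s", len(events), out)
    return true, asm_a, asm_b, truth, library


def write_result(result: ComparisonResult, out_dir) -> None:
    """Write every report table of a comparison run (1-based coordinates)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_anchors = [m for chrom in result.anchors_by_chrom for m in result.anchors_by_chrom[chrom]]
    anchors_table(all_anchors).to_csv(out / "anchors.tsv", sep="\t", index=False)

    rows = []
    for chrom in result.blocks_by_chrom:
        for b in result.blocks_by_chrom[chrom]:
            rows.append((chrom, b.orientation, b.a_span.start + 1, b.a_span.end,
                         b.b_span.start + 1, b.b_span.end, len(b.anchors), b.anchor_bp))
    pd.DataFrame(rows, columns=["chrom", "orient", "startA", "endA", "startB", "endB",
                                "n_anchors", "anchor_bp"]).to_csv(
        out / "blocks.tsv", sep="\t", index=False)

    dtable = discordance_table(result.discordances)
    dtable["chrun_match"] = [
        (",".join(result.ods_crosslinks[c]) or "NS") if c in result.ods_crosslinks else "-"
        for c in dtable["code"]
    ]
    dtable.to_csv(out / "discordances.tsv", sep="\t", index=False)
    placement_table(result.scaffold_reports).to_csv(out / "placements.tsv", sep="\t", index=False)
    probe_table(result.probe_plans).to_csv(out / "probes.tsv", sep="\t", index=False)

    rows = []
    for code, pair in sorted(result.pcr_assays.items()):
        for name, a in pair.items():
            site = a.fwd_site.to_report() if a.fwd_site else ("-", 0, 0)
            rsite = a.rev_site.to_report() if a.rev_site else ("-", 0, 0)
            rows.append((code, name, *site, *rsite, a.predicted_amplicon or 0,
                         int(a.feasible), a.note))
    pd.DataFrame(rows, columns=["target", "hypothesis", "fwd_seq", "fwd_start", "fwd_end",
                                "rev_seq", "rev_start", "rev_end", "amplicon",
                                "feasible", "note"]).to_csv(
        out / "assays.tsv", sep="\t", index=False)

    rows = [
        (t.code, t.category, t.test, t.supported,
         "" if t.verdict is None else t.verdict.n_cells, t.note)
        for t in result.tests
    ]
    pd.DataFrame(rows, columns=["code", "category", "test", "supported_draft",
                                "n_cells", "note"]).to_csv(
        out / "fish_results.tsv", sep="\t", index=False)

    counts = result.category_counts()
    with open(out / "summary.txt", "w") as fh:
        fh.write(f"assemblies: {result.asm_a.name} vs {result.asm_b.name}\n")
        fh.write("reportable discordances (DCM members counted once):\n")
        for cat in (INV, MDP, ODS, DCM):
            fh.write(f"  {cat}: {counts[cat]}\n")
        fh.write(f"excluded as gap/repeat: {len(result.excluded)}\n")
        fh.write(f"scaffold placements: {len(result.scaffold_reports)}\n")
        fh.write(f"tests simulated: {len(result.tests)}\n")
        for t in result.tests:
            fh.write(f"  {t.code}\t{t.test}\t{t.supported}\n")


def run_synthetic_replicate(
    seed: int,
    config: SimConfig | None = None,
    thresholds: Thresholds | None = None,
    sim: SimParams | None = None,
):
    """One full in-memory study: synthetic genome, derived drafts, BES
    library, comparison, probe design, and simulated FISH/PCR.

    Returns ``(true_genome, truth_table, result)``; the standard study
    conditions are eight 2-Mbp chromosomes with 12 planted events and a
    300-clone BES library."""
    config = config or SimConfig()
    true = generate_true_genome(
        config.n_chrom,
        [config.chrom_length] * config.n_chrom,
        config.repeat_families,
        config.repeat_copies,
        seed=seed,
        repeat_noise=config.repeat_noise,
        segdup_families=config.segdup_families,
        segdup_copies=config.segdup_copies,
        segdup_len=config.segdup_len,
    )
    events = standard_event_suite(true, seed=seed)
    asm_a, asm_b, truth = derive_assemblies(true, events, seed=seed)
    asm_a.name, asm_b.name = "A", "B"
    library = generate_bes_library(
        true, config.n_clones, end_len=config.bes_end_len, seed=seed
    )
    result = compare_assemblies(
        asm_a, asm_b, library, true, thresholds=thresholds, sim=sim, seed=seed
    )
    return true, truth, result


def run_compare(config: RunConfig) -> ComparisonResult:
    """Load inputs, run :func:`compare_assemblies`, write the report bundle."""
    asm_a = read_fasta(config.assembly_a, name="A")
    asm_b = read_fasta(config.assembly_b, name="B")
    bes = read_bes_tsv(config.bes_tsv) if config.bes_tsv else None
    true = read_fasta(config.truth_fasta, name="true") if config.truth_fasta else None
    result = compare_assemblies(
        asm_a, asm_b, bes, true,
        thresholds=config.thresholds, anchor=config.anchor, sim=config.sim,
        seed=config.seed,
    )
    write_result(result, config.out_dir)
    return result
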