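# Methods

`asmcompare` implements a comparison-and-validation protocol for two
alternate genome assemblies ("drafts") built from the same organism: find
where the drafts disagree, classify each disagreement, design BAC probes
able to discriminate the two hypotheses, and decide between them with an
assembly-independent experiment — FISH on metaphase chromosomes or
interphase nuclei, or long-range junction PCR — here simulated against a
known true genome.

## Anchor matching and synteny blocks

Two like-named chromosomes are compared by finding **all maximal exact
matches** of at least `min_anchor` bp (default 50) on both strands.
Matching is case-insensitive; soft-masking (lowercase) and N count as
masked. The masking policy is: a match is kept iff its start is unmasked
on at least one draft, and extension runs freely through masked sequence.
Repeats therefore never seed repeat-vs-repeat noise, while a unique match
interrupted by a repeat is still recovered in one piece.

The implementation seeds with a rolling polynomial hash over numpy arrays
(k = `min_anchor`), matches sorted hash arrays, groups seed pairs into
diagonal runs, extends each run maximally in both directions, and verifies
every reported match by direct byte comparison — hash collisions cannot
produce a false anchor. Seeding is two-sided (unmasked starts of either
draft, the reverse-strand pass reusing the reverse index with transformed
coordinates), which makes discovery exact with respect to the stated rule;
the test suite checks exact agreement with a quadratic brute-force scan.
For large mask-blind queries (scaffold placement, FISH probes) seeding may
be strided: with stride *s*, every match of at least `min_anchor + s − 1`
bp is still found in full, so strides are chosen well below the smallest
match size that matters to the caller.

Anchors are chained into **synteny blocks** by a greedy left-to-right
sweep: an anchor joins the open block whose tail it can follow with the
same orientation, non-negative gaps of at most `max_gap` (default 50 kbp)
on both drafts, and diagonal drift of at most `max_drift` (default
20 kbp); ties prefer the smallest drift, then the earlier block. Both
chaining defaults sit below the 100 kbp reporting floor so chaining
artifacts cannot fabricate a reportable discordance. On all generated
inputs the sweep partitions the anchors into the provably minimal number
of valid chains (checked against an exact minimum-path-cover oracle).

## Discordance taxonomy

Per chromosome pair, blocks with fewer than 5 kbp of matched sequence are
set aside as noise (short cross-matches between diverged repeat copies);
the floor is 20× below the reporting threshold, so no reportable call can
consist of noise alone. The remaining blocks are read as a curator reads a
dot plot:

* **Backbone** — the anchor-bp-heaviest subsequence of same-orientation
  blocks whose positions increase on both drafts (weighted longest
  increasing subsequence).
* **INV** — an inverted-orientation block whose two spans coincide
  positionally once the A span is projected through the flanking backbone
  offsets; "almost coincidental" is fixed at ≥ 80% reciprocal overlap
  (the source protocol never quantifies it). Flank detection tolerates
  1 kbp of overrun, because a maximal anchor can extend a few bp past a
  breakpoint by chance.
* **MDP** — a same-orientation block whose B-side center is displaced
  from the colinear prediction by more than the block's own length.
* **ODS** — a maximal region of either draft's chromosome covered by no
  block, of at least `report_min`; boundaries are the exact ends of the
  flanking matches.
* **DCM** — two ODSs (one per draft) that cover each other reciprocally
  ≥ 50% by anchors yet lie on differently-named chromosomes. An unpaired
  ODS whose sequence still maps (≥ 50%, best position cluster) to a
  different chromosome of the other draft becomes a *one-sided* DCM
  flagged as duplicated in its source draft — the pattern produced by a
  spurious (or real) second copy.

Size rules are strict inequalities on the protocol's printed thresholds:
reported above 100 kbp; testable above 200 kbp for MDP/DCM/ODS (a BAC must
fit inside) and above 500 kbp for inversions (three non-overlapping BACs
must fit). A discordance whose defining locus is more than 75% masked
(`masked_frac_max`, the operationalization of "almost completely composed
of gaps and/or repeats") is excluded from testing but kept in the reports.
Codes are `<CAT>_<chromosome>_<start in Mbp, one decimal>` (trailing `.0`
stripped) and `DCM_<chrA>-<chrB>`, de-duplicated with `.2`, `.3` suffixes.

## Scaffold placement

An unassigned scaffold is aligned mask-blind against the whole other draft
(the in-silico analogue of aligning the full sequence with a BLAST-family
tool) and its chained placements are classified: `single-locus` (one block
covering ≥ 90%), `split-multi-chromosome` (two or more chromosomes each
receiving a distinct portion ≥ 100 kbp), `multi-site-dispersed` (some
portion matching ≥ 3 chromosome loci of ≥ 5 kbp each — the low-copy-repeat
pattern; checked before single-locus, since a dispersed segment inside an
otherwise clean scaffold is the informative signal), and `unplaced`
(chromosome coverage < 10%). Placements onto the target's own unassigned
scaffolds are reported but never yield chromosome verdicts. The 90%/10%
cutoffs operationalize qualitative verdicts and are configurable.
When simulated FISH later reveals more true loci than the target draft
places (a collapsed duplication), the scaffold report is flagged
`collapse_suspect`.

## Probe selection and assays

A clone qualifies as a probe when both end sequences map uniquely, on
opposite strands facing inward, with an implied insert of 50–300 kb
(inclusive bounds). End mapping seeds with exact anchors and verifies each
candidate locus with a banded edit-distance alignment (edlib); a second
locus within 2 mismatches per 100 bp makes the end non-unique — slightly
stricter than requiring an *equal-best* second hit, because a
98%-identical locus cross-hybridizes in practice.

* **Inversion triplet** — one qualifying clone wholly inside the inverted
  segment (preferring off-center inserts; see below) and two outside
  within 1 Mbp of the opposite breakpoints, pairwise non-overlapping.
* **Relocation (MDP)** — if the two predicted positions are ≥ 1 Mbp apart,
  the same triplet geometry with a centrally-preferred inside probe;
  otherwise a junction PCR (below).
* **Flank hygiene** — a flank candidate is rejected when any other
  discordant locus lies between it and the target (one-draft-only regions
  are projected to their insertion point on the probe-carrying draft):
  a signal distance measured across a draft disagreement is not
  comparable between the hypotheses. This mirrors choosing probes in
  concordant regions.
* **Reference panel** — one clone per chromosome whose insert lies wholly
  inside a same-orientation block with ≥ 99% reciprocal positional
  agreement between the drafts; chromosomes without a qualifying clone
  are reported missing.
* **Junction PCR** — each draft hypothesis predicts a junction at the
  upstream boundary of where it places the segment; a 25-bp unique exact
  primer site is taken on each side (sliding outward up to 2 kbp if a
  site is non-unique), and the assay is feasible when the predicted
  amplicon is at most `pcr_amplicon_max` (12 kbp, a long-PCR product).
  In-silico amplification on a genome requires both sites on one
  molecule, facing inward, within the limit. One positive assay names its
  draft; two positives are `both-consistent`; none is `neither` — the
  both-drafts-wrong outcome class.

## Simulated FISH and the verdict

Probe DNA is the insert sequence fetched from the draft the probe was
selected on; it is hybridized in silico against the true genome. A locus
lights up when it carries at least one contiguous exact match of
`fish_visibility_min` (5 kbp, the conservative end of the 5–10 kbp
visibility range); each metaphase cell reports one signal per visible
locus, dropped independently with probability `p_drop` (default 0.05).
The metaphase verdict is all-or-nothing: the supported draft is the one
whose predicted chromosome multiset equals the modal observed multiset.

Interphase nuclei report the **arrangement** of a signal triplet: the
linear order of the three labels read starting from the end whose two
signals lie closer together (nuclei have no intrinsic left/right, and the
informative datum for an inversion is which flank the inside probe sits
nearer — the coarse flank–inside–flank order is invariant under inverting
the segment, which is why the inside probe is chosen off-center). Each
nucleus shows the true arrangement with probability `1 − disorder_p` and
a uniformly random permutation otherwise; `disorder_p` defaults to 0.15,
motivated by the 73–98% support range such experiments report, without
claiming to fit any particular dataset. The verdict is the majority
hypothesis, printed as `<draft> (<percent>%)`. Because the true
arrangement is exactly one of the six permutations, the expected
true-arrangement fraction is `(1 − p) + p/6` — 0.75 at `p = 0.3` — which
the test suite checks against simulation at 2 000 nuclei.

Cell counts follow the protocol: 10 metaphases, 50 interphase nuclei per
experiment. At these counts and `disorder_p ≤ 0.2` a wrong majority is a
≤ 10⁻⁶ event per test, so the end-to-end suite requires every feasible
verdict to name the draft that matches the true genome.

## Synthetic studies

The generator emulates two drafts assembled from one genome. Background
sequence is i.i.d. uniform A/C/G/T, making 50-bp anchors unique with
overwhelming probability at desk scale. Interspersed repeat families
(2–6 kbp, lowercase) are planted with 1% per-copy substitution noise so
uniqueness filters have something to reject; shared low-copy segments
(30 kbp, exact lowercase copies, the near-identity of recent segmental
duplications) sit near chromosome ends — pericentromeric/subtelomeric in
an acrocentric karyotype — and reproduce multi-signal FISH patterns.
Event coordinates snap to unmasked sequence with unmasked breakpoint
flanks; all randomness flows from one seed.

The standard study is **eight 2-Mbp chromosomes with twelve planted
events**: two inversions (550–900 kbp), two same-chromosome relocations
(210–300 kbp, displaced by more than twice their length), two segments
demoted to unassigned scaffolds (500–900 kbp), two cross-chromosome
moves (300–450 kbp), one spurious duplicate insertion (210–300 kbp, the
one-sided DCM pattern), two deletions (120–200 kbp), and one collapse of
the six-copy low-copy family to a single copy. Expected recoveries:
inversion → INV, relocation → MDP, unplacement and deletion → ODS,
cross-move → two ODSs paired into a DCM, duplicate insertion → one-sided
DCM; the collapse produces no chromosome-level call (its copies sit below
the reporting floor) and surfaces only as extra FISH signals. The BES
library is 300 uniform-random clones of 60–250 kbp with 500-bp ends
facing inward.

What the generator does **not** emulate: base-calling errors and
assembly-consensus noise (drafts are exact rearrangements of the truth),
realistic repeat family structure, assembly gaps (N runs), nested or
overlapping events, and polymorphism between the sequenced individual and
the cytogenetic material. Passing tests therefore demonstrate that the
classification logic, thresholds, probe rules and decision procedure are
correct under clean rearrangements — not that the anchor engine is robust
to high sequence divergence, which exact matching deliberately does not
address.

## Numerical and procedural choices

* Coordinates are 0-based half-open internally; every emitted table is
  1-based inclusive.
* Determinism: a single integer seed drives genome generation, event
  placement, BES sampling and every FISH draw (independent child seeds
  per test, spawned from one seed sequence); identical configuration and
  seed reproduce byte-identical output tables.
* Tie-breaks are deterministic everywhere: chaining prefers smaller
  drift then earlier block; probe sorts break ties on clone id; the modal
  metaphase multiset breaks ties lexicographically.
* Degenerate inputs: empty sequences, empty anchor sets, empty libraries,
  zero cells, and chromosome-name mismatches raise explicit errors or
  return explicitly empty results (an infeasible probe plan is an
  expected, reported outcome, not an error).
* Problem sizes: the validation suite runs 20 seeded replicates of the
  standard study; the acceptance script recomputes the same quantities
  from scratch over 8 replicates. At these sizes one replicate takes
  roughly half a minute on one CPU.

## Known limitations

* Exact-match anchoring cannot compare drafts of diverged individuals or
  handle consensus error; real alternate drafts from the same read pool
  are near-identical where they agree, which is the regime modeled.
* The interphase model collapses nuclear geometry into a single
  `disorder_p`; it reproduces the support-percentage *format* of real
  experiments, not their physics.
* MDPs are detected by center displacement greater than the block's own
  length, so a relocation displaced by less than its length is reported
  as colinear slack, not an MDP.
* One-sided DCM detection requires the duplicate's source locus to be
  recoverable by anchors; a duplicate inserted inside a repeat would be
  excluded by the gap/repeat filter.
* `intervaltree`-style stabbing queries were unnecessary at these scales;
  coverage arithmetic uses sorted-interval sweeps.
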