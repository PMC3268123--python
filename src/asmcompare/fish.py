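"""Simulated FISH readouts and the supported-assembly decision.

The simulator hybridizes probe sequences against the *true* genome (the
stand-in for the wet lab, which is assembly independent).  Metaphase cells
report which chromosomes light up — one signal per genomic locus carrying
at least ``fish_visibility_min`` contiguous bp of probe homology, with a
small per-locus dropout probability.  Interphase nuclei report the linear
order of a three-probe signal triplet; each nucleus shows the true order
with probability ``1 - disorder_p`` and an arbitrary permutation otherwise
(nuclear geometry noise).  The verdict compares the observations with the
pattern each draft predicts and names the supported draft together with
the fraction of cells backing it, printed as e.g. ``B (90%)``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .anchors import AssemblyIndex, chain_anchors
from .core import Assembly, Thresholds


class ModalityError(ValueError):
    """The probes are incompatible with the requested FISH modality."""


def arrangement(positions: dict[str, float]) -> tuple[str, ...]:
    """Canonical signal arrangement of three labelled positions on a line.

    Interphase nuclei have no intrinsic left/right, so the linear order is
    read starting from the end whose two signals lie closer together.
    This is what makes an inversion test informative: with the inside
    probe off-center, inverting the segment moves it from one flank's
    neighbourhood to the other's, changing the canonical arrangement even
    though the coarse left-to-right order of (flank, inside, flank) does
    not."""
    if len(positions) != 3:
        raise ValueError("arrangement is defined for exactly 3 signals")
    order = sorted(positions, key=lambda lab: (positions[lab], lab))
    x, y, z = order
    if positions[y] - positions[x] <= positions[z] - positions[y]:
        return (x, y, z)
    return (z, y, x)


@dataclass(frozen=True)
class Hypothesis:
    """The signal pattern one draft predicts.

    For interphase, ``prediction`` is the ordered tuple of probe labels;
    for metaphase, the sorted tuple (multiset) of chromosome names that
    should show a signal."""

    name: str
    prediction: tuple


@dataclass
class FISHObservation:
    cell_id: int
    modality: str  # "metaphase" | "interphase"
    signals: list[tuple[str, str, int]]  # (probe label, chromosome, position)

    def chromosome_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(chrom for _lab, chrom, _pos in self.signals))


@dataclass
class Verdict:
    supported: str  # draft name | "neither" | "both-consistent"
    support_fraction: float
    n_cells: int

    def formatted(self) -> str:
        if self.supported in ("neither", "both-consistent"):
            return self.supported
        return f"{self.supported} ({round(100 * self.support_fraction)}%)"


def probe_loci(
    probe_seq: str,
    true_index: AssemblyIndex,
    thresholds: Thresholds,
    min_anchor: int = 50,
    max_gap: int = 50_000,
) -> list[tuple[str, int, int]]:
    """Genomic loci where the probe would hybridize visibly: chained match
    clusters containing at least one contiguous exact match of
    ``fish_visibility_min`` bp.  Loci below the visibility floor are
    silent."""
    # strided seeding is exact for matches >= min_anchor + stride - 1,
    # well below the visibility floor that defines a locus here
    stride = max(1, min(1024, thresholds.fish_visibility_min - min_anchor))
    anchors = true_index.query(probe_seq, min_anchor, stride=stride)
    by_seq: dict[str, list] = {}
    for m in anchors:
        by_seq.setdefault(m.b.seq_id, []).append(m)
    loci = []
    for sid, ms in by_seq.items():
        for block in chain_anchors(ms, max_gap=max_gap):
            if max(a.length for a in block.anchors) >= thresholds.fish_visibility_min:
                loci.append((sid, block.b_span.start, block.b_span.end))
    return sorted(loci)


def simulate_metaphase(
    probes: list[tuple[str, str]],
    true_genome: Assembly | AssemblyIndex,
    n_cells: int,
    thresholds: Thresholds,
    seed: int = 0,
    p_drop: float = 0.05,
    min_anchor: int = 50,
) -> list[FISHObservation]:
    """Metaphase FISH: each cell shows one signal per visible true-genome
    locus of each probe, dropped independently with probability ``p_drop``.
    A probe with no visible locus yields no signals (reportable outcome).
    """
    index = (
        true_genome
        if isinstance(true_genome, AssemblyIndex)
        else AssemblyIndex(true_genome)
    )
    loci_per_probe = {
        label: probe_loci(seq, index, thresholds, min_anchor) for label, seq in probes
    }
    rng = np.random.default_rng(seed)
    out = []
    for cell in range(n_cells):
        signals = []
        for label, loci in loci_per_probe.items():
            for sid, s, e in loci:
                if rng.random() >= p_drop:
                    signals.append((label, sid, (s + e) // 2))
        out.append(FISHObservation(cell, "metaphase", signals))
    return out


def simulate_interphase_triplet(
    probe_triplet: list[tuple[str, str]],
    true_genome: Assembly | AssemblyIndex,
    n_nuclei: int,
    disorder_p: float = 0.15,
    seed: int = 0,
    thresholds: Thresholds | None = None,
    min_anchor: int = 50,
) -> dict[tuple[str, ...], int]:
    """Interphase FISH on a probe triplet: counts over observed label
    orders.  Each nucleus reports the true chromosomal order with
    probability ``1 - disorder_p`` and a uniformly random permutation of
    the three labels otherwise.  All three probes must sit on one true
    chromosome (otherwise the experiment needs metaphase spreads)."""
    if len(probe_triplet) != 3:
        raise ValueError("an interphase triplet needs exactly 3 probes")
    thresholds = thresholds or Thresholds()
    index = (
        true_genome
        if isinstance(true_genome, AssemblyIndex)
        else AssemblyIndex(true_genome)
    )
    positions = {}
    for label, seq in probe_triplet:
        loci = probe_loci(seq, index, thresholds, min_anchor)
        if not loci:
            raise ModalityError(f"probe {label} has no visible locus on the true genome")
        # strongest locus: widest visible cluster
        sid, s, e = max(loci, key=lambda l: l[2] - l[1])
        positions[label] = (sid, (s + e) // 2)
    chroms = {sid for sid, _pos in positions.values()}
    if len(chroms) != 1:
        raise ModalityError(
            f"probes map to different chromosomes {sorted(chroms)}; metaphase required"
        )
    true_order = arrangement({lab: pos for lab, (_sid, pos) in positions.items()})
    labels = list(positions)
    perms = list(permutations(labels))
    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, ...], int] = {p: 0 for p in perms}
    for _ in range(n_nuclei):
        if rng.random() < disorder_p:
            obs = perms[int(rng.integers(0, len(perms)))]
        else:
            obs = true_order
        counts[obs] += 1
    return {k: v for k, v in counts.items() if v > 0}


def decide(
    observations: dict[tuple[str, ...], int] | list[FISHObservation],
    hypothesis_a: Hypothesis,
    hypothesis_b: Hypothesis,
) -> Verdict:
    """Pick the draft whose predicted pattern the cells support.

    Interphase (``observations`` is an order-count dict): the winner is the
    hypothesis whose predicted order the majority of nuclei show;
    ``support_fraction`` is the fraction showing the winning order.
    Metaphase (a list of observations): the winner is the hypothesis whose
    predicted chromosome multiset equals the modal observed multiset —
    an all-or-nothing readout.  Identical predictions give
    ``both-consistent``; no match gives ``neither``.
    """
    if isinstance(observations, dict):
        n = sum(observations.values())
        if n == 0:
            raise ValueError("verdict undefined for zero cells")
        ca = observations.get(tuple(hypothesis_a.prediction), 0)
        cb = observations.get(tuple(hypothesis_b.prediction), 0)
        if tuple(hypothesis_a.prediction) == tuple(hypothesis_b.prediction):
            return Verdict("both-consistent", ca / n, n)
        if ca == cb == 0:
            return Verdict("neither", 0.0, n)
        if ca >= cb:
            return Verdict(hypothesis_a.name, ca / n, n)
        return Verdict(hypothesis_b.name, cb / n, n)

    n = len(observations)
    if n == 0:
        raise ValueError("verdict undefined for zero cells")
    multisets = Counter(obs.chromosome_multiset() for obs in observations)
    modal = min(
        (ms for ms, c in multisets.items() if c == max(multisets.values())),
    )
    pa = tuple(sorted(hypothesis_a.prediction))
    pb = tuple(sorted(hypothesis_b.prediction))
    frac_a = sum(c for ms, c in multisets.items() if ms == pa) / n
    frac_b = sum(c for ms, c in multisets.items() if ms == pb) / n
    if pa == pb:
        return Verdict("both-consistent", frac_a, n)
    if modal == pa:
        return Verdict(hypothesis_a.name, frac_a, n)
    if modal == pb:
        return Verdict(hypothesis_b.name, frac_b, n)
    return Verdict("neither", multisets[modal] / n, n)
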