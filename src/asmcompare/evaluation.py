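"""Truth-based scoring of a comparison run on synthetic data.

Each planted event maps to one expected discordance category; a replicate
is scored by matching the truth table against the classified discordances
(category precision/recall, breakpoint error) and against the simulated
FISH/PCR verdicts (does the named draft equal the draft that matches the
true genome at that event).
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import DCM, INV, MDP, ODS, Discordance
from .core import Interval
from .pipeline import ComparisonResult
from .simulate import TruthRow, TruthTable

#: discordance category each event kind must produce (duplication-collapse
#: produces no chromosome-level discordance: its copies sit below the
#: reporting floor and the disagreement surfaces through FISH signal counts)
EXPECTED_CATEGORY = {
    "inversion": INV,
    "relocation": MDP,
    "unplace-to-scaffold": ODS,
    "deletion": ODS,
    "cross-chromosome-move": DCM,
    "duplication-insert": DCM,
    "duplication-collapse": None,
}


@dataclass
class EventMatch:
    kind: str
    expected_category: str | None
    matched_code: str | None
    breakpoint_error: int | None  # max |boundary - truth| over matched locus
    verdict_correct: bool | None  # None when the event was not testable


def _locus_error(found: Interval, truth: Interval) -> int | None:
    if found.seq_id != truth.seq_id:
        return None
    return max(abs(found.start - truth.start), abs(found.end - truth.end))


def _truth_locus(row: TruthRow, side: str) -> Interval | None:
    return row.a_locus if side == "A" else row.b_locus


def _match_one(row: TruthRow, discordances: list[Discordance]) -> tuple[str | None, int | None]:
    """Find the discordance recovering this event; return (code, bp error)."""
    ev = row.event
    cat = EXPECTED_CATEGORY[ev.kind]
    if cat is None:
        return None, None
    best: tuple[int, str] | None = None
    for d in discordances:
        if d.category != cat or d.eligibility == "sub-threshold":
            continue
        if cat in (INV, MDP):
            truth_a = row.a_locus
            if truth_a is None or d.a_locus is None:
                continue
            if d.a_locus.reciprocal_overlap(truth_a) < 0.5:
                continue
            err = _locus_error(d.a_locus, truth_a)
        elif cat == ODS:
            # the draft that kept the sequence on its chromosome
            side = ev.correct_assembly if ev.kind in ("unplace-to-scaffold", "deletion") else None
            truth_iv = _truth_locus(row, side)
            locus = d.defining_locus
            if d.source_assembly != side or truth_iv is None:
                continue
            if truth_iv.seq_id.startswith(("004.", "scaffold")):
                continue
            if locus.reciprocal_overlap(truth_iv) < 0.5:
                continue
            err = _locus_error(locus, truth_iv)
        else:  # DCM
            carrier = ev.applies_to
            truth_iv = _truth_locus(row, carrier)
            locus = d.a_locus if carrier == "A" else d.b_locus
            if truth_iv is None or locus is None:
                continue
            if locus.reciprocal_overlap(truth_iv) < 0.5:
                continue
            err = _locus_error(locus, truth_iv)
        if err is None:
            continue
        if best is None or err < best[0]:
            best = (err, d.code or "?")
    if best is None:
        return None, None
    return best[1], best[0]


@dataclass
class ReplicateScore:
    matches: list[EventMatch]
    n_expected: int
    n_recovered: int
    n_spurious: int  # reportable discordances not explained by any event
    max_breakpoint_error: int
    n_testable: int
    n_verdicts_correct: int

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_expected if self.n_expected else 1.0

    @property
    def precision(self) -> float:
        denom = self.n_recovered + self.n_spurious
        return self.n_recovered / denom if denom else 1.0


def score_replicate(truth: TruthTable, result: ComparisonResult) -> ReplicateScore:
    """Score one synthetic replicate against its truth table."""
    discordances = result.discordances
    matches: list[EventMatch] = []
    matched_codes: set[str] = set()
    verdict_by_code = {t.code: t for t in result.tests}
    for row in truth:
        ev = row.event
        cat = EXPECTED_CATEGORY[ev.kind]
        code, err = _match_one(row, discordances)
        if code is not None:
            matched_codes.add(code)
        verdict_ok: bool | None = None
        # a verdict may be recorded under the discordance code or, for
        # unplaced scaffolds, under the scaffold validation test
        test = verdict_by_code.get(code) if code else None
        if test is None and row.scaffold_id is not None:
            test = verdict_by_code.get(f"ChrUn_{row.scaffold_id}")
        if test is not None and test.verdict is not None:
            supported = test.verdict.supported
            if supported not in ("neither", "both-consistent"):
                correct_name = (
                    result.asm_a.name if ev.correct_assembly == "A" else result.asm_b.name
                )
                verdict_ok = supported == correct_name
            else:
                verdict_ok = False
        matches.append(EventMatch(ev.kind, cat, code, err, verdict_ok))

    expected = [m for m in matches if m.expected_category is not None]
    recovered = [m for m in expected if m.matched_code is not None]
    # spurious: reportable, non-excluded discordances (DCM-member ODSs are
    # represented by their DCM) that no event explains
    spurious = 0
    for d in result.kept:
        if d.eligibility == "sub-threshold":
            continue
        if d.category == ODS and d.dcm_partner is not None:
            continue
        if (d.code or "?") not in matched_codes:
            spurious += 1
    testable = [m for m in matches if m.verdict_correct is not None]
    return ReplicateScore(
        matches=matches,
        n_expected=len(expected),
        n_recovered=len(recovered),
        n_spurious=spurious,
        max_breakpoint_error=max((m.breakpoint_error for m in recovered), default=0),
        n_testable=len(testable),
        n_verdicts_correct=sum(1 for m in testable if m.verdict_correct),
    )
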