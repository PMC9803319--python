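"""Score an SV callset against a truth set.

Classification follows the reciprocal-overlap rule: a predicted variant is a
true positive iff some simulated (truth) variant of the same type overlaps it
with minimum reciprocal overlap >= 0.5 (ties at exactly 0.5 count as TP);
otherwise it is a false positive.  A truth variant no call matches is a false
negative.  Matching is many-to-one — every call reaching the threshold against
at least one truth variant counts as TP — so callsets should be deduplicated
with ``resolve_overlaps`` first, which is what keeps many-to-one matching from
inflating the counts.

From the counts: precision = TP/(TP+FP), recall = TP/(TP+FN), and F1 their
harmonic mean.  The binary counts ignore breakpoint and size errors among true
positives, so the base-pair Jaccard index (intersection over union of the base
pairs covered by calls vs truth, per type) is reported alongside; a single
multi-megabase false positive collapses Jaccard while barely moving F1.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .intervals import jaccard_index, reciprocal_overlap
from .variants import SV_TYPES, StructuralVariant, SvCallSet

__all__ = [
    "EvalResult",
    "SizeStratum",
    "classify_calls",
    "precision_recall_f1",
    "f1_from_pr",
    "jaccard_vs_truth",
    "evaluate_callset",
    "stratified_report",
    "round_half_up",
]


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from the classification counts.

    Degenerate denominators are defined as 0: precision with tp+fp=0, recall
    with tp+fn=0, F1 with precision+recall=0.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall, f1_from_pr(precision, recall)


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must be in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching report-table presentation."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class EvalResult:
    """Per-type classification counts, metrics, and the labeled variants."""

    sv_type: str
    tp: int = 0
    fp: int = 0
    fn: int = 0
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0
    jaccard: float = 0.0
    tp_calls: list[StructuralVariant] = field(default_factory=list)
    fp_calls: list[StructuralVariant] = field(default_factory=list)
    missed_truth: list[StructuralVariant] = field(default_factory=list)


@dataclass
class SizeStratum:
    """One half-open size range of a stratified report."""

    lo: int
    hi: int
    results: dict[str, EvalResult] = field(default_factory=dict)


def _check_namespaces(calls: SvCallSet, truth: SvCallSet) -> None:
    call_chroms = {v.chrom for v in calls.variants}
    truth_chroms = {v.chrom for v in truth.variants}
    if call_chroms and truth_chroms and not (call_chroms & truth_chroms):
        raise ValueError(
            "callset and truth set share no chromosome names; "
            f"calls use {sorted(call_chroms)[:5]}, truth uses {sorted(truth_chroms)[:5]}"
        )


def classify_calls(
    calls: SvCallSet,
    truth: SvCallSet,
    min_recip: float = 0.5,
    sv_types: Sequence[str] = SV_TYPES,
    check_namespaces: bool = True,
) -> dict[str, EvalResult]:
    """Label calls TP/FP and truth variants detected/missed, per SV type.

    A call is TP iff some same-type truth variant reaches reciprocal overlap
    >= ``min_recip`` against it; a truth variant is FN iff no same-type call
    reaches the threshold against it.  Deduplicate calls first
    (``resolve_overlaps``) — matching is many-to-one.
    """
    if not (0 < min_recip <= 1):
        raise ValueError("min_recip must be in (0, 1]")
    if check_namespaces:
        _check_namespaces(calls, truth)
    out: dict[str, EvalResult] = {}
    for sv_type in sv_types:
        typed_truth = truth.of_type(sv_type)
        typed_calls = calls.of_type(sv_type)
        trees: dict[str, IntervalTree] = {}
        for i, t in enumerate(typed_truth):
            trees.setdefault(t.chrom, IntervalTree()).addi(
                t.interval.start, t.interval.end, i
            )
        res = EvalResult(sv_type=sv_type)
        detected = [False] * len(typed_truth)
        for c in typed_calls:
            hit = False
            for node in trees.get(c.chrom, IntervalTree()).overlap(
                c.interval.start, c.interval.end
            ):
                t = typed_truth[node.data]
                if reciprocal_overlap(c.interval, t.interval) >= min_recip:
                    hit = True
                    detected[node.data] = True
            if hit:
                res.tp_calls.append(c)
            else:
                res.fp_calls.append(c)
        res.missed_truth = [t for t, d in zip(typed_truth, detected) if not d]
        res.tp = len(res.tp_calls)
        res.fp = len(res.fp_calls)
        res.fn = len(res.missed_truth)
        out[sv_type] = res
    return out


def jaccard_vs_truth(calls: SvCallSet, truth: SvCallSet, sv_type: str) -> float:
    """Base-pair Jaccard of same-type calls vs same-type truth coverage."""
    return jaccard_index(
        (v.interval for v in calls.of_type(sv_type)),
        (v.interval for v in truth.of_type(sv_type)),
    )


def evaluate_callset(
    calls: SvCallSet,
    truth: SvCallSet,
    min_recip: float = 0.5,
    sv_types: Sequence[str] = SV_TYPES,
    check_namespaces: bool = True,
) -> dict[str, EvalResult]:
    """Full per-type evaluation: classification, P/R/F1, and Jaccard."""
    results = classify_calls(
        calls, truth, min_recip=min_recip, sv_types=sv_types,
        check_namespaces=check_namespaces,
    )
    for sv_type, res in results.items():
        res.precision, res.recall, res.f1 = precision_recall_f1(res.tp, res.fp, res.fn)
        res.jaccard = jaccard_vs_truth(calls, truth, sv_type)
    return results


def _subset_by_size(cs: SvCallSet, lo: int, hi: int) -> SvCallSet:
    return SvCallSet(
        variants=[v for v in cs.variants if lo <= v.size < hi],
        caller=cs.caller,
        sample=cs.sample,
        depth_label=cs.depth_label,
    )


def stratified_report(
    calls: SvCallSet,
    truth: SvCallSet,
    strata_edges: Sequence[int],
    min_recip: float = 0.5,
    sv_types: Sequence[str] = SV_TYPES,
) -> tuple[list[SizeStratum], dict[str, EvalResult]]:
    """Per-size-range evaluation plus the overall (unstratified) result.

    Both truth variants and calls are assigned to strata by their own size
    (half-open ranges; the last edge is included in the final stratum), and
    each stratum is scored independently.  A call whose jittered size falls in
    a different stratum than its true event is scored in its own stratum; see
    the overall row for the assignment-free totals.
    """
    if list(strata_edges) != sorted(strata_edges) or len(strata_edges) < 2:
        raise ValueError("strata_edges must be >= 2 ascending values")
    strata = []
    for i, (lo, hi) in enumerate(zip(strata_edges, strata_edges[1:])):
        top = hi + 1 if i == len(strata_edges) - 2 else hi  # close the last bin
        sub_calls = _subset_by_size(calls, lo, top)
        sub_truth = _subset_by_size(truth, lo, top)
        results = {}
        for sv_type in sv_types:
            tc = SvCallSet(variants=sub_calls.of_type(sv_type))
            tt = SvCallSet(variants=sub_truth.of_type(sv_type))
            res = evaluate_callset(
                tc, tt, min_recip=min_recip, sv_types=[sv_type],
                check_namespaces=False,
            )[sv_type]
            results[sv_type] = res
        strata.append(SizeStratum(lo=lo, hi=hi, results=results))
    overall = evaluate_callset(calls, truth, min_recip=min_recip, sv_types=sv_types)
    return strata, overall
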