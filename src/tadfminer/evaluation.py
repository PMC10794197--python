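"""Precision/recall evaluation against gold annotations.

A record is a true positive iff it has (i) the correct property with
both the value and the unit, (ii) the correct compound name *or* label
mentioned in the same paragraph or table as the property phrase, and
(iii) the correct temperature value and unit when it is a delayed
lifetime record. Matching is greedy one-to-one per document, in document
order; value comparison uses exact equality after unit standardization
(relative tolerance 1e-9).

Convergence is diagnosed with accumulative curves: the cumulative metric
after k records, along several seeded random accumulating orders, whose
final point always equals the overall metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .document import normalize_name

_VALUE_RTOL = 1e-9

#: Published per-property benchmark of the TADF extraction pipeline this
#: package re-implements: precision %, recall %, F-score, record count.
REFERENCE_METRICS: dict[str, tuple[float, float, float, int]] = {
    "lambda_em": (84.5, 49.5, 0.624, 11264),
    "plqy": (78.2, 56.1, 0.653, 6711),
    "delta_e_st": (80.9, 61.3, 0.697, 5050),
    "tau_d": (78.2, 55.6, 0.650, 2457),
}

#: evaluation-protocol defaults: records sampled per property for
#: precision, publications for recall, random accumulating orders
PRECISION_SAMPLE_SIZE = 110
RECALL_SAMPLE_PUBLICATIONS = 40
DEFAULT_N_ORDERS = 5


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _values_equal(a: list[float], b: list[float]) -> bool:
    if len(a) != len(b):
        return False
    return all(
        abs(x - y) <= _VALUE_RTOL * max(abs(x), abs(y), 1.0)
        for x, y in zip(sorted(a), sorted(b))
    )


def _identifiers(rec: dict) -> set[str]:
    compound = rec.get("compound", {}) or {}
    ids = list(compound.get("names", [])) + list(compound.get("labels", []))
    return {normalize_name(i).lower() for i in ids if i}


def records_match(extracted: dict, gold: dict) -> bool:
    """Three-clause true-positive test on schema dictionaries."""
    if extracted.get("model_name") != gold.get("model_name"):
        return False
    if not _values_equal(extracted.get("standard_value", []),
                         gold.get("standard_value", [])):
        return False
    gold_ids = _identifiers(gold)
    if gold_ids and not (_identifiers(extracted) & gold_ids):
        return False
    if gold.get("model_name") == "tau_d":
        te, tg = extracted.get("temperature"), gold.get("temperature")
        if (te is None) != (tg is None):
            return False
        if te is not None and abs(te - tg) > _VALUE_RTOL * max(abs(tg), 1.0):
            return False
    return True


@dataclass
class MatchResult:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    assignments: list[tuple[int, int]] = field(default_factory=list)
    extracted_labels: list[bool] = field(default_factory=list)  # per extracted: TP?
    gold_labels: list[bool] = field(default_factory=list)       # per gold: found?


def match_records(extracted: list[dict], gold: list[dict]) -> MatchResult:
    """Greedy one-to-one matching per document, in document order."""
    result = MatchResult()
    gold_taken = [False] * len(gold)
    ext_tp = [False] * len(extracted)
    for i, ext in enumerate(extracted):
        for j, g in enumerate(gold):
            if gold_taken[j] or ext.get("doc_id") != g.get("doc_id"):
                continue
            if records_match(ext, g):
                gold_taken[j] = True
                ext_tp[i] = True
                result.assignments.append((i, j))
                break
    result.tp = sum(ext_tp)
    result.fp = len(extracted) - result.tp
    result.fn = len(gold) - result.tp
    result.extracted_labels = ext_tp
    result.gold_labels = gold_taken
    return result


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compute_metrics(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall, F-score with the zero-denominator → 0 convention."""
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = (2 * precision * recall / (precision + recall)
         if precision + recall else 0.0)
    return precision, recall, f


def f_score(precision: float, recall: float) -> float:
    return (2 * precision * recall / (precision + recall)
            if precision + recall else 0.0)


def accumulative_curves(labels: list[bool], n_orders: int = DEFAULT_N_ORDERS,
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative metric after k items along seeded random orders.

    Returns ``(curves, mean_curve)`` with ``curves`` of shape
    ``(n_orders, n)``. The final point of every order equals the overall
    metric (the ratio is order-invariant at k = n).
    """
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    arr = np.asarray(labels, dtype=float)
    if arr.size == 0:
        return np.zeros((n_orders, 0)), np.zeros(0)
    rng = np.random.default_rng(seed)
    curves = np.empty((n_orders, arr.size))
    ks = np.arange(1, arr.size + 1)
    for i in range(n_orders):
        perm = rng.permutation(arr.size)
        curves[i] = np.cumsum(arr[perm]) / ks
    return curves, curves.mean(axis=0)


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float
    per_property: dict[str, dict] = field(default_factory=dict)
    precision_curves: np.ndarray | None = None
    recall_curves: np.ndarray | None = None
    n_orders: int = DEFAULT_N_ORDERS

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall,
            "f_score": self.f_score, "per_property": self.per_property,
            "n_orders": self.n_orders,
        }


def evaluate(extracted: list[dict], gold: list[dict],
             n_orders: int = DEFAULT_N_ORDERS, seed: int = 0) -> EvaluationReport:
    """Full evaluation: matching, overall and per-property metrics, curves."""
    result = match_records(extracted, gold)
    precision, recall, f = compute_metrics(result.tp, result.fp, result.fn)
    per_property: dict[str, dict] = {}
    for pid in sorted({r["model_name"] for r in extracted + gold}):
        ext_idx = [i for i, r in enumerate(extracted) if r["model_name"] == pid]
        gold_idx = [j for j, r in enumerate(gold) if r["model_name"] == pid]
        tp = sum(result.extracted_labels[i] for i in ext_idx)
        p, r_, f_ = compute_metrics(tp, len(ext_idx) - tp, len(gold_idx) - tp)
        per_property[pid] = {"tp": tp, "fp": len(ext_idx) - tp,
                             "fn": len(gold_idx) - tp,
                             "precision": p, "recall": r_, "f_score": f_}
    p_curves, _ = accumulative_curves(result.extracted_labels, n_orders, seed)
    r_curves, _ = accumulative_curves(list(result.gold_labels), n_orders, seed + 1)
    return EvaluationReport(
        tp=result.tp, fp=result.fp, fn=result.fn,
        precision=precision, recall=recall, f_score=f,
        per_property=per_property,
        precision_curves=p_curves, recall_curves=r_curves, n_orders=n_orders,
    )


# ---------------------------------------------------------------------------
# Reference-benchmark arithmetic
# ---------------------------------------------------------------------------

def reference_f_scores() -> dict[str, float]:
    """Recompute F = 2PR/(P+R) from the benchmark precision/recall pairs."""
    return {
        pid: f_score(p / 100.0, r / 100.0)
        for pid, (p, r, _, _) in REFERENCE_METRICS.items()
    }


def reference_mean_recall() -> float:
    """Unweighted mean of the four benchmark recall values, in percent."""
    return float(np.mean([r for _, r, _, _ in REFERENCE_METRICS.values()]))


def reference_mean_precision(weighted: bool = False) -> float:
    """Mean benchmark precision, simple or record-count-weighted, percent.

    The published overall figure sits between the two; the weighting used
    there is not stated, so both are reported.
    """
    ps = np.array([p for p, _, _, _ in REFERENCE_METRICS.values()])
    if not weighted:
        return float(ps.mean())
    ns = np.array([n for _, _, _, n in REFERENCE_METRICS.values()], dtype=float)
    return float((ps * ns).sum() / ns.sum())
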