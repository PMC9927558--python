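"""Per-complex ranking metrics for docking-model scoring.

All metrics are computed per complex and only then aggregated across
complexes — scores are never pooled, since score scales are not comparable
between targets. For one complex with models ranked by descending score:

* ROC-AUC and PR-AUC of the scores against the binary near-native labels
  (PR-AUC uses step-wise interpolation: precision held constant between
  recall points, as in average precision);
* hit rate(k) = N_hits(k) / N_pos, the fraction of the complex's positives
  recovered among the top-k ranked models;
* success rate(k), across complexes: the fraction of complexes with at
  least one positive in their top k.

Complexes without a single positive model have no defined hit rate or AUC
and must be excluded by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass(frozen=True)
class PredictionRecord:
    complex_id: str
    model_id: str
    score: float
    is_positive: bool


@dataclass
class ComplexMetrics:
    complex_id: str
    roc_auc: float
    pr_auc: float
    n_pos: int
    n_neg: int
    hit_rate_curve: dict[int, float] = field(default_factory=dict)


def rank_models(records: list[PredictionRecord],
                complex_id: str) -> list[PredictionRecord]:
    """Models of one complex by descending score; ties by model_id."""
    subset = [r for r in records if r.complex_id == complex_id]
    if not subset:
        raise ValueError(f"no predictions for complex {complex_id!r}")
    ids = {r.model_id for r in subset}
    if len(ids) != len(subset):
        raise ValueError(f"duplicate model ids for complex {complex_id!r}")
    return sorted(subset, key=lambda r: (-r.score, r.model_id))


def hit_rate(ranked_positives: list[bool], k: int) -> float:
    """N_hits(k) / N_pos over a ranked positive/negative list."""
    if not 0 <= k <= len(ranked_positives):
        raise ValueError(f"k={k} out of range [0, {len(ranked_positives)}]")
    n_pos = sum(ranked_positives)
    if n_pos == 0:
        raise ValueError("hit rate undefined for a complex with no positives")
    return sum(ranked_positives[:k]) / n_pos


def hit_rate_curve(ranked_positives: list[bool]) -> dict[int, float]:
    """Hit rate for every k from 0 to the number of models."""
    return {k: hit_rate(ranked_positives, k)
            for k in range(len(ranked_positives) + 1)}


def success_rate(per_complex_ranked: dict[str, list[bool]], k: int) -> float:
    """Fraction of complexes with >=1 positive among their top-k models."""
    if not per_complex_ranked:
        raise ValueError("no complexes")
    hits = sum(any(flags[:k]) for flags in per_complex_ranked.values())
    return hits / len(per_complex_ranked)


def roc_auc(scores, labels) -> float:
    """ROC-AUC; equals the pairwise concordance P(s+ > s-) + 0.5 P(tie)."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC-AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall step curve (average precision)."""
    labels = np.asarray(labels, dtype=bool)
    if not labels.any():
        raise ValueError("PR-AUC undefined with no positives")
    return float(average_precision_score(labels,
                                         np.asarray(scores, dtype=float)))


def complex_metrics(records: list[PredictionRecord],
                    complex_id: str) -> ComplexMetrics:
    ranked = rank_models(records, complex_id)
    flags = [r.is_positive for r in ranked]
    scores = [r.score for r in ranked]
    return ComplexMetrics(
        complex_id=complex_id,
        roc_auc=roc_auc(scores, flags),
        pr_auc=pr_auc(scores, flags),
        n_pos=sum(flags),
        n_neg=len(flags) - sum(flags),
        hit_rate_curve=hit_rate_curve(flags),
    )


def evaluate_predictions(records: list[PredictionRecord],
                         ) -> list[ComplexMetrics]:
    """Per-complex metrics for every complex that has both classes.

    Complexes with no positives (metrics undefined) or no negatives are
    skipped, mirroring the exclusion of targets without positive samples.
    """
    out = []
    for cid in sorted({r.complex_id for r in records}):
        flags = [r.is_positive for r in records if r.complex_id == cid]
        if not any(flags) or all(flags):
            continue
        out.append(complex_metrics(records, cid))
    return out


def summarize(metrics: list[ComplexMetrics]) -> dict:
    """Median and 25/75% quantiles (linear interpolation) of each metric,
    and of the hit-rate curve at each k shared by all complexes."""
    if not metrics:
        raise ValueError("no per-complex metrics to summarize")

    def q(values):
        values = np.asarray(values, dtype=float)
        return {
            "q25": float(np.quantile(values, 0.25)),
            "median": float(np.quantile(values, 0.5)),
            "q75": float(np.quantile(values, 0.75)),
        }

    max_shared_k = min(max(m.hit_rate_curve) for m in metrics)
    return {
        "n_complexes": len(metrics),
        "roc_auc": q([m.roc_auc for m in metrics]),
        "pr_auc": q([m.pr_auc for m in metrics]),
        "hit_rate": {
            k: q([m.hit_rate_curve[k] for m in metrics])
            for k in range(max_shared_k + 1)
        },
    }
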