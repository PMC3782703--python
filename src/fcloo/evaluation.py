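"""Evaluation of classification scores: thresholding, accuracy with exact
binomial significance, proportion tests, behavioral correlations, FDR, and
site-level accuracy correlates."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import BEHAVIOR_FIELDS, PhenotypeRecord


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------


def threshold_scores(
    scores: np.ndarray, labels: Sequence[str], mode: str = "zero"
) -> tuple[np.ndarray, float, bool]:
    """Predict autism for scores above a threshold.

    ``mode="zero"`` uses 0.  ``mode="roc"`` picks the threshold on the full
    score vector that maximizes sensitivity + specificity (the Youden point of
    the ROC curve), ties broken toward the smaller threshold.  Returns
    (predictions, threshold, flagged); constant scores under ROC are flagged
    with the threshold at that constant.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if mode == "zero":
        thr = 0.0
        flagged = False
    elif mode == "roc":
        if len(set(labels.tolist())) < 2:
            raise EvaluationError("ROC thresholding needs both labels present")
        uniq = np.unique(scores)
        if uniq.size == 1:
            thr, flagged = float(uniq[0]), True
        else:
            is_aut = labels == "autism"
            n_aut, n_ctl = is_aut.sum(), (~is_aut).sum()
            candidates = np.concatenate([[-np.inf], uniq])
            best_j, thr = -np.inf, 0.0
            for c in candidates:  # ascending: first maximum is the smallest threshold
                pred_aut = scores > c
                sens = (pred_aut & is_aut).sum() / n_aut
                spec = (~pred_aut & ~is_aut).sum() / n_ctl
                j = sens + spec
                if j > best_j:
                    best_j, thr = j, float(c)
            flagged = False
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    return np.where(scores > thr, "autism", "control"), thr, flagged


# ---------------------------------------------------------------------------
# accuracy and binomial significance
# ---------------------------------------------------------------------------


@dataclass
class EvaluationResult:
    n: int
    n_correct: int
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    binomial_p: float
    threshold: float = 0.0
    threshold_mode: str = "zero"


def evaluate(
    predictions: Sequence[str],
    labels: Sequence[str],
    threshold: float = 0.0,
    threshold_mode: str = "zero",
) -> EvaluationResult:
    """Accuracy, sensitivity (autism recall), specificity (control recall), and
    the one-sided exact binomial tail P(X >= n_correct | n, 1/2)."""
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    if pred.shape != lab.shape:
        raise EvaluationError("predictions and labels must align")
    n = lab.size
    correct = pred == lab
    n_correct = int(correct.sum())
    is_aut = lab == "autism"
    sens = float(correct[is_aut].mean()) if is_aut.any() else None
    spec = float(correct[~is_aut].mean()) if (~is_aut).any() else None
    return EvaluationResult(
        n=n,
        n_correct=n_correct,
        accuracy=n_correct / n,
        sensitivity=sens,
        specificity=spec,
        binomial_p=float(stats.binom.sf(n_correct - 1, n, 0.5)),
        threshold=threshold,
        threshold_mode=threshold_mode,
    )


def binomial_critical_count(n: int, alpha: float) -> int:
    """Smallest k with exact one-sided tail P(X >= k | n, 1/2) < alpha."""
    if not (0.0 < alpha < 0.5):
        raise EvaluationError("alpha must lie in (0, 0.5)")
    k = int(np.ceil(n / 2))
    while stats.binom.sf(k - 1, n, 0.5) >= alpha:
        k += 1
        if k > n:
            raise EvaluationError("no achievable critical count")
    return k


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z statistic and two-tailed p.

    Degenerate pooled proportions (0 or 1) give z = 0, p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise EvaluationError("group sizes must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        return 0.0, 1.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# behavioral correlations and FDR
# ---------------------------------------------------------------------------


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the t-transform two-tailed p on n - 2 df."""
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def behavior_correlations(
    scores: np.ndarray, records: Sequence[PhenotypeRecord]
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation of classifier scores with each
    behavioral measure.  Measures with fewer than 3 pairs are reported with
    NaN statistics and their n."""
    scores = np.asarray(scores, dtype=float)
    rows = []
    for name in BEHAVIOR_FIELDS:
        vals = np.array(
            [np.nan if r.behavior(name) is None else r.behavior(name) for r in records],
            dtype=float,
        )
        ok = ~np.isnan(vals) & ~np.isnan(scores)
        n = int(ok.sum())
        if n < 3 or np.std(vals[ok]) == 0 or np.std(scores[ok]) == 0:
            rows.append({"measure": name, "r": np.nan, "p": np.nan, "n": n})
            continue
        r, p = pearson_with_p(scores[ok], vals[ok])
        rows.append({"measure": name, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows, columns=["measure", "r", "p", "n"])


def fdr_bh(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up pass mask at level q."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise EvaluationError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


# ---------------------------------------------------------------------------
# site-level analyses
# ---------------------------------------------------------------------------


def per_site_accuracy(
    scores: np.ndarray,
    labels: Sequence[str],
    sites: Sequence[str],
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Zero-threshold (or given-threshold) accuracy per acquisition site."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    sites = np.asarray(sites)
    pred = np.where(scores > threshold, "autism", "control")
    rows = []
    for site in sorted(set(sites.tolist())):
        m = sites == site
        rows.append(
            {
                "site": site,
                "n": int(m.sum()),
                "accuracy": float((pred[m] == labels[m]).mean()),
            }
        )
    return pd.DataFrame(rows, columns=["site", "n", "accuracy"])


def site_accuracy_analysis(
    accuracies: np.ndarray, volumes: np.ndarray, sample_sizes: np.ndarray
) -> dict[str, tuple[float, float]]:
    """Correlate per-site accuracy with imaging-volume count and sample size."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 3:
        raise EvaluationError("need at least 3 sites")
    out: dict[str, tuple[float, float]] = {}
    for key, other in (
        ("volumes", np.asarray(volumes, dtype=float)),
        ("sample_size", np.asarray(sample_sizes, dtype=float)),
    ):
        if np.std(acc) == 0 or np.std(other) == 0:
            out[key] = (float("nan"), float("nan"))
        else:
            out[key] = pearson_with_p(acc, other)
    return out
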