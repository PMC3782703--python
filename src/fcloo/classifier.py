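"""Leave-one-out dual-group GLM classifier with site harmonization.

For every left-out subject and every connection, the remaining subjects'
Fisher-z values are modeled separately for the autism and control groups by a
general linear model in age, age-squared, gender, and handedness.  The
left-out subject's value is compared with the two model predictions for their
covariates, and the difference of the two absolute deviations is weighted by
the F statistic (t-squared) of the group difference among remaining subjects:

    s_c = (|x - est_control| - |x - est_autism|) * F_c

so proximity to the autism estimate contributes positively.  Per-connection
scores are averaged within each ROI's incident connections and the per-ROI
averages summed into the subject's classification score: negative predicts
control, positive predicts autism.

Multisite acquisition differences are handled by a per-site mean-offset
adjustment.  The default (``site_adjust="harmonize"``) subtracts from every
value its site's mean for that connection (computed over the remaining
subjects only, never the left-out subject's own value) and re-centers on the
grand mean, before any fitting or statistics; adding a constant to one site's
matrices then provably changes no score.  The literal variant that fits on
raw values and shifts the two group estimates by the site offset is available
as ``site_adjust="estimates"``.

Leave-one-out hygiene: the left-out subject's connectivity values enter the
computation only as the ``x`` in the score formula — never the fits, the F
statistics, the connection selection, or the site means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort import (
    CohortDataset,
    CohortError,
    PhenotypeRecord,
    connection_pairs,
    n_connections,
)

COVARIATE_NAMES = ("age", "age_sq", "gender", "hand_left", "hand_ambi")


class ClassifierError(ValueError):
    """Raised when classifier preconditions are violated."""


# ---------------------------------------------------------------------------
# covariates and group models
# ---------------------------------------------------------------------------


@dataclass
class CovariateVector:
    """GLM covariates for one subject.

    ``gender`` is 1 for female (male reference); handedness uses two
    indicators with right-handed as reference.
    """

    age: float
    age_sq: float
    gender: float
    hand_left: float
    hand_ambi: float

    def __post_init__(self) -> None:
        if abs(self.age_sq - self.age**2) > 1e-9 * max(1.0, self.age**2):
            raise ClassifierError("age_sq must equal age squared")
        if self.hand_left and self.hand_ambi:
            raise ClassifierError("at most one handedness indicator may be set")

    @classmethod
    def from_record(cls, record: PhenotypeRecord) -> "CovariateVector":
        if record.handedness is None:
            raise ClassifierError(
                f"subject {record.subject_id!r} lacks handedness; impute upstream"
            )
        return cls(
            age=record.age,
            age_sq=record.age**2,
            gender=1.0 if record.gender == "female" else 0.0,
            hand_left=1.0 if record.handedness == "left" else 0.0,
            hand_ambi=1.0 if record.handedness == "ambidextrous" else 0.0,
        )

    def as_row(self) -> np.ndarray:
        return np.array(
            [self.age, self.age_sq, self.gender, self.hand_left, self.hand_ambi]
        )


def design_from_records(records: Sequence[PhenotypeRecord]) -> np.ndarray:
    """(n, 5) covariate design (no intercept column)."""
    return np.stack([CovariateVector.from_record(r).as_row() for r in records])


def _independent_columns(X: np.ndarray, tol: float = 1e-9) -> list[int]:
    """Greedy left-to-right selection of linearly independent columns."""
    kept: list[int] = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        cand = np.column_stack([basis, X[:, j]])
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(X).max())) > basis.shape[1]:
            kept.append(j)
            basis = cand
    return kept


@dataclass
class GroupModelFit:
    """Least-squares fit of one group's values on intercept + covariates."""

    coefficients: np.ndarray  # over intercept + kept covariate columns
    kept_columns: list[int]  # indices into COVARIATE_NAMES
    dropped_columns: list[int]
    group: str
    n_fit: int
    residual_df: int
    degenerate: bool = False

    def predict(self, cov: CovariateVector | np.ndarray) -> float:
        row = cov.as_row() if isinstance(cov, CovariateVector) else np.asarray(cov, dtype=float)
        full = np.concatenate([[1.0], row[self.kept_columns]])
        return float(full @ self.coefficients)


def fit_group_model(
    values: np.ndarray,
    covariates: Sequence[CovariateVector] | np.ndarray,
    group: str = "group",
) -> GroupModelFit:
    """Fit intercept + age + age^2 + gender + handedness to one group's values.

    Rank-deficient covariate columns (e.g. a single-gender group) are dropped
    and recorded.  When fewer subjects than retained columns + 1 remain, the
    fit is flagged degenerate and falls back to the group mean.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or y.shape[0] < 2:
        raise ClassifierError("need a 1-D vector of at least 2 values")
    if not np.isfinite(y).all():
        raise ClassifierError("values must be finite")
    D = (
        np.asarray(covariates, dtype=float)
        if isinstance(covariates, np.ndarray)
        else np.stack([c.as_row() for c in covariates])
    )
    if D.shape != (y.shape[0], len(COVARIATE_NAMES)):
        raise ClassifierError("covariate design must be (n, 5)")
    n = y.shape[0]
    X_full = np.column_stack([np.ones(n), D])
    kept_with_icpt = _independent_columns(X_full)
    if 0 not in kept_with_icpt:  # intercept always retained
        kept_with_icpt = [0] + [j for j in kept_with_icpt if j != 0]
    kept = [j - 1 for j in kept_with_icpt if j != 0]
    dropped = [j for j in range(len(COVARIATE_NAMES)) if j not in kept]
    if n < len(kept) + 2:  # fewer subjects than retained columns + intercept + 1
        return GroupModelFit(
            coefficients=np.array([y.mean()]),
            kept_columns=[],
            dropped_columns=list(range(len(COVARIATE_NAMES))),
            group=group,
            n_fit=n,
            residual_df=n - 1,
            degenerate=True,
        )
    X = X_full[:, kept_with_icpt]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return GroupModelFit(
        coefficients=beta,
        kept_columns=kept,
        dropped_columns=dropped,
        group=group,
        n_fit=n,
        residual_df=n - X.shape[1],
    )


def predict_for_subject(fit: GroupModelFit, cov: CovariateVector) -> float:
    """Model prediction for a subject's covariates (dropped columns contribute 0)."""
    return fit.predict(cov)


# ---------------------------------------------------------------------------
# per-connection statistics and scoring
# ---------------------------------------------------------------------------


@dataclass
class ConnectionStats:
    """Two-sample group statistics for one connection."""

    t: float
    F: float
    p: float
    degenerate: bool = False


def connection_stats(values_aut: np.ndarray, values_ctl: np.ndarray) -> ConnectionStats:
    """Pooled-variance two-sample t (autism minus control), F = t^2.

    Zero pooled variance makes t undefined: the stats are flagged and the
    connection is excluded from selection with F = 0.
    """
    a = np.asarray(values_aut, dtype=float)
    b = np.asarray(values_ctl, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ClassifierError("need at least 2 subjects per group")
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled <= 0:
        return ConnectionStats(t=float("nan"), F=0.0, p=1.0, degenerate=True)
    se = np.sqrt(pooled * (1.0 / a.size + 1.0 / b.size))
    t = (a.mean() - b.mean()) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return ConnectionStats(t=float(t), F=float(t * t), p=float(max(p, np.finfo(float).tiny)))


def score_connection(x: float, est_aut: float, est_ctl: float, F: float) -> float:
    """F-weighted contrast of absolute deviations from the two estimates.

    Positive when x is closer to the autism estimate than the control one.
    """
    return (abs(x - est_ctl) - abs(x - est_aut)) * F


def site_offset(
    values: np.ndarray,
    sites: Sequence[str],
    target_site: str,
    exclude: int | None = None,
) -> float:
    """Mean of ``target_site`` (excluding subject ``exclude``) minus the mean
    of all other sites.  Offset is 0 (with a warning) for single-site data."""
    v = np.asarray(values, dtype=float)
    sites_arr = np.asarray(sites)
    in_site = sites_arr == target_site
    if exclude is not None:
        keep = np.ones(v.shape[0], dtype=bool)
        keep[exclude] = False
    else:
        keep = np.ones(v.shape[0], dtype=bool)
    site_vals = v[in_site & keep]
    other_vals = v[~in_site & keep]
    if other_vals.size == 0:
        warnings.warn("single-site data: site offset defined as 0", RuntimeWarning, stacklevel=2)
        return 0.0
    if site_vals.size == 0:
        raise ClassifierError(
            f"site {target_site!r} has no subjects besides the excluded one"
        )
    return float(site_vals.mean() - other_vals.mean())


# ---------------------------------------------------------------------------
# vectorized leave-one-out engine
# ---------------------------------------------------------------------------


@dataclass
class LOOConnectionScores:
    """Per-(left-out subject, connection) scores and selection statistics.

    ``scores[s, c]`` is the F-weighted connection score of subject s at
    connection c, computed with s fully held out; ``pvals[s, c]`` the group
    t-test p-value among the remaining subjects (1.0 for degenerate
    connections, which are never selected).
    """

    subject_ids: list[str]
    labels: np.ndarray  # diagnosis per subject
    sites: np.ndarray
    scores: np.ndarray  # (n, C)
    pvals: np.ndarray  # (n, C)
    degenerate: np.ndarray  # (n, C) bool
    R: int

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def _site_adjusted_values(
    V: np.ndarray, sites: np.ndarray, left_out: int
) -> tuple[np.ndarray, np.ndarray]:
    """Harmonized values for all subjects given one left-out subject.

    Every subject's values get their site's mean (over remaining subjects)
    removed and the remaining grand mean restored; the left-out subject's own
    values never enter any mean.
    """
    n = V.shape[0]
    keep = np.ones(n, dtype=bool)
    keep[left_out] = False
    grand = V[keep].mean(axis=0)
    adjusted = np.empty_like(V)
    for site in np.unique(sites):
        members = sites == site
        train = members & keep
        m = V[train].mean(axis=0) if train.any() else grand
        adjusted[members] = V[members] - m + grand
    return adjusted, grand


def _group_predictions(
    V_rem: np.ndarray, D_rem: np.ndarray, cov_row: np.ndarray
) -> np.ndarray:
    """Vectorized GLM fit of one group's values at every connection, evaluated
    at the left-out subject's covariates.  Returns a (C,) prediction vector."""
    n = V_rem.shape[0]
    X_full = np.column_stack([np.ones(n), D_rem])
    kept_with_icpt = _independent_columns(X_full)
    if 0 not in kept_with_icpt:
        kept_with_icpt = [0] + [j for j in kept_with_icpt if j != 0]
    if n < len(kept_with_icpt) + 1:
        return V_rem.mean(axis=0)
    X = X_full[:, kept_with_icpt]
    beta, *_ = np.linalg.lstsq(X, V_rem, rcond=None)
    x_row = np.concatenate([[1.0], cov_row])[kept_with_icpt]
    return x_row @ beta


def _vectorized_group_stats(
    A: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled two-sample t, p, and degeneracy mask across connections."""
    n1, n2 = A.shape[0], B.shape[0]
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * A.var(axis=0, ddof=1) + (n2 - 1) * B.var(axis=0, ddof=1)) / df
    degen = pooled <= 0
    se = np.sqrt(np.where(degen, 1.0, pooled) * (1.0 / n1 + 1.0 / n2))
    t = (A.mean(axis=0) - B.mean(axis=0)) / se
    t = np.where(degen, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degen, 1.0, np.maximum(p, np.finfo(float).tiny))
    return t, p, degen


def per_connection_loo(
    dataset: CohortDataset,
    site_adjust: str = "harmonize",
) -> LOOConnectionScores:
    """Compute every subject's per-connection LOO scores and selection stats.

    This is the expensive step; its output feeds any subset rule (all
    connections, p-value thresholds, strength/distance bins, per-ROI) without
    refitting.
    """
    if site_adjust not in ("harmonize", "estimates"):
        raise ValueError(f"unknown site_adjust {site_adjust!r}")
    V = dataset.values_matrix()
    n, C = V.shape
    labels = np.array([p.diagnosis for p in dataset.phenotypes])
    sites = np.array([p.site for p in dataset.phenotypes])
    D = design_from_records(dataset.phenotypes)

    scores = np.zeros((n, C))
    pvals = np.ones((n, C))
    degen = np.zeros((n, C), dtype=bool)
    multi_site = len(np.unique(sites)) > 1

    for s in range(n):
        keep = np.ones(n, dtype=bool)
        keep[s] = False
        aut = keep & (labels == "autism")
        ctl = keep & (labels == "control")
        if aut.sum() < 2 or ctl.sum() < 2:
            raise ClassifierError(
                f"leaving out {dataset.phenotypes[s].subject_id!r} leaves fewer "
                "than 2 subjects in a diagnosis group"
            )
        if site_adjust == "harmonize" and multi_site:
            Vadj, _ = _site_adjusted_values(V, sites, s)
        else:
            Vadj = V
        x = Vadj[s]
        t, p, dg = _vectorized_group_stats(Vadj[aut], Vadj[ctl])
        est_aut = _group_predictions(Vadj[aut], D[aut], D[s])
        est_ctl = _group_predictions(Vadj[ctl], D[ctl], D[s])
        if site_adjust == "estimates" and multi_site:
            own = sites == sites[s]
            site_train = own & keep
            if site_train.any():
                off = V[site_train].mean(axis=0) - V[keep & ~own].mean(axis=0)
                est_aut = est_aut + off
                est_ctl = est_ctl + off
        F = np.where(dg, 0.0, t * t)
        scores[s] = (np.abs(x - est_ctl) - np.abs(x - est_aut)) * F
        pvals[s] = p
        degen[s] = dg

    return LOOConnectionScores(
        subject_ids=[p.subject_id for p in dataset.phenotypes],
        labels=labels,
        sites=sites,
        scores=scores,
        pvals=pvals,
        degenerate=degen,
        R=dataset.n_rois,
    )


def aggregate_roi_score(
    conn_scores: np.ndarray, subset: np.ndarray, R: int
) -> float:
    """ROI-aggregated classification score over a connection subset.

    Per-ROI value = mean of the subset connections incident to the ROI (ROIs
    with none contribute 0); the score is the sum of per-ROI values.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        return 0.0
    iu, ju = connection_pairs(R)
    vals = conn_scores[subset]
    roi_sum = np.bincount(iu[subset], weights=vals, minlength=R) + np.bincount(
        ju[subset], weights=vals, minlength=R
    )
    roi_cnt = np.bincount(iu[subset], minlength=R) + np.bincount(ju[subset], minlength=R)
    per_roi = np.divide(roi_sum, roi_cnt, out=np.zeros(R), where=roi_cnt > 0)
    return float(per_roi.sum())


def select_connections(
    dataset: CohortDataset,
    left_out: int,
    alpha: float,
    precomputed: LOOConnectionScores | None = None,
) -> np.ndarray:
    """Connections whose group t-test among remaining subjects has p < alpha."""
    if not (0.0 < alpha <= 1.0):
        raise ClassifierError("alpha must lie in (0, 1]")
    pre = precomputed or per_connection_loo(dataset)
    mask = (pre.pvals[left_out] < alpha) & ~pre.degenerate[left_out]
    if alpha == 1.0:
        mask = ~pre.degenerate[left_out]
    return np.flatnonzero(mask)


@dataclass
class ClassificationResult:
    """One subject's leave-one-out score and predicted label."""

    subject_id: str
    score: float
    predicted: str
    actual: str
    subset: str
    threshold: float = 0.0
    flagged: bool = False


def _subset_for(
    pre: LOOConnectionScores, s: int, subset_rule
) -> tuple[np.ndarray, str]:
    C = pre.scores.shape[1]
    if subset_rule == "all" or subset_rule is None:
        return np.arange(C), "all"
    kind = subset_rule[0]
    if kind == "p":
        alpha = float(subset_rule[1])
        mask = (pre.pvals[s] < alpha) & ~pre.degenerate[s]
        return np.flatnonzero(mask), f"p<{alpha:g}"
    if kind == "indices":
        return np.asarray(subset_rule[1], dtype=int), "indices"
    raise ValueError(f"unknown subset rule {subset_rule!r}")


def loo_scores(
    dataset: CohortDataset,
    subset_rule="all",
    precomputed: LOOConnectionScores | None = None,
    site_adjust: str = "harmonize",
) -> list[ClassificationResult]:
    """One leave-one-out classification score per subject.

    ``subset_rule`` is ``"all"``, ``("p", alpha)`` for per-left-out p-value
    selection, or ``("indices", array)`` for a fixed connection subset (e.g. a
    strength/distance bin).  An empty subset gives score 0, the majority label
    of the remaining subjects, and a flag.
    """
    pre = precomputed or per_connection_loo(dataset, site_adjust=site_adjust)
    results = []
    n = pre.n_subjects
    for s in range(n):
        subset, descr = _subset_for(pre, s, subset_rule)
        if subset.size == 0:
            rem = np.delete(pre.labels, s)
            counts = {lv: int((rem == lv).sum()) for lv in ("autism", "control")}
            majority = max(counts, key=lambda lv: (counts[lv], lv == "control"))
            results.append(
                ClassificationResult(
                    subject_id=pre.subject_ids[s],
                    score=0.0,
                    predicted=majority,
                    actual=str(pre.labels[s]),
                    subset=descr,
                    flagged=True,
                )
            )
            continue
        score = aggregate_roi_score(pre.scores[s], subset, pre.R)
        results.append(
            ClassificationResult(
                subject_id=pre.subject_ids[s],
                score=score,
                predicted="autism" if score > 0 else "control",
                actual=str(pre.labels[s]),
                subset=descr,
            )
        )
    return results


def classify_left_out(
    dataset: CohortDataset,
    left_out: int,
    subset: np.ndarray | str = "all",
    precomputed: LOOConnectionScores | None = None,
) -> float:
    """Classification score of one left-out subject over a connection subset."""
    pre = precomputed or per_connection_loo(dataset)
    if isinstance(subset, str) and subset == "all":
        subset_idx = np.arange(pre.scores.shape[1])
    else:
        subset_idx = np.asarray(subset, dtype=int)
    if subset_idx.size == 0:
        return 0.0
    return aggregate_roi_score(pre.scores[left_out], subset_idx, pre.R)


def left_out_details(
    dataset: CohortDataset, left_out: int, site_adjust: str = "harmonize"
) -> dict:
    """Instrumented single-subject computation for hygiene checks.

    Returns the per-connection estimates, F statistics, p-values, and the
    left-out subject's (site-adjusted) values, computed exactly as the engine
    does.  None of the returned model quantities depend on the left-out
    subject's connectivity values.
    """
    V = dataset.values_matrix()
    labels = np.array([p.diagnosis for p in dataset.phenotypes])
    sites = np.array([p.site for p in dataset.phenotypes])
    D = design_from_records(dataset.phenotypes)
    keep = np.ones(V.shape[0], dtype=bool)
    keep[left_out] = False
    multi_site = len(np.unique(sites)) > 1
    if site_adjust == "harmonize" and multi_site:
        Vadj, _ = _site_adjusted_values(V, sites, left_out)
    else:
        Vadj = V
    aut = keep & (labels == "autism")
    ctl = keep & (labels == "control")
    t, p, dg = _vectorized_group_stats(Vadj[aut], Vadj[ctl])
    est_aut = _group_predictions(Vadj[aut], D[aut], D[left_out])
    est_ctl = _group_predictions(Vadj[ctl], D[ctl], D[left_out])
    F = np.where(dg, 0.0, t * t)
    return {
        "x": Vadj[left_out],
        "est_aut": est_aut,
        "est_ctl": est_ctl,
        "F": F,
        "pvals": p,
        "degenerate": dg,
    }


# ---------------------------------------------------------------------------
# per-ROI and per-bin accuracy
# ---------------------------------------------------------------------------


@dataclass
class PerROIAccuracy:
    accuracy: np.ndarray  # (R,)
    display_floor: float


def per_roi_accuracy(
    dataset: CohortDataset,
    precomputed: LOOConnectionScores | None = None,
    fdr_q: float = 0.05,
) -> PerROIAccuracy:
    """Zero-threshold LOO accuracy of each ROI's incident-connection classifier.

    For each ROI the scoring is restricted to the connections it participates
    in (no p-value threshold).  Also reports a display floor: the binomial
    critical fraction at the Benjamini-Hochberg boundary where all R regions
    share one p-value, i.e. critical_count(n, q) / n.
    """
    from .evaluation import binomial_critical_count

    pre = precomputed or per_connection_loo(dataset)
    n, C = pre.scores.shape
    R = pre.R
    iu, ju = connection_pairs(R)
    # incidence matrix (C, R): connection c touches ROIs iu[c] and ju[c]
    M = np.zeros((C, R))
    M[np.arange(C), iu] = 1.0
    M[np.arange(C), ju] = 1.0
    inc_sum = pre.scores @ M  # (n, R): sum of scores over incident connections
    # restricted-subset score: own ROI mean over R-1 incident connections plus
    # one-connection means of every opposite ROI -> (1 + 1/(R-1)) * inc_sum
    roi_scores = inc_sum * (1.0 + 1.0 / (R - 1))
    predicted = np.where(roi_scores > 0, "autism", "control")
    acc = (predicted == pre.labels[:, None]).mean(axis=0)
    floor = binomial_critical_count(n, fdr_q) / n
    return PerROIAccuracy(accuracy=acc, display_floor=float(floor))


def per_bin_accuracy(
    dataset: CohortDataset,
    z_bins: np.ndarray,
    d_bins: np.ndarray,
    precomputed: LOOConnectionScores | None = None,
):
    """Zero-threshold LOO accuracy per occupied (strength, distance) bin.

    Returns a DataFrame with columns z_bin, d_bin, n_connections, accuracy;
    bins with no connections are absent.
    """
    import pandas as pd

    from .connectivity import bin_table

    pre = precomputed or per_connection_loo(dataset)
    table = bin_table(np.asarray(z_bins), np.asarray(d_bins))
    rows = []
    for (zb, db), idx in sorted(table.items()):
        correct = 0
        for s in range(pre.n_subjects):
            score = aggregate_roi_score(pre.scores[s], idx, pre.R)
            pred = "autism" if score > 0 else "control"
            correct += pred == pre.labels[s]
        rows.append(
            {
                "z_bin": zb,
                "d_bin": db,
                "n_connections": int(idx.size),
                "accuracy": correct / pre.n_subjects,
            }
        )
    return pd.DataFrame(rows, columns=["z_bin", "d_bin", "n_connections", "accuracy"])
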