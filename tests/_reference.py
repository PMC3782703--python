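"""Naive per-connection reference implementation of the LOO classifier.

Deliberately slow and explicit: Python loops over connections, group fits by
normal equations (pinv), hand-built site harmonization and ROI aggregation.
Independent of the vectorized production path; used as the oracle for
equivalence tests on small cohorts.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def _design(records):
    rows = []
    for r in records:
        rows.append(
            [
                r.age,
                r.age**2,
                1.0 if r.gender == "female" else 0.0,
                1.0 if r.handedness == "left" else 0.0,
                1.0 if r.handedness == "ambidextrous" else 0.0,
            ]
        )
    return np.array(rows)


def naive_loo(dataset):
    """Per-subject scores, per-connection scores, and p-values, the slow way."""
    n = dataset.n_subjects
    R = dataset.n_rois
    labels = [p.diagnosis for p in dataset.phenotypes]
    sites = [p.site for p in dataset.phenotypes]
    D = _design(dataset.phenotypes)
    pairs = [(i, j) for i in range(R) for j in range(i + 1, R)]
    C = len(pairs)
    V = np.array([[m.values[i, j] for (i, j) in pairs] for m in dataset.matrices])

    conn_scores = np.zeros((n, C))
    pvals = np.ones((n, C))
    subject_scores = np.zeros(n)
    multi_site = len(set(sites)) > 1

    for s in range(n):
        rem = [r for r in range(n) if r != s]
        if multi_site:
            grand = V[rem].mean(axis=0)
            adj = np.zeros_like(V)
            for r in range(n):
                members = [q for q in rem if sites[q] == sites[r]]
                m = V[members].mean(axis=0) if members else grand
                adj[r] = V[r] - m + grand
        else:
            adj = V
        a_idx = [r for r in rem if labels[r] == "autism"]
        c_idx = [r for r in rem if labels[r] == "control"]
        x_row = np.concatenate([[1.0], D[s]])
        Xa = np.column_stack([np.ones(len(a_idx)), D[a_idx]])
        Xc = np.column_stack([np.ones(len(c_idx)), D[c_idx]])
        Ha = np.linalg.pinv(Xa.T @ Xa) @ Xa.T
        Hc = np.linalg.pinv(Xc.T @ Xc) @ Xc.T
        for c in range(C):
            ya = adj[a_idx, c]
            yc = adj[c_idx, c]
            df = len(ya) + len(yc) - 2
            pooled = (
                (len(ya) - 1) * ya.var(ddof=1) + (len(yc) - 1) * yc.var(ddof=1)
            ) / df
            if pooled <= 0:
                F = 0.0
                pvals[s, c] = 1.0
            else:
                se = np.sqrt(pooled * (1.0 / len(ya) + 1.0 / len(yc)))
                t = (ya.mean() - yc.mean()) / se
                F = t * t
                pvals[s, c] = 2.0 * stats.t.sf(abs(t), df)
            est_a = float(x_row @ (Ha @ ya))
            est_c = float(x_row @ (Hc @ yc))
            x = adj[s, c]
            conn_scores[s, c] = (abs(x - est_c) - abs(x - est_a)) * F
        per_roi = []
        for roi in range(R):
            inc = [c for c, (i, j) in enumerate(pairs) if i == roi or j == roi]
            per_roi.append(np.mean(conn_scores[s, inc]))
        subject_scores[s] = float(np.sum(per_roi))
    return subject_scores, conn_scores, pvals
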