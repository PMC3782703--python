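"""ROI time courses, Fisher-z association matrices, ROI distances, and
strength-by-distance connection binning.

Binning follows a half-open floor convention: a value v falls in bin
``floor((v - origin) / spacing)``, so bins tile the axis as
[origin + k*spacing, origin + (k+1)*spacing).  Negative Fisher-z values index
into negative bins with the same rule.  Reference strengths for binning must
come from a cohort disjoint from the one being classified (the caller's
contract; in this package, a second synthetic cohort with an independent
seed).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from dataclasses import dataclass

from .cohort import AssociationMatrix, CohortError, ROISet

#: r is clipped to +/-(1 - CLIP_EPS) before atanh so duplicated rows give a
#: large finite Fisher z instead of infinity.
CLIP_EPS = 1e-7


@dataclass
class BinSpec:
    """Two-dimensional bin geometry: Fisher-z strength by ROI distance."""

    z_spacing: float = 0.05
    d_spacing: float = 5.0
    z_origin: float = 0.0
    d_origin: float = 0.0

    def __post_init__(self) -> None:
        if self.z_spacing <= 0 or self.d_spacing <= 0:
            raise CohortError("bin spacings must be positive")


def roi_timecourses(voxel_series: np.ndarray, labels: np.ndarray, n_rois: int | None = None) -> np.ndarray:
    """Mean time course per ROI: row r averages the voxels labeled r."""
    x = np.asarray(voxel_series, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if x.ndim != 2 or labels.shape != (x.shape[0],):
        raise CohortError("voxel_series must be V x T with one label per voxel")
    R = int(labels.max()) + 1 if n_rois is None else n_rois
    if labels.min() < 0 or labels.max() >= R:
        raise CohortError("labels must lie in 0..R-1")
    counts = np.bincount(labels, minlength=R)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise CohortError(f"ROI {int(empty[0])} has no member voxels")
    out = np.zeros((R, x.shape[1]))
    np.add.at(out, labels, x)
    return out / counts[:, None]


def association_matrix(roi_series: np.ndarray, subject_id: str = "subject") -> AssociationMatrix:
    """Fisher-z Pearson correlation matrix of ROI time courses.

    Off-diagonal entry (i, j) is atanh(r_ij) with r clipped to
    +/-(1 - 1e-7); the diagonal is set to 0 and excluded by convention.
    """
    x = np.asarray(roi_series, dtype=float)
    if x.ndim != 2:
        raise CohortError("roi_series must be R x T")
    if x.shape[1] < 4:
        raise CohortError("need at least 4 time points")
    sds = x.std(axis=1)
    dead = np.flatnonzero(sds == 0)
    if dead.size:
        raise CohortError(f"ROI {int(dead[0])} has zero variance")
    r = np.corrcoef(x)
    r = np.clip(r, -(1.0 - CLIP_EPS), 1.0 - CLIP_EPS)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return AssociationMatrix(subject_id=subject_id, values=z)


def distance_matrix(rois: ROISet) -> np.ndarray:
    """Pairwise Euclidean distances (mm) between ROI centroids."""
    return squareform(pdist(rois.centroids))


def assign_strength_distance_bins(
    reference_strength: np.ndarray,
    distances: np.ndarray,
    spec: BinSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-connection (z_bin, d_bin) integer indices under the floor rule.

    A tiny epsilon (1e-9 of a spacing) guards against values that are exact
    bin edges up to floating-point representation landing one bin low.
    """
    spec = spec or BinSpec()
    z = np.asarray(reference_strength, dtype=float)
    d = np.asarray(distances, dtype=float)
    if z.shape != d.shape:
        raise CohortError("strengths and distances must align per connection")
    z_bins = np.floor((z - spec.z_origin) / spec.z_spacing + 1e-9).astype(int)
    d_bins = np.floor((d - spec.d_origin) / spec.d_spacing + 1e-9).astype(int)
    return z_bins, d_bins


def bin_table(z_bins: np.ndarray, d_bins: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
    """Map each occupied (z_bin, d_bin) to the connection indices it holds."""
    out: dict[tuple[int, int], list[int]] = {}
    for c, key in enumerate(zip(z_bins.tolist(), d_bins.tolist())):
        out.setdefault(key, []).append(c)
    return {k: np.asarray(v, dtype=int) for k, v in out.items()}
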