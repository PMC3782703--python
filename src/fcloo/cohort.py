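"""Cohort data model and file I/O.

The unit of data is a subject: a phenotype record (site, diagnosis, demographic
covariates, behavioral scores, scan-volume accounting) paired with a symmetric
R x R Fisher-z association matrix over a fixed set of R regions of interest
(ROIs).  A "connection" is an unordered ROI pair (i, j) with i < j, enumerated
in lexicographic order; that enumeration is the canonical one everywhere in
this package (it matches ``numpy.triu_indices(R, k=1)``).

File formats
------------
* Phenotype tables: tab- or comma-separated with a header row; missing values
  are empty fields or ``NA``.
* ROI centroid tables: 4 delimited columns ``roi_id, x, y, z`` (mm).
* Association matrices: a binary container (8-byte little-endian uint64 header
  giving R, then R*R row-major float64) for bit-exact round trips, plus a
  tab-separated text dialect for human-readable fixtures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DIAGNOSIS_LEVELS = ("autism", "control")
GENDER_LEVELS = ("male", "female")
HANDEDNESS_LEVELS = ("right", "left", "ambidextrous")
EYES_LEVELS = ("open", "closed", "unknown")

#: Behavioral measures carried on a phenotype record, in canonical order.
BEHAVIOR_FIELDS = (
    "ados_social_comm",
    "adi_r_social",
    "adi_r_verbal",
    "verbal_iq",
    "performance_iq",
    "srs_total",
    "vineland_composite",
)

PHENOTYPE_COLUMNS = (
    "subject_id",
    "site",
    "diagnosis",
    "age",
    "gender",
    "handedness",
    "eyes",
    "n_volumes_acquired",
    "n_volumes_retained",
) + BEHAVIOR_FIELDS

_NA_SENTINELS = ("", "NA")


class CohortError(ValueError):
    """Raised when cohort data violate a documented invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeRecord:
    """One subject's demographics, site, diagnosis and behavioral scores."""

    subject_id: str
    site: str
    diagnosis: str
    age: float
    gender: str
    handedness: str | None = None
    eyes: str = "unknown"
    n_volumes_acquired: int | None = None
    n_volumes_retained: int | None = None
    ados_social_comm: float | None = None
    adi_r_social: float | None = None
    adi_r_verbal: float | None = None
    verbal_iq: float | None = None
    performance_iq: float | None = None
    srs_total: float | None = None
    vineland_composite: float | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSIS_LEVELS:
            raise CohortError(
                f"subject {self.subject_id!r}: unknown diagnosis {self.diagnosis!r}"
            )
        if self.gender not in GENDER_LEVELS:
            raise CohortError(
                f"subject {self.subject_id!r}: unknown gender {self.gender!r}"
            )
        if self.handedness is not None and self.handedness not in HANDEDNESS_LEVELS:
            raise CohortError(
                f"subject {self.subject_id!r}: unknown handedness {self.handedness!r}"
            )
        if self.eyes not in EYES_LEVELS:
            raise CohortError(f"subject {self.subject_id!r}: unknown eyes {self.eyes!r}")
        if not (self.age > 0):
            raise CohortError(f"subject {self.subject_id!r}: age must be positive")
        if (
            self.n_volumes_acquired is not None
            and self.n_volumes_retained is not None
            and self.n_volumes_retained > self.n_volumes_acquired
        ):
            raise CohortError(
                f"subject {self.subject_id!r}: retained volumes exceed acquired"
            )

    def behavior(self, name: str) -> float | None:
        if name not in BEHAVIOR_FIELDS:
            raise KeyError(name)
        return getattr(self, name)


@dataclass
class ROISet:
    """ROI ids with centroid coordinates in mm (and optional voxel counts)."""

    centroids: np.ndarray  # (R, 3) float mm
    n_voxels: np.ndarray | None = None  # (R,) int

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or self.centroids.shape[1] != 3:
            raise CohortError("centroids must be an (R, 3) array")
        if self.centroids.shape[0] < 2:
            raise CohortError("an ROISet needs at least 2 ROIs")
        if not np.isfinite(self.centroids).all():
            raise CohortError("centroids must be finite")
        uniq = np.unique(self.centroids, axis=0)
        if uniq.shape[0] != self.centroids.shape[0]:
            raise CohortError("ROI centroids must be unique")
        if self.n_voxels is not None:
            self.n_voxels = np.asarray(self.n_voxels, dtype=int)
            if self.n_voxels.shape != (self.centroids.shape[0],):
                raise CohortError("n_voxels must have one entry per ROI")

    @property
    def n_rois(self) -> int:
        return int(self.centroids.shape[0])


@dataclass
class AssociationMatrix:
    """A subject's symmetric R x R Fisher-z connectivity matrix.

    The diagonal is undefined by convention (stored as 0, never read by any
    downstream operation).  Off-diagonal entries must be finite and symmetric.
    """

    subject_id: str
    values: np.ndarray

    SYMMETRY_TOL = 1e-10

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise CohortError(f"matrix for {self.subject_id!r} is not square")
        asym = np.abs(v - v.T).max() if v.size else 0.0
        if asym > self.SYMMETRY_TOL:
            raise CohortError(
                f"matrix for {self.subject_id!r} asymmetric (max |A-A.T| = {asym:g})"
            )
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and not np.isfinite(off).all():
            raise CohortError(f"matrix for {self.subject_id!r} has non-finite entries")

    @property
    def n_rois(self) -> int:
        return int(self.values.shape[0])

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in canonical connection order (i < j)."""
        iu, ju = connection_pairs(self.n_rois)
        return self.values[iu, ju]


def connection_pairs(R: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical enumeration of connections: (i, j), i < j, lexicographic."""
    return np.triu_indices(R, k=1)


def n_connections(R: int) -> int:
    """Number of unordered ROI pairs for R ROIs."""
    return R * (R - 1) // 2


def matrix_from_condensed(subject_id: str, condensed: np.ndarray, R: int) -> AssociationMatrix:
    """Build a symmetric AssociationMatrix from condensed connection values."""
    condensed = np.asarray(condensed, dtype=float)
    if condensed.shape != (n_connections(R),):
        raise CohortError("condensed vector length does not match R")
    v = np.zeros((R, R))
    iu, ju = connection_pairs(R)
    v[iu, ju] = condensed
    v[ju, iu] = condensed
    return AssociationMatrix(subject_id=subject_id, values=v)


@dataclass
class CohortDataset:
    """Phenotypes + one association matrix per subject + ROI geometry."""

    phenotypes: list[PhenotypeRecord]
    matrices: list[AssociationMatrix]
    rois: ROISet | None = None
    single_site_ok: bool = False

    def __post_init__(self) -> None:
        if len(self.phenotypes) != len(self.matrices):
            raise CohortError("one matrix per phenotype record required")
        ids_p = [p.subject_id for p in self.phenotypes]
        ids_m = [m.subject_id for m in self.matrices]
        if ids_p != ids_m:
            raise CohortError("phenotype and matrix subject ids do not align")
        if len(set(ids_p)) != len(ids_p):
            raise CohortError("duplicate subject ids")
        Rs = {m.n_rois for m in self.matrices}
        if len(Rs) > 1:
            raise CohortError(f"inconsistent ROI counts across matrices: {sorted(Rs)}")
        if self.rois is not None and self.matrices and self.rois.n_rois != self.n_rois:
            raise CohortError("ROISet size does not match matrices")
        diagnoses = {p.diagnosis for p in self.phenotypes}
        if diagnoses != set(DIAGNOSIS_LEVELS):
            raise CohortError("both diagnoses must be present in a cohort")
        sites = {p.site for p in self.phenotypes}
        if len(sites) < 2 and not self.single_site_ok:
            raise CohortError(
                "single-site cohort; pass single_site_ok=True to accept it"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.phenotypes)

    @property
    def n_rois(self) -> int:
        return self.matrices[0].n_rois if self.matrices else 0

    def values_matrix(self) -> np.ndarray:
        """(n_subjects, n_connections) array of condensed connection values."""
        return np.stack([m.condensed() for m in self.matrices])

    def phenotype_frame(self) -> pd.DataFrame:
        return phenotypes_to_frame(self.phenotypes)


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------


def _parse_handedness(raw: object) -> str | None:
    """Categorical handedness, converting quantitative values by sign.

    Positive quantitative values map to right-handed, negative to left-handed,
    and exactly zero to ambidextrous.
    """
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if s in _NA_SENTINELS:
        return None
    low = s.lower()
    if low in HANDEDNESS_LEVELS:
        return low
    try:
        q = float(s)
    except ValueError as exc:
        raise CohortError(f"unparseable handedness value {s!r}") from exc
    if q > 0:
        return "right"
    if q < 0:
        return "left"
    return "ambidextrous"


def _opt_float(value: object) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _opt_int(value: object) -> int | None:
    f = _opt_float(value)
    return None if f is None else int(round(f))


def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    """Read a delimited phenotype table into validated records.

    The delimiter (tab or comma) is sniffed from the header line.  Unknown
    categorical levels raise with the offending row named; duplicate subject
    ids raise.
    """
    path = Path(path)
    header = path.read_text().splitlines()[0] if path.stat().st_size else ""
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(
        path, sep=sep, dtype=str, keep_default_na=False, na_values=list(_NA_SENTINELS)
    )
    missing_cols = [c for c in ("subject_id", "site", "diagnosis", "age", "gender") if c not in df.columns]
    if missing_cols:
        raise CohortError(f"phenotype table lacks required columns {missing_cols}")
    records: list[PhenotypeRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        sid = str(row["subject_id"]).strip()
        if sid in seen:
            raise CohortError(f"duplicate subject_id {sid!r}")
        seen.add(sid)
        raw_eyes = row.get("eyes")
        eyes = "unknown" if pd.isna(raw_eyes) else str(raw_eyes).strip().lower()
        try:
            rec = PhenotypeRecord(
                subject_id=sid,
                site=str(row["site"]).strip(),
                diagnosis=str(row["diagnosis"]).strip().lower(),
                age=float(row["age"]),
                gender=str(row["gender"]).strip().lower(),
                handedness=_parse_handedness(row.get("handedness")),
                eyes=eyes,
                n_volumes_acquired=_opt_int(row.get("n_volumes_acquired")),
                n_volumes_retained=_opt_int(row.get("n_volumes_retained")),
                **{f: _opt_float(row.get(f)) for f in BEHAVIOR_FIELDS},
            )
        except CohortError as exc:
            raise CohortError(f"row {idx}: {exc}") from exc
        records.append(rec)
    return records


def phenotypes_to_frame(records: Sequence[PhenotypeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in PHENOTYPE_COLUMNS})
    return pd.DataFrame(rows, columns=list(PHENOTYPE_COLUMNS))


def write_phenotypes(records: Sequence[PhenotypeRecord], path: str | Path) -> None:
    """Write records as a tab-separated table with NA for missing values."""
    df = phenotypes_to_frame(records)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


# ---------------------------------------------------------------------------
# handedness imputation
# ---------------------------------------------------------------------------


def impute_handedness(
    records: Sequence[PhenotypeRecord], k: int = 5
) -> list[PhenotypeRecord]:
    """Fill missing categorical handedness by k-nearest-neighbor majority vote.

    Features are standardized age plus one-hot gender and site (the covariates
    guaranteed present on every record); distance is Euclidean; ties among the
    k neighbors' labels go to the globally most frequent known label.  Known
    labels are never altered.
    """
    known = [r for r in records if r.handedness is not None]
    if not known:
        raise CohortError("cannot impute handedness: no record has a known label")
    if len(known) < k:
        raise CohortError(
            f"cannot impute handedness: need at least k={k} known labels, have {len(known)}"
        )
    if all(r.handedness is not None for r in records):
        return list(records)

    sites = sorted({r.site for r in records})
    ages = np.array([r.age for r in records], dtype=float)
    age_sd = ages.std()
    age_z = (ages - ages.mean()) / (age_sd if age_sd > 0 else 1.0)
    feats = np.column_stack(
        [age_z]
        + [np.array([1.0 if r.gender == g else 0.0 for r in records]) for g in GENDER_LEVELS]
        + [np.array([1.0 if r.site == s else 0.0 for r in records]) for s in sites]
    )
    known_idx = np.array([i for i, r in enumerate(records) if r.handedness is not None])
    counts = {lv: sum(1 for r in known if r.handedness == lv) for lv in HANDEDNESS_LEVELS}
    global_order = sorted(
        HANDEDNESS_LEVELS, key=lambda lv: (-counts[lv], HANDEDNESS_LEVELS.index(lv))
    )

    out: list[PhenotypeRecord] = []
    for i, r in enumerate(records):
        if r.handedness is not None:
            out.append(r)
            continue
        d = np.linalg.norm(feats[known_idx] - feats[i], axis=1)
        nearest = known_idx[np.argsort(d, kind="stable")[:k]]
        votes = {lv: 0 for lv in HANDEDNESS_LEVELS}
        for j in nearest:
            votes[records[j].handedness] += 1  # type: ignore[index]
        best = max(global_order, key=lambda lv: (votes[lv], -global_order.index(lv)))
        out.append(replace(r, handedness=best))
    return out


# ---------------------------------------------------------------------------
# lattice ROI construction
# ---------------------------------------------------------------------------


def build_lattice_rois(
    mask: np.ndarray,
    voxel_size_mm: float | Sequence[float],
    spacing_mm: float = 5.0,
    origin_mm: Sequence[float] = (0.0, 0.0, 0.0),
    z_range_mm: tuple[float, float] = (-35.0, 70.0),
) -> ROISet:
    """Regular lattice of ROI centroids restricted to a boolean voxel mask.

    Lattice candidates sit at integer multiples of ``spacing_mm`` in world
    coordinates (the frame in which voxel (0,0,0) starts at ``origin_mm``).  A
    candidate is kept when the voxel containing it is inside the mask and its z
    coordinate lies within ``z_range_mm``.  Each ROI's voxel count is the
    number of mask voxels whose centers fall in the half-open spacing-wide cube
    centered on the lattice point.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3 or not mask.any():
        raise CohortError("mask must be a nonempty 3-D boolean array")
    if spacing_mm <= 0:
        raise CohortError("spacing must be positive")
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,)).copy()
    origin = np.asarray(origin_mm, dtype=float)

    lo = origin
    hi = origin + vs * np.array(mask.shape)
    axes = []
    for a in range(3):
        k0 = math.ceil(lo[a] / spacing_mm - 1e-9)
        k1 = math.floor(hi[a] / spacing_mm + 1e-9)
        axes.append(np.arange(k0, k1 + 1) * spacing_mm)
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[(pts[:, 2] >= z_range_mm[0]) & (pts[:, 2] <= z_range_mm[1])]

    idx = np.floor((pts - origin) / vs).astype(int)
    in_bounds = np.all((idx >= 0) & (idx < np.array(mask.shape)), axis=1)
    covered = np.zeros(len(pts), dtype=bool)
    covered[in_bounds] = mask[tuple(idx[in_bounds].T)]
    centroids = pts[covered]
    if centroids.shape[0] == 0:
        raise CohortError("no lattice point falls inside the mask")

    vox_idx = np.argwhere(mask)
    centers = origin + (vox_idx + 0.5) * vs
    half = spacing_mm / 2.0
    nvox = np.zeros(centroids.shape[0], dtype=int)
    for r, p in enumerate(centroids):
        inside = np.all((centers >= p - half) & (centers < p + half), axis=1)
        nvox[r] = int(inside.sum())
    return ROISet(centroids=centroids, n_voxels=nvox)


def read_roi_centroids(path: str | Path) -> ROISet:
    """Read a 4-column delimited ROI table (roi_id, x, y, z in mm)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 4:
        raise CohortError("ROI table needs 4 columns: roi_id, x, y, z")
    df = df.sort_values(df.columns[0])
    return ROISet(centroids=df.iloc[:, 1:4].to_numpy(dtype=float))


def write_roi_centroids(rois: ROISet, path: str | Path) -> None:
    df = pd.DataFrame(rois.centroids, columns=["x", "y", "z"])
    df.insert(0, "roi_id", np.arange(rois.n_rois))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# association-matrix containers
# ---------------------------------------------------------------------------

_HEADER_DTYPE = np.dtype("<u8")


def write_matrix(
    matrix: AssociationMatrix, path: str | Path, fmt: str = "binary"
) -> None:
    """Write a matrix in the binary container (default) or the text dialect.

    Binary layout: 8-byte little-endian uint64 R, then R*R row-major float64.
    Text dialect: R tab-separated rows of 17-significant-digit floats.
    """
    path = Path(path)
    v = np.ascontiguousarray(matrix.values, dtype=float)
    if fmt == "binary":
        with open(path, "wb") as fh:
            fh.write(np.uint64(v.shape[0]).astype(_HEADER_DTYPE).tobytes())
            fh.write(v.astype("<f8").tobytes())
    elif fmt == "text":
        np.savetxt(path, v, fmt="%.17g", delimiter="\t")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")


def read_matrix(path: str | Path, subject_id: str | None = None) -> AssociationMatrix:
    """Read a matrix from either container, enforcing symmetry on read.

    The container is auto-detected: a file whose first 8 bytes decode to an R
    consistent with its size is binary, anything else is parsed as text.
    Asymmetry beyond 1e-10 and non-finite off-diagonal entries are rejected.
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem
    raw = path.read_bytes()
    values: np.ndarray | None = None
    if len(raw) >= 8:
        R = int(np.frombuffer(raw[:8], dtype=_HEADER_DTYPE)[0])
        if 0 < R < 10**6 and len(raw) == 8 + 8 * R * R:
            values = np.frombuffer(raw[8:], dtype="<f8").reshape(R, R).copy()
    if values is None:
        values = np.loadtxt(path, delimiter="\t", ndmin=2)
        if values.shape[0] != values.shape[1]:
            raise CohortError(f"{path}: non-square matrix payload")
    return AssociationMatrix(subject_id=subject_id, values=values)


def write_cohort_matrices(
    dataset: CohortDataset, directory: str | Path, fmt: str = "binary"
) -> list[Path]:
    """Write one matrix file per subject, named by subject_id."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = ".fzmat" if fmt == "binary" else ".tsv"
    paths = []
    for m in dataset.matrices:
        p = directory / f"{m.subject_id}{ext}"
        write_matrix(m, p, fmt=fmt)
        paths.append(p)
    return paths
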