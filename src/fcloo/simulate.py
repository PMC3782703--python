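"""Synthetic multisite cohort generator.

Emulates the statistical structure a multisite connectivity classifier has to
cope with: a subset of connections carrying a diagnosis effect scaled by a
latent per-subject severity, additive per-(site, connection) offsets, age and
age-squared trends, subject-level noise, finite-scan-length measurement noise,
per-subject head-motion traces, and behavioral scores tied to severity.

The generative model for subject s at connection c is

    z_sc = baseline_c + beta_age * age_s + beta_age2 * age_s^2
           + site_offset(site_s, c)
           + severity_s * delta * 1[c in affected] + eps_sc

with eps_sc ~ Normal(0, sigma_e^2 + 1/(T_ret,s - 3)) when finite-scan noise is
enabled (the second term is the asymptotic sampling variance of a Fisher-z
correlation estimated from T_ret retained volumes), severity_s = |Normal(1,
0.3^2)| for autism subjects and 0 for controls.  Behavioral scores are linear
maps of severity plus noise, with group directions matching the usual clinical
instruments (higher SRS/ADOS in autism, lower verbal IQ and Vineland).

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so identical parameters give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import (
    AssociationMatrix,
    CohortDataset,
    CohortError,
    PhenotypeRecord,
    ROISet,
    connection_pairs,
    matrix_from_condensed,
    n_connections,
)
from .preprocess import ScrubParams, framewise_displacement, scrub_mask

#: behavioral measure -> (intercept, slope on severity, noise sd scale,
#: population): group means anchor at intercept (severity 0, controls) and
#: intercept + slope (severity ~ 1, autism).
BEHAVIOR_MODELS: dict[str, tuple[float, float, float, str]] = {
    "ados_social_comm": (1.25, 10.6, 1.4, "all"),
    "adi_r_social": (14.0, 5.7, 2.8, "autism"),
    "adi_r_verbal": (11.4, 4.5, 2.3, "autism"),
    "verbal_iq": (112.0, -7.0, 13.3, "all"),
    "performance_iq": (108.0, -2.0, 13.3, "all"),
    "srs_total": (21.2, 70.4, 16.2, "all"),
    "vineland_composite": (105.0, -30.0, 11.6, "all"),
}


@dataclass
class SimParams:
    """Study conditions for one synthetic cohort.

    Defaults describe a small multisite resting-state cohort: 5 sites of 12
    subjects (6 autism / 6 control), 100 lattice ROIs, 150 volumes at TR=2 s,
    2% of connections affected with a 0.5 Fisher-z group effect, 0.1 z per-site
    offsets and 0.2 z subject noise, ages 6-60 years.
    """

    R: int = 100
    n_sites: int = 5
    subjects_per_site: int | Sequence[int] = 12
    autism_fraction: float = 0.5
    volumes_per_site: int | Sequence[int] = 150
    tr: float = 2.0
    effect_fraction: float = 0.02
    effect_size: float = 0.5
    site_offset_sd: float = 0.1
    age_slope: float = -0.003
    age_curvature: float = 2.0e-5
    subject_noise_sd: float = 0.2
    baseline_strength_range: tuple[float, float] = (-0.2, 0.8)
    motion_spike_rate: float = 0.05
    autism_motion_factor: float = 1.0
    behavior_noise_sd: float = 1.0
    scan_length_noise: bool = True
    age_range: tuple[float, float] = (6.0, 60.0)
    male_fraction: float = 0.85
    handedness_probs: tuple[float, float, float] = (0.862, 0.124, 0.014)
    handedness_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.effect_fraction <= 1.0):
            raise CohortError("effect_fraction must lie in [0, 1]")
        for name in ("site_offset_sd", "subject_noise_sd", "behavior_noise_sd"):
            if getattr(self, name) < 0:
                raise CohortError(f"{name} must be non-negative")
        if self.R < 2 or self.n_sites < 1:
            raise CohortError("need R >= 2 and at least one site")

    def site_counts(self) -> np.ndarray:
        c = self.subjects_per_site
        if np.isscalar(c):
            return np.full(self.n_sites, int(c))
        arr = np.asarray(c, dtype=int)
        if arr.shape != (self.n_sites,):
            raise CohortError("subjects_per_site must be scalar or length n_sites")
        return arr

    def site_volumes(self) -> np.ndarray:
        v = self.volumes_per_site
        if np.isscalar(v):
            return np.full(self.n_sites, int(v))
        arr = np.asarray(v, dtype=int)
        if arr.shape != (self.n_sites,):
            raise CohortError("volumes_per_site must be scalar or length n_sites")
        return arr


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    affected: np.ndarray  # indices into the canonical connection enumeration
    affected_pairs: list[tuple[int, int]]
    site_offsets: np.ndarray  # (n_sites, C)
    severity: np.ndarray  # (n,)
    baseline: np.ndarray  # (C,)
    coefficients: dict[str, float]


def _severity(diagnoses: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    sev = np.zeros(len(diagnoses))
    aut = diagnoses == "autism"
    sev[aut] = np.abs(rng.normal(1.0, 0.3, size=int(aut.sum())))
    return sev


def simulate_cohort(params: SimParams) -> tuple[CohortDataset, GroundTruth]:
    """Generate a multisite cohort and its ground truth.

    Deterministic for a fixed ``params.seed``.  Sites with a single diagnosis
    are allowed but trigger a warning downstream; per-site group splits follow
    ``autism_fraction`` with rounding.
    """
    ss = np.random.SeedSequence(params.seed)
    rng_struct, rng_subj, rng_mat, rng_motion, rng_behav = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    R = params.R
    C = n_connections(R)
    n_affected = int(round(params.effect_fraction * C))
    affected = np.sort(rng_struct.choice(C, size=n_affected, replace=False))
    affected_mask = np.zeros(C, dtype=bool)
    affected_mask[affected] = True
    baseline = rng_struct.uniform(*params.baseline_strength_range, size=C)
    site_offsets = rng_struct.normal(0.0, params.site_offset_sd, size=(params.n_sites, C))
    site_eyes = rng_struct.choice(["open", "closed"], size=params.n_sites)

    counts = params.site_counts()
    volumes = params.site_volumes()
    site_idx = np.repeat(np.arange(params.n_sites), counts)
    n = int(counts.sum())
    diagnoses = np.empty(n, dtype=object)
    pos = 0
    for s, c in enumerate(counts):
        n_aut = int(round(params.autism_fraction * c))
        labels = np.array(["autism"] * n_aut + ["control"] * (c - n_aut), dtype=object)
        rng_subj.shuffle(labels)
        diagnoses[pos : pos + c] = labels
        pos += c

    ages = rng_subj.uniform(*params.age_range, size=n)
    genders = np.where(rng_subj.random(n) < params.male_fraction, "male", "female")
    handed = rng_subj.choice(
        ["right", "left", "ambidextrous"], size=n, p=params.handedness_probs
    )
    handed_missing = rng_subj.random(n) < params.handedness_missing_rate
    severity = _severity(diagnoses, rng_subj)

    # motion + retained-volume accounting
    scrub = ScrubParams()
    n_acquired = volumes[site_idx]
    n_retained = np.empty(n, dtype=int)
    motion_seeds = rng_motion.integers(0, 2**31 - 1, size=n)
    for i in range(n):
        rate = params.motion_spike_rate * (
            params.autism_motion_factor if diagnoses[i] == "autism" else 1.0
        )
        motion = simulate_motion(int(n_acquired[i]), rate, int(motion_seeds[i]))
        fd = framewise_displacement(motion)
        n_retained[i] = int(scrub_mask(fd, np.zeros_like(fd), scrub).sum())

    # connection values
    noise_sd = np.full(n, params.subject_noise_sd, dtype=float)
    if params.scan_length_noise:
        t_eff = np.maximum(n_retained, 10)
        noise_sd = np.sqrt(noise_sd**2 + 1.0 / (t_eff - 3.0))
    values = (
        baseline[None, :]
        + params.age_slope * ages[:, None]
        + params.age_curvature * (ages**2)[:, None]
        + site_offsets[site_idx]
        + np.outer(severity * params.effect_size, affected_mask.astype(float))
        + rng_mat.standard_normal((n, C)) * noise_sd[:, None]
    )

    # behavioral scores
    behaviors: dict[str, np.ndarray] = {}
    for name, (b0, b1, sd, pop) in BEHAVIOR_MODELS.items():
        score = b0 + b1 * severity + rng_behav.normal(
            0.0, sd * params.behavior_noise_sd, size=n
        )
        if pop == "autism":
            score = np.where(diagnoses == "autism", score, np.nan)
        behaviors[name] = score

    records = []
    matrices = []
    for i in range(n):
        sid = f"sub-{i:04d}"
        records.append(
            PhenotypeRecord(
                subject_id=sid,
                site=f"site{site_idx[i]:02d}",
                diagnosis=str(diagnoses[i]),
                age=float(ages[i]),
                gender=str(genders[i]),
                handedness=None if handed_missing[i] else str(handed[i]),
                eyes=str(site_eyes[site_idx[i]]),
                n_volumes_acquired=int(n_acquired[i]),
                n_volumes_retained=int(n_retained[i]),
                **{
                    name: (None if np.isnan(behaviors[name][i]) else float(behaviors[name][i]))
                    for name in BEHAVIOR_MODELS
                },
            )
        )
        matrices.append(matrix_from_condensed(sid, values[i], R))

    rois = lattice_roi_geometry(R, rng_struct)
    dataset = CohortDataset(
        phenotypes=records,
        matrices=matrices,
        rois=rois,
        single_site_ok=params.n_sites == 1,
    )
    iu, ju = connection_pairs(R)
    truth = GroundTruth(
        affected=affected,
        affected_pairs=[(int(iu[c]), int(ju[c])) for c in affected],
        site_offsets=site_offsets,
        severity=severity,
        baseline=baseline,
        coefficients={
            "effect_size": params.effect_size,
            "age_slope": params.age_slope,
            "age_curvature": params.age_curvature,
        },
    )
    return dataset, truth


def lattice_roi_geometry(R: int, rng: np.random.Generator, spacing: float = 5.0) -> ROISet:
    """Deterministic lattice centroid geometry for R synthetic ROIs.

    Centroids are the first R points of a 5-mm lattice filling a roughly
    brain-sized box, enumerated in raster order; `rng` is unused for positions
    (kept for interface symmetry) so the geometry depends only on R.
    """
    side = int(np.ceil(R ** (1.0 / 3.0)))
    grid = np.array(
        [
            (x, y, z)
            for z in range(side + 2)
            for y in range(side + 2)
            for x in range(side + 2)
        ],
        dtype=float,
    )[:R]
    return ROISet(centroids=grid * spacing)


def simulate_timeseries(
    target: AssociationMatrix,
    T: int,
    seed: int,
    max_ridge: float = 0.1,
) -> np.ndarray:
    """Draw an ROI-by-T series whose population correlations match ``target``.

    The target Fisher-z matrix is mapped back to correlation scale (tanh), the
    diagonal set to 1, and if needed regularized by a diagonal load of at most
    ``max_ridge`` (then rescaled to unit diagonal).  Samples are i.i.d.
    zero-mean multivariate normal, so the empirical Fisher-z matrix converges
    to the target at the usual 1/sqrt(T-3) rate.
    """
    z = np.array(target.values, dtype=float)
    corr = np.tanh(z)
    np.fill_diagonal(corr, 1.0)
    eigs = np.linalg.eigvalsh(corr)
    lam = 0.0
    if eigs.min() < 1e-8:
        lam = float(-eigs.min() + 1e-8)
        if lam > max_ridge:
            raise CohortError(
                f"target correlation matrix not positive definite after diagonal "
                f"load (needed ridge {lam:.3g} > max {max_ridge:g})"
            )
        corr = (corr + lam * np.eye(corr.shape[0])) / (1.0 + lam)
    L = np.linalg.cholesky(corr)
    rng = np.random.default_rng(seed)
    samples = rng.standard_normal((T, corr.shape[0])) @ L.T
    return samples.T


def simulate_motion(
    T: int,
    spike_rate: float,
    seed: int,
    drift_amplitude: float = 0.05,
    spike_min_mm: float = 0.6,
    spike_max_mm: float = 1.0,
    rotation_radius_mm: float = 50.0,
) -> np.ndarray:
    """Six rigid-body motion parameters (3 translations mm, 3 rotations rad).

    Baseline is slow sinusoidal drift whose frame-to-frame displacement stays
    well under the 0.2 mm scrub threshold.  Spikes occur at Bernoulli
    (``spike_rate``) frames (never frame 0) as single-frame translation
    excursions of alternating sign and magnitude >= 0.6 mm, which guarantees a
    root-mean-square framewise displacement above 0.2 mm at every spike
    (sqrt(0.6^2 / 6) ~ 0.245 mm), including runs of consecutive spikes.
    """
    if T < 2:
        raise CohortError("need at least 2 volumes")
    rng = np.random.default_rng(seed)
    t = np.arange(T)
    motion = np.zeros((6, T))
    for p in range(6):
        period = rng.uniform(80.0, 200.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        amp = drift_amplitude if p < 3 else drift_amplitude / rotation_radius_mm
        motion[p] = amp * np.sin(2.0 * np.pi * t / period + phase)
    spikes = np.zeros(T, dtype=bool)
    spikes[1:] = rng.random(T - 1) < spike_rate
    amplitudes = rng.uniform(spike_min_mm, spike_max_mm, size=int(spikes.sum()))
    signs = np.where(np.arange(len(amplitudes)) % 2 == 0, 1.0, -1.0)
    motion[0, spikes] += amplitudes * signs
    return motion
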