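"""Synthetic multi-site resting-state cohorts with covariance-level group effects.

The generator emulates a two-group (patient/control), multi-site study in
which the discriminative signal lives in the *correlation structure* of the
regional time series, not in their means: patients' correlations on edges
incident to a designated set of "affected" regions are lowered by a fixed
amount ``edge_effect`` relative to controls, while age, sex and site enter
every subject's target correlation matrix as nuisance offsets.  Each
subject's time series is then a stationary Gaussian AR(1) process whose
marginal covariance equals that target, so downstream connectivity,
graph-metric and classification stages can be exercised against a known
ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "generate_cohort",
    "generate_volumes",
    "control_target_matrix",
    "subject_target_matrix",
]

#: reference age (years) at which the age effect on correlations is zero
AGE_CENTER = 36.5
#: the per-edge age slope is expressed per decade of age
AGE_SCALE = 10.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic multi-site two-group cohort.

    ``edge_effect`` is the correlation difference Delta r subtracted, in
    patients, from every edge incident to a node in ``affected_nodes``.
    ``confound_slopes`` is ``(age_slope_per_decade, sex_offset)`` applied
    uniformly to all off-diagonal target correlations; ``site_shift`` is a
    per-site global correlation offset (sites are spread symmetrically
    around zero).  ``ar_coefficient`` is the lag-1 autocorrelation of the
    temporal filter.
    """

    n_regions: int = 90
    n_timepoints: int = 170
    n_patients_per_site: int = 60
    n_controls_per_site: int = 60
    n_sites: int = 3
    affected_nodes: tuple[int, ...] = (0, 1, 2)
    edge_effect: float = 0.3
    topology_effect: float = 0.0
    confound_slopes: tuple[float, float] = (0.02, 0.02)
    site_shift: float = 0.15
    ar_coefficient: float = 0.3
    seed: int = 0
    # base connectivity template: ring of modules, correlated within and
    # weakly between (gives graph metrics dynamic range at 0.10 <= S <= 0.34)
    within_module_r: float = 0.4
    between_module_r: float = 0.1
    module_size: int = 15

    def __post_init__(self) -> None:
        for name in ("n_regions", "n_timepoints", "n_patients_per_site",
                     "n_controls_per_site", "n_sites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        nodes = tuple(int(i) for i in self.affected_nodes)
        if any(i < 0 or i >= self.n_regions for i in nodes):
            raise ValueError("affected_nodes must lie in [0, n_regions)")
        if len(set(nodes)) != len(nodes):
            raise ValueError("affected_nodes must be distinct")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must be in [0, 1)")
        object.__setattr__(self, "affected_nodes", nodes)

    @property
    def n_subjects(self) -> int:
        return (self.n_patients_per_site + self.n_controls_per_site) * self.n_sites


@dataclass
class SubjectRecord:
    """One subject: identity, group, site, confounds and ROI time series."""

    subject_id: str
    group: str  # "patient" | "control"
    site: str
    age: float
    sex: str  # "M" | "F"
    timeseries: np.ndarray  # (n_timepoints, n_regions)

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"group must be patient/control, got {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M/F, got {self.sex!r}")
        ts = np.asarray(self.timeseries, dtype=float)
        if not np.all(np.isfinite(ts)):
            raise ValueError(f"{self.subject_id}: time series has non-finite values")
        if np.any(ts.std(axis=0) == 0):
            raise ValueError(f"{self.subject_id}: constant region time course")
        self.timeseries = ts


def _module_labels(spec: CohortSpec) -> np.ndarray:
    n_modules = max(2, int(round(spec.n_regions / spec.module_size)))
    return np.arange(spec.n_regions) % n_modules


def control_target_matrix(spec: CohortSpec) -> np.ndarray:
    """Base (control, zero-confound, site-centered) target correlation matrix."""
    labels = _module_labels(spec)
    same = labels[:, None] == labels[None, :]
    r = np.where(same, spec.within_module_r, spec.between_module_r)
    np.fill_diagonal(r, 1.0)
    return r


def _site_offset(spec: CohortSpec, site_index: int) -> float:
    return spec.site_shift * (site_index - (spec.n_sites - 1) / 2.0)


def subject_target_matrix(
    spec: CohortSpec, *, group: str, site_index: int, age: float, sex: int
) -> np.ndarray:
    """Target correlation matrix for one subject before PSD repair.

    Off-diagonal entries are
    ``base + site_offset + age_slope * (age - 36.5)/10 + sex_offset * (sex - 0.5)``
    and, for patients, edges incident to an affected node are lowered by
    ``edge_effect``.  ``topology_effect`` additionally attenuates the
    affected nodes' within-module edges (shifting their degree ordering
    after sparsity thresholding) in patients.
    """
    r = control_target_matrix(spec)
    off = ~np.eye(spec.n_regions, dtype=bool)
    age_slope, sex_offset = spec.confound_slopes
    shift = (
        _site_offset(spec, site_index)
        + age_slope * (age - AGE_CENTER) / AGE_SCALE
        + sex_offset * (sex - 0.5)
    )
    r[off] += shift
    if group == "patient":
        idx = np.array(spec.affected_nodes, dtype=int)
        if idx.size:
            mask = np.zeros((spec.n_regions, spec.n_regions), dtype=bool)
            mask[idx, :] = True
            mask[:, idx] = True
            np.fill_diagonal(mask, False)
            r[mask] -= spec.edge_effect
            if spec.topology_effect != 0.0:
                labels = _module_labels(spec)
                within = labels[:, None] == labels[None, :]
                r[mask & within] -= spec.topology_effect
    bad = np.abs(r[off])
    if np.any(bad >= 1.0):
        raise ValueError(
            "combined edge/confound/site effects push a target correlation "
            f"outside (-1, 1): max |r| = {bad.max():.3f}"
        )
    return r


def _nearest_correlation(r: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """PSD repair by eigenvalue clipping, then rescale to unit diagonal."""
    w, v = np.linalg.eigh((r + r.T) / 2.0)
    if w.min() >= floor:
        return r
    w = np.clip(w, floor, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _ar1_gaussian(
    rng: np.random.Generator, corr: np.ndarray, n_timepoints: int, phi: float
) -> np.ndarray:
    """Stationary AR(1) process with marginal covariance ``corr``."""
    chol = np.linalg.cholesky(corr)
    innov = rng.standard_normal((n_timepoints, corr.shape[0])) @ chol.T
    if phi == 0.0:
        return innov
    out = np.empty_like(innov)
    out[0] = innov[0]
    scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, n_timepoints):
        out[t] = phi * out[t - 1] + scale * innov[t]
    return out


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate the full multi-site cohort; bit-identical under a fixed seed.

    Sites are laid out sequentially; within a site, patients come first.
    Ages are uniform on [18, 55] plus a +2-year shift per site index; sex is
    Bernoulli(1/2).
    """
    if spec.n_timepoints <= spec.n_regions / 2:
        warnings.warn(
            f"n_timepoints={spec.n_timepoints} <= n_regions/2: sample "
            "correlations will be unstable",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    records: list[SubjectRecord] = []
    for s in range(spec.n_sites):
        site = f"site{s + 1}"
        groups = ["patient"] * spec.n_patients_per_site + [
            "control"
        ] * spec.n_controls_per_site
        for k, group in enumerate(groups):
            age = float(rng.uniform(18.0, 55.0) + 2.0 * s)
            sex = int(rng.integers(0, 2))
            target = subject_target_matrix(
                spec, group=group, site_index=s, age=age, sex=sex
            )
            target = _nearest_correlation(target)
            ts = _ar1_gaussian(rng, target, spec.n_timepoints, spec.ar_coefficient)
            records.append(
                SubjectRecord(
                    subject_id=f"{site}_{group[:3]}{k + 1:03d}",
                    group=group,
                    site=site,
                    age=age,
                    sex="M" if sex == 1 else "F",
                    timeseries=ts,
                )
            )
    return records


def generate_volumes(
    cohort: list[SubjectRecord],
    voxel_grid: tuple[int, int, int] = (6, 5, 4),
    mixing_seed: int = 12345,
    noise_sd: float = 0.5,
) -> list[np.ndarray]:
    """Toy 4D volumes: voxels are fixed nonnegative mixtures of ROI signals.

    The mixing matrix is drawn once from ``mixing_seed`` and shared across
    subjects, so group information resides only in temporal covariance,
    never in spatial means.  Returns one ``voxel_grid + (n_timepoints,)``
    array per subject.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    n_regions = cohort[0].timeseries.shape[1]
    n_voxels = int(np.prod(voxel_grid))
    if n_voxels < n_regions:
        raise ValueError(
            f"voxel grid {voxel_grid} has {n_voxels} voxels < {n_regions} regions"
        )
    rng = np.random.default_rng(mixing_seed)
    mixing = rng.uniform(0.0, 1.0, size=(n_voxels, n_regions))
    mixing /= mixing.sum(axis=1, keepdims=True)
    volumes = []
    for rec in cohort:
        noise = rng.standard_normal((rec.timeseries.shape[0], n_voxels))
        vox = rec.timeseries @ mixing.T + noise_sd * noise
        volumes.append(
            np.ascontiguousarray(vox.T.reshape(voxel_grid + (rec.timeseries.shape[0],)))
        )
    return volumes


def null_spec(**overrides) -> CohortSpec:
    """A signal-free spec (no group, confound or site effects) for null studies."""
    base = CohortSpec(
        edge_effect=0.0,
        topology_effect=0.0,
        confound_slopes=(0.0, 0.0),
        site_shift=0.0,
    )
    return replace(base, **overrides)
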