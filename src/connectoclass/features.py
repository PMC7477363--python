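"""Subjects-by-features tables for the three representations.

A :class:`FeatureTable` pairs a subject manifest (id, group, site, age,
sex) with a dense feature matrix and a representation tag — ``image``
(flattened toy 4D volumes), ``fc`` (vectorized connectivity, 4005 features
for 90 regions) or ``graph`` (AUC-over-sparsity metrics, 277 features for
90 regions).  Builders construct each table from a cohort of
:class:`~connectoclass.cohort.SubjectRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import SubjectRecord, generate_volumes
from .connectome import compute_fc, vectorize_fc
from .graph import graph_feature_names, metric_profile

__all__ = [
    "FeatureTable",
    "fc_feature_table",
    "graph_feature_table",
    "image_feature_table",
]

REPRESENTATIONS = ("image", "fc", "graph")


@dataclass
class FeatureTable:
    """Immutable-representation feature table with subject metadata.

    ``subjects`` is a DataFrame with columns subject_id, group, site, age,
    sex, in row order matching ``features``.
    """

    subjects: pd.DataFrame
    features: np.ndarray
    representation: str
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.representation not in REPRESENTATIONS:
            raise ValueError(
                f"representation must be one of {REPRESENTATIONS}, "
                f"got {self.representation!r}"
            )
        x = np.asarray(self.features, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("feature matrix contains non-finite entries")
        required = {"subject_id", "group", "site", "age", "sex"}
        missing = required - set(self.subjects.columns)
        if missing:
            raise ValueError(f"subject manifest missing columns: {sorted(missing)}")
        if len(self.subjects) != x.shape[0]:
            raise ValueError("subjects and features row counts differ")
        if not self.feature_names:
            self.feature_names = [f"f{i:05d}" for i in range(x.shape[1])]
        if len(self.feature_names) != x.shape[1]:
            raise ValueError("feature_names length must match feature columns")
        self.features = x
        self.subjects = self.subjects.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def labels(self) -> np.ndarray:
        """Binary group labels: patient = 1 (positive class), control = 0."""
        return (self.subjects["group"].to_numpy() == "patient").astype(int)

    def subset(self, index: np.ndarray) -> "FeatureTable":
        index = np.asarray(index)
        return FeatureTable(
            subjects=self.subjects.iloc[index].reset_index(drop=True),
            features=self.features[index],
            representation=self.representation,
            feature_names=list(self.feature_names),
        )

    def per_site(self) -> dict[str, "FeatureTable"]:
        return {
            site: self.subset(np.flatnonzero(self.subjects["site"] == site))
            for site in self.subjects["site"].unique()
        }

    def with_features(self, features: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            subjects=self.subjects,
            features=features,
            representation=self.representation,
            feature_names=list(self.feature_names),
        )


def _manifest(cohort: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in cohort],
            "group": [r.group for r in cohort],
            "site": [r.site for r in cohort],
            "age": [r.age for r in cohort],
            "sex": [r.sex for r in cohort],
        }
    )


def fc_feature_table(cohort: list[SubjectRecord]) -> FeatureTable:
    """Vectorized lower-triangle Pearson connectivity per subject."""
    vectors, index_map = [], None
    for rec in cohort:
        vec, index_map = vectorize_fc(compute_fc(rec.timeseries))
        vectors.append(vec)
    names = [f"fc_r{i + 1:02d}_r{j + 1:02d}" for i, j in index_map]
    return FeatureTable(
        subjects=_manifest(cohort),
        features=np.vstack(vectors),
        representation="fc",
        feature_names=names,
    )


def graph_feature_table(
    cohort: list[SubjectRecord],
    grid: np.ndarray | None = None,
    n_nulls: int = 100,
    seed: int = 0,
    rank_by: str = "absolute",
    auc_rule: str = "trapezoid",
) -> FeatureTable:
    """AUC-over-sparsity graph-metric features (7 global + 3n nodal).

    Null-model seeds are derived per subject from ``seed`` so the table is
    reproducible subject by subject.
    """
    rows = []
    names: list[str] | None = None
    for si, rec in enumerate(cohort):
        prof = metric_profile(
            compute_fc(rec.timeseries),
            grid=grid,
            n_nulls=n_nulls,
            seed=(seed * 131071 + si) % (2**31),
            rank_by=rank_by,
            auc_rule=auc_rule,
        )
        rows.append(prof.auc_features)
        names = prof.feature_names
    return FeatureTable(
        subjects=_manifest(cohort),
        features=np.vstack(rows),
        representation="graph",
        feature_names=names or graph_feature_names(cohort[0].timeseries.shape[1]),
    )


def image_feature_table(
    cohort: list[SubjectRecord],
    voxel_grid: tuple[int, int, int] = (6, 5, 4),
    mixing_seed: int = 12345,
    noise_sd: float = 0.5,
    time_stride: int = 2,
) -> FeatureTable:
    """Flattened toy 4D volumes (voxels x retained time points) per subject.

    ``time_stride`` subsamples the temporal axis to keep the feature count
    manageable; with the defaults a 170-timepoint cohort yields
    ``6*5*4 * 85 = 10200`` features.
    """
    volumes = generate_volumes(
        cohort, voxel_grid=voxel_grid, mixing_seed=mixing_seed, noise_sd=noise_sd
    )
    rows = [v[..., ::time_stride].ravel() for v in volumes]
    return FeatureTable(
        subjects=_manifest(cohort),
        features=np.vstack(rows),
        representation="image",
    )
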