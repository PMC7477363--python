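"""Delimited-text and NIfTI persistence for cohorts, matrices and tables.

Everything round-trips through plain text: the subject manifest and the
per-subject ROI time series are tab-separated files, connectivity matrices
carry a header row of region labels, and feature tables are written with
the manifest columns first.  Toy 4D volumes go through the NIfTI standard
via nibabel.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec, SubjectRecord
from .connectome import ConnectivityMatrix
from .features import FeatureTable

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_matrix",
    "read_matrix",
    "write_feature_table",
    "read_feature_table",
    "write_volume",
    "read_volume",
    "write_cohort_spec",
    "read_cohort_spec",
]

MANIFEST_NAME = "manifest.tsv"


def write_cohort(cohort: list[SubjectRecord], outdir: str | Path) -> Path:
    """Write manifest.tsv plus one <subject_id>_timeseries.tsv per subject."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "site": rec.site,
                "age": rec.age,
                "sex": rec.sex,
            }
        )
        np.savetxt(
            outdir / f"{rec.subject_id}_timeseries.tsv",
            rec.timeseries,
            delimiter="\t",
            fmt="%.10g",
        )
    pd.DataFrame(rows).to_csv(outdir / MANIFEST_NAME, sep="\t", index=False)
    return outdir / MANIFEST_NAME


def read_cohort(indir: str | Path) -> list[SubjectRecord]:
    indir = Path(indir)
    manifest = pd.read_csv(indir / MANIFEST_NAME, sep="\t")
    cohort = []
    for _, row in manifest.iterrows():
        ts = np.loadtxt(indir / f"{row.subject_id}_timeseries.tsv", delimiter="\t")
        cohort.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                site=str(row.site),
                age=float(row.age),
                sex=str(row.sex),
                timeseries=ts,
            )
        )
    return cohort


def write_matrix(matrix: ConnectivityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, columns=matrix.region_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t")
    return ConnectivityMatrix(
        values=df.to_numpy(dtype=float), region_labels=list(df.columns)
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = pd.concat(
        [
            table.subjects.reset_index(drop=True),
            pd.DataFrame(table.features, columns=table.feature_names),
        ],
        axis=1,
    )
    df.attrs["representation"] = table.representation
    with open(path, "w") as fh:
        fh.write(f"# representation: {table.representation}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_feature_table(path: str | Path) -> FeatureTable:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# representation:"):
            raise ValueError(f"{path}: missing representation header line")
        representation = header.split(":", 1)[1].strip()
        df = pd.read_csv(fh, sep="\t")
    meta_cols = ["subject_id", "group", "site", "age", "sex"]
    feature_names = [c for c in df.columns if c not in meta_cols]
    return FeatureTable(
        subjects=df[meta_cols],
        features=df[feature_names].to_numpy(dtype=float),
        representation=representation,
        feature_names=feature_names,
    )


def write_volume(volume: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), np.eye(4)), str(path))


def read_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_cohort_spec(spec: CohortSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(spec), fh, sort_keys=True)


def read_cohort_spec(path: str | Path) -> CohortSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    for key in ("affected_nodes", "confound_slopes"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return CohortSpec(**data)


def write_json(payload: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
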