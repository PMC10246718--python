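"""Reading and writing count matrices, sample metadata and study artifacts.

Counts travel as TSV/CSV (genes as rows, header = sample ids) or as a
MatrixMarket triplet with ``.rownames.txt`` / ``.colnames.txt`` sidecar files.
Metadata is a CSV with the fixed clinical schema; an empty CA125 field means
the marker was not measured for that sample.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "write_study",
]

META_COLUMNS = [
    "sample_id",
    "cohort",
    "class",
    "histology",
    "figo_stage",
    "grade",
    "age",
    "ca125",
    "batch",
]
VALID_CLASSES = {"OC", "BAM", "healthy"}
VALID_STAGES = {"", "I", "IA", "IB", "IC", "II", "IIA", "IIB", "IIC", "III", "IIIA", "IIIB", "IIIC", "IV"}


def _validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    for axis, what in ((df.index, "gene"), (df.columns, "sample")):
        dup = axis[axis.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate {what} id(s): {sorted(set(dup))}")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("count matrix contains non-integer entries")
        df = df.round().astype(np.int64)
        vals = df.to_numpy()
    if (vals < 0).any():
        raise ValueError("count matrix contains negative entries")
    return df


def read_counts(path) -> pd.DataFrame:
    """Load a gene x sample count matrix from TSV/CSV or MatrixMarket."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = spio.mmread(path)
        rows = path.with_suffix(".rownames.txt").read_text().split()
        cols = path.with_suffix(".colnames.txt").read_text().split()
        arr = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        if arr.shape != (len(rows), len(cols)):
            raise ValueError(
                f"matrix shape {arr.shape} does not match id files ({len(rows)} x {len(cols)})"
            )
        df = pd.DataFrame(arr, index=rows, columns=cols)
    else:
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
    return _validate_counts(df)


def write_counts(counts: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        spio.mmwrite(str(path), sparse.csr_matrix(counts.to_numpy()))
        path.with_suffix(".rownames.txt").write_text("\n".join(counts.index) + "\n")
        path.with_suffix(".colnames.txt").write_text("\n".join(counts.columns) + "\n")
    else:
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        counts.to_csv(path, sep=sep)


def read_metadata(path, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Load and validate the sample-metadata CSV.

    Adds an ``early_stage`` flag (FIGO I-IIA). When ``counts`` is given, the
    metadata must cover exactly its samples; orphans on either side raise.
    """
    meta = pd.read_csv(path, dtype={"sample_id": str}, keep_default_na=False)
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata lacks required columns: {missing_cols}")
    bad = set(meta["class"]) - VALID_CLASSES
    if bad:
        raise ValueError(f"unknown class label(s): {sorted(bad)}; expected {sorted(VALID_CLASSES)}")
    bad_stage = set(meta["figo_stage"].astype(str)) - VALID_STAGES
    if bad_stage:
        raise ValueError(f"unknown FIGO stage(s): {sorted(bad_stage)}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample id(s) in metadata: {dups}")
    meta["ca125"] = pd.to_numeric(meta["ca125"].replace("", np.nan), errors="raise")
    meta["age"] = pd.to_numeric(meta["age"], errors="raise")
    meta["early_stage"] = meta["figo_stage"].isin({"I", "IA", "IB", "IC", "II", "IIA"})
    if counts is not None:
        meta_ids = set(meta["sample_id"])
        count_ids = set(counts.columns)
        orphans = sorted(meta_ids ^ count_ids)
        if orphans:
            raise ValueError(f"sample ids not shared between counts and metadata: {orphans}")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.loc[:, META_COLUMNS].copy()
    out.to_csv(path, index=False, na_rep="")


def write_study(study, outdir) -> None:
    """Dump a SyntheticStudy as per-cohort TSV counts + CSV metadata + JSON truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in study.counts:
        write_counts(study.counts[name], outdir / f"{name}_counts.tsv")
        write_metadata(study.meta[name], outdir / f"{name}_meta.csv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(study.truth, fh, indent=1, default=float)
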