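"""Readers and writers for count matrices, metadata, and results.

Tabular dialect: tab-separated, "." decimal, literal "NA" for missing —
stated so numeric outputs are bit-reproducible across runs.  Counts can
be read from TSV (gene rows, header of sample ids) or MatrixMarket with
``.rows``/``.cols`` sidecar id files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["read_counts", "write_counts", "read_metadata", "write_table"]

REQUIRED_META_COLUMNS = ("sample", "location", "sex", "dose",
                         "pregnancy", "pair_id")
VALID_LOCATIONS = {"EV", "Cell"}
VALID_SEXES = {"F", "M"}


def read_counts(path, fmt: str | None = None) -> pd.DataFrame:
    """Load and validate a genes x samples integer count matrix.

    ``fmt`` is "tsv" or "mtx"; inferred from the suffix when omitted.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif fmt == "mtx":
        from scipy.io import mmread
        m = mmread(path)
        mat = np.asarray(m.todense()) if hasattr(m, "todense") else np.asarray(m)
        genes = Path(str(path) + ".rows").read_text().split()
        samples = Path(str(path) + ".cols").read_text().split()
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown counts format {fmt!r}")
    _validate_counts(df, path)
    return df.astype(np.int64)


def _validate_counts(df: pd.DataFrame, path) -> None:
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][:5].tolist()
        raise ValueError(f"{path}: duplicate gene ids {dup}")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
        raise ValueError(f"{path}: non-numeric columns {list(bad)[:5]}")
    neg = np.argwhere(arr < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(f"{path}: negative count at gene {df.index[i]!r}, "
                         f"sample {df.columns[j]!r} (row {i + 2})")
    if not np.allclose(arr, np.round(arr)):
        frac = np.argwhere(arr != np.round(arr))[0]
        raise ValueError(f"{path}: non-integer count at row {frac[0] + 2}")


def write_counts(df: pd.DataFrame, path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        df.to_csv(path, sep="\t")
    elif fmt == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix
        mmwrite(str(path), csr_matrix(df.to_numpy()))
        Path(str(path) + ".rows").write_text("\n".join(df.index) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(df.columns) + "\n")
    else:
        raise ValueError(f"unknown counts format {fmt!r}")


def read_metadata(path) -> pd.DataFrame:
    """Load and validate the per-sample factor table.

    Requires columns sample, location (EV/Cell), sex (F/M), dose,
    pregnancy, pair_id; checks that every pair_id has exactly one EV and
    one Cell member with identical (sex, dose, pregnancy).
    """
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    if meta["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    bad_loc = meta.loc[~meta["location"].isin(VALID_LOCATIONS), "sample"]
    if len(bad_loc):
        raise ValueError(f"{path}: invalid location for sample "
                         f"{bad_loc.iloc[0]!r}")
    bad_sex = meta.loc[~meta["sex"].isin(VALID_SEXES), "sample"]
    if len(bad_sex):
        raise ValueError(f"{path}: invalid sex for sample {bad_sex.iloc[0]!r}")
    validate_pairing(meta, path)
    return meta


def validate_pairing(meta: pd.DataFrame, path="metadata") -> None:
    for pair_id, sub in meta.groupby("pair_id"):
        locs = sorted(sub["location"])
        if locs != ["Cell", "EV"]:
            raise ValueError(f"{path}: pair {pair_id!r} must have exactly "
                             f"one EV and one Cell sample, got {locs}")
        keys = sub[["sex", "dose", "pregnancy"]].drop_duplicates()
        if len(keys) != 1:
            raise ValueError(f"{path}: pair {pair_id!r} members differ in "
                             f"(sex, dose, pregnancy)")


def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    """TSV writer with the package's NA convention."""
    df.to_csv(path, sep="\t", na_rep="NA", index_label=index_label)
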