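"""TSV readers/writers for the pipeline's tables.

TSV is the canonical interchange format (gzip-transparent via pandas);
JSON holds reports and manifests.  β matrices are probes x samples with
a ``probe_id`` header on the first column; values are validated into
[0, 1] on read with row/column context on failure.  Floats are written
with a fixed repr so that reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_table",
    "write_table",
    "read_signature",
    "read_annotation",
    "read_clinical",
    "write_json",
]

FLOAT_FORMAT = "%.10g"


def read_beta_matrix(path, value_range=(0.0, 1.0)) -> pd.DataFrame:
    """Read a probes x samples β matrix from TSV/CSV.

    Rejects duplicate probe IDs and values outside ``value_range``
    (naming the offending probe and sample); empty cells become NaN.
    Pass ``value_range=None`` to skip range validation (e.g. expression
    matrices stored in the same layout).
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index.name = "probe_id"
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe IDs in {path}: {dups[:5]}")
    try:
        df = df.astype(float)
    except ValueError as err:
        raise ValueError(f"non-numeric value in {path}: {err}") from None
    if value_range is not None:
        lo, hi = value_range
        bad = (df < lo) | (df > hi)
        if bad.any().any():
            probe = df.index[bad.any(axis=1)][0]
            sample = df.columns[bad.loc[probe]][0]
            raise ValueError(
                f"value {df.loc[probe, sample]!r} outside [{lo}, {hi}] "
                f"at probe {probe!r}, sample {sample!r} in {path}"
            )
    return df


def write_beta_matrix(beta: pd.DataFrame, path, value_range=(0.0, 1.0)) -> None:
    if value_range is not None:
        lo, hi = value_range
        v = beta.to_numpy(dtype=float)
        if np.nanmin(v) < lo or np.nanmax(v) > hi:
            raise ValueError(f"matrix values outside [{lo}, {hi}]")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    beta.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_signature(path) -> pd.DataFrame:
    sig = read_table(path)
    missing = {"gene", "cell_type"} - set(sig.columns)
    if missing:
        raise ValueError(f"signature {path} missing columns {sorted(missing)}")
    return sig


def read_annotation(path) -> pd.DataFrame:
    ann = read_table(path)
    required = {"probe_id", "gene", "dist_to_tss_bp", "platform_450k", "platform_epic"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation {path} missing columns {sorted(missing)}")
    return ann


def read_clinical(path) -> pd.DataFrame:
    clin = read_table(path)
    missing = {"sample_id", "time", "event"} - set(clin.columns)
    if missing:
        raise ValueError(f"clinical table {path} missing columns {sorted(missing)}")
    return clin.set_index("sample_id")


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
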