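"""Readers and writers for the pipeline's plain-text formats.

Counts are TSV (``contig_id``, ``length_bp``, ``repeat_flag``, then one
column per sample) with a companion sample-metadata CSV (``sample``,
``sex``[, ``dataset``]).  Ct observations are a tidy CSV where the ``ct``
field may hold the instrument token ``Undetermined``; efficiencies come from
a companion CSV (``gene``, ``efficiency``).  All writers round-trip through
the readers, including the undetermined sentinel.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    CountMatrix,
    CtTable,
    FormatError,
    ValidationError,
)

UNDETERMINED_TOKEN = "Undetermined"
_COUNT_META_COLS = ["contig_id", "length_bp", "repeat_flag"]


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata CSV with columns sample, sex[, dataset]."""
    df = pd.read_csv(path, dtype=str)
    missing = {"sample", "sex"} - set(df.columns)
    if missing:
        raise FormatError(f"sample metadata missing columns: {sorted(missing)}")
    return df


def read_counts(path: str | Path, metadata: Mapping[str, str] | pd.DataFrame,
                dataset_id: str = "") -> CountMatrix:
    """Read a per-contig fragment-count TSV into a :class:`CountMatrix`.

    ``metadata`` maps sample id -> sex, either as a mapping or as a
    metadata DataFrame from :func:`read_sample_metadata`.  Samples named in
    the metadata but absent from the TSV are rejected, as are TSV samples
    without a sex label.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COUNT_META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"counts TSV missing columns: {missing}")
    if isinstance(metadata, pd.DataFrame):
        if dataset_id and "dataset" in metadata.columns:
            metadata = metadata[metadata["dataset"] == dataset_id]
        metadata = dict(zip(metadata["sample"], metadata["sex"]))
    sample_cols = [c for c in df.columns if c not in _COUNT_META_COLS]
    unknown = sorted(set(metadata) - set(sample_cols))
    if unknown:
        raise ValidationError(f"metadata names samples absent from counts file: {unknown}")
    counts = df[sample_cols].copy()
    for c in sample_cols:
        col = pd.to_numeric(counts[c], errors="raise")
        if (col < 0).any():
            raise ValidationError(f"negative count in sample {c!r}")
        counts[c] = col
    counts.index = pd.Index(df["contig_id"].astype(str), name="contig_id")
    length = pd.Series(pd.to_numeric(df["length_bp"], errors="raise").to_numpy(),
                       index=counts.index)
    repeat = df["repeat_flag"].map(_parse_bool)
    repeat.index = counts.index
    sex = pd.Series({s: metadata[s] for s in sample_cols if s in metadata})
    return CountMatrix(counts=counts, length_bp=length, repeat_flag=repeat,
                       sample_sex=sex, dataset_id=dataset_id)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    out = pd.DataFrame({
        "contig_id": cm.contigs,
        "length_bp": cm.length_bp.to_numpy(),
        "repeat_flag": cm.repeat_flag.to_numpy(),
    })
    for s in cm.samples:
        out[s] = cm.counts[s].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def write_sample_metadata(cm: CountMatrix, path: str | Path) -> None:
    pd.DataFrame({
        "sample": cm.samples,
        "sex": cm.sample_sex.to_numpy(),
        "dataset": cm.dataset_id,
    }).to_csv(path, index=False)


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f"}:
        return False
    raise FormatError(f"cannot parse boolean value {v!r}")


def read_efficiencies(path: str | Path) -> pd.Series:
    df = pd.read_csv(path)
    missing = {"gene", "efficiency"} - set(df.columns)
    if missing:
        raise FormatError(f"efficiency CSV missing columns: {sorted(missing)}")
    return pd.Series(pd.to_numeric(df["efficiency"]).to_numpy(),
                     index=pd.Index(df["gene"].astype(str)))


def read_ct(path: str | Path, efficiencies: str | Path | pd.Series) -> CtTable:
    """Read a tidy Ct CSV; ``ct`` may hold the token ``Undetermined``.

    ``efficiencies`` is a (gene, efficiency) CSV path or an equivalent
    Series; a gene appearing in the Ct table without an efficiency is a
    configuration error.
    """
    df = pd.read_csv(path, dtype={"gene": str, "sample": str})
    required = ["gene", "sample", "sex", "tissue", "tech_rep", "ct", "is_ntc"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"Ct CSV missing columns: {missing}")
    raw_ct = df["ct"].astype(str).str.strip()
    undet = raw_ct.str.lower() == UNDETERMINED_TOKEN.lower()
    ct = pd.to_numeric(raw_ct.mask(undet), errors="raise")
    if ct.isna().any() and not undet[ct.isna()].all():
        raise ValidationError("empty Ct cell: use the Undetermined token explicitly")
    tidy = df.copy()
    tidy["ct"] = ct
    tidy["undetermined"] = undet
    tidy["tech_rep"] = pd.to_numeric(tidy["tech_rep"]).astype(int)
    tidy["is_ntc"] = tidy["is_ntc"].map(_parse_bool)
    if not isinstance(efficiencies, pd.Series):
        efficiencies = read_efficiencies(efficiencies)
    return CtTable(tidy, efficiencies)


def write_ct(ct: CtTable, path: str | Path,
             efficiency_path: str | Path | None = None) -> None:
    df = ct.data.copy()
    out = df[["gene", "sample", "sex", "tissue", "tech_rep", "is_ntc"]].copy()
    ct_col = df["ct"].map(lambda v: "" if pd.isna(v) else format(v, "g"))
    ct_col[df["undetermined"]] = UNDETERMINED_TOKEN
    out.insert(5, "ct", ct_col)
    out.to_csv(path, index=False)
    if efficiency_path is not None:
        pd.DataFrame({"gene": ct.efficiency.index,
                      "efficiency": ct.efficiency.to_numpy()}).to_csv(
            efficiency_path, index=False)


def write_table_with_sidecar(df: pd.DataFrame, path: str | Path,
                             params: dict | None = None, index: bool = True) -> None:
    """Write a result TSV plus a JSON sidecar of the parameters that made it."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=index)
    if params is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump(params, fh, indent=2, sort_keys=True, default=str)
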