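"""Domain containers shared by all pipeline stages.

The pipeline moves between three table shapes: per-contig fragment counts
from RNA-seq (:class:`CountMatrix`), tidy qPCR cycle-threshold observations
(:class:`CtTable`), and derived per-gene / per-sample results
(:class:`StabilityReport`, :class:`NormalizedExpression`, sex-bias calls).
All containers wrap pandas objects and validate their invariants on
construction, so downstream numerical code can assume clean input.

A qPCR reaction that never crosses the fluorescence threshold is recorded as
*undetermined*.  This is an experimental outcome (too little template), not
missing data, so it is carried as an explicit boolean mask next to the Ct
column rather than silently as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

#: Maximum thermocycler cycle count; determined Ct values must lie in (0, 45].
MAX_CYCLES = 45.0


class RefstabError(Exception):
    """Base class for all package errors."""


class FormatError(RefstabError):
    """A file does not have the expected layout (missing columns etc.)."""


class ValidationError(RefstabError):
    """Well-formed input violates a data invariant."""


class ConfigurationError(RefstabError):
    """Inconsistent configuration (e.g. a gene without an efficiency)."""


class _Undetermined:
    """Singleton sentinel for a qPCR reaction with no detectable signal."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNDETERMINED"


UNDETERMINED = _Undetermined()


@dataclass
class CountMatrix:
    """Per-contig RNA-seq fragment counts for one dataset.

    Parameters
    ----------
    counts : DataFrame
        Integer fragment counts, contigs (index) x samples (columns).
    length_bp : Series
        Contig length in bases, indexed like ``counts``.
    repeat_flag : Series
        True where the contig matches a repeated element (annotation is an
        upstream input, consumed here as a flag).
    sample_sex : Series
        ``male`` / ``female`` per sample, indexed by sample id.
    dataset_id : str
        Label for the dataset (e.g. an inbred line or cross).
    """

    counts: pd.DataFrame
    length_bp: pd.Series
    repeat_flag: pd.Series
    sample_sex: pd.Series
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        if not self.counts.index.is_unique:
            raise ValidationError("contig ids must be unique")
        self.length_bp = self.length_bp.reindex(self.counts.index)
        self.repeat_flag = self.repeat_flag.reindex(self.counts.index).astype(bool)
        if self.length_bp.isna().any() or (self.length_bp <= 0).any():
            raise ValidationError("every contig needs a positive length_bp")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValidationError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.sample_sex.index]
        if missing:
            raise ValidationError(f"samples without sex label: {missing}")
        self.sample_sex = self.sample_sex.reindex(self.counts.columns)
        bad = set(self.sample_sex.unique()) - set(SEXES)
        if bad:
            raise ValidationError(f"unknown sex labels: {sorted(bad)}")

    @property
    def contigs(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset(self, contigs: Iterable[str]) -> "CountMatrix":
        keep = pd.Index(contigs)
        return CountMatrix(
            counts=self.counts.loc[keep],
            length_bp=self.length_bp.loc[keep],
            repeat_flag=self.repeat_flag.loc[keep],
            sample_sex=self.sample_sex,
            dataset_id=self.dataset_id,
        )


_CT_COLUMNS = ["gene", "sample", "sex", "tissue", "tech_rep", "ct", "undetermined", "is_ntc"]


@dataclass
class CtTable:
    """Tidy qPCR observations plus one amplification efficiency per gene.

    ``data`` holds one row per reaction well with columns ``gene``,
    ``sample``, ``sex``, ``tissue``, ``tech_rep``, ``ct`` (float, NaN where
    undetermined), ``undetermined`` (bool) and ``is_ntc`` (bool, no-template
    control wells).  ``efficiency`` maps gene -> fold amplification per
    cycle, E in (1, 2].
    """

    data: pd.DataFrame
    efficiency: pd.Series

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in _CT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"Ct table missing columns: {missing}")
        df["ct"] = pd.to_numeric(df["ct"], errors="raise")
        df["undetermined"] = df["undetermined"].astype(bool)
        df["is_ntc"] = df["is_ntc"].astype(bool)
        df.loc[df["undetermined"], "ct"] = np.nan
        det = df.loc[~df["undetermined"], "ct"]
        if det.isna().any():
            raise ValidationError("determined rows must carry a Ct value")
        if ((det <= 0) | (det > MAX_CYCLES)).any():
            raise ValidationError(f"determined Ct must lie in (0, {MAX_CYCLES}]")
        tmpl = df[~df["is_ntc"]]
        dup = tmpl.duplicated(subset=["gene", "sample", "tech_rep"])
        if dup.any():
            rows = tmpl.loc[dup, ["gene", "sample", "tech_rep"]].iloc[0].tolist()
            raise ValidationError(f"duplicate (gene, sample, tech_rep): {rows}")
        genes = pd.Index(df["gene"].unique())
        noeff = [g for g in genes if g not in self.efficiency.index]
        if noeff:
            raise ConfigurationError(f"genes without amplification efficiency: {noeff}")
        eff = self.efficiency.loc[genes].astype(float)
        if ((eff < 1.0) | (eff > 2.0)).any():
            raise ValidationError("efficiency E must lie in [1, 2]")
        self.data = df.reset_index(drop=True)
        self.efficiency = eff

    @property
    def genes(self) -> list[str]:
        return list(pd.unique(self.data.loc[~self.data["is_ntc"], "gene"]))

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.data.loc[~self.data["is_ntc"], "sample"]))

    def template_rows(self) -> pd.DataFrame:
        return self.data[~self.data["is_ntc"]]

    def ntc_rows(self) -> pd.DataFrame:
        return self.data[self.data["is_ntc"]]

    def sample_sex(self) -> pd.Series:
        """sample -> sex, from the template rows."""
        tmpl = self.template_rows()
        sex = tmpl.drop_duplicates("sample").set_index("sample")["sex"]
        return sex

    def ct_value(self, row: pd.Series):
        """Ct of a row, or the UNDETERMINED sentinel."""
        return UNDETERMINED if bool(row["undetermined"]) else float(row["ct"])

    def drop_samples(self, samples: Iterable[str]) -> "CtTable":
        drop = set(samples)
        keep = ~self.data["sample"].isin(drop) | self.data["is_ntc"]
        return CtTable(self.data[keep], self.efficiency)

    def wide_ct(self, genes: Sequence[str] | None = None,
                replicates: str = "mean") -> pd.DataFrame:
        """Gene x observation matrix of Ct values.

        replicates="mean" averages determined technical replicates per
        (gene, sample); "raw" keeps each replicate as its own column
        labelled ``(sample, tech_rep)``.  Undetermined wells become NaN.
        """
        tmpl = self.template_rows()
        if genes is not None:
            tmpl = tmpl[tmpl["gene"].isin(set(genes))]
        if replicates == "mean":
            wide = tmpl.pivot_table(index="gene", columns="sample", values="ct",
                                    aggfunc="mean", dropna=False)
        elif replicates == "raw":
            wide = tmpl.pivot_table(index="gene", columns=["sample", "tech_rep"],
                                    values="ct", aggfunc="mean", dropna=False)
        else:
            raise ConfigurationError(f"unknown replicates mode: {replicates!r}")
        if genes is not None:
            wide = wide.reindex(list(dict.fromkeys(genes)))
        return wide


@dataclass
class StabilityReport:
    """Per-gene stability statistics from the four estimators + consensus.

    ``table`` is indexed by gene with columns ``genorm_m`` (M value at the
    gene's exclusion step), ``genorm_m_first_pass``, ``genorm_exclusion_order``
    (1 = excluded first, i.e. least stable), ``dct_sd``, ``normfinder_rho``,
    ``bestkeeper_sd``, ``bestkeeper_cv_pct``, ``bestkeeper_r``,
    ``rank_genorm``, ``rank_dct``, ``rank_normfinder``, ``rank_bestkeeper``
    and ``consensus_rank`` (geometric mean of the four method ranks).
    ``pairwise_variation`` maps n -> V(n/n+1).
    """

    table: pd.DataFrame
    pairwise_variation: dict[int, float] = field(default_factory=dict)

    def ordered(self) -> pd.DataFrame:
        """Genes sorted most-stable first (consensus, ties by gene id)."""
        t = self.table.copy()
        t["_gene"] = t.index
        t = t.sort_values(["consensus_rank", "_gene"]).drop(columns="_gene")
        return t


@dataclass
class NormalizedExpression:
    """Efficiency-corrected relative quantities after reference normalization.

    rq[gene, sample] = E_g ** (meanCt_g - Ct(g, s));
    nf[sample] = geometric mean of the reference genes' rq;
    nrq = rq / nf.
    """

    rq: pd.DataFrame
    nf: pd.Series
    nrq: pd.DataFrame
    reference_set: list[str]
    dropped_samples: list[str] = field(default_factory=list)

    @property
    def samples(self) -> pd.Index:
        return self.nrq.columns

    def target_nrq(self) -> pd.DataFrame:
        targets = [g for g in self.nrq.index if g not in set(self.reference_set)]
        return self.nrq.loc[targets]


CALL_MALE = "male_biased"
CALL_FEMALE = "female_biased"
CALL_UNBIASED = "unbiased"
CALL_NOT_EXPRESSED = "not_expressed"
CALL_UNTESTABLE = "untestable"


def new_sexbias_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["gene", "log2_fc", "se", "p_wilcoxon", "q_bh", "call", "n_m", "n_f"]
    )


def geometric_mean(values: np.ndarray, axis=0) -> np.ndarray:
    """Geometric mean of strictly positive values."""
    arr = np.asarray(values, dtype=float)
    if (arr <= 0).any():
        raise ValidationError("geometric mean requires strictly positive values")
    return np.exp(np.mean(np.log(arr), axis=axis))
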