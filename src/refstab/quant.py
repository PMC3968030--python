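"""Ct quality control, multi-reference normalization and sex-bias calling.

QC applies instrument-level rules: a reaction past the cycle cutoff is
undetermined; wells too close to a no-template-control (NTC) signal fail;
assays with too much missing data are excluded; technical replicates are
averaged and their dispersion reported.  Normalization is efficiency
corrected in the qBase style: per-gene relative quantities calibrated on the
gene's mean Ct, divided by the geometric mean of the reference genes'
quantities per sample.  The differential test compares the sexes per gene
with an exact Wilcoxon rank-sum on normalized relative quantities after
outlier removal, a fold-change threshold, and Benjamini-Hochberg control
over the tested gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import (
    CALL_FEMALE,
    CALL_MALE,
    CALL_NOT_EXPRESSED,
    CALL_UNBIASED,
    CALL_UNTESTABLE,
    FEMALE,
    MALE,
    CtTable,
    NormalizedExpression,
    StabilityReport,
    ValidationError,
    geometric_mean,
)
from .stability import QuantityMatrix, _pairwise_m

log = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_UNDETERMINED = "undetermined"
STATUS_NTC_FAIL = "ntc_fail"


@dataclass
class QcReport:
    """Outcome of Ct quality control.

    ``well_status``: one row per (gene, sample) with status ok /
    undetermined / ntc_fail.  ``gene_stats``: per-gene missing fraction,
    exclusion flag, mean technical-replicate SD and its flag, and the NTC
    Ct used (NaN if no NTC signal).  ``removed_samples``: (sample, reason)
    pairs recorded by :func:`balance_design`.
    """

    well_status: pd.DataFrame
    gene_stats: pd.DataFrame
    removed_samples: list[tuple[str, str]] = field(default_factory=list)

    @property
    def excluded_genes(self) -> list[str]:
        return list(self.gene_stats.index[self.gene_stats["excluded"]])


def qc_ct(ct: CtTable, max_ct: float = 35.0, ntc_margin: float = 8.0,
          max_missing: float = 0.10, max_rep_sd: float = 0.3,
          collapse_replicates: bool = True) -> tuple[CtTable, QcReport]:
    """Apply the Ct quality rules; return the cleaned table and a report.

    Rules, in order: Ct above ``max_ct`` becomes undetermined; where a gene
    shows an NTC signal, template wells within ``ntc_margin`` cycles of the
    NTC Ct fail; genes whose missing fraction (undetermined + NTC-failed
    wells) reaches ``max_missing`` are excluded.  Technical replicates of
    surviving wells are averaged when ``collapse_replicates``; the per-gene
    mean replicate SD is reported and flagged (not removed) when it reaches
    ``max_rep_sd``.
    """
    df = ct.template_rows().copy()
    over = (~df["undetermined"]) & (df["ct"] > max_ct)
    df.loc[over, "undetermined"] = True
    df.loc[over, "ct"] = np.nan

    ntc = ct.ntc_rows()
    ntc_ct = (ntc[~ntc["undetermined"]].groupby("gene")["ct"].min()
              if len(ntc) else pd.Series(dtype=float))
    no_ntc = sorted(set(df["gene"]) - set(ntc["gene"])) if len(ntc) else \
        sorted(set(df["gene"]))
    if no_ntc:
        log.warning("no NTC well for gene(s) %s; NTC rule skipped", no_ntc)
    margin_to_ntc = df["gene"].map(ntc_ct) - df["ct"]
    df["ntc_fail"] = (~df["undetermined"]) & margin_to_ntc.notna() \
        & (margin_to_ntc < ntc_margin)

    missing = df["undetermined"] | df["ntc_fail"]
    miss_frac = missing.groupby(df["gene"]).mean()
    excluded = miss_frac >= max_missing

    ok = df[~missing]
    rep_sd = ok.groupby(["gene", "sample"])["ct"].std(ddof=1)
    rep_sd_mean = rep_sd.groupby("gene").mean()

    def _status(sub: pd.DataFrame) -> str:
        if (~(sub["undetermined"] | sub["ntc_fail"])).any():
            return STATUS_OK
        if sub["ntc_fail"].any():
            return STATUS_NTC_FAIL
        return STATUS_UNDETERMINED

    well_status = (df.groupby(["gene", "sample"])
                   .apply(_status, include_groups=False)
                   .rename("status").reset_index())
    gene_stats = pd.DataFrame({
        "missing_fraction": miss_frac,
        "excluded": excluded,
        "tech_rep_sd_mean": rep_sd_mean,
        "ntc_ct": ntc_ct.reindex(miss_frac.index),
    })
    gene_stats["rep_sd_flag"] = gene_stats["tech_rep_sd_mean"] >= max_rep_sd
    gene_stats.index.name = "gene"
    flagged = gene_stats.index[gene_stats["rep_sd_flag"].fillna(False)]
    if len(flagged):
        log.warning("mean technical-replicate SD >= %.2f Ct for %s",
                    max_rep_sd, list(flagged))

    keep_genes = set(gene_stats.index[~gene_stats["excluded"]])
    clean = df[df["gene"].isin(keep_genes) & ~df["ntc_fail"]].drop(columns="ntc_fail")
    if collapse_replicates:
        def _collapse(sub: pd.DataFrame) -> pd.Series:
            det = sub[~sub["undetermined"]]
            first = sub.iloc[0]
            if len(det):
                return pd.Series({"sex": first["sex"], "tissue": first["tissue"],
                                  "tech_rep": 1, "ct": det["ct"].mean(),
                                  "undetermined": False, "is_ntc": False})
            return pd.Series({"sex": first["sex"], "tissue": first["tissue"],
                              "tech_rep": 1, "ct": np.nan,
                              "undetermined": True, "is_ntc": False})
        clean = (clean.groupby(["gene", "sample"])
                 .apply(_collapse, include_groups=False).reset_index())
    clean_table = CtTable(clean, ct.efficiency)
    report = QcReport(well_status=well_status, gene_stats=gene_stats)
    return clean_table, report


def balance_design(ct: CtTable, removed: str | None = None,
                   seed: int | np.random.Generator = 0,
                   report: QcReport | None = None) -> CtTable:
    """Remove an outlier sample and one random opposite-sex counterpart.

    Keeps the per-sex sample counts equal within the outlier's tissue, as a
    balanced design requires.  With ``removed=None`` the table is returned
    unchanged.
    """
    if removed is None:
        return ct
    tmpl = ct.template_rows()
    row = tmpl[tmpl["sample"] == removed]
    if row.empty:
        raise ValidationError(f"sample {removed!r} not found")
    sex = row["sex"].iloc[0]
    tissue = row["tissue"].iloc[0]
    other = MALE if sex == FEMALE else FEMALE
    pool = sorted(tmpl.loc[(tmpl["sex"] == other) & (tmpl["tissue"] == tissue),
                           "sample"].unique())
    if len(pool) < 2:
        raise ValidationError(
            f"cannot rebalance: only {len(pool)} {other} sample(s) left")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    counterpart = pool[int(rng.integers(len(pool)))]
    if report is not None:
        report.removed_samples.append((removed, "outlier"))
        report.removed_samples.append((counterpart, "balance"))
    log.info("removed outlier sample %s and %s counterpart %s",
             removed, other, counterpart)
    return ct.drop_samples([removed, counterpart])


def select_references(report: StabilityReport, gene_mean_ct: pd.Series,
                      targets_mean_ct: float, k: int = 3,
                      ct_window: float = 3.0,
                      widen_step: float = 1.0) -> list[str]:
    """The k most stable genes with expression intensity near the targets.

    A reference should match the targets' Ct range, not just be stable;
    genes within ``ct_window`` cycles of ``targets_mean_ct`` are eligible,
    ranked by consensus stability.  If fewer than k qualify the window is
    widened stepwise (with a warning) until enough do.
    """
    t = report.ordered()
    genes = [g for g in t.index if g in gene_mean_ct.index]
    if k > len(genes):
        raise ValidationError(f"k={k} exceeds the {len(genes)} genes available")
    window = ct_window
    max_dist = float((gene_mean_ct.loc[genes] - targets_mean_ct).abs().max())
    while True:
        eligible = [g for g in genes
                    if abs(gene_mean_ct[g] - targets_mean_ct) <= window]
        if len(eligible) >= k:
            return eligible[:k]
        if window > max_dist:
            return genes[:k]  # unreachable guard: window now covers everything
        window += widen_step
        log.warning("only %d gene(s) within %.1f Ct of targets; widening "
                    "window to %.1f", len(eligible), window - widen_step, window)


def validate_reference_set(qm: QuantityMatrix, m_threshold: float = 0.5,
                           v_threshold: float = 0.15
                           ) -> tuple[pd.Series, float, bool]:
    """geNorm check of a chosen reference set: (M per gene, V, pass).

    M is the within-set geNorm value; V is the pairwise variation
    V((n-1)/n) comparing normalization factors from the n-1 most stable set
    members against the full set.  The set passes when every M is below
    ``m_threshold`` and V below ``v_threshold`` (V is NaN, and ignored, for
    a two-gene set).
    """
    genes = list(qm.genes)
    if len(genes) < 2:
        raise ValidationError("a reference set needs at least 2 genes")
    if len(genes) == 2:
        sd = float((qm.log2q.iloc[0] - qm.log2q.iloc[1]).std(ddof=1))
        m = pd.Series([sd, sd], index=genes, name="M")
        v = float("nan")
        return m, v, bool((m < m_threshold).all())
    m = _pairwise_m(qm.log2q)
    order = m.sort_values(kind="mergesort").index
    nf_sub = qm.log2q.loc[order[:-1]].mean(axis=0)
    nf_full = qm.log2q.mean(axis=0)
    v = float((nf_sub - nf_full).std(ddof=1))
    ok = bool((m < m_threshold).all() and v < v_threshold)
    return m, v, ok


def normalize(ct_clean: CtTable, reference_set: Sequence[str],
              efficiency: float | None = None) -> NormalizedExpression:
    """Efficiency-corrected normalization against a reference-gene set.

    rq(g, s) = E_g ** (meanCt_g - Ct(g, s)) with meanCt the gene's
    arithmetic mean over retained samples (the qBase calibrator), nf(s) the
    geometric mean of the reference genes' rq, nrq = rq / nf.  Samples in
    which any reference gene is undetermined are dropped (logged).  Genes
    undetermined in a sample get NaN there; an all-undetermined gene keeps
    an all-NaN row so it can be reported as not expressed downstream.
    """
    reference_set = list(reference_set)
    wide = ct_clean.wide_ct(replicates="mean")
    missing_refs = [g for g in reference_set if g not in wide.index]
    if missing_refs:
        raise ValidationError(f"reference genes absent from table: {missing_refs}")
    ref_ct = wide.loc[reference_set]
    bad = ref_ct.columns[ref_ct.isna().any(axis=0)]
    if len(bad):
        log.warning("dropping sample(s) with undetermined reference gene: %s",
                    list(bad))
    keep = [c for c in wide.columns if c not in set(bad)]
    wide = wide[keep]
    if efficiency is None:
        eff = ct_clean.efficiency.reindex(wide.index).to_numpy(float)
    else:
        eff = np.full(len(wide.index), float(efficiency))
    mean_ct = wide.mean(axis=1, skipna=True)
    rq = pd.DataFrame(
        np.power(eff[:, None], (mean_ct.to_numpy()[:, None] - wide.to_numpy(float))),
        index=wide.index, columns=wide.columns)
    nf = pd.Series(geometric_mean(rq.loc[reference_set].to_numpy(float), axis=0),
                   index=wide.columns, name="nf")
    nrq = rq.div(nf, axis=1)
    return NormalizedExpression(rq=rq, nf=nf, nrq=nrq,
                                reference_set=reference_set,
                                dropped_samples=list(bad))


def _remove_outliers(values: np.ndarray, mode: str) -> np.ndarray:
    """Per-sex outlier removal on log2 normalized quantities."""
    if mode == "none" or len(values) == 0:
        return values
    q1, q3 = np.percentile(values, [25, 75])
    if mode == "tukey":
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    elif mode == "literal_quartile":
        lo, hi = q1, q3
    else:
        raise ValidationError(f"unknown outlier mode: {mode!r}")
    return values[(values >= lo) & (values <= hi)]


def _wilcoxon_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 10) -> float:
    """Two-sided rank-sum p; exact enumeration at small n, else asymptotic."""
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if max(len(x), len(y)) <= exact_max_n and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


def sex_bias_test(ne: NormalizedExpression, sex: Mapping[str, str] | pd.Series,
                  genes: Sequence[str] | None = None,
                  fc_threshold: float = 1.5, alpha: float = 0.05,
                  outlier_mode: str = "tukey",
                  min_per_sex: int = 3) -> pd.DataFrame:
    """Per-gene sex-bias calls on normalized relative quantities.

    log2 fold change is the male minus female difference of per-sex mean
    log2 NRQ (a ratio of geometric means); its SE combines the per-sex
    standard errors.  Significance needs both |fold change| >=
    ``fc_threshold`` and a Benjamini-Hochberg q <= ``alpha`` from two-sided
    Wilcoxon rank-sum tests over the tested gene set.
    """
    sex = pd.Series(sex)
    if genes is None:
        genes = list(ne.target_nrq().index)
    log2_thr = np.log2(fc_threshold)
    rows = []
    for g in genes:
        vals = ne.nrq.loc[g]
        obs = vals.dropna()
        if obs.empty:
            rows.append((g, np.nan, np.nan, np.nan, CALL_NOT_EXPRESSED, 0, 0))
            continue
        log2v = np.log2(obs.to_numpy(float))
        sx = sex.reindex(obs.index)
        m = _remove_outliers(log2v[(sx == MALE).to_numpy()], outlier_mode)
        f = _remove_outliers(log2v[(sx == FEMALE).to_numpy()], outlier_mode)
        if len(m) < min_per_sex or len(f) < min_per_sex:
            rows.append((g, np.nan, np.nan, np.nan, CALL_UNTESTABLE,
                         len(m), len(f)))
            continue
        fc = float(m.mean() - f.mean())
        se = float(np.sqrt(m.var(ddof=1) / len(m) + f.var(ddof=1) / len(f)))
        p = _wilcoxon_p(np.exp2(m), np.exp2(f))
        rows.append((g, fc, se, p, None, len(m), len(f)))
    out = pd.DataFrame(rows, columns=["gene", "log2_fc", "se", "p_wilcoxon",
                                      "call", "n_m", "n_f"]).set_index("gene")
    tested = out.index[out["p_wilcoxon"].notna()]
    out["q_bh"] = np.nan
    if len(tested):
        out.loc[tested, "q_bh"] = multipletests(
            out.loc[tested, "p_wilcoxon"].to_numpy(float), method="fdr_bh")[1]
    for g in tested:
        fc, q = out.at[g, "log2_fc"], out.at[g, "q_bh"]
        if fc >= log2_thr and q <= alpha:
            out.at[g, "call"] = CALL_MALE
        elif fc <= -log2_thr and q <= alpha:
            out.at[g, "call"] = CALL_FEMALE
        else:
            out.at[g, "call"] = CALL_UNBIASED
    return out[["log2_fc", "se", "p_wilcoxon", "q_bh", "call", "n_m", "n_f"]]
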