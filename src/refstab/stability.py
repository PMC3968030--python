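"""The four qPCR reference-gene stability estimators and their consensus.

All four operate on a complete gene x observation matrix:

* geNorm — a gene's M value is the mean, over all other genes, of the
  standard deviation across samples of the pairwise log2 expression ratio;
  genes are excluded iteratively from the highest M until two remain.
  The pairwise variation V(n/n+1) compares normalization factors built from
  the n and n+1 most stable genes and indicates how many references suffice.
* Δct — the same pairwise idea on raw Ct values: mean across partners of
  the per-pair SD of Ct differences.
* NormFinder — a model-based estimator separating between-group bias (here
  the two sexes) from within-group variance on the log2 quantity scale.
* BestKeeper — descriptive: per-gene Ct SD plus Pearson correlation with
  the BestKeeper index (per-sample geometric mean Ct over candidates).

The consensus follows the geometric-mean-of-ranks scheme popularised by
RefFinder: each method contributes a rank (1 = most stable, ties averaged)
and the consensus is the geometric mean of the four.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    CtTable,
    StabilityReport,
    ValidationError,
    geometric_mean,
)


@dataclass
class QuantityMatrix:
    """Relative quantities q = E**(Ct_min - Ct) on complete observations.

    The per-gene minimum Ct is the calibrator, so q lies in (0, 1] with the
    most concentrated sample at 1.  Columns are samples (or (sample,
    tech_rep) pairs in replicate-level mode); only observations where every
    gene under analysis is determined are kept (complete case).
    """

    q: pd.DataFrame
    log2q: pd.DataFrame
    group: pd.Series | None = None

    @property
    def genes(self) -> pd.Index:
        return self.q.index

    @property
    def n_obs(self) -> int:
        return self.q.shape[1]


def complete_case(wide_ct: pd.DataFrame) -> pd.DataFrame:
    """Drop observation columns with any missing gene."""
    return wide_ct.dropna(axis=1, how="any")


def quantity_matrix(ct: CtTable, genes: Sequence[str] | None = None,
                    replicates: str = "raw",
                    efficiency: float | None = None) -> QuantityMatrix:
    """Build the relative-quantity matrix from a Ct table.

    ``efficiency=None`` uses each gene's own assay efficiency; a float
    (typically 2.0, perfect doubling) overrides all genes.
    """
    wide = complete_case(ct.wide_ct(genes=genes, replicates=replicates))
    if wide.shape[1] < 2:
        raise ValidationError("need >=2 complete observations")
    if efficiency is None:
        eff = ct.efficiency.reindex(wide.index).to_numpy(float)
    else:
        eff = np.full(len(wide.index), float(efficiency))
    ctmin = wide.min(axis=1).to_numpy(float)
    log2q = (ctmin[:, None] - wide.to_numpy(float)) * np.log2(eff)[:, None]
    log2q = pd.DataFrame(log2q, index=wide.index, columns=wide.columns)
    group = None
    sex = ct.sample_sex()
    cols = wide.columns
    names = [c[0] if isinstance(c, tuple) else c for c in cols]
    if all(n in sex.index for n in names):
        group = pd.Series([sex[n] for n in names], index=cols)
    return QuantityMatrix(q=np.exp2(log2q), log2q=log2q, group=group)


def _pairwise_m(log2q: pd.DataFrame) -> pd.Series:
    """geNorm M for every gene of a complete log2-quantity matrix."""
    arr = log2q.to_numpy(float)
    n = arr.shape[0]
    vjk = np.zeros((n, n))
    for j in range(n):
        diff = arr[j][None, :] - arr  # log2 ratios of gene j vs all genes
        vjk[j] = diff.std(axis=1, ddof=1)
    m = vjk.sum(axis=1) / (n - 1)  # diagonal is 0
    return pd.Series(m, index=log2q.index, name="M")


@dataclass
class GenormResult:
    m_first_pass: pd.Series
    m_exclusion: pd.Series
    exclusion_order: pd.Series
    rank: pd.Series
    pairwise_variation: dict[int, float] = field(default_factory=dict)
    stability_order: list[str] = field(default_factory=list)


def genorm(qm: QuantityMatrix) -> GenormResult:
    """Iterative geNorm: M values, exclusion order, ranks and V(n/n+1).

    The final two genes cannot be separated and share rank 1.5.  Ties on M
    during exclusion are broken by gene id (first lexicographically is
    excluded), so the procedure is deterministic.
    """
    log2q = qm.log2q
    genes = list(log2q.index)
    G = len(genes)
    if G < 3:
        raise ValidationError("geNorm needs at least 3 genes")
    m_first = _pairwise_m(log2q)

    remaining = sorted(genes)
    m_excl = {}
    excl_order = {}
    removed: list[str] = []
    step = 0
    while len(remaining) > 2:
        step += 1
        m = _pairwise_m(log2q.loc[remaining])
        worst = m.loc[sorted(remaining)].idxmax()
        m_excl[worst] = float(m[worst])
        excl_order[worst] = step
        remaining.remove(worst)
        removed.append(worst)
    # the last pair is tied: both keep their mutual M and share rank 1.5
    for g in remaining:
        m_excl[g] = float(np.std(
            log2q.loc[remaining[0]].to_numpy(float)
            - log2q.loc[remaining[1]].to_numpy(float), ddof=1))
        excl_order[g] = G - 1
    rank = {}
    for g in genes:
        e = excl_order[g]
        rank[g] = 1.5 if e == G - 1 else G - e + 1

    # normalization factors grow from the most stable pair outwards
    stability_order = sorted(remaining) + removed[::-1]
    v = {}
    for n in range(2, G):
        nf_n = qm.log2q.loc[stability_order[:n]].mean(axis=0)
        nf_n1 = qm.log2q.loc[stability_order[:n + 1]].mean(axis=0)
        v[n] = float((nf_n - nf_n1).std(ddof=1))
    return GenormResult(
        m_first_pass=m_first,
        m_exclusion=pd.Series(m_excl).reindex(genes),
        exclusion_order=pd.Series(excl_order).reindex(genes).astype(int),
        rank=pd.Series(rank).reindex(genes),
        pairwise_variation=v,
        stability_order=stability_order,
    )


def delta_ct(ct: CtTable, genes: Sequence[str] | None = None,
             replicates: str = "mean",
             wide: pd.DataFrame | None = None) -> pd.Series:
    """Comparative Δct stability: mean over partner genes of SD(Ct_j - Ct_k).

    Works on raw Ct (replicate-averaged by default), so it needs no
    efficiency assumption.
    """
    if wide is None:
        wide = complete_case(ct.wide_ct(genes=genes, replicates=replicates))
    arr = wide.to_numpy(float)
    n = arr.shape[0]
    if n < 2:
        raise ValidationError("delta-Ct needs at least 2 genes")
    out = np.zeros(n)
    for j in range(n):
        diff = arr[j][None, :] - arr
        out[j] = diff.std(axis=1, ddof=1).sum() / (n - 1)
    return pd.Series(out, index=wide.index, name="dct_sd")


def normfinder(qm: QuantityMatrix, group: pd.Series | None = None) -> pd.Series:
    """Model-based stability with the sexes as groups.

    On sample-centered log2 quantities, combines the estimated between-group
    expression bias of each gene (shrunk towards zero in proportion to the
    within-group sampling noise) with its within-group standard error:
    rho_i = mean over groups of |shrunk bias| + sqrt(var / n_group).
    """
    if group is None:
        group = qm.group
    if group is None:
        raise ValidationError("normfinder requires a sample -> group mapping")
    X = qm.log2q
    I = X.shape[0]
    if I < 3:
        raise ValidationError("normfinder needs at least 3 genes")
    group = group.reindex(X.columns)
    if group.isna().any():
        raise ValidationError("every observation needs a group label")
    centered = X - X.mean(axis=0)
    labels = list(pd.unique(group))
    n_g = {g: int((group == g).sum()) for g in labels}
    small = [g for g, n in n_g.items() if n < 2]
    if small:
        raise ValidationError(f"groups with <2 observations: {small}")
    G = len(labels)
    a = pd.DataFrame({g: centered.loc[:, (group == g).to_numpy()].mean(axis=1)
                      for g in labels})
    v = pd.DataFrame({g: centered.loc[:, (group == g).to_numpy()].var(axis=1, ddof=1)
                      for g in labels})
    sigma2 = (v * I / (I - 1)).clip(lower=0.0)
    total_n = sum(n_g.values())
    overall = sum(a[g] * n_g[g] for g in labels) / total_n
    d = a.sub(overall, axis=0)
    noise = sum(sigma2[g] / n_g[g] for g in labels) / G
    var_d = d.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        shrink = np.where(var_d > 0, 1.0 - noise / var_d, 0.0)
    shrink = np.clip(np.nan_to_num(shrink, nan=0.0), 0.0, None)
    d_tilde = d.mul(shrink, axis=0)
    rho = sum(d_tilde[g].abs() + np.sqrt(sigma2[g] / n_g[g]) for g in labels) / G
    return pd.Series(rho, index=X.index, name="normfinder_rho")


@dataclass
class BestKeeperResult:
    table: pd.DataFrame  # sd, cv_pct, r, p per gene
    index: pd.Series  # per-sample geometric mean Ct


def bestkeeper(ct: CtTable, genes: Sequence[str] | None = None,
               replicates: str = "mean", sd_mode: str = "sd",
               wide: pd.DataFrame | None = None) -> BestKeeperResult:
    """Descriptive BestKeeper statistics on raw Ct values.

    ``sd_mode="sd"`` is the sample standard deviation; ``"mad"`` is the mean
    absolute deviation around the mean, the original tool's dispersion
    measure.  A constant gene has an undefined correlation with the index
    and is reported with r = NaN.
    """
    if wide is None:
        wide = complete_case(ct.wide_ct(genes=genes, replicates=replicates))
    arr = wide.to_numpy(float)
    if arr.shape[1] < 2:
        raise ValidationError("bestkeeper needs >=2 complete observations")
    index = pd.Series(geometric_mean(arr, axis=0), index=wide.columns,
                      name="bestkeeper_index")
    mean = arr.mean(axis=1)
    if sd_mode == "sd":
        sd = arr.std(axis=1, ddof=1)
    elif sd_mode == "mad":
        sd = np.abs(arr - mean[:, None]).mean(axis=1)
    else:
        raise ValidationError(f"unknown sd_mode: {sd_mode!r}")
    rows = []
    for j, g in enumerate(wide.index):
        if np.ptp(arr[j]) == 0 or np.ptp(index.to_numpy()) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(arr[j], index.to_numpy())
        rows.append((sd[j], 100.0 * sd[j] / mean[j], r, p))
    table = pd.DataFrame(rows, index=wide.index,
                         columns=["bestkeeper_sd", "bestkeeper_cv_pct",
                                  "bestkeeper_r", "bestkeeper_p"])
    return BestKeeperResult(table=table, index=index)


def _avg_rank(values: pd.Series) -> pd.Series:
    """Ascending average ranks (1 = most stable = smallest instability)."""
    return values.rank(method="average")


def consensus_rank(rank_by_method: pd.DataFrame) -> pd.Series:
    """Geometric mean of per-method ranks; columns are methods."""
    if rank_by_method.isna().any().any():
        raise ValidationError("all methods must rank every gene")
    return pd.Series(
        geometric_mean(rank_by_method.to_numpy(float), axis=1),
        index=rank_by_method.index, name="consensus_rank")


def stability_report(ct: CtTable, genes: Sequence[str] | None = None,
                     replicates: str = "raw",
                     efficiency: float | None = None,
                     sd_mode: str = "sd") -> StabilityReport:
    """Run all four estimators on a shared complete-case matrix + consensus.

    ``replicates="raw"`` treats every technical replicate as an observation
    (matching validation studies that rank stability on all wells);
    ``"mean"`` averages replicates first.  ``efficiency=None`` uses each
    assay's own E for the quantity-scale methods.
    """
    wide = complete_case(ct.wide_ct(genes=genes, replicates=replicates))
    if wide.shape[0] < 3:
        raise ValidationError("stability suite needs at least 3 genes")
    if wide.shape[1] < 2:
        raise ValidationError("need >=2 complete observations")
    if efficiency is None:
        eff = ct.efficiency.reindex(wide.index).to_numpy(float)
    else:
        eff = np.full(len(wide.index), float(efficiency))
    ctmin = wide.min(axis=1).to_numpy(float)
    log2q = pd.DataFrame(
        (ctmin[:, None] - wide.to_numpy(float)) * np.log2(eff)[:, None],
        index=wide.index, columns=wide.columns)
    sex = ct.sample_sex()
    names = [c[0] if isinstance(c, tuple) else c for c in wide.columns]
    group = pd.Series([sex.get(n) for n in names], index=wide.columns)
    qm = QuantityMatrix(q=np.exp2(log2q), log2q=log2q, group=group)

    gn = genorm(qm)
    dct = delta_ct(ct, wide=wide)
    nf = normfinder(qm)
    bk = bestkeeper(ct, wide=wide, sd_mode=sd_mode)

    ranks = pd.DataFrame({
        "rank_genorm": gn.rank,
        "rank_dct": _avg_rank(dct),
        "rank_normfinder": _avg_rank(nf),
        "rank_bestkeeper": _avg_rank(bk.table["bestkeeper_sd"]),
    })
    cons = consensus_rank(ranks)
    table = pd.DataFrame({
        "genorm_m": gn.m_exclusion,
        "genorm_m_first_pass": gn.m_first_pass,
        "genorm_exclusion_order": gn.exclusion_order,
        "dct_sd": dct,
        "normfinder_rho": nf,
        "bestkeeper_sd": bk.table["bestkeeper_sd"],
        "bestkeeper_cv_pct": bk.table["bestkeeper_cv_pct"],
        "bestkeeper_r": bk.table["bestkeeper_r"],
    }).join(ranks)
    table["consensus_rank"] = cons
    table.index.name = "gene"
    return StabilityReport(table=table, pairwise_variation=gn.pairwise_variation)
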