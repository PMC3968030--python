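"""RNA-seq screen for candidate reference contigs.

Filter contigs (repeat-flagged, never-expressed), length/depth-normalize to
FRPKM (fragments per kilobase per million mapped fragments), score each
contig by its coefficient of variation between the sexes, keep the lowest-CV
quantile per dataset, and intersect the per-dataset top sets into the final
candidate list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    FEMALE,
    MALE,
    CountMatrix,
    ValidationError,
)

log = logging.getLogger(__name__)


@dataclass
class ExpressionProfile:
    """Per-contig FRPKM with per-sex means and the between-sex CV."""

    frpkm: pd.DataFrame
    sex_mean: pd.DataFrame  # columns male, female
    cv: pd.Series | None = None


@dataclass
class ScreenResult:
    """Outcome of the cross-dataset reference-contig screen."""

    kept_contigs: dict[str, pd.Index]
    cv: dict[str, pd.Series]
    top_sets: dict[str, set[str]]
    candidates: set[str]
    expr_range: tuple[float, float] | None = None
    candidate_table: pd.DataFrame | None = None


def filter_contigs(cm: CountMatrix, min_reads: int = 10,
                   low_count_rule: str = "max") -> CountMatrix:
    """Drop repeat-flagged contigs and contigs that never reach ``min_reads``.

    ``low_count_rule="max"`` (default) reads "never reached >= min_reads
    reads" as: the maximum per-sample count is below ``min_reads``.  The
    alternative ``"total"`` drops contigs whose summed count is below
    ``min_reads``.
    """
    if low_count_rule == "max":
        expressed = (cm.counts >= min_reads).any(axis=1)
    elif low_count_rule == "total":
        expressed = cm.counts.sum(axis=1) >= min_reads
    else:
        raise ValidationError(f"unknown low_count_rule: {low_count_rule!r}")
    keep = expressed & ~cm.repeat_flag
    if not keep.any():
        log.warning("contig filter removed every contig of dataset %s",
                    cm.dataset_id or "<unnamed>")
    return cm.subset(cm.contigs[keep])


def compute_frpkm(cm: CountMatrix) -> ExpressionProfile:
    """Fragments per kilobase per million mapped fragments, per contig/sample.

    The per-sample mapped total is the column sum over the kept contigs, so
    FRPKM is invariant to rescaling any one sample's counts.
    """
    totals = cm.counts.sum(axis=0).astype(float)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"zero mapped fragments in sample(s): {list(zero.index)}")
    kb = cm.length_bp.astype(float) / 1e3
    frpkm = cm.counts.div(kb, axis=0).div(totals / 1e6, axis=1)
    sex_mean = pd.DataFrame({
        sx: frpkm.loc[:, cm.sample_sex == sx].mean(axis=1)
        for sx in (MALE, FEMALE)
    })
    return ExpressionProfile(frpkm=frpkm, sex_mean=sex_mean)


def sex_cv(profile: ExpressionProfile, mode: str = "sex_means") -> pd.Series:
    """Coefficient of variation of expression between the sexes, per contig.

    mode="sex_means" (default): FRPKM is first averaged within each sex and
    the CV is the sample standard deviation (n-1 denominator) over the two
    sex means divided by their mean.  mode="per_sample": CV across all
    individual samples.  Contigs with zero mean expression get NaN.
    """
    if profile.sex_mean[[MALE, FEMALE]].isna().any().any():
        raise ValidationError("both sexes must be represented")
    if mode == "sex_means":
        vals = profile.sex_mean[[MALE, FEMALE]].to_numpy(float)
        sd = vals.std(axis=1, ddof=1)
        mean = vals.mean(axis=1)
    elif mode == "per_sample":
        vals = profile.frpkm.to_numpy(float)
        sd = vals.std(axis=1, ddof=1)
        mean = vals.mean(axis=1)
    else:
        raise ValidationError(f"unknown CV mode: {mode!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    out = pd.Series(cv, index=profile.frpkm.index, name="cv")
    profile.cv = out
    return out


def top_quantile(cv: pd.Series, q: float = 0.01) -> set[str]:
    """Ids of the ceil(q*n) contigs with the smallest finite CV.

    NaN CVs are removed before the quantile is taken.  Ties at the boundary
    are broken lexicographically by contig id, so the result is
    deterministic.
    """
    if not 0 < q < 1:
        raise ValidationError("q must lie in (0, 1)")
    finite = cv.dropna()
    k = math.ceil(q * len(finite))
    frame = pd.DataFrame({"cv": finite, "contig": finite.index.astype(str)})
    frame = frame.sort_values(["cv", "contig"], kind="mergesort")
    return set(frame["contig"].iloc[:k])


def intersect_candidates(sets: list[set[str]]) -> set[str]:
    """Contigs present in every per-dataset top set."""
    if len(sets) < 2:
        raise ValidationError("need top sets from at least two datasets")
    out = set.intersection(*map(set, sets))
    if not out:
        log.warning("no contig is shared by all %d top sets", len(sets))
    return out


def run_screen(datasets: dict[str, CountMatrix], q: float = 0.01,
               min_reads: int = 10, cv_mode: str = "sex_means",
               low_count_rule: str = "max") -> ScreenResult:
    """Full screen across >=2 datasets; see the module docstring."""
    kept, cvs, tops, profiles = {}, {}, {}, {}
    for ds, cm in datasets.items():
        filtered = filter_contigs(cm, min_reads=min_reads,
                                  low_count_rule=low_count_rule)
        profile = compute_frpkm(filtered)
        cv = sex_cv(profile, mode=cv_mode)
        kept[ds] = filtered.contigs
        cvs[ds] = cv
        tops[ds] = top_quantile(cv, q=q)
        profiles[ds] = profile
    candidates = intersect_candidates(list(tops.values()))
    expr_range = None
    table = None
    if candidates:
        ordered = sorted(candidates)
        per_ds = {f"cv_{ds}": cvs[ds].reindex(ordered) for ds in datasets}
        all_frpkm = pd.concat(
            [profiles[ds].frpkm.reindex(ordered) for ds in datasets], axis=1)
        lo = all_frpkm.min(axis=1)
        hi = all_frpkm.max(axis=1)
        expr_range = (float(lo.min()), float(hi.max()))
        table = pd.DataFrame({"contig_id": ordered, **per_ds,
                              "frpkm_min": lo.to_numpy(),
                              "frpkm_max": hi.to_numpy()}).set_index("contig_id")
    return ScreenResult(kept_contigs=kept, cv=cvs, top_sets=tops,
                        candidates=candidates, expr_range=expr_range,
                        candidate_table=table)
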