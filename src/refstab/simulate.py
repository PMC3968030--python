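"""Synthetic RNA-seq counts and qPCR Ct tables with planted ground truth.

The generators emulate the two study designs the pipeline is built around:

* two independent flower-bud RNA-seq datasets — one with three males and
  three females (an inbred line, "U10"), one with four of each sex (an
  intraspecific cross, "C1") — in which a small minority of contigs is
  planted as sex-stable (zero sex effect, minimal biological dispersion),
  the ground truth for the coefficient-of-variation screen; and
* qPCR runs of a gene panel in triplicate over male and female biological
  replicates, with a shared per-sample loading shift (the nuisance that
  reference-gene normalization must remove), per-gene biological noise, and
  optional planted sex effects expressed in cycles.

Counts are negative binomial around log-normally distributed expression
levels with per-sample library sizes; planted stable contigs sit in the
strongly expressed range, as true housekeeping genes do, because counting
noise alone sets a floor on the CV of weakly expressed contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    FEMALE,
    MALE,
    MAX_CYCLES,
    ConfigurationError,
    CountMatrix,
    CtTable,
)


@dataclass
class RnaSeqSimConfig:
    """Parameters of the two-dataset RNA-seq count simulation.

    log2 expression of ordinary contigs ~ Normal(mean_log_expr, log_expr_sd);
    planted stable contigs ~ Normal(stable_log_expr, stable_log_expr_sd).
    Non-stable contigs carry a contig-specific sex effect
    ~ Normal(0, sex_effect_sd) (log2 units, shared across datasets) and
    negative-binomial overdispersion ``dispersion``; stable contigs have sex
    effect exactly 0 and dispersion ``stable_dispersion``.
    """

    n_contigs: int = 10_000
    n_per_sex: Mapping[str, int] = field(default_factory=lambda: {"U10": 3, "C1": 4})
    n_stable: int = 20
    mean_log_expr: float = 5.0
    log_expr_sd: float = 1.3
    stable_log_expr: float = 12.0
    stable_log_expr_sd: float = 0.5
    dispersion: float = 0.03
    stable_dispersion: float = 1e-6
    sex_effect_sd: float = 1.0
    library_size_range: tuple[int, int] = (18_000_000, 22_000_000)
    length_range_bp: tuple[int, int] = (500, 3000)
    repeat_fraction: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_stable > self.n_contigs:
            raise ConfigurationError("n_stable cannot exceed n_contigs")
        if self.dispersion <= 0 or self.stable_dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if not 0 <= self.repeat_fraction <= 1:
            raise ConfigurationError("repeat_fraction must lie in [0, 1]")


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial draws with mean mu and variance mu + alpha*mu^2."""
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_rnaseq(config: RnaSeqSimConfig
                    ) -> tuple[dict[str, CountMatrix], set[str]]:
    """Simulate per-dataset count matrices plus the planted stable-contig ids.

    Contig-level properties (expression, length, sex effect, repeat flag,
    which contigs are stable) are drawn once and shared across datasets;
    sampling noise is independent per dataset.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_contigs
    width = len(str(n))
    contigs = pd.Index([f"contig_{i:0{width}d}" for i in range(1, n + 1)],
                       name="contig_id")
    stable_idx = rng.choice(n, size=config.n_stable, replace=False)
    stable_mask = np.zeros(n, dtype=bool)
    stable_mask[stable_idx] = True

    log_expr = rng.normal(config.mean_log_expr, config.log_expr_sd, size=n)
    log_expr[stable_mask] = rng.normal(config.stable_log_expr,
                                       config.stable_log_expr_sd,
                                       size=config.n_stable)
    sex_effect = rng.normal(0.0, config.sex_effect_sd, size=n)
    sex_effect[stable_mask] = 0.0
    lengths = rng.integers(config.length_range_bp[0], config.length_range_bp[1] + 1,
                           size=n)
    repeat = rng.random(n) < config.repeat_fraction
    repeat[stable_mask] = False  # planted truth must survive the repeat filter

    datasets: dict[str, CountMatrix] = {}
    for ds, n_sex in config.n_per_sex.items():
        samples = [f"{ds}_M{i+1}" for i in range(n_sex)] + \
                  [f"{ds}_F{i+1}" for i in range(n_sex)]
        sexes = [MALE] * n_sex + [FEMALE] * n_sex
        # RNA-seq measures relative abundance, so "planted stable" must mean
        # a constant library fraction: sex effects redistribute mass among
        # the non-stable contigs only, leaving the stable contigs' expected
        # relative abundance (hence FRPKM) exactly equal between the sexes.
        base = np.exp2(log_expr)
        nonstable_total = base[~stable_mask].sum()
        w_by_sex = {}
        for sx, sign in ((MALE, 0.5), (FEMALE, -0.5)):
            w = base.copy()
            shifted = base[~stable_mask] * np.exp2(sign * sex_effect[~stable_mask])
            w[~stable_mask] = shifted * (nonstable_total / shifted.sum())
            w_by_sex[sx] = w / w.sum()
        counts = np.empty((n, 2 * n_sex), dtype=np.int64)
        for j, sx in enumerate(sexes):
            libsize = rng.uniform(*config.library_size_range)
            mu = w_by_sex[sx] * libsize
            col = np.empty(n, dtype=np.int64)
            for mask, alpha in ((stable_mask, config.stable_dispersion),
                                (~stable_mask, config.dispersion)):
                col[mask] = _nb_sample(rng, mu[mask], alpha)
            counts[:, j] = col
        datasets[ds] = CountMatrix(
            counts=pd.DataFrame(counts, index=contigs, columns=samples),
            length_bp=pd.Series(lengths, index=contigs),
            repeat_flag=pd.Series(repeat, index=contigs),
            sample_sex=pd.Series(sexes, index=samples),
            dataset_id=ds,
        )
    truth = set(contigs[stable_mask])
    return datasets, truth


@dataclass
class GeneSpec:
    """One qPCR assay in the Ct simulation.

    ``group_effect`` is the shift (cycles) added to male samples; a planted
    stable gene has group_effect 0.  ``efficiency`` is the fold
    amplification per cycle, E in (1, 2].
    """

    name: str
    mean_ct: float
    group_effect: float = 0.0
    noise_sd: float = 0.15
    efficiency: float = 2.0


@dataclass
class CtSimConfig:
    """Parameters of the qPCR Ct simulation.

    Ct(g, s, rep) = mean_ct_g + loading_s + group_effect_g * [s is male]
                    + biological(g, s) + technical(g, s, rep),
    with loading ~ Normal(0, sample_loading_sd) shared by all genes of a
    sample, biological ~ Normal(0, noise_sd_g) per gene x biological
    replicate, and technical ~ Normal(0, tech_rep_sd) per well.  Values
    above ``undetermined_above`` are emitted as undetermined.  Each gene
    gets one no-template control well with Ct drawn from ``ntc_ct_range``
    (undetermined when the draw exceeds the cycle limit).
    """

    genes: Sequence[GeneSpec] = ()
    n_per_sex: int = 7
    n_tech_rep: int = 3
    sample_loading_sd: float = 0.5
    tech_rep_sd: float = 0.1
    undetermined_above: float = 35.0
    ntc_ct_range: tuple[float, float] = (38.0, 45.0)
    tissue: str = "flower_bud"
    seed: int = 0

    def validate(self) -> None:
        if not self.genes:
            raise ConfigurationError("at least one gene is required")
        if self.n_per_sex < 1 or self.n_tech_rep < 1:
            raise ConfigurationError("need at least one sample and replicate")
        for g in self.genes:
            if g.noise_sd < 0:
                raise ConfigurationError(f"{g.name}: noise_sd must be >= 0")
            if not 1.0 <= g.efficiency <= 2.0:
                raise ConfigurationError(f"{g.name}: efficiency must lie in [1, 2]")


def default_reference_panel(n_genes: int = 10, ct_low: float = 22.0,
                            ct_high: float = 30.0, noise_sd: float = 0.15,
                            efficiency: float = 2.0,
                            unstable: Mapping[str, float] | None = None
                            ) -> list[GeneSpec]:
    """A panel of candidate reference genes with evenly spread mean Ct.

    ``unstable`` maps gene name -> group effect in cycles for genes planted
    as sex-affected (e.g. {"G01": 2.0}).
    """
    unstable = dict(unstable or {})
    means = np.linspace(ct_low, ct_high, n_genes)
    return [GeneSpec(name=f"G{i+1:02d}", mean_ct=float(m),
                     group_effect=unstable.get(f"G{i+1:02d}", 0.0),
                     noise_sd=noise_sd, efficiency=efficiency)
            for i, m in enumerate(means)]


def simulate_ct(config: CtSimConfig) -> tuple[CtTable, pd.Series]:
    """Simulate a tidy Ct table; truth is the per-gene male-shift in cycles."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = [f"M{i+1}" for i in range(config.n_per_sex)] + \
              [f"F{i+1}" for i in range(config.n_per_sex)]
    sexes = [MALE] * config.n_per_sex + [FEMALE] * config.n_per_sex
    loading = rng.normal(0.0, config.sample_loading_sd, size=len(samples))

    rows = []
    for g in config.genes:
        bio = rng.normal(0.0, g.noise_sd, size=len(samples))
        for j, (s, sx) in enumerate(zip(samples, sexes)):
            base = g.mean_ct + loading[j] + (g.group_effect if sx == MALE else 0.0) \
                + bio[j]
            for rep in range(1, config.n_tech_rep + 1):
                ct = base + rng.normal(0.0, config.tech_rep_sd)
                undet = ct > config.undetermined_above
                rows.append((g.name, s, sx, config.tissue, rep,
                             np.nan if undet else min(ct, MAX_CYCLES), undet, False))
        ntc_ct = rng.uniform(*config.ntc_ct_range)
        ntc_undet = ntc_ct > MAX_CYCLES
        rows.append((g.name, "NTC", "none", config.tissue, 1,
                     np.nan if ntc_undet else ntc_ct, ntc_undet, True))
    data = pd.DataFrame(rows, columns=["gene", "sample", "sex", "tissue",
                                       "tech_rep", "ct", "undetermined", "is_ntc"])
    eff = pd.Series({g.name: g.efficiency for g in config.genes})
    truth = pd.Series({g.name: g.group_effect for g in config.genes})
    return CtTable(data, eff), truth


def simulate_targets(config: CtSimConfig, log2_fc: Mapping[str, float]
                     ) -> tuple[CtTable, pd.Series]:
    """Simulate target genes with planted fold changes on the quantity scale.

    A male/female fold change of ``2**log2_fc`` corresponds, through a
    gene's own efficiency, to a male Ct shift of -log2_fc / log2(E) cycles
    (more template -> earlier threshold crossing).
    """
    gene_by_name = {g.name: g for g in config.genes}
    unknown = sorted(set(log2_fc) - set(gene_by_name))
    if unknown:
        raise ConfigurationError(f"log2_fc given for unknown genes: {unknown}")
    new_genes = []
    for g in config.genes:
        fc = float(log2_fc.get(g.name, 0.0))
        if fc != 0.0 and g.efficiency <= 1.0:
            raise ConfigurationError(
                f"{g.name}: efficiency must exceed 1 to express a fold change")
        shift = 0.0 if fc == 0.0 else -fc / np.log2(g.efficiency)
        new_genes.append(GeneSpec(g.name, g.mean_ct, shift, g.noise_sd, g.efficiency))
    sub = CtSimConfig(genes=new_genes, n_per_sex=config.n_per_sex,
                      n_tech_rep=config.n_tech_rep,
                      sample_loading_sd=config.sample_loading_sd,
                      tech_rep_sd=config.tech_rep_sd,
                      undetermined_above=config.undetermined_above,
                      ntc_ct_range=config.ntc_ct_range,
                      tissue=config.tissue, seed=config.seed)
    table, _ = simulate_ct(sub)
    truth = pd.Series({g.name: float(log2_fc.get(g.name, 0.0)) for g in config.genes})
    return table, truth
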