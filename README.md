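# refstab

Reference-gene discovery and validation for qPCR studies of between-sex
gene expression, built around the workflow used for dioecious plants such
as *Silene latifolia* (white campion): find candidate housekeeping genes in
RNA-seq data, validate their stability from qRT-PCR Ct measurements, and
use the best of them for efficiency-corrected normalization and sex-bias
calling of target genes.

It is aimed at molecular ecologists and plant biologists who have a de novo
transcriptome, RNA-seq counts from males and females, and a qPCR machine —
and who need defensible reference genes before running a target-gene study.

## What it computes

**RNA-seq screen.** Per-contig fragment counts are filtered (repeat-flagged
contigs and contigs never reaching ≥10 reads in any sample are dropped) and
converted to FRPKM (fragments per kilobase per million mapped fragments).
For each contig the coefficient of variation CV = sd/mean is computed
between the male and female mean FRPKM; the 1% of contigs with the lowest
CV is kept per dataset, and candidates are the intersection across ≥2
independent datasets.

**Stability suite.** Four estimators, applied to the efficiency-corrected
relative quantities q = E^(Ct_min − Ct) (or raw Ct where the method calls
for it):

- *geNorm*: M_j = mean over partner genes k of SD_s(log2 q_j/q_k), with
  iterative exclusion of the worst gene and the pairwise variation
  V(n/n+1) = SD_s(log2 NF_n/NF_{n+1}) between normalization factors built
  from the n and n+1 most stable genes;
- *Δct*: mean over partners of SD_s(Ct_j − Ct_k);
- *NormFinder*: a model-based score ρ combining a gene's shrunken
  between-sex bias with its within-sex standard error, on sample-centered
  log2 quantities;
- *BestKeeper*: per-gene Ct SD, CV% and Pearson r against the per-sample
  geometric-mean Ct index.

The consensus rank is the geometric mean of the four per-method ranks
(1 = most stable, ties averaged), the scheme popularised by RefFinder.

**Quantification.** Ct quality control (undetermined above 35 cycles,
≥8-cycle margin to any no-template-control signal, assays with ≥10% missing
data excluded, technical replicates averaged with their SD reported);
qBase-style normalization rq = E^(meanCt − Ct), NF = geometric mean of the
reference genes' rq per sample, NRQ = rq/NF; and a sex-bias test per gene:
log2 fold change = difference of per-sex means of log2 NRQ after outlier
removal, exact two-sided Wilcoxon rank-sum p, Benjamini–Hochberg q, and a
call of male/female-biased only when |FC| ≥ 1.5 and q ≤ 0.05.

**Primer QC.** Each assay is checked against the panel design rules
(primer 24–25 nt, amplicon 100–200 bp, GC 50–60%, Tm 60±1 °C with <0.5 °C
difference, hairpin score ≤6, self/pair dimer ≤4). The published
*S. latifolia* assay panel (21 novel + 6 traditional assays, GenBank
GARX01000000) ships as a packaged fixture.

**Simulator.** `refstab.simulate` generates RNA-seq count matrices (two
datasets, 3♂/3♀ and 4♂/4♀, negative-binomial counts with planted
sex-stable contigs) and qPCR Ct tables (triplicate wells, per-sample
loading shifts, planted sex effects expressed in cycles through each
assay's own efficiency) with known ground truth, so every stage can be
tested for recovery. See `docs/methods.md` for the model and its limits.

## Worked example

Simulate a study (two RNA-seq datasets of 10,000 contigs with 20 planted
stable contigs, and an 8-gene qPCR panel over 7♂/7♀), then run the screen,
the stability ranking and a sex-bias test:

```
refstab --seed 11 --out-dir demo simulate --n-genes 8 --n-per-sex 7
refstab --out-dir demo_res screen \
    --counts demo/counts_U10.tsv --metadata demo/metadata_U10.csv \
    --counts demo/counts_C1.tsv  --metadata demo/metadata_C1.csv
# -> 22 candidate contig(s); FRPKM range (3.53..., 17198.4...)
```

22 candidates pass the two-dataset top-1% CV intersection (the 20 planted
stable contigs plus two low-CV passengers); `screen_candidates.tsv` lists
each with its per-dataset CV and FRPKM range:

```
   contig_id   cv_U10    cv_C1   frpkm_min   frpkm_max
contig_00287 0.002312 0.003438 3861.925241 3920.244078
contig_00704 0.000329 0.001916 2029.031979 2047.343766
```

```
refstab --out-dir demo_res stability \
    --ct demo/ct.csv --efficiencies demo/efficiencies.csv
```

prints the panel sorted by consensus rank with each gene's geNorm M —
all M < 0.3, i.e. every simulated gene is a usable reference:

```
gene  consensus_rank  genorm_m
G08         1.414214  0.230939
G02         3.027400  0.192585
G05         3.464102  0.224231
...
G07         6.260338  0.277947
```

```
refstab --out-dir demo_res sexbias \
    --ct demo/ct.csv --efficiencies demo/efficiencies.csv \
    --references G01,G02,G03 --targets G07,G08
```

```
       log2_fc        se  p_wilcoxon      q_bh      call  n_m  n_f
G07  -0.037121  0.129749    0.455711  0.628205  unbiased    7    7
G08  -0.000299  0.064152    0.628205  0.628205  unbiased    6    7
```

Both targets were simulated without a sex effect, and both are called
unbiased with log2 fold changes near 0; `n_m`/`n_f` are the biological
replicates retained per sex after Tukey outlier removal.

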