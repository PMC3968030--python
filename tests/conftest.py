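import numpy as np
import pandas as pd
import pytest

from refstab.datamodel import CountMatrix, CtTable


def make_ct_frame(ct_values, genes=None, samples=None, sexes=None,
                  tissue="flower_bud", n_rep=1, ntc=None):
    """Build a tidy Ct DataFrame from a gene x sample array.

    ``ntc`` maps gene -> NTC Ct (or None for an undetermined NTC well).
    NaN entries in ``ct_values`` become undetermined template wells.
    """
    arr = np.asarray(ct_values, dtype=float)
    n_genes, n_samples = arr.shape
    genes = genes or [f"G{i+1}" for i in range(n_genes)]
    samples = samples or [f"S{j+1}" for j in range(n_samples)]
    if sexes is None:
        sexes = ["male" if j < n_samples // 2 else "female"
                 for j in range(n_samples)]
    rows = []
    for i, g in enumerate(genes):
        for j, s in enumerate(samples):
            for rep in range(1, n_rep + 1):
                v = arr[i, j]
                rows.append((g, s, sexes[j], tissue, rep,
                             np.nan if np.isnan(v) else v, bool(np.isnan(v)), False))
        if ntc is not None and g in ntc:
            v = ntc[g]
            rows.append((g, "NTC", "none", tissue, 1,
                         np.nan if v is None else v, v is None, True))
    return pd.DataFrame(rows, columns=["gene", "sample", "sex", "tissue",
                                       "tech_rep", "ct", "undetermined", "is_ntc"])


def make_ct_table(ct_values, efficiency=2.0, **kwargs) -> CtTable:
    df = make_ct_frame(ct_values, **kwargs)
    genes = list(pd.unique(df["gene"]))
    if np.isscalar(efficiency):
        eff = pd.Series({g: float(efficiency) for g in genes})
    else:
        eff = pd.Series(efficiency)
    return CtTable(df, eff)


def make_count_matrix(counts, lengths=None, repeat=None, sexes=None,
                      dataset_id="ds") -> CountMatrix:
    counts = pd.DataFrame(counts)
    counts.index = pd.Index([f"c{i+1}" for i in range(counts.shape[0])],
                            name="contig_id")
    counts.columns = [f"s{j+1}" for j in range(counts.shape[1])]
    n, m = counts.shape
    lengths = pd.Series(lengths if lengths is not None else [1000] * n,
                        index=counts.index)
    repeat = pd.Series(repeat if repeat is not None else [False] * n,
                       index=counts.index)
    if sexes is None:
        sexes = ["male" if j < m // 2 else "female" for j in range(m)]
    sex = pd.Series(sexes, index=counts.columns)
    return CountMatrix(counts=counts, length_bp=lengths, repeat_flag=repeat,
                       sample_sex=sex, dataset_id=dataset_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
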