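import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refstab.datamodel import StabilityReport, ValidationError
from refstab.quant import (
    _remove_outliers,
    _wilcoxon_p,
    balance_design,
    normalize,
    qc_ct,
    select_references,
    sex_bias_test,
    validate_reference_set,
)
from refstab.simulate import CtSimConfig, GeneSpec, simulate_ct, simulate_targets
from refstab.stability import quantity_matrix

from conftest import make_ct_table


class TestQcCt:
    def test_ct_above_cutoff_becomes_undetermined(self):
        ct = make_ct_table([[35.2, 30.0], [30.0, 30.0]] + [[25.0, 25.0]] * 8,
                           ntc={f"G{i+1}": None for i in range(10)})
        clean, report = qc_ct(ct)
        status = report.well_status.set_index(["gene", "sample"])["status"]
        assert status.loc[("G1", "S1")] == "undetermined"
        assert status.loc[("G1", "S2")] == "ok"

    def test_ntc_margin_rule(self):
        # NTC at 38, template at 31 -> margin 7 < 8 -> fail; 29 passes (margin 9)
        ct = make_ct_table([[31.0, 29.0], [25.0, 25.0], [26.0, 26.0]],
                           ntc={"G1": 38.0, "G2": None, "G3": None})
        clean, report = qc_ct(ct, max_missing=0.75)
        status = report.well_status.set_index(["gene", "sample"])["status"]
        assert status.loc[("G1", "S1")] == "ntc_fail"
        assert status.loc[("G1", "S2")] == "ok"

    def test_missing_fraction_excludes_assay(self):
        # 2 of 16 wells (12.5%) undetermined -> excluded at the 10% threshold
        vals = np.full((2, 8), 25.0)
        vals[0, 0] = np.nan  # one sample x two replicates = 2 of 16 wells
        ct = make_ct_table(vals.tolist(), n_rep=2)
        clean, report = qc_ct(ct)
        assert report.gene_stats.loc["G1", "missing_fraction"] == pytest.approx(0.125)
        assert report.excluded_genes == ["G1"]
        assert "G1" not in clean.genes

    def test_replicates_averaged_and_sd_flagged(self):
        df_vals = [[20.0, 21.0], [25.0, 26.0]]
        ct = make_ct_table(df_vals, n_rep=3)
        # spread replicates of G1/S1 by hand: 19, 20, 21 -> per-sample sd 1.0,
        # so the gene's mean replicate SD is 0.5 >= the 0.3-cycle flag level
        d = ct.data
        idx = d[(d["gene"] == "G1") & (d["sample"] == "S1")].index
        d.loc[idx, "ct"] = [19.0, 20.0, 21.0]
        clean, report = qc_ct(ct)
        assert report.gene_stats.loc["G1", "rep_sd_flag"]
        wide = clean.wide_ct(replicates="mean")
        assert wide.loc["G1", "S1"] == pytest.approx(20.0)

    def test_no_ntc_skips_rule_with_warning(self, caplog):
        ct = make_ct_table([[25.0, 25.0], [26.0, 26.0]])
        with caplog.at_level("WARNING"):
            qc_ct(ct)
        assert any("NTC" in r.message for r in caplog.records)


class TestBalanceDesign:
    def _table(self):
        return make_ct_table(np.linspace(20, 25, 18).reshape(3, 6).tolist(),
                             sexes=["male"] * 3 + ["female"] * 3)

    def test_counterpart_removed_keeps_balance(self):
        ct = self._table()
        out = balance_design(ct, "S4", seed=0)  # S4 is female
        sex = out.sample_sex()
        assert (sex == "male").sum() == 2 and (sex == "female").sum() == 2
        assert "S4" not in out.samples

    def test_identity_when_nothing_removed(self):
        ct = self._table()
        out = balance_design(ct, None)
        assert out.samples == ct.samples

    def test_deterministic_under_seed(self):
        picks = {tuple(sorted(balance_design(self._table(), "S1", seed=42).samples))
                 for _ in range(5)}
        assert len(picks) == 1

    def test_error_when_opposite_sex_exhausted(self):
        ct = make_ct_table([[20.0, 21.0]], sexes=["male", "female"])
        with pytest.raises(ValidationError):
            balance_design(ct, "S1", seed=0)


class TestSelectReferences:
    def _report(self, genes, consensus):
        table = pd.DataFrame({"consensus_rank": consensus}, index=genes)
        return StabilityReport(table=table)

    def test_infinite_window_returns_top_k(self):
        rep = self._report(list("ABCD"), [1.0, 2.0, 3.0, 4.0])
        mean_ct = pd.Series([20, 25, 30, 35], index=list("ABCD"), dtype=float)
        assert select_references(rep, mean_ct, 27.0, k=2, ct_window=1e9) == ["A", "B"]

    def test_intensity_window_excludes_off_scale_gene(self):
        # globally most stable gene is 8 cycles away -> not selected at window 3
        rep = self._report(list("ABCD"), [1.0, 2.0, 3.0, 4.0])
        mean_ct = pd.Series([20.0, 27.0, 28.0, 29.0], index=list("ABCD"))
        out = select_references(rep, mean_ct, 28.0, k=3, ct_window=3.0)
        assert out == ["B", "C", "D"]

    def test_window_widens_when_too_few(self, caplog):
        rep = self._report(list("ABC"), [1.0, 2.0, 3.0])
        mean_ct = pd.Series([24.0, 28.5, 31.0], index=list("ABC"))
        with caplog.at_level("WARNING"):
            out = select_references(rep, mean_ct, 24.0, k=2, ct_window=1.0)
        assert out == ["A", "B"]
        assert any("widening" in r.message for r in caplog.records)

    def test_k_too_large(self):
        rep = self._report(list("AB"), [1.0, 2.0])
        with pytest.raises(ValidationError):
            select_references(rep, pd.Series([20.0, 21.0], index=list("AB")),
                              20.0, k=3)


class TestValidateReferenceSet:
    def test_noise_free_set_passes_with_zero_m_and_v(self):
        vals = np.array([[20.0, 21.0, 22.0, 20.5],
                         [24.0, 25.0, 26.0, 24.5],
                         [27.0, 28.0, 29.0, 27.5]])  # pure loading shifts
        qm = quantity_matrix(make_ct_table(vals.tolist()), replicates="mean",
                             efficiency=2.0)
        m, v, ok = validate_reference_set(qm)
        assert m.max() == pytest.approx(0.0, abs=1e-12)
        assert v == pytest.approx(0.0, abs=1e-12)
        assert ok

    def test_planted_unstable_gene_fails(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 0.05, size=(3, 8)) + 25.0
        vals[0, :4] -= 2.0  # 2-cycle male shift on one "reference"
        ct = make_ct_table(vals.tolist())
        qm = quantity_matrix(ct, replicates="mean", efficiency=2.0)
        m, v, ok = validate_reference_set(qm)
        assert m.max() > 0.5
        assert not ok

    def test_pair_has_nan_v(self):
        vals = [[20.0, 21.0, 20.5], [24.0, 25.2, 24.4]]
        qm = quantity_matrix(make_ct_table(vals), replicates="mean")
        m, v, ok = validate_reference_set(qm)
        assert np.isnan(v)


class TestNormalize:
    def test_single_reference_ddct_identity(self):
        # with one reference and E=2 everywhere, the NRQ ratio between two
        # samples is exactly 2 ** (-ddCt)
        vals = [[24.0, 25.0], [30.0, 28.5]]
        ct = make_ct_table(vals, efficiency=2.0)
        ne = normalize(ct, ["G1"])
        ddct = (30.0 - 28.5) - (24.0 - 25.0)
        ratio = ne.nrq.loc["G2", "S1"] / ne.nrq.loc["G2", "S2"]
        assert ratio == pytest.approx(2.0 ** (-ddct), abs=1e-12)

    def test_rq_closed_form_with_assay_efficiency(self):
        # Ct one cycle below the gene mean -> rq = E = 1.89
        vals = [[24.0, 26.0]]
        ct = make_ct_table(vals, efficiency=1.89)
        ne = normalize(ct, ["G1"])
        assert ne.rq.loc["G1", "S1"] == pytest.approx(1.89, abs=1e-12)

    def test_loading_shift_removed(self, rng):
        vals = rng.uniform(20, 30, size=(4, 5))
        shifted = vals.copy()
        shifted[:, 1] += 2.5  # constant shift on every gene of one sample
        ne1 = normalize(make_ct_table(vals.tolist()), ["G1", "G2", "G3"])
        ne2 = normalize(make_ct_table(shifted.tolist()), ["G1", "G2", "G3"])
        np.testing.assert_allclose(ne1.nrq.to_numpy(), ne2.nrq.to_numpy(),
                                   atol=1e-12)

    def test_nf_is_geometric_mean_of_reference_rq(self, rng):
        vals = rng.uniform(20, 30, size=(5, 6))
        ne = normalize(make_ct_table(vals.tolist()), ["G1", "G3", "G5"])
        expected = np.exp(np.log(ne.rq.loc[["G1", "G3", "G5"]]).mean(axis=0))
        np.testing.assert_allclose(ne.nf.to_numpy(), expected, atol=1e-12)

    def test_sample_with_undetermined_reference_dropped(self):
        vals = [[24.0, np.nan, 25.0], [28.0, 29.0, 28.5]]
        ne = normalize(make_ct_table(vals), ["G1"])
        assert "S2" in ne.dropped_samples
        assert list(ne.nrq.columns) == ["S1", "S3"]


def bh_oracle(pvals):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank from smallest
        val = min(prev, pvals[idx] * m / i)
        adj[idx] = val
        prev = val
    return adj


def wilcoxon_enumeration_p(x, y):
    """Exact two-sided rank-sum p by full enumeration of labelings."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n = len(x)
    obs = ranks[:n].sum()
    stats_all = [sum(ranks[list(c)])
                 for c in itertools.combinations(range(len(pooled)), n)]
    stats_all = np.array(stats_all)
    p_le = np.mean(stats_all <= obs)
    p_ge = np.mean(stats_all >= obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestStatisticalMachinery:
    def test_bh_matches_enumeration_oracle(self):
        pvals = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205])
        from statsmodels.stats.multitest import multipletests
        q = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh_oracle(pvals), atol=1e-12)

    def test_exact_wilcoxon_matches_full_enumeration_5v5(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, 5)
            y = rng.normal(0.8, 1, 5)
            assert _wilcoxon_p(x, y) == pytest.approx(
                wilcoxon_enumeration_p(x, y), abs=1e-12)

    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=4, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_outlier_modes_are_nested(self, values):
        vals = np.asarray(values)
        none = set(_remove_outliers(vals, "none"))
        tukey = set(_remove_outliers(vals, "tukey"))
        literal = set(_remove_outliers(vals, "literal_quartile"))
        assert literal <= tukey <= none


class TestSexBiasTest:
    def _run(self, log2_fc, noise_sd=0.25, n_per_sex=7, seed=0, extra_null=True):
        genes = [GeneSpec(f"REF{i}", 24.0 + i, 0.0, 0.15, 2.0) for i in range(3)]
        genes += [GeneSpec("TARGET", 27.0, 0.0, noise_sd, 2.0)]
        if extra_null:
            genes += [GeneSpec("NULL", 28.0, 0.0, noise_sd, 2.0)]
        cfg = CtSimConfig(genes=genes, n_per_sex=n_per_sex, seed=seed)
        ct, _ = simulate_targets(cfg, {"TARGET": log2_fc})
        ne = normalize(ct, ["REF0", "REF1", "REF2"])
        return sex_bias_test(ne, ct.sample_sex())

    def test_no_effect_gives_unbiased_call(self):
        res = self._run(0.0, seed=5)
        assert res.loc["TARGET", "call"] == "unbiased"
        assert abs(res.loc["TARGET", "log2_fc"]) < 1.0

    def test_planted_male_bias_detected(self):
        res = self._run(1.0, seed=5)
        assert res.loc["TARGET", "call"] == "male_biased"
        assert res.loc["TARGET", "log2_fc"] == pytest.approx(1.0, abs=0.5)

    def test_planted_female_bias_detected(self):
        res = self._run(-1.5, seed=5)
        assert res.loc["TARGET", "call"] == "female_biased"

    def test_not_expressed_gene_reported(self):
        genes = [GeneSpec("REF0", 24.0, 0.0, 0.1, 2.0),
                 GeneSpec("DEAD", 44.0, 0.0, 0.1, 2.0)]
        ct, _ = simulate_ct(CtSimConfig(genes=genes, n_per_sex=4, seed=1,
                                        sample_loading_sd=0.1))
        ne = normalize(ct, ["REF0"])
        res = sex_bias_test(ne, ct.sample_sex(), min_per_sex=3)
        assert res.loc["DEAD", "call"] == "not_expressed"

    def test_untestable_when_too_few_samples(self):
        vals = [[24.0, 24.1, 24.2, 24.3], [27.0, 27.1, 27.3, 27.2]]
        ct = make_ct_table(vals)
        ne = normalize(ct, ["G1"])
        res = sex_bias_test(ne, ct.sample_sex(), min_per_sex=3)
        assert res.loc["G2", "call"] == "untestable"

    def test_fold_change_threshold_blocks_small_effects(self):
        # significant but tiny fold change must stay unbiased
        rng = np.random.default_rng(0)
        nrq = np.exp2(np.concatenate([np.full(7, 0.2), np.zeros(7)])
                      + rng.normal(0, 1e-3, 14))
        from refstab.datamodel import NormalizedExpression
        samples = [f"M{i}" for i in range(7)] + [f"F{i}" for i in range(7)]
        frame = pd.DataFrame([nrq], index=["G"], columns=samples)
        ne = NormalizedExpression(rq=frame, nf=pd.Series(1.0, index=samples),
                                  nrq=frame, reference_set=[])
        sex = pd.Series(["male"] * 7 + ["female"] * 7, index=samples)
        res = sex_bias_test(ne, sex, genes=["G"])
        assert res.loc["G", "p_wilcoxon"] < 0.01
        assert res.loc["G", "call"] == "unbiased"
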