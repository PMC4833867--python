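"""Array preprocessing, fold changes, enrichment, Venn selection, correlation."""

import numpy as np
import pandas as pd
import pytest

from pbodyquant.expression import (
    PercentileNormalizer,
    SelectionCriteria,
    SignalMatrix,
    association_expression_correlation,
    fold_change,
    ip_enrichment_with_pvalues,
    preprocess_signals,
    rip_enrichment,
    select_candidate_targets,
    venn_overlap,
)
from pbodyquant.synthdata import StudyConfig, generate_expression_study


def raw_matrix(values, columns=None):
    arr = np.asarray(values, float)
    columns = columns or [f"s{i}" for i in range(arr.shape[1])]
    frame = pd.DataFrame(arr, columns=columns,
                         index=[f"P{i:03d}" for i in range(arr.shape[0])])
    return SignalMatrix(frame)


class TestPreprocess:
    def test_values_below_one_floored(self):
        m = raw_matrix([[0.3, 2.0], [5.0, 8.0], [10.0, 20.0], [40.0, 80.0]])
        out = preprocess_signals(m)
        # the floored value 1 scales with its column; it can never be below
        # log2(scale/percentile) of the floor
        norm = PercentileNormalizer(log2=False).fit(m.data)
        scaled = norm.transform(m.data)
        assert scaled.iloc[0, 0] == pytest.approx(
            1.0 * norm.target_ / np.percentile(np.maximum(m.data["s0"], 1.0), 75)
        )
        assert out.state == "log2"

    def test_percentiles_equal_after_normalization(self):
        rng = np.random.default_rng(0)
        m = raw_matrix(rng.lognormal(5, 1, (200, 4)))
        out = preprocess_signals(m)
        p75 = np.percentile(2.0 ** out.data, 75, axis=0)
        assert np.allclose(p75, p75[0], rtol=1e-9)

    def test_scalar_multiple_columns_identical_after_normalization(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(5, 1, 100)
        m = raw_matrix(np.column_stack([base, 3.7 * base]))
        out = preprocess_signals(m)
        assert np.allclose(out.data["s0"], out.data["s1"], atol=1e-9)

    def test_all_zero_sample_rejected(self):
        m = raw_matrix([[0.0, 1.0], [0.0, 2.0]])
        with pytest.raises(ValueError, match="all-zero"):
            preprocess_signals(m)

    def test_non_raw_state_rejected(self):
        m = raw_matrix([[1.0, 2.0], [3.0, 4.0]])
        out = preprocess_signals(m)
        with pytest.raises(ValueError):
            preprocess_signals(out)


class TestFoldChange:
    def make_log2(self):
        rng = np.random.default_rng(2)
        m = raw_matrix(rng.lognormal(5, 1, (50, 4)),
                       columns=["a_1", "a_2", "b_1", "b_2"])
        return preprocess_signals(m)

    def test_identical_groups_zero(self):
        m = self.make_log2()
        fc = fold_change(m, ["a_1", "a_2"], ["a_1", "a_2"])
        assert np.allclose(fc, 0.0)

    def test_antisymmetry(self):
        m = self.make_log2()
        ab = fold_change(m, "a", "b")
        ba = fold_change(m, "b", "a")
        assert np.allclose(ab, -ba)

    def test_noiseless_planted_fold(self):
        study = generate_expression_study(
            StudyConfig(n_probes=300, n_planted_targets=4, noise_sd=0.0,
                        fold_down_xx=3.0, seed=3)
        )
        ds = study.datasets["induced_xx"]
        m = preprocess_signals(SignalMatrix(ds.matrix))
        fc = fold_change(m, ds.group_a, ds.group_b)
        # per-column percentile scaling can shift the fold change by a few
        # hundredths when planted probes move the column's 75th percentile
        for probe in study.planted:
            assert fc[probe] == pytest.approx(-np.log2(3.0), abs=0.03)

    def test_unknown_sample_rejected(self):
        m = self.make_log2()
        with pytest.raises(KeyError):
            fold_change(m, ["a_1", "nope"], ["b_1"])


class TestRipEnrichment:
    def test_reference_like_gene_ratio_one(self):
        ip = pd.Series({"gapdh": 10.0, "dazl": 10.0})
        inp = pd.Series({"gapdh": 5.0, "dazl": 5.0})
        tab = rip_enrichment(ip, inp, "gapdh")
        assert tab.loc["dazl", "normalized_ratio"] == pytest.approx(1.0)
        assert tab.loc["gapdh", "normalized_ratio"] == pytest.approx(1.0)

    def test_hand_computed_ratio(self):
        ip = pd.Series({"gapdh": 8.0, "dazl": 16.0})
        inp = pd.Series({"gapdh": 4.0, "dazl": 2.0})
        tab = rip_enrichment(ip, inp, "gapdh")
        # (16/2) / (8/4) = 8 / 2 = 4
        assert tab.loc["dazl", "normalized_ratio"] == pytest.approx(4.0)

    def test_invariant_to_global_ip_rescale(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(10)] + ["gapdh"]
        ip = pd.Series(rng.uniform(1, 100, 11), index=genes)
        inp = pd.Series(rng.uniform(1, 100, 11), index=genes)
        a = rip_enrichment(ip, inp, "gapdh")["normalized_ratio"]
        b = rip_enrichment(ip * 13.0, inp, "gapdh")["normalized_ratio"]
        assert np.allclose(a, b)

    def test_missing_reference_rejected(self):
        ip = pd.Series({"dazl": 1.0})
        with pytest.raises(KeyError):
            rip_enrichment(ip, ip, "gapdh")


class TestSelection:
    def run_study(self, noise_sd=0.0, seed=5, **crit_kwargs):
        study = generate_expression_study(
            StudyConfig(n_probes=1000, n_planted_targets=12, noise_sd=noise_sd, seed=seed)
        )
        fcs = {}
        for name in ("induced_xx", "knockout_xy"):
            ds = study.datasets[name]
            m = preprocess_signals(SignalMatrix(ds.matrix))
            fcs[name] = fold_change(m, ds.group_a, ds.group_b)
        rip_ds = study.datasets["nanos2_rip"]
        m = preprocess_signals(SignalMatrix(rip_ds.matrix))
        rip = ip_enrichment_with_pvalues(m.data[rip_ds.group_a], m.data[rip_ds.group_b])
        crit = SelectionCriteria(**crit_kwargs)
        sel = select_candidate_targets(fcs["induced_xx"], fcs["knockout_xy"], rip, crit)
        return study, sel

    def test_noiseless_recovery_is_exact(self):
        study, sel = self.run_study(noise_sd=0.0)
        assert sel.selected == study.planted
        assert sel.venn["ABC"] == len(study.planted)

    def test_membership_is_and_of_flags(self):
        _, sel = self.run_study(noise_sd=0.3)
        f = sel.flags
        assert (f["selected"] == (f["down_xx"] & f["up_ko"] & f["ip_enriched"])).all()

    def test_venn_regions_partition_union(self):
        _, sel = self.run_study(noise_sd=0.3)
        f = sel.flags
        union = (f[["down_xx", "up_ko", "ip_enriched"]].any(axis=1)).sum()
        assert sum(sel.venn.values()) == union

    def test_selection_monotone_in_thresholds(self):
        _, tight = self.run_study(noise_sd=0.3, down_fold_xx=2.0, up_fold_ko=3.0,
                                  ip_enrich_fold=6.0, ip_p_threshold=0.01)
        _, loose = self.run_study(noise_sd=0.3)
        assert tight.selected <= loose.selected

    def test_mismatched_universe_rejected(self):
        study, _ = self.run_study()
        rng = np.random.default_rng(0)
        down = pd.Series(rng.normal(size=5), index=[f"P{i:05d}" for i in range(5)])
        up = pd.Series(rng.normal(size=4), index=[f"P{i:05d}" for i in range(4)])
        rip = pd.DataFrame({"log2_enrichment": down, "pvalue": 0.5})
        with pytest.raises(ValueError, match="universe"):
            select_candidate_targets(down, up, rip)

    def test_empty_universe_empty_selection(self):
        empty = pd.Series(dtype=float)
        rip = pd.DataFrame({"log2_enrichment": empty, "pvalue": empty})
        sel = select_candidate_targets(empty, empty, rip)
        assert sel.selected == set()
        assert all(v == 0 for v in sel.venn.values())


class TestVennOverlap:
    def test_printed_overlap_percentage(self):
        a = {f"n{i}" for i in range(1256)}
        b = {f"n{i}" for i in range(274)} | {f"d{i}" for i in range(500)}
        ov = venn_overlap(a, b)
        assert (ov.size_a, ov.intersection) == (1256, 274)
        assert ov.percent_of_a == 21.8

    def test_identical_sets_100_percent(self):
        ov = venn_overlap({1, 2, 3}, {1, 2, 3})
        assert ov.percent_of_a == 100.0

    def test_disjoint_sets_zero_percent(self):
        assert venn_overlap({1, 2}, {3}).percent_of_a == 0.0

    def test_empty_a_flagged(self):
        assert venn_overlap(set(), {1}).percent_of_a is None


class TestAssociationCorrelation:
    def test_exact_linear_relation(self):
        x = pd.Series(np.arange(10.0), index=[f"p{i}" for i in range(10)])
        r, p, scatter = association_expression_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)
        assert len(scatter) == 10

    def test_negative_relation(self):
        x = pd.Series(np.arange(10.0), index=[f"p{i}" for i in range(10)])
        r, _, _ = association_expression_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_planted_bivariate_correlation_recovered(self):
        # 274 probes with true correlation 0.5
        rng = np.random.default_rng(12)
        n, rho = 274, 0.5
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
        idx = [f"p{i}" for i in range(n)]
        r, p, _ = association_expression_correlation(
            pd.Series(x, index=idx), pd.Series(y, index=idx)
        )
        assert r == pytest.approx(rho, abs=0.1)
        assert p < 1e-6

    def test_constant_vector_rejected(self):
        x = pd.Series(np.ones(5), index=list("abcde"))
        with pytest.raises(ValueError):
            association_expression_correlation(x, x)
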