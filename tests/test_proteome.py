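"""Enrichment screen: normalization, ratios, background test, classification."""

import numpy as np
import pandas as pd
import pytest

import synaptoscope as ss
from synaptoscope.proteome import (ScreenParams, background_test, bh_adjust,
                                   classify, ms_if_correlation, protein_ratio,
                                   screen, total_normalize)


def _long_table(rows):
    return pd.DataFrame(rows, columns=["protein_id", "peptide_id",
                                       "unique_flag", "sample", "intensity"])


class TestTotalNormalize:
    def _table(self, rng):
        rows = []
        for p in range(10):
            for s in ["SYN_1", "SYN_2", "SYN_3", "FASS_1", "FASS_2", "FASS_3"]:
                rows.append((f"P{p}", f"P{p}_pep1", True, s,
                             float(rng.uniform(10, 100))))
        return _long_table(rows)

    def test_equal_totals_unchanged(self):
        rows = [(f"P{p}", f"P{p}_pep1", True, s, 10.0)
                for p in range(5)
                for s in ["SYN_1", "SYN_2", "FASS_1", "FASS_2"]]
        t = _long_table(rows)
        out = total_normalize(t)
        np.testing.assert_allclose(out["intensity"], t["intensity"])

    def test_doubled_sample_scaled_back(self):
        rows = [("P0", "pep1", True, "SYN_1", 10.0),
                ("P0", "pep1", True, "FASS_1", 20.0)]
        out = total_normalize(_long_table(rows))
        totals = out.groupby("sample")["intensity"].sum()
        assert totals["SYN_1"] == pytest.approx(totals["FASS_1"])

    def test_all_totals_equal_after(self, rng):
        out = total_normalize(self._table(rng))
        totals = out.groupby("sample")["intensity"].sum()
        np.testing.assert_allclose(totals, totals.mean(), rtol=1e-9)

    def test_zero_total_sample_rejected(self):
        rows = [("P0", "pep1", True, "SYN_1", 0.0),
                ("P0", "pep1", True, "FASS_1", 5.0)]
        with pytest.raises(ValueError, match="non-positive total"):
            total_normalize(_long_table(rows))


class TestProteinRatio:
    def test_single_peptide_constant_fold(self):
        syn = np.array([[3.0, 3.0, 3.0]])
        fass = np.array([[6.0, 6.0, 6.0]])
        ratio, n = protein_ratio(syn, fass)
        assert ratio == 2.0 and n == 1

    def test_even_count_median_is_midpoint(self):
        # two peptides whose 9 pairwise ratios are all 1 and all 3
        syn = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        fass = np.array([[1.0, 1.0, 1.0], [3.0, 3.0, 3.0]])
        ratio, n = protein_ratio(syn, fass)
        assert ratio == 2.0 and n == 2

    def test_missing_values_skipped_pairwise(self):
        syn = np.array([[np.nan, 2.0, 0.0]])
        fass = np.array([[4.0, np.nan, 4.0]])
        ratio, n = protein_ratio(syn, fass)
        assert ratio == 2.0 and n == 1

    def test_no_valid_pair_raises(self):
        with pytest.raises(ValueError):
            protein_ratio(np.array([[np.nan]]), np.array([[1.0]]))

    def test_invariances(self, rng):
        syn = rng.uniform(1, 10, (3, 3))
        fass = rng.uniform(1, 10, (3, 3))
        r0, _ = protein_ratio(syn, fass)
        perm = rng.permutation(3)
        r1, _ = protein_ratio(syn[perm], fass[perm])  # peptide relabelling
        r2, _ = protein_ratio(7.0 * syn, 7.0 * fass)  # common scaling
        assert r0 == pytest.approx(r1) == pytest.approx(r2)


class TestBackgroundTest:
    def test_all_equal_ratios_give_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            p, info = background_test(np.zeros(30))
        assert np.all(p == 1.0)
        assert info["scale"] == 0.0

    def test_planted_outliers_detected_with_calibrated_background(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            lr = np.concatenate([rng.normal(0.0, 0.1, 950),
                                 rng.normal(2.5, 0.1, 50)])
            p, _ = background_test(lr)
            assert np.all(p[950:] < 1e-6)
            type1 = (p[:950] < 0.05).mean()
            assert type1 <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 950)

    def test_location_shift_invariance(self, rng):
        lr = rng.normal(0.0, 0.2, 200)
        p0, _ = background_test(lr)
        p1, _ = background_test(lr + 5.0)
        np.testing.assert_allclose(p0, p1, rtol=1e-9)

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            background_test(np.zeros(5))


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_adjusted_dominates_raw_and_is_monotone(self, rng):
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestClassify:
    @pytest.mark.parametrize("ratio,adj_p,n_pep,expected", [
        (1.6, 0.01, 3, "enriched"),
        (1.6, 0.2, 3, "retained"),
        (5.0, 1e-9, 1, "under_quantified"),
        (0.5, 0.01, 2, "depleted"),
        (1.5, 0.001, 4, "retained"),  # strict: ratio must exceed the cutoff
    ])
    def test_rules(self, ratio, adj_p, n_pep, expected):
        assert classify(ratio, adj_p, n_pep) == expected

    def test_param_validation(self):
        with pytest.raises(ValueError):
            ScreenParams(fold_up=0.9)
        with pytest.raises(ValueError):
            ScreenParams(alpha=1.5)


class TestScreen:
    def test_recall_and_fdr_on_planted_table(self):
        spec = ss.PeptideSpec(n_proteins=600, frac_enriched=0.05,
                              fold_effect=3.0, replicate_cv=0.2, seed=21)
        table, truth = ss.make_peptide_table(spec)
        res = screen(table).join(truth)
        quantified_planted = res[(res.true_class == "enriched")
                                 & (res.n_unique_peptides >= 2)]
        recall = (quantified_planted.klass == "enriched").mean()
        called = res[res.klass == "enriched"]
        fdr = ((called.true_class != "enriched").mean()
               if len(called) else 0.0)
        assert recall >= 0.9
        assert fdr <= 0.1

    def test_noiseless_fold_recovered_via_scale_invariance(self):
        # total normalization shifts every ratio by one constant, so the
        # enriched-to-background ratio of ratios recovers the planted fold
        spec = ss.PeptideSpec(n_proteins=40, frac_enriched=0.1,
                              fold_effect=2.0, replicate_cv=0.0, seed=22)
        table, truth = ss.make_peptide_table(spec)
        res = screen(table).join(truth)
        bg_ratio = res.loc[res.true_class == "background", "ratio"].median()
        for r in res.loc[res.true_class == "enriched", "ratio"]:
            assert r / bg_ratio == pytest.approx(2.0, abs=1e-9)

    def test_global_null_false_classification_rate(self):
        rates = []
        for seed in range(10):
            spec = ss.PeptideSpec(n_proteins=300, frac_enriched=0.0,
                                  replicate_cv=0.2, seed=seed)
            table, _ = ss.make_peptide_table(spec)
            res = screen(table)
            q = res[res.n_unique_peptides >= 2]
            rates.append((q.klass != "retained").mean())
        n_total = 10 * 300
        assert np.mean(rates) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_total)

    def test_under_quantified_never_called(self):
        spec = ss.PeptideSpec(n_proteins=200, frac_enriched=0.2,
                              peptides_per_protein=(1, 2), fold_effect=4.0,
                              seed=23)
        table, _ = ss.make_peptide_table(spec)
        res = screen(table)
        single = res[res.n_unique_peptides < 2]
        assert (single.klass == "under_quantified").all()

    def test_method_tag_recorded(self):
        spec = ss.PeptideSpec(n_proteins=50, seed=24)
        table, _ = ss.make_peptide_table(spec)
        res = screen(table)
        assert "non-vendor" in res.attrs["background"]["method"]


class TestMsIfCorrelation:
    def test_proportional_vectors(self):
        out = ms_if_correlation([1, 2, 3, 4.0], [2, 4, 6, 8.0])
        assert out["r_squared"] == pytest.approx(1.0)

    def test_anti_proportional_vectors(self):
        out = ms_if_correlation([1, 2, 3.0], [3, 2, 1.0])
        assert out["r"] == pytest.approx(-1.0)

    def test_printed_marker_panel(self):
        # six validated markers: MS fold changes vs IF enrichment ratios
        # (FASS% / SYN% of marker-positive events)
        ms = [1.72, 1.57, 1.62, 1.28, 3.36, 1.93]
        iff = [8.5 / 8, 8.4 / 3.6, 20.5 / 13, 71.8 / 28.7, 33.3 / 7.2,
               10.3 / 3.22]
        out = ms_if_correlation(ms, iff)
        assert out["r_squared"] == pytest.approx(0.6275, abs=0.005)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            ms_if_correlation([1.0, 1.0, 1.0], [1, 2, 3.0])
        with pytest.raises(ValueError):
            ms_if_correlation([1.0, 2.0], [1.0, 2.0])
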