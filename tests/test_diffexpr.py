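"""Differential-expression models, probe collapse, q-values and the dual
DEG filter, checked against closed-form/statsmodels oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nbx
from nbx.datasets import ExpressionDataset
from nbx.diffexpr import (
    collapse_probes,
    compute_qvalues,
    estimate_pi0,
    fit_hypoxia_model,
    fit_survivor_model,
    ingest_external_deg_table,
    select_degs,
)


def _cohort_dataset(Y, status, mycn, ids=None):
    n = len(status)
    samples = [f"S{i}" for i in range(n)]
    ann = pd.DataFrame(
        {"os_event": status, "mycn": mycn, "os_time": np.ones(n)},
        index=samples,
    )
    matrix = pd.DataFrame(
        np.atleast_2d(Y),
        index=ids or [f"F{i}" for i in range(np.atleast_2d(Y).shape[0])],
        columns=samples,
    )
    return ExpressionDataset(matrix, ann)


class TestSurvivorModel:
    def test_matches_statsmodels_ols(self):
        """The vectorized fit equals a per-feature statsmodels OLS."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 80
        status = (rng.random(n) < 0.4).astype(float)
        mycn = (rng.random(n) < 0.3).astype(float)
        Y = rng.normal(size=(5, n)) + 0.8 * status
        data = _cohort_dataset(Y, status, mycn)
        fits = fit_survivor_model(data)
        X = sm.add_constant(np.column_stack([status, mycn]))
        for i in range(5):
            ref = sm.OLS(Y[i], X).fit()
            assert fits["log2fc"].iloc[i] == pytest.approx(ref.params[1], rel=1e-9)
            assert fits["p"].iloc[i] == pytest.approx(ref.pvalues[1], rel=1e-6)

    def test_recovers_planted_status_effect(self):
        rng = np.random.default_rng(2)
        status = np.repeat([0.0, 1.0], 50)
        mycn = rng.permutation(np.repeat([0.0, 1.0], 50))
        y = 1.0 * status + rng.normal(0, 0.1, 100)
        fits = fit_survivor_model(_cohort_dataset(y, status, mycn))
        assert fits["log2fc"].iloc[0] == pytest.approx(1.0, abs=0.1)

    def test_mycn_adjustment_removes_confounded_signal(self):
        """A gene driven only by MYCN shows no status effect once MYCN is in
        the model, even when MYCN and status are correlated."""
        rng = np.random.default_rng(3)
        n = 400
        status = (rng.random(n) < 0.5).astype(float)
        # MYCN correlated ~0.5 with status
        mycn = np.where(rng.random(n) < 0.5, status, (rng.random(n) < 0.5))
        y = 2.0 * mycn + rng.normal(0, 0.3, n)
        fits = fit_survivor_model(_cohort_dataset(y, status, mycn.astype(float)))
        assert abs(fits["log2fc"].iloc[0]) < 3 * fits["se"].iloc[0]

    def test_constant_feature_flagged_with_p_one(self):
        status = np.repeat([0.0, 1.0], 5)
        data = _cohort_dataset(np.full(10, 3.0), status, np.zeros(10))
        fits = fit_survivor_model(data)
        assert fits["log2fc"].iloc[0] == 0.0
        assert fits["p"].iloc[0] == 1.0
        assert fits["flag"].iloc[0] == "zero_variance"

    def test_single_sample_level_rejected(self):
        status = np.array([1.0] + [0.0] * 9)
        with pytest.raises(ValueError, match="os_event"):
            fit_survivor_model(
                _cohort_dataset(np.random.default_rng(0).normal(size=10),
                                status, np.zeros(10))
            )

    def test_status_confounded_with_mycn_flagged_not_crashed(self):
        status = np.repeat([0.0, 1.0], 10)
        fits = fit_survivor_model(
            _cohort_dataset(np.random.default_rng(0).normal(size=20),
                            status, status.copy())
        )
        assert (fits["flag"] == "singular_design").all()


class TestHypoxiaModel:
    def test_single_line_equals_two_group_ols(self):
        ds, _ = nbx.simulate_cellline_experiment(
            nbx.CellLineSimConfig(n_lines=1, n_replicates_per_condition=4,
                                  line_sd=0.0, n_genes=6,
                                  n_hypoxia_responsive=2, seed=7)
        )
        fits = fit_hypoxia_model(ds)
        hyp = (ds.sample_annotations["condition"] == "hypoxia").to_numpy()
        for g in ds.matrix.index:
            x = ds.matrix.loc[g].to_numpy()
            assert fits.loc[g, "log2fc"] == pytest.approx(
                x[hyp].mean() - x[~hyp].mean(), rel=1e-9
            )
        assert (fits["flag"] == "single_line_ols").all()

    def test_mixed_model_matches_per_line_paired_oracle(self, small_cellline):
        """With a balanced design the hypoxia coefficient equals the mean of
        per-line (hypoxia - normoxia) differences."""
        ds, truth = small_cellline
        fits = fit_hypoxia_model(ds)
        ann = ds.sample_annotations
        for g in truth["hypoxia_genes"][:5]:
            x = ds.matrix.loc[g]
            per_line = []
            for line, sub in ann.groupby("line"):
                vals = x[sub.index]
                per_line.append(
                    vals[sub["condition"] == "hypoxia"].mean()
                    - vals[sub["condition"] == "normoxia"].mean()
                )
            assert fits.loc[g, "log2fc"] == pytest.approx(
                np.mean(per_line), abs=0.02
            )

    def test_all_one_condition_rejected(self, small_cellline):
        ds, _ = small_cellline
        normoxic = ds.sample_annotations[
            ds.sample_annotations["condition"] == "normoxia"
        ].index
        with pytest.raises(ValueError, match="condition"):
            fit_hypoxia_model(ds.subset_samples(normoxic))


class TestCollapseProbes:
    @staticmethod
    def _table(rows):
        df = pd.DataFrame(rows, columns=["probe", "log2fc", "p"]).set_index("probe")
        df["se"] = 0.1
        df["flag"] = ""
        return df

    def test_one_probe_per_gene_is_identity(self):
        table = self._table([("pA", 1.0, 0.01), ("pB", -0.5, 0.2)])
        fmap = pd.Series({"pA": "GA", "pB": "GB"})
        out = collapse_probes(table, fmap)
        assert list(out.index) == ["GA", "GB"]
        assert out.loc["GA", "log2fc"] == 1.0
        assert out.loc["GA", "source_probe"] == "pA"

    def test_most_significant_probe_retained(self):
        table = self._table([("p1", 1.0, 0.01), ("p2", -2.0, 0.001)])
        out = collapse_probes(table, pd.Series({"p1": "G", "p2": "G"}))
        assert out.loc["G", "p"] == 0.001
        assert out.loc["G", "log2fc"] == -2.0

    def test_tie_breaks_deterministic(self):
        # equal p: larger |fc| wins; equal p and |fc|: lexicographic probe
        table = self._table([("pz", 1.0, 0.01), ("pa", 1.0, 0.01)])
        out = collapse_probes(table, pd.Series({"pz": "G", "pa": "G"}))
        assert out.loc["G", "source_probe"] == "pa"
        table2 = self._table([("pa", 1.0, 0.01), ("pb", -3.0, 0.01)])
        out2 = collapse_probes(table2, pd.Series({"pa": "G", "pb": "G"}))
        assert out2.loc["G", "source_probe"] == "pb"

    def test_unmapped_probes_dropped(self):
        table = self._table([("p1", 1.0, 0.01), ("orphan", 2.0, 0.001)])
        out = collapse_probes(table, pd.Series({"p1": "G"}))
        assert list(out.index) == ["G"]

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            collapse_probes(self._table([("p1", 1.0, 0.01)]), pd.Series(dtype=object))


class TestQValues:
    def test_all_ones_stay_one(self):
        assert (compute_qvalues([1.0] * 7, pi0=1.0) == 1.0).all()

    def test_fixed_example_equals_bh(self):
        q = compute_qvalues([0.001, 0.01, 0.02, 0.8, 0.9], pi0=1.0)
        np.testing.assert_allclose(q, [0.005, 0.025, 1 / 30, 0.9, 0.9])

    @pytest.mark.parametrize("seed", range(5))
    def test_pi0_one_equals_statsmodels_bh(self, seed):
        from statsmodels.stats.multitest import multipletests

        p = np.random.default_rng(seed).random(200)
        q = compute_qvalues(p, pi0=1.0)
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, bh, atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_q_monotone_in_p_and_at_least_p(self, pvals):
        p = np.array(pvals)
        q = compute_qvalues(p, pi0=1.0)
        assert ((q >= p - 1e-12) & (q <= 1.0)).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_pi0_estimate_near_one_under_null(self):
        p = np.random.default_rng(4).random(2000)
        assert estimate_pi0(p) > 0.8

    def test_small_input_falls_back_to_pi0_one(self):
        p = [0.2, 0.5, 0.9]
        np.testing.assert_allclose(
            compute_qvalues(p), compute_qvalues(p, pi0=1.0)
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_qvalues([0.5, 1.5])

    def test_empty_gives_empty(self):
        assert compute_qvalues([]).size == 0


class TestSelectDEGs:
    @staticmethod
    def _hundred_gene_table(seed=9):
        rng = np.random.default_rng(seed)
        genes = [f"G{i:03d}" for i in range(100)]
        q = np.concatenate([rng.uniform(0, 0.009, 20), rng.uniform(0.02, 1, 80)])
        fc = rng.normal(0, 1, 100)
        return pd.DataFrame({"log2fc": fc, "p": q / 2, "q": q}, index=genes)

    def test_brute_force_double_filter(self):
        table = self._hundred_gene_table()
        out = select_degs(table, fdr_max=0.01, fc_decile=0.10)
        fc = table["log2fc"].to_numpy()
        hi, lo = np.quantile(fc, 0.9), np.quantile(fc, 0.1)
        expected = {
            g
            for g, row in table.iterrows()
            if row["q"] < 0.01 and (row["log2fc"] >= hi or row["log2fc"] <= lo)
        }
        assert set(out.records["gene"]) == expected
        assert out.universe_size == 100

    def test_row_order_invariant(self):
        table = self._hundred_gene_table()
        shuffled = table.sample(frac=1, random_state=0)
        a = select_degs(table).records.sort_values("gene").reset_index(drop=True)
        b = select_degs(shuffled).records.sort_values("gene").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_no_significant_genes_gives_empty_set(self):
        table = self._hundred_gene_table()
        table["q"] = np.clip(table["q"], 0.02, 1.0)
        assert len(select_degs(table).records) == 0

    def test_direction_follows_sign(self):
        table = self._hundred_gene_table()
        out = select_degs(table)
        for _, row in out.records.iterrows():
            assert row["direction"] == ("down" if row["log2fc"] < 0 else "up")

    def test_significant_scope_changes_thresholds(self):
        table = self._hundred_gene_table()
        uni = select_degs(table, fc_decile_scope="universe")
        sig = select_degs(table, fc_decile_scope="significant")
        # deciles over 20 significant genes keep fewer than all 20 but are
        # computed over a narrower distribution
        assert set(sig.records["gene"]) <= set(table.index[table["q"] < 0.01])
        assert len(sig.records) != len(uni.records) or set(
            sig.records["gene"]
        ) == set(uni.records["gene"])

    def test_bad_decile_rejected(self):
        with pytest.raises(ValueError):
            select_degs(self._hundred_gene_table(), fc_decile=0.6)


class TestIngestExternal:
    def test_roundtrip_write_read(self, tmp_path):
        table = select_degs(TestSelectDEGs._hundred_gene_table())
        path = tmp_path / "deg.tsv"
        table.write(path)
        back = nbx.DEGTable.read(path)
        assert back.universe_size == table.universe_size
        assert back.dataset_id == table.dataset_id
        pd.testing.assert_frame_equal(
            back.records[["gene", "log2fc", "p", "q", "direction"]],
            table.records[["gene", "log2fc", "p", "q", "direction"]],
        )

    def test_q_column_used_verbatim(self, tmp_path):
        path = tmp_path / "ext.tsv"
        pd.DataFrame(
            {"gene": ["A", "B"], "log2fc": [3.0, -3.0], "p": [0.5, 0.5],
             "q": [0.0001, 0.5]}
        ).to_csv(path, sep="\t", index=False)
        out = ingest_external_deg_table(path)
        rec = out.records.set_index("gene")
        assert list(rec.index) == ["A"]
        assert rec.loc["A", "q"] == 0.0001

    def test_q_computed_from_p_when_absent(self, tmp_path):
        path = tmp_path / "ext.tsv"
        pd.DataFrame(
            {"gene": ["A", "B", "C"], "log2fc": [1, 2, 3],
             "p": [0.001, 0.5, 1.0]}
        ).to_csv(path, sep="\t", index=False)
        out = ingest_external_deg_table(path, fdr_max=0.5, fc_decile=0.4)
        expected_q = compute_qvalues([0.001, 0.5, 1.0])
        rec = out.records.set_index("gene")
        assert rec.loc["A", "q"] == pytest.approx(expected_q[0])

    def test_missing_columns_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"gene": ["A"], "stat": [1.0]}).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(ValueError, match="log2fc"):
            ingest_external_deg_table(path)
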