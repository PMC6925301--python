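"""Filtering stages: missing values, outlier tests, reproducibility, VIF."""

import numpy as np
import pandas as pd
import pytest

from phenoselect import (
    DataError,
    PreprocessConfig,
    TraitTable,
    bonferroni_outliers,
    drop_empty_values,
    grubbs_outliers,
    preprocess_pipeline,
    reproducibility_filter,
    vif_stepwise,
)
from phenoselect.errors import (
    DegenerateInputError,
    DimensionalityError,
    InsufficientDataError,
)
from phenoselect.preprocess import (
    compute_vifs,
    grubbs_critical_value,
    remove_outliers,
    studentized_residuals_and_bonferroni,
)

from tests._oracles import (
    bonferroni_adjusted_pvalues,
    grubbs_decision,
    vif_direct,
)


def _table(values, trait_names=None, labels=None, metadata=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return TraitTable(
        values=values,
        trait_names=trait_names or [f"t{j + 1}" for j in range(p)],
        sample_ids=[f"s{i + 1}" for i in range(n)],
        labels=labels if labels is not None else np.zeros(n, dtype=int),
        metadata=metadata,
    )


class TestDropEmptyValues:
    def test_clean_table_unchanged(self):
        t = _table([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        out, trace = drop_empty_values(t, policy="drop_sample")
        assert np.array_equal(out.values, t.values)
        assert trace.removed_samples == [] and trace.removed_traits == []

    def test_all_zero_trait_dropped(self):
        t = _table([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        out, trace = drop_empty_values(t, policy="drop_trait", cutoff=0.5)
        assert out.trait_names == ["t1"]
        assert trace.removed_traits == ["t2"]

    def test_single_zero_drops_one_sample(self):
        t = _table([[1.0, 2.0], [0.0, 3.0], [4.0, 5.0]])
        out, _ = drop_empty_values(t, policy="drop_sample")
        assert out.n_samples == 2
        assert out.sample_ids == ["s1", "s3"]

    def test_exempt_trait_keeps_genuine_zeros(self):
        t = _table([[1.0, 0.0], [2.0, 0.0], [3.0, 1.0]])
        out, _ = drop_empty_values(t, policy="drop_sample", exempt_traits=("t2",))
        assert out.n_samples == 3

    def test_mask_policy_recodes_to_nan(self):
        t = _table([[1.0, 0.0], [2.0, 3.0], [4.0, 5.0]])
        out, trace = drop_empty_values(t, policy="mask")
        assert np.isnan(out.values[0, 1])
        assert trace.flagged_cells == [("s1", "t2")]

    def test_idempotent(self):
        t = _table([[1.0, 0.0], [0.0, 3.0], [4.0, 5.0]])
        once, _ = drop_empty_values(t, policy="drop_sample")
        twice, trace = drop_empty_values(once, policy="drop_sample")
        assert np.array_equal(once.values, twice.values)
        assert trace.removed_samples == []


class TestGrubbs:
    def test_textbook_example(self):
        # {1,2,3,100}: G = 73.5 / 49.0077 ~ 1.4998 exceeds G_crit(4, .05)
        report = grubbs_outliers([1, 2, 3, 100], alpha=0.05)
        assert [f.index for f in report.flagged] == [3]
        g, crit, idx = grubbs_decision([1, 2, 3, 100], alpha=0.05)
        assert report.flagged[0].statistic == pytest.approx(g, abs=1e-12)
        assert report.flagged[0].threshold == pytest.approx(crit, abs=1e-12)
        assert g == pytest.approx(1.4998, abs=1e-4)

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateInputError):
            grubbs_outliers([5, 5, 5, 5])

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            grubbs_outliers([1.0, 2.0])

    def test_tie_flags_lower_index(self):
        # two equidistant extremes; the lower sample index is flagged first
        x = [-10.0] + [0.0] * 18 + [10.0]
        report = grubbs_outliers(x, alpha=0.05)
        assert report.flagged[0].index == 0

    def test_iteration_catches_second_outlier(self):
        x = [1.0, 1.1, 0.9, 1.05, 0.95, 1.02, 0.98, 1.0, 100.0, 5.0]
        rep_iter = grubbs_outliers(x, alpha=0.05, iterate=True)
        rep_single = grubbs_outliers(x, alpha=0.05, iterate=False)
        assert {f.index for f in rep_iter.flagged} == {8, 9}
        assert len(rep_single.flagged) <= 1

    def test_matches_direct_formula_on_random_vectors(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 40))
            x = rng.normal(size=n)
            if rng.random() < 0.3:
                x[int(rng.integers(n))] += rng.choice([-1, 1]) * rng.uniform(3, 10)
            g, crit, idx = grubbs_decision(x, alpha=0.05)
            report = grubbs_outliers(x, alpha=0.05, iterate=False)
            flagged = report.flagged[0].index if report.flagged else None
            assert flagged == idx
            if report.flagged:
                assert report.flagged[0].statistic == pytest.approx(g, abs=1e-10)
                assert report.flagged[0].threshold == pytest.approx(crit, abs=1e-10)

    def test_critical_value_decreases_in_alpha(self):
        assert grubbs_critical_value(10, 0.01) > grubbs_critical_value(10, 0.10)


class TestBonferroni:
    def test_gross_outlier_flagged(self):
        report = bonferroni_outliers([1, 2, 3, 100], alpha=0.05)
        assert [f.index for f in report.flagged] == [3]

    def test_adjusted_p_capped_at_one(self):
        _, p_adj = studentized_residuals_and_bonferroni(
            np.array([0.1, -0.2, 0.05, 0.0, -0.05, 0.12])
        )
        assert np.all(p_adj <= 1.0)
        assert np.any(p_adj == 1.0)

    def test_matches_leave_one_out_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n)
            _, p_impl = studentized_residuals_and_bonferroni(x)
            p_oracle = bonferroni_adjusted_pvalues(x)
            assert np.allclose(p_impl, p_oracle, atol=1e-10)

    def test_familywise_error_control_on_null(self):
        # clean N(0,1) samples: a non-empty report is rare (FWER <= alpha)
        flagged_runs = 0
        for r in range(100):
            x = np.random.default_rng(300 + r).normal(size=50)
            if bonferroni_outliers(x, alpha=0.05).flagged:
                flagged_runs += 1
        assert flagged_runs <= 5

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            bonferroni_outliers([1.0, 2.0, 3.0])


class TestReproducibility:
    def _replicated_table(self, rep1, rep2, trait="t1"):
        values = np.concatenate([rep1, rep2])[:, None]
        n = len(values)
        meta = pd.DataFrame(
            {"replicate_group": [f"g{i}" for i in range(len(rep1))] * 2}
        )
        return TraitTable(
            values=values,
            trait_names=[trait],
            sample_ids=[f"s{i}" for i in range(n)],
            labels=np.zeros(n, dtype=int),
            metadata=meta,
        )

    def test_identical_replicates_retained(self, rng):
        base = rng.normal(size=20)
        t = self._replicated_table(base, base.copy())
        out, trace = reproducibility_filter(t, "replicate_group", r_min=0.99)
        assert out.trait_names == ["t1"]
        assert trace.details["r_by_trait"]["t1"] == pytest.approx(1.0)

    def test_shuffled_replicates_removed(self):
        # an independent shuffle has r ~ 0; removed at r_min = 0.5
        removed = 0
        for r in range(50):
            rng = np.random.default_rng(900 + r)
            base = rng.normal(size=100)
            shuffled = rng.permutation(base)
            t = self._replicated_table(base, shuffled)
            try:
                out, _ = reproducibility_filter(t, "replicate_group", r_min=0.5)
                removed += "t1" not in out.trait_names
            except DataError:  # every trait removed counts as removal
                removed += 1
        assert removed >= 48

    def test_r_min_zero_disables_filter(self, rng):
        base = rng.normal(size=30)
        t = self._replicated_table(base, rng.permutation(base))
        out, _ = reproducibility_filter(t, "replicate_group", r_min=0.0)
        assert out.trait_names == ["t1"]

    def test_few_pairs_not_assessable_and_retained(self, rng):
        t = self._replicated_table(rng.normal(size=2), rng.normal(size=2))
        out, trace = reproducibility_filter(t, "replicate_group", r_min=0.9)
        assert out.trait_names == ["t1"]
        assert trace.details["not_assessable"] == ["t1"]

    def test_mapping_input_equivalent_to_column(self, rng):
        base = rng.normal(size=10)
        t = self._replicated_table(base, base + rng.normal(0, 0.01, 10))
        mapping = dict(zip(t.sample_ids, t.metadata["replicate_group"]))
        out_a, tr_a = reproducibility_filter(t, "replicate_group", r_min=0.5)
        out_b, tr_b = reproducibility_filter(t, mapping, r_min=0.5)
        assert tr_a.details["r_by_trait"] == tr_b.details["r_by_trait"]


class TestVif:
    def test_orthogonal_traits_untouched(self):
        n = 60
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(n, 4)))
        t = _table(q)
        out, trace = vif_stepwise(t, vif_max=10.0)
        assert out.trait_names == t.trait_names
        # columns are mutually orthogonal; only the intercept introduces a
        # vanishing amount of shared variance, so VIFs sit at ~1
        assert all(
            v == pytest.approx(1.0, abs=0.1)
            for v in trace.details["final_vifs"].values()
        )

    def test_duplicated_column_removed_first(self, rng):
        x = rng.normal(size=(50, 3))
        values = np.column_stack([x, x[:, 0]])  # t4 duplicates t1
        t = _table(values)
        out, trace = vif_stepwise(t, vif_max=10.0)
        assert trace.removed_traits[0] in ("t1", "t4")
        assert trace.details["removal_sequence"][0][1] == np.inf
        # exactly one of the duplicate pair survives
        assert ("t1" in out.trait_names) != ("t4" in out.trait_names)

    def test_near_linear_combination_removed_once_then_stable(self, rng):
        x1, x2 = rng.normal(size=(2, 200))
        x3 = x1 + x2 + rng.normal(0, 0.05, 200)
        t = _table(np.column_stack([x1, x2, x3]))
        out, trace = vif_stepwise(t, vif_max=10.0)
        assert len(trace.removed_traits) == 1
        out2, trace2 = vif_stepwise(out, vif_max=10.0)
        assert trace2.removed_traits == []
        assert max(trace2.details["final_vifs"].values()) <= 10.0

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        for _ in range(25):
            n, p = int(rng.integers(20, 60)), int(rng.integers(2, 6))
            base = rng.normal(size=(n, p))
            base[:, -1] += 0.8 * base[:, 0]  # induce some collinearity
            mine = compute_vifs(base)
            design = np.column_stack([base, np.ones(n)])
            theirs = np.array(
                [variance_inflation_factor(design, j) for j in range(p)]
            )
            assert np.allclose(mine, theirs, rtol=1e-8)
            assert np.allclose(mine, vif_direct(base), rtol=1e-10)

    def test_output_respects_cap(self, rng):
        x = rng.normal(size=(80, 6))
        x[:, 3] = x[:, 0] + x[:, 1] + rng.normal(0, 0.1, 80)
        x[:, 4] = x[:, 2] + rng.normal(0, 0.1, 80)
        out, trace = vif_stepwise(_table(x), vif_max=5.0)
        if out.n_traits > 2:
            assert max(trace.details["final_vifs"].values()) <= 5.0

    def test_p_ge_n_rejected(self, rng):
        with pytest.raises(DimensionalityError):
            vif_stepwise(_table(rng.normal(size=(4, 5))), vif_max=10.0)


class TestPipeline:
    def test_all_stages_disabled_identity(self, rng):
        t = _table(rng.normal(size=(30, 4)))
        cfg = PreprocessConfig(drop_empty=False, outliers=False, vif=False)
        out, traces = preprocess_pipeline(t, cfg)
        assert np.array_equal(out.values, t.values)
        assert traces == []

    def test_mixed_defects_filtered(self, rng):
        n = 40
        clean = rng.normal(10, 1, size=(n, 3))
        zero_trait = np.zeros(n)
        dup = clean[:, 0].copy()
        values = np.column_stack([clean, zero_trait, dup])
        values[5, 1] = 90.0  # gross outlier in t2
        t = _table(values, trait_names=["t1", "t2", "t3", "zero", "dup"])
        cfg = PreprocessConfig(
            missing_policy="drop_trait", missing_cutoff=0.5,
            outlier_method="grubbs", vif_max=10.0,
        )
        out, traces = preprocess_pipeline(t, cfg)
        assert "zero" not in out.trait_names
        assert ("t1" in out.trait_names) != ("dup" in out.trait_names)
        stage_names = [tr.stage for tr in traces]
        assert stage_names[0] == "drop_empty_values"
        assert "vif_stepwise" in stage_names
        outlier_trace = [tr for tr in traces if tr.stage.startswith("outliers")][0]
        assert ("s6", "t2") in outlier_trace.flagged_cells
        # the gross value is gone (masked or dropped), never edited in place
        assert not np.any(out.values == 90.0)

    def test_grouped_outlier_detection(self, rng):
        # the outlier is extreme within its genotype group only
        g1 = rng.normal(0, 0.1, 20)
        g2 = rng.normal(100, 0.1, 20)
        g1[3] = 5.0  # wild for group 1, unremarkable overall
        values = np.concatenate([g1, g2])[:, None]
        meta = pd.DataFrame({"genotype": ["a"] * 20 + ["b"] * 20})
        t = TraitTable(
            values=values,
            trait_names=["t1"],
            sample_ids=[f"s{i}" for i in range(40)],
            labels=np.zeros(40, dtype=int),
            metadata=meta,
        )
        _, trace_grouped, rep = remove_outliers(t, group_columns=("genotype",))
        assert any(f.index == 3 for f in rep.flagged)
        _, _, rep_pooled = remove_outliers(t)
        assert not any(f.index == 3 for f in rep_pooled.flagged)

    def test_filters_never_edit_retained_values(self, rng):
        t = _table(rng.normal(size=(50, 5)) + 10)
        t.values[2, 1] = 0.0
        cfg = PreprocessConfig(missing_policy="drop_sample")
        out, _ = preprocess_pipeline(t, cfg)
        for i, sid in enumerate(out.sample_ids):
            orig_row = t.sample_ids.index(sid)
            for j, name in enumerate(out.trait_names):
                orig_col = t.trait_names.index(name)
                assert out.values[i, j] == t.values[orig_row, orig_col]
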