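import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import contrast, make_matrix
from stagewise import de
from stagewise.simulate import SimulationConfig, simulate_expression


class TestScaleTrimmedMean:
    def test_already_at_target_unchanged(self):
        col = np.full(9, 500.0)
        m = make_matrix(np.tile(col, (4, 1)).T.reshape(4, 9) * 0 + 500.0)
        out = de.scale_trimmed_mean(m)
        np.testing.assert_allclose(out.values.to_numpy(), 500.0)

    def test_scale_invariance(self, small_matrix):
        out1 = de.scale_trimmed_mean(small_matrix)
        doubled = small_matrix.with_values(small_matrix.values * 2)
        out2 = de.scale_trimmed_mean(doubled)
        pd.testing.assert_frame_equal(out1.values, out2.values)

    def test_known_column_arithmetic(self):
        # column 1..10: floor(0.02 * 10) = 0 values trimmed, mean 5.5
        vals = np.tile(np.arange(1.0, 11.0)[:, None], (1, 9))
        m = make_matrix(vals, probe_ids=[f"g{i}" for i in range(10)])
        out = de.scale_trimmed_mean(m)
        np.testing.assert_allclose(out.values.iloc[0, 0], 500.0 / 5.5)
        np.testing.assert_allclose(out.values.iloc[0, 0], 90.9090909090909)

    def test_zero_column_is_degenerate(self):
        m = make_matrix(np.zeros((3, 9)))
        with pytest.raises(ValueError, match="degenerate array"):
            de.scale_trimmed_mean(m)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.integers(0, 2**32 - 1),
        st.floats(0.0, 0.45),
        st.integers(5, 40),
    )
    def test_trimmed_mean_hits_target_within_1e9(self, seed, trim, n_probes):
        rng = np.random.default_rng(seed)
        m = make_matrix(rng.uniform(1, 1e4, size=(n_probes, 9)))
        cfg = de.NormalizationConfig(trim_fraction=trim)
        out = de.scale_trimmed_mean(m, cfg)
        for col in out.values.columns:
            tm = de.trimmed_mean(out.values[col].to_numpy(), trim)
            assert abs(tm - 500.0) <= 1e-9 * 500.0


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "test,ref,expected",
        [(400.0, 400.0, 1.0), (800.0, 400.0, 2.0), (100.0, 400.0, -4.0)],
    )
    def test_examples(self, test, ref, expected):
        assert de.signed_fold_change(test, ref) == pytest.approx(expected)

    def test_non_positive_mean_rejected(self):
        with pytest.raises(ValueError):
            de.signed_fold_change(0.0, 100.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.floats(1e-3, 1e6), st.floats(1e-3, 1e6)
    )
    def test_antisymmetry(self, a, b):
        fab = de.signed_fold_change(a, b)
        fba = de.signed_fold_change(b, a)
        assert abs(fab) >= 1.0
        if a / b != 1.0 and b / a != 1.0:
            assert abs(fab) == pytest.approx(abs(fba))
            assert np.sign(fab) == -np.sign(fba)


class TestTTest:
    def test_identical_groups_p_one(self):
        assert de.ttest_two_sample([1, 2, 3], [1, 2, 3]) == 1.0

    def test_pooled_example(self):
        # means 100 vs 200, common sd 10: t = -12.2474, df = 4
        p = de.ttest_two_sample([100, 110, 90], [200, 210, 190], "pooled")
        assert p == pytest.approx(2.552167494419266e-4, rel=1e-9)

    def test_zero_variance_conventions(self):
        assert de.ttest_two_sample([5, 5], [5, 5]) == 1.0
        assert de.ttest_two_sample([5, 5], [6, 6]) == 0.0

    def test_single_value_group_rejected(self):
        with pytest.raises(ValueError):
            de.ttest_two_sample([1], [1, 2])

    def test_welch_differs_under_unequal_variance(self):
        a, b = [100, 101, 99], [200, 260, 140]
        assert de.ttest_two_sample(a, b, "welch") != de.ttest_two_sample(a, b, "pooled")


class TestContrastStats:
    def test_degenerate_variance_convention(self):
        vals = np.array([[100, 100, 100, 100, 100, 100, 400, 400, 400]], dtype=float)
        df = de.contrast_stats(make_matrix(vals))
        row = df.iloc[0]
        assert row["fc_ie"] == 1.0 and row["p_ie"] == 1.0
        assert row["fc_le"] == 4.0 and row["p_le"] == 0.0
        assert row["max_intensity"] == 400.0

    def test_all_equal_probe(self):
        df = de.contrast_stats(make_matrix(np.full((1, 9), 7.0)))
        row = df.iloc[0]
        assert (row[["fc_ie", "fc_le", "fc_il"]] == 1.0).all()
        assert (row[["p_ie", "p_le", "p_il"]] == 1.0).all()

    def test_matches_scalar_operations(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(100, 2000, size=(5, 9))
        m = make_matrix(vals)
        df = de.contrast_stats(m)
        for i, probe in enumerate(m.probe_ids):
            e, mid, late = vals[i, :3], vals[i, 3:6], vals[i, 6:]
            assert df.loc[probe, "fc_le"] == pytest.approx(
                de.signed_fold_change(late.mean(), e.mean())
            )
            assert df.loc[probe, "p_ie"] == pytest.approx(
                de.ttest_two_sample(mid, e)
            )
            assert df.loc[probe, "p_il"] == pytest.approx(
                de.ttest_two_sample(late, mid)
            )

    def test_missing_stage_named(self):
        from stagewise.io import ExpressionMatrix, Sample

        samples = [Sample(f"E_{r}", "E", r) for r in (1, 2, 3)] + [
            Sample(f"I_{r}", "I", r) for r in (1, 2, 3)
        ]
        df = pd.DataFrame(
            np.ones((2, 6)), index=["a", "b"], columns=[s.sample_id for s in samples]
        )
        with pytest.raises(ValueError, match="'L'"):
            de.contrast_stats(ExpressionMatrix(df, samples))

    def test_planted_fold_recovered_with_significance(self):
        # 4-fold late effect at CV 5% lands in [3, 5] with p < 0.05
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            base = 1000.0
            e = base * rng.lognormal(0, 0.05, 3)
            i = base * rng.lognormal(0, 0.05, 3)
            l = 4 * base * rng.lognormal(0, 0.05, 3)
            df = de.contrast_stats(make_matrix(np.concatenate([e, i, l])[None, :]))
            row = df.iloc[0]
            if 3.0 <= row["fc_le"] <= 5.0 and row["p_le"] < 0.05:
                hits += 1
        assert hits >= 99


class TestDeFilter:
    @pytest.mark.parametrize(
        "mx,fc,p,kept,direction",
        [
            (499.0, 10.0, 0.001, False, None),   # below intensity floor
            (600.0, -2.0, 0.05, True, "down"),   # inclusive thresholds
            (600.0, 1.9, 0.001, False, None),    # fold too small
            (600.0, 2.0, 0.051, False, None),    # p too large
        ],
    )
    def test_boundary_conventions(self, mx, fc, p, kept, direction):
        df = pd.DataFrame(
            {"fc_ie": [1.0], "p_ie": [1.0], "fc_le": [fc], "p_le": [p],
             "fc_il": [1.0], "p_il": [1.0], "max_intensity": [mx]},
            index=["probe"],
        )
        res = de.de_filter(df)
        if kept:
            target = res.down if direction == "down" else res.up
            assert "probe" in target.index
        else:
            assert "probe" in res.excluded.index

    def test_partition_is_exhaustive_and_disjoint(self):
        cfg = SimulationConfig(seed=5, n_probes=300)
        matrix, _ = simulate_expression(cfg)
        contrasts = de.contrast_stats(matrix)
        res = de.de_filter(contrasts)
        assert res.n_total == len(contrasts)
        idx = set(res.up.index) | set(res.down.index) | set(res.excluded.index)
        assert idx == set(contrasts.index)
        assert not (set(res.up.index) & set(res.down.index))


class TestCollapseToGenes:
    MAP = {"p1": "Acta2", "p2": "Acta2", "p3": "Vcl"}

    def test_same_gene_probes_collapse(self):
        out = de.collapse_to_genes({"up": ["p1", "p2"], "down": []}, self.MAP)
        assert out.up == ["Acta2"] and out.down == []

    def test_gene_in_both_directions_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            out = de.collapse_to_genes({"up": ["p1"], "down": ["p2"]}, self.MAP)
        assert out.up == ["Acta2"] and out.down == ["Acta2"]
        assert out.both_directions == ["Acta2"]
        assert "both directions" in caplog.text

    def test_unmapped_probe_counted(self):
        out = de.collapse_to_genes({"up": ["p1", "zzz"], "down": []}, self.MAP)
        assert out.up == ["Acta2"]
        assert out.n_unannotated == 1


def test_null_type_one_error_calibrated():
    """On null data (no effects, CV 10%, n=3), the L-vs-E t-test rejects at
    about its nominal 5% level."""
    cfg = SimulationConfig(
        seed=1, n_probes=10_000, cv=0.10,
        class_proportions={"early": 0.0, "progressive": 0.0, "late": 0.0, "null": 1.0},
    )
    matrix, _ = simulate_expression(cfg)
    contrasts = de.contrast_stats(matrix)
    frac = (contrasts["p_le"] <= 0.05).mean()
    assert abs(frac - 0.05) <= 0.01
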