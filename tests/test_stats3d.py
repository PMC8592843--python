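"""Transforms, mixed models, post-hoc contrasts, FDR and variance share."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from hypothesis import given, settings
from hypothesis import strategies as st

from meriquant.stats3d import (
    TransformSpec,
    analyze_geometry,
    anisotropy_index,
    apply_transform,
    bh_reject,
    fit_mixed_model,
    pct_variance_br,
    posthoc_pairwise,
    transformed_col,
    two_step_adaptive_fdr,
)
from meriquant.synth import SynthGeometryConfig, ZoneMixture, generate_geometry_table


def _simple_table(rng, shift=0.3, root_sd=0.1, resid_sd=0.2, n_roots=12, n_cells=50,
                  dist_slope=0.05):
    """Two-condition log-length data with known generating parameters."""
    rows = []
    for treatment in ("WT", "BL"):
        for r in range(n_roots // 2):
            root = f"{treatment}_{r}"
            b = rng.normal(0, root_sd)
            d = rng.uniform(4, 200, n_cells)
            y = (
                2.0
                + (shift if treatment == "BL" else 0.0)
                + dist_slope * np.sqrt(d)
                + b
                + rng.normal(0, resid_sd, n_cells)
            )
            for di, yi in zip(d, y):
                rows.append((root, treatment, "cortex", di, np.exp(yi)))
    return pd.DataFrame(
        rows, columns=["root_id", "treatment", "tissue", "distance_qc", "length"]
    )


class TestTransforms:
    def test_known_values(self):
        tab = pd.DataFrame(
            {
                "length": [np.e**2],
                "depth": [np.e],
                "width": [5.0],
                "surface_area": [49.0],
                "volume": [27.0],
                "distance_qc": [16.0],
            }
        )
        out = apply_transform(tab)
        assert out["length_t"].iloc[0] == pytest.approx(2.0)
        assert out["surface_area_t"].iloc[0] == pytest.approx(7.0)
        assert out["volume_t"].iloc[0] == pytest.approx(3.0)
        assert out["width_t"].iloc[0] == pytest.approx(5.0)
        assert out["sqrt_distance"].iloc[0] == pytest.approx(4.0)

    def test_round_trip_inverse(self, geometry_table):
        spec = TransformSpec()
        out = apply_transform(geometry_table, spec)
        for p in ("length", "volume", "surface_area"):
            back = spec.inverse(p)(out[transformed_col(p)])
            np.testing.assert_allclose(back, out[p], rtol=1e-10)

    def test_nonpositive_value_raises(self):
        tab = pd.DataFrame(
            {"length": [1.0, -1.0], "distance_qc": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="length"):
            apply_transform(tab, TransformSpec(transforms={"length": "log"}))


class TestAnisotropy:
    @pytest.mark.parametrize(
        "ldw,expected", [((1, 1, 1), 1.0), ((2, 1, 1), 4.0), ((3, 2, 1.5), 3.0)]
    )
    def test_values(self, ldw, expected):
        l, d, w = ldw
        assert anisotropy_index(l, d, w) == pytest.approx(expected)

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            anisotropy_index(1.0, 0.0, 1.0)


class TestMixedModel:
    def test_treatment_shift_recovery(self, rng):
        """A generating shift of 0.3 on the log scale is recovered within
        3 SE of the contrast."""
        tab = _simple_table(rng)
        fit = fit_mixed_model(tab, "length", tissue="cortex")
        name = [n for n in fit.fe_params.index if "BL" in n][0]
        est = fit.fe_params[name]
        se = np.sqrt(fit.cov_fe.loc[name, name])
        assert abs(est - 0.3) < 3 * se

    def test_zero_root_variance_detected(self, rng):
        """Data without a root effect yield a negligible random-intercept
        variance (optimizer stops at the boundary) and a singular flag."""
        tab = _simple_table(rng, root_sd=0.0)
        with pytest.warns(UserWarning, match="singular"):
            fit = fit_mixed_model(tab, "length", tissue="cortex")
        assert fit.random_var < 1e-2 * fit.resid_var
        assert fit.singular

    def test_ols_limit_with_singleton_groups(self, rng):
        """One observation per root: V ∝ I, so the GLS fixed coefficients
        equal OLS regardless of how variance splits between components."""
        import warnings as _warnings

        tab = _simple_table(rng, n_roots=2, n_cells=40, root_sd=0.0)
        tab["root_id"] = [f"r{i}" for i in range(len(tab))]
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = fit_mixed_model(tab, "length", tissue="cortex")
        data = apply_transform(tab)
        ols = smf.ols(
            "length_t ~ C(treatment, Treatment('WT')) + sqrt_distance", data
        ).fit()
        np.testing.assert_allclose(fit.fe_params, ols.params, atol=1e-6)


class TestPosthoc:
    def _three_group_fit(self, rng, shifts=(0.0, 0.0, 0.0), resid=0.05):
        rows = []
        for treatment, shift in zip(("WT", "bri1", "BL"), shifts):
            for r in range(3):
                d = rng.uniform(4, 200, 40)
                y = 2.0 + shift + 0.02 * np.sqrt(d) + rng.normal(0, resid, 40)
                for di, yi in zip(d, y):
                    rows.append((f"{treatment}_{r}", treatment, "cortex", di, np.exp(yi)))
        tab = pd.DataFrame(
            rows, columns=["root_id", "treatment", "tissue", "distance_qc", "length"]
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # no root effect -> singular fit
            return fit_mixed_model(tab, "length", tissue="cortex")

    def test_three_groups_three_comparisons(self, rng):
        comps = posthoc_pairwise(self._three_group_fit(rng))
        assert len(comps) == 3
        assert {frozenset(c.pair) for c in comps} == {
            frozenset(p) for p in itertools.combinations(("WT", "bri1", "BL"), 2)
        }

    def test_null_effect_large_p(self, rng):
        comps = posthoc_pairwise(self._three_group_fit(rng))
        assert all(c.adjusted_p > 0.2 for c in comps)
        assert all(c.adjusted_p >= c.raw_p for c in comps)

    def test_huge_effect_tiny_p(self, rng):
        comps = posthoc_pairwise(self._three_group_fit(rng, shifts=(0.0, 0.0, 2.0)))
        big = [c for c in comps if "BL" in c.pair]
        assert all(c.adjusted_p < 1e-6 for c in big)


class TestTwoStepFDR:
    def test_adapted_level_arithmetic(self, rng):
        """25 models with 17 stage-1 BH rejections give a stage-2 level of
        exactly 0.05 × 17/25 = 0.034."""
        # construct p-values with exactly 17 BH rejections at alpha=0.05
        pvals = np.concatenate([np.full(17, 1e-6), np.full(8, 0.9)])
        posthoc = [[0.01, 0.5, 0.9]] * 25
        res = two_step_adaptive_fdr(pvals, posthoc, alpha=0.05)
        assert res.n_stage1_significant == 17
        assert res.stage2_alpha == pytest.approx(0.05 * 17 / 25, abs=1e-15)
        assert res.stage2_alpha == pytest.approx(0.034)

    def test_all_null_skips_stage2(self):
        res = two_step_adaptive_fdr([1.0] * 10, [[0.001]] * 10, alpha=0.05)
        assert res.n_stage1_significant == 0
        assert res.stage2_alpha == 0.0
        assert not any(f.any() for f in res.stage2_flags)

    def test_all_signal_keeps_full_alpha(self):
        res = two_step_adaptive_fdr([0.0] * 10, [[0.5]] * 10, alpha=0.05)
        assert res.stage2_alpha == pytest.approx(0.05)

    def test_nonsurviving_models_never_tested(self):
        res = two_step_adaptive_fdr(
            [1e-9, 0.99], [[1e-12], [1e-12]], alpha=0.05
        )
        assert res.stage2_flags[0][0]
        assert not res.stage2_flags[1][0]

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12),
        st.floats(min_value=0.01, max_value=0.2),
    )
    @settings(max_examples=200, deadline=None)
    def test_bh_matches_bruteforce_stepup(self, pvals, alpha):
        """BH flags equal the definitional step-up rule on small vectors."""
        p = np.array(pvals)
        flags = bh_reject(p, alpha)
        m = p.size
        psort = np.sort(p)
        ks = [k + 1 for k in range(m) if psort[k] <= (k + 1) * alpha / m]
        # step-up rule: reject everything at or below the k*-th order stat
        brute = (
            p <= psort[max(ks) - 1] if ks else np.zeros(m, dtype=bool)
        )
        np.testing.assert_array_equal(flags, brute)

    def test_null_fdr_controlled(self, rng):
        """On fully null uniform p-values the procedure makes any stage-1
        rejection in at most ~alpha of replicates (binomial CI, 500 reps)."""
        alpha = 0.05
        hits = 0
        for _ in range(500):
            p = rng.uniform(size=10)
            res = two_step_adaptive_fdr(p, [[1.0]] * 10, alpha=alpha)
            hits += res.n_stage1_significant > 0
        # 3-sigma upper bound of Binomial(500, 0.05)
        assert hits <= 500 * alpha + 3 * np.sqrt(500 * alpha * (1 - alpha))


class TestVarianceShare:
    def test_pure_treatment_effect_near_100(self, rng):
        tab = _simple_table(rng, shift=3.0, root_sd=0.0, resid_sd=0.01, dist_slope=0.0)
        with pytest.warns(UserWarning):
            fit = fit_mixed_model(tab, "length", tissue="cortex")
        assert pct_variance_br(fit) > 95.0

    def test_null_effect_near_0(self, rng):
        tab = _simple_table(
            rng, shift=0.0, root_sd=0.05, resid_sd=0.2, n_cells=400
        )
        fit = fit_mixed_model(tab, "length", tissue="cortex")
        assert pct_variance_br(fit) < 2.0

    def test_analytic_share_recovered(self, rng):
        """Treatment : distance : root : residual variance of 2:1:1:1 gives
        a BR share of (3/5)·(2/3) = 40% within Monte-Carlo tolerance."""
        # variances: treatment 2 => balanced ±sqrt(2); sqrt-distance uniform
        # on [2, 2+sqrt(12)] with slope 1 => var 1; root 1; residual 1
        n_roots, n_cells = 40, 250
        rows = []
        for i, treatment in enumerate(("WT", "BL")):
            delta = (1 if treatment == "BL" else -1) * np.sqrt(2.0)
            for r in range(n_roots // 2):
                b = rng.normal(0, 1.0)
                s = rng.uniform(2.0, 2.0 + np.sqrt(12.0), n_cells)
                y = delta + s + b + rng.normal(0, 1.0, n_cells)
                for si, yi in zip(s, y):
                    rows.append((f"{treatment}{r}", treatment, "cortex", si**2, np.exp(yi)))
        tab = pd.DataFrame(
            rows, columns=["root_id", "treatment", "tissue", "distance_qc", "length"]
        )
        fit = fit_mixed_model(tab, "length", tissue="cortex")
        assert pct_variance_br(fit) == pytest.approx(40.0, abs=4.0)

    def test_share_bounded(self, rng):
        fit = fit_mixed_model(_simple_table(rng), "length", tissue="cortex")
        assert 0.0 <= pct_variance_br(fit) <= 100.0


class TestPipeline:
    def test_analyze_geometry_end_to_end(self):
        """Full pipeline on a small synthetic atlas: shape of the output,
        monotone adjusted p's, bounded variance shares."""
        cfg = SynthGeometryConfig(
            roots_per_treatment=3, cells_per_root_per_tissue=40, seed=3
        )
        tab = generate_geometry_table(cfg)
        tab = tab.rename(columns={"true_zone": "zone"})  # classifier bypassed
        comparisons, fits, fdr = analyze_geometry(
            tab, parameters=("length", "width"), tissues=("cortex", "pericycle")
        )
        assert len(fits) == 4
        assert len(comparisons) == 4 * 3
        assert (comparisons["adjusted_p"] >= comparisons["raw_p"] - 1e-12).all()
        assert comparisons["pct_variance_br"].between(0, 100).all()
        assert 0 <= fdr.stage2_alpha <= 0.05
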