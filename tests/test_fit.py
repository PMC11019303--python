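import math

import numpy as np
import pandas as pd
import pytest

from packstep import fit
from packstep.experiments import simulate_choice_strata


def brute_force_loglik(X, used_idx, beta):
    """Independent enumeration oracle: plain-python softmax per stratum."""
    total = 0.0
    for s in range(len(X)):
        ws = [math.exp(sum(b * x for b, x in zip(beta, X[s][r]))) for r in range(len(X[s]))]
        total += math.log(ws[used_idx[s]] / sum(ws))
    return total


def arrays_to_table(X, used_idx, pack_ids=None):
    rows = []
    S, R, p = X.shape
    for s in range(S):
        for r in range(R):
            row = {
                "stratum_id": f"s{s:04d}",
                "pack_id": pack_ids[s] if pack_ids is not None else "p0",
                "y": int(r == used_idx[s]),
            }
            for j in range(p):
                row[f"x{j}"] = X[s, r, j]
            rows.append(row)
    return pd.DataFrame(rows)


class TestConditionalLoglik:
    def test_uniform_choice_closed_form(self):
        X = np.zeros((7, 21, 3))
        used = np.zeros(7, int)
        ll = fit.conditional_loglik(X, used, np.zeros(3))
        assert ll == pytest.approx(7 * np.log(1 / 21))

    def test_single_stratum_closed_form(self):
        # rows x = (1, 0, 0), used = first, beta = 1 -> 1 - log(e + 2)
        X = np.array([[[1.0], [0.0], [0.0]]])
        ll = fit.conditional_loglik(X, np.array([0]), np.array([1.0]))
        assert ll == pytest.approx(1.0 - np.log(np.e + 2))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            S = int(rng.integers(1, 8))
            R = int(rng.integers(2, 6))
            p = int(rng.integers(1, 4))
            X = rng.normal(size=(S, R, p))
            used = rng.integers(0, R, size=S)
            beta = rng.normal(size=p)
            ours = fit.conditional_loglik(X, used, beta)
            assert abs(ours - brute_force_loglik(X, used, beta)) < 1e-10

    def test_extreme_coefficients_stay_finite(self):
        X = np.random.default_rng(1).normal(size=(5, 21, 2))
        used = np.zeros(5, int)
        ll = fit.conditional_loglik(X, used, np.array([500.0, -500.0]))
        assert np.isfinite(ll)


class TestFitFixed:
    def test_recovers_generating_coefficients(self):
        beta = np.array([1.0, -0.5, 0.25])
        X, used = simulate_choice_strata(4000, beta, seed=5)
        table = arrays_to_table(X, used)
        spec = fit.ModelSpec(name="m", fixed=["x0", "x1", "x2"])
        res = fit.fit_fixed(table, spec)
        assert res.converged
        for j in range(3):
            assert abs(res.estimates[j] - beta[j]) < 3 * res.se[j]

    def test_agrees_with_statsmodels_conditional_logit(self, small_strata):
        """Cross-check the primary estimator against an independent
        implementation of stratified conditional logistic regression."""
        sm = pytest.importorskip("statsmodels.api")
        spec = fit.ModelSpec(name="m", fixed=["u", "v"])
        ours = fit.fit_fixed(small_strata, spec, min_strata_per_param=1)
        groups = small_strata["stratum_id"].astype("category").cat.codes
        model = sm.ConditionalLogit(
            small_strata["y"], small_strata[["u", "v"]], groups=groups
        )
        theirs = model.fit(disp=False)
        np.testing.assert_allclose(ours.estimates, theirs.params, atol=5e-4)
        np.testing.assert_allclose(ours.se, theirs.bse, atol=5e-4)

    def test_duplicating_strata_halves_variance(self, small_strata):
        spec = fit.ModelSpec(name="m", fixed=["u", "v"])
        one = fit.fit_fixed(small_strata, spec, min_strata_per_param=1)
        doubled = pd.concat(
            [
                small_strata,
                small_strata.assign(
                    stratum_id=small_strata["stratum_id"] + "_copy"
                ),
            ]
        )
        two = fit.fit_fixed(doubled, spec, min_strata_per_param=1)
        np.testing.assert_allclose(two.estimates, one.estimates, atol=1e-6)
        np.testing.assert_allclose(two.se, one.se / np.sqrt(2), rtol=1e-4)

    def test_stratum_constant_shift_invariance(self, small_strata):
        """Adding a per-stratum constant to a covariate leaves estimates
        unchanged (conditioning eliminates stratum effects)."""
        spec = fit.ModelSpec(name="m", fixed=["u", "v"])
        base = fit.fit_fixed(small_strata, spec, min_strata_per_param=1)
        rng = np.random.default_rng(2)
        shifted = small_strata.copy()
        offsets = {
            sid: rng.normal() for sid in shifted["stratum_id"].unique()
        }
        shifted["u"] = shifted["u"] + shifted["stratum_id"].map(offsets)
        res = fit.fit_fixed(shifted, spec, min_strata_per_param=1)
        np.testing.assert_allclose(res.estimates, base.estimates, atol=1e-6)

    def test_estimator_consistency_in_n(self):
        """Median absolute recovery error shrinks as strata grow."""
        beta = np.array([0.8, -0.4])
        errs = []
        for n in (500, 2000, 8000):
            per_seed = []
            for seed in range(3):
                X, used = simulate_choice_strata(n, beta, seed=100 * n + seed)
                table = arrays_to_table(X, used)
                res = fit.fit_fixed(
                    table, fit.ModelSpec(name="m", fixed=["x0", "x1"])
                )
                per_seed.append(np.abs(res.estimates - beta).mean())
            errs.append(np.median(per_seed))
        assert errs[0] > errs[1] > errs[2]

    def test_missing_term_values_drop_stratum(self, small_strata):
        broken = small_strata.copy()
        broken.loc[broken["stratum_id"] == "s000", "u"] = np.nan
        res = fit.fit_fixed(
            broken, fit.ModelSpec(name="m", fixed=["u", "v"]), min_strata_per_param=1
        )
        assert res.n_dropped == 1
        assert res.n_strata == 59

    def test_sanity_floor(self, small_strata):
        with pytest.raises(ValueError, match="sanity floor"):
            fit.fit_fixed(
                small_strata.head(40),  # 10 full strata
                fit.ModelSpec(name="m", fixed=["u", "v"]),
                min_strata_per_param=50,
            )

    def test_bic_identity(self, small_strata):
        res = fit.fit_fixed(
            small_strata, fit.ModelSpec(name="m", fixed=["u", "v"]),
            min_strata_per_param=1,
        )
        assert res.bic == pytest.approx(
            -2 * res.loglik + 2 * np.log(res.n_strata)
        )


class TestPoissonDevice:
    def test_poisson_trick_has_same_maximizer(self, small_strata):
        """A Poisson regression with one intercept per stratum (the
        estimation device that absorbs availability) yields the same
        fixed-effect estimates as the exact conditional likelihood."""
        sm = pytest.importorskip("statsmodels.api")
        import numpy as np

        spec = fit.ModelSpec(name="m", fixed=["u", "v"])
        cond = fit.fit_fixed(small_strata, spec, min_strata_per_param=1)
        dummies = pd.get_dummies(small_strata["stratum_id"], dtype=float)
        exog = pd.concat([small_strata[["u", "v"]], dummies], axis=1)
        pois = sm.GLM(
            small_strata["y"], exog, family=sm.families.Poisson()
        ).fit()
        np.testing.assert_allclose(
            cond.estimates, pois.params[["u", "v"]].to_numpy(), atol=1e-4
        )


class TestModelConfig:
    def test_json_round_trip(self, tmp_path):
        import json

        cfg = {
            "models": [
                {"name": "base", "fixed": ["step_length_km"], "random": ["dist_pans"]}
            ],
            "ladder": {"windows": [7, 30], "levels": [95]},
        }
        path = tmp_path / "model.json"
        path.write_text(json.dumps(cfg))
        specs, ladder = fit.load_model_config(path)
        assert specs[0].terms == ["step_length_km", "dist_pans"]
        assert tuple(ladder.windows) == (7, 30)
        assert tuple(ladder.levels) == (95,)


class TestFitRandom:
    def _heterogeneous_table(self, n_packs=8, n_strata=400, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for i in range(n_packs):
            slope = rng.normal(-1.0, 0.5)
            X, used = simulate_choice_strata(
                n_strata, np.array([slope]), n_rows=10, seed=seed + 7 * i
            )
            t = arrays_to_table(X, used)
            t["stratum_id"] = f"pk{i}_" + t["stratum_id"]
            t["pack_id"] = f"pk{i}"
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def test_identical_packs_give_zero_between_variance(self, small_strata):
        # replicate one pack's data under three pack labels
        frames = []
        for pk in ("a", "b", "c"):
            t = small_strata.copy()
            t["pack_id"] = pk
            t["stratum_id"] = pk + "_" + t["stratum_id"]
            frames.append(t)
        table = pd.concat(frames)
        spec = fit.ModelSpec(name="m", random=["u", "v"])
        res = fit.fit_random(table, spec, min_strata_per_param=1)
        single = fit.fit_fixed(small_strata, spec, min_strata_per_param=1)
        np.testing.assert_allclose(res.estimates, single.estimates, atol=1e-5)
        assert all(v == pytest.approx(0.0, abs=1e-8) for v in res.between_pack_var.values())

    def test_equal_precision_pooling_is_the_mean(self):
        mu, se, tau2 = fit._dersimonian_laird(
            np.array([1.0, 3.0]), np.array([0.5, 0.5])
        )
        assert mu == pytest.approx(2.0)

    def test_recovers_population_mean_with_heterogeneity(self):
        table = self._heterogeneous_table(seed=3)
        spec = fit.ModelSpec(name="m", random=["x0"])
        res = fit.fit_random(table, spec, min_strata_per_param=1)
        assert abs(res.coef("x0") - (-1.0)) < 3 * max(res.coef_se("x0"), 0.5 / np.sqrt(8))
        assert res.between_pack_var["x0"] > 0


class TestLadder:
    def test_extra_parameter_costs_log_n_bic(self, small_strata):
        """Two candidates with identical fit: the one extra parameter
        costs exactly ln(n_strata) BIC."""
        spec = fit.ModelSpec(name="small", fixed=["u", "v"])
        res = fit.fit_fixed(small_strata, spec, min_strata_per_param=1)
        bigger = fit.FitResult(
            spec=fit.ModelSpec(name="big", fixed=["u", "v", "w"]),
            estimates=np.r_[res.estimates, 0.0],
            se=np.r_[res.se, 1.0],
            cov=np.eye(3),
            loglik=res.loglik,  # identical fit
            n_strata=res.n_strata,
            n_dropped=0,
            converged=True,
            n_iter=1,
        )
        assert bigger.bic - res.bic == pytest.approx(np.log(60), abs=1e-9)

    def test_fixed_and_random_overlap_rejected(self):
        with pytest.raises(ValueError, match="both fixed and random"):
            fit.ModelSpec(name="m", fixed=["u"], random=["u"])
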