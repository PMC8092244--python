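"""Log-response-ratio effects, shared-control covariance and REML fits."""

import numpy as np
import pandas as pd
import pytest

import predsip as p
from predsip.exceptions import MissingControlError
from predsip.meta import GroupSummary, effects_from_summary_table


def _gs(mean, sd=0.5, n=10, group="Myxococcales", exp="E1", site="S1"):
    return GroupSummary(exp, site, group, mean, sd, n)


class TestEffectSizes:
    def test_identical_summaries_zero_lrr(self):
        e = p.effect_from_summaries(_gs(2.0), _gs(2.0, group="control"))
        assert e.lrr == 0.0

    def test_e_fold_is_unit_lrr(self):
        e = p.effect_from_summaries(_gs(np.e * 3.0), _gs(3.0, group="control"))
        assert e.lrr == pytest.approx(1.0, rel=1e-12)

    def test_back_transform_percent(self):
        e = p.effect_from_summaries(_gs(1.231), _gs(1.000, group="control"))
        pct = p.meta.percent_difference(e.lrr)
        assert pct == pytest.approx(23.1, abs=1e-10)

    def test_variance_formula(self):
        e = p.effect_from_summaries(
            _gs(2.0, sd=0.4, n=8), _gs(1.0, sd=0.3, n=20, group="control")
        )
        expected = 0.4**2 / (8 * 2.0**2) + 0.3**2 / (20 * 1.0**2)
        assert e.variance == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            p.effect_from_summaries(_gs(-1.0), _gs(1.0, group="control"))

    def test_scale_invariance_of_effects(self):
        rows = []
        for exp in ("E1", "E2"):
            rows.append({"experiment_id": exp, "site_id": "S1", "group": "control",
                         "mean": 1.0, "sd": 0.2, "n": 30})
            rows.append({"experiment_id": exp, "site_id": "S1",
                         "group": "Myxococcales", "mean": 1.4, "sd": 0.3, "n": 5})
        base = pd.DataFrame(rows)
        scaled = base.assign(mean=base["mean"] * 1000, sd=base["sd"] * 1000)
        e1, _ = effects_from_summary_table(base)
        e2, _ = effects_from_summary_table(scaled)
        assert np.allclose(e1["lrr"], e2["lrr"])
        assert np.allclose(e1["variance"], e2["variance"])

    def test_exclusion_tally(self):
        rows = [
            {"experiment_id": "E1", "site_id": "S1", "group": "control",
             "mean": 1.0, "sd": 0.2, "n": 30},
            {"experiment_id": "E1", "site_id": "S1", "group": "Myxococcales",
             "mean": -0.1, "sd": 0.3, "n": 5},
            {"experiment_id": "E1", "site_id": "S1", "group": "Lysobacter",
             "mean": 1.2, "sd": 0.3, "n": 5},
        ]
        eff, _ = effects_from_summary_table(pd.DataFrame(rows))
        assert len(eff) == 1
        assert eff.attrs["n_excluded"] == 1


class TestSharedControlCovariance:
    def test_hand_arithmetic(self):
        assert p.shared_control_covariance(
            _gs(5.0, sd=2.0, n=4, group="control")
        ) == pytest.approx(0.04, abs=1e-15)

    def test_zero_sd(self):
        assert p.shared_control_covariance(_gs(5.0, sd=0.0, n=4, group="control")) == 0.0

    def test_equals_control_term_of_effect_variance(self):
        ctrl = _gs(1.7, sd=0.6, n=12, group="control")
        e = p.effect_from_summaries(_gs(2.0, sd=0.0, n=5), ctrl)
        assert e.variance == pytest.approx(p.shared_control_covariance(ctrl))


class TestVMatrix:
    def _tables(self, shared=True):
        effects = pd.DataFrame(
            {
                "effect_id": ["a", "b"],
                "lrr": [0.1, 0.2],
                "variance": [0.05, 0.07],
                "control_id": ["E1", "E1" if shared else "E2"],
                "site_id": ["S1", "S1"],
            }
        )
        controls = pd.DataFrame(
            {
                "control_id": ["E1", "E2"],
                "site_id": ["S1", "S1"],
                "mean": [2.0, 2.0],
                "sd": [0.4, 0.4],
                "n": [10, 10],
            }
        )
        return effects, controls

    def test_no_sharing_diagonal(self):
        v = p.build_v_matrix(*self._tables(shared=False))
        assert v[0, 1] == 0.0 and v[1, 0] == 0.0

    def test_shared_control_off_diagonal(self):
        v = p.build_v_matrix(*self._tables(shared=True))
        assert v[0, 1] == pytest.approx(0.4**2 / (10 * 4.0))
        assert v[0, 1] == v[1, 0]

    def test_missing_control_error(self):
        effects, controls = self._tables()
        with pytest.raises(MissingControlError):
            p.build_v_matrix(effects, controls.iloc[1:])

    def test_psd_on_generated_designs(self, effect_config):
        for seed in (1, 2, 3):
            eff, ctrl, _ = p.generate_effect_dataset(effect_config, seed=seed)
            v = p.build_v_matrix(eff, ctrl)
            assert np.allclose(v, v.T)
            assert np.linalg.eigvalsh(v).min() >= -1e-10


def _reml_ll_oracle(tau2, y, X, V, Z):
    """Independent REML restricted log-likelihood (plain inverses)."""
    S = V + tau2 * Z @ Z.T
    Si = np.linalg.inv(S)
    XtSiX = X.T @ Si @ X
    beta = np.linalg.solve(XtSiX, X.T @ Si @ y)
    r = y - X @ beta
    return -0.5 * (
        np.linalg.slogdet(S)[1] + np.linalg.slogdet(XtSiX)[1] + r @ Si @ r
    ), beta


class TestMultilevelFit:
    def _small_effects(self, n=8, tau=0.3, seed=5):
        rng = np.random.default_rng(seed)
        sites = [f"S{i % 3}" for i in range(n)]
        u = {s: rng.normal(0, tau) for s in set(sites)}
        var = rng.uniform(0.02, 0.08, n)
        lrr = 0.2 + np.array([u[s] for s in sites]) + rng.normal(0, np.sqrt(var))
        return pd.DataFrame(
            {"lrr": lrr, "variance": var, "site_id": sites,
             "mode": ["obligate" if i % 2 else "facultative" for i in range(n)]}
        )

    def test_equal_variances_no_tau_gives_arithmetic_mean(self):
        eff = self._small_effects()
        V = np.eye(len(eff)) * 0.05
        fit = p.MultilevelMetaAnalysis(random_levels=()).fit(eff, V=V)
        assert fit.pooled_lrr_ == pytest.approx(eff["lrr"].mean(), rel=1e-12)

    def test_diagonal_v_no_tau_is_inverse_variance_mean(self):
        eff = self._small_effects()
        V = np.diag(eff["variance"].to_numpy())
        fit = p.MultilevelMetaAnalysis(random_levels=()).fit(eff, V=V)
        w = 1.0 / eff["variance"].to_numpy()
        assert fit.pooled_lrr_ == pytest.approx(
            (w * eff["lrr"]).sum() / w.sum(), rel=1e-12
        )

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_reml_matches_profile_likelihood_grid(self, seed):
        """On <=8-effect instances the optimizer must agree with a brute
        force tau^2 grid (0..2, step 1e-4) to 1e-3."""
        eff = self._small_effects(seed=seed)
        V = np.diag(eff["variance"].to_numpy())
        X = np.ones((len(eff), 1))
        codes = pd.factorize(eff["site_id"])[0]
        Z = np.zeros((len(eff), codes.max() + 1))
        Z[np.arange(len(eff)), codes] = 1.0
        y = eff["lrr"].to_numpy()
        grid = np.arange(0.0, 2.0 + 1e-9, 1e-4)
        lls = np.array([_reml_ll_oracle(t, y, X, V, Z)[0] for t in grid])
        t_star = grid[np.argmax(lls)]
        beta_star = _reml_ll_oracle(t_star, y, X, V, Z)[1][0]
        fit = p.MultilevelMetaAnalysis(random_levels=("site_id",), tau2_max=2.0).fit(
            eff, V=V
        )
        assert fit.tau2_["site_id"] == pytest.approx(t_star, abs=1e-3)
        assert fit.pooled_lrr_ == pytest.approx(beta_star, abs=1e-3)

    def test_wald_single_contrast_equals_z_squared(self):
        eff = self._small_effects(n=8)
        fit = p.MultilevelMetaAnalysis(random_levels=(), moderator="mode").fit(
            eff, V=np.diag(eff["variance"].to_numpy())
        )
        # two-level moderator: QM equals the squared z of the difference
        d = fit.beta_[0] - fit.beta_[1]
        var_d = fit.cov_beta_[0, 0] + fit.cov_beta_[1, 1] - 2 * fit.cov_beta_[0, 1]
        assert fit.moderator_test_["stat"] == pytest.approx(d**2 / var_d, abs=1e-10)
        assert fit.moderator_test_["df"] == 1
        # per-coefficient Wald identity
        assert np.allclose(fit.zvalues_**2, (fit.beta_ / fit.se_) ** 2)

    def test_single_level_moderator_flagged(self):
        eff = self._small_effects().assign(mode="obligate")
        fit = p.MultilevelMetaAnalysis(random_levels=(), moderator="mode").fit(
            eff, V=np.diag(eff["variance"].to_numpy())
        )
        assert fit.moderator_test_["df"] == 0

    def test_sparse_level_estimate_only(self):
        eff = self._small_effects(n=8)
        eff.loc[:, "mode"] = ["obligate"] + ["facultative"] * 7
        fit = p.MultilevelMetaAnalysis(random_levels=(), moderator="mode").fit(
            eff, V=np.diag(eff["variance"].to_numpy())
        )
        assert fit.moderator_test_["df"] == 0
        assert "obligate" in fit.moderator_test_["excluded_levels"]

    def test_too_few_effects_error(self):
        eff = self._small_effects(n=8).iloc[:1]
        with pytest.raises(ValueError):
            p.MultilevelMetaAnalysis(random_levels=()).fit(
                eff, V=np.diag(eff["variance"].to_numpy())
            )

    def test_pooled_invariant_to_response_rescaling(self, effect_config):
        eff, ctrl, _ = p.generate_effect_dataset(effect_config, seed=4)
        fit1 = p.fit_multilevel(eff, controls=ctrl)
        scaled_ctrl = ctrl.assign(mean=ctrl["mean"] * 50, sd=ctrl["sd"] * 50)
        # scaling means and sds leaves lrr and variances untouched
        fit2 = p.fit_multilevel(eff, controls=scaled_ctrl)
        assert fit1.pooled_lrr_ == pytest.approx(fit2.pooled_lrr_, rel=1e-10)

    def test_ci_coverage_of_planted_effect(self, null_substrate):
        """95% CIs for the planted overall effect should cover at the
        nominal rate (within [90%, 99%]) across simulated surveys."""
        cfg = p.GeneratorConfig(
            n_sites=6, experiments_per_site=2,
            effect_obligate=0.231, effect_facultative=0.231,
            substrate_effects=null_substrate, seed=0,
        )
        true_lrr = np.log(1.231)
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            eff, ctrl, _ = p.generate_effect_dataset(cfg, seed=10_000 + i)
            fit = p.fit_multilevel(eff, controls=ctrl)
            lo = fit.pooled_lrr_ - 1.96 * fit.pooled_se_
            hi = fit.pooled_lrr_ + 1.96 * fit.pooled_se_
            hits += lo <= true_lrr <= hi
        coverage = 100.0 * hits / n_rep
        assert 90.0 <= coverage <= 99.0

    def test_moderator_ordering_recovery(self, null_substrate):
        """Planted obligate > facultative ordering is recovered in nearly
        every replicate at survey scale."""
        cfg = p.GeneratorConfig(
            n_sites=8, experiments_per_site=3,
            effect_obligate=0.577, effect_facultative=0.176,
            substrate_effects=null_substrate, seed=0,
        )
        wins = 0
        n_rep = 30
        for i in range(n_rep):
            eff, ctrl, _ = p.generate_effect_dataset(cfg, seed=20_000 + i)
            fit = p.fit_multilevel(eff, controls=ctrl, moderator="mode")
            est = dict(zip(fit.levels_, fit.beta_))
            wins += est["obligate"] > est["facultative"]
        assert wins >= int(0.95 * n_rep)

    def test_substrate_moderator_recovery(self):
        """Substrate strata planted at +19.1% (C) and +38.6% (C+N) above
        the no-substrate predator response are recovered within 2 SEs."""
        cfg = p.GeneratorConfig(
            effect_obligate=0.0, effect_facultative=0.0,
            substrate_effects={"none": 0.0, "C": 0.191, "C+N": 0.386},
            seed=0,
        )
        eff, ctrl, _ = p.generate_effect_dataset(cfg, seed=31)
        fit = p.fit_multilevel(eff, controls=ctrl, moderator="substrate_treatment")
        tab = fit.percent_table().set_index("level")
        for level, target in [("C", 19.1), ("C+N", 38.6), ("none", 0.0)]:
            row = tab.loc[level]
            assert abs(row["percent"] - target) < 2 * row["percent_se"] + 1e-9

    def test_moderator_analysis_bundle(self, effect_config):
        eff, ctrl, _ = p.generate_effect_dataset(effect_config, seed=2)
        fits = p.moderator_analysis(eff, controls=ctrl)
        assert set(fits) == {"overall", "mode", "predator_group", "substrate_treatment"}
        assert fits["mode"].moderator_test_["df"] == 1
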