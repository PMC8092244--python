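"""Multilevel random-effects meta-analysis of log response ratios.

Each effect size is the log ratio of a predator group's mean response
(AFE, growth rate or C uptake) to the nonpredator control mean of the
same experiment:

    lrr = ln(mean_T / mean_C),
    var(lrr) = sd_T^2 / (n_T mean_T^2) + sd_C^2 / (n_C mean_C^2).

Effects computed against the same control share its sampling error; the
covariance between two such effects is the control term
``sd_C^2 / (n_C mean_C^2)``, assembled into a block-diagonal
variance-covariance matrix V.

The model is a multilevel random-effects meta-regression

    y = X beta + sum_l Z_l u_l + e,   e ~ N(0, V),  u_l ~ N(0, tau_l^2 I),

estimated by restricted maximum likelihood (REML) implemented from
first principles: the variance components are profiled numerically and
the fixed effects solved by generalized least squares at each step.
Moderators (trophic mode, predator group, substrate) enter as
cell-means fixed effects; between-level differences are tested by Wald
chi-square.  Pooled log ratios are back-transformed to percent
differences, ``(exp(lrr) - 1) * 100``, with delta-method SEs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator

from .exceptions import MissingControlError

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSummary",
    "EffectSize",
    "effect_from_summaries",
    "effects_from_summary_table",
    "shared_control_covariance",
    "build_v_matrix",
    "MultilevelMetaAnalysis",
    "fit_multilevel",
    "moderator_analysis",
    "percent_difference",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean/SD/N of one group (a predator group or the nonpredator control)."""

    experiment_id: str
    site_id: str
    group: str  # predator group name or "control"
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class EffectSize:
    """One predator:nonpredator log response ratio with its variance."""

    effect_id: str
    lrr: float
    variance: float
    experiment_id: str
    site_id: str
    predator_group: str
    mode: str
    isotope: str = "O18"
    substrate_treatment: str = "none"


def effect_from_summaries(treated: GroupSummary, control: GroupSummary) -> EffectSize:
    """Log response ratio and sampling variance from two group summaries."""
    if treated.mean <= 0 or control.mean <= 0:
        raise ValueError("log response ratio requires positive group means")
    if treated.n < 2 or control.n < 2:
        raise ValueError("variance computation requires n >= 2 in both groups")
    lrr = float(np.log(treated.mean / control.mean))
    variance = treated.sd**2 / (treated.n * treated.mean**2) + control.sd**2 / (
        control.n * control.mean**2
    )
    from .taxonomy import GROUP_MODES

    return EffectSize(
        effect_id=f"{treated.experiment_id}:{treated.group}",
        lrr=lrr,
        variance=float(variance),
        experiment_id=treated.experiment_id,
        site_id=treated.site_id,
        predator_group=treated.group,
        mode=GROUP_MODES.get(treated.group, "none"),
    )


def shared_control_covariance(control: GroupSummary) -> float:
    """Sampling covariance of two log ratios sharing this control group."""
    if control.mean <= 0:
        raise ValueError("control mean must be positive")
    if control.n < 2:
        raise ValueError("control n must be >= 2")
    return float(control.sd**2 / (control.n * control.mean**2))


def effects_from_summary_table(summaries: pd.DataFrame):
    """Effects + controls from a long group-summary table.

    ``summaries`` has one row per group per experiment with columns
    ``experiment_id``, ``site_id``, ``group`` (``"control"`` for the
    nonpredator pool), ``mean``, ``sd``, ``n`` and optional carry-through
    columns (``isotope``, ``substrate_treatment``).  Effects with
    nonpositive means are excluded and tallied.
    """
    effects, controls, n_excluded = [], [], 0
    for exp_id, sub in summaries.groupby("experiment_id", sort=False):
        ctrl_rows = sub[sub["group"] == "control"]
        if len(ctrl_rows) != 1:
            raise MissingControlError(f"experiment {exp_id!r} needs exactly 1 control")
        c = ctrl_rows.iloc[0]
        control = GroupSummary(exp_id, c["site_id"], "control", c["mean"], c["sd"], int(c["n"]))
        if control.mean <= 0:
            n_excluded += len(sub) - 1
            continue
        controls.append(
            {
                "control_id": exp_id,
                "experiment_id": exp_id,
                "site_id": c["site_id"],
                "mean": control.mean,
                "sd": control.sd,
                "n": control.n,
            }
        )
        for _, row in sub[sub["group"] != "control"].iterrows():
            treated = GroupSummary(
                exp_id, row["site_id"], row["group"], row["mean"], row["sd"], int(row["n"])
            )
            try:
                eff = effect_from_summaries(treated, control)
            except ValueError:
                n_excluded += 1
                continue
            rec = {
                "effect_id": eff.effect_id,
                "lrr": eff.lrr,
                "variance": eff.variance,
                "experiment_id": exp_id,
                "site_id": eff.site_id,
                "predator_group": eff.predator_group,
                "mode": eff.mode,
                "control_id": exp_id,
            }
            for col in ("isotope", "substrate_treatment"):
                if col in row.index:
                    rec[col] = row[col]
            effects.append(rec)
    if n_excluded:
        logger.info("excluded %d effects with nonpositive or degenerate means", n_excluded)
    eff_df = pd.DataFrame(effects)
    eff_df.attrs["n_excluded"] = n_excluded
    return eff_df, pd.DataFrame(controls)


def build_v_matrix(effects: pd.DataFrame, controls: pd.DataFrame) -> np.ndarray:
    """Variance-covariance matrix of the effects.

    Diagonal: effect sampling variances.  Off-diagonal: the shared
    control term for effect pairs with the same ``control_id``, zero
    otherwise, so V is block-diagonal by experiment and symmetric PSD.
    """
    n = len(effects)
    v = np.zeros((n, n))
    var = effects["variance"].to_numpy(dtype=float)
    np.fill_diagonal(v, var)
    ctrl = controls.set_index("control_id")
    cov_cache = {}
    control_ids = effects["control_id"].to_numpy()
    for cid in pd.unique(control_ids):
        if cid not in ctrl.index:
            raise MissingControlError(f"control {cid!r} not found")
        c = ctrl.loc[cid]
        cov_cache[cid] = shared_control_covariance(
            GroupSummary(cid, c.get("site_id", ""), "control", c["mean"], c["sd"], int(c["n"]))
        )
        idx = np.flatnonzero(control_ids == cid)
        for i in idx:
            for j in idx:
                if i != j:
                    v[i, j] = cov_cache[cid]
    return v


# ---------------------------------------------------------------------------
# REML machinery


def _indicator(effects: pd.DataFrame, level: str) -> np.ndarray:
    """Indicator matrix for a random level; ``"a:b"`` crosses two columns."""
    cols = level.split(":")
    for c in cols:
        if c not in effects.columns:
            raise ValueError(f"random level column {c!r} not in effects table")
    key = effects[cols[0]].astype(str)
    for c in cols[1:]:
        key = key + ":" + effects[c].astype(str)
    codes, uniques = pd.factorize(key)
    z = np.zeros((len(effects), len(uniques)))
    z[np.arange(len(effects)), codes] = 1.0
    return z


def _reml_nll(tau2: np.ndarray, y, X, V, ZZt_list):
    """Negative restricted log-likelihood at the given variance components."""
    sigma = V.copy()
    for t2, zzt in zip(tau2, ZZt_list):
        sigma += t2 * zzt
    try:
        c, low = linalg.cho_factor(sigma, lower=True)
    except linalg.LinAlgError:
        return np.inf
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(c)))
    sinv_X = linalg.cho_solve((c, low), X)
    sinv_y = linalg.cho_solve((c, low), y)
    xtx = X.T @ sinv_X
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(xtx, X.T @ sinv_y)
    r = y - X @ beta
    quad = float(r @ linalg.cho_solve((c, low), r))
    return 0.5 * (logdet_sigma + logdet_xtx + quad)


def _gls(y, X, sigma):
    c, low = linalg.cho_factor(sigma, lower=True)
    sinv_X = linalg.cho_solve((c, low), X)
    xtx = X.T @ sinv_X
    beta = np.linalg.solve(xtx, X.T @ linalg.cho_solve((c, low), y))
    cov = np.linalg.inv(xtx)
    return beta, cov


def percent_difference(lrr, se=None):
    """Back-transform a log ratio to percent difference with delta-method SE."""
    pct = (np.exp(lrr) - 1.0) * 100.0
    if se is None:
        return pct
    return pct, np.exp(lrr) * np.asarray(se) * 100.0


class MultilevelMetaAnalysis(BaseEstimator):
    """Multilevel random-effects meta-regression estimated by REML.

    Parameters
    ----------
    random_levels : tuple of str
        Column names (or ``"a:b"`` interactions) of the effects table
        defining random-intercept levels, e.g. ``("site_id",)`` or
        ``("site_id", "isotope:site_id")``.
    moderator : str or None
        Column defining cell-means fixed effects; ``None`` fits a single
        pooled intercept.
    tau2_max : float
        Upper bound of each variance component during optimization.
    tol, max_iter : float, int
        Optimizer tolerance and iteration cap.

    Fitted attributes (trailing underscore) include ``beta_``, ``se_``,
    ``tau2_``, ``levels_``, ``pooled_lrr_``, ``percent_difference_``,
    ``moderator_test_`` and ``n_effects_``.
    """

    def __init__(
        self,
        random_levels=("site_id",),
        moderator=None,
        tau2_max=5.0,
        tol=1e-8,
        max_iter=500,
    ):
        self.random_levels = random_levels
        self.moderator = moderator
        self.tau2_max = tau2_max
        self.tol = tol
        self.max_iter = max_iter

    # -- design construction ------------------------------------------------
    def _design(self, effects: pd.DataFrame):
        if self.moderator is None:
            X = np.ones((len(effects), 1))
            levels = ["pooled"]
        else:
            if self.moderator not in effects.columns:
                raise ValueError(f"moderator column {self.moderator!r} missing")
            codes, uniques = pd.factorize(effects[self.moderator], sort=True)
            X = np.zeros((len(effects), len(uniques)))
            X[np.arange(len(effects)), codes] = 1.0
            levels = list(uniques)
        return X, levels

    def fit(self, effects: pd.DataFrame, V: np.ndarray | None = None, controls=None):
        """Fit the model to an effects table.

        ``effects`` needs ``lrr`` and ``variance`` columns plus whatever
        columns the random levels and moderator reference.  ``V`` may be
        given directly, or built from ``controls`` (see
        :func:`build_v_matrix`); otherwise V is diagonal.
        """
        effects = effects.reset_index(drop=True)
        y = effects["lrr"].to_numpy(dtype=float)
        n = len(y)
        if V is None:
            if controls is not None:
                V = build_v_matrix(effects, controls)
            else:
                V = np.diag(effects["variance"].to_numpy(dtype=float))
        V = np.asarray(V, dtype=float)
        if V.shape != (n, n):
            raise ValueError("V must be n x n")
        X, levels = self._design(effects)
        p = X.shape[1]
        if n <= p:
            raise ValueError("more fixed-effect coefficients than effects")
        Zs = [_indicator(effects, lv) for lv in self.random_levels]
        ZZt = [z @ z.T for z in Zs]
        k = len(ZZt)

        if k == 0:
            tau2 = np.array([])
            converged = True
        else:
            nll = lambda t2: _reml_nll(t2, y, X, V, ZZt)
            # coarse grid seed, then bounded quasi-Newton polish
            grid = np.concatenate([[0.0], np.geomspace(1e-6, self.tau2_max, 40)])
            if k == 1:
                starts = [np.array([g]) for g in grid]
                vals = [nll(s) for s in starts]
                x0 = starts[int(np.argmin(vals))]
            else:
                cands = [np.full(k, g) for g in [0.0, 1e-4, 1e-2, 0.1, 1.0]]
                x0 = min(cands, key=nll)
            res = optimize.minimize(
                nll,
                x0,
                method="L-BFGS-B",
                bounds=[(0.0, self.tau2_max)] * k,
                options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-10},
            )
            tau2 = np.maximum(res.x, 0.0)
            converged = bool(res.success)
            if not converged:
                logger.warning("REML optimizer did not report convergence: %s", res.message)

        sigma = V.copy()
        for t2, zzt in zip(tau2, ZZt):
            sigma += t2 * zzt
        beta, cov = _gls(y, X, sigma)
        se = np.sqrt(np.diag(cov))

        self.effects_ = effects
        self.levels_ = levels
        self.beta_ = beta
        self.cov_beta_ = cov
        self.se_ = se
        self.tau2_ = dict(zip(self.random_levels, tau2))
        self.converged_ = converged
        self.n_effects_ = n
        self.restricted_loglik_ = -_reml_nll(tau2, y, X, V, ZZt) if k else -_reml_nll(
            np.array([]), y, X, V, []
        )
        self.V_ = V

        pct, pct_se = percent_difference(beta, se)
        self.percent_difference_ = pct
        self.percent_se_ = pct_se
        if self.moderator is None:
            self.pooled_lrr_ = float(beta[0])
            self.pooled_se_ = float(se[0])
        self.zvalues_ = beta / se
        self.pvalues_ = 2.0 * stats.norm.sf(np.abs(self.zvalues_))
        self.moderator_test_ = self._wald_equal_levels(effects)
        return self

    def _wald_equal_levels(self, effects):
        """Wald chi-square test that all moderator levels share one mean.

        Levels with fewer than 2 effects are reported estimate-only and
        excluded from the test.
        """
        if self.moderator is None:
            return None
        counts = effects[self.moderator].value_counts()
        testable = [i for i, lv in enumerate(self.levels_) if counts.get(lv, 0) >= 2]
        sparse = [lv for lv in self.levels_ if counts.get(lv, 0) < 2]
        if sparse:
            logger.info("moderator levels excluded from test (<2 effects): %s", sparse)
        if len(testable) < 2:
            return {"stat": np.nan, "df": 0, "p": np.nan, "excluded_levels": sparse}
        L = np.zeros((len(testable) - 1, len(self.levels_)))
        for row, idx in enumerate(testable[1:]):
            L[row, testable[0]] = 1.0
            L[row, idx] = -1.0
        est = L @ self.beta_
        cov = L @ self.cov_beta_ @ L.T
        stat = float(est @ np.linalg.solve(cov, est))
        df = L.shape[0]
        return {
            "stat": stat,
            "df": df,
            "p": float(stats.chi2.sf(stat, df)),
            "excluded_levels": sparse,
        }

    def percent_table(self) -> pd.DataFrame:
        """Per-level back-transformed percent differences with SEs and p-values."""
        return pd.DataFrame(
            {
                "level": self.levels_,
                "lrr": self.beta_,
                "se": self.se_,
                "percent": self.percent_difference_,
                "percent_se": self.percent_se_,
                "p": self.pvalues_,
            }
        )

    def summary(self) -> str:
        lines = [
            f"Multilevel meta-analysis (REML), n = {self.n_effects_} effects",
            "tau2: "
            + ", ".join(f"{k} = {v:.5f}" for k, v in self.tau2_.items()),
        ]
        for _, row in self.percent_table().iterrows():
            lines.append(
                f"  {row['level']}: {row['percent']:+.1f} ± {row['percent_se']:.1f} % "
                f"(lrr {row['lrr']:+.4f} ± {row['se']:.4f}, p = {row['p']:.4g})"
            )
        if self.moderator_test_ is not None and self.moderator_test_["df"] > 0:
            mt = self.moderator_test_
            lines.append(
                f"  moderator test: QM = {mt['stat']:.3f}, df = {mt['df']}, p = {mt['p']:.4g}"
            )
        return "\n".join(lines)


def fit_multilevel(
    effects: pd.DataFrame,
    V: np.ndarray | None = None,
    random_levels=("site_id",),
    moderator=None,
    controls=None,
) -> MultilevelMetaAnalysis:
    """Functional wrapper over :class:`MultilevelMetaAnalysis`."""
    return MultilevelMetaAnalysis(
        random_levels=random_levels, moderator=moderator
    ).fit(effects, V=V, controls=controls)


def moderator_analysis(
    effects: pd.DataFrame,
    V: np.ndarray | None = None,
    moderators=("mode", "predator_group", "substrate_treatment"),
    random_levels=("site_id",),
    controls=None,
) -> dict:
    """Fit one model per requested moderator, plus the overall pooled model."""
    fits = {
        "overall": fit_multilevel(
            effects, V, random_levels=random_levels, controls=controls
        )
    }
    for mod in moderators:
        if mod not in effects.columns:
            logger.warning("moderator column %r missing; skipped", mod)
            continue
        fits[mod] = fit_multilevel(
            effects, V, random_levels=random_levels, moderator=mod, controls=controls
        )
    return fits
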