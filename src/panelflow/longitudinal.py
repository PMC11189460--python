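"""Conditional growth models for repeated biomarker measurements.

A conditional growth model is a linear mixed-effects model of a response
(protein ratio or clinical score) against time since each subject's
baseline visit, with per-subject random intercepts and random slopes:

    y_ij = β0 + β1·t_ij + b0_i + b1_i·t_ij + ε_ij,
    (b0_i, b1_i) ~ N(0, Ψ),  ε_ij ~ N(0, σ²)

Estimates come from REML; the fixed-slope p-value comes from a
likelihood-ratio test of β1 = 0 with both fits under full ML (REML
likelihoods are not comparable across fixed-effect structures).  A
singular 2×2 random-effect covariance triggers a flagged refit with
independent (diagonal) random effects.  Screening many responses applies
Benjamini–Hochberg across their slope p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .stats import benjamini_hochberg

__all__ = ["GrowthFit", "ConditionalGrowthModel", "fit_growth_model", "lmm_screen"]


class GrowthModelError(RuntimeError):
    pass


@dataclass
class GrowthFit:
    """Fitted conditional growth model for one response."""

    response_id: str
    fixed_intercept: float
    fixed_slope: float
    var_random_intercept: float
    var_random_slope: float
    cov_int_slope: float
    var_residual: float
    slope_p: float
    n_subjects: int
    n_observations: int
    converged: bool
    flags: list[str]

    def summary(self) -> str:
        return "\n".join(
            [
                f"Conditional growth model: {self.response_id}",
                "-" * 40,
                f"n subjects / observations: {self.n_subjects} / {self.n_observations}",
                f"fixed intercept (β0):      {self.fixed_intercept:.4f}",
                f"fixed slope (β1, /year):   {self.fixed_slope:.4f}",
                f"slope LRT p:               {self.slope_p:.4g}",
                f"var(random intercept):     {self.var_random_intercept:.4f}",
                f"var(random slope):         {self.var_random_slope:.4f}",
                f"cov(intercept, slope):     {self.cov_int_slope:.4f}",
                f"var(residual):             {self.var_residual:.4f}",
                f"converged: {self.converged}  flags: {self.flags or 'none'}",
            ]
        )


def _diag_free(k_fe: int) -> MixedLMParams:
    """Free-parameter mask fixing the random-effect covariance to diagonal."""
    return MixedLMParams.from_components(
        fe_params=np.ones(k_fe), cov_re=np.eye(2)
    )


def _fit_mixed(model: MixedLM, reml: bool, free: MixedLMParams | None = None):
    """L-BFGS fit with a Powell polish when the solution sits on the
    boundary of the variance parameter space (a common, benign outcome
    when a random-effect variance is truly ~0)."""
    res = model.fit(reml=reml, method="lbfgs", free=free)
    if not res.converged:
        polished = model.fit(reml=reml, method="powell", free=free, maxiter=2000)
        if np.isfinite(polished.llf) and polished.llf >= res.llf - 1e-8:
            res = polished
    return res


class ConditionalGrowthModel:
    """Specification of a random-intercept/random-slope growth model.

    Parameters
    ----------
    data : long-format DataFrame.
    response, subject, time : column names; ``time`` is years since the
        subject's own baseline (non-negative).
    """

    def __init__(self, data: pd.DataFrame, response: str, subject: str = "subject_id",
                 time: str = "years_since_baseline", min_subjects: int = 5):
        cols = [subject, time, response]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise KeyError(f"missing columns: {missing}")
        d = data[cols].dropna().copy()
        d.columns = ["subject", "time", "y"]
        d["time"] = d["time"].astype(float)
        if (d["time"] < 0).any():
            raise ValueError("time since baseline must be non-negative")
        n_subj = d["subject"].nunique()
        if n_subj < min_subjects:
            raise ValueError(f"need >= {min_subjects} subjects, got {n_subj}")
        self.data = d
        self.response = response
        visits = d.groupby("subject")["time"].nunique()
        self.degenerate_slopes = bool((visits < 2).all())

    def fit(self) -> GrowthFit:
        d = self.data
        flags: list[str] = []
        if self.degenerate_slopes:
            # one timepoint per subject: the random slope is inestimable
            flags.append("degenerate_single_timepoint")
            return self._intercept_only_fit(flags)

        exog = np.column_stack([np.ones(len(d)), d["time"].to_numpy()])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = MixedLM(d["y"].to_numpy(), exog, groups=d["subject"].to_numpy(),
                            exog_re=exog)
            try:
                res = _fit_mixed(model, reml=True)
            except Exception as exc:  # noqa: BLE001 — surfaced as diagnostics
                raise GrowthModelError(f"REML fit failed for {self.response}: {exc}") from exc

            cov_re = np.asarray(res.cov_re)
            if self._is_singular(cov_re):
                flags.append("singular_fallback")
                res = _fit_mixed(model, reml=True, free=_diag_free(2))
                cov_re = np.asarray(res.cov_re)

            slope_p = self._slope_lrt(d, exog, diagonal="singular_fallback" in flags)

        return GrowthFit(
            response_id=self.response,
            fixed_intercept=float(res.fe_params[0]),
            fixed_slope=float(res.fe_params[1]),
            var_random_intercept=float(cov_re[0, 0]),
            var_random_slope=float(cov_re[1, 1]),
            cov_int_slope=float(cov_re[0, 1]),
            var_residual=float(res.scale),
            slope_p=slope_p,
            n_subjects=int(d["subject"].nunique()),
            n_observations=len(d),
            converged=bool(res.converged),
            flags=flags,
        )

    @staticmethod
    def _is_singular(cov_re: np.ndarray, tol: float = 1e-8) -> bool:
        eig = np.linalg.eigvalsh(cov_re)
        if eig[0] < tol * max(eig[-1], 1.0):
            return True
        denom = np.sqrt(cov_re[0, 0] * cov_re[1, 1])
        return bool(denom > 0 and abs(cov_re[0, 1]) / denom > 0.999)

    def _slope_lrt(self, d: pd.DataFrame, exog_full: np.ndarray, diagonal: bool) -> float:
        """LRT of β1 = 0: full vs intercept-only fixed effects, both under ML."""
        groups = d["subject"].to_numpy()
        y = d["y"].to_numpy()
        free_full = _diag_free(2) if diagonal else None
        free_null = _diag_free(1) if diagonal else None
        full = _fit_mixed(
            MixedLM(y, exog_full, groups=groups, exog_re=exog_full),
            reml=False, free=free_full,
        )
        null = _fit_mixed(
            MixedLM(y, exog_full[:, :1], groups=groups, exog_re=exog_full),
            reml=False, free=free_null,
        )
        lr = max(0.0, 2.0 * (full.llf - null.llf))
        return float(sps.chi2.sf(lr, df=1))

    def _intercept_only_fit(self, flags: list[str]) -> GrowthFit:
        """Random-intercept-only fallback when slopes are unidentifiable."""
        d = self.data
        time_varies = d["time"].nunique() > 1
        if time_varies:
            exog = np.column_stack([np.ones(len(d)), d["time"].to_numpy()])
        else:
            # no temporal spread at all: the fixed slope is inestimable too
            exog = np.ones((len(d), 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(d["y"].to_numpy(), exog, groups=d["subject"].to_numpy())
            res = _fit_mixed(model, reml=True)
            if time_varies:
                full = _fit_mixed(
                    MixedLM(d["y"].to_numpy(), exog, groups=d["subject"].to_numpy()),
                    reml=False,
                )
                null = _fit_mixed(
                    MixedLM(d["y"].to_numpy(), exog[:, :1], groups=d["subject"].to_numpy()),
                    reml=False,
                )
                lr = max(0.0, 2.0 * (full.llf - null.llf))
                slope_p = float(sps.chi2.sf(lr, df=1))
                slope = float(res.fe_params[1])
            else:
                slope_p, slope = float("nan"), float("nan")
        return GrowthFit(
            response_id=self.response,
            fixed_intercept=float(res.fe_params[0]),
            fixed_slope=slope,
            var_random_intercept=float(np.asarray(res.cov_re)[0, 0]),
            var_random_slope=float("nan"),
            cov_int_slope=float("nan"),
            var_residual=float(res.scale),
            slope_p=slope_p,
            n_subjects=int(d["subject"].nunique()),
            n_observations=len(d),
            converged=bool(res.converged),
            flags=flags,
        )


def fit_growth_model(
    data: pd.DataFrame,
    response: str,
    subject: str = "subject_id",
    time: str = "years_since_baseline",
) -> GrowthFit:
    """Fit one conditional growth model (see :class:`ConditionalGrowthModel`)."""
    return ConditionalGrowthModel(data, response, subject=subject, time=time).fit()


def lmm_screen(
    data: pd.DataFrame,
    responses: list[str],
    subject: str = "subject_id",
    time: str = "years_since_baseline",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit a growth model per response and BH-adjust the slope p-values.

    Per-response fit failures are recorded (``error`` column) and the
    screen continues; BH runs across the successful fits only.
    """
    if not responses:
        raise ValueError("no responses given")
    rows = []
    for resp in responses:
        try:
            fit = fit_growth_model(data, resp, subject=subject, time=time)
            rows.append(
                {
                    "response_id": resp,
                    "fixed_intercept": fit.fixed_intercept,
                    "fixed_slope": fit.fixed_slope,
                    "slope_p": fit.slope_p,
                    "var_random_intercept": fit.var_random_intercept,
                    "var_random_slope": fit.var_random_slope,
                    "var_residual": fit.var_residual,
                    "n_subjects": fit.n_subjects,
                    "n_observations": fit.n_observations,
                    "converged": fit.converged,
                    "flags": ",".join(fit.flags),
                    "error": "",
                }
            )
        except Exception as exc:  # noqa: BLE001 — screen must continue
            rows.append({"response_id": resp, "slope_p": np.nan, "error": str(exc)})
    df = pd.DataFrame(rows)
    df["slope_p_adjusted"] = np.nan
    df["significant"] = False
    ok = df["slope_p"].notna()
    if ok.any():
        rej, adj = benjamini_hochberg(df.loc[ok, "slope_p"].to_numpy(), alpha)
        df.loc[ok, "slope_p_adjusted"] = adj
        df.loc[ok, "significant"] = rej
    return df
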