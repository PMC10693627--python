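"""Longitudinal mixed-effects outcome models.

Gaussian models: outcome ~ 1 + week + z with per-subject random
intercept and week slope (unstructured 2x2 covariance), REML via
statsmodels MixedLM, Wald p-values, automatic fallback to a random
intercept-only fit and finally pooled OLS on failure.

Binomial models: logistic mixed model with the same fixed/random
structure, fitted by direct maximization of the Laplace-approximate
marginal likelihood (vectorized inner Newton over subjects).

``run_regionwise`` fits one model per region (or one on the mean
regional z) and applies Benjamini-Hochberg across the regional
z-coefficient p-values, excluding non-converged fits from the family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize

from .errors import ValidationError
from .normative import DeviationMatrix
from .stats import bh_adjust

__all__ = ["LMEResult", "fit_gaussian_lmm", "fit_binomial_glmm", "run_regionwise"]

logger = logging.getLogger(__name__)

FIXED_NAMES = ("intercept", "week", "z")
SEPARATION_BOUND = 15.0


@dataclass
class LMEResult:
    """Fixed effects with SEs/p-values plus random-effect variance estimates."""

    family: str
    coef: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    re_intercept_sd: float
    re_slope_sd: float
    re_corr: float
    resid_sd: float
    converged: bool
    fallback: str | None = None
    or_z: float | None = None
    n_subjects: int = 0
    n_obs: int = 0
    extras: dict = field(default_factory=dict)

    def ci95(self, name: str) -> tuple[float, float]:
        c, s = self.coef[name], self.se[name]
        return c - 1.96 * s, c + 1.96 * s


def _prepare(data: pd.DataFrame, outcome: str) -> pd.DataFrame:
    needed = ["subject_id", "week", outcome, "z"]
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValidationError(f"long-format table missing columns: {missing}")
    d = data[needed].dropna().copy()
    if d.empty:
        raise ValidationError("no complete-case rows in long-format table")
    per_subj = d.groupby("subject_id")["z"].nunique()
    if (per_subj > 1).any():
        bad = per_subj.index[per_subj > 1].tolist()[:5]
        raise ValidationError(f"baseline predictor varies within subjects: {bad}")
    if d.groupby("subject_id")["z"].first().nunique() == 1:
        raise ValidationError("singular design: baseline predictor constant across subjects")
    return d


def fit_gaussian_lmm(
    data: pd.DataFrame, outcome: str = "outcome", random_effects: str = "full"
) -> LMEResult:
    """Gaussian linear mixed model of a longitudinal outcome.

    ``random_effects``: "full" (intercept + week slope), "intercept", or
    "none" (pooled OLS; useful as the zero-variance limit).
    """
    d = _prepare(data, outcome)
    y = d[outcome].to_numpy(dtype=float)
    week_raw = d["week"].to_numpy(float)
    # fit on unit-scaled weeks (much better conditioned), report per week
    wscale = float(np.abs(week_raw).max()) or 1.0
    week = week_raw / wscale
    X = np.column_stack([np.ones(len(d)), week, d["z"].to_numpy(float)])
    groups = d["subject_id"].to_numpy()
    n_subjects = d["subject_id"].nunique()
    if n_subjects < 30:
        warnings.warn(f"only {n_subjects} subjects; mixed-model estimates may be unstable",
                      stacklevel=2)

    def package(fe, bse, pv, re_i, re_s, re_c, sd, conv, fb):
        fe = np.asarray(fe, dtype=float).copy()
        bse = np.asarray(bse, dtype=float).copy()
        fe[1] /= wscale
        bse[1] /= wscale
        re_s /= wscale
        return LMEResult(
            family="gaussian",
            coef=dict(zip(FIXED_NAMES, map(float, fe))),
            se=dict(zip(FIXED_NAMES, map(float, bse))),
            pvalues=dict(zip(FIXED_NAMES, map(float, pv))),
            re_intercept_sd=re_i, re_slope_sd=re_s, re_corr=re_c,
            resid_sd=sd, converged=conv, fallback=fb,
            n_subjects=n_subjects, n_obs=len(d),
        )

    def try_mixed(exog_re, label):
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
            for opt in ("lbfgs", "bfgs", "cg", "powell"):
                try:
                    res = model.fit(reml=True, method=opt)
                except Exception:
                    continue
                if res.converged:
                    break
        if res is None or not res.converged:
            raise RuntimeError(f"{label} fit did not converge")
        cov = np.atleast_2d(np.asarray(res.cov_re))
        re_i = float(np.sqrt(max(cov[0, 0], 0.0)))
        re_s = float(np.sqrt(max(cov[1, 1], 0.0))) if cov.shape[0] > 1 else 0.0
        re_c = (
            float(cov[0, 1] / (re_i * re_s)) if cov.shape[0] > 1 and re_i > 0 and re_s > 0 else 0.0
        )
        return package(res.fe_params, res.bse[:3], res.pvalues[:3], re_i, re_s, re_c,
                       float(np.sqrt(res.scale)), True, None)

    if random_effects == "full":
        exog_re = np.column_stack([np.ones(len(d)), week])
        try:
            return try_mixed(exog_re, "random-slope")
        except Exception:
            logger.info("random-slope LMM failed; falling back to random intercept")
        random_effects = "intercept"
        fallback = "intercept_only"
    else:
        fallback = None

    if random_effects == "intercept":
        try:
            res = try_mixed(np.ones((len(d), 1)), "random-intercept")
            res.converged = fallback is None
            res.fallback = fallback
            return res
        except Exception:
            logger.info("random-intercept LMM failed; falling back to OLS")
            fallback = "ols"
    elif random_effects != "none":
        raise ValidationError(f"unknown random_effects option {random_effects!r}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ols = sm.OLS(y, X).fit()
    res = package(ols.params, ols.bse, ols.pvalues, 0.0, 0.0, 0.0,
                  float(np.sqrt(ols.scale)), random_effects == "none", fallback)
    return res


# ---------------------------------------------------------------------------
# Laplace-approximate logistic mixed model
# ---------------------------------------------------------------------------


def _pad_by_subject(d: pd.DataFrame, outcome: str):
    """Stack per-subject visits into padded (n_subjects, max_visits) arrays."""
    subjects = d["subject_id"].drop_duplicates().to_numpy()
    groups = [d[d["subject_id"] == s] for s in subjects]
    J = max(len(g) for g in groups)
    n = len(groups)
    y = np.zeros((n, J))
    week = np.zeros((n, J))
    zval = np.zeros(n)
    m = np.zeros((n, J))
    for i, g in enumerate(groups):
        k = len(g)
        y[i, :k] = g[outcome].to_numpy(dtype=float)
        week[i, :k] = g["week"].to_numpy(dtype=float)
        zval[i] = float(g["z"].iloc[0])
        m[i, :k] = 1.0
    return subjects, y, week, zval, m


def _laplace_nll(theta, y, week, zval, m, newton_iter=40):
    """Negative Laplace-approximate marginal log-likelihood."""
    beta = theta[:3]
    # clamp the Cholesky parameters so line searches cannot make Sigma singular
    t3 = float(np.clip(theta[3], -8.0, 5.0))
    t4 = float(np.clip(theta[4], -50.0, 50.0))
    t5 = float(np.clip(theta[5], -8.0, 5.0))
    L = np.array([[np.exp(t3), 0.0], [t4, np.exp(t5)]])
    Sigma = L @ L.T
    P = np.linalg.inv(Sigma + 1e-10 * np.eye(2))
    logdet_sigma = 2.0 * (t3 + t5)

    n, J = y.shape
    eta0 = beta[0] + beta[1] * week + beta[2] * zval[:, None]
    b = np.zeros((n, 2))
    for _ in range(newton_iter):
        eta = eta0 + b[:, 0:1] + b[:, 1:2] * week
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = m * p * (1.0 - p) + 1e-12 * m
        r = m * (y - p)
        g0 = r.sum(axis=1) - (P[0, 0] * b[:, 0] + P[0, 1] * b[:, 1])
        g1 = (r * week).sum(axis=1) - (P[1, 0] * b[:, 0] + P[1, 1] * b[:, 1])
        h00 = w.sum(axis=1) + P[0, 0]
        h01 = (w * week).sum(axis=1) + P[0, 1]
        h11 = (w * week**2).sum(axis=1) + P[1, 1]
        det = h00 * h11 - h01**2
        db0 = (h11 * g0 - h01 * g1) / det
        db1 = (h00 * g1 - h01 * g0) / det
        b[:, 0] += db0
        b[:, 1] += db1
        if max(np.abs(db0).max(), np.abs(db1).max()) < 1e-10:
            break

    eta = eta0 + b[:, 0:1] + b[:, 1:2] * week
    eta_c = np.clip(eta, -35, 35)
    ll_obs = (m * (y * eta_c - np.logaddexp(0.0, eta_c))).sum(axis=1)
    quad = P[0, 0] * b[:, 0] ** 2 + 2 * P[0, 1] * b[:, 0] * b[:, 1] + P[1, 1] * b[:, 1] ** 2
    p = 1.0 / (1.0 + np.exp(-eta_c))
    w = m * p * (1.0 - p) + 1e-12 * m
    h00 = w.sum(axis=1) + P[0, 0]
    h01 = (w * week).sum(axis=1) + P[0, 1]
    h11 = (w * week**2).sum(axis=1) + P[1, 1]
    logdet_h = np.log(h00 * h11 - h01**2)
    ll = ll_obs - 0.5 * quad - 0.5 * logdet_sigma - 0.5 * logdet_h
    return -ll.sum()


def _numeric_hessian(f, x, h=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    return H


def fit_binomial_glmm(data: pd.DataFrame, outcome: str = "outcome") -> LMEResult:
    """Logistic mixed model (random intercept + week slope) via Laplace.

    Reports the odds ratio per unit of the baseline predictor as
    exp(z coefficient).  Complete separation is flagged with an
    infinite-coefficient sentinel rather than raised.
    """
    d = _prepare(data, outcome)
    yvals = d[outcome].astype(float)
    if not set(np.unique(yvals)).issubset({0.0, 1.0}):
        raise ValidationError("binomial outcome must be boolean/0-1")
    if yvals.nunique() < 2:
        raise ValidationError("binomial outcome has a single class")
    subjects, y, week, zval, m = _pad_by_subject(d, outcome)
    n_subjects = len(subjects)
    if n_subjects < 30:
        warnings.warn(f"only {n_subjects} subjects; mixed-model estimates may be unstable",
                      stacklevel=2)

    # pooled logistic warm start
    X = np.column_stack([np.ones(len(d)), d["week"], d["z"]]).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            beta0 = sm.GLM(yvals.to_numpy(), X, family=sm.families.Binomial()).fit().params
        except Exception:
            beta0 = np.zeros(3)
    if np.abs(beta0).max() > SEPARATION_BOUND:
        beta0 = np.clip(beta0, -2, 2)

    theta0 = np.r_[beta0, np.log(0.5), 0.0, np.log(0.02)]
    nll = lambda th: _laplace_nll(th, y, week, zval, m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        opt = minimize(nll, theta0, method="BFGS",
                       options={"maxiter": 300, "gtol": 1e-6})
    theta = opt.x
    beta = theta[:3]
    L = np.array([[np.exp(np.clip(theta[3], -8.0, 5.0)), 0.0],
                  [np.clip(theta[4], -50.0, 50.0), np.exp(np.clip(theta[5], -8.0, 5.0))]])
    Sigma = L @ L.T
    re_i = float(np.sqrt(Sigma[0, 0]))
    re_s = float(np.sqrt(Sigma[1, 1]))
    re_c = float(Sigma[0, 1] / (re_i * re_s)) if re_i > 0 and re_s > 0 else 0.0

    separated = bool(np.abs(beta).max() > SEPARATION_BOUND)
    se = np.full(3, np.nan)
    pv = np.full(3, np.nan)
    if not separated:
        # conditional observed information for the fixed effects (variance
        # parameters held at their estimates), as in standard GLMM practice
        def nll_beta(b):
            return nll(np.r_[b, theta[3:]])

        try:
            H = _numeric_hessian(nll_beta, beta)
            cov = np.linalg.inv(H)
            diag = np.diag(cov)
            if np.all(diag > 0):
                se = np.sqrt(diag)
                from scipy.stats import norm as _norm
                pv = 2.0 * _norm.sf(np.abs(beta) / se)
        except np.linalg.LinAlgError:
            pass

    coef = dict(zip(FIXED_NAMES, map(float, beta)))
    if separated:
        coef = {k: float(np.sign(v) * np.inf) if abs(v) > SEPARATION_BOUND else v
                for k, v in coef.items()}
    converged = bool(opt.success or opt.status == 2) and not separated and np.all(np.isfinite(se))
    return LMEResult(
        family="binomial",
        coef=coef,
        se=dict(zip(FIXED_NAMES, map(float, se))),
        pvalues=dict(zip(FIXED_NAMES, map(float, pv))),
        re_intercept_sd=re_i, re_slope_sd=re_s, re_corr=re_c,
        resid_sd=np.nan,
        converged=converged,
        or_z=float(np.exp(coef["z"])) if np.isfinite(coef["z"]) else float("inf"),
        n_subjects=n_subjects, n_obs=len(d),
    )


# ---------------------------------------------------------------------------
# region-wise driver
# ---------------------------------------------------------------------------

OUTCOME_COLUMNS = ("negative", "positive", "general", "remission_score", "remission_status")


def run_regionwise(
    z: DeviationMatrix,
    clinical: pd.DataFrame,
    outcome: str = "negative",
    family: str = "auto",
    alpha: float = 0.05,
    predictor: str = "regional",
    regions: list[str] | None = None,
) -> pd.DataFrame:
    """One mixed model per region (or one on the mean regional z).

    ``clinical`` must be a scored table (see :func:`normdev.clinical.score_panss`)
    sharing subjects with ``z``.  BH correction runs across the regional
    z-coefficient p-values of converged fits only.
    """
    if outcome not in OUTCOME_COLUMNS:
        raise ValidationError(f"outcome must be one of {OUTCOME_COLUMNS}, got {outcome!r}")
    if outcome not in clinical.columns:
        raise ValidationError(f"clinical table lacks outcome column {outcome!r}")
    if predictor not in ("regional", "mean"):
        raise ValidationError(f"predictor must be 'regional' or 'mean', got {predictor!r}")
    if family == "auto":
        family = "binomial" if outcome == "remission_status" else "gaussian"

    shared = z.z.index.intersection(pd.Index(clinical["subject_id"].unique()))
    if len(shared) < 2:
        raise ValidationError("fewer than 2 subjects shared between z matrix and clinical table")
    clin = clinical[clinical["subject_id"].isin(shared)][["subject_id", "week", outcome]].copy()
    if outcome == "remission_status":
        clin[outcome] = clin[outcome].astype("boolean").astype("Float64").astype(float)
    clin = clin.dropna()

    if predictor == "mean":
        region_preds = {"mean_z": z.z.loc[shared].mean(axis=1)}
    else:
        cols = regions if regions is not None else list(z.z.columns)
        region_preds = {r: z.z.loc[shared, r] for r in cols}

    fit = fit_binomial_glmm if family == "binomial" else fit_gaussian_lmm
    rows = []
    for region, pred in region_preds.items():
        long = clin.merge(
            pred.rename("z"), left_on="subject_id", right_index=True, how="inner"
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fit(long.rename(columns={outcome: "outcome"}), outcome="outcome")
        except ValidationError:
            raise
        except Exception as exc:  # keep the region, flag the failure
            logger.warning("region %s: fit failed (%s)", region, exc)
            rows.append({"region_id": region, "coef_time": np.nan, "coef_z": np.nan,
                         "se_z": np.nan, "p_z": np.nan, "converged": False, "or_z": np.nan})
            continue
        rows.append(
            {
                "region_id": region,
                "coef_time": res.coef["week"],
                "coef_z": res.coef["z"],
                "se_z": res.se["z"],
                "p_z": res.pvalues["z"],
                "converged": res.converged,
                "or_z": res.or_z if family == "binomial" else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    usable = out["converged"] & np.isfinite(out["p_z"]) & (out["p_z"] > 0)
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("%d region fits excluded from the BH family", n_excluded)
    out["p_z_adj"] = np.nan
    out["significant"] = False
    if usable.any():
        adj, rej = bh_adjust(out.loc[usable, "p_z"].to_numpy(), alpha=alpha)
        out.loc[usable, "p_z_adj"] = adj
        out.loc[usable, "significant"] = rej
    out.attrs["n_excluded_from_bh"] = n_excluded
    out.attrs["family"] = family
    out.attrs["outcome"] = outcome
    return out
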