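"""Finlay-Wilkinson reaction-norm regression per trait and trial location.

The model is ``y_ij = mu + g_i + (1 + b_i) h_j + eps_ij`` where environments
``j`` are the sowing stages of one location.  The slope ``1 + b_i`` measures
the responsiveness of hybrid ``i`` to the environmental gradient: slope 1
(``b = 0``) is average responsiveness, ``b < 0`` a more stable hybrid.

Identifiability is fixed by the unweighted constraints ``sum_j h_j = 0`` and
``sum_i b_i = 0``.  Two fitters are provided:

* :func:`fit_fw_als` — deterministic alternating least squares.  Each sweep
  solves the per-hybrid regressions ``(mu, g, b | h)`` and the per-environment
  update ``(h | mu, g, b)`` exactly, then renormalises within the invariance
  group of the model (which leaves the objective unchanged), so the objective
  is non-increasing across iterations.
* :func:`fit_fw_gibbs` — a Gibbs sampler over the hierarchical version with
  independent normal priors on g, b, h and scaled-inverse-chi-square priors
  on their variances; posterior means are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (ConflictError, InsufficientDataError, ParameterError)

logger = logging.getLogger(__name__)


@dataclass
class FWFit:
    """Fitted reaction-norm decomposition for one trait in one location."""

    trait_name: str
    location_id: str
    mu: float
    g: pd.Series                  # per-hybrid main effect (trait units)
    h: pd.Series                  # per-environment effect (trait units)
    b: pd.Series                  # per-hybrid plasticity deviation (unitless)
    resid_var: float
    n_env_used: int
    method: str                   # "ALS" | "Gibbs"
    n_iter: int = 0
    converged: bool = True
    degenerate: bool = False      # no environmental signal; b forced to 0
    objective: float = np.nan
    grad_norm: float = np.nan
    dropped_hybrids: list[str] = field(default_factory=list)

    @property
    def slope(self) -> pd.Series:
        return 1.0 + self.b


def _pivot_one_cell(pheno: pd.DataFrame, min_env: int):
    """Validate single (trait, location) input and pivot to hybrid x sowing."""
    traits = pheno["trait_name"].unique()
    locs = pheno["location_id"].unique()
    if len(traits) != 1 or len(locs) != 1:
        raise ParameterError(
            "expected records for exactly one trait and one location, got "
            f"traits={list(traits)} locations={list(locs)}")
    Y = pheno.pivot_table(index="hybrid_id", columns="sowing_index",
                          values="value", aggfunc="first")
    n_obs = Y.notna().sum(axis=1)
    dropped = Y.index[n_obs < min_env].tolist()
    if dropped:
        logger.info("FW %s/%s: dropping %d hybrids with < %d sowings",
                    traits[0], locs[0], len(dropped), min_env)
    Y = Y.loc[n_obs >= min_env]
    if len(Y) < 2:
        raise InsufficientDataError(
            f"fewer than 2 hybrids observed in >= {min_env} sowings "
            f"for {traits[0]} at {locs[0]}")
    # keep only environments still observed
    Y = Y.loc[:, Y.notna().any(axis=0)]
    return str(traits[0]), str(locs[0]), Y, dropped


def _objective(Y, M, mu, g, s, h):
    R = Y - mu - g[:, None] - s[:, None] * h[None, :]
    return float(np.nansum(np.where(M, R * R, 0.0)))


def fit_fw_als(pheno: pd.DataFrame, tol: float = 1e-10,
               max_iter: int = 500, min_env: int = 3) -> FWFit:
    """Fit the reaction norm by alternating least squares.

    ``pheno`` must be restricted to one trait and one location; hybrids seen
    in fewer than ``min_env`` sowings are dropped (with a log entry).
    Convergence is declared when the objective decreases by less than ``tol``.
    """
    trait, loc, Ydf, dropped = _pivot_one_cell(pheno, min_env)
    Y = Ydf.to_numpy(float)
    M = np.isfinite(Y)
    n_i, n_j = Y.shape

    mu = float(np.nanmean(Y))
    col_mean = np.nanmean(Y, axis=0)
    h = col_mean - mu
    g = np.nanmean(Y, axis=1) - mu
    s = np.ones(n_i)

    y_sd = float(np.nanstd(Y)) or 1.0
    degenerate = float(np.std(h)) < 1e-10 * y_sd
    obj = _objective(Y, M, mu, g, s, h)
    n_iter, converged = 0, False

    if not degenerate:
        for n_iter in range(1, max_iter + 1):
            # (h | mu, g, s): exact per-environment weighted update
            R = np.where(M, Y - mu - g[:, None], 0.0)
            num = (R * s[:, None] * M).sum(axis=0)
            den = ((s ** 2)[:, None] * M).sum(axis=0)
            h = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)

            # (mu, g, s | h): exact per-hybrid simple regression on h
            W = M.astype(float)
            n_obs = W.sum(axis=1)
            hbar = (W * h[None, :]).sum(axis=1) / n_obs
            ybar = np.nansum(np.where(M, Y, 0.0), axis=1) / n_obs
            hc = h[None, :] - hbar[:, None]
            Sxx = (W * hc * hc).sum(axis=1)
            Sxy = (W * hc * np.where(M, Y - ybar[:, None], 0.0)).sum(axis=1)
            s = np.where(Sxx > 1e-12 * y_sd ** 2, Sxy / np.maximum(Sxx, 1e-300), 1.0)
            g = ybar - s * hbar - mu

            # renormalise within the invariance group (objective unchanged):
            # mean slope -> 1, mean h -> 0, mean g -> 0
            c = s.mean()
            if abs(c) < 1e-12:
                degenerate = True
                s = np.ones(n_i)
                break
            h = h * c
            s = s / c
            hb = h.mean()
            g = g + s * hb
            h = h - hb
            gb = g.mean()
            mu += gb
            g = g - gb

            new_obj = _objective(Y, M, mu, g, s, h)
            if obj - new_obj < tol:
                obj = new_obj
                converged = True
                break
            obj = new_obj
        else:
            converged = False
            logger.warning("FW ALS %s/%s did not converge in %d iterations",
                           trait, loc, max_iter)

    if degenerate:
        h = np.zeros(n_j)
        s = np.ones(n_i)
        g = np.nanmean(Y, axis=1) - mu
        gb = g.mean()
        mu += gb
        g -= gb
        obj = _objective(Y, M, mu, g, s, h)
        converged = True

    # gradient of the objective at the solution (diagnostic)
    R = np.where(M, Y - mu - g[:, None] - s[:, None] * h[None, :], 0.0)
    grad = np.concatenate([
        [-2 * R.sum()],
        -2 * R.sum(axis=1),
        -2 * (R * s[:, None]).sum(axis=0),
        -2 * (R * h[None, :]).sum(axis=1),
    ])
    n_par = 1 + 2 * (n_i - 1) + (n_j - 1)
    dof = max(int(M.sum()) - n_par, 1)
    return FWFit(trait_name=trait, location_id=loc, mu=mu,
                 g=pd.Series(g, index=Ydf.index, name="g"),
                 h=pd.Series(h, index=Ydf.columns, name="h"),
                 b=pd.Series(s - 1.0, index=Ydf.index, name="b"),
                 resid_var=obj / dof, n_env_used=n_j, method="ALS",
                 n_iter=n_iter, converged=converged, degenerate=degenerate,
                 objective=obj, grad_norm=float(np.linalg.norm(grad)),
                 dropped_hybrids=dropped)


def fit_fw_gibbs(pheno: pd.DataFrame, prior_df: float = 5.0,
                 prior_scale: float | None = None, n_iter: int = 20_000,
                 burn_in: int = 5_000, seed: int = 0, min_env: int = 3,
                 fixed_variances: tuple[float, float, float, float] | None = None,
                 ) -> FWFit:
    """Bayesian reaction-norm fit by Gibbs sampling; posterior means returned.

    Priors: ``g_i ~ N(0, s_g^2)``, ``b_i ~ N(0, s_b^2)``, ``h_j ~ N(0, s_h^2)``
    with scaled-inverse-chi-square hyperpriors (``prior_df`` degrees of
    freedom, scale defaulting to half the data variance).  With
    ``fixed_variances`` = (s_g^2, s_b^2, s_h^2, s_e^2) the variances are held
    constant, which in the large-variance limit reproduces the flat-prior
    (least-squares) fit on balanced data.
    """
    if n_iter <= burn_in:
        raise ParameterError("n_iter must exceed burn_in")
    trait, loc, Ydf, dropped = _pivot_one_cell(pheno, min_env)
    Y = Ydf.to_numpy(float)
    M = np.isfinite(Y)
    W = M.astype(float)
    Y0 = np.where(M, Y, 0.0)
    n_i, n_j = Y.shape
    rng = np.random.default_rng(seed)

    vy = float(np.nanvar(Y)) or 1.0
    S0 = prior_scale if prior_scale is not None else vy / 2.0
    nu0 = prior_df

    mu = float(np.nanmean(Y))
    g = np.zeros(n_i)
    b = np.zeros(n_i)
    h = np.nanmean(Y, axis=0) - mu
    if fixed_variances is not None:
        sg2, sb2, sh2, se2 = (float(v) for v in fixed_variances)
    else:
        sg2 = sb2 = sh2 = se2 = vy / 2.0

    keep = n_iter - burn_in
    acc_mu, acc_g, acc_b, acc_h = 0.0, np.zeros(n_i), np.zeros(n_i), np.zeros(n_j)

    def scaled_inv_chi2(df, scale):
        return df * scale / rng.chisquare(df)

    n_obs_i = W.sum(axis=1)
    n_obs_j = W.sum(axis=0)
    n_all = float(M.sum())

    for it in range(n_iter):
        slope = 1.0 + b
        # mu
        r = Y0 - (g[:, None] + slope[:, None] * h[None, :]) * W
        mean = float((r * W).sum()) / n_all
        mu = rng.normal(mean, np.sqrt(se2 / n_all))
        # g
        r = Y0 - (mu + slope[:, None] * h[None, :]) * W
        prec = n_obs_i / se2 + 1.0 / sg2
        mean = ((r * W).sum(axis=1) / se2) / prec
        g = rng.normal(mean, np.sqrt(1.0 / prec))
        # b: residual against coefficient h_j
        r = Y0 - (mu + g[:, None] + h[None, :]) * W
        sxx = (W * h[None, :] ** 2).sum(axis=1)
        prec = sxx / se2 + 1.0 / sb2
        mean = ((r * W * h[None, :]).sum(axis=1) / se2) / prec
        b = rng.normal(mean, np.sqrt(1.0 / prec))
        slope = 1.0 + b
        # h: coefficient (1 + b_i)
        r = Y0 - (mu + g[:, None]) * W
        sxx = (W * slope[:, None] ** 2).sum(axis=0)
        prec = sxx / se2 + 1.0 / sh2
        mean = ((r * W * slope[:, None]).sum(axis=0) / se2) / prec
        h = rng.normal(mean, np.sqrt(1.0 / prec))
        # variances
        if fixed_variances is None:
            resid = np.where(M, Y - mu - g[:, None] - slope[:, None] * h[None, :], 0.0)
            se2 = scaled_inv_chi2(nu0 + n_all, (nu0 * S0 + (resid ** 2).sum())
                                  / (nu0 + n_all))
            sg2 = scaled_inv_chi2(nu0 + n_i, (nu0 * S0 + g @ g) / (nu0 + n_i))
            sb2 = scaled_inv_chi2(nu0 + n_i, (nu0 * S0 + b @ b) / (nu0 + n_i))
            sh2 = scaled_inv_chi2(nu0 + n_j, (nu0 * S0 + h @ h) / (nu0 + n_j))
        if it >= burn_in:
            # store under the estimator's identifiability convention
            c = slope.mean()
            h_d = h * c
            s_d = slope / c
            hb = h_d.mean()
            g_d = g + s_d * hb
            h_d = h_d - hb
            mu_d = mu + g_d.mean()
            g_d = g_d - g_d.mean()
            acc_mu += mu_d
            acc_g += g_d
            acc_b += s_d - 1.0
            acc_h += h_d

    mu_hat = acc_mu / keep
    g_hat = acc_g / keep
    b_hat = acc_b / keep
    h_hat = acc_h / keep
    R = np.where(M, Y - mu_hat - g_hat[:, None]
                 - (1 + b_hat)[:, None] * h_hat[None, :], 0.0)
    n_par = 1 + 2 * (n_i - 1) + (n_j - 1)
    dof = max(int(M.sum()) - n_par, 1)
    return FWFit(trait_name=trait, location_id=loc, mu=float(mu_hat),
                 g=pd.Series(g_hat, index=Ydf.index, name="g"),
                 h=pd.Series(h_hat, index=Ydf.columns, name="h"),
                 b=pd.Series(b_hat, index=Ydf.index, name="b"),
                 resid_var=float((R ** 2).sum()) / dof, n_env_used=n_j,
                 method="Gibbs", n_iter=n_iter, converged=True,
                 objective=float((R ** 2).sum()),
                 dropped_hybrids=dropped)


def plasticity_matrix(fits: list[FWFit]) -> pd.DataFrame:
    """Assemble hybrid x (trait, location) table of plasticity deviations b.

    Cells without a fit stay missing; duplicate fits for the same
    (trait, location) raise :class:`ConflictError`.
    """
    seen = set()
    cols = {}
    for fit in fits:
        key = (fit.trait_name, fit.location_id)
        if key in seen:
            raise ConflictError(f"duplicate FW fit for trait/location {key}")
        seen.add(key)
        cols[key] = fit.b
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["trait_name", "location_id"])
    out.index.name = "hybrid_id"
    return out.sort_index()
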