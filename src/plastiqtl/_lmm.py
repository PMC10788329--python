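"""Shared restricted-maximum-likelihood (REML) machinery for linear mixed models.

Two fitters live here:

* :func:`fit_ratio_reml` — the single-kinship model ``y = X a + u + e`` with
  ``u ~ N(0, s_g^2 K)`` and ``e ~ N(0, s_e^2 I)``.  After one eigendecomposition
  of ``K`` the covariance is diagonal in the rotated basis and the REML
  criterion is a smooth one-dimensional function of the variance ratio
  ``delta = s_e^2 / s_g^2``; it is maximised by a coarse log-grid scan followed
  by bounded scalar refinement.  This is the exact per-SNP mixed-model used for
  association scans and (with an overlay incidence kinship) for combining
  ability.

* :func:`reml_vc` — the general multi-component model
  ``y = X b + sum_k Z_k u_k + e`` with independent variance components, fit by
  a short EM warm start followed by Nelder-Mead on log-variances.  All matrix
  work goes through the Woodbury identity so the cost is governed by the total
  number of random-effect levels, not the number of records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .exceptions import NumericalError, ParameterError

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# single variance ratio (EMMA-style)
# ---------------------------------------------------------------------------

@dataclass
class EigenK:
    """Cached eigendecomposition of a kinship matrix."""

    values: np.ndarray   # (n,)
    vectors: np.ndarray  # (n, n), columns are eigenvectors

    @classmethod
    def of(cls, K: np.ndarray) -> "EigenK":
        s, U = np.linalg.eigh(K)
        s = np.clip(s, 0.0, None)
        return cls(values=s, vectors=U)


@dataclass
class RatioREMLResult:
    delta: float          # s_e^2 / s_g^2
    sigma_g2: float
    sigma_e2: float
    beta: np.ndarray
    se: np.ndarray        # standard errors of beta
    loglik: float         # restricted log-likelihood (up to an X-only constant)
    dof: int              # residual degrees of freedom n - c


def _reml_pieces(log10_delta: float, s: np.ndarray, yt: np.ndarray,
                 Xt: np.ndarray):
    """Return (loglik, beta, XtVX_inv, rss) at a given log10 variance ratio."""
    delta = 10.0 ** log10_delta
    lam = s + delta
    w = 1.0 / lam
    Xw = Xt * w[:, None]
    A = Xt.T @ Xw                      # X' V^-1 X (up to s_g^2)
    b = Xw.T @ yt
    try:
        cho = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return -np.inf, None, None, None
    beta = np.linalg.solve(A, b)
    resid = yt - Xt @ beta
    rss = float(np.sum(w * resid * resid))
    if rss <= 0:
        rss = np.finfo(float).tiny
    n, c = Xt.shape
    nc = n - c
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf, None, None, None
    ll = 0.5 * (nc * (np.log(nc) - _LOG2PI) - nc
                - nc * np.log(rss) - np.sum(np.log(lam)) - logdetA)
    return ll, beta, A, rss


def reml_loglik_rotated(log10_delta: float, s: np.ndarray, yt: np.ndarray,
                        Xt: np.ndarray) -> float:
    """Restricted log-likelihood, profiled over s_g^2, in the rotated basis."""
    return _reml_pieces(log10_delta, s, yt, Xt)[0]


def fit_ratio_reml(y: np.ndarray, X: np.ndarray, eig: EigenK,
                   log10_bounds: tuple[float, float] = (-5.0, 5.0),
                   n_grid: int = 61) -> RatioREMLResult:
    """Fit the single-ratio mixed model by REML.

    The variance ratio is located on a log10 grid of ``n_grid`` points across
    ``log10_bounds`` and refined with bounded Brent search in the bracketing
    interval.
    """
    n, c = X.shape
    if n <= c:
        raise ParameterError(f"need more observations ({n}) than covariates ({c})")
    yt = eig.vectors.T @ y
    Xt = eig.vectors.T @ X
    lo, hi = log10_bounds
    grid = np.linspace(lo, hi, n_grid)
    lls = np.array([reml_loglik_rotated(g, eig.values, yt, Xt) for g in grid])
    if not np.isfinite(lls).any():
        raise NumericalError("REML criterion not finite anywhere on the ratio grid")
    k = int(np.nanargmax(np.where(np.isfinite(lls), lls, -np.inf)))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, n_grid - 1)]
    if b > a:
        res = optimize.minimize_scalar(
            lambda g: -reml_loglik_rotated(g, eig.values, yt, Xt),
            bounds=(a, b), method="bounded",
            options={"xatol": 1e-8})
        best = float(res.x) if -res.fun >= lls[k] else float(grid[k])
    else:
        best = float(grid[k])
    ll, beta, A, rss = _reml_pieces(best, eig.values, yt, Xt)
    if beta is None:
        raise NumericalError("singular design at the REML optimum")
    dof = n - c
    sigma_g2 = rss / dof
    delta = 10.0 ** best
    sigma_e2 = delta * sigma_g2
    cov = sigma_g2 * np.linalg.inv(A)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return RatioREMLResult(delta=delta, sigma_g2=sigma_g2, sigma_e2=sigma_e2,
                           beta=beta, se=se, loglik=ll, dof=dof)


# ---------------------------------------------------------------------------
# multi-component REML (Woodbury)
# ---------------------------------------------------------------------------

@dataclass
class VCResult:
    sigma2: np.ndarray          # per-component variances, residual last
    beta: np.ndarray
    blups: list[np.ndarray] = field(default_factory=list)
    loglik: float = np.nan
    converged: bool = True
    n_iter: int = 0


class _VCWork:
    """Woodbury workspace for one (y, X, Z_list) problem."""

    def __init__(self, y: np.ndarray, X: np.ndarray, Z_list: list[np.ndarray]):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.Z = [np.asarray(Z, dtype=float) for Z in Z_list]
        self.n, self.c = self.X.shape
        self.q = [Z.shape[1] for Z in self.Z]
        self.Zall = np.hstack(self.Z) if self.Z else np.zeros((self.n, 0))
        self.ZtZ = self.Zall.T @ self.Zall
        self.ZtX = self.Zall.T @ self.X
        self.Zty = self.Zall.T @ self.y
        self.Xty = self.X.T @ self.y
        self.XtX = self.X.T @ self.X
        self.yty = float(self.y @ self.y)
        # column slices of Zall per component
        self.slices = []
        off = 0
        for qk in self.q:
            self.slices.append(slice(off, off + qk))
            off += qk

    def _core(self, sigma2: np.ndarray):
        """Solve the Woodbury core for the given variances (residual last)."""
        se2 = sigma2[-1]
        d = np.concatenate([np.full(qk, s2) for qk, s2 in zip(self.q, sigma2[:-1])]) \
            if self.q else np.zeros(0)
        # C = I + D^{1/2} Z'Z D^{1/2} / se2
        sd = np.sqrt(d)
        C = np.eye(sum(self.q)) + (sd[:, None] * self.ZtZ * sd[None, :]) / se2
        try:
            cho = np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise NumericalError("variance-component core matrix not PD") from exc
        logdetC = 2.0 * np.sum(np.log(np.diag(cho)))
        return se2, d, sd, cho, logdetC

    def reml_loglik(self, sigma2: np.ndarray, want_effects: bool = False):
        """Restricted log-likelihood (up to the X-only constant).

        With ``want_effects`` also returns ``(ll, beta, Z'Py)``; component
        BLUPs are ``sigma2_k * (Z'Py)[slice_k]``.
        """
        se2, d, sd, cho, logdetC = self._core(sigma2)

        def cinv(M):
            return np.linalg.solve(cho.T, np.linalg.solve(cho, M))

        def dcd(Mzt):     # D^{1/2} C^-1 D^{1/2} (Z'M)
            Mzt = np.atleast_2d(Mzt.T).T
            return sd[:, None] * cinv(sd[:, None] * Mzt)

        dcdX = dcd(self.ZtX)            # q x c
        dcdy = dcd(self.Zty)[:, 0]      # q
        XtVX = self.XtX / se2 - (self.ZtX.T @ dcdX) / se2 ** 2
        XtVy = self.Xty / se2 - (self.ZtX.T @ dcdy) / se2 ** 2
        ytVy = self.yty / se2 - (self.Zty @ dcdy) / se2 ** 2
        sign, logdetB = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return (-np.inf, None, None) if want_effects else -np.inf
        beta = np.linalg.solve(XtVX, XtVy)
        ypy = ytVy - XtVy @ beta
        logdetV = self.n * np.log(se2) + logdetC
        ll = -0.5 * (logdetV + logdetB + ypy + (self.n - self.c) * _LOG2PI)
        if not want_effects:
            return ll
        ZtVy = self.Zty / se2 - (self.ZtZ @ dcdy) / se2 ** 2
        ZtVX = self.ZtX / se2 - (self.ZtZ @ dcdX) / se2 ** 2
        ZtPy = ZtVy - ZtVX @ beta
        return ll, beta, ZtPy

    def em_step(self, sigma2: np.ndarray) -> np.ndarray:
        """One EM-REML update of all variances (residual last)."""
        se2, d, sd, cho, _ = self._core(sigma2)

        def cinv(M):      # C^-1 M via the cached Cholesky factor
            return np.linalg.solve(cho.T, np.linalg.solve(cho, M))

        def dcd(Mzt):     # D^{1/2} C^-1 D^{1/2} (Z'M)
            Mzt = np.atleast_2d(Mzt.T).T
            return sd[:, None] * cinv(sd[:, None] * Mzt)

        dcdX = dcd(self.ZtX)
        dcdy = dcd(self.Zty)[:, 0]
        ZtVX = self.ZtX / se2 - (self.ZtZ @ dcdX) / se2 ** 2
        ZtVy = self.Zty / se2 - (self.ZtZ @ dcdy) / se2 ** 2
        ZtVZ = self.ZtZ / se2 - (self.ZtZ @ dcd(self.ZtZ)) / se2 ** 2
        XtVX = self.XtX / se2 - (self.ZtX.T @ dcdX) / se2 ** 2
        XtVy = self.Xty / se2 - (self.ZtX.T @ dcdy) / se2 ** 2
        Binv = np.linalg.inv(XtVX)
        beta = Binv @ XtVy
        ZtPy = ZtVy - ZtVX @ beta
        ZtPZ = ZtVZ - ZtVX @ Binv @ ZtVX.T
        new = np.empty_like(sigma2)
        for k, sl in enumerate(self.slices):
            s2 = sigma2[k]
            u = s2 * ZtPy[sl]
            tr = np.trace(ZtPZ[sl, sl])
            new[k] = (u @ u + s2 * (self.q[k] - s2 * tr)) / self.q[k]
        # residual update needs tr(P) and ||Py||^2 with
        # P = V^-1 - V^-1 X B^-1 X' V^-1 and
        # V^-1 = I/se2 - Z D^{1/2} C^-1 D^{1/2} Z' / se2^2
        W = sd[:, None] * self.ZtZ * sd[None, :]        # D^{1/2} Z'Z D^{1/2}
        trVinv = self.n / se2 - np.trace(cinv(W)) / se2 ** 2
        VX = self.X / se2 - (self.Zall @ (sd[:, None] * cinv(sd[:, None] * self.ZtX))) / se2 ** 2
        trP = trVinv - np.trace(Binv @ (VX.T @ VX))
        Vy = self.y / se2 - (self.Zall @ (sd * cinv((sd * self.Zty)[:, None])[:, 0])) / se2 ** 2
        Py = Vy - VX @ beta
        nc = self.n - self.c
        new[-1] = (se2 ** 2 * float(Py @ Py) + se2 * (nc - se2 * trP)) / nc
        return np.clip(new, 1e-12, None)


def reml_vc(y: np.ndarray, X: np.ndarray, Z_list: list[np.ndarray],
            n_em: int = 20, tol: float = 1e-8, maxiter: int = 400,
            start: np.ndarray | None = None,
            fixed: np.ndarray | None = None) -> VCResult:
    """Multi-component REML fit.

    Parameters
    ----------
    fixed:
        If given, no optimization is performed: variances are taken as-is and
        only the GLS fixed effects and BLUPs are computed (used by oracles and
        by callers that already know the components).
    """
    work = _VCWork(y, X, Z_list)
    k = len(Z_list)
    vy = float(np.var(work.y)) or 1.0

    if fixed is not None:
        sig = np.asarray(fixed, dtype=float)
        ll, beta, ZtPy = work.reml_loglik(sig, want_effects=True)
        blups = [sig[j] * ZtPy[work.slices[j]] for j in range(k)]
        return VCResult(sigma2=sig, beta=beta, blups=blups, loglik=ll, n_iter=0)

    if start is None:
        sig = np.full(k + 1, vy / (k + 1))
    else:
        sig = np.asarray(start, dtype=float).copy()
    sig = np.clip(sig, 1e-10 * vy, None)

    # EM warm start (each step increases the restricted likelihood)
    for _ in range(n_em):
        try:
            sig = work.em_step(sig)
        except NumericalError:
            break
        sig = np.clip(sig, 1e-10 * vy, None)

    # Nelder-Mead polish on log-variances
    def nll(logsig):
        s2 = np.exp(logsig)
        ll = work.reml_loglik(s2)
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(nll, np.log(sig), method="Nelder-Mead",
                            options={"xatol": 1e-9, "fatol": tol,
                                     "maxiter": maxiter * (k + 1)})
    sig = np.exp(res.x)
    ll, beta, ZtPy = work.reml_loglik(sig, want_effects=True)
    blups = [sig[j] * ZtPy[work.slices[j]] for j in range(k)]
    return VCResult(sigma2=sig, beta=beta, blups=blups, loglik=ll,
                    converged=bool(res.success), n_iter=int(res.nit))
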