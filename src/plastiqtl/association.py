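"""Mixed-linear-model association scans for plasticity and BLUP phenotypes.

The per-SNP model is

    y = Xc a + x beta + u + e,   u ~ N(0, s_g^2 K),  e ~ N(0, s_e^2 I)

with Xc the intercept plus leading principal components and K the centered
genomic relationship matrix.  K is eigendecomposed once; for every SNP the
variance ratio is re-optimised by REML on the rotated data (exact mixed model,
not the null-ratio approximation) and the Wald test of beta = 0 is reported
with t-distributed reference (df = n - #covariates - 1), which reduces exactly
to ordinary least squares when K is the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._lmm import EigenK, fit_ratio_reml
from .exceptions import (AlignmentError, DataError, ParameterError)
from .io_formats import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

ASSOC_COLUMNS = ["chr", "pos", "allele0", "allele1", "af",
                 "beta", "se", "wald", "p_wald", "neglog10p"]


@dataclass
class KinshipMatrix:
    """Centered genomic relationship matrix (VanRaden-style, unscaled MAF)."""

    sample_ids: list[str]
    K: np.ndarray
    n_snps_used: int = 0

    def __post_init__(self):
        if self.K.shape != (len(self.sample_ids),) * 2:
            raise AlignmentError("kinship shape does not match sample ids")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise DataError("kinship matrix is not symmetric")


@dataclass
class PCAResult:
    coords: pd.DataFrame        # samples x PCs (scores)
    components: np.ndarray      # n_pc x n_snps loadings, rows orthonormal
    explained_var: np.ndarray


def _imputed_centered(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed, column-centered dosage plus a polymorphic-column mask."""
    d = G.dosage.astype(float)
    d[d == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), mean, d)
    poly = np.nanstd(d, axis=0) > 0
    return d - mean, poly


def compute_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """K = W W' / m over the m polymorphic SNPs, W the centered dosages.

    Missing dosages are mean-imputed for the kinship only.
    """
    if G.n_samples < 2:
        raise DataError("kinship needs >= 2 samples")
    W, poly = _imputed_centered(G)
    m = int(poly.sum())
    if m == 0:
        raise DataError("no polymorphic SNPs available for kinship")
    W = W[:, poly]
    K = (W @ W.T) / m
    return KinshipMatrix(sample_ids=list(G.sample_ids), K=K, n_snps_used=m)


def compute_pcs(G: GenotypeMatrix, n_pc: int = 3) -> PCAResult:
    """Principal components of the centered genotype matrix.

    Loadings follow the fixed sign convention that the largest-magnitude
    loading of each component is positive.
    """
    if n_pc >= G.n_samples:
        raise ParameterError("n_pc must be smaller than the number of samples")
    W, poly = _imputed_centered(G)
    W = W[:, poly]
    U, S, Vt = np.linalg.svd(W, full_matrices=False)
    rank = int((S > 1e-9 * S[0]).sum()) if S.size else 0
    k = min(n_pc, rank)
    if k < n_pc:
        logger.warning("compute_pcs: rank %d < requested %d PCs", rank, n_pc)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    for i in range(k):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    coords = pd.DataFrame(U * S, index=G.sample_ids,
                          columns=[f"PC{i + 1}" for i in range(k)])
    return PCAResult(coords=coords, components=Vt,
                     explained_var=S ** 2 / max(G.n_samples - 1, 1))


def bonferroni_threshold(n_snps: int, alpha: float = 0.05) -> tuple[float, float]:
    """Genome-wide p threshold alpha / n_snps and its -log10."""
    if n_snps < 1:
        raise ParameterError("n_snps must be >= 1")
    thr = alpha / n_snps
    return thr, float(-np.log10(thr))


def mlm_gwas(y: pd.Series, G: GenotypeMatrix, K: KinshipMatrix,
             covariates: pd.DataFrame | None = None, n_pc: int = 3,
             log10_bounds: tuple[float, float] = (-5.0, 5.0),
             n_grid: int = 41, approx_null_ratio: bool = False) -> pd.DataFrame:
    """Exact mixed-model association scan of every SNP in ``G``.

    ``y`` is indexed by sample id (plasticity b values or BLUPs); samples with
    missing phenotype are dropped listwise.  ``covariates`` defaults to the
    intercept plus the first ``n_pc`` genotype principal components.  SNPs
    that are monomorphic among the analysed samples are reported with NaN
    statistics; samples with a missing call at a SNP are dropped for that SNP
    only.

    With ``approx_null_ratio`` the variance ratio is estimated once under the
    covariate-only null model and reused for every SNP (the fast
    approximation popularised by EMMAX) instead of being re-optimised per
    SNP; the exact per-SNP optimisation is the default.

    Returns a frame with columns :data:`ASSOC_COLUMNS` (Wald statistic is the
    squared t ratio; p from the t reference with n - c dof).
    """
    y = y.dropna()
    keep = [s for s in G.sample_ids if s in set(y.index)]
    if len(keep) < 5:
        raise DataError(f"only {len(keep)} samples shared between y and genotypes")
    Gs = G.take_samples(keep)
    yv = y.loc[keep].to_numpy(float)

    if set(K.sample_ids) < set(keep):
        raise AlignmentError("kinship does not cover the analysed samples")
    kidx = [K.sample_ids.index(s) for s in keep]
    Kmat = K.K[np.ix_(kidx, kidx)]

    if covariates is None:
        C = compute_pcs(Gs, n_pc=n_pc).coords.to_numpy() if n_pc > 0 \
            else np.empty((len(keep), 0))
    else:
        if not set(keep) <= set(covariates.index):
            raise AlignmentError("covariates do not cover the analysed samples")
        C = covariates.loc[keep].to_numpy(float)
    Xc = np.column_stack([np.ones(len(keep)), C])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ParameterError("covariate matrix is singular")

    eig_full = EigenK.of(Kmat)
    sub_cache: dict[bytes, EigenK] = {}

    if approx_null_ratio:
        null = fit_ratio_reml(yv, Xc, eig_full, log10_bounds=log10_bounds,
                              n_grid=n_grid)
        fixed_log10 = float(np.log10(null.delta))
        log10_bounds = (fixed_log10, fixed_log10)
        n_grid = 1

    dosage = Gs.dosage
    out = []
    for j in range(Gs.n_snps):
        x = dosage[:, j].astype(float)
        obs = x != MISSING
        snp_row = {"chr": Gs.chrom[j], "pos": int(Gs.pos[j]),
                   "allele0": Gs.ref[j], "allele1": Gs.alt[j]}
        xo = x[obs]
        if xo.size < Xc.shape[1] + 2 or np.all(xo == xo[0]):
            out.append({**snp_row, "af": float(xo.mean() / 2) if xo.size else np.nan,
                        "beta": np.nan, "se": np.nan, "wald": np.nan,
                        "p_wald": np.nan, "neglog10p": np.nan})
            continue
        if obs.all():
            eig = eig_full
            yj, Xj = yv, np.column_stack([Xc, x])
        else:
            key = obs.tobytes()
            if key not in sub_cache:
                sub_cache[key] = EigenK.of(Kmat[np.ix_(obs, obs)])
            eig = sub_cache[key]
            yj, Xj = yv[obs], np.column_stack([Xc[obs], xo])
        res = fit_ratio_reml(yj, Xj, eig, log10_bounds=log10_bounds,
                             n_grid=n_grid)
        beta = float(res.beta[-1])
        se = float(res.se[-1])
        if se > 0:
            t = beta / se
            p = float(2.0 * stats.t.sf(abs(t), res.dof))
            p = max(p, np.finfo(float).tiny)
        else:
            t, p = np.nan, np.nan
        out.append({**snp_row, "af": float(xo.mean() / 2),
                    "beta": beta, "se": se,
                    "wald": t * t if np.isfinite(t) else np.nan,
                    "p_wald": p,
                    "neglog10p": -np.log10(p) if p and np.isfinite(p) else np.nan})
    return pd.DataFrame(out, columns=ASSOC_COLUMNS)


def write_assoc(assoc: pd.DataFrame, path: str) -> None:
    """Tab-separated association output with a stable, documented header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# exact mixed-model scan; Wald test; pos is 1-based\n")
        assoc.to_csv(fh, sep="\t", index=False)


def read_assoc(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
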