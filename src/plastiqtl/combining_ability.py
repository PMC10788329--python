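"""General combining ability (GCA) of plasticity under an additive model.

The plasticity of a hybrid with mother m and father f is modelled as

    p_mf = mu + u_m + u_f + eps

with a single parental random-effect vector u shared by both sides (specific
combining ability is fixed at zero — without replicated crosses it is not
estimable).  Variance components are estimated by REML on the overlay
incidence (each hybrid row carries +1 on each of its two parents), GCA values
are the BLUPs of u re-centered to sum exactly to zero, and a fit with no
detectable parental variance reports all GCA values as exactly 0 with the
``zeroed`` flag set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lmm import EigenK, fit_ratio_reml
from .exceptions import AlignmentError, ConflictError, InsufficientDataError
from .io_formats import validate_design

logger = logging.getLogger(__name__)

#: relative parental-variance floor below which the fit is declared null
ZERO_VARIANCE_RTOL = 1e-8


@dataclass
class GCAFit:
    trait_name: str
    location_id: str
    mu: float
    gca: pd.Series           # per-parent breeding value for plasticity
    var_parent: float
    var_resid: float
    zeroed: bool
    loglik: float = np.nan


def _overlay_incidence(design: pd.DataFrame, hybrids: list[str]):
    parents = sorted(set(design["female_parent"]) | set(design["male_parent"]))
    pidx = {p: i for i, p in enumerate(parents)}
    mother = dict(zip(design["hybrid_id"], design["female_parent"]))
    father = dict(zip(design["hybrid_id"], design["male_parent"]))
    Z = np.zeros((len(hybrids), len(parents)))
    for r, hyb in enumerate(hybrids):
        Z[r, pidx[mother[hyb]]] += 1.0
        Z[r, pidx[father[hyb]]] += 1.0
    return Z, parents


def _is_connected(Z: np.ndarray) -> bool:
    """Whether the parent graph (parents linked by shared crosses) is connected."""
    p = Z.shape[1]
    adj = (Z.T @ Z) > 0
    seen = np.zeros(p, dtype=bool)
    stack = [0]
    while stack:
        i = stack.pop()
        if seen[i]:
            continue
        seen[i] = True
        stack.extend(np.flatnonzero(adj[i] & ~seen).tolist())
    return bool(seen.all())


def fit_gca(plasticity: pd.Series, design: pd.DataFrame,
            trait_name: str = "", location_id: str = "") -> GCAFit:
    """Estimate parental GCA of plasticity for one trait and location.

    ``plasticity`` is indexed by hybrid_id (e.g. the ``b`` column of an FW
    fit).  Every hybrid must have a design row; the returned GCA values sum
    to zero by construction.
    """
    validate_design(design)
    plasticity = plasticity.dropna()
    unknown = [h for h in plasticity.index if h not in set(design["hybrid_id"])]
    if unknown:
        raise AlignmentError(f"hybrids without a design row: {unknown[:5]}")
    sub = design.set_index("hybrid_id").loc[plasticity.index].reset_index()
    if sub["female_parent"].nunique() < 2 or sub["male_parent"].nunique() < 2:
        raise InsufficientDataError("need >= 2 distinct parents on each side")

    y = plasticity.to_numpy(float)
    Z, parents = _overlay_incidence(sub, list(plasticity.index))
    if not _is_connected(Z):
        logger.warning("fit_gca %s/%s: cross design is disconnected; "
                       "GCA contrasts across components are not estimable",
                       trait_name, location_id)

    vy = float(np.var(y))
    if vy <= 0:
        return GCAFit(trait_name=trait_name, location_id=location_id,
                      mu=float(y.mean()),
                      gca=pd.Series(0.0, index=parents, name="gca"),
                      var_parent=0.0, var_resid=0.0, zeroed=True)

    K = Z @ Z.T
    X = np.ones((len(y), 1))
    res = fit_ratio_reml(y, X, EigenK.of(K), log10_bounds=(-8.0, 8.0),
                         n_grid=81)
    var_parent = res.sigma_g2
    var_resid = res.sigma_e2
    mu = float(res.beta[0])

    if var_parent < ZERO_VARIANCE_RTOL * vy:
        return GCAFit(trait_name=trait_name, location_id=location_id, mu=mu,
                      gca=pd.Series(0.0, index=parents, name="gca"),
                      var_parent=float(var_parent), var_resid=float(var_resid),
                      zeroed=True, loglik=res.loglik)

    # BLUP of u: var_parent * Z' V^-1 (y - mu), V = var_parent*K + var_resid*I
    V = var_parent * K + var_resid * np.eye(len(y))
    u = var_parent * (Z.T @ np.linalg.solve(V, y - mu))
    u = u - u.mean()        # exact sum-to-zero constraint
    return GCAFit(trait_name=trait_name, location_id=location_id, mu=mu,
                  gca=pd.Series(u, index=parents, name="gca"),
                  var_parent=float(var_parent), var_resid=float(var_resid),
                  zeroed=False, loglik=res.loglik)


def gca_heatmap_table(fits: list[GCAFit],
                      zero_tol: float = 1e-12) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parent x (trait, location) tables of GCA values and sign tags.

    A cell is tagged ``zero`` iff |gca| < ``zero_tol`` or the fit was zeroed,
    otherwise ``positive``/``negative``.
    """
    seen = set()
    vals = {}
    zeroed_cols = set()
    for fit in fits:
        key = (fit.trait_name, fit.location_id)
        if key in seen:
            raise ConflictError(f"duplicate GCA fit for {key}")
        seen.add(key)
        vals[key] = fit.gca
        if fit.zeroed:
            zeroed_cols.add(key)
    values = pd.DataFrame(vals)
    values.columns = pd.MultiIndex.from_tuples(values.columns,
                                               names=["trait_name", "location_id"])
    values.index.name = "parent_id"
    signs = pd.DataFrame("zero", index=values.index, columns=values.columns)
    for col in values.columns:
        v = values[col]
        if col in zeroed_cols:
            continue
        signs[col] = np.select([v > zero_tol, v < -zero_tol],
                               ["positive", "negative"], default="zero")
        signs.loc[v.isna(), col] = "missing"
    return values.sort_index(), signs.sort_index()


def select_stable_parents(values: pd.DataFrame, max_gca: float = 0.0,
                          min_locations: int = 4,
                          min_traits: int = 5) -> list[str]:
    """Parents with consistently low GCA for plasticity.

    A parent qualifies in a location when its GCA is <= ``max_gca`` for at
    least ``min_traits`` of the traits fitted there; it is selected when it
    qualifies in at least ``min_locations`` locations (default: more than
    three of the five trial locations).
    """
    locations = values.columns.get_level_values("location_id").unique()
    selected = []
    for parent in values.index:
        n_loc = 0
        for loc in locations:
            sub = values.loc[parent, values.columns.get_level_values(
                "location_id") == loc].dropna()
            if len(sub) == 0:
                continue
            need = min(min_traits, len(sub))
            if (sub <= max_gca).sum() >= need:
                n_loc += 1
        if n_loc >= min_locations:
            selected.append(parent)
    return selected
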