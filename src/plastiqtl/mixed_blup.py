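"""Line-level genetic values (BLUPs) from a three-random-term mixed model.

For one trait the records are modelled as

    Y = mu + (1|LINE) + (1|ENV) + (1|LINE:ENV) + eps

where ENV is either the sowing stage within one location (``scope =
"per_location"``) or the trial location itself (``scope = "cross_location"``).
When each LINE x ENV cell holds at most one record the interaction variance is
confounded with the residual and the term is dropped automatically (logged).
Variance components are estimated by REML (EM warm start, then Nelder-Mead on
log-variances); the reported line effects are the empirical BLUPs at the REML
estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lmm import reml_vc
from .exceptions import InsufficientDataError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class BLUPFit:
    trait_name: str
    scope: str                      # "per_location" | "cross_location"
    var_line: float
    var_env: float
    var_interaction: float          # NaN when the term was dropped
    var_resid: float
    line_blup: pd.Series
    loglik_reml: float
    interaction_dropped: bool = False
    env_dropped: bool = False
    degenerate: bool = False        # all records identical
    location_id: str | None = None


def _indicator(labels: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(labels.unique())
    lut = {v: i for i, v in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), [lut[v] for v in labels]] = 1.0
    return Z, levels


def fit_blup(pheno: pd.DataFrame, scope: str = "per_location",
             fixed_components: dict[str, float] | None = None,
             n_em: int = 20, tol: float = 1e-8,
             start: dict[str, float] | None = None) -> BLUPFit:
    """Fit the mixed model for one trait and return line BLUPs.

    Parameters
    ----------
    pheno:
        Long-format records for a single trait; for ``scope="per_location"``
        they must come from a single location.
    fixed_components:
        Optional ``{"line": .., "env": .., "interaction": .., "resid": ..}``
        variances; when given the components are held fixed and only the
        BLUPs are computed (closed-form oracle mode).
    """
    traits = pheno["trait_name"].unique()
    if len(traits) != 1:
        raise ParameterError(f"expected one trait, got {list(traits)}")
    trait = str(traits[0])
    df = pheno.dropna(subset=["value"]).copy()

    if scope == "per_location":
        locs = df["location_id"].unique()
        if len(locs) != 1:
            raise ParameterError(
                f"per_location scope expects a single location, got {list(locs)}")
        location_id = str(locs[0])
        env = df["sowing_index"].astype(str)
    elif scope == "cross_location":
        location_id = None
        env = df["location_id"].astype(str)
    else:
        raise ParameterError(f"unknown scope {scope!r}")

    line = df["hybrid_id"].astype(str)
    if line.nunique() < 2:
        raise InsufficientDataError("need >= 2 lines")
    y = df["value"].to_numpy(float)
    n = len(y)

    if np.ptp(y) == 0.0:
        levels = sorted(line.unique())
        return BLUPFit(trait_name=trait, scope=scope, var_line=0.0,
                       var_env=0.0, var_interaction=np.nan, var_resid=0.0,
                       line_blup=pd.Series(0.0, index=levels, name="blup"),
                       loglik_reml=np.nan, interaction_dropped=True,
                       degenerate=True, location_id=location_id)

    Z_line, line_levels = _indicator(line)
    terms = ["line"]
    Zs = [Z_line]

    env_dropped = env.nunique() < 2
    if env_dropped:
        logger.info("fit_blup %s: single environment level; ENV term dropped",
                    trait)
    else:
        Z_env, _ = _indicator(env)
        terms.append("env")
        Zs.append(Z_env)

    interaction_dropped = True
    if not env_dropped:
        cell = line.str.cat(env, sep="\x1f")
        max_cell = cell.value_counts().max()
        if max_cell > 1:
            Z_int, _ = _indicator(cell)
            terms.append("interaction")
            Zs.append(Z_int)
            interaction_dropped = False
        else:
            logger.info("fit_blup %s: one record per LINE x ENV cell; "
                        "interaction confounded with residual and dropped",
                        trait)

    X = np.ones((n, 1))
    if fixed_components is not None:
        fixed = np.array([fixed_components[t] for t in terms]
                         + [fixed_components["resid"]], dtype=float)
        res = reml_vc(y, X, Zs, fixed=fixed)
    else:
        start_vec = None
        if start is not None:
            start_vec = np.array([start[t] for t in terms] + [start["resid"]],
                                 dtype=float)
        res = reml_vc(y, X, Zs, n_em=n_em, tol=tol, start=start_vec)

    comp = dict(zip(terms, res.sigma2[:-1]))
    blup = pd.Series(res.blups[0], index=line_levels, name="blup")
    return BLUPFit(trait_name=trait, scope=scope,
                   var_line=float(comp.get("line", 0.0)),
                   var_env=float(comp.get("env", 0.0)) if not env_dropped else 0.0,
                   var_interaction=(float(comp["interaction"])
                                    if "interaction" in comp else np.nan),
                   var_resid=float(res.sigma2[-1]),
                   line_blup=blup, loglik_reml=float(res.loglik),
                   interaction_dropped=interaction_dropped,
                   env_dropped=env_dropped, location_id=location_id)
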