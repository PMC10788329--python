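"""Synthetic multi-environment hybrid-rice trials with recorded ground truth.

The generator emulates a two-line hybrid breeding study: fully inbred TGMS
(female) and restorer (male) parents are simulated as biallelic SNP dosages,
F1 hybrids are derived from a partial-factorial cross design, and quality
traits are produced from the reaction-norm model

    y_ij = mu + g_i + h_j + b_i * h_j + eps_ij

where ``g_i`` is the genetic main effect of hybrid ``i``, ``h_j`` the effect
of environment ``j`` (a sowing stage within a trial location) and ``b_i`` the
plasticity deviation, so ``1 + b_i`` is the Finlay-Wilkinson slope.  Both
``g`` and ``b`` carry programmed causal SNPs, and ``b`` additionally carries
additive parental (GCA) contributions, so every downstream stage — plasticity
regression, combining ability, BLUP, association, QTL calling — can be tested
against known truth.

The default scenario mirrors the field design this package targets: 32
parents (7 x 25), 141 crosses, 5 locations with 3-5 staggered sowings each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, DataError, ParameterError
from .io_formats import MISSING, TRAITS, GenotypeMatrix, validate_design

logger = logging.getLogger(__name__)

#: sowings per trial location in the default scenario
DEFAULT_ENV_DESIGN = {"SC-GH": 3, "HB-EZ": 4, "AH-HF": 4, "HN-CS": 5, "HN-LS": 4}

#: approximate rice chromosome lengths (bp), used to place simulated SNPs
DEFAULT_CHROM_LENGTHS = {
    "Chr01": 43_000_000, "Chr02": 36_000_000, "Chr03": 36_000_000,
    "Chr04": 35_000_000, "Chr05": 30_000_000, "Chr06": 32_000_000,
    "Chr07": 30_000_000, "Chr08": 28_000_000, "Chr09": 23_000_000,
    "Chr10": 23_000_000, "Chr11": 29_000_000, "Chr12": 27_500_000,
}

#: plausible trait means in their reporting units (AC/PGWC/MRR %, GC mm,
#: ASV/TP grades, CD index)
DEFAULT_TRAIT_MEANS = {"AC": 16.0, "ASV": 5.0, "GC": 60.0, "CD": 3.5,
                       "PGWC": 12.0, "TP": 2.0, "MRR": 63.0}


@dataclass
class TruthRecord:
    """Every generated parameter of one phenotype simulation.

    ``g``/``b`` are hybrid x trait frames, ``h`` is (location, sowing) x
    trait, ``gca`` is parent x trait.  Within each trait: ``h`` sums to zero
    per location, ``b`` sums to zero over hybrids and ``gca`` over parents.
    """

    mu: dict[str, float]
    g: pd.DataFrame
    h: pd.DataFrame
    b: pd.DataFrame
    gca: pd.DataFrame
    causal_main: dict[str, dict[int, float]]
    causal_plast: dict[str, dict[int, float]]
    sigma_e: float


@dataclass
class PhenotypeParams:
    """Effect-size and noise specification for :func:`simulate_phenotypes`.

    All scales are in trait units (per-trait means come from ``mu``);
    plasticity quantities are unitless slope deviations.
    """

    trait_names: tuple[str, ...] = TRAITS
    mu: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    sigma_h: float = 1.0            # sd of environment effects within a location
    sigma_e: float = 0.5            # residual sd
    n_causal_main: int = 2          # causal SNPs behind g, per trait
    n_causal_plast: int = 2         # causal SNPs behind b, per trait
    n_shared_causal: int = 0        # loci causal for both g and b
    main_effect: float = 0.8        # per-allele effect on g (trait units)
    plast_effect: float = 0.35      # per-allele effect on b (slope units)
    sigma_g_noise: float = 0.5      # polygenic remainder of g
    gca_sd: float = 0.25            # parental additive plasticity sd
    sigma_b_noise: float = 0.30     # non-additive remainder of b
    causal_main_snps: tuple[int, ...] | None = None   # override SNP indices
    causal_plast_snps: tuple[int, ...] | None = None
    causal_main_effects: tuple[float, ...] | None = None  # signed, per override SNP
    causal_plast_effects: tuple[float, ...] | None = None


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_parents(n_parents: int, n_snps: int,
                     chrom_lengths: dict[str, int] | None = None,
                     maf_range: tuple[float, float] = (0.1, 0.5),
                     seed: int = 0,
                     sample_ids: list[str] | None = None) -> GenotypeMatrix:
    """Simulate fully inbred parental genotypes (dosage 0 or 2).

    Per SNP an allele frequency is drawn uniformly from ``maf_range`` and each
    parent is homozygous ALT with that probability.  Columns that come out
    monomorphic in the sample are redrawn, so every SNP is polymorphic.
    """
    if n_parents < 2 or n_snps < 1:
        raise ParameterError("need n_parents >= 2 and n_snps >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ParameterError(f"maf_range must lie in (0, 0.5], got {maf_range}")
    chrom_lengths = chrom_lengths or DEFAULT_CHROM_LENGTHS
    rng = np.random.default_rng(seed)

    # spread SNPs over chromosomes proportionally to length
    # (largest-remainder apportionment; short panels may leave chromosomes empty)
    names = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in names], dtype=float)
    raw = n_snps * lens / lens.sum()
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts))
    counts[order[:n_snps - counts.sum()]] += 1
    chrom, pos = [], []
    for name, cnt in zip(names, counts):
        if cnt == 0:
            continue
        length = chrom_lengths[name]
        draws = np.unique(rng.integers(1, length + 1, size=2 * cnt + 10))
        while draws.size < cnt:
            draws = np.unique(np.concatenate(
                [draws, rng.integers(1, length + 1, size=cnt)]))
        p = np.sort(rng.permutation(draws)[:cnt])
        chrom.extend([name] * cnt)
        pos.extend(p.tolist())

    maf = rng.uniform(lo, hi, size=n_snps)
    dosage = np.where(rng.random((n_parents, n_snps)) < maf, 2, 0).astype(np.int8)
    for _ in range(1000):
        mono = np.flatnonzero((dosage == dosage[0]).all(axis=0))
        if mono.size == 0:
            break
        dosage[:, mono] = np.where(
            rng.random((n_parents, mono.size)) < maf[mono], 2, 0)
    else:
        # guarantee polymorphism even in pathological corners (e.g. 2 parents
        # at maf -> 0): flip one haplotype
        mono = np.flatnonzero((dosage == dosage[0]).all(axis=0))
        dosage[0, mono] = 2 - dosage[0, mono]

    if sample_ids is None:
        sample_ids = [f"P{i + 1:02d}" for i in range(n_parents)]
    snp_ids = [f"{c}_{p}" for c, p in zip(chrom, pos)]
    return GenotypeMatrix(sample_ids=sample_ids, snp_ids=snp_ids,
                          chrom=np.array(chrom, dtype=object),
                          pos=np.array(pos, dtype=np.int64),
                          ref=np.full(n_snps, "A", dtype=object),
                          alt=np.full(n_snps, "G", dtype=object),
                          dosage=dosage)


def default_parent_ids(n_female: int = 7, n_male: int = 25) -> list[str]:
    """Parent ids consistent with :func:`make_cross_design` defaults."""
    return [f"TGMS{i + 1:02d}" for i in range(n_female)] \
        + [f"R{i + 1:02d}" for i in range(n_male)]


def make_cross_design(n_female: int = 7, n_male: int = 25,
                      n_hybrids: int = 141, seed: int = 0,
                      female_ids: list[str] | None = None,
                      male_ids: list[str] | None = None) -> pd.DataFrame:
    """Sample a partial-factorial TGMS x restorer cross design.

    Draws ``n_hybrids`` distinct pairs from the full factorial, re-sampling
    until every parent appears in at least one cross.
    """
    if female_ids is None:
        female_ids = [f"TGMS{i + 1:02d}" for i in range(n_female)]
    if male_ids is None:
        male_ids = [f"R{i + 1:02d}" for i in range(n_male)]
    total = len(female_ids) * len(male_ids)
    if n_hybrids > total:
        raise ParameterError(f"cannot draw {n_hybrids} crosses from a "
                             f"{len(female_ids)}x{len(male_ids)} factorial")
    rng = np.random.default_rng(seed)
    pairs = [(f, m) for f in female_ids for m in male_ids]
    for _ in range(1000):
        idx = rng.choice(total, size=n_hybrids, replace=False)
        chosen = [pairs[i] for i in sorted(idx)]
        used = {p for pair in chosen for p in pair}
        if used == set(female_ids) | set(male_ids):
            break
    else:
        raise DataError("could not cover every parent; increase n_hybrids")
    return pd.DataFrame({
        "hybrid_id": [f"H{i + 1:03d}" for i in range(n_hybrids)],
        "female_parent": [f for f, _ in chosen],
        "male_parent": [m for _, m in chosen],
    })


def make_hybrids(parents: GenotypeMatrix, design: pd.DataFrame) -> GenotypeMatrix:
    """Derive F1 genotypes: hybrid dosage = (mother + father) / 2.

    Parents are expected inbred; a stray heterozygous parental call is
    resolved to the nearest homozygote (1 -> 2, i.e. rounded up to the ALT
    homozygote) with a logged warning.  Missing parental calls propagate to
    missing hybrid calls.
    """
    validate_design(design)
    lookup = {s: i for i, s in enumerate(parents.sample_ids)}
    unknown = [p for p in pd.concat([design["female_parent"],
                                     design["male_parent"]]).unique()
               if p not in lookup]
    if unknown:
        raise AlignmentError(f"cross design references unknown parents: {unknown}")

    pd_dosage = parents.dosage.astype(np.int16)
    het = pd_dosage == 1
    if het.any():
        logger.warning("make_hybrids: %d heterozygous parental calls rounded "
                       "to the ALT homozygote", int(het.sum()))
        pd_dosage = np.where(het, 2, pd_dosage)

    mothers = pd_dosage[[lookup[f] for f in design["female_parent"]], :]
    fathers = pd_dosage[[lookup[m] for m in design["male_parent"]], :]
    miss = (mothers == MISSING) | (fathers == MISSING)
    dosage = ((mothers + fathers) // 2).astype(np.int8)
    dosage[miss] = MISSING
    return GenotypeMatrix(sample_ids=design["hybrid_id"].tolist(),
                          snp_ids=list(parents.snp_ids),
                          chrom=parents.chrom.copy(), pos=parents.pos.copy(),
                          ref=parents.ref.copy(), alt=parents.alt.copy(),
                          dosage=dosage)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _centered_dosage(G: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    d = G.dosage[:, idx].astype(float)
    d[d == MISSING] = np.nan
    col_mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_mean, d)
    return d - col_mean


def simulate_phenotypes(hybrids: GenotypeMatrix, design: pd.DataFrame,
                        env_design: dict[str, int] | None = None,
                        params: PhenotypeParams | None = None,
                        seed: int = 0) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate reaction-norm phenotype records plus their full truth.

    One record per hybrid x location x sowing x trait.  With
    ``params.sigma_e = 0`` the records satisfy the reaction-norm identity
    exactly.  Environment effects are drawn and centered per location;
    ``b`` and ``gca`` are centered at generation so the truth obeys the same
    identifiability constraints the estimators impose.
    """
    env_design = dict(env_design or DEFAULT_ENV_DESIGN)
    params = params or PhenotypeParams()
    too_few = [loc for loc, k in env_design.items() if k < 2]
    if too_few:
        raise ParameterError(
            f"plasticity is undefined with < 2 sowings per location: {too_few}")
    if set(design["hybrid_id"]) != set(hybrids.sample_ids):
        raise AlignmentError("design hybrids do not match genotype samples")

    rng = np.random.default_rng(seed)
    n_hyb = hybrids.n_samples
    hyb_ids = hybrids.sample_ids
    parents = pd.unique(pd.concat([design["female_parent"],
                                   design["male_parent"]]))
    mother_of = dict(zip(design["hybrid_id"], design["female_parent"]))
    father_of = dict(zip(design["hybrid_id"], design["male_parent"]))

    traits = list(params.trait_names)
    mu = {t: float(params.mu.get(t, 0.0)) for t in traits}
    g_tbl = pd.DataFrame(index=hyb_ids, columns=traits, dtype=float)
    b_tbl = pd.DataFrame(index=hyb_ids, columns=traits, dtype=float)
    gca_tbl = pd.DataFrame(index=list(parents), columns=traits, dtype=float)
    env_index = pd.MultiIndex.from_tuples(
        [(loc, s) for loc, k in env_design.items() for s in range(1, k + 1)],
        names=["location_id", "sowing_index"])
    h_tbl = pd.DataFrame(index=env_index, columns=traits, dtype=float)
    causal_main: dict[str, dict[int, float]] = {}
    causal_plast: dict[str, dict[int, float]] = {}

    records = []
    for t in traits:
        # causal architecture -------------------------------------------------
        if params.causal_main_snps is not None:
            idx_main = np.asarray(params.causal_main_snps, dtype=int)
        else:
            idx_main = rng.choice(hybrids.n_snps,
                                  size=min(params.n_causal_main, hybrids.n_snps),
                                  replace=False)
        if params.causal_plast_snps is not None:
            idx_plast = np.asarray(params.causal_plast_snps, dtype=int)
        else:
            pool = np.setdiff1d(np.arange(hybrids.n_snps), idx_main)
            n_own = max(0, params.n_causal_plast - params.n_shared_causal)
            own = rng.choice(pool, size=min(n_own, pool.size), replace=False)
            shared = idx_main[:params.n_shared_causal]
            idx_plast = np.concatenate([shared, own]).astype(int)

        if params.causal_main_effects is not None:
            eff_main = np.asarray(params.causal_main_effects, dtype=float)
            if eff_main.size != idx_main.size:
                raise ParameterError("causal_main_effects length mismatch")
        else:
            eff_main = params.main_effect * rng.choice([-1.0, 1.0],
                                                       size=idx_main.size)
        if params.causal_plast_effects is not None:
            eff_plast = np.asarray(params.causal_plast_effects, dtype=float)
            if eff_plast.size != idx_plast.size:
                raise ParameterError("causal_plast_effects length mismatch")
        else:
            eff_plast = params.plast_effect * rng.choice([-1.0, 1.0],
                                                         size=idx_plast.size)
        causal_main[t] = dict(zip(idx_main.tolist(), eff_main.tolist()))
        causal_plast[t] = dict(zip(idx_plast.tolist(), eff_plast.tolist()))

        g = _centered_dosage(hybrids, idx_main) @ eff_main \
            + rng.normal(0.0, params.sigma_g_noise, n_hyb)
        g -= g.mean()

        gca = rng.normal(0.0, params.gca_sd, len(parents))
        gca -= gca.mean()
        gca_s = pd.Series(gca, index=list(parents))
        b = _centered_dosage(hybrids, idx_plast) @ eff_plast \
            + np.array([gca_s[mother_of[h]] + gca_s[father_of[h]] for h in hyb_ids]) \
            + rng.normal(0.0, params.sigma_b_noise, n_hyb)
        b -= b.mean()

        g_tbl[t] = g
        b_tbl[t] = b
        gca_tbl[t] = gca_s

        for loc, k in env_design.items():
            h = rng.normal(0.0, params.sigma_h, k)
            h -= h.mean()
            h_tbl.loc[(loc, slice(None)), t] = h
            eps = rng.normal(0.0, params.sigma_e, (n_hyb, k)) \
                if params.sigma_e > 0 else np.zeros((n_hyb, k))
            y = mu[t] + g[:, None] + h[None, :] + b[:, None] * h[None, :] + eps
            for jj in range(k):
                records.append(pd.DataFrame({
                    "hybrid_id": hyb_ids,
                    "location_id": loc,
                    "sowing_index": jj + 1,
                    "trait_name": t,
                    "value": y[:, jj],
                }))

    pheno = pd.concat(records, ignore_index=True)
    truth = TruthRecord(mu=mu, g=g_tbl, h=h_tbl, b=b_tbl, gca=gca_tbl,
                        causal_main=causal_main, causal_plast=causal_plast,
                        sigma_e=float(params.sigma_e))
    return pheno, truth


def pick_unlinked_loci(G: GenotypeMatrix, chrom_targets: tuple[str, ...],
                       maf_min: float = 0.25, n_pc: int = 3) -> list[int]:
    """Choose one marker per target chromosome to carry a programmed QTL.

    In an F1 panel bred from few founders every marker is collinear with the
    founder structure, so an arbitrary marker can be confounded with the
    population-structure covariates or with another programmed locus — in
    which case no association method could attribute the signal to it.  This
    picker returns, per chromosome, the polymorphic marker (sample MAF >
    ``maf_min``) least explained by the leading principal components and the
    loci already picked, i.e. loci that segregate (approximately)
    independently of structure and of each other.
    """
    from .association import compute_pcs   # deferred: avoids import cycle

    maf = G.minor_allele_freq()
    pcs = compute_pcs(G, n_pc).coords.to_numpy()
    base = [np.ones(G.n_samples)] + list(pcs.T)
    picks: list[int] = []
    for ch in chrom_targets:
        cand = np.flatnonzero((maf > maf_min) & (G.chrom == ch))
        if cand.size == 0:
            raise DataError(f"no marker with MAF > {maf_min} on {ch}")
        X = np.column_stack(base + [G.dosage[:, j].astype(float) for j in picks])
        best, best_r2 = int(cand[0]), np.inf
        for j in cand:
            x = G.dosage[:, j].astype(float)
            beta, *_ = np.linalg.lstsq(X, x, rcond=None)
            r2 = 1.0 - (x - X @ beta).var() / x.var()
            if r2 < best_r2:
                best, best_r2 = int(j), r2
        picks.append(best)
    return picks


# ---------------------------------------------------------------------------
# meteorology
# ---------------------------------------------------------------------------

def simulate_meteorology(locations: list[str],
                         date_ranges: dict[str, tuple[str, str]],
                         seed: int = 0, rain_prob: float = 0.4) -> pd.DataFrame:
    """Simulate daily weather per location over the given calendar ranges.

    Produces the ingredients of the seven summary factors used downstream:
    tmin/tmax/tavg, diurnal range, solar radiation (MJ m^-2 day^-1),
    daily rainfall (mm).  ``rain_prob = 0`` yields an all-dry table.
    """
    if not (0.0 <= rain_prob <= 1.0):
        raise ParameterError("rain_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    frames = []
    for loc in locations:
        try:
            start, end = date_ranges[loc]
        except KeyError as exc:
            raise ParameterError(f"no date range for location {loc}") from exc
        days = pd.date_range(start, end, freq="D")
        if len(days) == 0:
            raise ParameterError(f"reversed/empty date range for {loc}: "
                                 f"{start}..{end}")
        n = len(days)
        doy = days.dayofyear.to_numpy(float)
        tmid = 22.0 + 6.0 * np.sin(2 * np.pi * (doy - 100) / 365.0) \
            + rng.normal(0, 2.0, n)
        spread = 4.0 + np.abs(rng.normal(0, 2.0, n))
        tmin = tmid - spread / 2
        tmax = tmid + spread / 2
        tavg = tmin + rng.beta(5, 5, n) * spread
        solar = np.clip(15.0 + 5.0 * np.sin(2 * np.pi * (doy - 100) / 365.0)
                        + rng.normal(0, 3.0, n), 0.1, None)
        wet = rng.random(n) < rain_prob
        rain = np.where(wet, rng.gamma(1.5, 6.0, n), 0.0)
        frames.append(pd.DataFrame({
            "location_id": loc, "date": days,
            "tmin": tmin, "tmax": tmax, "tavg": tavg,
            "diurnal_range": tmax - tmin, "solar": solar, "rainfall": rain,
        }))
    return pd.concat(frames, ignore_index=True)
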