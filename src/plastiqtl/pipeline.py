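"""End-to-end orchestration: simulate-or-load -> FW -> GCA -> BLUP -> GWAS ->
QTL -> environment statistics.

Every stage is a pure function of (inputs, parameters, seed) and writes its
declared outputs under the run directory; :func:`run_pipeline` executes the
stages in dependency order and records a manifest (parameters, seed, output
checksums) so a rerun with the same config reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import (association, combining_ability, environment_analysis,
               fw_regression, io_formats, mixed_blup, qtl_blocks,
               synthetic_data)
from .config import RunConfig
from .exceptions import DataError, InsufficientDataError
from .qtl_blocks import qtls_to_frame

logger = logging.getLogger(__name__)

#: first-sowing calendar date and between-sowing interval (days) per default
#: location, emulating staggered spring-summer sowings
SOWING_CALENDAR = {
    "SC-GH": ("2020-04-01", 10),
    "HB-EZ": ("2020-04-15", 15),
    "AH-HF": ("2020-04-15", 15),
    "HN-CS": ("2020-04-10", 15),
    "HN-LS": ("2020-06-15", 15),
}
HEADING_OFFSET_DAYS = 75


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float)
                    + "\n", encoding="utf-8")


def make_headings(env_design: dict[str, int]) -> pd.DataFrame:
    """Deterministic sowing/heading dates per location x sowing."""
    rows = []
    for loc, k in env_design.items():
        start, interval = SOWING_CALENDAR.get(loc, ("2020-04-15", 15))
        for s in range(1, k + 1):
            sow = pd.Timestamp(start) + pd.Timedelta(days=interval * (s - 1))
            rows.append({"location_id": loc, "sowing_index": s,
                         "sowing_date": sow,
                         "heading_date": sow + pd.Timedelta(days=HEADING_OFFSET_DAYS)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    sim = cfg.simulate
    seed = cfg.stage_seed("simulate")
    env_design = dict(sim.env_design) or dict(synthetic_data.DEFAULT_ENV_DESIGN)
    ids = synthetic_data.default_parent_ids(sim.n_female, sim.n_male)
    parents = synthetic_data.simulate_parents(
        sim.n_female + sim.n_male, sim.n_snps, maf_range=sim.maf_range,
        seed=seed, sample_ids=ids)
    design = synthetic_data.make_cross_design(
        sim.n_female, sim.n_male, sim.n_hybrids, seed=seed)
    hybrids = synthetic_data.make_hybrids(parents, design)
    params = synthetic_data.PhenotypeParams(
        trait_names=sim.traits, sigma_h=sim.sigma_h, sigma_e=sim.sigma_e,
        n_causal_main=sim.n_causal_main, n_causal_plast=sim.n_causal_plast,
        n_shared_causal=sim.n_shared_causal)
    pheno, truth = synthetic_data.simulate_phenotypes(
        hybrids, design, env_design, params, seed=seed + 1)
    headings = make_headings(env_design)
    span = (headings["sowing_date"].min() - pd.Timedelta(days=5),
            headings["heading_date"].max() + pd.Timedelta(days=25))
    met = synthetic_data.simulate_meteorology(
        list(env_design), {loc: (span[0].isoformat(), span[1].isoformat())
                           for loc in env_design},
        seed=seed + 2, rain_prob=sim.rain_prob)

    io_formats.write_vcf(parents, outdir / "parents.vcf")
    io_formats.write_vcf(hybrids, outdir / "hybrids.vcf")
    io_formats.write_design(design, outdir / "design.csv")
    io_formats.write_phenotypes(pheno, outdir / "phenotypes.csv")
    io_formats.write_meteorology(met, outdir / "meteorology.csv")
    hd = headings.copy()
    for col in ("sowing_date", "heading_date"):
        hd[col] = hd[col].dt.strftime("%Y-%m-%d")
    hd.to_csv(outdir / "headings.csv", index=False)
    _write_json({
        "mu": truth.mu,
        "sigma_e": truth.sigma_e,
        "b": {t: truth.b[t].round(10).to_dict() for t in truth.b.columns},
        "gca": {t: truth.gca[t].round(10).to_dict() for t in truth.gca.columns},
        "causal_main": {t: {str(k): v for k, v in d.items()}
                        for t, d in truth.causal_main.items()},
        "causal_plast": {t: {str(k): v for k, v in d.items()}
                         for t, d in truth.causal_plast.items()},
    }, outdir / "truth.json")
    return {"outputs": ["parents.vcf", "hybrids.vcf", "design.csv",
                        "phenotypes.csv", "meteorology.csv", "headings.csv",
                        "truth.json"]}


def _pheno_path(cfg: RunConfig, outdir: Path) -> Path:
    if cfg.inputs is not None:
        return Path(cfg.inputs.phenotypes_csv)
    return outdir / "phenotypes.csv"


def _design_path(cfg: RunConfig, outdir: Path) -> Path:
    if cfg.inputs is not None:
        return Path(cfg.inputs.design_csv)
    return outdir / "design.csv"


def _geno_path(cfg: RunConfig, outdir: Path) -> Path:
    if cfg.inputs is not None:
        return Path(cfg.inputs.genotypes_vcf)
    return outdir / "hybrids.vcf"


def stage_fw(cfg: RunConfig, outdir: Path) -> dict:
    pheno = io_formats.read_phenotypes(_pheno_path(cfg, outdir))
    fits, rows, summaries = [], [], {}
    for (trait, loc), grp in pheno.groupby(["trait_name", "location_id"]):
        try:
            fit = fw_regression.fit_fw_als(grp, tol=cfg.fw_tol,
                                           max_iter=cfg.fw_max_iter,
                                           min_env=cfg.fw_min_env)
        except InsufficientDataError as exc:
            logger.warning("fw %s/%s skipped: %s", trait, loc, exc)
            continue
        fits.append(fit)
        for hyb in fit.b.index:
            rows.append({"trait_name": trait, "location_id": loc,
                         "hybrid_id": hyb, "g": fit.g[hyb], "b": fit.b[hyb],
                         "slope": 1.0 + fit.b[hyb]})
        summaries[f"{trait}:{loc}"] = {
            "mu": fit.mu, "h": fit.h.to_dict(), "resid_var": fit.resid_var,
            "n_iter": fit.n_iter, "converged": fit.converged,
            "degenerate": fit.degenerate,
            "dropped_hybrids": fit.dropped_hybrids}
    if not fits:
        raise DataError("no (trait, location) cell could be fitted")
    pd.DataFrame(rows).to_csv(outdir / "fw_estimates.csv", index=False)
    _write_json(summaries, outdir / "fw_summary.json")
    return {"outputs": ["fw_estimates.csv", "fw_summary.json"]}


def stage_gca(cfg: RunConfig, outdir: Path) -> dict:
    est = pd.read_csv(outdir / "fw_estimates.csv")
    design = io_formats.read_design(_design_path(cfg, outdir))
    fits = []
    for (trait, loc), grp in est.groupby(["trait_name", "location_id"]):
        b = grp.set_index("hybrid_id")["b"]
        fits.append(combining_ability.fit_gca(b, design, trait_name=trait,
                                              location_id=loc))
    values, signs = combining_ability.gca_heatmap_table(fits)
    rows = []
    for fit in fits:
        for parent, val in fit.gca.items():
            rows.append({"parent_id": parent, "trait": fit.trait_name,
                         "location": fit.location_id, "gca": val,
                         "sign_tag": signs.loc[parent,
                                               (fit.trait_name, fit.location_id)],
                         "zeroed": fit.zeroed})
    pd.DataFrame(rows).to_csv(outdir / "gca.csv", index=False)
    stable = combining_ability.select_stable_parents(values)
    _write_json({"stable_parents": stable,
                 "rule": {"max_gca": 0.0, "min_locations": 4, "min_traits": 5}},
                outdir / "gca_selection.json")
    return {"outputs": ["gca.csv", "gca_selection.json"]}


def stage_blup(cfg: RunConfig, outdir: Path) -> dict:
    pheno = io_formats.read_phenotypes(_pheno_path(cfg, outdir))
    rows, comps = [], {}
    if cfg.blup_scope == "per_location":
        for (trait, loc), grp in pheno.groupby(["trait_name", "location_id"]):
            fit = mixed_blup.fit_blup(grp, scope="per_location")
            comps[f"{trait}:{loc}"] = _blup_components(fit)
            for hyb, v in fit.line_blup.items():
                rows.append({"hybrid_id": hyb, "trait": trait, "scope": loc,
                             "blup": v})
    else:
        for trait in pheno["trait_name"].unique():
            fit = mixed_blup.fit_blup(pheno[pheno["trait_name"] == trait],
                                      scope="cross_location")
            comps[trait] = _blup_components(fit)
            for hyb, v in fit.line_blup.items():
                rows.append({"hybrid_id": hyb, "trait": trait,
                             "scope": "pooled", "blup": v})
    pd.DataFrame(rows).to_csv(outdir / "blup.csv", index=False)
    _write_json(comps, outdir / "blup_components.json")
    return {"outputs": ["blup.csv", "blup_components.json"]}


def _blup_components(fit: mixed_blup.BLUPFit) -> dict:
    return {"var_line": fit.var_line, "var_env": fit.var_env,
            "var_interaction": fit.var_interaction,
            "var_resid": fit.var_resid, "loglik_reml": fit.loglik_reml,
            "interaction_dropped": fit.interaction_dropped}


def _gwas_targets(cfg: RunConfig, est: pd.DataFrame):
    traits = cfg.gwas_traits or tuple(est["trait_name"].unique())
    locs = cfg.gwas_locations or tuple(est["location_id"].unique())
    return [t for t in traits if t in set(est["trait_name"])], \
           [l for l in locs if l in set(est["location_id"])]


def stage_gwas(cfg: RunConfig, outdir: Path) -> dict:
    G = io_formats.read_vcf(_geno_path(cfg, outdir))
    K = association.compute_kinship(G)
    est = pd.read_csv(outdir / "fw_estimates.csv")
    blup = pd.read_csv(outdir / "blup.csv")
    traits, locs = _gwas_targets(cfg, est)
    outputs = []
    for trait in traits:
        for loc in locs:
            sub = est[(est["trait_name"] == trait) & (est["location_id"] == loc)]
            if not sub.empty:
                y = sub.set_index("hybrid_id")["b"]
                res = association.mlm_gwas(y, G, K, n_pc=cfg.gwas_n_pc)
                name = f"gwas_fw_{trait}_{loc}.tsv"
                association.write_assoc(res, outdir / name)
                outputs.append(name)
            bsub = blup[(blup["trait"] == trait)
                        & (blup["scope"].isin([loc, "pooled"]))]
            if not bsub.empty:
                y = bsub.set_index("hybrid_id")["blup"]
                res = association.mlm_gwas(y, G, K, n_pc=cfg.gwas_n_pc)
                name = f"gwas_blup_{trait}_{bsub['scope'].iloc[0]}.tsv"
                if name not in outputs:
                    association.write_assoc(res, outdir / name)
                    outputs.append(name)
    if not outputs:
        raise DataError("no GWAS target matched the configuration")
    return {"outputs": outputs}


def stage_qtl(cfg: RunConfig, outdir: Path) -> dict:
    G = io_formats.read_vcf(_geno_path(cfg, outdir))
    blocks = qtl_blocks.partition_ld_blocks(G, r2_threshold=cfg.qtl_r2_threshold,
                                            window=cfg.qtl_window)
    frames = []
    for path in sorted(outdir.glob("gwas_*.tsv")):
        res = association.read_assoc(path)
        n_tested = int(res["p_wald"].notna().sum())
        if n_tested == 0:
            continue
        thr, _ = association.bonferroni_threshold(n_tested, cfg.gwas_alpha)
        tag = path.stem.replace("gwas_", "")
        calls = qtl_blocks.call_qtls(res, blocks, p_threshold=thr,
                                     merge_bp=cfg.qtl_merge_bp,
                                     trait_name=tag, qtl_prefix=f"{tag}_QTL")
        if calls:
            frames.append(qtls_to_frame(calls).assign(scan=tag))
    qtls = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end", "qtl_id", "lead_pos",
                 "lead_neglog10p", "trait", "location", "pve_pct", "scan"])
    with open(outdir / "qtls.tsv", "w", encoding="utf-8") as fh:
        fh.write("# 0-based half-open intervals\n")
        qtls.to_csv(fh, sep="\t", index=False)
    return {"outputs": ["qtls.tsv"]}


def stage_envstats(cfg: RunConfig, outdir: Path) -> dict:
    pheno = io_formats.read_phenotypes(_pheno_path(cfg, outdir))
    if cfg.inputs is not None:
        met = io_formats.read_meteorology(cfg.inputs.meteorology_csv)
        headings = pd.read_csv(cfg.inputs.headings_csv)
    else:
        met = io_formats.read_meteorology(outdir / "meteorology.csv")
        headings = pd.read_csv(outdir / "headings.csv")
    factors = environment_analysis.window_factors(
        met, headings, window_days=cfg.env_window_days)
    corr = environment_analysis.correlate_traits_factors(pheno, factors)
    factors.to_csv(outdir / "window_factors.csv", index=False)
    corr.to_csv(outdir / "trait_weather_correlations.csv", index=False)
    return {"outputs": ["window_factors.csv", "trait_weather_correlations.csv"]}


STAGE_FUNCS = {
    "simulate": stage_simulate, "fw": stage_fw, "gca": stage_gca,
    "blup": stage_blup, "gwas": stage_gwas, "qtl": stage_qtl,
    "envstats": stage_envstats,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in dependency order; returns the run manifest."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(STAGE_FUNCS)
    if cfg.simulate is None:
        stages.remove("simulate")
        if cfg.inputs.meteorology_csv is None or cfg.inputs.headings_csv is None:
            stages.remove("envstats")
    manifest: dict = {"seed": cfg.seed, "stages": {}, "config": _cfg_dict(cfg)}
    for stage in stages:
        try:
            info = STAGE_FUNCS[stage](cfg, outdir)
        except Exception:
            manifest["stages"][stage] = {"status": "failed"}
            _write_json(manifest, outdir / "manifest.json")
            logger.error("pipeline aborted at stage %s", stage)
            raise
        info["status"] = "ok"
        info["checksums"] = {f: _sha256(outdir / f) for f in info["outputs"]}
        manifest["stages"][stage] = info
    _write_json(manifest, outdir / "manifest.json")
    return manifest


def _cfg_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    return d
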