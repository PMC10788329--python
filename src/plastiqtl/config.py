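"""Run configuration: one YAML file drives simulation and every stage.

All stage parameters are validated before any stage runs; a single global
seed fans out to per-stage streams (derived deterministically, kept below
2^31 so they remain portable integers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ParameterError

STAGES = ("simulate", "fw", "gca", "blup", "gwas", "qtl", "envstats")


@dataclass
class SimulateConfig:
    n_female: int = 7
    n_male: int = 25
    n_hybrids: int = 141
    n_snps: int = 600
    maf_range: tuple[float, float] = (0.1, 0.5)
    env_design: dict[str, int] = field(default_factory=dict)  # empty -> default
    traits: tuple[str, ...] = ("AC", "CD")
    sigma_h: float = 1.0
    sigma_e: float = 0.5
    n_causal_main: int = 2
    n_causal_plast: int = 2
    n_shared_causal: int = 1
    rain_prob: float = 0.4


@dataclass
class InputConfig:
    """Paths to pre-existing inputs (alternative to simulation)."""

    genotypes_vcf: str | None = None
    phenotypes_csv: str | None = None
    design_csv: str | None = None
    meteorology_csv: str | None = None
    headings_csv: str | None = None


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "plastiqtl_out"
    simulate: SimulateConfig | None = None
    inputs: InputConfig | None = None
    fw_tol: float = 1e-10
    fw_max_iter: int = 500
    fw_min_env: int = 3
    blup_scope: str = "per_location"
    gwas_n_pc: int = 3
    gwas_alpha: float = 0.05
    qtl_r2_threshold: float = 0.6
    qtl_window: int = 20
    qtl_merge_bp: int = 1_000_000
    env_window_days: int = 15
    gwas_traits: tuple[str, ...] = ()       # empty -> all simulated traits
    gwas_locations: tuple[str, ...] = ()    # empty -> all locations

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed below 2^31."""
        if stage not in STAGES:
            raise ParameterError(f"unknown stage {stage!r}")
        ss = np.random.SeedSequence([int(self.seed), STAGES.index(stage)])
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))

    def validate(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ParameterError(
                "config needs either a 'simulate' block or an 'inputs' block")
        if self.simulate is not None and self.inputs is not None:
            raise ParameterError("give either 'simulate' or 'inputs', not both")
        if self.inputs is not None:
            missing = [f for f in ("genotypes_vcf", "phenotypes_csv", "design_csv")
                       if getattr(self.inputs, f) is None]
            if missing:
                raise ParameterError(f"inputs block lacks {missing}")
        if self.blup_scope not in ("per_location", "cross_location"):
            raise ParameterError(f"bad blup_scope {self.blup_scope!r}")
        if not (0 < self.gwas_alpha < 1):
            raise ParameterError("gwas_alpha must lie in (0,1)")
        if not (0 < self.qtl_r2_threshold <= 1):
            raise ParameterError("qtl_r2_threshold must lie in (0,1]")
        if self.fw_min_env < 3:
            raise ParameterError("fw_min_env must be >= 3")


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    sim = raw.pop("simulate", None)
    inp = raw.pop("inputs", None)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**{k: tuple(v) if isinstance(v, list) else v
                       for k, v in raw.items()})
    if sim is not None:
        bad = set(sim) - set(SimulateConfig.__dataclass_fields__)
        if bad:
            raise ParameterError(f"unknown simulate keys: {sorted(bad)}")
        sim = {k: tuple(v) if isinstance(v, list) and k in
               ("maf_range", "traits") else v for k, v in sim.items()}
        cfg.simulate = SimulateConfig(**sim)
    if inp is not None:
        bad = set(inp) - set(InputConfig.__dataclass_fields__)
        if bad:
            raise ParameterError(f"unknown inputs keys: {sorted(bad)}")
        cfg.inputs = InputConfig(**inp)
    cfg.validate()
    return cfg
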