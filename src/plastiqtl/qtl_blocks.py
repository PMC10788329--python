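"""LD-block partitioning and block-based QTL calling.

The genome is split into blocks of adjacent SNPs in high linkage
disequilibrium (pairwise composite-genotype r^2 against a threshold, default
0.6) by a deterministic greedy rule: a SNP extends the current block when its
r^2 with at least one of the last ``window`` SNPs already in the block reaches
the threshold, otherwise it starts a new block.  Blocks containing at least
one significant SNP are candidate QTLs; significant blocks on a chromosome
separated by less than 1 Mb are merged (strictly: a gap of exactly 1 Mb is
not merged).  Internally coordinates are 1-based inclusive; exports are
BED-style 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io_formats import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class LDBlock:
    chrom: str
    start: int                  # bp of first member SNP (1-based)
    end: int                    # bp of last member SNP (1-based, inclusive)
    snp_indices: list[int]      # column indices into the genotype matrix

    @property
    def start0(self) -> int:    # BED-style export
        return self.start - 1

    @property
    def end0(self) -> int:
        return self.end


@dataclass
class QTLCall:
    qtl_id: str
    chrom: str
    start: int                  # merged span, 1-based inclusive
    end: int
    lead_pos: int
    lead_alleles: tuple[str, str]
    lead_neglog10p: float
    trait_name: str = ""
    location_id: str = ""
    pve_pct: float = np.nan


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def pairwise_r2(G: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of two dosage columns.

    Samples missing either call are dropped pairwise; a monomorphic SNP
    yields NaN (undefined LD).
    """
    a = G.dosage[:, i].astype(float)
    b = G.dosage[:, j].astype(float)
    keep = (a != MISSING) & (b != MISSING)
    a, b = a[keep], b[keep]
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def partition_ld_blocks(G: GenotypeMatrix, r2_threshold: float = 0.6,
                        window: int = 20) -> list[LDBlock]:
    """Greedy adjacency segmentation of each chromosome into LD blocks.

    Every SNP belongs to exactly one block; singleton blocks are allowed.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ParameterError("r2_threshold must lie in (0, 1]")
    if window < 1:
        raise ParameterError("window must be >= 1")
    blocks: list[LDBlock] = []
    for ch in dict.fromkeys(G.chrom):
        idx = np.flatnonzero(G.chrom == ch)
        current = [int(idx[0])]
        for k in idx[1:]:
            k = int(k)
            tail = current[-window:]
            linked = False
            for t in tail:
                r2 = pairwise_r2(G, k, t)
                if not np.isnan(r2) and r2 >= r2_threshold:
                    linked = True
                    break
            if linked:
                current.append(k)
            else:
                blocks.append(LDBlock(chrom=str(ch),
                                      start=int(G.pos[current[0]]),
                                      end=int(G.pos[current[-1]]),
                                      snp_indices=current))
                current = [k]
        blocks.append(LDBlock(chrom=str(ch), start=int(G.pos[current[0]]),
                              end=int(G.pos[current[-1]]), snp_indices=current))
    return blocks


# ---------------------------------------------------------------------------
# QTL calling
# ---------------------------------------------------------------------------

def pve_of_snp(beta: float, af: float, var_y: float) -> float:
    """Percent phenotypic variance explained: 2 af (1-af) beta^2 / var_y x 100.

    The estimate is capped at 100 with a warning when sampling noise pushes
    it past the ceiling.
    """
    if not (0.0 < af < 1.0):
        raise ParameterError(f"allele frequency must lie in (0,1), got {af}")
    if var_y <= 0:
        raise ParameterError("var_y must be positive")
    pve = 100.0 * 2.0 * af * (1.0 - af) * beta * beta / var_y
    if pve > 100.0:
        logger.warning("PVE estimate %.1f%% exceeds 100%%; capped", pve)
        pve = 100.0
    return float(pve)


def call_qtls(assoc: pd.DataFrame, blocks: list[LDBlock], p_threshold: float,
              merge_bp: int = 1_000_000, trait_name: str = "",
              location_id: str = "", var_y: float | None = None,
              qtl_prefix: str = "QTL") -> list[QTLCall]:
    """Call QTLs from an association scan and an LD-block partition.

    A SNP is significant iff ``p < p_threshold``; blocks holding at least one
    significant SNP are selected and same-chromosome selected blocks whose
    gap is below ``merge_bp`` are merged.  The lead SNP of a QTL is its
    member with the largest -log10 p (ties broken by smaller position).
    With ``var_y`` the lead SNP's percent variance explained is attached.
    """
    if assoc.empty:
        return []
    sig = assoc.loc[assoc["p_wald"] < p_threshold]
    if sig.empty:
        return []
    sig_keys = set(zip(sig["chr"], sig["pos"]))

    selected = []
    for blk in blocks:
        members = {(blk.chrom, int(p)) for p in _member_positions(assoc, blk)}
        if members & sig_keys:
            selected.append(blk)

    # merge selected blocks per chromosome when the gap is < merge_bp
    calls: list[QTLCall] = []
    regions: list[tuple[str, int, int]] = []
    for chrom in dict.fromkeys(b.chrom for b in selected):
        chrom_blocks = sorted((b for b in selected if b.chrom == chrom),
                              key=lambda b: b.start)
        cur = [chrom_blocks[0].start, chrom_blocks[0].end]
        for blk in chrom_blocks[1:]:
            gap = blk.start - cur[1]
            if gap < merge_bp:
                cur[1] = max(cur[1], blk.end)
            else:
                regions.append((chrom, cur[0], cur[1]))
                cur = [blk.start, blk.end]
        regions.append((chrom, cur[0], cur[1]))

    for k, (chrom, start, end) in enumerate(regions, start=1):
        members = assoc.loc[(assoc["chr"] == chrom) & (assoc["pos"] >= start)
                            & (assoc["pos"] <= end)
                            & assoc["neglog10p"].notna()]
        members = members.sort_values(["neglog10p", "pos"],
                                      ascending=[False, True])
        lead = members.iloc[0]
        pve = np.nan
        if var_y is not None and 0.0 < lead["af"] < 1.0:
            pve = pve_of_snp(float(lead["beta"]), float(lead["af"]), var_y)
        calls.append(QTLCall(
            qtl_id=f"{qtl_prefix}{k}", chrom=str(chrom), start=int(start),
            end=int(end), lead_pos=int(lead["pos"]),
            lead_alleles=(str(lead["allele0"]), str(lead["allele1"])),
            lead_neglog10p=float(lead["neglog10p"]),
            trait_name=trait_name, location_id=location_id, pve_pct=pve))
    return calls


def _member_positions(assoc: pd.DataFrame, blk: LDBlock) -> np.ndarray:
    mask = (assoc["chr"] == blk.chrom) & (assoc["pos"] >= blk.start) \
        & (assoc["pos"] <= blk.end)
    return assoc.loc[mask, "pos"].to_numpy()


def overlap_qtls(set_a: list[QTLCall],
                 set_b: list[QTLCall]) -> list[tuple[QTLCall, QTLCall]]:
    """Pairs of QTLs whose half-open regions share >= 1 bp on one chromosome."""
    pairs = []
    for qa in set_a:
        for qb in set_b:
            if qa.chrom != qb.chrom:
                continue
            # half-open [start-1, end) intersection
            lo = max(qa.start - 1, qb.start - 1)
            hi = min(qa.end, qb.end)
            if hi - lo >= 1:
                pairs.append((qa, qb))
    return pairs


def qtls_to_frame(calls: list[QTLCall]) -> pd.DataFrame:
    """BED-like table (0-based half-open) for export."""
    return pd.DataFrame([{
        "chrom": q.chrom, "start": q.start - 1, "end": q.end,
        "qtl_id": q.qtl_id, "lead_pos": q.lead_pos,
        "lead_neglog10p": q.lead_neglog10p, "trait": q.trait_name,
        "location": q.location_id, "pve_pct": q.pve_pct,
    } for q in calls])
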