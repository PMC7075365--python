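"""Four-stage SNP retention: hard INFO thresholds, biallelic-only,
MAF/missingness, and sliding-window LD pruning.

LD here is composite (genotypic): r² is the squared Pearson correlation of
ALT dosages over pairwise-complete samples — phase is never inferred.  When a
pair violates the r² ceiling the lower-MAF site is removed (tie: the later
site in order), which keeps the sweep deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io_formats import MISSING, GenotypeMatrix

__all__ = [
    "FilterConfig",
    "StageReport",
    "FilterReport",
    "hard_filter_info",
    "site_sample_filter",
    "ld_prune",
    "apply_filters",
]

logger = logging.getLogger(__name__)

#: comparator name -> "value fails if comparator(value, threshold)"
_COMPARATORS: dict[str, Callable[[float, float], bool]] = {
    "lt": lambda v, t: v < t,
    "gt": lambda v, t: v > t,
}

DEFAULT_HARD_FILTERS: dict[str, tuple[str, float]] = {
    "QUAL": ("lt", 50.0),
    "QD": ("lt", 2.0),
    "FS": ("gt", 60.0),
    "MQ": ("lt", 40.0),
    "MQRankSum": ("lt", -12.5),
    "ReadPosRankSum": ("lt", -8.0),
}


@dataclass
class FilterConfig:
    maf_min: float = 0.05
    missing_max: float = 0.10
    biallelic_only: bool = True
    hard_filter_thresholds: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_HARD_FILTERS)
    )
    ld_window_sites: int = 50
    ld_step_sites: int = 10
    ld_r2_max: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if not 0.0 <= self.missing_max <= 1.0:
            raise ValueError("missing_max must be in [0, 1]")
        if not self.ld_window_sites >= self.ld_step_sites >= 1:
            raise ValueError("require window >= step >= 1")
        for key, (op, _) in self.hard_filter_thresholds.items():
            if op not in _COMPARATORS:
                raise ValueError(f"unknown comparator {op!r} for {key}")


@dataclass
class StageReport:
    stage: str
    n_in: int
    n_out: int
    removed_indices: list[int]  # indices into the stage's *input* site order


@dataclass
class FilterReport:
    stages: list[StageReport] = field(default_factory=list)

    def add(self, stage: StageReport) -> None:
        if self.stages and stage.n_in != self.stages[-1].n_out:
            raise ValueError("stage inputs do not chain")
        self.stages.append(stage)

    @property
    def n_in(self) -> int:
        return self.stages[0].n_in if self.stages else 0

    @property
    def n_out(self) -> int:
        return self.stages[-1].n_out if self.stages else 0

    def to_rows(self) -> list[dict]:
        return [
            {
                "stage": s.stage,
                "sites_in": s.n_in,
                "sites_out": s.n_out,
                "sites_removed": s.n_in - s.n_out,
            }
            for s in self.stages
        ]


def hard_filter_info(
    geno: GenotypeMatrix, cfg: FilterConfig
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop a site iff any *present* INFO key violates its threshold.

    Absent keys never trigger removal; sites with no INFO map at all are kept
    with a logged warning.
    """
    keep, removed = [], []
    n_blank = 0
    for j, site in enumerate(geno.sites):
        if not site.info:
            n_blank += 1
        bad = False
        for key, (op, threshold) in cfg.hard_filter_thresholds.items():
            if key in site.info and _COMPARATORS[op](site.info[key], threshold):
                bad = True
                break
        (removed if bad else keep).append(j)
    if n_blank:
        logger.warning("%d sites had no INFO map; kept by policy", n_blank)
    report = FilterReport(
        [StageReport("hard_info", geno.n_sites, len(keep), removed)]
    )
    return geno.take_sites(keep), report


def site_sample_filter(
    geno: GenotypeMatrix, cfg: FilterConfig
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove non-biallelic sites, then sites with MAF < maf_min or missing
    fraction > missing_max (MAF on non-missing alleles)."""
    report = FilterReport()

    if cfg.biallelic_only:
        keep = [j for j, s in enumerate(geno.sites) if s.is_biallelic]
        removed = [j for j in range(geno.n_sites) if j not in set(keep)]
        report.add(StageReport("biallelic", geno.n_sites, len(keep), removed))
        geno = geno.take_sites(keep)

    d = geno.dosages
    called = d != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(d == MISSING, 0, d).sum(axis=0) / (2.0 * n_called)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    missing_frac = 1.0 - n_called / geno.n_samples
    ok = (n_called > 0) & (maf >= cfg.maf_min) & (missing_frac <= cfg.missing_max)
    keep = np.flatnonzero(ok).tolist()
    removed = np.flatnonzero(~ok).tolist()
    report.add(StageReport("maf_missing", geno.n_sites, len(keep), removed))
    if not keep:
        warnings.warn("all sites removed by MAF/missingness filter")
    return geno.take_sites(keep), report


def _dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation over pairwise-complete samples.

    Undefined correlations (fewer than 2 complete pairs, or a constant
    vector) count as 0, i.e. never trigger removal.
    """
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    c = np.mean((x - x.mean()) * (y - y.mean()))
    return float(c * c / (vx * vy))


def ld_prune(
    geno: GenotypeMatrix, cfg: FilterConfig
) -> tuple[GenotypeMatrix, FilterReport]:
    """Sliding-window greedy LD pruning (windows counted in sites).

    Within each window of ``ld_window_sites`` kept sites, advanced by
    ``ld_step_sites`` per chromosome, every ordered pair is scanned; when r²
    exceeds ``ld_r2_max`` the lower-MAF member is removed (tie: the later
    site).  Sweeps repeat over the surviving sites until a full pass removes
    nothing, so no within-window pair of the *output* violates the ceiling.
    A window with < 2 sites is a no-op.
    """
    n = geno.n_sites
    kept = np.ones(n, dtype=bool)

    d = geno.dosages
    called = d != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(d == MISSING, 0, d).sum(axis=0) / (2.0 * n_called)
    maf = np.minimum(p_alt, 1.0 - p_alt)

    # chromosome-contiguous index blocks, in input order
    blocks: list[list[int]] = []
    for j, site in enumerate(geno.sites):
        if blocks and geno.sites[blocks[-1][-1]].chrom == site.chrom:
            blocks[-1].append(j)
        else:
            blocks.append([j])

    changed = True
    while changed:
        changed = False
        for block in blocks:
            alive = [j for j in block if kept[j]]
            m = len(alive)
            start = 0
            while True:
                window = alive[start : start + cfg.ld_window_sites]
                if len(window) >= 2:
                    for a_pos, ja in enumerate(window):
                        if not kept[ja]:
                            continue
                        for jb in window[a_pos + 1 :]:
                            if not kept[ja]:
                                break
                            if not kept[jb]:
                                continue
                            r2 = _dosage_r2(d[:, ja], d[:, jb])
                            if r2 > cfg.ld_r2_max:
                                if maf[ja] < maf[jb]:
                                    kept[ja] = False
                                else:
                                    kept[jb] = False  # tie: drop the later site
                                changed = True
                if start + cfg.ld_window_sites >= m:
                    break
                start += cfg.ld_step_sites

    keep = np.flatnonzero(kept).tolist()
    removed = np.flatnonzero(~kept).tolist()
    report = FilterReport([StageReport("ld_prune", n, len(keep), removed)])
    return geno.take_sites(keep), report


def apply_filters(
    geno: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Full chain: hard INFO filter → biallelic → MAF/missing → LD prune."""
    cfg = cfg or FilterConfig()
    out = FilterReport()
    geno, rep = hard_filter_info(geno, cfg)
    for s in rep.stages:
        out.add(s)
    geno, rep = site_sample_filter(geno, cfg)
    for s in rep.stages:
        out.add(s)
    geno, rep = ld_prune(geno, cfg)
    for s in rep.stages:
        out.add(s)
    return geno, out
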