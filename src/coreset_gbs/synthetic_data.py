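"""Structured SNP panels and leaf-trait phenotypes for pipeline testing.

Genotypes follow a Balding–Nichols construction with admixture: each site
has an ancestral frequency drawn uniformly from a configured range, each
subpopulation draws its own frequency from Beta(p(1−F)/F, (1−p)(1−F)/F),
individual ancestries come from a Dirichlet, and genotypes are
Binomial(2, ancestry-weighted frequency).  This matches exactly the
structure the Q+K association model assumes and runs in milliseconds.

Traits are built from a latent genetic value (planted additive effects plus
an optional polygenic term drawn against the realized kinship), shared
across the two seasons, with a shared non-genetic accession effect sized to
hit the target cross-season correlation and independent per-season noise.
Leaf length and width are generated jointly; shape index and area are
derived as MLL/MLW and 0.75·MLW·MLL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, PhenotypeTable, SiteRecord

__all__ = [
    "PanelSimConfig",
    "TraitSimConfig",
    "PanelTruth",
    "TraitTruth",
    "simulate_panel",
    "simulate_traits",
    "simulate_traits_with_admixture",
]

_NUCS = np.array(list("ACGT"))


@dataclass
class PanelSimConfig:
    n_samples: int = 400
    n_sites: int = 5000
    n_subpops: int = 3
    fst: float = 0.10
    admixture_alpha: float = 0.2
    freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.02
    n_chroms: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("freq_range must satisfy 0 < lo < hi < 1")


@dataclass
class PanelTruth:
    config: PanelSimConfig
    ancestral_freqs: np.ndarray  # (n_sites,)
    subpop_freqs: np.ndarray  # (n_subpops, n_sites)
    admixture: np.ndarray  # (n_samples, n_subpops)
    subpop_of: np.ndarray  # argmax ancestry per sample

    def to_jsonable(self) -> dict:
        return {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.config.__dict__.items()
            },
            "ancestral_freqs": self.ancestral_freqs.tolist(),
            "subpop_freqs": self.subpop_freqs.tolist(),
            "admixture": self.admixture.tolist(),
            "subpop_of": self.subpop_of.tolist(),
        }


def simulate_panel(cfg: PanelSimConfig) -> tuple[GenotypeMatrix, PanelTruth]:
    """Generate a seeded structured panel plus its truth record."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.freq_range
    p_anc = rng.uniform(lo, hi, size=cfg.n_sites)
    f = cfg.fst
    a = p_anc * (1.0 - f) / f
    b = (1.0 - p_anc) * (1.0 - f) / f
    subpop_freqs = rng.beta(a, b, size=(cfg.n_subpops, cfg.n_sites))
    admixture = rng.dirichlet(
        np.full(cfg.n_subpops, cfg.admixture_alpha), size=cfg.n_samples
    )
    p_ind = admixture @ subpop_freqs  # (n_samples, n_sites)
    dosages = rng.binomial(2, p_ind).astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = MISSING

    sample_ids = [f"acc{i+1:04d}" for i in range(cfg.n_samples)]
    per_chrom = int(np.ceil(cfg.n_sites / cfg.n_chroms))
    sites = []
    for j in range(cfg.n_sites):
        chrom = f"PG_{j // per_chrom + 1}"
        pos = (j % per_chrom + 1) * 100 + int(rng.integers(0, 50))
        ref, alt = rng.choice(_NUCS, size=2, replace=False)
        sites.append(SiteRecord(chrom, pos, str(ref), str(alt)))
    geno = GenotypeMatrix(sample_ids, sites, dosages)
    truth = PanelTruth(
        config=cfg,
        ancestral_freqs=p_anc,
        subpop_freqs=subpop_freqs,
        admixture=admixture,
        subpop_of=np.argmax(admixture, axis=1),
    )
    return geno, truth


@dataclass
class TraitSimConfig:
    causal_sites: tuple[int, ...] = ()
    causal_effects: tuple[float, ...] = ()
    h2: float = 0.4
    polygenic_share: float = 0.5
    subpop_shifts: tuple[float, ...] = ()
    season_r: float = 0.9
    trait_cor: float = 0.86
    mll_mean: float = 8.65
    mll_sd: float = 2.25
    mlw_mean: float = 3.75
    mlw_sd: float = 0.93
    seasons: tuple[str, str] = ("spring", "fall")
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.causal_sites) != len(self.causal_effects):
            raise ValueError("causal_sites and causal_effects differ in length")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if not 0.0 <= self.polygenic_share <= 1.0:
            raise ValueError("polygenic_share must be in [0, 1]")
        if not 0.0 < self.season_r <= 1.0:
            raise ValueError("season_r must be in (0, 1]")
        if self.season_r < self.h2:
            raise ValueError(
                "season_r < h2 is unreachable: the shared genetic value alone "
                "induces a cross-season correlation of h2"
            )
        if self.h2 == 1.0 and self.season_r < 1.0:
            raise ValueError("h2 = 1 forces season_r = 1 (no room for noise)")


@dataclass
class TraitTruth:
    config: TraitSimConfig
    genetic_values: np.ndarray  # latent standardized genetic value per sample
    causal_component: np.ndarray
    polygenic_component: np.ndarray
    effective_betas_mll: dict[int, float]  # per causal site, on the MLL scale

    def to_jsonable(self) -> dict:
        return {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.config.__dict__.items()
            },
            "genetic_values": self.genetic_values.tolist(),
            "effective_betas_mll": {
                str(k): v for k, v in self.effective_betas_mll.items()
            },
        }


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    if sd == 0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def simulate_traits(
    geno: GenotypeMatrix, cfg: TraitSimConfig
) -> tuple[PhenotypeTable, TraitTruth]:
    """Two-season leaf traits with planted causal SNPs and known truth.

    The per-season variance decomposition of the latent MLL-scale trait is
    h2 genetic (split causal vs polygenic by ``polygenic_share``),
    ``season_r − h2`` shared non-genetic accession effect, and the remainder
    independent season noise — so the cross-season correlation targets
    ``season_r``.  Subpopulation mean shifts (confounders) are added on top
    when configured.
    """
    rng = np.random.default_rng(cfg.seed)
    n = geno.n_samples
    for j in cfg.causal_sites:
        if not 0 <= j < geno.n_sites:
            raise ValueError(f"causal site index {j} outside panel")

    # causal component on the standardized latent scale
    causal = np.zeros(n)
    if cfg.causal_sites:
        d = geno.dosages[:, list(cfg.causal_sites)].astype(float)
        d[d == MISSING] = np.nan
        d = np.where(np.isnan(d), np.nanmean(d, axis=0), d)
        causal = d @ np.asarray(cfg.causal_effects, dtype=float)

    poly = np.zeros(n)
    if cfg.polygenic_share > 0 and cfg.h2 > 0:
        from .gwas_mlm import kinship

        K = kinship(geno, method="centered-cross-product").values
        K = K + 1e-4 * np.eye(n)
        poly = np.linalg.cholesky(K) @ rng.standard_normal(n)

    var_causal = cfg.h2 * (1.0 - cfg.polygenic_share) if cfg.causal_sites else 0.0
    var_poly = cfg.h2 * cfg.polygenic_share if cfg.polygenic_share > 0 else 0.0
    if not cfg.causal_sites:
        var_poly = cfg.h2  # all genetic variance is polygenic
    causal_scaled = (
        _standardize(causal) * np.sqrt(var_causal) if var_causal > 0 else np.zeros(n)
    )
    scale_c = (
        np.sqrt(var_causal) / np.std(causal)
        if var_causal > 0 and np.std(causal) > 0
        else 0.0
    )
    poly_scaled = _standardize(poly) * np.sqrt(var_poly) if var_poly > 0 else np.zeros(n)
    g = causal_scaled + poly_scaled

    var_shared_env = max(cfg.season_r - cfg.h2, 0.0)
    var_noise = max(1.0 - cfg.h2 - var_shared_env, 0.0)
    shared_env = rng.standard_normal(n) * np.sqrt(var_shared_env)

    shifts = np.zeros(n)
    if cfg.subpop_shifts:
        # ancestry-driven mean shifts need the truth admixture matrix
        raise ValueError(
            "subpop_shifts requires the admixture-aware entry point "
            "simulate_traits_with_admixture"
        )

    rows = []
    z_mll = {}
    z_mlw = {}
    rho = cfg.trait_cor
    mlw_indep = rng.standard_normal(n)
    for season in cfg.seasons:
        noise = rng.standard_normal(n) * np.sqrt(var_noise)
        z1 = g + shared_env + shifts + noise
        noise_w = rng.standard_normal(n) * np.sqrt(var_noise)
        z2 = rho * (g + shared_env + shifts) + np.sqrt(1 - rho ** 2) * mlw_indep + noise_w
        z_mll[season] = z1
        z_mlw[season] = z2
        mll = np.maximum(cfg.mll_mean + cfg.mll_sd * z1, 0.5)
        mlw = np.maximum(cfg.mlw_mean + cfg.mlw_sd * z2, 0.3)
        for i, sid in enumerate(geno.sample_ids):
            rows.append(
                {
                    "accession": sid,
                    "season": season,
                    "MLL": mll[i],
                    "MLW": mlw[i],
                    "MLSI": mll[i] / mlw[i],
                    "MLA": 0.75 * mlw[i] * mll[i],
                }
            )

    betas = {
        j: float(e * scale_c * cfg.mll_sd)
        for j, e in zip(cfg.causal_sites, cfg.causal_effects)
    }
    truth = TraitTruth(
        config=cfg,
        genetic_values=g,
        causal_component=causal_scaled,
        polygenic_component=poly_scaled,
        effective_betas_mll=betas,
    )
    return PhenotypeTable(pd.DataFrame(rows)), truth


def simulate_traits_with_admixture(
    geno: GenotypeMatrix,
    admixture: np.ndarray,
    cfg: TraitSimConfig,
) -> tuple[PhenotypeTable, TraitTruth]:
    """Variant of :func:`simulate_traits` adding ancestry-driven mean shifts.

    ``subpop_shifts`` (one value per ancestry component, on the latent
    standardized scale) are applied as Σ_k shift_k · q_ik, the canonical
    structure confounder for calibration experiments.
    """
    shifts = np.zeros(geno.n_samples)
    if cfg.subpop_shifts:
        q = np.asarray(admixture, dtype=float)
        if q.shape != (geno.n_samples, len(cfg.subpop_shifts)):
            raise ValueError("admixture shape does not match subpop_shifts")
        shifts = q @ np.asarray(cfg.subpop_shifts, dtype=float)
    inner = TraitSimConfig(**{**cfg.__dict__, "subpop_shifts": ()})
    table, truth = simulate_traits(geno, inner)
    if cfg.subpop_shifts:
        df = table.data.copy()
        add_mll = cfg.mll_sd * shifts
        add_mlw = cfg.mlw_sd * cfg.trait_cor * shifts
        for season in cfg.seasons:
            sel = df["season"] == season
            df.loc[sel, "MLL"] = np.maximum(df.loc[sel, "MLL"].to_numpy() + add_mll, 0.5)
            df.loc[sel, "MLW"] = np.maximum(df.loc[sel, "MLW"].to_numpy() + add_mlw, 0.3)
        df["MLSI"] = df["MLL"] / df["MLW"]
        df["MLA"] = 0.75 * df["MLW"] * df["MLL"]
        table = PhenotypeTable(df)
        truth.config = cfg
    return table, truth
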