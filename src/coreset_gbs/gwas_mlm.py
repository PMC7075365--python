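"""Mixed-linear-model association (Q+K / P+K) with REML variance components.

Model per marker:  y = X β + g·b + u + e,  u ~ N(0, σg² K),  e ~ N(0, σe² I).

The variance ratio δ = σe²/σg² is profiled out by spectral decomposition of
K: rotating by the eigenvectors diagonalizes the covariance, after which a
weighted regression with weights 1/(λ_i + δ) is exact GLS.  REML of δ uses a
grid over log δ ∈ [−10, 10] (100 points) refined by golden-section search.
``p3d`` mode fixes δ at the no-marker null fit and reuses it for every
marker (fast, vectorized); ``exact`` mode re-estimates δ per marker.

The per-marker test is the F test on the additive dosage coefficient, and
marker R² is the proportional reduction in residual sum of squares in the
whitened model.  Accessions with a missing dosage at a tested marker are
dropped for that marker only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .io_formats import MISSING, GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "CovariateSet",
    "AssociationRecord",
    "MixedModelFit",
    "kinship",
    "pca_covariates",
    "q_covariates",
    "mlm_associate",
    "allele_class_effects",
    "bonferroni_threshold",
    "genomic_inflation",
    "qq_table",
    "manhattan_table",
]

_RIDGE = 1e-6
#: theoretical median of the 1-df chi-square distribution
_CHI2_MEDIAN = sps.chi2.ppf(0.5, df=1)


@dataclass
class KinshipMatrix:
    labels: list[str]
    values: np.ndarray
    method: str  # "ibs-similarity" | "centered-cross-product"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")

    def submatrix(self, labels: Sequence[str]) -> np.ndarray:
        index = {lab: i for i, lab in enumerate(self.labels)}
        idx = [index[lab] for lab in labels]
        return self.values[np.ix_(idx, idx)]


@dataclass
class CovariateSet:
    kind: str  # "Q" | "P"
    labels: list[str]
    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.labels):
            raise ValueError("covariate rows must match labels")
        if self.values.shape[1] >= len(self.labels):
            raise ValueError("more covariates than samples")
        spans = self.values.max(axis=0) - self.values.min(axis=0)
        if (spans == 0).any():
            raise ValueError("constant covariate column")
        if not self.names:
            self.names = [f"{self.kind}{i+1}" for i in range(self.values.shape[1])]

    def aligned(self, labels: Sequence[str]) -> np.ndarray:
        index = {lab: i for i, lab in enumerate(self.labels)}
        return self.values[[index[lab] for lab in labels], :]


@dataclass
class AssociationRecord:
    chrom: str
    pos: int
    marker: str
    major_allele: str
    minor_allele: str
    maf: float
    p_value: float
    marker_r2: float
    beta: float
    beta_se: float
    major_effect: float
    minor_effect: float
    n_hom_major: int
    n_het: int
    n_hom_minor: int
    n_used: int


@dataclass
class MixedModelFit:
    sigma_g2: float
    sigma_e2: float
    delta: float  # sigma_e2 / sigma_g2
    reml_loglik: float
    n: int
    n_covariates: int


# ---------------------------------------------------------------------------
# Kinship and structure covariates
# ---------------------------------------------------------------------------

def kinship(geno: GenotypeMatrix, method: str = "ibs-similarity") -> KinshipMatrix:
    """Relatedness matrix for the random polygenic effect.

    ``ibs-similarity``: 1 − IBS distance (diagonal 1, row maxima on the
    diagonal).  ``centered-cross-product``: standardized-dosage cross-product
    scaled by the site count (VanRaden-style).  A small ridge keeps the
    result numerically positive semidefinite.
    """
    if geno.n_sites == 0:
        raise ValueError("empty site set")
    if method == "ibs-similarity":
        from .popgen_stats import ibs_distance

        values = 1.0 - ibs_distance(geno).values
    elif method == "centered-cross-product":
        d = geno.dosages.astype(float)
        d[geno.dosages == MISSING] = np.nan
        p = np.nanmean(d, axis=0) / 2.0
        var = 2.0 * p * (1.0 - p)
        keep = var > 0
        z = (d[:, keep] - 2.0 * p[keep]) / np.sqrt(var[keep])
        z = np.nan_to_num(z, nan=0.0)  # mean-impute after standardization
        values = z @ z.T / keep.sum()
    else:
        raise ValueError(f"unknown kinship method {method!r}")
    values = values + _RIDGE * np.eye(len(values))
    return KinshipMatrix(list(geno.sample_ids), values, method)


def pca_covariates(geno: GenotypeMatrix, n_pcs: int = 3) -> CovariateSet:
    """Top principal components of the mean-imputed, centered dosage matrix.

    Sign convention: the entry of largest magnitude in each component is
    made positive, so output is deterministic across LAPACK builds.
    """
    if n_pcs <= 0:
        raise ValueError("n_pcs must be positive")
    if n_pcs >= min(geno.n_samples, geno.n_sites):
        raise ValueError("n_pcs must be < min(n_samples, n_sites)")
    d = geno.dosages.astype(float)
    d[geno.dosages == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    centered = np.nan_to_num(d - mean, nan=0.0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    pcs = u[:, :n_pcs] * s[:n_pcs]
    for k in range(n_pcs):
        j = int(np.argmax(np.abs(pcs[:, k])))
        if pcs[j, k] < 0:
            pcs[:, k] = -pcs[:, k]
    return CovariateSet("P", list(geno.sample_ids), pcs)


def q_covariates(labels: Sequence[str], q_matrix: np.ndarray) -> CovariateSet:
    """Admixture proportions as fixed effects, dropping the last column to
    avoid collinearity with the intercept (rows sum to one)."""
    q = np.asarray(q_matrix, dtype=float)
    if q.shape[1] < 2:
        raise ValueError("Q matrix needs >= 2 ancestry columns")
    return CovariateSet("Q", list(labels), q[:, :-1])


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def _reml_neg_ll(log_delta: float, s: np.ndarray, y_rot: np.ndarray, x_rot: np.ndarray) -> float:
    delta = math.exp(log_delta)
    w = 1.0 / (s + delta)
    sw = np.sqrt(w)
    xw = x_rot * sw[:, None]
    yw = y_rot * sw
    xtx = xw.T @ xw
    try:
        beta = np.linalg.solve(xtx, xw.T @ yw)
    except np.linalg.LinAlgError:
        return np.inf
    resid = yw - xw @ beta
    rss = float(resid @ resid)
    n, q = x_rot.shape
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    if sign <= 0 or rss <= 0:
        return np.inf
    return 0.5 * ((n - q) * math.log(rss) - np.log(w).sum() + logdet_xtx)


def _golden_section(f, lo: float, hi: float, tol: float = 1e-6) -> float:
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def _fit_delta(s: np.ndarray, y_rot: np.ndarray, x_rot: np.ndarray) -> tuple[float, float]:
    """REML point estimate of log-delta: coarse grid then golden-section."""
    grid = np.linspace(-10.0, 10.0, 100)
    values = [_reml_neg_ll(g, s, y_rot, x_rot) for g in grid]
    k = int(np.argmin(values))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    best = _golden_section(lambda g: _reml_neg_ll(g, s, y_rot, x_rot), lo, hi)
    return best, -_reml_neg_ll(best, s, y_rot, x_rot)


def _full_reml_ll(log_delta: float, s: np.ndarray, y_rot: np.ndarray, x_rot: np.ndarray) -> float:
    """REML log-likelihood with constants, for reporting."""
    delta = math.exp(log_delta)
    w = 1.0 / (s + delta)
    sw = np.sqrt(w)
    xw = x_rot * sw[:, None]
    yw = y_rot * sw
    xtx = xw.T @ xw
    beta = np.linalg.solve(xtx, xw.T @ yw)
    resid = yw - xw @ beta
    rss = float(resid @ resid)
    n, q = x_rot.shape
    sigma_g2 = rss / (n - q)
    _, logdet_xtx = np.linalg.slogdet(xtx)
    _, logdet_xtx0 = np.linalg.slogdet(x_rot.T @ x_rot)
    return -0.5 * (
        (n - q) * (math.log(2 * math.pi * sigma_g2) + 1)
        - np.log(w).sum()
        + logdet_xtx
        - logdet_xtx0
    )


def _marker_tests(
    y_rot: np.ndarray,
    x_rot: np.ndarray,
    g_rot: np.ndarray,
    s: np.ndarray,
    delta: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-marker F tests at fixed delta.

    Returns (p, beta, se, r2) arrays; markers whose whitened residual
    vector is constant get NaN.
    """
    w = 1.0 / (s + delta)
    sw = np.sqrt(w)
    xw = x_rot * sw[:, None]
    yw = y_rot * sw
    gw = g_rot * sw[:, None]
    qx, _ = np.linalg.qr(xw)
    yr = yw - qx @ (qx.T @ yw)
    gr = gw - qx @ (qx.T @ gw)
    rss0 = float(yr @ yr)
    gty = gr.T @ yr
    gtg = (gr ** 2).sum(axis=0)
    n, q = x_rot.shape
    df = n - q - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gty / gtg
        rss1 = rss0 - gty ** 2 / gtg
        f = (rss0 - rss1) / (rss1 / df)
        se = np.sqrt(rss1 / df / gtg)
        r2 = np.where(rss0 > 0, (rss0 - rss1) / rss0, np.nan)
    p = sps.f.sf(f, 1, df)
    bad = (gtg <= 1e-12) | ~np.isfinite(f)
    p[bad] = np.nan
    beta = np.where(bad, np.nan, beta)
    se = np.where(bad, np.nan, se)
    r2 = np.where(bad, np.nan, r2)
    return p, beta, se, r2


def mlm_associate(
    y: np.ndarray,
    geno: GenotypeMatrix,
    covariates: CovariateSet | None = None,
    K: KinshipMatrix | None = None,
    mode: str = "p3d",
) -> tuple[list[AssociationRecord], MixedModelFit]:
    """Single-marker mixed-model scan over all sites of ``geno``.

    ``y`` is aligned to ``geno.sample_ids``; missing phenotypes are dropped.
    With ``K=None`` an identity kinship is used, in which case p-values equal
    ordinary least-squares F-test p-values.
    """
    if mode not in ("p3d", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    y = np.asarray(y, dtype=float)
    if y.shape != (geno.n_samples,):
        raise ValueError("y must align with geno.sample_ids")
    phenotyped = ~np.isnan(y)
    ids = [s for s, ok in zip(geno.sample_ids, phenotyped) if ok]
    if len(ids) < 3:
        raise ValueError("need >= 3 phenotyped samples")
    yv = y[phenotyped]
    if np.std(yv) == 0:
        raise ValueError("constant phenotype")

    if K is not None:
        if set(geno.sample_ids) - set(K.labels):
            raise ValueError("kinship labels do not cover the panel")
        k_full = K.submatrix(ids)
    else:
        k_full = np.eye(len(ids))
    x_cov = covariates.aligned(ids) if covariates is not None else np.empty((len(ids), 0))
    x_full = np.column_stack([np.ones(len(ids)), x_cov])

    s_full, u_full = np.linalg.eigh(k_full)
    s_full = np.maximum(s_full, 0.0)
    y_rot = u_full.T @ yv
    x_rot = u_full.T @ x_full

    log_delta, _ = _fit_delta(s_full, y_rot, x_rot)
    delta = math.exp(log_delta)
    n, q = x_rot.shape
    w = 1.0 / (s_full + delta)
    sw = np.sqrt(w)
    xw = x_rot * sw[:, None]
    yw = y_rot * sw
    beta0 = np.linalg.solve(xw.T @ xw, xw.T @ yw)
    rss = float((yw - xw @ beta0) @ (yw - xw @ beta0))
    sigma_g2 = rss / (n - q)
    fit = MixedModelFit(
        sigma_g2=sigma_g2,
        sigma_e2=delta * sigma_g2,
        delta=delta,
        reml_loglik=_full_reml_ll(log_delta, s_full, y_rot, x_rot),
        n=n,
        n_covariates=x_cov.shape[1],
    )

    sample_idx = np.flatnonzero(phenotyped)
    dos = geno.dosages[sample_idx, :]
    complete = ~(dos == MISSING).any(axis=0)

    p_all = np.full(geno.n_sites, np.nan)
    beta_all = np.full(geno.n_sites, np.nan)
    se_all = np.full(geno.n_sites, np.nan)
    r2_all = np.full(geno.n_sites, np.nan)

    if mode == "p3d":
        if complete.any():
            g_rot = u_full.T @ dos[:, complete].astype(float)
            p, b, se, r2 = _marker_tests(y_rot, x_rot, g_rot, s_full, delta)
            p_all[complete] = p
            beta_all[complete] = b
            se_all[complete] = se
            r2_all[complete] = r2
        todo = np.flatnonzero(~complete)
    else:
        todo = np.arange(geno.n_sites)

    # slow path: per-marker subsetting (missing dosages) and/or exact REML
    cache: dict[bytes, tuple] = {}
    for j in todo:
        col = dos[:, j]
        ok = col != MISSING
        if ok.sum() < q + 3:
            continue
        key = ok.tobytes()
        if key not in cache:
            k_sub = k_full[np.ix_(ok, ok)]
            s_sub, u_sub = np.linalg.eigh(k_sub)
            s_sub = np.maximum(s_sub, 0.0)
            cache[key] = (s_sub, u_sub, u_sub.T @ yv[ok], u_sub.T @ x_full[ok, :])
        s_sub, u_sub, y_sub, x_sub = cache[key]
        g_sub = u_sub.T @ col[ok].astype(float)
        if mode == "exact" and np.ptp(col[ok]) > 0:
            x_aug = np.column_stack([x_sub, g_sub])
            ld_j, _ = _fit_delta(s_sub, y_sub, x_aug)
            delta_j = math.exp(ld_j)
        else:
            delta_j = delta
        p, b, se, r2 = _marker_tests(y_sub, x_sub, g_sub[:, None], s_sub, delta_j)
        p_all[j], beta_all[j], se_all[j], r2_all[j] = p[0], b[0], se[0], r2[0]

    records = []
    for j, site in enumerate(geno.sites):
        col = dos[:, j]
        ok = col != MISSING
        if not ok.any():
            continue
        eff = allele_class_effects(yv[ok], col[ok], site.ref_allele, site.alt_allele)
        (major, minor, maf, major_eff, minor_eff, counts) = eff
        records.append(
            AssociationRecord(
                chrom=site.chrom,
                pos=site.pos,
                marker=site.site_id,
                major_allele=major,
                minor_allele=minor,
                maf=maf,
                p_value=float(p_all[j]),
                marker_r2=float(r2_all[j]),
                beta=float(beta_all[j]),
                beta_se=float(se_all[j]),
                major_effect=major_eff,
                minor_effect=minor_eff,
                n_hom_major=counts[0],
                n_het=counts[1],
                n_hom_minor=counts[2],
                n_used=int(ok.sum()),
            )
        )
    return records, fit


def allele_class_effects(
    y: np.ndarray,
    dosages: np.ndarray,
    ref_allele: str = "REF",
    alt_allele: str = "ALT",
) -> tuple[str, str, float, float, float, tuple[int, int, int]]:
    """Genotype-class effects for one site.

    The major (minor) allele effect is the mean phenotype of the homozygous
    major (minor) class minus the grand mean over phenotyped, genotyped
    accessions; an empty class yields a missing effect.  Returns
    (major, minor, maf, major_effect, minor_effect, counts) with counts as
    (hom-major, het, hom-minor).
    """
    dosages = np.asarray(dosages)
    ok = dosages != MISSING
    if not ok.any():
        raise ValueError("all genotypes missing")
    d = dosages[ok]
    yy = np.asarray(y, dtype=float)[ok]
    p_alt = d.sum() / (2.0 * len(d))
    if p_alt > 0.5:
        major, minor = alt_allele, ref_allele
        hom_major, hom_minor = 2, 0
        maf = 1.0 - p_alt
    else:
        major, minor = ref_allele, alt_allele
        hom_major, hom_minor = 0, 2
        maf = p_alt
    grand = float(np.mean(yy))
    n_major = int((d == hom_major).sum())
    n_het = int((d == 1).sum())
    n_minor = int((d == hom_minor).sum())
    major_eff = float(np.mean(yy[d == hom_major]) - grand) if n_major else np.nan
    minor_eff = float(np.mean(yy[d == hom_minor]) - grand) if n_minor else np.nan
    return major, minor, float(maf), major_eff, minor_eff, (n_major, n_het, n_minor)


def bonferroni_threshold(alpha: float, m: int) -> tuple[float, float]:
    """Family-wise threshold alpha/m, returned at full precision and rounded
    to 3 significant digits."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    exact = alpha / m
    rounded = float(f"{exact:.3g}")
    return exact, rounded


def genomic_inflation(p_values: Sequence[float]) -> float:
    """λ: median observed 1-df chi-square quantile over the theoretical
    median (≈ 0.4549)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p) & (p > 0) & (p <= 1)]
    if len(p) == 0:
        raise ValueError("no valid p-values")
    chi2 = sps.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_MEDIAN)


def qq_table(p_values: Sequence[float]):
    """Observed vs expected −log10 p, sorted (plot-ready)."""
    import pandas as pd

    p = np.asarray(p_values, dtype=float)
    p = np.sort(p[np.isfinite(p) & (p > 0) & (p <= 1)])
    n = len(p)
    if n == 0:
        raise ValueError("no valid p-values")
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {
            "expected_neglog10p": -np.log10(expected),
            "observed_neglog10p": -np.log10(p),
        }
    )


def manhattan_table(records: Sequence[AssociationRecord]):
    """p by chromosome and position (plot-ready)."""
    import pandas as pd

    rows = [
        {
            "chrom": r.chrom,
            "pos": r.pos,
            "marker": r.marker,
            "p_value": r.p_value,
            "neglog10p": -np.log10(r.p_value) if r.p_value > 0 else np.nan,
        }
        for r in records
        if np.isfinite(r.p_value)
    ]
    return pd.DataFrame(rows)
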