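"""Marker and diversity statistics: allele frequencies, MAF, PIC, observed
heterozygosity, IBS genetic distance, and per-group diversity summaries.

PIC for a site with allele frequencies p_i is

    PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²

which for a biallelic site reduces to ``1 − p² − q² − 2p²q²`` with maximum
0.375 at p = q = 0.5.  The heterozygote–heterozygote IBS distance convention
is 0 (full allele sharing), making d(a, a) = 0 exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, SquareMatrix

__all__ = [
    "SiteStats",
    "SampleStats",
    "DiversitySummary",
    "site_stats",
    "sample_heterozygosity",
    "ibs_distance",
    "diversity_summary",
    "segregating_mask",
]


@dataclass
class SiteStats:
    """Per-site frequencies, informativeness and genotype counts."""

    chrom: str
    pos: int
    p_alt: float
    maf: float
    pic: float
    missing_frac: float
    major_allele: str
    minor_allele: str
    genotype_counts: tuple[int, int, int, int]  # hom-major, het, hom-minor, missing
    defined: bool = True


@dataclass
class SampleStats:
    sample_id: str
    ho: float  # NaN when n_called == 0
    n_called: int


@dataclass
class DiversitySummary:
    """Group-level diversity row: sizes, Ho/PIC/MAF means ± SE, distance range.

    ``avg_site_count`` is the mean number of non-missing genotyped sites per
    accession in the group (an interpretation; see output headers).  The ±
    values are standard errors of the mean.
    """

    group: str
    S: int
    avg_site_count: float
    ho_mean: float
    ho_se: float
    pic_mean: float
    pic_se: float
    maf_mean: float
    maf_se: float
    gd_min: float
    gd_mean: float
    gd_max: float


def _biallelic_pic(p: float) -> float:
    q = 1.0 - p
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


def site_stats(geno: GenotypeMatrix) -> list[SiteStats]:
    """Per-site ALT frequency, MAF, PIC, missingness and genotype counts.

    Frequencies are computed on non-missing alleles.  A site with no calls
    is flagged undefined (all statistics NaN).  Major/minor allele labels are
    assigned from observed frequency, not from REF/ALT order.
    """
    out = []
    n = geno.n_samples
    for j, site in enumerate(geno.sites):
        col = geno.dosages[:, j]
        called = col != MISSING
        n_called = int(called.sum())
        n_missing = n - n_called
        if n_called == 0:
            out.append(
                SiteStats(site.chrom, site.pos, np.nan, np.nan, np.nan,
                          1.0, site.ref_allele, site.alt_allele,
                          (0, 0, 0, n_missing), defined=False)
            )
            continue
        vals = col[called]
        p_alt = float(vals.sum()) / (2.0 * n_called)
        maf = min(p_alt, 1.0 - p_alt)
        pic = _biallelic_pic(p_alt)
        n_hom_ref = int((vals == 0).sum())
        n_het = int((vals == 1).sum())
        n_hom_alt = int((vals == 2).sum())
        if p_alt > 0.5:
            major, minor = site.alt_allele, site.ref_allele
            counts = (n_hom_alt, n_het, n_hom_ref, n_missing)
        else:
            major, minor = site.ref_allele, site.alt_allele
            counts = (n_hom_ref, n_het, n_hom_alt, n_missing)
        out.append(
            SiteStats(site.chrom, site.pos, p_alt, maf, pic,
                      n_missing / n, major, minor, counts)
        )
    return out


def sample_heterozygosity(geno: GenotypeMatrix) -> list[SampleStats]:
    """Observed heterozygosity per sample: het calls / non-missing calls."""
    called = geno.dosages != MISSING
    n_called = called.sum(axis=1)
    n_het = (geno.dosages == 1).sum(axis=1)
    out = []
    for i, sid in enumerate(geno.sample_ids):
        ho = float(n_het[i]) / n_called[i] if n_called[i] else np.nan
        out.append(SampleStats(sid, ho, int(n_called[i])))
    return out


def ibs_distance(geno: GenotypeMatrix) -> SquareMatrix:
    """Identity-by-state genetic distance.

    d(a, b) is the mean over pairwise non-missing sites of |x_a − x_b| / 2,
    i.e. one minus the average fraction of alleles shared.  Computed through
    genotype-class indicator matrix products, so it scales to hundreds of
    samples × tens of thousands of sites.
    """
    if geno.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = geno.dosages
    called = (d != MISSING).astype(np.float64)
    g0 = (d == 0).astype(np.float64)
    g1 = (d == 1).astype(np.float64)
    g2 = (d == 2).astype(np.float64)
    # sum over shared sites of |x_a - x_b|
    num = (
        g0 @ g1.T + g1 @ g0.T + g1 @ g2.T + g2 @ g1.T
        + 2.0 * (g0 @ g2.T + g2 @ g0.T)
    )
    shared = called @ called.T
    no_overlap = shared == 0
    if no_overlap.any():
        i, j = np.argwhere(no_overlap)[0]
        raise ValueError(
            f"samples {geno.sample_ids[i]!r} and {geno.sample_ids[j]!r} share "
            "no called sites; IBS distance undefined"
        )
    values = num / (2.0 * shared)
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0
    return SquareMatrix(list(geno.sample_ids), values)


def segregating_mask(geno: GenotypeMatrix) -> np.ndarray:
    """Boolean mask of sites where both alleles are observed (het counts)."""
    d = geno.dosages
    has_ref = ((d == 0) | (d == 1)).any(axis=0)
    has_alt = ((d == 2) | (d == 1)).any(axis=0)
    return has_ref & has_alt


def _sem(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    if len(x) < 2:
        return np.nan
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def diversity_summary(
    geno: GenotypeMatrix,
    distances: SquareMatrix,
    groups: Mapping[str, str],
) -> tuple[list[DiversitySummary], pd.DataFrame]:
    """Per-group diversity rows plus allele/genotype frequency spectra.

    ``groups`` maps sample id → group label and may cover a subset of the
    panel.  PIC and MAF are recomputed within each group.  For a singleton
    group the distance fields are NaN.  The second return value is a long
    table of per-group mean genotype-class frequencies and a binned MAF
    spectrum (plot-ready).
    """
    unknown = set(groups) - set(geno.sample_ids)
    if unknown:
        raise ValueError(f"group labels for unknown samples: {sorted(unknown)}")
    by_group: dict[str, list[str]] = {}
    for sid, lab in groups.items():
        by_group.setdefault(lab, []).append(sid)

    summaries = []
    spectra_rows = []
    bins = np.linspace(0.0, 0.5, 11)
    for lab in sorted(by_group):
        members = sorted(by_group[lab])
        sub = geno.take_samples(members)
        sstats = site_stats(sub)
        hstats = sample_heterozygosity(sub)
        ho = np.array([h.ho for h in hstats])
        asc = float(np.mean([h.n_called for h in hstats]))
        # polymorphic-within-group sites only, as diversity is about variation
        pics = np.array([s.pic for s in sstats if s.defined])
        mafs = np.array([s.maf for s in sstats if s.defined])
        if len(members) >= 2:
            dsub = distances.submatrix(members).offdiag_values()
            gd_min, gd_mean, gd_max = float(dsub.min()), float(dsub.mean()), float(dsub.max())
        else:
            gd_min = gd_mean = gd_max = np.nan
        summaries.append(
            DiversitySummary(
                group=lab,
                S=len(members),
                avg_site_count=asc,
                ho_mean=float(np.nanmean(ho)),
                ho_se=_sem(ho),
                pic_mean=float(np.nanmean(pics)),
                pic_se=_sem(pics),
                maf_mean=float(np.nanmean(mafs)),
                maf_se=_sem(mafs),
                gd_min=gd_min,
                gd_mean=gd_mean,
                gd_max=gd_max,
            )
        )
        counts = np.array([s.genotype_counts[:3] for s in sstats if s.defined], dtype=float)
        totals = counts.sum(axis=1, keepdims=True)
        freqs = np.where(totals > 0, counts / np.maximum(totals, 1), np.nan)
        for name, val in zip(("hom_major", "het", "hom_minor"), np.nanmean(freqs, axis=0)):
            spectra_rows.append(
                {"group": lab, "kind": "genotype_freq", "bin": name, "value": float(val)}
            )
        hist, _ = np.histogram(mafs[~np.isnan(mafs)], bins=bins)
        total = hist.sum()
        for lo, hi, count in zip(bins[:-1], bins[1:], hist):
            spectra_rows.append(
                {
                    "group": lab,
                    "kind": "maf_spectrum",
                    "bin": f"{lo:.2f}-{hi:.2f}",
                    "value": count / total if total else np.nan,
                }
            )
    return summaries, pd.DataFrame(spectra_rows)
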