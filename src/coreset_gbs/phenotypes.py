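"""Leaf-size trait derivation and descriptive/correlation statistics.

Traits: mature-leaf length (MLL, cm) and width (MLW, cm) are measured; the
shape index MLSI = MLL / MLW and area MLA = 0.75 · MLW · MLL are derived.
Skewness and kurtosis use the small-sample adjusted estimators (G1 and
excess G2, the spreadsheet/SPSS convention) with their classical closed-form
standard errors, so printed Std.Err columns are reproducible:

    SE(G1) = sqrt(6 n (n−1) / ((n−2)(n+1)(n+3)))
    SE(G2) = 2 · SE(G1) · sqrt((n²−1) / ((n−3)(n+5)))
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import PhenotypeTable

__all__ = [
    "TraitRecord",
    "TraitSummary",
    "CorrelationResult",
    "TRAITS",
    "derive_traits",
    "trait_summary",
    "correlations",
    "skewness_se",
    "kurtosis_se",
]

TRAITS = ("MLL", "MLW", "MLSI", "MLA")


@dataclass
class TraitRecord:
    accession: str
    season: str
    MLL: float
    MLW: float
    MLSI: float
    MLA: float


@dataclass
class TraitSummary:
    trait: str
    n: int
    mean: float
    sd: float
    minimum: float
    maximum: float
    skewness: float
    skewness_se: float
    kurtosis: float
    kurtosis_se: float


def skewness_se(n: int) -> float:
    """Closed-form standard error of sample skewness (G1)."""
    if n < 3:
        raise ValueError("need n >= 3")
    return math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))


def kurtosis_se(n: int) -> float:
    """Closed-form standard error of sample excess kurtosis (G2)."""
    if n < 4:
        raise ValueError("need n >= 4")
    return 2.0 * skewness_se(n) * math.sqrt((n * n - 1) / ((n - 3.0) * (n + 5.0)))


def derive_traits(table: PhenotypeTable) -> list[TraitRecord]:
    """Compute MLSI and MLA per record; rows with missing MLL or MLW carry
    missing derived traits but are retained."""
    records = []
    for _, row in table.data.iterrows():
        mll = row.get("MLL", np.nan)
        mlw = row.get("MLW", np.nan)
        if pd.notna(mlw) and mlw == 0:
            raise ValueError(f"MLW is zero for accession {row['accession']}")
        if pd.notna(mll) and pd.notna(mlw):
            mlsi = mll / mlw
            mla = 0.75 * mlw * mll
        else:
            mlsi = np.nan
            mla = np.nan
        records.append(
            TraitRecord(
                accession=str(row["accession"]),
                season=str(row["season"]),
                MLL=float(mll) if pd.notna(mll) else np.nan,
                MLW=float(mlw) if pd.notna(mlw) else np.nan,
                MLSI=float(mlsi) if pd.notna(mlsi) else np.nan,
                MLA=float(mla) if pd.notna(mla) else np.nan,
            )
        )
    return records


def records_frame(records: list[TraitRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def trait_summary(records: list[TraitRecord]) -> dict[str, TraitSummary]:
    """Descriptive statistics per trait across all records.

    A constant trait reports sd = 0 with missing skewness/kurtosis; traits
    with fewer than 4 values report missing shape statistics too.
    """
    df = records_frame(records)
    out = {}
    for trait in TRAITS:
        vals = df[trait].dropna().to_numpy(dtype=float)
        n = len(vals)
        if n == 0:
            continue
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        if n >= 4 and sd > 0:
            skew = float(sps.skew(vals, bias=False))
            kurt = float(sps.kurtosis(vals, bias=False, fisher=True))
            sk_se = skewness_se(n)
            ku_se = kurtosis_se(n)
        else:
            skew = kurt = sk_se = ku_se = np.nan
        out[trait] = TraitSummary(
            trait=trait,
            n=n,
            mean=float(np.mean(vals)),
            sd=sd,
            minimum=float(np.min(vals)),
            maximum=float(np.max(vals)),
            skewness=skew,
            skewness_se=sk_se,
            kurtosis=kurt,
            kurtosis_se=ku_se,
        )
    return out


@dataclass
class CorrelationResult:
    """Pearson correlations within and across seasons.

    ``within[season]`` holds (r, p) DataFrames over the four traits;
    ``between[trait]`` is the (r, p) pair of the same trait in the two
    seasons (only when exactly two seasons are present).
    """

    within: dict[str, tuple[pd.DataFrame, pd.DataFrame]]
    between: dict[str, tuple[float, float]]


def correlations(records: list[TraitRecord]) -> CorrelationResult:
    df = records_frame(records)
    seasons = sorted(df["season"].unique())
    within = {}
    for season in seasons:
        sub = df[df["season"] == season]
        r = pd.DataFrame(np.nan, index=TRAITS, columns=TRAITS)
        p = pd.DataFrame(np.nan, index=TRAITS, columns=TRAITS)
        for i, ta in enumerate(TRAITS):
            for tb in TRAITS[i:]:
                if ta == tb:
                    vals = sub[ta].dropna()
                    if len(vals) >= 2 and vals.std() > 0:
                        r.loc[ta, tb], p.loc[ta, tb] = 1.0, 0.0
                    continue
                pair = sub[[ta, tb]].dropna()
                if len(pair) >= 3 and pair[ta].std() > 0 and pair[tb].std() > 0:
                    res = sps.pearsonr(pair[ta], pair[tb])
                    r.loc[ta, tb] = r.loc[tb, ta] = res.statistic
                    p.loc[ta, tb] = p.loc[tb, ta] = res.pvalue
        within[season] = (r, p)

    between = {}
    if len(seasons) == 2:
        a = df[df["season"] == seasons[0]].set_index("accession")
        b = df[df["season"] == seasons[1]].set_index("accession")
        common = a.index.intersection(b.index)
        for trait in TRAITS:
            x = a.loc[common, trait]
            y = b.loc[common, trait]
            ok = x.notna() & y.notna()
            if ok.sum() >= 3 and x[ok].std() > 0 and y[ok].std() > 0:
                res = sps.pearsonr(x[ok], y[ok])
                between[trait] = (float(res.statistic), float(res.pvalue))
            else:
                between[trait] = (np.nan, np.nan)
    return CorrelationResult(within=within, between=between)
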