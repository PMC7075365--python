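"""Readers and writers for every on-disk artifact the pipeline touches.

Genotypes come in as multi-sample VCF (via :mod:`cyvcf2`) and are held as an
ALT-allele dosage matrix.  Distance matrices use the PHYLIP square dialect,
trees use Newick, and phenotype/metadata/result tables are tab-separated text.

Conventions
-----------
* Dosage coding is the count of ALT alleles (0, 1, 2); major/minor status is
  derived later from observed frequencies, never from REF/ALT order.
* Missing genotypes use the out-of-band sentinel ``MISSING`` (−1) so that 0
  remains a legal homozygote.
* Coordinates are 1-based, as in VCF.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "MISSING",
    "SiteRecord",
    "GenotypeMatrix",
    "SquareMatrix",
    "PhenotypeTable",
    "VcfFormatError",
    "read_vcf",
    "write_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "read_square_matrix",
    "write_square_matrix",
    "read_newick",
    "write_newick",
]

#: Out-of-band sentinel for a missing genotype call.
MISSING: int = -1


class VcfFormatError(ValueError):
    """Raised when a VCF violates the contract this reader requires."""


@dataclass
class SiteRecord:
    """One variant site: location, alleles, and optional numeric INFO keys."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    info: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt ({self.ref_allele}) at {self.chrom}:{self.pos}")

    @property
    def is_biallelic(self) -> bool:
        """True unless the ALT field carries more than one allele."""
        return "," not in self.alt_allele

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


class GenotypeMatrix:
    """Accessions × biallelic sites, ALT-dosage coded with a missing sentinel."""

    def __init__(
        self,
        sample_ids: Sequence[str],
        sites: Sequence[SiteRecord],
        dosages: np.ndarray,
    ) -> None:
        sample_ids = list(sample_ids)
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.shape != (len(sample_ids), len(sites)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(sample_ids)} samples x {len(sites)} sites"
            )
        bad = ~np.isin(dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"illegal dosage values: {np.unique(dosages[bad])}")
        self.sample_ids = sample_ids
        self.sites = list(sites)
        self.dosages = dosages
        self._sample_index = {s: i for i, s in enumerate(sample_ids)}

    # -- shape helpers -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def missing_mask(self) -> np.ndarray:
        """Boolean n_samples × n_sites mask of missing calls."""
        return self.dosages == MISSING

    # -- subsetting ----------------------------------------------------
    def take_sites(self, indices: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            self.sample_ids,
            [self.sites[i] for i in idx],
            self.dosages[:, idx],
        )

    def take_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._sample_index[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.sites, self.dosages[idx, :])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_sites} sites)"


@dataclass
class SquareMatrix:
    """Symmetric labelled dissimilarity matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    #: symmetry tolerance used at validation time
    SYM_ATOL = 1e-12
    DIAG_ATOL = 1e-8

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=self.SYM_ATOL, rtol=0.0):
            raise ValueError("matrix is not symmetric within tolerance")
        if np.abs(np.diag(self.values)).max(initial=0.0) > self.DIAG_ATOL:
            raise ValueError("diagonal is not zero")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, labels: Sequence[str]) -> "SquareMatrix":
        idx = [self._index[lab] for lab in labels]
        return SquareMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def offdiag_values(self) -> np.ndarray:
        """Upper-triangle pairwise values as a flat vector."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class PhenotypeTable:
    """Long-format phenotype table: one row per (accession, season)."""

    data: pd.DataFrame

    REQUIRED = ("accession", "season")
    TRAITS = ("MLL", "MLW", "MLSI", "MLA")

    def __post_init__(self) -> None:
        df = self.data
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        dup = df.duplicated(subset=["accession", "season"])
        if dup.any():
            pairs = df.loc[dup, ["accession", "season"]].values.tolist()
            raise ValueError(f"duplicate (accession, season) rows: {pairs}")
        for trait in ("MLL", "MLW"):
            if trait in df.columns:
                bad = df[trait].dropna() <= 0
                if bad.any():
                    raise ValueError(f"{trait} must be positive where present")
        self.data = df.reset_index(drop=True)

    @property
    def seasons(self) -> list[str]:
        return sorted(self.data["season"].unique().tolist())

    def for_season(self, season: str) -> pd.DataFrame:
        return self.data[self.data["season"] == season].reset_index(drop=True)

    def trait_vector(self, trait: str, season: str, sample_ids: Sequence[str]) -> np.ndarray:
        """Trait values aligned to ``sample_ids`` (NaN where absent)."""
        sub = self.for_season(season).set_index("accession")
        out = np.full(len(sample_ids), np.nan)
        for i, sid in enumerate(sample_ids):
            if sid in sub.index and trait in sub.columns:
                out[i] = sub.at[sid, trait]
        return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load a VCF 4.x into a :class:`GenotypeMatrix`.

    Multi-allelic records are loaded with their full ALT string so the filter
    stage can drop them; their dosage counts only the first ALT allele.
    Numeric INFO keys and QUAL (under key ``"QUAL"``) are kept per site.
    """
    # htslib collapses duplicate sample names before we can see them, so
    # check the raw header line first
    with open(path) as fh:
        for line in fh:
            if line.startswith("#CHROM"):
                names = line.rstrip("\n").split("\t")[9:]
                if len(set(names)) != len(names):
                    raise VcfFormatError("duplicated sample name in VCF header")
                break
            if not line.startswith("#"):
                break
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise VcfFormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfFormatError("VCF has no samples")

    sites: list[SiteRecord] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        if "GT" not in (var.FORMAT or []):
            raise VcfFormatError(f"record {var.CHROM}:{var.POS} has no GT field")
        info: dict[str, float] = {}
        if var.QUAL is not None:
            info["QUAL"] = float(var.QUAL)
        for key, value in dict(var.INFO).items():
            if isinstance(value, (int, float)) and not isinstance(value, bool):
                info[str(key)] = float(value)
        alt = ",".join(var.ALT) if var.ALT else "."
        sites.append(SiteRecord(var.CHROM, var.POS, var.REF, alt, info))
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                col[i] = MISSING
            else:
                col[i] = sum(1 for a in alleles if a == 1)
        rows.append(col)

    dosages = (
        np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, sites, dosages)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal valid VCF 4.2 with GT fields and numeric INFO keys."""
    info_keys = sorted({k for s in geno.sites for k in s.info if k != "QUAL"})
    chroms = list(dict.fromkeys(s.chrom for s in geno.sites))
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        for key in info_keys:
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        for j, site in enumerate(geno.sites):
            qual = f"{site.info['QUAL']:g}" if "QUAL" in site.info else "."
            pairs = [f"{k}={site.info[k]:g}" for k in info_keys if k in site.info]
            info = ";".join(pairs) if pairs else "."
            gts = "\t".join(gt_strings[int(d)] for d in geno.dosages[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.site_id}\t{site.ref_allele}\t"
                f"{site.alt_allele}\t{qual}\t.\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

_COLUMN_ALIASES = {
    "accession": "accession",
    "accession_id": "accession",
    "id": "accession",
    "season": "season",
    "environment": "season",
    "mll": "MLL",
    "mlw": "MLW",
    "mlsi": "MLSI",
    "mli": "MLSI",
    "mla": "MLA",
}


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a delimited phenotype table (TSV/CSV auto-detected).

    Header must name accession, season and trait columns (case-insensitive;
    common aliases accepted).  Empty trait cells become missing values; a
    non-numeric trait cell is an error naming the offending row.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    renames: dict[str, str] = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _COLUMN_ALIASES:
            renames[col] = _COLUMN_ALIASES[key]
    df = df.rename(columns=renames)
    for col in ("accession", "season"):
        if col not in df.columns:
            raise ValueError(f"phenotype table lacks a {col!r} column")
        df[col] = df[col].astype(str).str.strip()
    for trait in PhenotypeTable.TRAITS:
        if trait not in df.columns:
            continue
        raw = df[trait]
        parsed = pd.to_numeric(raw.astype(str).str.strip().replace({"": None, "nan": None, "NA": None, ".": None}), errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "") & ~raw.astype(str).str.strip().isin(["nan", "NA", "."])
        if bad.any():
            row = int(np.flatnonzero(bad.values)[0])
            raise ValueError(
                f"non-numeric {trait} value {raw.iloc[row]!r} in row {row + 2} "
                f"(accession {df['accession'].iloc[row]})"
            )
        df[trait] = parsed
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PHYLIP square distance matrices
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s")


def write_square_matrix(matrix: SquareMatrix, path: str | Path) -> None:
    """Write in PHYLIP square dialect: count line, then label + n values/row.

    Labels containing whitespace are rejected (the dialect is whitespace
    delimited); values carry 10 significant digits so that a write/read
    round-trip is an identity at that precision.
    """
    for lab in matrix.labels:
        if _WS.search(lab):
            raise ValueError(f"label {lab!r} contains whitespace; not representable")
    with open(path, "w") as fh:
        fh.write(f"{matrix.n}\n")
        for i, lab in enumerate(matrix.labels):
            row = " ".join(format(v, ".10g") for v in matrix.values[i])
            fh.write(f"{lab} {row}\n")


def read_square_matrix(path: str | Path) -> SquareMatrix:
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise ValueError("empty distance matrix file")
    n = int(tokens[0])
    expected = 1 + n * (n + 1)
    if len(tokens) != expected:
        raise ValueError(
            f"expected {expected} tokens for a {n}x{n} PHYLIP square matrix, got {len(tokens)}"
        )
    labels: list[str] = []
    values = np.empty((n, n))
    pos = 1
    for i in range(n):
        labels.append(tokens[pos])
        pos += 1
        values[i] = [float(t) for t in tokens[pos : pos + n]]
        pos += n
    return SquareMatrix(labels, values)


# ---------------------------------------------------------------------------
# Newick (delegates to the tree model; lazy import avoids a module cycle)
# ---------------------------------------------------------------------------

def read_newick(path: str | Path):
    """Parse a Newick file into an :class:`~coreset_gbs.nj_tree.UnrootedTree`."""
    from .nj_tree import UnrootedTree

    return UnrootedTree.from_newick(Path(path).read_text())


def write_newick(tree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
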