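"""Stepwise maximum-length-subtree core-collection selection.

The selector greedily deletes the retained leaf with the *shortest* terminal
edge (the most redundant accession), merging the two edges around the freed
degree-2 node so the tree backbone and all remaining path lengths are kept.
Each removal is logged with the deleted edge length, the nearest retained
neighbour at removal time, the retained total tree length, and a sphericity
index — yielding nested core sets of every size down to the target.

The sphericity index implemented here is the mean over max pairwise distance
within the retained set: bounded in (0, 1], equal to 1 for a perfectly even
(or degenerate) configuration, and monotone-friendly under removal of
near-duplicates.  It is an artifact convention, clearly an interpretation of
the upstream tooling's stopping diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import GenotypeMatrix, SquareMatrix
from .nj_tree import UnrootedTree

__all__ = [
    "CoreRemoval",
    "CoreTrace",
    "CoreSet",
    "KneeResult",
    "CoreEvaluation",
    "max_length_subtree",
    "sphericity_index",
    "choose_core_size",
    "detect_synonyms",
    "evaluate_core",
]

#: default Euclidean-distance ceiling below which a pruned accession is
#: reported as a presumptive synonym of its nearest retained neighbour
SYNONYM_THRESHOLD = 0.0008


@dataclass
class CoreRemoval:
    step: int
    removed: str
    removed_edge_value: float
    nearest_retained: str
    retained_length: float
    sphericity: float
    retained_size: int


@dataclass
class CoreTrace:
    initial_length: float
    initial_size: int
    removals: list[CoreRemoval] = field(default_factory=list)

    def retained_at(self, size: int, all_ids: Sequence[str]) -> list[str]:
        """Accessions retained once the trace has been replayed down to ``size``."""
        if not self.initial_size >= size >= self.initial_size - len(self.removals):
            raise ValueError(f"size {size} outside traced range")
        removed = {r.removed for r in self.removals[: self.initial_size - size]}
        return sorted(set(all_ids) - removed)


@dataclass
class CoreSet:
    retained: list[str]
    target_size: int
    must_keep: frozenset
    trace: CoreTrace

    def __post_init__(self) -> None:
        if not self.must_keep <= set(self.retained):
            raise ValueError("must_keep not contained in retained set")
        if len(self.retained) != self.target_size:
            raise ValueError("retained size != target size")


@dataclass
class KneeResult:
    size: int
    no_knee: bool
    distances: dict[int, float]


def max_length_subtree(
    tree: UnrootedTree,
    target_size: int,
    must_keep: Iterable[str] = (),
    distances: SquareMatrix | None = None,
) -> tuple[CoreSet, CoreTrace]:
    """Prune to ``target_size`` leaves by repeated shortest-terminal-edge removal.

    ``must_keep`` accessions are never candidates for removal.  Ties on edge
    length break toward the lexicographically smallest label.  When a
    ``distances`` matrix is supplied, the sphericity index of each retained
    set is recorded; otherwise it is NaN in the trace.
    """
    must_keep = frozenset(must_keep)
    labels = set(tree.leaf_labels)
    unknown = must_keep - labels
    if unknown:
        raise ValueError(f"must_keep contains unknown ids: {sorted(unknown)}")
    if target_size > tree.n_leaves:
        raise ValueError(f"target_size {target_size} > {tree.n_leaves} leaves")
    if target_size < max(2, len(must_keep)):
        raise ValueError("target_size must be >= max(2, |must_keep|)")

    work = tree.copy()
    trace = CoreTrace(initial_length=work.total_length(), initial_size=work.n_leaves)
    step = 0
    while work.n_leaves > target_size:
        step += 1
        candidates = [
            lab for lab in work.leaf_labels if lab not in must_keep
        ]
        # shortest terminal edge; among ties the lexicographically later
        # accession is pruned, so the canonical (smallest) twin is retained
        lengths = {x: work.terminal_edge_length(x) for x in candidates}
        shortest = min(lengths.values())
        lab = max(x for x, l in lengths.items() if l == shortest)
        dists = work.distances_from(lab)
        nearest = min(dists, key=lambda x: (dists[x], x))
        removed_len = work.remove_leaf(lab)
        retained = work.leaf_labels
        sph = (
            sphericity_index(distances, retained)
            if distances is not None and len(retained) >= 2
            else float("nan")
        )
        trace.removals.append(
            CoreRemoval(
                step=step,
                removed=lab,
                removed_edge_value=removed_len,
                nearest_retained=nearest,
                retained_length=work.total_length(),
                sphericity=sph,
                retained_size=work.n_leaves,
            )
        )
    core = CoreSet(
        retained=work.leaf_labels,
        target_size=target_size,
        must_keep=must_keep,
        trace=trace,
    )
    return core, trace


def sphericity_index(d: SquareMatrix, subset: Iterable[str]) -> float:
    """Mean over max pairwise distance within ``subset``; 1 when degenerate."""
    subset = list(subset)
    if len(subset) < 2:
        raise ValueError("need at least 2 members")
    vals = d.submatrix(subset).offdiag_values()
    vmax = vals.max()
    if vmax == 0.0:
        return 1.0
    return float(min(vals.mean() / vmax, 1.0))


def choose_core_size(trace: CoreTrace, curve: str = "sphericity") -> KneeResult:
    """Pick the stopping size at the knee of a pruning curve.

    The curve is (retained size, value) over the trace, with value either the
    sphericity index or the retained tree length.  Both axes are rescaled to
    [0, 1]; the knee is the point with maximum perpendicular distance from
    the chord joining the endpoints, ties broken toward the larger retained
    size.  A flat (chord-hugging) curve is flagged ``no_knee`` and the
    largest retained size is returned.
    """
    if curve not in ("sphericity", "retained_length"):
        raise ValueError(f"unknown curve {curve!r}")
    if len(trace.removals) < 3:
        raise ValueError("need at least 3 trace steps to locate a knee")
    attr = "sphericity" if curve == "sphericity" else "retained_length"
    pts = [(r.retained_size, getattr(r, attr)) for r in trace.removals]
    pts.sort(key=lambda p: -p[0])
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"curve {curve!r} contains NaN values")
    xs = (x - x.min()) / (x.max() - x.min()) if x.max() > x.min() else x * 0
    ys = (y - y.min()) / (y.max() - y.min()) if y.max() > y.min() else y * 0
    # perpendicular distance from the chord (first point -> last point)
    dx, dy = xs[-1] - xs[0], ys[-1] - ys[0]
    norm = float(np.hypot(dx, dy))
    if norm == 0.0:
        dists = np.zeros(len(xs))
    else:
        dists = np.abs(dy * (xs - xs[0]) - dx * (ys - ys[0])) / norm
    dist_map = {int(xi): float(di) for xi, di in zip(x, dists)}
    best = dists.max()
    if best < 1e-12:
        return KneeResult(size=int(x.max()), no_knee=True, distances=dist_map)
    ties = np.flatnonzero(dists >= best - 1e-15)
    size = int(max(x[ties]))
    return KneeResult(size=size, no_knee=False, distances=dist_map)


def detect_synonyms(
    trace: CoreTrace, threshold: float = SYNONYM_THRESHOLD
) -> list[tuple[str, str]]:
    """Removals with removed-edge value below ``threshold`` as
    (removed accession, nearest retained neighbour at removal time) pairs."""
    return [
        (r.removed, r.nearest_retained)
        for r in trace.removals
        if r.removed_edge_value < threshold
    ]


@dataclass
class CoreEvaluation:
    n_whole: int
    n_core: int
    seg_sites_whole: int
    seg_sites_core: int
    retention_pct: float
    ho_mean_whole: float
    ho_mean_core: float
    pic_mean_whole: float
    pic_mean_core: float
    maf_mean_whole: float
    maf_mean_core: float
    max_allele_freq_delta: float
    mean_allele_freq_delta: float
    genotype_freq_whole: tuple[float, float, float]
    genotype_freq_core: tuple[float, float, float]
    gd_min_core: float
    gd_mean_core: float
    gd_max_core: float
    ho_ttest_p: float

    @property
    def ho_ratio(self) -> float:
        return self.ho_mean_core / self.ho_mean_whole

    @property
    def pic_ratio(self) -> float:
        return self.pic_mean_core / self.pic_mean_whole

    @property
    def maf_ratio(self) -> float:
        return self.maf_mean_core / self.maf_mean_whole


def evaluate_core(geno: GenotypeMatrix, core: CoreSet | Sequence[str]) -> CoreEvaluation:
    """Diversity retention of a core subset against the whole panel.

    Reports the percentage of full-panel segregating sites still segregating
    in the core, core-vs-whole Ho/PIC/MAF means, allele-frequency deltas,
    mean genotype-class frequencies, the within-core distance range, and a
    Welch two-sample test of per-sample Ho between core and whole panel.
    """
    from scipy import stats as sps

    from .popgen_stats import (
        ibs_distance,
        sample_heterozygosity,
        segregating_mask,
        site_stats,
    )

    ids = core.retained if isinstance(core, CoreSet) else list(core)
    if not ids:
        raise ValueError("empty core")
    unknown = set(ids) - set(geno.sample_ids)
    if unknown:
        raise ValueError(f"core ids not in panel: {sorted(unknown)}")

    sub = geno.take_samples(ids)
    seg_whole = segregating_mask(geno)
    seg_core = segregating_mask(sub)
    n_seg_whole = int(seg_whole.sum())
    n_seg_core_among = int((seg_whole & seg_core).sum())
    retention = 100.0 * n_seg_core_among / n_seg_whole if n_seg_whole else np.nan

    stats_whole = site_stats(geno)
    stats_core = site_stats(sub)
    p_whole = np.array([s.p_alt for s in stats_whole])
    p_core = np.array([s.p_alt for s in stats_core])
    delta = np.abs(p_whole - p_core)
    delta = delta[~np.isnan(delta)]

    def _gt_freqs(stats_list):
        counts = np.array(
            [s.genotype_counts[:3] for s in stats_list if s.defined], dtype=float
        )
        tot = counts.sum(axis=1, keepdims=True)
        return tuple(float(v) for v in np.nanmean(counts / np.maximum(tot, 1), axis=0))

    ho_whole = np.array([h.ho for h in sample_heterozygosity(geno)])
    ho_core = np.array([h.ho for h in sample_heterozygosity(sub)])

    if len(ids) >= 2:
        gd = ibs_distance(sub).offdiag_values()
        gd_min, gd_mean, gd_max = float(gd.min()), float(gd.mean()), float(gd.max())
    else:
        gd_min = gd_mean = gd_max = np.nan

    if len(ids) >= 2 and len(ho_whole) >= 2 and np.nanstd(ho_whole) > 0:
        ttest = sps.ttest_ind(
            ho_core[~np.isnan(ho_core)], ho_whole[~np.isnan(ho_whole)], equal_var=False
        )
        ttest_p = float(ttest.pvalue)
    else:
        ttest_p = np.nan

    return CoreEvaluation(
        n_whole=geno.n_samples,
        n_core=len(ids),
        seg_sites_whole=n_seg_whole,
        seg_sites_core=int(seg_core.sum()),
        retention_pct=retention,
        ho_mean_whole=float(np.nanmean(ho_whole)),
        ho_mean_core=float(np.nanmean(ho_core)),
        pic_mean_whole=float(np.nanmean([s.pic for s in stats_whole])),
        pic_mean_core=float(np.nanmean([s.pic for s in stats_core])),
        maf_mean_whole=float(np.nanmean([s.maf for s in stats_whole])),
        maf_mean_core=float(np.nanmean([s.maf for s in stats_core])),
        max_allele_freq_delta=float(delta.max()) if len(delta) else np.nan,
        mean_allele_freq_delta=float(delta.mean()) if len(delta) else np.nan,
        genotype_freq_whole=_gt_freqs(stats_whole),
        genotype_freq_core=_gt_freqs(stats_core),
        gd_min_core=gd_min,
        gd_mean_core=gd_mean,
        gd_max_core=gd_max,
        ho_ttest_p=ttest_p,
    )
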