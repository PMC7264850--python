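"""Hybrid index, interclass heterozygosity, and hybrid-class inference.

Plotting each individual's proportion of heterozygous marker loci (H)
against its hybrid index (HI, the proportion of alleles derived from the
eastern parental pool) separates early hybrid generations: with fully
diagnostic markers F1s sit at (0.5, 1.0), F2s at (0.5, 0.5) on average,
and first backcrosses at (0.25, 0.5) / (0.75, 0.5).  Because real
marker panels are only semi-diagnostic, expected class distributions
are obtained by in-silico crossing of empirical parental pools
(individual-based gametes, free recombination), and individuals are
assigned to the nearest simulated class by Mahalanobis distance with a
chi-square admission gate; points beyond every gate are called
"advanced/unassigned".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AncestryPoint",
    "HybridClassCloud",
    "ancestry_point",
    "ancestry_points",
    "simulate_cross",
    "build_class_clouds",
    "classify",
    "CLASS_NAMES",
]

CLASS_NAMES = ("pure_west", "pure_east", "F1", "F2", "BC_west", "BC_east")


@dataclass(frozen=True)
class AncestryPoint:
    """Hybrid index and heterozygosity of one individual."""

    tree_id: str
    hi: float
    h: float
    n_loci_used: int

    def __post_init__(self) -> None:
        if self.n_loci_used <= 0:
            raise ValueError("n_loci_used must be > 0")
        if not (0.0 <= self.hi <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ValueError("HI and H must lie in [0, 1]")


@dataclass
class HybridClassCloud:
    """Simulated (HI, H) distribution for one cross type."""

    name: str
    points: np.ndarray  # (n, 2) columns HI, H
    mean: np.ndarray
    cov: np.ndarray

    @classmethod
    def from_points(cls, name: str, pts: np.ndarray) -> "HybridClassCloud":
        pts = np.asarray(pts, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise ValueError("a cloud needs >= 2 (HI, H) points")
        return cls(name, pts, pts.mean(axis=0), np.cov(pts.T))


def ancestry_point(
    genotypes: np.ndarray, tree_id: str = "tree"
) -> AncestryPoint:
    """HI and H over the non-missing loci of one individual.

    ``genotypes`` counts copies of the eastern-associated allele per
    locus (0/1/2, NaN = missing).  HI = sum(count) / (2 * loci used);
    H = fraction of loci with count 1.
    """
    g = np.asarray(genotypes, dtype=float)
    used = np.isfinite(g)
    n_used = int(np.sum(used))
    if n_used == 0:
        raise ValueError(f"tree {tree_id}: all genotypes missing")
    gg = g[used]
    if np.any(~np.isin(gg, (0.0, 1.0, 2.0))):
        raise ValueError(f"tree {tree_id}: genotype outside {{0,1,2}}")
    hi = float(np.sum(gg) / (2.0 * n_used))
    h = float(np.sum(gg == 1.0) / n_used)
    return AncestryPoint(tree_id, hi, h, n_used)


def ancestry_points(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-row AncestryPoints of a genotype matrix (rows = trees)."""
    rows = []
    for tid, row in zip(genotypes.index, genotypes.to_numpy(dtype=float)):
        ap = ancestry_point(row, str(tid))
        rows.append((ap.tree_id, ap.hi, ap.h, ap.n_loci_used))
    return pd.DataFrame(rows, columns=["tree_id", "hybrid_index", "heterozygosity", "n_loci_used"])


def simulate_cross(
    pool_a: np.ndarray,
    pool_b: np.ndarray,
    n_offspring: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Individual-based in-silico cross between two genotype pools.

    For each offspring one parent is drawn uniformly (with replacement)
    from each pool; each parent contributes a gamete holding, per locus,
    one of its two alleles chosen independently and uniformly (free
    recombination, r = 0.5).  A missing parental locus yields a missing
    offspring locus.  Deterministic per seed.
    """
    pool_a = np.asarray(pool_a, dtype=float)
    pool_b = np.asarray(pool_b, dtype=float)
    for nm, p in (("a", pool_a), ("b", pool_b)):
        if p.ndim != 2 or len(p) == 0:
            raise ValueError(f"pool {nm} must be a nonempty 2-D genotype matrix")
    if pool_a.shape[1] != pool_b.shape[1]:
        raise ValueError("pools must share the locus panel")
    rng = np.random.default_rng(seed)
    n_loci = pool_a.shape[1]
    pa = pool_a[rng.integers(len(pool_a), size=n_offspring)]
    pb = pool_b[rng.integers(len(pool_b), size=n_offspring)]
    # gamete allele ~ Bernoulli(g/2): 0 copies for g=0, coin flip for g=1, 1 for g=2
    ga = (rng.random((n_offspring, n_loci)) < pa / 2.0).astype(float)
    gb = (rng.random((n_offspring, n_loci)) < pb / 2.0).astype(float)
    off = ga + gb
    off[np.isnan(pa) | np.isnan(pb)] = np.nan
    return off


def build_class_clouds(
    pure_west: np.ndarray,
    pure_east: np.ndarray,
    n_per_class: int = 500,
    seed: int = 0,
) -> dict[str, HybridClassCloud]:
    """Simulate the early hybrid classes and return their (HI, H) clouds.

    F1 = west x east; F2 = F1 x F1; BC_east = F1 x pure_east;
    BC_west = F1 x pure_west; the parental pools themselves are included
    as clouds.  500 simulated individuals per cross type by default.
    """
    pure_west = np.asarray(pure_west, dtype=float)
    pure_east = np.asarray(pure_east, dtype=float)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    f1 = simulate_cross(pure_west, pure_east, n_per_class, int(seeds[0]))
    f2 = simulate_cross(f1, f1, n_per_class, int(seeds[1]))
    bc_east = simulate_cross(f1, pure_east, n_per_class, int(seeds[2]))
    bc_west = simulate_cross(f1, pure_west, n_per_class, int(seeds[3]))

    def to_pts(mat: np.ndarray) -> np.ndarray:
        return np.array(
            [[ap.hi, ap.h] for ap in (ancestry_point(r, f"sim{i}") for i, r in enumerate(mat))]
        )

    clouds = {
        "pure_west": HybridClassCloud.from_points("pure_west", to_pts(pure_west)),
        "pure_east": HybridClassCloud.from_points("pure_east", to_pts(pure_east)),
        "F1": HybridClassCloud.from_points("F1", to_pts(f1)),
        "F2": HybridClassCloud.from_points("F2", to_pts(f2)),
        "BC_west": HybridClassCloud.from_points("BC_west", to_pts(bc_west)),
        "BC_east": HybridClassCloud.from_points("BC_east", to_pts(bc_east)),
    }
    return clouds


def classify(
    point: AncestryPoint,
    clouds: dict[str, HybridClassCloud],
    gate_quantile: float = 0.99,
    ridge: float = 1e-6,
) -> tuple[str, dict[str, float]]:
    """Assign a point to the nearest simulated class, or "advanced/unassigned".

    Distances are squared Mahalanobis distances to each cloud (a ridge
    is added to degenerate covariances); a class is admitted only if the
    minimum distance falls inside the chi-square(2 df) quantile gate.
    """
    if not clouds:
        raise ValueError("no class clouds supplied")
    x = np.array([point.hi, point.h])
    d2: dict[str, float] = {}
    for name, cloud in clouds.items():
        cov = cloud.cov + ridge * np.eye(2)
        try:
            inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            inv = np.linalg.pinv(cov)
        delta = x - cloud.mean
        d2[name] = float(delta @ inv @ delta)
    best = min(d2, key=d2.get)
    gate = stats.chi2.ppf(gate_quantile, df=2)
    label = best if d2[best] <= gate else "advanced/unassigned"
    return label, d2
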