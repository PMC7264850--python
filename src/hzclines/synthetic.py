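"""Synthetic hybrid-zone datasets with known ground truth.

The generator emulates the statistical structure of a two-species
contact zone sampled in two dimensions: a (possibly curved) zone center
line; a sigmoid hybrid-index cline in signed distance from that line;
semi-diagnostic SNP loci whose per-locus clines jitter around the zone
cline (plus a configurable fraction of flat "null" loci); a steep,
offset chloroplast haplotype cline; clinal trait means with Gaussian
noise; and moth trap counts whose species identity follows a logistic
model in host genotype and location.  Every draw is taken from one
seeded generator, so identical configurations yield identical datasets.

Conventions: the transect coordinate is signed distance to the center
line with the western species (low hybrid index) on the negative side;
the hybrid index q is the proportion of ancestry from the eastern
species; genotypes count copies of the eastern-associated (focal)
allele.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .clines import ClineModel, FrequencyBinTable, evaluate
from .transect import ContourLine, signed_distances

__all__ = [
    "SnpFreqModel",
    "TraitSpec",
    "MothModel",
    "ZoneConfig",
    "TreeRecord",
    "generate_zone",
    "generate_pure_pools",
    "generate_bin_table",
    "zone_frames",
    "write_zone",
    "contour_polyline",
]


@dataclass(frozen=True)
class SnpFreqModel:
    """Per-locus allele-frequency cline model for the SNP panel.

    Non-null loci share the configured parental frequencies (pmin in the
    west, pmax in the east — semi-diagnostic by default) but jitter
    their centers (Normal sd ``center_offset_sd``) and widths
    (log-normal sd ``width_mult_sd``) around the zone cline.  A fraction
    of loci are "null": flat at a frequency drawn uniformly from
    [0.25, 0.75].
    """

    pmin: float = 0.02
    pmax: float = 0.99
    center_offset_sd: float = 300.0
    width_mult_sd: float = 0.3
    fraction_null: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.pmin, self.pmax):
            if not 0.0 <= v <= 1.0:
                raise ValueError("parental frequencies must lie in [0, 1]")
        if not 0.0 <= self.fraction_null <= 1.0:
            raise ValueError("fraction_null must lie in [0, 1]")


@dataclass(frozen=True)
class TraitSpec:
    """One quantitative trait: parental means, noise sd, transform tag."""

    name: str
    mean_west: float
    mean_east: float
    noise_sd: float
    transform: str = "none"  # none | log | sqrt


@dataclass(frozen=True)
class MothModel:
    """Log-odds model for species identity of trapped moths.

    P(eastern moth species) = logistic(intercept + coef_q * q_true +
    coef_distance * d); the eastern species tracks the eastern host.
    The default intercept offsets the hybrid-index term at q = 0.5, so
    species frequencies transition at the zone center.
    """

    intercept: float = -3.0
    coef_q: float = 6.0
    coef_distance: float = 3e-4  # per meter


def _default_traits() -> tuple[TraitSpec, ...]:
    # style length long in the west, trunks and trees taller in the west
    return (
        TraitSpec("style_length", 10.0, 4.0, 1.0, "none"),
        TraitSpec("tree_height", 8.0, 3.0, 0.8, "log"),
        TraitSpec("trunk_height", 1.5, 0.3, 0.25, "sqrt"),
    )


@dataclass(frozen=True)
class ZoneConfig:
    """Ground-truth parameters for one synthetic hybrid zone."""

    n_trees: int = 400
    extent: tuple[float, float, float, float] = (-8000.0, 8000.0, 0.0, 4000.0)
    contour_shape: str = "straight"  # straight | sinusoid
    contour_amplitude: float = 800.0
    contour_period: float = 4000.0
    true_center: float = 0.0
    true_width: float = 2236.39
    n_snps: int = 84
    snp_freq_model: SnpFreqModel = field(default_factory=SnpFreqModel)
    cp_center_offset: float = -852.0
    cp_width: float = 276.4
    cp_pmin: float = 0.02
    cp_pmax: float = 1.0
    traits: tuple[TraitSpec, ...] = field(default_factory=_default_traits)
    moth_model: MothModel = field(default_factory=MothModel)
    trap_rate: float = 5.0
    flowering_fraction: float = 0.25
    missing_rate: float = 0.0
    gap_band: tuple[float, float] | None = None  # x-range with no trees
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        if not self.true_width > 0:
            raise ValueError("true_width must be > 0")
        for nm in ("flowering_fraction", "missing_rate"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must lie in [0, 1]")
        for v in (self.cp_pmin, self.cp_pmax):
            if not 0.0 <= v <= 1.0:
                raise ValueError("chloroplast frequencies must lie in [0, 1]")
        if self.contour_shape not in ("straight", "sinusoid"):
            raise ValueError(f"unknown contour_shape {self.contour_shape!r}")
        numeric = [
            *self.extent, self.contour_amplitude, self.contour_period,
            self.true_center, self.true_width, self.cp_center_offset,
            self.cp_width, self.trap_rate,
        ]
        if not all(math.isfinite(v) for v in numeric):
            raise ValueError("non-finite configuration value")


@dataclass
class TreeRecord:
    """One sampled tree with coordinates, genotypes, haplotype and traits."""

    tree_id: str
    x: float
    y: float
    distance: float  # signed distance to the configured center line (m)
    q_true: float
    genotypes: np.ndarray  # float, nan = missing, values in {0,1,2}
    cp_haplotype: str  # "west" | "east" | "missing"
    traits: dict[str, float]
    moth_counts: tuple[int, int] | None  # (n_west_species, n_east_species)


def _sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(np.clip(-np.asarray(z, dtype=float), -700, 700)))


def contour_polyline(config: ZoneConfig, n_points: int = 400) -> ContourLine:
    """The configured true center line as a polyline."""
    _, _, ymin, ymax = config.extent
    ys = np.linspace(ymin, ymax, n_points)
    if config.contour_shape == "straight":
        xs = np.zeros_like(ys)
    else:
        xs = config.contour_amplitude * np.sin(2.0 * np.pi * ys / config.contour_period)
    return ContourLine(np.column_stack([xs, ys]), grid_resolution=1.0,
                       interpolation_tag="ground_truth")


def _signed_distance_to_center(config: ZoneConfig, xy: np.ndarray) -> np.ndarray:
    if len(xy) == 0:
        return np.zeros(0)
    if config.contour_shape == "straight":
        return xy[:, 0].astype(float)
    line = contour_polyline(config)
    xmin = config.extent[0]
    ref = np.array([xmin - 1.0, 0.5 * (config.extent[2] + config.extent[3])])
    # reference sits far west; flip so west is negative
    d = signed_distances(xy, line, ref)
    return d


def generate_zone(config: ZoneConfig) -> list[TreeRecord]:
    """Generate a seeded synthetic hybrid-zone dataset.

    Trees are placed uniformly over the extent (minus the optional
    density gap), each tree's signed distance to the center line sets
    its expected hybrid index through the zone's sigmoid cline, and all
    characters are sampled conditionally on that distance, independently
    across loci (free recombination).
    """
    rng = np.random.default_rng(config.seed)
    xmin, xmax, ymin, ymax = config.extent
    n = config.n_trees

    xs = np.empty(n)
    ys = np.empty(n)
    filled = 0
    while filled < n:
        need = n - filled
        cx = rng.uniform(xmin, xmax, size=need)
        cy = rng.uniform(ymin, ymax, size=need)
        if config.gap_band is not None:
            glo, ghi = config.gap_band
            keep = (cx < glo) | (cx > ghi)
            cx, cy = cx[keep], cy[keep]
        xs[filled : filled + len(cx)] = cx
        ys[filled : filled + len(cy)] = cy
        filled += len(cx)

    xy = np.column_stack([xs, ys])
    d = _signed_distance_to_center(config, xy)
    q_true = np.asarray(_sigmoid(4.0 * (d - config.true_center) / config.true_width))

    # per-locus cline parameters
    m = config.snp_freq_model
    null_mask = rng.random(config.n_snps) < m.fraction_null
    centers = config.true_center + rng.normal(0.0, m.center_offset_sd, config.n_snps)
    widths = config.true_width * np.exp(rng.normal(0.0, m.width_mult_sd, config.n_snps))
    null_freqs = rng.uniform(0.25, 0.75, config.n_snps)

    if config.n_snps > 0 and n > 0:
        shape = np.asarray(_sigmoid(4.0 * (d[:, None] - centers[None, :]) / widths[None, :]))
        p = m.pmin + (m.pmax - m.pmin) * shape
        p[:, null_mask] = null_freqs[null_mask][None, :]
        geno = rng.binomial(2, p).astype(float)
        if config.missing_rate > 0:
            geno[rng.random(geno.shape) < config.missing_rate] = np.nan
    else:
        geno = np.zeros((n, config.n_snps))

    # chloroplast: its own offset, steep cline (haploid)
    cp_center = config.true_center + config.cp_center_offset
    p_cp = config.cp_pmin + (config.cp_pmax - config.cp_pmin) * np.asarray(
        _sigmoid(4.0 * (d - cp_center) / config.cp_width)
    )
    cp_east = rng.random(n) < p_cp
    cp_missing = rng.random(n) < config.missing_rate

    # traits: clinal means on the zone sigmoid, Gaussian noise, floored so
    # log/sqrt transforms stay in-domain
    trait_vals: dict[str, np.ndarray] = {}
    for t in config.traits:
        mu = t.mean_west + (t.mean_east - t.mean_west) * q_true
        trait_vals[t.name] = np.maximum(rng.normal(mu, t.noise_sd), 1e-2)

    # moths on a flowering subset
    flowering = rng.random(n) < config.flowering_fraction
    totals = np.where(flowering, rng.poisson(config.trap_rate, n), 0)
    mm = config.moth_model
    p_east_moth = np.asarray(_sigmoid(mm.intercept + mm.coef_q * q_true + mm.coef_distance * d))
    n_east_moth = rng.binomial(totals, p_east_moth)

    trees = []
    for i in range(n):
        if flowering[i]:
            counts = (int(totals[i] - n_east_moth[i]), int(n_east_moth[i]))
        else:
            counts = None
        trees.append(
            TreeRecord(
                tree_id=f"t{i:05d}",
                x=float(xs[i]),
                y=float(ys[i]),
                distance=float(d[i]),
                q_true=float(q_true[i]),
                genotypes=geno[i].copy(),
                cp_haplotype="missing" if cp_missing[i] else ("east" if cp_east[i] else "west"),
                traits={k: float(v[i]) for k, v in trait_vals.items()},
                moth_counts=counts,
            )
        )
    return trees


def generate_pure_pools(
    config: ZoneConfig, q_low: float = 0.15, q_high: float = 0.85
) -> tuple[list[TreeRecord], list[TreeRecord]]:
    """Partition a generated zone into parental pools by true hybrid index.

    Trees with ``q_true <= q_low`` form the western pool, ``>= q_high``
    the eastern pool; intermediate (hybrid) trees are excluded.
    """
    if not 0.0 <= q_low < q_high <= 1.0:
        raise ValueError("need 0 <= q_low < q_high <= 1")
    trees = generate_zone(config)
    west = [t for t in trees if t.q_true <= q_low]
    east = [t for t in trees if t.q_true >= q_high]
    if not west:
        raise ValueError(f"empty western pool at threshold q_low={q_low}")
    if not east:
        raise ValueError(f"empty eastern pool at threshold q_high={q_high}")
    return west, east


def generate_bin_table(
    model: ClineModel,
    bin_distances: np.ndarray,
    n_per_bin: np.ndarray | list[int],
    seed: int = 0,
) -> FrequencyBinTable:
    """Direct binomial sampling of a frequency bin table from a cline model."""
    bin_distances = np.asarray(bin_distances, dtype=float)
    n_per_bin = np.asarray(n_per_bin, dtype=int)
    if np.any(n_per_bin <= 0):
        raise ValueError("allele counts per bin must be positive")
    p = np.asarray(evaluate(model, bin_distances), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("model frequency outside [0, 1] at a bin distance")
    rng = np.random.default_rng(seed)
    counts = rng.binomial(n_per_bin, p)
    return FrequencyBinTable(bin_distances, n_per_bin, counts)


# ---------------------------------------------------------------------------
# tabular views / writers


def zone_frames(trees: list[TreeRecord]) -> dict[str, pd.DataFrame]:
    """DataFrame views: coordinates, genotypes, haplotypes, traits, moths, truth q."""
    ids = [t.tree_id for t in trees]
    coords = pd.DataFrame({"tree_id": ids, "x_m": [t.x for t in trees], "y_m": [t.y for t in trees]})
    n_loci = len(trees[0].genotypes) if trees else 0
    geno = pd.DataFrame(
        np.array([t.genotypes for t in trees]).reshape(len(trees), n_loci),
        index=pd.Index(ids, name="tree_id"),
        columns=[f"snp{j:04d}" for j in range(n_loci)],
    )
    hap = pd.DataFrame({"tree_id": ids, "cp_haplotype": [t.cp_haplotype for t in trees]})
    trait_names = sorted(trees[0].traits) if trees else []
    traits = pd.DataFrame({"tree_id": ids, **{nm: [t.traits[nm] for t in trees] for nm in trait_names}})
    moth_rows = [
        (t.tree_id, t.moth_counts[0], t.moth_counts[1])
        for t in trees
        if t.moth_counts is not None
    ]
    moths = pd.DataFrame(moth_rows, columns=["tree_id", "n_synthetica", "n_antithetica"])
    truth = pd.DataFrame(
        {"tree_id": ids, "distance_m": [t.distance for t in trees], "q_true": [t.q_true for t in trees]}
    )
    return {"coordinates": coords, "genotypes": geno, "haplotypes": hap,
            "traits": traits, "moths": moths, "truth": truth}


def write_zone(trees: list[TreeRecord], config: ZoneConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the standard pipeline input tables plus a ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = zone_frames(trees)
    paths = {}
    fmt = "%.10g"
    frames["coordinates"].to_csv(outdir / "coordinates.csv", index=False, float_format=fmt)
    paths["coordinates"] = outdir / "coordinates.csv"
    frames["genotypes"].to_csv(outdir / "genotypes.tsv", sep="\t", na_rep="NA", float_format="%g")
    paths["genotypes"] = outdir / "genotypes.tsv"
    for key, fname in (("haplotypes", "haplotypes.tsv"), ("traits", "traits.tsv"),
                       ("moths", "moths.tsv"), ("truth", "truth.tsv")):
        frames[key].to_csv(outdir / fname, sep="\t", index=False, na_rep="NA", float_format=fmt)
        paths[key] = outdir / fname
    truth = asdict(config)
    truth["traits"] = [asdict(t) for t in config.traits]
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    paths["ground_truth"] = outdir / "ground_truth.json"
    return paths
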