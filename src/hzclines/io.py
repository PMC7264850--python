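"""Readers and writers for the pipeline's tabular formats.

All tables are TSV (CSV for coordinates) with a header, tab delimiter
and ``NA`` as the missing token.  Genotypes travel as a matrix of
0/1/2 focal-allele counts (rows = trees, columns = loci); a VCF reader
(biallelic sites only) is available when cyvcf2 is installed.  Bin
tables use the columns (bin_id, distance_m, n, count | mean, variance)
— the pipeline's HZAR-format analogue.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clines import FrequencyBinTable, TraitBinTable, delta_p
from .fitting import ClineFit
from .transect import ContourLine, TransectBin, project_coordinates

__all__ = [
    "read_coordinates",
    "read_genotype_matrix",
    "read_column_table",
    "write_frequency_table",
    "read_frequency_table",
    "write_trait_table",
    "read_trait_table",
    "write_contour",
    "read_contour",
    "write_distances",
    "write_bins",
    "orient_genotypes",
    "frequency_table_from_bins",
    "haploid_table_from_bins",
    "trait_table_from_bins",
    "moth_table_from_bins",
    "write_table2_style",
    "fit_to_dict",
    "write_fit_json",
]

FLOAT_FMT = "%.10g"


def read_coordinates(path: str | Path) -> pd.DataFrame:
    """Read a coordinates CSV (tree_id + lon/lat or x_m/y_m) and project it."""
    df = pd.read_csv(path)
    if "tree_id" not in df.columns:
        raise ValueError(f"{path}: missing tree_id column")
    if df["tree_id"].duplicated().any():
        dup = df.loc[df["tree_id"].duplicated(), "tree_id"].iloc[0]
        raise ValueError(f"{path}: duplicated tree id {dup!r}")
    df["tree_id"] = df["tree_id"].astype(str)
    return project_coordinates(df)


def read_genotype_matrix(path: str | Path, format: str = "tsv012") -> pd.DataFrame:
    """Load a per-tree per-locus focal-allele count matrix (NaN = missing)."""
    if format == "tsv012":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        df.index = df.index.astype(str)
        df.index.name = "tree_id"
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"{path}: duplicated tree id {dup!r}")
        arr = df.to_numpy(dtype=float)
        bad = np.argwhere(np.isfinite(arr) & ~np.isin(arr, (0.0, 1.0, 2.0)))
        if len(bad):
            r, c = bad[0]
            raise ValueError(
                f"{path}: invalid genotype {arr[r, c]!r} at row {df.index[r]!r}, "
                f"column {df.columns[c]!r}"
            )
        return df.astype(float)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str | Path) -> pd.DataFrame:
    import logging

    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF reading requires the optional cyvcf2 dependency") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci, rows = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        loci.append(f"{var.CHROM}:{var.POS}")
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = np.asarray(var.gt_types, dtype=float)
        counts = np.where(gt == 3, 2.0, np.where(gt == 2, np.nan, gt))
        rows.append(counts)
    if n_skipped:
        logging.getLogger(__name__).warning(
            "%s: skipped %d non-biallelic site(s)", path, n_skipped
        )
    mat = np.array(rows).T if rows else np.zeros((len(samples), 0))
    return pd.DataFrame(mat, index=pd.Index(samples, name="tree_id"),
                        columns=loci, dtype=float)


def read_column_table(path: str | Path, column: str) -> pd.Series:
    """One named column of a TSV, indexed by tree_id."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "tree_id" not in df.columns or column not in df.columns:
        raise ValueError(f"{path}: needs tree_id and {column!r} columns")
    df["tree_id"] = df["tree_id"].astype(str)
    return df.set_index("tree_id")[column]


# ---------------------------------------------------------------------------
# bin tables


def write_frequency_table(table: FrequencyBinTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_frequency_table(path: str | Path) -> FrequencyBinTable:
    df = pd.read_csv(path, sep="\t")
    for col in ("bin_id", "distance_m", "n", "count"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return FrequencyBinTable(
        df["distance_m"].to_numpy(), df["n"].to_numpy(), df["count"].to_numpy(),
        bin_id=df["bin_id"].astype(str).tolist(),
    )


def write_trait_table(table: TraitBinTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_trait_table(path: str | Path) -> TraitBinTable:
    df = pd.read_csv(path, sep="\t")
    for col in ("bin_id", "distance_m", "n", "mean", "variance"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return TraitBinTable(
        df["distance_m"].to_numpy(), df["n"].to_numpy(), df["mean"].to_numpy(),
        df["variance"].to_numpy(), bin_id=df["bin_id"].astype(str).tolist(),
    )


def write_contour(contour: ContourLine, path: str | Path) -> None:
    contour.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_contour(path: str | Path, grid_resolution: float = float("nan")) -> ContourLine:
    df = pd.read_csv(path, sep="\t")
    return ContourLine(df[["x_m", "y_m"]].to_numpy(), grid_resolution=grid_resolution
                       if np.isfinite(grid_resolution) else 1.0)


def write_distances(tree_ids: list[str], distances: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"tree_id": tree_ids, "distance_m": distances}).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def write_bins(bins: list[TransectBin], path: str | Path) -> None:
    rows = [
        (b.bin_id, tid, b.mean_distance, b.n_trees)
        for b in bins
        for tid in b.member_ids
    ]
    pd.DataFrame(rows, columns=["bin_id", "tree_id", "mean_distance_m", "n_trees"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# genotype orientation and per-bin aggregation


def orient_genotypes(
    genotypes: pd.DataFrame, east_ids: list[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Orient each locus so counts track the eastern-associated allele.

    The focal allele at a locus is the one at higher frequency in the
    designated eastern pool; loci where the recorded allele is the
    western one are flipped (count -> 2 - count).  Returns the oriented
    matrix and a boolean Series (flipped per locus) — the allele-key
    sidecar that makes hybrid index reproducible across runs.
    """
    east = genotypes.loc[genotypes.index.intersection(east_ids)]
    if east.empty:
        raise ValueError("no eastern-pool trees present in the genotype matrix")
    freq_east = east.mean(axis=0, skipna=True) / 2.0
    flipped = freq_east < 0.5
    out = genotypes.copy()
    out.loc[:, flipped] = 2.0 - out.loc[:, flipped]
    return out, flipped


def _bin_members(bins: list[TransectBin]) -> list[tuple[TransectBin, list[str]]]:
    return [(b, b.member_ids) for b in bins]


def frequency_table_from_bins(
    bins: list[TransectBin], genotypes: pd.Series
) -> FrequencyBinTable:
    """Diploid allele-count bin table from one per-tree genotype column."""
    dist, n_alleles, count, ids = [], [], [], []
    for b in bins:
        g = genotypes.reindex(b.member_ids).dropna()
        if g.empty:
            continue
        dist.append(b.mean_distance)
        n_alleles.append(2 * len(g))
        count.append(int(g.sum()))
        ids.append(b.bin_id)
    if not dist:
        raise ValueError("no bin holds genotyped trees")
    return FrequencyBinTable(np.array(dist), np.array(n_alleles), np.array(count), bin_id=ids)


def haploid_table_from_bins(
    bins: list[TransectBin], haplotypes: pd.Series, east_value: str = "east"
) -> FrequencyBinTable:
    """Haploid haplotype-count bin table (e.g. chloroplast)."""
    dist, n, count, ids = [], [], [], []
    for b in bins:
        h = haplotypes.reindex(b.member_ids).dropna()
        h = h[h != "missing"]
        if h.empty:
            continue
        dist.append(b.mean_distance)
        n.append(len(h))
        count.append(int((h == east_value).sum()))
        ids.append(b.bin_id)
    if not dist:
        raise ValueError("no bin holds haplotyped trees")
    return FrequencyBinTable(np.array(dist), np.array(n), np.array(count), bin_id=ids)


def trait_table_from_bins(bins: list[TransectBin], values: pd.Series) -> TraitBinTable:
    """Mean/variance bin table from per-tree (standardized) trait values."""
    dist, n, mean, var, ids = [], [], [], [], []
    for b in bins:
        v = values.reindex(b.member_ids).dropna()
        if v.empty:
            continue
        dist.append(b.mean_distance)
        n.append(len(v))
        mean.append(float(v.mean()))
        var.append(float(v.var(ddof=1)) if len(v) > 1 else 0.0)
        ids.append(b.bin_id)
    if not dist:
        raise ValueError("no bin holds measured trees")
    return TraitBinTable(np.array(dist), np.array(n), np.array(mean), np.array(var), bin_id=ids)


def moth_table_from_bins(bins: list[TransectBin], moths: pd.DataFrame) -> FrequencyBinTable:
    """Moth species counts per bin (focal = eastern species)."""
    m = moths.set_index("tree_id") if "tree_id" in moths.columns else moths
    dist, n, count, ids = [], [], [], []
    for b in bins:
        sub = m.reindex(b.member_ids).dropna()
        tot = int(sub["n_synthetica"].sum() + sub["n_antithetica"].sum())
        if tot == 0:
            continue
        dist.append(b.mean_distance)
        n.append(tot)
        count.append(int(sub["n_antithetica"].sum()))
        ids.append(b.bin_id)
    if not dist:
        raise ValueError("no bin holds moth observations")
    return FrequencyBinTable(np.array(dist), np.array(n), np.array(count), bin_id=ids)


# ---------------------------------------------------------------------------
# fit output


def write_table2_style(fits: list[ClineFit], path: str | Path) -> pd.DataFrame:
    """Summary TSV: character, best model, center, width, center 2LL bounds,
    pmin (west) and pmax (east), sorted by center (null fits sort last)."""
    if not fits:
        raise ValueError("no fits to write")
    rows = []
    for f in fits:
        m = f.best_model
        if f.is_null:
            center = width = lo = hi = float("nan")
        else:
            center, width = m.center, m.width
            lo, hi = f.center_interval
        rows.append((f.character, f.model_type, center, width, lo, hi, m.pmin, m.pmax))
    df = pd.DataFrame(
        rows,
        columns=[
            "character", "best_model", "center", "width",
            "center_low", "center_high", "pmin_west", "pmax_east",
        ],
    ).sort_values("center", na_position="last", kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=FLOAT_FMT)
    return df


def fit_to_dict(fit: ClineFit) -> dict:
    m = fit.best_model
    return {
        "character": fit.character,
        "data_kind": fit.data_kind,
        "model_type": fit.model_type,
        "is_null": fit.is_null,
        "lnl_max": None if np.isnan(fit.lnl_max) else fit.lnl_max,
        "aic": fit.aic,
        "parameters": {
            "center": m.center, "width": m.width, "pmin": m.pmin, "pmax": m.pmax,
            "delta_l": m.delta_l, "tau_l": m.tau_l, "delta_r": m.delta_r, "tau_r": m.tau_r,
            "d_min": m.d_min, "d_max": m.d_max,
        },
        "delta_p": delta_p(m),
        "intervals": {k: list(v) for k, v in fit.intervals.items()},
        "rhat": {k: (None if not np.isfinite(v) else v) for k, v in fit.rhat.items()},
        "converged": fit.converged,
        "null_regression_p": fit.null_regression_p,
    }


def write_fit_json(fit: ClineFit, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(fit_to_dict(fit), fh, indent=1)
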