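"""End-to-end pipeline: project -> contour -> distances -> bins -> fits ->
comparisons -> hybrid classes -> pollinator stats.

Stages are skipped (with a logged notice) when their input tables are
absent.  A run manifest records the configuration, software version,
SHA-256 checksums of every written output, per-stage wall-clock time
and collected warnings, so identical configurations reproduce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as hio
from .clines import standardize_trait
from .compare import comparison_matrix
from .fitting import ClineFit, FitConfig, select_model
from .hybrids import ancestry_point, ancestry_points, build_class_clouds, classify
from .pollinators import host_choice_glm, pearson_q_distance
from .transect import estimate_contour, make_bins, signed_distances

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class PipelineConfig:
    """File paths, column-role bindings and tuning for a full run.

    ``transect_index_col`` names the hybrid-index column used to place
    the 0.5 contour; ``fitting_index_col`` the one fitted as the
    hybrid-index cline (they may come from different marker sets).
    Optional tables (traits, moths, haplotypes) skip their stages when
    absent.
    """

    coordinates: str | Path
    hybrid_index: str | Path
    output_dir: str | Path
    genotypes: str | Path | None = None
    haplotypes: str | Path | None = None
    traits: str | Path | None = None
    moths: str | Path | None = None
    transect_index_col: str = "q"
    fitting_index_col: str = "q"
    trait_transforms: dict[str, str] = field(default_factory=dict)
    bin_width: float = 250.0
    min_per_bin: int = 3
    grid_resolution: float = 250.0
    contour_level: float = 0.5
    contour_smoothing: float = 1e-3
    q_low: float = 0.15
    q_high: float = 0.85
    n_per_class: int = 500
    max_snp_clines: int = 0
    fit: FitConfig = field(default_factory=FitConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for nm in ("coordinates", "hybrid_index"):
            p = getattr(self, nm)
            if not Path(p).exists():
                raise FileNotFoundError(f"{nm} table not found: {p}")
        for nm in ("genotypes", "haplotypes", "traits", "moths"):
            p = getattr(self, nm)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{nm} table not found: {p}")


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict[str, float]  # wall-clock seconds
    checksums: dict[str, str]
    warnings: list[str]
    seed: int

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every applicable stage and return the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}
    written: list[Path] = []
    caught: list[str] = []

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                log.info("stage %s: start", name)
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, *exc):
                stages[name] = time.perf_counter() - self_inner.t0
                log.info("stage %s: done (%.2fs)", name, stages[name])
                return False

        return _Timer()

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # --- coordinates & transect -------------------------------------
        with stage("transect"):
            coords = hio.read_coordinates(config.coordinates)
            q_transect = hio.read_column_table(config.hybrid_index, config.transect_index_col)
            merged = coords.set_index("tree_id").join(q_transect.rename("q"), how="inner").dropna(subset=["q"])
            pts = merged[["x_m", "y_m"]].to_numpy()
            contour = estimate_contour(
                pts, merged["q"].to_numpy(), config.grid_resolution,
                config.contour_level, config.contour_smoothing,
            )
            west = merged[merged["q"] <= config.q_low]
            ref = (west if len(west) else merged.nsmallest(max(len(merged) // 10, 1), "q"))[
                ["x_m", "y_m"]
            ].mean().to_numpy()
            all_pts = coords[["x_m", "y_m"]].to_numpy()
            dists = signed_distances(all_pts, contour, ref)
            hio.write_contour(contour, out / "contour.tsv")
            hio.write_distances(coords["tree_id"].tolist(), dists, out / "distances.tsv")
            written += [out / "contour.tsv", out / "distances.tsv"]
            dist_by_tree = pd.Series(dists, index=coords["tree_id"])

        # --- bins --------------------------------------------------------
        with stage("bins"):
            geno = (
                hio.read_genotype_matrix(config.genotypes)
                if config.genotypes is not None
                else None
            )
            if geno is not None:
                bin_ids = [t for t in geno.index if t in dist_by_tree.index]
            else:
                bin_ids = list(merged.index)
            bins = make_bins(
                bin_ids, dist_by_tree.reindex(bin_ids).to_numpy(),
                config.bin_width, config.min_per_bin,
            )
            hio.write_bins(bins, out / "bins.tsv")
            written.append(out / "bins.tsv")

        # --- per-character fits ------------------------------------------
        fits: list[ClineFit] = []
        with stage("fits"):
            fit_cfg = FitConfig(**{**asdict(config.fit), "seed": config.seed})

            if geno is not None:
                fit_q = hio.read_column_table(config.hybrid_index, config.fitting_index_col)
                std_q, _ = standardize_trait(fit_q.dropna().to_numpy())
                q_series = pd.Series(std_q, index=fit_q.dropna().index)
                table = hio.trait_table_from_bins(bins, q_series)
                fits.append(select_model(table, fit_cfg, "trait", "hybrid_index"))

                if config.max_snp_clines > 0:
                    for j, locus in enumerate(geno.columns[: config.max_snp_clines]):
                        t = hio.frequency_table_from_bins(bins, geno[locus])
                        fits.append(select_model(t, fit_cfg, "frequency", str(locus)))

            if config.haplotypes is not None:
                hap = hio.read_column_table(config.haplotypes, "cp_haplotype")
                t = hio.haploid_table_from_bins(bins, hap)
                fits.append(select_model(t, fit_cfg, "frequency", "cp_haplotype"))

            if config.traits is not None:
                traits_df = pd.read_csv(config.traits, sep="\t", na_values=["NA"])
                traits_df["tree_id"] = traits_df["tree_id"].astype(str)
                traits_df = traits_df.set_index("tree_id")
                for col in traits_df.columns:
                    vals = traits_df[col].dropna()
                    std, _ = standardize_trait(
                        vals.to_numpy(), config.trait_transforms.get(col, "none"),
                        ids=list(vals.index),
                    )
                    t = hio.trait_table_from_bins(bins, pd.Series(std, index=vals.index))
                    fits.append(select_model(t, fit_cfg, "trait", col))

            if config.moths is not None:
                moths = pd.read_csv(config.moths, sep="\t", na_values=["NA"])
                moths["tree_id"] = moths["tree_id"].astype(str)
                t = hio.moth_table_from_bins(bins, moths)
                fits.append(select_model(t, fit_cfg, "frequency", "moth_frequency"))

            if fits:
                hio.write_table2_style(fits, out / "cline_summary.tsv")
                written.append(out / "cline_summary.tsv")
                for f in fits:
                    p = out / f"fit_{f.character}.json"
                    hio.write_fit_json(f, p)
                    written.append(p)
            else:
                log.warning("no characters to fit; fits stage produced no output")

        # --- comparisons --------------------------------------------------
        with stage("comparisons"):
            comparable = [f for f in fits if not f.is_null]
            if len(comparable) >= 2:
                for param in ("center", "width"):
                    m = comparison_matrix(comparable, param)
                    p = out / f"comparisons_{param}.tsv"
                    m.to_csv(p, sep="\t")
                    written.append(p)
            else:
                log.warning("fewer than two non-null fits; comparison stage skipped")

        # --- hybrid classes ----------------------------------------------
        with stage("hybrid_classes"):
            if geno is not None:
                fit_q = hio.read_column_table(config.hybrid_index, config.fitting_index_col)
                common = geno.index.intersection(fit_q.dropna().index)
                gsub = geno.loc[common]
                qsub = fit_q.loc[common]
                west_ids = list(qsub[qsub <= config.q_low].index)
                east_ids = list(qsub[qsub >= config.q_high].index)
                if west_ids and east_ids:
                    oriented, key = hio.orient_genotypes(gsub, east_ids)
                    key.rename("flipped").to_frame().to_csv(
                        out / "allele_key.tsv", sep="\t"
                    )
                    written.append(out / "allele_key.tsv")
                    clouds = build_class_clouds(
                        oriented.loc[west_ids].to_numpy(),
                        oriented.loc[east_ids].to_numpy(),
                        config.n_per_class,
                        config.seed,
                    )
                    pts = ancestry_points(oriented)
                    labels = []
                    for _, row in pts.iterrows():
                        ap = ancestry_point(
                            oriented.loc[row["tree_id"]].to_numpy(), row["tree_id"]
                        )
                        labels.append(classify(ap, clouds)[0])
                    pts["class"] = labels
                    pts.to_csv(out / "ancestry.tsv", sep="\t", index=False,
                               float_format=hio.FLOAT_FMT)
                    written.append(out / "ancestry.tsv")
                    cloud_summary = {
                        nm: {"mean": c.mean.tolist(), "cov": c.cov.tolist(),
                             "n": int(len(c.points))}
                        for nm, c in clouds.items()
                    }
                    with open(out / "class_clouds.json", "w") as fh:
                        json.dump(cloud_summary, fh, indent=1)
                    written.append(out / "class_clouds.json")
                else:
                    log.warning("empty parental pool at the configured thresholds; "
                                "hybrid-class stage skipped")
            else:
                log.warning("no genotype table; hybrid-class stage skipped")

        # --- pollinators --------------------------------------------------
        with stage("pollinators"):
            if config.moths is not None:
                moths = pd.read_csv(config.moths, sep="\t", na_values=["NA"])
                moths["tree_id"] = moths["tree_id"].astype(str)
                fit_q = hio.read_column_table(config.hybrid_index, config.fitting_index_col)
                rec = moths.set_index("tree_id").join(fit_q.rename("q"))
                rec = rec.join(dist_by_tree.rename("distance")).dropna()
                if len(rec) >= 3:
                    pear = pearson_q_distance(rec)
                    coef = host_choice_glm(rec)
                    coef.to_csv(out / "pollinator_glm.tsv", sep="\t",
                                float_format=hio.FLOAT_FMT)
                    written.append(out / "pollinator_glm.tsv")
                    with open(out / "pollinator_pearson.json", "w") as fh:
                        json.dump(asdict(pear), fh, indent=1)
                    written.append(out / "pollinator_pearson.json")
                else:
                    log.warning("too few moth records with q and distance; "
                                "pollinator stage skipped")
            else:
                log.warning("no moth table; pollinator stage skipped")

        caught = [str(w.message) for w in wrec]

    cfg_dict = asdict(config)
    cfg_dict = {k: (str(v) if isinstance(v, Path) else v) for k, v in cfg_dict.items()}
    manifest = RunManifest(
        config=cfg_dict,
        version=__version__,
        stages=stages,
        checksums={str(p.name): _sha256(p) for p in written},
        warnings=caught,
        seed=config.seed,
    )
    manifest.write(out / "manifest.json")
    return manifest
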