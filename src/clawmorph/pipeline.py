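"""End-to-end analysis orchestration.

Two pipelines mirror the study design:

``run_morphometrics``
    landmarks -> GPA with semi-landmark sliding -> tangent-space PCA
    (axes oriented by elongation) -> lever scores -> SMA regressions of the
    scores on PC axes, Welch group tests, and grouped five-number
    summaries; writes aligned coordinates, a PC table, a biomechanics
    table, a tidy statistics table, figures, and a JSON manifest with
    content hashes.

``run_phylogeny``
    character matrix -> random-addition Wagner builds -> branch swapping ->
    pooled most parsimonious trees -> strict and 50% majority-rule
    consensus -> scores (length, CI, RI); same manifest contract.

Reruns with an identical config and seed reproduce identical file hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .landmarks import (
    LandmarkDataset,
    SliderTable,
    read_landmark_csv,
    read_levers,
    read_sliders,
    read_tps,
    write_tps,
)
from .mechanics import scores_table
from .parsimony import ParsimonySearch, read_matrix, tree_length
from .shape_space import orient_axes, shape_pca
from .stats import group_summary, sma_fit, welch_test
from .superimposition import gpa
from .trees import majority_rule_consensus, strict_consensus

logger = logging.getLogger("clawmorph")

__all__ = ["PipelineConfig", "run_morphometrics", "run_phylogeny"]


@dataclass
class PipelineConfig:
    """Inputs, mode flags and search settings for one pipeline run."""

    landmarks: str | None = None
    landmark_format: str = "tps"  # tps | csv-long | csv-wide
    sliders: str | None = None
    levers: str | None = None
    matrix: str | None = None
    matrix_format: str | None = None
    sliding_mode: str = "bending_energy"
    residual_convention: str = "vertical"
    ordered_characters: list[int] = field(default_factory=list)
    excluded_characters: list[int] = field(default_factory=list)
    replicates: int = 100
    hold: int = 10
    swap: str = "tbr"
    seed: int = 0
    output_dir: str = "clawmorph_out"
    tip_landmark: int = 1   # 1-based, elongation chord endpoints
    proximal_landmark: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate_paths(self, need: list[str]) -> None:
        for name in need:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"config requires {name!r}")
            if not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value} does not exist")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, config: PipelineConfig, stage: str,
                    files: list[Path]) -> Path:
    manifest = {
        "stage": stage,
        "clawmorph_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "outputs": {f.name: _sha256(f) for f in sorted(files)},
    }
    path = outdir / f"{stage}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


class _StageTimer:
    def __init__(self, stage: str):
        self.stage = stage

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.stage)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is not None:
            logger.error("stage %s: FAILED after %.2fs: %s",
                         self.stage, dt, exc)
            raise RuntimeError(f"stage {self.stage!r} failed: {exc}") from exc
        logger.info("stage %s: done in %.2fs", self.stage, dt)


def _load_landmarks(config: PipelineConfig) -> LandmarkDataset:
    if config.landmark_format == "tps":
        return read_tps(config.landmarks)
    if config.landmark_format in ("csv-long", "csv-wide"):
        schema = config.landmark_format.split("-")[1]
        return read_landmark_csv(config.landmarks, schema=schema)
    raise ValueError(f"unknown landmark format {config.landmark_format!r}")


def run_morphometrics(config: PipelineConfig) -> dict:
    """Run the morphometrics + mechanics pipeline; returns a results bundle."""
    config.validate_paths(["landmarks", "levers"])
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    bundle: dict = {}

    with _StageTimer("landmarks"):
        dataset = _load_landmarks(config)
        if config.sliders:
            sliders = read_sliders(config.sliders, dataset.n_landmarks)
        else:
            logger.warning(
                "no slider table configured: running plain GPA "
                "(all landmarks fixed)"
            )
            sliders = SliderTable(())

    with _StageTimer("gpa"):
        result = gpa(dataset, sliders=sliders, mode=config.sliding_mode)
        aligned_rows = []
        for sid, shape in zip(result.specimen_ids, result.aligned):
            for j, (x, y) in enumerate(shape, start=1):
                aligned_rows.append(
                    {"specimen": sid, "landmark": j, "x": x, "y": y}
                )
        aligned_path = outdir / "aligned_coordinates.csv"
        pd.DataFrame(aligned_rows).to_csv(
            aligned_path, index=False, float_format="%.12g"
        )
        files.append(aligned_path)
        consensus_path = outdir / "consensus_shape.tps"
        from .landmarks import LandmarkConfiguration

        write_tps(
            [LandmarkConfiguration("consensus", result.consensus)],
            consensus_path,
        )
        files.append(consensus_path)
        bundle["procrustes"] = result

    with _StageTimer("pca"):
        space = shape_pca(result)
        space = orient_axes(
            space,
            tip_index=config.tip_landmark - 1,
            proximal_index=config.proximal_landmark - 1,
        )
        n_pc = space.n_components
        pc_table = pd.DataFrame(
            space.scores, columns=[f"PC{i + 1}" for i in range(n_pc)]
        )
        pc_table.insert(0, "specimen", space.specimen_ids)
        pc_path = outdir / "pc_scores.csv"
        pc_table.to_csv(pc_path, index=False, float_format="%.6g")
        var_table = pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(n_pc)],
                "eigenvalue": space.eigenvalues,
                "percent_variance": space.percent_variance,
                "cumulative_percent": np.cumsum(space.percent_variance),
            }
        )
        var_path = outdir / "percent_variance.csv"
        var_table.to_csv(var_path, index=False, float_format="%.6g")
        files += [pc_path, var_path]
        bundle["shape_space"] = space

    with _StageTimer("mechanics"):
        levers = read_levers(config.levers)
        scores = scores_table(levers)
        scores_path = outdir / "biomechanics_scores.csv"
        scores.to_csv(scores_path, index=False, float_format="%.6g")
        files.append(scores_path)
        bundle["scores"] = scores

    with _StageTimer("stats"):
        stats_rows = []
        merged = scores.merge(
            pc_table, left_on="specimen_id", right_on="specimen", how="inner"
        )
        for metric in ("MA", "DFT", "output"):
            for pc in ("PC1", "PC2"):
                if pc not in merged or len(merged) < 3:
                    continue
                try:
                    fit = sma_fit(
                        merged[pc], merged[metric],
                        residual_convention=config.residual_convention,
                    )
                except ValueError:
                    continue
                stats_rows.append(
                    {
                        "analysis": "sma", "term": f"{metric}~{pc}",
                        "estimate": fit.slope, "intercept": fit.intercept,
                        "statistic": fit.r, "df": fit.n - 2, "p": fit.p_corr,
                    }
                )
            groups = merged.groupby("clade_group")[metric]
            labels = [g for g in groups.groups if g != "unknown"]
            if len(labels) == 2:
                a = groups.get_group(labels[0])
                b = groups.get_group(labels[1])
                try:
                    res = welch_test(a, b)
                except ValueError:
                    continue
                stats_rows.append(
                    {
                        "analysis": "welch",
                        "term": f"{metric}:{labels[0]}-vs-{labels[1]}",
                        "estimate": float(np.mean(a) - np.mean(b)),
                        "intercept": np.nan, "statistic": res.t,
                        "df": res.df, "p": res.p,
                    }
                )
        stats_df = pd.DataFrame(stats_rows)
        stats_path = outdir / "statistics.csv"
        stats_df.to_csv(stats_path, index=False, float_format="%.6g")
        files.append(stats_path)
        summaries = pd.concat(
            [
                group_summary(scores[m], scores["clade_group"]).assign(metric=m)
                for m in ("MA", "DFT", "output")
            ]
        )
        summary_path = outdir / "group_summaries.csv"
        summaries.to_csv(summary_path, index=False, float_format="%.6g")
        files.append(summary_path)
        bundle["statistics"] = stats_df
        bundle["summaries"] = summaries

    with _StageTimer("figures"):
        fig_path = outdir / "morphospace.svg"
        fig, ax = plt.subplots(figsize=(5, 4))
        groups = merged.groupby("clade_group")
        for name, sub in groups:
            ax.scatter(sub["PC1"], sub.get("PC2", 0 * sub["PC1"]),
                       label=name, s=22)
        ax.set_xlabel(f"PC1 ({space.percent_variance[0]:.1f}%)")
        if n_pc > 1:
            ax.set_ylabel(f"PC2 ({space.percent_variance[1]:.1f}%)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(fig_path)
        plt.close(fig)
        files.append(fig_path)
        box_path = outdir / "score_boxplots.svg"
        fig, axes = plt.subplots(1, 3, figsize=(9, 3))
        for ax, metric in zip(axes, ("MA", "DFT", "output")):
            data = [
                scores.loc[scores.clade_group == g, metric]
                for g in scores.clade_group.unique()
            ]
            ax.boxplot(data, tick_labels=scores.clade_group.unique())
            ax.set_title(metric)
            ax.tick_params(axis="x", labelsize=6, rotation=20)
        fig.tight_layout()
        fig.savefig(box_path)
        plt.close(fig)
        files.append(box_path)
        # thin-plate-spline deformation grid for the positive PC1 extreme
        from .shape_space import tps_warp

        extreme = float(2 * np.sqrt(space.eigenvalues[0]))
        warped_grid, target, _ = tps_warp(
            result.consensus, [extreme], space, n_grid=16
        )
        grid_path = outdir / "tps_warp_grid.csv"
        pd.DataFrame(warped_grid, columns=["x", "y"]).to_csv(
            grid_path, index=False, float_format="%.6g"
        )
        files.append(grid_path)
        warp_fig = outdir / "tps_warp.svg"
        fig, ax = plt.subplots(figsize=(4, 4))
        pts = warped_grid.reshape(16, 16, 2)
        for i in range(16):
            ax.plot(pts[i, :, 0], pts[i, :, 1], color="0.8", lw=0.5)
            ax.plot(pts[:, i, 0], pts[:, i, 1], color="0.8", lw=0.5)
        ax.scatter(*result.consensus.T, s=12, color="0.5", label="consensus")
        ax.scatter(*target.T, s=12, color="k", label="PC1 +2sd")
        ax.set_aspect("equal")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(warp_fig)
        plt.close(fig)
        files.append(warp_fig)

    bundle["manifest"] = _write_manifest(outdir, config, "morpho", files)
    bundle["files"] = files
    return bundle


def run_phylogeny(config: PipelineConfig) -> dict:
    """Run the parsimony pipeline; returns a results bundle."""
    config.validate_paths(["matrix"])
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    bundle: dict = {}

    with _StageTimer("matrix"):
        matrix = read_matrix(
            config.matrix, format=config.matrix_format,
            ordered=config.ordered_characters or None,
            excluded=config.excluded_characters or None,
        )
        logger.info("matrix: %d taxa x %d characters",
                    matrix.ntax, matrix.nchar)

    with _StageTimer("search"):
        search = ParsimonySearch(
            n_replicates=config.replicates, hold=config.hold,
            strategy=config.swap, random_state=config.seed,
        )
        search.fit(matrix)
        best_path = outdir / "best_trees.nwk"
        best_path.write_text(
            "\n".join(t.newick() for t in search.best_trees_) + "\n"
        )
        files.append(best_path)
        scores_rows = [
            {
                "tree": i,
                "length": tree_length(t, matrix).length,
                "CI": tree_length(t, matrix).ci,
                "RI": tree_length(t, matrix).ri,
            }
            for i, t in enumerate(search.best_trees_)
        ]
        scores_path = outdir / "tree_scores.csv"
        pd.DataFrame(scores_rows).to_csv(
            scores_path, index=False, float_format="%.6g"
        )
        files.append(scores_path)
        bundle["search"] = search

    with _StageTimer("consensus"):
        strict = strict_consensus(search.best_trees_)
        major = majority_rule_consensus(search.best_trees_, threshold=0.5)
        strict_path = outdir / "strict_consensus.nwk"
        strict_path.write_text(strict.newick() + "\n")
        major_path = outdir / "majority_consensus.nwk"
        major_path.write_text(major.newick(with_support=True) + "\n")
        files += [strict_path, major_path]
        bundle["strict_consensus"] = strict
        bundle["majority_consensus"] = major

    bundle["manifest"] = _write_manifest(outdir, config, "phylo", files)
    bundle["files"] = files
    return bundle
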