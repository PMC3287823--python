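"""End-to-end orchestration: QC -> grouping -> markers -> trees -> testing.

``run_all`` executes the five stages in order, writing every intermediate
artifact (QC report, group table, marker set, usage counts, significance
calls) under ``outdir`` so that the pipeline equals running the stage
functions one at a time on each other's outputs. A single global seed fans
out to per-stage seeds through ``numpy.random.SeedSequence`` so each stage
is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .grouping import assign_groups, groups_to_frame
from .lasso import PathSpec
from .markers import build_composite_markers
from .preprocess import QcThresholds, filter_variants
from .significance import (
    SignificanceConfig,
    call_significant,
    permutation_null,
)
from .simulate import CohortConfig, generate_cohort, write_cohort_files
from .trees import TreeSpec, run_ensemble

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "trees", "permutation")


@dataclass
class RunConfig:
    """Everything a full run needs; round-trips through YAML."""

    outdir: str = "raremark_out"
    # input paths (ignored when `simulate` is set)
    genotypes: str | None = None
    annotation: str | None = None
    covariates: str | None = None
    phenotypes: str | None = None
    simulate: CohortConfig | None = None
    qc: QcThresholds = field(default_factory=QcThresholds)
    min_gene_size: int = 5
    bin_size: int = 20
    prevalence_min: float = 0.05
    lasso_path: PathSpec = field(default_factory=PathSpec)
    tree: TreeSpec = field(default_factory=TreeSpec)
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)
    construction_replicate: int = 0
    value_mode: str = "weighted"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("simulate", CohortConfig),
            ("qc", QcThresholds),
            ("lasso_path", PathSpec),
            ("tree", TreeSpec),
            ("significance", SignificanceConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from the global seed."""
    states = np.random.SeedSequence(seed).generate_state(len(_STAGES)) % (2**31)
    return dict(zip(_STAGES, (int(s) for s in states)))


@dataclass
class RunResult:
    config: RunConfig
    qc_report: pd.DataFrame
    groups: list
    markers: rio.MarkerSet
    diagnostics: pd.DataFrame
    usage: object
    result: object
    truth: dict | None
    paths: dict[str, Path]


def run_all(config: RunConfig) -> RunResult:
    """Execute the full pipeline; every stage artifact lands in ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    paths: dict[str, Path] = {}
    config.to_yaml(outdir / "effective_config.yaml")
    paths["config"] = outdir / "effective_config.yaml"

    truth = None
    stage = "load"
    try:
        if config.simulate is not None:
            stage = "simulate"
            sim_cfg = dataclasses.replace(config.simulate, seed=seeds["simulate"])
            genotypes, variants, covariates, phenotypes, truth = generate_cohort(sim_cfg)
            data_paths = write_cohort_files(
                outdir / "data", genotypes, variants, covariates, phenotypes
            )
            paths.update({f"data_{k}": v for k, v in data_paths.items()})
            with open(outdir / "truth.json", "w") as fh:
                json.dump(truth, fh, indent=1)
            paths["truth"] = outdir / "truth.json"
        else:
            for k in ("genotypes", "annotation", "covariates", "phenotypes"):
                if getattr(config, k) is None:
                    raise rio.ValidationError(f"config must set {k} or simulate")
            genotypes, variants = rio.load_genotypes(
                config.genotypes, config.annotation
            )
            covariates = rio.load_covariates(config.covariates, genotypes.subject_ids)
            phenotypes = rio.load_phenotypes(config.phenotypes, genotypes.subject_ids)

        if phenotypes.n_replicates < 2:
            raise rio.ValidationError(
                "tree ensemble needs >= 1 evaluation replicate (R >= 2)"
            )
        if not (0 <= config.construction_replicate < phenotypes.n_replicates):
            raise rio.ValidationError("construction_replicate out of range")

        stage = "preprocess"
        genotypes_f, variants_f, qc_report = filter_variants(
            genotypes, variants, config.qc
        )
        qc_report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        paths["qc_report"] = outdir / "qc_report.tsv"

        stage = "group"
        groups = assign_groups(variants_f, config.min_gene_size, config.bin_size)
        groups_to_frame(groups).to_csv(outdir / "groups.tsv", sep="\t", index=False)
        paths["groups"] = outdir / "groups.tsv"
        logger.info("grouping: %d groups over %d variants", len(groups), len(variants_f))

        stage = "build-markers"
        y_build = phenotypes.values[:, config.construction_replicate]
        markers, diagnostics = build_composite_markers(
            groups, genotypes_f, variants_f, covariates, y_build,
            prevalence_min=config.prevalence_min,
            path_spec=config.lasso_path,
            value_mode=config.value_mode,
        )
        rio.write_marker_set(markers, outdir / "markers.tsv")
        diagnostics.to_csv(outdir / "marker_diagnostics.tsv", sep="\t", index=False)
        paths["markers"] = outdir / "markers.tsv"
        paths["marker_diagnostics"] = outdir / "marker_diagnostics.tsv"
        logger.info("markers: M = %d non-rare composite markers", markers.n_markers)

        stage = "trees"
        usage = run_ensemble(
            markers, covariates, phenotypes,
            construction_replicate_index=config.construction_replicate,
            spec=config.tree, seed=seeds["trees"],
        )
        usage.to_frame().to_csv(outdir / "usage.tsv", sep="\t", index=False)
        eval_reps = [
            r for r in range(phenotypes.n_replicates)
            if r != config.construction_replicate
        ]
        pd.DataFrame(
            {"replicate": eval_reps, "s_i": usage.tree_sizes}
        ).to_csv(outdir / "ensemble.tsv", sep="\t", index=False)
        paths["usage"] = outdir / "usage.tsv"
        paths["ensemble"] = outdir / "ensemble.tsv"
        logger.info(
            "trees: %d trees, S = %d splits, mean markers/tree = %.2f",
            len(usage.tree_sizes), usage.S, usage.mean_markers_per_tree,
        )

        stage = "test"
        if config.significance.method == "permutation":
            perm = permutation_null(
                markers, covariates, y_build, spec=config.tree,
                config=dataclasses.replace(
                    config.significance, seed=seeds["permutation"]
                ),
            )
            result = perm
            res_df = pd.DataFrame(
                {
                    "marker_id": perm.marker_ids,
                    "count": perm.observed_counts,
                    "critical_value": perm.critical_value,
                    "significant": perm.significant,
                    "pvalue": perm.pvalues,
                    "method": "permutation",
                }
            )
            summary = {
                "method": "permutation",
                "critical_value": perm.critical_value,
                "alpha": perm.alpha,
                "n_significant": int(perm.significant.sum()),
            }
        else:
            result = call_significant(usage, config.significance)
            res_df = result.to_frame()
            summary = {
                "method": "binomial",
                "S": result.S,
                "M": result.M,
                "alpha": result.alpha,
                "per_marker_level": result.per_marker_level if result.M else None,
                "critical_value": result.critical_value,
                "n_significant": int(result.significant.sum()),
            }
            logger.info(
                "significance: critical value %d, %d/%d markers significant",
                result.critical_value, summary["n_significant"], result.M,
            )
        res_df.to_csv(outdir / "significance.tsv", sep="\t", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        paths["significance"] = outdir / "significance.tsv"
        paths["summary"] = outdir / "summary.json"
    except Exception:
        logger.error(
            "pipeline aborted in stage %r; artifacts so far: %s",
            stage, {k: str(v) for k, v in paths.items()},
        )
        raise

    return RunResult(
        config=config, qc_report=qc_report, groups=groups, markers=markers,
        diagnostics=diagnostics, usage=usage, result=result, truth=truth,
        paths=paths,
    )
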