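"""End-to-end orchestration of the two-stage strategy.

The testing phase trains one network from the training compendium and, for
every test experiment (a group of replicate columns with a condition
label), writes per-replicate rankings, averaged ranks and percentiles for
the listed target/orthogonal genes, and per-gene-set AUC%.  The training
phase appends each modification experiment to the compendium individually,
retrains, re-ranks every test experiment and reports genome-wide rank
changes with RC percentiles for the listed genes.

Every run writes a machine-readable ``manifest.json`` (input paths, seed,
config hash, package version) so reports can be compared across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    average_auc,
    format_rank_percentile,
    format_rc_percentile,
    gene_set_roc,
    rank_percentile,
    rc_percentile,
)
from .io import (
    ExpressionCompendium,
    GeneSet,
    append_experiments,
    read_expression_table,
    read_gene_set,
    write_ranking_table,
)
from .scoring import GeneRanking, average_rankings, compute_residuals, rank_genes
from .training import InteractionNetwork, LassoConfig, fit_network

__all__ = ["ExperimentSpec", "ModificationSpec", "RunConfig", "run_testing_phase", "run_training_phase"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentSpec:
    """One test condition: a table plus the replicate columns belonging to it."""

    label: str
    table: Path
    columns: tuple[str, ...] = ()  # empty -> all columns of the table


@dataclass(frozen=True)
class ModificationSpec:
    """One training-compendium modification: an experiment file to append."""

    label: str
    table: Path


@dataclass
class RunConfig:
    training_compendium: Path
    output_dir: Path
    seed: int = 0
    lasso: LassoConfig = field(default_factory=LassoConfig)
    experiments: list[ExperimentSpec] = field(default_factory=list)
    gene_sets: list[Path] = field(default_factory=list)
    target_genes: list[str] = field(default_factory=list)
    orthogonal_genes: list[str] = field(default_factory=list)
    modifications: list[ModificationSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.training_compendium = Path(self.training_compendium)
        self.output_dir = Path(self.output_dir)
        if not self.training_compendium.exists():
            raise FileNotFoundError(self.training_compendium)
        for exp in self.experiments:
            if not Path(exp.table).exists():
                raise FileNotFoundError(exp.table)
        for mod in self.modifications:
            if not Path(mod.table).exists():
                raise FileNotFoundError(mod.table)
        for gs in self.gene_sets:
            if not Path(gs).exists():
                raise FileNotFoundError(gs)
        if not self.experiments:
            raise ValueError("at least one test experiment is required")
        if not (self.gene_sets or self.target_genes):
            raise ValueError("provide gene sets and/or target genes to evaluate")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent

        def resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        lasso_raw = raw.get("lasso", {})
        lasso = LassoConfig(
            penalty_mode=lasso_raw.get("penalty_mode", "cv"),
            cv_folds=lasso_raw.get("cv_folds", 5),
            fixed_lambda=lasso_raw.get("fixed_lambda"),
            max_iter=lasso_raw.get("max_iter", 50_000),
            tol=lasso_raw.get("tol", 1e-6),
            seed=lasso_raw.get("seed", raw.get("seed", 0)),
        )
        experiments = [
            ExperimentSpec(
                label=e["label"],
                table=resolve(e["table"]),
                columns=tuple(e.get("columns", ())),
            )
            for e in raw.get("experiments", [])
        ]
        modifications = [
            ModificationSpec(label=m["label"], table=resolve(m["table"]))
            for m in raw.get("modifications", [])
        ]
        return cls(
            training_compendium=resolve(raw["training_compendium"]),
            output_dir=resolve(raw.get("output_dir", "ssemlasso_out")),
            seed=raw.get("seed", 0),
            lasso=lasso,
            experiments=experiments,
            gene_sets=[resolve(p) for p in raw.get("gene_sets", [])],
            target_genes=list(raw.get("target_genes", [])),
            orthogonal_genes=list(raw.get("orthogonal_genes", [])),
            modifications=modifications,
        )

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "training_compendium": str(self.training_compendium),
                "seed": self.seed,
                "lasso": repr(self.lasso),
                "experiments": [(e.label, str(e.table), e.columns) for e in self.experiments],
                "gene_sets": [str(p) for p in self.gene_sets],
                "target_genes": self.target_genes,
                "orthogonal_genes": self.orthogonal_genes,
                "modifications": [(m.label, str(m.table)) for m in self.modifications],
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(config: RunConfig, out_dir: Path, phase: str) -> None:
    manifest = {
        "phase": phase,
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "training_compendium": str(config.training_compendium),
        "experiments": [
            {"label": e.label, "table": str(e.table), "columns": list(e.columns)}
            for e in config.experiments
        ],
        "gene_sets": [str(p) for p in config.gene_sets],
        "modifications": [
            {"label": m.label, "table": str(m.table)} for m in config.modifications
        ],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _experiment_rankings(
    net: InteractionNetwork, exp: ExperimentSpec
) -> tuple[list[str], list[GeneRanking], pd.DataFrame]:
    table = read_expression_table(exp.table)
    columns = list(exp.columns) if exp.columns else table.samples
    missing = [c for c in columns if c not in table.samples]
    if missing:
        raise ValueError(f"experiment {exp.label!r}: unknown columns {missing}")
    rankings = [rank_genes(compute_residuals(net, table.column(c))) for c in columns]
    averaged = average_rankings(rankings)
    return columns, rankings, averaged


def run_testing_phase(config: RunConfig, network: InteractionNetwork | None = None):
    """Testing-phase series: per-condition gene ranks/percentiles and gene-set AUC%.

    Returns ``(gene_table, auc_table, networks_dict)`` and writes all
    artifacts under ``config.output_dir / 'testing'``.
    """
    out_dir = config.output_dir / "testing"
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    train = read_expression_table(config.training_compendium)
    if network is None:
        logger.info("training network on %d genes x %d samples", train.p, train.n)
        network = fit_network(train, config.lasso)
    gene_sets = [read_gene_set(p) for p in config.gene_sets]
    watched = list(dict.fromkeys(config.target_genes + config.orthogonal_genes))
    gene_rows = []
    auc_rows = []
    p = network.p
    for exp in config.experiments:
        stage_t = time.perf_counter()
        try:
            columns, rankings, averaged = _experiment_rankings(network, exp)
        except Exception as exc:
            raise RuntimeError(f"testing phase failed at experiment {exp.label!r}: {exc}") from exc
        for col, ranking in zip(columns, rankings):
            write_ranking_table(ranking, out_dir / f"ranks_{exp.label}_{col}.tsv")
        averaged.to_csv(out_dir / f"ranks_{exp.label}_averaged.tsv", sep="\t")
        for gene in watched:
            if gene not in averaged.index:
                raise RuntimeError(f"gene {gene!r} absent from the compendium universe")
            mean_rank = float(averaged.loc[gene, "mean_rank"])
            display_rank = int(averaged.loc[gene, "display_rank"])
            gene_rows.append(
                {
                    "condition": exp.label,
                    "gene": gene,
                    "role": "target" if gene in config.target_genes else "orthogonal",
                    "mean_rank": mean_rank,
                    "display_rank": display_rank,
                    "percentile": rank_percentile(mean_rank, p),
                    "display_percentile": format_rank_percentile(display_rank, p),
                }
            )
        for gs in gene_sets:
            curves = [gene_set_roc(r, gs) for r in rankings]
            for col, curve in zip(columns, curves):
                auc_rows.append(
                    {
                        "condition": exp.label,
                        "gene_set": gs.name,
                        "replicate": col,
                        "auc_percent": curve.auc_percent,
                    }
                )
            auc_rows.append(
                {
                    "condition": exp.label,
                    "gene_set": gs.name,
                    "replicate": "mean",
                    "auc_percent": average_auc(curves),
                }
            )
        logger.info("condition %s done in %.2fs", exp.label, time.perf_counter() - stage_t)
    gene_table = pd.DataFrame(gene_rows)
    auc_table = pd.DataFrame(auc_rows)
    if not gene_table.empty:
        gene_table.to_csv(out_dir / "gene_ranks.tsv", sep="\t", index=False)
    if not auc_table.empty:
        auc_table.to_csv(out_dir / "gene_set_auc.tsv", sep="\t", index=False)
    _write_manifest(config, out_dir, "testing")
    logger.info("testing phase finished in %.2fs", time.perf_counter() - t0)
    return gene_table, auc_table, network


def run_training_phase(config: RunConfig, network: InteractionNetwork | None = None):
    """Training-phase series: per-modification rank-change reports.

    For each modification the experiment file is appended to the original
    compendium, the network is retrained, every test experiment re-ranked,
    and the genome-wide RC vector (original averaged rank minus modified
    averaged rank) computed.  Failures of one modification are recorded and
    do not abort the rest.  Returns ``(reports, errors)`` where ``reports``
    maps (modification label, condition label) to a per-gene RC frame.
    """
    if not config.modifications:
        raise ValueError("training phase requires a non-empty modification list")
    out_dir = config.output_dir / "training"
    out_dir.mkdir(parents=True, exist_ok=True)
    train = read_expression_table(config.training_compendium)
    if network is None:
        network = fit_network(train, config.lasso)
    watched = list(dict.fromkeys(config.target_genes + config.orthogonal_genes))
    original: dict[str, pd.DataFrame] = {}
    for exp in config.experiments:
        _, _, averaged = _experiment_rankings(network, exp)
        original[exp.label] = averaged
    reports: dict[tuple[str, str], pd.DataFrame] = {}
    errors: dict[str, str] = {}
    for mod in config.modifications:
        try:
            extra = read_expression_table(mod.table)
            modified = append_experiments(train, extra)
            logger.info("retraining with modification %s (+%d samples)", mod.label, extra.n)
            mod_network = fit_network(modified, config.lasso)
            for exp in config.experiments:
                _, _, averaged_mod = _experiment_rankings(mod_network, exp)
                orig = original[exp.label]
                rc_vector = (
                    orig["mean_rank"] - averaged_mod["mean_rank"]
                ).to_numpy(dtype=float)
                genes_out = watched if watched else list(orig.index)
                rows = []
                for gene in genes_out:
                    r_orig = float(orig.loc[gene, "mean_rank"])
                    r_mod = float(averaged_mod.loc[gene, "mean_rank"])
                    rc = r_orig - r_mod
                    pct = rc_percentile(rc, rc_vector)
                    rows.append(
                        {
                            "modification": mod.label,
                            "condition": exp.label,
                            "gene": gene,
                            "rank_original": r_orig,
                            "rank_modified": r_mod,
                            "rc": rc,
                            "rc_percentile": pct if pct is not None else np.nan,
                            "rc_percentile_display": format_rc_percentile(pct),
                        }
                    )
                report = pd.DataFrame(rows)
                report.to_csv(out_dir / f"rc_{mod.label}_{exp.label}.tsv", sep="\t", index=False)
                reports[(mod.label, exp.label)] = report
        except Exception as exc:  # keep going; report per-modification failures
            logger.error("modification %s failed: %s", mod.label, exc)
            errors[mod.label] = str(exc)
    _write_manifest(config, out_dir, "training")
    return reports, errors
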