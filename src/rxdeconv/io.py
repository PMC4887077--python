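"""Readers, writers, run configuration and the end-to-end pipeline.

Matrix files are tab-delimited with a header row of sample ids and a first
column of gene ids; clinical tables are comma-separated with the documented
header.  ``run_pipeline`` chains normalize -> discretize -> fit -> extract ->
delta -> rank, with optional sensitivity, cell-type and clinical stages, and
writes a run manifest sufficient to reproduce the run bit-identically.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, ParseError
from .delta_analysis import compute_delta, rank_genes, ttest_per_gene, compare_rankings
from .downstream_stats import (
    CellTypePanel,
    ClinicalTable,
    CLINICAL_INDICATORS,
    celltype_correlation,
    clinical_correlation_table,
    sensitivity_test,
)
from .inference import FitConfig, extract_treatment_response, dominant_reference, fit_map
from .model_core import discretize_counts, normalize_reference

logger = logging.getLogger("rxdeconv")

_FLOAT_FMT = "%.17g"  # full double precision so outputs are byte-reproducible


def read_matrix(path) -> pd.DataFrame:
    """Read a tab-delimited gene x sample matrix, preserving file order.

    Raises :class:`ParseError` naming the offending line for duplicate gene
    ids, ragged rows, or non-numeric cells.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        gene_ids, rows, seen = [], [], {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise ParseError(
                    f"{path.name}: line {lineno} has {len(parts)} fields, expected {n_cols}"
                )
            gid = parts[0]
            if gid in seen:
                raise ParseError(
                    f"{path.name}: duplicate gene id {gid!r} at line {lineno} "
                    f"(first seen at line {seen[gid]})"
                )
            seen[gid] = lineno
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path.name}: non-numeric cell at line {lineno}: {exc}") from exc
            gene_ids.append(gid)
    if not gene_ids:
        raise ParseError(f"{path.name}: no data rows")
    return pd.DataFrame(rows, index=gene_ids, columns=header[1:], dtype=float)


def write_matrix(df: pd.DataFrame, path, id_label: str = "gene_id") -> None:
    df = df.copy()
    df.index.name = id_label
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_clinical(path) -> ClinicalTable:
    """Read the comma-separated clinical table."""
    return ClinicalTable(pd.read_csv(path))


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_celltype_panel(path) -> CellTypePanel:
    return CellTypePanel(read_matrix(path))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunConfig:
    """Declarative configuration of a pipeline run."""

    reference: str = None
    post: str = None
    out: str = "rxdeconv_out"
    clinical: str = None
    celltype_panel: str = None
    seed: int = 0
    restarts: int = 10
    max_iter: int = 35
    rel_tol: float = 1e-7
    total_counts: int = 1_000_000
    top_k: int = 20
    n_subsets: int = 0            # 0 disables the sensitivity stage
    bonferroni_m: int = 4
    epsilon: float = 1e-12
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load from a YAML mapping; keyword overrides take precedence."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def fit_config(self) -> FitConfig:
        return FitConfig(
            max_outer_iterations=self.max_iter,
            rel_tol=self.rel_tol,
            n_restarts=self.restarts,
            seed=self.seed,
        )


def _validate(config: RunConfig, want_clinical: bool, want_celltype: bool) -> None:
    if config.reference is None or config.post is None:
        raise ConfigError("both --reference and --post inputs are required")
    for label, p in (("reference", config.reference), ("post", config.post)):
        if not Path(p).exists():
            raise ConfigError(f"{label} matrix not found: {p}")
    if want_clinical:
        if config.clinical is None:
            raise ConfigError("clinical stage requested but no clinical table given")
        if not Path(config.clinical).exists():
            raise ConfigError(f"clinical table not found: {config.clinical}")
    if want_celltype:
        if config.celltype_panel is None:
            raise ConfigError("cell-type stage requested but no panel given")
        if not Path(config.celltype_panel).exists():
            raise ConfigError(f"cell-type panel not found: {config.celltype_panel}")


def run_pipeline(
    config: RunConfig,
    run_sensitivity: bool = None,
    run_celltype: bool = None,
    run_clinical: bool = None,
) -> Path:
    """Execute the full analysis; returns the output directory.

    Optional stages default to "run if their input/setting is present".
    All declared outputs plus a manifest are written under ``config.out``.
    """
    t_start = time.time()
    if run_sensitivity is None:
        run_sensitivity = config.n_subsets > 0
    if run_celltype is None:
        run_celltype = config.celltype_panel is not None
    if run_clinical is None:
        run_clinical = config.clinical is not None
    _validate(config, run_clinical, run_celltype)

    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "software": f"rxdeconv {__version__}",
        "seed": config.seed,
        "stage_seconds": {},
        "inputs": {},
        "outputs": [],
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
    }

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.time()

            def __exit__(self, *exc):
                manifest["stage_seconds"][name] = round(time.time() - self.t0, 3)
                if exc[0] is not None:
                    logger.error("stage %r failed", name)

        return _T()

    def declare(path: Path):
        manifest["outputs"].append(path.name)
        return path

    with stage("read"):
        ref_raw = read_matrix(config.reference)
        post_raw = read_matrix(config.post)
        manifest["inputs"][config.reference] = _sha256(config.reference)
        manifest["inputs"][config.post] = _sha256(config.post)

    with stage("normalize"):
        panel = normalize_reference(ref_raw)
        counts = discretize_counts(post_raw, target_total=config.total_counts)

    with stage("fit"):
        result = fit_map(panel, counts, config.fit_config())
        logger.info("restart likelihoods: %s", result.per_restart_logliks)
        logger.info(
            "converged=%s after %d outer iterations",
            result.converged,
            result.iterations_used,
        )
    state = result.best_state

    with stage("write_fit"):
        theta_df = pd.DataFrame(
            state.theta.values,
            index=counts.sample_ids,
            columns=list(panel.sample_ids) + ["treatment_response"],
        )
        write_matrix(theta_df, declare(out / "theta.tsv"), id_label="sample_id")
        state.response.to_series().rename_axis("gene_id").to_csv(
            declare(out / "response.tsv"), sep="\t", float_format=_FLOAT_FMT
        )
        trace = pd.DataFrame(
            {"iteration": range(len(state.loglik_trace)), "loglik": state.loglik_trace}
        )
        trace.to_csv(
            declare(out / "loglik_trace.tsv"),
            sep="\t",
            index=False,
            float_format=_FLOAT_FMT,
        )
        responses = extract_treatment_response(result)
        responses.rename_axis("sample_id").to_csv(
            declare(out / "pct_treatment_response.tsv"), sep="\t", float_format=_FLOAT_FMT
        )
        dominant_reference(result).rename_axis("sample_id").to_csv(
            declare(out / "dominant_reference.tsv"), sep="\t"
        )
        hyper_lines = [
            "kappa\t" + (_FLOAT_FMT % state.hyper.kappa),
            "v\t" + "\t".join(_FLOAT_FMT % x for x in state.hyper.v),
            "omega\t" + "\t".join(_FLOAT_FMT % x for x in state.hyper.omega),
        ]
        declare(out / "hyperparams.tsv").write_text("\n".join(hyper_lines) + "\n")

    with stage("delta"):
        delta = compute_delta(state.response, state.hyper, panel, epsilon=config.epsilon)
        ranked = rank_genes(delta, k=min(config.top_k, panel.n_genes))
        delta.to_series().rename_axis("gene_id").to_csv(
            declare(out / "delta.tsv"), sep="\t", float_format=_FLOAT_FMT
        )
        pd.concat([ranked.up, ranked.down]).to_csv(
            declare(out / "ranked_genes.tsv"),
            sep="\t",
            index=False,
            float_format=_FLOAT_FMT,
        )
        declare(out / "top_genes.txt").write_text(
            "\n".join(ranked.top_abs(min(config.top_k, panel.n_genes))) + "\n"
        )
        ttest = ttest_per_gene(panel.to_frame(), counts.to_frame())
        ttest.to_csv(
            declare(out / "ttest.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT
        )
        k = min(config.top_k, panel.n_genes)
        overlap = compare_rankings(
            ranked.top_abs(k), list(ttest["gene_id"].iloc[:k]), k
        )
        manifest["delta_vs_ttest_overlap"] = {"k": k, "overlap": overlap}

    if run_sensitivity:
        with stage("sensitivity"):
            sens = sensitivity_test(
                panel, counts, config.fit_config(), n_subsets=config.n_subsets
            )
            table = sens.subset_estimates.copy()
            table.insert(0, "full", sens.full_estimates)
            table["standard_error"] = sens.standard_errors
            table.rename_axis("sample_id").to_csv(
                declare(out / "sensitivity.tsv"), sep="\t", float_format=_FLOAT_FMT
            )
            manifest["sensitivity"] = {
                "average_se": sens.average_se,
                "max_se": sens.max_se,
                "failures": sens.failures,
            }

    if run_celltype:
        with stage("celltype"):
            ct_panel = read_celltype_panel(config.celltype_panel)
            manifest["inputs"][config.celltype_panel] = _sha256(config.celltype_panel)
            ct = celltype_correlation(delta, ct_panel)
            ct.to_csv(
                declare(out / "celltype_correlation.tsv"),
                sep="\t",
                float_format=_FLOAT_FMT,
            )

    if run_clinical:
        with stage("clinical"):
            clin = read_clinical(config.clinical)
            manifest["inputs"][config.clinical] = _sha256(config.clinical)
            table = clinical_correlation_table(
                responses, clin, n_tests=config.bonferroni_m
            )
            table.to_csv(
                declare(out / "clinical_correlation.tsv"),
                sep="\t",
                index=False,
                float_format=_FLOAT_FMT,
            )

    manifest["stage_seconds"]["total"] = round(time.time() - t_start, 3)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    for name in manifest["outputs"]:
        p = out / name
        if not p.exists() or p.stat().st_size == 0:
            raise ConfigError(f"declared output {name} missing or empty")
    return out
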