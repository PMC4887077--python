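"""Clinical correlation, gene-subset sensitivity test, and cell-type analysis.

Ties the fitted per-patient % treatment response back to clinical disease
activity (percent reductions in the four juvenile-arthritis core-set
indicators, Bonferroni-corrected over the indicator family), probes the
stability of the estimates by refitting on disjoint gene subsets, and
interprets the delta profile against a panel of blood cell-type expression
profiles via Spearman correlation after per-gene centering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientOverlapError,
    InvalidInputError,
    UndefinedCorrelationError,
)
from .delta_analysis import DeltaProfile
from .inference import FitConfig, FitResult, extract_treatment_response, fit_map
from .model_core import CountMatrix, ReferencePanel, normalize_reference

logger = logging.getLogger("rxdeconv")

#: Indicator column stems expected in a clinical table.
CLINICAL_INDICATORS = ("pga", "esr", "active", "lrm")

CLINICAL_COLUMNS = ("patient_id",) + tuple(
    f"{ind}_{t}" for ind in CLINICAL_INDICATORS for t in (0, 6)
)


@dataclass(frozen=True)
class ClinicalTable:
    """Per-patient disease-activity indicators at baseline (0) and 6 months.

    Columns: patient_id, pga_0, pga_6, esr_0, esr_6, active_0, active_6,
    lrm_0, lrm_6.  Joint counts (active, lrm) must be non-negative integers.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidInputError(f"clinical table missing columns {missing}")
        if df["patient_id"].duplicated().any():
            raise InvalidInputError("clinical table has duplicate patient ids")
        for col in ("active_0", "active_6", "lrm_0", "lrm_6"):
            vals = df[col].to_numpy(dtype=float)
            if np.any(vals < 0):
                raise InvalidInputError(f"clinical column {col} has negative counts")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    def reductions(self, indicator: str) -> pd.Series:
        """Percent reduction baseline -> 6 months, NaN where baseline is 0."""
        if indicator not in CLINICAL_INDICATORS:
            raise InvalidInputError(f"unknown indicator {indicator!r}")
        base = self.data[f"{indicator}_0"].to_numpy(dtype=float)
        follow = self.data[f"{indicator}_6"].to_numpy(dtype=float)
        out = np.full(base.shape, np.nan)
        ok = base > 0
        out[ok] = 100.0 * (base[ok] - follow[ok]) / base[ok]
        n_excluded = int((~ok).sum())
        if n_excluded:
            logger.info(
                "indicator %s: %d patient(s) excluded for zero baseline",
                indicator,
                n_excluded,
            )
        return pd.Series(out, index=self.data["patient_id"], name=f"{indicator}_pct_reduction")


@dataclass(frozen=True)
class CellTypePanel:
    """Gene x cell-type expression matrix with unique cell-type labels."""

    data: pd.DataFrame  # index = gene ids, columns = cell-type labels

    def __post_init__(self):
        if self.data.columns.duplicated().any():
            raise InvalidInputError("cell-type labels must be unique")
        if self.data.index.duplicated().any():
            raise InvalidInputError("cell-type panel gene ids must be unique")


@dataclass(frozen=True)
class SensitivityResult:
    """Full-data estimates, per-subset estimates, and per-patient standard errors."""

    full_estimates: pd.Series
    subset_estimates: pd.DataFrame  # patients x subsets
    standard_errors: pd.Series
    average_se: float
    max_se: float
    failures: list = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.standard_errors.to_numpy() < 0):
            raise InvalidInputError("standard errors must be non-negative")
        if self.average_se > self.max_se + 1e-12:
            raise InvalidInputError("average SE cannot exceed the maximum SE")


def pct_reduction(baseline: float, followup: float) -> float:
    """100*(baseline - followup)/baseline; NaN (undefined) when baseline is 0.

    Negative values mean the indicator worsened.
    """
    if baseline < 0 or followup < 0:
        raise InvalidInputError("indicator values must be non-negative")
    if baseline == 0:
        logger.info("pct_reduction undefined for zero baseline")
        return float("nan")
    return 100.0 * (baseline - followup) / baseline


def correlate_outcome(responses, reductions, method: str = "spearman"):
    """Correlation between % treatment response and a clinical % reduction.

    Pairs with a NaN on either side are dropped listwise.  Returns
    ``(rho, raw two-sided p-value, n)``.
    """
    if method not in ("spearman", "pearson"):
        raise InvalidInputError(f"unknown method {method!r}")
    x = pd.Series(responses)
    y = pd.Series(reductions)
    if isinstance(responses, pd.Series) and isinstance(reductions, pd.Series):
        x, y = x.align(y, join="inner")
    elif len(x) != len(y):
        raise InvalidInputError("responses and reductions must have equal length")
    mask = np.isfinite(x.to_numpy(dtype=float)) & np.isfinite(y.to_numpy(dtype=float))
    xv = x.to_numpy(dtype=float)[mask]
    yv = y.to_numpy(dtype=float)[mask]
    n = int(mask.sum())
    if n < 3:
        raise InvalidInputError(f"need >= 3 paired finite observations, have {n}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise UndefinedCorrelationError("correlation against a constant vector")
    if method == "spearman":
        rho, p = stats.spearmanr(xv, yv)
    else:
        rho, p = stats.pearsonr(xv, yv)
    return float(rho), float(p), n


def bonferroni(raw_p: float, n_tests: int) -> float:
    """min(1, raw_p * n_tests)."""
    if not 0.0 <= raw_p <= 1.0:
        raise InvalidInputError(f"raw p-value {raw_p!r} outside [0, 1]")
    if n_tests < 1:
        raise InvalidInputError("n_tests must be a positive integer")
    return min(1.0, raw_p * n_tests)


def clinical_correlation_table(
    responses: pd.Series, clinical: ClinicalTable, n_tests: int = 4
) -> pd.DataFrame:
    """Spearman and Pearson correlations of % treatment response against the
    percent reduction of each clinical indicator, Bonferroni-corrected.

    The correction family defaults to the four indicators tested per method.
    """
    rows = []
    for ind in CLINICAL_INDICATORS:
        red = clinical.reductions(ind)
        row = {"indicator": ind}
        for method in ("spearman", "pearson"):
            rho, p, n = correlate_outcome(responses, red, method=method)
            row[f"{method}_rho"] = rho
            row[f"{method}_p_bonf"] = bonferroni(p, n_tests)
            row["n"] = n
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["indicator", "spearman_rho", "spearman_p_bonf", "pearson_rho", "pearson_p_bonf", "n"],
    )


def partition_genes(
    G: int, n_subsets: int, scheme: str = "round_robin", seed: int | None = None
) -> list:
    """Disjoint gene-index subsets: deterministic round-robin or a seeded shuffle."""
    idx = np.arange(G)
    if scheme == "random":
        idx = np.random.default_rng(seed).permutation(G)
    elif scheme != "round_robin":
        raise InvalidInputError(f"unknown partition scheme {scheme!r}")
    return [np.sort(idx[j::n_subsets]) for j in range(n_subsets)]


def sensitivity_test(
    panel: ReferencePanel,
    counts: CountMatrix,
    config: FitConfig,
    n_subsets: int = 4,
    scheme: str = "round_robin",
) -> SensitivityResult:
    """Refit on disjoint gene subsets and summarize per-patient variability.

    Each subset's reference columns are renormalized to sum to one before
    fitting.  The per-patient standard error is the sample standard deviation
    of the subset estimates divided by sqrt(n_subsets), i.e. the standard
    error of the mean of the subset estimates.
    """
    G = panel.n_genes
    if G < n_subsets * 10:
        raise InvalidInputError(
            f"need G >= {n_subsets * 10} genes for {n_subsets} subsets, have {G}"
        )
    full = fit_map(panel, counts, config)
    full_est = extract_treatment_response(full)

    subsets = partition_genes(G, n_subsets, scheme=scheme, seed=config.seed)
    est_cols = {}
    failures = []
    for j, idx in enumerate(subsets):
        sub_genes = [panel.gene_ids[i] for i in idx]
        sub_panel = normalize_reference(
            pd.DataFrame(panel.values[idx], index=sub_genes, columns=panel.sample_ids)
        )
        sub_counts = CountMatrix(
            values=counts.values[idx], gene_ids=sub_genes, sample_ids=counts.sample_ids
        )
        try:
            res = fit_map(sub_panel, sub_counts, config)
        except Exception as exc:  # noqa: BLE001 - partial results are the contract
            logger.warning("sensitivity subset %d failed: %s", j, exc)
            failures.append((j, repr(exc)))
            continue
        est_cols[f"subset_{j}"] = extract_treatment_response(res)
    subset_df = pd.DataFrame(est_cols)
    if subset_df.shape[1] >= 2:
        se = subset_df.std(axis=1, ddof=1) / np.sqrt(n_subsets)
    else:
        se = pd.Series(np.nan, index=full_est.index)
    se.name = "standard_error"
    return SensitivityResult(
        full_estimates=full_est,
        subset_estimates=subset_df,
        standard_errors=se,
        average_se=float(np.nanmean(se.to_numpy())),
        max_se=float(np.nanmax(se.to_numpy())),
        failures=failures,
    )


def celltype_correlation(delta: DeltaProfile, panel: CellTypePanel) -> pd.DataFrame:
    """Spearman correlation of the delta profile against each cell type.

    Genes are matched by identifier; each matched panel row (probe) is first
    centered by its mean across the panel's cell-type columns, then each
    centered column is rank-correlated with delta.  Requires >= 100 shared
    genes.  Returns a DataFrame indexed by cell-type label with columns
    ``rho`` and ``pvalue``.
    """
    dseries = delta.to_series()
    shared = [g for g in dseries.index if g in panel.data.index]
    if len(shared) < 100:
        raise InsufficientOverlapError(
            f"only {len(shared)} genes shared with the cell-type panel (need >= 100)"
        )
    sub = panel.data.loc[shared].to_numpy(dtype=float)
    centered = sub - sub.mean(axis=1, keepdims=True)
    dvals = dseries.loc[shared].to_numpy(dtype=float)
    rows = []
    for j, label in enumerate(panel.data.columns):
        rho, p = stats.spearmanr(dvals, centered[:, j])
        rows.append({"cell_type": label, "rho": float(rho), "pvalue": float(p)})
    return pd.DataFrame(rows).set_index("cell_type")
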