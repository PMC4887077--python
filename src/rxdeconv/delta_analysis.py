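"""Delta profile, gene ranking, and the per-gene t-test comparator.

The delta profile is the per-gene log2 difference between the fitted
treatment-response profile r and the fitted convex blend of pre-treatment
references omega.B:  delta_g = log2(r_g) - log2((omega.B)_g).  Genes at its
extremes are the candidate treatment-affected genes; the per-gene two-sample
t-test on the raw profiles serves as the conventional baseline to compare
against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, InvalidInputError
from .model_core import HyperParams, ReferencePanel, ResponseProfile, floored_blend

logger = logging.getLogger("rxdeconv")


@dataclass(frozen=True)
class DeltaProfile:
    """Per-gene log2 fold change between response profile and reference blend."""

    values: np.ndarray
    gene_ids: list

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size != len(list(self.gene_ids)):
            raise InvalidInputError("DeltaProfile values/gene_ids mismatch")
        if not np.all(np.isfinite(vals)):
            raise InvalidInputError("DeltaProfile contains non-finite values")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "gene_ids", list(self.gene_ids))

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.gene_ids, name="log2_delta")


@dataclass(frozen=True)
class RankedGeneTable:
    """Up- and down-regulated views of a delta profile, ranked 1..k."""

    up: pd.DataFrame    # descending delta
    down: pd.DataFrame  # ascending delta

    def top(self, k: int, direction: str) -> list:
        view = {"up": self.up, "down": self.down}[direction]
        return list(view["gene_id"].iloc[:k])

    def top_abs(self, k: int) -> list:
        """Top-k genes by absolute delta, ties by gene id."""
        combined = pd.concat([self.up, self.down]).drop_duplicates("gene_id")
        combined = combined.assign(absdelta=combined["log2_delta"].abs())
        combined = combined.sort_values(
            ["absdelta", "gene_id"], ascending=[False, True], kind="stable"
        )
        return list(combined["gene_id"].iloc[:k])


def compute_delta(
    response: ResponseProfile,
    hyper: HyperParams,
    panel: ReferencePanel,
    epsilon: float = 1e-12,
) -> DeltaProfile:
    """delta_g = log2(max(r_g, eps)) - log2(max((omega.B)_g, eps))."""
    if list(response.gene_ids) != list(panel.gene_ids):
        raise AlignmentError("response and panel gene identifiers differ")
    if not epsilon > 0:
        raise InvalidInputError("epsilon must be positive")
    blend = floored_blend(panel.values, hyper.omega, floor=0.0)
    r = response.values
    hits = int((r < epsilon).sum() + (blend < epsilon).sum())
    if hits:
        logger.info("compute_delta: epsilon floor applied to %d entries", hits)
    delta = np.log2(np.maximum(r, epsilon)) - np.log2(np.maximum(blend, epsilon))
    return DeltaProfile(values=delta, gene_ids=list(panel.gene_ids))


def rank_genes(delta: DeltaProfile, k: int) -> RankedGeneTable:
    """Top-k genes in each direction; ties break by lexicographic gene id."""
    G = delta.values.size
    if not 1 <= k <= G:
        raise InvalidInputError(f"k must be in [1, {G}], got {k}")
    df = pd.DataFrame({"gene_id": delta.gene_ids, "log2_delta": delta.values})
    up = df.sort_values(
        ["log2_delta", "gene_id"], ascending=[False, True], kind="stable"
    ).head(k)
    down = df.sort_values(
        ["log2_delta", "gene_id"], ascending=[True, True], kind="stable"
    ).head(k)
    up = up.assign(rank=np.arange(1, len(up) + 1), direction="up").reset_index(drop=True)
    down = down.assign(rank=np.arange(1, len(down) + 1), direction="down").reset_index(
        drop=True
    )
    return RankedGeneTable(up=up, down=down)


def ttest_per_gene(
    pre_matrix: pd.DataFrame, post_matrix: pd.DataFrame, paired: bool = False
) -> pd.DataFrame:
    """Per-gene two-sample t-test on raw expression profiles.

    The default is the unequal-variance (Welch) two-sided test of post vs pre;
    ``paired=True`` runs a paired test instead (requires equal sample counts).
    Genes where the statistic is undefined (both groups constant and equal)
    are flagged and ranked last.

    Returns a DataFrame with columns gene_id, statistic, pvalue, undefined,
    rank — sorted by ascending p-value.
    """
    if list(pre_matrix.index) != list(post_matrix.index):
        raise AlignmentError("pre and post matrices have different gene identifiers")
    pre = pre_matrix.to_numpy(dtype=float)
    post = post_matrix.to_numpy(dtype=float)
    if pre.shape[1] < 2 or post.shape[1] < 2:
        raise InvalidInputError("each group needs at least two samples")
    if paired:
        if pre.shape[1] != post.shape[1]:
            raise InvalidInputError("paired test requires equal group sizes")
        res = stats.ttest_rel(post, pre, axis=1)
    else:
        res = stats.ttest_ind(post, pre, axis=1, equal_var=False)
    stat = np.asarray(res.statistic, dtype=float)
    pval = np.asarray(res.pvalue, dtype=float)
    undefined = ~np.isfinite(stat)
    if undefined.any():
        logger.info("ttest_per_gene: %d genes with undefined statistic", undefined.sum())
    df = pd.DataFrame(
        {
            "gene_id": list(pre_matrix.index),
            "statistic": stat,
            "pvalue": pval,
            "undefined": undefined,
        }
    )
    df = df.sort_values(
        ["undefined", "pvalue", "gene_id"], ascending=[True, True, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def compare_rankings(genes_a, genes_b, k: int) -> int:
    """Size of the intersection of the two top-k gene sets.

    Accepts ordered gene-id sequences; a :class:`RankedGeneTable` is reduced
    to its top-k by absolute delta.
    """
    if isinstance(genes_a, RankedGeneTable):
        genes_a = genes_a.top_abs(k)
    if isinstance(genes_b, RankedGeneTable):
        genes_b = genes_b.top_abs(k)
    return len(set(list(genes_a)[:k]) & set(list(genes_b)[:k]))
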