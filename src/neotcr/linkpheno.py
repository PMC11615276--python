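"""Linking clonotypes to transcriptome phenotypes.

Joins the V(D)J clonotype assignment of each barcode to its transcriptome
cluster and scores, computes per-clonotype (or per-known-TCR) cluster
composition with a minimum-cell threshold, and runs two-group differential
expression with a Wilcoxon rank-sum test and Bonferroni correction.

The Wilcoxon p-value is exact (full null distribution of the rank sum by
dynamic programming) for small tie-free comparisons and a tie- and
continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .gex import LOGNORM_LAYER, _dense

EXACT_MAX_N = 12  # exact rank-sum distribution up to this total sample size


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _exact_ranksum_pvalue(w: float, n_a: int, n_b: int) -> float:
    """Two-sided exact p for rank-sum ``w`` of group A, no ties.

    Builds the exact null distribution of the sum of ``n_a`` ranks chosen
    from 1..n_a+n_b by dynamic programming, and returns
    2 * min(P(W <= w), P(W >= w)), capped at 1 (the distribution is
    symmetric, so this equals the usual extreme-arrangement count).
    """
    n = n_a + n_b
    max_w = n_a * n + 1  # sums range 0..n_a*n (offset storage)
    # counts[k][s] = number of ways to pick k of the first r ranks with sum s
    counts = np.zeros((n_a + 1, max_w), dtype=float)
    counts[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n_a), 0, -1):
            counts[k, r:] += counts[k - 1, :-r]
    dist = counts[n_a]
    total = dist.sum()
    w_int = int(round(w))
    p_le = dist[: w_int + 1].sum() / total
    p_ge = dist[w_int:].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact when the pooled sample size is at most :data:`EXACT_MAX_N` and
    there are no ties; otherwise normal approximation with tie correction
    and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_a, n_b = len(x), len(y)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = ranks[:n_a].sum()
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    n = n_a + n_b
    if n <= EXACT_MAX_N and not has_ties:
        return _exact_ranksum_pvalue(w, n_a, n_b)
    mu = n_a * (n + 1) / 2.0
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0  # all values identical
    diff = w - mu
    # continuity correction toward the mean
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(sigma2)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """p_adj = min(1, p * m); ``m`` defaults to the number of tests."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------
# linking


def link(tcr: pd.DataFrame, gex_meta: pd.DataFrame) -> pd.DataFrame:
    """Join clonotype calls onto per-cell transcriptome metadata.

    ``tcr`` needs columns ``sample``, ``barcode``, ``clonotype`` (canonical
    key string) and optionally ``known_name``; ``gex_meta`` needs
    ``sample``, ``barcode`` plus whatever per-cell columns it carries
    (cluster, scores).  The result has one row per transcriptome cell;
    cells without TCR keep ``clonotype`` as ``None`` so they remain usable
    as background.  Zero barcode overlap raises (wrong modality pairing).
    """
    for df, cols, name in (
        (tcr, {"sample", "barcode", "clonotype"}, "tcr"),
        (gex_meta, {"sample", "barcode"}, "gex_meta"),
    ):
        missing = cols - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing column(s): {sorted(missing)}")
    merged = gex_meta.merge(
        tcr, on=["sample", "barcode"], how="left", validate="one_to_one")
    merged["clonotype"] = merged["clonotype"].where(
        merged["clonotype"].notna(), None)
    if merged["clonotype"].notna().sum() == 0:
        raise ValueError("modalities do not share barcodes")
    return merged


@dataclass
class CompositionTable:
    """Percent-of-group cluster composition for groups above a size cut."""

    table: pd.DataFrame        # rows: group, cols: cluster ids, values: percent
    n_cells: pd.Series         # per included group
    excluded: pd.DataFrame     # groups at or below the threshold, with counts
    min_cells: int


def cluster_composition(
    linked: pd.DataFrame,
    group_col: str = "known_name",
    cluster_col: str = "cluster",
    sample_col: str | None = "sample",
    min_cells: int = 25,
) -> CompositionTable:
    """Per-group percentage distribution over clusters.

    Groups are ``group_col`` (crossed with sample when ``sample_col`` is
    given).  Only groups with strictly more than ``min_cells`` cells are
    included; the rest are listed in ``excluded`` with their counts.  Each
    included row sums to 100.
    """
    df = linked[linked[group_col].notna()].copy()
    keys = [group_col] if sample_col is None else [group_col, sample_col]
    counts = df.groupby(keys, observed=True)[cluster_col].value_counts().unstack(
        fill_value=0)
    n_cells = counts.sum(axis=1)
    include = n_cells > min_cells
    table = counts[include].div(n_cells[include], axis=0) * 100.0
    excluded = pd.DataFrame({"n_cells": n_cells[~include]})
    table = table.sort_index()
    table.columns = [int(c) for c in table.columns]
    return CompositionTable(
        table=table,
        n_cells=n_cells[include].sort_index(),
        excluded=excluded.reset_index(),
        min_cells=min_cells,
    )


# ---------------------------------------------------------------------------
# differential expression


def de_between_groups(
    adata,
    cells_a: Sequence[str] | np.ndarray,
    cells_b: Sequence[str] | np.ndarray,
    min_pct: float = 0.1,
    min_abs_log2fc: float = 0.25,
) -> pd.DataFrame:
    """Wilcoxon differential expression between two cell groups.

    ``cells_a`` / ``cells_b`` are barcode lists or boolean masks over
    ``adata.obs_names``.  Genes are pre-filtered to those detected in at
    least ``min_pct`` of either group and with
    ``|log2_fc| >= min_abs_log2fc``, where the fold change compares the
    group means of the back-transformed (expm1) normalized expression
    with a +1 pseudocount.  Bonferroni correction runs over the tested
    genes.  Returns a DataFrame (gene, log2_fc, pct_in, pct_out, p_value,
    p_adj) sorted by p then gene.
    """
    def _mask(cells):
        arr = np.asarray(cells)
        if arr.dtype == bool:
            return arr
        return adata.obs_names.isin(arr)

    mask_a, mask_b = _mask(cells_a), _mask(cells_b)
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("each group needs at least 3 cells")
    if (mask_a & mask_b).any():
        raise ValueError("groups overlap")
    Y = _dense(adata.layers[LOGNORM_LAYER]).astype(float)
    A, B = Y[mask_a], Y[mask_b]
    pct_in = (A > 0).mean(axis=0)
    pct_out = (B > 0).mean(axis=0)
    mean_a = np.expm1(A).mean(axis=0)
    mean_b = np.expm1(B).mean(axis=0)
    log2_fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    tested = ((pct_in >= min_pct) | (pct_out >= min_pct)) & (
        np.abs(log2_fc) >= min_abs_log2fc)
    genes = np.where(tested)[0]
    p = np.array([wilcoxon_rank_sum(A[:, g], B[:, g]) for g in genes])
    out = pd.DataFrame({
        "gene": np.asarray(adata.var_names)[genes],
        "log2_fc": log2_fc[genes],
        "pct_in": pct_in[genes],
        "pct_out": pct_out[genes],
        "p_value": p,
        "p_adj": bonferroni(p),
    })
    return out.sort_values(["p_value", "gene"]).reset_index(drop=True)


def group_signature_heatmap_table(
    adata,
    groups: pd.Series | dict,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Group means of normalized expression, z-scored across groups.

    ``groups`` maps barcodes to group labels (cells with no label are
    ignored).  Per gene, the group means are standardized to mean 0 and
    (sample) SD 1 across groups; genes constant across groups get 0.
    Needs at least two groups.
    """
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    groups = groups.reindex(adata.obs_names)
    labels = groups.dropna().unique()
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if genes is None:
        genes = list(adata.var_names)
    idx = [adata.var_names.get_loc(g) for g in genes]
    Y = _dense(adata.layers[LOGNORM_LAYER])[:, idx].astype(float)
    means = {}
    for lab in sorted(labels):
        mask = (groups == lab).to_numpy()
        means[lab] = Y[mask].mean(axis=0)
    table = pd.DataFrame(means, index=genes).T  # groups x genes
    mu = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1)
    z = (table - mu).div(sd.replace(0.0, np.inf), axis=1)
    return z
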