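"""Bulk RNA-seq normalization and PCA preparation.

Size factors follow the median-of-ratios rule: for every gene with
positive counts in all samples, compute its geometric mean across samples;
a sample's factor is the median over those genes of count / geometric
mean.  Counts divided by the factors are then optionally expressed
relative to a control condition (ratio to the mean of the mapped control
samples, with an additive pseudocount), which removes culture- and
processing-driven signatures shared with the control.  For visualization,
normalized counts are log2(x+1)-transformed and projected onto the first
two principal components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one per sample/column).

    Requires at least two samples and at least one gene with positive
    counts in every sample.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene has positive counts in all samples")
    pos = mat[all_positive]
    geo_mean = np.exp(np.log(pos).mean(axis=1))
    ratios = pos / geo_mean[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    if not counts.columns.equals(size_factors.index):
        size_factors = size_factors.reindex(counts.columns)
        if size_factors.isna().any():
            raise ValueError("size factors do not cover all samples")
    return counts.div(size_factors, axis=1)


@dataclass
class ControlNormalizedMatrix:
    """Expression relative to control samples, per group."""

    ratios: pd.DataFrame          # genes x samples, natural scale
    log2_ratios: pd.DataFrame     # log2 of the same
    pseudocount: float
    control_map: dict


def control_ratio(
    normalized: pd.DataFrame,
    control_map: Mapping[str, Sequence[str] | str],
    pseudocount: float = 1.0,
) -> ControlNormalizedMatrix:
    """Express each sample relative to its mapped control sample(s).

    entry = (normalized + pseudocount) / (mean control normalized +
    pseudocount).  When several control replicates are mapped, their mean
    normalized expression is the denominator.  A control mapped to itself
    normalizes to exactly 1.
    """
    cmap: dict[str, list[str]] = {}
    for sample, controls in control_map.items():
        if isinstance(controls, str):
            controls = [controls]
        controls = list(controls)
        if sample not in normalized.columns:
            raise ValueError(f"unknown sample {sample!r}")
        for c in controls:
            if c not in normalized.columns:
                raise ValueError(f"unknown control sample {c!r} for {sample!r}")
        if not controls:
            raise ValueError(f"sample {sample!r} mapped to no control")
        cmap[sample] = controls
    unmapped = [s for s in normalized.columns if s not in cmap]
    if unmapped:
        raise ValueError(f"sample(s) not mapped to a control: {unmapped}")
    out = {}
    for sample, controls in cmap.items():
        denom = normalized[controls].mean(axis=1) + pseudocount
        out[sample] = (normalized[sample] + pseudocount) / denom
    ratios = pd.DataFrame(out)[normalized.columns]
    return ControlNormalizedMatrix(
        ratios=ratios,
        log2_ratios=np.log2(ratios),
        pseudocount=pseudocount,
        control_map={k: list(v) for k, v in cmap.items()},
    )


def pca_input(normalized: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log2(x+1) transform and scores of the first two principal components.

    PCA is computed on the centered, log-transformed genes x samples
    matrix with samples as observations.  Returns (transformed matrix,
    scores DataFrame with columns PC1/PC2 indexed by sample).
    """
    if normalized.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA")
    log_mat = np.log2(normalized + 1.0)
    X = log_mat.to_numpy(dtype=float).T  # samples x genes
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < 2:
        raise ValueError("matrix rank < 2; PCA with 2 components impossible")
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(Xc)
    scores_df = pd.DataFrame(
        scores, index=normalized.columns, columns=["PC1", "PC2"])
    return log_mat, scores_df


def read_count_matrix(path) -> pd.DataFrame:
    """Genes x samples TSV with a header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df < 0).any().any():
        raise ValueError("negative counts in bulk matrix")
    return df


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: sample, condition, timepoint, TCR, is_control."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "condition", "timepoint", "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing column(s): {sorted(missing)}")
    return df


def control_map_from_sheet(sheet: pd.DataFrame) -> dict[str, list[str]]:
    """Map every sample to the control samples of its condition x timepoint group."""
    cmap: dict[str, list[str]] = {}
    for (_, _), grp in sheet.groupby(["condition", "timepoint"], observed=True):
        controls = list(grp.loc[grp["is_control"].astype(bool), "sample"])
        if not controls:
            raise ValueError(
                "group without control sample: "
                f"condition={grp['condition'].iloc[0]!r} "
                f"timepoint={grp['timepoint'].iloc[0]!r}")
        for s in grp["sample"]:
            cmap[s] = controls
    return cmap
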