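"""Single-cell gene-expression processing.

Implements the standard scRNA-seq workflow used to phenotype the
restimulation experiment: per-cell QC (gene counts, UMI counts,
mitochondrial fraction), log-normalization, variance-stabilizing
variable-gene detection, scaling with regression on technical covariates,
PCA + kNN-graph Leiden clustering, bin-matched-control gene-signature
module scores, and cell-cycle phase calls.

Functions operate on an :class:`anndata.AnnData` with raw counts in
``adata.X`` (cells x genes); results land in ``obs`` / ``var`` columns and
the ``"lognorm"`` layer, mirroring the conventions of scanpy-style
pipelines.  Batch correction is deliberately simple: variable genes can be
standardized per sample before the joint PCA (see
:func:`scale_with_regression`); no anchor-based integration is attempted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

LOGNORM_LAYER = "lognorm"


def load_mtx_dir(path, sample: str | None = None) -> ad.AnnData:
    """Load a 10x-style MTX bundle (matrix.mtx genes x cells) as cells x genes."""
    path = Path(path)
    mat = scipy.io.mmread(path / "matrix.mtx").tocsr().T.tocsr()
    barcodes = pd.read_csv(path / "barcodes.tsv", header=None)[0].astype(str)
    feats = pd.read_csv(path / "features.tsv", sep="\t", header=None)
    gene_names = feats[1] if feats.shape[1] > 1 else feats[0]
    adata = ad.AnnData(
        X=mat.astype(np.int64),
        obs=pd.DataFrame(index=barcodes.to_numpy()),
        var=pd.DataFrame(index=gene_names.astype(str).to_numpy()),
    )
    if sample is not None:
        adata.obs["sample"] = sample
    return adata


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def compute_qc_metrics(adata: ad.AnnData, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell QC metrics: n_genes, n_umi, pct_mito (stored in ``obs``).

    ``pct_mito`` is the fraction (0..1) of UMIs from genes whose name
    starts with ``mito_prefix`` (case-sensitive).  Zero-UMI cells get
    ``pct_mito = 0`` and are flagged in ``obs["zero_umi"]``.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty count matrix")
    X = adata.X
    if sp.issparse(X):
        n_umi = np.asarray(X.sum(axis=1)).ravel()
        n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        n_umi = np.asarray(X).sum(axis=1)
        n_genes = (np.asarray(X) > 0).sum(axis=1)
    is_mito = adata.var_names.str.startswith(mito_prefix)
    if is_mito.any():
        Xm = X[:, np.where(is_mito)[0]]
        mito_umi = np.asarray(Xm.sum(axis=1)).ravel()
    else:
        mito_umi = np.zeros(adata.n_obs)
    zero = n_umi == 0
    pct_mito = np.zeros(adata.n_obs)
    np.divide(mito_umi, n_umi, out=pct_mito, where=~zero)
    adata.obs["n_genes"] = n_genes.astype(int)
    adata.obs["n_umi"] = n_umi.astype(int)
    adata.obs["pct_mito"] = pct_mito
    adata.obs["zero_umi"] = zero
    return adata.obs[["n_genes", "n_umi", "pct_mito"]].copy()


def filter_cells_genes(
    adata: ad.AnnData,
    min_genes: int = 200,
    max_genes: int = 6000,
    max_mito: float = 0.18,
    min_cells_per_gene: int = 3,
    mito_prefix: str = "MT-",
) -> ad.AnnData:
    """Apply the object-construction QC filters.

    Genes detected (count > 0) in fewer than ``min_cells_per_gene`` cells
    of the raw matrix are dropped first; then cells are kept when
    ``min_genes <= n_genes < max_genes`` and ``pct_mito <= max_mito``,
    with the metrics computed on the raw matrix.  The filters are applied
    once, in that order, with no re-iteration, so they are idempotent.
    """
    if not {"n_genes", "n_umi", "pct_mito"}.issubset(adata.obs.columns):
        compute_qc_metrics(adata, mito_prefix=mito_prefix)
    X = adata.X
    cells_per_gene = np.asarray((X > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= min_cells_per_gene
    keep_cells = (
        (adata.obs["n_genes"].to_numpy() >= min_genes)
        & (adata.obs["n_genes"].to_numpy() < max_genes)
        & (adata.obs["pct_mito"].to_numpy() <= max_mito)
    )
    if not keep_cells.any():
        raise ValueError("no cells pass QC")
    return adata[keep_cells, keep_genes].copy()


def log_normalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Library-size log-normalization: ln(1 + count / n_umi * scale_factor).

    Stored in ``adata.layers["lognorm"]``; the per-cell total is taken
    from the current matrix, so rescaling all counts of a cell leaves the
    result unchanged.
    """
    X = adata.X.tocsr().astype(float) if sp.issparse(adata.X) else np.asarray(
        adata.X, dtype=float)
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    safe = np.where(n_umi > 0, n_umi, 1.0)
    if sp.issparse(X):
        Y = X.multiply((scale_factor / safe)[:, None]).tocsr()
        Y.data = np.log1p(Y.data)
    else:
        Y = np.log1p(X * (scale_factor / safe)[:, None])
    adata.layers[LOGNORM_LAYER] = Y
    adata.uns["lognorm_scale_factor"] = scale_factor
    return adata


@dataclass
class VariableGeneSet:
    """Genes ordered by decreasing standardized-variance score."""

    genes: list[str]
    scores: np.ndarray  # aligned with ``genes``, nonincreasing
    n_top: int
    table: pd.DataFrame = None  # full per-gene table (mean, variance, score)

    def __post_init__(self):
        assert np.all(np.diff(self.scores) <= 1e-12)


def find_variable_genes(
    adata: ad.AnnData,
    n_top: int = 2000,
    loess_span: float = 0.3,
    clip: float | None = None,
) -> VariableGeneSet:
    """Variance-stabilizing variable-gene detection on raw counts.

    Fits the expected standard deviation of each gene as a smooth function
    of its mean (local regression of log10 variance on log10 mean over
    genes with positive variance), standardizes counts by
    ``(x - mean) / expected_sd`` clipped at ``clip`` (default
    ``sqrt(n_cells)``), and scores each gene by the variance of the
    standardized values.  The top ``n_top`` genes by score are returned.
    """
    if adata.n_vars < 10 or adata.n_obs < 10:
        raise ValueError("need at least 10 genes and 10 cells")
    X = _dense(adata.X).astype(float)
    n_cells = X.shape[0]
    if clip is None:
        clip = float(np.sqrt(n_cells))
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    score = np.zeros(adata.n_vars)
    pos = (var > 0) & (mean > 0)
    if pos.sum() >= 2:
        lx = np.log10(mean[pos])
        ly = np.log10(var[pos])
        fitted = lowess(ly, lx, frac=loess_span, return_sorted=False)
        exp_sd = np.sqrt(10.0 ** fitted)
        Z = (X[:, pos] - mean[pos]) / exp_sd
        np.clip(Z, -clip, clip, out=Z)
        score[pos] = Z.var(axis=0, ddof=1)
    order = np.lexsort((np.asarray(adata.var_names), -score))
    table = pd.DataFrame(
        {"mean": mean, "variance": var, "vst_score": score},
        index=adata.var_names,
    )
    if n_top > adata.n_vars:
        warnings.warn(
            f"requested {n_top} variable genes but only {adata.n_vars} present; "
            "returning all")
        n_top = adata.n_vars
    top = order[:n_top]
    adata.var["vst_score"] = score
    adata.var["highly_variable"] = False
    adata.var.iloc[
        top, adata.var.columns.get_loc("highly_variable")
    ] = True
    return VariableGeneSet(
        genes=list(np.asarray(adata.var_names)[top]),
        scores=score[top],
        n_top=n_top,
        table=table,
    )


@dataclass
class ScaledMatrix:
    """Covariate-regressed, standardized expression of the variable genes."""

    data: np.ndarray  # cells x genes
    genes: list[str]
    covariates: tuple
    clip: float
    batch_key: str | None = None


def scale_with_regression(
    adata: ad.AnnData,
    genes: VariableGeneSet | list[str],
    covariates: tuple = ("n_umi", "pct_mito"),
    clip: float = 10.0,
    batch_key: str | None = None,
) -> ScaledMatrix:
    """Regress technical covariates out of normalized expression and scale.

    Per gene: ordinary least squares of log-normalized expression on an
    intercept plus the given ``obs`` covariates; residuals are centered,
    scaled to unit variance, then clipped to ``±clip``.  Constant genes
    yield all-zero residuals (their SD is treated as 1).

    With ``batch_key`` set, regression and standardization run within
    each batch independently — a deliberately simple stand-in for
    anchor-based batch integration, adequate when batches share the
    cluster structure.
    """
    gene_list = genes.genes if isinstance(genes, VariableGeneSet) else list(genes)
    idx = [adata.var_names.get_loc(g) for g in gene_list]
    Y = _dense(adata.layers[LOGNORM_LAYER])[:, idx].astype(float)

    def _scale_block(Yb: np.ndarray, obs: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(obs))]
        cols += [obs[c].to_numpy(dtype=float) for c in covariates]
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, Yb, rcond=None)
        R = Yb - X @ beta
        R -= R.mean(axis=0)
        sd = R.std(axis=0, ddof=1)
        # genes fit exactly (constant, or linear in a covariate) leave only
        # rounding noise; standardizing that would amplify it to unit scale
        scale = np.maximum(np.abs(Yb).max(axis=0), 1.0)
        negligible = sd <= 1e-10 * scale
        R[:, negligible] = 0.0
        sd[negligible] = 1.0
        R /= sd
        np.clip(R, -clip, clip, out=R)
        return R

    if batch_key is None:
        Z = _scale_block(Y, adata.obs)
    else:
        Z = np.empty_like(Y)
        batch_vals = adata.obs[batch_key].to_numpy()
        for b in pd.unique(batch_vals):
            rows = np.where(batch_vals == b)[0]
            Z[rows] = _scale_block(Y[rows], adata.obs.iloc[rows])
    return ScaledMatrix(
        data=Z, genes=gene_list, covariates=tuple(covariates), clip=clip,
        batch_key=batch_key,
    )


@dataclass
class ClusterAssignment:
    """Leiden community labels (relabeled by decreasing cluster size)."""

    labels: np.ndarray  # int per cell, 0..K-1, sizes nonincreasing
    n_pcs: int
    n_neighbors: int
    resolution: float
    seed: int
    pca_scores: np.ndarray = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def embed_and_cluster(
    scaled: ScaledMatrix,
    n_pcs: int = 30,
    n_neighbors: int = 15,
    resolution: float = 0.8,
    seed: int = 0,
) -> ClusterAssignment:
    """PCA, kNN graph and Leiden community detection.

    PCA (exact SVD, deterministic) reduces the scaled matrix to ``n_pcs``
    components; an undirected kNN graph on Euclidean distance feeds Leiden
    modularity optimization at the given resolution with a fixed seed.
    Cluster ids are relabeled by decreasing size.
    """
    import igraph
    import leidenalg

    n_cells, n_genes = scaled.data.shape
    if n_pcs > min(n_cells, n_genes):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds matrix rank bound {min(n_cells, n_genes)}")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(scaled.data)

    k = min(n_neighbors, n_cells - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scores)
    _, ind = nn.kneighbors(scores)
    edges = set()
    for i in range(n_cells):
        for j in ind[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    graph = igraph.Graph(n=n_cells, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    # relabel by decreasing size; ties by original label for determinism
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in raw], dtype=int)
    return ClusterAssignment(
        labels=labels, n_pcs=n_pcs, n_neighbors=n_neighbors,
        resolution=resolution, seed=seed, pca_scores=scores,
    )


@dataclass
class ModuleScoreResult:
    """Per-cell signature score: mean signature minus bin-matched controls."""

    scores: np.ndarray
    gene_set: list[str]
    n_bins: int
    n_ctrl: int
    seed: int


def module_score(
    adata: ad.AnnData,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """Gene-signature module score with expression-bin-matched controls.

    All genes are binned into ``n_bins`` equal-size bins by their average
    log-normalized expression across cells.  For each signature gene,
    ``n_ctrl`` control genes are drawn (with replacement, seeded) from its
    bin, excluding the signature itself so the contrast is against
    expression-matched background; the score of a cell is its mean
    expression over the signature genes minus its mean expression over the
    pooled control draws.  Signature genes missing from the matrix are
    dropped with a warning; an empty effective set is an error.
    """
    present = [g for g in gene_set if g in adata.var_names]
    missing = set(gene_set) - set(present)
    if missing:
        warnings.warn(
            f"{len(missing)} signature gene(s) absent from matrix: "
            + ", ".join(sorted(missing)[:5]))
    if not present:
        raise ValueError("no signature genes present in the matrix")
    Y = _dense(adata.layers[LOGNORM_LAYER]).astype(float)
    avg = Y.mean(axis=0)
    # equal-size bins over the expression ranking (ntile)
    order = np.lexsort((np.asarray(adata.var_names), avg))
    bin_of = np.empty(adata.n_vars, dtype=int)
    bin_of[order] = np.floor(
        np.arange(adata.n_vars) * n_bins / adata.n_vars).astype(int)
    rng = np.random.default_rng(seed)
    sig_idx = np.array([adata.var_names.get_loc(g) for g in present])
    sig_set = set(sig_idx.tolist())
    ctrl_idx: list[int] = []
    for gi in sig_idx:
        pool = np.where(bin_of == bin_of[gi])[0]
        # controls are the non-signature bin-mates; keep the full bin only
        # if the signature occupies it entirely
        non_sig = pool[[p not in sig_set for p in pool]]
        if non_sig.size:
            pool = non_sig
        ctrl_idx.extend(rng.choice(pool, size=n_ctrl, replace=True))
    scores = Y[:, sig_idx].mean(axis=1) - Y[:, np.asarray(ctrl_idx)].mean(axis=1)
    return ModuleScoreResult(
        scores=scores, gene_set=present, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed,
    )


@dataclass
class CellCycleCall:
    """Per-cell S and G2M scores plus the called phase."""

    s_score: np.ndarray
    g2m_score: np.ndarray
    phase: np.ndarray  # "G1" | "S" | "G2M"


def cell_cycle_score(
    adata: ad.AnnData,
    s_genes: list[str],
    g2m_genes: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> CellCycleCall:
    """Cell-cycle phase from S and G2M module scores.

    A cell is called G1 when neither score is positive, otherwise the
    phase of the larger score (S wins exact ties).
    """
    s_present = [g for g in s_genes if g in adata.var_names]
    g2m_present = [g for g in g2m_genes if g in adata.var_names]
    if not s_present or not g2m_present:
        raise ValueError("cell-cycle gene lists empty after intersection")
    s = module_score(adata, s_present, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    g2m = module_score(adata, g2m_present, n_bins=n_bins, n_ctrl=n_ctrl,
                       seed=seed + 1)
    phase = np.where(
        np.maximum(s.scores, g2m.scores) <= 0,
        "G1",
        np.where(s.scores >= g2m.scores, "S", "G2M"),
    )
    adata.obs["s_score"] = s.scores
    adata.obs["g2m_score"] = g2m.scores
    adata.obs["phase"] = phase
    return CellCycleCall(s_score=s.scores, g2m_score=g2m.scores, phase=phase)


def run_standard_pipeline(
    adata: ad.AnnData,
    min_genes: int = 200,
    max_genes: int = 6000,
    max_mito: float = 0.18,
    min_cells_per_gene: int = 3,
    n_top_genes: int = 2000,
    n_pcs: int = 30,
    n_neighbors: int = 15,
    resolution: float = 0.8,
    seed: int = 0,
    batch_key: str | None = None,
) -> ad.AnnData:
    """QC -> normalize -> variable genes -> scale -> cluster, in one call.

    Returns the filtered AnnData with ``obs["cluster"]`` set and the run
    parameters recorded in ``uns["pipeline_params"]``.
    """
    compute_qc_metrics(adata)
    adata = filter_cells_genes(
        adata, min_genes=min_genes, max_genes=max_genes, max_mito=max_mito,
        min_cells_per_gene=min_cells_per_gene)
    log_normalize(adata)
    hvg = find_variable_genes(adata, n_top=n_top_genes)
    n_pcs_eff = min(n_pcs, len(hvg.genes) - 1, adata.n_obs - 1)
    scaled = scale_with_regression(adata, hvg, batch_key=batch_key)
    clusters = embed_and_cluster(
        scaled, n_pcs=n_pcs_eff, n_neighbors=n_neighbors,
        resolution=resolution, seed=seed)
    adata.obs["cluster"] = clusters.labels
    adata.obsm["X_pca"] = clusters.pca_scores
    adata.uns["pipeline_params"] = {
        "min_genes": min_genes, "max_genes": max_genes, "max_mito": max_mito,
        "min_cells_per_gene": min_cells_per_gene, "n_top_genes": n_top_genes,
        "n_pcs": n_pcs_eff, "n_neighbors": n_neighbors,
        "resolution": resolution, "seed": seed, "batch_key": batch_key,
    }
    return adata
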