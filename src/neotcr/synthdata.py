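"""Synthetic paired-repertoire and expression-matrix generator.

Emulates the statistical structure of an antigen-restimulation experiment:
an unstimulated CD8 T-cell repertoire with heavy-tailed (power-law) clonal
frequencies, and a restimulated, activation-marker-enriched repertoire in
which antigen-specific ("spiked") clonotypes are multiplicatively enriched.
Per-cell chain dropout, multi-chain artifacts and non-productive contigs
reproduce the cells the V(D)J QC must remove.  The companion expression
generator emits count matrices with cluster-structured programs (naive /
effector / inhibitory / proliferative), lognormal library sizes and
per-cell mitochondrial fractions, so every downstream stage is testable
against known ground truth.

All randomness flows from ``SimConfig.seed`` through one independent
stream per output artifact, so the repertoire pair and the expression
matrices are each byte-reproducible on their own.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

CONTIG_COLUMNS = [
    "barcode", "is_cell", "contig_id", "high_confidence", "length",
    "chain", "v_gene", "d_gene", "j_gene", "c_gene", "full_length",
    "productive", "cdr3", "cdr3_nt", "reads", "umis", "raw_clonotype_id",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODON = {  # one representative codon per amino acid, for cdr3_nt
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

DEFAULT_PROGRAMS = ("naive", "effector", "inhibitory", "proliferative")


class SimConfigError(ValueError):
    """Invalid synthetic-data configuration; message names the field."""


@dataclass
class SimConfig:
    """Parameters of one synthetic paired-sample experiment.

    ``spikes`` lists ``(clonotype_id, enrichment_factor)`` pairs: the
    post-stimulation sampling probability of each listed clonotype is the
    pre-stimulation probability multiplied by the factor, then the vector
    is renormalized.  ``programs`` lists ``(name, gene_index_set,
    mean_shift)`` expression programs; ``mean_shift`` acts on the log
    gene-weight scale.
    """

    n_clonotypes: int = 2000
    clonal_alpha: float = 1.5
    n_cells_pre: int = 5000
    n_cells_post: int = 5000
    spikes: list = field(default_factory=list)
    chain_dropout_rate: float = 0.10
    multi_chain_rate: float = 0.05
    nonproductive_rate: float = 0.05
    n_genes: int = 300
    programs: list = None
    mito_gene_fraction: float = 0.05
    library_size_lognormal: tuple = (7.824046010856292, 0.35)  # ln(2500), 0.35
    seed: int = 0

    def __post_init__(self):
        if self.programs is None:
            self.programs = default_programs(self.n_genes, self.mito_gene_fraction)
        self.validate()

    def validate(self) -> None:
        for name in ("n_clonotypes", "n_cells_pre", "n_cells_post", "n_genes"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise SimConfigError(f"{name} must be a positive integer, got {v!r}")
        if not self.clonal_alpha > 0:
            raise SimConfigError(f"clonal_alpha must be > 0, got {self.clonal_alpha!r}")
        for name in ("chain_dropout_rate", "multi_chain_rate",
                     "nonproductive_rate", "mito_gene_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimConfigError(f"{name} must be in [0, 1], got {v!r}")
        for cid, factor in self.spikes:
            if not (0 <= int(cid) < self.n_clonotypes):
                raise SimConfigError(
                    f"spikes: clonotype_id {cid} outside [0, {self.n_clonotypes})")
            if not factor > 0:
                raise SimConfigError(
                    f"spikes: enrichment_factor must be > 0, got {factor!r}")
        n_mito = _n_mito(self.n_genes, self.mito_gene_fraction)
        for pname, genes, _shift in self.programs:
            genes = np.asarray(sorted(genes))
            if genes.size and (genes.min() < 0 or genes.max() >= self.n_genes):
                raise SimConfigError(
                    f"programs: gene set of {pname!r} outside [0, {self.n_genes})")
            if genes.size and genes.min() < n_mito:
                raise SimConfigError(
                    f"programs: gene set of {pname!r} overlaps mitochondrial genes")
        mu, sigma = self.library_size_lognormal
        if not sigma >= 0:
            raise SimConfigError(
                f"library_size_lognormal sigma must be >= 0, got {sigma!r}")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "spikes" in raw:
            raw["spikes"] = [tuple(s) for s in raw["spikes"]]
        if raw.get("programs") is not None:
            raw["programs"] = [
                (p[0], list(p[1]), float(p[2])) for p in raw["programs"]
            ]
        if "library_size_lognormal" in raw:
            raw["library_size_lognormal"] = tuple(raw["library_size_lognormal"])
        return cls(**raw)


def _n_mito(n_genes: int, mito_gene_fraction: float) -> int:
    return int(round(n_genes * mito_gene_fraction))


def default_programs(n_genes: int, mito_gene_fraction: float = 0.05,
                     genes_per_program: int = 15, mean_shift: float = 1.0):
    """Four canonical T-cell programs over disjoint non-mito gene blocks."""
    n_mito = _n_mito(n_genes, mito_gene_fraction)
    programs = []
    start = n_mito
    for name in DEFAULT_PROGRAMS:
        stop = min(start + genes_per_program, n_genes)
        programs.append((name, list(range(start, stop)), mean_shift))
        start = stop
    return programs


@dataclass
class SimTruth:
    """Ground truth emitted alongside the synthetic data.

    ``clonotypes`` has one row per clonotype (sequences, true pre/post
    sampling probabilities, realized counts); ``cells`` one row per cell
    (sample, barcode, true clonotype id, program, mito fraction).
    """

    config: SimConfig
    clonotypes: pd.DataFrame
    cells: pd.DataFrame
    spikes: list

    def cells_of(self, sample: str) -> pd.DataFrame:
        return self.cells[self.cells["sample"] == sample]


_STREAM_IDS = {"clonotypes": 1, "pre": 2, "post": 3, "cells": 4, "gex": 5}


def _stream(config: SimConfig, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _STREAM_IDS[name]])
    )


def _random_cdr3(rng: np.random.Generator, prefix: str, n_var: int = 8) -> str:
    body = "".join(_AA[i] for i in rng.integers(0, len(_AA), size=n_var))
    return prefix + body + "F"


def _nt_of(aa: str) -> str:
    return "".join(_CODON[a] for a in aa)


def _make_clonotype_defs(config: SimConfig) -> pd.DataFrame:
    rng = _stream(config, "clonotypes")
    n = config.n_clonotypes
    seen: set[tuple] = set()
    rows = []
    for i in range(n):
        while True:
            a_cdr3 = _random_cdr3(rng, "CA")
            b_cdr3 = _random_cdr3(rng, "CASS")
            ident = (a_cdr3, b_cdr3)
            if ident not in seen:
                seen.add(ident)
                break
        rows.append({
            "clonotype_id": i,
            "alpha_cdr3_aa": a_cdr3,
            "beta_cdr3_aa": b_cdr3,
            "alpha_v": f"TRAV{rng.integers(1, 42)}",
            "alpha_j": f"TRAJ{rng.integers(1, 62)}",
            "beta_v": f"TRBV{rng.integers(1, 31)}",
            "beta_j": f"TRBJ{rng.integers(1, 3)}-{rng.integers(1, 8)}",
        })
    return pd.DataFrame(rows)


def clonal_probabilities(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Pre/post sampling probability vectors (each sums to 1).

    Pre-stimulation frequencies follow a discrete power law
    p_i ∝ (i+1)^(-clonal_alpha); spiked clonotypes are multiplied by their
    enrichment factor post-stimulation and the vector renormalized.
    """
    ranks = np.arange(1, config.n_clonotypes + 1, dtype=float)
    p_pre = ranks ** (-config.clonal_alpha)
    p_pre /= p_pre.sum()
    p_post = p_pre.copy()
    for cid, factor in config.spikes:
        p_post[int(cid)] *= float(factor)
    p_post /= p_post.sum()
    return p_pre, p_post


def _barcodes(rng: np.random.Generator, n: int) -> list[str]:
    alphabet = np.array(list("ACGT"))
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        bc = "".join(alphabet[rng.integers(0, 4, size=16)]) + "-1"
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _emit_contigs(
    rng: np.random.Generator,
    config: SimConfig,
    defs: pd.DataFrame,
    cell_clonotypes: np.ndarray,
    barcodes: Sequence[str],
) -> pd.DataFrame:
    """Contig rows for one sample, with configured corruption."""
    rows = []
    n_clono = len(defs)
    for barcode, cid in zip(barcodes, cell_clonotypes):
        d = defs.iloc[int(cid)]
        chains = [
            ("TRA", d.alpha_cdr3_aa, d.alpha_v, d.alpha_j, "TRAC"),
            ("TRB", d.beta_cdr3_aa, d.beta_v, d.beta_j, "TRBC1"),
        ]
        # multi-chain artifact: extra alpha or beta copied from another clonotype
        if rng.random() < config.multi_chain_rate:
            other = int(rng.integers(0, n_clono - 1))
            if other >= cid:
                other += 1
            o = defs.iloc[other]
            if rng.random() < 0.5:
                chains.append(("TRA", o.alpha_cdr3_aa, o.alpha_v, o.alpha_j, "TRAC"))
            else:
                chains.append(("TRB", o.beta_cdr3_aa, o.beta_v, o.beta_j, "TRBC1"))
        contig_no = 0
        for chain, cdr3, v, j, c in chains:
            if rng.random() < config.chain_dropout_rate:
                continue
            productive = "True"
            if rng.random() < config.nonproductive_rate:
                productive = "False"
            contig_no += 1
            umis = int(rng.integers(2, 40))
            rows.append({
                "barcode": barcode,
                "is_cell": "True",
                "contig_id": f"{barcode}_contig_{contig_no}",
                "high_confidence": "True",
                "length": 500 + len(cdr3) * 3,
                "chain": chain,
                "v_gene": v,
                "d_gene": "None" if chain == "TRA" else "TRBD1",
                "j_gene": j,
                "c_gene": c,
                "full_length": "True",
                "productive": productive,
                "cdr3": cdr3,
                "cdr3_nt": _nt_of(cdr3),
                "reads": umis * 25,
                "umis": umis,
                "raw_clonotype_id": f"clonotype{int(cid)}",
            })
    return pd.DataFrame(rows, columns=CONTIG_COLUMNS)


def generate_repertoire_pair(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate paired pre/post contig annotation tables plus ground truth.

    Post-stimulation sampling probabilities are the pre-stimulation ones
    with spiked clonotypes multiplied by their enrichment factor and
    renormalized; cells are multinomial draws; every cell emits one
    productive TRA and one productive TRB contig row except under the
    configured dropout / multi-chain / non-productive corruption.
    """
    config.validate()
    defs = _make_clonotype_defs(config)
    p_pre, p_post = clonal_probabilities(config)

    tables = {}
    cell_frames = []
    counts = {}
    cell_rng = _stream(config, "cells")
    for sample, n_cells, probs in (
        ("pre", config.n_cells_pre, p_pre),
        ("post", config.n_cells_post, p_post),
    ):
        rng = _stream(config, sample)
        draw = rng.multinomial(n_cells, probs)
        counts[sample] = draw
        cell_clono = np.repeat(np.arange(config.n_clonotypes), draw)
        rng.shuffle(cell_clono)
        barcodes = _barcodes(rng, n_cells)
        tables[sample] = _emit_contigs(rng, config, defs, cell_clono, barcodes)
        program_names = [p[0] for p in config.programs]
        programs = cell_rng.choice(program_names, size=n_cells)
        mito_frac = cell_rng.beta(2.0, 23.0, size=n_cells)
        cell_frames.append(pd.DataFrame({
            "sample": sample,
            "barcode": barcodes,
            "clonotype_id": cell_clono,
            "program": programs,
            "mito_fraction": mito_frac,
        }))

    clono = defs.copy()
    clono["p_pre"] = p_pre
    clono["p_post"] = p_post
    clono["count_pre"] = counts["pre"]
    clono["count_post"] = counts["post"]
    truth = SimTruth(
        config=config,
        clonotypes=clono,
        cells=pd.concat(cell_frames, ignore_index=True),
        spikes=list(config.spikes),
    )
    return tables["pre"], tables["post"], truth


def gene_names(config: SimConfig) -> list[str]:
    n_mito = _n_mito(config.n_genes, config.mito_gene_fraction)
    names = [f"MT-SIM{i + 1}" for i in range(n_mito)]
    names += [f"GENE{i + 1:05d}" for i in range(config.n_genes - n_mito)]
    return names


def generate_gex(config: SimConfig, truth: SimTruth) -> ad.AnnData:
    """Generate a cells x genes count matrix matching the repertoire truth.

    Per cell, counts are Poisson with rate = library_size x softmax(gene
    weights): program genes are mean-shifted on the log-weight scale for
    cells of that program, and mitochondrial genes (prefix ``MT-``)
    receive the cell's true mitochondrial fraction of the rate mass.
    Barcodes match the repertoire tables; ``obs`` carries the truth.
    """
    if truth.config is not config and truth.config != config:
        raise ValueError("truth was not produced from this config")
    rng = _stream(config, "gex")
    names = gene_names(config)
    n_genes = config.n_genes
    n_mito = _n_mito(n_genes, config.mito_gene_fraction)
    cells = truth.cells.reset_index(drop=True)
    n_cells = len(cells)

    base = rng.normal(0.0, 1.0, size=n_genes)
    mu, sigma = config.library_size_lognormal
    lib = rng.lognormal(mean=mu, sigma=sigma, size=n_cells)

    nonmito = slice(n_mito, n_genes)
    if n_mito:
        w_mito = np.exp(base[:n_mito] - base[:n_mito].max())
        q_mito = w_mito / w_mito.sum()
    program_q = {}
    for pname, genes, shift in config.programs:
        w = base[nonmito].copy()
        idx = np.asarray(genes, dtype=int) - n_mito
        if idx.size:
            w[idx] += shift
        w = np.exp(w - w.max())
        program_q[pname] = w / w.sum()

    rates = np.empty((n_cells, n_genes))
    f = cells["mito_fraction"].to_numpy() if n_mito else np.zeros(n_cells)
    for pname, q in program_q.items():
        mask = (cells["program"] == pname).to_numpy()
        rates[np.ix_(mask, np.arange(n_mito, n_genes))] = (
            (lib[mask] * (1.0 - f[mask]))[:, None] * q[None, :]
        )
    if n_mito:
        rates[:, :n_mito] = (lib * f)[:, None] * q_mito[None, :]

    counts = rng.poisson(rates).astype(np.int64)
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame({
            "sample": cells["sample"].to_numpy(),
            "true_clonotype_id": cells["clonotype_id"].to_numpy(),
            "true_program": cells["program"].to_numpy(),
            "true_mito_fraction": f,
            "true_library_size": lib,
        }, index=cells["barcode"]),
        var=pd.DataFrame(index=names),
    )
    adata.obs_names.name = None
    adata.var_names.name = None
    return adata


# ---------------------------------------------------------------------------
# writers


def write_contigs(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, lineterminator="\n")


def write_gex(adata: ad.AnnData, outdir, sample: str | None = None) -> None:
    """Write a 10x-style MTX bundle (matrix.mtx, barcodes.tsv, features.tsv).

    The matrix is written genes x cells, as Cell Ranger does.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if sample is not None:
        adata = adata[adata.obs["sample"] == sample]
    mat = sp.csc_matrix(adata.X.T)
    scipy.io.mmwrite(outdir / "matrix.mtx", mat, field="integer")
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", index=False, header=False)
    feats = pd.DataFrame({
        "gene_id": [f"SIMENSG{i + 1:08d}" for i in range(adata.n_vars)],
        "gene_name": adata.var_names,
        "feature_type": "Gene Expression",
    })
    feats.to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)


def write_truth(truth: SimTruth, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.clonotypes.to_csv(outdir / "truth_clonotypes.tsv", sep="\t", index=False)
    truth.cells.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
    cfg = dataclasses.asdict(truth.config)
    cfg["library_size_lognormal"] = [
        float(v) for v in cfg["library_size_lognormal"]]
    cfg["spikes"] = [[int(c), float(f)] for c, f in cfg["spikes"]]
    cfg["programs"] = [[p, list(g), float(s)] for p, g, s in cfg["programs"]]
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def simulate_to_dir(config: SimConfig, outdir) -> SimTruth:
    """Run the full generator and write all artifacts under ``outdir``."""
    outdir = Path(outdir)
    pre, post, truth = generate_repertoire_pair(config)
    adata = generate_gex(config, truth)
    outdir.mkdir(parents=True, exist_ok=True)
    write_contigs(pre, outdir / "pre_filtered_contig_annotations.csv")
    write_contigs(post, outdir / "post_filtered_contig_annotations.csv")
    write_gex(adata, outdir / "gex_pre", sample="pre")
    write_gex(adata, outdir / "gex_post", sample="post")
    write_truth(truth, outdir)
    return truth
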