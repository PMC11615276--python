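"""Parsing and quality control of single-cell V(D)J contig annotations.

This module turns 10x-Genomics-style ``filtered_contig_annotations.csv``
tables into per-cell chain sets, applies clonotype-level QC (paired-chain
filters), and builds per-sample clonotype frequency tables.  Clonotype
identity is keyed on the paired CDR3 amino-acid sequences plus V/J gene
names; known TCRs of interest are matched against a table by their CDR3
regions.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel used in ClonotypeKey fields when a chain is undefined
#: (single-chain clonotypes from the relaxed filter).
MISSING = "*"

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

MANDATORY_COLUMNS = ("barcode", "chain", "cdr3", "productive")

#: Full 10x contig-annotation column set; optional ones get defaults.
OPTIONAL_DEFAULTS = {
    "cdr3_nt": "",
    "v_gene": "",
    "j_gene": "",
    "c_gene": "",
    "umis": 0,
    "reads": 0,
}


class ContigFormatError(ValueError):
    """Raised when a contig table is missing a mandatory column."""


@dataclass
class ContigRecord:
    """One annotated V(D)J contig (one chain of one cell)."""

    barcode: str
    chain: str  # "TRA", "TRB" or "other"
    cdr3_aa: str
    cdr3_nt: str = ""
    v_gene: str = ""
    j_gene: str = ""
    c_gene: str = ""
    productive: bool = False
    umis: int = 0
    reads: int = 0
    is_cell: bool = True
    high_confidence: bool = True


@dataclass
class CellChains:
    """All TRA/TRB contigs observed for one cell barcode."""

    barcode: str
    tra: list[ContigRecord] = field(default_factory=list)
    trb: list[ContigRecord] = field(default_factory=list)

    def productive_tra(self) -> list[ContigRecord]:
        return [c for c in _dedup_contigs(self.tra) if c.productive]

    def productive_trb(self) -> list[ContigRecord]:
        return [c for c in _dedup_contigs(self.trb) if c.productive]


@dataclass(frozen=True)
class ClonotypeKey:
    """Paired-chain clonotype identity: CDR3 amino acids plus V/J genes.

    Missing chain fields (relaxed filter) carry the :data:`MISSING`
    sentinel.  Keys are hashable and compare field-wise.
    """

    alpha_cdr3_aa: str
    beta_cdr3_aa: str
    alpha_v: str = MISSING
    alpha_j: str = MISSING
    beta_v: str = MISSING
    beta_j: str = MISSING

    def canonical(self) -> str:
        return (
            f"{self.alpha_v}:{self.alpha_cdr3_aa}|{self.beta_v}:{self.beta_cdr3_aa}"
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical()


@dataclass
class ClonotypeTable:
    """Per-sample clonotype cell counts and frequencies.

    Frequencies are computed over the cells that passed the *same* filter
    that produced this table, so totals differ between the strict and the
    relaxed clonotype universes.
    """

    sample_label: str
    counts: "OrderedDict[ClonotypeKey, int]"
    total_cells: int

    def frequency(self, key: ClonotypeKey) -> float:
        return self.counts.get(key, 0) / self.total_cells

    def frequencies(self) -> dict[ClonotypeKey, float]:
        return {k: c / self.total_cells for k, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "alpha_cdr3_aa": k.alpha_cdr3_aa,
                "beta_cdr3_aa": k.beta_cdr3_aa,
                "alpha_v": k.alpha_v,
                "alpha_j": k.alpha_j,
                "beta_v": k.beta_v,
                "beta_j": k.beta_j,
                "cell_count": c,
                "frequency": c / self.total_cells,
            }
            for k, c in self.counts.items()
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "alpha_cdr3_aa",
                "beta_cdr3_aa",
                "alpha_v",
                "alpha_j",
                "beta_v",
                "beta_j",
                "cell_count",
                "frequency",
            ],
        )


def _parse_bool(value) -> bool:
    """10x encodes booleans as "True"/"False"/"None"; None counts as False."""
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        return False
    return str(value).strip().lower() == "true"


def read_contigs(
    path,
    *,
    drop_non_cell: bool = True,
    drop_low_confidence: bool = True,
) -> list[ContigRecord]:
    """Read a contig annotation CSV into :class:`ContigRecord` objects.

    Rows with ``is_cell`` or ``high_confidence`` false are dropped when
    those columns exist (configurable).  Chains other than TRA/TRB are
    mapped to ``"other"``.  Missing optional columns get zero/empty
    defaults with a logged warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ContigFormatError(
            f"contig table {path!r} is missing mandatory column(s): "
            + ", ".join(missing)
        )
    for col, default in OPTIONAL_DEFAULTS.items():
        if col not in df.columns:
            logger.warning(
                "contig table %r has no %r column; defaulting to %r",
                str(path), col, default,
            )
            df[col] = default

    records: list[ContigRecord] = []
    for row in df.itertuples(index=False):
        is_cell = _parse_bool(getattr(row, "is_cell", True)) if "is_cell" in df.columns else True
        high_conf = (
            _parse_bool(getattr(row, "high_confidence", True))
            if "high_confidence" in df.columns
            else True
        )
        if drop_non_cell and not is_cell:
            continue
        if drop_low_confidence and not high_conf:
            continue
        chain = str(row.chain).strip()
        if chain not in ("TRA", "TRB"):
            chain = "other"
        cdr3 = "" if pd.isna(row.cdr3) else str(row.cdr3)
        if cdr3 in ("None", "nan"):
            cdr3 = ""
        records.append(
            ContigRecord(
                barcode=str(row.barcode),
                chain=chain,
                cdr3_aa=cdr3,
                cdr3_nt="" if pd.isna(row.cdr3_nt) else str(row.cdr3_nt),
                v_gene="" if pd.isna(row.v_gene) else str(row.v_gene),
                j_gene="" if pd.isna(row.j_gene) else str(row.j_gene),
                c_gene="" if pd.isna(row.c_gene) else str(row.c_gene),
                productive=_parse_bool(row.productive),
                umis=int(float(row.umis)) if not pd.isna(row.umis) else 0,
                reads=int(float(row.reads)) if not pd.isna(row.reads) else 0,
                is_cell=is_cell,
                high_confidence=high_conf,
            )
        )
    return records


def assemble_cells(records: Iterable[ContigRecord]) -> list[CellChains]:
    """Group contigs by barcode, preserving input order within chains.

    Chains other than TRA/TRB are ignored.
    """
    cells: "OrderedDict[str, CellChains]" = OrderedDict()
    for rec in records:
        cell = cells.get(rec.barcode)
        if cell is None:
            cell = cells[rec.barcode] = CellChains(barcode=rec.barcode)
        if rec.chain == "TRA":
            cell.tra.append(rec)
        elif rec.chain == "TRB":
            cell.trb.append(rec)
    return list(cells.values())


def _dedup_contigs(contigs: Sequence[ContigRecord]) -> list[ContigRecord]:
    # Identical productive contigs (same chain/CDR3/V/J) are sequencing
    # artifacts, not genuine dual chains; collapse before filtering.
    seen: set[tuple] = set()
    out: list[ContigRecord] = []
    for c in contigs:
        ident = (c.chain, c.cdr3_aa, c.v_gene, c.j_gene, c.productive)
        if ident in seen:
            continue
        seen.add(ident)
        out.append(c)
    return out


def filter_paired_strict(cells: Iterable[CellChains]) -> list[CellChains]:
    """Retain cells with exactly one productive TRA and one productive TRB."""
    return [
        c
        for c in cells
        if len(c.productive_tra()) == 1 and len(c.productive_trb()) == 1
    ]


def filter_any_defined(cells: Iterable[CellChains]) -> list[CellChains]:
    """Retain cells with at least one defined (productive) chain.

    Cells with more than one productive alpha or more than one productive
    beta chain are removed; a single productive chain of either type is
    enough.  This is a superset of :func:`filter_paired_strict`.
    """
    out = []
    for c in cells:
        n_a = len(c.productive_tra())
        n_b = len(c.productive_trb())
        if n_a > 1 or n_b > 1:
            continue
        if n_a + n_b >= 1:
            out.append(c)
    return out


def clonotype_key_for_cell(cell: CellChains) -> ClonotypeKey:
    """Derive the clonotype key of a QC-passing cell.

    The cell must have at most one productive chain of each type; a
    missing chain yields sentinel fields.
    """
    tra = cell.productive_tra()
    trb = cell.productive_trb()
    if len(tra) > 1 or len(trb) > 1:
        raise ValueError(
            f"cell {cell.barcode} has multiple productive chains; filter first"
        )
    if not tra and not trb:
        raise ValueError(f"cell {cell.barcode} has no productive chain")
    a = tra[0] if tra else None
    b = trb[0] if trb else None
    return ClonotypeKey(
        alpha_cdr3_aa=a.cdr3_aa if a else MISSING,
        beta_cdr3_aa=b.cdr3_aa if b else MISSING,
        alpha_v=a.v_gene if a else MISSING,
        alpha_j=a.j_gene if a else MISSING,
        beta_v=b.v_gene if b else MISSING,
        beta_j=b.j_gene if b else MISSING,
    )


def build_clonotype_table(
    cells: Sequence[CellChains], sample_label: str
) -> ClonotypeTable:
    """Count cells per clonotype key and compute frequencies."""
    if not cells:
        raise ValueError("empty repertoire")
    counts: "OrderedDict[ClonotypeKey, int]" = OrderedDict()
    for cell in cells:
        key = clonotype_key_for_cell(cell)
        counts[key] = counts.get(key, 0) + 1
    return ClonotypeTable(
        sample_label=sample_label, counts=counts, total_cells=len(cells)
    )


def match_known(
    table: ClonotypeTable,
    known: Mapping[str, tuple] | pd.DataFrame,
    mode: str = "cdr3_pair",
) -> dict[str, list[ClonotypeKey]]:
    """Match a named list of known TCRs against a clonotype table.

    Known TCRs are matched by exact string equality of the paired CDR3
    amino-acid sequences (``mode="cdr3_pair"``, the default) or the pair
    plus V/J genes (``mode="cdr3_pair_plus_vj"``).  One name may match
    several keys (convergent V/J usage); all matches are reported.  Names
    absent from the table map to empty lists.

    ``known`` is either a mapping name -> (alpha_cdr3, beta_cdr3[, alpha_v,
    alpha_j, beta_v, beta_j]) or a DataFrame with columns ``name``,
    ``alpha_cdr3_aa``, ``beta_cdr3_aa`` (plus gene columns for the vj mode).
    """
    if mode not in ("cdr3_pair", "cdr3_pair_plus_vj"):
        raise ValueError(f"unknown matching mode: {mode!r}")
    if isinstance(known, pd.DataFrame):
        names = list(known["name"])
        if len(names) != len(set(names)):
            raise ValueError("duplicate known-TCR names")
        entries = {
            row["name"]: (
                row["alpha_cdr3_aa"],
                row["beta_cdr3_aa"],
                row.get("alpha_v", MISSING),
                row.get("alpha_j", MISSING),
                row.get("beta_v", MISSING),
                row.get("beta_j", MISSING),
            )
            for _, row in known.iterrows()
        }
    else:
        entries = {name: tuple(vals) for name, vals in known.items()}
        if len(entries) != len(known):
            raise ValueError("duplicate known-TCR names")

    result: dict[str, list[ClonotypeKey]] = {name: [] for name in entries}
    for key in table.counts:
        for name, vals in entries.items():
            if key.alpha_cdr3_aa != vals[0] or key.beta_cdr3_aa != vals[1]:
                continue
            if mode == "cdr3_pair_plus_vj":
                if len(vals) < 6:
                    raise ValueError(
                        f"known TCR {name!r} lacks V/J genes required by "
                        "cdr3_pair_plus_vj matching"
                    )
                if (key.alpha_v, key.alpha_j, key.beta_v, key.beta_j) != tuple(
                    vals[2:6]
                ):
                    continue
            result[name].append(key)
    return result


def write_clonotype_table(table: ClonotypeTable, path) -> None:
    df = table.to_frame()
    df.insert(0, "sample", table.sample_label)
    df.to_csv(path, sep="\t", index=False)


def read_clonotype_table(path) -> ClonotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str}, keep_default_na=False)
    if df.empty:
        raise ValueError("empty repertoire")
    counts: "OrderedDict[ClonotypeKey, int]" = OrderedDict()
    for _, row in df.iterrows():
        key = ClonotypeKey(
            alpha_cdr3_aa=str(row["alpha_cdr3_aa"]),
            beta_cdr3_aa=str(row["beta_cdr3_aa"]),
            alpha_v=str(row["alpha_v"]),
            alpha_j=str(row["alpha_j"]),
            beta_v=str(row["beta_v"]),
            beta_j=str(row["beta_j"]),
        )
        counts[key] = int(row["cell_count"])
    total = int(sum(counts.values()))
    return ClonotypeTable(
        sample_label=str(df["sample"].iloc[0]), counts=counts, total_cells=total
    )
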