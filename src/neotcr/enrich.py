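"""Clonotype enrichment ranking between unstimulated and restimulated samples.

Candidate antigen-specific TCRs are ranked by two metrics over the union
of clonotypes seen in either sample: fold change of clonotype frequency
from the unstimulated to the restimulated repertoire, and absolute
frequency in the restimulated repertoire.  Clonotypes matching previously
characterized TCRs are flagged and excluded from the candidate ranks (they
validate the enrichment; they are not new candidates).

Fold change uses additive smoothing so clonotypes absent before
stimulation remain rankable::

    FC = [(count_post + pc) / (total_post + pc)]
         / [(count_pre + pc) / (total_pre + pc)]

with pseudocount ``pc`` = 1 cell by default.  Reported frequencies are
raw (no pseudocount).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .vdj import ClonotypeKey, ClonotypeTable


@dataclass
class EnrichmentRecord:
    """Pre/post statistics and candidate ranks of one clonotype."""

    key: ClonotypeKey
    count_pre: int
    count_post: int
    freq_pre: float
    freq_post: float
    fold_change: float
    rank_fc: int | None = None
    rank_abs: int | None = None
    is_known: bool = False
    known_name: str | None = None


@dataclass
class CandidateRanking:
    """All enrichment records plus the selected candidate set."""

    records: list[EnrichmentRecord]
    selected: list[EnrichmentRecord]
    top_k: int
    excluded_known: list[str] = field(default_factory=list)


def compare_frequencies(
    pre: ClonotypeTable,
    post: ClonotypeTable,
    pseudocount: float = 1.0,
) -> list[EnrichmentRecord]:
    """Fold change of clonotype frequency over the union of both tables."""
    if pre.total_cells <= 0 or post.total_cells <= 0:
        raise ValueError("clonotype table with zero total cells")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    keys = list(pre.counts)
    seen = set(keys)
    keys += [k for k in post.counts if k not in seen]

    records = []
    for key in keys:
        c_pre = pre.counts.get(key, 0)
        c_post = post.counts.get(key, 0)
        fc = ((c_post + pseudocount) / (post.total_cells + pseudocount)) / (
            (c_pre + pseudocount) / (pre.total_cells + pseudocount)
        )
        records.append(
            EnrichmentRecord(
                key=key,
                count_pre=c_pre,
                count_post=c_post,
                freq_pre=c_pre / pre.total_cells,
                freq_post=c_post / post.total_cells,
                fold_change=fc,
            )
        )
    return records


def rank_candidates(
    records: Sequence[EnrichmentRecord],
    known: Mapping[str, Sequence[ClonotypeKey]] | None = None,
    top_k: int = 2,
) -> CandidateRanking:
    """Rank non-known clonotypes by fold change and by absolute frequency.

    ``known`` maps TCR names to the clonotype keys they matched (as
    produced by :func:`neotcr.vdj.match_known`); matching records are
    flagged ``is_known`` and excluded from the candidate ranks.  The
    candidate selection is the union of the top ``top_k`` records under
    each metric.  Ties break by descending post-stimulation count, then
    by canonical key string.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    known = known or {}
    key_to_name = {}
    for name, keys in known.items():
        for key in keys:
            key_to_name[key] = name
    for rec in records:
        rec.known_name = key_to_name.get(rec.key)
        rec.is_known = rec.known_name is not None
        rec.rank_fc = None
        rec.rank_abs = None

    candidates = [r for r in records if not r.is_known]
    by_fc = sorted(
        candidates,
        key=lambda r: (-r.fold_change, -r.count_post, r.key.canonical()),
    )
    by_abs = sorted(
        candidates,
        key=lambda r: (-r.freq_post, -r.count_post, r.key.canonical()),
    )
    for i, rec in enumerate(by_fc, start=1):
        rec.rank_fc = i
    for i, rec in enumerate(by_abs, start=1):
        rec.rank_abs = i

    selected_keys = {r.key for r in by_fc[:top_k]} | {r.key for r in by_abs[:top_k]}
    selected = sorted(
        (r for r in candidates if r.key in selected_keys),
        key=lambda r: (r.rank_fc, r.key.canonical()),
    )
    return CandidateRanking(
        records=list(records),
        selected=selected,
        top_k=top_k,
        excluded_known=sorted({r.known_name for r in records if r.is_known}),
    )


_REPORT_COLUMNS = [
    "alpha_cdr3_aa", "beta_cdr3_aa", "alpha_v", "alpha_j", "beta_v", "beta_j",
    "count_pre", "count_post", "freq_pre", "freq_post", "fold_change",
    "rank_fc", "rank_abs", "is_known", "known_name", "selected",
]


def ranking_to_frame(ranking: CandidateRanking) -> pd.DataFrame:
    selected_keys = {r.key for r in ranking.selected}
    ordered = sorted(
        ranking.records,
        key=lambda r: (
            r.is_known,  # candidates first, knowns after
            r.rank_fc if r.rank_fc is not None else 0,
            r.key.canonical(),
        ),
    )
    rows = []
    for r in ordered:
        rows.append({
            "alpha_cdr3_aa": r.key.alpha_cdr3_aa,
            "beta_cdr3_aa": r.key.beta_cdr3_aa,
            "alpha_v": r.key.alpha_v,
            "alpha_j": r.key.alpha_j,
            "beta_v": r.key.beta_v,
            "beta_j": r.key.beta_j,
            "count_pre": r.count_pre,
            "count_post": r.count_post,
            "freq_pre": r.freq_pre,
            "freq_post": r.freq_post,
            "fold_change": r.fold_change,
            "rank_fc": r.rank_fc,
            "rank_abs": r.rank_abs,
            "is_known": r.is_known,
            "known_name": r.known_name if r.known_name is not None else "",
            "selected": r.key in selected_keys,
        })
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def write_enrichment_report(ranking: CandidateRanking, path) -> None:
    """Write the full ranking as TSV in deterministic order."""
    ranking_to_frame(ranking).to_csv(path, sep="\t", index=False)


def read_enrichment_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       na_values={"rank_fc": [""], "rank_abs": [""]})
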