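"""Gene-overlap annotation and replication lookup.

Variants are annotated against transcript models with four ordered,
mutually exclusive categories per (variant, gene) pair: "within" the
transcript bounds, "upstream" (< 100 kb 5' of the transcript start),
"downstream" (< 40 kb 3' of the transcript end), and — only when the first
three are empty for a variant — the single "closest" gene by distance to
the nearest transcript edge.  Upstream/downstream are strand-aware by
default (5'/3' of the transcript); a plus-strand-literal mode is available.

Replication of previously reported associations applies Benjamini-Hochberg
FDR within the lookup set and counts SNPs with q below a cut-off (0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .association import bh_fdr

__all__ = [
    "GENE_MODEL_COLUMNS",
    "GeneAnnotation",
    "make_gene_models",
    "annotate_genes",
    "replication_lookup",
]

GENE_MODEL_COLUMNS = ["gene_id", "biotype", "chrom", "strand", "tx_start", "tx_end"]
BIOTYPES = {"protein-coding", "antisense", "lincRNA", "miRNA"}


@dataclass
class GeneAnnotation:
    """Gene context of one variant."""

    variant_id: str
    within: list[str] = field(default_factory=list)
    upstream: list[str] = field(default_factory=list)
    downstream: list[str] = field(default_factory=list)
    closest: str | None = None
    flag: str = ""

    @property
    def genes_all(self) -> list[str]:
        union = sorted(set(self.within) | set(self.upstream) | set(self.downstream))
        if union:
            return union
        return [self.closest] if self.closest else []


def make_gene_models(records: Sequence[dict] | pd.DataFrame) -> pd.DataFrame:
    """Validate a transcript-model table (1-based inclusive coordinates)."""
    df = pd.DataFrame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    missing = [c for c in GENE_MODEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene model table missing columns: {missing}")
    if (df["tx_start"] >= df["tx_end"]).any():
        raise ValueError("tx_start must be < tx_end")
    if not set(df["strand"]).issubset({"+", "-"}):
        raise ValueError("strand must be '+' or '-'")
    bad = set(df["biotype"]) - BIOTYPES
    if bad:
        raise ValueError(f"unknown biotypes: {sorted(bad)}")
    return df[GENE_MODEL_COLUMNS].reset_index(drop=True)


def annotate_genes(
    variant_id: str,
    chrom: str,
    pos: int,
    models: pd.DataFrame,
    up_bp: int = 100_000,
    down_bp: int = 40_000,
    strand_aware: bool = True,
) -> GeneAnnotation:
    """Annotate one variant position against transcript models.

    Distance cut-offs are strict ("< 100 kb", "< 40 kb").  Ties for the
    closest gene break toward the lower transcript start.
    """
    ann = GeneAnnotation(variant_id=variant_id)
    sub = models[models["chrom"] == chrom]
    if len(sub) == 0:
        ann.flag = "no-genes-on-chromosome"
        return ann

    starts = sub["tx_start"].to_numpy()
    ends = sub["tx_end"].to_numpy()
    plus = (sub["strand"] == "+").to_numpy() if strand_aware else np.ones(len(sub), bool)

    inside = (starts <= pos) & (pos <= ends)
    # distance 5' of the transcript start / 3' of the transcript end
    five_prime_gap = np.where(plus, starts - pos, pos - ends)
    three_prime_gap = np.where(plus, pos - ends, starts - pos)
    ups = (~inside) & (five_prime_gap > 0) & (five_prime_gap < up_bp)
    downs = (~inside) & (three_prime_gap > 0) & (three_prime_gap < down_bp)

    ids = sub["gene_id"].to_numpy()
    ann.within = list(ids[inside])
    ann.upstream = list(ids[ups & ~inside])
    ann.downstream = list(ids[downs & ~inside & ~ups])
    if not (ann.within or ann.upstream or ann.downstream):
        dist = np.where(inside, 0, np.minimum(np.abs(starts - pos), np.abs(ends - pos)))
        order = np.lexsort((starts, dist))
        ann.closest = str(ids[order[0]])
    return ann


def replication_lookup(
    lookup: pd.DataFrame,
    fdr_cut: float = 0.1,
    p_column: str = "p",
    q_column: str | None = None,
) -> tuple[pd.DataFrame, int, int]:
    """Replication of previously reported SNPs at FDR < ``fdr_cut``.

    By default BH-FDR is computed within the lookup set from ``p_column``;
    if ``q_column`` names a column of pre-computed FDR values those are
    used directly.  Returns (replicated rows with a ``q`` column,
    n_replicated, n_total).
    """
    df = lookup.copy()
    if q_column is not None:
        df["q"] = df[q_column].astype(float)
    else:
        df["q"] = bh_fdr(df[p_column].to_numpy(dtype=float))
    hits = df[df["q"] < fdr_cut].reset_index(drop=True)
    return hits, len(hits), len(df)
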