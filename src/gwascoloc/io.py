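"""Delimited-file readers and writers (gzip-transparent via pandas).

Formats: tab-delimited summary statistics with the fixed header
(chrom, pos, id, ea, oa, eaf, beta, se, z, p, n, stage); dosage matrices as
variants x samples tables alongside a variant metadata table; per-variant
signal tables mirroring supplementary-worksheet layouts; BED (0-based
half-open) exports of signal ranges; eQTL signal sets as JSON lines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .association import SUMSTATS_COLUMNS
from .eqtl_signals import EqtlSignal, EqtlSignalSet
from .signal_refine import AssociationSignal
from .synthetic import GenotypeMatrix

__all__ = [
    "read_summary_stats",
    "write_summary_stats",
    "write_genotypes",
    "read_genotypes",
    "write_phenotypes",
    "read_phenotypes",
    "write_signal_table",
    "signals_to_bed",
    "write_signal_sets_jsonl",
    "read_signal_sets_jsonl",
]


def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in SUMSTATS_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"summary-stats table missing columns: {missing}")
    stats[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str, "stage": str})
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_genotypes(G: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write <prefix>.dosages.tsv (variants x samples) and <prefix>.variants.tsv."""
    prefix = Path(prefix)
    dosage_path = prefix.with_suffix(".dosages.tsv")
    var_path = prefix.with_suffix(".variants.tsv")
    dos = pd.DataFrame(G.dosages.T, index=G.variants["id"], columns=G.sample_ids)
    dos.index.name = "id"
    dos.to_csv(dosage_path, sep="\t")
    G.variants.to_csv(var_path, sep="\t", index=False)
    return dosage_path, var_path


def read_genotypes(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    dos = pd.read_csv(prefix.with_suffix(".dosages.tsv"), sep="\t", index_col="id")
    variants = pd.read_csv(prefix.with_suffix(".variants.tsv"), sep="\t",
                           dtype={"chrom": str, "id": str})
    dosages = dos.loc[variants["id"]].to_numpy(dtype=np.int8).T
    return GenotypeMatrix(dosages, variants, list(dos.columns))


def write_phenotypes(phenotype: pd.Series, covariates: pd.DataFrame,
                     path: str | Path) -> None:
    table = covariates.copy()
    table.insert(0, phenotype.name or "phenotype", phenotype)
    table.to_csv(path, sep="\t")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_signal_table(signals: Iterable[AssociationSignal], path: str | Path) -> None:
    """Per-variant signal table (signal_id, rank, r2, d_prime, r2_equiv, rss ...)."""
    frames = []
    for k, sig in enumerate(signals):
        m = sig.members.copy()
        m.insert(0, "signal_id", k)
        m.insert(1, "top_id", sig.top_id)
        m["rank"] = m["rss"].rank(ascending=False, method="first").astype(int)
        frames.append(m)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    out.to_csv(path, sep="\t", index=False)


def signals_to_bed(signals: Iterable[AssociationSignal], path: str | Path) -> None:
    """Signal boundaries as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for sig in signals:
            chrom, start, end = sig.boundary
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{sig.top_id}\n")


def write_signal_sets_jsonl(sets: Iterable[EqtlSignalSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write(json.dumps({
                "gene_id": s.gene_id,
                "tissue": s.tissue,
                "signals": [
                    {"top_id": sig.top_id, "member_ids": sig.member_ids,
                     "rss": sig.rss}
                    for sig in s.signals
                ],
                "unassigned_ids": s.unassigned_ids,
            }) + "\n")


def read_signal_sets_jsonl(path: str | Path) -> list[EqtlSignalSet]:
    out = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            out.append(EqtlSignalSet(
                gene_id=rec["gene_id"],
                tissue=rec["tissue"],
                signals=[EqtlSignal(s["top_id"], s["member_ids"], s["rss"])
                         for s in rec["signals"]],
                unassigned_ids=rec["unassigned_ids"],
            ))
    return out
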