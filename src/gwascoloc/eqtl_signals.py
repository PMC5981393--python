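"""Greedy decomposition of a cis-eQTL region into independent signals.

A gene x tissue eQTL table is sorted by association strength; the strongest
unassigned SNP seeds a signal and every unassigned SNP with reference-panel
LD r^2 above a link threshold (default 0.05, the maximum across panels when
several are supplied) joins it — unless its relative signal strength is out
of proportion to its LD (RSS / r^2 above a ratio threshold), in which case
it is left unassigned and may seed a later signal.  Seeding stops when no
remaining SNP reaches a floor significance.

Helpers decide which signals are eligible for colocalization against a
refined GWAS signal, mask other signals' SNPs out of a region before
testing, and choose between fixed-effects beta/SE and RE2 p-value inputs
for the ABF step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_refine import AssociationSignal

__all__ = [
    "EqtlSignal",
    "EqtlSignalSet",
    "assign_eqtl_signals",
    "eligible_for_coloc",
    "mask_other_signals",
    "choose_input_stats",
]


@dataclass
class EqtlSignal:
    """One independent eQTL signal: a top SNP plus its assigned members."""

    top_id: str
    member_ids: list[str]
    rss: dict[str, float]  # per-member |z| ratio to the top SNP

    @property
    def rank_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.member_ids, "rss": [self.rss[v] for v in self.member_ids]}
        )


@dataclass
class EqtlSignalSet:
    """Disjoint SNP-to-signal assignment for one gene x tissue region."""

    gene_id: str
    tissue: str
    signals: list[EqtlSignal] = field(default_factory=list)
    unassigned_ids: list[str] = field(default_factory=list)

    @property
    def n_signals(self) -> int:
        return len(self.signals)

    def signal_of(self, variant_id: str) -> int | None:
        for k, sig in enumerate(self.signals):
            if variant_id in sig.member_ids:
                return k
        return None


def _order_by_strength(stats: pd.DataFrame) -> pd.DataFrame:
    df = stats.assign(_absz=stats["z"].abs())
    by = ["_absz", "pos"] if "pos" in df.columns else ["_absz", "id"]
    return df.sort_values(by, ascending=[False, True], kind="stable")


def assign_eqtl_signals(
    stats: pd.DataFrame,
    ld_r2: pd.DataFrame,
    gene_id: str = "",
    tissue: str = "single-tissue",
    link_r2: float = 0.05,
    ratio_threshold: float = 3.0,
    floor_p: float = 1e-4,
) -> EqtlSignalSet:
    """Greedy LD-based assignment of eQTL SNPs to independent signals.

    ``stats`` needs columns (id, z, p) and optionally pos (position breaks
    ties in seed order); ``ld_r2`` is the combined (max-across-panels)
    square r^2 matrix indexed by variant id.  Deterministic given inputs.
    """
    set_out = EqtlSignalSet(gene_id=gene_id, tissue=tissue)
    if len(stats) == 0:
        return set_out
    ordered = _order_by_strength(stats)
    unassigned = list(ordered["id"])
    zmap = dict(zip(stats["id"], stats["z"].abs()))
    pmap = dict(zip(stats["id"], stats["p"]))

    while unassigned:
        seed = unassigned[0]
        if pmap[seed] >= floor_p:
            break
        z_seed = zmap[seed]
        members = [seed]
        rss_map = {seed: 1.0}
        for vid in unassigned[1:]:
            r2 = float(ld_r2.loc[seed, vid])
            if not (r2 > link_r2):
                continue
            rel = zmap[vid] / z_seed if z_seed > 0 else 0.0
            if rel / r2 > ratio_threshold:
                continue  # signal too strong for its LD: leave unassigned
            members.append(vid)
            rss_map[vid] = rel
        set_out.signals.append(EqtlSignal(seed, members, rss_map))
        assigned = set(members)
        unassigned = [v for v in unassigned if v not in assigned]

    set_out.unassigned_ids = unassigned
    return set_out


def eligible_for_coloc(
    eqtl_signal: EqtlSignal,
    gwas_signal: AssociationSignal,
    rank_threshold: float = 0.7,
) -> bool:
    """Test an eQTL signal only if its highly ranked SNPs overlap the GWAS signal's.

    True iff some SNP has GWAS r2_equiv > ``rank_threshold`` and eQTL
    RSS > ``rank_threshold`` (both strict).
    """
    gwas = gwas_signal.members.set_index("id")
    for vid in eqtl_signal.member_ids:
        if vid not in gwas.index:
            continue
        if (
            float(gwas.loc[vid, "r2_equiv"]) > rank_threshold
            and eqtl_signal.rss[vid] > rank_threshold
        ):
            return True
    return False


def mask_other_signals(
    region_stats: pd.DataFrame,
    target: EqtlSignal,
    signal_set: EqtlSignalSet,
) -> pd.DataFrame:
    """Drop SNPs assigned to non-target signals; keep target and unassigned SNPs."""
    if target.top_id not in {s.top_id for s in signal_set.signals}:
        raise ValueError("target signal is not part of the signal set")
    other = set()
    for sig in signal_set.signals:
        if sig.top_id != target.top_id:
            other.update(sig.member_ids)
    other -= set(target.member_ids)
    return region_stats[~region_stats["id"].isin(other)].reset_index(drop=True)


def choose_input_stats(z_fe, z_re2, min_snps: int = 10) -> str:
    """Pick ABF inputs for a multi-tissue signal: 'fe' (beta/SE) or 're2' (p/MAF/n).

    FE beta and SE are used when |Z_FE| and |Z_RE2| are strongly positively
    correlated (Pearson r > 0.8, strict); otherwise the RE2 p-values are
    used.  With fewer than ``min_snps`` SNPs the correlation is unstable:
    warn and default to 'fe'.
    """
    a = np.abs(np.asarray(z_fe, dtype=float))
    b = np.abs(np.asarray(z_re2, dtype=float))
    if a.shape != b.shape:
        raise ValueError("z_fe and z_re2 must align")
    if a.size < min_snps:
        warnings.warn("fewer than %d SNPs; defaulting to FE beta/SE inputs" % min_snps)
        return "fe"
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("degenerate z columns; defaulting to FE beta/SE inputs")
        return "fe"
    r = float(np.corrcoef(a, b)[0, 1])
    return "fe" if r > 0.8 else "re2"
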