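"""GWAS signal clustering, conditional regression and ranking statistics.

Associated variants are grouped into positional clusters (single linkage
within a maximum gap, never across chromosomes).  Within a cluster the top
variant A is the smallest-p member, and every other variant B is refit with
A's dosage added as a covariate.  Two statistics rank candidate causal
variants relative to the top SNP:

* ``r2_equiv = (Z_B - Z_B|A) / Z_A`` on chi-square statistics — the
  fraction of the top signal recovered at B; under a single causal variant
  at A its expectation is the LD r^2 between A and B.
* ``RSS = |z_B| / |z_A|`` — relative signal strength on |z| scores.

A signal's boundary is the positional span of members with dosage
r^2 > 0.5 to the top SNP, and the high-LD candidate set is the members
with r2_equiv > 0.8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import ld as ldmod
from .association import single_variant_assoc

__all__ = [
    "AssociationSignal",
    "cluster_signals",
    "conditional_scan",
    "conditional_z_approx",
    "r2_equiv",
    "rss",
    "build_signal",
]


@dataclass
class AssociationSignal:
    """A refined GWAS signal around one top variant.

    ``members`` holds one row per clustered variant with columns
    (id, chrom, pos, p, z, chi2, chi2_cond, r2, d_prime, r2_equiv, rss).
    """

    top_id: str
    members: pd.DataFrame
    boundary: tuple[str, int, int] = ("", 0, 0)
    high_ld_ids: list[str] = field(default_factory=list)

    @property
    def member_ids(self) -> list[str]:
        return list(self.members["id"])


def cluster_signals(variants: pd.DataFrame, max_gap: int = 1_000_000) -> list[list[str]]:
    """Single-linkage positional clustering of significant variants.

    ``variants`` needs columns (chrom, pos, id).  Variants within
    ``max_gap`` bp of any cluster member join that cluster; chromosomes
    never merge.  Returns lists of variant ids, ordered by genome position.
    """
    if len(variants) == 0:
        return []
    df = variants.sort_values(["chrom", "pos"], kind="stable")
    clusters: list[list[str]] = []
    last_chrom, last_pos = None, None
    for _, row in df.iterrows():
        if (
            last_chrom != row["chrom"]
            or last_pos is None
            or row["pos"] - last_pos > max_gap
        ):
            clusters.append([])
        clusters[-1].append(row["id"])
        last_chrom, last_pos = row["chrom"], row["pos"]
    return clusters


def conditional_scan(
    G,
    phenotype,
    covariates,
    top_id: str,
    family: str = "linear",
    member_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Refit each variant with the top SNP's dosage added as a covariate.

    Returns a DataFrame (id, chi2, chi2_cond, flag).  The top SNP's own
    conditional statistic is 0 by definition; a variant collinear with the
    top SNP (|r| ~ 1) gets conditional statistic 0 with flag
    'collinear-with-top'.
    """
    ids = member_ids if member_ids is not None else list(G.variants["id"])
    x_top = G.column(top_id).astype(float)
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    else:
        C = np.empty((len(x_top), 0))
    C_cond = np.column_stack([C, x_top]) if C.size else x_top[:, None]

    rows = []
    for vid in ids:
        x = G.column(vid).astype(float)
        base = single_variant_assoc(x, phenotype, C if C.size else None, family=family)
        if vid == top_id:
            rows.append({"id": vid, "chi2": base["chi2"], "chi2_cond": 0.0, "flag": ""})
            continue
        r = np.corrcoef(x, x_top)[0, 1] if np.ptp(x) > 0 else 0.0
        if abs(r) > 1 - 1e-10:
            rows.append(
                {"id": vid, "chi2": base["chi2"], "chi2_cond": 0.0,
                 "flag": "collinear-with-top"}
            )
            continue
        cond = single_variant_assoc(x, phenotype, C_cond, family=family)
        rows.append(
            {"id": vid, "chi2": base["chi2"], "chi2_cond": cond["chi2"],
             "flag": cond.get("flag", "")}
        )
    return pd.DataFrame(rows)


def conditional_z_approx(z_b: float, z_a: float, r: float) -> float:
    """Summary-statistic approximation to the conditional z of B given A.

    ``r`` is the signed dosage correlation between B and A.  Exact in the
    limit of jointly Gaussian standardized dosages: z_B|A =
    (z_B - r z_A) / sqrt(1 - r^2).
    """
    if abs(r) >= 1:
        return 0.0
    return (z_b - r * z_a) / math.sqrt(1.0 - r * r)


def r2_equiv(z_a_chi2: float, z_b_chi2: float, z_b_given_a_chi2: float) -> float:
    """(Z_B - Z_B|A) / Z_A on chi-square statistics.

    May fall outside [0, 1] in finite samples; values are reported, not
    clipped.
    """
    if z_a_chi2 <= 0:
        raise ValueError("top-SNP chi-square must be positive")
    return (z_b_chi2 - z_b_given_a_chi2) / z_a_chi2


def rss(abs_z_b: float, abs_z_a: float) -> float:
    """Relative signal strength |z_B| / |z_A|."""
    if abs_z_a == 0:
        raise ValueError("top-SNP z must be non-zero")
    return abs(abs_z_b) / abs(abs_z_a)


def _pick_top(stats_df: pd.DataFrame) -> str:
    """Top variant: smallest p, ties by largest |z|, then lowest position."""
    df = stats_df.assign(_absz=stats_df["z"].abs())
    df = df.sort_values(["p", "_absz", "pos"], ascending=[True, False, True],
                        kind="stable")
    return df.iloc[0]["id"]


def build_signal(
    cluster_ids: list[str],
    stats_df: pd.DataFrame,
    conditional: pd.DataFrame,
    G,
    boundary_r2: float = 0.5,
    high_ld_r2_equiv: float = 0.8,
) -> AssociationSignal:
    """Assemble an AssociationSignal for one cluster.

    ``stats_df`` is a sumstats table covering the cluster; ``conditional``
    is the output of :func:`conditional_scan` for the cluster's top SNP.
    LD (r^2 and D') is computed from ``G``'s dosages.
    """
    if not cluster_ids:
        raise ValueError("cluster must be non-empty")
    sub = stats_df[stats_df["id"].isin(cluster_ids)].copy()
    top_id = _pick_top(sub)
    x_top = G.column(top_id).astype(float)
    cond = conditional.set_index("id")
    chi2_a = float(cond.loc[top_id, "chi2"])
    z_a = math.sqrt(chi2_a)

    rows = []
    for _, rec in sub.iterrows():
        vid = rec["id"]
        x = G.column(vid).astype(float)
        r2 = 1.0 if vid == top_id else ldmod.r2_dosage(x, x_top)
        dp = 1.0 if vid == top_id else ldmod.d_prime(x, x_top)
        chi2_b = float(cond.loc[vid, "chi2"])
        chi2_ba = float(cond.loc[vid, "chi2_cond"])
        r2e = 1.0 if vid == top_id else r2_equiv(chi2_a, chi2_b, chi2_ba)
        rss_b = 1.0 if vid == top_id else rss(math.sqrt(chi2_b), z_a)
        rows.append(
            {
                "id": vid, "chrom": rec["chrom"], "pos": rec["pos"],
                "p": rec["p"], "z": rec["z"], "chi2": chi2_b,
                "chi2_cond": chi2_ba, "r2": r2, "d_prime": dp,
                "r2_equiv": r2e, "rss": rss_b,
                "flag": "low-r2-equiv" if (vid != top_id and r2e < -0.05) else "",
            }
        )
    members = pd.DataFrame(rows).sort_values("pos", kind="stable").reset_index(drop=True)
    in_bound = members[members["r2"] > boundary_r2]
    chrom = str(members.iloc[0]["chrom"])
    boundary = (chrom, int(in_bound["pos"].min()), int(in_bound["pos"].max()))
    high = list(members.loc[members["r2_equiv"] > high_ld_r2_equiv, "id"])
    return AssociationSignal(top_id=top_id, members=members, boundary=boundary,
                             high_ld_ids=high)
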