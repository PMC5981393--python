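"""Colocalization of GWAS and eQTL signals: ABF, SMR, HEIDI, tiering.

The Bayesian test assumes at most one causal variant per trait in the
region.  Each SNP gets a Wakefield log approximate Bayes factor per trait,

    log ABF = 1/2 log(V / (V + W)) + Z^2 W / (2 (V + W)),   V = SE^2,

with prior effect variance W (0.15^2 for quantitative traits on an
sd-1 scale, 0.2^2 on the log-odds scale for case-control traits).
Summing ABF products over causal configurations gives posteriors for five
hypotheses: H0 no association, H1/H2 one trait only, H3 two distinct causal
variants, H4 one shared causal variant.

SMR tests the trait-expression link through a shared instrument,
T = z1^2 z2^2 / (z1^2 + z2^2) ~ chi-square(1); HEIDI asks whether Wald
ratios b_xy at SNPs linked to the top eQTL are homogeneous (pleiotropy)
or not (linkage of distinct causal variants), using an LD-aware
weighted-chi-square null computed by Ruben's chi-square series.

Decision tiers: PP_H4 > 0.3 nominal, > 0.5 moderate, > 0.9 strong;
P_SMR < 0.05 supports linkage/colocalization and, combined with
P_HEIDI >= 0.05, flags pleiotropy (also counted as strong support).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "ColocPriors",
    "ColocResult",
    "wakefield_abf",
    "abf_from_pvalue",
    "align_stats",
    "coloc_abf",
    "smr_test",
    "heidi_test",
    "weighted_chi2_sf",
    "classify",
]

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP causal priors and prior effect variances for the ABF test."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w_quant: float = 0.15**2
    w_cc: float = 0.2**2
    sdY_expression: float = 1.0

    def __post_init__(self):
        for p in (self.p1, self.p2, self.p12):
            if not (0.0 < p < 1.0):
                raise ValueError("priors must lie in (0, 1)")
        if self.p12 > min(self.p1, self.p2):
            warnings.warn("p12 exceeds min(p1, p2); check prior specification")

    def w_for(self, trait_kind: str) -> float:
        return self.w_cc if trait_kind == "cc" else self.w_quant


@dataclass
class ColocResult:
    """Posteriors, SMR/HEIDI p-values and the decision tier for one signal pair."""

    pp: dict = field(default_factory=dict)  # keys PP_H0..PP_H4
    p_smr: float = float("nan")
    p_heidi: float = float("nan")
    n_snps_heidi: int = 0
    tier: str = "none"
    pleiotropy: bool = False
    heidi_flag: str = ""


def wakefield_abf(beta, se, W: float):
    """Log approximate Bayes factor for association at one SNP.

    Accepts scalars or arrays; monotone increasing in |beta| at fixed se.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if W < 0:
        raise ValueError("prior variance must be non-negative")
    V = se**2
    z2 = (beta / se) ** 2
    lab = 0.5 * np.log(V / (V + W)) + z2 * W / (2.0 * (V + W))
    return lab if lab.ndim else float(lab)


def abf_from_pvalue(p, maf, n, trait_kind: str = "quant", W: float | None = None,
                    priors: ColocPriors = ColocPriors()):
    """Log ABF reconstructed from a p-value, MAF and sample size.

    z is recovered from the two-sided normal p-value and the sampling
    variance approximated as V = 1 / (2 n f (1-f)) — the variance of a
    regression slope on dosage for a trait with unit residual sd (sdY = 1).
    """
    p = np.asarray(p, dtype=float)
    maf = np.asarray(maf, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        tiny = np.nextafter(0, 1)
        if np.any(p <= 0):
            warnings.warn("p-values at the floating floor clipped")
        p = np.clip(p, tiny, 1.0)
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    if np.any(n <= 1):
        raise ValueError("n must exceed 1")
    z = stats.norm.isf(p / 2.0)
    V = 1.0 / (2.0 * n * maf * (1.0 - maf))
    if W is None:
        W = priors.w_for(trait_kind)
    se = np.sqrt(V)
    return wakefield_abf(z * se, se, W)


def align_stats(stats1: pd.DataFrame, stats2: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersect and allele-align two sumstats tables.

    Matches on id (falling back to chrom/pos when ids differ is the
    caller's concern); when the effect/other alleles are swapped the
    second table's beta and z flip sign and eaf reflects; strand-ambiguous
    mismatches (A/T, C/G) are dropped with a warning.
    """
    m = stats1.merge(stats2, on="id", suffixes=("_1", "_2"))
    keep, flip = [], []
    for i, row in m.iterrows():
        a1 = (row["ea_1"], row["oa_1"])
        a2 = (row["ea_2"], row["oa_2"])
        if a2 == a1:
            keep.append(i), flip.append(False)
        elif a2 == (a1[1], a1[0]):
            keep.append(i), flip.append(True)
        else:
            if a1 in AMBIGUOUS_PAIRS or a2 in AMBIGUOUS_PAIRS:
                warnings.warn(f"strand-ambiguous allele mismatch at {row['id']}; dropped")
            else:
                warnings.warn(f"allele mismatch at {row['id']}; dropped")
    m = m.loc[keep].reset_index(drop=True)
    flip = np.asarray(flip)
    out1 = pd.DataFrame(
        {c: m[f"{c}_1"] for c in ("chrom", "pos", "ea", "oa", "eaf", "beta", "se", "z", "p", "n")}
    )
    out1.insert(2, "id", m["id"])
    out2 = pd.DataFrame(
        {c: m[f"{c}_2"] for c in ("chrom", "pos", "ea", "oa", "eaf", "beta", "se", "z", "p", "n")}
    )
    out2.insert(2, "id", m["id"])
    if flip.size:
        out2.loc[flip, "beta"] *= -1
        out2.loc[flip, "z"] *= -1
        out2.loc[flip, "eaf"] = 1.0 - out2.loc[flip, "eaf"]
        out2.loc[flip, ["ea", "oa"]] = out1.loc[flip, ["ea", "oa"]].to_numpy()
    return out1, out2


def _log_abf_vector(stats_df: pd.DataFrame, trait_kind: str, mode: str,
                    priors: ColocPriors) -> np.ndarray:
    if mode == "beta_se":
        return np.asarray(
            wakefield_abf(stats_df["beta"].to_numpy(), stats_df["se"].to_numpy(),
                          priors.w_for(trait_kind))
        )
    if mode == "pvalue":
        return np.asarray(
            abf_from_pvalue(
                stats_df["p"].to_numpy(),
                np.minimum(stats_df["eaf"].to_numpy(), 1 - stats_df["eaf"].to_numpy()),
                stats_df["n"].to_numpy(),
                trait_kind=trait_kind, priors=priors,
            )
        )
    raise ValueError(f"unknown input mode {mode!r}")


def coloc_abf(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    priors: ColocPriors = ColocPriors(),
    trait1_kind: str = "quant",
    trait2_kind: str = "quant",
    mode1: str = "beta_se",
    mode2: str = "beta_se",
    align: bool = True,
) -> ColocResult:
    """Five-hypothesis colocalization posteriors from two sumstats tables.

    Tables are intersected/allele-aligned unless ``align=False`` (then they
    must already be row-aligned on the same SNPs).  ``mode*`` selects
    beta/SE or p-value(+MAF, n) ABF inputs per trait.
    """
    if align:
        s1, s2 = align_stats(stats1, stats2)
    else:
        s1, s2 = stats1.reset_index(drop=True), stats2.reset_index(drop=True)
    if len(s1) < 2:
        raise ValueError("need at least 2 shared SNPs for colocalization")
    l1 = _log_abf_vector(s1, trait1_kind, mode1, priors)
    l2 = _log_abf_vector(s2, trait2_kind, mode2, priors)

    lsum = l1 + l2
    lh1 = logsumexp(l1)
    lh2 = logsumexp(l2)
    lh4 = logsumexp(lsum)
    # sum over i != j of exp(l1_i + l2_j) = exp(lh1 + lh2) - exp(lh4-component)
    lh3_all = lh1 + lh2
    # guard against tiny negative mass from cancellation
    diff = 1.0 - math.exp(min(lh4 - lh3_all, 0.0))
    lh3 = lh3_all + math.log(diff) if diff > 0 else -math.inf

    logpost = np.array(
        [
            0.0,
            math.log(priors.p1) + lh1,
            math.log(priors.p2) + lh2,
            math.log(priors.p1) + math.log(priors.p2) + lh3,
            math.log(priors.p12) + lh4,
        ]
    )
    logpost -= logsumexp(logpost)
    pp = np.exp(logpost)
    pp /= pp.sum()
    return ColocResult(pp={f"PP_H{k}": float(pp[k]) for k in range(5)})


def smr_test(z_gwas: float, z_eqtl: float) -> tuple[float, float]:
    """SMR statistic and p-value from the two top-SNP z-scores.

    T = z1^2 z2^2 / (z1^2 + z2^2), chi-square with 1 df; symmetric in its
    arguments and bounded by min(z1^2, z2^2).
    """
    if not (np.isfinite(z_gwas) and np.isfinite(z_eqtl)):
        raise ValueError("z-scores must be finite")
    z1sq, z2sq = z_gwas**2, z_eqtl**2
    if z1sq + z2sq == 0:
        return 0.0, 1.0
    t = z1sq * z2sq / (z1sq + z2sq)
    return float(t), float(stats.chi2.sf(t, 1))


def weighted_chi2_sf(x: float, weights: np.ndarray, tol: float = 1e-9,
                     max_terms: int = 100_000) -> float:
    """P(sum_k w_k chi2_1 > x) by Ruben's chi-square series.

    The CDF of a positively weighted sum of 1-df chi-squares is expanded as
    sum_j a_j F_chi2(x / beta; n + 2j) with beta = 2 w_min w_max /
    (w_min + w_max); the non-negative coefficients a_j sum to 1, so the
    truncation error is bounded by the unaccumulated coefficient mass
    (series stopped below ``tol``, well inside 1e-6 absolute accuracy).
    Non-positive x returns 1; eigenvalues near zero are dropped.
    """
    w = np.asarray(weights, dtype=float)
    if w.size:
        w = w[w > 1e-10 * max(w.max(), 1.0)]
    if x <= 0 or w.size == 0:
        return 1.0
    n = w.size
    beta = 2.0 * w.min() * w.max() / (w.min() + w.max())
    r = 1.0 - beta / w  # in [0, 1)
    a = [float(np.prod(np.sqrt(beta / w)))]
    cdf = a[0] * stats.chi2.cdf(x / beta, n)
    mass = a[0]
    g: list[float] = []
    r_pow = np.ones_like(r)
    for k in range(1, max_terms):
        r_pow = r_pow * r
        g.append(float(np.sum(r_pow)))
        a_k = sum(g[j] * a[k - 1 - j] for j in range(k)) / (2.0 * k)
        a.append(a_k)
        cdf += a_k * stats.chi2.cdf(x / beta, n + 2 * k)
        mass += a_k
        if 1.0 - mass < tol:
            break
    return float(min(1.0, max(0.0, 1.0 - cdf)))


def heidi_test(
    top_id: str,
    snp_stats: pd.DataFrame,
    ld_r: pd.DataFrame,
    eqtl_p_max: float = 1.57e-3,
    r2_window: tuple[float, float] = (0.05, 0.9),
    max_snps: int = 20,
    min_snps: int = 3,
) -> tuple[float, int, str]:
    """HEIDI heterogeneity test around the top eQTL SNP.

    ``snp_stats`` needs columns (id, beta_gwas, se_gwas, beta_eqtl,
    se_eqtl, p_eqtl); ``ld_r`` is a signed correlation matrix over the
    SNPs.  Neighbors are usable when their eQTL p-value passes
    ``eqtl_p_max`` and their LD r^2 to the top SNP lies inside
    ``r2_window``; the strongest ``max_snps`` are kept.  Returns
    (p_heidi, n_snps_used, flag); with fewer than ``min_snps`` usable
    neighbors the flag is 'not-computed' and p is NaN — never silently
    significant.

    Per SNP i the Wald ratio is b_xy(i) = beta_gwas(i) / beta_eqtl(i);
    deviations d_i = b_xy(i) - b_xy(top) are standardized with a
    delta-method covariance built from the LD correlations, and
    sum_i z_d(i)^2 is referred to the eigenvalue-weighted chi-square null
    of the deviation correlation matrix.
    """
    df = snp_stats.set_index("id")
    if top_id not in df.index:
        raise KeyError(f"top SNP {top_id!r} missing from snp_stats")
    neighbors = []
    for vid in df.index:
        if vid == top_id:
            continue
        r = float(ld_r.loc[top_id, vid])
        if not (r2_window[0] < r * r < r2_window[1]):
            continue
        if df.loc[vid, "p_eqtl"] >= eqtl_p_max:
            continue
        neighbors.append(vid)
    if len(neighbors) > max_snps:
        neighbors = sorted(neighbors, key=lambda v: df.loc[v, "p_eqtl"])[:max_snps]
        neighbors = list(neighbors)
    if len(neighbors) < min_snps:
        return float("nan"), len(neighbors), "not-computed"

    ids = [top_id] + neighbors
    bg = df.loc[ids, "beta_gwas"].to_numpy(dtype=float)
    sg = df.loc[ids, "se_gwas"].to_numpy(dtype=float)
    be = df.loc[ids, "beta_eqtl"].to_numpy(dtype=float)
    se = df.loc[ids, "se_eqtl"].to_numpy(dtype=float)
    if np.any(be == 0):
        raise ValueError("eQTL effect of zero; Wald ratio undefined")
    R = ld_r.loc[ids, ids].to_numpy(dtype=float)

    bxy = bg / be
    # delta-method covariance of the Wald ratios
    cov_g = R * np.outer(sg, sg)
    cov_e = R * np.outer(se, se)
    denom = np.outer(be, be)
    cov_bxy = cov_g / denom + np.outer(bxy, bxy) * cov_e / denom

    k = len(neighbors)
    d = bxy[1:] - bxy[0]
    V = (
        cov_bxy[1:, 1:]
        - cov_bxy[1:, [0]]
        - cov_bxy[[0], 1:]
        + cov_bxy[0, 0]
    )
    sd = np.sqrt(np.diag(V))
    if np.any(sd <= 0):
        return float("nan"), k, "not-computed"
    zd = d / sd
    C = V / np.outer(sd, sd)
    statistic = float(np.sum(zd**2))
    eigvals = np.linalg.eigvalsh((C + C.T) / 2.0)
    p = weighted_chi2_sf(statistic, eigvals)
    return p, k, ""


def classify(result: ColocResult, pp_nominal: float = 0.3, pp_moderate: float = 0.5,
             pp_strong: float = 0.9, alpha_smr: float = 0.05,
             alpha_heidi: float = 0.05) -> ColocResult:
    """Assign the decision tier and pleiotropy flag in place (and return it).

    strong  : PP_H4 > 0.9 or (P_SMR < 0.05 and P_HEIDI >= 0.05)
    moderate: PP_H4 > 0.5
    nominal : PP_H4 > 0.3 or P_SMR < 0.05
    none    : otherwise.  A missing HEIDI p-value (NaN) makes the
    pleiotropy clause false.
    """
    pp_h4 = result.pp.get("PP_H4", 0.0)
    heidi_ok = np.isfinite(result.p_heidi) and result.p_heidi >= alpha_heidi
    smr_ok = np.isfinite(result.p_smr) and result.p_smr < alpha_smr
    result.pleiotropy = bool(smr_ok and heidi_ok)
    if pp_h4 > pp_strong or result.pleiotropy:
        result.tier = "strong"
    elif pp_h4 > pp_moderate:
        result.tier = "moderate"
    elif pp_h4 > pp_nominal or smr_ok:
        result.tier = "nominal"
    else:
        result.tier = "none"
    return result
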