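"""Variant QC, per-variant association, meta-analysis and thresholds.

Association tests are additive-dosage Wald regressions (linear or
logistic).  Two study stages are combined by inverse-variance-weighted
fixed-effects meta-analysis; a variant genotyped in only one stage passes
through unchanged.  Genome-wide multiple testing uses an effective test
count M_E (nominal cut-off alpha / M_E, further divided by the number of
phenotypes for the strong cut-off), genomic control is monitored through
lambda_GC, and replication lookups use Benjamini-Hochberg FDR within the
lookup set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "QcThresholds",
    "ThresholdConfig",
    "SUMSTATS_COLUMNS",
    "variant_qc",
    "hwe_exact_test",
    "single_variant_assoc",
    "gwas_scan",
    "meta_fixed_effects",
    "lambda_gc",
    "significance_thresholds",
    "bh_fdr",
]

#: Fixed header for summary-statistic tables.
SUMSTATS_COLUMNS = [
    "chrom", "pos", "id", "ea", "oa", "eaf", "beta", "se", "z", "p", "n", "stage",
]

#: Median of the chi-square(1) distribution.
CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)


@dataclass(frozen=True)
class QcThresholds:
    """Per-variant QC filters, applied in both study stages."""

    min_call_rate: float = 0.99
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6
    min_concordance: float = 0.90

    def __post_init__(self):
        for f in (self.min_call_rate, self.min_maf, self.min_hwe_p, self.min_concordance):
            if not (0.0 <= f <= 1.0):
                raise ValueError("QC thresholds must lie in [0, 1]")


@dataclass(frozen=True)
class ThresholdConfig:
    """Significance-threshold inputs: alpha, effective test count, phenotype count."""

    alpha: float = 0.05
    m_effective: float = 411_521.0
    n_phenotypes: int = 22

    def __post_init__(self):
        if self.alpha <= 0 or self.m_effective <= 0 or self.n_phenotypes <= 0:
            raise ValueError("threshold inputs must be positive")


def variant_qc(
    stage_summaries: Mapping[str, pd.DataFrame],
    concordance: Mapping[str, float] | pd.Series,
    thresholds: QcThresholds = QcThresholds(),
) -> pd.DataFrame:
    """Apply the four QC filters; a variant must pass in every stage.

    ``stage_summaries`` maps stage label -> DataFrame with columns
    (id, call_rate, maf, hwe_p); ``concordance`` maps variant id -> the
    cross-stage duplicate-sample concordance rate.  Returns a DataFrame
    with columns (id, passed, reasons) where ``reasons`` is a
    comma-joined list of reason codes such as ``maf:LL01`` or
    ``missing-stage:LL02``.
    """
    if not stage_summaries:
        raise ValueError("need at least one stage summary")
    conc = pd.Series(dict(concordance)) if not isinstance(concordance, pd.Series) else concordance
    all_ids: list[str] = []
    seen = set()
    for df in stage_summaries.values():
        for vid in df["id"]:
            if vid not in seen:
                seen.add(vid)
                all_ids.append(vid)
    indexed = {stage: df.set_index("id") for stage, df in stage_summaries.items()}

    rows = []
    for vid in all_ids:
        reasons: list[str] = []
        for stage, df in indexed.items():
            if vid not in df.index:
                reasons.append(f"missing-stage:{stage}")
                continue
            rec = df.loc[vid]
            if rec["call_rate"] < thresholds.min_call_rate:
                reasons.append(f"call_rate:{stage}")
            maf = min(rec["maf"], 1.0 - rec["maf"])
            if maf < thresholds.min_maf:
                reasons.append(f"maf:{stage}")
            if rec["hwe_p"] < thresholds.min_hwe_p:
                reasons.append(f"hwe:{stage}")
        c = conc.get(vid, np.nan)
        if not (c > thresholds.min_concordance):  # NaN fails too
            reasons.append("concordance")
        rows.append({"id": vid, "passed": not reasons, "reasons": ",".join(reasons)})
    return pd.DataFrame(rows)


def hwe_exact_test(n_aa_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts that are no more probable than the observed
    one.  Monomorphic input returns 1.
    """
    n_AA, n_Aa, n_aa = int(n_aa_hom_major), int(n_het), int(n_hom_minor)
    if min(n_AA, n_Aa, n_aa) < 0 or (n_AA + n_Aa + n_aa) == 0:
        raise ValueError("genotype counts must be non-negative with positive total")
    n = n_AA + n_Aa + n_aa
    n_minor = 2 * n_aa + n_Aa
    n_minor = min(n_minor, 2 * n - n_minor)
    if n_minor == 0:
        return 1.0

    # log P(het = h | allele counts) up to a shared constant
    def logprob(h: int) -> float:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        return (
            h * math.log(2.0)
            - math.lgamma(h + 1)
            - math.lgamma(hom_minor + 1)
            - math.lgamma(hom_major + 1)
        )

    hets = range(n_minor % 2, n_minor + 1, 2)
    logps = np.array([logprob(h) for h in hets])
    logps -= logps.max()
    probs = np.exp(logps)
    probs /= probs.sum()
    obs = (n_Aa - n_minor % 2) // 2
    p_obs = probs[obs]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _design(x: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    n = x.shape[0]
    cols = [np.ones(n), x]
    if covariates is not None and covariates.size:
        cols.append(covariates)
    return np.column_stack(cols)


def single_variant_assoc(
    dosage: Sequence[float],
    phenotype: Sequence[float],
    covariates: np.ndarray | pd.DataFrame | None = None,
    family: str = "linear",
) -> dict:
    """Additive Wald regression of a phenotype on one variant's dosage.

    Returns a dict with beta, se, z, chi2, p, n, eaf and a ``flag`` field
    ('' normally, 'separation' when a logistic fit separates perfectly).
    """
    x = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage and phenotype must align")
    if np.ptp(x) == 0:
        raise ValueError("variant is constant; association undefined")
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    X = _design(x, C)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more samples than parameters")

    flag = ""
    if family == "linear":
        beta_hat, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_hat
        dof = n - rank
        sigma2 = resid @ resid / dof if dof > 0 else 0.0
        xtx_inv = np.linalg.pinv(X.T @ X)
        se = math.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0))
        beta = float(beta_hat[1])
    elif family == "logistic":
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            except Exception:
                return {
                    "beta": np.nan, "se": np.nan, "z": np.nan, "chi2": np.nan,
                    "p": np.nan, "n": n, "eaf": float(x.mean() / 2.0),
                    "flag": "separation",
                }
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        if not np.isfinite(se) or se > 50 or abs(beta) > 20:
            flag = "separation"
    else:
        raise ValueError(f"unknown family {family!r}")

    if se == 0:
        z = math.inf if beta != 0 else 0.0
        pval = 0.0 if beta != 0 else 1.0
    else:
        z = beta / se
        pval = 2.0 * stats.norm.sf(abs(z))
    return {
        "beta": beta, "se": se, "z": z, "chi2": z * z, "p": pval,
        "n": n, "eaf": float(x.mean() / 2.0), "flag": flag,
    }


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Project columns of M off the column space of [1, C]."""
    Q, _ = np.linalg.qr(C)
    return M - Q @ (Q.T @ M)


def gwas_scan(
    G,
    phenotype: Sequence[float],
    covariates: np.ndarray | pd.DataFrame | None = None,
    family: str = "linear",
    stage: str = "LL01",
) -> pd.DataFrame:
    """Per-variant association scan, returned in the fixed sumstats layout.

    Linear scans use Frisch-Waugh residualization (exactly equivalent to
    per-variant multiple regression, including degrees of freedom);
    logistic scans loop over variants.  Monomorphic variants yield NaN
    rows.
    """
    y = np.asarray(phenotype, dtype=float)
    D = G.dosages.astype(float)
    n, m = D.shape
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        base = np.column_stack([np.ones(n), C])
    else:
        base = np.ones((n, 1))
    k = base.shape[1]

    if family == "linear":
        Dr = _residualize(D, base)
        yr = _residualize(y[:, None], base)[:, 0]
        sxx = (Dr * Dr).sum(axis=0)
        sxy = Dr.T @ yr
        ok = sxx > 1e-12
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        beta[ok] = sxy[ok] / sxx[ok]
        dof = n - k - 1
        rss = (yr @ yr) - beta[ok] ** 2 * sxx[ok]
        sigma2 = np.maximum(rss, 0.0) / dof
        se[ok] = np.sqrt(sigma2 / sxx[ok])
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))
    elif family == "logistic":
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        for j in range(m):
            if np.ptp(D[:, j]) == 0:
                continue
            row = single_variant_assoc(D[:, j], y, covariates, family="logistic")
            beta[j], se[j] = row["beta"], row["se"]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))
    else:
        raise ValueError(f"unknown family {family!r}")

    out = G.variants[["chrom", "pos", "id"]].copy()
    out["ea"] = G.variants["alt"]
    out["oa"] = G.variants["ref"]
    out["eaf"] = D.mean(axis=0) / 2.0
    out["beta"] = beta
    out["se"] = se
    out["z"] = z
    out["p"] = pvals
    out["n"] = n
    out["stage"] = stage
    return out[SUMSTATS_COLUMNS]


def _align_alleles(row_ref: pd.Series, row_other: pd.Series) -> float | None:
    """Return the sign to apply to row_other's beta, or None if unresolvable."""
    if (row_other["ea"], row_other["oa"]) == (row_ref["ea"], row_ref["oa"]):
        return 1.0
    if (row_other["ea"], row_other["oa"]) == (row_ref["oa"], row_ref["ea"]):
        return -1.0
    return None


def meta_fixed_effects(stage_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance-weighted fixed-effects meta-analysis across stages.

    Tables are merged on variant id; effect alleles are aligned to the
    first stage carrying the variant (a swapped allele pair flips the beta
    sign), variants with irreconcilable alleles are dropped with a
    warning, and variants present in a single stage pass through.
    """
    tables = [t for t in stage_tables if t is not None and len(t)]
    if not tables:
        raise ValueError("no stage tables supplied")
    by_id: dict[str, list[pd.Series]] = {}
    order: list[str] = []
    for t in tables:
        for _, row in t.iterrows():
            vid = row["id"]
            if vid not in by_id:
                by_id[vid] = []
                order.append(vid)
            by_id[vid].append(row)

    rows = []
    for vid in order:
        recs = by_id[vid]
        ref = recs[0]
        betas, ses, ns = [], [], []
        dropped = False
        for rec in recs:
            sign = _align_alleles(ref, rec)
            if sign is None:
                warnings.warn(f"variant {vid}: unresolvable allele mismatch; dropped")
                dropped = True
                break
            if np.isfinite(rec["beta"]) and np.isfinite(rec["se"]) and rec["se"] > 0:
                betas.append(sign * rec["beta"])
                ses.append(rec["se"])
                ns.append(rec["n"])
        if dropped or not betas:
            continue
        w = 1.0 / np.square(ses)
        beta_meta = float(np.dot(w, betas) / w.sum())
        se_meta = float(math.sqrt(1.0 / w.sum()))
        z = beta_meta / se_meta
        rows.append(
            {
                "chrom": ref["chrom"], "pos": ref["pos"], "id": vid,
                "ea": ref["ea"], "oa": ref["oa"], "eaf": ref["eaf"],
                "beta": beta_meta, "se": se_meta, "z": z,
                "p": 2.0 * stats.norm.sf(abs(z)), "n": int(np.sum(ns)),
                "stage": "META",
            }
        )
    return pd.DataFrame(rows, columns=SUMSTATS_COLUMNS)


def lambda_gc(pvalues: Sequence[float]) -> float:
    """Genomic-control inflation factor from a vector of p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size < 100:
        raise ValueError("lambda_gc needs at least 100 p-values")
    if (p <= 0).any():
        warnings.warn("p-values of 0 clipped for lambda_gc")
        p = np.clip(p, 1e-300, 1.0)
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def significance_thresholds(config: ThresholdConfig) -> tuple[float, float]:
    """(nominal, strong) genome-wide cut-offs: alpha/M_E and alpha/M_E/n_phenotypes."""
    nominal = config.alpha / config.m_effective
    return nominal, nominal / config.n_phenotypes


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    return multipletests(p, method="fdr_bh")[1]
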