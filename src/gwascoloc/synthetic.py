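"""Synthetic genotype, phenotype and expression simulators.

Genotypes follow a block-LD model: within each block the two haplotypes of
every individual are latent AR(rho) Gaussian processes thresholded at the
per-variant MAF quantile, so dosages are Hardy-Weinberg distributed and
adjacent variants within a block are correlated while blocks are
independent.  Phenotypes are built on a latent liability that sums genetic
effects at causal variants, an optional confounder (e.g. BMI), and Gaussian
noise scaled so the genetic variance fraction equals ``heritability_like``;
the liability is then observed directly (quantitative), dichotomised at a
prevalence quantile (binary), or cut into ordered levels (ordinal5 pain
scale, 8-level bust scale).  Expression traits are standardized to mean 0 /
sd 1, matching the convention of eQTL analyses run on inverse-normalised
expression.

All randomness flows from one explicit integer seed; the same seed gives
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LdBlockSpec",
    "TraitSpec",
    "ExpressionSpec",
    "GenotypeMatrix",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_expression",
]

# Default ordinal cut points (cumulative level probabilities).  ordinal5
# emulates a right-heavy menstrual-pain distribution (most respondents
# report at least some pain); bust8 emulates a bra-size distribution
# concentrated on the A-D codes.
ORDINAL5_CUMPROBS = (0.15, 0.35, 0.55, 0.80)
BUST8_CUMPROBS = (0.04, 0.22, 0.52, 0.76, 0.89, 0.95, 0.98)


@dataclass(frozen=True)
class LdBlockSpec:
    """Block-LD layout of a simulated variant panel.

    ``block_sizes`` are the variant counts of consecutive independent LD
    blocks; ``rho`` is the latent adjacent-variant correlation within a
    block; ``maf_range`` bounds the per-variant minor-allele frequencies
    (drawn uniformly).
    """

    block_sizes: tuple[int, ...]
    maf_range: tuple[float, float] = (0.05, 0.5)
    rho: float = 0.8

    def __post_init__(self):
        object.__setattr__(self, "block_sizes", tuple(int(b) for b in self.block_sizes))
        if not self.block_sizes or any(b < 1 for b in self.block_sizes):
            raise ValueError("block_sizes must be non-empty positive counts")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")

    @property
    def n_variants(self) -> int:
        return int(sum(self.block_sizes))


@dataclass(frozen=True)
class TraitSpec:
    """Architecture of a simulated trait on the latent-liability scale."""

    kind: str  # quantitative | binary | ordinal5 | bust8
    causal_ids: tuple[str, ...] = ()
    effect_sizes: tuple[float, ...] = ()
    heritability_like: float = 0.0
    confounder: tuple[str, float] | None = None  # (covariate name, effect)
    prevalence: float = 0.1  # binary traits only
    ordinal_cumprobs: tuple[float, ...] | None = None

    KINDS = ("quantitative", "binary", "ordinal5", "bust8")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if len(self.causal_ids) != len(self.effect_sizes):
            raise ValueError("causal_ids and effect_sizes must align")
        if not (0.0 <= self.heritability_like < 1.0):
            raise ValueError("heritability_like must be in [0, 1)")
        if self.kind == "binary" and not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")

    def cumprobs(self) -> tuple[float, ...]:
        if self.ordinal_cumprobs is not None:
            return self.ordinal_cumprobs
        return ORDINAL5_CUMPROBS if self.kind == "ordinal5" else BUST8_CUMPROBS


@dataclass(frozen=True)
class ExpressionSpec:
    """cis-eQTL architecture for one gene.

    ``causal_groups`` lists one tuple of causal variant ids per independent
    eQTL signal; ``n_signals`` is implied by its length.  When
    ``shared_with_gwas`` is set the first causal variant is (by convention
    of the caller) the GWAS causal variant.
    """

    gene_id: str
    causal_groups: tuple[tuple[str, ...], ...]
    effect_sizes: tuple[tuple[float, ...], ...] | None = None
    shared_with_gwas: bool = False
    noise_sd: float = 1.0

    def __post_init__(self):
        if not self.causal_groups or any(not g for g in self.causal_groups):
            raise ValueError("causal_groups must be non-empty groups of variant ids")
        if self.effect_sizes is not None and tuple(
            len(g) for g in self.effect_sizes
        ) != tuple(len(g) for g in self.causal_groups):
            raise ValueError("effect_sizes must mirror causal_groups")

    @property
    def n_signals(self) -> int:
        return len(self.causal_groups)

    @property
    def causal_ids(self) -> tuple[str, ...]:
        return tuple(v for g in self.causal_groups for v in g)

    def flat_effects(self) -> tuple[float, ...]:
        if self.effect_sizes is None:
            return tuple(0.6 for _ in self.causal_ids)
        return tuple(e for g in self.effect_sizes for e in g)


@dataclass
class GenotypeMatrix:
    """Dosage matrix (samples x variants) with per-variant metadata.

    ``variants`` has columns chrom, pos, id, ref, alt, eaf where ``eaf`` is
    the effect (alt) allele frequency used in simulation.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant metadata does not match dosage columns")
        if not self.sample_ids:
            self.sample_ids = [f"S{i:06d}" for i in range(self.dosages.shape[0])]
        self._col = {v: j for j, v in enumerate(self.variants["id"])}

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        try:
            return self.dosages[:, self._col[variant_id]]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in panel") from None

    def columns(self, variant_ids: Sequence[str]) -> np.ndarray:
        return np.column_stack([self.column(v) for v in variant_ids])

    def empirical_eaf(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[index],
            self.variants.copy(),
            [self.sample_ids[i] for i in np.asarray(index)],
        )


def _latent_rho(maf: float, target_rho: float) -> float:
    """Latent Gaussian correlation whose thresholded 0/1 alleles correlate at
    ``target_rho`` (inverts the dichotomization attenuation; equal MAFs)."""
    if target_rho <= 0:
        return 0.0
    cut = stats.norm.ppf(maf)

    def phi(rho_lat: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [cut, cut], mean=[0, 0], cov=[[1, rho_lat], [rho_lat, 1]]
        )
        return (p11 - maf * maf) / (maf * (1 - maf))

    from scipy.optimize import brentq

    hi = 1 - 1e-9
    if phi(hi) <= target_rho:
        return hi
    return float(brentq(lambda r: phi(r) - target_rho, 0.0, hi, xtol=1e-6))


def _simulate_haplotypes(
    n_haplotypes: int, spec: LdBlockSpec, mafs: np.ndarray,
    latent_rhos: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """0/1 haplotype alleles with AR latent correlation per block."""
    out = np.empty((n_haplotypes, spec.n_variants), dtype=np.int8)
    start = 0
    for b, size in enumerate(spec.block_sizes):
        rho_lat = latent_rhos[b]
        z = np.empty((n_haplotypes, size))
        eps = rng.standard_normal((n_haplotypes, size))
        z[:, 0] = eps[:, 0]
        scale = np.sqrt(1.0 - rho_lat**2)
        for k in range(1, size):
            z[:, k] = rho_lat * z[:, k - 1] + scale * eps[:, k]
        cut = stats.norm.ppf(mafs[start : start + size])
        out[:, start : start + size] = (z < cut[None, :]).astype(np.int8)
        start += size
    return out


def simulate_genotypes(
    n_samples: int,
    spec: LdBlockSpec,
    seed: int,
    *,
    chrom: str = "1",
    start_pos: int = 1_000_000,
    spacing: int = 5_000,
    id_prefix: str = "var",
    return_haplotypes: bool = False,
):
    """Simulate a dosage matrix under the block-LD haplotype model.

    Variants are laid out on one chromosome at fixed ``spacing``; each
    individual's dosage is the sum of two independent haplotypes so that
    genotypes are in Hardy-Weinberg proportions at the drawn MAF.  One MAF
    is drawn per block (shared by its variants) and the latent AR
    correlation is calibrated so that adjacent alleles correlate at
    ``spec.rho`` on the observed scale.
    """
    if n_samples < 2:
        raise ValueError("need n_samples >= 2")
    rng = np.random.default_rng(seed)
    m = spec.n_variants
    block_mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1],
                             size=len(spec.block_sizes))
    mafs = np.repeat(block_mafs, spec.block_sizes)
    latent_rhos = np.array([_latent_rho(f, spec.rho) for f in block_mafs])
    h1 = _simulate_haplotypes(n_samples, spec, mafs, latent_rhos, rng)
    h2 = _simulate_haplotypes(n_samples, spec, mafs, latent_rhos, rng)
    dosages = (h1 + h2).astype(np.int8)
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start_pos + spacing * np.arange(m),
            "id": [f"{id_prefix}{i}" for i in range(m)],
            "ref": "A",
            "alt": "G",
            "eaf": mafs,
        }
    )
    G = GenotypeMatrix(dosages, variants)
    if return_haplotypes:
        return G, np.vstack([h1, h2])
    return G


def _latent_liability(
    G: GenotypeMatrix,
    spec: TraitSpec,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    n = G.n_samples
    g = np.zeros(n)
    for vid, beta in zip(spec.causal_ids, spec.effect_sizes):
        x = G.column(vid).astype(float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"causal variant {vid!r} is monomorphic in this draw")
        g += beta * (x - x.mean()) / sd
    var_g = g.var()
    if var_g > 0 and spec.heritability_like > 0:
        noise_sd = np.sqrt(var_g * (1.0 - spec.heritability_like) / spec.heritability_like)
    else:
        noise_sd = 1.0
    latent = g + noise_sd * rng.standard_normal(n)
    if spec.confounder is not None:
        name, effect = spec.confounder
        c = covariates[name].to_numpy(dtype=float)
        latent = latent + effect * (c - c.mean()) / c.std()
    return latent


def _default_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Age/BMI/PC covariates for a cohort of adult women."""
    age = np.clip(rng.normal(35.0, 8.0, size=n), 18.0, 55.0)
    bmi = np.clip(rng.normal(21.0, 3.0, size=n), 14.0, 40.0)
    return pd.DataFrame(
        {
            "Age": age,
            "BMI": bmi,
            "PC1": rng.standard_normal(n),
            "PC2": rng.standard_normal(n),
        }
    )


def simulate_phenotype(
    G: GenotypeMatrix, spec: TraitSpec, seed: int
) -> tuple[pd.Series, pd.DataFrame]:
    """Simulate one phenotype plus an Age/BMI/PC covariate table.

    Returns ``(phenotype, covariates)`` aligned to ``G``'s samples.
    Quantitative traits are the latent liability itself; binary traits cut
    it at the (1 - prevalence) quantile; ordinal traits cut it at the
    spec's cumulative level probabilities (ordinal5 -> levels 1..5, bust8
    -> codes 0..7).
    """
    missing = [v for v in spec.causal_ids if v not in set(G.variants["id"])]
    if missing:
        raise KeyError(f"causal variants absent from genotype panel: {missing}")
    rng = np.random.default_rng(seed)
    cov = _default_covariates(G.n_samples, rng)
    cov.index = pd.Index(G.sample_ids, name="sample_id")
    latent = _latent_liability(G, spec, cov, rng)

    if spec.kind == "quantitative":
        y = latent
    elif spec.kind == "binary":
        y = (latent > np.quantile(latent, 1.0 - spec.prevalence)).astype(int)
    else:
        cuts = np.quantile(latent, spec.cumprobs())
        levels = np.searchsorted(cuts, latent, side="left")
        y = levels + 1 if spec.kind == "ordinal5" else levels
    return pd.Series(y, index=cov.index, name="phenotype"), cov


def simulate_expression(
    G: GenotypeMatrix, spec: ExpressionSpec, seed: int
) -> pd.Series:
    """Simulate a standardized (mean 0, sd 1) cis expression trait."""
    ids = set(G.variants["id"])
    missing = [v for v in spec.causal_ids if v not in ids]
    if missing:
        raise KeyError(f"causal variants absent from genotype panel: {missing}")
    rng = np.random.default_rng(seed)
    n = G.n_samples
    expr = spec.noise_sd * rng.standard_normal(n)
    for vid, beta in zip(spec.causal_ids, spec.flat_effects()):
        x = G.column(vid).astype(float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"causal variant {vid!r} is monomorphic in this draw")
        expr += beta * (x - x.mean()) / sd
    expr = (expr - expr.mean()) / expr.std()
    return pd.Series(expr, index=pd.Index(G.sample_ids, name="sample_id"),
                     name=spec.gene_id)
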