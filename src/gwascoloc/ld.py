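"""Linkage-disequilibrium measures on dosage data.

r^2 is the squared Pearson correlation of dosages (the composite measure
used in practice on unphased data).  D' is haplotype-based: two-locus
haplotype frequencies are estimated from dosage pairs by an EM algorithm
that resolves the double-heterozygote phase ambiguity, and D is normalised
by its frequency-constrained maximum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["r2_dosage", "d_prime", "ld_matrix", "combine_ld_panels"]


def r2_dosage(x: np.ndarray, y: np.ndarray) -> float:
    """Squared correlation of two dosage vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _em_haplotype_freqs(x: np.ndarray, y: np.ndarray, tol: float = 1e-10,
                        max_iter: int = 200) -> np.ndarray:
    """EM estimate of the four two-locus haplotype frequencies (pAB, pAb, paB, pab).

    Alleles: 'A'/'B' denote the alt allele at each locus (dosage counts).
    Only the double-heterozygote genotype is phase-ambiguous.
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    counts = np.zeros((3, 3))
    for gx, gy in zip(x, y):
        counts[gx, gy] += 1
    n_hap = 2.0 * counts.sum()

    pA = (2 * counts[2, :].sum() + counts[1, :].sum()) / n_hap
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / n_hap
    # start at linkage equilibrium
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()

    # unambiguous haplotype contributions per genotype cell (AB, Ab, aB, ab)
    fixed = np.zeros(4)
    cell_haps = {
        (0, 0): (0, 0, 0, 2), (0, 1): (0, 0, 1, 1), (0, 2): (0, 0, 2, 0),
        (1, 0): (0, 1, 0, 1), (1, 2): (1, 0, 1, 0),
        (2, 0): (0, 2, 0, 0), (2, 1): (1, 1, 0, 0), (2, 2): (2, 0, 0, 0),
    }
    for cell, haps in cell_haps.items():
        fixed += counts[cell] * np.array(haps)
    n_dhet = counts[1, 1]

    for _ in range(max_iter):
        # P(phase = AB/ab) within double heterozygotes
        num = f[0] * f[3]
        den = f[0] * f[3] + f[1] * f[2]
        w = num / den if den > 0 else 0.5
        new = fixed + n_dhet * np.array([w, 1 - w, 1 - w, w])
        new /= n_hap
        if np.abs(new - f).max() < tol:
            f = new
            break
        f = new
    return f


def d_prime(x: np.ndarray, y: np.ndarray) -> float:
    """Normalised disequilibrium |D'| from EM-phased dosage pairs."""
    f = _em_haplotype_freqs(x, y)
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return float("nan")
    D = f[0] - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax == 0:
        return float("nan")
    return float(min(1.0, abs(D) / dmax))


def ld_matrix(G, ids=None, signed: bool = False) -> pd.DataFrame:
    """Pairwise dosage r^2 (or signed r) matrix over the panel.

    ``G`` is a GenotypeMatrix; ``ids`` optionally restricts and orders the
    variants.
    """
    if ids is None:
        ids = list(G.variants["id"])
    D = G.columns(ids).astype(float)
    sd = D.std(axis=0)
    if (sd == 0).any():
        D = D + 1e-9 * np.random.default_rng(0).standard_normal(D.shape)
    R = np.corrcoef(D, rowvar=False)
    if not signed:
        R = R * R
    return pd.DataFrame(R, index=ids, columns=ids)


def combine_ld_panels(*panels: pd.DataFrame) -> pd.DataFrame:
    """Element-wise maximum r^2 across reference panels (e.g. EUR and AFR).

    With a single panel the combined matrix is that panel itself.
    """
    if not panels:
        raise ValueError("need at least one LD panel")
    combined = panels[0].copy()
    for p in panels[1:]:
        if not combined.index.equals(p.index) or not combined.columns.equals(p.columns):
            raise ValueError("LD panels must share variant sets and order")
        combined = pd.DataFrame(
            np.maximum(combined.to_numpy(), p.to_numpy()),
            index=combined.index, columns=combined.columns,
        )
    return combined
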