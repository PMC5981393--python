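"""Reference inputs of the two-stage cohort design the pipeline models.

A two-stage GWAS of Japanese women's-health phenotypes (stages labelled
LL01 and LL02, roughly 5,700 samples each) motivates the defaults used
throughout: the effective-test-count significance thresholds, the
menstrual-fever case counts, and the catalog of previously reported
bust-size and dysmenorrhea/endometriosis associations used by the
replication workflow.  These values are analysis inputs, kept here so that
every module and script derives reported quantities by computation.
"""

from __future__ import annotations

import pandas as pd

from .association import ThresholdConfig

__all__ = [
    "THRESHOLDS",
    "STAGE_LABELS",
    "MENSTRUAL_FEVER_COUNTS",
    "BUST_SIZE_LOOKUP",
    "DYSMENORRHEA_LOOKUP",
    "fever_case_percent",
]

#: alpha 0.05, effective SNP count M_E for the genotyping platform / JPT
#: population, and the number of phenotypes scanned.
THRESHOLDS = ThresholdConfig(alpha=0.05, m_effective=411_521, n_phenotypes=22)

STAGE_LABELS = ("LL01", "LL02")

#: Menstrual fever (QOL impact) cases / analyzed samples per stage.
MENSTRUAL_FEVER_COUNTS = {
    "LL01": {"cases": 112, "n": 5734},
    "LL02": {"cases": 157, "n": 5614},
}

#: Previously reported bust-size / mammographic-density associations with
#: the association statistics observed in the two-stage cohort (minimum
#: p-value across reported SNPs, and the FDR computed within the full
#: 18-signal lookup set).
BUST_SIZE_LOOKUP = pd.DataFrame(
    [
        ("rs10034692", "AREG", "4", 2.0e-10, 1.98e-3, 7.92e-3),
        ("rs12642133", "AREG,BTC", "4", 9.0e-13, 1.04e-2, 5.08e-2),
        ("rs12173570", "C6orf97,CCDC170,ESR1", "6", 1.0e-11, 2.02e-14, 2.43e-13),
        ("rs7816345", "KCNU1,MRPS7P1,ZNF703", "8", 7.0e-31, 1.14e-8, 6.84e-8),
        ("rs17356907", "NTN4,USP44", "12", 1.0e-13, 5.13e-3, 3.13e-2),
        ("rs17001868", "MKL1,SGSM3,TNRC6B", "22", 2.0e-13, 7.06e-7, 7.06e-6),
    ],
    columns=["id", "genes", "chrom", "previous_p", "current_p", "current_fdr"],
)

#: Previously reported dysmenorrhea / endometriosis associations.
DYSMENORRHEA_LOOKUP = pd.DataFrame(
    [
        ("rs7523086", "NGF,RP4-663N10.1,TSPAN2", "1", 4.0e-14, 1.65e-15, 5.47e-15),
        ("rs10167914", "IL1A", "2", 1.0e-9, 1.60e-15, 3.51e-14),
        ("rs7739264", "ID4", "6", 2.0e-10, 3.86e-3, 4.25e-2),
        ("rs1971256", "CCDC170", "6", 4.0e-8, 1.93e-3, 2.55e-2),
    ],
    columns=["id", "genes", "chrom", "previous_p", "current_p", "current_fdr"],
)


def fever_case_percent(stage: str) -> float:
    """Percentage of samples reporting menstrual-fever QOL impact in a stage."""
    rec = MENSTRUAL_FEVER_COUNTS[stage]
    return 100.0 * rec["cases"] / rec["n"]
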