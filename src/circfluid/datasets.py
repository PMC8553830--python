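"""Bundled reference datasets.

The qPCR/RNA-Seq validation panel: the 15 most highly expressed circRNAs
in each biofluid, with their published mean qRT-PCR Ct and mean RNA-Seq
JRPM values and the abundance ranks assigned on each platform (Ct
ascending, JRPM descending; circRNAs undetected by qRT-PCR have no Ct and
were ranked last).  Used to exercise cross-platform rank concordance on
real measured values.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = ["validation_panel"]

# columns: circRNA, mean Ct (NaN = undetected by qRT-PCR), published
# qRT-PCR rank, mean JRPM, published RNA-Seq rank
_PLASMA = [
    ("circUXS1", 27.41, 1, 51.21, 15),
    ("circNRIP1", 27.96, 2, 89.80, 10),
    ("circARHGEF12", 28.04, 3, 110.13, 5),
    ("circMCU", 28.53, 4, 415.78, 1),
    ("circPCMTD1", 28.85, 5, 60.09, 13),
    ("circFIP1L1-1", 28.99, 6, 250.67, 2),
    ("circRHBDD1", 29.75, 7, 217.81, 4),
    ("circETFA", 30.05, 8, 66.35, 11),
    ("circPRKCB", 30.16, 9, 65.81, 12),
    ("circSMARCA5", 30.64, 10, 99.59, 9),
    ("circSIAE", 31.41, 11, 234.59, 3),
    ("circYPEL2", 31.88, 12, 51.44, 14),
    ("circCDK17", 32.12, 13, 102.04, 7),
    ("circFIP1L1-2", 32.36, 14, 100.46, 8),
    ("circPOMT1", 32.60, 15, 106.79, 6),
]

_URINE = [
    ("circARHGEF12", 31.27, 1, 5.27, 15),
    ("circRBM23", 31.46, 2, 8.21, 5),
    ("circUBAP2", 31.68, 3, 6.49, 10),
    ("circCDYL2", 31.93, 4, 6.72, 8),
    ("circPAPOLA", 32.64, 5, 6.61, 9),
    ("circSMARCA5", 32.72, 6, 7.85, 6),
    ("circRHBDD1", 33.22, 7, 10.72, 3),
    ("circYPEL2", 33.25, 8, 9.30, 4),
    ("circDMXL1", 33.63, 9, 6.29, 11),
    ("circPOMT1", 33.67, 10, 28.46, 2),
    ("circFARSA", 33.75, 11, 7.50, 7),
    ("circFIP1L1-2", 33.81, 12, 5.61, 14),
    ("circSTK39", 34.45, 13, 6.24, 12),
    ("circMYO5B", math.nan, 14, 5.70, 13),
    ("circPHC3", math.nan, 15, 81.19, 1),
]


def validation_panel(biofluid: str) -> pd.DataFrame:
    """Return the qPCR/RNA-Seq panel for ``"plasma"`` or ``"urine"``.

    Columns: circRNA, mean_ct, qpcr_rank (published), mean_jrpm,
    rnaseq_rank (published).  Row order is the published qRT-PCR rank
    order, which also defines the insertion order used to break missing-Ct
    ties.
    """
    rows = {"plasma": _PLASMA, "urine": _URINE}.get(biofluid)
    if rows is None:
        raise ValueError(f"unknown biofluid {biofluid!r}")
    return pd.DataFrame(
        rows,
        columns=["circRNA", "mean_ct", "qpcr_rank", "mean_jrpm", "rnaseq_rank"],
    )
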