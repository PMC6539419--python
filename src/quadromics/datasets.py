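"""Packaged worked-example tables.

Small TSV transcriptions of published results shipped with the package:
the differentially accumulated metabolites of the purine-metabolism
(PEC vs. NEC) and flavonoid-biosynthesis (GE vs. PEC) pathways, and the
curated gene–metabolite correlation pairs behind the two signed networks.
Values are transcribed as printed (fold changes to three significant
figures, log2 fold changes at their printed precision, PCC = ±1),
including one internally inconsistent printed row (the BBM gene carries a
positive log2FC yet PCC = −1 against upregulated metabolites), which is
kept verbatim.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .association import AssociationPair

__all__ = [
    "load_purine_dams",
    "load_flavonoid_dams",
    "load_purine_pairs",
    "load_flavonoid_pairs",
    "pairs_from_frame",
    "printed_precision_tolerance",
]


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("quadromics.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"log2fc_printed": str})


def load_purine_dams() -> pd.DataFrame:
    """Purine-metabolism DAMs (PEC vs. NEC): fc, printed log2fc, status."""
    return _load("purine_dams.tsv")


def load_flavonoid_dams() -> pd.DataFrame:
    """Flavonoid-biosynthesis DAMs (GE vs. PEC): fc, printed log2fc, status."""
    return _load("flavonoid_dams.tsv")


def load_purine_pairs() -> pd.DataFrame:
    """Curated gene–metabolite pairs of the purine-metabolism network (81 rows)."""
    return _load("purine_pairs.tsv")


def load_flavonoid_pairs() -> pd.DataFrame:
    """Curated gene–metabolite pairs of the flavonoid-biosynthesis network (13 rows)."""
    return _load("flavonoid_pairs.tsv")


def pairs_from_frame(frame: pd.DataFrame) -> list[AssociationPair]:
    """Convert a curated pair table into :class:`AssociationPair` records.

    Statuses are derived from the sign of the printed log2 fold changes
    (all curated features are differential).
    """
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            AssociationPair(
                gene_id=row.gene_id,
                metabolite_id=row.metabolite_id,
                pcc=float(row.pcc),
                gene_status="up" if row.gene_log2fc > 0 else "down",
                metabolite_status="up" if row.metabolite_log2fc > 0 else "down",
                gene_log2fc=float(row.gene_log2fc),
                metabolite_log2fc=float(row.metabolite_log2fc),
            )
        )
    return out


def printed_precision_tolerance(fc: float, log2fc_printed: str, fc_sig_figs: int = 3) -> float:
    """Tolerance for comparing log2(fc) against a printed log2FC.

    Half a unit in the last printed decimal of the log2FC, plus the
    propagated half-ulp of the fold change itself (printed to
    ``fc_sig_figs`` significant figures).
    """
    text = log2fc_printed.strip()
    decimals = len(text.split(".")[1]) if "." in text else 0
    mantissa = fc / (10 ** np.floor(np.log10(abs(fc))))
    rel = 0.5 * 10 ** (1 - fc_sig_figs) / mantissa
    return 0.5 * 10**-decimals + float(np.log2(1 + rel))
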