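"""Quantification of anti-CRISPR assay readouts.

* Plasmid interference (bacteria): inhibitory activity (%) is the cfu ratio
  between the matching-spacer and mismatching-spacer Cas9 transformations,
  averaged over replicates.
* T7E1 (human cells): editing efficiency indel(%) = 100·(1 − √(1 − f_cleaved)).
* Chemically inducible Acr: fold regulation = efficiency without 4-HT over
  efficiency with 4-HT (inducible Acrs inhibit editing only upon 4-HT, so a
  larger fold means stronger ligand-dependent control).
* Activity symbols: ≤20% "-", (20,50] "+", (50,80] "++", >80% "+++"
  (bands closed on the right; the legend leaves the exact boundaries and the
  low end unassigned, and this closure reproduces every printed mean/symbol
  pair). Missing combinations are reported "ND".
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SYMBOLS = ("-", "+", "++", "+++")


class UndefinedResultError(ZeroDivisionError):
    """A ratio with a zero denominator."""


def inhibitory_activity(cfu_matching: float, cfu_mismatching: float) -> float:
    """Inhibitory activity (%) from one replicate's colony counts.

    100 × cfu_matching / cfu_mismatching, clamped to [0, 100] (sampling noise
    can push the raw ratio above 1; the quantity is conceptually bounded).
    """
    if cfu_matching < 0 or cfu_mismatching < 0:
        raise ValueError("cfu counts must be non-negative")
    if cfu_mismatching == 0:
        raise UndefinedResultError(
            "cfu_mismatching is 0: the control transformation yielded no "
            "colonies, the activity ratio is undefined")
    ratio = 100.0 * cfu_matching / cfu_mismatching
    if ratio > 100.0:
        logger.debug("cfu ratio %.1f%% > 100%%; clamped", ratio)
    return min(max(ratio, 0.0), 100.0)


def indel_percent(fraction_cleaved: float) -> float:
    """Editing efficiency from the T7E1 cleaved fraction:
    indel(%) = 100 × (1 − √(1 − fraction_cleaved))."""
    if not (0.0 <= fraction_cleaved <= 1.0):
        raise ValueError("fraction_cleaved must be in [0, 1]")
    return 100.0 * (1.0 - math.sqrt(1.0 - fraction_cleaved))


def indel_to_fraction(indel_pct: float) -> float:
    """Inverse of :func:`indel_percent`: f = 1 − (1 − indel/100)²."""
    if not (0.0 <= indel_pct <= 100.0):
        raise ValueError("indel percent must be in [0, 100]")
    return 1.0 - (1.0 - indel_pct / 100.0) ** 2


def classify_activity(mean_activity: float) -> str:
    """Map a mean inhibitory activity (%) to its summary symbol."""
    if not (0.0 <= mean_activity <= 100.0):
        raise ValueError("mean_activity must be in [0, 100]")
    if mean_activity <= 20.0:
        return "-"
    if mean_activity <= 50.0:
        return "+"
    if mean_activity <= 80.0:
        return "++"
    return "+++"


def fold_regulation(efficiency_no4ht: float, efficiency_4ht: float,
                    pseudo_efficiency: Optional[float] = None) -> float:
    """Ligand-dependence of an inducible Acr: editing efficiency without 4-HT
    divided by efficiency with 4-HT."""
    if efficiency_no4ht < 0 or efficiency_4ht < 0:
        raise ValueError("efficiencies must be non-negative")
    if efficiency_4ht == 0:
        if pseudo_efficiency:
            return efficiency_no4ht / pseudo_efficiency
        raise UndefinedResultError(
            "efficiency with 4-HT is 0; pass pseudo_efficiency to report a "
            "floor-adjusted fold instead")
    return efficiency_no4ht / efficiency_4ht


@dataclass(frozen=True)
class ActivityResult:
    acr_label: str
    cas9_label: str
    assay: str
    activities: tuple  # per-replicate activity %
    mean: Optional[float]
    sem: Optional[float]
    symbol_class: str  # -, +, ++, +++, ND


def summarize(
    table: pd.DataFrame,
    expected_groups: Optional[Iterable[tuple[str, str, str]]] = None,
) -> pd.DataFrame:
    """Per-(acr, cas9, assay) activity summary in the style of the reported
    inhibition table: per-replicate activity, mean, SEM, symbol.

    Groups listed in ``expected_groups`` but absent from the data are reported
    as "ND" (not determined). Single-replicate groups get SEM NaN with a
    warning.
    """
    rows = []
    seen = set()
    if not table.empty:
        for (acr, cas9, assay_kind), grp in table.groupby(
                ["acr_label", "cas9_label", "assay"], sort=True):
            acts = [
                inhibitory_activity(m, mm)
                for m, mm in zip(grp["cfu_matching"], grp["cfu_mismatching"])
            ]
            mean = float(np.mean(acts))
            if len(acts) > 1:
                sem = float(np.std(acts, ddof=1) / np.sqrt(len(acts)))
            else:
                logger.warning("group (%s, %s, %s): single replicate, SEM "
                               "not available", acr, cas9, assay_kind)
                sem = float("nan")
            rows.append({
                "acr_label": acr, "cas9_label": cas9, "assay": assay_kind,
                "n_replicates": len(acts), "mean_activity": mean, "sem": sem,
                "symbol": classify_activity(mean),
            })
            seen.add((acr, cas9, assay_kind))
    for grp_key in sorted(set(expected_groups or []) - seen):
        rows.append({
            "acr_label": grp_key[0], "cas9_label": grp_key[1],
            "assay": grp_key[2], "n_replicates": 0,
            "mean_activity": float("nan"), "sem": float("nan"),
            "symbol": "ND",
        })
    return pd.DataFrame(
        rows, columns=["acr_label", "cas9_label", "assay", "n_replicates",
                       "mean_activity", "sem", "symbol"])
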