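"""Prophase-I DSB dynamics from RPA focus counts.

RPA foci mark resected double-strand-break repair intermediates; their
per-cell count declines as prophase I progresses (leptotene → pachytene).
This module summarizes counts per condition × stage and runs the
multi-group comparison: one-way ANOVA followed by Tukey's HSD on the
studentized-range distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import Dataset, EmptySelectionError, InsufficientDataError, MeiocoError, STAGES

__all__ = ["StageSummary", "rpa_stage_summary", "compare_groups_tukey"]


@dataclass(frozen=True)
class StageSummary:
    condition: str
    stage: str
    mean: float
    sd: float
    n_cells: int

    def __post_init__(self):
        if self.n_cells < 1:
            raise MeiocoError("StageSummary requires n_cells >= 1")

    @property
    def singleton(self) -> bool:
        """True when n = 1, where the SD is 0 by definition."""
        return self.n_cells == 1


def rpa_stage_summary(dataset: Dataset, temperature: Optional[float] = None) -> pd.DataFrame:
    """Mean/SD/n of RPA foci per cell for every condition × stage group.

    Stage ordering is fixed temporal order; a group of one cell reports
    SD = 0 and is flagged in the ``singleton`` column.
    """
    recs = dataset.rpa_records(temperature)
    if not recs:
        raise EmptySelectionError("no records with RPA counts in selection")
    bad = {r.stage for r in recs} - set(STAGES)
    if bad:
        raise MeiocoError(f"unknown stage label(s) {sorted(bad)}; expected one of {STAGES}")
    rows = []
    for temp in sorted({r.temperature_C for r in recs}):
        for stage in STAGES:
            counts = [r.rpa_count for r in recs if r.temperature_C == temp and r.stage == stage]
            if not counts:
                continue
            x = np.asarray(counts, dtype=float)
            rows.append(
                {
                    "condition": f"{temp:g}C",
                    "temperature_C": temp,
                    "stage": stage,
                    "mean": float(x.mean()),
                    "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
                    "n_cells": len(x),
                    "singleton": len(x) == 1,
                }
            )
    return pd.DataFrame(rows)


def compare_groups_tukey(groups: Dict[str, Sequence[float]]) -> pd.DataFrame:
    """One-way ANOVA + Tukey HSD pairwise comparisons.

    ``groups`` maps label → sample.  Returns one row per pair with the
    mean difference, the studentized-range-based family-wise adjusted p,
    and the overall ANOVA F and p attached.  When the pooled within-group
    variance is zero the adjusted p degenerates to 1 for equal means and
    0 otherwise (documented convention).
    """
    labels = list(groups)
    if len(labels) < 2:
        raise InsufficientDataError("Tukey comparison needs >= 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(len(a) < 2 for a in arrays):
        raise InsufficientDataError("every group needs n >= 2")

    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / (
        sum(len(a) for a in arrays) - len(arrays)
    )
    if mse == 0:
        rows = [
            {
                "group_a": a_lab,
                "group_b": b_lab,
                "mean_diff": float(np.mean(groups[b_lab]) - np.mean(groups[a_lab])),
                "p_adj": 1.0 if np.mean(groups[a_lab]) == np.mean(groups[b_lab]) else 0.0,
            }
            for a_lab, b_lab in combinations(labels, 2)
        ]
        df = pd.DataFrame(rows)
        df["anova_F"] = 0.0 if df["p_adj"].eq(1.0).all() else np.inf
        df["anova_p"] = 1.0 if df["p_adj"].eq(1.0).all() else 0.0
        return df

    F, anova_p = stats.f_oneway(*arrays)
    res = stats.tukey_hsd(*arrays)
    rows = []
    for ia, ib in combinations(range(len(labels)), 2):
        rows.append(
            {
                "group_a": labels[ia],
                "group_b": labels[ib],
                "mean_diff": float(arrays[ib].mean() - arrays[ia].mean()),
                "p_adj": float(res.pvalue[ia, ib]),
            }
        )
    df = pd.DataFrame(rows)
    df["anova_F"] = float(F)
    df["anova_p"] = float(anova_p)
    return df


def tukey_by_stage(dataset: Dataset) -> pd.DataFrame:
    """Tukey comparisons of temperatures within each stage (the usual axis).

    The complementary mode — stages within each temperature — is
    :func:`tukey_by_temperature`.
    """
    recs = dataset.rpa_records()
    out = []
    for stage in STAGES:
        groups = {}
        for temp in sorted({r.temperature_C for r in recs}):
            sample = [r.rpa_count for r in recs if r.stage == stage and r.temperature_C == temp]
            if len(sample) >= 2:
                groups[f"{temp:g}C"] = sample
        if len(groups) >= 2:
            df = compare_groups_tukey(groups)
            df.insert(0, "stage", stage)
            out.append(df)
    if not out:
        raise EmptySelectionError("no stage had >= 2 comparable temperature groups")
    return pd.concat(out, ignore_index=True)


def tukey_by_temperature(dataset: Dataset) -> pd.DataFrame:
    """Tukey comparisons of stages within each temperature."""
    recs = dataset.rpa_records()
    out = []
    for temp in sorted({r.temperature_C for r in recs}):
        groups = {}
        for stage in STAGES:
            sample = [r.rpa_count for r in recs if r.stage == stage and r.temperature_C == temp]
            if len(sample) >= 2:
                groups[stage] = sample
        if len(groups) >= 2:
            df = compare_groups_tukey(groups)
            df.insert(0, "temperature_C", temp)
            out.append(df)
    if not out:
        raise EmptySelectionError("no temperature had >= 2 comparable stage groups")
    return pd.concat(out, ignore_index=True)
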