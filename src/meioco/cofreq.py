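"""Per-cell and per-SC MLH1 focus statistics and their comparisons.

The MLH1 focus count per pachytene cell is the cytological estimate of
the crossover number; its distribution over cells is compared between
thermal conditions with a two-tailed Welch t-test, and the per-SC focus
class distribution (0, 1, 2, 3, ≥4 foci) with a contingency chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model import Dataset, EmptySelectionError, InsufficientDataError, MeiocoError

__all__ = [
    "FociDistribution",
    "FociSummary",
    "foci_per_cell",
    "foci_class_distribution",
    "compare_means_ttest",
    "compare_class_distribution_chisq",
]

#: Focus-count classes; the top class is open-ended (≥4).
CLASSES = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class FociDistribution:
    """Relative frequency of SCs bearing 0, 1, 2, 3 or ≥4 MLH1 foci.

    Absolute counts are kept alongside the frequencies so chi-square
    comparisons remain possible.
    """

    condition: str
    per_class_freq: dict
    per_class_count: dict
    n_scs: int

    def __post_init__(self):
        total = sum(self.per_class_freq.values())
        if self.n_scs <= 0:
            raise MeiocoError("FociDistribution requires n_scs > 0")
        if abs(total - 1.0) > 1e-9:
            raise MeiocoError(f"class frequencies sum to {total}, not 1")

    def counts_array(self) -> np.ndarray:
        return np.array([self.per_class_count.get(c, 0) for c in CLASSES], dtype=float)


class FociSummary(NamedTuple):
    mean: float
    sd: float
    n: int


class StatTestResult(NamedTuple):
    statistic: float
    pvalue: float
    df: float


def _pachytene(dataset: Dataset, temperature: Optional[float]):
    cells = dataset.pachytene_cells(temperature)
    if not cells:
        raise EmptySelectionError(
            f"no pachytene cells with scored SCs for temperature={temperature!r}"
        )
    return cells


def foci_per_cell(dataset: Dataset, temperature: Optional[float] = None):
    """Per-cell MLH1 focus counts and their summary.

    Returns ``(counts, summary)``: a DataFrame with one row per cell
    (cell_id, animal_id, temperature_C, n_foci) and a
    :class:`FociSummary` (mean, SD over cells, n).  The per-cell count is
    the sum of focus counts over the cell's SCs.
    """
    cells = _pachytene(dataset, temperature)
    counts = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "animal_id": [c.animal_id for c in cells],
            "temperature_C": [c.temperature_C for c in cells],
            "n_foci": [c.total_foci for c in cells],
        }
    )
    x = counts["n_foci"].to_numpy(dtype=float)
    sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
    return counts, FociSummary(mean=float(x.mean()), sd=sd, n=len(x))


def foci_class_distribution(
    dataset: Dataset,
    temperature: Optional[float] = None,
    sc_rank: Optional[int] = None,
    condition: Optional[str] = None,
):
    """Distribution of SCs over focus-count classes 0–≥4.

    ``sc_rank`` restricts to one rank (the per-chromosome stratification);
    by default all SCs of the selection are pooled.
    """
    cells = _pachytene(dataset, temperature)
    counts = {c: 0 for c in CLASSES}
    n = 0
    for cell in cells:
        for sc in cell.scs:
            if sc_rank is not None and sc.sc_rank != sc_rank:
                continue
            counts[min(sc.n_foci, 4)] += 1
            n += 1
    if n == 0:
        raise EmptySelectionError(f"no SCs selected (temperature={temperature!r}, sc_rank={sc_rank!r})")
    label = condition if condition is not None else (f"{temperature:g}C" if temperature is not None else "all")
    freq = {c: counts[c] / n for c in CLASSES}
    return FociDistribution(condition=label, per_class_freq=freq, per_class_count=dict(counts), n_scs=n)


def compare_means_ttest(a, b, equal_var: bool = False) -> StatTestResult:
    """Two-tailed t-test on two per-cell count samples (Welch by default).

    A degenerate comparison — both samples constant with equal means —
    returns p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each sample needs n >= 2 for a t-test")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return StatTestResult(0.0, 1.0, float(len(a) + len(b) - 2))
        return StatTestResult(np.inf, 0.0, float(len(a) + len(b) - 2))
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return StatTestResult(float(res.statistic), float(res.pvalue), float(res.df))


def _pool_sparse_classes(table: np.ndarray, min_expected: float) -> np.ndarray:
    """Merge adjacent class columns until every expected count is >= the floor.

    Columns are merged from the open tail downward first (≥4 into 3, …),
    then from class 0 upward, mirroring how sparse focus classes sit at
    the edges of the distribution.  Pooling preserves the total count.
    """
    table = table.astype(float).copy()
    while table.shape[1] > 2:
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        bad = np.where((expected < min_expected).any(axis=0))[0]
        if len(bad) == 0:
            break
        j = int(bad.max())
        if j == 0:
            j = 1  # merge class 0 into class 1
        table[:, j - 1] += table[:, j]
        table = np.delete(table, j, axis=1)
    return table


def compare_class_distribution_chisq(
    a: FociDistribution, b: FociDistribution, min_expected: float = 5.0
) -> StatTestResult:
    """Contingency chi-square on two focus-class count tables.

    Classes whose expected count falls below ``min_expected`` are pooled
    into the adjacent class before testing; no continuity correction.
    """
    table = np.vstack([a.counts_array(), b.counts_array()])
    table = table[:, table.sum(axis=0) > 0]
    table = _pool_sparse_classes(table, min_expected)
    if table.shape[1] < 2:
        raise InsufficientDataError("fewer than 2 non-empty classes after pooling; not testable")
    if np.allclose(table[0] / table[0].sum(), table[1] / table[1].sum()):
        # chi2_contingency is exact here too, but make the convention explicit
        df = table.shape[1] - 1
        return StatTestResult(0.0, 1.0, float(df))
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return StatTestResult(float(chi2), float(p), float(df))
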