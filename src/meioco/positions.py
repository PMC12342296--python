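"""SC axis morphometry and centromere-referenced crossover positions.

SCs within a cell are ranked 1–17 by descending axis length with the two
metacentrics pinned to the reference's metacentric ranks (1 and 4).
Focus positions are re-expressed as a fraction of arm length measured
from the centromere: an acrocentric SC is a single arm with the origin at
its centromeric end; a metacentric SC splits into p and q arms at the
centromere, each scaled independently.  On these relative coordinates the
module computes interval histograms, cumulative (ECDF) comparisons via
the two-sample Kolmogorov–Smirnov test, CO densities, and a centromere
suppression index.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    CellRecord,
    Dataset,
    EmptySelectionError,
    InsufficientDataError,
    PartialCellError,
    SCObservation,
)
from .simulate import DEFAULT_SC_PROFILE_UM, METACENTRIC_RANKS

__all__ = [
    "ReferenceKaryotype",
    "DEFAULT_REFERENCE",
    "rank_scs",
    "rank_dataset",
    "sc_length_summary",
    "co_density",
    "relative_positions",
    "bin_positions",
    "compare_position_distributions_ks",
    "centromere_effect",
]


@dataclass(frozen=True)
class ReferenceKaryotype:
    """Ranked reference lengths and the karyotype's metacentric ranks.

    ``large_ranks`` freezes the large/short split against the reference
    condition, so the classification does not drift between conditions.
    """

    lengths_um: tuple = DEFAULT_SC_PROFILE_UM
    metacentric_ranks: tuple = METACENTRIC_RANKS
    large_ranks: tuple = (1, 2, 3, 4)

    def size_class(self, rank: int) -> str:
        return "large" if rank in self.large_ranks else "short"


DEFAULT_REFERENCE = ReferenceKaryotype()


def _meta_index(sc: SCObservation) -> float:
    """Degree of metacentricity: min-arm fraction, 0 (acro) to 0.5."""
    if sc.length_um == 0:
        return 0.0
    f = sc.centromere_um / sc.length_um
    return min(f, 1.0 - f)


def rank_scs(cell: CellRecord, reference: ReferenceKaryotype = DEFAULT_REFERENCE) -> list:
    """Assign ranks 1–17 to a cell's SCs by descending length.

    Metacentric SCs are pinned to the reference's metacentric ranks; when
    distinguishable by length they take those ranks in length order.
    Ties break by metacentricity (more metacentric first), then input
    order, so the assignment is deterministic.  Returns a new list of
    :class:`SCObservation` with ``sc_rank`` set, in input order.

    Raises :class:`PartialCellError` if the cell does not carry exactly
    17 scored SCs.
    """
    scs = cell.scs
    if len(scs) != 17:
        raise PartialCellError(
            f"cell {cell.cell_id}: {len(scs)} SCs scored, ranking needs the full complement of 17"
        )
    n_meta_expected = len(reference.metacentric_ranks)
    meta_idx = [i for i, sc in enumerate(scs) if sc.morphology == "metacentric"]
    if len(meta_idx) != n_meta_expected:
        raise PartialCellError(
            f"cell {cell.cell_id}: {len(meta_idx)} metacentric SCs "
            f"(reference karyotype has {n_meta_expected})"
        )

    def key(i):
        return (-scs[i].length_um, -_meta_index(scs[i]), i)

    meta_sorted = sorted(meta_idx, key=key)
    acro_sorted = sorted((i for i in range(17) if i not in meta_idx), key=key)
    ranks = [0] * 17
    meta_ranks = sorted(reference.metacentric_ranks)
    for rank, i in zip(meta_ranks, meta_sorted):
        ranks[i] = rank
    acro_rank_slots = [r for r in range(1, 18) if r not in meta_ranks]
    for rank, i in zip(acro_rank_slots, acro_sorted):
        ranks[i] = rank
    return [dc_replace(sc, sc_rank=ranks[i]) for i, sc in enumerate(scs)]


def rank_dataset(dataset: Dataset, reference: ReferenceKaryotype = DEFAULT_REFERENCE):
    """Rank every fully scored pachytene cell; skip and report the rest.

    Returns ``(ranked_dataset, excluded)`` where ``excluded`` maps
    cell_id → reason for the cells that could not be ranked.
    """
    records = []
    excluded = {}
    for rec in dataset.records:
        if rec.stage == "pachytene" and rec.scs:
            try:
                ranked = rank_scs(rec, reference)
            except PartialCellError as err:
                excluded[rec.cell_id] = str(err)
                continue
            rec = CellRecord(
                cell_id=rec.cell_id,
                animal_id=rec.animal_id,
                temperature_C=rec.temperature_C,
                stage=rec.stage,
                scs=ranked,
                rpa_count=rec.rpa_count,
            )
        records.append(rec)
    return Dataset(records, dict(dataset.metadata)), excluded


def _ranked_cells(dataset: Dataset, temperature: Optional[float]):
    cells = dataset.pachytene_cells(temperature)
    cells = [c for c in cells if all(sc.sc_rank is not None for sc in c.scs)]
    if not cells:
        raise EmptySelectionError(
            f"no ranked pachytene cells for temperature={temperature!r}; run rank_dataset first"
        )
    return cells


class SCLengthSummary(NamedTuple):
    per_rank: pd.DataFrame          # rank, mean_um, sd_um, n
    grand_mean_um: float            # mean over all SCs of all cells
    grand_sd_um: float
    per_cell_totals: pd.DataFrame   # cell_id, total_um


def sc_length_summary(dataset: Dataset, temperature: Optional[float] = None) -> SCLengthSummary:
    """Axis-length morphometry: per-rank means, grand mean, per-cell totals."""
    cells = _ranked_cells(dataset, temperature)
    rows = [
        {"cell_id": c.cell_id, "sc_rank": sc.sc_rank, "length_um": sc.length_um}
        for c in cells
        for sc in c.scs
    ]
    df = pd.DataFrame(rows)
    per_rank = (
        df.groupby("sc_rank")["length_um"]
        .agg(mean_um="mean", sd_um=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n="count")
        .reset_index()
    )
    totals = df.groupby("cell_id", sort=False)["length_um"].sum().reset_index(name="total_um")
    x = df["length_um"].to_numpy()
    return SCLengthSummary(
        per_rank=per_rank,
        grand_mean_um=float(x.mean()),
        grand_sd_um=float(x.std(ddof=1)) if len(x) > 1 else 0.0,
        per_cell_totals=totals,
    )


def co_density(dataset: Dataset, temperature: Optional[float] = None) -> pd.DataFrame:
    """Per-rank CO density, MLH1 foci·µm⁻¹.

    ``density`` is (mean foci per SC) / (mean SC length); ``density_sd``
    is the dispersion of the per-SC densities around it.
    """
    cells = _ranked_cells(dataset, temperature)
    rows = [
        {
            "sc_rank": sc.sc_rank,
            "n_foci": sc.n_foci,
            "length_um": sc.length_um,
            "per_sc_density": sc.n_foci / sc.length_um,
        }
        for c in cells
        for sc in c.scs
    ]
    df = pd.DataFrame(rows)
    out = (
        df.groupby("sc_rank")
        .agg(
            mean_foci=("n_foci", "mean"),
            mean_length_um=("length_um", "mean"),
            density_sd=("per_sc_density", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0),
            n=("n_foci", "count"),
        )
        .reset_index()
    )
    out["density_per_um"] = out["mean_foci"] / out["mean_length_um"]
    return out[["sc_rank", "mean_foci", "mean_length_um", "density_per_um", "density_sd", "n"]]


def relative_positions(dataset: Dataset, temperature: Optional[float] = None) -> pd.DataFrame:
    """Centromere-referenced relative focus positions, one row per focus.

    Columns: cell_id, sc_rank, morphology, arm ('single' for acrocentric,
    'p'/'q' for metacentric), pos_frac in [0, 1] — the distance from the
    centromere as a fraction of arm length.  A focus exactly at a
    metacentric centromere is assigned to the q arm by convention.
    """
    cells = _ranked_cells(dataset, temperature)
    rows = []
    for c in cells:
        for sc in c.scs:
            for pos in sc.foci_um:
                if sc.morphology == "metacentric":
                    cen = sc.centromere_um
                    if pos < cen:
                        arm, arm_len, d = "p", cen, cen - pos
                    else:
                        arm, arm_len, d = "q", sc.length_um - cen, pos - cen
                else:
                    arm, arm_len, d = "single", sc.length_um, pos
                rows.append(
                    {
                        "cell_id": c.cell_id,
                        "sc_rank": sc.sc_rank,
                        "morphology": sc.morphology,
                        "arm": arm,
                        "pos_frac": d / arm_len,
                    }
                )
    return pd.DataFrame(rows, columns=["cell_id", "sc_rank", "morphology", "arm", "pos_frac"])


def bin_positions(pos_frac: Sequence[float], n_bins: int = 10) -> np.ndarray:
    """Relative frequency per interval of arm length.

    Bins are half-open [k/n, (k+1)/n) with the last bin closed so a focus
    at exactly 1.0 is counted; frequencies sum to 1.
    """
    x = np.asarray(pos_frac, dtype=float)
    if x.size == 0:
        raise EmptySelectionError("no positions to bin")
    counts, _ = np.histogram(x, bins=n_bins, range=(0.0, 1.0))
    return counts / x.size


def compare_position_distributions_ks(a, b):
    """Two-sample Kolmogorov–Smirnov test on pooled relative positions.

    Returns ``(D, pvalue)``.  The caller is expected to pass positions of
    one morphology class at a time, since acrocentric and metacentric
    arms are compared separately.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise InsufficientDataError("KS comparison needs n >= 5 per sample")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def centromere_effect(pos_frac: Sequence[float], window_frac: float = 0.1) -> float:
    """Centromere suppression index.

    Observed focus frequency within ``window_frac`` of the centromere,
    divided by the frequency expected if positions were uniform on the
    arm.  1 ≈ no suppression, < 1 suppression, 0 complete exclusion.
    """
    x = np.asarray(pos_frac, dtype=float)
    if x.size == 0:
        raise EmptySelectionError("no positions for centromere-effect index")
    if not (0 < window_frac <= 1):
        raise ValueError("window_frac must lie in (0, 1]")
    observed = float((x < window_frac).mean())
    return observed / window_frac
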