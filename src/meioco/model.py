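"""Domain types for cytological recombination data.

The coordinate convention, used everywhere in the package, is a single
stored frame per synaptonemal complex (SC): positions are in micrometres
from a fixed axis origin.  For acrocentric SCs the origin is the
centromeric end, so ``centromere_um == 0`` and a focus position is its
distance from the centromere.  For metacentric SCs the origin is the
p-arm telomere and ``0 < centromere_um < length_um``; arm-relative
coordinates are always *derived* from this frame, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "STAGES",
    "MORPHOLOGIES",
    "SCObservation",
    "CellRecord",
    "Dataset",
    "Violation",
    "ValidationReport",
    "validate",
    "MeiocoError",
    "SchemaError",
    "ValidationError",
    "EmptySelectionError",
    "ParameterError",
    "CalibrationError",
    "DegenerateFitError",
    "InsufficientDataError",
    "PartialCellError",
]

#: Prophase-I stages, in temporal order.  A closed factor.
STAGES = ("leptotene", "early_zygotene", "late_zygotene", "pachytene")

MORPHOLOGIES = ("acrocentric", "metacentric")


class MeiocoError(Exception):
    """Base class for package errors."""


class SchemaError(MeiocoError):
    """A tabular input does not match a declared schema."""


class ValidationError(MeiocoError):
    """A dataset violates a domain invariant.

    Carries the offending :class:`Violation` list in ``violations``.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations[:10])
        more = "" if len(self.violations) <= 10 else f" (+{len(self.violations) - 10} more)"
        super().__init__(f"{len(self.violations)} invariant violation(s): {lines}{more}")


class EmptySelectionError(MeiocoError):
    """A condition filter selected no usable records."""


class ParameterError(MeiocoError):
    """A parameter is outside its supported domain."""


class CalibrationError(MeiocoError):
    """Intensity calibration could not reach the requested target."""


class DegenerateFitError(MeiocoError):
    """The data admit no proper ML fit (e.g. zero variance)."""


class InsufficientDataError(MeiocoError):
    """Fewer observations than the configured floor for a fit/test."""


class PartialCellError(MeiocoError):
    """A cell does not carry the full SC complement expected for ranking."""


@dataclass(frozen=True)
class SCObservation:
    """One bivalent (synaptonemal complex) scored in one cell.

    ``foci_um`` are MLH1 focus positions, sorted ascending, in the stored
    axis frame described in the module docstring.
    """

    cell_id: str
    length_um: float
    centromere_um: float
    morphology: str
    foci_um: tuple = ()
    sc_rank: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "foci_um", tuple(float(x) for x in self.foci_um))

    @property
    def n_foci(self) -> int:
        return len(self.foci_um)

    def arm_lengths(self) -> tuple:
        """(p, q) arm lengths; an acrocentric has a zero-length p arm."""
        return (self.centromere_um, self.length_um - self.centromere_um)


@dataclass
class CellRecord:
    """A spermatocyte: its stage, provenance and measurements.

    Pachytene CO cells carry ``scs``; prophase-staging cells carry
    ``rpa_count`` (RPA foci mark DSB-repair intermediates).
    """

    cell_id: str
    animal_id: str
    temperature_C: float
    stage: str
    scs: list = field(default_factory=list)
    rpa_count: Optional[int] = None

    @property
    def total_foci(self) -> int:
        return sum(sc.n_foci for sc in self.scs)


@dataclass
class Dataset:
    """A collection of cells plus free-form provenance metadata."""

    records: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CellRecord]:
        return iter(self.records)

    def temperatures(self) -> list:
        return sorted({r.temperature_C for r in self.records})

    def select(self, temperature: Optional[float] = None, stage: Optional[str] = None) -> "Dataset":
        recs = [
            r
            for r in self.records
            if (temperature is None or r.temperature_C == temperature)
            and (stage is None or r.stage == stage)
        ]
        return Dataset(recs, dict(self.metadata))

    def pachytene_cells(self, temperature: Optional[float] = None) -> list:
        """Pachytene cells with scored SCs (the CO-analysis selection)."""
        return [
            r
            for r in self.records
            if r.stage == "pachytene"
            and r.scs
            and (temperature is None or r.temperature_C == temperature)
        ]

    def rpa_records(self, temperature: Optional[float] = None) -> list:
        return [
            r
            for r in self.records
            if r.rpa_count is not None
            and (temperature is None or r.temperature_C == temperature)
        ]


@dataclass(frozen=True)
class Violation:
    """One invariant violation, locatable to a cell and optionally an SC."""

    kind: str
    cell_id: str
    detail: str
    sc_index: Optional[int] = None

    def __str__(self):
        where = self.cell_id if self.sc_index is None else f"{self.cell_id}/sc{self.sc_index}"
        return f"[{self.kind}] {where}: {self.detail}"


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def raise_if_invalid(self):
        if self.violations:
            raise ValidationError(self.violations)

    def __str__(self):
        if self.ok:
            return "dataset valid"
        return "\n".join(str(v) for v in self.violations)


def _validate_sc(sc: SCObservation, idx: int, out: list) -> None:
    cid = sc.cell_id
    if sc.morphology not in MORPHOLOGIES:
        out.append(Violation("morphology", cid, f"unknown morphology {sc.morphology!r}", idx))
        return
    if not sc.length_um > 0:
        out.append(Violation("length", cid, f"non-positive SC length {sc.length_um}", idx))
        return
    if not (0 <= sc.centromere_um <= sc.length_um):
        out.append(
            Violation(
                "centromere",
                cid,
                f"centromere at {sc.centromere_um} outside [0, {sc.length_um}]",
                idx,
            )
        )
    if sc.morphology == "acrocentric" and sc.centromere_um != 0:
        out.append(
            Violation(
                "centromere",
                cid,
                f"acrocentric SC must have centromere_um == 0, got {sc.centromere_um}",
                idx,
            )
        )
    if sc.morphology == "metacentric" and not (0 < sc.centromere_um < sc.length_um):
        out.append(
            Violation(
                "centromere",
                cid,
                "metacentric SC requires an interior centromere "
                f"(got {sc.centromere_um} on length {sc.length_um})",
                idx,
            )
        )
    if list(sc.foci_um) != sorted(sc.foci_um):
        out.append(Violation("foci_order", cid, "focus positions not sorted ascending", idx))
    for pos in sc.foci_um:
        if not (0 <= pos <= sc.length_um):
            out.append(
                Violation(
                    "focus_range",
                    cid,
                    f"focus at {pos} µm outside SC of length {sc.length_um} µm",
                    idx,
                )
            )
    if sc.sc_rank is not None and not (1 <= sc.sc_rank <= 17):
        out.append(Violation("rank", cid, f"sc_rank {sc.sc_rank} outside 1–17", idx))


def validate(dataset: Dataset) -> ValidationReport:
    """Check every domain invariant; return a locatable report.

    The report is empty iff the dataset is valid.  Never raises.
    """
    out: list = []
    seen: set = set()
    for rec in dataset.records:
        if rec.cell_id in seen:
            out.append(Violation("duplicate_cell", rec.cell_id, "duplicate cell_id"))
        seen.add(rec.cell_id)
        if rec.stage not in STAGES:
            out.append(Violation("stage", rec.cell_id, f"unknown stage {rec.stage!r}"))
        if rec.rpa_count is not None and (rec.rpa_count < 0 or int(rec.rpa_count) != rec.rpa_count):
            out.append(Violation("rpa_count", rec.cell_id, f"rpa_count {rec.rpa_count} not a nonnegative integer"))
        # completeness (17 SCs) is enforced at ranking time, where partial
        # cells are excluded and logged rather than rejected wholesale
        for idx, sc in enumerate(rec.scs):
            if sc.cell_id != rec.cell_id:
                out.append(Violation("cell_link", rec.cell_id, f"SC carries cell_id {sc.cell_id!r}", idx))
            _validate_sc(sc, idx, out)
    return ValidationReport(out)
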