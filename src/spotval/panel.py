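"""Domain model of the analytical panel: SRM transitions, internal-standard
mapping, gradient program and spiking arithmetic.

The packaged panel fixture (``data/transitions.csv``) describes a 25-analyte
PFAS panel plus 9 isotope-labelled internal standards monitored by SRM.  The
transition table is stored in long format, one row per (analyte, product ion),
with an ``ordinal`` column: the ordinal-1 product ion is the quantifier.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

FAMILIES = (
    "perfluorocarboxylic acid",
    "perfluorosulfonic acid",
    "replacement PFAS",
    "perfluoroalkylether",
    "internal standard",
)

_TRANSITION_COLUMNS = [
    "analyte_id",
    "name",
    "family",
    "rt_min",
    "precursor_mz",
    "product_mz",
    "ce_v",
    "cxp_v",
    "ordinal",
    "internal_standard_id",
]


class PanelError(ValueError):
    """Raised for malformed panel definitions or lookups."""


@dataclass(frozen=True)
class SrmTransition:
    """A single precursor -> product ion pair with collision parameters."""

    precursor_mz: float
    product_mz: float
    collision_energy: float
    cell_exit_potential: float
    is_quantifier: bool = False

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise PanelError("m/z values must be positive")
        if self.collision_energy >= 0 or self.cell_exit_potential >= 0:
            raise PanelError("collision parameters must be negative (negative-mode SRM)")


@dataclass
class Analyte:
    """One panel entry: a target compound or an internal standard."""

    id: str
    name: str
    family: str
    retention_time: float
    transitions: list[SrmTransition]
    internal_standard_id: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise PanelError(f"unknown family {self.family!r} for {self.id}")
        if self.retention_time <= 0:
            raise PanelError(f"retention time must be positive for {self.id}")
        if not self.transitions:
            raise PanelError(f"analyte {self.id} has no transitions")
        n_quant = sum(t.is_quantifier for t in self.transitions)
        if n_quant != 1:
            raise PanelError(f"analyte {self.id} must have exactly one quantifier, got {n_quant}")
        if self.is_internal_standard and self.internal_standard_id:
            raise PanelError(f"internal standard {self.id} cannot itself have an IS")
        if not self.is_internal_standard and not self.internal_standard_id:
            raise PanelError(f"target analyte {self.id} lacks an internal standard assignment")

    @property
    def is_internal_standard(self) -> bool:
        return self.family == "internal standard"

    @property
    def quantifier(self) -> SrmTransition:
        return next(t for t in self.transitions if t.is_quantifier)

    @property
    def qualifier(self) -> SrmTransition | None:
        """The lower-ranked (confirmation) transition, if present."""
        quals = [t for t in self.transitions if not t.is_quantifier]
        return quals[0] if quals else None

    @property
    def single_transition(self) -> bool:
        return len(self.transitions) == 1


@dataclass(frozen=True)
class GradientSegment:
    duration_min: float
    pct_b_end: float
    mode: str  # "isocratic" | "linear"

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise PanelError("segment duration must be positive")
        if not 0.0 <= self.pct_b_end <= 100.0:
            raise PanelError("mobile-phase composition must lie in [0, 100]")
        if self.mode not in ("isocratic", "linear"):
            raise PanelError(f"unknown segment mode {self.mode!r}")


@dataclass
class GradientProgram:
    segments: list[GradientSegment] = field(default_factory=list)
    flow_ml_min: float = 0.5


@dataclass(frozen=True)
class SpikePlan:
    """Addition of a working solution to a reference sample volume."""

    added_volume_ul: float
    stock_concentration_ng_ml: float
    reference_volume_ul: float

    def __post_init__(self) -> None:
        if self.added_volume_ul <= 0 or self.reference_volume_ul <= 0:
            raise PanelError("volumes must be positive")
        if self.stock_concentration_ng_ml < 0:
            raise PanelError("stock concentration cannot be negative")


def gradient_runtime(program: GradientProgram) -> float:
    """Total run time in minutes: the sum of segment durations."""
    return float(sum(seg.duration_min for seg in program.segments))


def default_gradient() -> GradientProgram:
    """The validated elution program: 25% B isocratic 0.5 min, linear ramp to
    95% B over 9.5 min, 2 min isocratic hold, 1 min re-equilibration."""
    return GradientProgram(
        segments=[
            GradientSegment(0.5, 25.0, "isocratic"),
            GradientSegment(9.5, 95.0, "linear"),
            GradientSegment(2.0, 95.0, "isocratic"),
            GradientSegment(1.0, 25.0, "linear"),
        ],
        flow_ml_min=0.5,
    )


def load_gradient(path: str | Path) -> GradientProgram:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    segs = [
        GradientSegment(float(s["duration_min"]), float(s["pct_b_end"]), str(s["mode"]))
        for s in doc["segments"]
    ]
    return GradientProgram(segments=segs, flow_ml_min=float(doc.get("flow_ml_min", 0.5)))


def write_gradient(program: GradientProgram, path: str | Path) -> None:
    doc = {
        "flow_ml_min": program.flow_ml_min,
        "segments": [
            {"duration_min": s.duration_min, "pct_b_end": s.pct_b_end, "mode": s.mode}
            for s in program.segments
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spike_final_concentration(plan: SpikePlan) -> float:
    """Concentration (ng/mL) contributed by a spike, referred to the reference
    sample volume: added mass / reference volume."""
    added_mass_ng = plan.added_volume_ul * 1e-3 * plan.stock_concentration_ng_ml
    return added_mass_ng / (plan.reference_volume_ul * 1e-3)


def _packaged(name: str):
    return resources.files("spotval.data").joinpath(name)


def load_transition_table(path: str | Path | None = None) -> list[Analyte]:
    """Parse a long-format transition CSV into the list of panel analytes.

    ``path=None`` loads the packaged panel fixture.  Rows sharing an
    ``analyte_id`` are merged into one :class:`Analyte`; the row with
    ordinal 1 becomes the quantifier transition.
    """
    if path is None:
        with resources.as_file(_packaged("transitions.csv")) as p:
            return load_transition_table(p)

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != _TRANSITION_COLUMNS:
            raise PanelError(
                f"unexpected transition-table header {reader.fieldnames}; "
                f"expected {_TRANSITION_COLUMNS}"
            )
        rows = list(reader)
    if not rows:
        raise PanelError("transition table contains no data rows (empty panel)")

    grouped: dict[str, list[dict]] = {}
    order: list[str] = []
    for row in rows:
        aid = row["analyte_id"]
        if aid not in grouped:
            grouped[aid] = []
            order.append(aid)
        grouped[aid].append(row)

    analytes: list[Analyte] = []
    for aid in order:
        group = sorted(grouped[aid], key=lambda r: int(r["ordinal"]))
        ordinals = [int(r["ordinal"]) for r in group]
        if ordinals != list(range(1, len(group) + 1)):
            raise PanelError(f"analyte {aid}: ordinals {ordinals} are not 1..n (duplicate row?)")
        first = group[0]
        transitions = [
            SrmTransition(
                precursor_mz=float(r["precursor_mz"]),
                product_mz=float(r["product_mz"]),
                collision_energy=float(r["ce_v"]),
                cell_exit_potential=float(r["cxp_v"]),
                is_quantifier=(int(r["ordinal"]) == 1),
            )
            for r in group
        ]
        try:
            analytes.append(
                Analyte(
                    id=aid,
                    name=first["name"],
                    family=first["family"],
                    retention_time=float(first["rt_min"]),
                    transitions=transitions,
                    internal_standard_id=first["internal_standard_id"] or None,
                )
            )
        except PanelError as err:
            raise PanelError(f"row group {aid!r}: {err}") from err

    is_ids = {a.id for a in analytes if a.is_internal_standard}
    for a in analytes:
        if a.internal_standard_id and a.internal_standard_id not in is_ids:
            raise PanelError(
                f"analyte {a.id}: internal_standard_id {a.internal_standard_id!r} "
                "does not resolve to an internal-standard entry"
            )
    return analytes


def write_transition_table(analytes: Sequence[Analyte], path: str | Path) -> None:
    """Inverse of :func:`load_transition_table` (field-for-field round trip)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TRANSITION_COLUMNS)
        for a in analytes:
            for ordinal, t in enumerate(a.transitions, start=1):
                writer.writerow(
                    [
                        a.id,
                        a.name,
                        a.family,
                        _fmt(a.retention_time),
                        _fmt(t.precursor_mz),
                        _fmt(t.product_mz),
                        _fmt(t.collision_energy),
                        _fmt(t.cell_exit_potential),
                        ordinal,
                        a.internal_standard_id or "",
                    ]
                )


def _fmt(value: float) -> str:
    return f"{value:g}"


def default_panel() -> list[Analyte]:
    """The packaged 25-target + 9-IS panel."""
    return load_transition_table(None)


def map_internal_standard(analyte_id: str, panel: Iterable[Analyte]) -> str:
    """Return the internal-standard id assigned to a target analyte."""
    by_id = {a.id: a for a in panel}
    if analyte_id not in by_id:
        raise PanelError(f"unknown analyte {analyte_id!r}")
    analyte = by_id[analyte_id]
    if analyte.is_internal_standard:
        raise PanelError(f"{analyte_id} is an internal standard and has no IS of its own")
    assert analyte.internal_standard_id is not None
    return analyte.internal_standard_id
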