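"""Blue Applicability Grade Index (BAGI) practicability scoring.

Ten attributes of equal importance are each graded on the discrete scale
{2.5, 5, 7.5, 10}; the total therefore spans 25-100 points and a method is
considered practical at >= 60.  Grades map to shades for the pictogram:
2.5 white (low), 5 pale blue, 7.5 light blue (medium), 10 dark blue (high).

The packaged reference assessment grades four attributes low (2.5), four
medium (7.5) and two high (10), totalling exactly the 60-point threshold.
The medium shade is mapped to 7.5 rather than 5 because only that choice
makes a 4-low/4-medium/2-high assignment attain the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ALLOWED_GRADES = (2.5, 5.0, 7.5, 10.0)
PRACTICALITY_THRESHOLD = 60.0

SHADES = {2.5: "white", 5.0: "pale blue", 7.5: "light blue", 10.0: "dark blue"}

ATTRIBUTE_NAMES = (
    "type of analysis",
    "number of analytes determined simultaneously",
    "analytical technique / instrumentation",
    "simultaneous sample preparation capacity",
    "sample preparation steps",
    "samples analysed per hour",
    "reagents and materials availability",
    "preconcentration requirement",
    "degree of automation",
    "amount of sample required",
)


class BagiError(ValueError):
    pass


@dataclass(frozen=True)
class BagiAttribute:
    name: str
    grade: float
    justification: str = ""

    def __post_init__(self) -> None:
        if self.grade not in ALLOWED_GRADES:
            raise BagiError(f"grade {self.grade} not in allowed set {ALLOWED_GRADES}")

    @property
    def shade(self) -> str:
        return SHADES[self.grade]


@dataclass
class BagiAssessment:
    attributes: list[BagiAttribute] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.attributes) != 10:
            raise BagiError(f"exactly 10 attributes required, got {len(self.attributes)}")


@dataclass(frozen=True)
class BagiScore:
    total: float
    practical: bool


def bagi_score(assessment: BagiAssessment) -> BagiScore:
    """Sum of the ten grades plus the >= 60-point practicality verdict."""
    total = float(sum(a.grade for a in assessment.attributes))
    return BagiScore(total=total, practical=total >= PRACTICALITY_THRESHOLD)


def reference_assessment() -> BagiAssessment:
    """The packaged assessment of the DBS LC-MS/MS workflow: quantitative
    multi-analyte analysis with moderate automation and throughput (medium),
    complex multi-step preparation with preconcentration on expensive
    instrumentation (low), commercial reagents and a 10 uL sample (high)."""
    grades = {
        "type of analysis": (7.5, "quantitative analysis"),
        "number of analytes determined simultaneously": (7.5, "25 compounds from four classes"),
        "analytical technique / instrumentation": (2.5, "UHPLC-MS/MS required"),
        "simultaneous sample preparation capacity": (7.5, "13-95 samples in parallel"),
        "sample preparation steps": (2.5, "multi-step preparation"),
        "samples analysed per hour": (2.5, "about one sample per hour"),
        "reagents and materials availability": (10.0, "commercially available reagents"),
        "preconcentration requirement": (2.5, "extraction, evaporation and reconstitution"),
        "degree of automation": (7.5, "automatic injection, semi-automatic detection"),
        "amount of sample required": (10.0, "10 uL of capillary blood"),
    }
    return BagiAssessment(
        attributes=[BagiAttribute(name, g, j) for name, (g, j) in grades.items()]
    )


def render_text(assessment: BagiAssessment) -> str:
    """Plain-text pictogram substitute: one line per attribute plus total."""
    score = bagi_score(assessment)
    lines = [f"BAGI assessment - total {score.total:g} points "
             f"({'practical' if score.practical else 'not practical'}, threshold {PRACTICALITY_THRESHOLD:g})"]
    for i, attr in enumerate(assessment.attributes, start=1):
        lines.append(f" {i:2d}. [{attr.grade:>4g} | {attr.shade:<10s}] {attr.name}"
                     + (f" - {attr.justification}" if attr.justification else ""))
    return "\n".join(lines)
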