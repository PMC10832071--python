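"""The matrix-model composite score.

Three dichotomous components, each worth 1 or 2 points, multiplied:

* ARCO stage — I scores 1, II scores 2;
* JIC lesion location — medial column (A, B) scores 1, lateral column
  (C1, C2) scores 2;
* necrotic area — at most 50% of the femoral head scores 1, above 50%
  scores 2.

The product therefore takes exactly the values {1, 2, 4, 8}; higher values
flag hips at higher risk of structural collapse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .cohort import AreaCategory, ArcoStage, JicType

SCORE_LEVELS = (1, 2, 4, 8)

_ARCO_POINTS = {ArcoStage.I: 1, ArcoStage.II: 2}
_JIC_POINTS = {JicType.A: 1, JicType.B: 1, JicType.C1: 2, JicType.C2: 2}
_AREA_POINTS = {
    AreaCategory.LT30: 1,
    AreaCategory.FROM30TO50: 1,
    AreaCategory.GT50: 2,
}


@dataclass(frozen=True)
class MatrixScore:
    arco_points: int
    jic_points: int
    area_points: int

    def __post_init__(self) -> None:
        for p in (self.arco_points, self.jic_points, self.area_points):
            if p not in (1, 2):
                raise ValueError(f"component points must be 1 or 2, got {p}")

    @property
    def value(self) -> int:
        return self.arco_points * self.jic_points * self.area_points


def discretize_area(fraction: float) -> AreaCategory:
    """Bin a necrotic-area fraction: [0, 0.30) / [0.30, 0.50] / (0.50, 1].

    A fraction of exactly 0.50 falls in the 30-50% bin (and scores 1 point):
    the published bins are "<30%", "30-50%" and ">50%", so the boundary
    belongs to the lower stratum.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"area fraction must lie in [0, 1], got {fraction}")
    if fraction < 0.30:
        return AreaCategory.LT30
    if fraction <= 0.50:
        return AreaCategory.FROM30TO50
    return AreaCategory.GT50


def component_points(
    factor: str, value: Union[str, float, ArcoStage, JicType, AreaCategory]
) -> int:
    """Points (1 or 2) for one component: factor in {"ARCO", "JIC", "AREA"}.

    AREA accepts either a category or a fraction in [0, 1]; a fraction of
    exactly 0.50 scores 1 (the lower stratum, see :func:`discretize_area`).
    """
    factor = factor.upper()
    if factor == "ARCO":
        stage = ArcoStage(value) if not isinstance(value, ArcoStage) else value
        return _ARCO_POINTS[stage]
    if factor == "JIC":
        jic = JicType(value) if not isinstance(value, JicType) else value
        return _JIC_POINTS[jic]
    if factor == "AREA":
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            return _AREA_POINTS[discretize_area(float(value))]
        cat = AreaCategory(value) if not isinstance(value, AreaCategory) else value
        return _AREA_POINTS[cat]
    raise ValueError(f"unknown factor {factor!r} (expected ARCO, JIC or AREA)")


def matrix_score(
    arco_stage: Union[str, ArcoStage],
    jic_type: Union[str, JicType],
    area: Union[str, float, AreaCategory],
) -> MatrixScore:
    """Composite score for one hip: the product of the three component points."""
    return MatrixScore(
        arco_points=component_points("ARCO", arco_stage),
        jic_points=component_points("JIC", jic_type),
        area_points=component_points("AREA", area),
    )
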