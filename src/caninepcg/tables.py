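"""Published cohort frequency tables, stored verbatim as fixtures.

Two cross-tabulations from the study cohort (756 referral-centre dogs) are
encoded as printed:

* ``table2`` — murmur maximum intensity (reduced scale) and point of maximal
  intensity, per primary diagnosis.  Column totals can exceed the per-disease
  case counts because dogs with multiple diagnoses are counted in each
  relevant column; printed percentages use the column total as denominator.
* ``table3`` — characteristics of MMVD dogs by ACVIM stage (A, B1, B2, C/D):
  left-apex murmur grade, body condition score, sex, medication and
  arrhythmia frequencies, plus medians and interquartile ranges for age,
  body weight, LA/Ao and LVIDDN.

These drive both the default marginals of the synthetic-cohort generator and
the cross-tabulation reproduction checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .grades import GRADES

DISEASES = ("normal", "MMVD", "PS", "AS", "PDA", "DCM")
SITES = ("left_apex", "left_base", "right_side")
STAGES = ("A", "B1", "B2", "C/D")

# Murmur maximum intensity counts per primary diagnosis.
_T2_MAX_INTENSITY = {
    "normal": {"none": 94, "soft": 37, "moderate": 3, "loud": 0, "thrilling": 0},
    "MMVD": {"none": 7, "soft": 87, "moderate": 114, "loud": 139, "thrilling": 64},
    "PS": {"none": 0, "soft": 3, "moderate": 11, "loud": 10, "thrilling": 25},
    "AS": {"none": 0, "soft": 9, "moderate": 9, "loud": 11, "thrilling": 3},
    "PDA": {"none": 2, "soft": 8, "moderate": 2, "loud": 3, "thrilling": 19},
    "DCM": {"none": 4, "soft": 11, "moderate": 7, "loud": 2, "thrilling": 0},
}

# Point of maximal intensity per primary diagnosis ("none" = no murmur).
_T2_POINT_OF_MAX = {
    "normal": {"none": 94, "left_base": 21, "left_apex": 17, "right_side": 2},
    "MMVD": {"none": 7, "left_base": 3, "left_apex": 384, "right_side": 15},
    "PS": {"none": 0, "left_base": 41, "left_apex": 8, "right_side": 0},
    "AS": {"none": 0, "left_base": 23, "left_apex": 8, "right_side": 1},
    "PDA": {"none": 2, "left_base": 23, "left_apex": 8, "right_side": 1},
    "DCM": {"none": 4, "left_base": 3, "left_apex": 17, "right_side": 0},
}

_T3_N = {"A": 62, "B1": 225, "B2": 131, "C/D": 51}

_T3_LEFT_APEX_GRADE = {
    "A": {"none": 50, "soft": 12, "moderate": 0, "loud": 0, "thrilling": 0},
    "B1": {"none": 7, "soft": 88, "moderate": 79, "loud": 47, "thrilling": 4},
    "B2": {"none": 0, "soft": 2, "moderate": 33, "loud": 64, "thrilling": 32},
    "C/D": {"none": 0, "soft": 1, "moderate": 3, "loud": 25, "thrilling": 22},
}

_T3_CATEGORICAL = {
    "bcs_lt5": {"A": 44, "B1": 129, "B2": 71, "C/D": 39},
    "bcs_5to9": {"A": 16, "B1": 85, "B2": 52, "C/D": 8},
    "ckcs": {"A": 2, "B1": 38, "B2": 33, "C/D": 11},
    "female_entire": {"A": 11, "B1": 18, "B2": 9, "C/D": 2},
    "female_neutered": {"A": 22, "B1": 80, "B2": 59, "C/D": 24},
    "male_entire": {"A": 15, "B1": 48, "B2": 16, "C/D": 6},
    "male_neutered": {"A": 14, "B1": 78, "B2": 45, "C/D": 18},
    "pimobendan": {"A": 0, "B1": 16, "B2": 50, "C/D": 37},
    "arrhythmia": {"A": 14, "B1": 57, "B2": 38, "C/D": 22},
}

# median, (lower quartile, upper quartile)
_T3_CONTINUOUS = {
    "age_years": {
        "A": (4.4, (2.1, 8.2)), "B1": (9.5, (7.8, 11.0)),
        "B2": (10.0, (8.6, 12.0)), "C/D": (10.0, (9.2, 12.0)),
    },
    "body_weight_kg": {
        "A": (8.8, (5.3, 11.0)), "B1": (9.8, (6.9, 15.0)),
        "B2": (8.7, (6.0, 12.0)), "C/D": (9.3, (5.2, 13.0)),
    },
    "la_ao": {
        "A": (1.40, (1.30, 1.43)), "B1": (1.42, (1.35, 1.50)),
        "B2": (1.80, (1.70, 1.98)), "C/D": (2.29, (1.96, 2.69)),
    },
    "lviddn": {
        "A": (1.52, (1.42, 1.59)), "B1": (1.57, (1.44, 1.66)),
        "B2": (1.88, (1.77, 1.99)), "C/D": (2.20, (1.95, 2.38)),
    },
}


@dataclass(frozen=True)
class PublishedTableFixture:
    """Printed frequency counts for one published cross-tabulation."""

    table_id: str
    counts: dict = field(default_factory=dict)

    def count(self, *keys) -> int:
        node = self.counts
        for k in keys:
            try:
                node = node[k]
            except KeyError:
                raise KeyError(f"no cell {keys!r} in {self.table_id}")
        if not isinstance(node, int):
            raise KeyError(f"{keys!r} does not address a single cell of {self.table_id}")
        return node


_FIXTURES = {
    "table2": PublishedTableFixture(
        "table2",
        {"max_intensity": _T2_MAX_INTENSITY, "point_of_max": _T2_POINT_OF_MAX},
    ),
    "table3": PublishedTableFixture(
        "table3",
        {
            "n": _T3_N,
            "left_apex_grade": _T3_LEFT_APEX_GRADE,
            **{k: dict(v) for k, v in _T3_CATEGORICAL.items()},
        },
    ),
}


def load_table_fixtures(table_id: str) -> PublishedTableFixture:
    """Return the fixture for ``table2`` or ``table3``."""
    try:
        return _FIXTURES[table_id]
    except KeyError:
        raise ValueError(f"unknown table_id {table_id!r}; known: {sorted(_FIXTURES)}")


def stage_medians(variable: str) -> dict[str, tuple[float, tuple[float, float]]]:
    """Median and IQR of a continuous MMVD-stage variable, as printed."""
    try:
        return dict(_T3_CONTINUOUS[variable])
    except KeyError:
        raise ValueError(f"unknown variable {variable!r}; known: {sorted(_T3_CONTINUOUS)}")


def _column_proportions(column: dict[str, int]) -> dict[str, float]:
    total = sum(column.values())
    return {k: v / total for k, v in column.items()}


def disease_grade_proportions(disease: str) -> dict[str, float]:
    """Reduced-grade proportions for a diagnosis (column-total denominator)."""
    if disease not in _T2_MAX_INTENSITY:
        raise ValueError(f"unknown disease {disease!r}")
    return _column_proportions(_T2_MAX_INTENSITY[disease])


def stage_grade_proportions(stage: str) -> dict[str, float]:
    """Left-apex reduced-grade proportions for an ACVIM MMVD stage."""
    if stage not in _T3_LEFT_APEX_GRADE:
        raise ValueError(f"unknown stage {stage!r}")
    return _column_proportions(_T3_LEFT_APEX_GRADE[stage])


def point_of_max_proportions(disease: str) -> dict[str, float]:
    """Point-of-maximal-intensity proportions for a diagnosis."""
    if disease not in _T2_POINT_OF_MAX:
        raise ValueError(f"unknown disease {disease!r}")
    return _column_proportions(_T2_POINT_OF_MAX[disease])


assert set(GRADES) == set(next(iter(_T2_MAX_INTENSITY.values())))
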