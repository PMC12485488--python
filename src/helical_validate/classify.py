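"""Error-class assignment for deposited helical parameters.

EMDB surveys of helical reconstructions show a recurring taxonomy of
metadata faults: parameters missing entirely, numerically swapped twist
and rise, a flipped twist sign, a correct-but-partial symmetry (an
integer multiple of the full screw step), and outright incorrect values.
Given a density map, the deposited parameters and the map-derived
parameters, :func:`classify` assigns one of these classes by a fixed
decision cascade, and :func:`validate_entry` runs the whole pipeline on
a map.

The cascade order — consistent → swapped → sign → partial → incorrect —
puts cheap, specific explanations before generic ones, so near-degenerate
parameter pairs (e.g. twist numerically close to rise) are not relabelled
spuriously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import HelicalParams, flip_sign, swap, wrap_twist
from .indexing import (
    AMYLOID_ANGULAR_STEP,
    AMYLOID_AXIAL_STEP,
    DEFAULT_ANGULAR_STEP,
    DEFAULT_AXIAL_STEP,
    IndexingError,
    IndexingResult,
    estimate_radius,
    index_helical_params,
    radial_profile,
)
from .metrics import (
    CorrelationScores,
    NormalizedDifference,
    VectorMetricResult,
    compare_by_symmetrization,
    normalized_difference,
    vector_difference,
)
from .volume import DensityMap, normalize_axes, orient_helical_axis

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorClass",
    "ValidationConfig",
    "PartialSymmetryRelation",
    "ComparisonMetrics",
    "ValidationRecord",
    "EMDB_ERROR_SURVEY",
    "SurveyRow",
    "survey_percentages",
    "find_multiplier",
    "classify",
    "validate_entry",
    "write_report",
]


class ErrorClass(str, Enum):
    NO_VALUES = "no_values"
    INCORRECT_VALUES = "incorrect_values"
    TWIST_RISE_SWAPPED = "twist_rise_swapped"
    INCORRECT_TWIST_SIGN = "incorrect_twist_sign"
    PARTIAL_SYMMETRY = "partial_symmetry"
    CONSISTENT = "consistent"
    NOT_VALIDATED = "not_validated"


@dataclass(frozen=True)
class SurveyRow:
    """One row of the published EMDB helical-parameter error survey."""

    error_class: ErrorClass
    count: int
    printed_percent: float
    example_entry: str
    deposited: HelicalParams | None
    validated: HelicalParams


#: Published tally of error classes among the 2025 helical-reconstruction
#: entries of the EMDB (April 2025 snapshot), with one worked example per
#: class.  Percentages are as printed in the survey, to two decimals.
EMDB_ERROR_SURVEY: tuple[SurveyRow, ...] = (
    SurveyRow(ErrorClass.NO_VALUES, 58, 2.86, "EMD-5185", None, HelicalParams(22.03, 1.41)),
    SurveyRow(ErrorClass.INCORRECT_VALUES, 13, 0.64, "EMD-31367",
              HelicalParams(-16.82, 3.49), HelicalParams(-26.83, 3.5)),
    SurveyRow(ErrorClass.TWIST_RISE_SWAPPED, 10, 0.49, "EMD-25211",
              HelicalParams(9.68, 130.78), HelicalParams(130.78, 9.68)),
    SurveyRow(ErrorClass.INCORRECT_TWIST_SIGN, 151, 7.46, "EMD-60656",
              HelicalParams(75.13, 11.54), HelicalParams(-75.13, 11.54)),
    SurveyRow(ErrorClass.PARTIAL_SYMMETRY, 50, 2.47, "EMD-43868",
              HelicalParams(-0.3, 111.12), HelicalParams(65.42, 5.07)),
)

EMDB_SURVEY_TOTAL_ENTRIES = 2025


def survey_percentages() -> dict[ErrorClass, float]:
    """Error-class percentages recomputed from the survey counts."""
    return {
        row.error_class: round(100.0 * row.count / EMDB_SURVEY_TOTAL_ENTRIES, 2)
        for row in EMDB_ERROR_SURVEY
    }


@dataclass(frozen=True)
class ValidationConfig:
    """Tunable thresholds of the validation cascade.

    The defaults accept the EMD-43868-style partial-symmetry relation
    (rise error 0.38%, twist error 0.46°) with margin, and treat
    correlation scores below 0.5 as uninformative.
    """

    tol_rise: float = 0.02  # fractional rise mismatch for the multiplier test
    tol_twist: float = 1.0  # degrees, twist mismatch for the multiplier test
    n_max: int = 100  # multiplier search bound
    cc_high: float = 0.5  # a symmetrize-and-correlate score below this is "low"
    cc_close: float = 0.1  # |cc_dep - cc_val| below this counts as "similar"
    cc_significant: float = 0.1  # cc_val - cc_dep above this is "significantly higher"
    # indexing
    angular_step: float = DEFAULT_ANGULAR_STEP
    axial_step: float = DEFAULT_AXIAL_STEP
    amyloid_auto: bool = True  # fine sampling when deposited rise < 10 Å, |twist| < 10 deg
    retry_grid: tuple[tuple[float, float], ...] = (
        (1.0, 1.0),
        (1.0, 0.5),
        (0.5, 0.5),
        (0.5, 0.2),
        (1.0, 0.2),
        (0.5, 1.0),
    )


@dataclass(frozen=True)
class PartialSymmetryRelation:
    """Deposited and validated parameters related by an integer multiplier."""

    n: int
    rise_error: float  # fractional
    twist_error: float  # degrees, wrapped
    deposited_is_coarser: bool = True  # False when roles were exchanged


@dataclass(frozen=True)
class ComparisonMetrics:
    """Bundle of all three metrics for one entry."""

    normalized: NormalizedDifference | None
    vector: VectorMetricResult | None
    cc: CorrelationScores | None  # None when symmetrize-and-correlate failed
    radius: float  # Å, from the radial profile of the map


@dataclass(frozen=True)
class ValidationRecord:
    entry_id: str
    deposited: HelicalParams | None
    detected: HelicalParams | None  # None when indexing failed
    error_class: ErrorClass
    corrected: HelicalParams | None
    multiplier: int | None
    metrics: ComparisonMetrics | None
    reported_resolution: float | None
    note: str = ""


def find_multiplier(
    p_dep: HelicalParams,
    p_val: HelicalParams,
    n_max: int = 100,
    tol_rise: float = 0.02,
    tol_twist: float = 1.0,
) -> PartialSymmetryRelation | None:
    """Test whether two parameter sets are related by an integer multiplier.

    With z_small the smaller rise, the candidate is n = round(z_big /
    z_small); it is accepted if 2 <= n <= n_max, the reconstructed rise
    matches within ``tol_rise`` (fractional) and the reconstructed twist
    within ``tol_twist`` degrees modulo 360.  Returns None otherwise.
    """
    if p_val.rise <= p_dep.rise:
        small, big = p_val, p_dep
        deposited_is_coarser = True
    else:
        small, big = p_dep, p_val
        deposited_is_coarser = False
    n = round(big.rise / small.rise)
    if n < 2 or n > n_max:
        return None
    rise_error = abs(big.rise - n * small.rise) / big.rise
    twist_error = abs(wrap_twist(n * small.twist - big.twist))
    if rise_error <= tol_rise and twist_error <= tol_twist:
        return PartialSymmetryRelation(
            n=n,
            rise_error=rise_error,
            twist_error=twist_error,
            deposited_is_coarser=deposited_is_coarser,
        )
    return None


def _is_swap_plausible(
    deposited: HelicalParams, voxel_size: float, box_height: float
) -> bool:
    """A swapped reading must put a physically sensible rise on the grid."""
    candidate_rise = abs(deposited.twist)
    return voxel_size < candidate_rise < box_height


def classify(
    deposited: HelicalParams | None,
    detected: IndexingResult | None,
    metrics: ComparisonMetrics | None,
    reported_resolution: float | None,
    config: ValidationConfig = ValidationConfig(),
    voxel_size: float = 1.0,
    box_height: float = float("inf"),
    entry_id: str = "",
) -> ValidationRecord:
    """Assign an error class by the decision cascade (first match wins).

    1. no deposited parameters → ``no_values``;
    2. indexing failed, or both correlation scores low → ``not_validated``;
    3. deposited ≈ detected (vector metric vs resolution) → ``consistent``;
    4. swap(deposited) ≈ detected → ``twist_rise_swapped``;
    5. flip_sign(deposited) ≈ detected → ``incorrect_twist_sign``;
    6. integer multiplier found and both scores high and close →
       ``partial_symmetry``;
    7. validated score significantly higher → ``incorrect_values``;
       otherwise ``not_validated``.
    """
    det_params = detected.params if detected is not None else None

    def record(error_class, corrected, multiplier=None, note=""):
        return ValidationRecord(
            entry_id=entry_id,
            deposited=deposited,
            detected=det_params,
            error_class=error_class,
            corrected=corrected,
            multiplier=multiplier,
            metrics=metrics,
            reported_resolution=reported_resolution,
            note=note,
        )

    if deposited is None:
        if det_params is None:
            return record(ErrorClass.NOT_VALIDATED, None, note="indexing failed")
        return record(ErrorClass.NO_VALUES, det_params)

    cc = metrics.cc if metrics is not None else None
    if det_params is None or (
        cc is not None
        and np.isfinite(cc.cc_deposited)
        and cc.cc_deposited < config.cc_high
        and cc.cc_validated < config.cc_high
    ):
        return record(
            ErrorClass.NOT_VALIDATED,
            None,
            note="indexing failed" if det_params is None else "both correlations low",
        )

    threshold = (
        reported_resolution if reported_resolution is not None else 2.0 * voxel_size
    )
    radius = metrics.radius

    def similar(p: HelicalParams) -> bool:
        return vector_difference(p, det_params, radius).distance < threshold

    if similar(deposited):
        return record(ErrorClass.CONSISTENT, deposited)

    if (
        deposited.twist > 0
        and _is_swap_plausible(deposited, voxel_size, box_height)
        and similar(swap(deposited))
    ):
        return record(ErrorClass.TWIST_RISE_SWAPPED, det_params)

    if similar(flip_sign(deposited)):
        return record(ErrorClass.INCORRECT_TWIST_SIGN, det_params)

    relation = find_multiplier(
        deposited,
        det_params,
        n_max=config.n_max,
        tol_rise=config.tol_rise,
        tol_twist=config.tol_twist,
    )
    cc_ok = (
        cc is not None
        and np.isfinite(cc.cc_deposited)
        and cc.cc_deposited >= config.cc_high
        and cc.cc_validated >= config.cc_high
        and abs(cc.cc_validated - cc.cc_deposited) <= config.cc_close
    )
    if relation is not None and cc_ok:
        return record(
            ErrorClass.PARTIAL_SYMMETRY, det_params, multiplier=relation.n
        )

    if (
        cc is not None
        and np.isfinite(cc.cc_deposited)
        and cc.cc_validated - cc.cc_deposited > config.cc_significant
    ):
        return record(ErrorClass.INCORRECT_VALUES, det_params)

    return record(ErrorClass.NOT_VALIDATED, None, note="no cascade rule matched")


def _maybe_amyloid_steps(
    deposited: HelicalParams | None, config: ValidationConfig
) -> tuple[float, float]:
    """Fine sampling for thin-twist, short-rise (amyloid-like) entries."""
    if (
        config.amyloid_auto
        and deposited is not None
        and deposited.rise < 10.0
        and abs(deposited.twist) < 10.0
    ):
        return AMYLOID_ANGULAR_STEP, AMYLOID_AXIAL_STEP
    return config.angular_step, config.axial_step


def validate_entry(
    density_map: DensityMap,
    deposited: HelicalParams | None,
    reported_resolution: float | None = None,
    config: ValidationConfig = ValidationConfig(),
    entry_id: str = "",
    helical_axis: str = "Z",
) -> ValidationRecord:
    """Full validation pipeline for one map.

    normalize axes → orient the helical axis → index (retrying over the
    sampling grid on failure) → metrics → classify.  Deterministic for a
    given map, inputs and configuration.
    """
    m = normalize_axes(density_map)
    m = orient_helical_axis(m, helical_axis)

    angular_step, axial_step = _maybe_amyloid_steps(deposited, config)
    detected: IndexingResult | None = None
    tried = [(angular_step, axial_step)] + [
        g for g in config.retry_grid if g != (angular_step, axial_step)
    ]
    for astep, zstep in tried:
        try:
            candidate = index_helical_params(m, angular_step=astep, axial_step=zstep)
        except (IndexingError, ValueError) as exc:
            logger.info("indexing failed at (%.2f deg, %.2f A): %s", astep, zstep, exc)
            continue
        if candidate.params.rise < m.voxel_size:
            # a rise below one voxel cannot be resolved on this grid;
            # treat it as a spurious near-equator peak and retry finer
            logger.info(
                "discarding sub-voxel rise %.2f A at (%.2f deg, %.2f A)",
                candidate.params.rise, astep, zstep,
            )
            continue
        detected = candidate
        break
    metrics = None
    if detected is not None:
        radius = estimate_radius(radial_profile(m))
        try:
            cc = compare_by_symmetrization(m, deposited, detected.params)
        except ValueError as exc:
            logger.info("symmetrize-and-correlate failed: %s", exc)
            cc = None
        norm = vec = None
        if deposited is not None:
            norm = normalized_difference(deposited, detected.params)
            vec = vector_difference(
                deposited, detected.params, radius, resolution=reported_resolution
            )
        metrics = ComparisonMetrics(normalized=norm, vector=vec, cc=cc, radius=radius)
    return classify(
        deposited,
        detected,
        metrics,
        reported_resolution,
        config=config,
        voxel_size=m.voxel_size,
        box_height=m.axial_extent,
        entry_id=entry_id,
    )


_REPORT_COLUMNS = [
    "entry_id",
    "deposited_twist",
    "deposited_rise",
    "deposited_csym",
    "validated_twist",
    "validated_rise",
    "validated_csym",
    "error_class",
    "multiplier",
    "delta_twist",
    "delta_rise",
    "vector_distance",
    "cc_deposited",
    "cc_validated",
    "reported_resolution",
    "note",
]


def write_report(records: Iterable[ValidationRecord], path: str | Path) -> pd.DataFrame:
    """Write validation records to CSV, one row per entry (order preserved)."""
    rows = []
    for r in records:
        m = r.metrics
        rows.append(
            {
                "entry_id": r.entry_id,
                "deposited_twist": r.deposited.twist if r.deposited else None,
                "deposited_rise": r.deposited.rise if r.deposited else None,
                "deposited_csym": r.deposited.csym if r.deposited else None,
                "validated_twist": r.detected.twist if r.detected else None,
                "validated_rise": r.detected.rise if r.detected else None,
                "validated_csym": r.detected.csym if r.detected else None,
                "error_class": r.error_class.value,
                "multiplier": r.multiplier,
                "delta_twist": m.normalized.delta_twist if m and m.normalized else None,
                "delta_rise": m.normalized.delta_rise if m and m.normalized else None,
                "vector_distance": m.vector.distance if m and m.vector else None,
                "cc_deposited": m.cc.cc_deposited if m else None,
                "cc_validated": m.cc.cc_validated if m else None,
                "reported_resolution": r.reported_resolution,
                "note": r.note,
            }
        )
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.4f")
    return df
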