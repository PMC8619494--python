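"""End-to-end glue: study → nSSC + c-Ag pairs → fitted calibration.

These helpers chain the per-module operations in the order a real analysis
runs them: summarize and normalize side scatter per batch, convert ICPMS
masses to particles per cell, pair the two per sample, and fit the per-size
lines plus the exponential size model.
"""

from __future__ import annotations

from .calibration import CalibrationModel, CalibrationPoint
from .cytometry import normalize_ssc, summarize_ssc
from .icpms import cellular_np_count
from .synthetic import SyntheticStudy


def study_to_points(
    study: SyntheticStudy, ssc_channel: str = "SSC-A"
) -> list[CalibrationPoint]:
    """Pair each exposed sample's nSSC with its ICPMS-derived c-Ag."""
    tables = {t.sample_id: t for t in study.event_tables}
    summaries = {}
    for s in study.design:
        summaries[s.sample_id] = summarize_ssc(
            tables[s.sample_id], ssc_channel, batch_id=s.batch_id
        )
    icpms_by_id = {m.sample_id: m for m in study.icpms_table}

    points: list[CalibrationPoint] = []
    for s in study.design:
        if s.condition is None:
            continue
        norm = normalize_ssc(
            summaries[s.sample_id], summaries[s.control_id], condition=s.condition
        )
        count = cellular_np_count(
            icpms_by_id[s.sample_id],
            s.condition.core_diameter,
            density=study.config.density,
        )
        points.append(
            CalibrationPoint(
                nssc=norm.nssc, c_ag=count.c_ag, condition=s.condition
            )
        )
    return points


def calibrate_study(
    study: SyntheticStudy, ssc_channel: str = "SSC-A", fit_size_model: bool = True
) -> CalibrationModel:
    """Run the full calibration on a study (all points used for training)."""
    return CalibrationModel.fit(
        study_to_points(study, ssc_channel), fit_size_model=fit_size_model
    )


__all__ = ["calibrate_study", "study_to_points"]
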