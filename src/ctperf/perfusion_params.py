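"""Quantitative static-CTP parameters per myocardial segment.

Three parameters, all of which decrease with hypoperfusion:

* endocardial CT attenuation (HU) — raw, affected by patient-level
  variability in delivered contrast;
* TPR (transmural perfusion ratio) — a segment's endocardial attenuation
  divided by the mean epicardial attenuation of all 16 segments;
* MPR (myocardial perfusion ratio) — a segment's subendocardial
  *enhancement* (baseline-subtracted) divided by the aortic peak
  enhancement of the timing-bolus scan.

MPR and TPR are scale-invariant: multiplying every HU input by c > 0
changes neither.  Raw attenuation is not — that differential is the whole
point of the ratio parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateStatisticError, InputError

__all__ = [
    "PAPER_CUTOFFS",
    "SegmentParameters",
    "compute_mpr",
    "compute_tpr",
    "classify_segment",
    "parameter_table",
]

#: Published operating cutoffs (Youden-optimal in the source study):
#: endocardial attenuation 106 HU, TPR 0.92, MPR 0.81.
PAPER_CUTOFFS = {"endo_hu": 106.0, "tpr": 0.92, "mpr": 0.81}


@dataclass(frozen=True)
class SegmentParameters:
    segment_id: int
    endo_attenuation: float
    tpr: float
    mpr: float


def compute_mpr(endo_enhancement: float, aortic_pe_timing_bolus: float) -> float:
    """Myocardial perfusion ratio: subendocardial enhancement / timing-bolus aortic PE.

    A nonpositive denominator signals failed bolus detection.
    """
    if aortic_pe_timing_bolus <= 0:
        raise DegenerateStatisticError(
            f"aortic timing-bolus PE must be positive, got {aortic_pe_timing_bolus}")
    return float(endo_enhancement) / float(aortic_pe_timing_bolus)


def compute_tpr(segment_endo_attenuation: float, all_epi_attenuations) -> float:
    """Transmural perfusion ratio: endocardial attenuation of one segment
    divided by the mean epicardial attenuation of all 16 segments."""
    epi = np.asarray(all_epi_attenuations, dtype=float)
    if epi.shape != (16,):
        raise InputError(f"all_epi_attenuations must hold 16 values, got shape {epi.shape}")
    mean_epi = float(epi.mean())
    if mean_epi <= 0:
        raise DegenerateStatisticError(
            f"mean epicardial attenuation must be positive, got {mean_epi}")
    return float(segment_endo_attenuation) / mean_epi


def classify_segment(value: float, cutoff: float,
                     direction: str = "lower_is_abnormal") -> bool:
    """Binary call against a cutoff; returns True when abnormal.

    All three parameters decrease with hypoperfusion, so the convention is
    abnormal iff ``value < cutoff``; a value exactly at the cutoff is
    called normal.
    """
    if direction != "lower_is_abnormal":
        raise InputError(f"unsupported direction '{direction}'")
    if not np.isfinite(cutoff):
        raise InputError(f"cutoff must be finite, got {cutoff}")
    return bool(value < cutoff)


def parameter_table(segment_frame: pd.DataFrame, pe_timing: float,
                    cutoffs: dict | None = None) -> pd.DataFrame:
    """Append mpr/tpr (and optional binary calls) to a 16-row segment table.

    ``segment_frame`` needs columns ``segment_id, endo_hu, epi_hu,
    endo_enh_hu`` (one patient, 16 rows).
    """
    df = segment_frame.copy()
    if len(df) != 16:
        raise InputError(f"expected 16 segment rows per patient, got {len(df)}")
    epi = df["epi_hu"].to_numpy()
    df["mpr"] = [compute_mpr(e, pe_timing) for e in df["endo_enh_hu"]]
    df["tpr"] = [compute_tpr(v, epi) for v in df["endo_hu"]]
    if cutoffs is not None:
        for key in ("mpr", "tpr", "endo_hu"):
            if key in cutoffs:
                df[f"call_{key}"] = [
                    classify_segment(v, cutoffs[key]) for v in df[key]
                ]
    return df
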