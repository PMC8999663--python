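"""Time-attenuation-curve analysis for cardiac CT perfusion.

A time-attenuation curve (TAC) samples the CT attenuation (HU) of a region
of interest — the ascending aorta or a myocardial segment — over the frames
of a dynamic acquisition.  Peak enhancement (PE) is the difference between
the baseline attenuation (before contrast arrival) and the peak attenuation
of the curve; the aortic PE of a diluted timing-bolus scan is the
denominator of the myocardial perfusion ratio.

The static perfusion image is one frame selected from the dynamic series:
late enough that the myocardium has enhanced, at or after the aortic
first-pass peak.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import InputError, DegenerateStatisticError

__all__ = [
    "TimeAttenuationCurve",
    "PeakEnhancement",
    "compute_peak_enhancement",
    "select_static_phase",
    "pe_correlation",
    "tacs_to_csv",
    "tacs_from_csv",
]


@dataclass(frozen=True)
class TimeAttenuationCurve:
    """Sampled HU values over frames for one anatomical ROI.

    Parameters
    ----------
    frame_times : array of float
        Acquisition time of each frame in seconds, strictly increasing.
    values : array of float
        Mean ROI attenuation in HU, one per frame.
    roi_label : str
        ``"aorta"`` or a segment identifier such as ``"segment_07"``.
    """

    frame_times: np.ndarray
    values: np.ndarray
    roi_label: str = "aorta"

    def __post_init__(self):
        times = np.asarray(self.frame_times, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or vals.ndim != 1 or times.size != vals.size:
            raise InputError("frame_times and values must be 1-D and the same length")
        if times.size < 3:
            raise InputError("a time-attenuation curve needs at least 3 frames")
        if not np.all(np.diff(times) > 0):
            raise InputError("frame_times must be strictly increasing")
        object.__setattr__(self, "frame_times", times)
        object.__setattr__(self, "values", vals)

    @property
    def n_frames(self) -> int:
        return self.frame_times.size


@dataclass(frozen=True)
class PeakEnhancement:
    """Baseline, peak, and their difference for one TAC.

    ``pe = peak - baseline`` exactly; ``peak`` is the maximum over the
    frames after the baseline window (not necessarily the global maximum).
    """

    baseline: float
    peak: float
    pe: float
    peak_frame: int

    def to_record(self) -> dict:
        return asdict(self)


def compute_peak_enhancement(
    tac: TimeAttenuationCurve,
    n_baseline_frames: int = 1,
    smooth_window: int = 1,
) -> PeakEnhancement:
    """Peak enhancement of a TAC: peak minus pre-contrast baseline.

    The baseline is the mean of the first ``n_baseline_frames`` values; the
    peak is the maximum of the remaining values.  A flat curve yields
    ``pe = 0`` (not an error).

    Parameters
    ----------
    n_baseline_frames : int
        Length of the pre-contrast window; must satisfy
        ``1 <= n_baseline_frames < n_frames``.
    smooth_window : int
        Optional centred moving-average width applied before peak detection
        (1 = no smoothing).  Phantom curves are clean, so the default is off.
    """
    n = tac.n_frames
    if not 1 <= n_baseline_frames < n:
        raise InputError(
            f"n_baseline_frames must be in [1, {n - 1}], got {n_baseline_frames}"
        )
    values = tac.values
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        values = np.convolve(values, kernel, mode="same")
    baseline = float(np.mean(values[:n_baseline_frames]))
    tail = values[n_baseline_frames:]
    k = int(np.argmax(tail))
    peak = float(tail[k])
    return PeakEnhancement(
        baseline=baseline, peak=peak, pe=peak - baseline,
        peak_frame=n_baseline_frames + k,
    )


def select_static_phase(
    aorta: TimeAttenuationCurve,
    myocardium_mean: TimeAttenuationCurve,
    fixed_offset: int | None = None,
) -> int:
    """Choose the frame of the dynamic series used as the static image.

    Default rule: the first frame at or after the aortic peak frame at which
    the mean myocardial curve attains its maximum over the remaining frames.
    Alternative (``fixed_offset``): exactly ``fixed_offset`` frames after the
    aortic peak, clamped to the last frame.

    Never returns a frame earlier than the aortic peak frame.
    """
    if not np.array_equal(aorta.frame_times, myocardium_mean.frame_times):
        raise InputError("aortic and myocardial curves must share frame times")
    peak_frame = int(np.argmax(aorta.values))
    n = aorta.n_frames
    if fixed_offset is not None:
        if fixed_offset < 0:
            raise InputError("fixed_offset must be nonnegative")
        return min(peak_frame + fixed_offset, n - 1)
    tail = myocardium_mean.values[peak_frame:]
    return peak_frame + int(np.argmax(tail))


def pe_correlation(pe_pairs) -> float:
    """Pearson correlation between per-patient timing-bolus and dynamic PEs.

    Parameters
    ----------
    pe_pairs : sequence of (float, float)
        One (timing-bolus PE, dynamic PE) pair per patient.
    """
    arr = np.asarray(pe_pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InputError("pe_pairs must be a sequence of (timing, dynamic) pairs")
    if arr.shape[0] < 3:
        raise InputError("at least 3 pairs are required")
    x, y = arr[:, 0], arr[:, 1]
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        raise DegenerateStatisticError("correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


# --- CSV serialization (frame_time_s, value_hu, roi_label) -----------------

def tacs_to_csv(tacs, path) -> None:
    """Write one or more TACs to a long-format CSV."""
    frames = [
        pd.DataFrame(
            {"frame_time_s": t.frame_times, "value_hu": t.values,
             "roi_label": t.roi_label}
        )
        for t in tacs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def tacs_from_csv(path) -> list[TimeAttenuationCurve]:
    """Read TACs from a long-format CSV written by :func:`tacs_to_csv`."""
    df = pd.read_csv(path)
    out = []
    for label, g in df.groupby("roi_label", sort=False):
        out.append(
            TimeAttenuationCurve(
                frame_times=g["frame_time_s"].to_numpy(),
                values=g["value_hu"].to_numpy(),
                roi_label=str(label),
            )
        )
    return out
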