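"""Model-vs-experiment comparison metrics.

The relative pose of the ulna and radius anatomical frames in the humerus
frame is decomposed into a body-fixed Euler sequence — flexion-extension
about the humeral medial-lateral axis, then varus-valgus, then
internal-external rotation (a joint-coordinate-system convention) — plus the
child-frame origin expressed along the humeral ML/AP/SI axes.  Channels are
compared with RMS error and the Pearson correlation coefficient; a signed
r > 0.8 is flagged as a good correlation.

Raw EMG is demeaned, rectified, low-pass filtered with a causal second-order
Butterworth at 6 Hz, and normalized to the trial maximum per channel (a
zero-phase variant is available behind a flag; it doubles the effective
filter order).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial.transform import Rotation
from scipy.stats import pearsonr

from .errors import ParameterError, ShapeError, UndefinedCorrelationError
from .geometry import AnatomicalFrame
from .kinematics import MotionTrial

log = logging.getLogger(__name__)

#: report row order: rotations then translations, ulna before radius
CHANNELS = [
    "ulna_IE_deg", "ulna_VV_deg", "ulna_FE_deg",
    "radius_IE_deg", "radius_VV_deg", "radius_FE_deg",
    "ulna_SI_mm", "ulna_AP_mm", "ulna_ML_mm",
    "radius_SI_mm", "radius_AP_mm", "radius_ML_mm",
]

GOOD_CORRELATION_THRESHOLD = 0.8


@dataclass
class KinematicsSeries:
    """12 anatomical channels (2 bones x 6 DOF) on a common time grid."""

    time: np.ndarray
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        missing = set(CHANNELS) - set(self.data.columns)
        if missing:
            raise ShapeError(f"kinematics series missing channels {sorted(missing)}")
        if len(self.data) != len(self.time):
            raise ShapeError("kinematics data does not match time grid")

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def resampled_to(self, time: np.ndarray) -> "KinematicsSeries":
        out = {c: np.interp(time, self.time, self.channel(c)) for c in CHANNELS}
        return KinematicsSeries(time=np.asarray(time, dtype=float),
                                data=pd.DataFrame(out))


def _relative_channels(parent_R: np.ndarray, parent_o: np.ndarray,
                       child_R: np.ndarray, child_o: np.ndarray,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Euler angles (FE, VV, IE, deg) and translations (ML, AP, SI, mm)."""
    r_rel = parent_R.T @ child_R
    fe, vv, ie = Rotation.from_matrix(r_rel).as_euler("XYZ", degrees=True)
    trans = parent_R.T @ (child_o - parent_o)
    return np.array([fe, vv, ie]), trans


def decompose_kinematics(trial: MotionTrial,
                         frames: Mapping[str, AnatomicalFrame],
                         parent: str = "humerus",
                         children: Sequence[str] = ("ulna", "radius"),
                         ) -> KinematicsSeries:
    """Decompose ulna/radius motion relative to the humerus frame.

    ``frames`` give each bone's anatomical frame in its own body coordinates.
    A varus-valgus angle close to 90 deg means the decomposition is near its
    gimbal singularity; a warning is issued but values are still returned.
    """
    for name in (parent, *children):
        if name not in frames:
            raise ShapeError(f"missing anatomical frame for '{name}'")
        if name not in trial.bodies:
            raise ShapeError(f"trial lacks poses for '{name}'")
    n = trial.n_frames
    cols = {c: np.empty(n) for c in CHANNELS}
    pf = frames[parent]
    for i in range(n):
        poses = trial.frame(i)
        pp = poses[parent]
        parent_R = pp.R @ pf.axes
        parent_o = pp.transform_points(pf.origin)
        for child in children:
            cf = frames[child]
            cp = poses[child]
            angles, trans = _relative_channels(
                parent_R, parent_o, cp.R @ cf.axes,
                cp.transform_points(cf.origin))
            cols[f"{child}_FE_deg"][i], cols[f"{child}_VV_deg"][i], \
                cols[f"{child}_IE_deg"][i] = angles
            cols[f"{child}_ML_mm"][i], cols[f"{child}_AP_mm"][i], \
                cols[f"{child}_SI_mm"][i] = trans
    for child in children:
        vv = cols[f"{child}_VV_deg"]
        if np.any(np.abs(np.abs(vv) - 90.0) < 2.0):
            warnings.warn(f"{child}: varus-valgus near 90 deg, decomposition "
                          "close to gimbal singularity", stacklevel=2)
    return KinematicsSeries(time=trial.time.copy(), data=pd.DataFrame(cols))


def compose_relative_pose(fe_deg: float, vv_deg: float, ie_deg: float,
                          ml: float, ap: float, si: float,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild the relative rotation matrix and translation from the six
    reported channels (round-trip check of the decomposition)."""
    r = Rotation.from_euler("XYZ", [fe_deg, vv_deg, ie_deg], degrees=True)
    return r.as_matrix(), np.array([ml, ap, si])


# ---------------------------------------------------------------------------
# Scalar metrics
# ---------------------------------------------------------------------------

def rms_error(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square difference between two equally sampled series."""
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if len(a) != len(b):
        raise ShapeError(f"series lengths differ: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ShapeError("need at least 2 samples")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient in [-1, 1]."""
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if len(a) != len(b):
        raise ShapeError(f"series lengths differ: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ShapeError("need at least 2 samples")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise UndefinedCorrelationError("correlation undefined for a "
                                        "zero-variance series")
    return float(pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# EMG processing
# ---------------------------------------------------------------------------

@dataclass
class EMGEnvelope:
    """Normalized muscle-activity envelopes: per-channel series in [0, 1]
    whose trial maximum is exactly 1 unless the channel is identically zero."""

    time: np.ndarray
    data: pd.DataFrame


def process_emg(raw: pd.DataFrame, rate: float = 1400.0,
                cutoff_hz: float = 6.0, zero_phase: bool = False) -> EMGEnvelope:
    """Demean, rectify, Butterworth low-pass and trial-max normalize.

    ``raw`` is a table with a ``time_s`` column plus one column per channel
    (volts).  The filter is a causal second-order Butterworth at 6 Hz;
    ``zero_phase`` applies it forward-backward instead (no lag, but the
    effective order doubles).
    """
    if rate <= 2.0 * cutoff_hz:
        raise ParameterError(
            f"sample rate {rate} Hz too low for a {cutoff_hz} Hz cutoff")
    if "time_s" in raw.columns:
        time = raw["time_s"].to_numpy(dtype=float)
        channels = [c for c in raw.columns if c != "time_s"]
    else:
        time = np.arange(len(raw)) / rate
        channels = list(raw.columns)
    b, a = sps.butter(2, cutoff_hz, btype="low", fs=rate)
    out = {}
    for ch in channels:
        x = raw[ch].to_numpy(dtype=float)
        x = np.abs(x - x.mean())
        y = sps.filtfilt(b, a, x) if zero_phase else sps.lfilter(b, a, x)
        peak = np.max(np.abs(y))
        if peak == 0.0:
            warnings.warn(f"EMG channel '{ch}' is identically zero after "
                          "demeaning; returned unnormalized", stacklevel=2)
            out[ch] = y
        else:
            out[ch] = y / peak
    return EMGEnvelope(time=time, data=pd.DataFrame(out))


def normalize_muscle_forces(forces: pd.DataFrame) -> pd.DataFrame:
    """Divide each muscle force series by its own trial maximum."""
    out = {}
    for col in forces.columns:
        x = forces[col].to_numpy(dtype=float)
        peak = x.max(initial=0.0)
        if peak <= 0.0:
            warnings.warn(f"muscle '{col}' produced no force in this trial",
                          stacklevel=2)
            out[col] = np.zeros_like(x)
        else:
            out[col] = x / peak
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def build_report(reference: KinematicsSeries,
                 predicted: KinematicsSeries) -> pd.DataFrame:
    """RMS error and correlation per channel, in the standard 12-row order.

    The predicted series is linearly resampled onto the reference time grid
    before comparison.  ``good`` flags a signed correlation above 0.8.
    """
    predicted = predicted.resampled_to(reference.time)
    rows = []
    for ch in CHANNELS:
        ref = reference.channel(ch)
        pred = predicted.channel(ch)
        try:
            r = pearson_r(ref, pred)
        except UndefinedCorrelationError:
            r = np.nan
        rows.append({
            "channel": ch,
            "rms_error": rms_error(ref, pred),
            "correlation": r,
            "good": bool(r > GOOD_CORRELATION_THRESHOLD) if np.isfinite(r) else False,
        })
    return pd.DataFrame(rows)
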