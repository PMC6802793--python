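"""Grip-aperture time series and maximum grip aperture (MGA) extraction.

Two markers, on the thumb nail and index-finger nail, are tracked in 3D at
50 or 100 Hz. Grip aperture is their Euclidean distance; the MGA is the
largest aperture between movement start (release of the start button) and
object contact. The source studies leave the segmentation and filtering
rules unstated, so the ones here are declared conventions, all
configurable: a 4th-order zero-lag Butterworth low-pass at 10 Hz on marker
coordinates, linear interpolation across marker dropouts of at most 3
samples, and an end-of-reach rule that looks for the aperture settling near
its final-contact value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, filtfilt

logger = logging.getLogger(__name__)


@dataclass
class KinematicTrace:
    """Thumb and index 3D trajectories for one reach, in mm and seconds.

    Marker dropout is encoded as NaN rows in ``thumb_xyz``/``index_xyz``.
    ``meta`` may carry generator ground truth (e.g. the programmed aperture
    peak) for round-trip tests.
    """

    participant_id: str
    trial_id: str
    sample_rate_hz: float
    t: np.ndarray
    thumb_xyz: np.ndarray
    index_xyz: np.ndarray
    start_event_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.thumb_xyz = np.asarray(self.thumb_xyz, dtype=float).reshape(-1, 3)
        self.index_xyz = np.asarray(self.index_xyz, dtype=float).reshape(-1, 3)
        if len(self.thumb_xyz) != len(self.t) or len(self.index_xyz) != len(self.t):
            raise ValueError("marker sequences must match the time vector in length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time vector must be strictly increasing")
        if not (self.t[0] <= self.start_event_s <= self.t[-1]):
            raise ValueError("start_event_s outside the recorded time range")


@dataclass
class ApertureSeries:
    """Aperture (thumb-index distance) per sample, with a missingness mask."""

    t: np.ndarray
    aperture_mm: np.ndarray
    missing_mask: np.ndarray


def _interpolate_short_gaps(coords: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate NaN runs of length <= max_gap, per coordinate column."""
    out = coords.copy()
    n = len(out)
    for j in range(out.shape[1]):
        col = out[:, j]
        isnan = np.isnan(col)
        if not isnan.any() or isnan.all():
            continue
        i = 0
        while i < n:
            if isnan[i]:
                j0 = i
                while i < n and isnan[i]:
                    i += 1
                gap = i - j0
                if 0 < gap <= max_gap and j0 > 0 and i < n:
                    col[j0:i] = np.interp(
                        np.arange(j0, i), [j0 - 1, i], [col[j0 - 1], col[i]]
                    )
            else:
                i += 1
    return out


def compute_aperture(
    trace: KinematicTrace,
    lowpass_hz: float | None = 10.0,
    max_gap_samples: int = 3,
) -> ApertureSeries:
    """Euclidean thumb-index distance per sample.

    Short dropout gaps (``<= max_gap_samples``) are linearly interpolated;
    longer gaps stay missing. With ``lowpass_hz`` set, marker coordinates
    are filtered with a 4th-order zero-lag Butterworth low-pass before the
    distance is taken; pass ``None`` to bypass (exactness tests, very short
    traces).
    """
    thumb = _interpolate_short_gaps(trace.thumb_xyz, max_gap_samples)
    index = _interpolate_short_gaps(trace.index_xyz, max_gap_samples)
    missing = np.isnan(thumb).any(axis=1) | np.isnan(index).any(axis=1)

    if lowpass_hz is not None and not missing.all():
        nyq = trace.sample_rate_hz / 2.0
        if lowpass_hz < nyq and len(trace.t) > 15:
            b, a = butter(4, lowpass_hz / nyq)
            # filtfilt cannot cross missing runs; filter contiguous valid segments
            thumb, index = thumb.copy(), index.copy()
            for seg in _contiguous_valid_segments(missing):
                if seg.stop - seg.start > 15:
                    thumb[seg] = filtfilt(b, a, thumb[seg], axis=0)
                    index[seg] = filtfilt(b, a, index[seg], axis=0)

    aperture = np.linalg.norm(thumb - index, axis=1)
    aperture[missing] = np.nan
    return ApertureSeries(t=trace.t.copy(), aperture_mm=aperture, missing_mask=missing)


def _contiguous_valid_segments(missing: np.ndarray) -> list[slice]:
    segs, start = [], None
    for i, m in enumerate(missing):
        if not m and start is None:
            start = i
        elif m and start is not None:
            segs.append(slice(start, i))
            start = None
    if start is not None:
        segs.append(slice(start, len(missing)))
    return segs


def segment_reach(
    trace: KinematicTrace,
    aperture: ApertureSeries,
    contact_tolerance_mm: float = 2.0,
    dwell_s: float = 0.1,
) -> tuple[float, float]:
    """Locate the analysed reach window (t_start, t_end).

    t_start is the start-button release. t_end is the first time after
    t_start at which the aperture *falls* below the final-contact aperture
    plus ``contact_tolerance_mm`` (i.e. having been above it) and stays
    there for ``dwell_s``; if the aperture never rises above the threshold
    or never settles, the window is capped at the last sample.
    """
    t = aperture.t
    a = aperture.aperture_mm
    t_start = trace.start_event_s
    after = np.nonzero(t > t_start)[0]
    if after.size == 0:
        raise ValueError("no samples after the start event")
    valid = ~aperture.missing_mask
    if not valid[after].any():
        return t_start, t[-1]
    final = a[after][valid[after]][-1]
    thresh = final + contact_tolerance_mm
    dwell_n = max(1, int(round(dwell_s * trace.sample_rate_hz)))
    below = (a <= thresh) & valid
    opened = False
    for i in after:
        if not opened:
            opened = valid[i] and a[i] > thresh
            continue
        if below[i]:
            j = min(len(t), i + dwell_n)
            if np.all(below[i:j] | ~valid[i:j]):
                return t_start, t[i]
    return t_start, t[-1]


def extract_mga(
    aperture: ApertureSeries, window: tuple[float, float]
) -> float | None:
    """Maximum aperture within the reach window, or ``None`` if unusable.

    Requires at least 3 non-missing samples in the window; otherwise the
    trial's MGA is missing (logged, not raised — dropout is a data feature,
    not a programming error).
    """
    t_start, t_end = window
    sel = (aperture.t >= t_start) & (aperture.t <= t_end) & ~aperture.missing_mask
    if sel.sum() < 3:
        logger.info("MGA missing: only %d usable samples in window", int(sel.sum()))
        return None
    return float(np.max(aperture.aperture_mm[sel]))


def trace_mga(trace: KinematicTrace, lowpass_hz: float | None = 10.0) -> float | None:
    """Convenience: aperture -> reach window -> MGA for one trace."""
    ap = compute_aperture(trace, lowpass_hz=lowpass_hz)
    window = segment_reach(trace, ap)
    return extract_mga(ap, window)


# ---------------------------------------------------------------------------
# plain-text trace format: '#'-prefixed header keys, then CSV columns
# t,thumb_x,thumb_y,thumb_z,index_x,index_y,index_z (mm, s; NaN = dropout)

def write_trace(trace: KinematicTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# participant_id={trace.participant_id}\n")
        fh.write(f"# trial_id={trace.trial_id}\n")
        fh.write(f"# sample_rate_hz={trace.sample_rate_hz!r}\n")
        fh.write(f"# start_event_s={trace.start_event_s!r}\n")
        fh.write("t,thumb_x,thumb_y,thumb_z,index_x,index_y,index_z\n")
        for i in range(len(trace.t)):
            row = [trace.t[i], *trace.thumb_xyz[i], *trace.index_xyz[i]]
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_trace(path: str | Path) -> KinematicTrace:
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                header[key.strip()] = value.strip()
            elif not line.startswith("t,"):
                rows.append([float(v) for v in line.split(",")])
    arr = np.asarray(rows, dtype=float)
    return KinematicTrace(
        participant_id=header.get("participant_id", ""),
        trial_id=header.get("trial_id", ""),
        sample_rate_hz=float(header["sample_rate_hz"]),
        t=arr[:, 0],
        thumb_xyz=arr[:, 1:4],
        index_xyz=arr[:, 4:7],
        start_event_s=float(header["start_event_s"]),
    )
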