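"""Trace processing: peak detection, ladder calibration, marker alignment, sizing.

The sizing chain mirrors how a chip instrument turns raw traces into fragment
lengths:

1. detect peaks in the ladder well; the first and last qualifying peaks are
   the lower/upper internal markers, the ones between are the ladder rungs;
2. fit a strictly monotone piecewise-linear map from migration time to
   log10(size) through the rung anchors (exact at the anchors, linearly
   extrapolated towards the markers);
3. for each sample well, locate its two marker peaks and solve the affine
   time transform that lays them onto the ladder's marker times — this
   removes well-to-well drift in injection time and field strength;
4. map every remaining peak's aligned time through the calibration to an
   estimated size in bp, flagging anything outside the chip's 25-1000 bp
   sizing range.

Baseline and noise are estimated from the trace itself: baseline as a rolling
median over a window much wider than a peak, noise as the scaled median
absolute deviation of the detrended signal.  Peak apexes are refined to
sub-sample precision with a local parabola fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks, peak_widths

from .errors import AlignmentError, CalibrationError
from .panel import SIZING_RANGE_BP
from .simulate import Electropherogram

#: MAD-to-standard-deviation factor for Gaussian noise.
_MAD_SCALE = 1.4826

#: Rolling-median window in seconds (must dwarf a peak's footprint).
BASELINE_WINDOW_S = 2.0

#: Half-width in samples of the parabolic apex refinement window.
_APEX_HALF_WINDOW = 3

DEFAULT_MIN_SNR = 5.0

#: Minimum apex-to-apex separation accepted between distinct peaks (seconds);
#: closer maxima are noise wiggles on one peak and collapse to the tallest.
#: Must stay below the closest genuine peak spacing (adjacent 4 bp alleles sit
#: ~0.18 s apart under the default migration model).
DEFAULT_MIN_SEPARATION_S = 0.1

#: A peak qualifies as an internal-marker (or ladder-rung) candidate only if
#: it reaches this fraction of the trace's tallest peak.  The markers are the
#: tallest features of every well, so this keeps rare near-threshold noise
#: blips in the dead time before/after the markers from being mistaken for
#: them; ordinary sample peaks are never height-qualified.
MARKER_HEIGHT_FRACTION = 0.25


@dataclass(frozen=True)
class Peak:
    """A detected local maximum, baseline-subtracted."""

    time_s: float
    height_fu: float
    area: float
    is_internal_marker: bool = False


@dataclass(frozen=True)
class SizedPeak:
    """A peak with its calibrated fragment-size estimate."""

    time_s: float
    height_fu: float
    area: float
    size_bp: float
    in_sizing_range: bool


@dataclass(frozen=True)
class AffineTransform:
    """t_ladder = scale * t_sample + shift."""

    scale: float
    shift: float

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        return self.scale * t + self.shift


class Calibration:
    """Monotone time→size map anchored at the ladder rungs.

    Piecewise linear in (time, log10 size) between consecutive rungs and
    linearly extrapolated beyond the first/last rung (out to the internal
    markers); passes through every anchor exactly.
    """

    def __init__(
        self,
        rung_times_s: Sequence[float],
        rung_sizes_bp: Sequence[float],
        marker_times_s: tuple[float, float],
    ) -> None:
        times = np.asarray(rung_times_s, dtype=float)
        sizes = np.asarray(rung_sizes_bp, dtype=float)
        if times.size != sizes.size or times.size < 2:
            raise CalibrationError(
                f"need >=2 matching rung anchors, got {times.size} times "
                f"and {sizes.size} sizes"
            )
        if not (np.all(np.diff(times) > 0) and np.all(np.diff(sizes) > 0)):
            raise CalibrationError("rung anchors must be strictly increasing")
        self.rung_times_s = times
        self.rung_sizes_bp = sizes
        self.marker_times_s = marker_times_s
        self._log_sizes = np.log10(sizes)

    def size_at(self, time_s: float | np.ndarray) -> float | np.ndarray:
        """Estimated fragment size (bp) at a (ladder-aligned) migration time."""
        t = np.asarray(time_s, dtype=float)
        # np.interp clamps outside the anchors; extend the end segments instead.
        log_size = np.interp(t, self.rung_times_s, self._log_sizes)
        lo_slope = (self._log_sizes[1] - self._log_sizes[0]) / (
            self.rung_times_s[1] - self.rung_times_s[0]
        )
        hi_slope = (self._log_sizes[-1] - self._log_sizes[-2]) / (
            self.rung_times_s[-1] - self.rung_times_s[-2]
        )
        log_size = np.where(
            t < self.rung_times_s[0],
            self._log_sizes[0] + lo_slope * (t - self.rung_times_s[0]),
            log_size,
        )
        log_size = np.where(
            t > self.rung_times_s[-1],
            self._log_sizes[-1] + hi_slope * (t - self.rung_times_s[-1]),
            log_size,
        )
        out = 10.0 ** log_size
        return float(out) if np.isscalar(time_s) else out


def _refine_apex(detrended: np.ndarray, idx: int, dt: float, t0: float) -> tuple[float, float]:
    """Sub-sample apex (time, height) via a least-squares parabola around idx."""
    lo = max(0, idx - _APEX_HALF_WINDOW)
    hi = min(detrended.size, idx + _APEX_HALF_WINDOW + 1)
    x = np.arange(lo, hi, dtype=float)
    y = detrended[lo:hi]
    if x.size < 3:
        return t0 + idx * dt, float(detrended[idx])
    a, b, c = np.polyfit(x - idx, y, 2)
    if a >= 0:  # degenerate (flat/noise-dominated): keep the grid apex
        return t0 + idx * dt, float(detrended[idx])
    x_apex = -b / (2 * a)
    x_apex = float(np.clip(x_apex, -_APEX_HALF_WINDOW, _APEX_HALF_WINDOW))
    height = float(c + b * x_apex + a * x_apex**2)
    return t0 + (idx + x_apex) * dt, height


def detect_peaks(
    trace: Electropherogram,
    min_snr: float = DEFAULT_MIN_SNR,
    min_height_fu: float = 0.0,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
) -> list[Peak]:
    """Local maxima exceeding baseline + min_snr * noise and min_height_fu.

    Returns peaks ordered by migration time; an all-constant trace yields an
    empty list.  Heights and areas are baseline-subtracted.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    fu = trace.fu
    dt = float(np.median(np.diff(trace.time_s))) if len(trace) > 1 else 1.0
    window = max(3, int(round(BASELINE_WINDOW_S / dt)) | 1)
    baseline = median_filter(fu, size=min(window, len(trace)), mode="nearest")
    detrended = fu - baseline
    noise = _MAD_SCALE * float(np.median(np.abs(detrended - np.median(detrended))))
    threshold = max(min_snr * noise, min_height_fu, 1e-9)
    # Prominence guards against noise wiggles on a peak's flank being counted
    # as separate maxima.
    distance = max(1, int(round(min_separation_s / dt)))
    idx, _props = find_peaks(
        detrended, height=threshold, prominence=threshold / 2, distance=distance
    )
    if idx.size == 0:
        return []
    widths, _, _, _ = peak_widths(detrended, idx, rel_height=0.5)
    peaks = []
    for i, w in zip(idx, widths):
        t_apex, h_apex = _refine_apex(detrended, int(i), dt, float(trace.time_s[0]))
        h_apex = max(h_apex, float(detrended[i]))
        # Gaussian: area = height * FWHM * sqrt(pi/(4 ln 2))
        area = h_apex * w * dt * 1.0645
        peaks.append(Peak(time_s=t_apex, height_fu=h_apex, area=area))
    return sorted(peaks, key=lambda p: p.time_s)


def _marker_peaks(peaks: Sequence[Peak]) -> tuple[Peak, Peak]:
    """The lower/upper internal markers: first and last qualifying peaks.

    Identification is positional (by time, as on the instrument) among peaks
    tall enough to be marker candidates.
    """
    tallest = max(p.height_fu for p in peaks)
    candidates = [p for p in peaks if p.height_fu >= MARKER_HEIGHT_FRACTION * tallest]
    if len(candidates) < 2:
        raise AlignmentError(
            f"found {len(candidates)} marker-height peaks; need both internal markers"
        )
    return candidates[0], candidates[-1]


def fit_calibration(
    ladder_trace: Electropherogram,
    ladder_sizes_bp: Sequence[float],
    min_snr: float = DEFAULT_MIN_SNR,
) -> Calibration:
    """Pair ladder peaks to rung sizes in order and fit the time→size map.

    The first and last detected peaks are taken as the internal markers; the
    peaks between them must match the rung count exactly.
    """
    sizes = list(ladder_sizes_bp)
    if not sizes:
        raise CalibrationError("empty ladder size list")
    peaks = detect_peaks(ladder_trace, min_snr=min_snr)
    if len(peaks) < 2:
        raise CalibrationError(
            f"ladder trace shows {len(peaks)} peaks; need both internal markers"
        )
    try:
        lower, upper = _marker_peaks(peaks)
    except AlignmentError as exc:
        raise CalibrationError(str(exc)) from exc
    tallest = max(p.height_fu for p in peaks)
    rung_peaks = [
        p
        for p in peaks
        if lower.time_s < p.time_s < upper.time_s
        and p.height_fu >= MARKER_HEIGHT_FRACTION * tallest
    ]
    if len(rung_peaks) != len(sizes):
        raise CalibrationError(
            f"detected {len(rung_peaks)} ladder rung peaks but the ladder "
            f"defines {len(sizes)} rungs"
        )
    return Calibration(
        rung_times_s=[p.time_s for p in rung_peaks],
        rung_sizes_bp=sizes,
        marker_times_s=(lower.time_s, upper.time_s),
    )


def marker_transform(
    sample_trace: Electropherogram,
    calibration: Calibration,
    min_snr: float = DEFAULT_MIN_SNR,
) -> AffineTransform:
    """Affine map taking the sample's marker times onto the ladder's.

    The sample's markers are the first and last qualifying peaks (positional
    identification, as on the instrument).  Identity when they already
    coincide.
    """
    peaks = detect_peaks(sample_trace, min_snr=min_snr)
    if len(peaks) < 2:
        raise AlignmentError(
            f"sample trace {sample_trace.label!r} shows {len(peaks)} peaks; "
            "need both internal markers for alignment"
        )
    lower, upper = _marker_peaks(peaks)
    t_lo, t_hi = lower.time_s, upper.time_s
    ref_lo, ref_hi = calibration.marker_times_s
    scale = (ref_hi - ref_lo) / (t_hi - t_lo)
    shift = ref_lo - scale * t_lo
    return AffineTransform(scale=scale, shift=shift)


def align_internal_markers(
    sample_trace: Electropherogram,
    calibration: Calibration,
    min_snr: float = DEFAULT_MIN_SNR,
) -> Electropherogram:
    """Sample trace with its time axis affinely mapped onto the ladder's."""
    tf = marker_transform(sample_trace, calibration, min_snr=min_snr)
    return Electropherogram(
        time_s=tf(sample_trace.time_s),
        fu=sample_trace.fu.copy(),
        well_kind=sample_trace.well_kind,
        label=sample_trace.label,
    )


def size_peaks(
    sample_trace: Electropherogram,
    calibration: Calibration,
    min_snr: float = DEFAULT_MIN_SNR,
    min_height_fu: float = 0.0,
) -> list[SizedPeak]:
    """Detect, marker-align and size all non-marker peaks of a sample well.

    The two positional marker peaks are excluded from the output; peaks whose
    estimate falls outside the 25-1000 bp sizing range are flagged
    ``in_sizing_range=False`` rather than dropped.
    """
    peaks = detect_peaks(sample_trace, min_snr=min_snr, min_height_fu=min_height_fu)
    if len(peaks) < 2:
        raise AlignmentError(
            f"sample trace {sample_trace.label!r} shows {len(peaks)} peaks; "
            "need both internal markers for alignment"
        )
    lower, upper = _marker_peaks(peaks)
    ref_lo, ref_hi = calibration.marker_times_s
    scale = (ref_hi - ref_lo) / (upper.time_s - lower.time_s)
    tf = AffineTransform(scale=scale, shift=ref_lo - scale * lower.time_s)
    lo, hi = SIZING_RANGE_BP
    sized = []
    for p in peaks:
        if p is lower or p is upper:
            continue
        size = float(calibration.size_at(tf(p.time_s)))
        sized.append(
            SizedPeak(
                time_s=p.time_s,
                height_fu=p.height_fu,
                area=p.area,
                size_bp=size,
                in_sizing_range=lo <= size <= hi,
            )
        )
    return sized


def sizing_error_study(
    panel,
    model,
    n_fragments: int = 500,
    seed: int = 42,
    min_snr: float = DEFAULT_MIN_SNR,
) -> "np.ndarray":
    """Absolute sizing errors of the full chain over random single fragments.

    Simulates one ladder well and ``n_fragments`` single-fragment sample
    wells with true sizes uniform across the chip's sizing range, runs
    calibration, alignment and sizing, and returns |estimated - true| per
    fragment.  Each well holds one fragment, so its estimate is the tallest
    non-marker peak (rare near-threshold noise blips are far below the
    fragment's height and do not enter).
    """
    from .simulate import simulate_ladder_trace, simulate_trace

    rng = np.random.default_rng(seed)
    ladder = simulate_ladder_trace(panel, model, int(rng.integers(2**31 - 1)))
    calibration = fit_calibration(ladder, panel.ladder_sizes_bp, min_snr=min_snr)
    lo, hi = SIZING_RANGE_BP
    errors = np.empty(n_fragments)
    for i in range(n_fragments):
        true_size = float(rng.uniform(lo, hi))
        trace = simulate_trace(
            [(true_size, 1.0)],
            model,
            int(rng.integers(2**31 - 1)),
            lower_marker_bp=panel.lower_marker_bp,
            upper_marker_bp=panel.upper_marker_bp,
        )
        sized = size_peaks(trace, calibration, min_snr=min_snr)
        if not sized:
            raise AlignmentError(f"fragment of {true_size:.1f} bp not detected")
        best = max(sized, key=lambda p: p.height_fu)
        errors[i] = abs(best.size_bp - true_size)
    return errors
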