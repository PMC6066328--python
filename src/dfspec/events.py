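"""Rupture-event extraction from retraction force curves.

Four stages, matching standard single-molecule force-spectroscopy
practice:

1. detect the candidate rupture: the largest abrupt force drop toward
   baseline preceded by a monotone force ramp;
2. fit the tether-stretching region to the extended freely jointed chain
   by total least squares (orthogonal distance regression) to estimate
   the contour length Lc;
3. gate events on Lc: the Lc histogram is fit to a Gaussian and only
   events within one standard deviation of the center are accepted --
   ruptures at the two-tether contour length are the fingerprint of a
   specific single-molecule unbinding event, short-Lc adhesion is
   nonspecific;
4. estimate the loading rate as the least-squares slope of force versus
   time over the final part of the ramp (default: from 90% of the peak
   force to rupture), where the ramp is closest to linear and the slope
   approximates the instantaneous rate v/(1/k_c + dx/dF) at rupture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .exceptions import DomainError, EstimationError, FitError
from .physics import LoadingRate, TetherModel, _fjc_extension_signed
from .simulate import ForceCurve

__all__ = [
    "DetectionParams",
    "RuptureEvent",
    "LcFilterResult",
    "detect_candidate_event",
    "fit_tether_tls",
    "filter_by_contour_length",
    "lc_within_band",
    "estimate_loading_rate",
]


@dataclass(frozen=True)
class DetectionParams:
    """Rupture-detection thresholds.

    ``min_force`` is the absolute detection threshold in pN; if None it is
    set to ``noise_mult`` times the estimated per-sample noise SD of the
    curve. ``min_points`` is the minimum length of the rising segment that
    must precede the drop; ``smoothing_window`` (samples) applies only to
    detection, never to fitting.
    """

    min_force: Optional[float] = 15.0
    min_points: int = 10
    smoothing_window: int = 5
    noise_mult: float = 5.0
    baseline_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.min_points < 5:
            raise DomainError(f"min_points must be >= 5, got {self.min_points}")
        if self.smoothing_window < 1:
            raise DomainError("smoothing_window must be >= 1")


@dataclass
class RuptureEvent:
    """Per-event record extracted from one force curve.

    Immediately after detection only ``rupture_force``/``rupture_index``
    are set; ``contour_length`` and ``loading_rate`` are filled by the
    later stages, ``accepted`` by the Lc gate.
    """

    curve_id: str
    rupture_force: float  # pN, baseline-subtracted
    rupture_index: int
    contour_length: Optional[float] = None  # nm
    loading_rate: Optional[float] = None  # pN/s
    pulling_velocity: Optional[float] = None  # nm/s
    accepted: bool = False


@dataclass
class LcFilterResult:
    """Gaussian center/width of the Lc histogram and the acceptance set."""

    mu: float
    sigma: float
    accepted_ids: list
    histogram: tuple  # (bin_edges, counts)
    degenerate: bool = False
    gaussian_fallback: bool = False


def _baseline(force: np.ndarray, fraction: float) -> float:
    n_tail = max(int(len(force) * fraction), 1)
    return float(np.median(force[-n_tail:]))


def _noise_sd(force: np.ndarray, window: int) -> float:
    """Per-sample force noise estimated as the residual about the smoothed trace.

    The residual of a w-sample moving average carries variance
    (1 - 1/w) sigma^2, so the raw residual SD is corrected upward.
    """
    if window <= 1:
        return 0.0
    raw = float(np.std(force - _smooth(force, window)))
    return raw / np.sqrt(1.0 - 1.0 / window)


def _smooth(force: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return force.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate((np.full(pad, force[0]), force, np.full(window - 1 - pad, force[-1])))
    return np.convolve(padded, kernel, mode="valid")


def detect_candidate_event(curve: ForceCurve, det: DetectionParams = DetectionParams()):
    """Locate the candidate rupture in one curve, or return None.

    The baseline (median of the final 10% of the trace) is subtracted,
    the trace smoothed by a centered moving average, and the largest drop
    toward baseline occurring within <= 3 samples is located. A candidate
    is kept only if the drop exceeds ``min_force`` and is preceded by a
    monotone (to within the smoothed noise) rising segment of at least
    ``min_points`` samples. The rupture index/force are then refined on
    the raw trace at the largest single-sample drop near the candidate.
    """
    f = np.asarray(curve.force, dtype=float) - _baseline(curve.force, det.baseline_fraction)
    n = len(f)
    w = det.smoothing_window
    if n < det.min_points + w + 4:
        return None
    fs = _smooth(f, w)

    noise_sd = float(np.std(f - fs)) if w > 1 else 0.0
    smooth_noise_sd = noise_sd / np.sqrt(max(w, 1))
    min_force = det.min_force if det.min_force is not None else det.noise_mult * noise_sd

    future_min = np.minimum(np.minimum(fs[1:n - 2], fs[2:n - 1]), fs[3:n])
    drops = fs[:n - 3] - future_min
    cand = int(np.argmax(drops))
    # the moving average smears an abrupt drop over ~w samples, so the
    # lag-3 smoothed statistic undershoots the amplitude; gate loosely
    # here and test the true amplitude on the raw trace after refinement
    if drops[cand] < 0.5 * min_force:
        return None

    # the centered moving average smears the drop ~w/2 samples backwards;
    # the rising segment must end before that edge
    margin = w // 2 + 1 if w > 1 else 0
    j1 = cand - margin
    j0 = j1 - det.min_points + 1
    if j0 < 0:
        return None
    segment = fs[j0:j1 + 1]
    rise_tol = max(3.0 * smooth_noise_sd, 1e-9)
    if np.any(np.diff(segment) < -rise_tol):
        return None
    # net rise assessed over a lookback long enough that a real ramp beats
    # the noise even at dense sampling and for ruptures low on the ramp
    # (12.5% of the trace, >= min_points)
    lookback = min(j1, max(det.min_points, n // 8))
    if fs[j1] - fs[j1 - lookback] <= max(rise_tol, 1e-9):
        return None

    # refine on the raw trace: largest single-sample drop near the candidate
    lo = max(cand - w, 1)
    hi = min(cand + w + 1, n - 1)
    steps = f[lo:hi] - f[lo + 1:hi + 1]
    idx = lo + int(np.argmax(steps))
    # full-amplitude test: pre-drop smoothed level minus post-drop smoothed
    # minimum; the smoothed read-out keeps the effective force threshold
    # crisp (noise on the amplitude ~ sd/sqrt(w) per side)
    post = fs[min(idx + 1, n - 1):min(idx + w + 3, n)]
    if fs[max(j1, 0)] - float(np.min(post)) < min_force:
        return None
    return RuptureEvent(
        curve_id=curve.curve_id,
        rupture_force=float(f[idx]),
        rupture_index=idx,
        pulling_velocity=curve.pulling_velocity,
    )


def _stretch_segment(curve: ForceCurve, event: RuptureEvent, det: DetectionParams) -> slice:
    """Samples from the onset of tether loading up to the rupture index.

    The onset is the last crossing below a small force floor on a
    heavily smoothed trace (window scaled to the ramp length): on the
    lightly smoothed trace the crossing position is noise-dominated
    whenever the ramp dwells many samples near the floor.
    """
    f = np.asarray(curve.force, dtype=float) - _baseline(curve.force, det.baseline_fraction)
    i_r = event.rupture_index
    w_seg = max(det.smoothing_window, min(151, i_r // 20))
    fs = _smooth(f, w_seg)
    f_lo = max(2.0, 0.05 * event.rupture_force)
    below = np.nonzero(fs[:i_r] < f_lo)[0]
    i0 = int(below[-1]) + 1 if below.size else 0
    # heavy smoothing can push the apparent onset past the floor; never
    # start the segment beyond half of the ramp
    i0 = min(i0, max(i_r // 2, i_r - 5))
    return slice(i0, i_r + 1)


def fit_tether_tls(
    curve: ForceCurve,
    event: RuptureEvent,
    template: TetherModel,
    det: DetectionParams = DetectionParams(),
    min_points: int = 10,
    max_points: int = 300,
    sigma_z: float = 0.05,
    sigma_z0: float = 2.0,
    f_fit_cap: Optional[float] = None,
) -> tuple[float, float]:
    """Total-least-squares fit of the stretch region; returns (Lc, residual).

    Orthogonal distance regression over the (force, distance) samples of
    the stretching segment, with the contour length Lc and a distance
    offset free and every other tether parameter held at the template
    values. The model predicts the tip-sample distance as tether
    extension plus cantilever deflection:

        z(F) = x_fjc(F; Lc) + F / k_c + z0 .

    The distance axis is the commanded retraction (noise well below the
    force noise), so the orthogonal-distance objective reduces, in the
    anisotropic metric set by the coordinate noise levels, to minimizing
    force residuals against the model inverted to F(z): this is total
    least squares in the exact-regressor limit and is free of the
    errors-in-variables bias that isotropic orthogonal distances would
    rectify out of the force noise. Because the tether extension is
    proportional to Lc, z(F) = Lc g(F) + F/k_c + z0 with g computed once
    from the template, and F(z) follows by monotone interpolation.

    The free distance offset z0 is weakly anchored (scale ``sigma_z0``
    nm): the dialect defines distance zero at tip-sample contact, and
    without the anchor short low-force segments leave (Lc, z0) nearly
    degenerate. Returns (Lc, root-mean-square force residual in pN).
    """
    seg = _stretch_segment(curve, event, det)
    stop = seg.stop
    if f_fit_cap is not None and event.rupture_force > f_fit_cap:
        # truncate at a fixed force so that the fit sees the same force
        # window for every event; estimator precision is then uniform in
        # rupture force and the Lc gate cannot select on force
        f_sm = _smooth(
            np.asarray(curve.force, dtype=float)
            - _baseline(curve.force, det.baseline_fraction),
            det.smoothing_window,
        )
        above = np.nonzero(f_sm[seg.start:seg.stop] >= f_fit_cap)[0]
        if above.size:
            stop = max(seg.start + int(above[0]), seg.start + min_points)
    n_seg = stop - seg.start
    if n_seg < min_points:
        raise FitError(f"stretch segment has {n_seg} samples; need >= {min_points}")

    baseline = _baseline(curve.force, det.baseline_fraction)
    idx = np.unique(np.linspace(seg.start, stop - 1, min(max_points, n_seg)).astype(int))
    f_all = np.asarray(curve.force, dtype=float) - baseline
    f_d = f_all[idx]
    z_d = np.asarray(curve.tip_sample_distance, dtype=float)[idx]
    k_c = curve.spring_constant
    sigma_f = max(_noise_sd(f_all, det.smoothing_window), 0.5)

    # per-nm-of-contour-length extension of the template chain
    f_grid = np.linspace(0.0, 1.5 * float(np.max(f_d)) + 50.0, 2048)
    g_unit = _fjc_extension_signed(f_grid, template) / template.contour_length

    def force_of_z(z, lc, z0):
        lc = max(lc, template.l_planar)
        return np.interp(z - z0, lc * g_unit + f_grid / k_c, f_grid)

    def residuals(params):
        lc, z0 = params
        return np.concatenate(
            (
                (f_d - force_of_z(z_d, lc, z0)) / sigma_f,
                [z0 / sigma_z0],
            )
        )

    lc0 = max(5.0, (z_d[-1] - f_d[-1] / k_c) / 0.9)
    fit = least_squares(residuals, x0=[lc0, 0.0], method="lm", max_nfev=400)
    if not fit.success:
        raise FitError(f"tether fit did not converge: {fit.message}")
    lc = float(fit.x[0])
    if lc <= template.l_planar:
        raise FitError(f"non-physical contour length {lc:.3g} nm from TLS fit")
    residual = float(sigma_f * np.sqrt(2.0 * fit.cost / len(f_d)))
    return lc, residual


def lc_within_band(lc, mu: float, sigma: float):
    """Acceptance rule |Lc - mu| <= sigma, boundary inclusive."""
    return np.abs(np.asarray(lc, dtype=float) - mu) <= sigma


def filter_by_contour_length(events: Sequence[RuptureEvent]) -> LcFilterResult:
    """Gaussian-gate events on contour length.

    The Lc histogram (Freedman-Diaconis bins, at least 8) is fit to a
    Gaussian by least squares on the bin counts; events within one fitted
    standard deviation of the center are accepted. Fewer than 10 events,
    or a failed Gaussian fit, fall back to the sample mean/SD with the
    corresponding flag set.
    """
    lcs = np.array([e.contour_length for e in events], dtype=float)
    if lcs.size == 0:
        return LcFilterResult(np.nan, np.nan, [], (np.array([]), np.array([])), degenerate=True)

    degenerate = False
    fallback = False
    mu, sigma = float(np.mean(lcs)), float(np.std(lcs, ddof=1)) if lcs.size > 1 else 0.0

    if lcs.size < 10 or np.ptp(lcs) == 0.0:
        degenerate = True
        if np.ptp(lcs) == 0.0:
            sigma = 0.0
        edges = np.histogram_bin_edges(lcs, bins=8)
        counts, edges = np.histogram(lcs, bins=edges)
    else:
        iqr = float(np.subtract(*np.percentile(lcs, [75, 25])))
        h = 2.0 * iqr / lcs.size ** (1.0 / 3.0)
        n_bins = max(8, int(np.ceil(np.ptp(lcs) / h))) if h > 0 else 8
        counts, edges = np.histogram(lcs, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])

        def gauss(x, amp, center, width):
            return amp * np.exp(-0.5 * ((x - center) / width) ** 2)

        try:
            p0 = [float(counts.max()), float(centers[np.argmax(counts)]), max(float(np.std(lcs)), 1e-3)]
            popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=10000)
            mu, sigma = float(popt[1]), abs(float(popt[2]))
        except (RuntimeError, ValueError):
            fallback = True  # keep sample mean/SD

    mask = lc_within_band(lcs, mu, sigma)
    accepted_ids = [e.curve_id for e, ok in zip(events, mask) if ok]
    for e, ok in zip(events, mask):
        e.accepted = bool(ok)
    return LcFilterResult(mu, sigma, accepted_ids, (edges, counts), degenerate, fallback)


def _fit_ramp(
    curve: ForceCurve,
    event: RuptureEvent,
    det: DetectionParams,
    window: float,
    min_samples: int,
) -> tuple[float, float, int]:
    """OLS line on the final ramp; returns (slope, force at rupture, n)."""
    f = np.asarray(curve.force, dtype=float) - _baseline(curve.force, det.baseline_fraction)
    fs = _smooth(f, det.smoothing_window)
    i_r = event.rupture_index
    threshold = window * event.rupture_force
    # first crossing of the threshold, scanning forward from the onset of
    # tether loading: a last-crossing rule would be dominated by noise
    # whenever the ramp dwells many samples within (1-window) of the peak
    start = _stretch_segment(curve, event, det).start
    above = np.nonzero(fs[start:i_r + 1] >= threshold)[0]
    i0 = start + int(above[0]) if above.size else start
    if i_r - i0 + 1 < min_samples:
        i0 = max(0, i_r - min_samples + 1)
    n = i_r - i0 + 1
    if n < 3:
        raise EstimationError(f"loading-rate window has {n} samples; need >= 3")
    t_seg = np.asarray(curve.time, dtype=float)[i0:i_r + 1]
    slope, intercept = np.polyfit(t_seg, f[i0:i_r + 1], 1)
    return float(slope), float(slope * curve.time[i_r] + intercept), n


def estimate_loading_rate(
    curve: ForceCurve,
    event: RuptureEvent,
    window: float = 0.9,
    det: DetectionParams = DetectionParams(),
    min_samples: int = 25,
) -> LoadingRate:
    """Loading rate: OLS slope of force vs time over the final ramp.

    The window runs from ``window`` x peak force up to rupture (widened to
    at least ``min_samples`` samples when the sampling is sparse). A
    non-positive slope raises ``EstimationError``; the pipeline excludes
    such events.
    """
    slope, _, _ = _fit_ramp(curve, event, det, window, min_samples)
    if slope <= 0:
        raise EstimationError(f"non-positive loading-rate slope {slope:.3g} pN/s")
    return LoadingRate(slope)
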