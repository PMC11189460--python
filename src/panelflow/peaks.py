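"""Chromatographic peak integration for MRM transitions.

The processing chain per transition is: LOWESS-smooth each sample's trace
(5-point locally weighted linear fit), detect the peak apex and bounds on a
reference sample, rigidly align the remaining samples' retention times onto
the reference apex, and trapezoid-integrate every sample's *raw* trace over
the aligned shared window.  Smoothing decides where the peak is; the area
itself always comes from the unsmoothed signal, because smoothing biases
peak areas while the bounds only need robustness to noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .chromio import AreaMatrix, ChromatogramTrace
from .panel import PanelConfig, PipelineParams

__all__ = [
    "PeakResult",
    "PeakError",
    "AlignmentError",
    "smooth_lowess5",
    "detect_peak",
    "align_retention_times",
    "integrate_trapezoid",
    "integrate_batch",
]


class PeakError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass
class PeakResult:
    """A detected/integrated peak for one (sample, transition).

    ``area`` is in counts·minutes; NaN when no peak could be integrated.
    ``n_points`` counts raw acquisition points inside [left_rt, right_rt];
    the ``low_points`` flag marks peaks sampled with fewer points than the
    acquisition target (12 by default).
    """

    sample_id: str
    transition_key: str
    apex_rt: float = np.nan
    left_rt: float = np.nan
    right_rt: float = np.nan
    area: float = np.nan
    height: float = np.nan
    n_points: int = 0
    flags: set[str] = field(default_factory=set)
    rt_shift: float = 0.0

    @property
    def ok(self) -> bool:
        return "no_peak" not in self.flags and np.isfinite(self.area)


def smooth_lowess5(trace: ChromatogramTrace, window: int = 5) -> ChromatogramTrace:
    """LOWESS-smooth a trace over a sliding window of ``window`` points.

    Locally weighted linear regression (tricube weights) over the
    ``window`` nearest neighbours of each point; exact on linear signals.
    Output intensities are clipped at zero.
    """
    n = len(trace)
    if n < window:
        raise PeakError(
            f"trace {trace.sample_id}/{trace.transition_key}: {n} points < window {window}"
        )
    frac = window / n
    smoothed = _sm_lowess(
        trace.intensities, trace.times, frac=frac, it=0, return_sorted=False
    )
    return trace.replace_intensities(np.clip(smoothed, 0.0, None))


def _edge_baseline(y: np.ndarray) -> tuple[float, float]:
    """Baseline level and noise SD from the first/last 10% of points.

    Median and scaled MAD rather than mean/SD, so a peak eluting close to
    a window edge does not inflate the baseline estimate.
    """
    k = max(2, int(round(0.10 * y.size)))
    edges = np.concatenate([y[:k], y[-k:]])
    med = float(np.median(edges))
    noise = 1.4826 * float(np.median(np.abs(edges - med)))
    return med, noise


def detect_peak(
    trace: ChromatogramTrace,
    expected_rt: float | None = None,
    rt_window: float = 0.5,
    min_points: int = 12,
) -> PeakResult:
    """Locate the peak apex and integration bounds on a *smoothed* trace.

    The apex is the maximum of the smoothed signal, restricted to
    ``expected_rt ± rt_window`` when an expected retention time (from
    calibrant injections) is supplied.  Bounds descend from the apex until
    the signal drops below ``max(baseline + 3·noise_sd, 1% of apex height)``
    or turns back up (a local minimum).  A peak whose apex fails
    ``baseline + 5·noise_sd`` is flagged ``no_peak``.
    """
    t, y = trace.times, trace.intensities
    res = PeakResult(trace.sample_id, trace.transition_key)
    if not np.any(y > 0):
        res.flags.add("no_peak")
        return res
    if expected_rt is not None:
        if rt_window <= 0:
            raise PeakError("rt_window must be positive when expected_rt is given")
        mask = (t >= expected_rt - rt_window) & (t <= expected_rt + rt_window)
        if not mask.any():
            res.flags.add("no_peak")
            return res
        idx_candidates = np.flatnonzero(mask)
    else:
        idx_candidates = np.arange(t.size)
    apex = idx_candidates[np.argmax(y[idx_candidates])]
    baseline, noise_sd = _edge_baseline(y)
    height = float(y[apex])
    if height < baseline + 5.0 * noise_sd or height <= 0:
        res.flags.add("no_peak")
        return res
    floor = max(baseline + 3.0 * noise_sd, 0.01 * height)

    # a rise within ~3 noise SDs is not a real local minimum
    rise_tol = 3.0 * noise_sd
    left = apex
    while left > 0 and y[left - 1] >= floor and y[left - 1] <= y[left] + rise_tol:
        left -= 1
    right = apex
    while right < y.size - 1 and y[right + 1] >= floor and y[right + 1] <= y[right] + rise_tol:
        right += 1
    # the bound sits one point beyond the last in-peak point where possible,
    # so the apex is strictly interior and the tail point is captured
    left = max(left - 1, 0)
    right = min(right + 1, y.size - 1)
    if left == apex:
        apex = min(apex + 1, right)
    res.apex_rt = float(t[apex])
    res.left_rt = float(t[left])
    res.right_rt = float(t[right])
    res.height = height
    res.n_points = int(right - left + 1)
    if res.n_points < min_points:
        res.flags.add("low_points")
    return res


def align_retention_times(
    peaks: dict[str, PeakResult], reference: str | None = None
) -> dict[str, float]:
    """Per-sample rigid RT shifts mapping each apex onto the reference apex.

    ``shift[s]`` is the amount to *add* to sample ``s``'s time axis so its
    apex lands on the reference apex (a sample eluting 0.10 min late gets
    shift −0.10).  ``reference=None`` aligns onto the median apex RT.
    Samples without a detectable peak receive the median shift.
    """
    detected = {s: p for s, p in peaks.items() if "no_peak" not in p.flags}
    if not detected:
        raise AlignmentError("no sample has a detectable peak")
    if reference is None:
        ref_rt = float(np.median([p.apex_rt for p in detected.values()]))
    else:
        if reference not in detected:
            raise AlignmentError(f"reference sample {reference!r} has no peak")
        ref_rt = detected[reference].apex_rt
    shifts = {s: ref_rt - p.apex_rt for s, p in detected.items()}
    median_shift = float(np.median(list(shifts.values())))
    for s in peaks:
        if s not in shifts:
            shifts[s] = median_shift
    for s, p in peaks.items():
        p.rt_shift = shifts[s]
        p.flags.add("aligned")
    return shifts


def integrate_trapezoid(
    trace: ChromatogramTrace, left_rt: float, right_rt: float
) -> tuple[float, int]:
    """Composite trapezoid area of the raw trace over [left_rt, right_rt].

    Returns ``(area, n_points)`` where n_points is the number of raw
    acquisition points inside the window; area is NaN when fewer than two
    points fall inside.
    """
    if left_rt >= right_rt:
        raise PeakError(f"invalid integration window [{left_rt}, {right_rt}]")
    mask = (trace.times >= left_rt) & (trace.times <= right_rt)
    n = int(mask.sum())
    if n < 2:
        return float("nan"), n
    return float(np.trapezoid(trace.intensities[mask], trace.times[mask])), n


def _integrate_transition(
    traces: list[ChromatogramTrace],
    expected_rt: float | None,
    rt_window: float,
    params: PipelineParams,
) -> list[PeakResult]:
    smoothed: dict[str, ChromatogramTrace] = {}
    peaks: dict[str, PeakResult] = {}
    for tr in traces:
        try:
            sm = smooth_lowess5(tr, params.smooth_window)
        except PeakError:
            p = PeakResult(tr.sample_id, tr.transition_key)
            p.flags |= {"no_peak", "low_points"}
            peaks[tr.sample_id] = p
            continue
        smoothed[tr.sample_id] = sm
        peaks[tr.sample_id] = detect_peak(
            sm, expected_rt, rt_window, params.min_points_per_peak
        )

    detected = {s: p for s, p in peaks.items() if "no_peak" not in p.flags}
    if not detected:
        return list(peaks.values())
    # reference: detected sample with the tallest smoothed apex
    ref_sample = max(detected, key=lambda s: detected[s].height)
    align_retention_times(peaks, reference=ref_sample)
    ref = detected[ref_sample]

    by_sample = {tr.sample_id: tr for tr in traces}
    for s, p in peaks.items():
        if "no_peak" in p.flags:
            continue
        left = ref.left_rt - p.rt_shift
        right = ref.right_rt - p.rt_shift
        area, n = integrate_trapezoid(by_sample[s], left, right)
        p.left_rt, p.right_rt = left, right
        p.apex_rt = ref.apex_rt - p.rt_shift
        p.area, p.n_points = area, n
        if n < params.min_points_per_peak:
            p.flags.add("low_points")
        if n < 2:
            p.area = float("nan")
    return list(peaks.values())


def integrate_batch(
    traces: list[ChromatogramTrace],
    panel: PanelConfig | None = None,
    params: PipelineParams | None = None,
    runsheet: pd.DataFrame | None = None,
    expected_rts: dict[str, float] | None = None,
    rt_window: float = 0.5,
) -> tuple[AreaMatrix, list[PeakResult]]:
    """Integrate every transition across all samples.

    Per transition: smooth, detect on the reference sample, align, and
    integrate each sample over the aligned shared window.  A bad trace
    flags its own cell (NaN area) and never aborts the batch.  The result
    is deterministic — there is no stochastic step in integration.
    """
    params = params or PipelineParams()
    by_key: dict[str, list[ChromatogramTrace]] = {}
    for tr in traces:
        by_key.setdefault(tr.transition_key, []).append(tr)
    if not by_key:
        raise PeakError("no traces supplied")
    if panel is not None:
        known = {t.key for t in panel.transitions}
        unknown = set(by_key) - known
        if unknown:
            warnings.warn(
                f"integrating {len(unknown)} transition(s) not in the panel",
                stacklevel=2,
            )

    all_results: list[PeakResult] = []
    for key in sorted(by_key):
        exp = expected_rts.get(key) if expected_rts else None
        all_results.extend(
            _integrate_transition(by_key[key], exp, rt_window, params)
        )

    samples = sorted({tr.sample_id for tr in traces})
    keys = sorted(by_key)
    values = pd.DataFrame(np.nan, index=samples, columns=keys)
    for p in all_results:
        if np.isfinite(p.area):
            values.loc[p.sample_id, p.transition_key] = p.area
    matrix = AreaMatrix(values, runsheet if runsheet is not None else pd.DataFrame())
    return matrix, all_results


def peak_results_frame(results: list[PeakResult]) -> pd.DataFrame:
    """Tabulate peak results (sidecar TSV content: bounds, flags, shifts)."""
    return pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in results],
            "transition_key": [p.transition_key for p in results],
            "apex_rt": [p.apex_rt for p in results],
            "left_rt": [p.left_rt for p in results],
            "right_rt": [p.right_rt for p in results],
            "area": [p.area for p in results],
            "height": [p.height for p in results],
            "n_points": [p.n_points for p in results],
            "rt_shift": [p.rt_shift for p in results],
            "flags": [",".join(sorted(p.flags)) for p in results],
        }
    )
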