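"""ECG preprocessing and Pan-Tompkins R-peak detection.

The detection pipeline follows the classic construction: band-pass
(5-15 Hz) -> five-point derivative -> squaring -> 150 ms moving-window
integration -> dual adaptive thresholds with a 200 ms refractory period,
search-back when a beat is overdue, and T-wave rejection by slope
comparison.  The original integer filters were designed for 200 Hz
records; here the band-pass is a Butterworth filter redesigned at the
record's own sampling rate and applied forward-backward (zero phase), so
R-peak timing is preserved at 500 Hz without resampling.

Detected integration-window peaks are refined to the local maximum of
the band-passed signal within +-150 ms and then of the raw signal
within +-25 ms, giving sample-accurate R apices for RR-interval work.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sps

from .containers import (
    REFRACTORY_MS,
    RR_MAX_MS,
    RR_MIN_MS,
    BeatSeries,
    EcgRecord,
    InsufficientDataError,
    InvalidSpecError,
    RRSeries,
)

__all__ = [
    "bandpass_filter",
    "baseline_correct",
    "pan_tompkins_detect",
    "beats_to_rr",
    "rr_artifact_filter",
    "detection_performance",
]

log = logging.getLogger(__name__)

_BAND = (5.0, 15.0)  # Hz


def _filtfilt_all_leads(ecg: EcgRecord, b, a) -> EcgRecord:
    out = np.vstack([sps.filtfilt(b, a, row) for row in ecg.samples])
    return EcgRecord(out, fs=ecg.fs, leads=tuple(ecg.leads), start_time=ecg.start_time)


def bandpass_filter(ecg: EcgRecord, order: int = 3) -> EcgRecord:
    """Zero-phase Butterworth band-pass (~5-15 Hz) on every lead."""
    if ecg.fs < 2 * _BAND[1] * 1.05:
        raise InvalidSpecError(
            f"fs={ecg.fs} Hz too low for a {_BAND[1]} Hz passband edge"
        )
    b, a = sps.butter(order, _BAND, btype="bandpass", fs=ecg.fs)
    return _filtfilt_all_leads(ecg, b, a)


def baseline_correct(ecg: EcgRecord, cutoff_hz: float = 0.5, order: int = 2) -> EcgRecord:
    """Remove slow baseline drift (< ~0.5 Hz) with a zero-phase high-pass."""
    if ecg.duration < 2.0:
        raise InsufficientDataError("record shorter than 2 s; cannot estimate baseline")
    b, a = sps.butter(order, cutoff_hz, btype="highpass", fs=ecg.fs)
    return _filtfilt_all_leads(ecg, b, a)


def _five_point_derivative(x: np.ndarray, fs: float) -> np.ndarray:
    # y[n] = (fs/8) * (-x[n-2] - 2 x[n-1] + 2 x[n+1] + x[n+2])
    y = np.zeros_like(x)
    y[2:-2] = (-x[:-4] - 2 * x[1:-3] + 2 * x[3:-1] + x[4:]) * (fs / 8.0)
    return y


def pan_tompkins_detect(
    ecg: EcgRecord,
    lead: Optional[str] = None,
    refine: bool = True,
) -> BeatSeries:
    """Detect R peaks on one lead with the Pan-Tompkins algorithm.

    Lead II is analyzed when present (the rhythm-analysis convention),
    otherwise the first lead.  Requires at least 10 s of signal for the
    threshold learning phase; signal/noise running levels are
    initialized from the max/mean of the first 2 s of the integrated
    trace.  THRESHOLD = noise + 0.25 (signal - noise); beats within the
    200 ms refractory window are rejected; candidates within 360 ms of
    the previous beat whose maximal slope is below half the previous
    beat's are rejected as T waves; when no beat arrives within 166% of
    the running average RR, a search-back pass accepts the best
    candidate above half threshold.
    """
    raw = ecg.lead(lead)
    if not np.all(np.isfinite(raw)):
        raise InvalidSpecError("ECG contains non-finite samples")
    fs = ecg.fs
    if ecg.duration < 10.0:
        raise InsufficientDataError("need >= 10 s of ECG for threshold learning")

    sel = lead if lead is not None else ("II" if "II" in ecg.leads else ecg.leads[0])
    one = EcgRecord(ecg.lead(sel)[np.newaxis, :], fs=fs, leads=(sel,))
    corrected = baseline_correct(one).samples[0]
    bp = bandpass_filter(
        EcgRecord(corrected[np.newaxis, :], fs=fs, leads=(sel,))
    ).samples[0]
    der = _five_point_derivative(bp, fs)
    sq = der**2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_MS / 1000.0 * fs))
    # candidate peaks of the integrated trace; a loose spacing floor only,
    # the true refractory is enforced against accepted beats below
    cand, _ = sps.find_peaks(mwi, distance=max(1, int(round(0.05 * fs))))
    if cand.size == 0:
        warnings.warn("no candidate peaks found; returning empty beat series")
        return BeatSeries(np.array([], dtype=np.int64), fs=fs)

    learn = mwi[: int(round(2.0 * fs))]
    spki = float(np.max(learn))
    npki = float(np.mean(learn))
    if spki <= 0:
        warnings.warn("flat signal during learning phase; returning empty beat series")
        return BeatSeries(np.array([], dtype=np.int64), fs=fs)

    slope_win = int(round(0.075 * fs))

    def max_slope(i: int) -> float:
        lo, hi = max(0, i - slope_win), min(der.size, i + slope_win + 1)
        return float(np.max(np.abs(der[lo:hi])))

    qrs: list[int] = []
    rr_hist: list[float] = []
    noise_cands: list[int] = []

    def accept(i: int, searchback: bool = False) -> None:
        nonlocal spki
        a = mwi[i]
        if searchback:
            spki = 0.25 * a + 0.75 * spki
        else:
            spki = 0.125 * a + 0.875 * spki
        if qrs:
            rr_hist.append(float(i - qrs[-1]))
            if len(rr_hist) > 8:
                rr_hist.pop(0)
        qrs.append(i)

    for i in cand:
        thr = npki + 0.25 * (spki - npki)
        a = mwi[i]
        is_beat = False
        if a > thr:
            if qrs and (i - qrs[-1]) < refractory:
                pass  # inside refractory: ignore entirely
            elif qrs and (i - qrs[-1]) < int(round(0.360 * fs)) and max_slope(i) < 0.5 * max_slope(qrs[-1]):
                npki = 0.125 * a + 0.875 * npki  # T wave
                noise_cands.append(i)
            else:
                accept(i)
                is_beat = True
        else:
            npki = 0.125 * a + 0.875 * npki
            noise_cands.append(i)
        # search-back: beat overdue relative to the running average RR
        if not is_beat and qrs and rr_hist:
            rr_avg = float(np.mean(rr_hist))
            if (i - qrs[-1]) > 1.66 * rr_avg:
                thr_half = 0.5 * (npki + 0.25 * (spki - npki))
                window = [
                    j for j in noise_cands if qrs[-1] + refractory <= j <= i and mwi[j] > thr_half
                ]
                if window:
                    best = max(window, key=lambda j: mwi[j])
                    accept(best, searchback=True)
                    # keep ordering if the searchback beat precedes i
                    qrs.sort()

    if not qrs:
        warnings.warn("no peaks above threshold after learning phase")
        return BeatSeries(np.array([], dtype=np.int64), fs=fs)

    idx = np.array(sorted(set(qrs)), dtype=np.int64)
    if refine:
        idx = _refine_peaks(idx, bp, corrected, fs)
    # enforce the refractory contract on the final series
    keep = [int(idx[0])]
    for j in idx[1:]:
        if j - keep[-1] >= refractory:
            keep.append(int(j))
    return BeatSeries(np.array(keep, dtype=np.int64), fs=fs)


def _refine_peaks(idx: np.ndarray, bp: np.ndarray, raw: np.ndarray, fs: float) -> np.ndarray:
    w_bp = int(round(0.150 * fs))
    w_raw = int(round(0.025 * fs))
    out = []
    for i in idx:
        lo, hi = max(0, i - w_bp), min(bp.size, i + w_bp + 1)
        j = lo + int(np.argmax(bp[lo:hi]))
        lo2, hi2 = max(0, j - w_raw), min(raw.size, j + w_raw + 1)
        out.append(lo2 + int(np.argmax(raw[lo2:hi2])))
    return np.array(sorted(set(out)), dtype=np.int64)


def beats_to_rr(beats: BeatSeries, label: str = "") -> RRSeries:
    """RR intervals (ms) from successive R-peak indices."""
    if len(beats) < 2:
        raise InsufficientDataError("need at least 2 beats to form RR intervals")
    rr_ms = np.diff(beats.indices) / beats.fs * 1000.0
    return RRSeries(rr_ms, label=label)


def rr_artifact_filter(
    rr: RRSeries,
    bounds_ms: Tuple[float, float] = (RR_MIN_MS, RR_MAX_MS),
    max_rel_dev: float = 0.30,
    quality_threshold: float = 0.20,
) -> RRSeries:
    """Remove physiologically implausible and ectopic intervals.

    Drops intervals outside ``bounds_ms`` or deviating more than
    ``max_rel_dev`` from the running median of 5 neighbours.  The
    removal count is logged and stored in ``meta["n_removed"]``; when
    more than ``quality_threshold`` of intervals are removed the output
    carries ``meta["quality_warning"] = True``.
    """
    if len(rr) == 0:
        raise InsufficientDataError("empty RR series")
    iv = rr.intervals
    med = sps.medfilt(iv, kernel_size=min(5, len(iv) if len(iv) % 2 else len(iv) - 1) or 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(iv - med) / med
    bad = (iv < bounds_ms[0]) | (iv > bounds_ms[1]) | (rel > max_rel_dev)
    n_removed = int(bad.sum())
    if n_removed:
        log.info("rr_artifact_filter removed %d of %d intervals", n_removed, len(iv))
    meta = dict(rr.meta)
    meta["n_removed"] = n_removed
    frac = n_removed / len(iv)
    meta["quality_warning"] = bool(frac > quality_threshold)
    if meta["quality_warning"]:
        warnings.warn(
            f"artifact filter removed {frac:.0%} of intervals; segment quality suspect"
        )
    return RRSeries(iv[~bad], label=rr.label, meta=meta)


def detection_performance(
    detected: BeatSeries, truth: BeatSeries, tol_ms: float = 20.0
) -> Tuple[float, float]:
    """Sensitivity and positive predictivity of a detection, percent.

    Greedy one-to-one matching of detected to true beats within
    ``+-tol_ms``: Se = TP/(TP+FN) x 100, +P = TP/(TP+FP) x 100.
    """
    if tol_ms <= 0:
        raise InvalidSpecError("tolerance must be positive")
    if detected.fs != truth.fs:
        raise InvalidSpecError("beat series must share a sampling rate")
    tol = tol_ms / 1000.0 * truth.fs
    det = detected.indices
    tru = truth.indices
    used = np.zeros(det.size, dtype=bool)
    tp = 0
    for t in tru:
        if det.size == 0:
            break
        d = np.abs(det - t).astype(float)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol:
            used[j] = True
            tp += 1
    fn = tru.size - tp
    fp = det.size - tp
    se = 100.0 * tp / (tp + fn) if tru.size else float("nan")
    ppv = 100.0 * tp / (tp + fp) if det.size else float("nan")
    return se, ppv
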