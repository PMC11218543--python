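"""The 21 HRV features: time domain, frequency domain, nonlinear.

Feature definitions follow the study's printed formula dialect by
default (``dialect="printed"``): SDNN uses the 1/N population form,
RMSSD averages the N-1 squared successive differences with 1/(N-1), and
PNN50 divides NN50 by the total interval count N.  Conventional HRV
practice (sample-variance SDNN, PNN50 over N-1 differences) is
available with ``dialect="conventional"``.

Frequency-domain features are computed from a Welch periodogram of the
RR tachogram cubic-spline-resampled at 4 Hz (120 s windows, 50%
overlap); band powers integrate the PSD over VLF [0.003, 0.04), LF
[0.04, 0.15) and HF [0.15, 0.4] Hz, and total power is defined as their
sum, so the normalized powers HFn = HF/(TP - VLF) x 100 and LFn
complement to exactly 100.  A Lomb-Scargle estimator for irregularly
sampled tachograms is available behind ``method="lombscargle"``.

Nonlinear features derive from the lag-1 Poincare plot: SD1/SD2 are the
dispersions across/along the identity line (population form), S = pi
SD1 SD2 the fitted ellipse area, VLI the dispersion of vector lengths
along the identity line (identically SD2 under this definition — the
study's own summaries for the two are numerically near-identical), PI
the Porta index (percentage of negative nonzero successive
differences), and CCM_1 the complex correlation measure: mean absolute
area of the triangles of three consecutive Poincare points, normalized
by pi SD1 SD2.

Undefined features (degenerate normalizations, zero variance) are
returned as NaN with a reason recorded in ``HrvFeatures.flags`` — never
as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .containers import InsufficientDataError, InvalidSpecError, RRSeries

__all__ = [
    "FEATURE_NAMES",
    "SpectralEstimate",
    "HrvFeatures",
    "time_domain",
    "tinn",
    "psd_welch",
    "band_powers",
    "poincare",
    "vli",
    "porta_index",
    "ccm",
    "extract_all",
]

VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)

#: stable column order of the 21-feature schema
FEATURE_NAMES = (
    "meanHR", "meanRR", "SDNN", "RMSSD", "TINN", "PNN50", "SDSD",
    "HF", "LF", "HFn", "LFn", "LFn_HFn", "TP", "VLF",
    "SD1", "SD2", "SD1_SD2", "S", "VLI", "PI", "CCM_1",
)

TINN_BIN_MS = 1000.0 / 128.0  # 7.8125 ms


@dataclass
class SpectralEstimate:
    """PSD of the RR tachogram: frequency grid (Hz), density (ms^2/Hz)."""

    freqs: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs.shape != self.psd.shape:
            raise InvalidSpecError("frequency grid and PSD must have equal shapes")
        if np.any(np.diff(self.freqs) <= 0):
            raise InvalidSpecError("frequency grid must be strictly increasing")
        if np.any(self.psd < 0):
            raise InvalidSpecError("PSD must be non-negative")


@dataclass
class HrvFeatures:
    """The 21 named features for one segment; NaN marks undefined values."""

    values: Dict[str, float] = field(default_factory=dict)
    flags: Dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_dict(self) -> Dict[str, float]:
        return {k: self.values.get(k, float("nan")) for k in FEATURE_NAMES}

    @property
    def n_missing(self) -> int:
        return sum(1 for k in FEATURE_NAMES if np.isnan(self.values.get(k, np.nan)))


def _check_min(rr: RRSeries, n: int) -> np.ndarray:
    if len(rr) < n:
        raise InsufficientDataError(f"need at least {n} intervals, got {len(rr)}")
    return rr.intervals


def time_domain(rr: RRSeries, dialect: str = "printed") -> Dict[str, float]:
    """meanHR, meanRR, SDNN, RMSSD, SDSD, PNN50 for one segment.

    ``dialect="printed"`` uses the study's printed forms (population
    SDNN, PNN50 denominator N); ``"conventional"`` uses sample-variance
    SDNN and the N-1 difference count for PNN50.
    """
    x = _check_min(rr, 3)
    n = x.size
    d = np.diff(x)
    mean_rr = float(np.mean(x))
    if dialect == "printed":
        sdnn = float(np.std(x, ddof=0))
        pnn50_den = n
    elif dialect == "conventional":
        sdnn = float(np.std(x, ddof=1))
        pnn50_den = n - 1
    else:
        raise InvalidSpecError(f"unknown dialect {dialect!r}")
    rmssd = float(np.sqrt(np.mean(d**2)))  # 1/(N-1) over the N-1 differences
    sdsd = float(np.std(d, ddof=0))
    nn50 = int(np.sum(np.abs(d) > 50.0))
    return {
        "meanRR": mean_rr,
        "meanHR": 60000.0 / mean_rr,
        "SDNN": sdnn,
        "RMSSD": rmssd,
        "SDSD": sdsd,
        "PNN50": 100.0 * nn50 / pnn50_den,
    }


def _histogram_128(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Counts and bin centers with centers on multiples of 1/128 s."""
    w = TINN_BIN_MS
    k_lo = int(np.floor(x.min() / w + 0.5))
    k_hi = int(np.floor(x.max() / w + 0.5))
    centers = np.arange(k_lo, k_hi + 1) * w
    edges = np.arange(k_lo, k_hi + 2) * w - w / 2.0
    counts, _ = np.histogram(x, bins=edges)
    return counts.astype(float), centers


def tinn(rr: RRSeries, return_flag: bool = False):
    """Triangular interpolation of the RR histogram: base width M - N, ms.

    The RR histogram uses 1/128 s bins (centers on multiples of
    7.8125 ms).  A triangular function with apex at the modal bin center
    (height = modal count) is fitted by exhaustive search of its zero
    crossings N <= mode <= M over bin edges, minimizing the summed
    squared error against the bin counts; TINN = M - N.

    A single occupied bin is degenerate: returns 0 (with flag
    ``"degenerate-histogram"`` when ``return_flag``).
    """
    x = _check_min(rr, 3)
    counts, centers = _histogram_128(x)
    occupied = np.nonzero(counts)[0]
    if occupied.size == 1:
        return (0.0, "degenerate-histogram") if return_flag else 0.0
    w = TINN_BIN_MS
    m = int(np.argmax(counts))
    peak = counts[m]
    c_m = centers[m]
    nbins = counts.size
    # The apex is pinned at (c_m, peak) and only the zero crossings move,
    # so the squared error splits into independent left (bins <= mode)
    # and right (bins > mode) parts; each side is searched exhaustively
    # over bin edges, extended one histogram-width beyond the occupied
    # range so wide shallow triangles remain reachable.
    pad = nbins + 1
    left_edges = c_m - w / 2.0 - w * np.arange(0, m + pad)
    right_edges = c_m + w / 2.0 + w * np.arange(0, nbins - m - 1 + pad)

    def side_fit(edges: np.ndarray, cs: np.ndarray, ds: np.ndarray, left: bool) -> float:
        best_err, best_edge = np.inf, edges[0]
        for e in edges:
            if left:
                q = np.where(cs >= e, peak * (cs - e) / (c_m - e), 0.0)
            else:
                q = np.where(cs <= e, peak * (e - cs) / (e - c_m), 0.0)
            err = float(np.sum((ds - q) ** 2))
            if err < best_err - 1e-12:
                best_err, best_edge = err, float(e)
        return best_edge

    N = side_fit(left_edges, centers[: m + 1], counts[: m + 1], left=True)
    M = side_fit(right_edges, centers[m + 1 :], counts[m + 1 :], left=False)
    return (float(M - N), "") if return_flag else float(M - N)


def psd_welch(
    rr: RRSeries,
    resample_hz: float = 4.0,
    window_s: float = 120.0,
    method: str = "welch",
) -> SpectralEstimate:
    """Welch PSD of the 4 Hz cubic-spline-resampled RR tachogram.

    The tachogram assigns each interval to the time of its closing
    beat, is resampled on a uniform grid, linearly detrended, and
    estimated with 120 s Hann windows at 50% overlap.  Requires at
    least 120 s of cumulative time (one full window).  With
    ``method="lombscargle"`` the PSD is estimated directly on the
    irregular beat times instead.
    """
    x = _check_min(rr, 4)
    if rr.total_time_s < window_s:
        raise InsufficientDataError(
            f"need >= {window_s:.0f} s of cumulative RR time, got {rr.total_time_s:.1f} s"
        )
    t = np.cumsum(x) / 1000.0  # closing-beat times, s

    if method == "lombscargle":
        freqs = VLF_BAND[0] + np.arange(0.0, HF_BAND[1] + 0.1, 1.0 / window_s)
        xc = x - np.mean(x)
        pgram = sps.lombscargle(t, xc, 2 * np.pi * freqs)
        # scale the periodogram to a one-sided density whose integral
        # over the evaluated grid equals the tachogram variance
        total = np.trapezoid(pgram, freqs)
        scale = np.var(xc) / total if total > 0 else 0.0
        return SpectralEstimate(freqs, pgram * scale)
    if method != "welch":
        raise InvalidSpecError(f"unknown spectral method {method!r}")

    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    y = CubicSpline(t, x)(grid)
    y = sps.detrend(y, type="linear")
    nperseg = min(int(window_s * resample_hz), y.size)
    freqs, psd = sps.welch(
        y,
        fs=resample_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
    )
    return SpectralEstimate(freqs, psd)


def band_powers(spec: SpectralEstimate) -> Dict[str, float]:
    """VLF/LF/HF/TP (ms^2) and normalized powers from a PSD.

    Trapezoidal panels of the PSD are assigned to a band by their
    midpoint frequency, so the three band powers partition the total
    power over [0.003, 0.4] Hz exactly; TP is their sum, making
    HFn + LFn = 100 hold identically whenever defined.
    """
    f, p = spec.freqs, spec.psd
    if f[0] > VLF_BAND[0] or f[-1] < HF_BAND[1]:
        raise InvalidSpecError(
            f"grid [{f[0]}, {f[-1]}] Hz does not cover [{VLF_BAND[0]}, {HF_BAND[1]}] Hz"
        )
    mid = 0.5 * (f[1:] + f[:-1])
    panel = 0.5 * (p[1:] + p[:-1]) * np.diff(f)
    out = {}
    for name, (lo, hi) in (("VLF", VLF_BAND), ("LF", LF_BAND), ("HF", HF_BAND)):
        out[name] = float(panel[(mid >= lo) & (mid < hi)].sum())
    out["TP"] = out["VLF"] + out["LF"] + out["HF"]
    denom = out["TP"] - out["VLF"]
    # a physiologically empty spectrum (< 1e-10 ms^2) only normalizes noise
    if denom <= 0 or out["TP"] <= 1e-10:
        raise InvalidSpecError("TP - VLF <= 0; normalized powers undefined")
    out["HFn"] = 100.0 * out["HF"] / denom
    out["LFn"] = 100.0 * out["LF"] / denom
    out["LFn_HFn"] = out["LFn"] / out["HFn"] if out["HFn"] > 0 else float("inf")
    return out


def _poincare_points(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    return x[:-1], x[1:]


def poincare(rr: RRSeries) -> Dict[str, float]:
    """SD1, SD2, SD1/SD2 and ellipse area S from the lag-1 Poincare plot."""
    x = _check_min(rr, 3)
    a, b = _poincare_points(x)
    sd1 = float(np.std((a - b) / np.sqrt(2.0), ddof=0))
    sd2 = float(np.std((a + b) / np.sqrt(2.0), ddof=0))
    return {
        "SD1": sd1,
        "SD2": sd2,
        "SD1_SD2": sd1 / sd2 if sd2 > 0 else float("nan"),
        "S": float(np.pi * sd1 * sd2),
    }


def vli(rr: RRSeries) -> float:
    """Vector length index: dispersion of Poincare points along the identity line.

    Defined as the population standard deviation of (RR_i + RR_{i+1})/sqrt(2),
    i.e. identically SD2.
    """
    x = _check_min(rr, 3)
    a, b = _poincare_points(x)
    return float(np.std((a + b) / np.sqrt(2.0), ddof=0))


def porta_index(rr: RRSeries) -> float:
    """Porta index: % of negative successive differences among nonzero ones.

    Returns NaN when every successive difference is zero.
    """
    x = _check_min(rr, 2)
    d = np.diff(x)
    nz = d[d != 0]
    if nz.size == 0:
        return float("nan")
    return 100.0 * float(np.sum(nz < 0)) / nz.size


def triangle_areas(rr: RRSeries) -> np.ndarray:
    """Unsigned areas of triangles of three consecutive Poincare points, ms^2."""
    x = _check_min(rr, 4)
    a, b = _poincare_points(x)
    x1, y1 = a[:-2], b[:-2]
    x2, y2 = a[1:-1], b[1:-1]
    x3, y3 = a[2:], b[2:]
    shoelace = x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2)
    return np.abs(shoelace) / 2.0


def ccm(rr: RRSeries, lag: int = 1) -> float:
    """Complex correlation measure of the lag-``lag`` Poincare plot.

    CCM = sum_i |A(i)| / ((N' - 2) pi SD1 SD2), with A(i) the area of
    the triangle of Poincare points i, i+1, i+2 and N' the number of
    points.  Raises when the fitted ellipse is degenerate (S = 0).
    """
    if lag != 1:
        raise InvalidSpecError("only the lag-1 CCM is defined here")
    x = _check_min(rr, 4)
    pc = poincare(rr)
    s = pc["S"]
    if s <= 0:
        raise InvalidSpecError("degenerate Poincare ellipse (S = 0); CCM undefined")
    areas = triangle_areas(rr)
    n_points = x.size - 1
    return float(areas.sum() / ((n_points - 2) * np.pi * pc["SD1"] * pc["SD2"]))


def extract_all(
    rr: RRSeries,
    dialect: str = "printed",
    spectral_method: str = "welch",
) -> HrvFeatures:
    """All 21 features for one (nominally 5-min) segment.

    Sub-operation failures become NaN values with reason flags rather
    than exceptions, so one degenerate feature never aborts a batch run.
    """
    feats = HrvFeatures()

    def put(vals: Dict[str, float]) -> None:
        feats.values.update(vals)

    def fail(names, reason: str) -> None:
        for nm in names:
            feats.values[nm] = float("nan")
            feats.flags[nm] = reason

    try:
        put(time_domain(rr, dialect=dialect))
    except (InsufficientDataError, InvalidSpecError) as e:
        fail(("meanHR", "meanRR", "SDNN", "RMSSD", "SDSD", "PNN50"), str(e))

    try:
        t, flag = tinn(rr, return_flag=True)
        feats.values["TINN"] = t
        if flag:
            feats.flags["TINN"] = flag
    except (InsufficientDataError, InvalidSpecError) as e:
        fail(("TINN",), str(e))

    freq_names = ("HF", "LF", "HFn", "LFn", "LFn_HFn", "TP", "VLF")
    try:
        bp = band_powers(psd_welch(rr, method=spectral_method))
        put({k: bp[k] for k in freq_names})
        if not np.isfinite(bp["LFn_HFn"]):
            feats.values["LFn_HFn"] = float("nan")
            feats.flags["LFn_HFn"] = "HFn is zero; ratio undefined"
    except (InsufficientDataError, InvalidSpecError) as e:
        fail(freq_names, str(e))

    try:
        pc = poincare(rr)
        put(pc)
        if np.isnan(pc["SD1_SD2"]):
            feats.flags["SD1_SD2"] = "SD2 is zero; ratio undefined"
        feats.values["VLI"] = vli(rr)
    except (InsufficientDataError, InvalidSpecError) as e:
        fail(("SD1", "SD2", "SD1_SD2", "S", "VLI"), str(e))

    try:
        pi_val = porta_index(rr)
        feats.values["PI"] = pi_val
        if np.isnan(pi_val):
            feats.flags["PI"] = "all successive differences are zero"
    except (InsufficientDataError, InvalidSpecError) as e:
        fail(("PI",), str(e))

    try:
        feats.values["CCM_1"] = ccm(rr)
    except (InsufficientDataError, InvalidSpecError) as e:
        fail(("CCM_1",), str(e))

    return feats
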