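"""Independent brute-force oracles for the HRV features and test statistics.

Everything here is written as naive loops over the printed formula
definitions (no shared code with the package), so agreement with the
implementation is evidence, not tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.interpolate import CubicSpline

BIN_W = 1000.0 / 128.0


def o_mean_rr(x):
    return sum(x) / len(x)


def o_mean_hr(x):
    return 60000.0 / o_mean_rr(x)


def o_sdnn(x, dialect="printed"):
    n = len(x)
    m = o_mean_rr(x)
    ss = sum((v - m) ** 2 for v in x)
    den = n if dialect == "printed" else n - 1
    return math.sqrt(ss / den)


def o_rmssd(x):
    n = len(x)
    ss = sum((x[i + 1] - x[i]) ** 2 for i in range(n - 1))
    return math.sqrt(ss / (n - 1))


def o_sdsd(x):
    d = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    m = sum(d) / len(d)
    return math.sqrt(sum((v - m) ** 2 for v in d) / len(d))


def o_pnn50(x, dialect="printed"):
    nn50 = sum(1 for i in range(len(x) - 1) if abs(x[i + 1] - x[i]) > 50.0)
    den = len(x) if dialect == "printed" else len(x) - 1
    return 100.0 * nn50 / den


def o_sd1(x):
    pts = [((x[i] - x[i + 1]) / math.sqrt(2)) for i in range(len(x) - 1)]
    m = sum(pts) / len(pts)
    return math.sqrt(sum((v - m) ** 2 for v in pts) / len(pts))


def o_sd2(x):
    pts = [((x[i] + x[i + 1]) / math.sqrt(2)) for i in range(len(x) - 1)]
    m = sum(pts) / len(pts)
    return math.sqrt(sum((v - m) ** 2 for v in pts) / len(pts))


def o_s(x):
    return math.pi * o_sd1(x) * o_sd2(x)


def o_vli(x):
    return o_sd2(x)


def o_pi(x):
    d = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    nz = [v for v in d if v != 0]
    if not nz:
        return float("nan")
    return 100.0 * sum(1 for v in nz if v < 0) / len(nz)


def o_ccm(x):
    pts = [(x[i], x[i + 1]) for i in range(len(x) - 1)]
    areas = []
    for i in range(len(pts) - 2):
        (x1, y1), (x2, y2), (x3, y3) = pts[i], pts[i + 1], pts[i + 2]
        a = x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2)
        areas.append(abs(a) / 2.0)
    return sum(areas) / ((len(pts) - 2) * math.pi * o_sd1(x) * o_sd2(x))


def o_tinn(x):
    """Joint brute force over all (N, M) edge pairs; bins centered on k/128 s.

    Unlike the implementation (which exploits that the error splits at
    the apex), this scans every (N, M) pair jointly; the per-pair error
    uses vectorized arithmetic for speed only.
    """
    k_lo = int(math.floor(min(x) / BIN_W + 0.5))
    k_hi = int(math.floor(max(x) / BIN_W + 0.5))
    centers = np.array([k * BIN_W for k in range(k_lo, k_hi + 1)])
    counts = np.zeros(len(centers))
    for v in x:
        k = int(math.floor(v / BIN_W + 0.5))
        counts[k - k_lo] += 1
    if np.count_nonzero(counts) == 1:
        return 0.0
    m = int(np.argmax(counts))
    peak, c_m = counts[m], centers[m]
    nbins = len(counts)
    pad = nbins + 1
    lefts = [c_m - BIN_W / 2 - BIN_W * j for j in range(0, m + pad)]
    rights = [c_m + BIN_W / 2 + BIN_W * j for j in range(0, nbins - m - 1 + pad)]
    best_err, best_w = float("inf"), 0.0
    for N in lefts:
        for M in rights:
            rise = np.where(
                (centers >= N) & (centers <= c_m), peak * (centers - N) / (c_m - N), 0.0
            )
            fall = np.where(
                (centers > c_m) & (centers <= M), peak * (M - centers) / (M - c_m), 0.0
            )
            err = float(np.sum((counts - rise - fall) ** 2))
            if err < best_err - 1e-12:
                best_err, best_w = err, M - N
    return best_w


def o_welch_psd(x, resample_hz=4.0, window_s=120.0):
    """Manual Welch on the 4 Hz cubic-spline tachogram (Hann, 50% overlap)."""
    x = np.asarray(x, dtype=float)
    t = np.cumsum(x) / 1000.0
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    y = CubicSpline(t, x)(grid)
    # linear detrend by least squares
    A = np.vstack([grid, np.ones_like(grid)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    y = y - A @ coef
    nper = min(int(window_s * resample_hz), y.size)
    step = nper - nper // 2
    n_seg = (y.size - nper) // step + 1
    k = np.arange(nper)
    w = 0.5 - 0.5 * np.cos(2 * np.pi * k / nper)  # periodic Hann
    scale = 1.0 / (resample_hz * np.sum(w**2))
    psds = []
    for i in range(n_seg):
        seg = y[i * step : i * step + nper] * w
        spec = np.abs(np.fft.rfft(seg)) ** 2 * scale
        spec[1:] *= 2.0
        if nper % 2 == 0:
            spec[-1] /= 2.0
        psds.append(spec)
    freqs = np.fft.rfftfreq(nper, d=1.0 / resample_hz)
    return freqs, np.mean(psds, axis=0)


def o_band_powers(freqs, psd):
    """Naive panel loop with midpoint band assignment; TP = band sum."""
    bands = {"VLF": (0.003, 0.04), "LF": (0.04, 0.15), "HF": (0.15, 0.4)}
    out = {k: 0.0 for k in bands}
    for i in range(len(freqs) - 1):
        mid = (freqs[i] + freqs[i + 1]) / 2.0
        area = (psd[i] + psd[i + 1]) / 2.0 * (freqs[i + 1] - freqs[i])
        for name, (lo, hi) in bands.items():
            if lo <= mid < hi:
                out[name] += area
    out["TP"] = out["VLF"] + out["LF"] + out["HF"]
    den = out["TP"] - out["VLF"]
    out["HFn"] = 100.0 * out["HF"] / den
    out["LFn"] = 100.0 * out["LF"] / den
    out["LFn_HFn"] = out["LFn"] / out["HFn"]
    return out


# -- statistics -------------------------------------------------------------


def o_oneway_f(groups):
    """Sums-of-squares one-way ANOVA F."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def o_paired_t(pre, post):
    d = [a - b for a, b in zip(pre, post)]
    n = len(d)
    m = sum(d) / n
    sd = math.sqrt(sum((v - m) ** 2 for v in d) / (n - 1))
    return m / (sd / math.sqrt(n))


def o_mannwhitney_u(a, b):
    """Rank-based U statistic (midranks for ties), larger-sample convention free."""
    vals = [(v, "a") for v in a] + [(v, "b") for v in b]
    vals.sort(key=lambda t: t[0])
    ranks = [0.0] * len(vals)
    i = 0
    while i < len(vals):
        j = i
        while j + 1 < len(vals) and vals[j + 1][0] == vals[i][0]:
            j += 1
        r = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[k] = r
        i = j + 1
    ra = sum(r for r, (_, lab) in zip(ranks, vals) if lab == "a")
    return ra - len(a) * (len(a) + 1) / 2.0
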