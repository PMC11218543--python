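"""Synthetic cohort generation with known ground truth.

Three generators, in increasing order of aggregation:

* :func:`generate_rr_ipfm` — RR interval series from an integral pulse
  frequency modulation (IPFM) model.  An integrator of the instantaneous
  heart rate ``(1 + m(t)) / T0`` fires a beat each time it crosses an
  integer; ``m(t)`` is a sum of per-band (VLF/LF/HF) modulations.  With
  sinusoidal modulation the injected band powers are known analytically,
  which makes the output a parameter-recovery fixture for the spectral
  HRV features.
* :func:`generate_ecg` — a 500 Hz ECG voltage trace from an RR series
  using a Gaussian-bump PQRST template per beat, plus sinusoidal
  baseline wander and white noise.  True R-peak sample indices are
  returned for scoring QRS detectors.
* :func:`generate_cohort` — a three-group (blank / tDCS / tACS) by
  three-state (pre-fatigue / post-fatigue / post-stimulation) cohort of
  :class:`~hrvfatigue.containers.SessionRecord`: per-state RR series
  from state-shifted modulation specs, subjective fatigue scale (SFS)
  totals, and 2-back+parity trial records.  Default effect directions
  follow the published group-level summaries (fatigue raises SFS and
  lowers task accuracy; stimulation partially reverses both, most
  strongly for tACS).

:func:`generate_feature_cohort` additionally draws HRV feature matrices
directly (no signal synthesis) for statistical calibration and power
studies of the analysis stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .containers import (
    GROUPS,
    STATES,
    EcgRecord,
    InvalidSpecError,
    RRSeries,
    SessionRecord,
    TrialRecord,
)

__all__ = [
    "ModulationSpec",
    "EcgSynthConfig",
    "GroupStateSpec",
    "CohortDesign",
    "generate_rr_ipfm",
    "generate_ecg",
    "generate_cohort",
    "generate_feature_cohort",
    "inject_ectopy",
    "default_design",
    "FEATURE_BASELINES",
    "TACS_EFFECT_SIGNS",
]

# Spectral band edges (Hz) shared with the HRV stage.
VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)


@dataclass(frozen=True)
class ModulationSpec:
    """Parameters of the IPFM heart-rate modulation.

    Each band contributes a sinusoid ``amp * sin(2 pi f t + phase)`` to
    the dimensionless modulation ``m(t)``; phases are drawn from
    ``seed`` unless fixed with ``phases``.  ``amp`` values are fractions
    of the mean rate, so their sum must stay below 1 to keep the
    instantaneous rate positive.
    """

    mean_rr: float = 850.0  # ms
    amp_vlf: float = 0.01
    amp_lf: float = 0.04
    amp_hf: float = 0.04
    f_vlf: float = 0.02  # Hz
    f_lf: float = 0.1  # Hz
    f_hf: float = 0.25  # Hz
    duration: float = 300.0  # s
    seed: int = 0
    phases: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise InvalidSpecError(f"mean_rr must be positive, got {self.mean_rr}")
        amps = (self.amp_vlf, self.amp_lf, self.amp_hf)
        if any(a < 0 for a in amps):
            raise InvalidSpecError("modulation amplitudes must be non-negative")
        if sum(amps) >= 1:
            raise InvalidSpecError(
                "sum of modulation amplitudes must be < 1 to keep the rate positive"
            )
        if not (LF_BAND[0] <= self.f_lf < LF_BAND[1]):
            raise InvalidSpecError(f"f_lf={self.f_lf} outside the LF band {LF_BAND}")
        if not (HF_BAND[0] <= self.f_hf <= HF_BAND[1]):
            raise InvalidSpecError(f"f_hf={self.f_hf} outside the HF band {HF_BAND}")
        if not (VLF_BAND[0] <= self.f_vlf < VLF_BAND[1]):
            raise InvalidSpecError(f"f_vlf={self.f_vlf} outside the VLF band {VLF_BAND}")
        if self.duration <= 0:
            raise InvalidSpecError("duration must be positive")

    def true_band_powers_ms2(self) -> Dict[str, float]:
        """Analytic power of the RR tachogram modulation per band, ms^2.

        A sinusoidal rate modulation of fractional amplitude ``a`` at
        frequency ``f`` modulates the RR tachogram with amplitude
        ``a * mean_rr * sinc(f T0)`` to first order: each interval
        averages the instantaneous rate over one beat (length ~T0), so
        faster modulations are attenuated by the aperture factor
        ``sinc(f T0) = sin(pi f T0)/(pi f T0)``.  Band power is then
        ``(a * mean_rr * sinc(f T0))^2 / 2``.
        """
        T0 = self.mean_rr / 1000.0

        def power(amp: float, f: float) -> float:
            att = np.sinc(f * T0)  # numpy sinc is sin(pi x)/(pi x)
            return (amp * self.mean_rr * att) ** 2 / 2.0

        return {
            "VLF": power(self.amp_vlf, self.f_vlf),
            "LF": power(self.amp_lf, self.f_lf),
            "HF": power(self.amp_hf, self.f_hf),
        }


def generate_rr_ipfm(spec: ModulationSpec, grid_dt: float = 0.004) -> RRSeries:
    """Generate an RR series from the IPFM model.

    Beat times ``t_k`` satisfy ``integral_0^{t_k} (1 + m(t)) / T0 dt = k``
    with ``T0 = mean_rr``.  The integral is accumulated by the
    trapezoidal rule on a ``grid_dt`` grid (4 ms default) and integer
    crossings are located by linear interpolation, giving
    sub-millisecond beat-time accuracy.

    Returns an :class:`RRSeries` (ms) whose ``meta`` holds the analytic
    per-band ground-truth powers under ``"true_band_powers_ms2"``.
    """
    T0 = spec.mean_rr / 1000.0  # s
    t = np.arange(0.0, spec.duration + grid_dt, grid_dt)

    if spec.phases is not None:
        ph = np.asarray(spec.phases, dtype=float)
    else:
        ph = np.random.default_rng(spec.seed).uniform(0, 2 * np.pi, size=3)
    m = (
        spec.amp_vlf * np.sin(2 * np.pi * spec.f_vlf * t + ph[0])
        + spec.amp_lf * np.sin(2 * np.pi * spec.f_lf * t + ph[1])
        + spec.amp_hf * np.sin(2 * np.pi * spec.f_hf * t + ph[2])
    )
    rate = (1.0 + m) / T0
    if np.any(rate <= 0):
        raise InvalidSpecError("modulation drives the instantaneous rate non-positive")

    # cumulative trapezoid of the rate; integer crossings are beats
    integ = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) * 0.5 * grid_dt)])
    n_beats = int(np.floor(integ[-1]))
    ks = np.arange(1, n_beats + 1, dtype=float)
    right = np.searchsorted(integ, ks)  # integ[right-1] < k <= integ[right]
    frac = (ks - integ[right - 1]) / (integ[right] - integ[right - 1])
    beat_times = t[right - 1] + frac * grid_dt
    beat_times = np.concatenate([[0.0], beat_times])

    rr_ms = np.diff(beat_times) * 1000.0
    return RRSeries(
        rr_ms,
        label="ipfm",
        meta={
            "true_band_powers_ms2": spec.true_band_powers_ms2(),
            "beat_times_s": beat_times,
            "spec": spec,
        },
    )


# ---------------------------------------------------------------------------
# ECG synthesis
# ---------------------------------------------------------------------------

#: (amplitude uV, Gaussian sigma s, offset from R apex s) per wave
_DEFAULT_WAVES: Dict[str, Tuple[float, float, float]] = {
    "P": (150.0, 0.025, -0.20),
    "Q": (-150.0, 0.010, -0.035),
    "R": (1000.0, 0.012, 0.0),
    "S": (-200.0, 0.010, 0.035),
    "T": (300.0, 0.060, 0.30),
}


@dataclass(frozen=True)
class EcgSynthConfig:
    """Gaussian PQRST template plus additive artifact parameters."""

    fs: float = 500.0
    waves: Mapping[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_WAVES)
    )
    wander_amp: float = 0.0  # uV
    wander_freq: float = 0.2  # Hz
    noise_sd: float = 0.0  # uV
    seed: int = 0
    lead: str = "II"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise InvalidSpecError("fs must be positive")
        if self.waves["R"][0] <= 0:
            raise InvalidSpecError("R amplitude must be positive")
        if any(w[1] <= 0 for w in self.waves.values()):
            raise InvalidSpecError("wave widths must be positive")

    def qrs_support_s(self) -> float:
        """Span of the QRS sub-template (Q..S offsets +- 3 sigma), seconds."""
        aq, sq, oq = self.waves["Q"]
        as_, ss, os_ = self.waves["S"]
        return (os_ + 3 * ss) - (oq - 3 * sq)


def generate_ecg(rr: RRSeries, cfg: EcgSynthConfig = EcgSynthConfig()) -> Tuple[EcgRecord, np.ndarray]:
    """Render an RR series as a single-lead ECG voltage trace.

    One PQRST complex is laid down per beat, the R apex at the
    cumulative beat time (plus a lead-in pad that lets the first P wave
    fit) rounded to the nearest sample; baseline wander and white noise
    are added afterwards, so the returned true R indices describe the
    noise-free construction.

    Returns ``(record, true_r_indices)``.
    """
    if len(rr) == 0:
        raise InvalidSpecError("RR series is empty")
    if cfg.fs < 100:
        raise InvalidSpecError("fs must be at least 100 Hz for QRS morphology")
    if float(np.min(rr.intervals)) / 1000.0 < cfg.qrs_support_s():
        raise InvalidSpecError(
            "beat spacing shorter than the QRS template support; complexes would merge"
        )

    # widest wave decides the per-beat stamp window and the edge pad
    half = max(abs(o) + 4 * s for (_, s, o) in cfg.waves.values())
    kmax = int(math.ceil(half * cfg.fs))

    beat_times = rr.beat_times_s() + half
    n = int(math.ceil((beat_times[-1] + half) * cfg.fs)) + 1
    x = np.zeros(n)
    r_idx = np.rint(beat_times * cfg.fs).astype(np.int64)
    rel = np.arange(-kmax, kmax + 1) / cfg.fs
    template = np.zeros_like(rel)
    for amp, sigma, off in cfg.waves.values():
        template += amp * np.exp(-0.5 * ((rel - off) / sigma) ** 2)

    for idx in r_idx:
        lo, hi = idx - kmax, idx + kmax + 1
        tlo = max(0, -lo)
        thi = template.size - max(0, hi - n)
        x[max(0, lo) : min(n, hi)] += template[tlo:thi]

    rng = np.random.default_rng(cfg.seed)
    if cfg.wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        tgrid = np.arange(n) / cfg.fs
        x = x + cfg.wander_amp * np.sin(2 * np.pi * cfg.wander_freq * tgrid + phase)
    if cfg.noise_sd > 0:
        x = x + rng.normal(0.0, cfg.noise_sd, size=n)

    rec = EcgRecord(x[np.newaxis, :], fs=cfg.fs, leads=(cfg.lead,))
    return rec, r_idx


def inject_ectopy(rr: RRSeries, positions: Sequence[int], short_frac: float = 0.55) -> RRSeries:
    """Replace interval pairs at ``positions`` with ectopic short+long couplets.

    The pair ``(rr[i], rr[i+1])`` becomes ``(s, rr[i] + rr[i+1] - s)``
    with ``s = short_frac * rr[i]``, preserving total time — the classic
    premature-beat signature the RR artifact filter must remove.
    """
    iv = rr.intervals.copy()
    for i in positions:
        if i + 1 >= iv.size:
            raise InvalidSpecError(f"ectopy position {i} out of range")
        total = iv[i] + iv[i + 1]
        s = short_frac * iv[i]
        iv[i] = s
        iv[i + 1] = total - s
    meta = dict(rr.meta)
    meta["ectopy_positions"] = list(positions)
    return RRSeries(iv, label=rr.label, meta=meta)


# ---------------------------------------------------------------------------
# Cohort design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupStateSpec:
    """Distributional targets for one group x state cell."""

    modulation: ModulationSpec
    sfs_mean: float
    sfs_sd: float
    acc_mean: float
    acc_sd: float

    def __post_init__(self) -> None:
        if self.sfs_sd < 0 or self.acc_sd < 0:
            raise InvalidSpecError("SDs must be non-negative")
        if not (0 <= self.acc_mean <= 100):
            raise InvalidSpecError("ACC mean must lie in [0, 100]")
        if not (0 <= self.sfs_mean <= 60):
            raise InvalidSpecError("SFS mean must lie in [0, 60]")


@dataclass(frozen=True)
class CohortDesign:
    """Three-group by three-state cohort specification."""

    cells: Mapping[Tuple[str, str], GroupStateSpec]
    n_subjects: int = 10
    master_seed: int = 0
    n_trials: int = 375  # 5 min of 800 ms inter-stimulus intervals
    no_response_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidSpecError("need at least 2 subjects")
        missing = [
            (g, s) for g in GROUPS for s in STATES if (g, s) not in self.cells
        ]
        if missing:
            raise InvalidSpecError(f"design missing cells: {missing}")


# ACC defaults are the published group means/SDs (pre-fatigue, post-fatigue,
# post-stimulation); SFS and modulation shifts emulate the reported effect
# directions (fatigue: slower mean HR, higher overall variability; tACS
# stimulation: LF/VLF/total power and SD2 up, normalized HF down).
_ACC_DEFAULTS = {
    ("blank", "pre-fatigue"): (90.21, 5.60),
    ("blank", "post-fatigue"): (84.68, 8.10),
    ("blank", "post-stimulation"): (86.76, 7.40),
    ("tDCS", "pre-fatigue"): (89.00, 5.80),
    ("tDCS", "post-fatigue"): (82.04, 8.50),
    ("tDCS", "post-stimulation"): (88.44, 7.00),
    ("tACS", "pre-fatigue"): (89.56, 8.20),
    ("tACS", "post-fatigue"): (83.28, 9.70),
    ("tACS", "post-stimulation"): (88.60, 7.10),
}

_SFS_DEFAULTS = {
    "pre-fatigue": (12.0, 4.0),
    "post-fatigue": (35.0, 6.0),
    ("blank", "post-stimulation"): (32.0, 6.0),
    ("tDCS", "post-stimulation"): (24.0, 6.0),
    ("tACS", "post-stimulation"): (20.0, 6.0),
}

_MOD_DEFAULTS = {
    "pre-fatigue": dict(mean_rr=850.0, amp_vlf=0.010, amp_lf=0.040, amp_hf=0.040),
    "post-fatigue": dict(mean_rr=900.0, amp_vlf=0.015, amp_lf=0.054, amp_hf=0.057),
    ("blank", "post-stimulation"): dict(
        mean_rr=895.0, amp_vlf=0.015, amp_lf=0.055, amp_hf=0.056
    ),
    ("tDCS", "post-stimulation"): dict(
        mean_rr=890.0, amp_vlf=0.017, amp_lf=0.060, amp_hf=0.056
    ),
    ("tACS", "post-stimulation"): dict(
        mean_rr=905.0, amp_vlf=0.022, amp_lf=0.075, amp_hf=0.050
    ),
}


def default_design(n_subjects: int = 10, master_seed: int = 0, duration: float = 300.0) -> CohortDesign:
    """The default three-group by three-state design.

    ACC cell means/SDs are the published group summaries; SFS and
    autonomic-modulation shifts reproduce the published effect
    *directions* (per-subject raw data are not deposited, so magnitudes
    are the package's own realistic choices).
    """
    cells = {}
    for g in GROUPS:
        for s in STATES:
            mod_kw = _MOD_DEFAULTS.get((g, s), _MOD_DEFAULTS.get(s))
            sfs = _SFS_DEFAULTS.get((g, s), _SFS_DEFAULTS.get(s))
            acc = _ACC_DEFAULTS[(g, s)]
            cells[(g, s)] = GroupStateSpec(
                modulation=ModulationSpec(duration=duration, **mod_kw),
                sfs_mean=sfs[0],
                sfs_sd=sfs[1],
                acc_mean=acc[0],
                acc_sd=acc[1],
            )
    return CohortDesign(cells=cells, n_subjects=n_subjects, master_seed=master_seed)


def _cell_rng(master_seed: int, group: str, subject: int, state: str) -> np.random.Generator:
    # deterministic per-cell seed; insertion-order independent
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=master_seed,
            spawn_key=(GROUPS.index(group), subject, STATES.index(state)),
        )
    )


def _draw_sfs_items(total_target: float, rng: np.random.Generator) -> List[int]:
    """15 items in 0..4 summing to the (clipped, rounded) target total."""
    total = int(np.clip(np.rint(total_target), 0, 60))
    items = [0] * 15
    for _ in range(total):
        open_items = [i for i, v in enumerate(items) if v < 4]
        items[open_items[int(rng.integers(len(open_items)))]] += 1
    return items


def _draw_trials(
    acc_mean: float, n_trials: int, no_response_rate: float, rng: np.random.Generator
) -> List[TrialRecord]:
    """Trials whose scored accuracy hits ``acc_mean`` in expectation.

    Non-responses count as incorrect in the accuracy denominator, so the
    per-response correctness probability is inflated by the response
    rate.  RT ~ Normal(450, 80) ms truncated to (0, 800].
    """
    p_resp = 1.0 - no_response_rate
    p_correct = min(1.0, (acc_mean / 100.0) / p_resp)
    trials: List[TrialRecord] = []
    for i in range(n_trials):
        stim = "letter" if i % 2 == 0 else "digit"
        responded = bool(rng.random() < p_resp)
        if responded:
            rt = float(rng.normal(450.0, 80.0))
            while not (0 < rt <= 800):
                rt = float(rng.normal(450.0, 80.0))
            correct = bool(rng.random() < p_correct)
            trials.append(TrialRecord(stim, correct, True, rt))
        else:
            trials.append(TrialRecord(stim, False, False, None))
    return trials


def generate_cohort(design: CohortDesign) -> List[SessionRecord]:
    """Generate one full cohort of session records.

    Pure function of the design (including ``master_seed``): per-cell
    RNG seeds derive deterministically from (master seed, group index,
    subject index, state index).
    """
    sessions: List[SessionRecord] = []
    for g in GROUPS:
        for subj in range(design.n_subjects):
            for s in STATES:
                rng = _cell_rng(design.master_seed, g, subj, s)
                cell = design.cells[(g, s)]
                mod = replace(cell.modulation, seed=int(rng.integers(2**31)))
                rr = generate_rr_ipfm(mod)
                sfs_target = rng.normal(cell.sfs_mean, cell.sfs_sd)
                items = _draw_sfs_items(sfs_target, rng)
                trials = _draw_trials(
                    float(np.clip(rng.normal(cell.acc_mean, cell.acc_sd), 0, 100)),
                    design.n_trials,
                    design.no_response_rate,
                    rng,
                )
                sessions.append(
                    SessionRecord(
                        subject=f"S{subj + 1:02d}",
                        group=g,
                        state=s,
                        sfs_items=items,
                        trials=trials,
                        rr=rr,
                    )
                )
    return sessions


# ---------------------------------------------------------------------------
# Feature-level cohorts (calibration / power studies of the stats stage)
# ---------------------------------------------------------------------------

#: plausible resting-state baselines (mean, SD) per HRV feature
FEATURE_BASELINES: Dict[str, Tuple[float, float]] = {
    "meanHR": (70.0, 8.0),
    "meanRR": (860.0, 90.0),
    "SDNN": (45.0, 15.0),
    "RMSSD": (38.0, 14.0),
    "TINN": (180.0, 60.0),
    "PNN50": (18.0, 10.0),
    "SDSD": (38.0, 14.0),
    "HF": (600.0, 300.0),
    "LF": (900.0, 400.0),
    "LFn": (60.0, 12.0),
    "LFn_HFn": (1.8, 0.8),
    "TP": (2200.0, 800.0),
    "VLF": (700.0, 350.0),
    "SD1": (27.0, 10.0),
    "SD2": (60.0, 18.0),
    "SD1_SD2": (0.45, 0.12),
    "S": (5200.0, 2200.0),
    "VLI": (60.0, 18.0),
    "PI": (50.0, 6.0),
    "CCM_1": (0.55, 0.15),
}

#: direction of the significant post-stimulation changes in the tACS arm
TACS_EFFECT_SIGNS: Dict[str, int] = {
    "SDNN": +1,
    "LF": +1,
    "LFn": +1,
    "LFn_HFn": +1,
    "TP": +1,
    "VLF": +1,
    "SD2": +1,
    "VLI": +1,
    "HFn": -1,
    "SD1_SD2": -1,
    "CCM_1": -1,
}


def generate_feature_cohort(
    n_subjects: int = 10,
    effects: Optional[Mapping[Tuple[str, str], Mapping[str, float]]] = None,
    seed: int = 0,
    groups: Sequence[str] = GROUPS,
    states: Sequence[str] = STATES,
):
    """Draw an HRV feature table directly (no signal synthesis).

    Each feature is Normal(baseline mean, baseline SD) per subject, with
    per-cell shifts expressed in baseline-SD units via ``effects``
    (mapping ``(group, state) -> {feature: shift_in_sds}``).  ``HFn`` is
    derived as ``100 - LFn`` so the normalization constraint of the
    spectral features holds by construction; other features are drawn
    independently.  With ``effects=None`` the cohort is an exact null.

    Returns a long-form :class:`pandas.DataFrame` with columns
    ``subject, group, state`` plus the 21 feature columns.
    """
    import pandas as pd

    from .hrv import FEATURE_NAMES

    rng = np.random.default_rng(seed)
    effects = effects or {}
    draw_names = [f for f in FEATURE_NAMES if f != "HFn"]
    rows = []
    for g in groups:
        for subj in range(n_subjects):
            for s in states:
                shifts = effects.get((g, s), {})
                row = {"subject": f"S{subj + 1:02d}", "group": g, "state": s}
                for f in draw_names:
                    mu, sd = FEATURE_BASELINES[f]
                    row[f] = rng.normal(mu + shifts.get(f, 0.0) * sd, sd)
                # normalized powers are complementary by definition;
                # an LFn shift therefore implies the opposite HFn shift
                row["HFn"] = 100.0 - row["LFn"]
                rows.append(row)
    df = pd.DataFrame(rows)
    return df[["subject", "group", "state"] + list(FEATURE_NAMES)]


def tacs_effect_design(shift_sds: float = 1.0) -> Dict[Tuple[str, str], Dict[str, float]]:
    """Per-cell feature shifts emulating the tACS intervention pattern."""
    if shift_sds < 0:
        raise InvalidSpecError("shift must be non-negative")
    return {
        ("tACS", "post-stimulation"): {
            f: sign * shift_sds for f, sign in TACS_EFFECT_SIGNS.items() if f != "HFn"
        }
    }
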