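"""Synthetic gait-study generator with known ground truth.

Every signal modality of a treadmill gait study is emulated with its
generating parameters exposed: a double-bumped vertical ground reaction
force with one dominant peak per step, mediolateral/anterior-posterior
center-of-pressure traces, quasi-periodic trunk accelerations, phase-locked
band-limited EMG bursts, and per-breath metabolic variables.  Stride
intervals are drawn as ``mean + SD * fGn(H)`` where the fractional Gaussian
noise comes from an exact-spectrum circulant-embedding sampler, so the
stride series has a known Hurst exponent and serves as an oracle for the
correlation analyses.

Group and condition effects are planted by shifting generator parameters,
so the downstream measure and ranking layers can be tested for recovery of
known effects.  A fast measure-level generator
(:func:`generate_measure_table`) draws a wide measure table directly from a
subject-random-effects model for tests that only exercise the statistical
layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import MetabolicRecord, Recording, StudyDesign, TimeSeries
from .events import EventSeries

__all__ = [
    "SyntheticSpec",
    "PlantedEffect",
    "GroundTruth",
    "fractional_gaussian_noise",
    "generate_gait_recording",
    "generate_study",
    "generate_measure_table",
    "study_a_spec",
    "study_b_spec",
]


# ---------------------------------------------------------------------------
# fractional Gaussian noise (exact-spectrum circulant embedding)
# ---------------------------------------------------------------------------

def _fgn_autocovariance(k: np.ndarray, H: float) -> np.ndarray:
    k = np.abs(k).astype(float)
    return 0.5 * (np.abs(k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))


def fractional_gaussian_noise(n: int, H: float,
                              seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Unit-variance fractional Gaussian noise of length ``n``.

    Uses circulant embedding (Davies-Harte), which reproduces the process's
    second-order structure exactly; the lag-k autocovariance is
    ``(|k+1|^2H - 2|k|^2H + |k-1|^2H) / 2``.
    """
    if not 0 < H < 1:
        raise ValueError(f"Hurst exponent must be in (0, 1), got {H}")
    if n < 1:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if H == 0.5:
        return rng.standard_normal(n)
    m = 1 << max(1, int(np.ceil(np.log2(n))))  # power-of-two padding
    # first row of the circulant matrix embedding the Toeplitz autocovariance
    gamma = _fgn_autocovariance(np.arange(m + 1), H)
    row = np.concatenate([gamma[: m + 1], gamma[m - 1: 0: -1]])
    eigs = np.fft.fft(row).real
    eigs = np.clip(eigs, 0.0, None)  # tiny negatives from roundoff
    size = row.size
    w = rng.standard_normal(size) + 1j * rng.standard_normal(size)
    sample = np.fft.fft(np.sqrt(eigs / (2 * size)) * w)
    return sample.real[:n] * math.sqrt(2.0)


# ---------------------------------------------------------------------------
# study specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEffect:
    """Shift a generator parameter for one factor level.

    ``size`` is in units of the parameter's between-subject SD, applied on
    top of the baseline for observations at ``level`` of ``factor``
    ('group' or 'condition').
    """

    parameter: str  # e.g. 'stride_period', 'step_width', 'metabolic.cmet'
    factor: str     # 'group' | 'condition'
    level: str
    size: float


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic gait study."""

    groups: tuple[str, ...] = ("patients",)
    subjects_per_group: int = 14
    conditions: tuple[str, ...] = ("no_support", "support_pref", "support_enforced")
    duration_s: float = 300.0
    rate: float = 100.0
    emg_rate: float = 1000.0
    belt_speed: float = 1.0  # m/s
    body_mass_mean: float = 75.0  # kg
    body_mass_sd: float = 10.0
    stride_period: float = 1.1  # s
    stride_period_subject_sd: float = 0.05  # between-subject SD of the mean
    stride_period_cv: float = 0.03  # within-trial stride-to-stride CV
    hurst: float = 0.75  # long-range correlation of stride intervals
    step_width: float = 0.10  # m
    step_width_subject_sd: float = 0.015
    cop_y_excursion: float = 0.35  # m per step
    grf_body_weight: float = 735.0  # N
    grf_noise_sd: float = 5.0  # N
    cop_noise_sd: float = 0.003  # m
    acc_amplitude: float = 1.5  # m/s^2
    acc_noise_sd: float = 0.3
    #: per-muscle EMG burst (onset fraction of the step cycle, width fraction)
    emg_bursts: dict = field(default_factory=lambda: {
        "ta": (0.00, 0.12), "g": (0.45, 0.15), "vm": (0.05, 0.12),
        "s": (0.85, 0.12), "tfl": (0.10, 0.15)})
    emg_amplitude_mv: float = 0.3
    emg_carrier_band: tuple[float, float] = (150.0, 400.0)
    breaths_per_min: float = 18.0
    #: per-breath metabolic means and within-trial SDs
    metabolic_means: dict = field(default_factory=lambda: {
        "ve": 30.0, "vo2": 1100.0, "vco2": 950.0, "rer": 0.87,
        "bf": 18.0, "hr": 95.0})
    metabolic_cv: float = 0.06
    metabolic_subject_cv: float = 0.10  # between-subject CV of the means
    include_emg: bool = False
    planted_effects: tuple[PlantedEffect, ...] = ()
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.stride_period <= 0:
            raise ValueError("stride period must be positive")
        if not 0 < self.hurst < 1:
            raise ValueError("Hurst exponent must be in (0, 1)")
        if self.subjects_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.emg_rate <= 2 * self.emg_carrier_band[1]:
            raise ValueError("emg_rate inconsistent with the carrier band (Nyquist)")


def study_a_spec(**overrides) -> SyntheticSpec:
    """One patient group, three support/speed conditions (five-minute trials)."""
    return replace(SyntheticSpec(), **overrides)


def study_b_spec(**overrides) -> SyntheticSpec:
    """Three groups (two amputation levels + controls), two task conditions."""
    base = SyntheticSpec(
        groups=("transtibial", "transfemoral", "control"),
        subjects_per_group=19,
        conditions=("walk", "dual_task"),
        duration_s=240.0,
        include_emg=True,
    )
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# per-recording signal synthesis
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """What the generator knows: events, stride series, target measures."""

    event_indices: np.ndarray
    stride_intervals: np.ndarray  # seconds, per stride
    step_width: float
    stride_period: float
    hurst: float
    targets: dict[str, float] = field(default_factory=dict)


def _smoothed_square(phase: np.ndarray, transition: float = 0.4) -> np.ndarray:
    """+-1 square wave over phase in [0, 2), with cosine transitions.

    Plateaus at +1 on [t/2, 1 - t/2] and -1 on [1 + t/2, 2 - t/2], so the
    value at integer phase (the step events) is mid-transition; shifting by
    half a step puts events on the plateaus.
    """
    p = np.mod(phase, 2.0)
    out = np.empty_like(p)
    half_t = transition / 2
    for lo, hi, sign in ((half_t, 1 - half_t, 1.0), (1 + half_t, 2 - half_t, -1.0)):
        out[(p >= lo) & (p <= hi)] = sign
    trans = (p > 1 - half_t) & (p < 1 + half_t)
    out[trans] = np.cos(np.pi * (p[trans] - (1 - half_t)) / transition)
    trans = (p > 2 - half_t) | (p < half_t)
    q = np.mod(p[trans] - (2 - half_t), 2.0)
    out[trans] = -np.cos(np.pi * q / transition)
    return out


def _bandpass_noise(n: int, rate: float, band: tuple[float, float],
                    rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited via the FFT."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _effective_params(spec: SyntheticSpec, group: str, condition: str,
                      rng: np.random.Generator) -> dict:
    """Baseline parameters plus subject random effects plus planted shifts."""
    params = {
        "stride_period": spec.stride_period + rng.normal(0, spec.stride_period_subject_sd),
        "step_width": spec.step_width + rng.normal(0, spec.step_width_subject_sd),
        "body_mass": max(45.0, spec.body_mass_mean + rng.normal(0, spec.body_mass_sd)),
    }
    for var, mean in spec.metabolic_means.items():
        params[f"metabolic.{var}"] = mean * (1 + rng.normal(0, spec.metabolic_subject_cv))
    sds = {
        "stride_period": spec.stride_period_subject_sd,
        "step_width": spec.step_width_subject_sd,
        "body_mass": spec.body_mass_sd,
    }
    for eff in spec.planted_effects:
        hit = (eff.factor == "group" and eff.level == group) or \
              (eff.factor == "condition" and eff.level == condition)
        if not hit:
            continue
        if eff.parameter.startswith("metabolic."):
            var = eff.parameter.split(".", 1)[1]
            base = spec.metabolic_means[var]
            params[eff.parameter] += eff.size * base * spec.metabolic_subject_cv
        elif eff.parameter in params:
            params[eff.parameter] += eff.size * sds[eff.parameter]
        else:
            raise ValueError(f"planted effect on unknown parameter {eff.parameter!r}")
    return params


def generate_gait_recording(spec: SyntheticSpec, subject: str = "s01",
                            condition: str | None = None,
                            seed: int | np.random.Generator | None = None,
                            group: str | None = None,
                            params: dict | None = None,
                            include_emg: bool | None = None,
                            ) -> tuple[Recording, GroundTruth]:
    """Synthesize one observation's multichannel recording plus ground truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    condition = condition or spec.conditions[0]
    group = group or spec.groups[0]
    if params is None:
        params = _effective_params(spec, group, condition, rng)
    if include_emg is None:
        include_emg = spec.include_emg and bool(spec.emg_bursts)

    rate = spec.rate
    n = int(round(spec.duration_s * rate))
    t = np.arange(n) / rate

    # --- stride intervals with long-range correlation -----------------------
    stride_mean = params["stride_period"]
    stride_sd = spec.stride_period_cv * stride_mean
    n_strides = int(np.ceil(spec.duration_s / stride_mean)) + 4
    strides = stride_mean + stride_sd * fractional_gaussian_noise(n_strides, spec.hurst, rng)
    strides = np.clip(strides, 0.5 * stride_mean, 1.5 * stride_mean)

    # step events: two steps per stride, small left/right asymmetry jitter;
    # gait is continuous across the whole record (virtual events beyond both
    # borders), so signals have no flat lead-in that would bias the matcher
    step_durs = np.empty(2 * n_strides)
    split = 0.5 + rng.normal(0, 0.01, n_strides)
    step_durs[0::2] = strides * split
    step_durs[1::2] = strides * (1 - split)
    all_times = -1.5 * stride_mean + np.cumsum(np.concatenate([[0.0], step_durs]))
    in_range = (all_times >= 0.1) & (all_times < spec.duration_s - 0.05)
    event_times = all_times[in_range]
    event_idx = np.round(event_times * rate).astype(int)

    # continuous step phase: advances by 1 per step, linear between events
    phase = np.interp(t, all_times, np.arange(all_times.size))

    # --- vertical GRF: asymmetric double bump, one dominant peak per step ---
    p_in = np.mod(phase, 1.0)
    bump1 = np.exp(-0.5 * ((p_in - 0.22) / 0.10) ** 2)
    bump2 = 0.5 * np.exp(-0.5 * ((p_in - 0.55) / 0.12) ** 2)
    fz = spec.grf_body_weight * (0.75 + 0.45 * (bump1 + bump2))
    fz += rng.normal(0, spec.grf_noise_sd, n)

    # --- center of pressure -------------------------------------------------
    # ML: alternates between foot positions; shifted half a step so the
    # plateau (the stance foot) is reached at each event instant
    copx = 0.5 * params["step_width"] * _smoothed_square(phase + 0.5)
    copx += rng.normal(0, spec.cop_noise_sd, n)
    # AP: per-step sawtooth (heel-to-toe progression), identical every step
    copy_ = spec.cop_y_excursion * (p_in - 0.5)
    copy_ += rng.normal(0, spec.cop_noise_sd, n)

    # --- trunk accelerations: harmonics of the step/stride rhythm ----------
    two_pi = 2 * np.pi
    acc = {}
    acc["accx"] = spec.acc_amplitude * (0.6 * np.sin(np.pi * phase)
                                        + 0.2 * np.sin(two_pi * phase + 0.7))
    acc["accy"] = spec.acc_amplitude * (0.8 * np.sin(two_pi * phase + 1.1)
                                        + 0.3 * np.sin(2 * two_pi * phase))
    acc["accz"] = spec.acc_amplitude * (1.0 * np.sin(two_pi * phase + 2.0)
                                        + 0.4 * np.sin(2 * two_pi * phase + 0.5))
    for key in acc:
        acc[key] = acc[key] + rng.normal(0, spec.acc_noise_sd, n)

    signals = {
        "fz": TimeSeries(fz, rate, label="fz", units="N"),
        "copx": TimeSeries(copx, rate, label="copx", units="m"),
        "copy": TimeSeries(copy_, rate, label="copy", units="m"),
        "accx": TimeSeries(acc["accx"], rate, label="accx", units="m/s^2"),
        "accy": TimeSeries(acc["accy"], rate, label="accy", units="m/s^2"),
        "accz": TimeSeries(acc["accz"], rate, label="accz", units="m/s^2"),
    }

    # --- EMG: band-limited noise bursts phase-locked to the stride ---------
    if include_emg:
        n_e = int(round(spec.duration_s * spec.emg_rate))
        t_e = np.arange(n_e) / spec.emg_rate
        phase_e = np.interp(t_e, event_times, np.arange(event_times.size))
        p_stride = np.mod(phase_e, 2.0) / 2.0  # fraction of the stride cycle
        for muscle, (onset, width) in spec.emg_bursts.items():
            d = np.abs(p_stride - onset)
            d = np.minimum(d, 1 - d)  # circular distance in cycle fractions
            modulator = np.exp(-0.5 * (d / (width / 2.355)) ** 2)  # FWHM = width
            carrier = _bandpass_noise(n_e, spec.emg_rate, spec.emg_carrier_band, rng)
            emg = spec.emg_amplitude_mv * (0.05 + modulator) * carrier
            signals[f"emg_{muscle}"] = TimeSeries(emg, spec.emg_rate,
                                                  label=f"emg_{muscle}", units="mV")

    # --- metabolic breath-by-breath series ----------------------------------
    n_breaths = max(5, int(round(spec.duration_s / 60.0 * spec.breaths_per_min)))
    variables = {}
    for var in spec.metabolic_means:
        mean = params[f"metabolic.{var}"]
        vals = mean * (1 + spec.metabolic_cv * rng.standard_normal(n_breaths))
        variables[var] = np.clip(vals, 0.0, None)
    metabolic = MetabolicRecord(variables=variables,
                                body_mass=params["body_mass"],
                                walking_speed=spec.belt_speed)

    rec = Recording(signals=signals, metabolic=metabolic,
                    meta={"rate": rate, "subject": subject, "condition": condition,
                          "group": group, "belt_speed": spec.belt_speed})
    # ipsilateral stride intervals aligned to stride boundaries (even global
    # parity), so the truth series is exactly the drawn fGn stride sequence
    ev_global = np.flatnonzero(in_range)
    even_globals = ev_global[ev_global % 2 == 0]
    kept = strides[even_globals[:-1] // 2]
    truth = GroundTruth(
        event_indices=event_idx,
        stride_intervals=kept,
        step_width=params["step_width"],
        stride_period=stride_mean,
        hurst=spec.hurst,
        targets={
            "stride_duration_mean": float(kept.mean()),
            "stride_duration_cv": float(kept.std(ddof=1) / kept.mean()),
            "step_width": params["step_width"],
            "stride_length_mean": float(spec.belt_speed * kept.mean()),
        },
    )
    return rec, truth


def true_events(truth: GroundTruth, rate: float) -> EventSeries:
    return EventSeries(truth.event_indices, rate)


# ---------------------------------------------------------------------------
# whole-study generation
# ---------------------------------------------------------------------------

def generate_study(spec: SyntheticSpec, seed: int | None = None
                   ) -> tuple[dict[tuple[str, str], Recording], StudyDesign, pd.DataFrame]:
    """Generate recordings for every subject x condition observation.

    Returns the recordings keyed by (subject, condition), the study design,
    and a ground-truth table (one row per observation) for recovery tests.
    Identical spec and seed give identical output.
    """
    master = spec.master_seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    recordings: dict[tuple[str, str], Recording] = {}
    observations: list[tuple[str, str, str]] = []
    truth_rows = []
    subj_counter = 0
    for gi, group in enumerate(spec.groups):
        for si in range(spec.subjects_per_group):
            subj_counter += 1
            subject = f"s{subj_counter:02d}"
            subj_rng = np.random.default_rng(ss.spawn(1)[0])
            for condition in spec.conditions:
                params = _effective_params(spec, group, condition, subj_rng)
                rec, truth = generate_gait_recording(
                    spec, subject=subject, condition=condition,
                    seed=subj_rng, group=group, params=params)
                recordings[(subject, condition)] = rec
                observations.append((subject, group, condition))
                truth_rows.append({"subject": subject, "group": group,
                                   "condition": condition, **truth.targets})
    design = StudyDesign(observations)
    return recordings, design, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# fast measure-level generator for the statistical layer
# ---------------------------------------------------------------------------

def generate_measure_table(n_measures: int = 61,
                           groups: dict[str, int] | None = None,
                           conditions: tuple[str, ...] = ("c1", "c2", "c3"),
                           effects: tuple[tuple[str, str, str, float], ...] = (),
                           subject_sd: float = 1.0,
                           noise_sd: float = 1.0,
                           baseline: float = 10.0,
                           seed: int | None = None
                           ) -> tuple[pd.DataFrame, StudyDesign]:
    """Draw a wide measure table from a subject-random-effects model.

    Each measure column m for subject s in condition c is
    ``baseline + b_sm + e`` with ``b_sm ~ N(0, subject_sd^2)`` a
    subject-by-measure random intercept and ``e ~ N(0, noise_sd^2)`` the
    within-subject error, plus any planted shift.  The baseline keeps the
    measures positive-valued (as physiological measures are), so paired
    relative differences stay well-behaved.

    ``effects`` entries are ``(measure_name, factor, level, size)`` with
    ``size`` in within-subject SD units.  ``factor`` is 'group',
    'condition', or 'group_condition' (level ``"group:condition"``) — the
    last plants a group-dependent condition response, which is the kind of
    group signal a two-condition relative-difference analysis can see.
    Measures are named ``m001 ... mNNN`` unless an effect names one
    explicitly, in which case that name replaces the corresponding generic
    column.

    This bypasses signal synthesis entirely and is the intended input for
    testing the screening/regression layer at scale.
    """
    rng = np.random.default_rng(seed)
    groups = groups or {"g1": 14}
    names = [f"m{i + 1:03d}" for i in range(n_measures)]
    for k, eff in enumerate(effects):
        if eff[0] not in names:
            names[k] = eff[0]

    observations = []
    subj_counter = 0
    rows = {}
    for group, n_subj in groups.items():
        for _ in range(n_subj):
            subj_counter += 1
            subject = f"s{subj_counter:02d}"
            intercepts = rng.normal(0, subject_sd, n_measures)
            for condition in conditions:
                observations.append((subject, group, condition))
                vals = baseline + intercepts + rng.normal(0, noise_sd, n_measures)
                for name, factor, level, size in effects:
                    hit = (factor == "group" and level == group) or \
                          (factor == "condition" and level == condition) or \
                          (factor == "group_condition"
                           and level == f"{group}:{condition}")
                    if hit:
                        vals[names.index(name)] += size * noise_sd
                rows[(subject, condition)] = vals
    table = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    table.index = pd.MultiIndex.from_tuples(table.index, names=["subject", "condition"])
    return table, StudyDesign(observations)
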