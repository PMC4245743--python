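"""The shotgun measure catalog.

Every candidate gait measure is computed per observation (subject x
condition) and assembled into one wide table: spatiotemporal statistics
from template-matched step events, regularity (sample entropy of analytic
amplitude and phase), long-range correlation (detrended fluctuation
analysis), local dynamic stability (Rosenstein's largest Lyapunov
exponent), principal-component spectra, EMG median frequency, and
breath-by-breath metabolic summaries.

Measure names follow the dotted ``modality.measure.channel`` convention
(for example ``force_plate.sampen_phase.copy``); channel-less measures use
``modality.measure``.  This naming is stable across runs and is part of the
public contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core_io import MetabolicRecord, Recording, StudyDesign, TimeSeries, get_logger
from .events import EventSeries, assign_legs, initial_events, refine_events, slice_epochs
from .preprocess import emg_envelope, hilbert_decompose, phase_for_entropy

log = get_logger("gaitshotgun.measures")

__all__ = [
    "SampEnResult",
    "DfaResult",
    "LyapResult",
    "PcaResult",
    "MetabolicSummary",
    "CatalogConfig",
    "STUDY_A_CONFIG",
    "STUDY_B_CONFIG",
    "FORCE_PLATE_ONLY_CONFIG",
    "coefficient_of_variation",
    "sample_entropy",
    "sample_entropy_fixed_r",
    "dfa_alpha",
    "lyapunov_rosenstein",
    "pca_decompose",
    "median_frequency",
    "metabolic_summary",
    "template_consistency",
    "spatiotemporal_measures",
    "assemble_catalog",
    "catalog_columns",
]

#: default tolerance grid for sample entropy, in units of the series SD
SAMPEN_R_GRID = tuple(round(0.01 * k, 2) for k in range(1, 8))
SAMPEN_M = 3

LYAP_M = 7
LYAP_TAU = 20


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def coefficient_of_variation(values) -> float:
    """Sample SD (n-1 denominator) divided by the absolute mean.

    Returns NaN (with a warning) when the mean is zero.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("coefficient of variation needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        log.warning("coefficient of variation undefined for zero mean")
        return math.nan
    return float(arr.std(ddof=1) / abs(mean))


# ---------------------------------------------------------------------------
# sample entropy (with tolerance selection by estimated relative error)
# ---------------------------------------------------------------------------

@dataclass
class SampEnResult:
    """Sample entropy with its error estimate and the tolerance used."""

    m: int
    r_grid: tuple[float, ...]
    sampen: float
    se: float
    r_selected: float
    #: per-grid-point (sampen, se); NaN where no matches were found
    grid_values: dict[float, tuple[float, float]] = field(default_factory=dict)


def _match_counts_numpy(x: np.ndarray, m: int, r_values: np.ndarray,
                        chunk: int = 256) -> tuple[np.ndarray, np.ndarray]:
    n = x.size
    n_templ = n - m  # both m- and (m+1)-templates are taken from i = 0..n-m-1
    if n_templ < 2:
        raise ValueError("series too short for the requested embedding length")
    b_counts = np.zeros(r_values.size, dtype=np.int64)
    a_counts = np.zeros(r_values.size, dtype=np.int64)
    cols = [x[k:k + n_templ] for k in range(m + 1)]
    for start in range(0, n_templ, chunk):
        stop = min(start + chunk, n_templ)
        d_m = np.zeros((stop - start, n_templ))
        for k in range(m):
            np.maximum(d_m, np.abs(cols[k][start:stop, None] - cols[k][None, :]), out=d_m)
        d_m1 = np.maximum(d_m, np.abs(cols[m][start:stop, None] - cols[m][None, :]))
        # mask to strict upper triangle (i < j)
        upper = np.arange(n_templ)[None, :] > np.arange(start, stop)[:, None]
        for ri, r in enumerate(r_values):
            b_counts[ri] += int(np.count_nonzero((d_m <= r) & upper))
            a_counts[ri] += int(np.count_nonzero((d_m1 <= r) & upper))
    return a_counts, b_counts


try:  # pairwise counting is the hot loop; JIT it when numba is present
    import numba

    @numba.njit(cache=False, fastmath=False)
    def _match_counts_jit(x, m, r_sorted):  # pragma: no cover - exercised via wrapper
        n_templ = x.size - m
        nr = r_sorted.size
        r_max = r_sorted[nr - 1]
        a_counts = np.zeros(nr, dtype=np.int64)
        b_counts = np.zeros(nr, dtype=np.int64)
        for i in range(n_templ - 1):
            for j in range(i + 1, n_templ):
                d = 0.0
                for k in range(m):
                    diff = abs(x[i + k] - x[j + k])
                    if diff > d:
                        d = diff
                        if d > r_max:
                            break
                if d > r_max:
                    continue
                for ri in range(nr):
                    if d <= r_sorted[ri]:
                        b_counts[ri] += 1
                d1 = abs(x[i + m] - x[j + m])
                if d1 < d:
                    d1 = d
                if d1 <= r_max:
                    for ri in range(nr):
                        if d1 <= r_sorted[ri]:
                            a_counts[ri] += 1
        return a_counts, b_counts

    def _match_counts(x, m, r_values):
        n_templ = x.size - m
        if n_templ < 2:
            raise ValueError("series too short for the requested embedding length")
        r_values = np.asarray(r_values, dtype=float)
        order = np.argsort(r_values)
        a_s, b_s = _match_counts_jit(np.ascontiguousarray(x, dtype=np.float64),
                                     m, r_values[order])
        a = np.empty_like(a_s)
        b = np.empty_like(b_s)
        a[order] = a_s
        b[order] = b_s
        return a, b
except ImportError:  # pragma: no cover
    _match_counts = _match_counts_numpy


def sample_entropy_fixed_r(series, m: int, r: float) -> float:
    """SampEn = -ln(A/B) at one tolerance ``r`` (in SD units of the series)."""
    x = np.asarray(series, dtype=float)
    sd = x.std()
    if sd == 0:
        return 0.0
    a, b = _match_counts(x / sd, m, np.asarray([r]))
    if b[0] == 0 or a[0] == 0:
        return math.nan
    return float(-math.log(a[0] / b[0]))


def sample_entropy(series, m: int = SAMPEN_M,
                   r_grid=SAMPEN_R_GRID) -> SampEnResult:
    """Sample entropy with tolerance chosen by minimum estimated relative error.

    The series is standardized to unit SD, so tolerances are in SD units.
    For every tolerance on the grid the conditional probability
    ``CP = A/B`` (matches of length m+1 over matches of length m, Chebyshev
    distance, self-matches excluded) yields ``SampEn = -ln CP``.  The
    standard error of CP is estimated binomially from the match count,
    ``sigma_CP = sqrt(CP(1-CP)/B)``, and the reported value uses the grid
    tolerance minimizing the larger of the relative errors of CP and of
    SampEn — the efficiency criterion of tolerance selection for short
    physiological series.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 200:
        log.warning("sample entropy on only %d samples; estimate may be unstable", x.size)
    sd = x.std()
    r_grid = tuple(float(r) for r in r_grid)
    if sd == 0:
        # a constant series matches itself at any positive tolerance
        return SampEnResult(m=m, r_grid=r_grid, sampen=0.0, se=0.0,
                            r_selected=r_grid[0],
                            grid_values={r: (0.0, 0.0) for r in r_grid})
    a_counts, b_counts = _match_counts(x / sd, m, np.asarray(r_grid))

    grid_values: dict[float, tuple[float, float]] = {}
    best = None  # (criterion, r, sampen, se)
    for r, a, b in zip(r_grid, a_counts, b_counts):
        if b == 0 or a == 0:
            grid_values[r] = (math.nan, math.nan)
            continue
        cp = a / b
        sampen = -math.log(cp)
        sigma_cp = math.sqrt(cp * (1.0 - cp) / b)
        se = sigma_cp / cp  # delta method for -ln CP
        grid_values[r] = (sampen, se)
        if sampen > 0:
            criterion = max(sigma_cp / cp, sigma_cp / (cp * sampen))
        else:
            criterion = math.inf
        if best is None or criterion < best[0]:
            best = (criterion, r, sampen, se)
    if best is None:
        log.warning("sample entropy: no template matches at any tolerance")
        return SampEnResult(m=m, r_grid=r_grid, sampen=math.nan, se=math.nan,
                            r_selected=math.nan, grid_values=grid_values)
    _, r_sel, sampen, se = best
    return SampEnResult(m=m, r_grid=r_grid, sampen=sampen, se=se,
                        r_selected=r_sel, grid_values=grid_values)


# ---------------------------------------------------------------------------
# detrended fluctuation analysis
# ---------------------------------------------------------------------------

@dataclass
class DfaResult:
    """DFA scaling exponent with the underlying fluctuation function."""

    alpha: float
    box_sizes: np.ndarray
    fluctuations: np.ndarray
    fit_range: tuple[int, int]


def dfa_alpha(series, n_boxes: int = 20) -> DfaResult:
    """Scaling exponent of the detrended fluctuation function.

    The mean-centered series is integrated into a profile; for log-spaced
    box sizes n in [4, N/4] each non-overlapping box is detrended with a
    first-order polynomial and the RMS residual F(n) is computed.  ``alpha``
    is the least-squares slope of log F(n) versus log n over all box sizes
    (no crossover splitting): 0.5 for white noise, >0.5 for persistent and
    <0.5 for anti-persistent correlations; alpha equals the Hurst exponent
    for fractional Gaussian noise.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 64:
        raise ValueError("DFA needs at least 64 samples")
    profile = np.cumsum(x - x.mean())
    sizes = np.unique(np.floor(np.logspace(math.log10(4), math.log10(n // 4),
                                           n_boxes)).astype(int))
    sizes = sizes[sizes >= 4]
    if sizes.size < 6:
        raise ValueError("fewer than 6 usable box sizes")
    flucts = np.empty(sizes.size)
    t_cache: dict[int, np.ndarray] = {}
    for i, s in enumerate(sizes):
        k = n // s
        seg = profile[: k * s].reshape(k, s)
        t = t_cache.setdefault(s, np.arange(s, dtype=float))
        # first-order detrend per box, vectorized via least squares
        coeffs = np.polynomial.polynomial.polyfit(t, seg.T, 1)
        resid = seg - (coeffs[0][:, None] + coeffs[1][:, None] * t[None, :])
        flucts[i] = math.sqrt(np.mean(resid ** 2))
    if np.any(flucts <= 0):
        raise ValueError("zero fluctuation (degenerate series)")
    slope, _ = np.polyfit(np.log(sizes), np.log(flucts), 1)
    return DfaResult(alpha=float(slope), box_sizes=sizes, fluctuations=flucts,
                     fit_range=(int(sizes[0]), int(sizes[-1])))


# ---------------------------------------------------------------------------
# largest Lyapunov exponent (Rosenstein's method)
# ---------------------------------------------------------------------------

@dataclass
class LyapResult:
    """Largest Lyapunov exponent from mean nearest-neighbor divergence."""

    lambda_max: float
    M: int
    tau: int
    divergence: np.ndarray  # mean log divergence per step, in sample steps
    fit_window: tuple[int, int]


def _mean_period_samples(x: np.ndarray, rate: float) -> float:
    """Reciprocal of the spectral mean frequency, in samples."""
    freqs, pxx = sps.periodogram(x - x.mean(), fs=rate)
    p = pxx[1:]
    f = freqs[1:]
    total = p.sum()
    if total == 0:
        raise ValueError("zero-power signal")
    mean_freq = float((f * p).sum() / total)
    return rate / mean_freq


def lyapunov_rosenstein(series: TimeSeries, M: int = LYAP_M, tau: int = LYAP_TAU,
                        theiler: int | None = None,
                        fit_window: tuple[int, int] | None = None,
                        max_steps: int | None = None) -> LyapResult:
    """Largest Lyapunov exponent via nearest-neighbor divergence tracking.

    The signal is delay-embedded (dimension ``M``, delay ``tau`` samples);
    each embedded point is paired with its nearest neighbor outside a
    temporal exclusion window (default: one mean period, from the spectral
    mean frequency), and the log of the mean pairwise distance is tracked
    forward in time.  ``lambda_max`` is the least-squares slope of the
    initial linear region (default: 0 to half a mean period) divided by the
    sample interval, in 1/s.
    """
    x = np.asarray(series.values, dtype=float)
    n = x.size
    min_len = (M - 1) * tau + 100
    if n <= min_len:
        raise ValueError(f"series too short for embedding: need > {min_len} samples")
    n_pts = n - (M - 1) * tau
    emb = np.empty((n_pts, M))
    for k in range(M):
        emb[:, k] = x[k * tau: k * tau + n_pts]

    period = _mean_period_samples(x, series.rate)
    if theiler is None:
        theiler = max(1, int(round(period)))
    if fit_window is None:
        fit_window = (0, max(2, int(round(0.5 * period))))
    if max_steps is None:
        max_steps = max(fit_window[1] + 1, int(round(2 * period)))
    max_steps = min(max_steps, n_pts - 2)

    # nearest neighbor outside the Theiler window, chunked matmul distances
    nn = np.empty(n_pts, dtype=int)
    idx = np.arange(n_pts)
    sq = (emb ** 2).sum(axis=1)
    chunk = max(1, int(4e6 // max(1, n_pts)))
    for start in range(0, n_pts, chunk):
        stop = min(start + chunk, n_pts)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (emb[start:stop] @ emb.T)
        excl = np.abs(idx[None, :] - idx[start:stop, None]) <= theiler
        d2[excl] = np.inf
        nn[start:stop] = np.argmin(d2, axis=1)

    # mean log divergence per forward step; distances are floored at a
    # relative epsilon so exactly recurrent (noise-free periodic) neighbors
    # yield a flat curve instead of amplified roundoff
    floor = 1e-12 * math.sqrt(float(sq.mean()))
    div = np.full(max_steps + 1, np.nan)
    for k in range(max_steps + 1):
        valid = (idx + k < n_pts) & (nn + k < n_pts)
        if valid.sum() < 10:
            break
        d = np.linalg.norm(emb[idx[valid] + k] - emb[nn[valid] + k], axis=1)
        div[k] = float(np.mean(np.log(np.maximum(d, floor))))

    lo, hi = fit_window
    ks = np.arange(lo, min(hi, max_steps) + 1)
    ks = ks[np.isfinite(div[ks])]
    if ks.size < 2:
        raise ValueError("divergence curve too short for a slope fit")
    slope, _ = np.polyfit(ks, div[ks], 1)
    return LyapResult(lambda_max=float(slope * series.rate), M=M, tau=tau,
                      divergence=div, fit_window=(int(ks[0]), int(ks[-1])))


# ---------------------------------------------------------------------------
# PCA of multichannel signals
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    """Eigenvalue spectrum (variance fractions) and component time series."""

    eigenvalue_fractions: np.ndarray
    components: list[TimeSeries]


def pca_decompose(channels: list[TimeSeries]) -> PcaResult:
    """Eigen-decomposition of the channel covariance.

    Channels are mean-centered; eigenvalues are reported as fractions of
    total variance (descending) and the principal-component time series are
    returned for downstream stability analysis.
    """
    if len(channels) < 2:
        raise ValueError("PCA needs at least 2 channels")
    lengths = {len(c) for c in channels}
    if len(lengths) > 1:
        raise ValueError("channels must have equal lengths")
    data = np.stack([c.values - c.values.mean() for c in channels], axis=1)
    cov = data.T @ data / (data.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    if total == 0:
        raise ValueError("all channels constant; covariance has no variance")
    if np.any(evals < 1e-12 * total):
        log.warning("rank-deficient channel covariance (near-zero eigenvalue)")
    scores = data @ evecs
    rate = channels[0].rate
    comps = [TimeSeries(scores[:, i], rate=rate, label=f"pc{i + 1}")
             for i in range(scores.shape[1])]
    return PcaResult(eigenvalue_fractions=evals / total, components=comps)


# ---------------------------------------------------------------------------
# spectral and metabolic summaries
# ---------------------------------------------------------------------------

def median_frequency(emg: TimeSeries) -> float:
    """Frequency below which half of the EMG spectral power lies.

    Uses an averaged (Welch) periodogram of the raw pre-envelope signal;
    the half-power point is linearly interpolated on the cumulative
    spectrum.
    """
    if emg.duration < 2.0:
        raise ValueError("median frequency needs at least 2 s of signal")
    nperseg = min(len(emg), max(256, len(emg) // 8))
    freqs, pxx = sps.welch(emg.values - emg.values.mean(), fs=emg.rate, nperseg=nperseg)
    total = pxx.sum()
    if total == 0:
        raise ValueError("zero spectral power")
    cum = np.cumsum(pxx) / total
    return float(np.interp(0.5, cum, freqs))


@dataclass
class MetabolicSummary:
    """Per-variable mean and CV plus the net metabolic cost of transport."""

    means: dict[str, float]
    cvs: dict[str, float]
    c_met: float  # mL O2 per kg per m


def metabolic_summary(record: MetabolicRecord) -> MetabolicSummary:
    """Mean and CV per metabolic variable and the cost of transport.

    ``C_met`` is the mean oxygen uptake (mL/min) normalized by body mass
    (kg) and walking speed (converted to m/min), i.e. mL O2 per kg per m.
    """
    means: dict[str, float] = {}
    cvs: dict[str, float] = {}
    for name, vals in record.variables.items():
        means[name] = float(np.mean(vals))
        if vals.size >= 2:
            cvs[name] = coefficient_of_variation(vals)
        else:
            cvs[name] = math.nan
    c_met = math.nan
    if "vo2" in record.variables:
        if record.body_mass is None or record.walking_speed is None:
            log.warning("C_met missing: body mass or walking speed unavailable")
        else:
            c_met = means["vo2"] / (record.body_mass * record.walking_speed * 60.0)
    return MetabolicSummary(means=means, cvs=cvs, c_met=c_met)


# ---------------------------------------------------------------------------
# template statistics and spatiotemporal measures
# ---------------------------------------------------------------------------

def template_consistency(epochs: np.ndarray) -> tuple[float, float, float]:
    """Template statistics from an epoch matrix (events x window).

    Returns the template's mean and variance over its time axis, and the
    across-epoch variance at each time point averaged over time (the
    movement-regularity index: 0 for perfectly repeated cycles).
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 2:
        raise ValueError("epoch matrix must be 2-d")
    template = epochs.mean(axis=0)
    t_mean = float(template.mean())
    t_var = float(template.var(ddof=0))
    if epochs.shape[0] < 2:
        log.warning("single epoch: across-epoch variance undefined")
        return t_mean, t_var, math.nan
    mv = float(epochs.var(axis=0, ddof=0).mean())
    return t_mean, t_var, mv


def _safe_dfa(series) -> float:
    try:
        return dfa_alpha(series).alpha
    except ValueError as exc:
        log.warning("DFA skipped: %s", exc)
        return math.nan


def spatiotemporal_measures(copx: TimeSeries, copy_: TimeSeries, fz: TimeSeries,
                            events: EventSeries,
                            belt_speed: float | None = None) -> dict[str, float]:
    """Event-based spatiotemporal statistics.

    Step width is the absolute mediolateral COP difference between
    successive (contralateral) events; stride duration is the interval
    between successive ipsilateral events; stride length is belt speed
    times stride duration (treadmill convention).  Event position is the
    signal value at the event instants, per channel.  DFA exponents of the
    stride-duration and event-position series quantify their long-range
    correlation.
    """
    if len(events) < 10:
        raise ValueError("need at least 10 events for spatiotemporal measures")
    out: dict[str, float] = {}

    if events.legs is not None and any(
            a == b for a, b in zip(events.legs, events.legs[1:])):
        log.warning("events do not alternate legs; step width not computed")
        out["step_width_mean"] = math.nan
        out["step_width_cv"] = math.nan
    else:
        widths = np.abs(np.diff(copx.values[events.indices]))
        out["step_width_mean"] = float(widths.mean())
        out["step_width_cv"] = coefficient_of_variation(widths)

    strides = np.diff(events.indices[::2]) / events.rate
    out["stride_duration_mean"] = float(strides.mean())
    out["stride_duration_cv"] = coefficient_of_variation(strides)
    out["stride_duration_dfa"] = _safe_dfa(strides)

    if belt_speed is None:
        log.warning("belt speed missing: stride length not computed")
        out["stride_length_mean"] = math.nan
        out["stride_length_cv"] = math.nan
    else:
        lengths = belt_speed * strides
        out["stride_length_mean"] = float(lengths.mean())
        out["stride_length_cv"] = coefficient_of_variation(lengths)

    for tag, ts in (("copx", copx), ("copy", copy_), ("fz", fz)):
        pos = ts.values[events.indices]
        out[f"event_position_mean.{tag}"] = float(pos.mean())
        out[f"event_position_cv.{tag}"] = coefficient_of_variation(pos)
        out[f"event_position_dfa.{tag}"] = _safe_dfa(pos)
    return out


# ---------------------------------------------------------------------------
# catalog assembly
# ---------------------------------------------------------------------------

FP_CHANNELS = ("copx", "copy", "fz")
ACC_CHANNELS = ("accx", "accy", "accz")
DEFAULT_MUSCLES = ("ta", "g", "vm", "s", "tfl")
METABOLIC_VARS_A = ("ve", "vo2", "vco2", "rer", "cmet", "hr")
METABOLIC_VARS_B = ("ve", "vo2", "vco2", "rer", "bf", "cmet", "hr")


@dataclass
class CatalogConfig:
    """Which modalities (and channels within them) enter the catalog."""

    force_plate: bool = True
    accelerometer: bool = True
    metabolic_vars: tuple[str, ...] | None = METABOLIC_VARS_A
    emg_muscles: tuple[str, ...] | None = None
    #: rate (Hz) to which EMG envelopes are decimated for entropy/stability
    emg_analysis_rate: float = 100.0
    window_frac: float = 0.4


STUDY_A_CONFIG = CatalogConfig(metabolic_vars=METABOLIC_VARS_A)
STUDY_B_CONFIG = CatalogConfig(metabolic_vars=METABOLIC_VARS_B,
                               emg_muscles=DEFAULT_MUSCLES)
FORCE_PLATE_ONLY_CONFIG = CatalogConfig(accelerometer=False, metabolic_vars=None)


def catalog_columns(config: CatalogConfig) -> list[str]:
    """The exact measure-column list implied by a modality configuration."""
    cols: list[str] = []
    if config.force_plate:
        for meas in ("step_width", "stride_length", "stride_duration"):
            cols += [f"force_plate.{meas}_mean", f"force_plate.{meas}_cv"]
        cols.append("force_plate.stride_duration_dfa")
        for fam in ("event_position_mean", "event_position_cv", "event_position_dfa",
                    "template_mean", "template_event_variance",
                    "sampen", "sampen_se", "sampen_phase", "sampen_phase_se"):
            cols += [f"force_plate.{fam}.{ch}" for ch in FP_CHANNELS]
    if config.accelerometer:
        for fam in ("lyapunov", "sampen", "sampen_se"):
            cols += [f"accelerometer.{fam}.{ch}" for ch in ACC_CHANNELS]
        cols += [f"accelerometer.pca_eigenvalue.pc{i}" for i in range(1, 4)]
        cols += [f"accelerometer.lyapunov_pc.pc{i}" for i in range(1, 4)]
    if config.metabolic_vars:
        cols += [f"metabolism.mean.{v}" for v in config.metabolic_vars]
        cols += [f"metabolism.cv.{v}" for v in config.metabolic_vars]
    if config.emg_muscles:
        muscles = config.emg_muscles
        for fam in ("median_frequency", "template_mean", "template_event_variance",
                    "sampen", "sampen_se"):
            cols += [f"emg.{fam}.{m}" for m in muscles]
        cols += [f"emg.lyapunov.{m}" for m in muscles]
        cols += [f"emg.pca_eigenvalue.pc{i}" for i in range(1, len(muscles) + 1)]
        cols += [f"emg.lyapunov_pc.pc{i}" for i in range(1, len(muscles) + 1)]
        for fam in ("sampen_phase", "sampen_phase_se"):
            cols += [f"emg.{fam}.{m}" for m in muscles]
    return cols


def _sampen_pair(values: np.ndarray) -> tuple[float, float, float, float]:
    """(sampen, se) of analytic amplitude and of sin(phase) of a signal."""
    ts = TimeSeries(values, rate=1.0)
    dec = hilbert_decompose(ts)
    amp = sample_entropy(dec.amplitude.values)
    ph = sample_entropy(phase_for_entropy(dec))
    return amp.sampen, amp.se, ph.sampen, ph.se


def _safe_lyap(ts: TimeSeries) -> float:
    try:
        return lyapunov_rosenstein(ts).lambda_max
    except ValueError as exc:
        log.warning("Lyapunov skipped: %s", exc)
        return math.nan


def _decimate_to(ts: TimeSeries, target_rate: float) -> TimeSeries:
    factor = int(round(ts.rate / target_rate))
    if factor <= 1:
        return ts
    dec = sps.decimate(ts.values, factor, ftype="fir", zero_phase=True)
    return TimeSeries(dec, rate=ts.rate / factor, label=ts.label, units=ts.units)


def measures_for_recording(rec: Recording, config: CatalogConfig) -> dict[str, float]:
    """Compute the full measure catalog for one observation's recording."""
    row: dict[str, float] = {}

    events: EventSeries | None = None
    if config.force_plate or config.emg_muscles:
        # refine on the AP center of pressure: it repeats every step, whereas
        # the ML trace alternates sign between legs and would cancel in the
        # across-step template
        fz = rec.channel("fz")
        copx = rec.channel("copx")
        init = initial_events(fz)
        events, _ = refine_events(rec.channel("copy"), init,
                                  window_frac=config.window_frac)
        events = assign_legs(events, copx)

    if config.force_plate:
        copx = rec.channel("copx")
        copy_ = rec.channel("copy")
        fz = rec.channel("fz")
        belt = rec.meta.get("belt_speed")
        if belt is None and rec.metabolic is not None:
            belt = rec.metabolic.walking_speed
        st = spatiotemporal_measures(copx, copy_, fz, events, belt_speed=belt)
        for key, val in st.items():
            if "." in key:
                fam, ch = key.split(".")
                row[f"force_plate.{fam}.{ch}"] = val
            else:
                row[f"force_plate.{key}"] = val
        window = 2 * (int(round(config.window_frac *
                                2 * np.mean(np.diff(events.indices)))) // 2)
        for ch_tag, ts in (("copx", copx), ("copy", copy_), ("fz", fz)):
            epochs, _ = slice_epochs(ts, events, window)
            t_mean, _, mv = template_consistency(epochs)
            row[f"force_plate.template_mean.{ch_tag}"] = t_mean
            row[f"force_plate.template_event_variance.{ch_tag}"] = mv
            s, s_se, p, p_se = _sampen_pair(ts.values)
            row[f"force_plate.sampen.{ch_tag}"] = s
            row[f"force_plate.sampen_se.{ch_tag}"] = s_se
            row[f"force_plate.sampen_phase.{ch_tag}"] = p
            row[f"force_plate.sampen_phase_se.{ch_tag}"] = p_se

    if config.accelerometer:
        acc = [rec.channel(ch) for ch in ACC_CHANNELS]
        for ch_tag, ts in zip(ACC_CHANNELS, acc):
            row[f"accelerometer.lyapunov.{ch_tag}"] = _safe_lyap(ts)
            dec = hilbert_decompose(ts)
            res = sample_entropy(dec.amplitude.values)
            row[f"accelerometer.sampen.{ch_tag}"] = res.sampen
            row[f"accelerometer.sampen_se.{ch_tag}"] = res.se
        pca = pca_decompose(acc)
        for i, frac in enumerate(pca.eigenvalue_fractions, start=1):
            row[f"accelerometer.pca_eigenvalue.pc{i}"] = float(frac)
        for i, comp in enumerate(pca.components, start=1):
            row[f"accelerometer.lyapunov_pc.pc{i}"] = _safe_lyap(comp)

    if config.metabolic_vars:
        if rec.metabolic is None:
            raise ValueError("metabolic modality enabled but recording has no metabolic data")
        summ = metabolic_summary(rec.metabolic)
        for v in config.metabolic_vars:
            if v == "cmet":
                row["metabolism.mean.cmet"] = summ.c_met
                # per-breath cost series shares VO2's relative spread
                row["metabolism.cv.cmet"] = summ.cvs.get("vo2", math.nan)
            else:
                row[f"metabolism.mean.{v}"] = summ.means.get(v, math.nan)
                row[f"metabolism.cv.{v}"] = summ.cvs.get(v, math.nan)

    if config.emg_muscles:
        envelopes: list[TimeSeries] = []
        for muscle in config.emg_muscles:
            raw = rec.channel(f"emg_{muscle}")
            row[f"emg.median_frequency.{muscle}"] = median_frequency(raw)
            # all envelope analysis runs at the (2 Hz-bandwidth) envelope's
            # decimated analysis rate
            env_lo = _decimate_to(emg_envelope(raw), config.emg_analysis_rate)
            # envelope events: the refined force-plate events as initial
            # values, one per stride (a muscle bursts once per stride); the
            # parity whose events sit nearer the bursts is used; no
            # re-anchoring (preserves electro-mechanical delay)
            scale = env_lo.rate / events.rate
            idx_all = np.round(events.indices * scale).astype(int)
            idx_all = idx_all[idx_all < len(env_lo)]
            parity = int(env_lo.values[idx_all[1::2]].mean()
                         > env_lo.values[idx_all[0::2]].mean())
            init_emg = EventSeries(idx_all[parity::2], rate=env_lo.rate)
            stride_smp = 2.0 * scale * float(np.mean(np.diff(events.indices)))
            ev_emg, _ = refine_events(env_lo, init_emg, window_frac=config.window_frac,
                                      anchor_to_max=False, stride_samples=stride_smp)
            window = 2 * (int(round(config.window_frac * stride_smp)) // 2)
            epochs, _ = slice_epochs(env_lo, ev_emg, window)
            t_mean, _, mv = template_consistency(epochs)
            row[f"emg.template_mean.{muscle}"] = t_mean
            row[f"emg.template_event_variance.{muscle}"] = mv
            envelopes.append(env_lo)
            s, s_se, p, p_se = _sampen_pair(env_lo.values)
            row[f"emg.sampen.{muscle}"] = s
            row[f"emg.sampen_se.{muscle}"] = s_se
            row[f"emg.sampen_phase.{muscle}"] = p
            row[f"emg.sampen_phase_se.{muscle}"] = p_se
            row[f"emg.lyapunov.{muscle}"] = _safe_lyap(env_lo)
        pca = pca_decompose(envelopes)
        for i, frac in enumerate(pca.eigenvalue_fractions, start=1):
            row[f"emg.pca_eigenvalue.pc{i}"] = float(frac)
        for i, comp in enumerate(pca.components, start=1):
            row[f"emg.lyapunov_pc.pc{i}"] = _safe_lyap(comp)

    return row


def assemble_catalog(recordings: dict[tuple[str, str], Recording],
                     design: StudyDesign,
                     config: CatalogConfig) -> pd.DataFrame:
    """Assemble the wide measure table for a whole study.

    ``recordings`` maps (subject, condition) to the observation's recording;
    the result has a (subject, condition) MultiIndex and exactly the columns
    of :func:`catalog_columns` for the given configuration.
    """
    columns = catalog_columns(config)
    rows = {}
    for subj, _, cond in design.observations:
        key = (subj, cond)
        if key not in recordings:
            raise ValueError(f"no recording for observation {key}")
        rec = recordings[key]
        if config.emg_muscles:
            missing = [m for m in config.emg_muscles
                       if f"emg_{m}" not in rec.signals]
            if missing:
                raise ValueError(f"emg modality enabled but muscles missing: {missing}")
        row = measures_for_recording(rec, config)
        rows[key] = [row.get(c, math.nan) for c in columns]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    table.index = pd.MultiIndex.from_tuples(table.index, names=["subject", "condition"])
    return table
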