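"""Step-event detection by peak picking plus iterative template matching.

The detector first places one event per step from peaks of the vertical
ground reaction force, then refines them on a chosen signal (typically a
center-of-pressure trace) by alternating between (i) averaging epochs
around the current events into a template and (ii) shifting each event by
the lag that maximizes the cross-covariance between its epoch and the
template, until the events are a fixed point.  Finally the events are
re-anchored to the template's maximum so they approximate heel contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core_io import TimeSeries, get_logger

__all__ = [
    "EventSeries",
    "Template",
    "dominant_frequency",
    "step_rate",
    "initial_events",
    "refine_events",
    "slice_epochs",
    "assign_legs",
]

log = get_logger("gaitshotgun.events")

STRIDE_BAND_HZ = (0.3, 3.0)
STEP_BAND_HZ = (0.6, 6.0)
#: spectral peak must exceed this multiple of the median band power
PEAK_PROMINENCE_FACTOR = 3.0
#: lag search range as a fraction of the epoch window
LAG_SEARCH_FRAC = 0.25
DEFAULT_WINDOW_FRAC = 0.4
DEFAULT_MAX_ITER = 50


@dataclass
class EventSeries:
    """Strictly increasing sample indices of step (or burst) events."""

    indices: np.ndarray
    rate: float
    legs: list[str] | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size >= 2:
            d = np.diff(self.indices)
            if np.any(d <= 0):
                raise ValueError("event indices must be strictly increasing")
            med = float(np.median(d))
            if np.any(d < 0.25 * med) or np.any(d > 4.0 * med):
                raise ValueError(
                    "event spacing outside [0.25, 4.0] x median interval "
                    "(gross outlier among detected events)"
                )
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.legs is not None and len(self.legs) != self.indices.size:
            raise ValueError("one leg label per event required")

    def __len__(self) -> int:
        return self.indices.size

    @property
    def times(self) -> np.ndarray:
        """Event times in seconds."""
        return self.indices / self.rate

    def step_intervals(self) -> np.ndarray:
        """Successive inter-event intervals in seconds."""
        return np.diff(self.indices) / self.rate

    def stride_intervals(self) -> np.ndarray:
        """Every-second-event (ipsilateral) intervals in seconds."""
        idx = self.indices
        return (idx[2:] - idx[:-2]) / self.rate

    def shifted(self, s: int) -> "EventSeries":
        return EventSeries(self.indices + int(s), self.rate, self.legs)


@dataclass
class Template:
    """Across-epoch mean waveform with its per-point across-epoch variance."""

    waveform: np.ndarray
    variance: np.ndarray
    window: int
    n_epochs: int

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.waveform.size != self.window or self.variance.size != self.window:
            raise ValueError("waveform/variance length must equal the window length")
        if np.any(self.variance < -1e-12):
            raise ValueError("variance must be non-negative")

    @property
    def mean_variance_over_events(self) -> float:
        """Across-epoch variance averaged over the window (regularity index)."""
        return float(np.mean(self.variance))


# ---------------------------------------------------------------------------
# rhythm estimation and initial peak detection
# ---------------------------------------------------------------------------

def dominant_frequency(ts: TimeSeries, band: tuple[float, float] = STRIDE_BAND_HZ) -> float:
    """Frequency of the largest spectral peak within ``band``.

    Uses an averaged (Welch) periodogram of the linearly detrended signal so
    the flat-spectrum guard is not fooled by single-periodogram variance.
    Raises ``ValueError('no dominant rhythm')`` when the peak does not stand
    out from the band's median power.
    """
    x = sps.detrend(ts.values)
    nperseg = min(x.size, max(256, x.size // 8))
    freqs, pxx = sps.welch(x, fs=ts.rate, nperseg=nperseg)
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if not np.any(sel):
        raise ValueError(f"no spectral support in band {band} Hz")
    band_p = pxx[sel]
    peak = band_p.max()
    if peak < PEAK_PROMINENCE_FACTOR * np.median(band_p):
        raise ValueError("no dominant rhythm")
    return float(freqs[sel][np.argmax(band_p)])


def step_rate(fz: TimeSeries) -> float:
    """Step frequency (Hz) from the rectified, detrended vertical force."""
    rect = fz.copy_with(np.abs(sps.detrend(fz.values)))
    return dominant_frequency(rect, band=STEP_BAND_HZ)


def initial_events(fz: TimeSeries) -> EventSeries:
    """Initial step events: force peaks separated by at least half a step.

    Peaks must exceed the signal's 60th percentile; the minimum peak
    separation is half the step period estimated from the spectrum, which
    keeps one event per step even for double-bumped force profiles.
    """
    f_step = step_rate(fz)
    min_dist = max(1, int(round(0.5 / f_step * fz.rate)))
    height = np.percentile(fz.values, 60)
    peaks, _ = sps.find_peaks(fz.values, height=height, distance=min_dist)
    if peaks.size < 4:
        raise ValueError("too few force peaks for event detection")
    return EventSeries(indices=peaks, rate=fz.rate)


# ---------------------------------------------------------------------------
# epoch slicing and template matching
# ---------------------------------------------------------------------------

def slice_epochs(ts: TimeSeries, events: EventSeries, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Extract the epoch matrix around events.

    Each row is ``ts[e - window/2 : e + window/2]``; events whose window
    would cross the signal borders are dropped (logged).  Returns the epoch
    matrix and the indices of the kept events.
    """
    if window % 2 or window < 2:
        raise ValueError("window must be a positive even number of samples")
    half = window // 2
    idx = events.indices
    keep = (idx - half >= 0) & (idx + half <= len(ts))
    if not np.all(keep):
        log.info("dropping %d border event(s) with incomplete windows", int(np.sum(~keep)))
    kept = idx[keep]
    if kept.size == 0:
        raise ValueError("no event has a complete epoch within the signal")
    offsets = np.arange(-half, half)
    epochs = ts.values[kept[:, None] + offsets[None, :]]
    return epochs, kept


def _template_of(epochs: np.ndarray) -> Template:
    return Template(
        waveform=epochs.mean(axis=0),
        variance=epochs.var(axis=0, ddof=0),
        window=epochs.shape[1],
        n_epochs=epochs.shape[0],
    )


def _best_lags(ts_values: np.ndarray, events: np.ndarray, template: np.ndarray,
               window: int, max_lag: int) -> np.ndarray:
    """Per-event lag maximizing the epoch-template cross-covariance.

    Ties are broken toward the smallest absolute lag (then toward the
    negative lag) so the search is deterministic.
    """
    half = window // 2
    w = window
    t_c = template - template.mean()
    t_norm = np.linalg.norm(t_c)
    if t_norm == 0:
        return np.zeros(events.size, dtype=int)
    # normalized cross-correlation: centering the template makes the per-lag
    # epoch mean drop out of the numerator, and normalizing by the epoch's
    # own spread guarantees (Cauchy-Schwarz) that an epoch identical to the
    # template matches at zero lag
    lags = np.arange(-max_lag, max_lag + 1)
    # tie preference: smallest |lag|, then the negative one
    tie_rank = np.abs(lags) * 2 + (lags > 0)
    best = np.zeros(events.size, dtype=int)
    n = ts_values.size

    def _corr_at(e: int, l: int) -> float:
        s = e + l
        if s - half < 0 or s + half > n:
            return -np.inf
        ep = ts_values[s - half: s + half]
        spread = math.sqrt(max(np.dot(ep, ep) - ep.sum() ** 2 / w, 0.0))
        if spread == 0:
            return -np.inf
        return float(np.dot(ep, t_c)) / spread

    for i, e in enumerate(events):
        lo = e - max_lag - half
        hi = e + max_lag + half
        if lo < 0 or hi > n:
            corr = np.array([_corr_at(e, l) for l in lags])
        else:
            ext = ts_values[lo:hi]
            dots = np.correlate(ext, t_c, mode="valid")
            c1 = np.concatenate([[0.0], np.cumsum(ext)])
            c2 = np.concatenate([[0.0], np.cumsum(ext ** 2)])
            s1 = c1[w:] - c1[:-w]
            s2 = c2[w:] - c2[:-w]
            spread = np.sqrt(np.maximum(s2 - s1 ** 2 / w, 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = np.where(spread > 0, dots / spread, -np.inf)
        top = corr.max()
        ties = np.flatnonzero(corr >= top - 1e-9 * max(1.0, abs(top)))
        best[i] = lags[ties[np.argmin(tie_rank[ties])]]
    return best


def refine_events(ts: TimeSeries, initial: EventSeries,
                  window_frac: float = DEFAULT_WINDOW_FRAC,
                  max_iter: int = DEFAULT_MAX_ITER,
                  tol: int = 0,
                  anchor_to_max: bool = True,
                  stride_samples: float | None = None) -> tuple[EventSeries, Template]:
    """Refine step events by iterative template matching on ``ts``.

    Parameters
    ----------
    ts:
        Signal to match on (center-of-pressure channel, or an EMG envelope).
    initial:
        Initial step events (from :func:`initial_events`, or the refined
        force-plate events when matching EMG envelopes).
    window_frac:
        Epoch window as a fraction of the mean stride duration (two steps).
    max_iter, tol:
        The loop stops when no event moves by more than ``tol`` samples
        (default: an exact integer fixed point) or after ``max_iter``
        iterations with a warning.
    anchor_to_max:
        After convergence, uniformly shift all events so each sits at the
        template's maximum (approximately heel contact).  Disable for EMG
        envelopes to preserve electro-mechanical delay.
    stride_samples:
        Mean stride duration in samples; by default twice the mean initial
        event spacing (step events).  Pass it explicitly when the initial
        events are already one per stride (EMG burst matching).

    Returns
    -------
    (EventSeries, Template)
        The refined events (border events without complete windows are
        dropped) and the template computed from the final alignment.
    """
    if len(initial) < 4:
        raise ValueError("refine_events needs at least 4 initial events")
    if stride_samples is None:
        stride_samples = 2.0 * float(np.mean(np.diff(initial.indices)))
    window = int(round(window_frac * stride_samples))
    window -= window % 2
    if window < 8:
        raise ValueError(
            f"epoch window of {window} samples is too short (need >= 8); "
            "increase window_frac or the sampling rate"
        )
    max_lag = max(1, int(round(LAG_SEARCH_FRAC * window)))
    half = window // 2

    x = ts.values
    events = initial.indices.copy()

    converged = False
    for _ in range(max_iter):
        keep = (events - half >= 0) & (events + half <= x.size)
        events = events[keep]
        if events.size < 2:
            raise ValueError("too few events with complete epochs")
        epochs = x[events[:, None] + np.arange(-half, half)[None, :]]
        template = epochs.mean(axis=0)
        shifts = _best_lags(x, events, template, window, max_lag)
        events = events + shifts
        if np.any(np.diff(events) < half):
            raise ValueError("event collision: two events within half a window")
        if np.max(np.abs(shifts)) <= tol:
            converged = True
            break
    if not converged:
        log.warning("template matching did not converge within %d iterations", max_iter)

    if anchor_to_max:
        epochs, events = slice_epochs(ts, EventSeries(events, ts.rate), window)
        template = epochs.mean(axis=0)
        events = events + (int(np.argmax(template)) - half)

    keep = (events - half >= 0) & (events + half <= x.size)
    events = events[keep]
    epochs = x[events[:, None] + np.arange(-half, half)[None, :]]
    final = EventSeries(events, ts.rate)
    return final, _template_of(epochs)


def assign_legs(events: EventSeries, copx: TimeSeries,
                negative_label: str = "left", positive_label: str = "right") -> EventSeries:
    """Alternate leg labels, starting from the lateral sign of the first event.

    The first event's label is decided by whether the mediolateral
    center-of-pressure value at that instant is negative (``negative_label``)
    or positive; the remaining events alternate.
    """
    first = copx.values[events.indices[0]]
    a, b = (negative_label, positive_label) if first < 0 else (positive_label, negative_label)
    legs = [a if i % 2 == 0 else b for i in range(len(events))]
    return EventSeries(events.indices.copy(), events.rate, legs=legs)
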