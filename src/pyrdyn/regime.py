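"""Classification of trajectories: steady state vs sustained oscillation.

The detector is a deterministic periodogram-plus-envelope test. For each
channel of the trajectory (after discarding a burn-in window):

1. a channel whose span is negligible relative to its level is steady;
2. otherwise the detrended signal must concentrate its variance in a single
   spectral line (dominant periodogram peak >= ``peak_power_ratio`` times the
   median power, and a large fraction of variance within the peak +- 1 bin);
3. a candidate line is accepted as a *sustained* oscillation only if the
   amplitude envelope, measured on successive maxima, decays by less than
   ``max_decay_per_period`` per period and at least three full periods are
   observed.

A damped transient therefore classifies as steady, a noisy plateau as steady
(its spectrum is broadband), and a persistent spectral line with a flat
envelope as oscillatory. All thresholds are relative, so the call is
invariant to uniform rescaling of concentrations and to a change of time
unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .simulate import Trajectory

__all__ = ["RegimeCall", "classify", "period_and_amplitude"]

#: minimum relative span below which a channel counts as constant
_FLAT_RTOL = 1e-6
#: dominant peak power vs median periodogram power
PEAK_POWER_RATIO = 10.0
#: fraction of variance that must sit in the dominant peak +- 1 bin
MIN_PEAK_VARIANCE_FRACTION = 0.4
#: maximum relative envelope decay per period for a sustained oscillation
MAX_DECAY_PER_PERIOD = 0.05
#: minimum number of full periods inside the analysis window
MIN_PERIODS = 3


@dataclass
class RegimeCall:
    """Outcome of regime classification for one trajectory."""

    label: str                                  # steady | oscillatory | undetermined
    period: float | None = None                 # seconds, oscillatory only
    amplitude: dict[str, float] = field(default_factory=dict)  # mM per channel
    evidence: float = 0.0                       # dominant peak / median power
    channel: str | None = None                  # channel carrying the evidence
    diagnostic: str = ""

    def __post_init__(self) -> None:
        if self.label not in ("steady", "oscillatory", "undetermined"):
            raise ValueError(f"bad label {self.label!r}")
        if self.label == "oscillatory" and not (self.period and self.period > 0):
            raise ValueError("oscillatory call requires a positive period")
        if any(a < 0 for a in self.amplitude.values()):
            raise ValueError("amplitudes must be >= 0")

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {"label": self.label, "period_s": self.period,
               "amplitude_mM": self.amplitude, "evidence": self.evidence,
               "channel": self.channel, "diagnostic": self.diagnostic}
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _smooth(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y
    kernel = np.ones(width) / width
    pad = width // 2
    yp = np.pad(y, pad, mode="edge")
    return np.convolve(yp, kernel, mode="same")[pad: pad + len(y)]


def _envelope_decay(t: np.ndarray, y: np.ndarray, period: float):
    """(decay per period, n_periods, maxima indices, spacing CV).

    Works on a lightly smoothed copy (boxcar ~ period/6) so that additive
    noise does not masquerade as extra maxima or as envelope decay.
    """
    dt = t[1] - t[0]
    ys = _smooth(y, max(1, int(round(period / (6.0 * dt)))))
    dev = ys - np.median(ys)
    amp = np.max(np.abs(dev))
    if amp == 0:
        return None
    dist = max(1, int(0.6 * period / dt))
    peaks, _props = sps.find_peaks(dev, distance=dist, prominence=0.2 * amp)
    if len(peaks) < MIN_PERIODS + 1:
        return None
    heights = np.maximum(dev[peaks], 1e-300)
    spacings = np.diff(t[peaks])
    n_per = (t[peaks[-1]] - t[peaks[0]]) / period
    # geometric decay rate per period, medians of first vs last third
    k = max(1, len(heights) // 3)
    h0 = float(np.median(heights[:k]))
    h1 = float(np.median(heights[-k:]))
    decay = 1.0 - (h1 / h0) ** (1.0 / max(n_per, 1e-9))
    cv = float(np.std(spacings) / np.mean(spacings)) if len(spacings) > 1 else 0.0
    return decay, n_per, peaks, cv


def _analyse_channel(t: np.ndarray, y: np.ndarray,
                     full_scale: float | None = None):
    """Classify one channel. Returns (label, period, amplitude, score).

    ``full_scale`` is the channel's magnitude over the whole record
    (including burn-in); window variation negligible on that scale is
    numerically zero, i.e. a settled channel.
    """
    level = max(np.mean(np.abs(y)), np.max(np.abs(y)) * 1e-3, 1e-300)
    if full_scale:
        level = max(level, full_scale)
    span = float(np.max(y) - np.min(y))
    if span <= _FLAT_RTOL * level:
        return "steady", None, 0.0, 0.0
    z = sps.detrend(y)
    # dominant monotone trend: either a settled approach to a fixed level
    # (flat tail: steady) or still in transit / divergent (undetermined)
    if np.std(z) < 0.05 * span / 2:
        tail = y[-max(4, len(y) // 3):]
        if np.max(tail) - np.min(tail) < 0.01 * span:
            return "steady", None, span / 2, 0.0
        return "undetermined", None, span / 2, 0.0
    freqs, power = sps.periodogram(z, fs=1.0 / (t[1] - t[0]), window="boxcar")
    freqs, power = freqs[1:], power[1:]
    if len(power) < 8:
        return "undetermined", None, span / 2, 0.0
    i = int(np.argmax(power))
    med = float(np.median(power))
    score = power[i] / med if med > 0 else np.inf
    frac = float(np.sum(power[max(0, i - 1): i + 2]) / np.sum(power))
    if score < PEAK_POWER_RATIO or frac < MIN_PEAK_VARIANCE_FRACTION:
        # broadband fluctuation around a level: steady
        return "steady", None, span / 2, float(min(score, PEAK_POWER_RATIO))
    period = 1.0 / freqs[i]
    env = _envelope_decay(t, y, period)
    if env is None or env[1] < MIN_PERIODS - 0.2 or env[3] > 0.35:
        # a spectral line but no usable train of maxima: a decaying transient
        # (late variance collapsed) is steady, anything else inconclusive
        k = len(z) // 3
        if k > 3 and np.std(z[-k:]) < 0.5 * np.std(z[:k]):
            return "steady", None, span / 2, score
        return "undetermined", None, span / 2, score
    decay, n_per, peaks, cv = env
    if decay > MAX_DECAY_PER_PERIOD:
        return "steady", None, span / 2, score
    # refine the period from successive-maxima spacing
    period_ref = float(np.mean(np.diff(t[peaks])))
    return "oscillatory", period_ref, span / 2, score


def classify(traj: Trajectory, burn_in: float = 0.5,
             min_points: int = 20) -> RegimeCall:
    """Classify a trajectory as steady, oscillatory, or undetermined.

    ``burn_in`` is the fraction of the record discarded before analysis.
    The trajectory is oscillatory if any channel carries a sustained spectral
    line; steady if every channel is steady; otherwise undetermined.
    """
    n = len(traj.times)
    start = int(n * burn_in)
    t = traj.times[start:]
    if len(t) < min_points:
        return RegimeCall("undetermined",
                          diagnostic=f"only {len(t)} points after burn-in")
    labels, best = {}, None
    amplitudes: dict[str, float] = {}
    for j, name in enumerate(traj.names):
        label, period, amp, score = _analyse_channel(
            t, traj.states[start:, j],
            full_scale=float(np.max(np.abs(traj.states[:, j]))))
        labels[name] = label
        amplitudes[name] = float(amp or 0.0)
        if label == "oscillatory" and (best is None or score > best[2]):
            best = (name, period, score)
    if best is not None:
        return RegimeCall("oscillatory", period=best[1], amplitude=amplitudes,
                          evidence=float(best[2]), channel=best[0])
    if all(v == "steady" for v in labels.values()):
        return RegimeCall("steady", amplitude=amplitudes)
    bad = [k for k, v in labels.items() if v != "steady"]
    return RegimeCall("undetermined", amplitude=amplitudes,
                      diagnostic=f"inconclusive channels: {bad}")


def period_and_amplitude(traj: Trajectory, burn_in: float = 0.5):
    """(period s, amplitude per channel mM) of an oscillatory trajectory.

    The period comes from the dominant spectral peak refined by the spacing
    of successive maxima; the amplitude per channel is half the peak-to-trough
    span over the last three detected periods. Raises ``ValueError`` for a
    non-oscillatory trajectory (period undefined).
    """
    call = classify(traj, burn_in=burn_in)
    if call.label != "oscillatory":
        raise ValueError(f"period undefined for a {call.label} trajectory")
    n = len(traj.times)
    start = int(n * burn_in)
    t = traj.times[start:]
    dt = t[1] - t[0]
    k = int(np.ceil(3 * call.period / dt))
    amp = {}
    for j, name in enumerate(traj.names):
        y = traj.states[-min(k, len(t)):, j]
        amp[name] = float((np.max(y) - np.min(y)) / 2)
    return call.period, amp
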