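"""Distance functions for the oscillatory and chaotic behaviour objectives.

The oscillation objective summarises each strain signal with three numbers:
the dominant Fourier period ``T``, the count ``A_K`` of peak-to-trough
amplitudes above a threshold ``K``, and the final amplitude ``A_F``.  The
distance triple is

    d_o1 = |T - t/2|  (set to 0 when T < t/2)
    d_o2 = |A_K - p|  with expected peak count p = t/T
    d_o3 = |A_F - K|  (set to 0 when it exceeds K)

compared against the final thresholds eps_F = (2.0, 2.5, 20.0).  The chaos
objective uses the single distance d_C1 = 1/(1 + lambda_1), whose final
threshold 0.997 is equivalent to lambda_1 > 0.003.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dynamics import Trajectory

__all__ = [
    "DistanceVector",
    "OscillationStats",
    "dominant_period",
    "peak_amplitudes",
    "oscillation_stats",
    "oscillation_distances",
    "chaos_distance",
    "chaos_prescreen",
    "SENTINEL_DISTANCE",
    "OSCILLATION_EPS_FINAL",
    "CHAOS_EPS_FINAL",
    "AMPLITUDE_THRESHOLD",
]

#: Distance assigned to extinct/failed simulations ("set to maximum").
SENTINEL_DISTANCE = 1e6
#: Final oscillation-objective thresholds (d_o1, d_o2, d_o3).
OSCILLATION_EPS_FINAL = (2.0, 2.5, 20.0)
#: Final chaos-objective threshold on d_C1 = 1/(1+lambda_1).
CHAOS_EPS_FINAL = (0.997,)
#: Peak-to-trough amplitude threshold K.
AMPLITUDE_THRESHOLD = 0.05


@dataclass(frozen=True)
class DistanceVector:
    values: tuple[float, ...]
    sentinel: bool = False
    rejected: bool = False      # hard rejection independent of thresholds

    def accepted(self, eps: Sequence[float]) -> bool:
        if self.sentinel or self.rejected:
            return False
        return all(v < e for v, e in zip(self.values, eps))

    @classmethod
    def max_distance(cls, n: int) -> "DistanceVector":
        return cls(values=(SENTINEL_DISTANCE,) * n, sentinel=True)


@dataclass(frozen=True)
class OscillationStats:
    """Per-signal oscillation summary."""

    T: float                    # dominant period (h); inf if no spectral power
    p: float                    # expected peak count t/T
    amplitudes: tuple[float, ...]
    A_K: int                    # amplitudes above threshold K
    A_F: float                  # final amplitude (0 if none)
    K: float = AMPLITUDE_THRESHOLD


def dominant_period(signal: np.ndarray, dt: float = 1.0) -> float:
    """Period of the strongest positive-frequency Fourier component.

    The mean (zero-frequency) component is removed first.  Returns ``inf``
    when the signal has no spectral power above the numerical floor
    (e.g. constants).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples for a period estimate")
    x = x - x.mean()
    mag = np.abs(np.fft.rfft(x))[1:]  # positive frequencies only
    floor = 1e-9 * x.size * (np.abs(x).max() if x.size else 0.0)
    if mag.size == 0 or mag.max() <= max(floor, 1e-300):
        return np.inf
    k = int(np.argmax(mag)) + 1
    freq = k / (x.size * dt)
    return 1.0 / freq


def _extrema_indices(x: np.ndarray) -> np.ndarray:
    """Indices of alternating peaks/troughs found by gradient sign changes."""
    g = np.diff(x)
    sign = np.sign(g)
    # carry the previous sign through flat segments
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    change = np.nonzero(sign[1:] * sign[:-1] < 0)[0] + 1
    return change


def peak_amplitudes(signal: np.ndarray) -> tuple[tuple[float, ...], float]:
    """Peak-to-trough amplitudes, one per oscillation cycle.

    Alternating peaks and troughs are located by gradient sign changes and
    paired off consecutively (first with second, third with fourth, ...), so
    a clean oscillation of ``p`` cycles yields about ``p`` amplitudes —
    directly comparable with the expected peak count ``t/T``.  Returns
    ``(amplitudes, A_F)`` where ``A_F`` is the final amplitude (0 for
    monotone signals).
    """
    x = np.asarray(signal, dtype=float)
    idx = _extrema_indices(x)
    if idx.size < 2:
        return (), 0.0
    vals = x[idx]
    pairs = vals[: 2 * (vals.size // 2)].reshape(-1, 2)
    amps = tuple(np.abs(pairs[:, 1] - pairs[:, 0]))
    return amps, amps[-1]


def oscillation_stats(signal: np.ndarray, dt: float = 1.0,
                      duration: float | None = None,
                      K: float = AMPLITUDE_THRESHOLD) -> OscillationStats:
    x = np.asarray(signal, dtype=float)
    t = duration if duration is not None else (x.size - 1) * dt
    T = dominant_period(x, dt)
    p = t / T if np.isfinite(T) else 0.0
    amps, A_F = peak_amplitudes(x)
    A_K = int(sum(a > K for a in amps))
    return OscillationStats(T=T, p=p, amplitudes=amps, A_K=A_K, A_F=A_F, K=K)


def oscillation_distances(trajectory: Trajectory, n_strains: int | None = None,
                          K: float = AMPLITUDE_THRESHOLD) -> DistanceVector:
    """Oscillation-objective distance triple for a community trajectory.

    Statistics are computed per strain and combined by componentwise
    maximum, so acceptance requires *every* strain to oscillate.  Extinct or
    failed simulations get the sentinel (maximal) distance.
    """
    if not trajectory.termination.completed:
        return DistanceVector.max_distance(3)
    n = n_strains if n_strains is not None else trajectory.n_states
    dt = float(trajectory.times[1] - trajectory.times[0])
    t = float(trajectory.times[-1] - trajectory.times[0])
    d = np.zeros((n, 3))
    for x in range(n):
        st = oscillation_stats(trajectory.strain(x), dt, duration=t, K=K)
        d1 = 0.0 if st.T < t / 2 else abs(st.T - t / 2)
        d2 = abs(st.A_K - st.p)
        d3 = abs(st.A_F - K)
        if d3 > K:
            d3 = 0.0
        d[x] = (d1, d2, d3)
    return DistanceVector(values=tuple(d.max(axis=0)))


def chaos_distance(lambda1: float) -> DistanceVector:
    """Chaos-objective distance d_C1 = 1/(1 + lambda_1).

    Strictly decreasing in lambda_1 for lambda_1 > -1, so the threshold
    d_C1 < 0.997 is equivalent to lambda_1 > 0.003.  Negative distances
    (lambda_1 < -1) and the singularity at -1 are hard rejections.
    """
    if lambda1 == -1.0:
        return DistanceVector(values=(np.inf,), rejected=True)
    d = 1.0 / (1.0 + lambda1)
    return DistanceVector(values=(d,), rejected=d < 0)


def chaos_prescreen(trajectory: Trajectory, n_strains: int | None = None,
                    K: float = AMPLITUDE_THRESHOLD,
                    min_oscillations: int = 2) -> bool:
    """Cheap accept/reject before the expensive Lyapunov computation.

    Rejects extinct simulations and any in which some strain shows fewer
    than ``min_oscillations`` above-threshold amplitudes.
    """
    if not trajectory.termination.completed:
        return False
    n = n_strains if n_strains is not None else trajectory.n_states
    for x in range(n):
        amps, _ = peak_amplitudes(trajectory.strain(x))
        if sum(a > K for a in amps) < min_oscillations:
            return False
    return True
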