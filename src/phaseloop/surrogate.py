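"""Ground-truth surrogate oscillations with AR(1)-correlated cycle periods.

Cycle-to-cycle period lengths follow a stationary first-order autoregressive
process T_i = T_mean + a (T_{i-1} - T_mean) + eps_i with i.i.d. Gaussian
residuals, mimicking the period statistics of the simulated gamma LFP.  Each
cycle renders one waveform template time-warped to its period, so the phase,
locking and closed-loop analysis code can be exercised in milliseconds with
known ground truth.  This is strictly a test fixture, not a generative model
of real LFPs.

The asymmetric default template places the waveform maximum at phase 0.3 and
the minimum at 0.6 (fast fall, slow rise), emulating the waveform asymmetry
of inhibition-dominated gamma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phase import PhaseSeries

__all__ = ["SurrogateSpec", "generate_periods", "render_signal", "surrogate_lfp"]


@dataclass(frozen=True)
class SurrogateSpec:
    T_mean: float = 18.0       # ms (~55 Hz gamma)
    a: float = 0.3             # AR(1) coefficient, |a| < 1
    sigma: float = 1.0         # residual std of the period process, ms
    waveform: str = "asym"     # "sine" | "asym"
    phi_max: float = 0.3       # phase of the waveform maximum (asym template)
    phi_min: float = 0.6       # phase of the waveform minimum (asym template)
    amplitude: float = 1.0
    noise_std: float = 0.05    # additive white measurement noise
    fs: float = 1000.0         # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.a) < 1:
            raise ValueError("|a| must be < 1 for a stationary AR(1) process")
        if self.sigma < 0 or self.noise_std < 0:
            raise ValueError("noise levels must be non-negative")


def generate_periods(spec: SurrogateSpec, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` periods from the stationary AR(1) process.

    Returns (periods, crossing_times); crossing_times[0] = 0 and
    crossing_times[i] is the ground-truth start of cycle i (cumulative sum).
    Periods are clipped at 10% of the mean to stay positive.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    stat_sd = spec.sigma / np.sqrt(1.0 - spec.a ** 2) if spec.sigma > 0 else 0.0
    T = np.empty(n)
    T[0] = spec.T_mean + rng.normal(0.0, stat_sd) if stat_sd else spec.T_mean
    eps = rng.normal(0.0, spec.sigma, n) if spec.sigma > 0 else np.zeros(n)
    for i in range(1, n):
        T[i] = spec.T_mean + spec.a * (T[i - 1] - spec.T_mean) + eps[i]
    np.clip(T, 0.1 * spec.T_mean, None, out=T)
    crossings = np.concatenate([[0.0], np.cumsum(T)])
    return T, crossings


def _template(phi: np.ndarray, spec: SurrogateSpec) -> np.ndarray:
    if spec.waveform == "sine":
        return np.sin(2 * np.pi * phi)
    if spec.waveform == "asym":
        # monotone piecewise-linear phase warp sending the sine peak (0.25)
        # to phi_max and the trough (0.75) to phi_min
        xp = [0.0, spec.phi_max, spec.phi_min, 1.0]
        fp = [0.0, 0.25, 0.75, 1.0]
        return np.sin(2 * np.pi * np.interp(phi, xp, fp))
    raise ValueError(f"unknown waveform {spec.waveform!r}")


def render_signal(
    periods: np.ndarray, spec: SurrogateSpec,
) -> tuple[np.ndarray, np.ndarray, PhaseSeries]:
    """Render the cycle sequence into a sampled signal.

    Returns (t_ms, signal, ground_truth_phase); the ground-truth phase grows
    linearly from 0 to 1 within each cycle.
    """
    periods = np.asarray(periods, float)
    crossings = np.concatenate([[0.0], np.cumsum(periods)])
    t = np.arange(0.0, crossings[-1], 1000.0 / spec.fs)
    idx = np.clip(np.searchsorted(crossings, t, side="right") - 1, 0, len(periods) - 1)
    phi = (t - crossings[idx]) / periods[idx]
    x = spec.amplitude * _template(phi, spec)
    if spec.noise_std > 0:
        rng = np.random.default_rng([spec.seed, 1])
        x = x + rng.normal(0.0, spec.noise_std, x.shape)
    truth = PhaseSeries(t=t, phase=phi % 1.0, method="linear")
    return t, x, truth


def surrogate_lfp(spec: SurrogateSpec, n_cycles: int):
    """Convenience: periods + rendered signal in one call."""
    T, crossings = generate_periods(spec, n_cycles)
    t, x, truth = render_signal(T, spec)
    return t, x, truth, T, crossings
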