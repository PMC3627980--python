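"""Inter-areal phase locking and light-induced shifting / switching.

Two mutually coupled gamma-oscillating areas settle into one of two
out-of-phase locked modes with inter-areal phase differences Delta-phi and
1 - Delta-phi (one area leading, the other lagging).  Background noise
causes rare spontaneous switches between the modes.  A single light pulse
applied to the transduced (leader) area can transiently shift the phase
difference (*shifting*, measured over the first 5 cycles after the pulse)
or persistently reverse the locking mode (*switching*, measured over 50
cycles after a 10-cycle transient).  Both probabilities are estimated per
onset-phase bin and compared with the rate of equally large spontaneous
fluctuations in matched unperturbed windows of the same network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from . import chr2 as chr2mod
from . import network as netmod
from .phase import (PhaseSeries, circular_mean, circular_std, hilbert_phase,
                    wrap_difference)

__all__ = [
    "LockingState",
    "PolarHistogram",
    "PulseExperiment",
    "phase_difference_series",
    "find_locking_modes",
    "run_pulse_experiments",
    "shifting_probability",
    "switching_probability",
    "spontaneous_switching_stats",
    "cross_correlogram",
]


@dataclass
class LockingState:
    """A detected out-of-phase locking configuration."""

    dphi_locked: float           # mode in (0, 0.5): leader = area a
    occupancy: tuple[float, float]   # fraction of time in (mode, 1 - mode)
    leader: int                  # area id leading over the analyzed span

    @property
    def modes(self) -> tuple[float, float]:
        return (self.dphi_locked, 1.0 - self.dphi_locked)


@dataclass
class PolarHistogram:
    """Per onset-phase-bin probability with a spontaneous baseline."""

    bin_centers: np.ndarray
    probability: np.ndarray
    count: np.ndarray
    baseline: float
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"bin_centers": self.bin_centers.tolist(),
                "probability": self.probability.tolist(),
                "count": self.count.tolist(),
                "baseline": self.baseline, "meta": self.meta}


def phase_difference_series(
    lfp_a: np.ndarray, lfp_b: np.ndarray, fs: float,
    t: np.ndarray | None = None, freq_tolerance: float = 10.0,
    f_common: float | None = None,
) -> tuple[PhaseSeries, np.ndarray]:
    """Instantaneous Hilbert-phase difference (a minus b) on the unit circle.

    Both areas must share a common spectral peak (within
    ``freq_tolerance`` Hz); the difference series is returned in [0, 1)
    together with the common-band phase of area a for timing reference.
    ``f_common`` overrides the per-area peak estimate (e.g., for short
    windows whose spectral peak is unstable).
    """
    if f_common is None:
        fa = netmod.oscillation_frequency(lfp_a, fs)
        fb = netmod.oscillation_frequency(lfp_b, fs)
        if abs(fa - fb) > freq_tolerance:
            raise ValueError(f"no common spectral peak ({fa:.1f} vs {fb:.1f} Hz)")
        f_common = 0.5 * (fa + fb)
    ph_a = hilbert_phase(lfp_a, fs, t=t, f_peak=f_common)
    ph_b = hilbert_phase(lfp_b, fs, t=t, f_peak=f_common)
    dphi = (ph_a.phase - ph_b.phase) % 1.0
    return ph_a, dphi


def find_locking_modes(dphi: np.ndarray, bw: float = 0.03) -> LockingState:
    """Detect the two locking modes from the circular density of the
    phase-difference series (kernel smoothing, not a fixed 0.5 threshold)."""
    grid = np.linspace(0.0, 1.0, 200, endpoint=False)
    d = wrap_difference(dphi[None, :] - grid[:, None])
    dens = np.exp(-0.5 * (d / bw) ** 2).sum(axis=1)
    # the two modes are symmetric partners m and 1-m; estimate m from the
    # dominant peak folded into (0, 0.5)
    peak = grid[int(np.argmax(dens))]
    m = peak if peak < 0.5 else 1.0 - peak
    u = wrap_difference(dphi)  # >0 : mode m (a leads), <0 : mode 1-m
    occ_m = float(np.mean(u > 0))
    leader = 0 if occ_m >= 0.5 else 1
    return LockingState(dphi_locked=float(m), occupancy=(occ_m, 1.0 - occ_m),
                        leader=leader)


# ---------------------------------------------------------------------------
# Pulse experiments (frozen-noise perturbed continuations of one base run)
# ---------------------------------------------------------------------------

@dataclass
class PulseExperiment:
    onset_phase: float          # phase of the leader (transduced) area at t_on
    t_on: float
    pre_dphi: float             # circular mean over the 20 pre-pulse cycles
    post5_dphi: float           # cycles 1-5 after the pulse (perturbed)
    post50_dphi: float          # cycles 11-60 after the pulse (perturbed)
    spont5_dphi: float          # same windows in the unperturbed twin
    spont50_dphi: float
    locked_ok: bool             # pre-pulse lock verified (leader = transduced)


def _window_mean_dphi(t, dphi, t_start, t_end) -> float:
    sel = (t >= t_start) & (t <= t_end)
    return float(circular_mean(dphi[sel]) % 1.0)


def run_pulse_experiments(
    config: netmod.NetworkConfig,
    n_onsets: int = 150,
    W_light: float = 0.20,
    T_light: float = 3.0,
    settle_cycles: int = 100,
    onset_window_cycles: float = 50.0,
    lock_window_cycles: int = 20,
    lock_std_max: float = 0.05,
    conn: netmod.Connectivity | None = None,
    seed: int = 0,
) -> tuple[list[PulseExperiment], LockingState, float]:
    """Run the two-area single-pulse protocol.

    A base (unperturbed) run settles for ``settle_cycles`` cycles, then
    ``n_onsets`` uniformly spread onset times are tested by frozen-noise
    perturbed continuations (pulse applied to area 0, the transduced area).
    Experiments whose 20-cycle pre-pulse window is not locked with the
    transduced area leading are flagged and excluded by the downstream
    probability estimators.  Returns (experiments, locking state, mean
    period in ms).
    """
    cfg = config
    if cfg.n_areas != 2:
        raise ValueError("the pulse protocol needs a two-area motif")
    if cfg.P_chr2 <= 0:
        raise ValueError("area 0 must be transduced")
    if conn is None:
        conn = netmod.build_connectivity(cfg)

    probe = netmod.simulate(cfg, 1500.0, conn=conn)
    f_peak = netmod.oscillation_frequency(probe.lfp[0][probe.t_lfp > 500], probe.fs_lfp)
    T = 1000.0 / f_peak

    settle = settle_cycles * T
    post = 63.0 * T
    onsets = settle + np.linspace(0.0, onset_window_cycles * T, n_onsets, endpoint=False)
    onsets = np.round(onsets / cfg.dt) * cfg.dt
    total = settle + onset_window_cycles * T + post + 2 * T
    base = netmod.simulate(cfg, total, conn=conn, checkpoint_times=onsets)

    ph_a, dphi_u = phase_difference_series(base.lfp[0], base.lfp[1],
                                           base.fs_lfp, t=base.t_lfp)
    lock = find_locking_modes(dphi_u[base.t_lfp > settle / 2])

    experiments: list[PulseExperiment] = []
    for t_on in onsets:
        cp = base.checkpoints[t_on]
        stim = chr2mod.LightStimulus.pulse(float(t_on), T_light, W_light)
        pert = netmod.simulate(cfg, post, light={0: stim}, state=cp, conn=conn)
        tb = base.t_lfp
        # pre-pulse lock verification on the unperturbed series
        pre_sel = (tb >= t_on - lock_window_cycles * T) & (tb <= t_on)
        pre_mean = float(circular_mean(dphi_u[pre_sel]) % 1.0)
        pre_std = circular_std(dphi_u[pre_sel])
        leading = wrap_difference(pre_mean) > 0  # transduced area (0) leads
        locked_ok = bool(leading and pre_std <= lock_std_max)

        _, dphi_p = phase_difference_series(pert.lfp[0], pert.lfp[1],
                                            base.fs_lfp, t=pert.t_lfp,
                                            f_common=ph_a.f_peak)
        tp = pert.t_lfp
        post5 = _window_mean_dphi(tp, dphi_p, t_on, t_on + 5 * T)
        post50 = _window_mean_dphi(tp, dphi_p, t_on + 10 * T, t_on + 60 * T)
        spont5 = _window_mean_dphi(tb, dphi_u, t_on, t_on + 5 * T)
        spont50 = _window_mean_dphi(tb, dphi_u, t_on + 10 * T, t_on + 60 * T)
        experiments.append(PulseExperiment(
            onset_phase=float(ph_a.at(float(t_on))), t_on=float(t_on),
            pre_dphi=pre_mean, post5_dphi=post5, post50_dphi=post50,
            spont5_dphi=spont5, spont50_dphi=spont50, locked_ok=locked_ok))
    n_bad = sum(not e.locked_ok for e in experiments)
    if n_bad:
        warnings.warn(f"{n_bad}/{len(experiments)} experiments discarded: "
                      "pre-pulse state not locked with the transduced area leading")
    return experiments, lock, T


def _changed(pre: float, post: float, threshold: float, relative: bool) -> bool:
    """Has the phase difference changed by more than the threshold?

    Delta-phi magnitudes are measured as circular distance from 0.
    """
    a = abs(wrap_difference(pre))
    b = abs(wrap_difference(post))
    if relative:
        return a > 0 and abs(b - a) / a > threshold
    return abs(b - a) > threshold


def _polar(experiments, outcome, n_bins, baseline_outcome, meta) -> PolarHistogram:
    kept = [e for e in experiments if e.locked_ok]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    prob = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    phases = np.array([e.onset_phase for e in kept]) % 1.0
    idx = np.clip(np.digitize(phases, edges) - 1, 0, n_bins - 1)
    flags = np.array([outcome(e) for e in kept], dtype=float)
    for b in range(n_bins):
        sel = idx == b
        count[b] = int(sel.sum())
        if count[b]:
            prob[b] = float(flags[sel].mean())
    base = float(np.mean([baseline_outcome(e) for e in kept])) if kept else np.nan
    meta = dict(meta or {}, n_used=len(kept), n_total=len(experiments))
    return PolarHistogram(bin_centers=centers, probability=prob, count=count,
                          baseline=base, meta=meta)


def shifting_probability(
    experiments: list[PulseExperiment],
    n_bins: int = 10,
    threshold: float = 0.10,
    relative: bool = True,
) -> PolarHistogram:
    """Probability that a pulse changes the inter-areal phase difference by
    more than ``threshold`` (relative by default) over the first 5 cycles;
    the baseline is the rate of equally large spontaneous fluctuations."""
    return _polar(
        experiments,
        lambda e: _changed(e.pre_dphi, e.post5_dphi, threshold, relative),
        n_bins,
        lambda e: _changed(e.pre_dphi, e.spont5_dphi, threshold, relative),
        {"measure": "shifting", "threshold": threshold, "relative": relative},
    )


def switching_probability(
    experiments: list[PulseExperiment],
    lock: LockingState,
    n_bins: int = 10,
    delta: float = 0.05,
) -> PolarHistogram:
    """Probability that the 50-cycle mean phase difference lands within
    +-``delta`` of the opposite locking mode 1 - Delta-phi; the baseline is
    the spontaneous switching rate over matched windows."""
    target = 1.0 - lock.dphi_locked

    def switched(d):
        return abs(wrap_difference(d - target)) <= delta

    return _polar(
        experiments,
        lambda e: switched(e.post50_dphi),
        n_bins,
        lambda e: switched(e.spont50_dphi),
        {"measure": "switching", "delta": delta, "target": target},
    )


def spontaneous_switching_stats(
    dphi: np.ndarray,
    t: np.ndarray,
    period: float,
    smooth_cycles: float = 50.0,
    hysteresis: float = 0.05,
) -> dict:
    """Mode-change statistics of an unperturbed phase-difference series.

    The series is circularly smoothed over ``smooth_cycles`` oscillation
    periods; a switch is a sign change of the smoothed centered difference
    that passes beyond +-``hysteresis``.  Reports the mean waiting time in
    periods, or a lower bound when fewer than 2 switches occur.
    """
    z = np.exp(2j * np.pi * np.asarray(dphi))
    dt = float(t[1] - t[0])
    w = max(int(round(smooth_cycles * period / dt)), 1)
    kern = np.ones(w) / w
    zs = np.convolve(z, kern, mode="valid")
    ts = t[w - 1:]
    u = np.angle(zs) / (2 * np.pi)  # in [-0.5, 0.5): sign = mode
    state = 0
    switch_times = []
    for ti, ui in zip(ts, u):
        if state == 0 and abs(ui) > hysteresis:
            state = 1 if ui > 0 else -1
        elif state == 1 and ui < -hysteresis:
            state = -1
            switch_times.append(ti)
        elif state == -1 and ui > hysteresis:
            state = 1
            switch_times.append(ti)
    span_periods = (ts[-1] - ts[0]) / period
    if len(switch_times) >= 2:
        waits = np.diff(switch_times) / period
        return {"n_switches": len(switch_times),
                "mean_waiting_periods": float(np.mean(waits)),
                "rate_per_period": len(switch_times) / span_periods,
                "lower_bound_only": False}
    return {"n_switches": len(switch_times),
            "mean_waiting_periods": float(span_periods),
            "rate_per_period": len(switch_times) / span_periods,
            "lower_bound_only": True}


def cross_correlogram(
    lfp_a: np.ndarray, lfp_b: np.ndarray, fs: float,
    window_ms: float = 500.0, max_lag_ms: float | None = None,
) -> dict:
    """Normalized cross-correlation over the trailing ``window_ms`` window.

    Positive peak lag means area a temporally precedes (leads) area b.
    """
    n = int(window_ms * fs / 1000.0)
    a = np.asarray(lfp_a, float)[-n:]
    b = np.asarray(lfp_b, float)[-n:]
    a = (a - a.mean()) / (a.std() or 1.0)
    b = (b - b.mean()) / (b.std() or 1.0)
    full = sp_signal.correlate(b, a, mode="full") / len(a)
    lags = sp_signal.correlation_lags(len(b), len(a), mode="full") * 1000.0 / fs
    if max_lag_ms is None:
        f = netmod.oscillation_frequency(a, fs)
        max_lag_ms = 0.5 * 1000.0 / f
    sel = np.abs(lags) <= max_lag_ms
    lags, cc = lags[sel], full[sel]
    k = int(np.argmax(cc))
    peak_lag = float(lags[k])
    return {"lags_ms": lags, "correlation": cc, "peak_lag_ms": peak_lag,
            "leader": 0 if peak_lag > 0 else 1}
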