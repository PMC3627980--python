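"""Phenomenological model of the ChR2-evoked photoconductance.

The light-gated conductance is described as a product of a single-exponential
activation factor and a biphasic inactivation envelope::

    F(t) = A_act (1 - e^-(t-tON-d)/tau_act)
           * (A_persist + A1 e^-(t-tON-d)/tau1 + A2 e^-(t-tON-d)/tau2)

valid while the light is on; after light-off the conductance relaxes to zero
with a single time constant ``tau_off``.  The latency ``d``, activation time
constant ``tau_act``, amplitude ``A_act`` and the inactivating fractions
``A1``/``A2`` all depend on the relative light intensity ``W`` (expressed as a
fraction of the maximal deliverable intensity), while the two inactivation
time constants are global.  The intensity laws give the model its signature
non-monotonic peak-current dependence on light intensity, with an interior
optimum near 18 % of maximal intensity for short pulses.

Units: time in ms, voltages in mV, conductances in nS, currents in pA.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ChR2GlobalParams",
    "ChR2IntensityParams",
    "LightStimulus",
    "ConductanceTrace",
    "FitResult",
    "intensity_params",
    "conductance_timecourse",
    "photocurrent",
    "optimal_intensity",
    "calibrated_g_chr2",
    "fit_model",
    "PRINTED_G_CHR2_NS",
]

#: Conductance prefactor as printed in the source calibration (0.007 uS).
PRINTED_G_CHR2_NS = 7.0


@dataclass(frozen=True)
class ChR2GlobalParams:
    """Global (light-independent) parameters of the photoconductance model.

    Defaults are the published least-squares fit values.  ``g_chr2`` of
    ``None`` means "calibrate the prefactor so that a 3 ms pulse at the
    optimal intensity evokes a 2 nA peak photocurrent at neuronal resting
    potential" (see :func:`calibrated_g_chr2`); the printed value
    :data:`PRINTED_G_CHR2_NS` can be passed explicitly instead.
    """

    # inactivation / deactivation kinetics
    tau_inact_1: float = 9.06   # ms
    tau_inact_2: float = 59.6   # ms
    tau_off: float = 10.0       # ms
    # latency law  d(W) = d_A + d_B W + d_C / W
    d_A: float = 0.27           # ms
    d_B: float = -0.05          # ms / [W]
    d_C: float = 0.0126         # ms * [W]
    # activation law  tau_act(W) = tau_act_0 + c_act exp(-k_act W)
    tau_act_0: float = 0.74     # ms
    c_act: float = 12.0         # ms
    k_act: float = 25.0         # 1/[W]
    # amplitude law  A_act(W) = a_0 + (a_min - 1) / (1 + (W_half/W)^2)
    a_0: float = 1.00
    a_min: float = 0.4
    W_half: float = 0.38        # [W]
    # first inactivating fraction  A1(W) = b_0 + b_1 / (b_2 + (W - W_inact)^2)
    b_0: float = 0.16
    b_1: float = 0.013          # [W]^2
    b_2: float = 0.027          # [W]^2
    W_inact: float = 0.11       # [W]
    # second inactivating fraction  A2(W) = c_inact exp(-k_inact W)
    c_inact: float = 0.29
    k_inact: float = 2.4        # 1/[W]
    # coupling
    g_chr2: float | None = None  # nS; None => calibrated (see module docstring)
    V_chr2: float = 0.0          # mV

    def __post_init__(self) -> None:
        for name in ("tau_inact_1", "tau_inact_2", "tau_off", "tau_act_0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ChR2IntensityParams:
    """Intensity-dependent parameters at one relative light intensity."""

    W: float
    d: float          # latency, ms (clipped at 0)
    tau_act: float    # ms
    A_act: float
    A_inact_1: float
    A_inact_2: float

    @property
    def A_persist(self) -> float:
        # complement rule keeps the inactivation envelope non-negative
        return 1.0 - self.A_inact_1 - self.A_inact_2


def intensity_params(W: float, params: ChR2GlobalParams | None = None) -> ChR2IntensityParams:
    """Evaluate the intensity laws at relative intensity ``W`` in (0, 1]."""
    p = params or ChR2GlobalParams()
    if not 0.0 < W <= 1.0:
        raise ValueError(f"relative intensity must lie in (0, 1], got {W}")
    d = p.d_A + p.d_B * W + p.d_C / W
    tau_act = p.tau_act_0 + p.c_act * math.exp(-p.k_act * W)
    A_act = p.a_0 + (p.a_min - 1.0) / (1.0 + (p.W_half / W) ** 2)
    A1 = p.b_0 + p.b_1 / (p.b_2 + (W - p.W_inact) ** 2)
    A2 = p.c_inact * math.exp(-p.k_inact * W)
    return ChR2IntensityParams(
        W=W, d=max(d, 0.0), tau_act=tau_act, A_act=A_act,
        A_inact_1=A1, A_inact_2=A2,
    )


@dataclass(frozen=True)
class LightStimulus:
    """Piecewise-constant light waveform.

    ``segments`` is a time-ordered, non-overlapping sequence of
    ``(t_on, duration, W)`` triples with relative intensity ``W`` in [0, 1].
    Ramps are represented as many short constant segments
    (:meth:`ramp`).
    """

    segments: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for t_on, dur, w in self.segments:
            if dur <= 0:
                raise ValueError("segment duration must be positive")
            if not 0.0 <= w <= 1.0:
                raise ValueError("relative intensity must lie in [0, 1]")
            if t_on < prev_end - 1e-9:
                raise ValueError("segments must be time-ordered and non-overlapping")
            prev_end = t_on + dur

    @classmethod
    def pulse(cls, t_on: float, duration: float, W: float) -> "LightStimulus":
        """Single rectangular pulse."""
        return cls(((t_on, duration, W),))

    @classmethod
    def ramp(cls, t_on: float, duration: float, W_start: float, W_end: float,
             resolution: float = 1.0) -> "LightStimulus":
        """Linear intensity ramp sampled as constant segments of ``resolution`` ms."""
        n = max(int(round(duration / resolution)), 1)
        edges = np.linspace(0.0, duration, n + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        levels = W_start + (W_end - W_start) * mids / duration
        segs = tuple(
            (t_on + float(edges[i]), float(edges[i + 1] - edges[i]), float(np.clip(levels[i], 0, 1)))
            for i in range(n)
        )
        return cls(segs)

    @property
    def end_time(self) -> float:
        if not self.segments:
            return 0.0
        t_on, dur, _ = self.segments[-1]
        return t_on + dur


@dataclass
class ConductanceTrace:
    """Dimensionless conductance factor F sampled on a time grid (ms)."""

    time: np.ndarray
    F: np.ndarray


def _envelope(ip: ChR2IntensityParams, i1: float, i2: float) -> float:
    return ip.A_persist + ip.A_inact_1 * i1 + ip.A_inact_2 * i2


def conductance_timecourse(
    stim: LightStimulus,
    grid: np.ndarray,
    params: ChR2GlobalParams | None = None,
) -> ConductanceTrace:
    """Evaluate the conductance factor F(t) for an arbitrary light waveform.

    Piecewise-exponential stepping is exact between events (segment
    boundaries, latency expirations, grid samples), so single rectangular
    pulses reproduce the closed form to machine precision.  Conductance state
    is continuous across contiguous segment boundaries (ramps); across dark
    gaps F decays with ``tau_off`` and the latency and inactivation envelope
    restart at the next dark-to-light transition.
    """
    p = params or ChR2GlobalParams()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a non-empty strictly increasing 1-d array")
    out = np.zeros_like(grid)
    if not stim.segments:
        return ConductanceTrace(grid, out)

    # precompute intensity params and effective-onset (latency) per segment;
    # latency applies only at dark->light transitions
    seg_params: list[ChR2IntensityParams | None] = []
    eff_on: list[float] = []
    prev_end = None
    for t_on, dur, w in stim.segments:
        if w <= 0:
            seg_params.append(None)
            eff_on.append(t_on)
        else:
            ip = intensity_params(w, p)
            contiguous = prev_end is not None and abs(t_on - prev_end) < 1e-9
            seg_params.append(ip)
            eff_on.append(t_on if contiguous else t_on + ip.d)
        prev_end = t_on + dur

    events = set()
    for (t_on, dur, _), e in zip(stim.segments, eff_on):
        events.update((t_on, e, t_on + dur))
    times = np.unique(np.concatenate([grid, np.fromiter(events, float)]))

    def regime_at(t: float):
        """Return the active intensity params at time t, or None (dark/latent)."""
        for (t_on, dur, _), ip, e in zip(stim.segments, seg_params, eff_on):
            if t_on - 1e-12 <= t < t_on + dur - 1e-12:
                if ip is None or t < e - 1e-12:
                    return None
                return ip
        return None

    F = 0.0
    i1 = i2 = 1.0
    u = 0.0
    active: ChR2IntensityParams | None = None
    grid_idx = {t: k for k, t in enumerate(grid)}
    for j, t in enumerate(times):
        if j > 0:
            dt = t - times[j - 1]
            if active is None:
                F *= math.exp(-dt / p.tau_off)
            else:
                u = 1.0 + (u - 1.0) * math.exp(-dt / active.tau_act)
                i1 *= math.exp(-dt / p.tau_inact_1)
                i2 *= math.exp(-dt / p.tau_inact_2)
                F = active.A_act * u * _envelope(active, i1, i2)
        new = regime_at(t)
        if new is not active:
            if new is not None:
                if active is None and F < 1e-15:
                    i1 = i2 = 1.0  # fresh pulse: envelope restarts at unity
                # continuity: choose activation level reproducing current F
                env = _envelope(new, i1, i2)
                u = F / (new.A_act * env) if new.A_act * env > 0 else 0.0
                u = min(max(u, 0.0), 1.0)
            active = new
        k = grid_idx.get(t)
        if k is not None:
            out[k] = F
    return ConductanceTrace(grid, out)


def photocurrent(
    trace: ConductanceTrace,
    V: float | np.ndarray,
    g: float,
    V_rev: float = 0.0,
) -> np.ndarray:
    """Photocurrent I = -g F (V - V_rev) in pA (g in nS, V in mV).

    Positive current is depolarizing in the membrane-equation sign
    convention, so an inward current at rest (V < V_rev) is positive.
    """
    if g < 0:
        raise ValueError("conductance prefactor must be non-negative")
    return -g * trace.F * (np.asarray(V, dtype=float) - V_rev)


def _single_pulse_peak_F(W: float, duration: float, p: ChR2GlobalParams) -> float:
    """Peak of F during a rectangular pulse of ``duration`` ms (closed form)."""
    ip = intensity_params(W, p)
    if duration <= ip.d:
        return 0.0
    t = np.linspace(0.0, duration - ip.d, max(int(duration * 20), 200))
    act = ip.A_act * (1.0 - np.exp(-t / ip.tau_act))
    env = (ip.A_persist
           + ip.A_inact_1 * np.exp(-t / p.tau_inact_1)
           + ip.A_inact_2 * np.exp(-t / p.tau_inact_2))
    return float(np.max(act * env))


def optimal_intensity(
    pulse_duration: float,
    params: ChR2GlobalParams | None = None,
    clamp_mV: float = -60.0,
    n_scan: int = 400,
) -> float:
    """Relative intensity maximizing the peak photocurrent for a given pulse.

    The clamp voltage only scales the current, so the argmax is that of the
    peak conductance; a dense scan over (0, 1] is refined by parabolic
    interpolation around the maximum.  Deterministic.
    """
    if pulse_duration <= 0:
        raise ValueError("pulse_duration must be positive")
    p = params or ChR2GlobalParams()
    Ws = np.unique(np.concatenate([
        np.geomspace(0.01, 1.0, n_scan // 2),
        np.linspace(0.01, 1.0, n_scan // 2),
    ]))
    peaks = np.array([_single_pulse_peak_F(w, pulse_duration, p) for w in Ws])
    k = int(np.argmax(peaks))
    if 0 < k < len(Ws) - 1:
        x0, x1, x2 = Ws[k - 1:k + 2]
        y0, y1, y2 = peaks[k - 1:k + 2]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
        if a < 0:
            w_star = -b / (2 * a)
            if x0 <= w_star <= x2:
                return float(w_star)
    return float(Ws[k])


@functools.lru_cache(maxsize=8)
def calibrated_g_chr2(
    params: ChR2GlobalParams | None = None,
    v_rest: float = -64.0,
    target_peak_pA: float = 2000.0,
    pulse_duration: float = 3.0,
) -> float:
    """Conductance prefactor (nS) such that an optimal-intensity pulse of
    ``pulse_duration`` ms evokes ``target_peak_pA`` peak photocurrent in a
    neuron at rest."""
    p = params or ChR2GlobalParams()
    w_star = optimal_intensity(pulse_duration, p)
    peak_F = _single_pulse_peak_F(w_star, pulse_duration, p)
    return target_peak_pA / (peak_F * abs(v_rest - p.V_chr2))


def effective_g_chr2(params: ChR2GlobalParams | None = None, v_rest: float = -64.0) -> float:
    """Resolve the prefactor: explicit value if set, calibrated otherwise."""
    p = params or ChR2GlobalParams()
    if p.g_chr2 is not None:
        return p.g_chr2
    return calibrated_g_chr2(p, v_rest=v_rest)


# ---------------------------------------------------------------------------
# Model fitting (validated on synthetic voltage-clamp conductance traces)
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    globals_fit: ChR2GlobalParams
    per_intensity: dict[float, ChR2IntensityParams]
    rss: float
    stderr: dict[str, float]
    intensity_law_fitted: bool
    message: str = ""


def _trace_model(t, d, tau_act, A_act, A1, A2, tau1, tau2):
    tt = np.maximum(t - d, 0.0)
    on = t >= d
    act = A_act * (1.0 - np.exp(-tt / tau_act))
    env = (1.0 - A1 - A2) + A1 * np.exp(-tt / tau1) + A2 * np.exp(-tt / tau2)
    return np.where(on, act * env, 0.0)


def fit_model(
    traces: Sequence[tuple[float, np.ndarray, np.ndarray]],
    params0: ChR2GlobalParams | None = None,
    fix_k_inact: bool = True,
    n_starts: int = 3,
    seed: int = 0,
) -> FitResult:
    """Fit the conductance model to (W, t, F) voltage-clamp traces.

    Stage 1 fits all traces simultaneously with the two inactivation time
    constants shared (global) and (d, tau_act, A_act, A1, A2) free per
    intensity.  Stage 2 fits the intensity laws to the per-intensity values
    (requires >= 4 intensities spanning at least one decade); ``k_inact`` is
    held fixed by default to aid convergence.  Bounded least squares with a
    small number of perturbed restarts guards against local minima.
    """
    if len(traces) == 0:
        raise ValueError("no traces supplied")
    p0 = params0 or ChR2GlobalParams()
    rng = np.random.default_rng(seed)
    n_tr = len(traces)

    def unpack(x):
        tau1, tau2 = x[0], x[1]
        per = x[2:].reshape(n_tr, 5)
        return tau1, tau2, per

    def resid(x):
        tau1, tau2, per = unpack(x)
        rs = []
        for (w, t, f), (d, ta, aa, a1, a2) in zip(traces, per):
            rs.append(_trace_model(np.asarray(t, float), d, ta, aa, a1, a2, tau1, tau2)
                      - np.asarray(f, float))
        return np.concatenate(rs)

    x0 = [p0.tau_inact_1, p0.tau_inact_2]
    for w, _, _ in traces:
        ip = intensity_params(min(max(w, 1e-3), 1.0), p0)
        x0.extend([ip.d, ip.tau_act, ip.A_act, ip.A_inact_1, ip.A_inact_2])
    x0 = np.asarray(x0)
    lb = np.concatenate([[0.5, 5.0], np.tile([0.0, 0.05, 0.01, 0.0, 0.0], n_tr)])
    ub = np.concatenate([[50.0, 500.0], np.tile([5.0, 20.0, 2.0, 0.95, 0.95], n_tr)])

    best = None
    for trial in range(n_starts):
        xi = x0 if trial == 0 else np.clip(x0 * rng.uniform(0.7, 1.4, x0.shape), lb, ub)
        try:
            sol = least_squares(resid, xi, bounds=(lb, ub), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError("stage 1 (joint trace fit) failed to converge")

    tau1, tau2, per = unpack(best.x)
    rss = float(2 * best.cost)
    per_intensity = {
        float(w): ChR2IntensityParams(W=float(w), d=float(d), tau_act=float(ta),
                                      A_act=float(aa), A_inact_1=float(a1),
                                      A_inact_2=float(a2))
        for (w, _, _), (d, ta, aa, a1, a2) in zip(traces, per)
    }

    # approximate standard errors from the stage-1 jacobian
    stderr: dict[str, float] = {}
    try:
        J = best.jac
        dof = max(J.shape[0] - J.shape[1], 1)
        s2 = rss / dof
        cov = s2 * np.linalg.pinv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        stderr["tau_inact_1"] = float(se[0])
        stderr["tau_inact_2"] = float(se[1])
    except np.linalg.LinAlgError:
        pass

    g = replace(p0, tau_inact_1=float(tau1), tau_inact_2=float(tau2))
    ws = np.array(sorted(per_intensity))
    law_ok = len(ws) >= 4 and ws.max() / ws.min() >= 10.0
    msg = ""
    if law_ok:
        g, law_err = _fit_intensity_laws(per_intensity, g, fix_k_inact)
        msg = law_err or "intensity laws fitted"
    else:
        msg = "insufficient intensities for the intensity-law stage (need >= 4 spanning a decade)"
    return FitResult(globals_fit=g, per_intensity=per_intensity, rss=rss,
                     stderr=stderr, intensity_law_fitted=law_ok and not msg.startswith("law"),
                     message=msg)


def _fit_intensity_laws(per, g: ChR2GlobalParams, fix_k_inact: bool):
    ws = np.array(sorted(per))
    d = np.array([per[w].d for w in ws])
    ta = np.array([per[w].tau_act for w in ws])
    aa = np.array([per[w].A_act for w in ws])
    a1 = np.array([per[w].A_inact_1 for w in ws])
    a2 = np.array([per[w].A_inact_2 for w in ws])

    def fit(fun, x0, y, bounds=(-np.inf, np.inf)):
        sol = least_squares(lambda x: fun(x, ws) - y, x0, bounds=bounds)
        if not sol.success:
            raise RuntimeError
        return sol.x

    try:
        dA, dB, dC = fit(lambda x, w: x[0] + x[1] * w + x[2] / w, [g.d_A, g.d_B, g.d_C], d)
        t0, ca, ka = fit(lambda x, w: x[0] + x[1] * np.exp(-x[2] * w),
                         [g.tau_act_0, g.c_act, g.k_act], ta,
                         bounds=([1e-3, 1e-3, 0.1], [20, 100, 200]))
        a0, am, wh = fit(lambda x, w: x[0] + (x[1] - 1) / (1 + (x[2] / w) ** 2),
                         [g.a_0, g.a_min, g.W_half], aa,
                         bounds=([0.1, 0.0, 0.01], [3, 1.0, 5]))
        b0, b1, b2, wi = fit(lambda x, w: x[0] + x[1] / (x[2] + (w - x[3]) ** 2),
                             [g.b_0, g.b_1, g.b_2, g.W_inact], a1,
                             bounds=([0, 1e-5, 1e-4, 0.0], [1, 1, 1, 1]))
        if fix_k_inact:
            ci = fit(lambda x, w: x[0] * np.exp(-g.k_inact * w), [g.c_inact], a2)[0]
            ki = g.k_inact
        else:
            ci, ki = fit(lambda x, w: x[0] * np.exp(-x[1] * w), [g.c_inact, g.k_inact], a2,
                         bounds=([1e-4, 0.01], [5, 50]))
    except RuntimeError:
        return g, "law-stage fit failed to converge"
    g = replace(g, d_A=float(dA), d_B=float(dB), d_C=float(dC),
                tau_act_0=float(t0), c_act=float(ca), k_act=float(ka),
                a_0=float(a0), a_min=float(am), W_half=float(wh),
                b_0=float(b0), b_1=float(b1), b_2=float(b2), W_inact=float(wi),
                c_inact=float(ci), k_inact=float(ki))
    return g, ""
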