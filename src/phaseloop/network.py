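"""Spiking networks of Wang-Buzsaki neurons with partial ChR2 transduction.

One or two local areas of randomly connected excitatory (AMPA) and inhibitory
(GABA) conductance-based neurons, driven by independent Poisson background
input.  With strong, delayed recurrent inhibition the population undergoes
interneuron-generated (ING) gamma oscillations; the "LFP" is defined as the
average membrane potential of all neurons of an area.  A configurable
fraction of neurons (the transduction rate ``P_chr2``) carries the ChR2
photoconductance of :mod:`phaseloop.chr2` and responds to a per-area light
schedule.

Design notes
------------
* All stochastic elements (topology, transduction mask, Poisson noise,
  initial conditions) are functions of named seeds.  Background noise is
  generated in fixed chunks keyed by ``(noise_seed, chunk_index)`` so a
  perturbed run continued from a checkpoint consumes bit-identical noise:
  paired runs differ only through the photocurrent.
* Synaptic peak conductances are interpreted in nanosiemens.  The printed
  microsiemens values (g_E = 0.5, g_I = 18, g_noise = 0.5) would deliver
  per-synapse inputs orders of magnitude above the leak conductance; the
  nanosiemens reading preserves the printed ratios and reproduces the target
  regime (gamma 40-70 Hz, excitatory rates 1-3 Hz).  The literal reading is
  selectable via ``literal_microsiemens``.
* Down-scaled networks keep the product (in-degree x peak conductance)
  invariant per synapse class by multiplying recurrent conductances with
  ``N_E_ref / N_E`` (background noise and photoconductance are per-neuron and
  are not rescaled).
* Integration: exponential Euler for the gating variables, forward Euler for
  the membrane potential, fixed ``dt`` (default 0.05 ms).  Spikes are upward
  crossings of -20 mV.

Units: ms, mV, nS, pF, pA; rates in kHz for the noise drive, Hz elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import signal as sp_signal

from . import chr2 as chr2mod

__all__ = [
    "Seeds",
    "WBNeuronParams",
    "SynapseParams",
    "NetworkConfig",
    "Connectivity",
    "NetworkState",
    "SimulationResult",
    "build_connectivity",
    "synaptic_kernel",
    "simulate",
    "continue_run",
    "synchronization_index",
    "oscillation_frequency",
    "regime_scan",
    "ramp_stimulation",
    "wb_steady_state_current",
]

NOISE_CHUNK_STEPS = 20_000  # 1 s at dt = 0.05 ms


@dataclass(frozen=True)
class Seeds:
    topology: int = 11
    noise: int = 12
    transduction: int = 13
    init: int = 14


@dataclass(frozen=True)
class WBNeuronParams:
    """Single-compartment Wang-Buzsaki neuron (instantaneous Na activation)."""

    C: float = 100.0      # pF
    g_L: float = 10.0     # nS (0.01 uS)
    V_L: float = -65.0    # mV
    g_Na: float = 3500.0  # nS
    V_Na: float = 55.0    # mV
    g_K: float = 900.0    # nS
    V_K: float = -90.0    # mV
    phi: float = 5.0      # gating temperature factor


@dataclass(frozen=True)
class SynapseParams:
    tau_rise: float   # ms
    tau_decay: float  # ms
    g_peak: float     # nS
    V_rev: float      # mV
    d_syn: float      # ms

    def __post_init__(self) -> None:
        if not self.tau_decay > self.tau_rise > 0:
            raise ValueError("require tau_decay > tau_rise > 0")


def _kernel_norm(tau_r: float, tau_d: float) -> float:
    """Normalization making the difference-of-exponentials kernel peak at 1."""
    if tau_r == tau_d:
        raise ValueError("degenerate kernel: tau_rise == tau_decay")
    tp = tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)
    return 1.0 / (math.exp(-tp / tau_d) - math.exp(-tp / tau_r))


def synaptic_kernel(t: np.ndarray | float, params: SynapseParams) -> np.ndarray:
    """Peak-normalized postsynaptic conductance factor at time ``t`` after the
    presynaptic spike (zero before the delay ``d_syn`` has elapsed)."""
    t = np.asarray(t, dtype=float)
    norm = _kernel_norm(params.tau_rise, params.tau_decay)
    tt = t - params.d_syn
    val = norm * (np.exp(-tt / params.tau_decay) - np.exp(-tt / params.tau_rise))
    return np.where(tt >= 0, val, 0.0)


@dataclass(frozen=True)
class NetworkConfig:
    """Network topology, drive and transduction parameters (per area)."""

    n_areas: int = 1
    N_E: int = 400
    N_I: int | None = None          # default N_E / 4
    P_E: float = 0.12
    P_I: float = 0.3
    P_E_lr: float = 0.06            # long-range, excitatory sources only
    nu_noise: float = 3.0           # kHz per neuron
    g_noise: float = 0.5            # nS (not rescaled)
    g_E: float = 0.5                # nS at reference size
    g_I: float = 18.0               # nS at reference size
    tau_rise_E: float = 1.0
    tau_decay_E: float = 3.0
    tau_rise_I: float = 1.0
    tau_decay_I: float = 4.0
    V_rev_E: float = 0.0
    V_rev_I: float = -80.0
    d_syn_local: float = 1.5        # ms
    d_syn_lr: float = 1.0           # ms
    P_chr2: float = 0.0
    N_E_ref: int = 4000             # reference size for conductance compensation
    compensate: bool = True
    literal_microsiemens: bool = False
    dt: float = 0.05                # ms
    seeds: Seeds = field(default_factory=Seeds)
    neuron: WBNeuronParams = field(default_factory=WBNeuronParams)
    chr2_params: chr2mod.ChR2GlobalParams = field(default_factory=chr2mod.ChR2GlobalParams)

    def __post_init__(self) -> None:
        if self.n_areas not in (1, 2):
            raise ValueError("n_areas must be 1 or 2")
        for p in (self.P_E, self.P_I, self.P_E_lr, self.P_chr2):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.N_I is None:
            object.__setattr__(self, "N_I", self.N_E // 4)

    @property
    def n_per_area(self) -> int:
        return self.N_E + self.N_I  # type: ignore[operator]

    @property
    def n_total(self) -> int:
        return self.n_per_area * self.n_areas

    @property
    def scale_comp(self) -> float:
        return self.N_E_ref / self.N_E if self.compensate else 1.0

    def conductances(self) -> tuple[float, float, float]:
        """Effective (g_E, g_I, g_noise) in nS after unit reading and scaling."""
        unit = 1000.0 if self.literal_microsiemens else 1.0
        c = self.scale_comp
        return self.g_E * unit * c, self.g_I * unit * c, self.g_noise * unit

    def g_chr2_effective(self) -> float:
        return chr2mod.effective_g_chr2(self.chr2_params)


@dataclass
class Connectivity:
    """CSR adjacency (source-major) with per-edge delays, plus masks."""

    indptr: np.ndarray     # int64, len n_total + 1
    indices: np.ndarray    # int32 targets
    delay_steps: np.ndarray  # int32 per edge
    is_exc: np.ndarray     # bool per neuron
    area: np.ndarray       # int32 per neuron
    kappa: np.ndarray      # float64 transduction mask (0/1)
    buf_len: int


def build_connectivity(config: NetworkConfig) -> Connectivity:
    """Draw the random graph, delays and transduction mask from the seeds.

    Each directed pair is connected independently with its class probability;
    inhibitory neurons never project across areas, only excitatory neurons
    form long-range connections.  Self-connections are excluded.
    """
    cfg = config
    n = cfg.n_total
    npa = cfg.n_per_area
    is_exc = np.zeros(n, dtype=np.bool_)
    area = np.zeros(n, dtype=np.int32)
    for a in range(cfg.n_areas):
        is_exc[a * npa: a * npa + cfg.N_E] = True
        area[a * npa: (a + 1) * npa] = a

    dt = cfg.dt
    d_local = max(int(round(cfg.d_syn_local / dt)), 1)
    d_lr = max(int(round(cfg.d_syn_lr / dt)), 1)
    rng = np.random.default_rng(cfg.seeds.topology)

    indptr = np.zeros(n + 1, dtype=np.int64)
    idx_chunks: list[np.ndarray] = []
    dly_chunks: list[np.ndarray] = []
    all_ids = np.arange(n, dtype=np.int32)
    for j in range(n):
        a = area[j]
        local = all_ids[(area == a) & (all_ids != j)]
        p = cfg.P_E if is_exc[j] else cfg.P_I
        sel = local[rng.random(local.size) < p]
        tgts = [sel]
        dlys = [np.full(sel.size, d_local, dtype=np.int32)]
        if is_exc[j] and cfg.n_areas == 2:
            remote = all_ids[area != a]
            sel_lr = remote[rng.random(remote.size) < cfg.P_E_lr]
            tgts.append(sel_lr)
            dlys.append(np.full(sel_lr.size, d_lr, dtype=np.int32))
        tj = np.concatenate(tgts)
        idx_chunks.append(tj.astype(np.int32))
        dly_chunks.append(np.concatenate(dlys))
        indptr[j + 1] = indptr[j] + tj.size

    rng_t = np.random.default_rng(cfg.seeds.transduction)
    kappa = (rng_t.random(n) < cfg.P_chr2).astype(np.float64)

    return Connectivity(
        indptr=indptr,
        indices=np.concatenate(idx_chunks) if idx_chunks else np.empty(0, np.int32),
        delay_steps=np.concatenate(dly_chunks) if dly_chunks else np.empty(0, np.int32),
        is_exc=is_exc,
        area=area,
        kappa=kappa,
        buf_len=max(d_local, d_lr) + 1,
    )


# ---------------------------------------------------------------------------
# Numba core
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _vtrap(x):
    # x / (1 - exp(-x)) with the removable singularity handled
    if abs(x) < 1e-6:
        return 1.0 + 0.5 * x
    return x / (1.0 - math.exp(-x))


@njit(cache=True, fastmath=True)
def _integrate(V, h, n_g, aer, aed, air, aid_, anr, and_,
               bufe, bufi, start_step, n_steps, dt,
               indptr, indices, delay_steps, is_exc, area, kappa,
               C, gL, VL, gNa, VNa, gK, VK, phi,
               gE, gI, gN, normE, normI, VrevE, VrevI,
               fr_e, fd_e, fr_i, fd_i,
               noise, noise_offset,
               F_light, g_chr2,
               rec_every, lfp_out, rec_offset,
               vsum, vsumsq,
               spike_ids, spike_steps, n_spikes_in):
    N = V.shape[0]
    L = bufe.shape[0]
    n_areas = lfp_out.shape[0]
    n_sp = n_spikes_in
    max_sp = spike_ids.shape[0]
    rec_i = rec_offset
    for i in range(n_steps):
        gstep = start_step + i
        pos = gstep % L
        # synaptic filter decay + delivery of delayed spikes and noise events
        for k in range(N):
            be = bufe[pos, k]
            bi = bufi[pos, k]
            nz = float(noise[noise_offset + i, k])
            aer[k] = aer[k] * fr_e + be
            aed[k] = aed[k] * fd_e + be
            air[k] = air[k] * fr_i + bi
            aid_[k] = aid_[k] * fd_i + bi
            anr[k] = anr[k] * fr_e + nz
            and_[k] = and_[k] * fd_e + nz
            bufe[pos, k] = 0.0
            bufi[pos, k] = 0.0
        # membrane + gating update, spike detection
        for k in range(N):
            v = V[k]
            ge_t = gE * normE * (aed[k] - aer[k])
            gi_t = gI * normI * (aid_[k] - air[k])
            gn_t = gN * normE * (and_[k] - anr[k])
            g_ch = 0.0
            if kappa[k] > 0.0:
                g_ch = g_chr2 * F_light[area[k], i]
            am = _vtrap(0.1 * (v + 35.0))  # 0.1(v+35)/(1-exp(-0.1(v+35)))
            bm = 4.0 * math.exp(-(v + 60.0) / 18.0)
            m_inf = am / (am + bm)
            ah = 0.07 * math.exp(-(v + 58.0) / 20.0)
            bh = 1.0 / (math.exp(-0.1 * (v + 28.0)) + 1.0)
            an = 0.1 * _vtrap(0.1 * (v + 34.0))
            bn = 0.125 * math.exp(-(v + 44.0) / 80.0)
            hk = h[k]
            nk = n_g[k]
            g_na = gNa * m_inf * m_inf * m_inf * hk
            g_k = gK * nk * nk * nk * nk
            # exponential Euler on V: all terms are conductance-based, so the
            # update is stable even during synchronous inhibitory volleys
            g_tot = gL + g_na + g_k + ge_t + gi_t + gn_t + g_ch
            v_eq = (gL * VL + g_na * VNa + g_k * VK + gi_t * VrevI
                    + (ge_t + gn_t) * VrevE) / g_tot
            v_new = v_eq + (v - v_eq) * math.exp(-dt * g_tot / C)
            # exponential Euler for the gates at the pre-step voltage
            th = ah + bh
            h_inf = ah / th
            h[k] = h_inf + (hk - h_inf) * math.exp(-dt * phi * th)
            tn = an + bn
            n_inf = an / tn
            n_g[k] = n_inf + (nk - n_inf) * math.exp(-dt * phi * tn)
            if v_new > 200.0 or v_new < -200.0 or v_new != v_new:
                return n_sp, 1, rec_i  # numerical blow-up
            if v_new >= -20.0 and v < -20.0:
                if n_sp >= max_sp:
                    return n_sp, 2, rec_i  # spike buffer overflow
                spike_ids[n_sp] = k
                spike_steps[n_sp] = gstep
                n_sp += 1
                for e in range(indptr[k], indptr[k + 1]):
                    tgt = indices[e]
                    dpos = (pos + delay_steps[e]) % L
                    if is_exc[k]:
                        bufe[dpos, tgt] += 1.0
                    else:
                        bufi[dpos, tgt] += 1.0
            V[k] = v_new
        if (gstep + 1) % rec_every == 0:
            for a in range(n_areas):
                lfp_out[a, rec_i] = 0.0
            for k in range(N):
                lfp_out[area[k], rec_i] += V[k]
                vsum[k] += V[k]
                vsumsq[k] += V[k] * V[k]
            for a in range(n_areas):
                lfp_out[a, rec_i] /= N / n_areas
            rec_i += 1
    return n_sp, 0, rec_i


# ---------------------------------------------------------------------------
# State, results and the simulation driver
# ---------------------------------------------------------------------------

@dataclass
class NetworkState:
    """Complete dynamical state at one global time step (checkpointable)."""

    step: int
    V: np.ndarray
    h: np.ndarray
    n: np.ndarray
    syn: tuple[np.ndarray, ...]   # aer, aed, air, aid, anr, and
    bufe: np.ndarray
    bufi: np.ndarray

    def copy(self) -> "NetworkState":
        return NetworkState(
            step=self.step, V=self.V.copy(), h=self.h.copy(), n=self.n.copy(),
            syn=tuple(s.copy() for s in self.syn),
            bufe=self.bufe.copy(), bufi=self.bufi.copy(),
        )


@dataclass
class SimulationResult:
    config: NetworkConfig
    t_lfp: np.ndarray              # ms, record grid
    lfp: np.ndarray                # (n_areas, n_rec) mean membrane potential
    spike_ids: np.ndarray
    spike_times: np.ndarray        # ms
    v_sum: np.ndarray              # per-neuron accumulators over record samples
    v_sumsq: np.ndarray
    n_rec: int
    state: NetworkState
    checkpoints: dict[float, NetworkState]
    light_log: list[tuple[int, chr2mod.LightStimulus]]
    duration: float

    @property
    def fs_lfp(self) -> float:
        """LFP sampling rate in Hz."""
        dt_rec = float(self.t_lfp[1] - self.t_lfp[0]) if len(self.t_lfp) > 1 else 1.0
        return 1000.0 / dt_rec

    def chi(self) -> float:
        """Synchronization index from the accumulated per-neuron statistics
        and the recorded LFP (single-area convenience; areas pooled)."""
        m = self.n_rec
        var_i = self.v_sumsq / m - (self.v_sum / m) ** 2
        lfp_all = self.lfp.mean(axis=0)
        return float(np.var(lfp_all) / np.mean(var_i))

    def rates(self) -> dict[str, float]:
        """Mean firing rate (Hz) by class, pooled over areas."""
        cfg = self.config
        npa = cfg.n_per_area
        within = np.mod(self.spike_ids, npa)
        exc = within < cfg.N_E
        dur_s = self.duration / 1000.0
        ne = cfg.N_E * cfg.n_areas
        ni = (npa - cfg.N_E) * cfg.n_areas
        return {
            "E": float(np.sum(exc)) / (ne * dur_s),
            "I": float(np.sum(~exc)) / (ni * dur_s),
        }


def _initial_state(cfg: NetworkConfig, conn: Connectivity) -> NetworkState:
    n = cfg.n_total
    rng = np.random.default_rng(cfg.seeds.init)
    V = rng.uniform(-70.0, -55.0, n)
    h = np.empty(n)
    ng = np.empty(n)
    for k in range(n):
        _, h_inf, n_inf = gating_steady_state(V[k])
        h[k] = h_inf
        ng[k] = n_inf
    syn = tuple(np.zeros(n) for _ in range(6))
    L = conn.buf_len
    return NetworkState(step=0, V=V, h=h, n=ng, syn=syn,
                        bufe=np.zeros((L, n)), bufi=np.zeros((L, n)))


def gating_steady_state(v: float) -> tuple[float, float, float]:
    """(m_inf, h_inf, n_inf) of the Wang-Buzsaki gating at voltage ``v``."""
    am = _am(v)
    bm = 4.0 * math.exp(-(v + 60.0) / 18.0)
    ah = 0.07 * math.exp(-(v + 58.0) / 20.0)
    bh = 1.0 / (math.exp(-0.1 * (v + 28.0)) + 1.0)
    an = _an(v)
    bn = 0.125 * math.exp(-(v + 44.0) / 80.0)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def _am(v: float) -> float:
    x = 0.1 * (v + 35.0)
    return (1.0 + 0.5 * x if abs(x) < 1e-6 else x / (1.0 - math.exp(-x)))


def _an(v: float) -> float:
    x = 0.1 * (v + 34.0)
    return 0.1 * (1.0 + 0.5 * x if abs(x) < 1e-6 else x / (1.0 - math.exp(-x)))


def wb_steady_state_current(v: float, p: WBNeuronParams | None = None) -> float:
    """Total intrinsic membrane current at voltage ``v`` with gates at their
    steady state; its root is the resting potential."""
    p = p or WBNeuronParams()
    m_inf, h_inf, n_inf = gating_steady_state(v)
    return -(p.g_L * (v - p.V_L)
             + p.g_Na * m_inf ** 3 * h_inf * (v - p.V_Na)
             + p.g_K * n_inf ** 4 * (v - p.V_K))


_NOISE_CACHE: "dict[tuple, np.ndarray]" = {}
_NOISE_CACHE_MAX = 6


def _noise_chunk(cfg: NetworkConfig, chunk_idx: int) -> np.ndarray:
    """Poisson event counts for one fixed-size chunk of the noise stream.

    Keyed by (seed, chunk, size, rate, dt) so paired perturbed/unperturbed
    runs re-use bit-identical chunks; a tiny LRU cache avoids regenerating
    them for every continuation run.
    """
    key = (cfg.seeds.noise, chunk_idx, cfg.n_total, cfg.nu_noise, cfg.dt)
    hit = _NOISE_CACHE.get(key)
    if hit is not None:
        return hit
    rng = np.random.default_rng([cfg.seeds.noise, chunk_idx])
    lam = cfg.nu_noise * cfg.dt
    counts = rng.poisson(lam, (NOISE_CHUNK_STEPS, cfg.n_total)).astype(np.uint8)
    if len(_NOISE_CACHE) >= _NOISE_CACHE_MAX:
        _NOISE_CACHE.pop(next(iter(_NOISE_CACHE)))
    _NOISE_CACHE[key] = counts
    return counts


def _light_F(cfg: NetworkConfig, light, start_step: int, n_steps: int) -> np.ndarray:
    """Per-area scalar conductance-factor drive on the simulation grid."""
    F = np.zeros((cfg.n_areas, n_steps))
    if not light:
        return F
    t_grid = (start_step + np.arange(n_steps)) * cfg.dt
    for a, stim in light.items():
        if stim is None or not stim.segments:
            continue
        tr = chr2mod.conductance_timecourse(stim, t_grid, cfg.chr2_params)
        F[a] = tr.F
    return F


def simulate(
    config: NetworkConfig,
    duration: float,
    light: Mapping[int, chr2mod.LightStimulus] | None = None,
    state: NetworkState | None = None,
    conn: Connectivity | None = None,
    record_dt: float = 1.0,
    checkpoint_times: Sequence[float] = (),
    max_rate_hz: float = 120.0,
) -> SimulationResult:
    """Integrate the network for ``duration`` ms.

    ``state`` continues a previous run (frozen noise guaranteed: the noise
    stream is addressed by absolute step index).  ``checkpoint_times`` are
    absolute times (ms, quantized to the grid) at which full state copies are
    returned for later perturbed continuations.
    """
    cfg = config
    if conn is None:
        conn = build_connectivity(cfg)
    if state is None:
        state = _initial_state(cfg, conn)
    else:
        state = state.copy()
    if light:
        for a in light:
            if not 0 <= a < cfg.n_areas:
                raise ValueError(f"light schedule references invalid area {a}")

    dt = cfg.dt
    n_steps = int(round(duration / dt))
    start_step = state.step
    rec_every = max(int(round(record_dt / dt)), 1)
    gE, gI, gN = cfg.conductances()
    normE = _kernel_norm(cfg.tau_rise_E, cfg.tau_decay_E)
    normI = _kernel_norm(cfg.tau_rise_I, cfg.tau_decay_I)
    fr_e = math.exp(-dt / cfg.tau_rise_E)
    fd_e = math.exp(-dt / cfg.tau_decay_E)
    fr_i = math.exp(-dt / cfg.tau_rise_I)
    fd_i = math.exp(-dt / cfg.tau_decay_I)
    p = cfg.neuron
    g_chr2 = cfg.g_chr2_effective() if (light and cfg.P_chr2 > 0) else 0.0

    n_rec_total = (start_step + n_steps) // rec_every - start_step // rec_every
    lfp = np.zeros((cfg.n_areas, n_rec_total))
    vsum = np.zeros(cfg.n_total)
    vsumsq = np.zeros(cfg.n_total)
    max_spikes = int(cfg.n_total * duration / 1000.0 * max_rate_hz) + 10_000
    spike_ids = np.zeros(max_spikes, dtype=np.int32)
    spike_steps = np.zeros(max_spikes, dtype=np.int64)

    F_all = _light_F(cfg, light, start_step, n_steps)
    cp_steps = {int(round(t / dt)): t for t in checkpoint_times}
    checkpoints: dict[float, NetworkState] = {}

    aer, aed, air, aid_, anr, and_ = state.syn
    n_sp = 0
    rec_i = 0
    done = 0
    while done < n_steps:
        gstep = start_step + done
        chunk_idx = gstep // NOISE_CHUNK_STEPS
        chunk_off = gstep - chunk_idx * NOISE_CHUNK_STEPS
        span = min(NOISE_CHUNK_STEPS - chunk_off, n_steps - done)
        # stop early at checkpoint steps inside this span
        for cs in sorted(cp_steps):
            if gstep < cs < gstep + span:
                span = cs - gstep
                break
        if gstep in cp_steps:
            checkpoints[cp_steps[gstep]] = state.copy()
        noise = _noise_chunk(cfg, chunk_idx)
        n_sp, status, rec_i = _integrate(
            state.V, state.h, state.n, aer, aed, air, aid_, anr, and_,
            state.bufe, state.bufi, gstep, span, dt,
            conn.indptr, conn.indices, conn.delay_steps, conn.is_exc,
            conn.area, conn.kappa,
            p.C, p.g_L, p.V_L, p.g_Na, p.V_Na, p.g_K, p.V_K, p.phi,
            gE, gI, gN, normE, normI, cfg.V_rev_E, cfg.V_rev_I,
            fr_e, fd_e, fr_i, fd_i,
            noise, chunk_off,
            F_all[:, done:done + span].copy(), g_chr2,
            rec_every, lfp, rec_i,
            vsum, vsumsq,
            spike_ids, spike_steps, n_sp)
        if status == 1:
            raise FloatingPointError(
                f"numerical blow-up (|V| > 200 mV) near t = {(gstep + span) * dt:.1f} ms")
        if status == 2:
            raise RuntimeError("spike buffer overflow; raise max_rate_hz")
        done += span
        state.step = start_step + done
    # trailing checkpoint exactly at the end
    end_step = start_step + n_steps
    if end_step in cp_steps:
        checkpoints[cp_steps[end_step]] = state.copy()

    first_rec = (start_step // rec_every + 1) * rec_every
    t_lfp = (first_rec + rec_every * np.arange(rec_i)) * dt
    return SimulationResult(
        config=cfg, t_lfp=t_lfp, lfp=lfp[:, :rec_i],
        spike_ids=spike_ids[:n_sp].copy(),
        spike_times=spike_steps[:n_sp] * dt,
        v_sum=vsum, v_sumsq=vsumsq, n_rec=rec_i,
        state=state, checkpoints=checkpoints,
        light_log=[(a, s) for a, s in (light or {}).items() if s is not None],
        duration=duration,
    )


def continue_run(
    base: SimulationResult | NetworkState,
    config: NetworkConfig,
    duration: float,
    light: Mapping[int, chr2mod.LightStimulus] | None = None,
    conn: Connectivity | None = None,
    **kw,
) -> SimulationResult:
    """Continue from a checkpointed state with bit-identical frozen noise."""
    state = base.state if isinstance(base, SimulationResult) else base
    return simulate(config, duration, light=light, state=state, conn=conn, **kw)


# ---------------------------------------------------------------------------
# Measures
# ---------------------------------------------------------------------------

def synchronization_index(V: np.ndarray) -> float:
    """chi = var(population-mean potential) / mean(single-neuron variance).

    ``V`` has shape (n_neurons, n_samples).  chi lies in [0, 1] up to
    estimator noise: 1 for identical traces, ~1/N for independent ones.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[0] < 2:
        raise ValueError("need >= 2 neurons")
    if V.shape[1] < 100:
        raise ValueError("need >= 100 samples")
    var_i = V.var(axis=1)
    mean_var = float(np.mean(var_i))
    if mean_var == 0.0:
        raise ValueError("zero single-neuron variance")
    return float(V.mean(axis=0).var() / mean_var)


def oscillation_frequency(
    lfp: np.ndarray, fs: float, fmin: float = 10.0, fmax: float = 200.0,
    nperseg: int = 1024,
) -> float:
    """Spectral-peak frequency (Hz) of the demeaned LFP via Welch PSD."""
    x = np.asarray(lfp, float)
    x = x - x.mean()
    f, p = sp_signal.welch(x, fs=fs, nperseg=min(nperseg, len(x)))
    band = (f >= fmin) & (f <= fmax)
    return float(f[band][np.argmax(p[band])])


def regime_scan(
    config: NetworkConfig,
    nu_grid: Sequence[float],
    pi_grid: Sequence[float],
    duration: float = 2000.0,
    settle: float = 500.0,
) -> pd.DataFrame:
    """Map chi, oscillation frequency and class firing rates over the
    (nu_noise, P_I) plane.  Per-point duration is configurable."""
    rows = []
    for nu in nu_grid:
        for pi in pi_grid:
            cfg = replace(config, nu_noise=float(nu), P_I=float(pi))
            res = simulate(cfg, settle + duration)
            keep = res.t_lfp >= settle
            lfp = res.lfp[0, keep]
            m = res.n_rec
            var_i = res.v_sumsq / m - (res.v_sum / m) ** 2
            chi = float(np.var(lfp) / np.mean(var_i))
            post = res.spike_times >= settle
            within = np.mod(res.spike_ids[post], cfg.n_per_area)
            dur_s = duration / 1000.0
            rows.append({
                "nu_noise": nu, "P_I": pi,
                "chi": chi,
                "f_peak": oscillation_frequency(lfp, res.fs_lfp),
                "rate_E": float(np.sum(within < cfg.N_E)) / (cfg.N_E * dur_s),
                "rate_I": float(np.sum(within >= cfg.N_E)) / (cfg.N_I * dur_s),
            })
    return pd.DataFrame(rows)


def ramp_stimulation(
    config: NetworkConfig,
    ramp: chr2mod.LightStimulus,
    duration: float,
    nperseg: int = 256,
):
    """Simulate under a ramping light waveform applied to area 0 and return
    (result, (f, t, Sxx)) with a windowed-FFT spectrogram of the LFP."""
    res = simulate(config, duration, light={0: ramp})
    x = res.lfp[0] - res.lfp[0].mean()
    f, t, S = sp_signal.spectrogram(x, fs=res.fs_lfp, nperseg=nperseg,
                                    noverlap=nperseg // 2)
    return res, (f, t, S)
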