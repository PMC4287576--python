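"""Clock-driven simulation of recurrent PIF/LIF networks with delta synapses.

The integration scheme is *exact integration*: between input events the
linear subthreshold dynamics is propagated in closed form, so the only
discretization is the alignment of spikes and PSP deliveries to the step
grid.  Per step and neuron the update is

1. propagate the membrane potential (LIF: exponential relaxation towards
   rest with time constant ``tau_m``; PIF: identity),
2. add the delayed recurrent PSP amplitudes due this step (ring buffer) and
   the external background/feedforward Poisson PSPs (per-step Poisson
   counts times the efficacy — the delta-synapse pulse model),
3. threshold test: on ``v >= v_th`` emit a spike, reset to ``v_reset`` and
   clamp for the absolute refractory period, during which all synaptic
   input is shunted (discarded).

External input streams are homogeneous Poisson processes; identical seeds
give bit-identical spike output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .network import (ConfigurationError, DelaySpec, NetworkTopology,
                      WeightMatrix)
from .stimulus import DriveSpec

DEFAULT_DT = 0.1  # ms


class SimulationError(RuntimeError):
    """Internal simulator failure (non-finite state, event overflow)."""


@dataclass
class NeuronParams:
    """Integrate-and-fire parameters (voltages mV, times ms).

    ``model='pif'`` is the perfect integrator: no leak, equivalent to an
    infinite membrane time constant.  ``v_reset`` defaults to the resting
    potential (the membrane potential is reset to rest).
    """

    model: str = "lif"
    tau_m: float = 20.0
    v_rest: float = 0.0
    v_th: float = 20.0
    v_reset: float | None = None
    tau_ref: float = 2.0

    def __post_init__(self) -> None:
        if self.model not in ("pif", "lif"):
            raise ConfigurationError(f"unknown neuron model {self.model!r}")
        if self.v_reset is None:
            self.v_reset = self.v_rest
        if self.v_th <= self.v_reset:
            raise ConfigurationError("v_th must exceed v_reset")
        if self.tau_ref < 0:
            raise ConfigurationError("tau_ref must be >= 0")
        if self.model == "lif" and self.tau_m <= 0:
            raise ConfigurationError("tau_m must be positive for LIF")

    @property
    def delta_v(self) -> float:
        """Threshold-to-reset distance (mV)."""
        return self.v_th - self.v_reset

    def decay_factor(self, dt: float) -> float:
        """Per-step subthreshold propagator (1.0 for PIF)."""
        if self.model == "pif":
            return 1.0
        return math.exp(-dt / self.tau_m)


@dataclass
class SpikeData:
    """Spike events of one simulated condition, sorted by time."""

    ids: np.ndarray          # int64 neuron indices
    times: np.ndarray        # float64 spike times, ms
    duration: float          # ms
    n_neurons: int

    def __len__(self) -> int:
        return self.ids.size

    def counts(self, t_start: float = 0.0, t_end: float | None = None) -> np.ndarray:
        """Per-neuron spike counts in the window (t_start, t_end]."""
        t_end = self.duration if t_end is None else t_end
        mask = (self.times > t_start) & (self.times <= t_end)
        return np.bincount(self.ids[mask], minlength=self.n_neurons)

    def rates(self, t_start: float = 0.0, t_end: float | None = None) -> np.ndarray:
        """Per-neuron stationary rates (spikes/s) over the window."""
        t_end = self.duration if t_end is None else t_end
        if t_end <= t_start:
            raise ConfigurationError("empty rate-estimation window")
        return self.counts(t_start, t_end) / ((t_end - t_start) / 1000.0)

    def spike_train(self, neuron: int) -> np.ndarray:
        return np.sort(self.times[self.ids == neuron])

    # gdf dialect: two whitespace-delimited columns (neuron_id, time_ms)
    def to_gdf(self, path) -> None:
        with open(path, "w") as fh:
            for i, t in zip(self.ids, self.times):
                fh.write(f"{i} {t:.3f}\n")

    @classmethod
    def from_gdf(cls, path, duration: float, n_neurons: int) -> "SpikeData":
        data = np.loadtxt(path, ndmin=2)
        if data.size == 0:
            data = data.reshape(0, 2)
        order = np.argsort(data[:, 1], kind="stable")
        return cls(ids=data[order, 0].astype(np.int64),
                   times=data[order, 1].astype(np.float64),
                   duration=duration, n_neurons=n_neurons)


@dataclass
class VoltageTrace:
    """Membrane potentials sampled every step for a subset of neurons."""

    neuron_ids: np.ndarray   # (n_rec,)
    dt: float                # ms
    v: np.ndarray            # (n_rec, n_steps), sampled after reset
    psp_input: np.ndarray | None = None  # summed PSP increment per step

    @property
    def t(self) -> np.ndarray:
        return (np.arange(self.v.shape[1]) + 1) * self.dt

    def mean(self, t_start: float = 0.0) -> np.ndarray:
        """Time-averaged membrane potential per recorded neuron (mV)."""
        keep = self.t > t_start
        return self.v[:, keep].mean(axis=1)


def propagate_subthreshold(v, neuron: NeuronParams, dt: float):
    """Closed-form subthreshold propagation over one step of length dt (ms)."""
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    if neuron.model == "pif":
        return np.asarray(v) + 0.0 if np.ndim(v) else float(v)
    d = neuron.decay_factor(dt)
    return neuron.v_rest + (np.asarray(v) - neuron.v_rest) * d if np.ndim(v) \
        else neuron.v_rest + (v - neuron.v_rest) * d


@njit(cache=True)
def _run_kernel(n_steps, dt, decay, is_pif, v_rest, v_th, v_reset, ref_steps,
                lam_a, j_a, lam_b, j_b,
                indptr, targets, wts, dsteps, buf,
                v, ref_count,
                rec_pos, rec_v, rec_inp,
                out_ids, out_times, seed):
    np.random.seed(seed)
    n = v.size
    L = buf.shape[0]
    n_events = 0
    cap = out_ids.size
    for step in range(n_steps):
        slot = step % L
        t_spike = (step + 1) * dt
        for i in range(n):
            if ref_count[i] > 0:
                ref_count[i] -= 1
                v[i] = v_reset
                # refractory: all synaptic input shunted; still consume the
                # external draws so the input realization is independent of
                # the spiking history
                if lam_a[i] > 0.0:
                    np.random.poisson(lam_a[i])
                if lam_b[i] > 0.0:
                    np.random.poisson(lam_b[i])
                if rec_pos[i] >= 0:
                    rec_v[rec_pos[i], step] = v[i]
                    rec_inp[rec_pos[i], step] = 0.0
                continue
            if not is_pif:
                v[i] = v_rest + (v[i] - v_rest) * decay
            inp = buf[slot, i]
            if lam_a[i] > 0.0:
                inp += j_a * np.random.poisson(lam_a[i])
            if lam_b[i] > 0.0:
                inp += j_b * np.random.poisson(lam_b[i])
            v[i] = v[i] + inp
            if rec_pos[i] >= 0:
                rec_inp[rec_pos[i], step] = inp
            if v[i] >= v_th:
                if n_events < cap:
                    out_ids[n_events] = i
                    out_times[n_events] = t_spike
                n_events += 1
                v[i] = v_reset
                ref_count[i] = ref_steps
                for k in range(indptr[i], indptr[i + 1]):
                    buf[(slot + dsteps[k]) % L, targets[k]] += wts[k]
            if rec_pos[i] >= 0:
                rec_v[rec_pos[i], step] = v[i]
        for i in range(n):
            buf[slot, i] = 0.0
    return n_events


def simulate(topology: NetworkTopology | None, weights: WeightMatrix | None,
             delays: DelaySpec | np.ndarray | None, neuron: NeuronParams,
             drive: DriveSpec, duration: float, dt: float = DEFAULT_DT,
             seed: int = 0, record_v=None, record_input: bool = False,
             delay_seed: int | None = None, v_init=None):
    """Simulate the network for ``duration`` ms; returns ``SpikeData``
    (and a :class:`VoltageTrace` when ``record_v`` is given).

    ``topology``/``weights`` may be ``None`` for unconnected neurons driven
    only by the external Poisson streams.  ``delays`` is either a
    :class:`DelaySpec` (sampled with ``delay_seed``, default ``seed``) or a
    precomputed per-synapse delay array in ms.  ``v_init`` is an explicit
    initial voltage vector; by default initial voltages are drawn uniformly
    on [v_reset, v_th) to suppress startup synchrony.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    n = int(drive.ffw_rate.size)
    if topology is not None:
        if topology.n_total != n:
            raise ConfigurationError("drive size does not match network size")
        if weights is None:
            raise ConfigurationError("topology given without weights")

    n_steps = int(round(duration / dt))
    ref_steps = int(round(neuron.tau_ref / dt))

    # outgoing adjacency in CSR-by-source form for spike delivery
    if topology is not None and (topology.k_exc + topology.k_inh) > 0:
        k = topology.k_exc + topology.k_inh
        src = topology.sources.ravel()
        tgt = np.repeat(np.arange(n, dtype=np.int64), k)
        w = weights.weights.ravel()
        if isinstance(delays, DelaySpec):
            d_ms = delays.sample(src.shape,
                                 seed if delay_seed is None else delay_seed)
        elif delays is None:
            raise ConfigurationError("recurrent network requires delays")
        else:
            d_ms = np.asarray(delays, dtype=np.float64).ravel()
            if d_ms.size != src.size:
                raise ConfigurationError("delay array does not match synapse count")
        dsteps = np.rint(d_ms / dt).astype(np.int64)
        if (dsteps < 1).any():
            raise ConfigurationError(
                "transmission delay shorter than the simulation step after rounding")
        order = np.argsort(src, kind="stable")
        src_s, tgt_s = src[order], tgt[order]
        w_s, dsteps_s = w[order], dsteps[order]
        indptr = np.searchsorted(src_s, np.arange(n + 1))
        max_d = int(dsteps.max())
    else:
        indptr = np.zeros(n + 1, dtype=np.int64)
        tgt_s = np.zeros(0, dtype=np.int64)
        w_s = np.zeros(0, dtype=np.float64)
        dsteps_s = np.zeros(0, dtype=np.int64)
        max_d = 1

    buf = np.zeros((max_d + 1, n), dtype=np.float64)

    # external Poisson streams: merge background and feedforward when their
    # efficacies coincide (single draw per neuron and step)
    lam_ffw = drive.ffw_rate * dt / 1000.0
    lam_bkg = np.full(n, drive.bkg_rate * dt / 1000.0)
    if drive.j_ffw == drive.j_bkg:
        lam_a, j_a = lam_ffw + lam_bkg, drive.j_ffw
        lam_b, j_b = np.zeros(n), 0.0
    else:
        lam_a, j_a = lam_bkg, drive.j_bkg
        lam_b, j_b = lam_ffw, drive.j_ffw

    # event capacity: hard bound from the refractory period
    cap = n * (n_steps // (ref_steps + 1) + 1)
    if cap > 80_000_000:
        raise ConfigurationError(
            "event bound too large; increase tau_ref or shorten the run")
    out_ids = np.empty(cap, dtype=np.int64)
    out_times = np.empty(cap, dtype=np.float64)

    rec_pos = np.full(n, -1, dtype=np.int64)
    if record_v is not None:
        rec_ids = np.asarray(record_v, dtype=np.int64)
        rec_pos[rec_ids] = np.arange(rec_ids.size)
        rec_v = np.empty((rec_ids.size, n_steps), dtype=np.float64)
        rec_inp = np.zeros((rec_ids.size, n_steps), dtype=np.float64)
    else:
        rec_ids = np.zeros(0, dtype=np.int64)
        rec_v = np.zeros((0, n_steps), dtype=np.float64)
        rec_inp = np.zeros((0, 1), dtype=np.float64)

    v = np.empty(n, dtype=np.float64)
    kernel_seed = int(seed) % (2 ** 32)
    if v_init is not None:
        v[:] = np.asarray(v_init, dtype=np.float64)
    else:
        rng = np.random.default_rng(seed)
        v[:] = rng.uniform(neuron.v_reset, neuron.v_th, size=n)
    ref_count = np.zeros(n, dtype=np.int64)

    n_events = _run_kernel(
        n_steps, dt, neuron.decay_factor(dt), neuron.model == "pif",
        neuron.v_rest, neuron.v_th, neuron.v_reset, ref_steps,
        lam_a, j_a, lam_b, j_b,
        indptr, tgt_s, w_s, dsteps_s, buf,
        v, ref_count, rec_pos, rec_v, rec_inp,
        out_ids, out_times, kernel_seed)
    if n_events > cap:  # cannot happen given the refractory bound
        raise SimulationError("spike event buffer overflow")
    if not np.isfinite(v).all():
        raise SimulationError("non-finite membrane potential")

    spikes = SpikeData(ids=out_ids[:n_events].copy(),
                       times=out_times[:n_events].copy(),
                       duration=duration, n_neurons=n)
    if record_v is not None:
        trace = VoltageTrace(neuron_ids=rec_ids, dt=dt, v=rec_v,
                             psp_input=rec_inp if record_input else None)
        return spikes, trace
    return spikes


def population_psth(spikes: SpikeData, bin_ms: float, groups=None):
    """Binned population rates (spikes/s per neuron).

    ``groups`` maps a group label to an array of neuron ids (default: one
    group 'all').  Returns (bin_edges_ms, {label: rate trace}).
    """
    if bin_ms <= 0:
        raise ConfigurationError("bin width must be positive")
    edges = np.arange(0.0, spikes.duration + bin_ms, bin_ms)
    if groups is None:
        groups = {"all": np.arange(spikes.n_neurons)}
    out = {}
    for label, ids in groups.items():
        ids = np.asarray(ids)
        mask = np.isin(spikes.ids, ids)
        counts, _ = np.histogram(spikes.times[mask], bins=edges)
        out[label] = counts / (bin_ms / 1000.0) / max(ids.size, 1)
    return edges, out
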