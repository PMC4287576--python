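"""Random network construction: topology, weights, delays, input preferred orientations.

The model network is a sparse random recurrent circuit of ``n_exc``
excitatory and ``n_inh`` inhibitory neurons with *fixed in-degree*: every
neuron, excitatory or inhibitory, receives exactly ``k_exc`` excitatory and
``k_inh`` inhibitory synapses, drawn uniformly without replacement from the
respective population, excluding self-connections and multiple contacts.
Excitatory synapses all have PSP amplitude ``+j_epsp`` (mV); inhibitory
synapses all have ``-g * j_epsp`` (Dale's rule), with ``g`` the
inhibition-dominance ratio.  Each neuron is additionally assigned an *input
preferred orientation* drawn uniformly on [0, 180) degrees, which determines
the orientation tuning of its feedforward drive (see :mod:`osnet.stimulus`).

Neuron indices: excitatory block ``[0, n_exc)``, inhibitory block
``[n_exc, n_exc + n_inh)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


class ConfigurationError(ValueError):
    """Raised for invalid network / stimulus / simulation configuration."""


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass
class NetworkTopology:
    """Fixed in-degree random topology.

    ``sources[i]`` holds the presynaptic indices of target ``i``: first the
    ``k_exc`` excitatory sources, then the ``k_inh`` inhibitory ones.
    """

    n_exc: int
    n_inh: int
    k_exc: int
    k_inh: int
    sources: np.ndarray  # (N, k_exc + k_inh) int64

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh

    def is_exc(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx) < self.n_exc

    def validate(self) -> None:
        n = self.n_total
        if self.sources.shape != (n, self.k_exc + self.k_inh):
            raise ConfigurationError("sources array has wrong shape")
        exc = self.sources[:, : self.k_exc]
        inh = self.sources[:, self.k_exc:]
        if exc.size and not ((exc >= 0).all() and (exc < self.n_exc).all()):
            raise ConfigurationError("excitatory sources outside excitatory block")
        if inh.size and not ((inh >= self.n_exc).all() and (inh < n).all()):
            raise ConfigurationError("inhibitory sources outside inhibitory block")
        targets = np.arange(n)[:, None]
        if self.sources.size and (self.sources == targets).any():
            raise ConfigurationError("self-connection present")
        for i in range(n):
            row = self.sources[i]
            if len(np.unique(row)) != len(row):
                raise ConfigurationError(f"duplicate synapse onto neuron {i}")


def build_topology(n_exc: int, n_inh: int, k_exc: int, k_inh: int,
                   seed: int) -> NetworkTopology:
    """Sample a fixed in-degree topology.

    Sources are drawn uniformly without replacement, independently per
    target, excluding the target itself.  Deterministic for a given seed.
    """
    for name, v in (("n_exc", n_exc), ("n_inh", n_inh),
                    ("k_exc", k_exc), ("k_inh", k_inh)):
        if v < 0:
            raise ConfigurationError(f"{name} must be >= 0, got {v}")
    # a target inside a population has only (pop size - 1) admissible
    # same-population sources (no self-contacts, no multiple contacts)
    if k_exc > 0 and k_exc > n_exc - 1:
        raise ConfigurationError(
            f"excitatory in-degree k_exc={k_exc} exceeds the "
            f"{max(n_exc - 1, 0)} admissible distinct excitatory sources")
    if k_inh > 0 and k_inh > n_inh - 1:
        raise ConfigurationError(
            f"inhibitory in-degree k_inh={k_inh} exceeds the "
            f"{max(n_inh - 1, 0)} admissible distinct inhibitory sources")

    rng = np.random.default_rng(seed)
    n = n_exc + n_inh
    sources = np.empty((n, k_exc + k_inh), dtype=np.int64)
    exc_pool = np.arange(n_exc)
    inh_pool = np.arange(n_exc, n)
    for i in range(n):
        if k_exc:
            pool = exc_pool if i >= n_exc else np.delete(exc_pool, i)
            sources[i, :k_exc] = rng.choice(pool, size=k_exc, replace=False)
        if k_inh:
            pool = inh_pool if i < n_exc else np.delete(inh_pool, i - n_exc)
            sources[i, k_exc:] = rng.choice(pool, size=k_inh, replace=False)
    return NetworkTopology(n_exc=n_exc, n_inh=n_inh, k_exc=k_exc,
                           k_inh=k_inh, sources=sources)


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

@dataclass
class WeightMatrix:
    """Dale-compliant synaptic efficacies (PSP amplitudes, mV).

    Stored per target (rows), aligned with ``topology.sources``: excitatory
    entries equal ``+j_epsp``, inhibitory entries ``-g * j_epsp``.  Every
    row sums to ``j_epsp * (k_exc - g * k_inh)``.
    """

    topology: NetworkTopology
    j_epsp: float
    g: float
    weights: np.ndarray = field(repr=False)  # (N, k_exc + k_inh) float64

    @property
    def row_sum(self) -> float:
        t = self.topology
        return self.j_epsp * (t.k_exc - self.g * t.k_inh)

    def to_sparse(self) -> sp.csr_matrix:
        """N x N CSR matrix W with W[i, j] = efficacy of synapse j -> i."""
        t = self.topology
        n = t.n_total
        k = t.k_exc + t.k_inh
        rows = np.repeat(np.arange(n), k)
        cols = t.sources.ravel()
        return sp.csr_matrix((self.weights.ravel(), (rows, cols)), shape=(n, n))

    def to_dense(self) -> np.ndarray:
        return self.to_sparse().toarray()


def build_weight_matrix(topology: NetworkTopology, j_epsp: float,
                        g: float) -> WeightMatrix:
    """Assign ``+j_epsp`` to excitatory and ``-g*j_epsp`` to inhibitory synapses."""
    if j_epsp <= 0:
        raise ConfigurationError(f"j_epsp must be positive, got {j_epsp}")
    if g < 0:
        raise ConfigurationError(f"g must be non-negative, got {g}")
    n = topology.n_total
    w = np.empty((n, topology.k_exc + topology.k_inh), dtype=np.float64)
    w[:, : topology.k_exc] = j_epsp
    w[:, topology.k_exc:] = -g * j_epsp
    return WeightMatrix(topology=topology, j_epsp=j_epsp, g=g, weights=w)


# ---------------------------------------------------------------------------
# Delays
# ---------------------------------------------------------------------------

@dataclass
class DelaySpec:
    """Recurrent transmission delays (ms).

    ``mode='fixed'``: all delays equal ``value``.  ``mode='uniform'``:
    per-synapse delays drawn iid uniform on [d_min, d_max].  Delays are
    rounded to integer multiples of the simulation step at simulation time.
    """

    mode: str = "uniform"
    value: float | None = None
    d_min: float | None = None
    d_max: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "fixed":
            if self.value is None or self.value <= 0:
                raise ConfigurationError("fixed delay must be positive")
        elif self.mode == "uniform":
            if self.d_min is None or self.d_max is None:
                raise ConfigurationError("uniform delay needs d_min and d_max")
            if not 0 < self.d_min < self.d_max:
                raise ConfigurationError(
                    "uniform delay requires 0 < d_min < d_max")
        else:
            raise ConfigurationError(f"unknown delay mode {self.mode!r}")

    def sample(self, shape: tuple[int, ...], seed: int) -> np.ndarray:
        """Per-synapse delay array (ms), deterministic for a given seed."""
        if self.mode == "fixed":
            return np.full(shape, float(self.value))
        rng = np.random.default_rng(seed)
        return rng.uniform(self.d_min, self.d_max, size=shape)


# ---------------------------------------------------------------------------
# Input preferred orientations
# ---------------------------------------------------------------------------

@dataclass
class InputPOAssignment:
    """Per-neuron input preferred orientation, degrees in [0, 180)."""

    po: np.ndarray

    def __post_init__(self) -> None:
        self.po = np.asarray(self.po, dtype=np.float64)
        if self.po.ndim != 1 or self.po.size == 0:
            raise ConfigurationError("PO assignment must be a non-empty vector")
        if ((self.po < 0) | (self.po >= 180)).any():
            raise ConfigurationError("input POs must lie in [0, 180)")

    def __len__(self) -> int:
        return self.po.size


def assign_input_pos(n: int, seed: int) -> InputPOAssignment:
    """Draw ``n`` input POs iid uniform on [0, 180) degrees."""
    if n < 1:
        raise ConfigurationError(f"need at least one neuron, got n={n}")
    rng = np.random.default_rng(seed)
    return InputPOAssignment(po=rng.uniform(0.0, 180.0, size=n))


# ---------------------------------------------------------------------------
# Serialization: coordinate-list text format
# ---------------------------------------------------------------------------

def save_connectivity(path, weights: WeightMatrix, delays_ms: np.ndarray) -> None:
    """Write (source, target, weight_mV, delay_ms) rows with a one-line header."""
    t = weights.topology
    k = t.k_exc + t.k_inh
    tgt = np.repeat(np.arange(t.n_total), k)
    src = t.sources.ravel()
    w = weights.weights.ravel()
    d = np.asarray(delays_ms).ravel()
    if d.size != w.size:
        raise ConfigurationError("delay array does not match synapse count")
    with open(path, "w") as fh:
        fh.write("# source target weight_mV delay_ms\n")
        for s, tg, wi, di in zip(src, tgt, w, d):
            fh.write(f"{s} {tg} {wi:.6g} {di:.6g}\n")


def load_connectivity(path):
    """Read the coordinate-list format back as (src, tgt, weight, delay) arrays."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    src = data[:, 0].astype(np.int64)
    tgt = data[:, 1].astype(np.int64)
    return src, tgt, data[:, 2], data[:, 3]
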