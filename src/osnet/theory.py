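"""Mean-field rate theory: linear, rectified, and Siegert fixed points.

For perfect integrators the stationarity of the mean membrane potential
gives a *linear* relation between the rate vector ``r`` (spikes/s) and the
external drift ``h`` (mV/s)::

    (v_th - v_reset) * r = W r + h

with ``W`` the recurrent PSP-amplitude matrix (mV).  Solving it by linear
algebra yields the linear prediction; entries may come out negative, which
the linear layer deliberately reports as such.  The *rectified* fixed point
replaces the right-hand side by its positive part and is solved by damped
Picard iteration — the dominant nonlinearity of spiking networks
(rectification of "negative rates") and the source of tuning-curve
sharpening and modulation suppression.

For leaky integrators the input-output transfer function depends on both
input moments.  Given the mean ``mu`` and the stationary free-potential
standard deviation ``sigma`` (diffusion approximation, uncorrelated
Poissonian inputs), the stationary rate is the first-passage (Siegert)
rate, and the network fixed point ``r_i = F(mu_i(r), sigma_i(r))`` is again
solved by damped Picard iteration.

Units: voltages mV, times ms at the interface, rates spikes/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import erfcx, roots_legendre

from .network import ConfigurationError, WeightMatrix
from .simulate import NeuronParams
from .stimulus import DriveSpec


class StabilityError(RuntimeError):
    """The linearized rate dynamics is unstable (no meaningful fixed point)."""


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to reach tolerance; carries the trace."""

    def __init__(self, msg: str, trace: "SolverTrace"):
        super().__init__(msg)
        self.trace = trace


@dataclass
class SolverTrace:
    """Residual history of a fixed-point solve (RMS of successive iterates)."""

    residuals: np.ndarray
    converged: bool
    r_uncorrected: np.ndarray | None = None

    @property
    def iterations(self) -> int:
        return len(self.residuals)


# ---------------------------------------------------------------------------
# Linear layer
# ---------------------------------------------------------------------------

def external_drift(drive) -> np.ndarray:
    """Per-neuron external drift h_i = j_ffw s_i + j_bkg s_bkg (mV/s).

    Accepts a :class:`DriveSpec` or a raw drift vector (mV/s), so the
    linear and rectified layers can be used on arbitrary right-hand sides.
    """
    if isinstance(drive, DriveSpec):
        return drive.mean_potential_rate
    return np.asarray(drive, dtype=float)


def stability_margin(weights: WeightMatrix | sp.spmatrix | np.ndarray,
                     neuron: NeuronParams) -> float:
    """Largest real part of the spectrum of W/(v_th - v_reset).

    The stationary rate dynamics ``tau r' = -DeltaV r + W r + h`` is stable
    iff this margin is < 1.  (Inhibition-dominated networks have a strongly
    negative row-sum eigenvalue of large *magnitude*; that does not
    threaten stability, which is why the real part is the relevant
    quantity.)  Cached on WeightMatrix instances.
    """
    if isinstance(weights, WeightMatrix):
        cached = weights.__dict__.get("_stab_margin")
        if cached is not None:
            return cached
        w = weights.to_sparse()
    else:
        w = sp.csr_matrix(weights)
    n = w.shape[0]
    if n <= 2000:
        margin = float(np.linalg.eigvals(w.toarray()).real.max()) / neuron.delta_v
    else:
        lam = spla.eigs(w.astype(float), k=4, which="LR",
                        return_eigenvectors=False, maxiter=5000, tol=1e-6)
        margin = float(lam.real.max()) / neuron.delta_v
    if isinstance(weights, WeightMatrix):
        weights.__dict__["_stab_margin"] = margin
    return margin


def _w_sparse(weights) -> sp.csr_matrix:
    if isinstance(weights, WeightMatrix):
        cached = weights.__dict__.get("_w_csr")
        if cached is None:
            cached = weights.__dict__["_w_csr"] = weights.to_sparse()
        return cached
    if weights is None:
        raise ConfigurationError("weights required")
    return sp.csr_matrix(weights)


def refractory_correction(r, tau_ref: float):
    """Map free rates through the refractory saturation r / (1 + r tau_ref).

    ``tau_ref`` in ms, rates in spikes/s.  Monotone increasing, bounded by
    1000/tau_ref.  Negative entries (linear-layer artifacts) pass through
    unchanged.
    """
    if tau_ref < 0:
        raise ConfigurationError("tau_ref must be >= 0")
    r = np.asarray(r, dtype=np.float64)
    tau_s = tau_ref / 1000.0
    return r / (1.0 + np.maximum(r, 0.0) * tau_s)


def linear_rates(weights, drive: DriveSpec, neuron: NeuronParams, *,
                 apply_refractory: bool = True,
                 check_stability: bool = True) -> np.ndarray:
    """Linear stationary rate prediction (spikes/s).

    Solves ``(DeltaV I - W) r = h`` and optionally applies the post-hoc
    refractory correction.  Exact stationarity condition for PIF networks;
    for LIF it is the mean-drive limit (a PIF network is equivalent to a
    LIF network with the mean membrane potential clamped).  Negative
    solutions are reported as such — this layer does not rectify.
    """
    w = _w_sparse(weights)
    dv = neuron.delta_v
    if check_stability and stability_margin(weights, neuron) >= 1.0:
        raise StabilityError(
            "rate dynamics unstable: max Re eig(W)/DeltaV >= 1")
    h = external_drift(drive)
    n = w.shape[0]
    a = dv * sp.identity(n, format="csc") - w.tocsc()
    if n <= 4000:
        r = np.linalg.solve(a.toarray(), h)
    else:
        r = spla.spsolve(a, h)
    if not np.isfinite(r).all():
        raise np.linalg.LinAlgError("singular linear rate system")
    return refractory_correction(r, neuron.tau_ref) if apply_refractory else r


# ---------------------------------------------------------------------------
# Rectified fixed point
# ---------------------------------------------------------------------------

def _picard(gmap, n: int, tol: float, max_iter: int, damping: float,
            r0=None) -> tuple[np.ndarray, SolverTrace]:
    if tol <= 0:
        raise ConfigurationError("tol must be positive")
    if not 0 < damping <= 1:
        raise ConfigurationError("damping must be in (0, 1]")
    r = np.zeros(n) if r0 is None else np.asarray(r0, dtype=np.float64).copy()
    residuals = []
    for _ in range(max_iter):
        r_new = (1.0 - damping) * r + damping * gmap(r)
        res = float(np.sqrt(np.mean((r_new - r) ** 2)))
        residuals.append(res)
        r = r_new
        if res <= tol:
            return r, SolverTrace(np.asarray(residuals), True)
    trace = SolverTrace(np.asarray(residuals), False)
    raise ConvergenceError(
        f"no convergence after {max_iter} iterations (residual {res:.3g})",
        trace)


def rectified_fixed_point(weights, drive: DriveSpec, neuron: NeuronParams,
                          tol: float = 1e-6, max_iter: int = 10000,
                          damping: float = 0.2, r0=None
                          ) -> tuple[np.ndarray, SolverTrace]:
    """Solve ``r = [(W r + h) / DeltaV]_+`` by damped Picard iteration.

    Returns the refractory-corrected rate vector and the solver trace; the
    trace carries the uncorrected fixed point (which is what satisfies the
    identity).  Raises :class:`ConvergenceError` with the trace attached if
    the residual does not reach ``tol`` within ``max_iter``.
    """
    w = _w_sparse(weights)
    dv = neuron.delta_v
    h = external_drift(drive)

    def gmap(r):
        return np.maximum(0.0, (w @ r + h) / dv)

    r, trace = _picard(gmap, w.shape[0], tol, max_iter, damping, r0)
    trace.r_uncorrected = r
    return refractory_correction(r, neuron.tau_ref), trace


def rectified_active_set_oracle(weights, h, delta_v: float):
    """Exhaustive active-set solution of the rectified fixed point.

    Brute force over all 2^N support patterns: solve the linear system
    restricted to each support, keep solutions that are feasible (positive
    on the support, non-positive linear drive off it).  Exponential — only
    for N <= ~15; serves as an independent oracle for the iterative solver.
    Returns the feasible rate vector (the first found if several).
    """
    w = np.asarray(weights.to_dense() if isinstance(weights, WeightMatrix)
                   else weights, dtype=float)
    h = np.asarray(h, dtype=float)
    n = w.shape[0]
    if n > 15:
        raise ConfigurationError("active-set enumeration limited to N <= 15")
    for pattern in range(2 ** n):
        active = np.array([(pattern >> i) & 1 for i in range(n)], dtype=bool)
        r = np.zeros(n)
        if active.any():
            a = delta_v * np.eye(active.sum()) - w[np.ix_(active, active)]
            try:
                r_a = np.linalg.solve(a, h[active])
            except np.linalg.LinAlgError:
                continue
            if (r_a < 0).any():
                continue
            r[active] = r_a
        drive_off = (w @ r + h)[~active]
        if (drive_off > 1e-10).any():
            continue
        return r
    raise RuntimeError("no feasible active set found")


# ---------------------------------------------------------------------------
# Siegert transfer function
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = roots_legendre(24)
_U_TAIL = -15.0   # below this, use the asymptotic expansion of erfcx
_U_MAX = 8.0      # above this, the first-passage time is astronomically long


def _asym_antideriv(x):
    """Antiderivative of erfcx on [15, inf): (1/sqrt(pi)) (ln x + 1/(4x^2) - 3/(16x^4) + 5/(16x^6))."""
    x2 = x * x
    return (np.log(x) + 0.25 / x2 - 3.0 / (16.0 * x2 * x2)
            + 5.0 / (16.0 * x2 * x2 * x2)) / np.sqrt(np.pi)


def _gl_panel(lo, hi):
    """Gauss-Legendre integral of erfcx(-u) over per-element panels [lo, hi]."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    u = mid[..., None] + half[..., None] * _GL_NODES
    vals = erfcx(-u) @ _GL_WEIGHTS
    return half * vals


def _erfcx_neg_integral(a, b):
    """Vectorized integral of erfcx(-u) du from a to b (a < b <= _U_MAX).

    Splits into an asymptotic tail on (-inf, -15] and unit-length
    Gauss-Legendre panels on [-15, b].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = np.zeros(np.broadcast(a, b).shape)
    a, b = np.broadcast_arrays(a, b)

    # tail: integral over [a, min(b, -15)] via x = -u asymptotics
    tail_hi = np.minimum(b, _U_TAIL)
    has_tail = a < _U_TAIL
    if has_tail.any():
        p = -tail_hi[has_tail]   # lower x bound (>= 15)
        q = -a[has_tail]         # upper x bound
        out[has_tail] += _asym_antideriv(q) - _asym_antideriv(p)

    # main: [max(a, -15), b] in integer-aligned panels
    lo = np.maximum(a, _U_TAIL)
    has_main = b > lo
    if has_main.any():
        lo_m, b_m = lo[has_main], b[has_main]
        k_lo = np.ceil(lo_m)
        k_hi = np.floor(b_m)
        main = np.zeros(lo_m.shape)
        single = k_lo > k_hi  # both ends inside one unit panel
        if single.any():
            main[single] = _gl_panel(lo_m[single], b_m[single])
        multi = ~single
        if multi.any():
            main[multi] = (_gl_panel(lo_m[multi], k_lo[multi])
                           + _gl_panel(k_hi[multi], b_m[multi]))
            # full integer panels between k_lo and k_hi
            k0 = int(np.floor(k_lo[multi].min()))
            k1 = int(np.ceil(k_hi[multi].max()))
            if k1 > k0:
                edges = np.arange(k0, k1 + 1, dtype=float)
                panel_int = _gl_panel(edges[:-1], edges[1:])
                cum = np.concatenate([[0.0], np.cumsum(panel_int)])
                i_lo = (k_lo[multi] - k0).astype(int)
                i_hi = (k_hi[multi] - k0).astype(int)
                main[multi] += cum[i_hi] - cum[i_lo]
        out_main = np.zeros(lo.shape)
        out_main[has_main] = main
        out += out_main
    return out


def siegert_rate(mu, sigma, neuron: NeuronParams):
    """Stationary first-passage rate of the LIF diffusion (spikes/s).

    ``mu`` is the mean free membrane potential (mV) and ``sigma`` its
    stationary standard deviation (mV), as produced by
    :func:`input_moments`.  The mean first-passage time is

        1/r = tau_ref + tau_m sqrt(pi) * Integral_{y_r}^{y_th} erfcx(-u) du,

    with ``y = (v - mu) / (sqrt(2) sigma)`` — the sqrt(2) converts the
    stationary free-potential SD to the diffusion normalization.  The
    ``sigma -> 0`` limit reduces to the deterministic LIF rate
    ``1/(tau_ref + tau_m ln((mu - v_reset)/(mu - v_th)))`` for
    suprathreshold mean, and 0 otherwise; ``sigma = 0`` takes this branch
    in closed form.
    """
    if neuron.model != "lif":
        raise ConfigurationError("Siegert rate is defined for LIF neurons")
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if (sigma < 0).any():
        raise ConfigurationError("sigma must be >= 0")
    scalar = mu.ndim == 0 and sigma.ndim == 0
    mu, sigma = np.atleast_1d(*np.broadcast_arrays(mu, sigma))
    tau_s = neuron.tau_m / 1000.0
    ref_s = neuron.tau_ref / 1000.0
    out = np.zeros(mu.shape)

    det = sigma == 0.0
    if det.any():
        m = mu[det]
        r = np.zeros(m.shape)
        supra = m > neuron.v_th
        r[supra] = 1.0 / (ref_s + tau_s * np.log(
            (m[supra] - neuron.v_reset) / (m[supra] - neuron.v_th)))
        out[det] = r

    sto = ~det
    if sto.any():
        denom = np.sqrt(2.0) * sigma[sto]
        a = (neuron.v_reset - mu[sto]) / denom
        b = (neuron.v_th - mu[sto]) / denom
        r = np.zeros(a.shape)
        solvable = b < _U_MAX  # otherwise the rate underflows to 0
        integral = _erfcx_neg_integral(a[solvable], b[solvable])
        r[solvable] = 1.0 / (ref_s + tau_s * np.sqrt(np.pi) * integral)
        out[sto] = r
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Input moments and LIF fixed point
# ---------------------------------------------------------------------------

def _w2_sparse(weights) -> sp.csr_matrix:
    if isinstance(weights, WeightMatrix):
        cached = weights.__dict__.get("_w2_csr")
        if cached is None:
            w = _w_sparse(weights).copy()
            w.data = w.data ** 2
            cached = weights.__dict__["_w2_csr"] = w
        return cached
    w = sp.csr_matrix(weights).copy()
    w.data = w.data ** 2
    return w


def input_moments(weights, rates, drive: DriveSpec,
                  neuron: NeuronParams) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD of the free membrane potential under Poisson input.

    Diffusion approximation for uncorrelated Poissonian spike trains::

        mu_i      = v_rest + tau_m (sum_j w_ij r_j + j_ffw s_i + j_bkg s_bkg)
        sigma_i^2 = (tau_m / 2) (sum_j w_ij^2 r_j + j_ffw^2 s_i + j_bkg^2 s_bkg)

    with rates in spikes/s, tau_m converted to seconds, weights in mV.
    ``sigma`` is the stationary SD of the freely evolving potential (the
    quantity a long subthreshold simulation measures).
    """
    if neuron.model != "lif":
        raise ConfigurationError("input moments require a finite tau_m (LIF)")
    rates = np.asarray(rates, dtype=float)
    if (rates < 0).any():
        raise ConfigurationError("rates must be non-negative")
    tau_s = neuron.tau_m / 1000.0
    if weights is None:
        rec_mean = rec_var = 0.0
    else:
        w = _w_sparse(weights)
        rec_mean = w @ rates
        rec_var = _w2_sparse(weights) @ rates
    mu = neuron.v_rest + tau_s * (rec_mean + drive.mean_potential_rate)
    sigma = np.sqrt(0.5 * tau_s * (rec_var + drive.variance_rate))
    return mu, np.atleast_1d(sigma) if np.ndim(mu) else sigma


class SiegertLookup:
    """Bilinear interpolation table for the Siegert transfer function.

    Optional accelerator for :func:`lif_fixed_point`; the grid must bracket
    all (mu, sigma) pairs encountered, otherwise a range error is raised
    (or, with ``fallback=True``, the exact evaluation is used for
    out-of-range points).
    """

    def __init__(self, neuron: NeuronParams, mu_range, sigma_range,
                 shape=(200, 100), fallback: bool = True):
        from scipy.interpolate import RegularGridInterpolator
        self.neuron = neuron
        self.fallback = fallback
        self.mu_grid = np.linspace(mu_range[0], mu_range[1], shape[0])
        self.sigma_grid = np.linspace(max(sigma_range[0], 1e-6),
                                      sigma_range[1], shape[1])
        mm, ss = np.meshgrid(self.mu_grid, self.sigma_grid, indexing="ij")
        table = siegert_rate(mm.ravel(), ss.ravel(), neuron).reshape(mm.shape)
        self._interp = RegularGridInterpolator(
            (self.mu_grid, self.sigma_grid), table, method="linear",
            bounds_error=False, fill_value=np.nan)

    def __call__(self, mu, sigma):
        out = self._interp(np.column_stack([np.atleast_1d(mu),
                                            np.atleast_1d(sigma)]))
        bad = ~np.isfinite(out)
        if bad.any():
            if not self.fallback:
                raise ConfigurationError(
                    "(mu, sigma) outside the Siegert lookup range")
            out[bad] = siegert_rate(np.atleast_1d(mu)[bad],
                                    np.atleast_1d(sigma)[bad], self.neuron)
        return out


def lif_fixed_point(weights, drive: DriveSpec, neuron: NeuronParams,
                    tol: float = 1e-6, max_iter: int = 10000,
                    damping: float = 0.2, lookup: SiegertLookup | None = None,
                    r0=None) -> tuple[np.ndarray, SolverTrace]:
    """Self-consistent LIF rates ``r_i = F(mu_i(r), sigma_i(r))``.

    ``F`` is the Siegert rate (or its lookup interpolant), which carries
    the refractory period natively — no post-hoc correction.  Solved by
    damped Picard iteration from ``r0`` (default: zero rates).
    """
    n = drive.ffw_rate.size
    func = lookup if lookup is not None else (
        lambda m, s: siegert_rate(m, s, neuron))

    def gmap(r):
        mu, sigma = input_moments(weights, r, drive, neuron)
        return np.asarray(func(mu, sigma), dtype=float)

    r, trace = _picard(gmap, n, tol, max_iter, damping, r0)
    trace.r_uncorrected = r
    return r, trace
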