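"""Tuning curves and selectivity statistics.

Orientation is 180-degree periodic, so all circular statistics operate on
doubled angles.  For a tuning curve r(theta_k) on a uniform grid:

* OSI / PO — length and (half-)angle of the normalized circular resultant
  ``sum_k r_k exp(i 2 theta_k) / sum_k r_k``; OSI = 0 for a flat curve,
  1 for a response at a single orientation.
* von Mises fit — least squares of ``A exp(kappa cos 2(theta - phi))``;
  the error index is the RMS residual in percent of the curve mean.
* tuning width (TW) — half width at half height of the fitted curve
  between its min and max, ``0.5 arccos(ln cosh kappa / kappa)``; by
  continuity 45 deg at kappa = 0 (the unrectified cosine reference) and
  -> 0 as kappa -> inf.
* F0 / F2 — mean and second-Fourier-harmonic amplitude; with the
  conventions used here ``OSI = F2 / (2 F0)`` identically.
* dPO — circular difference between output and input PO in [-90, 90).
* SC — sharpening coefficient, TW_out / TW_in (< 1 means sharpening;
  cosine input has TW_in = 45 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .network import ConfigurationError
from .simulate import NeuronParams, SpikeData

COSINE_INPUT_TW = 45.0  # deg; TW of the unrectified cosine input tuning


# ---------------------------------------------------------------------------
# Tuning curve extraction
# ---------------------------------------------------------------------------

@dataclass
class TuningCurveSet:
    """Per-neuron rate vs orientation for one contrast.

    ``rates`` has shape (n_neurons, n_theta); ``theta`` is the uniform
    orientation grid in degrees on [0, 180).
    """

    theta: np.ndarray
    rates: np.ndarray
    contrast: float | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        if self.theta.ndim != 1 or (np.diff(self.theta) <= 0).any():
            raise ConfigurationError("orientation grid must be strictly increasing")
        if self.rates.shape[1] != self.theta.size:
            raise ConfigurationError("rates do not match the orientation grid")
        if (self.rates < 0).any():
            raise ConfigurationError("tuning-curve rates must be non-negative")

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]


def extract_tuning_curves(spikes_by_theta: dict, window: tuple[float, float],
                          contrast: float | None = None) -> TuningCurveSet:
    """Stationary rates per neuron and orientation from spike data.

    ``spikes_by_theta`` maps orientation (deg) to the :class:`SpikeData`
    of that condition; ``window = (t_start, t_end)`` in ms excludes the
    onset transient.
    """
    thetas = np.array(sorted(spikes_by_theta))
    t0, t1 = window
    n_set = {spikes_by_theta[th].n_neurons for th in thetas}
    if len(n_set) != 1:
        raise ConfigurationError("spike sets disagree on network size")
    for th in thetas:
        if t1 > spikes_by_theta[th].duration or t0 < 0 or t1 <= t0:
            raise ConfigurationError("window outside the simulated duration")
    rates = np.column_stack([spikes_by_theta[th].rates(t0, t1) for th in thetas])
    return TuningCurveSet(theta=thetas, rates=rates, contrast=contrast)


# ---------------------------------------------------------------------------
# Circular statistics
# ---------------------------------------------------------------------------

def osi_po(rates, theta):
    """Orientation selectivity index and preferred orientation.

    ``rates`` may be 1D (one curve) or 2D (neurons x orientations).
    Returns (osi, po_deg); all-zero curves yield NaN for both.
    """
    r = np.atleast_2d(np.asarray(rates, dtype=float))
    th = np.deg2rad(2.0 * np.asarray(theta, dtype=float))
    z = (r * np.exp(1j * th)).sum(axis=1)
    total = r.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        osi = np.abs(z) / total
        po = np.rad2deg(np.angle(z)) / 2.0 % 180.0
    osi = np.where(total > 0, osi, np.nan)
    po = np.where(total > 0, po, np.nan)
    if np.ndim(rates) == 1:
        return float(osi[0]), float(po[0])
    return osi, po


def f0_f2(rates, theta):
    """Baseline (mean) and modulation (second Fourier amplitude).

    The amplitude convention is such that a curve
    ``r = f0 + f2 cos 2(theta - phi)`` on a uniform grid is recovered
    exactly: ``f2 = (2 / n) |sum_k r_k exp(i 2 theta_k)|``.
    """
    r = np.atleast_2d(np.asarray(rates, dtype=float))
    th = np.deg2rad(2.0 * np.asarray(theta, dtype=float))
    f0 = r.mean(axis=1)
    f2 = 2.0 * np.abs((r * np.exp(1j * th)).sum(axis=1)) / r.shape[1]
    if np.ndim(rates) == 1:
        return float(f0[0]), float(f2[0])
    return f0, f2


def dpo(po_out, po_in):
    """Circular difference of orientations, period 180, mapped to [-90, 90)."""
    d = (np.asarray(po_out, dtype=float) - np.asarray(po_in, dtype=float)
         + 90.0) % 180.0 - 90.0
    return float(d) if np.ndim(po_out) == 0 and np.ndim(po_in) == 0 else d


# ---------------------------------------------------------------------------
# von Mises fitting
# ---------------------------------------------------------------------------

@dataclass
class VonMisesFit:
    """Least-squares fit of ``A exp(kappa cos 2(theta - phi))``."""

    amplitude: float
    kappa: float
    phi: float                   # deg in [0, 180)
    error_index: float           # RMS residual in percent of curve mean
    flag: str = "ok"             # ok | flat | zero | nofit

    @property
    def ok(self) -> bool:
        return self.flag == "ok"


def _von_mises(theta_deg, a, kappa, phi_deg):
    return a * np.exp(kappa * np.cos(np.deg2rad(2.0 * (theta_deg - phi_deg))))


def fit_von_mises(rates, theta, kappa_flat: float = 1e-3) -> VonMisesFit:
    """Fit one tuning curve; deterministic multi-start over phi.

    Starts are seeded at the circular-resultant PO and three 45-degree
    rotations of it.  Curves that are all zero, or whose best kappa is
    below ``kappa_flat`` (phi unidentifiable), are flagged.
    """
    r = np.asarray(rates, dtype=float)
    th = np.asarray(theta, dtype=float)
    if r.size < 4:
        raise ConfigurationError("need at least 4 grid points to fit")
    mean = r.mean()
    if mean <= 0:
        return VonMisesFit(0.0, 0.0, np.nan, np.nan, flag="zero")
    _, po = osi_po(r, th)
    starts = [(po + k * 45.0) % 180.0 for k in range(4)]
    best = None
    for phi0 in starts:
        try:
            popt, _ = curve_fit(
                _von_mises, th, r, p0=[mean, 1.0, phi0],
                bounds=([0.0, 0.0, -360.0], [np.inf, 50.0, 540.0]),
                maxfev=5000)
        except RuntimeError:
            continue
        resid = _von_mises(th, *popt) - r
        sse = float(resid @ resid)
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        return VonMisesFit(np.nan, np.nan, np.nan, np.nan, flag="nofit")
    (a, kappa, phi), sse = best
    err = 100.0 * np.sqrt(sse / r.size) / mean
    if kappa < kappa_flat:
        return VonMisesFit(a, kappa, np.nan, err, flag="flat")
    return VonMisesFit(a, kappa, phi % 180.0, err, flag="ok")


def tuning_width(kappa) -> float | np.ndarray:
    """Half width at half height of the fitted von Mises curve (degrees).

    ``tw = 0.5 arccos(ln cosh kappa / kappa)``; 45 deg at kappa = 0 by
    continuity, strictly decreasing, -> 0 as kappa -> inf.
    """
    k = np.asarray(kappa, dtype=float)
    if (k < 0).any():
        raise ConfigurationError("kappa must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        # ln cosh k computed overflow-safely: |k| + log1p(exp(-2|k|)) - ln 2
        lncosh = k + np.log1p(np.exp(-2.0 * k)) - np.log(2.0)
        ratio = np.where(k > 1e-8, lncosh / np.where(k > 0, k, 1.0), k / 2.0)
    tw = 0.5 * np.rad2deg(np.arccos(np.clip(ratio, -1.0, 1.0)))
    return float(tw) if np.ndim(kappa) == 0 else tw


def sharpening_coefficient(tw_out, tw_in=COSINE_INPUT_TW):
    """Ratio of output to input tuning width; < 1 indicates sharpening."""
    tw_in = np.asarray(tw_in, dtype=float)
    if (tw_in <= 0).any():
        raise ConfigurationError("input tuning width must be positive")
    out = np.asarray(tw_out, dtype=float) / tw_in
    return float(out) if np.ndim(out) == 0 else out


def align_curves(rates, theta, po) -> np.ndarray:
    """Shift each curve so its (input or measured) PO lands on the grid
    center.

    ``po`` in degrees; shifts are integer grid steps (nearest).  Used for
    population-average tuning curves ("aligned mean tuning curve").
    """
    r = np.atleast_2d(np.asarray(rates, dtype=float))
    th = np.asarray(theta, dtype=float)
    step = 180.0 / th.size
    center = th.size // 2
    shifts = np.round(np.asarray(po, dtype=float) / step).astype(int) % th.size
    return np.vstack([np.roll(r[i], center - shifts[i])
                      for i in range(r.shape[0])])


# ---------------------------------------------------------------------------
# Spike-train statistics
# ---------------------------------------------------------------------------

def cv_isi(spikes: SpikeData, min_spikes: int = 20) -> dict[int, float]:
    """Coefficient of variation of inter-spike intervals per neuron.

    Only neurons with at least ``min_spikes`` spikes are included
    (``min_spikes >= 2``).  CV near 1 indicates Poisson-like irregularity.
    """
    if min_spikes < 2:
        raise ConfigurationError("min_spikes must be >= 2")
    out = {}
    order = np.lexsort((spikes.times, spikes.ids))
    ids = spikes.ids[order]
    times = spikes.times[order]
    boundaries = np.flatnonzero(np.diff(ids)) + 1
    for chunk_ids, chunk_t in zip(np.split(ids, boundaries),
                                  np.split(times, boundaries)):
        if chunk_t.size >= min_spikes:
            isi = np.diff(chunk_t)
            out[int(chunk_ids[0])] = float(isi.std() / isi.mean())
    return out


# ---------------------------------------------------------------------------
# Membrane-potential tuning
# ---------------------------------------------------------------------------

def free_membrane_potential(v_mean_measured, rate, neuron: NeuronParams):
    """Reset-corrected mean membrane potential (mV).

    Each spike hyperpolarizes the neuron by (v_th - v_reset), which decays
    with tau_m; time-averaging gives the correction
    ``tau_m (v_th - v_reset) rate``.  ``rate`` in spikes/s, tau_m in ms.
    """
    if neuron.model != "lif":
        raise ConfigurationError("free-potential correction assumes LIF")
    tau_s = neuron.tau_m / 1000.0
    return np.asarray(v_mean_measured, dtype=float) + \
        tau_s * neuron.delta_v * np.asarray(rate, dtype=float)


def reconstruct_free_potential(weights, rates, drive, neuron: NeuronParams):
    """Input-based prediction of the free potential: the mu moment."""
    from .theory import input_moments
    mu, _ = input_moments(weights, rates, drive, neuron)
    return mu


# ---------------------------------------------------------------------------
# Normalization and summary tables
# ---------------------------------------------------------------------------

def normalize_tuning(curves: TuningCurveSet, mode: str = "max",
                     subtract_spont: bool = False, spont=None) -> np.ndarray:
    """Per-curve normalization by mean or max.

    With ``subtract_spont`` the neuron's spontaneous rate is subtracted
    first and the result clipped at zero.  Curves whose denominator is not
    positive come out as NaN rows (flagged missing).
    """
    if mode not in ("mean", "max"):
        raise ConfigurationError(f"unknown normalization mode {mode!r}")
    r = curves.rates.astype(float).copy()
    if subtract_spont:
        if spont is None:
            raise ConfigurationError("subtract_spont requires spont rates")
        r = np.clip(r - np.asarray(spont, dtype=float)[:, None], 0.0, None)
    denom = r.mean(axis=1) if mode == "mean" else r.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = r / denom[:, None]
    out[denom <= 0] = np.nan
    return out


def selectivity_stats(curves: TuningCurveSet, input_po=None,
                      error_threshold: float = 5.0) -> pd.DataFrame:
    """Full per-neuron selectivity table.

    Columns: osi, po_deg, f0, f2, kappa, tw_deg, error_index_pct, sc,
    dpo_deg (if ``input_po`` given), flags.  Fits whose error index
    exceeds ``error_threshold`` (percent) are flagged 'badfit' and their
    TW/SC left as NaN, mirroring the exclusion of poor fits.
    """
    osi, po = osi_po(curves.rates, curves.theta)
    f0, f2 = f0_f2(curves.rates, curves.theta)
    rows = []
    for i in range(curves.n_neurons):
        fit = fit_von_mises(curves.rates[i], curves.theta)
        flag = fit.flag
        tw = sc = np.nan
        if fit.ok and fit.error_index <= error_threshold:
            tw = tuning_width(fit.kappa)
            sc = sharpening_coefficient(tw)
        elif fit.ok:
            flag = "badfit"
        rows.append((osi[i], po[i], f0[i], f2[i], fit.kappa, tw,
                     fit.error_index, sc, flag))
    df = pd.DataFrame(rows, columns=["osi", "po_deg", "f0", "f2", "kappa",
                                     "tw_deg", "error_index_pct", "sc",
                                     "flag"])
    df.insert(0, "neuron_id", np.arange(curves.n_neurons))
    if curves.contrast is not None:
        df.insert(1, "contrast", curves.contrast)
    if input_po is not None:
        df["dpo_deg"] = dpo(df["po_deg"].to_numpy(), np.asarray(input_po))
    return df
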