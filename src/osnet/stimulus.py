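"""Orientation-tuned external drive.

Every neuron receives two external Poisson input streams:

* a stimulus-independent *background* of total rate ``s_bkg`` (spikes/s)
  with PSP efficacy ``j_bkg`` (mV), shared by all neurons;
* a *feedforward* sensory stream whose intensity depends on stimulus
  contrast ``C`` and orientation ``theta``.  The convergent thalamic
  population is collapsed into a single Poisson process of total rate

      s_i(theta, C) = s_b(C) * (1 + m * cos 2(theta - po_i)),

  where ``s_b(C) = s_max * C`` is the contrast-dependent baseline,
  ``m`` in [0, 1] is the input modulation ratio (the tuned fraction of the
  feedforward input) and ``po_i`` is neuron i's input preferred
  orientation.  Orientation is 180-degree periodic throughout.

The *spontaneous* condition is the response to the background input only
(feedforward intensity identically zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ConfigurationError, InputPOAssignment


@dataclass
class StimulusConfig:
    """Stimulus ensemble parameters.

    Defaults are the package's standard operating point (see
    ``docs/methods.md``); the three default contrasts realize a three-fold
    range of the feedforward baseline intensity.
    """

    m: float = 0.5                     # input modulation ratio, dimensionless
    s_max: float = 3000.0              # max total feedforward rate, spikes/s
    s_bkg: float = 9000.0              # total background rate, spikes/s
    j_ffw: float = 0.1                 # feedforward PSP efficacy, mV
    j_bkg: float = 0.1                 # background PSP efficacy, mV
    contrasts: tuple = (1 / 3, 2 / 3, 1.0)
    n_theta: int = 12                  # stimulus orientations per 180 deg
    m_inh: float | None = None         # optional separate modulation for
                                       # inhibitory neurons (config-only variant)

    def __post_init__(self) -> None:
        if not 0 <= self.m <= 1:
            raise ConfigurationError(f"modulation ratio m={self.m} not in [0, 1]")
        if self.m_inh is not None and not 0 <= self.m_inh <= 1:
            raise ConfigurationError(f"m_inh={self.m_inh} not in [0, 1]")
        if self.s_max <= 0:
            raise ConfigurationError("s_max must be positive")
        if self.s_bkg < 0:
            raise ConfigurationError("s_bkg must be non-negative")
        if self.j_ffw < 0 or self.j_bkg < 0:
            raise ConfigurationError("efficacies must be non-negative")
        c = np.asarray(self.contrasts, dtype=float)
        if c.size == 0 or (np.diff(c) <= 0).any() or (c <= 0).any() or (c > 1).any():
            raise ConfigurationError(
                "contrasts must be strictly increasing values in (0, 1]")
        if self.n_theta < 2:
            raise ConfigurationError("need at least two stimulus orientations")

    @property
    def theta_grid(self) -> np.ndarray:
        """Uniform orientation grid on [0, 180), degrees."""
        return np.arange(self.n_theta) * (180.0 / self.n_theta)


@dataclass
class DriveSpec:
    """Resolved per-neuron external intensities for one stimulus condition."""

    ffw_rate: np.ndarray               # per-neuron feedforward rate, spikes/s
    bkg_rate: float                    # shared background rate, spikes/s
    j_ffw: float                       # mV
    j_bkg: float                       # mV
    theta: float | None = None         # stimulus orientation (deg), None if spontaneous
    contrast: float | None = None
    evoked: bool = True

    def __post_init__(self) -> None:
        self.ffw_rate = np.atleast_1d(np.asarray(self.ffw_rate, dtype=np.float64))
        if (self.ffw_rate < 0).any() or self.bkg_rate < 0:
            raise ConfigurationError("Poisson intensities must be non-negative")

    @property
    def mean_potential_rate(self) -> np.ndarray:
        """Per-neuron external drift h_i = j_ffw*s_i + j_bkg*s_bkg (mV/s)."""
        return self.j_ffw * self.ffw_rate + self.j_bkg * self.bkg_rate

    @property
    def variance_rate(self) -> np.ndarray:
        """Per-neuron external variance rate j_ffw^2*s_i + j_bkg^2*s_bkg (mV^2/s)."""
        return self.j_ffw ** 2 * self.ffw_rate + self.j_bkg ** 2 * self.bkg_rate


def contrast_baseline(C: float, s_max: float) -> float:
    """Contrast-dependent feedforward baseline, ``s_b = s_max * C`` (spikes/s)."""
    if not 0 <= C <= 1:
        raise ConfigurationError(f"contrast C={C} not in [0, 1]")
    return float(s_max) * float(C)


def feedforward_rate(po, theta, s_b, m):
    """Cosine orientation tuning of the feedforward intensity.

    ``s = s_b * (1 + m cos 2(theta - po))``, 180-degree periodic in both
    angles; non-negative for m <= 1.  Accepts scalars or arrays for ``po``.
    """
    if not 0 <= m <= 1:
        raise ConfigurationError(
            f"m={m} outside [0, 1] would produce negative intensities")
    po = np.asarray(po, dtype=np.float64)
    delta = np.deg2rad(2.0 * (theta - po))
    return s_b * (1.0 + m * np.cos(delta))


def build_drive(pos: InputPOAssignment, theta: float, C: float,
                stim: StimulusConfig, evoked: bool = True,
                n_exc: int | None = None) -> DriveSpec:
    """Resolve the external drive for one stimulus condition.

    With ``evoked=False`` (spontaneous condition) the feedforward intensity
    is identically zero and only the background remains.  If
    ``stim.m_inh`` is set, neurons with index >= ``n_exc`` (the inhibitory
    block) receive the reduced modulation ratio.
    """
    n = len(pos)
    if not evoked:
        return DriveSpec(ffw_rate=np.zeros(n), bkg_rate=stim.s_bkg,
                         j_ffw=stim.j_ffw, j_bkg=stim.j_bkg,
                         theta=None, contrast=None, evoked=False)
    s_b = contrast_baseline(C, stim.s_max)
    if stim.m_inh is None or n_exc is None:
        ffw = feedforward_rate(pos.po, theta, s_b, stim.m)
    else:
        ffw = np.empty(n)
        ffw[:n_exc] = feedforward_rate(pos.po[:n_exc], theta, s_b, stim.m)
        ffw[n_exc:] = feedforward_rate(pos.po[n_exc:], theta, s_b, stim.m_inh)
    return DriveSpec(ffw_rate=ffw, bkg_rate=stim.s_bkg, j_ffw=stim.j_ffw,
                     j_bkg=stim.j_bkg, theta=float(theta), contrast=float(C),
                     evoked=True)
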