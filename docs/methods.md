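# Methods

`osnet` models the emergence of orientation selectivity (OS) in random
recurrent networks of spiking neurons that have *no* feature-specific
connectivity — the salt-and-pepper regime of rodent primary visual cortex.
The package has three layers: a clock-driven spiking simulator, a
mean-field rate theory that predicts every neuron's stationary rate from
the exact network realization, and a tuning-statistics toolkit.  This note
documents the model, the numerical choices, and what the shipped
benchmarks do and do not establish.

## Neuron and synapse model

Neurons are integrate-and-fire units with instantaneous (delta) synapses:
each presynaptic spike deposits its full PSP amplitude `w` (mV) in one
step.  Two variants are supported:

* **LIF** — leaky integrator, `tau_m dv/dt = -(v - v_rest) + R I(t)`;
  default `tau_m = 20 ms`, `v_rest = v_reset = 0 mV`, `v_th = 20 mV`,
  `tau_ref = 2 ms`.
* **PIF** — perfect integrator (no leak), implemented as the LIF update
  with the decay disabled; equivalent to `tau_m -> inf`.  A PIF neuron
  responds to the *mean* of its input only, which is what makes a fully
  linear network theory possible.

On `v >= v_th` a spike is emitted, the potential is reset to rest, and all
synaptic input is shunted for the absolute refractory period.

**Integration.** Subthreshold propagation is exact (closed-form
exponential per step for LIF, identity for PIF); the only discretization
is the alignment of spikes, PSP deliveries, and threshold tests to the
step grid (`dt = 0.1 ms` by default).  The benchmark suite verifies the
silenced LIF trajectory against the analytic exponential at ~1e-14 mV and
the PIF trajectory against the cumulative PSP sum bitwise.  The remaining
`O(sqrt(dt))` effect is the detection of diffusion-driven threshold
crossings between grid points; it biases fluctuation-driven rates down by
~2 % at `dt = 0.1 ms` and is why the single-neuron Monte-Carlo benchmark
runs at `dt = 0.01 ms`.

**External input.** Each neuron receives two independent Poisson streams,
realized as per-step Poisson PSP counts: a background of total rate
`s_bkg` (efficacy `j_bkg`) and a feedforward sensory stream.  When the two
efficacies coincide the streams are merged into one draw per step.
Initial voltages are uniform on `[v_reset, v_th)` to suppress startup
synchrony; the first 200 ms of every run are excluded from rate estimates.

## Network model

Fixed in-degree random connectivity: every neuron receives exactly `k_exc`
excitatory and `k_inh` inhibitory synapses drawn uniformly without
replacement (no self-contacts, no multiple contacts).  Dale's rule:
excitatory PSPs are `+j_epsp`, inhibitory ones `-g j_epsp`.  Because the
in-degree is fixed, every row of the weight matrix sums to exactly
`j_epsp (k_exc - g k_inh)`; with 4:1 excitatory/inhibitory in-degrees,
`g = 4` makes the network exactly balanced (zero net recurrent drift) and
`g > 4` inhibition-dominated.  Recurrent delays are either drawn uniformly
per synapse (0.5–3 ms; asynchronous-irregular regime) or identical
(1.5 ms; synchronous regime); delays are rounded to integer step
multiples.

## Stimulus model

An oriented stimulus at orientation `theta` and contrast `C` drives neuron
`i` with a collapsed-thalamus Poisson rate

    s_i(theta, C) = s_max * C * (1 + m * cos 2(theta - po_i)),

with input preferred orientations `po_i` iid uniform on [0, 180) degrees
and modulation ratio `m` (the tuned fraction of the feedforward input).
The contrast-to-baseline map is linear; the default contrasts
{1/3, 2/3, 1} span a three-fold range of the input baseline.

## Rate theory

Stationarity of the mean membrane potential of a PIF neuron gives the
linear relation `DeltaV r = W r + h`, with `h_i = j_ffw s_i + j_bkg s_bkg`
the external drift (mV/s).  Three solution layers:

1. **Linear** — direct solve of `(DeltaV I - W) r = h`; negative entries
   are reported as such (the linear layer never rectifies).  A post-hoc
   refractory correction `r -> r / (1 + r tau_ref)` is applied.
2. **Rectified** — damped Picard iteration of
   `r = [(W r + h)/DeltaV]_+`, the dominant nonlinearity of spiking
   networks.  Rectification couples baseline and modulation processing
   and produces tuning-curve sharpening and modulation suppression
   ("normalization").
3. **LIF (Siegert)** — `r_i = F(mu_i(r), sigma_i(r))` with the
   first-passage transfer function and the diffusion-approximation
   moments

       mu_i      = v_rest + tau_m (sum_j w_ij r_j + h_i)
       sigma_i^2 = (tau_m / 2) (sum_j w_ij^2 r_j + j_ffw^2 s_i + j_bkg^2 s_bkg)

   `sigma` is the stationary SD of the *free* membrane potential (the
   quantity a threshold-free simulation measures, and the one the test
   suite pins against simulation); the Siegert formula converts it
   internally to the diffusion normalization (a factor sqrt(2) in the
   integration bounds).  `tau_ref` enters the Siegert formula natively,
   so no extra correction is applied there.

**Stability guard.** Inhibition-dominated weight matrices have a row-sum
eigenvalue that is strongly *negative* with `|lambda| > DeltaV`; the naive
condition "spectral radius of `W/DeltaV` below 1" would reject every
network of interest even though the dynamics is stable.  The implemented
guard therefore tests the actual stability condition of the rate
dynamics, `max Re lambda(W) < DeltaV` (dense spectrum for N <= 2000,
Arnoldi for larger networks; cached per weight matrix).

**Solver numerics.** Damped Picard `r <- (1 - a) r + a G(r)` with
`a = 0.2` by default, zero initialization, convergence when the RMS of
successive iterates falls below 1e-6 spikes/s (max 10,000 iterations; a
non-convergent solve raises an error carrying the residual trace).  The
damping is set by the negative row-sum mode: the iteration matrix
eigenvalue `1 - a (1 + |row sum|/DeltaV)` must stay inside the unit
circle, which for the shipped presets (|row sum| up to 4 DeltaV) requires
`a < 0.4`; 0.2 converges on all presets with a comfortable margin, at
~300 iterations per solve.  Within a sweep each condition starts from the
previous condition's solution.

**Siegert evaluation.** `1/r = tau_ref + tau_m sqrt(pi) * I` with
`I = integral of erfcx(-u)` between the reset and threshold bounds.
`erfcx` keeps the integrand overflow-free; the integral is evaluated by
unit-length Gauss–Legendre panels (24 nodes) on [-15, 8], an asymptotic
tail expansion below -15, and rate 0 above 8 (where the first-passage
time is astronomically long).  This vectorized rule matches adaptive
quadrature to ~1e-10 relative and recovers the deterministic
`sigma -> 0` limit analytically, so the fixed point iterates on exact
transfer-function values; an optional bilinear lookup table
(`SiegertLookup`) is provided but off by default because the direct
evaluation is already ~10 ms per iteration at N = 1250.

**Rectified-solver oracle.** For systems up to N = 10 the package also
ships an exhaustive active-set enumeration (solve the linear system on
each of the 2^N supports, keep the feasible one), used as an independent
check of the iterative solver.

## Tuning analysis

All statistics operate on doubled angles (orientation has period 180
degrees).  OSI/PO are the length and half-angle of the normalized
circular resultant; F0/F2 use the amplitude convention that recovers
`r = f0 + f2 cos 2(theta - phi)` exactly, which makes `OSI = F2/(2 F0)`
an identity.  The von Mises fit is the 3-parameter family
`A exp(kappa cos 2(theta - phi))` without additive offset (the tuning
width depends on `kappa` alone); fits are deterministic with four
phi-starts seeded at the circular-resultant PO, and the error index is
the RMS residual in percent of the curve mean (default exclusion
threshold 5 %, 20 % in the benchmark fits of strongly rectified curves).
Tuning width is the half-width at half-height between the fitted curve's
min and max, `0.5 arccos(ln cosh kappa / kappa)`, chosen because it is
the only convention that assigns the unrectified cosine input the finite
reference width of 45 degrees — the denominator of the sharpening
coefficient `SC = TW_out / TW_in`.  Note that with this convention a
*pure cosine* output of modulation depth c already fits with
`kappa ~ c > 0`, i.e. SC is slightly below 1 even in a perfectly linear
network; this bias is ~0.035 at the benchmark operating point and is why
"no sharpening" is read as SC within 0.05 of 1 rather than SC = 1.

The free-membrane-potential analysis corrects the measured mean potential
for reset hyperpolarization (`+ tau_m DeltaV r`) and compares it with the
input-based reconstruction, which is exactly the `mu` moment of the
theory.

## Default parameters and the benchmark fixtures

All defaults are package choices (overridable via config).  Full-scale
presets: N = 12,500 (80 % excitatory), 10 % in-degrees (1000/250),
`j_epsp = 0.2 mV`, `g = 4` (balanced, "linear") or `g = 8`
(inhibition-dominated).  The frozen benchmark fixtures scale this to
N = 1250 so a full sweep runs on one CPU in minutes:

| fixture          | model | g | k_exc/k_inh | delays        |
|------------------|-------|---|-------------|---------------|
| `pif_linear`     | PIF   | 4 | 40/10       | uniform 0.5–3 |
| `pif_rectified`  | PIF   | 8 | 400/100     | uniform 0.5–3 |
| `lif`            | LIF   | 8 | 400/100     | uniform 0.5–3 |
| `lif_synchronous`| LIF   | 8 | 400/100     | fixed 1.5 ms  |

The inhibition-dominated fixtures use denser in-degrees than the sparse
balanced one because the common-mode suppression scales with
`j (g k_inh - k_exc)`: at 400/100 the net row sum is -80 mV, giving a
five-fold suppression of the input baseline relative to the modulation,
while the bulk spectral radius (16.5 mV) stays below threshold distance.

Stimulus defaults: `m = 0.5`, `s_max = 3000 /s`, `s_bkg = 9000 /s`,
`j_ffw = j_bkg = 0.1 mV`, 12 orientations, contrasts {1/3, 2/3, 1},
5 s per condition.  This operating point was chosen once, from the rate
theory (not from simulations), to land the networks in the regime the
model is about: spontaneous activity of a few spikes/s, evoked rates
around 5–10 spikes/s (LIF) with median OSI ~0.55, prevalent rectification
in the g = 8 regime at all contrasts, none in the balanced g = 4 regime,
and a background drive large enough that the *output* baseline rises far
less than three-fold over the three-fold input-baseline range.  Two of
the regime properties pull in opposite directions in pure linear theory
(output-baseline contrast growth times base/mod-ratio spread equals the
input factor 3 exactly), so their joint satisfaction runs through the
nonlinearities: rectification-driven normalization and, for the contrast
invariance display, subtraction of the spontaneous rate before
normalization — the same procedure used for population tuning curves in
the experimental literature.

## What the benchmarks show — and what they do not

The synthetic networks realize the model's own assumptions: Poisson
external input, delta synapses, uncorrelated drive, exact in-degrees.
Passing benchmarks therefore establish the *internal* consistency of
simulator, theory, and analysis (simulation and mean-field prediction
agree neuron by neuron; rectification sharpens; tuning is contrast
invariant; the prediction is insensitive to the synchrony state), not the
biological fidelity of any parameter.  Real cortical input is correlated
and conductance-based, synapses have kinetics and heterogeneous
amplitudes, and connectivity is distance- and feature-dependent — all out
of scope here.  The diffusion approximation behind the Siegert layer
additionally assumes PSPs small against `sigma`; with `j_epsp = 0.2 mV`
and IPSPs of 1.6 mV against `sigma ~ 4-5 mV` the residual error is at the
percent level, visible as a small flat offset in the LIF benchmark (the
per-neuron correlation is ~0.97 while the RMS difference is ~30 % of the
low mean rate).

## Known limitations

* Threshold crossings are grid-aligned; fluctuation-driven rates carry a
  `-O(sqrt(dt))` bias (~2 % at 0.1 ms).
* The rectified solver handles degenerate active sets by damping;
  persistent cycling raises a non-convergence error rather than silently
  accepting an oscillating solution.
* `cv_isi` requires only `min_spikes` spikes (default 20); at the 2-spike
  minimum a single interval yields CV = 0.
* The von Mises family has no additive offset, so curves with a large
  untuned pedestal fit with inflated error indices and are excluded by
  the error-index threshold rather than fitted with a baseline term (an
  offset variant can be added via the fit bounds if needed).
* Simulated and analytical sweeps share the weight matrix but not input
  realizations; comparisons are therefore of stationary rates, not of
  trial-by-trial responses.
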