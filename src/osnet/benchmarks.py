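"""Validation benchmarks: end-to-end checks of simulator, theory, analysis.

Each function recomputes one headline property of the model from scratch at
the frozen benchmark fixture scale (N = 1250; see
:func:`osnet.experiment.fixture_config`) and returns a dict of plain
numbers.  They are exercised by the test suite and by
``scripts/acceptance.py``.

The benchmark problems:

* simulated stationary rates vs the linear rate prediction on the balanced
  PIF fixture (per-neuron scatter, pooled over contrasts and orientations);
* the rectified fixed point vs exhaustive active-set enumeration on small
  random systems, plus its residual-trace behaviour;
* the Siegert transfer function vs long single-neuron Monte-Carlo runs and
  vs its deterministic closed-form limit;
* the Siegert fixed point vs simulated rates on the inhibition-dominated
  LIF fixture;
* exactness of the subthreshold integration scheme;
* closed-form identities of the circular statistics and tuning width, and
  von Mises parameter recovery under noise;
* contrast invariance of population tuning (spontaneous-subtracted,
  aligned, max-normalized mean curves; PO stability of well-tuned
  neurons);
* sharpening coefficients of the rectified vs the linear PIF regime;
* robustness of the rate prediction to the dynamical state (identical
  fixed vs distributed delays);
* reconstruction of the free membrane potential from the net input.
"""

from __future__ import annotations

import numpy as np

from .experiment import (ExperimentConfig, build_network, derived_seed,
                         fixture_config, run_orientation_sweep)
from .network import DelaySpec
from .simulate import NeuronParams, simulate
from .stimulus import DriveSpec, StimulusConfig, build_drive
from .theory import (input_moments, lif_fixed_point, linear_rates,
                     rectified_active_set_oracle, rectified_fixed_point,
                     siegert_rate, _picard)
from .tuning import (align_curves, dpo, f0_f2, fit_von_mises,
                     free_membrane_potential, osi_po, tuning_width)

DT = 0.1                 # ms, network simulations
T_COND = 5000.0          # ms per stimulus condition
T_TRANSIENT = 200.0      # ms excluded from rate estimates


def _pearson(x, y) -> float:
    return float(np.corrcoef(np.asarray(x, float), np.asarray(y, float))[0, 1])


# ---------------------------------------------------------------------------
# Fixture sweeps
# ---------------------------------------------------------------------------

def pif_linear_fixture(seed: int) -> ExperimentConfig:
    cfg = fixture_config("pif_linear")
    cfg.seed = derived_seed(seed, 11)
    cfg.simulation.duration = T_COND
    return cfg


def lif_fixture(seed: int) -> ExperimentConfig:
    cfg = fixture_config("lif")
    cfg.seed = derived_seed(seed, 12)
    cfg.simulation.duration = T_COND
    return cfg


def sim_vs_linear_theory(seed: int) -> dict:
    """Balanced PIF fixture: simulated rates against the linear prediction.

    Pools every neuron in every evoked condition (4 orientations x 3
    contrasts, 5 s each) and reports the Pearson correlation and the RMS
    difference in percent of the population mean rate.
    """
    bundle = run_orientation_sweep(pif_linear_fixture(seed))
    sim, th = [], []
    for key, cond in bundle.conditions.items():
        if key == "spont":
            continue
        sim.append(cond.sim_rates)
        th.append(np.maximum(cond.theory["linear"], 0.0))
    sim = np.concatenate(sim)
    th = np.concatenate(th)
    rms = float(np.sqrt(np.mean((sim - th) ** 2)))
    return {
        "pearson_r": _pearson(sim, th),
        "rms_pct_of_mean": 100.0 * rms / sim.mean(),
        "mean_rate_hz": float(sim.mean()),
        "n": int(sim.size),
    }


# ---------------------------------------------------------------------------
# Rectified fixed point vs enumeration
# ---------------------------------------------------------------------------

def rectified_vs_active_set_oracle(seed: int, n_systems: int = 100) -> dict:
    """Damped Picard solution vs brute-force active-set enumeration.

    Random dense systems (N <= 10, spectral norm <= 0.85 DeltaV, mixed-sign
    drives) solved both ways; reports the worst rate deviation, the number
    of support mismatches, and whether any residual trace increased after
    the initial transient.
    """
    rng = np.random.default_rng(derived_seed(seed, 21))
    dv = 20.0
    max_dev = 0.0
    support_mismatch = 0
    monotone_violations = 0
    worst_residual = 0.0
    for _ in range(n_systems):
        n = int(rng.integers(2, 11))
        w = rng.normal(0.0, 1.0, (n, n))
        w *= rng.uniform(0.3, 0.85) * dv / max(np.linalg.norm(w, 2), 1e-12)
        h = rng.normal(0.0, 5.0 * dv, n)
        r_oracle = rectified_active_set_oracle(w, h, dv)

        def gmap(r, w=w, h=h):
            return np.maximum(0.0, (w @ r + h) / dv)

        r, trace = _picard(gmap, n, 1e-10, 50000, 0.5)
        max_dev = max(max_dev, float(np.abs(r - r_oracle).max()))
        if ((r > 1e-8) != (r_oracle > 1e-8)).any():
            support_mismatch += 1
        res = trace.residuals
        worst_residual = max(worst_residual, float(res[-1]))
        tail = res[max(2, len(res) // 5):]
        if (np.diff(tail) > 1e-14).any():
            monotone_violations += 1
    return {
        "max_rate_dev": max_dev,
        "support_mismatches": support_mismatch,
        "monotone_violations": monotone_violations,
        "final_residual": worst_residual,
        "n": n_systems,
    }


# ---------------------------------------------------------------------------
# Siegert transfer function
# ---------------------------------------------------------------------------

def siegert_deterministic_limit(seed: int = 0) -> dict:
    """Relative error of the sigma -> 0 limit against the closed form."""
    neuron = NeuronParams(model="lif", tau_m=20.0, v_th=20.0, tau_ref=0.0)
    errs = []
    for mu in (25.0, 30.0, 40.0, 60.0):
        exact = 1.0 / (0.02 * np.log(mu / (mu - 20.0)))
        approx = siegert_rate(mu, 1e-6, neuron)
        errs.append(abs(approx - exact) / exact)
    return {"max_rel_err": float(max(errs)), "n": len(errs)}


def siegert_vs_monte_carlo(seed: int, t_sim_ms: float = 150_000.0,
                           dt: float = 0.01) -> dict:
    """Single-neuron LIF Monte-Carlo rates vs the Siegert prediction.

    Five (mu, sigma) points spanning the sub- and suprathreshold regimes,
    realized by balanced excitatory/inhibitory Poisson streams with small
    PSPs (0.05 mV) so the diffusion approximation is accurate.  The
    z-score uses the batch-means standard error of the simulated rate.
    """
    neuron = NeuronParams(model="lif", tau_m=20.0, v_th=20.0, tau_ref=2.0)
    j = 0.05
    # (mu mV, sigma mV) targets -> Poisson rates of the +j / -j streams
    points = [(10.0, 4.0), (15.0, 5.0), (18.0, 3.0), (21.0, 3.0), (25.0, 5.0)]
    zs, rates, preds = [], [], []
    for idx, (mu_t, sig_t) in enumerate(points):
        tau_s = neuron.tau_m / 1000.0
        tot = 2.0 * sig_t ** 2 / (tau_s * j ** 2)      # s_e + s_i
        diff = (mu_t - neuron.v_rest) / (tau_s * j)    # s_e - s_i
        s_e, s_i = (tot + diff) / 2.0, (tot - diff) / 2.0
        drive = DriveSpec(ffw_rate=np.array([s_e]), bkg_rate=float(s_i),
                          j_ffw=j, j_bkg=-j)
        mu, sig = input_moments(None, np.zeros(1), drive, neuron)
        pred = float(np.atleast_1d(siegert_rate(mu, sig, neuron))[0])
        sp = simulate(None, None, None, neuron, drive, duration=t_sim_ms,
                      dt=dt, seed=derived_seed(seed, 31, idx))
        t0 = T_TRANSIENT
        r = float(sp.rates(t0, t_sim_ms)[0])
        n_batch = 20
        width = (t_sim_ms - t0) / n_batch
        batch = np.array([sp.rates(t0 + k * width, t0 + (k + 1) * width)[0]
                          for k in range(n_batch)])
        se = float(batch.std(ddof=1) / np.sqrt(n_batch))
        zs.append(abs(r - pred) / se if se > 0 else np.inf)
        rates.append(r)
        preds.append(pred)
    return {
        "max_abs_z": float(max(zs)),
        "sim_rates_hz": rates,
        "siegert_rates_hz": preds,
        "n": len(points),
    }


# ---------------------------------------------------------------------------
# LIF fixture: theory vs simulation, contrast invariance, PO stability
# ---------------------------------------------------------------------------

def run_lif_bundle(seed: int):
    """The inhibition-dominated LIF fixture sweep (3 contrasts x 12
    orientations x 5 s + spontaneous), shared by several benchmarks."""
    return run_orientation_sweep(lif_fixture(seed))


def lif_sim_vs_theory(bundle) -> dict:
    """Per-neuron simulated rates vs the Siegert fixed point, pooled over
    all evoked conditions of the LIF fixture."""
    sim, th = [], []
    for key, cond in bundle.conditions.items():
        if key == "spont":
            continue
        sim.append(cond.sim_rates)
        th.append(cond.theory["lif"])
    sim, th = np.concatenate(sim), np.concatenate(th)
    rms = float(np.sqrt(np.mean((sim - th) ** 2)))
    return {
        "pearson_r": _pearson(sim, th),
        "rms_pct_of_mean": 100.0 * rms / sim.mean(),
        "mean_rate_hz": float(sim.mean()),
        "n": int(sim.size),
    }


def contrast_invariance(bundle) -> dict:
    """Shape stability of population tuning across the three contrasts.

    Per contrast: subtract each neuron's spontaneous rate (clipped at 0),
    align curves on the input PO, average over the population, normalize to
    the maximum.  Reports the worst pointwise difference between contrast
    pairs, and the fraction of well-tuned neurons (OSI above the
    population median at the highest contrast) whose measured PO moves by
    at most one grid step between the lowest and highest contrast.
    """
    cfg = bundle.config
    contrasts = cfg.stimulus.contrasts
    theta = cfg.stimulus.theta_grid
    spont = bundle.spont_rates("sim")
    aligned = {}
    curves = {}
    for c in contrasts:
        cur = bundle.tuning_curves(c, "sim")
        curves[c] = cur
        r = np.clip(cur.rates - spont[:, None], 0.0, None)
        mean_curve = align_curves(r, theta, bundle.pos.po).mean(axis=0)
        aligned[c] = mean_curve / mean_curve.max()
    devs = []
    cs = list(contrasts)
    for i in range(len(cs)):
        for k in range(i + 1, len(cs)):
            devs.append(float(np.abs(aligned[cs[i]] - aligned[cs[k]]).max()))

    osi_hi, po_hi = osi_po(curves[cs[-1]].rates, theta)
    _, po_lo = osi_po(curves[cs[0]].rates, theta)
    well = osi_hi > np.nanmedian(osi_hi)
    shift = np.abs(dpo(po_hi[well], po_lo[well]))
    step = 180.0 / theta.size
    return {
        "max_shape_dev": max(devs),
        "po_stable_frac": float((shift <= step + 1e-9).mean()),
        "median_osi": float(np.nanmedian(osi_hi)),
        "n": int(curves[cs[-1]].n_neurons),
    }


# ---------------------------------------------------------------------------
# Exact integration
# ---------------------------------------------------------------------------

def exact_integration(seed: int = 0) -> dict:
    """Input-silenced LIF trajectory vs the analytic exponential, and PIF
    trajectory vs the cumulative PSP sum (bitwise)."""
    lif = NeuronParams(model="lif", tau_m=20.0, v_th=20.0, tau_ref=2.0)
    silent = DriveSpec(ffw_rate=np.array([0.0]), bkg_rate=0.0,
                       j_ffw=0.1, j_bkg=0.1)
    _, tr = simulate(None, None, None, lif, silent, duration=50.0, dt=0.1,
                     seed=1, record_v=[0], v_init=[15.0])
    ana = 15.0 * np.exp(-tr.t / 20.0)
    lif_err = float(np.abs(tr.v[0] - ana).max())

    pif = NeuronParams(model="pif", tau_m=np.inf, v_th=1e9, tau_ref=0.0)
    drv = DriveSpec(ffw_rate=np.array([20000.0]), bkg_rate=10000.0,
                    j_ffw=0.1, j_bkg=-0.05)
    _, tr2 = simulate(None, None, None, pif, drv, duration=1000.0, dt=0.1,
                      seed=derived_seed(seed, 41), record_v=[0],
                      record_input=True, v_init=[0.0])
    ref = np.empty_like(tr2.psp_input[0])
    acc = 0.0
    for i, inc in enumerate(tr2.psp_input[0]):
        acc = acc + inc
        ref[i] = acc
    pif_err = float(np.abs(tr2.v[0] - ref).max())
    return {"lif_max_err_mv": lif_err, "pif_max_err_mv": pif_err,
            "n": int(tr.v.shape[1])}


# ---------------------------------------------------------------------------
# Circular statistics and von Mises closed forms
# ---------------------------------------------------------------------------

def circular_closed_forms(seed: int = 0) -> dict:
    """OSI/PO/F2 identities on flat, single-orientation and cosine curves."""
    theta = np.arange(12) * 15.0
    flat = np.full(12, 3.0)
    osi_flat, _ = osi_po(flat, theta)
    single = np.zeros(12)
    single[4] = 7.0
    osi_single, po_single = osi_po(single, theta)
    m = 0.6
    phi = 75.0
    cos_curve = 1.0 + m * np.cos(np.deg2rad(2 * (theta - phi)))
    osi_cos, po_cos = osi_po(cos_curve, theta)
    f0, f2 = f0_f2(cos_curve, theta)
    return {
        "osi_flat": abs(osi_flat),
        "osi_single_err": abs(osi_single - 1.0),
        "po_single_err": abs(po_single - theta[4]),
        "osi_cosine_err": abs(osi_cos - m / 2.0),
        "po_cosine_err": abs(po_cos - phi),
        "f2_err": abs(f2 - m * f0),
        "n": theta.size,
    }


def von_mises_recovery(seed: int, n_rep: int = 100) -> dict:
    """Noiseless and noisy von Mises parameter recovery.

    Noiseless: exact recovery of (A, kappa, phi).  Noisy: Gaussian noise
    with SD 5% of the peak on 12-point curves, 100 replicates; reports the
    median absolute phi error.  Also the tuning-width closed forms.
    """
    theta = np.arange(12) * 15.0
    a, kappa, phi = 10.0, 2.0, 60.0
    clean = a * np.exp(kappa * np.cos(np.deg2rad(2 * (theta - phi))))
    fit = fit_von_mises(clean, theta)
    noiseless = max(abs(fit.amplitude - a) / a, abs(fit.kappa - kappa) / kappa,
                    abs(dpo(fit.phi, phi)))
    rng = np.random.default_rng(derived_seed(seed, 51))
    peak = clean.max()
    phi_errs = []
    for _ in range(n_rep):
        noisy = np.clip(clean + rng.normal(0, 0.05 * peak, 12), 0, None)
        f = fit_von_mises(noisy, theta)
        if f.ok:
            phi_errs.append(abs(dpo(f.phi, phi)))
    tw_checks = {
        "tw_kappa0_deg": tuning_width(0.0),
        "tw_kappa1_deg": tuning_width(1.0),
        "tw_monotone": float(np.all(np.diff(
            tuning_width(np.linspace(0.01, 20, 200))) < 0)),
    }
    return {
        "noiseless_max_rel_err": float(noiseless),
        "median_abs_phi_err_deg": float(np.median(phi_errs)),
        "n": n_rep,
        **tw_checks,
    }


# ---------------------------------------------------------------------------
# Sharpening
# ---------------------------------------------------------------------------

def _median_sc(rates, theta, subsample: int = 1) -> float:
    scs = []
    for i in range(0, rates.shape[0], subsample):
        f = fit_von_mises(rates[i], theta)
        if f.ok and f.error_index < 20.0:
            scs.append(tuning_width(f.kappa) / 45.0)
    return float(np.median(scs))


def sharpening(seed: int) -> dict:
    """Median sharpening coefficient: rectified vs linear PIF regime.

    Computed from the analytical tuning curves (rectified fixed point for
    the inhibition-dominated fixture, linear solution for the balanced
    one) at the highest contrast, against the 45-degree cosine input
    width.
    """
    theta = np.arange(12) * 15.0
    neuron = NeuronParams(model="pif", tau_m=np.inf)

    cfg = fixture_config("pif_rectified")
    cfg.seed = derived_seed(seed, 61)
    w, _, pos = build_network(cfg)
    r0 = None
    cols = []
    for th in theta:
        drive = build_drive(pos, th, 1.0, cfg.stimulus)
        r0, _ = rectified_fixed_point(w, drive, neuron, damping=0.2, r0=r0)
        cols.append(r0)
    sc_rect = _median_sc(np.column_stack(cols), theta)

    cfg = fixture_config("pif_linear")
    cfg.stimulus.n_theta = 12
    cfg.seed = derived_seed(seed, 62)
    w, _, pos = build_network(cfg)
    cols = [linear_rates(w, build_drive(pos, th, 1.0, cfg.stimulus), neuron)
            for th in theta]
    sc_lin = _median_sc(np.maximum(np.column_stack(cols), 0.0), theta)
    return {
        "median_sc_rectified": sc_rect,
        "median_sc_linear": sc_lin,
        "n": 1250,
    }


# ---------------------------------------------------------------------------
# Dynamic-state robustness
# ---------------------------------------------------------------------------

def state_robustness(seed: int) -> dict:
    """One weight matrix, distributed vs identical delays: the same Siegert
    fixed point should predict both simulated rate vectors equally well."""
    cfg = lif_fixture(seed)
    w, delays, pos = build_network(cfg)
    neuron = cfg.neuron
    drive = build_drive(pos, 90.0, 2 / 3, cfg.stimulus)
    r_th, _ = lif_fixed_point(w, drive, neuron, damping=0.2)
    sp_dist = simulate(w.topology, w, delays, neuron, drive,
                       duration=T_COND, dt=DT, seed=derived_seed(seed, 71))
    fixed = np.full(delays.shape, 1.5)
    sp_fix = simulate(w.topology, w, fixed, neuron, drive,
                      duration=T_COND, dt=DT, seed=derived_seed(seed, 72))
    r_dist = _pearson(sp_dist.rates(T_TRANSIENT), r_th)
    r_fix = _pearson(sp_fix.rates(T_TRANSIENT), r_th)
    return {
        "pearson_distributed": r_dist,
        "pearson_fixed": r_fix,
        "pearson_diff": abs(r_dist - r_fix),
        "n": int(w.topology.n_total),
    }


# ---------------------------------------------------------------------------
# Membrane-potential reconstruction
# ---------------------------------------------------------------------------

def vm_reconstruction(seed: int, n_rec: int = 250) -> dict:
    """Reset-corrected measured mean potential vs the input-based
    reconstruction (the mu moment), on the LIF fixture."""
    cfg = lif_fixture(seed)
    w, delays, pos = build_network(cfg)
    neuron = cfg.neuron
    drive = build_drive(pos, 90.0, 2 / 3, cfg.stimulus)
    rec = np.linspace(0, w.topology.n_total - 1, n_rec).astype(int)
    sp, tr = simulate(w.topology, w, delays, neuron, drive, duration=T_COND,
                      dt=DT, seed=derived_seed(seed, 81), record_v=rec)
    rates = sp.rates(T_TRANSIENT)
    v_free = free_membrane_potential(tr.mean(T_TRANSIENT), rates[rec], neuron)
    mu, _ = input_moments(w, rates, drive, neuron)
    mad = float(np.abs(v_free - mu[rec]).mean())
    return {"mad_mv": mad, "n": int(n_rec)}
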