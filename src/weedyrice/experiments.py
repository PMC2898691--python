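"""Reusable simulation experiments: simulator calibration, bottleneck
signatures, scenario recovery and a closed-form rejection-sampler check.

Each routine seeds all randomness from a single integer and returns plain
dictionaries, so the command line, the test-suite and reproduction scripts
all exercise identical code paths.
"""

from __future__ import annotations

import numpy as np

from .abc_scenarios import (
    default_scenarios,
    likelihood_surface,
    rejection_sample,
    run_abc,
    simulate_reference_table,
)
from .demography_sim import (
    CoalescentConfig,
    DemographicModel,
    ScalingConfig,
    constant_size_demography,
    locus_seed,
    simulate_dataset,
    simulate_locus,
)
from .popgen_stats import _harmonic, _tajima_constants, summary_vector_from_arrays
from .synthetic_data import default_scaling, preset_model

__all__ = [
    "calibrate_constant_size",
    "bottleneck_signature",
    "bottleneck_surface_mode",
    "scenario_recovery",
    "toy_normal_posterior",
]


def calibrate_constant_size(n: int = 10, n_loci: int = 48,
                            length_bp: int = 500, replicates: int = 2000,
                            seed: int = 1,
                            scaling: ScalingConfig | None = None) -> dict:
    """Neutral constant-size calibration of the simulator.

    Simulates ``replicates`` panels of ``n_loci`` independent loci at the
    default per-locus theta = 4*N_ref*mu*L and compares mean S, mean pi
    (pairwise differences per locus) and mean Tajima's D per locus with
    their analytic expectations theta*L*a_{n-1}, theta*L and 0.
    """
    scaling = scaling or default_scaling()
    theta = scaling.theta_locus(length_bp)
    demography = constant_size_demography(1.0)
    a1, e1, e2 = _tajima_constants(n)

    s_vals, pi_vals, d_vals = [], [], []
    for rep in range(replicates):
        for j in range(n_loci):
            locus = simulate_locus(demography, (n,), theta, 0.0,
                                   locus_seed(seed + rep, j))
            c = locus.genotypes.sum(axis=1)
            s = len(c)
            s_vals.append(s)
            k_hat = float(np.sum(2.0 * c * (n - c) / (n * (n - 1.0))))
            pi_vals.append(k_hat)
            if s > 0:
                var = e1 * s + e2 * s * (s - 1)
                d_vals.append((k_hat - s / a1) / np.sqrt(var))
    s_vals = np.asarray(s_vals, dtype=float)
    pi_vals = np.asarray(pi_vals)
    d_vals = np.asarray(d_vals)
    m = len(s_vals)
    return {
        "theta_locus": theta,
        "expected_s": theta * _harmonic(n),
        "mean_s": float(s_vals.mean()),
        "se_s": float(s_vals.std(ddof=1) / np.sqrt(m)),
        "expected_pi": theta,
        "mean_pi": float(pi_vals.mean()),
        "se_pi": float(pi_vals.std(ddof=1) / np.sqrt(m)),
        "mean_tajimas_d": float(d_vals.mean()),
        "se_tajimas_d": float(d_vals.std(ddof=1) / np.sqrt(len(d_vals))),
        "n_loci_total": m,
    }


def _pooled_pi(locus_arrays, col_slice, total_length_bp: float) -> float:
    """Pooled per-kb pi for one population slice of the haplotype columns."""
    total = 0.0
    for g in locus_arrays:
        if g.size == 0:
            continue
        sub = g[:, col_slice]
        n = sub.shape[1]
        c = sub.sum(axis=1)
        total += float(np.sum(2.0 * c * (n - c) / (n * (n - 1.0))))
    return total / total_length_bp * 1000.0


def bottleneck_signature(replicates: int = 100, n_loci: int = 48,
                         length_bp: int = 500, seed: int = 1,
                         preset: str = "SH") -> dict:
    """Fraction of replicate panels in which the weed's pooled diversity
    falls below the progenitor's, under a named preset."""
    scaling = default_scaling()
    model = preset_model(preset, scaling)
    from .synthetic_data import preset_config
    config = preset_config(preset, n_loci=n_loci, length_bp=length_bp)
    below = 0
    ratios = []
    for rep in range(replicates):
        ds = simulate_dataset(model, scaling, config, seed + rep)
        arrays = ds.locus_arrays()
        pi_w = _pooled_pi(arrays, slice(0, config.n_weed), ds.total_length_bp)
        pi_p = _pooled_pi(arrays, slice(config.n_weed, None),
                          ds.total_length_bp)
        if pi_w < pi_p:
            below += 1
        ratios.append(pi_w / pi_p if pi_p > 0 else np.nan)
    return {
        "replicates": replicates,
        "fraction_weed_below_progenitor": below / replicates,
        "mean_diversity_ratio": float(np.nanmean(ratios)),
    }


def bottleneck_surface_mode(sims: int = 4000, n_loci: int = 16,
                            length_bp: int = 500, n_weed: int = 12,
                            n_progenitor: int = 12, tolerance: float = 0.05,
                            seed: int = 1) -> dict:
    """Recover the bottleneck-intensity surface for data planted with a
    99% decline (eta_b/eta_r = 0.01) under the founding-time scenario.

    Returns the surface mode on the (current-size ratio, intensity) plane.
    """
    scaling = default_scaling()
    config = CoalescentConfig.uniform_panel(n_weed, n_progenitor, n_loci,
                                            length_bp)
    eta_c = 0.28 * scaling.n_ref
    truth = DemographicModel(eta_c=eta_c, eta_b=max(0.01 * 0.06 * eta_c, 1),
                             eta_r=0.06 * eta_c, tau_s=200.0, tau_f=200.0,
                             tau_g=100.0)
    observed_ds = simulate_dataset(truth, scaling, config, seed)
    observed = summary_vector_from_arrays(observed_ds.locus_arrays(), n_weed,
                                          observed_ds.total_length_bp)
    scenarios = {"founding_us": default_scenarios()["founding_us"]}
    table = simulate_reference_table(scenarios, sims, scaling, config,
                                     seed=seed + 1)
    result = run_abc(observed, table, tolerance, "pooled-quantile")
    surface = likelihood_surface(result, "founding_us")
    x_mode, y_mode = surface.mode()
    return {
        "planted_intensity_percent": truth.bottleneck_intensity,
        "n_accepted": result.n_accepted["founding_us"],
        "mode_eta_r_ratio": x_mode,
        "mode_intensity_percent": y_mode,
    }


def _recovery_truth_models(scaling: ScalingConfig) -> dict[str, DemographicModel]:
    """Generating models for the recovery experiment: a founding-time
    divergence with a severe bottleneck, and a pre-domestication
    divergence (split 30,000 ybp) with a mild bottleneck."""
    eta_c = 0.28 * scaling.n_ref
    return {
        "founding_us": DemographicModel(
            eta_c=eta_c, eta_r=0.06 * eta_c,
            eta_b=max(0.01 * 0.06 * eta_c, 1.0),
            tau_s=200.0, tau_f=200.0, tau_g=100.0),
        "pre_domestication": DemographicModel(
            eta_c=eta_c, eta_r=0.3 * eta_c, eta_b=0.5 * 0.3 * eta_c,
            tau_s=30_000.0, tau_f=200.0, tau_g=100.0),
    }


def scenario_recovery(n_replicates: int = 20, sims_per_scenario: int = 10_000,
                      n_loci: int = 32, length_bp: int = 500,
                      n_weed: int = 16, n_progenitor: int = 16,
                      tolerance: float = 0.002, seed: int = 1,
                      scenario_names: tuple[str, ...] = (
                          "founding_us", "pre_domestication"),
                      progress: bool = False) -> dict:
    """Paired scenario-recovery experiment.

    One reference table (``sims_per_scenario`` per scenario) is simulated
    once and shared: rejection only compares distances, so the table is
    independent of any observed dataset. For each generating condition,
    ``n_replicates`` pseudo-observed panels are classified by the highest
    approximate likelihood; ties count as failures.
    """
    scaling = default_scaling()
    config = CoalescentConfig.uniform_panel(n_weed, n_progenitor, n_loci,
                                            length_bp)
    scenarios = {k: v for k, v in default_scenarios().items()
                 if k in scenario_names}
    table = simulate_reference_table(scenarios, sims_per_scenario, scaling,
                                     config, seed=seed, progress=progress)
    truths = _recovery_truth_models(scaling)
    recovery, assignments = {}, {}
    for cond_idx, truth_name in enumerate(scenario_names):
        model = truths[truth_name]
        correct = 0
        calls = []
        for rep in range(n_replicates):
            obs_seed = seed + 100_000 + 1000 * rep + cond_idx
            ds = simulate_dataset(model, scaling, config, obs_seed)
            observed = summary_vector_from_arrays(
                ds.locus_arrays(), n_weed, ds.total_length_bp)
            result = run_abc(observed, table, tolerance, "pooled-quantile")
            lik = result.likelihoods
            best = max(lik, key=lik.get)
            unique_best = sum(
                1 for v in lik.values() if v == lik[best]) == 1
            calls.append(best if unique_best else "tie")
            if unique_best and best == truth_name:
                correct += 1
        recovery[truth_name] = correct / n_replicates
        assignments[truth_name] = calls
    return {
        "sims_per_scenario": sims_per_scenario,
        "n_replicates": n_replicates,
        "tolerance": tolerance,
        "recovery_rate": recovery,
        "assignments": assignments,
    }


def toy_normal_posterior(n_draws: int = 100_000, epsilon: float = 0.2,
                         observed: float = 1.0, seed: int = 1) -> dict:
    """Conjugate normal-normal check of the rejection kernel.

    Prior theta ~ N(0, 1), one observation x | theta ~ N(theta, 1). The
    analytic posterior mean given x is x/2; rejection sampling with window
    epsilon around the observed x must converge to it.
    """
    rng = np.random.default_rng(seed)
    theta = rng.normal(0.0, 1.0, n_draws)
    x = theta + rng.normal(0.0, 1.0, n_draws)
    idx = rejection_sample(np.array([observed]), x[:, None],
                           np.array([1.0]), epsilon)
    analytic = observed / 2.0
    return {
        "n_accepted": int(len(idx)),
        "posterior_mean": float(theta[idx].mean()),
        "analytic_posterior_mean": analytic,
    }
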