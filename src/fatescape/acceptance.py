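"""End-to-end validation computations on synthetic study-scale panels.

Each function regenerates its inputs from a seed, runs the relevant part
of the package, and returns the measured quantities.  These are the checks
behind the test suite's integration tests and the repository's
reproduction script: projector geometry, Glauber equilibrium, basin
stability under burst noise and dilution, signal-driven switching, the
projection null, permutation statistics, and full-pipeline recovery.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .dynamics import (
    DynamicsConfig,
    boltzmann_distribution,
    dilute_coupling,
    glauber_state_counts,
    simulate,
    switch_fate,
)
from .hybrids import classify_hybrid, projection_null
from .landscape import EpigeneticLandscape
from .preprocess import preprocess_pipeline, rank_to_zscore
from .reprogramming import (
    hypergeometric_tail,
    permutation_tail_probability,
    reprogramming_scores,
)
from .synthetic import (
    SyntheticSpec,
    synth_fate_panel,
    synth_hybrid_profiles,
    synth_replicates,
)


def projector_identities(seed: int, n_panels: int = 50) -> dict:
    """Worst-case deviation of the projector identities over random panels.

    Panel sizes are drawn log-uniformly with N up to 2000 and p up to 50
    (one panel pinned at the maximum), and for each panel the checks are
    J^2 = J, J xi = xi, trace J = p, a(xi^b) = indicator, H_basin(xi) =
    -N/2 and H_basin >= -N/2 on random states.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    sizes = []
    for k in range(n_panels):
        if k == 0:
            n, p = 2000, 50
        else:
            n = int(np.exp(rng.uniform(np.log(100), np.log(2000))))
            p = int(rng.integers(2, min(50, max(3, n // 20)) + 1))
        sizes.append((n, p))
        panel = synth_fate_panel(
            SyntheticSpec(n_tfs=n, n_fates=p, seed=int(rng.integers(2**31)))
        )
        land = EpigeneticLandscape().fit(panel)
        j = land.coupling_
        xi = land.xi_
        worst = max(worst, float(np.abs(j @ j - j).max()))
        worst = max(worst, float(np.abs(j @ xi - xi).max()))
        worst = max(worst, abs(float(np.trace(j)) - p))
        worst = max(worst, float(np.abs(land.transform(xi.T) - np.eye(p)).max()))
        for col in range(p):
            e = land.energy(xi[:, col])
            worst = max(worst, abs(e.h_basin + n / 2))
        states = rng.choice([-1.0, 1.0], size=(5, n))
        for s in states:
            gap = land.energy(s).h_basin + n / 2
            worst = max(worst, max(0.0, -gap))
    return {"max_abs_error": worst, "n_panels": n_panels, "sizes": sizes}


def equilibrium_tv_distance(
    seed: int,
    n_tfs: int = 10,
    n_fates: int = 2,
    beta: float = 1.0,
    n_updates: int = 2_000_000,
) -> dict:
    """Total-variation distance between a Glauber run and the exact Boltzmann law."""
    panel = synth_fate_panel(SyntheticSpec(n_tfs=n_tfs, n_fates=n_fates, seed=seed))
    land = EpigeneticLandscape().fit(panel)
    b = np.zeros(n_tfs)
    counts = glauber_state_counts(
        land.coupling_, b, beta=beta, n_updates=n_updates,
        burn_in=n_updates // 20, seed=seed + 1,
    )
    emp = counts / counts.sum()
    exact = boltzmann_distribution(land.coupling_, b, beta=beta)
    return {
        "tv_distance": float(0.5 * np.abs(emp - exact).sum()),
        "n_updates": n_updates,
    }


def predictivity_reconstruction_error(seed: int, n_states: int = 100) -> dict:
    """Max error of rebuilding projections from the predictivity matrix."""
    panel = synth_fate_panel(SyntheticSpec(n_tfs=500, n_fates=12, seed=seed))
    land = EpigeneticLandscape().fit(panel)
    rng = np.random.default_rng(seed + 1)
    states = rng.choice([-1.0, 1.0], size=(n_states, 500))
    direct = land.transform(states)
    rebuilt = states @ land.predictivity_ / 500
    return {"max_abs_error": float(np.abs(direct - rebuilt).max()), "n_states": n_states}


def basin_stability(
    seed: int,
    n_tfs: int = 1000,
    n_fates: int = 10,
    flip_fraction: float = 0.10,
    dilution: float = 0.20,
    n_sweeps: int = 50,
) -> dict:
    """Return of a perturbed fate under burst noise, intact and diluted couplings.

    10% of TF states are flipped, then beta = 4 Glauber dynamics with 2%
    bursts every 10 sweeps runs for 50 sweeps; reported is the median
    projection on the start fate over the last half of the recording.
    """
    panel = synth_fate_panel(SyntheticSpec(n_tfs=n_tfs, n_fates=n_fates, seed=seed))
    land = EpigeneticLandscape().fit(panel)
    rng = np.random.default_rng(seed + 1)
    s0 = land.xi_[:, 0].copy()
    s0[rng.choice(n_tfs, int(round(flip_fraction * n_tfs)), replace=False)] *= -1
    cfg = DynamicsConfig(
        beta=4.0, n_sweeps=n_sweeps, burst_fraction=0.02,
        burst_period_sweeps=10, seed=seed + 2,
    )
    traj = simulate(s0, land, cfg)
    half = traj.projections.shape[0] // 2
    full = float(np.median(traj.projections[half:, 0]))
    jd = dilute_coupling(land.coupling_, dilution, seed=seed + 3)
    traj_d = simulate(s0, land, cfg, j=jd)
    diluted = float(np.median(traj_d.projections[half:, 0]))
    return {
        "projection_full": full,
        "projection_diluted": diluted,
        "initial_projection": float(traj.projections[0, 0]),
        "n_tfs": n_tfs,
    }


def signal_switching(seed: int, n_tfs: int = 500, n_sweeps: int = 40) -> dict:
    """Directed fate switching: D[target, source] = 1 vs no signal."""
    panel = synth_fate_panel(SyntheticSpec(n_tfs=n_tfs, n_fates=3, seed=seed))
    land = EpigeneticLandscape().fit(panel)
    cfg = DynamicsConfig(beta=4.0, n_sweeps=n_sweeps, burst_fraction=0.0, seed=seed + 1)
    a, b = land.fate_names_[0], land.fate_names_[1]
    driven = switch_fate(a, {(b, a): 1.0}, land, cfg)
    held = switch_fate(a, {}, land, cfg)
    return {
        "projection_on_target_driven": float(driven.projections[-1][1]),
        "projection_on_source_driven": float(driven.projections[-1][0]),
        "projection_on_source_held": float(held.projections[-1][0]),
        "projection_on_target_held": float(held.projections[-1][1]),
        "n_tfs": n_tfs,
    }


def null_sd_agreement(seed: int, n_tfs: int = 1000, n_fates: int = 20, n_draws: int = 10_000) -> dict:
    """Sampled per-fate projection null sd vs the closed form sqrt((A^-1)_aa/N)."""
    panel = synth_fate_panel(SyntheticSpec(n_tfs=n_tfs, n_fates=n_fates, seed=seed))
    land = EpigeneticLandscape().fit(panel)
    null = projection_null(land, n_draws=n_draws, seed=seed + 1)
    closed = null.closed_form_sd(land.correlation_inv_, n_tfs)
    rel = np.abs(null.sd / closed - 1.0)
    return {
        "max_rel_error": float(rel.max()),
        "pooled_sd": float(null.pooled_sd),
        "closed_form_mean_sd": float(closed.mean()),
        "n_draws": n_draws,
    }


def permutation_consistency(seed: int, n_perm: int = 100_000) -> dict:
    """Monte-Carlo label permutation vs the hypergeometric closed form.

    The Monte-Carlo check runs at N = 200, k = 20, |set| = 2; the
    study-scale closed form (N = 1337, k = 50, |set| = 4) is the
    one-in-a-million level of the original protocol check.
    """
    panel = synth_fate_panel(SyntheticSpec(n_tfs=200, n_fates=4, seed=seed))
    land = EpigeneticLandscape().fit(panel)
    rng = np.random.default_rng(seed + 1)
    z = pd.DataFrame(
        rng.normal(size=(200, 4)),
        index=list(panel.tf_ids),
        columns=list(panel.fate_names),
    )
    table = reprogramming_scores(z, land)
    tf_set = [panel.tf_ids[5], panel.tf_ids[77]]
    res = permutation_tail_probability(
        table, panel.fate_names[0], tf_set, k=20, n_perm=n_perm, seed=seed + 2
    )
    return {
        "mc_frequency": res.frequency,
        "closed_form": res.closed_form,
        "abs_error_in_se": float(
            abs(res.frequency - res.closed_form) / res.standard_error
        ),
        "study_scale_tail": hypergeometric_tail(1337, 50, 4),
        "n_perm": n_perm,
    }


def pipeline_recovery(seed: int, n_tfs: int = 1000, n_fates: int = 8) -> dict:
    """synth -> preprocess -> build: fraction of planted panel entries recovered."""
    spec = SyntheticSpec(n_tfs=n_tfs, n_fates=n_fates, delta=2.0, sigma=0.5, seed=seed)
    panel = synth_fate_panel(spec)
    raw = synth_replicates(panel, spec)
    recovered, _, removed = preprocess_pipeline(raw)
    truth = panel.restrict(recovered.tf_ids)
    agreement = float((np.asarray(recovered.xi) == np.asarray(truth.xi)).mean())
    # the recovered panel must itself build a valid landscape
    EpigeneticLandscape().fit(recovered)
    return {
        "agreement": agreement,
        "n_removed": len(removed),
        "n_tfs": n_tfs,
    }


def hybrid_recovery(seed: int, n_tfs: int = 1000, n_fates: int = 20) -> dict:
    """Planted 3-way hybrids classified as exactly their constituent fates."""
    spec = SyntheticSpec(n_tfs=n_tfs, n_fates=n_fates, seed=seed)
    panel = synth_fate_panel(spec)
    rng = np.random.default_rng(seed + 1)
    subsets = []
    for _ in range(3):
        pick = rng.choice(n_fates, size=3, replace=False)
        subsets.append(tuple(panel.fate_names[int(i)] for i in sorted(pick)))
    hyb = synth_hybrid_profiles(panel, subsets, spec)
    z = rank_to_zscore(hyb)
    exact = 0
    for col, subset in zip(z.columns, subsets):
        rep = classify_hybrid(z[col], panel, seed=seed + 2)
        if set(rep.significant_fates) == set(subset):
            exact += 1
    return {
        "exact_fraction": exact / len(subsets),
        "n_hybrids": len(subsets),
        "n_tfs": n_tfs,
    }
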