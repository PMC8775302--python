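"""Simulation-based validation: parameter recovery and CI coverage.

Fitting pooled binomial likelihoods and bootstrapping them is only
trustworthy if, on data simulated from known truth under the package's
standing study conditions, the point estimates recover the truth and the
nominal 95% double-bootstrap intervals cover it at close to nominal rate.
This module runs that experiment end to end; tests assert the resulting
empirical coverage band.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .bootstrap_inference import double_bootstrap, efron_ci
from .synthetic_data import DEFAULT_TRUTH, SimulationConfig, TrueSelectivity, simulate_dataset

__all__ = ["coverage_experiment"]

_PARAM_GETTERS = {
    "C_smp": ("smp", lambda p: p.C),
    "L50_smp": ("smp", lambda p: p.L50),
    "SR_smp": ("smp", lambda p: p.SR),
    "L50_cd": ("codend", lambda p: p.L50),
    "SR_cd": ("codend", lambda p: p.SR),
}


def coverage_experiment(
    n_datasets: int = 100,
    B: int = 200,
    seed: int = 0,
    truth: TrueSelectivity = DEFAULT_TRUTH,
    config: SimulationConfig | None = None,
    level: float = 0.95,
) -> dict:
    """Empirical coverage of double-bootstrap parameter CIs over simulations.

    Simulates ``n_datasets`` covered-codend experiments from ``truth`` under
    ``config`` (defaults: 10 hauls x 500 fish), fits both stages, bootstraps
    each with ``B`` repetitions, and reports the fraction of datasets whose
    Efron percentile CI covers the true value of each parameter (percent),
    plus the mean point estimates.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    truth_values = {
        name: getter(getattr(truth, stage))
        for name, (stage, getter) in _PARAM_GETTERS.items()
        if getattr(truth, stage) is not None
    }
    covered = {name: 0 for name in truth_values}
    estimates: dict[str, list[float]] = {name: [] for name in truth_values}

    for _ in range(n_datasets):
        ds_seed, smp_seed, cd_seed = rng.integers(0, 2**31 - 1, size=3)
        ds = simulate_dataset(replace(config, seed=int(ds_seed)), truth)
        ensembles = {}
        if truth.smp is not None:
            ensembles["smp"] = double_bootstrap(ds, "smp", B=B, seed=int(smp_seed))
        ensembles["codend"] = double_bootstrap(ds, "codend", B=B, seed=int(cd_seed))
        for name, (stage, getter) in _PARAM_GETTERS.items():
            if name not in truth_values:
                continue
            ens = ensembles[stage]
            values = [getter(p) for p in ens.reps]
            lo, hi = efron_ci(values, level)
            if lo <= truth_values[name] <= hi:
                covered[name] += 1
            estimates[name].append(getter(ens.point))

    return {
        "n_datasets": n_datasets,
        "B": B,
        "level": level,
        "truth": truth_values,
        "coverage_pct": {k: 100.0 * v / n_datasets for k, v in covered.items()},
        "mean_estimate": {k: float(np.mean(v)) for k, v in estimates.items()},
    }
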