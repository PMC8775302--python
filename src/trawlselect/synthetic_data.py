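"""Synthetic covered-codend datasets and population scenarios.

No raw haul data ship with this package, so every pipeline stage is
exercised on simulated data with known ground truth.  The generator mirrors
the assumed observation process of a dual-cover selectivity experiment:

1. a multimodal length population (mixture of normal components discretised
   to 1-cm classes) describes the fish entering the gear;
2. each haul draws its entrants multinomially from that population;
3. each fish's fate is an independent Bernoulli chain: it escapes through
   the SMP with probability ``1 - r_SMP(l)`` (landing in the panel cover),
   otherwise reaches the codend and is retained with probability
   ``r_CD(l)`` (codend) or escapes into the codend cover;
4. between-haul variation perturbs each haul's L50s by a log-normal
   multiplicative factor, the simplest structure that makes the
   between-haul bootstrap component consequential;
5. measurement subsampling thins each compartment's true counts binomially
   at rate ``q``, and ``q`` is recorded as the known raising factor.

Defaults (10 hauls of 500 fish, a bimodal population straddling the
selective range, 5% CV between-haul variation on L50, no subsampling) are
the package's standing study conditions for recovery and coverage tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .catch_patterns import PopulationStructure
from .data_model import HaulRecord, SelectivityDataset, write_dataset
from .reference import EXAMPLE_FITS, MCRS
from .selection_models import (
    ClogitParams,
    CombinedParams,
    LogitParams,
    class_midpoints,
    clogit_retention,
    logit_retention,
    params_to_dict,
)

__all__ = [
    "TrueSelectivity",
    "PopulationComponent",
    "SimulationConfig",
    "DEFAULT_TRUTH",
    "simulate_population",
    "simulate_haul",
    "simulate_dataset",
    "population_scenario",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class TrueSelectivity:
    """Ground-truth selection: optional SMP (CLogit) stage plus codend (logit)."""

    codend: LogitParams
    smp: ClogitParams | None = None

    @property
    def combined(self) -> CombinedParams:
        return CombinedParams(codend=self.codend, smp=self.smp)


@dataclass(frozen=True)
class PopulationComponent:
    """One bell-shaped component of the entering length distribution."""

    mean: float  # cm
    sd: float  # cm; 0 collapses the component to a single class
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sd < 0 or self.weight <= 0 or self.mean < 0:
            raise ValueError("component needs mean >= 0, sd >= 0, weight > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic covered-codend experiment."""

    components: tuple[PopulationComponent, ...] = (
        PopulationComponent(mean=20.0, sd=4.0, weight=0.5),
        PopulationComponent(mean=34.0, sd=6.0, weight=0.5),
    )
    n_hauls: int = 10
    fish_per_haul: int = 500
    between_haul_sd: float = 0.05  # log-normal sigma on each haul's L50s
    q: dict = field(default_factory=lambda: {"CD": 1.0, "CC": 1.0, "PC": 1.0})
    length_range: tuple[int, int] = (5, 60)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("population mixture needs at least one component")
        if self.n_hauls < 1 or self.fish_per_haul < 1:
            raise ValueError("need n_hauls >= 1 and fish_per_haul >= 1")
        if self.between_haul_sd < 0:
            raise ValueError("between_haul_sd must be >= 0")
        for comp, qv in self.q.items():
            if not (0.0 < qv <= 1.0):
                raise ValueError(f"q_{comp}={qv} outside (0, 1]")


#: Default ground truth: a moderately selective codend behind a panel that
#: 40% of fish contact — well inside the identifiable region of both models.
DEFAULT_TRUTH = TrueSelectivity(
    codend=LogitParams(L50=24.0, SR=4.0),
    smp=ClogitParams(C=0.4, L50=30.0, SR=6.0),
)


def simulate_population(
    components, total: float, length_range: tuple[int, int] = (5, 60)
) -> PopulationStructure:
    """Expected mixture counts discretised to 1-cm classes, scaled to ``total``.

    Each component contributes the normal probability mass of each bin
    [l, l+1); a zero-sd component collapses onto the bin containing its mean.
    Mass outside ``length_range`` is truncated and the result renormalised.
    """
    components = tuple(components)
    if not components:
        raise ValueError("population mixture needs at least one component")
    lo, hi = length_range
    lengths = np.arange(lo, hi + 1)
    mass = np.zeros(lengths.size)
    wsum = sum(c.weight for c in components)
    for c in components:
        if c.sd == 0:
            k = int(np.floor(c.mean))
            if not (lo <= k <= hi):
                raise ValueError(f"degenerate component at {c.mean} cm falls outside the length range")
            mass[k - lo] += c.weight / wsum
        else:
            edges = np.arange(lo, hi + 2, dtype=float)
            cdf = norm.cdf(edges, loc=c.mean, scale=c.sd)
            mass += (c.weight / wsum) * np.diff(cdf)
    if mass.sum() <= 0:
        raise ValueError("population mixture has no mass inside the length range")
    mass /= mass.sum()
    return PopulationStructure(lengths=lengths, n=mass * total)


def simulate_haul(
    pop: PopulationStructure,
    truth: TrueSelectivity,
    *,
    n_fish: int,
    rng: np.random.Generator,
    q: dict | None = None,
    haul_id: str = "haul_1",
    eval_at: str = "midpoint",
) -> HaulRecord:
    """Simulate one haul: entrants drawn from the population, fates Bernoulli.

    Per length class, entrants are a multinomial draw from the population
    proportions; each fish escapes through the SMP with probability
    ``1 - r_SMP`` (panel cover), otherwise is retained by the codend with
    probability ``r_CD`` (codend) or escapes into the codend cover.  Measured
    counts are binomial thinnings of the true counts at the compartment's
    subsampling rate ``q``, which is recorded on the record.
    """
    q = dict(q) if q is not None else {"CD": 1.0, "CC": 1.0, "PC": 1.0}
    x = class_midpoints(pop.lengths, eval_at)
    entrants = rng.multinomial(n_fish, pop.n / pop.total)

    if truth.smp is not None:
        r_smp = clogit_retention(x, truth.smp)
        n_pc = rng.binomial(entrants, 1.0 - r_smp)
        reaching = entrants - n_pc
    else:
        n_pc = None
        reaching = entrants
    r_cd = logit_retention(x, truth.codend)
    n_cd = rng.binomial(reaching, r_cd)
    n_cc = reaching - n_cd

    counts = {"CD": rng.binomial(n_cd, q["CD"]), "CC": rng.binomial(n_cc, q["CC"])}
    qs = {"CD": q["CD"], "CC": q["CC"]}
    if n_pc is not None:
        counts["PC"] = rng.binomial(n_pc, q.get("PC", 1.0))
        qs["PC"] = q.get("PC", 1.0)
    return HaulRecord(haul_id=haul_id, lengths=pop.lengths.copy(), counts=counts, q=qs)


def _perturbed_truth(truth: TrueSelectivity, sigma: float, rng: np.random.Generator) -> TrueSelectivity:
    """Haul-level truth: L50s scaled by a log-normal factor (mean-log 0)."""
    if sigma == 0:
        return truth
    codend = LogitParams(L50=truth.codend.L50 * rng.lognormal(0.0, sigma), SR=truth.codend.SR)
    smp = None
    if truth.smp is not None:
        smp = ClogitParams(C=truth.smp.C, L50=truth.smp.L50 * rng.lognormal(0.0, sigma), SR=truth.smp.SR)
    return TrueSelectivity(codend=codend, smp=smp)


def simulate_dataset(config: SimulationConfig, truth: TrueSelectivity = DEFAULT_TRUTH) -> SelectivityDataset:
    """Simulate a full multi-haul covered-codend experiment.

    Reproducible: the same config (including seed) yields a bit-identical
    dataset.  Gears without an SMP stage (``truth.smp is None``) produce
    datasets without a PC compartment.
    """
    rng = np.random.default_rng(config.seed)
    pop = simulate_population(config.components, total=1.0, length_range=config.length_range)
    q = dict(config.q)
    if truth.smp is None:
        q.pop("PC", None)
    hauls = []
    for j in range(config.n_hauls):
        haul_truth = _perturbed_truth(truth, config.between_haul_sd, rng)
        hauls.append(
            simulate_haul(
                pop, haul_truth, n_fish=config.fish_per_haul, rng=rng, q=q,
                haul_id=f"haul_{j + 1}",
            )
        )
    # drop all-zero length classes haul by haul (nothing was measured there)
    trimmed = []
    for haul in hauls:
        keep = np.zeros(haul.lengths.shape, dtype=bool)
        for arr in haul.counts.values():
            keep |= arr > 0
        if not keep.any():
            keep[:] = True  # pathological tiny haul: keep structure intact
        trimmed.append(
            HaulRecord(
                haul_id=haul.haul_id,
                lengths=haul.lengths[keep],
                counts={c: a[keep] for c, a in haul.counts.items()},
                q=dict(haul.q),
            )
        )
    gear = "SMP+CD (synthetic)" if truth.smp is not None else "CD (synthetic)"
    return SelectivityDataset(hauls=tuple(trimmed), gear_label=gear, species="synthetic")


# ---------------------------------------------------------------------------
# Population scenarios and canonical fixtures

_SCENARIOS = {
    # shapes spanning the policy-relevant cases: mostly undersized fish,
    # fish concentrated near the hake MCRS, and mostly-marketable fish
    "below_20": (PopulationComponent(mean=16.0, sd=2.5, weight=1.0),),
    "near_mcrs": (PopulationComponent(mean=25.0, sd=3.0, weight=1.0),),
    "above_22": (
        PopulationComponent(mean=28.0, sd=3.5, weight=0.7),
        PopulationComponent(mean=36.0, sd=4.0, weight=0.3),
    ),
}


def population_scenario(name: str, total: float = 10_000.0) -> PopulationStructure:
    """A named population scenario ('below_20', 'near_mcrs', 'above_22')."""
    try:
        comps = _SCENARIOS[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}") from None
    return simulate_population(comps, total=total)


def make_fixture_suite(out_dir: str | Path, seed: int = 20220120) -> dict[str, Path]:
    """Write the canonical text fixtures used by tests and worked examples.

    Produces the worked-example parameter table (JSON), the three population
    scenarios (CSV), and a small and a large synthetic dataset (CSV) with
    ground-truth sidecars (JSON).  Deterministic given ``seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    params_path = out_dir / "example_fits.json"
    params_path.write_text(json.dumps({"MCRS": MCRS, "fits": EXAMPLE_FITS}, indent=1))
    written["example_fits"] = params_path

    for name in sorted(_SCENARIOS):
        pop = population_scenario(name)
        path = out_dir / f"population_{name}.csv"
        pop.as_series().rename("n").reset_index().to_csv(path, index=False)
        written[f"population_{name}"] = path

    for label, cfg in (
        ("small", SimulationConfig(n_hauls=3, fish_per_haul=200, seed=seed)),
        ("large", SimulationConfig(n_hauls=10, fish_per_haul=500, seed=seed + 1)),
    ):
        ds = simulate_dataset(cfg, DEFAULT_TRUTH)
        data_path = out_dir / f"synthetic_{label}.csv"
        write_dataset(ds, data_path)
        truth_path = out_dir / f"synthetic_{label}_truth.json"
        truth_path.write_text(json.dumps({
            "smp": params_to_dict(DEFAULT_TRUTH.smp),
            "codend": params_to_dict(DEFAULT_TRUTH.codend),
            "config": {
                "n_hauls": cfg.n_hauls,
                "fish_per_haul": cfg.fish_per_haul,
                "between_haul_sd": cfg.between_haul_sd,
                "seed": cfg.seed,
            },
        }, indent=1))
        written[f"synthetic_{label}"] = data_path
        written[f"synthetic_{label}_truth"] = truth_path
    return written
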