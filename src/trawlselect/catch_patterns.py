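"""Population entering the gear, retained catch, and exploitation indicators.

The population entering the gear per 1-cm length class, ``nPop_l``, is the
full accounting of a dual-cover experiment: everything that ended in the
codend, codend cover or panel cover, raised and summed over hauls.  Applying
a combined gear retention curve projects the retained catch::

    nr_l = nPop_l * r_comb(l)

Three exploitation-pattern indicators summarise the projected catch against
a species' minimum conservation reference size (MCRS; hake 27 cm, blue
whiting's marketable-size proxy 18 cm):

* ``nP-``  — % of entering fish below MCRS that the gear retains,
* ``nP+``  — % of entering fish at or above MCRS that the gear retains,
* ``nDiscard`` — % of the retained catch that is below MCRS.

Because length-class labels are lower bounds, a class counts as "below MCRS"
when its label is strictly less than the MCRS.  Uncertainties come from
recomputing the indicators per bootstrap repetition (retention and, when
supplied, population ensembles paired by index) and taking Efron percentile
intervals.  A traffic-light colour maps each indicator onto a gradual
green-yellow-red scale for at-a-glance reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap_inference import BootstrapEnsemble, BootstrapError, efron_ci, resample_haul_counts
from .data_model import SelectivityDataset, ValidationError
from .selection_models import class_midpoints, retention_function

__all__ = [
    "PopulationStructure",
    "RetainedPopulation",
    "IndicatorSet",
    "TrafficLightColor",
    "estimate_entering_population",
    "bootstrap_entering_population",
    "retained_population",
    "exploitation_indicators",
    "indicator_cis",
    "traffic_light_color",
    "indicator_table",
]


@dataclass(frozen=True, eq=False)
class PopulationStructure:
    """Numbers of fish entering the gear per 1-cm length class."""

    lengths: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=int)
        n = np.asarray(self.n, dtype=float)
        if lengths.shape != n.shape or lengths.ndim != 1:
            raise ValidationError("lengths and n must be aligned 1-d arrays")
        if np.any(np.diff(lengths) <= 0):
            raise ValidationError("lengths must be sorted and unique")
        if np.any(n < 0) or not np.all(np.isfinite(n)):
            raise ValidationError("population numbers must be finite and >= 0")
        if n.sum() <= 0:
            raise ValidationError("population total must be > 0")
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "n", n)

    @property
    def total(self) -> float:
        return float(self.n.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.n, index=pd.Index(self.lengths, name="length_cm"), name="n")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PopulationStructure):
            return NotImplemented
        return np.array_equal(self.lengths, other.lengths) and np.array_equal(self.n, other.n)


@dataclass(frozen=True)
class RetainedPopulation:
    """Projected retained catch per length class, with an optional CI band."""

    lengths: np.ndarray
    n: np.ndarray
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    level: float | None = None


@dataclass(frozen=True)
class IndicatorSet:
    """Exploitation-pattern indicators (percent), with optional Efron CIs."""

    np_minus: float | None
    np_plus: float | None
    n_discard: float | None
    mcrs: float
    cis: dict | None = None


@dataclass(frozen=True)
class TrafficLightColor:
    """An RGB colour on the green-yellow-red gradient plus its category."""

    rgb: tuple[float, float, float]
    category: str


# ---------------------------------------------------------------------------
# Population


def estimate_entering_population(ds: SelectivityDataset) -> PopulationStructure:
    """Population entering the gear: raised CD + CC + PC summed over hauls.

    Requires the full dual-cover accounting (a PC compartment), since fish
    escaping through the panel are part of what entered.
    """
    if not ds.has_pc:
        raise ValidationError("entering population requires PC counts (full dual-cover accounting)")
    grid = ds.length_grid()
    n = np.zeros(grid.size)
    for haul in ds.hauls:
        idx = np.searchsorted(grid, haul.lengths)
        for comp in haul.compartments:
            n[idx] += haul.raised(comp)
    return PopulationStructure(lengths=grid, n=n)


def bootstrap_entering_population(
    ds: SelectivityDataset, B: int, seed: int | None = None
) -> list[PopulationStructure]:
    """Double-bootstrap ensemble of entering populations (index-pairable).

    Uses the same two-level resampling as the selectivity bootstrap: hauls
    with replacement, then within-haul multinomial redraws of measured
    counts, re-raised by the fixed subsampling factors.
    """
    if not ds.has_pc:
        raise ValidationError("entering population requires PC counts")
    if B < 1:
        raise BootstrapError("B must be >= 1")
    rng = np.random.default_rng(seed)
    grid = ds.length_grid()
    out = []
    for _ in range(B):
        n = np.zeros(grid.size)
        for lengths, counts, qs in resample_haul_counts(ds, rng):
            idx = np.searchsorted(grid, lengths)
            for comp, c in counts.items():
                n[idx] += c / qs[comp]
        out.append(PopulationStructure(lengths=grid, n=np.maximum(n, 0.0)))
    return out


def retained_population(
    pop: PopulationStructure,
    cp,
    comb_ens: BootstrapEnsemble | None = None,
    pop_ens: list[PopulationStructure] | None = None,
    *,
    level: float = 0.95,
    eval_at: str = "midpoint",
) -> RetainedPopulation:
    """Project the retained catch ``nr_l = nPop_l * r_comb(l)``.

    ``cp`` is a combined parameter set (or any retention callable).  When a
    combined-curve ensemble (and optionally a paired population ensemble) is
    given, pointwise Efron CIs are attached.
    """
    x = class_midpoints(pop.lengths, eval_at)
    r = np.asarray(retention_function(cp)(x), dtype=float)
    point = pop.n * r
    if comb_ens is None:
        return RetainedPopulation(lengths=pop.lengths, n=point)

    if pop_ens is not None:
        if len(pop_ens) != comb_ens.B:
            raise BootstrapError(
                f"population ensemble ({len(pop_ens)}) and curve ensemble (B={comb_ens.B}) differ"
            )
        for p in pop_ens:
            if not np.array_equal(p.lengths, pop_ens[0].lengths):
                raise ValidationError("population ensemble members must share one length grid")
        if not np.array_equal(pop_ens[0].lengths, pop.lengths):
            raise ValidationError("population ensemble grid must match the point population grid")
        pops = np.vstack([p.n for p in pop_ens])
    else:
        pops = np.broadcast_to(pop.n, (comb_ens.B, pop.n.size))
    mat = comb_ens.curves(x) * pops
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(mat, [alpha, 1.0 - alpha], axis=0)
    return RetainedPopulation(lengths=pop.lengths, n=point, lo=lo, hi=hi, level=level)


# ---------------------------------------------------------------------------
# Indicators


def _indicators_from_arrays(lengths, n, r, mcrs: float):
    below = lengths < mcrs
    above = ~below
    retained = r * n
    np_minus = 100.0 * retained[below].sum() / n[below].sum() if n[below].sum() > 0 else None
    np_plus = 100.0 * retained[above].sum() / n[above].sum() if n[above].sum() > 0 else None
    total_ret = retained.sum()
    n_discard = 100.0 * retained[below].sum() / total_ret if total_ret > 0 else None
    return np_minus, np_plus, n_discard


def exploitation_indicators(
    pop: PopulationStructure, cp, mcrs: float, *, eval_at: str = "midpoint"
) -> IndicatorSet:
    """nP-, nP+ and nDiscard (percent) for one retention curve and population.

    An indicator whose denominator is empty (no entering fish on that side of
    the MCRS, or nothing retained at all) is reported as None with a warning.
    """
    x = class_midpoints(pop.lengths, eval_at)
    r = np.asarray(retention_function(cp)(x), dtype=float)
    np_minus, np_plus, n_discard = _indicators_from_arrays(pop.lengths, pop.n, r, mcrs)
    if np_minus is None or np_plus is None:
        warnings.warn("population lacks fish on one side of the MCRS; indicator undefined", stacklevel=2)
    if n_discard is None:
        warnings.warn("total retained catch is zero; nDiscard undefined", stacklevel=2)
    return IndicatorSet(np_minus=np_minus, np_plus=np_plus, n_discard=n_discard, mcrs=mcrs)


def indicator_cis(
    pop: PopulationStructure,
    cp,
    comb_ens: BootstrapEnsemble,
    mcrs: float,
    pop_ens: list[PopulationStructure] | None = None,
    *,
    level: float = 0.95,
    eval_at: str = "midpoint",
) -> IndicatorSet:
    """Indicators with Efron CIs from per-repetition recomputation.

    The indicator of repetition ``i`` uses the i-th combined curve and — when
    a population ensemble is supplied — the i-th resampled population, so
    curve and population uncertainty propagate jointly through the ratios.
    """
    point = exploitation_indicators(pop, cp, mcrs, eval_at=eval_at)
    if pop_ens is not None and len(pop_ens) != comb_ens.B:
        raise BootstrapError(
            f"population ensemble ({len(pop_ens)}) and curve ensemble (B={comb_ens.B}) differ"
        )
    per_rep = {"np_minus": [], "np_plus": [], "n_discard": []}
    for i, params in enumerate(comb_ens.reps):
        p = pop_ens[i] if pop_ens is not None else pop
        x = class_midpoints(p.lengths, eval_at)
        r = np.asarray(retention_function(params)(x), dtype=float)
        vals = _indicators_from_arrays(p.lengths, p.n, r, mcrs)
        for key, v in zip(per_rep, vals):
            if v is not None:
                per_rep[key].append(v)
    cis = {}
    for key, vals in per_rep.items():
        if len(vals) < comb_ens.B:
            warnings.warn(f"{comb_ens.B - len(vals)} repetitions had an undefined {key}", stacklevel=2)
        cis[key] = efron_ci(vals, level) if vals else None
    return IndicatorSet(
        np_minus=point.np_minus,
        np_plus=point.np_plus,
        n_discard=point.n_discard,
        mcrs=mcrs,
        cis=cis,
    )


# ---------------------------------------------------------------------------
# Traffic lights

_GREEN = np.array([0.0, 1.0, 0.0])
_YELLOW = np.array([1.0, 1.0, 0.0])
_RED = np.array([1.0, 0.0, 0.0])


def traffic_light_color(value: float, direction: str) -> TrafficLightColor:
    """Map an indicator value in [0, 100] onto the green-yellow-red gradient.

    ``direction="higher_is_worse"`` (nP-, nDiscard) puts 0 at pure green and
    100 at pure red; ``"higher_is_better"`` (nP+) reverses the scale.  The
    colour interpolates linearly green -> yellow (at the 50 midpoint) -> red;
    the category is the nearest anchor.  Out-of-range values are clamped with
    a warning.
    """
    if direction not in ("higher_is_worse", "higher_is_better"):
        raise ValueError(f"unknown direction {direction!r}")
    if not (0.0 <= value <= 100.0):
        warnings.warn(f"indicator value {value} outside [0, 100]; clamped", stacklevel=2)
        value = min(max(value, 0.0), 100.0)
    badness = value / 100.0 if direction == "higher_is_worse" else 1.0 - value / 100.0
    if badness <= 0.5:
        rgb = _GREEN + (badness / 0.5) * (_YELLOW - _GREEN)
    else:
        rgb = _YELLOW + ((badness - 0.5) / 0.5) * (_RED - _YELLOW)
    if badness < 0.25:
        category = "green"
    elif badness <= 0.75:
        category = "yellow"
    else:
        category = "red"
    return TrafficLightColor(rgb=tuple(float(c) for c in rgb), category=category)


_DIRECTIONS = {"np_minus": "higher_is_worse", "np_plus": "higher_is_better", "n_discard": "higher_is_worse"}


def indicator_table(results: dict[str, IndicatorSet]) -> pd.DataFrame:
    """Tabulate (gear, indicator, value, lo, hi, category) for reporting."""
    rows = []
    for gear, ind in results.items():
        for key, value in (("np_minus", ind.np_minus), ("np_plus", ind.np_plus), ("n_discard", ind.n_discard)):
            ci = (ind.cis or {}).get(key)
            rows.append({
                "gear": gear,
                "indicator": key,
                "value": value,
                "lo": ci[0] if ci else None,
                "hi": ci[1] if ci else None,
                "category": traffic_light_color(value, _DIRECTIONS[key]).category if value is not None else None,
            })
    return pd.DataFrame(rows)
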