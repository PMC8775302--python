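"""Double bootstrap of selectivity fits and Efron percentile inference.

Uncertainty in pooled selectivity estimates has two sources: hauls differ
from each other (between-haul variation) and, within a haul, the measured
fish are a finite — possibly subsampled — draw from the fish that met the
gear (within-haul variation).  The double bootstrap resamples both levels:

* outer: draw ``m`` hauls with replacement from the ``m`` observed hauls;
* inner: within each drawn haul, resample the measured fish of each
  compartment by a multinomial over length classes that preserves the
  compartment's measured total (the known subsampling factor ``q`` is then
  re-applied as a fixed raising constant).

Each repetition is refitted, giving an ensemble of parameter sets indexed
``i = 1..B``.  All confidence statements are Efron percentile intervals of
per-repetition quantities; paired comparisons (delta curves) difference the
two ensembles repetition by repetition, which is valid because the two
bootstraps are independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import SelectivityDataset
from .mle_fitting import NoDataError, NonIdentifiableError, _fit_pooled, fit_smp, fit_codend
from .selection_models import (
    ClogitParams,
    CombinedParams,
    LogitParams,
    params_from_dict,
    params_to_dict,
    retention_function,
)

__all__ = [
    "BootstrapEnsemble",
    "CurveBand",
    "DeltaCurveResult",
    "BootstrapError",
    "double_bootstrap",
    "resample_haul_counts",
    "efron_ci",
    "curve_band",
    "combine_ensembles",
    "delta_curve",
    "significant_ranges",
    "save_ensemble",
    "load_ensemble",
]


class BootstrapError(RuntimeError):
    """Raised when the bootstrap cannot produce a usable ensemble."""


@dataclass(frozen=True)
class BootstrapEnsemble:
    """An indexed collection of refitted parameter sets.

    The repetition order is part of the contract: paired quantities (delta
    curves, combined-gear curves, indicator uncertainties) are computed by
    differencing or combining ensembles repetition by repetition.
    """

    reps: tuple
    point: object
    B: int
    seed: int | None = None
    fit_spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.B < 1:
            raise BootstrapError("B must be >= 1")
        if len(self.reps) != self.B:
            raise BootstrapError(f"ensemble holds {len(self.reps)} reps but B={self.B}")

    def curves(self, lengths) -> np.ndarray:
        """Retention evaluated per repetition: array of shape (B, n_lengths)."""
        lengths = np.asarray(lengths, dtype=float)
        return np.vstack([retention_function(p)(lengths) for p in self.reps])


@dataclass(frozen=True)
class CurveBand:
    """A retention curve with a pointwise Efron percentile band."""

    lengths: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    level: float


@dataclass(frozen=True)
class DeltaCurveResult:
    """Delta selectivity (treatment minus baseline) with its CI band.

    ``significant_ranges`` lists the (first, last) lengths of every
    contiguous run of the grid where the band excludes zero.
    """

    lengths: np.ndarray
    delta: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    level: float
    significant_ranges: tuple[tuple[float, float], ...]


# ---------------------------------------------------------------------------
# Resampling engine


def _haul_cache(ds: SelectivityDataset):
    """Precomputed per-haul arrays for fast repeated resampling."""
    cache = []
    for haul in ds.hauls:
        comp_data = {}
        for comp in haul.compartments:
            counts = haul.counts[comp]
            total = int(round(counts.sum()))
            probs = counts / counts.sum() if total > 0 else None
            comp_data[comp] = (total, probs, haul.q[comp])
        cache.append((haul.lengths, comp_data))
    return cache


def resample_haul_counts(ds: SelectivityDataset, rng: np.random.Generator, _cache=None):
    """One double-bootstrap draw: list of (lengths, {comp: measured counts}, {comp: q}).

    Outer level resamples hauls with replacement; inner level redraws each
    compartment's measured counts from a multinomial over length classes with
    the compartment's measured total fixed.
    """
    cache = _cache if _cache is not None else _haul_cache(ds)
    m = len(cache)
    picks = rng.integers(0, m, size=m)
    out = []
    for k in picks:
        lengths, comp_data = cache[k]
        counts = {}
        qs = {}
        for comp, (total, probs, q) in comp_data.items():
            counts[comp] = rng.multinomial(total, probs) if total > 0 else np.zeros(lengths.size)
            qs[comp] = q
        out.append((lengths, counts, qs))
    return out


def _pool_resampled(resampled, grid: np.ndarray, model: str):
    """Pooled raised (retained, escaped) arrays for one bootstrap draw."""
    a = np.zeros(grid.size)
    b = np.zeros(grid.size)
    for lengths, counts, qs in resampled:
        idx = np.searchsorted(grid, lengths)
        if model == "smp":
            a[idx] += counts["CD"] / qs["CD"] + counts["CC"] / qs["CC"]
            b[idx] += counts["PC"] / qs["PC"]
        else:
            a[idx] += counts["CD"] / qs["CD"]
            b[idx] += counts["CC"] / qs["CC"]
    keep = (a + b) > 0
    return grid[keep], a[keep], b[keep]


def double_bootstrap(
    ds: SelectivityDataset,
    model: str,
    B: int = 1000,
    seed: int | None = None,
    *,
    eval_at: str = "midpoint",
    max_fail_frac: float = 0.2,
) -> BootstrapEnsemble:
    """Double bootstrap (between-haul and within-haul) of a selectivity fit.

    The point estimate is fitted first with the full multi-start search; each
    repetition is refitted warm-started from it.  Repetitions whose refit
    fails (e.g. a resample with complete separation) are redrawn so that the
    ensemble keeps exactly ``B`` index-paired entries; more than
    ``max_fail_frac * B`` failures abort with a diagnostic.
    """
    if B < 1:
        raise BootstrapError("B must be >= 1")
    point_fit = fit_smp(ds, eval_at=eval_at, with_diagnostics=False) if model == "smp" \
        else fit_codend(ds, eval_at=eval_at, with_diagnostics=False)

    rng = np.random.default_rng(seed)
    cache = _haul_cache(ds)
    grid = ds.length_grid()
    reps = []
    failures = 0
    max_failures = max(1, int(np.ceil(max_fail_frac * B)))
    while len(reps) < B:
        resampled = resample_haul_counts(ds, rng, _cache=cache)
        try:
            lengths, a, b = _pool_resampled(resampled, grid, model)
            if lengths.size == 0:
                raise NoDataError("empty resample")
            res = _fit_pooled(lengths, a, b, model, eval_at=eval_at, x0=point_fit.params)
            reps.append(res.params)
        except (NonIdentifiableError, NoDataError):
            failures += 1
            if failures > max_failures:
                raise BootstrapError(
                    f"{failures} failed bootstrap refits out of {len(reps) + failures} draws "
                    f"(> {max_fail_frac:.0%} of B={B}); the dataset is too sparse for stable refits"
                )
    return BootstrapEnsemble(
        reps=tuple(reps),
        point=point_fit.params,
        B=B,
        seed=seed,
        fit_spec={
            "model": model,
            "gear_label": ds.gear_label,
            "species": ds.species,
            "n_hauls": ds.n_hauls,
            "eval_at": eval_at,
            "n_redraws": failures,
        },
    )


# ---------------------------------------------------------------------------
# Efron percentile inference


def efron_ci(values: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Efron percentile interval: empirical quantiles at (1 +/- level)/2.

    Quantiles use linear interpolation between order statistics.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take percentiles of an empty collection")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level={level} must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def curve_band(ens: BootstrapEnsemble, lengths, level: float = 0.95) -> CurveBand:
    """Pointwise Efron band around the point-estimate retention curve."""
    lengths = np.asarray(lengths, dtype=float)
    mat = ens.curves(lengths)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(mat, [alpha, 1.0 - alpha], axis=0)
    mean = retention_function(ens.point)(lengths)
    return CurveBand(lengths=lengths, mean=np.asarray(mean), lo=lo, hi=hi, level=level)


def combine_ensembles(smp_ens: BootstrapEnsemble | None, cd_ens: BootstrapEnsemble) -> BootstrapEnsemble:
    """Pair an SMP and a codend ensemble index-by-index into combined-gear
    parameter sets (absent SMP models a gear without a panel)."""
    if smp_ens is None:
        reps = tuple(CombinedParams(codend=p) for p in cd_ens.reps)
        point = CombinedParams(codend=cd_ens.point)
        spec = {"model": "combined", "smp": None, "codend": cd_ens.fit_spec}
        return BootstrapEnsemble(reps=reps, point=point, B=cd_ens.B, seed=cd_ens.seed, fit_spec=spec)
    if smp_ens.B != cd_ens.B:
        raise BootstrapError(f"cannot pair ensembles with B={smp_ens.B} and B={cd_ens.B}")
    reps = tuple(CombinedParams(codend=c, smp=s) for s, c in zip(smp_ens.reps, cd_ens.reps))
    point = CombinedParams(codend=cd_ens.point, smp=smp_ens.point)
    spec = {"model": "combined", "smp": smp_ens.fit_spec, "codend": cd_ens.fit_spec}
    return BootstrapEnsemble(reps=reps, point=point, B=cd_ens.B, seed=cd_ens.seed, fit_spec=spec)


def significant_ranges(lengths: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> tuple[tuple[float, float], ...]:
    """Contiguous length runs where the CI band excludes zero (lo > 0 or hi < 0)."""
    sig = (lo > 0.0) | (hi < 0.0)
    ranges = []
    start = None
    for i, flag in enumerate(sig):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            ranges.append((float(lengths[start]), float(lengths[i - 1])))
            start = None
    if start is not None:
        ranges.append((float(lengths[start]), float(lengths[-1])))
    return tuple(ranges)


def delta_curve(
    treat: BootstrapEnsemble,
    base: BootstrapEnsemble,
    lengths,
    level: float = 0.95,
) -> DeltaCurveResult:
    """Delta selectivity: treatment retention minus baseline retention.

    The point curve differences the two point estimates; the CI band takes
    Efron percentiles of the per-repetition differences (ensembles paired by
    index, so both must have the same B).  A length class is significant when
    the band excludes zero.
    """
    if treat.B != base.B:
        raise BootstrapError(f"cannot pair ensembles with B={treat.B} and B={base.B}")
    lengths = np.asarray(lengths, dtype=float)
    diffs = treat.curves(lengths) - base.curves(lengths)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha], axis=0)
    delta = np.asarray(retention_function(treat.point)(lengths)) - np.asarray(
        retention_function(base.point)(lengths)
    )
    return DeltaCurveResult(
        lengths=lengths,
        delta=delta,
        lo=lo,
        hi=hi,
        level=level,
        significant_ranges=significant_ranges(lengths, lo, hi),
    )


# ---------------------------------------------------------------------------
# Serialization


def save_ensemble(ens: BootstrapEnsemble, path: str | Path) -> None:
    """Write an ensemble as JSON: point fit, reps in index order, provenance."""
    payload = {
        "B": ens.B,
        "seed": ens.seed,
        "fit_spec": ens.fit_spec,
        "point": params_to_dict(ens.point),
        "reps": [params_to_dict(p) for p in ens.reps],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_ensemble(path: str | Path) -> BootstrapEnsemble:
    payload = json.loads(Path(path).read_text())
    return BootstrapEnsemble(
        reps=tuple(params_from_dict(r) for r in payload["reps"]),
        point=params_from_dict(payload["point"]),
        B=payload["B"],
        seed=payload["seed"],
        fit_spec=payload.get("fit_spec", {}),
    )
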