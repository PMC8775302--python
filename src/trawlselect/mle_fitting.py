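"""Pooled binomial maximum-likelihood estimation of SMP and codend selectivity.

Covered-codend data are two-outcome data per length class: for the SMP stage
the fish that stayed in the gear (codend + codend cover) versus the fish that
escaped into the panel cover; for the codend stage the fish retained in the
codend versus those in the codend cover.  Counts are raised by their
subsampling factors and pooled over hauls, and the negative binomial
log-likelihood

    -sum_l sum_j [ retained_lj/q * ln r(l)  +  escaped_lj/q * ln(1 - r(l)) ]

is minimised over the model parameters (CLogit for the SMP stage, logit for
the codend stage).  Zero raised counts contribute nothing (0 * ln 0 = 0).

Goodness of fit is judged by the model deviance against its degrees of
freedom: cells are (haul, length) pairs with a positive raised total, and the
p-value is the upper-tail chi-square probability of the deviance.  A p-value
below 0.05 with deviance well above the degrees of freedom calls for a look
at the deviance residuals to separate structural misfit from over-dispersion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, xlogy
from scipy.stats import chi2

from .data_model import SelectivityDataset
from .selection_models import (
    LN9,
    PARAM_FLOOR,
    ClogitParams,
    LogitParams,
    class_midpoints,
    clogit_retention,
    logit_retention,
)

__all__ = [
    "FitResult",
    "NonIdentifiableError",
    "NoDataError",
    "nll_smp",
    "nll_codend",
    "fit_smp",
    "fit_codend",
    "model_diagnostics",
    "deviance_residuals",
    "deviance_p_value",
]


class NoDataError(ValueError):
    """Raised when a dataset has no usable counts for the requested stage."""


class NonIdentifiableError(ValueError):
    """Raised on complete separation: both outcome groups occur in the data
    but never within the same length class, so L50/SR are not identifiable."""


@dataclass(frozen=True)
class FitResult:
    """A fitted selectivity model with its goodness-of-fit diagnostics."""

    params: ClogitParams | LogitParams
    nll: float
    deviance: float | None
    dof: int | None
    p_value: float | None
    converged: bool
    n_starts_used: int
    at_boundary: bool = False

    @property
    def model(self) -> str:
        return "smp" if isinstance(self.params, ClogitParams) else "codend"


# ---------------------------------------------------------------------------
# Pooled count extraction


def _stage_groups(ds: SelectivityDataset, model: str):
    """Per-haul (retained, escaped) raised counts for one selection stage."""
    if model == "smp":
        if not ds.has_pc:
            raise NoDataError("SMP estimation needs a PC compartment")
        return [(h.lengths, h.raised("CD") + h.raised("CC"), h.raised("PC")) for h in ds.hauls]
    if model == "codend":
        return [(h.lengths, h.raised("CD"), h.raised("CC")) for h in ds.hauls]
    raise ValueError(f"model must be 'smp' or 'codend', got {model!r}")


def _pooled_counts(ds: SelectivityDataset, model: str):
    """Pool raised counts over hauls; returns (lengths, retained, escaped)."""
    grid = ds.length_grid()
    a = np.zeros(grid.size)
    b = np.zeros(grid.size)
    for lengths, ret, esc in _stage_groups(ds, model):
        idx = np.searchsorted(grid, lengths)
        a[idx] += ret
        b[idx] += esc
    keep = (a + b) > 0
    if not np.any(keep):
        raise NoDataError(f"no data left for the {model} stage after filtering")
    return grid[keep], a[keep], b[keep]


def _nll_terms(r: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """-[a ln r + b ln(1-r)] with the 0*ln(0)=0 convention; +inf at a
    saturated boundary (r = 1 with escapees, or r = 0 with retained fish)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term_a = np.where(a > 0, a * np.log(r), 0.0)
        term_b = np.where(b > 0, b * np.log1p(-r), 0.0)
    total = term_a.sum() + term_b.sum()
    return float(np.inf) if np.isnan(total) else float(-total)


def nll_smp(ds: SelectivityDataset, p: ClogitParams, *, eval_at: str = "midpoint") -> float:
    """Pooled negative log-likelihood of the SMP stage under CLogit ``p``."""
    lengths, a, b = _pooled_counts(ds, "smp")
    r = clogit_retention(class_midpoints(lengths, eval_at), p)
    return _nll_terms(r, a, b)


def nll_codend(ds: SelectivityDataset, p: LogitParams, *, eval_at: str = "midpoint") -> float:
    """Pooled negative log-likelihood of the codend stage under logit ``p``."""
    lengths, a, b = _pooled_counts(ds, "codend")
    r = logit_retention(class_midpoints(lengths, eval_at), p)
    return _nll_terms(r, a, b)


# ---------------------------------------------------------------------------
# Optimisation
#
# Parameters are searched in a transformed space: C through a logistic link
# (keeps [0, 1] without hard clipping; CLogit likelihoods are multimodal in
# C), L50 and SR through a shifted log link (keeps the 0.1 cm floor at which
# degenerate estimates are clamped).

_MAX_EXP = 50.0  # exp cap; lengths are tens of cm, exp(50) is far past any fit


def _from_transformed(theta: np.ndarray, model: str):
    if model == "smp":
        w, u, v = theta
        return expit(w), PARAM_FLOOR + np.exp(min(u, _MAX_EXP)), PARAM_FLOOR + np.exp(min(v, _MAX_EXP))
    u, v = theta
    return None, PARAM_FLOOR + np.exp(min(u, _MAX_EXP)), PARAM_FLOOR + np.exp(min(v, _MAX_EXP))


def _to_transformed(params) -> np.ndarray:
    def loglink(x):
        return np.log(max(x - PARAM_FLOOR, 1e-9))

    if isinstance(params, ClogitParams):
        w = np.log(min(max(params.C, 1e-9), 1 - 1e-9) / (1 - min(max(params.C, 1e-9), 1 - 1e-9)))
        return np.array([w, loglink(params.L50), loglink(params.SR)])
    return np.array([loglink(params.L50), loglink(params.SR)])


def _objective(x: np.ndarray, a: np.ndarray, b: np.ndarray, model: str):
    """Numerically stable pooled NLL in transformed parameter space.

    Uses log-sum-exp forms so that the objective stays finite and smooth even
    deep into the saturated tails, which keeps Nelder-Mead moving.
    """

    def f(theta):
        C, L50, SR = _from_transformed(theta, model)
        z = LN9 * (x - L50) / SR
        log_lg = -np.logaddexp(0.0, -z)  # ln logit(l)
        log_1mlg = -np.logaddexp(0.0, z)  # ln (1 - logit(l))
        if model == "codend":
            term = np.dot(a, log_lg) + np.dot(b, log_1mlg)
        else:
            r = 1.0 - C + C * np.exp(log_lg)
            with np.errstate(divide="ignore"):
                log_r = np.log(r)
                # 1 - r = C * (1 - logit): exact and stable for C > 0
                log_1mr = np.log(C) + log_1mlg
            term = np.dot(a, log_r) + np.dot(b, log_1mr)
        return np.inf if np.isnan(term) else -term

    return f


def _default_starts(lengths: np.ndarray, a: np.ndarray, b: np.ndarray, model: str):
    """Deterministic multi-start grid spanning the observed length range:
    L50 at weighted data quantiles, SR at {1, 5, 10} cm, C at {.1, .5, .9}."""
    w = a + b
    order = np.argsort(lengths)
    cum = np.cumsum(w[order])
    qs = []
    for q in (0.25, 0.5, 0.75):
        qs.append(float(lengths[order][np.searchsorted(cum, q * cum[-1])]))
    l50s = sorted(set(max(q, PARAM_FLOOR + 0.5) for q in qs))
    l50s = sorted(set(l50s + [l50s[0] * 0.5 + PARAM_FLOOR, l50s[-1] * 1.5]))
    srs = (1.0, 5.0, 10.0)
    starts = []
    if model == "smp":
        for c in (0.1, 0.5, 0.9):
            for l50 in l50s:
                for sr in srs:
                    starts.append(_to_transformed(ClogitParams(c, l50, sr)))
    else:
        for l50 in l50s:
            for sr in srs:
                starts.append(_to_transformed(LogitParams(l50, sr)))
    return starts


_BOUNDARY_TOL = 1e-3


def _fit(ds: SelectivityDataset, model: str, *, eval_at: str = "midpoint",
         x0=None, with_diagnostics: bool = True) -> FitResult:
    lengths, a, b = _pooled_counts(ds, model)
    result = _fit_pooled(lengths, a, b, model, eval_at=eval_at, x0=x0)
    if with_diagnostics:
        deviance, dof, p_value = model_diagnostics(ds, result.params, eval_at=eval_at)
        result = FitResult(
            params=result.params, nll=result.nll, deviance=deviance, dof=dof,
            p_value=p_value, converged=result.converged,
            n_starts_used=result.n_starts_used, at_boundary=result.at_boundary,
        )
    return result


def _fit_pooled(lengths: np.ndarray, a: np.ndarray, b: np.ndarray, model: str, *,
                eval_at: str = "midpoint", x0=None) -> FitResult:
    """Fit from already-pooled raised counts (no diagnostics attached)."""
    x = class_midpoints(lengths, eval_at)

    degenerate = a.sum() == 0 or b.sum() == 0
    if not degenerate and not np.any((a > 0) & (b > 0)):
        raise NonIdentifiableError(
            f"{model} stage: no length class contains fish in both outcome groups "
            "(complete separation); L50/SR are not identifiable"
        )

    obj = _objective(x, a, b, model)
    if x0 is not None:
        starts = [_to_transformed(x0)]
    else:
        starts = _default_starts(lengths, a, b, model)

    best = None
    converged = False
    for theta0 in starts:
        res = minimize(obj, theta0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
        elif res.fun == best.fun and res.success:
            converged = True
    if x0 is not None and not np.isfinite(best.fun):
        # warm start failed outright; fall back to the full grid
        return _fit_pooled(lengths, a, b, model, eval_at=eval_at, x0=None)

    C, L50, SR = _from_transformed(best.x, model)
    at_boundary = (
        SR <= PARAM_FLOOR + _BOUNDARY_TOL
        or L50 <= PARAM_FLOOR + _BOUNDARY_TOL
        or (model == "smp" and (C <= _BOUNDARY_TOL or C >= 1 - _BOUNDARY_TOL))
        or degenerate
    )
    if model == "smp":
        params: ClogitParams | LogitParams = ClogitParams(float(C), float(L50), float(SR))
    else:
        params = LogitParams(float(L50), float(SR))

    return FitResult(
        params=params,
        nll=float(best.fun),
        deviance=None,
        dof=None,
        p_value=None,
        converged=converged and not degenerate,
        n_starts_used=len(starts),
        at_boundary=bool(at_boundary),
    )


def fit_smp(ds: SelectivityDataset, *, eval_at: str = "midpoint", x0: ClogitParams | None = None,
            with_diagnostics: bool = True) -> FitResult:
    """Fit the CLogit SMP selectivity (C, L50, SR) by pooled binomial MLE.

    Apply :func:`~trawlselect.data_model.apply_length_filters` first when the
    cover meshes cannot retain the smallest fish.  ``x0`` warm-starts the
    optimiser from a single point (used for bootstrap refits); otherwise a
    deterministic multi-start grid is searched.
    """
    return _fit(ds, "smp", eval_at=eval_at, x0=x0, with_diagnostics=with_diagnostics)


def fit_codend(ds: SelectivityDataset, *, eval_at: str = "midpoint", x0: LogitParams | None = None,
               with_diagnostics: bool = True) -> FitResult:
    """Fit the logit codend selectivity (L50, SR) by pooled binomial MLE."""
    return _fit(ds, "codend", eval_at=eval_at, x0=x0, with_diagnostics=with_diagnostics)


# ---------------------------------------------------------------------------
# Diagnostics


def _predicted_retention(params, lengths: np.ndarray, eval_at: str) -> np.ndarray:
    x = class_midpoints(lengths, eval_at)
    if isinstance(params, ClogitParams):
        return clogit_retention(x, params)
    return logit_retention(x, params)


def _cells(ds: SelectivityDataset, model: str):
    """(haul_id, lengths, observed retained, total) per haul, raised counts."""
    out = []
    for haul, (lengths, ret, esc) in zip(ds.hauls, _stage_groups(ds, model)):
        t = ret + esc
        keep = t > 0
        out.append((haul.haul_id, lengths[keep], ret[keep], t[keep]))
    return out


def _deviance_contributions(o: np.ndarray, t: np.ndarray, e: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_o = np.where(o > 0, o / np.where(e > 0, e, 1.0), 1.0)
        ratio_o = np.where((o > 0) & (e == 0), np.inf, ratio_o)
        oe = t - o
        ee = t - e
        ratio_e = np.where(oe > 0, oe / np.where(ee > 0, ee, 1.0), 1.0)
        ratio_e = np.where((oe > 0) & (ee <= 0), np.inf, ratio_e)
        return 2.0 * (xlogy(o, ratio_o) + xlogy(oe, ratio_e))


def model_diagnostics(ds: SelectivityDataset, params, *, eval_at: str = "midpoint"):
    """Deviance, degrees of freedom and chi-square p-value for a fitted model.

    Cells are (haul, length) pairs with a positive raised total; dof is the
    number of cells minus the number of parameters.  Returns
    ``(deviance, dof, p_value)``, with ``p_value=None`` (and a warning) when
    dof <= 0.
    """
    model = "smp" if isinstance(params, ClogitParams) else "codend"
    n_params = 3 if model == "smp" else 2
    deviance = 0.0
    n_cells = 0
    for _, lengths, o, t in _cells(ds, model):
        e = t * _predicted_retention(params, lengths, eval_at)
        deviance += float(_deviance_contributions(o, t, e).sum())
        n_cells += lengths.size
    dof = n_cells - n_params
    if dof <= 0:
        warnings.warn("degrees of freedom <= 0; goodness-of-fit p-value undefined", stacklevel=2)
        return deviance, dof, None
    return deviance, dof, deviance_p_value(deviance, dof)


def deviance_p_value(deviance: float, dof: int) -> float:
    """Upper-tail chi-square survival probability of a deviance at ``dof``."""
    return float(chi2.sf(deviance, dof))


def deviance_residuals(ds: SelectivityDataset, params, *, eval_at: str = "midpoint") -> pd.DataFrame:
    """Signed square-root deviance contribution per (haul, length) cell.

    The residual carries the sign of (observed - expected) retained fish and
    its squares sum to the total deviance.
    """
    model = "smp" if isinstance(params, ClogitParams) else "codend"
    frames = []
    for haul_id, lengths, o, t in _cells(ds, model):
        e = t * _predicted_retention(params, lengths, eval_at)
        contrib = _deviance_contributions(o, t, e)
        frames.append(pd.DataFrame({
            "haul_id": haul_id,
            "length_cm": lengths,
            "observed": o,
            "total": t,
            "expected": e,
            "residual": np.sign(o - e) * np.sqrt(np.maximum(contrib, 0.0)),
        }))
    return pd.concat(frames, ignore_index=True)
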