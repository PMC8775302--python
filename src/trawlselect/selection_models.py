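"""Closed-form retention models: logit, CLogit, and their sequential product.

Codend retention follows the classic logistic ("logit") selection curve
parameterised by L50 (length at 50% retention) and SR = L75 - L25 (selection
range)::

    logit(l) = exp(ln 9 * (l - L50) / SR) / (1 + exp(ln 9 * (l - L50) / SR))

Escape through a square mesh panel additionally requires that the fish makes
contact with the panel.  The CLogit model mixes full retention (no contact)
with logistic retention (contact) through a length-independent contact
probability C in [0, 1]::

    clogit(l) = 1 - C + C * logit(l)

so retention never falls below 1 - C.  A gear combining an SMP and a codend
selects sequentially, and its combined retention is the product of the two
stage retentions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit as _logit_link

__all__ = [
    "LN9",
    "PARAM_FLOOR",
    "DomainError",
    "LogitParams",
    "ClogitParams",
    "CombinedParams",
    "logit_retention",
    "clogit_retention",
    "combined_retention",
    "retention_quantile",
    "retention_function",
    "class_midpoints",
    "params_to_dict",
    "params_from_dict",
]

LN9 = math.log(9.0)

#: Lower bound for L50 and SR, matching the boundary value at which
#: degenerate fits are clamped (estimates of exactly 0.10 denote a boundary).
PARAM_FLOOR = 0.1


class DomainError(ValueError):
    """Raised for parameter or argument values outside the model domain."""


@dataclass(frozen=True)
class LogitParams:
    """Logistic selection parameters for a codend: L50 and SR, both in cm."""

    L50: float
    SR: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.L50) and self.L50 >= PARAM_FLOOR):
            raise DomainError(f"L50={self.L50} must be >= {PARAM_FLOOR}")
        if not (np.isfinite(self.SR) and self.SR >= PARAM_FLOOR):
            raise DomainError(f"SR={self.SR} must be >= {PARAM_FLOOR}")


@dataclass(frozen=True)
class ClogitParams:
    """CLogit parameters for an SMP: contact probability C, L50 and SR."""

    C: float
    L50: float
    SR: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.C) and 0.0 <= self.C <= 1.0):
            raise DomainError(f"C={self.C} must lie in [0, 1]")
        LogitParams(self.L50, self.SR)  # reuse the positivity checks

    @property
    def logit(self) -> LogitParams:
        return LogitParams(self.L50, self.SR)


@dataclass(frozen=True)
class CombinedParams:
    """Sequential SMP x codend selection; absent SMP is equivalent to C = 0."""

    codend: LogitParams
    smp: ClogitParams | None = None


def logit_retention(l, p: LogitParams):
    """Logistic retention probability at length(s) ``l`` (cm).

    Strictly increasing in ``l``; equals 0.5 at L50 and 0.25/0.75 at
    L50 -/+ SR/2.
    """
    if p.SR <= 0:
        raise DomainError(f"SR={p.SR} must be > 0")
    return expit(LN9 * (np.asarray(l, dtype=float) - p.L50) / p.SR)


def clogit_retention(l, p: ClogitParams):
    """CLogit retention: 1 - C + C * logit(l).  Bounded in [1 - C, 1]."""
    return 1.0 - p.C + p.C * logit_retention(l, p.logit)


def combined_retention(l, cp: CombinedParams):
    """Combined retention of an SMP (if any) followed by a codend."""
    r_cd = logit_retention(l, cp.codend)
    if cp.smp is None:
        return r_cd
    return clogit_retention(l, cp.smp) * r_cd


def retention_quantile(p: float, lp: LogitParams) -> float:
    """Length at which logistic retention equals ``p`` (exact inverse).

    ``retention_quantile(0.25)`` and ``(0.75)`` are L25 and L75; their
    difference is SR by construction.
    """
    if not (0.0 < p < 1.0):
        raise DomainError(f"retention probability p={p} must lie strictly in (0, 1)")
    return float(lp.L50 + lp.SR * _logit_link(p) / LN9)


def retention_function(params):
    """Return the retention curve ``l -> r(l)`` for any parameter set.

    Accepts :class:`LogitParams`, :class:`ClogitParams`,
    :class:`CombinedParams`, or an already-callable curve (returned as is).
    """
    if isinstance(params, LogitParams):
        return lambda l: logit_retention(l, params)
    if isinstance(params, ClogitParams):
        return lambda l: clogit_retention(l, params)
    if isinstance(params, CombinedParams):
        return lambda l: combined_retention(l, params)
    if callable(params):
        return params
    raise TypeError(f"no retention curve for {type(params).__name__}")


def params_to_dict(params) -> dict:
    """Flat JSON-ready record for a parameter set: {model, C, L50, SR}."""
    if isinstance(params, ClogitParams):
        return {"model": "clogit", "C": params.C, "L50": params.L50, "SR": params.SR}
    if isinstance(params, LogitParams):
        return {"model": "logit", "L50": params.L50, "SR": params.SR}
    if isinstance(params, CombinedParams):
        return {
            "model": "combined",
            "smp": None if params.smp is None else params_to_dict(params.smp),
            "codend": params_to_dict(params.codend),
        }
    raise TypeError(f"cannot serialise {type(params).__name__}")


def params_from_dict(record: dict):
    """Inverse of :func:`params_to_dict`."""
    model = record["model"]
    if model == "clogit":
        return ClogitParams(C=record["C"], L50=record["L50"], SR=record["SR"])
    if model == "logit":
        return LogitParams(L50=record["L50"], SR=record["SR"])
    if model == "combined":
        smp = None if record["smp"] is None else params_from_dict(record["smp"])
        return CombinedParams(codend=params_from_dict(record["codend"]), smp=smp)
    raise ValueError(f"unknown model {model!r}")


def class_midpoints(lengths, eval_at: str = "midpoint") -> np.ndarray:
    """Lengths at which binned retention is evaluated.

    Length-class labels are lower bounds of 1-cm bins; by default curves are
    evaluated at bin midpoints (label + 0.5), which minimises binning bias.
    ``eval_at="lower"`` evaluates at the labels themselves.
    """
    lengths = np.asarray(lengths, dtype=float)
    if eval_at == "midpoint":
        return lengths + 0.5
    if eval_at == "lower":
        return lengths
    raise ValueError(f"eval_at must be 'midpoint' or 'lower', got {eval_at!r}")
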