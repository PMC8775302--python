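"""Worked-example selectivity estimates for hake and blue whiting.

Point estimates, 95% CI bounds and fit statistics for the six individually
estimated gear components (four SMP designs and two codends) from
covered-codend sea trials in the Bay of Biscay bottom-trawl fishery.  They
serve as ready-made inputs for combined-gear predictions and worked examples;
the raw haul data behind them are not distributed, so they cannot be
re-estimated here.  L50/SR estimates of exactly 0.10 sit on the estimation
floor (degenerate, boundary-clamped fits).
"""

from __future__ import annotations

from .selection_models import ClogitParams, CombinedParams, LogitParams

__all__ = ["EXAMPLE_FITS", "MCRS", "example_params", "example_combined"]

#: Species-specific minimum size used by the exploitation indicators (cm):
#: a legal minimum conservation reference size for hake, a marketable-size
#: proxy for blue whiting (which has no MCRS).
MCRS = {"hake": 27.0, "blue_whiting": 18.0}

#: Fitted selectivity parameters per species and gear component.
#: C is None for codends (no contact stage); p_value is None where only an
#: inequality (< 0.001) was reported.
EXAMPLE_FITS: dict[str, dict[str, dict]] = {
    "hake": {
        "SMP_TS": {"L50": 37.07, "L50_ci": (21.22, 37.10), "SR": 0.10, "SR_ci": (0.10, 7.42),
                   "C": 0.01, "C_ci": (0.00, 0.02), "p_value": 0.972, "dev": 59.29, "dof": 82},
        "SMP_TL": {"L50": 32.07, "L50_ci": (31.04, 32.10), "SR": 0.10, "SR_ci": (0.10, 0.10),
                   "C": 0.02, "C_ci": (0.01, 0.03), "p_value": 0.05, "dev": 102.44, "dof": 81},
        "SMP_BS": {"L50": 35.03, "L50_ci": (0.10, 35.09), "SR": 0.10, "SR_ci": (0.10, 27.08),
                   "C": 0.05, "C_ci": (0.02, 1.00), "p_value": 0.8735, "dev": 14.73, "dof": 22},
        "SMP_BL": {"L50": 31.33, "L50_ci": (15.02, 34.73), "SR": 6.51, "SR_ci": (0.10, 19.72),
                   "C": 0.38, "C_ci": (0.27, 1.00), "p_value": 0.6995, "dev": 23.66, "dof": 28},
        "CD_D": {"L50": 15.68, "L50_ci": (12.47, 17.51), "SR": 7.92, "SR_ci": (5.07, 11.84),
                 "C": None, "p_value": 0.4420, "dev": 36.57, "dof": 36},
        "CD_S": {"L50": 23.49, "L50_ci": (22.82, 24.46), "SR": 4.36, "SR_ci": (3.73, 4.92),
                 "C": None, "p_value": 0.8543, "dev": 25.46, "dof": 34},
    },
    "blue_whiting": {
        "SMP_TS": {"L50": 27.62, "L50_ci": (23.14, 34.76), "SR": 8.99, "SR_ci": (0.10, 15.73),
                   "C": 0.27, "C_ci": (0.21, 0.38), "p_value": None, "dev": 105.10, "dof": 40},
        "SMP_TL": {"L50": 32.39, "L50_ci": (29.81, 197.57), "SR": 1.99, "SR_ci": (0.10, 48.72),
                   "C": 0.45, "C_ci": (0.26, 0.66), "p_value": 0.31, "dev": 25.81, "dof": 23},
        "SMP_BS": {"L50": 28.97, "L50_ci": (0.10, 56.51), "SR": 0.10, "SR_ci": (0.10, 4.60),
                   "C": 0.00, "C_ci": (0.00, 1.00), "p_value": 0.9793, "dev": 4.21, "dof": 12},
        "SMP_BL": {"L50": 0.10, "L50_ci": (0.10, 1.00), "SR": 27.73, "SR_ci": (0.10, 40.50),
                   "C": 0.18, "C_ci": (0.01, 1.00), "p_value": 0.6226, "dev": 8.99, "dof": 11},
        "CD_D": {"L50": 22.88, "L50_ci": (20.76, 24.12), "SR": 4.37, "SR_ci": (3.60, 5.61),
                 "C": None, "p_value": 0.1159, "dev": 21.70, "dof": 15},
        "CD_S": {"L50": 27.06, "L50_ci": (26.70, 27.44), "SR": 3.32, "SR_ci": (2.85, 3.84),
                 "C": None, "p_value": 0.3349, "dev": 19.96, "dof": 18},
    },
}


def example_params(species: str, component: str):
    """Parameter object for one fitted gear component.

    Returns :class:`ClogitParams` for SMP components and
    :class:`LogitParams` for codends.
    """
    rec = EXAMPLE_FITS[species][component]
    if rec["C"] is None:
        return LogitParams(L50=rec["L50"], SR=rec["SR"])
    return ClogitParams(C=rec["C"], L50=rec["L50"], SR=rec["SR"])


def example_combined(species: str, smp: str | None, codend: str) -> CombinedParams:
    """Combined SMP x codend parameter set from the worked-example fits."""
    cd = example_params(species, codend)
    if smp is None or smp == "NONE":
        return CombinedParams(codend=cd)
    return CombinedParams(codend=cd, smp=example_params(species, smp))
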