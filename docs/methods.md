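# Methods

## Data model

A covered-codend selectivity experiment observes, per haul `j` and 1-cm
length class `l`, the measured counts `nCD_lj` (codend), `nCC_lj` (codend
cover) and — for gears with a square mesh panel — `nPC_lj` (panel cover).
Fish are measured to the nearest centimetre **below**, so a length-class
label is the lower bound of the bin `[l, l+1)`; a fish recorded as 27 cm
counts as at-or-above an MCRS of 27 cm. When a compartment's catch is
subsampled, the subsampling factor `q ∈ (0, 1]` (measured / total fish) is a
known constant of the observation process and counts enter every likelihood
raised by `1/q`. Raised counts are kept real-valued throughout; nothing is
rounded.

Because fine-mesh covers can themselves release the smallest fish, cover
counts below configurable thresholds are excluded before fitting (defaults:
panel-cover fish ≤ 20 cm, codend-cover fish ≤ 15 cm; codend counts are never
filtered). The thresholds are in centimetres: the corresponding filtering
rule has been printed elsewhere in millimetres, which is dimensionally
inconsistent with the species involved, and the package treats that as a
typo. Duplicate (haul, length) rows in input CSVs are summed rather than
rejected, which tolerates concatenated field sheets.

## Selection models

* Codend: `logit(l) = expit(ln 9 · (l − L50)/SR)`; SR = L75 − L25.
* SMP: `CLogit(l) = 1 − C + C · logit(l)`, with contact probability `C`
  length-independent. `C = 0` means no fish contacts the panel (retention 1
  everywhere); `C = 1` reduces to the plain logit.
* Combined gear: `r_comb(l) = r_SMP(l) · r_CD(l)` (sequential selection).

When applied to binned counts, curves are evaluated at **bin midpoints**
(label + 0.5 cm) by default, which minimises binning bias for 1-cm bins;
lower-bound evaluation is available via `eval_at="lower"` everywhere it
matters.

L50 and SR have a hard floor of 0.1 cm. Published tables report boundary
estimates of exactly "0.10" for degenerate fits, so adopting the same clamp
keeps degenerate fits comparable; `C` is bounded in [0, 1] by definition.

## Estimation

The SMP stage treats (CD + CC) vs PC as two-outcome data; the codend stage
treats CD vs CC likewise. Parameters minimise the pooled binomial negative
log-likelihood over hauls, e.g. for the SMP stage

```
-Σ_l Σ_j [ (nCD_lj/qCD_j + nCC_lj/qCC_j) ln r_SMP(l) + (nPC_lj/qPC_j) ln(1 − r_SMP(l)) ]
```

with the convention `0 · ln 0 = 0`; a saturated boundary (r = 1 with
observed escapees) yields `+inf`, steering the optimizer away rather than
raising.

**Optimisation.** Nelder-Mead in a transformed space — `C` through a
logistic link (the CLogit likelihood is multimodal in C and hard clipping
creates spurious boundary optima), `L50` and `SR` through a shifted log link
that enforces the 0.1 cm floor smoothly. Point fits run a deterministic
multi-start grid (L50 at weighted data quantiles extended by ±50%, SR at
{1, 5, 10} cm, C at {0.1, 0.5, 0.9}; 15 starts for the codend, 45 for the
SMP). Internally the objective uses log-sum-exp forms so it stays finite and
smooth deep into saturated tails. On toy datasets the optimum matches an
exhaustive 0.01-resolution grid search to better than 1e-6 (tested).

**Degenerate data.** If one outcome group is empty over the whole dataset
(e.g. every fish retained), the fit proceeds to the boundary and is flagged
(`at_boundary=True`, `converged=False`). If both groups occur but never in
the same length class (complete separation), L50/SR are not identifiable and
a `NonIdentifiableError` is raised instead.

**Diagnostics.** Deviance is computed on raised counts over (haul, length)
cells with positive totals,
`2 Σ [o ln(o/e) + (t−o) ln((t−o)/(t−e))]`, with `dof = #cells − #params` and
an upper-tail chi-square p-value (reported missing with a warning when
dof ≤ 0). Signed square-root deviance residuals per cell support
over-dispersion inspection; their squares sum to the total deviance. The
cell convention is per (haul, length); published DOFs cannot be re-derived
without the raw data, so the convention is documented rather than claimed to
match.

## Double bootstrap

Each of `B` repetitions resamples `m` hauls with replacement (between-haul
variation), then redraws each selected haul's measured counts per
compartment from a multinomial over length classes holding the compartment's
measured total fixed (within-haul variation). Resampling operates on
*measured* counts and re-applies `q` afterwards: subsampling factors are
known raising constants, not random outcomes. Each repetition is refitted
warm-started from the point estimate; warm starts agree with the full
multi-start search to ~1e-6 in the refitted parameters (tested) and keep a
B = 1000 bootstrap on a 10-haul dataset in the seconds range. Repetitions
whose refit fails (complete separation in the resample) are redrawn so the
ensemble keeps exactly `B` index-paired entries; more than 20% failures
abort with a diagnostic. The default is B = 1000; desk-scale tests use
B = 200.

All intervals are **Efron percentile** intervals — empirical quantiles at
(1 ± level)/2 with linear interpolation between order statistics (the
finite-sample rule is otherwise open; numpy's default linear rule is used
and frozen in a test). Percentile bands around curves are pointwise and do
not mathematically guarantee containment of the point-estimate curve at
every length, so containment is asserted statistically (≥ 95% of lengths),
not structurally.

**Delta curves.** `Δr(l) = r_treatment(l) − r_baseline(l)` from the point
fits; the CI band takes percentiles of per-repetition differences, pairing
the two independent ensembles by repetition index. A length class differs
significantly when the band excludes zero (a zero-width band sitting exactly
on zero counts as overlapping). Combined-gear ensembles are built by pairing
an SMP and a codend ensemble index-by-index, so they inherit the pairing
contract and are valid delta inputs.

## Treatment trees

Gear designs are points on three SMP axes (presence, size S/L, position
top/bottom) crossed with codend geometry (diamond/square): ten designs in
all. Forward modifications away from the reference design (small top panel +
diamond codend) are: increase SMP size, move SMP to the bottom, remove the
SMP (one step from any panel configuration), and change codend geometry
(diamond → square). Edges of the treatment tree are exactly the ordered
design pairs one forward modification apart — a DAG rooted at the reference
in which all ten designs are reachable (21 edges). Nodes and edges are
ordered breadth-first with lexicographic tie-breaks so exports and figures
are reproducible. Rendering draws one panel per edge (delta curve with CI
band, zero line, significant ranges shaded) or per node (selection curve or
retained-population profile, MCRS as a vertical line).

## Populations and indicators

The population entering the gear is the full dual-cover accounting
`nPop_l = Σ_j raised(CD + CC + PC)`; projecting a combined curve gives the
retained catch `nr_l = nPop_l · r_comb(l)`. Indicators (MCRS 27 cm for hake;
18 cm marketable-size proxy for blue whiting):

```
nP⁻ = 100 Σ_{l<MCRS} r_comb nPop / Σ_{l<MCRS} nPop
nP⁺ = 100 Σ_{l≥MCRS} r_comb nPop / Σ_{l≥MCRS} nPop
nDiscard = 100 Σ_{l<MCRS} r_comb nPop / Σ_l r_comb nPop
```

"Below" means class label strictly less than the MCRS (labels are lower
bounds). Indicator CIs recompute the ratios per bootstrap repetition, using
the i-th combined curve and (when supplied) the i-th resampled population —
curve and population uncertainty propagate jointly through the ratios,
paired by index. An indicator with an empty denominator is reported missing
with a warning. The traffic light maps an indicator onto a linear
green → yellow (50) → red gradient, oriented by whether higher is worse
(nP⁻, nDiscard) or better (nP⁺); anchors at 0/50/100 are a presentation
choice and configurable in spirit — only a gradual gradient is prescribed.

## Synthetic data

The generator mirrors the assumed observation process: a mixture-of-normals
length population discretised to 1-cm bins; per haul a multinomial draw of
entrants; independent Bernoulli fates per fish (escape through the SMP with
probability 1 − r_SMP, then codend retention with probability r_CD);
binomial thinning at rate `q` per compartment with `q` recorded. Between-haul
variation multiplies each haul's L50s by a log-normal factor (σ = 0.05 by
default) — the simplest structure that makes the between-haul bootstrap
component consequential; it is a modelling choice, not an estimate from
data, and no quantitative between-haul variance is published, so recovery
tests verify CI *coverage* rather than a variance value.

Standing study conditions (defaults): 10 hauls × 500 fish, a bimodal
population (means 20 and 34 cm, sds 4 and 6) straddling the selective range
of the default truth (SMP C = 0.4, L50 = 30, SR = 6; codend L50 = 24,
SR = 4), no subsampling. Under these conditions the empirical coverage of
nominal 95% double-bootstrap CIs over 100 simulated experiments (B = 200) is
checked to lie in [88, 99]% per parameter; codend parameters sit near the
low 90s, the known small-m behaviour of percentile intervals with 10 hauls.
Three named population scenarios (mostly-undersized "below_20", "near_mcrs",
mostly-marketable "above_22") emulate the qualitative population shapes
relevant for indicator comparisons.

What the generator does **not** emulate: fish behaviour mechanisms (panel
contact is a single length-independent probability, not a swimming-endurance
process), towing-condition covariates, between-haul variation in C or SR,
over-dispersion beyond multinomial sampling, and measurement error in
length. Passing tests therefore demonstrate the statistical machinery under
the model's own assumptions, not robustness to field realities outside them.

## Numerical choices and limitations

* Retention quantile and curve are exact inverses (logit link), tested to
  1e-10.
* Deviance uses `xlogy`-style zero conventions; expected-zero cells with
  observed fish contribute `+inf` honestly.
* Problem sizes in tests and the acceptance script (100 datasets, B = 200,
  20 grid-oracle datasets) are desk-scale choices that keep a full run in a
  few minutes while leaving each check statistically meaningful.
* No over-dispersion correction factor is applied (residuals are provided
  for inspection); no Fryer-type random-effects model; no paired-gear
  (uncovered) estimation designs; no biomass-based indicators; no
  Richards/asymmetric selection curves.
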