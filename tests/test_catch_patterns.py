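import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trawlselect.bootstrap_inference import BootstrapEnsemble, efron_ci
from trawlselect.catch_patterns import (
    PopulationStructure,
    bootstrap_entering_population,
    estimate_entering_population,
    exploitation_indicators,
    indicator_cis,
    retained_population,
    traffic_light_color,
)
from trawlselect.data_model import SelectivityDataset, ValidationError
from trawlselect.selection_models import ClogitParams, CombinedParams, LogitParams, combined_retention

from conftest import make_haul, random_dataset


def test_entering_population_hand_values():
    haul = make_haul("h", [30], cd=[3], cc=[2], pc=[1])
    pop = estimate_entering_population(SelectivityDataset(hauls=(haul,)))
    assert pop.as_series().to_dict() == {30: 6.0}
    # q = 0.5 in CC doubles only the CC contribution
    haul2 = make_haul("h", [30], cd=[3], cc=[2], pc=[1], q_cc=0.5)
    pop2 = estimate_entering_population(SelectivityDataset(hauls=(haul2,)))
    assert pop2.as_series().to_dict() == {30: 8.0}


def test_entering_population_requires_pc(rng):
    ds = random_dataset(rng, with_pc=False)
    with pytest.raises(ValidationError):
        estimate_entering_population(ds)


def test_entering_population_matches_brute_force(rng):
    ds = random_dataset(rng, n_hauls=4, n_classes=6)
    pop = estimate_entering_population(ds)
    expected = {}
    for haul in ds.hauls:
        for comp in haul.compartments:
            for l, c in zip(haul.lengths, haul.counts[comp]):
                expected[int(l)] = expected.get(int(l), 0.0) + c / haul.q[comp]
    assert pop.as_series().to_dict() == pytest.approx(expected)


def test_retained_population_is_elementwise_product():
    pop = PopulationStructure(lengths=np.arange(20, 30), n=np.linspace(10, 100, 10))
    cp = CombinedParams(codend=LogitParams(24.0, 4.0), smp=ClogitParams(0.4, 27.0, 5.0))
    ret = retained_population(pop, cp)
    expected = pop.n * combined_retention(pop.lengths + 0.5, cp)
    assert np.allclose(ret.n, expected)
    # full retention: codend selects far below the population
    full = retained_population(pop, CombinedParams(codend=LogitParams(0.1, 0.1)))
    assert np.array_equal(full.n, pop.n)
    # arbitrary retention callables are accepted (e.g. flat 50%)
    half = retained_population(pop, lambda l: np.full_like(np.asarray(l, float), 0.5))
    assert np.allclose(half.n, pop.n / 2)


def test_retained_population_cis_from_ensembles():
    pop = PopulationStructure(lengths=np.arange(20, 30), n=np.full(10, 100.0))
    curves = [lambda l, c=c: np.full_like(np.asarray(l, float), c) for c in (0.4, 0.5, 0.6)]
    ens = BootstrapEnsemble(reps=tuple(curves), point=curves[1], B=3)
    ret = retained_population(pop, curves[1], comb_ens=ens, level=1 - 1e-12)
    assert np.allclose(ret.n, 50.0)
    assert np.allclose(ret.lo, 40.0) and np.allclose(ret.hi, 60.0)


def test_indicators_full_retention_toy():
    # 40 fish below MCRS, 60 above, everything retained
    pop = PopulationStructure(lengths=np.array([20, 30]), n=np.array([40.0, 60.0]))
    ind = exploitation_indicators(pop, lambda l: np.ones_like(np.asarray(l, float)), mcrs=27.0)
    assert ind.np_minus == pytest.approx(100.0)
    assert ind.np_plus == pytest.approx(100.0)
    assert ind.n_discard == pytest.approx(40.0)


def test_indicators_knife_edge():
    pop = PopulationStructure(lengths=np.arange(20, 35), n=np.full(15, 10.0))
    knife = lambda l: (np.asarray(l, float) >= 27.0).astype(float)
    ind = exploitation_indicators(pop, knife, mcrs=27.0)
    assert ind.np_minus == pytest.approx(0.0)
    assert ind.np_plus == pytest.approx(100.0)
    assert ind.n_discard == pytest.approx(0.0)


def test_indicators_match_brute_force_sums(rng):
    pop = PopulationStructure(lengths=np.arange(22, 32), n=rng.uniform(5, 50, 10))
    cp = CombinedParams(codend=LogitParams(26.0, 3.0))
    mcrs = 27.0
    ind = exploitation_indicators(pop, cp, mcrs)
    r = combined_retention(pop.lengths + 0.5, cp)
    below = pop.lengths < mcrs
    np_minus = 100 * (r[below] * pop.n[below]).sum() / pop.n[below].sum()
    np_plus = 100 * (r[~below] * pop.n[~below]).sum() / pop.n[~below].sum()
    ndisc = 100 * (r[below] * pop.n[below]).sum() / (r * pop.n).sum()
    assert ind.np_minus == pytest.approx(np_minus, rel=1e-12)
    assert ind.np_plus == pytest.approx(np_plus, rel=1e-12)
    assert ind.n_discard == pytest.approx(ndisc, rel=1e-12)


def test_indicators_undefined_sides_warn():
    pop = PopulationStructure(lengths=np.array([30, 32]), n=np.array([5.0, 5.0]))
    with pytest.warns(UserWarning):
        ind = exploitation_indicators(pop, lambda l: np.ones_like(np.asarray(l, float)), mcrs=27.0)
    assert ind.np_minus is None and ind.np_plus == pytest.approx(100.0)
    with pytest.warns(UserWarning):
        ind = exploitation_indicators(pop, lambda l: np.zeros_like(np.asarray(l, float)), mcrs=27.0)
    assert ind.n_discard is None


@settings(derandomize=True, max_examples=40, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), scale=st.floats(min_value=0.01, max_value=1000.0))
def test_indicator_identities(seed, scale):
    """nDiscard == 100 R-/(R- + R+) and scale invariance of all indicators."""
    rng = np.random.default_rng(seed)
    pop = PopulationStructure(lengths=np.arange(18, 40), n=rng.uniform(1, 100, 22))
    cp = CombinedParams(
        codend=LogitParams(float(rng.uniform(15, 35)), float(rng.uniform(1, 8))),
        smp=ClogitParams(float(rng.uniform(0, 1)), float(rng.uniform(15, 35)), float(rng.uniform(1, 8))),
    )
    mcrs = 27.0
    ind = exploitation_indicators(pop, cp, mcrs)
    r = combined_retention(pop.lengths + 0.5, cp)
    below = pop.lengths < mcrs
    r_minus = (r[below] * pop.n[below]).sum()
    r_plus = (r[~below] * pop.n[~below]).sum()
    assert ind.n_discard == pytest.approx(100 * r_minus / (r_minus + r_plus), abs=1e-9)
    scaled = PopulationStructure(lengths=pop.lengths, n=pop.n * scale)
    ind2 = exploitation_indicators(scaled, cp, mcrs)
    assert ind2.np_minus == pytest.approx(ind.np_minus, rel=1e-9)
    assert ind2.np_plus == pytest.approx(ind.np_plus, rel=1e-9)
    assert ind2.n_discard == pytest.approx(ind.n_discard, rel=1e-9)


def test_indicator_monotone_in_retention(rng):
    pop = PopulationStructure(lengths=np.arange(18, 40), n=rng.uniform(1, 100, 22))
    base = CombinedParams(codend=LogitParams(26.0, 4.0))
    more = lambda l: np.minimum(1.0, combined_retention(l, base) + 0.1)
    i1 = exploitation_indicators(pop, base, 27.0)
    i2 = exploitation_indicators(pop, more, 27.0)
    assert i2.np_minus >= i1.np_minus and i2.np_plus >= i1.np_plus


def test_indicator_cis_recomputation_oracle():
    pop = PopulationStructure(lengths=np.arange(20, 35), n=np.full(15, 10.0))
    flat = [lambda l, c=c: np.full_like(np.asarray(l, float), c) for c in (0.3, 0.5, 0.7, 0.9)]
    ens = BootstrapEnsemble(reps=tuple(flat), point=flat[1], B=4)
    ind = indicator_cis(pop, flat[1], ens, mcrs=27.0)
    # flat retention: nP- = nP+ = 100 c; recompute the Efron CI independently
    per_rep = [100 * c for c in (0.3, 0.5, 0.7, 0.9)]
    assert ind.cis["np_minus"] == pytest.approx(efron_ci(per_rep))
    assert ind.cis["np_plus"] == pytest.approx(efron_ci(per_rep))
    # nDiscard is retention-invariant for flat curves
    assert ind.cis["n_discard"][0] == pytest.approx(ind.cis["n_discard"][1])
    # degenerate single repetition: CI collapses onto that repetition's value
    one = BootstrapEnsemble(reps=(flat[0],), point=flat[0], B=1)
    ind1 = indicator_cis(pop, flat[0], one, mcrs=27.0)
    assert ind1.cis["np_minus"] == pytest.approx((30.0, 30.0))


def test_bootstrap_entering_population_pairs_with_curves(rng):
    ds = random_dataset(rng, n_hauls=3, n_classes=5)
    pops = bootstrap_entering_population(ds, B=12, seed=4)
    assert len(pops) == 12
    assert all(np.array_equal(p.lengths, pops[0].lengths) for p in pops)
    # deterministic under the same seed
    pops2 = bootstrap_entering_population(ds, B=12, seed=4)
    assert all(p1 == p2 for p1, p2 in zip(pops, pops2))


def test_traffic_light_endpoints_and_midpoint():
    assert traffic_light_color(0.0, "higher_is_worse").rgb == (0.0, 1.0, 0.0)
    assert traffic_light_color(0.0, "higher_is_worse").category == "green"
    assert traffic_light_color(100.0, "higher_is_worse").rgb == (1.0, 0.0, 0.0)
    assert traffic_light_color(100.0, "higher_is_better").rgb == (0.0, 1.0, 0.0)
    assert traffic_light_color(50.0, "higher_is_worse").category == "yellow"
    assert traffic_light_color(50.0, "higher_is_better").rgb == (1.0, 1.0, 0.0)
    with pytest.warns(UserWarning):
        clamped = traffic_light_color(120.0, "higher_is_worse")
    assert clamped.rgb == (1.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        traffic_light_color(10.0, "sideways")
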