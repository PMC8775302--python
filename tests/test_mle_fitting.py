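import math

import numpy as np
import pytest

from trawlselect.data_model import SelectivityDataset
from trawlselect.mle_fitting import (
    NonIdentifiableError,
    deviance_p_value,
    deviance_residuals,
    fit_codend,
    fit_smp,
    model_diagnostics,
    nll_codend,
    nll_smp,
)
from trawlselect.selection_models import (
    ClogitParams,
    LogitParams,
    clogit_retention,
    logit_retention,
)

from conftest import make_haul, random_dataset


def _oracle_nll(ds, params, model):
    """Independent double-loop summation of the pooled binomial NLL."""
    if model == "smp":
        r_fn = lambda l: float(clogit_retention(l + 0.5, params))
    else:
        r_fn = lambda l: float(logit_retention(l + 0.5, params))
    total = 0.0
    for haul in ds.hauls:
        for i, l in enumerate(haul.lengths):
            if model == "smp":
                kept = haul.counts["CD"][i] / haul.q["CD"] + haul.counts["CC"][i] / haul.q["CC"]
                esc = haul.counts["PC"][i] / haul.q["PC"]
            else:
                kept = haul.counts["CD"][i] / haul.q["CD"]
                esc = haul.counts["CC"][i] / haul.q["CC"]
            r = r_fn(int(l))
            if kept > 0:
                total += kept * math.log(r)
            if esc > 0:
                total += esc * math.log(1.0 - r)
    return -total


def test_nll_single_class_hand_value():
    # one class, retained-group raised count 3, escapees 1, r_SMP = 0.75:
    # logit(30.5; L50=28.5, SR=4) = expit(ln9 * 2/4) = 0.75 with full contact
    haul = make_haul("h", [30], cd=[2], cc=[1], pc=[1])
    ds = SelectivityDataset(hauls=(haul,))
    p = ClogitParams(C=1.0, L50=28.5, SR=4.0)
    expected = -(3 * math.log(0.75) + 1 * math.log(0.25))
    assert nll_smp(ds, p) == pytest.approx(expected, rel=1e-12)


def test_nll_subsampling_scales_linearly():
    h1 = make_haul("h", [28, 30, 32], cd=[4, 6, 9], cc=[3, 2, 1], pc=[5, 3, 1])
    h2 = make_haul("h", [28, 30, 32], cd=[4, 6, 9], cc=[3, 2, 1], pc=[5, 3, 1],
                   q_cd=0.5, q_cc=0.5, q_pc=0.5)
    ds1 = SelectivityDataset(hauls=(h1,))
    ds2 = SelectivityDataset(hauls=(h2,))
    p = ClogitParams(C=0.6, L50=30.0, SR=5.0)
    assert nll_smp(ds2, p) == pytest.approx(2.0 * nll_smp(ds1, p), rel=1e-12)
    lp = LogitParams(L50=30.0, SR=5.0)
    assert nll_codend(ds2, lp) == pytest.approx(2.0 * nll_codend(ds1, lp), rel=1e-12)


def test_nll_infinite_at_saturated_boundary():
    # retention saturates to exactly 1.0 in floating point far above a tiny
    # L50/SR, so observed escapees have zero likelihood
    haul = make_haul("h", [30], cd=[5], cc=[3])
    ds = SelectivityDataset(hauls=(haul,))
    assert nll_codend(ds, LogitParams(L50=0.1, SR=0.1)) == np.inf


def test_nll_matches_independent_oracle(rng):
    for _ in range(5):
        ds = random_dataset(rng, n_hauls=3, n_classes=6)
        sp = ClogitParams(C=float(rng.uniform(0.1, 0.9)), L50=float(rng.uniform(15, 30)),
                          SR=float(rng.uniform(1, 10)))
        lp = LogitParams(L50=float(rng.uniform(15, 30)), SR=float(rng.uniform(1, 10)))
        assert nll_smp(ds, sp) == pytest.approx(_oracle_nll(ds, sp, "smp"), rel=1e-10)
        assert nll_codend(ds, lp) == pytest.approx(_oracle_nll(ds, lp, "codend"), rel=1e-10)


def test_fit_recovers_noise_free_logistic():
    # expected-count data generated exactly from logit(L50=30, SR=5) with
    # large per-class totals: the MLE must sit on the generating parameters
    lengths = np.arange(15, 46)
    truth = LogitParams(L50=30.0, SR=5.0)
    total = 2_000_000.0
    r = logit_retention(lengths + 0.5, truth)
    haul = make_haul("h", lengths, cd=total * r, cc=total * (1 - r))
    ds = SelectivityDataset(hauls=(haul,))
    res = fit_codend(ds)
    assert res.converged
    assert res.params.L50 == pytest.approx(30.0, abs=1e-3)
    assert res.params.SR == pytest.approx(5.0, abs=1e-3)
    # noise-free data fit perfectly: deviance ~ 0, p ~ 1
    assert res.deviance == pytest.approx(0.0, abs=1e-6)
    assert res.p_value == pytest.approx(1.0, abs=1e-9)


def test_fit_recovers_noise_free_clogit():
    lengths = np.arange(15, 51)
    truth = ClogitParams(C=0.4, L50=30.0, SR=6.0)
    total = 2_000_000.0
    r = clogit_retention(lengths + 0.5, truth)
    haul = make_haul("h", lengths, cd=total * r / 2, cc=total * r / 2, pc=total * (1 - r))
    ds = SelectivityDataset(hauls=(haul,))
    res = fit_smp(ds)
    assert res.converged
    assert res.params.C == pytest.approx(0.4, abs=1e-3)
    assert res.params.L50 == pytest.approx(30.0, abs=2e-3)
    assert res.params.SR == pytest.approx(6.0, abs=5e-3)


def test_fit_flags_degenerate_all_retained():
    haul = make_haul("h", [20, 25, 30], cd=[40, 50, 60], cc=[0, 0, 0])
    ds = SelectivityDataset(hauls=(haul,))
    res = fit_codend(ds)
    assert res.at_boundary
    assert not res.converged
    # retention ~ 1 across the observed range
    r = logit_retention(np.array([20.5, 25.5, 30.5]), res.params)
    assert np.all(r > 0.999)


def test_fit_raises_on_complete_separation():
    # both outcome groups occur, but never within the same length class
    haul = make_haul("h", [20, 30], cd=[0, 50], cc=[50, 0])
    ds = SelectivityDataset(hauls=(haul,))
    with pytest.raises(NonIdentifiableError):
        fit_codend(ds)


def _grid_min_nll_codend(ds, l50_grid, sr_grid):
    from trawlselect.mle_fitting import _pooled_counts

    lengths, a, b = _pooled_counts(ds, "codend")
    x = lengths + 0.5
    best = np.inf
    ln9 = math.log(9.0)
    for l50 in l50_grid:
        z = ln9 * (x[None, :] - l50) / sr_grid[:, None]
        r = 1.0 / (1.0 + np.exp(-z))
        with np.errstate(divide="ignore", invalid="ignore"):
            nll = -(np.where(a > 0, a * np.log(r), 0.0).sum(axis=1)
                    + np.where(b > 0, b * np.log1p(-r), 0.0).sum(axis=1))
        nll = np.where(np.isnan(nll), np.inf, nll)
        best = min(best, float(nll.min()))
    return best


def test_optimizer_beats_grid_search(rng):
    """Optimizer NLL within 1e-6 of an exhaustive 0.01-resolution grid."""
    l50_grid = np.arange(10.0, 35.0, 0.01)
    sr_grid = np.arange(0.1, 12.0, 0.01)
    for _ in range(3):
        ds = random_dataset(rng, n_hauls=2, with_pc=False, n_classes=3, base_length=20)
        res = fit_codend(ds, with_diagnostics=False)
        grid_best = _grid_min_nll_codend(ds, l50_grid, sr_grid)
        assert res.nll <= grid_best + 1e-6


def test_diagnostics_perfect_fit_and_table_pairs():
    # cells generated exactly at the model expectation: deviance 0, p = 1
    lengths = np.arange(20, 30)
    p = LogitParams(L50=24.0, SR=4.0)
    r = logit_retention(lengths + 0.5, p)
    t = 500.0
    haul = make_haul("h", lengths, cd=t * r, cc=t * (1 - r))
    ds = SelectivityDataset(hauls=(haul,))
    dev, dof, pval = model_diagnostics(ds, p)
    assert dev == pytest.approx(0.0, abs=1e-10)
    assert dof == lengths.size - 2
    assert pval == pytest.approx(1.0)
    # chi-square survival at a printed (deviance, dof) pair
    assert deviance_p_value(25.46, 34) == pytest.approx(0.8543, abs=0.002)


def test_diagnostics_warn_on_nonpositive_dof():
    haul = make_haul("h", [25], cd=[10], cc=[10])
    ds = SelectivityDataset(hauls=(haul,))
    with pytest.warns(UserWarning):
        dev, dof, pval = model_diagnostics(ds, LogitParams(L50=25.0, SR=4.0))
    assert pval is None and dof <= 0


def test_deviance_residuals_conserve_deviance(rng):
    ds = random_dataset(rng, n_hauls=3, n_classes=6)
    res = fit_codend(ds)
    resid = deviance_residuals(ds, res.params)
    assert (resid["residual"] ** 2).sum() == pytest.approx(res.deviance, rel=1e-9)
    # sign convention: residual sign follows observed - expected
    nonzero = resid[np.abs(resid["observed"] - resid["expected"]) > 1e-9]
    assert (np.sign(nonzero["residual"]) == np.sign(nonzero["observed"] - nonzero["expected"])).all()
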