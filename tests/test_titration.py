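"""Saturation-isotherm fitting: exact recovery, bootstrap, ratios, consistency."""
import numpy as np
import pytest

from xtal2d import (
    FitResult,
    TitrationModel,
    TitrationSeries,
    background_correct,
    consistency_report,
    fit_titration,
    kd_ratio,
)
from xtal2d.titration import (
    InsufficientDataError,
    NoSignalError,
    PropagationError,
    _fit_core,
)

LADDER = (0.0, 20.0, 50.0, 100.0, 250.0, 500.0)


def _hyper(c, kd, h):
    c = np.asarray(c, float)
    return h * c / (c + kd)


# --------------------------------------------------------------- exact cases
def test_noiseless_continuous_counts_recover_kd_exactly():
    y = _hyper(LADDER, 30.0, 15.0)
    model = TitrationModel(LADDER, y, region_id="set1")
    res = model.fit(n_boot=50, seed=0)
    assert res.kd_app == pytest.approx(30.0, rel=1e-6)
    assert res.h_max == pytest.approx(15.0, rel=1e-6)
    assert res.rss < 1e-16


def test_fit_core_matches_independent_grid_search_oracle():
    rng = np.random.default_rng(2)
    conc = np.array(LADDER)
    y = _hyper(conc, 75.0, 12.0) + rng.normal(0, 0.5, conc.size)
    y[0] = 0.0
    kd, h, rss = _fit_core(conc, y)
    # brute-force oracle over a fine 2D grid
    kds = np.linspace(1.0, 400.0, 2000)
    hs = np.linspace(1.0, 25.0, 800)
    x = conc[None, None, :] / (conc[None, None, :] + kds[:, None, None])
    losses = ((hs[None, :, None] * x - y) ** 2).sum(axis=-1)
    i, j = np.unravel_index(np.argmin(losses), losses.shape)
    assert kd == pytest.approx(kds[i], rel=0.01)
    assert h == pytest.approx(hs[j], rel=0.01)
    assert rss <= losses[i, j] + 1e-9


def test_flat_counts_flagged_unidentifiable():
    y = np.array([5.0] * len(LADDER))
    res = TitrationModel(LADDER, y).fit(n_boot=200, seed=1)
    assert not res.well_determined


def test_error_conditions():
    with pytest.raises(NoSignalError):
        TitrationModel(LADDER, np.zeros(len(LADDER)))
    with pytest.raises(InsufficientDataError):
        TitrationModel((0.0, 10.0), (0.0, 3.0))


def test_fit_invariant_to_concentration_order_and_label():
    y = _hyper(LADDER, 40.0, 10.0) + np.array([0, 0.3, -0.2, 0.1, -0.4, 0.2])
    perm = [3, 0, 5, 1, 4, 2]
    a = TitrationModel(np.array(LADDER)[perm], y[perm], region_id="p").fit(50, seed=3)
    b = TitrationModel(LADDER, y, region_id="q").fit(50, seed=3)
    assert a.kd_app == pytest.approx(b.kd_app, rel=1e-9)
    assert a.ci_low == pytest.approx(b.ci_low, rel=1e-9)


def test_bootstrap_deterministic_in_seed():
    y = _hyper(LADDER, 30.0, 15.0) + np.array([0, 1, -1, 0.5, -0.5, 0.2])
    a = TitrationModel(LADDER, y).fit(n_boot=100, seed=7)
    b = TitrationModel(LADDER, y).fit(n_boot=100, seed=7)
    c = TitrationModel(LADDER, y).fit(n_boot=100, seed=8)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
    assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)
    assert a.ci_low <= a.kd_app <= a.ci_high


# --------------------------------------------------------------- series ops
def test_series_validation():
    with pytest.raises(ValueError):
        TitrationSeries(ph=8.0, concentrations=(0.0, 10.0, 10.0), counts={})
    with pytest.raises(ValueError):
        TitrationSeries(ph=8.0, concentrations=(-5.0, 10.0, 20.0), counts={})
    with pytest.raises(ValueError):
        TitrationSeries(ph=8.0, concentrations=(0.0, 10.0), counts={"a": (1, 2, 3)})


def test_background_correction_arithmetic():
    series = TitrationSeries(
        ph=8.0, concentrations=(0.0, 20.0, 100.0),
        counts={"s1": (2, 7, 9), "s2": (1, 1, 3), "s3": (0, 4, 6)},
    )
    out = background_correct(series, {"s1": 2, "s2": 2, "s3": 0})
    assert out.counts["s1"] == (0.0, 5.0, 7.0)     # raw 7, control 2 -> 5
    assert out.counts["s2"] == (0.0, 0.0, 1.0)     # raw <= control -> 0
    assert out.counts["s3"] == (0.0, 4.0, 6.0)     # control 0 -> identity
    assert out.corrected
    with pytest.raises(KeyError):
        background_correct(series, {"s1": 2})


def test_fit_from_series_requires_correction():
    series = TitrationSeries(
        ph=8.0, concentrations=LADDER,
        counts={"s1": tuple(_hyper(LADDER, 30.0, 15.0))},
    )
    with pytest.raises(ValueError):
        fit_titration(series, "s1")
    ok = background_correct(series, {"s1": 0})
    res = fit_titration(ok, "s1", seed=0, n_boot=50)
    assert res.kd_app == pytest.approx(30.0, rel=1e-6)
    assert res.region_id == "s1"
    assert "K_D,app" in res.summary()


# --------------------------------------------------------------- ratios
def _fit_like(kd, region="r", samples=None):
    s = np.asarray(samples if samples is not None else [kd] * 10, float)
    return FitResult(
        region_id=region, kd_app=kd, h_max=10.0, rss=0.0,
        ci_low=kd * 0.9, ci_high=kd * 1.1, n_boot=len(s), seed=0, kd_samples=s,
    )


def test_kd_ratio_examples():
    r = kd_ratio(_fit_like(280.0), _fit_like(30.0))
    assert r.ratio == pytest.approx(280.0 / 30.0)   # ~9.3-fold
    assert kd_ratio(_fit_like(42.0), _fit_like(42.0)).ratio == pytest.approx(1.0)
    fwd = kd_ratio(_fit_like(280.0), _fit_like(30.0)).ratio
    rev = kd_ratio(_fit_like(30.0), _fit_like(280.0)).ratio
    assert fwd == pytest.approx(1.0 / rev)


def test_kd_ratio_requires_converged_fits():
    bad = FitResult(region_id="x", kd_app=np.nan, h_max=1.0, rss=0.0,
                    ci_low=1.0, ci_high=2.0, n_boot=0, seed=0)
    with pytest.raises(PropagationError):
        kd_ratio(bad, _fit_like(30.0))


def test_consistency_report_spread_and_flag():
    same = [_fit_like(30.0, r) for r in ("a", "b", "c")]
    rep = consistency_report(same)
    assert rep.spread == pytest.approx(1.0)
    assert not rep.flagged
    mild = [_fit_like(v, r) for v, r in ((25.0, "a"), (30.0, "b"), (36.0, "c"))]
    rep = consistency_report(mild)
    assert rep.spread == pytest.approx(36.0 / 25.0)  # 1.44-fold
    assert not rep.flagged
    wide = consistency_report([_fit_like(30.0, "a"), _fit_like(90.0, "b")])
    assert wide.spread == pytest.approx(3.0)
    assert wide.flagged
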