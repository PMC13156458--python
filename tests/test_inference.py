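"""RBF forward models, maximum-likelihood fitting, rankings, cumulants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from microvas.inference import (
    RBFSignalModel,
    bias_index,
    fit_cumulants,
    fit_mle,
    offset_gaussian_objective,
    rank_metrics,
    spearman_with_ranges,
)

B6 = np.array([0.0, 10.0, 20.0, 40.0, 70.0, 100.0])


def _toy_model(n=60, lo=2e-3, hi=3e-2):
    """Training pairs from the smooth map s(u) = exp(-u b)."""
    u = np.linspace(lo, hi, n)
    s = np.exp(-np.outer(u, B6))
    return u, s


def test_rbf_interpolates_smooth_map():
    u, s = _toy_model()
    model = RBFSignalModel().fit(u, s)
    mid = 0.5 * (u[:-1] + u[1:])
    pred = model.predict(mid)
    truth = np.exp(-np.outer(mid, B6))
    assert np.max(np.abs(pred - truth)) < 0.01


def test_rbf_handles_duplicate_conflicting_u():
    u = np.array([1.0, 1.0, 2.0])
    s = np.array([[0.8], [0.6], [0.4]])
    model = RBFSignalModel(smoothing=1e-2).fit(u, s)
    pred = float(model.predict([1.0])[0, 0])
    assert 0.6 <= pred <= 0.8  # smoothed between the conflicting targets


def test_rbf_requires_two_distinct_params():
    with pytest.raises(ValueError):
        RBFSignalModel().fit(np.array([1.0, 1.0]), np.ones((2, 3)))


def test_rbf_sklearn_param_interface():
    model = RBFSignalModel()
    params = model.get_params()
    assert "kernel" in params and "smoothing" in params
    model.set_params(smoothing=0.5)
    assert model.smoothing == 0.5


def test_mle_recovers_training_point():
    u, s = _toy_model()
    model = RBFSignalModel().fit(u, s)
    target = s[30]
    res = fit_mle(model, target, sigma=1e-4)
    assert res.u[0] == pytest.approx(u[30], rel=1e-3)


def test_mle_grid_matches_brute_force():
    u, s = _toy_model()
    model = RBFSignalModel().fit(u, s)
    rng = np.random.default_rng(0)
    noisy = np.clip(s[17] + rng.normal(0, 0.05, size=6), 0, None)
    res = fit_mle(model, noisy, sigma=0.05, refine=False)
    grid_u, grid_s = model.parameter_grid()
    objs = offset_gaussian_objective(noisy, grid_s, 0.05)
    k = int(np.argmin(objs))
    assert res.u[0] == grid_u[k, 0]
    assert res.objective == pytest.approx(float(objs[k]))


def test_mle_small_sigma_approaches_least_squares():
    u, s = _toy_model()
    model = RBFSignalModel().fit(u, s)
    rng = np.random.default_rng(1)
    noisy = s[40] + rng.normal(0, 0.02, size=6)
    grid_u, grid_s = model.parameter_grid()
    res = fit_mle(model, noisy, sigma=1e-6, refine=False)
    lsq = grid_u[int(np.argmin(((grid_s - noisy) ** 2).sum(axis=1)))]
    assert res.u[0] == lsq[0]


def test_mle_two_dimensional():
    rng = np.random.default_rng(2)
    u = np.column_stack([rng.uniform(1e-3, 3e-2, 120), rng.uniform(0.5, 3.0, 120)])
    s = np.exp(-np.outer(u[:, 0], B6)) * (1 + 0.05 * u[:, 1][:, None])
    model = RBFSignalModel().fit(u, s)
    res = fit_mle(model, s[7], sigma=1e-4)
    assert res.u[0] == pytest.approx(u[7, 0], rel=0.05)


def test_spearman_examples():
    rs, _ = spearman_with_ranges([1, 2, 3, 4], [1, 2, 3, 4])
    assert rs == pytest.approx(1.0)
    rs, _ = spearman_with_ranges([1, 2, 3, 4], [4, 3, 2, 1])
    assert rs == pytest.approx(-1.0)
    rs, _ = spearman_with_ranges([1, 2, 3, 4], [1, 3, 2, 4])
    assert rs == pytest.approx(0.8)
    rs, rng_ = spearman_with_ranges(
        [1, 2, 3, 4, 5, 6], [1, 3, 2, 4, 6, 5], fold_ids=[0, 0, 0, 1, 1, 1]
    )
    assert rng_[0] <= rs <= 1.0


def test_spearman_constant_input_is_nan():
    rs, _ = spearman_with_ranges([1, 1, 1], [1, 2, 3])
    assert np.isnan(rs)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_spearman_invariant_under_monotone_transforms(seed):
    rng = np.random.default_rng(seed)
    gt = rng.normal(size=12)
    pred = rng.normal(size=12)
    rs, _ = spearman_with_ranges(gt, pred)
    rs2, _ = spearman_with_ranges(np.exp(gt), pred**3)
    assert rs2 == pytest.approx(rs, abs=1e-12)


def test_bias_index_examples():
    gt = np.linspace(1, 2, 101)
    assert bias_index(gt, gt) == 0.0
    assert bias_index(gt, 1.1 * gt) == pytest.approx(10.0)
    # a single gross outlier barely moves the median-based index
    pred = 1.1 * gt
    pred[50] = 100.0
    assert abs(bias_index(gt, pred) - 10.0) < 1.0
    with pytest.raises(ValueError):
        bias_index(np.array([0.0, 1.0]), np.array([1.0, 1.0]))


def test_rank_metrics_ordering():
    rng = np.random.default_rng(3)
    rows = []
    for name, noise in [("good", 0.1), ("fair", 1.0), ("poor", 10.0)]:
        gt = np.linspace(1, 2, 30)
        pred = gt + rng.normal(0, noise, 30)
        for f in range(3):
            for i in range(10):
                k = 10 * f + i
                rows.append({"metric": name, "fold": f, "gt": gt[k], "pred": pred[k]})
    table = rank_metrics(pd.DataFrame(rows))
    assert table.loc["good", "rank_rs"] == 1
    assert table.loc["poor", "rank_rs"] == 3
    assert set(table["rank_rs"]) == {1, 2, 3}
    with pytest.raises(ValueError):
        rank_metrics(pd.DataFrame(rows), metric_names=["good", "missing"])


def test_cumulant_fit_monoexponential():
    d_mm2s = 0.02  # 20 um^2/ms
    b = np.linspace(0, 100, 12)
    s = np.exp(-b * d_mm2s)
    fit = fit_cumulants(s, b)
    assert fit.dstar == pytest.approx(20.0, abs=1e-4 * 20)
    assert fit.kstar == pytest.approx(0.0, abs=1e-4)


def test_cumulant_fit_two_velocity_kurtosis():
    # equal mix of two monoexponential rates has positive apparent kurtosis
    b = np.linspace(0, 100, 12)
    s = 0.5 * np.exp(-b * 0.005) + 0.5 * np.exp(-b * 0.04)
    fit = fit_cumulants(s, b)
    assert fit.kstar > 0.1


def test_cumulant_fit_matches_grid_oracle():
    rng = np.random.default_rng(4)
    b = np.linspace(0, 100, 10)
    s = np.clip(np.exp(-b * 0.015 + (0.6 / 6) * (b * 0.015) ** 2)
                + rng.normal(0, 0.01, 10), 1e-3, None)
    fit = fit_cumulants(s, b)
    # brute-force the weighted log-space objective on a fine grid
    ds = np.linspace(1e-4, 0.05, 400)
    ks = np.linspace(-2, 5, 400)
    dd, kk = np.meshgrid(ds, ks, indexing="ij")
    logs = np.log(s)
    w2 = s**2
    obj = np.zeros_like(dd)
    for i, (bi, li, wi) in enumerate(zip(b, logs, w2)):
        bd = bi * dd
        obj += wi * (li - (-bd + kk * bd**2 / 6.0)) ** 2
    assert fit.residual <= obj.min() + 1e-9


def test_cumulant_fit_needs_three_b():
    with pytest.raises(ValueError):
        fit_cumulants(np.array([1.0, 0.5]), np.array([0.0, 50.0]))


def test_noise_free_ensemble_recovery_of_qm(mini_signals, mini_metrics, mini_protocols):
    """Fitting noise-free ensemble signals recovers qm almost perfectly."""
    from microvas.inference import leave_one_out

    res = leave_one_out(
        mini_signals["NC30"], mini_metrics, "qm", mini_protocols["NC30"],
        snr=1e6, seed=0,
    )
    rs, _ = spearman_with_ranges(res["gt"], res["pred"])
    assert rs > 0.9


def test_joint_2d_fit(study_signals, study_metrics, study_protocols):
    """Estimating (qm, ANB) jointly keeps qm recoverability close to the 1D
    fit; ANB retains a positive association but degrades, reflecting the
    qm-ANB degeneracy of the synthetic ensemble's low-b signal."""
    from microvas.inference import leave_one_out

    prot = study_protocols["NC"]
    one_d = leave_one_out(study_signals["NC"], study_metrics, ["qm", "ANB"],
                          prot, snr=5.0, seed=31)
    two_d = leave_one_out(study_signals["NC"], study_metrics, ["qm", "ANB"],
                          prot, snr=5.0, seed=31, joint=True)

    def rs_of(frame, name):
        sub = frame[frame["metric"] == name]
        return spearman_with_ranges(sub["gt"], sub["pred"])[0]

    assert abs(rs_of(one_d, "qm") - rs_of(two_d, "qm")) <= 0.15
    assert rs_of(two_d, "ANB") > 0.0


def test_rbf_model_save_load_roundtrip(tmp_path):
    u, s = _toy_model()
    model = RBFSignalModel().fit(u, s)
    model.protocol_hash_ = "abc123"
    p = tmp_path / "model.npz"
    model.save(p)
    back = RBFSignalModel.load(p)
    probe = np.linspace(u.min(), u.max(), 17)
    assert np.allclose(back.predict(probe), model.predict(probe))
    assert back.protocol_hash_ == "abc123"
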