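import numpy as np
import pandas as pd
import pytest

from leaflet_smlm import (
    ROI,
    DoCParams,
    SceneConfig,
    coloc_index,
    density_gradients,
    doc_control,
    doc_scores,
    gen_csr,
    gen_paired_channels,
    mean_density_gradient,
    random_shift,
)


def _table(x, y):
    return pd.DataFrame({"frame": np.ones(len(x), dtype=int), "x": x, "y": y})


# ---------------------------------------------------------------------------
# parameters


def test_params_defaults():
    p = DoCParams()
    assert p.r_max == 500.0 and p.dr == 50.0
    assert p.min_total_localizations == 100  # (r_max/dr) * 10
    assert np.allclose(p.radii, 50.0 * np.arange(1, 11))


def test_params_rmax_must_be_multiple_of_dr():
    with pytest.raises(ValueError):
        DoCParams(r_max=500.0, dr=33.0)


# ---------------------------------------------------------------------------
# density_gradients


def test_gradient_normalized_at_rmax(roi_small):
    a = gen_csr(800, roi_small, seed=0)
    b = gen_csr(800, roi_small, seed=1)
    g = density_gradients(a, b, focal=17)
    assert g.defined
    assert g.d_own[-1] == pytest.approx(1.0)
    assert g.d_other[-1] == pytest.approx(1.0)


def test_gradient_undefined_when_other_channel_far(roi_small):
    a = _table([100.0, 110.0, 120.0, 130.0], [100.0] * 4)
    b = _table([1900.0], [1900.0])  # > R_max from every A point
    g = density_gradients(a, b, focal=0)
    assert not g.defined
    assert np.isnan(g.d_other[-1])


def test_uniform_mean_gradient_is_one():
    """Binwise mean D(r) ~ 1 on CSR input (interior focals)."""
    roi = ROI(0.0, 0.0, 10_000.0, 10_000.0)
    table = gen_csr(10_000, roi, seed=3)
    prof = mean_density_gradient(table, n_focals=400, seed=4, roi=roi)
    mean = prof["mean_D"].to_numpy()
    se = prof["se_D"].to_numpy()
    exact = se == 0  # the R_max bin is exactly 1 by normalization
    assert np.allclose(mean[exact], 1.0, rtol=1e-12)
    assert (np.abs(mean[~exact] - 1.0) / se[~exact] < 3).all()


# ---------------------------------------------------------------------------
# doc_scores


def test_identical_copy_scores_plus_one(roi_small, csr_small):
    result = doc_scores(csr_small, csr_small.copy())
    scored = result.channel_a["scored"]
    assert scored.any()
    assert (result.channel_a.loc[scored, "C"] == 1.0).all()
    assert (result.channel_a.loc[scored, "S"] == 1.0).all()
    assert (result.channel_a.loc[scored, "E_nm"] == 0.0).all()


def test_exclusion_rule_requires_both_low():
    """Focal with both within-R_max counts < 100 is excluded; one channel
    over the bound rescues it."""
    rng = np.random.default_rng(0)
    roi = ROI(0.0, 0.0, 4000.0, 4000.0)
    center = np.array([2000.0, 2000.0])
    # focal + 98 own-channel points inside R_max (count 98 < 100)
    a_pts = np.vstack([center, center + rng.uniform(-300, 300, size=(98, 2))])
    # B sparse: 50 points near the focal -> both low -> excluded
    b_sparse = center + rng.uniform(-300, 300, size=(50, 2))
    res = doc_scores(_table(a_pts[:, 0], a_pts[:, 1]), _table(b_sparse[:, 0], b_sparse[:, 1]))
    assert res.channel_a["exclusion_reason"].iloc[0] == "low count"
    # B dense: 150 points -> B count >= 100 -> scored
    b_dense = center + rng.uniform(-300, 300, size=(150, 2))
    res2 = doc_scores(_table(a_pts[:, 0], a_pts[:, 1]), _table(b_dense[:, 0], b_dense[:, 1]))
    assert bool(res2.channel_a["scored"].iloc[0])


def test_scores_in_range(roi_default):
    a = gen_csr(4000, roi_default, seed=5)
    b = gen_csr(4000, roi_default, seed=6)
    res = doc_scores(a, b)
    for tab in (res.channel_a, res.channel_b):
        c = tab.loc[tab["scored"], "C"]
        s = tab.loc[tab["scored"], "S"]
        assert ((c >= -1) & (c <= 1)).all()
        assert ((s >= -1) & (s <= 1)).all()
        assert (tab["E_nm"] >= 0).all()


def test_channel_symmetry(roi_default):
    a = gen_csr(3000, roi_default, seed=7)
    b = gen_csr(3000, roi_default, seed=8)
    ab = doc_scores(a, b)
    ba = doc_scores(b, a)
    pd.testing.assert_frame_equal(ab.channel_a, ba.channel_b)
    pd.testing.assert_frame_equal(ab.channel_b, ba.channel_a)


def test_empty_channel_rejected(csr_small):
    with pytest.raises(ValueError, match="non-empty"):
        doc_scores(csr_small, csr_small.iloc[0:0])


def test_null_histogram_symmetric(roi_default):
    """CSR-CSR DoC scores of interior focals are symmetric about 0
    (two-sided sign test p > 0.01 on a 5000-score sample).

    The field density must clear the both-channels-<100 exclusion rule
    (15,000 points here); the sample is restricted to focals whose R_max
    disk lies inside the ROI, since boundary-clipped disks carry a small
    documented positive bias.
    """
    from scipy.stats import binomtest

    a = gen_csr(15_000, roi_default, seed=9)
    b = gen_csr(15_000, roi_default, seed=10)
    res = doc_scores(a, b)
    m = res.params.r_max
    vals = []
    for tab, src in ((res.channel_a, a), (res.channel_b, b)):
        pts = src[["x", "y"]].to_numpy(float)
        interior = (
            (pts[:, 0] >= roi_default.x_min + m)
            & (pts[:, 0] <= roi_default.x_max - m)
            & (pts[:, 1] >= roi_default.y_min + m)
            & (pts[:, 1] <= roi_default.y_max - m)
        )
        vals.append(tab.loc[tab["scored"].to_numpy() & interior, "C"].to_numpy())
    pooled = np.concatenate(vals)
    pooled = pooled[pooled != 0]
    sample = np.random.default_rng(0).choice(pooled, size=5000, replace=False)
    assert binomtest(int((sample > 0).sum()), len(sample)).pvalue > 0.01


# ---------------------------------------------------------------------------
# coloc_index


def test_index_all_ones(csr_small):
    res = doc_scores(csr_small, csr_small.copy())
    idx = coloc_index(res)
    assert idx["pooled"]["index"] == 1.0
    assert idx["a"]["raw_count"] == idx["a"]["n_scored"]


def test_index_zero_when_all_below(roi_default):
    a = gen_csr(15_000, roi_default, seed=11)
    b = gen_csr(15_000, roi_default, seed=12)
    res = doc_scores(a, b)
    # independent CSR: only rank-correlation noise reaches [0.7, 1]
    # (Spearman over 10 radius bins has heavy tails, so a few percent land
    # in the bin even with zero true colocalization)
    idx = coloc_index(res)
    assert idx["pooled"]["n_scored"] > 0
    assert idx["pooled"]["index"] < 0.1


def test_index_histogram_bins():
    res_edges = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 10)
    from leaflet_smlm.doc import HIST_BIN_EDGES, INDEX_BIN

    assert np.allclose(HIST_BIN_EDGES, res_edges)
    assert INDEX_BIN == (0.7, 1.0)


# ---------------------------------------------------------------------------
# doc_control


def test_control_deterministic(roi_default):
    a = gen_csr(3000, roi_default, seed=13)
    b = gen_csr(3000, roi_default, seed=14)
    c1 = doc_control(a, b, seed=5, roi=roi_default)
    c2 = doc_control(a, b, seed=5, roi=roi_default)
    pd.testing.assert_frame_equal(c1.channel_a, c2.channel_a)
    assert c1.control_seed == 5


def test_control_breaks_identity(roi_default):
    a = gen_csr(15_000, roi_default, seed=15)
    ctrl = doc_control(a, a.copy(), seed=1, roi=roi_default)
    c = ctrl.channel_a.loc[ctrl.channel_a["scored"], "C"]
    assert len(c) > 0
    assert (c < 1.0).any()


def test_coupled_channels_beat_control(roi_default):
    """Coupled clustered channels score a higher index than their shifted
    control (spot check of the Monte-Carlo property at a few seeds)."""
    wins = 0
    for seed in range(5):
        cfg = SceneConfig(
            n_clusters=20,
            cluster_radius_sd=45.0,
            locs_per_cluster=100,
            background_locs=2000,
            localization_precision_sd=22.0,
            seed=seed,
        )
        a, b, _ = gen_paired_channels(cfg, cfg, coloc_fraction=1.0, roi=roi_default, seed=seed)
        orig = coloc_index(doc_scores(a, b))["pooled"]["index"]
        ctrl = coloc_index(doc_control(a, b, seed=seed + 100, roi=roi_default))["pooled"]["index"]
        wins += orig > ctrl
    assert wins == 5
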