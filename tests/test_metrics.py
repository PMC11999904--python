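"""Overlap and surface-distance metrics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.distance import cdist

from headms import metrics
from headms.core import LabelVolume


# ---------------------------------------------------------------------------
# independent oracles: plain set arithmetic and pairwise distances


def brute_dice(p, g):
    ps = set(map(tuple, np.argwhere(p)))
    gs = set(map(tuple, np.argwhere(g)))
    if not ps and not gs:
        return 1.0
    return 2.0 * len(ps & gs) / (len(ps) + len(gs))


def brute_boundary(m):
    m = np.asarray(m, dtype=bool)
    pts = []
    for i, j in np.argwhere(m):
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if not (0 <= ni < m.shape[0] and 0 <= nj < m.shape[1]) or not m[ni, nj]:
                pts.append((i, j))
                break
    return np.array(pts, dtype=float) if pts else np.empty((0, 2))


def brute_assd(p, g, spacing=(1.0, 1.0)):
    bp = brute_boundary(p) * spacing
    bg = brute_boundary(g) * spacing
    d = cdist(bp, bg)
    return (d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(bp) + len(bg))


def random_nonempty_mask(rng, shape=(16, 16), p=0.2):
    while True:
        m = rng.random(shape) < p
        if m.any():
            return m


# ---------------------------------------------------------------------------


def test_dice_identity_disjoint_and_shifted_block():
    block = np.zeros((8, 8), dtype=bool)
    block[0:2, 0:2] = True
    assert metrics.dice(block, block) == 1.0
    other = np.zeros((8, 8), dtype=bool)
    other[5:7, 5:7] = True
    assert metrics.dice(block, other) == 0.0
    shifted = np.roll(block, 1, axis=1)  # |P|=|G|=4, overlap 2 -> 2*2/8
    assert metrics.dice(block, shifted) == 0.5


def test_dice_empty_mask_conventions():
    empty = np.zeros((4, 4), dtype=bool)
    one = empty.copy()
    one[1, 1] = True
    assert metrics.dice(empty, empty) == 1.0
    assert metrics.dice(one, empty) == 0.0
    assert metrics.dice(empty, one) == 0.0


def test_boundary_single_pixel_square_and_empty():
    single = np.zeros((5, 5), dtype=bool)
    single[2, 3] = True
    assert metrics.extract_boundary(single).tolist() == [[2, 3]]
    square = np.zeros((5, 5), dtype=bool)
    square[1:4, 1:4] = True
    b = metrics.extract_boundary(square)
    assert len(b) == 8 and [2, 2] not in b.tolist()
    assert len(metrics.extract_boundary(np.zeros((5, 5), dtype=bool))) == 0


def test_boundary_at_array_edge_counts_as_outside():
    full = np.ones((4, 4), dtype=bool)
    assert len(metrics.extract_boundary(full)) == 12  # perimeter of 4x4


def test_assd_two_single_pixels():
    p = np.zeros((4, 4), dtype=bool)
    g = np.zeros((4, 4), dtype=bool)
    p[0, 0] = True
    g[0, 3] = True
    assert metrics.assd(p, g) == pytest.approx(3.0)
    assert metrics.assd(p, g, spacing=(1.0, 2.0)) == pytest.approx(6.0)


def test_assd_identical_masks_is_zero(rng):
    m = random_nonempty_mask(rng)
    assert metrics.assd(m, m) == 0.0


def test_assd_empty_mask_is_undefined():
    m = np.zeros((4, 4), dtype=bool)
    n = m.copy()
    n[0, 0] = True
    with pytest.raises(ValueError, match="undefined"):
        metrics.assd(m, n)


@pytest.mark.parametrize("spacing", [(1.0, 1.0), (260 / 256, 260 / 256), (0.8, 1.3)])
def test_assd_matches_brute_force_oracle(spacing, rng):
    for _ in range(40):
        p = random_nonempty_mask(rng)
        g = random_nonempty_mask(rng)
        assert metrics.assd(p, g, spacing) == pytest.approx(
            brute_assd(p, g, spacing), abs=1e-9
        )
        assert metrics.assd(p, g, spacing) == pytest.approx(
            metrics.assd(g, p, spacing), abs=1e-12
        )


def test_extended_metrics_shifted_block_confusion_counts():
    block = np.zeros((8, 8), dtype=bool)
    block[0:2, 0:2] = True
    shifted = np.roll(block, 1, axis=1)
    ext = metrics.extended_metrics(shifted, block)  # TP=2 FP=2 FN=2
    assert ext["f1"] == pytest.approx(0.5)
    assert ext["precision"] == pytest.approx(0.5)
    assert ext["recall"] == pytest.approx(0.5)
    assert ext["jaccard"] == pytest.approx(1 / 3)


def test_extended_metrics_zero_denominator_is_missing():
    empty = np.zeros((4, 4), dtype=bool)
    ext = metrics.extended_metrics(empty, empty)
    assert np.isnan(ext["precision"]) and np.isnan(ext["jaccard"])
    assert ext["specificity"] == 1.0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    p=arrays(bool, (9, 9), elements=st.booleans()),
    g=arrays(bool, (9, 9), elements=st.booleans()),
)
def test_metric_identities_hold_on_arbitrary_masks(p, g):
    d = metrics.dice(p, g)
    assert 0.0 <= d <= 1.0
    assert d == metrics.dice(g, p)
    ext = metrics.extended_metrics(p, g)
    if p.any() or g.any():
        assert ext["f1"] == pytest.approx(d, abs=1e-12)  # F1 is Dice
        j = ext["jaccard"]
        assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)
    assert ext["recall"] is ext["sensitivity"] or ext["recall"] == ext["sensitivity"]
    assert metrics.dice(p, g) == pytest.approx(brute_dice(p, g), abs=1e-12)


def test_evaluate_prediction_perfect_and_background():
    lab = np.zeros((2, 16, 16), dtype=np.uint8)
    lab[:, 2:5, 2:5] = 1
    lab[:, 2:5, 10:13] = 2
    lab[:, 8:11, 2:5] = 3
    lab[:, 8:11, 10:13] = 4
    lab[:, 12:14, 6:9] = 5
    truth = LabelVolume(lab, (3.0, 1.0, 1.0), "s")
    perfect = metrics.evaluate_prediction(truth, truth)
    for frag in perfect:
        assert frag["dsc"] == 100.0
        assert frag["assd"] == 0.0
        assert frag["jaccard"] == 1.0
    background = LabelVolume(np.zeros_like(lab), (3.0, 1.0, 1.0), "s")
    worst = metrics.evaluate_prediction(background, truth)
    for frag in worst:
        assert frag["dsc"] == 0.0
        assert np.isnan(frag["assd"])  # empty prediction: missing, never 0


def test_evaluate_prediction_hand_computed_single_slice():
    truth = np.zeros((1, 8, 8), dtype=np.uint8)
    truth[0, 1:3, 1:3] = 1  # 4 pixels of RM
    pred = np.zeros_like(truth)
    pred[0, 1:3, 2:4] = 1  # shifted right: overlap 2
    frags = metrics.evaluate_prediction(pred, truth, spacing=(3.0, 1.0, 1.0))
    rm = next(f for f in frags if f["tissue"] == "right_masseter")
    assert rm["dsc"] == pytest.approx(50.0)
    assert rm["jaccard"] == pytest.approx(1 / 3)
    # boundaries are both full 2x2 blocks shifted by 1: mean NN distance
    p_mask, g_mask = pred[0] == 1, truth[0] == 1
    assert rm["assd"] == pytest.approx(brute_assd(p_mask, g_mask), abs=1e-12)


def test_evaluate_prediction_rejects_bad_labels():
    good = np.zeros((1, 4, 4), dtype=np.uint8)
    bad = good.copy()
    bad[0, 0, 0] = 7
    with pytest.raises(ValueError, match="labels"):
        metrics.evaluate_prediction(bad, good)


def test_aggregate_records_mean_of_identical_values():
    recs = [
        metrics.MetricsRecord("unet", "tongue", f, "test", 90.0, 1.0,
                              0.8, 0.9, 0.9, 0.9, 0.99, 0.9)
        for f in range(3)
    ]
    agg = metrics.aggregate_records(recs)
    row = agg[(agg.metric == "dsc")]
    assert row["mean"].iloc[0] == pytest.approx(90.0)
    assert row["sd"].iloc[0] == pytest.approx(0.0)
    assert row["iqr"].iloc[0] == pytest.approx(0.0)
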