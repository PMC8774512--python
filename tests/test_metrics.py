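"""Detection and 3D-overlap metrics against brute-force set oracles."""

import numpy as np
import pytest
from scipy import special

from kneeseg.metrics import (
    ConfusionCounts,
    EvalReport,
    OverlapCounts,
    accuracy,
    bone_volume,
    confusion_from_presence,
    dice,
    fnr,
    fpr,
    paired_t_test,
    pool_overlap,
    precision,
    recall,
    similarity,
    tpr,
    volume_agreement,
)
from kneeseg.volumes import MaskSequence


# -- slice-level detection ----------------------------------------------------

# detection performance on the 2400-slice testing set, per compartment:
# (fp, fn, tp, tn) with the accuracy/recall/precision each implies
DETECTION_ROWS = {
    "tibia": ((20, 9, 1679, 692), 98.79, 0.995, 0.988),
    "femur": ((20, 8, 1786, 586), 98.83, 0.996, 0.989),
    "patella": ((9, 28, 950, 1413), 98.46, 0.971, 0.991),
    "whole": ((20, 9, 1831, 540), 98.79, 0.995, 0.989),
}


@pytest.mark.parametrize("compartment", DETECTION_ROWS)
def test_detection_rates_from_published_confusion_counts(compartment):
    (fp, fn, tp, tn), acc, rec, prec = DETECTION_ROWS[compartment]
    c = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    assert c.total == 2400
    assert round(accuracy(c), 2) == acc
    assert round(recall(c), 3) == rec
    assert round(precision(c), 3) == prec


def test_confusion_matches_elementwise_tally(rng):
    pred = rng.random(50) > 0.5
    truth = rng.random(50) > 0.5
    c = confusion_from_presence(pred, truth)
    # brute-force per-element enumeration
    tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for p, t in zip(pred, truth):
        tally[("t" if p == t else "f") + ("p" if p else "n")] += 1
    assert (c.tp, c.tn, c.fp, c.fn) == (tally["tp"], tally["tn"], tally["fp"], tally["fn"])
    assert c.total == 50


def test_confusion_edge_cases():
    c = confusion_from_presence([True] * 5, [False] * 5)
    assert c.fp == 5 and c.tp == 0
    same = confusion_from_presence([True, False], [True, False])
    assert same.fp == same.fn == 0
    with pytest.raises(ValueError):
        confusion_from_presence([True], [True, False])


def test_rate_sentinels_on_zero_denominators():
    assert recall(ConfusionCounts(tp=0, tn=5, fp=0, fn=0)) is None
    assert precision(ConfusionCounts(tp=0, tn=5, fp=0, fn=0)) is None
    assert accuracy(ConfusionCounts()) is None


# -- 3D case-level overlap ----------------------------------------------------

def _overlap_oracle(g: np.ndarray, m: np.ndarray) -> OverlapCounts:
    """Explicit voxel-set computation on flattened indices."""
    sg = set(np.flatnonzero(g.ravel()))
    sm = set(np.flatnonzero(m.ravel()))
    return OverlapCounts(n_g=len(sg), n_m=len(sm), n_inter=len(sg & sm))


def test_pool_overlap_equals_voxel_set_oracle(rng):
    for _ in range(50):
        g = (rng.random((5, 8, 8)) > 0.5).astype(np.uint8)
        m = (rng.random((5, 8, 8)) > 0.5).astype(np.uint8)
        got = pool_overlap(MaskSequence("c", "whole", g), MaskSequence("c", "whole", m))
        assert got == _overlap_oracle(g, m)


def test_pool_overlap_identical_and_disjoint():
    g = np.zeros((3, 4, 4), np.uint8)
    g[1, :2] = 1
    k = int(g.sum())
    same = pool_overlap(MaskSequence("c", "whole", g), MaskSequence("c", "whole", g))
    assert (same.n_g, same.n_m, same.n_inter) == (k, k, k)
    m = np.zeros_like(g)
    m[2, 2:] = 1
    assert pool_overlap(MaskSequence("c", "whole", g), MaskSequence("c", "whole", m)).n_inter == 0
    with pytest.raises(ValueError):
        pool_overlap(MaskSequence("c", "whole", g), MaskSequence("c", "whole", g[:2]))


def test_overlap_ratio_worked_example():
    o = OverlapCounts(n_g=10, n_m=10, n_inter=5)
    assert dice(o) == 0.5
    assert similarity(o) == pytest.approx(1 / 3)
    assert tpr(o) == 0.5 and fpr(o) == 0.5 and fnr(o) == 0.5


def test_perfect_match_ratios():
    o = OverlapCounts(n_g=7, n_m=7, n_inter=7)
    assert dice(o) == similarity(o) == tpr(o) == 1.0
    assert fpr(o) == 0.0 and fnr(o) == 0.0


def test_fnr_complements_tpr_as_percentages():
    # e.g. a case-average TPR of 98.51% implies FNR 1.49%
    o = OverlapCounts(n_g=10000, n_m=10100, n_inter=9851)
    assert 100 * tpr(o) == pytest.approx(98.51)
    assert 100 * fnr(o) == pytest.approx(1.49)


def test_dice_jaccard_identity_and_bounds(rng):
    for _ in range(200):
        g = (rng.random((5, 8, 8)) > rng.random()).astype(np.uint8)
        m = (rng.random((5, 8, 8)) > rng.random()).astype(np.uint8)
        o = _overlap_oracle(g, m)
        d, j = dice(o), similarity(o)
        assert 0.0 <= d <= 1.0 and 0.0 <= j <= 1.0
        assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)
        if o.n_g:
            assert fnr(o) + tpr(o) == pytest.approx(1.0, abs=1e-12)
            assert fpr(o) >= 0.0


def test_empty_empty_convention_scores_one_with_flag():
    o = OverlapCounts(n_g=0, n_m=0, n_inter=0)
    assert o.empty_empty
    assert dice(o) == 1.0 and similarity(o) == 1.0
    assert tpr(o) is None and fpr(o) is None and fnr(o) is None


def test_overlap_counts_validate_set_algebra():
    with pytest.raises(ValueError):
        OverlapCounts(n_g=2, n_m=2, n_inter=3)


# -- volumes -------------------------------------------------------------------

def test_bone_volume_examples(rng):
    m = np.zeros((4, 10, 10), np.uint8)
    m.ravel()[rng.choice(m.size, 100, replace=False)] = 1
    assert bone_volume(MaskSequence("c", "whole", m), (1, 1, 0.5)) == 50.0
    assert bone_volume(MaskSequence("c", "whole", np.zeros_like(m))) == 0.0
    # brute force: explicit count times voxel volume
    spacing = (0.36, 0.36, 0.7)
    expected = sum(int(v) for v in m.ravel()) * 0.36 * 0.36 * 0.7
    assert bone_volume(MaskSequence("c", "whole", m), spacing) == pytest.approx(expected)


def test_volume_agreement_identity_scale_and_ols_oracle(rng):
    gt = rng.uniform(1e3, 1e5, size=15)
    slope, intercept, r2 = volume_agreement(gt, gt)
    assert slope == pytest.approx(1.0) and intercept == pytest.approx(0.0, abs=1e-6) and r2 == pytest.approx(1.0)
    slope, _, r2 = volume_agreement(gt, 2 * gt)
    assert slope == pytest.approx(2.0) and r2 == pytest.approx(1.0)
    pred = 0.97 * gt + rng.normal(0, 500, size=15)
    slope, intercept, r2 = volume_agreement(gt, pred)
    # closed-form OLS oracle
    sxy = np.mean(gt * pred) - gt.mean() * pred.mean()
    sxx = np.mean(gt * gt) - gt.mean() ** 2
    syy = np.mean(pred * pred) - pred.mean() ** 2
    assert slope == pytest.approx(sxy / sxx)
    assert intercept == pytest.approx(pred.mean() - slope * gt.mean())
    assert r2 == pytest.approx(sxy**2 / (sxx * syy))


def test_volume_agreement_degenerate():
    assert volume_agreement([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) is None
    with pytest.raises(ValueError):
        volume_agreement([1.0, 2.0], [1.0, 2.0])


# -- paired t-test -------------------------------------------------------------

def test_paired_t_identical_scores_degenerate():
    assert paired_t_test([0.9, 0.8, 0.7], [0.9, 0.8, 0.7]) is None
    assert paired_t_test([0.9, 0.8], [0.8, 0.7]) is None  # constant shift, zero-variance diffs


def test_paired_t_detects_systematic_shift(rng):
    a = rng.uniform(0.9, 0.99, 15)
    b = a - 0.05 + rng.normal(0, 1e-3, 15)
    t, p = paired_t_test(a, b)
    assert p < 0.05 and t > 0


def test_paired_t_fixed_vectors_match_closed_form():
    """t from the textbook formula; p from the t CDF via the regularized
    incomplete beta function, independent of scipy.stats.ttest_rel."""
    a = np.array([0.93, 0.95, 0.91, 0.97, 0.90, 0.94])
    b = np.array([0.92, 0.96, 0.88, 0.95, 0.91, 0.92])
    d = a - b
    n = d.size
    t_exp = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    df = n - 1
    x = df / (df + t_exp**2)
    p_exp = special.betainc(df / 2, 0.5, x)  # two-tailed
    t_got, p_got = paired_t_test(a, b)
    assert t_got == pytest.approx(t_exp, rel=1e-12)
    assert p_got == pytest.approx(p_exp, rel=1e-10)


# -- report --------------------------------------------------------------------

def test_eval_report_aggregate_is_mean_of_cases():
    rep = EvalReport()
    rep.add_case("c0", "whole", OverlapCounts(100, 100, 90), 100.0, 100.0)
    rep.add_case("c1", "whole", OverlapCounts(100, 100, 80), 100.0, 100.0)
    agg = rep.aggregate()
    d0 = dice(OverlapCounts(100, 100, 90))
    d1 = dice(OverlapCounts(100, 100, 80))
    assert agg.loc["whole", "dice"] == pytest.approx((d0 + d1) / 2)
    assert list(rep.scores("whole")) == [pytest.approx(d0), pytest.approx(d1)]


def test_eval_report_csv_and_summary_roundtrip(tmp_path):
    import json

    import pandas as pd

    rep = EvalReport()
    rep.add_case("c0", "femur", OverlapCounts(50, 60, 45), 50.0, 60.0)
    rep.to_csv(tmp_path / "r.csv")
    df = pd.read_csv(tmp_path / "r.csv")
    assert df.shape[0] == 1 and df.loc[0, "compartment"] == "femur"
    payload = json.loads(rep.summary_json(tmp_path / "s.json"))
    assert "femur" in payload and 0 <= payload["femur"]["dice_pct"] <= 100
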