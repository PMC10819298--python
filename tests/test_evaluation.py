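"""ROC machinery against brute-force, sklearn and R pROC oracles."""

import json
import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve

from emergepd.evaluation import (
    accuracy,
    auc_ci,
    compare_roc,
    evaluate_models,
    mann_whitney_auc,
    roc_auc,
)
from emergepd.exceptions import InvalidInputError


def brute_force_auc(scores, labels):
    """Exhaustive concordant-pair counting with ties at 1/2."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (pos.size * neg.size)


def test_trivial_auc_values():
    assert mann_whitney_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
    assert mann_whitney_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5
    assert mann_whitney_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)


def test_auc_equals_brute_force_and_trapezoid(rng):
    for _ in range(200):
        n = int(rng.integers(4, 30))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            continue
        s = np.round(rng.random(n), 2)  # coarse scores force ties
        ours = mann_whitney_auc(s, y)
        assert ours == pytest.approx(brute_force_auc(s, y), abs=1e-12)
        fpr, tpr, _ = roc_curve(y, s)
        assert ours == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)
        assert ours == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_auc_invariant_to_monotone_transform(rng):
    y = rng.integers(0, 2, 200)
    y[:2] = [0, 1]
    s = rng.normal(size=200)
    assert mann_whitney_auc(s, y) == pytest.approx(mann_whitney_auc(np.exp(s), y), abs=1e-12)


def test_roc_points_monotone(rng):
    y = rng.integers(0, 2, 500)
    y[:2] = [0, 1]
    res = roc_auc(rng.random(500) + 0.3 * y, y)
    assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)
    assert res.fpr[0] == 0 and res.tpr[0] == 0 and res.fpr[-1] == 1 and res.tpr[-1] == 1
    assert res.ci_low <= res.auc <= res.ci_high


def test_accuracy_definitions(rng):
    assert accuracy([0.9, 0.1], [1, 0]) == 1.0
    assert accuracy([0.9, 0.2, 0.6, 0.4], [1, 0, 0, 1]) == 0.5
    s = rng.random(100)
    y = rng.integers(0, 2, 100)
    # complementing scores maps accuracy a -> 1 - a (no ties at threshold)
    assert accuracy(1 - s, y) == pytest.approx(1 - accuracy(s, y), abs=1e-12)
    with pytest.raises(InvalidInputError):
        accuracy([], [])


def test_accuracy_at_best_threshold_beats_base_rate(rng):
    y = rng.integers(0, 2, 300)
    y[:2] = [0, 1]
    s = rng.random(300)
    best = max(accuracy(s, y, threshold=t) for t in np.linspace(0, 1.001, 200))
    prev = y.mean()
    assert best >= max(prev, 1 - prev) - 1e-12


def test_ci_collapses_on_perfect_separation():
    lo, hi = auc_ci([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert lo == pytest.approx(1.0) and hi == 1.0


def test_ci_widens_as_sample_shrinks():
    def make(n, seed):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        s = rng.normal(size=n) + y
        return s, y

    s_small, y_small = make(100, 5)
    s_big, y_big = make(10000, 5)
    w_small = np.subtract(*auc_ci(s_small, y_small)[::-1])
    w_big = np.subtract(*auc_ci(s_big, y_big)[::-1])
    assert w_small > w_big


def test_delong_ci_coverage_near_nominal():
    # binormal scores, true AUC = Phi(1/sqrt(2))
    true_auc = norm.cdf(1 / np.sqrt(2))
    rng = np.random.default_rng(99)
    hits = 0
    n_sim = 300
    for _ in range(n_sim):
        y = np.repeat([0, 1], 100)
        s = rng.normal(size=200) + y
        lo, hi = auc_ci(s, y)
        hits += lo <= true_auc <= hi
    assert 0.90 <= hits / n_sim <= 0.99


def test_bootstrap_ci_brackets_auc(rng):
    y = np.repeat([0, 1], 100)
    s = rng.normal(size=200) + y
    auc = mann_whitney_auc(s, y)
    lo, hi = auc_ci(s, y, method="bootstrap", n_boot=200, rng=rng)
    assert lo <= auc <= hi


def test_compare_identical_scores_is_null():
    y = np.repeat([0, 1], 20)
    s = np.linspace(0, 1, 40)
    comp = compare_roc(s, s, y)
    assert comp.diff == 0.0 and comp.p_value == 1.0


def test_compare_swap_antisymmetry(rng):
    y = rng.integers(0, 2, 400)
    y[:2] = [0, 1]
    a = rng.random(400) + 0.5 * y
    b = rng.random(400) + 0.3 * y
    ab = compare_roc(a, b, y)
    ba = compare_roc(b, a, y)
    assert ab.diff == pytest.approx(-ba.diff, abs=1e-15)
    assert ab.p_value == pytest.approx(ba.p_value, abs=1e-12)


def test_compare_detects_informative_vs_noise():
    rng = np.random.default_rng(3)
    y = np.repeat([0, 1], 2500)
    informative = rng.normal(size=5000) + 1.5 * y
    noise = rng.normal(size=5000)
    comp = compare_roc(informative, noise, y)
    assert comp.p_value < 0.001
    assert comp.diff > 0


def test_input_validation():
    with pytest.raises(InvalidInputError):
        mann_whitney_auc([0.1, 0.2], [1, 1])
    with pytest.raises(InvalidInputError):
        compare_roc([0.1, 0.2], [0.1], [0, 1])
    with pytest.raises(InvalidInputError):
        roc_auc([0.1, np.nan], [0, 1])


def test_evaluate_models_report_schema(labeled_default):
    report = evaluate_models(labeled_default)
    assert list(report.table["model"]) == ["greco_surface", "logistic"]
    assert {"auc", "ci_low", "ci_high", "accuracy", "n_rows", "n_patients"} <= set(
        report.table.columns
    )
    assert (report.table["auc"] > 0.9).all()
    assert 0 < report.comparison.p_value <= 1


def test_delong_matches_r_proc(rng, tmp_path):
    """Independent oracle: R pROC's DeLong CI and paired test on the same data."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    y = rng.integers(0, 2, 150)
    y[:2] = [0, 1]
    a = rng.random(150) + 0.8 * y
    b = rng.random(150) + 0.5 * y
    csv = tmp_path / "scores.csv"
    np.savetxt(csv, np.column_stack([y, a, b]), delimiter=",", header="y,a,b", comments="")
    script = textwrap.dedent(
        f"""
        suppressMessages(library(pROC))
        d <- read.csv("{csv}")
        ra <- roc(d$y, d$a, direction="<", levels=c(0,1), quiet=TRUE)
        rb <- roc(d$y, d$b, direction="<", levels=c(0,1), quiet=TRUE)
        ci <- ci.auc(ra, method="delong")
        tt <- roc.test(ra, rb, method="delong", paired=TRUE)
        cat(ci[1], ci[3], as.numeric(tt$p.value), sep="\\n")
        """
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    ).stdout.split()
    r_lo, r_hi, r_p = map(float, out[:3])
    lo, hi = auc_ci(a, y)
    comp = compare_roc(a, b, y)
    assert lo == pytest.approx(r_lo, abs=1e-6)
    assert hi == pytest.approx(r_hi, abs=1e-6)
    assert comp.p_value == pytest.approx(r_p, abs=1e-6)
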