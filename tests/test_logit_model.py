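import math

import numpy as np
import pytest

from rsalogit import (
    ModelError,
    ModelSpec,
    ResidueRecord,
    build_design,
    classify,
    complete_records,
    fit_linear_baseline,
    fit_logistic,
    odds_ratio,
    predict_proba,
    published_classic_fit,
)
from rsalogit.logit_model import INTERCEPT, LogisticFit, PUBLISHED_CLASSIC_COEFFICIENTS


def _records_from_arrays(e6, labels, aa=None):
    aa = aa if aa is not None else ["K"] * len(e6)
    return [
        ResidueRecord("c", i + 1, aa=aa[i], e6=float(e6[i]), label=int(labels[i]))
        for i in range(len(e6))
    ]


def _intercept_only_records(n_accessible, n_buried):
    labels = [1] * n_accessible + [0] * n_buried
    return [
        ResidueRecord("c", i + 1, aa="K", e6=0.0, label=lab)
        for i, lab in enumerate(labels)
    ]


# ------------------------------------------------------------- design

def test_design_val_baseline_all_indicators_zero():
    spec = ModelSpec(descriptors=("E6", "AA"))
    records = [
        ResidueRecord("c", 1, aa="V", e6=1.0, label=1),
        ResidueRecord("c", 2, aa="K", e6=0.5, label=0),
        ResidueRecord("c", 3, aa="A", e6=0.2, label=1),
    ]
    design = build_design(records, spec)
    aa_cols = [j for j, c in enumerate(design.columns) if c.startswith("AA:")]
    assert design.X[0, aa_cols].sum() == 0.0           # Val row: all zeros
    lys = design.columns.index("AA:LYS")
    assert design.X[1, lys] == 1.0
    assert design.X[1, aa_cols].sum() == 1.0           # one indicator per row
    assert design.columns[:2] == [INTERCEPT, "E6"]


def test_design_full_aa_factor_has_19_indicators():
    records = [
        ResidueRecord("c", i + 1, aa=aa, e6=0.1 * i, label=i % 2)
        for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")
    ]
    design = build_design(records, ModelSpec(descriptors=("E6", "AA")))
    aa_cols = [c for c in design.columns if c.startswith("AA:")]
    assert len(aa_cols) == 19
    assert aa_cols == sorted(aa_cols)  # alphabetical, three-letter codes
    assert "AA:VAL" not in aa_cols
    # 1 intercept + 1 quantitative + 19 indicators
    assert design.X.shape[1] == 21


def test_design_unseen_level_at_prediction_errors():
    spec = ModelSpec(descriptors=("AA",))
    train = [ResidueRecord("c", 1, aa="V", label=0),
             ResidueRecord("c", 2, aa="K", label=1)]
    design = build_design(train, spec)
    fit = LogisticFit(
        spec=spec, columns=design.columns,
        beta={c: 0.0 for c in design.columns},
        se={c: 1.0 for c in design.columns},
        loglik=0.0, n_records=2, converged=True, n_iter=1,
        levels=design.levels,
    )
    with pytest.raises(ModelError, match="'W'"):
        predict_proba(fit, [ResidueRecord("c", 3, aa="W")])


def test_design_requires_labels_and_descriptors():
    spec = ModelSpec(descriptors=("E6",))
    with pytest.raises(ModelError, match="no label"):
        build_design([ResidueRecord("c", 1, aa="K", e6=0.1)], spec)
    assert complete_records(
        [ResidueRecord("c", 1, aa="K", label=1)], spec
    ) == []


# ----------------------------------------------------------------- MLE

def test_intercept_only_logit_identity():
    import rsalogit.logit_model as lm

    for n1, n0, expected in ((10, 10, 0.0), (15, 5, math.log(3))):
        records = _intercept_only_records(n1, n0)
        spec = ModelSpec(descriptors=("AA",))  # all K -> no indicators vary
        # direct design: intercept only
        design = lm.DesignMatrix(
            X=np.ones((n1 + n0, 1)),
            y=np.array([r.label for r in records], dtype=float),
            columns=[INTERCEPT], levels={}, provenance=[], spec=spec,
        )
        fit = fit_logistic(design)
        assert fit.converged
        assert fit.beta[INTERCEPT] == pytest.approx(expected, abs=1e-8)


def test_mean_fitted_probability_equals_observed_fraction(rng):
    n = 2000
    e6 = rng.uniform(0, 1.8, n)
    p = 1 / (1 + np.exp(-(-0.5 + 0.9 * e6)))
    labels = (rng.random(n) < p).astype(int)
    records = _records_from_arrays(e6, labels)
    fit = fit_logistic(build_design(records, ModelSpec(descriptors=("E6",))))
    probs = predict_proba(fit, records)
    assert probs.mean() == pytest.approx(labels.mean(), abs=1e-8)


def test_refit_invariant_under_row_permutation(rng):
    n = 500
    e6 = rng.uniform(0, 1.8, n)
    labels = (rng.random(n) < 0.4 + 0.2 * e6).astype(int)
    records = _records_from_arrays(e6, labels)
    spec = ModelSpec(descriptors=("E6",))
    fit1 = fit_logistic(build_design(records, spec))
    perm = rng.permutation(n)
    fit2 = fit_logistic(build_design([records[i] for i in perm], spec))
    for c in fit1.columns:
        assert fit1.beta[c] == pytest.approx(fit2.beta[c], abs=1e-8)


def test_fit_matches_statsmodels(mixed_dataset):
    sm = pytest.importorskip("statsmodels.api")
    spec = ModelSpec.named("classic")
    records = complete_records(mixed_dataset.records, spec)
    design = build_design(records, spec)
    ours = fit_logistic(design)
    ref = sm.GLM(design.y, design.X, family=sm.families.Binomial()).fit()
    beta = np.array([ours.beta[c] for c in design.columns])
    se = np.array([ours.se[c] for c in design.columns])
    assert np.allclose(beta, ref.params, atol=1e-7)
    assert np.allclose(se, ref.bse, rtol=1e-4)
    assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)


def test_perfect_separation_flagged(rng):
    e6 = np.concatenate([rng.uniform(0, 0.4, 30), rng.uniform(0.6, 1.0, 30)])
    labels = (e6 > 0.5).astype(int)
    fit = fit_logistic(
        build_design(_records_from_arrays(e6, labels),
                     ModelSpec(descriptors=("E6",)))
    )
    assert not fit.converged
    assert "separation" in fit.diagnostic


def test_single_class_and_zero_column_errors():
    spec = ModelSpec(descriptors=("E6",))
    same = [ResidueRecord("c", i + 1, aa="K", e6=0.1 * i, label=1)
            for i in range(5)]
    with pytest.raises(ModelError, match="both classes"):
        fit_logistic(build_design(same, spec))
    zero_e6 = [ResidueRecord("c", i + 1, aa="K", e6=0.0, label=i % 2)
               for i in range(6)]
    with pytest.raises(ModelError, match="constant-zero"):
        fit_logistic(build_design(zero_e6, spec))


def test_wald_interval_coverage(rng):
    """95% Wald intervals cover the truth at about the nominal rate on data
    simulated from the model."""
    true = np.array([-0.5, 0.9])
    n, reps = 250, 300
    covered = np.zeros(2)
    for _ in range(reps):
        e6 = rng.uniform(0, 2.5, n)
        eta = true[0] + true[1] * e6
        labels = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        if labels.min() == labels.max():
            continue
        fit = fit_logistic(
            build_design(_records_from_arrays(e6, labels),
                         ModelSpec(descriptors=("E6",)))
        )
        beta = np.array([fit.beta[INTERCEPT], fit.beta["E6"]])
        se = np.array([fit.se[INTERCEPT], fit.se["E6"]])
        covered += (np.abs(beta - true) < 1.96 * se)
    coverage = covered / reps
    # binomial 3-sigma band around 0.95 at 300 replicates
    assert np.all(coverage > 0.91) and np.all(coverage <= 1.0)


# ----------------------------------------------------- odds and classes

def test_odds_ratio_published_lys_row():
    fit = published_classic_fit()
    assert odds_ratio(fit, "AA:LYS") == pytest.approx(4.522, abs=5e-4)
    assert odds_ratio(fit, "E6", delta=0.0) == 1.0
    assert odds_ratio(fit, "E6", delta=2.0) == pytest.approx(
        math.exp(2 * 0.862), abs=1e-12
    )
    with pytest.raises(ModelError, match="unknown column"):
        odds_ratio(fit, "AA:XYZ")


def test_exp_beta_consistent_with_beta():
    fit = published_classic_fit()
    for c in fit.columns:
        assert fit.exp_beta[c] == pytest.approx(math.exp(fit.beta[c]), rel=1e-12)


def test_predict_proba_examples():
    fit = published_classic_fit()
    val = ResidueRecord("c", 1, aa="V", e20=0.0, e6=0.0, fshp=0.0, fsr=0.0)
    (p,) = predict_proba(fit, [val])
    assert p == pytest.approx(0.371, abs=5e-4)
    # skipped record yields NaN
    incomplete = ResidueRecord("c", 2, aa="K")
    probs = predict_proba(fit, [val, incomplete])
    assert np.isnan(probs[1])


def test_predict_proba_stable_for_large_eta():
    spec = ModelSpec(descriptors=("E6",))
    fit = LogisticFit(
        spec=spec, columns=[INTERCEPT, "E6"],
        beta={INTERCEPT: 0.0, "E6": 40.0}, se={INTERCEPT: 1.0, "E6": 1.0},
        loglik=0.0, n_records=1, converged=True, n_iter=1, levels={},
    )
    (p,) = predict_proba(fit, [ResidueRecord("c", 1, aa="K", e6=1.0)])
    assert p == 1.0  # no overflow at eta = 40
    fit.beta["E6"] = -40.0
    (p,) = predict_proba(fit, [ResidueRecord("c", 1, aa="K", e6=1.0)])
    assert p == pytest.approx(0.0, abs=1e-15)


@pytest.mark.parametrize("p,expected", [(0.51, 1), (0.5, 1), (0.49, 0)])
def test_classify_boundary_inclusive(p, expected):
    assert classify(np.array([p]))[0] == expected


def test_classify_rejects_nan():
    with pytest.raises(ModelError):
        classify(np.array([float("nan")]))


# ------------------------------------------------------ linear baseline

def test_linear_baseline_exact_recovery(rng):
    intercepts = {"V": 13.0, "D": 45.0, "K": 30.0}
    records = []
    for i in range(120):
        aa = ["V", "D", "K"][i % 3]
        e6 = float(rng.uniform(0, 1.8))
        records.append(
            ResidueRecord("c", i + 1, aa=aa, e6=e6,
                          rsa=intercepts[aa] + 10.0 * e6)
        )
    fit = fit_linear_baseline(records, "E6", rsa_threshold=20.0)
    assert fit.slope == pytest.approx(10.0, abs=1e-9)
    for aa, b in intercepts.items():
        assert fit.intercepts[aa] == pytest.approx(b, abs=1e-8)


def test_linear_baseline_single_aa_reduces_to_simple_regression(rng):
    e6 = rng.uniform(0, 2, 50)
    rsa = 5.0 + 12.0 * e6 + rng.normal(0, 0.5, 50)
    records = [ResidueRecord("c", i + 1, aa="K", e6=float(x), rsa=float(y))
               for i, (x, y) in enumerate(zip(e6, rsa))]
    fit = fit_linear_baseline(records, "E6")
    slope, intercept = np.polyfit(e6, rsa, 1)
    assert fit.slope == pytest.approx(slope, abs=1e-8)
    assert fit.intercepts["K"] == pytest.approx(intercept, abs=1e-8)


def test_linear_baseline_classification_boundary():
    records = [ResidueRecord("c", i + 1, aa="K", e6=float(i), rsa=10.0 * i)
               for i in range(1, 5)]
    fit = fit_linear_baseline(records, "E6", rsa_threshold=20.0)
    probe = [
        ResidueRecord("c", 10, aa="K", e6=2.1),   # predicted RSA 21 -> class 1
        ResidueRecord("c", 11, aa="K", e6=1.9),   # predicted RSA 19 -> class 0
    ]
    pred = fit.predict_rsa(probe)
    assert pred[0] == pytest.approx(21.0, abs=1e-9)
    assert list(fit.classify(probe)) == [1, 0]
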