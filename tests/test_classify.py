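"""Feature vectors, ARFF IO, the four classifiers and evaluation."""

import numpy as np
import pytest

from cryspect import (
    FeatureDataset,
    MeterTrace,
    RecordingMetadata,
    build_feature_vectors,
    evaluate,
    generate_cohort,
    read_arff,
    train,
    write_arff,
)
from cryspect.classify import ArffParseError, IB1Classifier

from conftest import short_preset


def meta(group, ordinal=1):
    return RecordingMetadata(
        first_last_name=f"NB-{group}{ordinal}", number=ordinal,
        indicative=f"{group}{ordinal}", sex="F", date_of_birth="2010-01-01",
        time_of_birth="10:00", weight_g=3400, head_circumference_cm=34.0,
        chest_circumference_cm=33.0, length_cm=51.0, gestational_age_weeks=39,
        apgar=10 if group == "M" else 9, birth_type="natural",
        presentation="cephalic", gesta=1, para=1, group=group)


def trace_record(values, group, ordinal=1):
    return (MeterTrace(kind="VU", values=np.asarray(values, float)),
            meta(group, ordinal))


def separated_dataset(n_per_class=10, n_attr=300, seed=0):
    """Well-separated two-class data: distinct levels plus small jitter."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_per_class):
        records.append(trace_record(100 + rng.uniform(0, 10, n_attr), "M", i + 1))
    for i in range(n_per_class):
        records.append(trace_record(500 + rng.uniform(0, 10, n_attr), "C", i + 1))
    return build_feature_vectors(records, meter="VU", window_s=n_attr / 10.0)


def test_feature_vector_truncation_and_padding():
    d = build_feature_vectors([trace_record(np.arange(900), "M")])
    assert d.X.shape == (1, 300)
    assert d.X[0, -1] == 299.0  # first 300 frames kept

    d = build_feature_vectors([trace_record(np.ones(100), "C")])
    assert d.X.shape == (1, 300)
    assert np.all(d.X[0, 100:] == 0.0)  # attributes 101..300 padded with silence
    assert list(d.y) == ["C"]


def test_feature_vectors_from_cohort_waveforms(small_cohort):
    d = build_feature_vectors(small_cohort, meter="PPM")
    assert d.X.shape == (12, 300)
    assert list(d.y).count("M") == 6 and list(d.y).count("C") == 6
    assert d.meter == "PPM"


def test_arff_round_trip_and_header(tmp_path):
    d = separated_dataset(n_per_class=3, n_attr=10, seed=1)
    path = tmp_path / "cry.arff"
    write_arff(d, path)
    lines = path.read_text().splitlines()
    assert sum(1 for l in lines if l.startswith("@attribute")) == 11
    back = read_arff(path)
    assert np.array_equal(back.X, d.X)
    assert list(back.y) == list(d.y)
    assert back.classes == d.classes


def test_arff_empty_dataset_header_only(tmp_path):
    d = FeatureDataset(X=np.zeros((0, 3)), y=np.array([], dtype=object),
                       meter="VU", attribute_names=["a", "b", "c"])
    path = tmp_path / "empty.arff"
    write_arff(d, path)
    back = read_arff(path)
    assert back.n_instances == 0 and len(back.attribute_names) == 3


def test_arff_agrees_with_scipy_reader(tmp_path):
    from scipy.io import arff as scipy_arff

    d = separated_dataset(n_per_class=3, n_attr=5, seed=2)
    path = tmp_path / "cry.arff"
    write_arff(d, path)
    data, _ = scipy_arff.loadarff(str(path))
    values = np.array([[row[name] for name in d.attribute_names] for row in data])
    assert np.allclose(values, d.X)
    labels = [row["class"].decode() for row in data]
    assert labels == list(d.y)


def test_arff_parse_error_reports_line_number(tmp_path):
    path = tmp_path / "bad.arff"
    path.write_text("@relation r\n@attribute a numeric\n"
                    "@attribute class {M,C}\n@data\n1.0,2.0,M\n")
    with pytest.raises(ArffParseError, match="line 5"):
        read_arff(path)


@pytest.mark.parametrize("kind", ["IB1", "RT", "DT", "NNGE"])
def test_two_separated_instances_are_learned(kind):
    d = FeatureDataset(X=[[0.0, 0.0], [10.0, 10.0]], y=np.array(["M", "C"]),
                       meter="VU", attribute_names=["a", "b"])
    clf = train(kind, d, seed=0)
    assert list(clf.predict(d.X)) == ["M", "C"]


@pytest.mark.parametrize("kind", ["IB1", "RT", "NNGE"])
def test_memorizing_classifiers_reach_100pct_on_training_data(kind):
    d = separated_dataset(n_per_class=10, seed=3)
    rep = evaluate(kind, d, "training", seed=0)
    assert rep.correctly_classified_pct == 100.0
    if kind in ("IB1", "NNGE"):
        assert rep.mean_absolute_error == 0.0
        assert rep.root_mean_squared_error == 0.0


def test_single_class_dataset_is_rejected():
    d = FeatureDataset(X=[[0.0], [1.0]], y=np.array(["M", "M"]), meter="VU",
                       attribute_names=["a"])
    with pytest.raises(ValueError):
        train("IB1", d)


def test_prior_baseline_normalizes_to_100pct():
    d = separated_dataset(n_per_class=10, seed=4)
    rep = evaluate("PRIOR", d, "training", seed=0)
    assert rep.relative_absolute_error_pct == pytest.approx(100.0)
    assert rep.root_relative_squared_error_pct == pytest.approx(100.0)


def test_ib1_cross_validation_on_separated_cohorts():
    rep = evaluate("IB1", separated_dataset(n_per_class=15, seed=5), "cv10", seed=1)
    assert rep.correctly_classified_pct >= 90.0


def test_decision_table_beats_prior_on_separated_data():
    d = separated_dataset(n_per_class=10, seed=6)
    rep = evaluate("DT", d, "training", seed=0)
    assert rep.correctly_classified_pct > 50.0


@pytest.mark.parametrize("protocol", ["training", "cv10", "split75"])
def test_confusion_matrix_totals_and_sum_invariant(protocol):
    d = separated_dataset(n_per_class=10, seed=7)
    rep = evaluate("IB1", d, protocol, seed=2)
    assert rep.confusion_matrix.sum() == rep.n_instances
    # row sums = per-class counts of the evaluated set
    counts = rep.confusion_matrix.sum(axis=1)
    assert all(c > 0 for c in counts)
    assert rep.correctly_classified_pct + rep.incorrectly_classified_pct \
        == pytest.approx(100.0)


@pytest.mark.parametrize("kind", ["IB1", "RT", "DT", "NNGE"])
def test_evaluation_is_seed_deterministic(kind):
    d = separated_dataset(n_per_class=10, seed=8)
    a = evaluate(kind, d, "cv10", seed=5)
    b = evaluate(kind, d, "cv10", seed=5)
    assert a.correctly_classified_pct == b.correctly_classified_pct
    assert a.mean_absolute_error == b.mean_absolute_error
    assert np.array_equal(a.confusion_matrix, b.confusion_matrix)


def test_cv10_folds_are_stratified_disjoint_cover():
    from sklearn.model_selection import StratifiedKFold

    d = separated_dataset(n_per_class=13, seed=9)
    skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=3)
    seen = []
    global_ratio = np.mean(d.y == "M")
    for train_idx, test_idx in skf.split(d.X, d.y.astype(str)):
        seen.extend(test_idx)
        fold_m = np.sum(d.y[test_idx] == "M")
        expected = global_ratio * len(test_idx)
        assert abs(fold_m - expected) <= 1.0
    assert sorted(seen) == list(range(d.n_instances))


def test_ib1_matches_brute_force_nearest_neighbor(rng):
    X_train = rng.uniform(0, 1, (30, 12))
    y_train = np.array(["M" if i % 2 else "C" for i in range(30)], dtype=object)
    X_test = rng.uniform(0, 1, (20, 12))
    clf = IB1Classifier().fit(X_train, y_train)
    pred = clf.predict(X_test)
    for x, p in zip(X_test, pred):
        d2 = [float(np.sum((x - t) ** 2)) for t in X_train]
        assert p == y_train[int(np.argmin(d2))]


def test_real_synthetic_cohort_is_classifiable(small_cohort):
    """Preset cohorts (distinct loudness levels) are learnable by IB1."""
    d = build_feature_vectors(small_cohort, meter="VU")
    rep = evaluate("IB1", d, "training", seed=0)
    assert rep.correctly_classified_pct == 100.0
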