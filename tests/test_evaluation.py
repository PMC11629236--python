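"""Confusion counting, metrics, binning, distances, essentiality, profiling."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panfill.evaluation import (
    ConfusionCounts,
    carbon_profile,
    confusion_from_gapfill,
    confusion_from_predictions,
    essential_reactions,
    frequency_binned_metrics,
    metrics,
    nearest_neighbor_distance,
)
from panfill.gapfill import Medium
from panfill.reactome import (
    GenomeRecord,
    MetabolicNetwork,
    Reaction,
    ReactionId,
    build_incidence_matrix,
)


def _rid(name: str) -> ReactionId:
    return ReactionId("toy", name)


# ---------------------------------------------------------------------------
# prediction confusion
# ---------------------------------------------------------------------------

def test_prediction_confusion_counts_masked_positions_only():
    truth = np.array([1, 1, 0, 0, 1])
    inp = np.array([0, 0, 0, 0, 1])  # last position was given as input
    scores = np.array([0.9, 0.2, 0.8, 0.1, 0.99])
    counts = confusion_from_predictions(scores, truth, inp)
    assert (counts.TP, counts.FN, counts.FP, counts.TN) == (1, 1, 1, 1)


def test_perfect_prediction_has_no_errors():
    truth = np.array([1, 0, 1, 0])
    inp = np.zeros(4, dtype=int)
    counts = confusion_from_predictions(truth.astype(float), truth, inp)
    assert counts.FP == 0 and counts.FN == 0


def test_fully_masked_input_gives_zero_counts():
    v = np.ones(5, dtype=int)
    counts = confusion_from_predictions(np.full(5, 0.9), v, v)
    assert (counts.TP, counts.FP, counts.FN, counts.TN) == (0, 0, 0, 0)


# ---------------------------------------------------------------------------
# gap-fill confusion
# ---------------------------------------------------------------------------

def test_gapfill_confusion_set_arithmetic():
    orig = {_rid(x) for x in "ABCD"}
    deleted = {_rid("C"), _rid("D")}
    added = {_rid("C"), _rid("E")}
    counts = confusion_from_gapfill(orig, deleted, added)
    assert (counts.TP, counts.FN, counts.FP) == (1, 1, 1)


def test_gapfill_perfect_recovery():
    orig = {_rid(x) for x in "AB"}
    deleted = {_rid("B")}
    counts = confusion_from_gapfill(orig, deleted, {_rid("B")})
    rep = metrics(counts)
    assert rep.recall == 1.0 and counts.FP == 0


def test_gapfill_nothing_added():
    orig = {_rid(x) for x in "ABC"}
    deleted = {_rid("B"), _rid("C")}
    counts = confusion_from_gapfill(orig, deleted, set())
    assert counts.TP == 0 and counts.FN == 2


def test_gapfill_universe_defines_tn():
    orig = {_rid("A")}
    universe = {_rid(x) for x in "AXYZ"}
    counts = confusion_from_gapfill(orig, set(), {_rid("X")}, universe)
    assert counts.TN == 2  # Y, Z


def test_gapfill_precondition_violations():
    with pytest.raises(ValueError):
        confusion_from_gapfill({_rid("A")}, {_rid("B")}, set())
    with pytest.raises(ValueError):
        confusion_from_gapfill({_rid("A")}, set(), {_rid("A")})


# ---------------------------------------------------------------------------
# metric formulas
# ---------------------------------------------------------------------------

def test_balanced_accuracy_is_mean_of_specificity_and_recall():
    counts = ConfusionCounts(TP=6, FP=1, FN=4, TN=4)  # recall .6, specificity .8
    rep = metrics(counts)
    assert rep.recall == pytest.approx(0.6)
    assert rep.specificity == pytest.approx(0.8)
    assert rep.balanced_accuracy == pytest.approx(0.7)


def test_degenerate_counts_give_zero_metrics():
    rep = metrics(ConfusionCounts(0, 0, 0, 0))
    assert rep.precision == rep.recall == rep.f1 == 0.0


def test_f1_formula():
    rep = metrics(ConfusionCounts(TP=2, FP=2, FN=0, TN=0))
    assert rep.precision == 0.5 and rep.recall == 1.0
    assert rep.f1 == pytest.approx(2 * 0.5 * 1.0 / 1.5)


# ---------------------------------------------------------------------------
# frequency binning
# ---------------------------------------------------------------------------

def test_binned_pooled_recall():
    counts = {
        "good": ConfusionCounts(5, 0, 0, 0),
        "bad": ConfusionCounts(0, 0, 5, 0),
    }
    occ = {"good": 10, "bad": 20}
    table = frequency_binned_metrics(counts, occ, bin_width=50)
    assert len(table) == 1
    assert table.loc[0, "recall"] == pytest.approx(0.5)  # pooled 5/(5+5)
    assert table.loc[0, "n_reactions"] == 2


def test_bins_split_by_occurrence():
    counts = {"a": ConfusionCounts(1, 0, 0, 0), "b": ConfusionCounts(0, 0, 1, 0)}
    table = frequency_binned_metrics(counts, {"a": 10, "b": 80}, bin_width=50)
    assert len(table) == 2
    assert table["recall"].tolist() == [1.0, 0.0]


def test_pooling_consistency_with_global_counts():
    rng = np.random.default_rng(4)
    per = {
        f"r{i}": ConfusionCounts(*rng.integers(0, 9, size=4).tolist())
        for i in range(20)
    }
    occ = {k: 25 for k in per}  # everything in one bin
    table = frequency_binned_metrics(per, occ, bin_width=50)
    total = ConfusionCounts(0, 0, 0, 0)
    for c in per.values():
        total = total + c
    assert table.loc[0, "recall"] == pytest.approx(metrics(total).recall)


# ---------------------------------------------------------------------------
# nearest-neighbor Jaccard distance
# ---------------------------------------------------------------------------

def _matrix_from_rows(rows: list[set[str]]):
    sets = [
        (GenomeRecord(f"g{i}", genus="g"), {_rid(x) for x in row})
        for i, row in enumerate(rows)
    ]
    return build_incidence_matrix(sets)


def test_distance_zero_for_identical_row():
    matrix = _matrix_from_rows([{"A", "B"}, {"C"}])
    assert nearest_neighbor_distance(matrix.presence[0], matrix) == 0.0


def test_distance_hand_computed():
    # query {A, B} vs single training row {B, C}: 1 - 1/3
    matrix = _matrix_from_rows([{"B", "C"}, {"A"}])
    labels = matrix.pan_reactome.labels
    query = np.array([1 if l in {"A", "B"} else 0 for l in labels])
    sub = matrix.subset(["g0"])  # only {B, C} as training
    assert nearest_neighbor_distance(query, sub) == pytest.approx(2 / 3)


def test_distance_empty_query_errors():
    matrix = _matrix_from_rows([{"A"}])
    with pytest.raises(ValueError):
        nearest_neighbor_distance(np.zeros(1, dtype=int), matrix)


@settings(derandomize=True, max_examples=40)
@given(data=st.data())
def test_jaccard_distance_properties(data):
    n = data.draw(st.integers(3, 12))
    q = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
    r = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
    if q.sum() == 0:
        q[0] = 1
    if r.sum() == 0:
        r[0] = 1
    rids = [_rid(f"r{i}") for i in range(n)]
    sets_r = [(GenomeRecord("t"), {rid for rid, v in zip(rids, r) if v})]
    sets_q = [(GenomeRecord("t"), {rid for rid, v in zip(rids, q) if v})]
    union = {rid for rid, v in zip(rids, np.maximum(q, r)) if v}
    # embed both vectors in identical coordinates via a shared union genome
    mat_r = build_incidence_matrix(sets_r + [(GenomeRecord("u"), union)])
    mat_q = build_incidence_matrix(sets_q + [(GenomeRecord("u"), union)])
    labels = mat_r.pan_reactome.labels
    assert labels == mat_q.pan_reactome.labels
    qv = mat_q.presence[0]
    rv = mat_r.presence[0]
    d_qr = nearest_neighbor_distance(qv, mat_r.subset(["t"]))
    d_rq = nearest_neighbor_distance(rv, mat_q.subset(["t"]))
    assert d_qr == pytest.approx(d_rq)  # symmetry
    assert 0.0 <= d_qr <= 1.0  # boundedness
    if (qv == rv).all():
        assert d_qr == 0.0  # identity


# ---------------------------------------------------------------------------
# essentiality and carbon profiling
# ---------------------------------------------------------------------------

def test_linear_chain_interior_reactions_all_essential():
    from panfill.synthetic import generate_toy_network

    fx = generate_toy_network("linear_chain", size=4)
    # complete the model first
    model = fx.model.with_added([fx.database.get("step2")])
    ess = {r.label for r in essential_reactions(model, fx.medium)}
    assert {"step0", "step1", "step2", "bio1"} <= ess


def test_parallel_paths_are_individually_dispensable(parallel_toy):
    ess = {r.label for r in essential_reactions(parallel_toy.model, parallel_toy.medium)}
    assert "path1" not in ess and "path2" not in ess
    assert "bio1" in ess and "upt" in ess


def test_essentiality_requires_growth(linear_chain_toy):
    with pytest.raises(ValueError, match="grow"):
        essential_reactions(linear_chain_toy.model, linear_chain_toy.medium)


def _two_source_model(include_y: bool = False):
    rxns = [
        Reaction(_rid("EX_X_e"), {"X_e": -1.0}, lower_bound=-1000.0),
        Reaction(_rid("EX_Y_e"), {"Y_e": -1.0}, lower_bound=-1000.0),
        Reaction(_rid("uptX"), {"X_e": -1.0, "a_c": 1.0}),
        Reaction(_rid("bio1"), {"a_c": -1.0}),
    ]
    if include_y:
        rxns.append(Reaction(_rid("uptY"), {"Y_e": -1.0, "a_c": 1.0}))
    return MetabolicNetwork(rxns, _rid("bio1"), model_id="twosrc")


def test_carbon_profile_growth_vector():
    model = _two_source_model(include_y=False)
    profile, report = carbon_profile(
        model, Medium({}), ["X_e", "Y_e"], observed={"X_e": 1, "Y_e": 0}
    )
    assert profile == {"X_e": 1, "Y_e": 0}
    assert report.balanced_accuracy == pytest.approx(1.0)


def test_carbon_profile_missing_exchange_recorded_as_no_growth(caplog):
    model = _two_source_model()
    with caplog.at_level("WARNING"):
        profile, _ = carbon_profile(model, Medium({}), ["Z_e"])
    assert profile["Z_e"] == 0
    assert any("no exchange" in r.message for r in caplog.records)


def test_model_growing_without_carbon_is_flagged_invalid():
    # a model with an internal source of biomass precursor
    rxns = [
        Reaction(_rid("spont"), {"a_c": 1.0}),
        Reaction(_rid("EX_X_e"), {"X_e": -1.0}, lower_bound=-1000.0),
        Reaction(_rid("bio1"), {"a_c": -1.0}),
    ]
    model = MetabolicNetwork(rxns, _rid("bio1"))
    with pytest.raises(ValueError, match="without any carbon"):
        carbon_profile(model, Medium({}), ["X_e"])
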