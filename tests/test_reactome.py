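"""Reaction databases, incidence matrices, genome selection and splits."""

from __future__ import annotations

import numpy as np
import pytest

from panfill.reactome import (
    GenomeRecord,
    IncidenceMatrix,
    ReactionId,
    build_incidence_matrix,
    exclude_partition,
    load_model,
    load_reaction_database,
    parse_equation,
    save_model_json,
    select_best_genomes,
    split_train_test,
)


def _rid(name: str) -> ReactionId:
    return ReactionId("toy", name)


# ---------------------------------------------------------------------------
# reaction database parsing
# ---------------------------------------------------------------------------

DB_TSV = """id\tname\tequation\treversibility
rxn1\thexokinase\t(1) glc_c + (1) atp_c --> (1) g6p_c + (1) adp_c\t>
rxn2\tisomerase\t(1) g6p_c <=> (1) f6p_c\t=
rxn3\tsink\t(2) f6p_c --> (1) fdp_c\t>
"""


def test_modelseed_tsv_parses_signed_stoichiometry(tmp_path):
    path = tmp_path / "db.tsv"
    path.write_text(DB_TSV)
    db = load_reaction_database(path, "modelseed_tsv")
    assert len(db) == 3
    rxn1 = db.get("rxn1")
    assert rxn1.stoichiometry == {
        "glc_c": -1.0, "atp_c": -1.0, "g6p_c": 1.0, "adp_c": 1.0,
    }
    assert not rxn1.reversible
    assert db.get("rxn2").reversible
    assert db.get("rxn3").stoichiometry["f6p_c"] == -2.0


def test_empty_database_file_is_a_parse_error(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("")
    with pytest.raises(ValueError, match="empty"):
        load_reaction_database(path, "modelseed_tsv")


def test_unknown_dialect_is_a_configuration_error(tmp_path):
    path = tmp_path / "db.tsv"
    path.write_text(DB_TSV)
    with pytest.raises(ValueError, match="dialect"):
        load_reaction_database(path, "kegg_flatfile")


def test_malformed_row_names_the_line(tmp_path):
    path = tmp_path / "db.tsv"
    path.write_text("id\tequation\nrxnX\tno arrow here\n")
    with pytest.raises(ValueError, match="line 2"):
        load_reaction_database(path, "modelseed_tsv")


def test_bigg_json_database(tmp_path):
    payload = """{
      "metabolites": [{"id": "a_c", "compartment": "c"}, {"id": "b_c", "compartment": "c"}],
      "reactions": [
        {"id": "MDH", "metabolites": {"a_c": -1.0, "b_c": 1.0},
         "lower_bound": -1000.0, "upper_bound": 1000.0}
      ]
    }"""
    path = tmp_path / "db.json"
    path.write_text(payload)
    db = load_reaction_database(path, "bigg_json")
    assert len(db) == 1
    assert db.get("MDH").reversible
    assert db.get("MDH").id.namespace == "bigg"


@pytest.mark.parametrize(
    "equation,expected_rev",
    [("(1) a_c <=> (1) b_c", True), ("(1) a_c --> (1) b_c", False)],
)
def test_parse_equation_reversibility(equation, expected_rev):
    stoich, reversible = parse_equation(equation)
    assert reversible is expected_rev
    assert stoich == {"a_c": -1.0, "b_c": 1.0}


# ---------------------------------------------------------------------------
# model loading via SBML / COBRA JSON
# ---------------------------------------------------------------------------

def _toy_cobra_model():
    import cobra

    model = cobra.Model("toy")
    mets = {m: cobra.Metabolite(m, compartment="c") for m in ("a_c", "b_c")}
    x_e = cobra.Metabolite("x_e", compartment="e")
    rxns = []
    for rid, stoich in [
        ("EX_x_e", {x_e: -1.0}),
        ("upt", {x_e: -1.0, mets["a_c"]: 1.0}),
        ("conv", {mets["a_c"]: -1.0, mets["b_c"]: 1.0}),
        ("bio1", {mets["b_c"]: -1.0}),
    ]:
        r = cobra.Reaction(rid)
        model.add_reactions([r])
        r.add_metabolites(stoich)
        r.bounds = (-1000.0, 1000.0) if rid == "EX_x_e" else (0.0, 1000.0)
        rxns.append(r)
    return model


def test_sbml_and_json_loads_agree(tmp_path):
    import cobra.io

    model = _toy_cobra_model()
    sbml = tmp_path / "toy.xml"
    jsonf = tmp_path / "toy.json"
    cobra.io.write_sbml_model(model, str(sbml))
    cobra.io.save_json_model(model, str(jsonf))
    net_sbml = load_model(sbml, "sbml")
    net_json = load_model(jsonf, "cobra_json")
    assert net_sbml.biomass_reaction_id.identifier == "bio1"
    assert {r.id.identifier for r in net_sbml.reactions} == {
        r.id.identifier for r in net_json.reactions
    }
    assert net_sbml.get("conv").stoichiometry == net_json.get("conv").stoichiometry


def test_model_without_biomass_id_warns_and_loads(tmp_path, caplog):
    import cobra.io

    model = _toy_cobra_model()
    model.reactions.get_by_id("bio1").id = "objective"
    path = tmp_path / "nobio.json"
    cobra.io.save_json_model(model, str(path))
    with caplog.at_level("WARNING"):
        net = load_model(path, "cobra_json")
    assert net.biomass_reaction_id is None
    assert any("biomass" in r.message for r in caplog.records)


def test_save_model_json_roundtrip(tmp_path, branched_toy):
    path = tmp_path / "model.json"
    save_model_json(branched_toy.model, path)
    net = load_model(path, "cobra_json")
    assert {r.id.identifier for r in net.reactions} == {
        r.id.label for r in branched_toy.model.reactions
    }
    assert net.biomass_reaction_id.identifier == "bio1"


# ---------------------------------------------------------------------------
# incidence matrix construction
# ---------------------------------------------------------------------------

def test_build_incidence_hand_counted_frequencies():
    a, b, c = _rid("A"), _rid("B"), _rid("C")
    sets = [
        (GenomeRecord("g1"), {a, b}),
        (GenomeRecord("g2"), {b}),
        (GenomeRecord("g3"), {b, c}),
    ]
    matrix = build_incidence_matrix(sets)
    pan = matrix.pan_reactome
    assert pan.frequency[a] == pytest.approx(1 / 3)
    assert pan.frequency[b] == pytest.approx(1.0)
    assert pan.frequency[c] == pytest.approx(1 / 3)
    np.testing.assert_array_equal(matrix.column_frequencies(), pan.frequency_vector())


def test_build_incidence_rejects_duplicate_genomes():
    a = _rid("A")
    sets = [(GenomeRecord("g1"), {a}), (GenomeRecord("g1"), {a})]
    with pytest.raises(ValueError, match="duplicate"):
        build_incidence_matrix(sets)


def test_incidence_tsv_roundtrip_is_bit_exact(tmp_path, small_world):
    matrix, _ = small_world
    p1, m1 = tmp_path / "inc.tsv", tmp_path / "meta.tsv"
    matrix.to_tsv(p1, m1)
    again = IncidenceMatrix.from_tsv(p1, m1, namespace="toy")
    np.testing.assert_array_equal(matrix.presence, again.presence)
    assert matrix.pan_reactome.labels == again.pan_reactome.labels
    p2 = tmp_path / "inc2.tsv"
    again.to_tsv(p2)
    assert p1.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------------------
# genome selection
# ---------------------------------------------------------------------------

def test_quality_formula_selects_winner():
    g1 = GenomeRecord("g1", species="s", completeness=95, contamination=1)
    g2 = GenomeRecord("g2", species="s", completeness=99, contamination=3)
    assert g1.quality_score == 90 and g2.quality_score == 84
    assert select_best_genomes([g1, g2]) == [g1]


def test_quality_tie_broken_by_coarse_consistency():
    g1 = GenomeRecord("g1", species="s", completeness=90, coarse_consistency=98)
    g2 = GenomeRecord("g2", species="s", completeness=90, coarse_consistency=91)
    assert select_best_genomes([g2, g1]) == [g1]


def test_full_tie_broken_lexicographically():
    g1 = GenomeRecord("b", species="s")
    g2 = GenomeRecord("a", species="s")
    assert select_best_genomes([g1, g2]) == [g2]


def test_single_member_group_passes_through_and_idempotent():
    recs = [
        GenomeRecord("g1", species="s1"),
        GenomeRecord("g2", species="s2", completeness=80),
    ]
    once = select_best_genomes(recs)
    assert once == recs
    assert select_best_genomes(once) == once


# ---------------------------------------------------------------------------
# train/test splitting and partition exclusion
# ---------------------------------------------------------------------------

def _matrix_with_genera(counts: dict[str, int]) -> IncidenceMatrix:
    rng = np.random.default_rng(5)
    a, b = _rid("A"), _rid("B")
    sets = []
    for genus, n in counts.items():
        for i in range(n):
            rec = GenomeRecord(
                f"{genus}{i}", species=f"{genus}_sp{i}", genus=genus,
                completeness=float(rng.uniform(85, 100)),
            )
            sets.append((rec, {a, b} if rng.random() < 0.5 else {a}))
    return build_incidence_matrix(sets)


def test_split_counts_per_genus():
    matrix = _matrix_with_genera({"x": 4, "y": 3, "z": 3})
    train, test = _split = split_train_test(matrix)
    assert test.n_genomes == 3 and train.n_genomes == 7
    assert set(train.genome_ids) | set(test.genome_ids) == set(matrix.genome_ids)
    assert not set(train.genome_ids) & set(test.genome_ids)
    # best-per-genus by the quality rule
    for genus in ("x", "y", "z"):
        members = [g for g in matrix.genomes if g.genus == genus]
        best = max(members, key=lambda g: g.quality_score)
        assert best.genome_id in test.genome_ids


def test_split_single_genus_puts_one_in_test():
    matrix = _matrix_with_genera({"only": 5})
    train, test = split_train_test(matrix)
    assert test.n_genomes == 1 and train.n_genomes == 4


def test_split_frequency_weighted_mean_identity(small_world):
    matrix, _ = small_world
    train, test = split_train_test(matrix)
    full = matrix.column_frequencies() * matrix.n_genomes
    parts = (
        train.column_frequencies() * train.n_genomes
        + test.column_frequencies() * test.n_genomes
    )
    np.testing.assert_allclose(full, parts)


def test_exclude_partition_drops_label():
    matrix = _matrix_with_genera({"x": 4, "y": 6})
    out = exclude_partition(matrix, "x")
    assert out.n_genomes == 6
    assert all(g.genus == "y" for g in out.genomes)


def test_exclude_missing_label_is_noop_with_warning(small_world, caplog):
    matrix, _ = small_world
    with caplog.at_level("WARNING"):
        out = exclude_partition(matrix, "no_such_clade")
    assert out is matrix
    assert any("nothing excluded" in r.message for r in caplog.records)


def test_exclude_everything_is_an_error():
    matrix = _matrix_with_genera({"x": 4})
    with pytest.raises(ValueError, match="no genomes"):
        exclude_partition(matrix, "x")
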