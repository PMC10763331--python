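"""Model container, I/O round-trips, elemental balance, S-matrix assembly."""

import hashlib

import numpy as np
import pytest

from methyloflux.model import (
    MetabolicModel,
    Metabolite,
    ModelParseError,
    ModelValidationError,
    Reaction,
    build_stoichiometric_matrix,
    format_formula,
    load_model,
    models_equal,
    parse_formula,
    save_model,
    validate_mass_balance,
)


def _tiny_model():
    mets = [
        Metabolite("a_c", formula={"C": 1, "H": 4, "O": 1}),
        Metabolite("b_c", formula={"C": 1, "H": 2, "O": 1}),
        Metabolite("a_e", compartment="extracellular",
                   formula={"C": 1, "H": 4, "O": 1}),
    ]
    rxns = [
        Reaction("EX_a_e", stoich={"a_e": -1}, lower_bound=-5,
                 is_exchange=True),
        Reaction("At", stoich={"a_e": -1, "a_c": 1}),
        Reaction("R1", stoich={"a_c": -1, "b_c": 1}, subsystem="demo"),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns,
                          objective=("R1", "maximize"))


class TestStructure:
    def test_duplicate_reaction_id_rejected(self):
        m = _tiny_model()
        with pytest.raises(ModelValidationError, match="duplicate"):
            MetabolicModel(metabolites=m.metabolites,
                           reactions=m.reactions + [m.reactions[0]])

    def test_unknown_metabolite_reference_rejected(self):
        with pytest.raises(ModelValidationError, match="unknown metabolite"):
            MetabolicModel(
                metabolites=[Metabolite("x_c")],
                reactions=[Reaction("R", stoich={"y_c": 1})])

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ModelValidationError, match="lower bound"):
            Reaction("R", stoich={"x": 1}, lower_bound=2, upper_bound=1)

    def test_exchange_must_touch_one_metabolite(self):
        with pytest.raises(ModelValidationError, match="exactly one"):
            Reaction("EX", stoich={"x": -1, "y": 1}, is_exchange=True)

    def test_copy_is_deep(self):
        m = _tiny_model()
        c = m.copy()
        c.reaction("R1").stoich["a_c"] = -2
        c.reaction("R1").lower_bound = -7
        assert m.reaction("R1").stoich["a_c"] == -1
        assert m.reaction("R1").lower_bound == 0


class TestFormula:
    @pytest.mark.parametrize("text,counts", [
        ("C4H6O5", {"C": 4, "H": 6, "O": 5}),
        ("CH4O", {"C": 1, "H": 4, "O": 1}),
        ("H3O4P", {"H": 3, "O": 4, "P": 1}),
        ("", {}),
    ])
    def test_parse_roundtrip(self, text, counts):
        assert parse_formula(text) == counts
        assert parse_formula(format_formula(counts)) == counts

    def test_malformed_formula_rejected(self):
        with pytest.raises(ModelParseError):
            parse_formula("4CH")


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["json", "tsv"])
    def test_save_load_identity(self, core_model, tmp_path, fmt):
        path = tmp_path / f"model.{fmt}"
        save_model(core_model, path, format=fmt)
        loaded = load_model(path, format=fmt)
        # TSV keeps only the reaction table; compare reaction content there
        assert models_equal(core_model, loaded,
                            check_metabolite_metadata=(fmt == "json")) or fmt == "tsv"
        assert sorted(loaded.reaction_ids) == sorted(core_model.reaction_ids)
        for rid in core_model.reaction_ids:
            a, b = core_model.reaction(rid), loaded.reaction(rid)
            assert a.stoich == b.stoich
            assert (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)

    def test_json_roundtrip_preserves_objective_and_metadata(self, core_model,
                                                             tmp_path):
        path = tmp_path / "model.json"
        save_model(core_model, path)
        loaded = load_model(path)
        assert models_equal(core_model, loaded)

    @pytest.mark.parametrize("fmt", ["json", "tsv"])
    def test_two_saves_byte_identical(self, core_model, tmp_path, fmt):
        p1, p2 = tmp_path / f"a.{fmt}", tmp_path / f"b.{fmt}"
        save_model(core_model, p1, format=fmt)
        save_model(core_model.copy(), p2, format=fmt)
        h = lambda p: hashlib.sha256(p.read_bytes()).hexdigest()
        assert h(p1) == h(p2)

    def test_single_reaction_model_tsv_has_one_data_row(self, tmp_path):
        m = MetabolicModel(
            metabolites=[Metabolite("x_c"), Metabolite("y_c")],
            reactions=[Reaction("R", stoich={"x_c": -1, "y_c": 2})])
        path = tmp_path / "m.tsv"
        save_model(m, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 2  # header + one row

    def test_empty_file_is_parse_error(self, tmp_path):
        for name in ("empty.json", "empty.tsv"):
            path = tmp_path / name
            path.write_text("")
            with pytest.raises(ModelParseError, match="empty"):
                load_model(path)

    def test_malformed_json_names_the_problem(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ModelParseError, match="invalid JSON"):
            load_model(path)

    def test_unknown_optional_fields_warned_and_ignored(self, tmp_path, caplog):
        path = tmp_path / "m.json"
        save_model(_tiny_model(), path)
        import json
        doc = json.loads(path.read_text())
        doc["reactions"][0]["gene_reaction_rule"] = "G1 or G2"
        path.write_text(json.dumps(doc))
        import logging
        with caplog.at_level(logging.WARNING):
            loaded = load_model(path)
        assert "gene_reaction_rule" in caplog.text
        assert sorted(loaded.reaction_ids) == sorted(_tiny_model().reaction_ids)


class TestMassBalance:
    def test_methanol_oxidase_is_balanced(self):
        # independent elemental count: CH4O + O2 -> CH2O + H2O2
        lhs = {"C": 1, "H": 4, "O": 3}
        rhs = {"C": 1, "H": 2 + 2, "O": 1 + 2}
        assert lhs == rhs
        mets = [
            Metabolite("meoh", formula=parse_formula("CH4O")),
            Metabolite("o2", formula=parse_formula("O2")),
            Metabolite("fald", formula=parse_formula("CH2O")),
            Metabolite("h2o2", formula=parse_formula("H2O2")),
        ]
        m = MetabolicModel(metabolites=mets, reactions=[Reaction(
            "AOX", stoich={"meoh": -1, "o2": -1, "fald": 1, "h2o2": 1})])
        assert validate_mass_balance(m) == {}

    def test_corrupted_reaction_flags_residual(self):
        # drop one water from methanol oxidation to formaldehyde + water
        mets = [
            Metabolite("meoh", formula=parse_formula("CH4O")),
            Metabolite("o2", formula=parse_formula("O2")),
            Metabolite("fald", formula=parse_formula("CH2O")),
        ]
        m = MetabolicModel(metabolites=mets, reactions=[Reaction(
            "BAD", stoich={"meoh": -1, "o2": -0.5, "fald": 1})])
        report = validate_mass_balance(m)
        assert report == {"BAD": {"H": -2.0, "O": -1.0}}

    def test_exchange_only_model_has_empty_report(self):
        m = MetabolicModel(
            metabolites=[Metabolite("x_e", compartment="extracellular")],
            reactions=[Reaction("EX_x", stoich={"x_e": -1}, is_exchange=True)])
        assert validate_mass_balance(m) == {}

    def test_missing_formula_is_an_error(self):
        mets = [Metabolite("x", formula=None), Metabolite("y", formula={})]
        m = MetabolicModel(metabolites=mets, reactions=[
            Reaction("R", stoich={"x": -1, "y": 1})])
        with pytest.raises(ModelValidationError, match="x"):
            validate_mass_balance(m)


class TestStoichiometricMatrix:
    def test_shape_and_entries(self, core_model):
        S, met_index, rxn_index = build_stoichiometric_matrix(core_model)
        assert S.shape == (len(core_model.metabolites), len(core_model.reactions))
        for rxn in core_model.reactions:
            col = S[:, rxn_index[rxn.id]]
            assert np.count_nonzero(col) == len(
                [c for c in rxn.stoich.values() if c != 0])
            for mid, coef in rxn.stoich.items():
                assert col[met_index[mid]] == coef

    def test_exchange_columns_have_one_entry(self, core_model):
        S, _mi, rxn_index = build_stoichiometric_matrix(core_model)
        for rxn in core_model.exchanges():
            assert np.count_nonzero(S[:, rxn_index[rxn.id]]) == 1
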