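"""Network container, file formats, and search preprocessing."""

import json

import pytest

from latentpath.network import (
    CurrencySpec,
    MetabolicNetwork,
    Metabolite,
    NetworkError,
    Reaction,
    add_currency_exchanges,
    carbon_balance_check,
    parse_equation,
    prune_for_search,
    read_bigg_json,
    read_network_table,
    write_network_table,
)


def _mini_bigg(tmp_path, reactions=None, metabolites=None):
    doc = {
        "metabolites": metabolites
        or [
            {"id": "a_c", "name": "A", "formula": "C3H4O3", "compartment": "c"},
            {"id": "b_c", "name": "B", "formula": "C3H6O3", "compartment": "c"},
            {"id": "c_c", "name": "C", "formula": "C6H12O6", "compartment": "c"},
        ],
        "reactions": reactions
        or [
            {"id": "R1", "metabolites": {"a_c": -1, "b_c": 1}, "lower_bound": -1000, "upper_bound": 1000},
            {"id": "R2", "metabolites": {"b_c": -2, "c_c": 1}, "lower_bound": 0, "upper_bound": 1000},
        ],
    }
    path = tmp_path / "model.json"
    path.write_text(json.dumps(doc))
    return path


class TestBiggJson:
    def test_minimal_roundtrip(self, tmp_path):
        net = read_bigg_json(_mini_bigg(tmp_path))
        assert len(net.metabolites) == 3
        assert len(net.reactions) == 2
        assert net.metabolite("a_c").carbon_count == 3
        assert net.reaction("R1").reversible
        assert not net.reaction("R2").reversible

    def test_undeclared_metabolite_rejected(self, tmp_path):
        path = _mini_bigg(
            tmp_path,
            reactions=[{"id": "R1", "metabolites": {"a_c": -1, "ghost_c": 1}}],
        )
        with pytest.raises(NetworkError, match="ghost_c"):
            read_bigg_json(path)

    def test_malformed_json_reports_parse_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(NetworkError, match="malformed"):
            read_bigg_json(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = _mini_bigg(
            tmp_path,
            reactions=[
                {"id": "R1", "metabolites": {"a_c": -1, "b_c": 1}},
                {"id": "R1", "metabolites": {"b_c": -1, "a_c": 1}},
            ],
        )
        with pytest.raises(NetworkError, match="duplicate"):
            read_bigg_json(path)

    def test_exchange_and_transport_detection(self, tmp_path):
        path = _mini_bigg(
            tmp_path,
            metabolites=[
                {"id": "a_c", "formula": "C1"},
                {"id": "a_e", "formula": "C1"},
            ],
            reactions=[
                {"id": "EX_a_e", "metabolites": {"a_e": -1}},
                {"id": "At", "metabolites": {"a_e": -1, "a_c": 1}},
            ],
        )
        net = read_bigg_json(path)
        assert net.reaction("EX_a_e").is_exchange
        assert net.reaction("At").is_transport


class TestEquationParsing:
    @pytest.mark.parametrize(
        "equation,expected",
        [
            ("a + b -> c", {"a": -1.0, "b": -1.0, "c": 1.0}),
            ("2 a <-> 3 c", {"a": -2.0, "c": 3.0}),
            ("a <->", {"a": -1.0}),
            ("0.5 a -> b", {"a": -0.5, "b": 1.0}),
        ],
    )
    def test_parse(self, equation, expected):
        assert parse_equation(equation) == expected

    def test_gnd_line_parses_with_dg0(self, tmp_path):
        (tmp_path / "metabolites.tsv").write_text(
            "id\tname\tcarbons\tcompartment\tcurrency\n"
            "6pgc_c\t6PG\t6\tc\t0\nnadp_c\tNADP\t21\tc\t1\n"
            "ru5p__D_c\tRu5P\t5\tc\t0\nco2_c\tCO2\t1\tc\t1\nnadph_c\tNADPH\t21\tc\t1\n"
        )
        (tmp_path / "reactions.tsv").write_text(
            "id\tequation\tdg0_prime_kj_mol\toxygen_sensitive\tnotes\n"
            "GND\t6pgc_c + nadp_c <-> ru5p__D_c + co2_c + nadph_c\t-1.5\t0\t\n"
        )
        net = read_network_table(tmp_path)
        gnd = net.reaction("GND")
        assert len(gnd.stoichiometry) == 5
        assert gnd.dg0_prime == -1.5

    def test_empty_file_gives_empty_network(self, tmp_path):
        (tmp_path / "metabolites.tsv").write_text("id\tcarbons\n")
        (tmp_path / "reactions.tsv").write_text("id\tequation\n")
        net = read_network_table(tmp_path)
        assert net.metabolites == [] and net.reactions == []

    def test_degenerate_reaction_rejected(self):
        with pytest.raises(NetworkError, match="zero net"):
            Reaction(id="NOOP", stoichiometry=parse_equation("a -> a") or {"a": 0.0})

    def test_unknown_metabolite_named(self, tmp_path):
        (tmp_path / "metabolites.tsv").write_text("id\tcarbons\na_c\t1\n")
        (tmp_path / "reactions.tsv").write_text(
            "id\tequation\nR1\ta_c -> mystery_c\n"
        )
        with pytest.raises(NetworkError, match="mystery_c"):
            read_network_table(tmp_path)


class TestRoundTrip:
    def test_fixture_roundtrip_identical(self, core_model, tmp_path):
        write_network_table(core_model, tmp_path)
        again = read_network_table(tmp_path)
        assert core_model.equals(again)

    def test_fixture_contains_key_reactions(self, core_model):
        for rid in ("GND", "EDD", "EDA", "PFK", "ZWF"):
            assert core_model.has_reaction(rid)


class TestPrune:
    def test_removes_exchanges_transports_and_external(self, core_model):
        pruned = prune_for_search(core_model)
        n_flagged = sum(
            1 for r in core_model.reactions if r.is_exchange or r.is_transport
        )
        assert len(pruned.reactions) == len(core_model.reactions) - n_flagged
        assert all(not (r.is_exchange or r.is_transport) for r in pruned.reactions)
        assert all(
            core_model.metabolite(m).compartment == "c"
            for r in pruned.reactions
            for m in r.stoichiometry
        )

    def test_original_unmodified_and_idempotent(self, core_model):
        n = len(core_model.reactions)
        once = prune_for_search(core_model)
        assert len(core_model.reactions) == n
        twice = prune_for_search(once)
        assert once.equals(twice)

    def test_identity_on_unflagged_network(self):
        net = MetabolicNetwork(
            [Metabolite(id="a_c", compartment="c"), Metabolite(id="b_c", compartment="c")],
            [Reaction(id="R", stoichiometry={"a_c": -1.0, "b_c": 1.0})],
        )
        assert prune_for_search(net).equals(net)


class TestCurrency:
    def test_default_spec_adds_eight_marked_pseudo_reactions(self, core_model):
        pruned = prune_for_search(core_model)
        augmented = add_currency_exchanges(pruned)
        added = [r for r in augmented.reactions if r.pseudo]
        assert len(added) == 8
        assert len(augmented.reactions) == len(pruned.reactions) + 8

    def test_empty_spec_is_identity(self, core_model):
        out = add_currency_exchanges(
            core_model, CurrencySpec(regeneration={}, free_exchange=())
        )
        assert out.equals(core_model)

    def test_missing_species_listed(self):
        net = MetabolicNetwork(
            [Metabolite(id="a_c", compartment="c"), Metabolite(id="b_c", compartment="c")],
            [Reaction(id="R", stoichiometry={"a_c": -1.0, "b_c": 1.0})],
        )
        with pytest.raises(NetworkError, match="atp_c"):
            add_currency_exchanges(net)

    def test_commutes_with_prune_on_fixture(self, core_model):
        a = add_currency_exchanges(prune_for_search(core_model))
        b = prune_for_search(add_currency_exchanges(core_model))
        assert sorted(a.reaction_ids) == sorted(b.reaction_ids)


class TestCarbonBalance:
    def test_fixture_is_balanced(self, core_model):
        assert carbon_balance_check(core_model) == []

    def test_deliberate_imbalance_detected(self):
        net = MetabolicNetwork(
            [
                Metabolite(id="pyr_c", carbon_count=3, compartment="c"),
                Metabolite(id="accoa_c", carbon_count=2, compartment="c"),
            ],
            [Reaction(id="BAD", stoichiometry={"pyr_c": -1.0, "accoa_c": 1.0})],
        )
        assert carbon_balance_check(net) == ["BAD"]

    def test_exchange_only_network_passes(self):
        net = MetabolicNetwork(
            [Metabolite(id="a_e", carbon_count=2, compartment="e")],
            [Reaction(id="EX_a_e", stoichiometry={"a_e": -1.0}, is_exchange=True)],
        )
        assert carbon_balance_check(net) == []

    def test_stoichiometric_matrix_carbon_nullspace(self, core_model):
        import numpy as np

        S = core_model.stoichiometric_matrix()
        carbons = np.array([m.carbon_count for m in core_model.metabolites], float)
        internal = [
            j
            for j, r in enumerate(core_model.reactions)
            if not (r.is_exchange or r.pseudo)
        ]
        assert np.allclose((carbons @ S)[internal], 0.0)
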