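"""MILP pathway enumeration, Pareto ranking, and ATP-cost accounting."""

import pytest

from latentpath.fixtures import (
    GED_CYCLE_SUPPORT,
    brute_force_enumerate,
    ged_cycle_pathway,
    random_network,
    rubp_cycle_pathway,
)
from latentpath.network import MetabolicNetwork, Metabolite, Reaction
from latentpath.search import (
    CandidatePathway,
    PathwayQuery,
    SearchError,
    SearchOptions,
    atp_cost,
    enumerate_pathways,
    net_conversion,
    pareto_front,
    remove_oxygen_sensitive,
)


def _toy_single_route():
    """Five reactions, exactly one directed route 3 sub -> prod."""
    mets = [
        Metabolite(id="sub", carbon_count=1, compartment="c"),
        Metabolite(id="a", carbon_count=3, compartment="c"),
        Metabolite(id="b", carbon_count=3, compartment="c"),
        Metabolite(id="c", carbon_count=3, compartment="c"),
        Metabolite(id="d", carbon_count=4, compartment="c"),
        Metabolite(id="prod", carbon_count=3, compartment="c"),
    ]
    rxns = [
        Reaction(id="R1", stoichiometry={"sub": -3.0, "a": 1.0}, dg0_prime=-10.0),
        Reaction(id="R2", stoichiometry={"a": -1.0, "b": 1.0}, dg0_prime=-5.0),
        Reaction(id="R3", stoichiometry={"b": -1.0, "prod": 1.0}, dg0_prime=-5.0),
        Reaction(id="R4", stoichiometry={"a": -1.0, "c": 1.0}, dg0_prime=0.0),
        Reaction(id="R5", stoichiometry={"c": -1.0, "sub": -1.0, "d": 1.0}, dg0_prime=-1.0),
    ]
    return MetabolicNetwork(mets, rxns)


TOY_QUERY = PathwayQuery(substrate="sub", product="prod")


class TestEnumerate:
    def test_single_route_toy(self):
        paths = enumerate_pathways(_toy_single_route(), TOY_QUERY, max_solutions=10)
        assert len(paths) == 1
        assert paths[0].support == [("R1", 1), ("R2", 1), ("R3", 1)]
        assert paths[0].net_conversion == {"sub": -3.0, "prod": 1.0}
        assert paths[0].mdf > 0

    def test_unreachable_product_gives_empty_list(self):
        net = _toy_single_route()
        rxns = [r for r in net.reactions if r.id != "R3"]
        cut = MetabolicNetwork(list(net.metabolites), rxns)
        assert enumerate_pathways(cut, TOY_QUERY, max_solutions=5) == []

    def test_fixture_top_ranked_is_ged_cycle(self, prepared_model):
        """The first/top-ranked pathway on the fixture is the GED cycle:
        reverse Gnd carboxylation feeding the ED pathway, closed through
        gluconeogenesis and the pentose phosphate pathway."""
        paths = enumerate_pathways(prepared_model, max_solutions=5)
        assert paths, "no pathway found on the fixture"
        assert paths[0].directed_support() == frozenset(GED_CYCLE_SUPPORT)

    def test_fixture_pathways_satisfy_contract(self, prepared_model):
        """Every returned pathway: positive MDF, balanced internals, and the
        3 CO2 -> 1 pyruvate net conversion."""
        paths = enumerate_pathways(prepared_model, max_solutions=8)
        assert paths
        supports = set()
        for p in paths:
            assert p.mdf > 0
            assert p.net_conversion == {"co2_c": -3.0, "pyr_c": 1.0}
            assert net_conversion(p, prepared_model) == p.net_conversion
            assert p.directed_support() not in supports  # integer cuts
            supports.add(p.directed_support())
            assert all(rid for rid, _ in p.support)
            assert not any(rid.startswith("PSEUDO_") for rid, _ in p.support)

    def test_weight_invariance_of_front(self, prepared_model):
        """The fixture Pareto front is unchanged for objective weights in
        {0.5, 1, 2}."""
        fronts = []
        for w in (0.5, 1.0, 2.0):
            paths = enumerate_pathways(
                prepared_model, max_solutions=8, options=SearchOptions(weight=w)
            )
            fronts.append(
                {p.directed_support() for p in pareto_front(paths)}
            )
        assert fronts[0] == fronts[1] == fronts[2]

    def test_oracle_agreement_on_random_networks(self):
        """MILP enumeration equals exhaustive subset search (sample; the full
        50-network sweep runs in the acceptance suite)."""
        q = PathwayQuery(substrate="sub", product="prod")
        for seed in range(6):
            net = random_network(6, 8, seed=seed, plant_route=(seed % 2 == 0))
            bf = {p.directed_support() for p in brute_force_enumerate(net, q)}
            milp = {
                p.directed_support()
                for p in enumerate_pathways(net, q, max_solutions=200)
            }
            assert bf == milp, f"seed {seed}"


class TestPareto:
    def _p(self, n, mdf):
        return CandidatePathway(
            support=[(f"R{i}", 1) for i in range(n)],
            fluxes={},
            net_conversion={},
            mdf=mdf,
            n_reactions=n,
        )

    def test_worked_example(self):
        front = pareto_front([self._p(5, 2.0), self._p(6, 5.0), self._p(7, 4.0)])
        assert {(p.n_reactions, p.mdf) for p in front} == {(5, 2.0), (6, 5.0)}

    def test_single_pathway_is_its_own_front(self):
        p = self._p(3, 1.0)
        assert pareto_front([p]) == [p]

    def test_exact_ties_all_kept(self):
        a, b = self._p(4, 2.0), self._p(4, 2.0)
        assert pareto_front([a, b]) == [a, b]

    def test_matches_pairwise_dominance_filter(self):
        import numpy as np

        rng = np.random.default_rng(11)
        pts = [self._p(int(n), float(m)) for n, m in
               zip(rng.integers(3, 20, 60), rng.uniform(-5, 10, 60))]
        front = {(p.n_reactions, p.mdf) for p in pareto_front(pts)}
        brute = {
            (p.n_reactions, p.mdf)
            for p in pts
            if not any(
                (q.mdf >= p.mdf and q.n_reactions <= p.n_reactions)
                and (q.mdf > p.mdf or q.n_reactions < p.n_reactions)
                for q in pts
            )
        }
        assert front == brute


class TestOxygenFilter:
    def test_removes_flagged_reactions_only(self, core_model):
        out = remove_oxygen_sensitive(core_model)
        assert not out.has_reaction("PFL")
        assert len(out.reactions) == len(core_model.reactions) - 1
        assert core_model.has_reaction("PFL")  # original untouched

    def test_identity_without_flags(self):
        net = _toy_single_route()
        assert remove_oxygen_sensitive(net).equals(net)

    def test_fixture_front_after_removal_is_ged_only(self, prepared_model):
        paths = enumerate_pathways(
            prepared_model, max_solutions=8, exclude_oxygen_sensitive=True
        )
        front = pareto_front(paths)
        assert len(front) == 1
        assert front[0].directed_support() == frozenset(GED_CYCLE_SUPPORT)


class TestNetConversionAndCost:
    def test_ged_cycle_net_conversion(self, core_model, prepared_model):
        p = ged_cycle_pathway(core_model)
        assert net_conversion(p, prepared_model) == {"co2_c": -3.0, "pyr_c": 1.0}

    def test_rubp_cycle_net_conversion(self, rubp_model, prepared_rubp_model):
        p = rubp_cycle_pathway(rubp_model)
        assert net_conversion(p, prepared_rubp_model) == {"co2_c": -3.0, "pyr_c": 1.0}

    def test_empty_pathway_converts_nothing(self, prepared_model):
        p = CandidatePathway(
            support=[], fluxes={}, net_conversion={}, mdf=0.0, n_reactions=0
        )
        assert net_conversion(p, prepared_model) == {}
        assert atp_cost(p, prepared_model) == 0.0

    def test_ged_cycle_costs_six_atp(self, core_model, prepared_model):
        p = ged_cycle_pathway(core_model)
        assert atp_cost(p, prepared_model) == pytest.approx(6.0, abs=1e-6)

    def test_rubp_cycle_costs_seven_atp(self, rubp_model, prepared_rubp_model):
        p = rubp_cycle_pathway(rubp_model)
        assert atp_cost(p, prepared_rubp_model) == pytest.approx(7.0, abs=1e-6)

    def test_atp_to_amp_counts_double(self, prepared_model):
        """Hand-balanced oracle: PEP synthetase alone at unit flux costs 2."""
        p = CandidatePathway(
            support=[("PPS", 1)],
            fluxes={"PPS": 1.0},
            net_conversion={},
            mdf=1.0,
            n_reactions=1,
        )
        assert atp_cost(p, prepared_model) == pytest.approx(2.0)

    def test_incomplete_accounting_table_rejected(self, core_model, prepared_model):
        p = ged_cycle_pathway(core_model)
        with pytest.raises(SearchError, match="accounting"):
            atp_cost(p, prepared_model, accounting={"ATP->ADP": 1.0})

    def test_non_steady_internal_species_detected(self, prepared_model):
        p = CandidatePathway(
            support=[("EDD", 1)],
            fluxes={"EDD": 1.0},  # produces 2ddg6p with no consumer
            net_conversion={},
            mdf=1.0,
            n_reactions=1,
        )
        with pytest.raises(SearchError, match="2ddg6p_c"):
            net_conversion(p, prepared_model)
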