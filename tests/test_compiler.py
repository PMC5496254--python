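from itertools import chain, combinations

import pytest

from gnsim import (
    DelayParams,
    DelaySpec,
    GeneNetwork,
    RateParams,
    compile_network,
    count_reactions,
    generate_network,
    transcription_combinations,
)
from gnsim.compiler import promoter_bound, promoter_free


def powerset_oracle(items):
    """Brute-force non-empty subsets, independent of the implementation."""
    return set(
        frozenset(c) for c in chain.from_iterable(combinations(items, r) for r in range(1, len(items) + 1))
    )


def transcription_reactions(system, gene):
    rna = f"R{gene}"
    out = []
    for rx in system.reactions:
        produces_rna = any(p.species == rna for p in rx.products)
        consumes_rna = any(r.species == rna and not r.catalyst for r in rx.reactants)
        if produces_rna and not consumes_rna and all(r.catalyst for r in rx.reactants):
            out.append(rx)
    return out


class TestTranscriptionCombinations:
    def test_worked_example_pair(self):
        assert transcription_combinations(["B", "C"]) == [("B",), ("C",), ("B", "C")]

    def test_empty(self):
        assert transcription_combinations([]) == []

    def test_four_activators_against_oracle(self):
        subsets = transcription_combinations(["X1", "X2", "X3", "X4"])
        assert len(subsets) == 15
        assert all(subsets)  # none empty
        assert len(set(subsets)) == 15
        assert {frozenset(s) for s in subsets} == powerset_oracle(["X1", "X2", "X3", "X4"])

    def test_order_by_size_then_lexicographic(self):
        subsets = transcription_combinations(["C", "A", "B"])
        assert subsets[:3] == [("A",), ("B",), ("C",)]
        assert subsets[3:6] == [("A", "B"), ("A", "C"), ("B", "C")]

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            transcription_combinations(["A", "A"])


class TestWorkedExample:
    def test_three_transcription_choices_for_a(self, four_gene_network):
        system = compile_network(four_gene_network)
        txn = transcription_reactions(system, "A")
        assert len(txn) == 3
        activator_sets = {
            frozenset(
                r.species for r in rx.reactants if r.species.startswith("ProA.") and "No" not in r.species
            )
            for rx in txn
        }
        assert activator_sets == {
            frozenset({promoter_bound("A", "B")}),
            frozenset({promoter_bound("A", "C")}),
            frozenset({promoter_bound("A", "B"), promoter_bound("A", "C")}),
        }

    def test_repressor_site_gates_every_transcription_of_a(self, four_gene_network):
        system = compile_network(four_gene_network)
        site = promoter_free("A", "D")
        for rx in transcription_reactions(system, "A"):
            names = [r.species for r in rx.reactants]
            assert site in names

    def test_total_reaction_count(self, four_gene_network):
        # 3 per-gene translation/decay blocks + 2 per edge + 3 combinations
        # for A + basal transcription for B, C, D
        assert count_reactions(four_gene_network) == 24
        system = compile_network(four_gene_network)
        assert len(system.reactions) == 24

    def test_binding_unbinding_per_edge(self, four_gene_network):
        system = compile_network(four_gene_network)
        for reg in ["B", "C", "D"]:
            site, bound = promoter_free("A", reg), promoter_bound("A", reg)
            binding = [
                rx
                for rx in system.reactions
                if any(r.species == site and not r.catalyst for r in rx.reactants)
                and any(p.species == bound for p in rx.products)
            ]
            unbinding = [
                rx
                for rx in system.reactions
                if any(r.species == bound and not r.catalyst for r in rx.reactants)
                and any(p.species == site for p in rx.products)
            ]
            assert len(binding) == 1 and len(unbinding) == 1
            assert any(r.species == f"P{reg}" for r in binding[0].reactants)

    def test_initial_populations(self, four_gene_network):
        four_gene_network.node_attrs["B"] = {"init_rna": 4, "init_protein": 7}
        system = compile_network(four_gene_network)
        assert system.species[promoter_free("A", "B")] == 1
        assert system.species[promoter_bound("A", "B")] == 0
        assert system.species["ProB"] == 1  # constitutive promoter, B has no regulators
        assert system.species["RB"] == 4 and system.species["PB"] == 7
        assert system.species["RA"] == 0 and system.species["PA"] == 0
        assert "ProA" not in system.species  # regulated gene has per-regulator sites only


class TestCountAndScaling:
    def test_single_gene_no_edges(self):
        net = GeneNetwork(nodes=["X"], edges=[])
        system = compile_network(net)
        assert count_reactions(net) == 4
        assert len(system.reactions) == 4
        txn = transcription_reactions(system, "X")
        assert len(txn) == 1
        assert [r.species for r in txn[0].reactants] == ["ProX"]
        binding = [rx for rx in system.reactions if len(rx.reactants) == 2]
        assert binding == []

    def test_five_activators_give_31_combinations(self):
        nodes = ["T"] + [f"A{i}" for i in range(5)]
        edges = [(f"A{i}", "T", "+") for i in range(5)]
        net = GeneNetwork(nodes=nodes, edges=edges)
        system = compile_network(net)
        txn = transcription_reactions(system, "T")
        assert len(txn) == 31
        subsets = {
            frozenset(r.species for r in rx.reactants) for rx in txn
        }
        oracle = {
            frozenset(promoter_bound("T", a) for a in s)
            for s in powerset_oracle([f"A{i}" for i in range(5)])
        }
        assert subsets == oracle

    def test_random_network_count_matches_compiled_length(self):
        net = generate_network("erdos_renyi", 10, {"p": 0.17, "activation_prob": 0.6}, seed=11)
        assert 5 <= len(net.edges) <= 25  # sanity on the fixture
        system = compile_network(net)
        assert len(system.reactions) == count_reactions(net)


class TestSemantics:
    def test_compilation_deterministic(self, four_gene_network):
        a = compile_network(four_gene_network)
        b = compile_network(four_gene_network)
        assert [rx.name for rx in a.reactions] == [rx.name for rx in b.reactions]
        assert a.signature() == b.signature()

    def test_promoter_copy_number_conserved(self, four_gene_network):
        """Stoichiometry audit: bound + free copies per site never change."""
        delays = DelayParams(promoter_delay=DelaySpec.constant(2.0))
        system = compile_network(four_gene_network, delays=delays)
        for reg in ["B", "C", "D"]:
            pool = {promoter_free("A", reg), promoter_bound("A", reg)}
            for rx in system.reactions:
                delta = 0
                product_names = {p.species for p in rx.products}
                for r in rx.reactants:
                    if r.species not in pool:
                        continue
                    if not r.catalyst or r.species in product_names:
                        delta -= r.stoichiometry
                for p in rx.products:
                    if p.species in pool:
                        delta += p.stoichiometry
                assert delta == 0, f"{rx.name} changes promoter copy number of {pool}"

    def test_no_consumed_reactant_is_delayed_product(self, four_gene_network):
        delays = DelayParams(
            rna_delay=DelaySpec.constant(1.0),
            protein_delay=DelaySpec.gamma(2, 1),
            promoter_delay=DelaySpec.constant(0.5),
        )
        system = compile_network(four_gene_network, delays=delays)
        for rx in system.reactions:
            consumed = {r.species for r in rx.reactants if not r.catalyst}
            delayed = {p.species for p in rx.products if not p.delay.is_zero}
            assert not (consumed & delayed), rx.name

    def test_delays_attached_to_right_products(self, four_gene_network):
        delays = DelayParams(
            rna_delay=DelaySpec.constant(3.0),
            protein_delay=DelaySpec.constant(4.0),
            promoter_delay=DelaySpec.constant(5.0),
        )
        system = compile_network(four_gene_network, delays=delays)
        for rx in transcription_reactions(system, "A"):
            for p in rx.products:
                expected = delays.rna_delay if p.species == "RA" else delays.promoter_delay
                assert p.delay == expected
        translation = next(rx for rx in system.reactions if rx.name == "translation:A")
        assert translation.products[0].delay == delays.protein_delay

    def test_repressors_block_flag_off(self, four_gene_network):
        system = compile_network(four_gene_network, repressors_block=False)
        site = promoter_free("A", "D")
        for rx in transcription_reactions(system, "A"):
            assert site not in [r.species for r in rx.reactants]

    def test_repressor_only_gene_keeps_basal_gated_transcription(self):
        net = GeneNetwork(nodes=["R", "T"], edges=[("R", "T", "-")])
        system = compile_network(net)
        txn = transcription_reactions(system, "T")
        assert len(txn) == 1
        assert [r.species for r in txn[0].reactants] == [promoter_free("T", "R")]

    def test_rate_overrides(self, four_gene_network):
        rates = RateParams(
            transcription=0.7,
            per_gene={"B": {"transcription": 0.9}},
            per_edge={("D", "A"): {"binding": 0.123}},
        )
        system = compile_network(four_gene_network, rates)
        by_name = {rx.name: rx for rx in system.reactions}
        assert by_name["transcription:B:basal"].rate_constant == 0.9
        assert by_name["transcription:C:basal"].rate_constant == 0.7
        assert by_name["binding:D->A"].rate_constant == 0.123

    def test_subset_rate_hook(self, four_gene_network):
        def synergy(gene, subset):
            return 0.7 * len(subset) if gene == "A" else None

        system = compile_network(four_gene_network, subset_rate=synergy)
        rates = sorted(rx.rate_constant for rx in transcription_reactions(system, "A"))
        assert rates == [0.7, 0.7, pytest.approx(1.4)]

    def test_unsigned_network_rejected(self):
        net = GeneNetwork(nodes=["A", "B"], edges=[("A", "B", None)])
        with pytest.raises(ValueError, match="unsigned"):
            compile_network(net)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            RateParams(transcription=-1.0)
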