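"""Layer splitting, fragment dictionaries and bonding descriptors."""

import itertools

import pytest

import cgline as cg
from cgline.descriptors import BondingDescriptor


class TestSplitLayers:
    def test_two_layers(self):
        blocks = cg.split_layers("{[#A][#B]}.{#A=CC=[$],#B=[$]=CCC}")
        assert blocks == ["[#A][#B]", "#A=CC=[$],#B=[$]=CCC"]

    def test_single_layer(self):
        assert cg.split_layers("{[#W]}") == ["[#W]"]

    @pytest.mark.parametrize("bad", ["{[#A]}{[#B]}", "{[#A]", "x{[#A]}",
                                     "{[#A]}.", "{{[#A]}}"])
    def test_malformed(self, bad):
        with pytest.raises(cg.ParseError):
            cg.split_layers(bad)


class TestFragmentList:
    def test_simple_smiles_fragment(self):
        peo = cg.parse_fragment_list("#PEO=COC")["PEO"]
        elements = [peo.graph.nodes[n]["element"] for n in peo.graph.nodes]
        assert elements == ["C", "O", "C"]
        assert not peo.descriptors

    def test_branched_pe_descriptor_hosts(self):
        pe = cg.parse_fragment_list("#PE=[$]CC[$][$]")["PE"]
        hosts = [d.host for d in pe.descriptors]
        assert hosts == [0, 1, 1]

    def test_bond_order_binds_to_descriptor(self):
        frags = cg.parse_fragment_list("#A=CC=[$],#B=[$]=CCC")
        (da,), (db,) = frags["A"].descriptors, frags["B"].descriptors
        assert (da.host, da.bond_order) == (1, 2)
        assert (db.host, db.bond_order) == (0, 2)

    def test_water_with_weights(self):
        water = cg.parse_fragment_list("#water=[H;w=0][O][H;w=0]")["water"]
        weights = [water.graph.nodes[n].get("weight", 1) for n in water.graph.nodes]
        assert weights == [0, 1, 0]

    def test_commas_inside_selection_are_not_separators(self):
        frags = cg.parse_fragment_list("#T=CC[*;s=C,0],#U=CC")
        assert set(frags) == {"T", "U"}
        wildcard = [d for _, d in frags["T"].graph.nodes(data=True)
                    if d.get("element") == "*"]
        assert wildcard[0]["select"] == ["C", "0"]

    @pytest.mark.parametrize("bad", ["#A=CC,#A=CC", "#A=", "A=CC", "#A"])
    def test_malformed(self, bad):
        with pytest.raises(cg.ParseError):
            cg.parse_fragment_list(bad)


class TestAtomicDialect:
    def test_chirality_keyword_and_positional(self):
        keyed, _ = cg.parse_atomic_fragment("C[C;x=S]C(=O)ON")
        positional, _ = cg.parse_atomic_fragment("C[C;1;S]C(=O)ON")
        assert keyed.nodes[1]["chirality"] == "S"
        assert positional.nodes[1]["chirality"] == "S"
        assert positional.nodes[1]["weight"] == 1
        assert cg.mol_isomorphic(keyed, positional)

    def test_wildcard_selection(self):
        graph, _ = cg.parse_atomic_fragment("CCCC[*;s=C,0][*;s=C,0]")
        selections = [d["select"] for _, d in graph.nodes(data=True)
                      if d.get("element") == "*"]
        assert selections == [["C", "0"], ["C", "0"]]

    def test_charges_and_hcount(self):
        graph, _ = cg.parse_atomic_fragment("[NH4+].[OH-]")
        n, o = graph.nodes[0], graph.nodes[1]
        assert n["charge"] == 1 and n["hcount"] == 4
        assert o["charge"] == -1 and o["hcount"] == 1

    def test_aromatic_flags(self):
        graph, _ = cg.parse_atomic_fragment("c1ccccc1")
        assert all(d["aromatic"] for _, d in graph.nodes(data=True))
        assert all(d["aromatic"] for *_, d in graph.edges(data=True))

    def test_select_on_non_wildcard_rejected(self):
        with pytest.raises(cg.ParseError):
            cg.parse_atomic_fragment("C[C;s=C,0]C")

    def test_annotation_with_equals_in_value_rejected(self):
        with pytest.raises(cg.ParseError):
            cg.parse_atomic_fragment("[C;w=1=2]")


class TestDescriptorCompatibility:
    KINDS = ("$", ">", "<", "!")
    COMPATIBLE = {("$", "$"), (">", "<"), ("<", ">"), ("!", "!")}

    @pytest.mark.parametrize("a,b", list(itertools.product(KINDS, KINDS)))
    def test_kind_pairing(self, a, b):
        da = BondingDescriptor(kind=a, label="x")
        db = BondingDescriptor(kind=b, label="x")
        assert da.compatible(db) == ((a, b) in self.COMPATIBLE)

    def test_labels_must_match(self):
        assert not BondingDescriptor("$", "a").compatible(BondingDescriptor("$", "b"))
        assert not BondingDescriptor("$", "a").compatible(BondingDescriptor("$", ""))
        assert BondingDescriptor("$", "").compatible(BondingDescriptor("$", ""))

    def test_bond_orders_must_match(self):
        da = BondingDescriptor("$", "", bond_order=2)
        assert not da.compatible(BondingDescriptor("$", "", bond_order=1))
        assert da.compatible(BondingDescriptor("$", "", bond_order=2))

    def test_consumed_descriptors_never_match(self):
        da = BondingDescriptor("$", "", consumed=True)
        assert not da.compatible(BondingDescriptor("$", ""))


def test_fragment_only_string_detected():
    layers = cg.parse_cgsmiles("{#PS=[$]CC[$]c1ccccc1,#PMMA=[$]CC[$](C)C(=O)OC}")
    assert layers.sampler_only
    assert set(layers.fragment_layers[0]) == {"PS", "PMMA"}
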