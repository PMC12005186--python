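"""Fragment instantiation, descriptor matching, squashing, pruning, wildcards."""

import networkx as nx
import pytest

import cgline as cg


class TestResolveLayer:
    def test_pentene_split(self, rdkit_graph):
        resolved = cg.resolve("{[#A][#B]}.{#A=CC=[$],#B=[$]=CCC}")
        molecule = resolved.molecule
        assert cg.molecular_formula(molecule) == "C5H10"
        doubles = [e for *e, d in molecule.edges(data=True) if d["order"] == 2]
        assert len(doubles) == 1
        assert cg.mol_isomorphic(molecule, rdkit_graph("CC=CCC"))

    def test_single_bead_water(self):
        molecule = cg.resolve("{[#W]}.{#W=O}").molecule
        assert cg.molecular_formula(molecule) == "H2O"

    def test_order_two_edge_consumes_two_pairs(self, rdkit_graph):
        # cyclohexane split into two beads joined by one order-2 coarse edge
        molecule = cg.resolve("{[#A]=[#A]}.{#A=[$]CCC[$]}").molecule
        assert cg.mol_isomorphic(molecule, rdkit_graph("C1CCCCC1"))

    def test_missing_fragment_reported(self):
        with pytest.raises(cg.ResolutionError, match="no fragment named 'B'"):
            cg.resolve("{[#A][#B]}.{#A=[$]C}")

    def test_exhausted_descriptors_reported(self):
        with pytest.raises(cg.ResolutionError, match="no compatible descriptor"):
            cg.resolve("{[#A][#A][#A]}.{#A=[$]C}")

    def test_membership_weights(self):
        resolved = cg.resolve("{[#water]}.{#water=[H;w=0][O][H;w=0]}")
        layer = resolved.layers[0]
        weights = sorted(w for m in layer.membership.values() for w in m.values())
        assert weights == [0, 0, 1]


class TestSquash:
    def test_propane_from_shared_atom(self):
        resolved = cg.resolve("{[#X][#Y]}.{#X=C[!]C,#Y=C[!]C}")
        assert cg.molecular_formula(resolved.molecule) == "C3H8"
        assert resolved.layers[0].merges == 1

    def test_merged_atom_belongs_to_both_beads(self):
        resolved = cg.resolve("{[#X][#Y]}.{#X=C[!]C,#Y=C[!]C}")
        layer = resolved.layers[0]
        shared_heavy = [n for n, m in layer.membership.items()
                        if len(m) == 2 and layer.fine.nodes[n]["element"] != "H"]
        assert len(shared_heavy) == 1
        # hydrogens on the shared atom belong to both beads as well
        for n in shared_heavy:
            for nbr in layer.fine.neighbors(n):
                if layer.fine.nodes[nbr]["element"] == "H":
                    assert len(layer.membership[nbr]) == 2

    def test_toluene_from_split_aromatic_ring(self, rdkit_graph):
        molecule = cg.resolve(
            "{[#A]=[#B]}.{#A=[!x]cccc[!y],#B=[!x]c(C)ccc[!y]}").molecule
        assert len(cg.heavy_atoms(molecule)) == 7
        assert cg.mol_isomorphic(molecule, rdkit_graph("Cc1ccccc1", kekulize=False))

    def test_element_mismatch_rejected(self):
        with pytest.raises(cg.ResolutionError, match="squash-merge"):
            cg.resolve("{[#X][#Y]}.{#X=C[!]C,#Y=O[!]O}")

    def test_conservation_of_membership(self):
        resolved = cg.resolve("{[#A]=[#B]}.{#A=[!x]cccc[!y],#B=[!x]c(C)ccc[!y]}")
        layer = resolved.layers[0]
        heavy = [n for n, d in layer.fine.nodes(data=True) if d["element"] != "H"]
        total = sum(len(layer.membership[n]) for n in heavy)
        assert total == len(heavy) + layer.merges


class TestVirtualNodes:
    GLUCOSE_STYLE = ("{[#SP4]1[#SP4][#SP1]1.[#TC4]}."
                     "{#SP4=[$]CC[$]O,#SP1=[$]CC[$]O}")

    def test_virtual_particle_has_no_image(self):
        resolved = cg.resolve(self.GLUCOSE_STYLE)
        layer = resolved.layers[0]
        assert layer.pruned == [3]
        coarse_images = {c for m in layer.membership.values() for c in m}
        assert 3 not in coarse_images

    def test_no_virtual_edges_unchanged(self):
        resolved = cg.resolve("{[#A][#B]}.{#A=[$]C,#B=[$]C}")
        assert resolved.layers[0].pruned == []

    def test_mixed_orders_keep_node(self):
        # A has one order-0 and one order-1 edge: kept, virtual edge ignored;
        # B hangs on virtual edges only: pruned
        resolved = cg.resolve("{[#B].[#A][#C]}.{#A=[$]C,#C=[$]C}")
        layer = resolved.layers[0]
        assert layer.pruned == [0]
        images = {c for m in layer.membership.values() for c in m}
        assert images == {1, 2}


class TestHydrogens:
    def test_unconsumed_descriptors_become_hydrogens(self):
        molecule = cg.resolve("{[#PE]}.{#PE=[$]CC[$][$]}").molecule
        assert cg.molecular_formula(molecule) == "C2H6"

    def test_explicit_hydrogens_untouched(self):
        molecule = cg.resolve("{[#W]}.{#W=[H;w=0][O][H;w=0]}").molecule
        assert cg.molecular_formula(molecule) == "H2O"

    def test_explicit_hcount_is_honored(self):
        molecule = cg.resolve("{[#M]}.{#M=[CH2]C}", validate=False).molecule
        assert cg.molecular_formula(molecule) == "C2H5"

    def test_hydrogens_inherit_membership(self):
        resolved = cg.resolve("{[#A][#B]}.{#A=[$]C,#B=[$]O}")
        layer = resolved.layers[0]
        for node, data in layer.fine.nodes(data=True):
            assert layer.membership[node], f"no membership for {node}"


class TestWildcards:
    TAIL = "{[#T]}.{#T=CCCC[*;s=C,0][*;s=C,0]}"

    def test_resolve_refuses_unresolved_selection(self):
        with pytest.raises(cg.WildcardError):
            cg.resolve(self.TAIL)

    def test_cartesian_enumeration(self):
        variants = list(cg.MoleculeResolver(self.TAIL).enumerate_variants())
        assert len(variants) == 4
        formulas = sorted(cg.molecular_formula(v.molecule) for v in variants)
        assert formulas == ["C4H10", "C5H12", "C5H12", "C6H14"]
        assert len(set(formulas)) == 3  # three distinct tail lengths

    def test_variant_by_index(self):
        resolved = cg.MoleculeResolver(self.TAIL).variant(0)
        assert cg.molecular_formula(resolved.molecule) == "C6H14"

    def test_single_token_selection(self):
        variants = list(cg.MoleculeResolver(
            "{[#T]}.{#T=CC[*;s=O]}").enumerate_variants())
        assert len(variants) == 1
        assert cg.molecular_formula(variants[0].molecule) == "C2H6O"

    def test_empty_selection_rejected(self):
        with pytest.raises((cg.WildcardError, cg.ParseError)):
            list(cg.MoleculeResolver("{[#T]}.{#T=CC[*;s=]}").enumerate_variants())

    def test_coarse_level_wildcard_selects_fragment(self):
        string = "{[#A][*;s=B,0]}.{#A=[$]CO,#B=[$]C}"
        variants = list(cg.MoleculeResolver(string).enumerate_variants())
        formulas = sorted(cg.molecular_formula(v.molecule) for v in variants)
        assert formulas == ["C2H6O", "CH4O"]


class TestStereoValidation:
    def test_isomer_mark_requires_double_bond(self):
        with pytest.raises(cg.ResolutionError, match="cis/trans"):
            cg.resolve("{[#M]}.{#M=C/CC}")

    def test_chiral_atom_needs_three_neighbors(self):
        # hydrogens collapse to one: CH3-CH3 cannot host a stereocenter ...
        with pytest.raises(cg.ResolutionError, match="chiral"):
            cg.resolve("{[#M]}.{#M=C[C;x=R]}")
        # ... while the printed alanine fragment is accepted
        cg.resolve("{[#M]}.{#M=C[C;x=S]C(=O)ON}")

    def test_split_cis_trans_carries_through(self, canon):
        molecule = cg.resolve("{[#A][#B]}.{#A=C/C=[$],#B=[$]=C/C}").molecule
        assert canon(cg.export_smiles(molecule)) == canon("C/C=C/C")


class TestMultiLayer:
    STACK = ("{[#blockA][#blockB]}."
             "{#blockA=[#PEO][#PEO][$],#blockB=[$][#PMA][#PMA]}."
             "{#PEO=[$]COC[$],#PMA=[$]CC[$]C(=O)OC}")

    def test_layer_chaining(self):
        resolved = cg.MoleculeResolver(self.STACK).resolve()
        assert len(resolved.layers) == 2
        assert resolved.layers[0].fine is resolved.layers[1].coarse

    def test_two_graphs_per_resolution(self):
        resolved = cg.MoleculeResolver(self.STACK).resolve()
        pairs = resolved.graphs()
        assert [c.number_of_nodes() for c, _ in pairs] == [2, 4]
        assert cg.molecular_formula(resolved.molecule) == "C12H22O6"

    def test_determinism(self):
        a = cg.MoleculeResolver(self.STACK).resolve().molecule
        b = cg.MoleculeResolver(self.STACK).resolve().molecule
        assert cg.graphs_identical(a, b)


class TestEdgeOrderSensitivity:
    FRAGS = "{#TN6a=[$]nc[$],#TC5=[>a][$]cc[$],#TC2=[<a]CC}"
    SENSITIVE_A = "{[#TN6a]1[#TC5][#TC5]1[#TC2]}." + FRAGS
    SENSITIVE_B = "{[#TN6a]1[#TC5]([#TC2])[#TC5]1}." + FRAGS
    STABLE = ("{[#TN6a]1[#TC5][#TC5A]1[#TC2]}."
              "{#TN6a=[$a]nc[$b],#TC5=[$a]cc[$c],"
              "#TC5A=[$b]cc([$d])[$c],#TC2=[$d]CC}")

    def test_node_swap_changes_isomer(self, rdkit_graph):
        a = cg.resolve(self.SENSITIVE_A).molecule
        b = cg.resolve(self.SENSITIVE_B).molecule
        assert not cg.mol_isomorphic(a, b)
        assert cg.mol_isomorphic(
            a, rdkit_graph("CCc1ccncc1", kekulize=False))  # 4-ethylpyridine
        assert cg.mol_isomorphic(
            b, rdkit_graph("CCc1ccccn1", kekulize=False))  # 2-ethylpyridine

    def test_labelled_variant_is_permutation_insensitive(self):
        import itertools
        layers = cg.parse_cgsmiles(self.STABLE)
        reference = cg.resolve_all(layers).molecule
        n = layers.base.number_of_edges()
        for perm in itertools.permutations(range(n)):
            work = cg.LayerSpec(base=cg.permute_edges(layers.base, list(perm)),
                                fragment_layers=layers.fragment_layers,
                                dialects=layers.dialects)
            assert cg.mol_isomorphic(reference, cg.resolve_all(work).molecule)
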