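"""Interaction fingerprint, volume estimator and the syntax census."""

import itertools

import numpy as np
import pandas as pd
import pytest

import cgline as cg


@pytest.fixture
def table():
    frame = pd.DataFrame([[5, 10, 3], [10, 2, 7], [3, 7, 1]],
                         index=["C1", "SN4", "TC5"],
                         columns=["C1", "SN4", "TC5"])
    return cg.InteractionTable.from_frame(frame)


class TestIndexing:
    def test_size_pair_order_follows_convention(self):
        assert cg.size_pair_index("regular", "regular") == 0
        assert cg.size_pair_index("regular", "small") == 1
        assert cg.size_pair_index("regular", "tiny") == 2
        assert cg.size_pair_index("small", "small") == 3
        assert cg.size_pair_index("small", "tiny") == 4
        assert cg.size_pair_index("tiny", "tiny") == 5

    def test_size_pair_symmetry(self):
        for a, b in itertools.product(("regular", "small", "tiny"), repeat=2):
            assert cg.size_pair_index(a, b) == cg.size_pair_index(b, a)

    def test_six_distinct_size_combinations(self):
        images = {cg.size_pair_index(a, b)
                  for a, b in itertools.combinations_with_replacement(
                      ("regular", "small", "tiny"), 2)}
        assert images == set(range(6))

    def test_interaction_index_bijection(self):
        images = {cg.interaction_index(level, pair)
                  for level in range(20) for pair in range(6)}
        assert images == set(range(120))

    def test_corner_values(self):
        assert cg.interaction_index(0, 0) == 0
        assert cg.interaction_index(19, 5) == 119

    def test_unknown_size_rejected(self):
        with pytest.raises(cg.FingerprintError):
            cg.size_pair_index("huge", "tiny")


class TestTable:
    def test_size_classification_from_type_names(self, table):
        assert table.size_of == {"C1": "regular", "SN4": "small", "TC5": "tiny"}

    def test_trailing_capital_disambiguation_stripped(self, table):
        assert table.resolve_type("TC5A") == "TC5"
        assert table.resolve_type("TC5") == "TC5"

    def test_missing_type_reported(self, table):
        with pytest.raises(cg.FingerprintError):
            table.resolve_type("Q5")

    def test_asymmetric_matrix_rejected(self):
        frame = pd.DataFrame([[1, 2], [3, 1]], index=["C1", "C2"],
                             columns=["C1", "C2"])
        with pytest.raises(cg.FingerprintError):
            cg.InteractionTable.from_frame(frame)


class TestFingerprint:
    def test_single_pair(self, table):
        solute = cg.parse_cg_graph("[#C1]")
        solvent = cg.parse_cg_graph("[#TC5]")
        vector = cg.martini_fingerprint(solute, [solvent, solvent], table,
                                        volume=1.0)
        assert vector.counts.sum(axis=1).tolist() == [1, 1]
        assert np.count_nonzero(vector.counts[0]) == 1

    def test_block_sums_equal_pair_counts(self, table):
        solute = cg.parse_cg_graph("[#C1][#SN4][#TC5A]")
        water = cg.parse_cg_graph("[#C1]")
        octanol = cg.parse_cg_graph("[#C1][#SN4]")
        vector = cg.martini_fingerprint(solute, [water, octanol], table,
                                        volume=1.0)
        assert vector.counts.sum(axis=1).tolist() == [3, 6]

    def test_symmetry_under_pair_swap(self, table):
        a = cg.parse_cg_graph("[#C1][#TC5]")
        b = cg.parse_cg_graph("[#TC5][#C1]")
        w = cg.parse_cg_graph("[#SN4]")
        va = cg.martini_fingerprint(a, [w, w], table, volume=1.0)
        vb = cg.martini_fingerprint(b, [w, w], table, volume=1.0)
        assert (va.counts == vb.counts).all()

    def test_volume_from_atomistic_graph(self, table):
        resolved = cg.resolve("{[#C1]}.{#C1=CCCC}")
        solute = cg.parse_cg_graph("[#C1]")
        w = cg.parse_cg_graph("[#C1]")
        vector = cg.martini_fingerprint(solute, [w, w], table,
                                        atomic_graph=resolved.molecule)
        assert vector.volume > 0


class TestVolume:
    def test_methane_additive_value(self):
        molecule = cg.resolve("{[#M]}.{#M=C}").molecule
        # 20.58 + 4*7.24 - 4*5.92
        assert cg.estimate_volume(molecule) == pytest.approx(25.86, abs=0.01)

    def test_benzene_ring_correction(self):
        molecule = cg.resolve("{[#M]}.{#M=c1ccccc1}").molecule
        assert cg.estimate_volume(molecule) == pytest.approx(81.2, abs=0.1)

    def test_additivity_scales_with_chain_length(self):
        volumes = [cg.estimate_volume(
            cg.resolve("{[#M]}.{#M=%s}" % ("C" * n)).molecule)
            for n in (2, 3, 4)]
        increments = np.diff(volumes)
        assert np.allclose(increments, increments[0])


class TestCensus:
    def test_plain_water_all_false(self):
        flags = cg.census_flags(cg.parse_cgsmiles("{[#W]}.{#W=O}"))
        assert not any(flags.values())

    def test_pentene_flags_descriptor_bond_order_only(self):
        flags = cg.census_flags(
            cg.parse_cgsmiles("{[#A][#B]}.{#A=CC=[$],#B=[$]=CCC}"))
        true_keys = {k for k, v in flags.items() if v}
        assert true_keys == {"descriptor_bond_orders"}

    def test_sterol_style_combination(self):
        # squash + weights + linearized ring + cis/trans in one entry
        string = ("{[#A]=[#B][#C]}."
                  "{#A=[!x]C[!y]CC[$a],#B=[!x]C[!y][C;w=0.5]C/C=C/[$b],"
                  "#C=[$a]CC[$b]}")
        flags = cg.census_flags(cg.parse_cgsmiles(string))
        assert flags["squash_operator"] and flags["weights"]
        assert flags["linearized_rings"] and flags["cis_trans"]

    def test_census_invariant_under_round_trip(self):
        strings = ["{[#A]=[#B]}.{#A=[!x]cccc[!y],#B=[!x]c(C)ccc[!y]}",
                   "{[#A][#B]}.{#A=CC=[$],#B=[$]=CCC}",
                   "{[#W]}.{#W=O}"]
        for string in strings:
            layers = cg.parse_cgsmiles(string)
            rewritten = cg.parse_cgsmiles(cg.write_full(layers))
            assert cg.census_flags(layers) == cg.census_flags(rewritten)

    def test_feature_table(self):
        pairs = [("water", cg.parse_cgsmiles("{[#W]}.{#W=O}")),
                 ("toluene", cg.parse_cgsmiles(
                     "{[#A]=[#B]}.{#A=[!x]cccc[!y],#B=[!x]c(C)ccc[!y]}"))]
        frame = cg.feature_census(pairs)
        assert frame.loc["toluene", "squash_operator"]
        assert frame.loc["toluene", "split_aromaticity"]
        assert not frame.loc["water"].any()
        assert frame.sum()["squash_operator"] == 1
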