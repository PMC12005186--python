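import logging

import networkx as nx
import pytest

logging.getLogger("cgline").setLevel(logging.ERROR)


def rdkit_molecule_graph(smiles, add_hs=True, kekulize=True):
    """Reference molecule graph from rdkit.

    By default the reference is kekulized with aromatic flags cleared,
    because the package's own aromaticity model keeps flags only under
    delocalization-induced equivalence.  Pass ``kekulize=False`` when the
    expected molecule genuinely keeps its aromatic flags (benzene,
    naphthalene, ...).
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, f"reference toolkit rejected {smiles!r}"
    if kekulize:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    if add_hs:
        mol = Chem.AddHs(mol)
    graph = nx.Graph()
    for atom in mol.GetAtoms():
        graph.add_node(atom.GetIdx(), element=atom.GetSymbol(),
                       aromatic=atom.GetIsAromatic(),
                       charge=atom.GetFormalCharge())
    for bond in mol.GetBonds():
        graph.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(),
                       order=int(bond.GetBondTypeAsDouble()),
                       aromatic=bond.GetIsAromatic())
    return graph


@pytest.fixture
def rdkit_graph():
    return rdkit_molecule_graph


@pytest.fixture
def canon():
    from rdkit import Chem
    return Chem.CanonSmiles
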