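"""Martini solute-solvent interaction fingerprints and the syntax census.

The Martini force field defines nonbonded interactions pairwise between bead
types.  Excluding ionic beads there are 20 interaction levels (0-19) and
three bead sizes (regular, small, tiny), hence 6 unordered size combinations
and 20 x 6 = 120 symmetric interaction types.  The fingerprint of a solute
against two solvents counts, for every interaction type, how many
(solute bead, solvent bead) pairs realize it — a 2 x 120 vector — and
appends the solute's molecular volume computed from its atomistic graph.

The interaction-level matrix is force-field data and therefore an *input*
(plain-text symmetric TSV), not bundled.
"""

import re
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .elements import VDW_VOLUME
from .errors import FingerprintError

SIZES = ("regular", "small", "tiny")
N_LEVELS = 20
N_SIZE_PAIRS = 6
N_TYPES = N_LEVELS * N_SIZE_PAIRS

# unordered size pairs in canonical order:
# regular-regular, regular-small, regular-tiny, small-small, small-tiny, tiny-tiny
_SIZE_PAIR_INDEX = {
    frozenset(["regular"]): 0,
    frozenset(["regular", "small"]): 1,
    frozenset(["regular", "tiny"]): 2,
    frozenset(["small"]): 3,
    frozenset(["small", "tiny"]): 4,
    frozenset(["tiny"]): 5,
}


def size_pair_index(size_a, size_b):
    """Index of the unordered size combination, 0-5."""
    for size in (size_a, size_b):
        if size not in SIZES:
            raise FingerprintError(f"unknown bead size '{size}'")
    return _SIZE_PAIR_INDEX[frozenset([size_a, size_b])]


def interaction_index(level, size_pair):
    """Bijection (level 0-19, size pair 0-5) -> 0-119 (level-major)."""
    if not 0 <= level < N_LEVELS:
        raise FingerprintError(f"interaction level {level} outside 0-19")
    if not 0 <= size_pair < N_SIZE_PAIRS:
        raise FingerprintError(f"size pair {size_pair} outside 0-5")
    return level * N_SIZE_PAIRS + size_pair


def bead_size(bead_type):
    """Size class from the Martini type-name convention (T.../S.../regular)."""
    if bead_type.startswith("T"):
        return "tiny"
    if bead_type.startswith("S"):
        return "small"
    return "regular"


@dataclass
class InteractionTable:
    """Symmetric (bead type, bead type) -> level lookup plus size classes."""
    level: dict                      # frozenset({a, b}) -> int
    size_of: dict                    # bead type -> size

    @classmethod
    def from_tsv(cls, path):
        frame = pd.read_csv(path, sep="\t", index_col=0, comment=";")
        return cls.from_frame(frame)

    @classmethod
    def from_frame(cls, frame):
        types = [str(t) for t in frame.index]
        if list(map(str, frame.columns)) != types:
            raise FingerprintError("interaction table must be a square matrix "
                                   "with identical row and column types")
        level = {}
        for a in types:
            for b in types:
                value = int(frame.loc[a, b])
                if not 0 <= value < N_LEVELS:
                    raise FingerprintError(
                        f"interaction level {value} for ({a}, {b}) outside 0-19")
                key = frozenset([a, b])
                if key in level and level[key] != value:
                    raise FingerprintError(
                        f"interaction matrix is not symmetric at ({a}, {b})")
                level[key] = value
        size_of = {t: bead_size(t) for t in types}
        return cls(level=level, size_of=size_of)

    def resolve_type(self, label):
        """Map a node label to a table bead type.

        Trailing capital letters disambiguate fragments sharing a bead type
        and are stripped until a known type is found.
        """
        candidate = label
        while candidate:
            if candidate in self.size_of:
                return candidate
            if candidate[-1].isupper() and len(candidate) > 1:
                candidate = candidate[:-1]
            else:
                break
        raise FingerprintError(f"bead type '{label}' not in interaction table")

    def lookup(self, label_a, label_b):
        a, b = self.resolve_type(label_a), self.resolve_type(label_b)
        return (self.level[frozenset([a, b])],
                size_pair_index(self.size_of[a], self.size_of[b]))


@dataclass
class FingerprintVector:
    counts: "np.ndarray"             # shape (2, 120)
    volume: float

    def as_array(self):
        return np.concatenate([self.counts.ravel(), [self.volume]])


def estimate_volume(atomic_graph):
    """Conformer-free van-der-Waals volume (A^3).

    Bond/ring-corrected additive scheme (Zhao, Abraham & Zissimos 2003):
    atomic contributions minus 5.92 per bond, 14.7 per aromatic ring and 3.8
    per nonaromatic ring (rings counted as a cycle basis).
    """
    volume = 0.0
    for _, data in atomic_graph.nodes(data=True):
        element = data.get("element")
        if element == "*":
            continue
        if element not in VDW_VOLUME:
            raise FingerprintError(f"no volume contribution for element '{element}'")
        volume += VDW_VOLUME[element]
    volume -= 5.92 * atomic_graph.number_of_edges()
    for cycle in nx.cycle_basis(atomic_graph):
        aromatic = all(atomic_graph.nodes[n].get("aromatic") for n in cycle)
        volume -= 14.7 if aromatic else 3.8
    return volume


def _bead_labels(cg_graph):
    return [data["label"] for _, data in cg_graph.nodes(data=True)
            if not data.get("is_wildcard")]


def martini_fingerprint(solute, solvents, table, *, atomic_graph=None,
                        volume=None, volume_fn=estimate_volume):
    """Count solute-solvent interaction types; returns a FingerprintVector.

    *solute* and each of the two *solvents* are coarse graphs whose node
    labels resolve to bead types in *table*.  The volume feature comes from
    *volume* if given, else from ``volume_fn(atomic_graph)``.
    """
    if len(solvents) != 2:
        raise FingerprintError("exactly two solvent graphs are required")
    counts = np.zeros((2, N_TYPES), dtype=int)
    solute_beads = _bead_labels(solute)
    for block, solvent in enumerate(solvents):
        for a in solute_beads:
            for b in _bead_labels(solvent):
                level, size_pair = table.lookup(a, b)
                counts[block, interaction_index(level, size_pair)] += 1
    if volume is None:
        if atomic_graph is None:
            raise FingerprintError("provide either volume= or atomic_graph=")
        volume = volume_fn(atomic_graph)
    return FingerprintVector(counts=counts, volume=float(volume))


# ---------------------------------------------------------------------------
# syntax-feature census

CENSUS_FEATURES = (
    "squash_operator",
    "virtual_edges",
    "linearized_rings",
    "charges",
    "weights",
    "chirality",
    "cis_trans",
    "split_aromaticity",
    "wildcard_select",
    "directed_descriptors",
    "descriptor_bond_orders",
)


def _graph_has(graph, predicate):
    return any(predicate(data) for _, data in graph.nodes(data=True))


def census_flags(layers):
    """Boolean feature detection for one parsed string (a LayerSpec)."""
    flags = dict.fromkeys(CENSUS_FEATURES, False)
    graphs = ([] if layers.base is None else [layers.base])
    descriptors = []
    fragment_graphs = []
    for fragments in layers.fragment_layers:
        for fragment in fragments.values():
            fragment_graphs.append(fragment)
            graphs.append(fragment.graph)
            descriptors.extend(fragment.descriptors)

    flags["squash_operator"] = any(d.kind == "!" for d in descriptors)
    flags["directed_descriptors"] = any(d.kind in "<>" for d in descriptors)
    flags["descriptor_bond_orders"] = any(d.bond_order > 1 for d in descriptors)
    for graph in graphs:
        for _, _, data in graph.edges(data=True):
            if data.get("order", 1) == 0:
                flags["virtual_edges"] = True
            if data.get("stereo"):
                flags["cis_trans"] = True
        for _, data in graph.nodes(data=True):
            annotations = data.get("annotations", {})
            if data.get("charge", 0) or annotations.get("q", 0):
                flags["charges"] = True
            if "weight" in data or "w" in annotations:
                flags["weights"] = True
            if data.get("chirality") or annotations.get("x"):
                flags["chirality"] = True
            if data.get("select") or annotations.get("s"):
                flags["wildcard_select"] = True
    # linearized rings: a coarse-level edge of order >= 2
    coarse_graphs = ([] if layers.base is None else [layers.base]) + \
        [f.graph for k, fragments in enumerate(layers.fragment_layers)
         for f in fragments.values() if layers.dialects[k] == "cg_graph"]
    for graph in coarse_graphs:
        if any(d.get("order", 1) >= 2 for _, _, d in graph.edges(data=True)):
            flags["linearized_rings"] = True
    # aromatic atoms split across fragments: an aromatic atom hosting a
    # descriptor can bond or merge with an aromatic atom of another fragment
    for fragment in fragment_graphs:
        for desc in fragment.descriptors:
            if fragment.graph.nodes[desc.host].get("aromatic"):
                flags["split_aromaticity"] = True
    return flags


def feature_census(library):
    """Per-molecule feature table for a library of parsed strings.

    *library* is an iterable of ``(name, LayerSpec)`` pairs; returns a
    DataFrame with one boolean column per feature plus a summary row access
    via ``frame.sum()``.
    """
    rows = []
    for name, layers in library:
        row = {"name": name}
        row.update(census_flags(layers))
        rows.append(row)
    return pd.DataFrame(rows).set_index("name")
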