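"""Random, guaranteed-resolvable strings for property tests.

The generator builds a random coarse tree (optionally with one ring-closure
edge, virtual particles, a higher-order edge, a squash edge or a directed
edge) and then constructs a matching fragment dictionary whose descriptors
are placed so that every coarse edge can be satisfied.  Two label regimes
exist: with a large fragment alphabet every node gets its own fragment and
every edge its own descriptor label (which makes resolution order-proof and
allows the squash/directed features); with a small alphabet labels are
reused and all descriptors are generic ``[$]``.
"""

import random
from dataclasses import dataclass

from . import graph as G
from .fragments import LayerSpec, Fragment, OPEN_SMILES
from .smiles import parse_atomic_fragment
from .writer import write_full

_BODIES = ("CCC", "CCO", "CCN", "CCCC", "COCC")


@dataclass
class FixtureSpec:
    n_strings: int = 100
    max_coarse_nodes: int = 8
    fragment_alphabet: int = 100         # >= max_coarse_nodes -> unique labels
    rings: bool = True
    branches: bool = True
    squash: bool = False
    virtual_edges: bool = False
    multi_order: bool = False
    directed: bool = False
    annotations: bool = True
    seed: int = 0


def _random_tree(rng, n, branches):
    edges = []
    degree = [0] * n
    for node in range(1, n):
        if branches:
            candidates = [p for p in range(node) if degree[p] < 4]
            parent = rng.choice(candidates)
        else:
            parent = node - 1
        edges.append([parent, node, 1])
        degree[parent] += 1
        degree[node] += 1
    return edges, degree


def generate_one(rng, spec):
    """One random (string, LayerSpec-equivalent) pair; returns the string."""
    n = rng.randint(2, spec.max_coarse_nodes)
    edges, degree = _random_tree(rng, n, spec.branches)

    if spec.rings and n >= 4 and rng.random() < 0.5:
        pairs = [(a, b) for a in range(n) for b in range(a + 1, n)
                 if degree[a] < 4 and degree[b] < 4
                 and not any({e[0], e[1]} == {a, b} for e in edges)]
        if pairs:
            a, b = pairs[rng.randrange(len(pairs))]
            edges.append([a, b, 1])
            degree[a] += 1
            degree[b] += 1

    if spec.multi_order and rng.random() < 0.5:
        edge = edges[rng.randrange(len(edges))]
        edge[2] = 2

    unique = spec.fragment_alphabet >= n
    special = {}                       # edge idx -> ('squash'|'directed')
    if unique:
        simple = [i for i, e in enumerate(edges) if e[2] == 1]
        if spec.squash and simple and rng.random() < 0.7:
            simple_idx = simple.pop(rng.randrange(len(simple)))
            special[simple_idx] = "squash"
        if spec.directed and simple and rng.random() < 0.7:
            special[simple.pop(rng.randrange(len(simple)))] = "directed"

    graph = G.new_graph()
    for node in range(n):
        label = f"F{node}" if unique else f"F{node % spec.fragment_alphabet}"
        annotations = {}
        if spec.annotations and rng.random() < 0.2:
            annotations["q"] = rng.choice([-1, 1])
        if spec.annotations and rng.random() < 0.2:
            annotations["w"] = 1.5
        G.add_node(graph, label=label, is_wildcard=False, annotations=annotations)
    for a, b, order in edges:
        G.add_edge(graph, a, b, order=order)

    n_virtual = 0
    if spec.virtual_edges and rng.random() < 0.5:
        virtual = G.add_node(graph, label="V0", is_wildcard=False, annotations={})
        for anchor in rng.sample(range(n), rng.randint(1, min(2, n))):
            G.add_edge(graph, virtual, anchor, order=0)
        n_virtual = 1

    # descriptor requirements per node: (label, order) per incident edge slot
    need = {node: [] for node in range(n)}
    for idx, (a, b, order) in enumerate(edges):
        kind = special.get(idx)
        label = f"e{idx}" if unique else ""
        for _ in range(order):
            if kind == "squash":
                need[a].append(("!", label))
                need[b].append(("!", label))
            elif kind == "directed":
                need[a].append((">", label))
                need[b].append(("<", label))
            else:
                need[a].append(("$", label))
                need[b].append(("$", label))

    fragments = {}
    for node in range(n):
        label = graph.nodes[node]["label"]
        slots = need[node]
        if label in fragments and not unique:
            # shared fragment: keep the larger requirement
            if len(fragments[label][1]) >= len(slots):
                continue
        body = _BODIES[rng.randrange(len(_BODIES))]
        fragments[label] = (body, slots)

    entries = []
    valences = {"C": 4, "O": 2, "N": 3}
    for label in sorted(fragments):
        body, slots = fragments[label]
        atoms = list(body)
        per_atom = [[] for _ in atoms]
        free = []
        for i, atom in enumerate(atoms):
            intra = (1 if i > 0 else 0) + (1 if i < len(atoms) - 1 else 0)
            free.extend([i] * (valences[atom] - intra))
        assert len(free) >= len(slots), "fixture body too small"
        # squash hosts must merge onto a matching element: pin them to carbons
        squash_slots = [s for s in slots if s[0] == "!"]
        other_slots = [s for s in slots if s[0] != "!"]
        for slot in squash_slots:
            position = next(i for i in free if atoms[i] == "C")
            free.remove(position)
            per_atom[position].append(slot)
        for slot, position in zip(other_slots, free):
            per_atom[position].append(slot)
        text = ""
        for atom, descs in zip(atoms, per_atom):
            text += atom
            for kind, dlabel in descs:
                text += f"[{kind}{dlabel}]"
        entries.append(f"#{label}={text}")

    string = "{" + _write_coarse(graph) + "}.{" + ",".join(entries) + "}"
    return string


def _write_coarse(graph):
    from .writer import write_cg_graph
    return write_cg_graph(graph)


def generate_fixtures(spec):
    """Generate ``spec.n_strings`` random strings (deterministic per seed)."""
    rng = random.Random(spec.seed)
    return [generate_one(rng, spec) for _ in range(spec.n_strings)]


def random_smiles(rng, max_atoms=12, ring_prob=0.3):
    """Compose one random valid non-aromatic SMILES string token by token.

    Built directly from the grammar with valence bookkeeping (not through the
    package's own writer), so it can feed oracle comparisons against an
    external toolkit.  Covers chains, branches, double/triple bonds and at
    most one ring.
    """
    valence = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1}
    pool = ["C", "C", "C", "C", "N", "O", "O", "S", "F", "Cl"]
    bond_symbol = {1: "", 2: "=", 3: "#"}
    out = []
    parent = {}
    state = {"n": 0, "budget": rng.randint(3, max_atoms),
             "opener": None, "ring_done": False}

    def emit_atom(min_valence, parent_id):
        candidates = [e for e in pool if valence[e] >= min_valence]
        element = rng.choice(candidates)
        out.append(element)
        atom_id = state["n"]
        state["n"] += 1
        parent[atom_id] = parent_id
        return atom_id, valence[element]

    def maybe_ring(atom_id, free):
        if state["opener"] is None and not state["ring_done"] and free >= 2 \
                and state["budget"] - state["n"] >= 3 and rng.random() < ring_prob:
            out.append("1")
            state["opener"] = atom_id
            return 1
        opener = state["opener"]
        # close only on a non-adjacent atom (parent is not the opener)
        if opener is not None and atom_id != opener \
                and parent.get(atom_id) != opener and free >= 1 \
                and rng.random() < 0.5:
            out.append("1")
            state.update(opener=None, ring_done=True)
            return 1
        return 0

    def pick_bond(free):
        bond = 1
        if free >= 2 and rng.random() < 0.2:
            bond = 2
        if free >= 3 and rng.random() < 0.05:
            bond = 3
        return bond

    def grow(atom_id, free):
        free -= maybe_ring(atom_id, free)
        while free > 0 and state["n"] < state["budget"]:
            bond = pick_bond(free)
            if free - bond >= 1 and state["n"] < state["budget"] - 1 \
                    and rng.random() < 0.3:
                out.append("(")
                out.append(bond_symbol[bond])
                child, child_valence = emit_atom(bond, atom_id)
                grow(child, child_valence - bond)
                out.append(")")
                free -= bond
            else:
                out.append(bond_symbol[bond])
                child, child_valence = emit_atom(bond, atom_id)
                grow(child, child_valence - bond)
                return

    root, root_valence = emit_atom(1, None)
    grow(root, root_valence)
    if state["opener"] is not None:  # never closed: drop the dangling marker
        out.remove("1")
    return "".join(out)
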