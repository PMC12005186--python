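"""Resolution of coarse graphs into finer ones.

For every non-virtual coarse node one fragment copy is instantiated; for
every coarse edge of order *n* >= 1 exactly *n* descriptor pairs are matched
and consumed between the two copies.  Matching walks coarse edges in the
order they appear in the string and, within a pair of fragment copies, scans
fragment nodes in written order and each node's descriptors in written order,
taking the first compatible unconsumed pair.  This first-match strategy makes
some strings sensitive to edge order — see :func:`permute_edges` and the
validator in the CLI.

Matched ``!`` (squash) descriptors merge their host atoms into one atom that
belongs to both parent beads.  Order-0 (virtual) edges never produce fine
edges, and a node whose edges are all virtual has no finer-resolution image.
"""

import itertools
import logging
from dataclasses import dataclass, field, replace

from . import graph as G
from .aromaticity import normalize_aromaticity
from .descriptors import scan_order
from .errors import ResolutionError, WildcardError
from .fragments import CG_GRAPH, OPEN_SMILES, LayerSpec, parse_cgsmiles
from .hydrogens import complete_hydrogens

LOGGER = logging.getLogger(__name__)


@dataclass
class ResolutionLayer:
    """One refinement step: a coarse graph and its finer image."""
    coarse: "object"
    fine: "object"
    membership: dict                 # fine node -> {coarse node: weight}
    consumed: list = field(default_factory=list)   # descriptor-consumption ledger
    pruned: list = field(default_factory=list)     # virtual nodes with no image
    merges: int = 0
    leftover: list = field(default_factory=list)   # unconsumed descriptors


@dataclass
class ResolvedMolecule:
    """All refinement layers of one string, coarsest first."""
    layers: list
    base: "object"

    @property
    def molecule(self):
        """The finest-resolution graph."""
        return self.layers[-1].fine if self.layers else self.base

    def graphs(self):
        """Per resolution, the (coarser, finer) graph pair."""
        return [(layer.coarse, layer.fine) for layer in self.layers]


def virtual_nodes(coarse):
    """Nodes whose incident edges are all order 0 (and that have edges)."""
    out = []
    for node in coarse.nodes:
        edges = list(coarse.edges(node, data=True))
        if edges and all(d.get("order", 1) == 0 for _, _, d in edges):
            out.append(node)
    return out


def _instantiate(fine, fragment, coarse_node, membership):
    """Copy a fragment into *fine*; returns its descriptor copies."""
    mapping = {}
    for old in fragment.graph.nodes:
        data = dict(fragment.graph.nodes[old])
        if "annotations" in data:
            data["annotations"] = dict(data["annotations"])
        if data.get("select") is not None:
            data["select"] = list(data["select"])
        data["fragment"] = fragment.name
        mapping[old] = G.add_node(fine, **data)
        membership.setdefault(mapping[old], {})[coarse_node] = \
            G.node_weight(fragment.graph, old)
    for u, v, data in G.ordered_edges(fragment.graph, data=True):
        attrs = {k: v2 for k, v2 in data.items() if k not in ("index", "written")}
        if "stereo_from" in attrs:
            attrs["stereo_from"] = mapping[attrs["stereo_from"]]
        order = attrs.pop("order", 1)
        G.add_edge(fine, mapping[u], mapping[v], order=order,
                   written=(mapping[u], mapping[v]), **attrs)
    return [replace(d, host=mapping[d.host], consumed=False)
            for d in fragment.descriptors]


def _merge_atoms(fine, keep, drop, membership, descs_by_coarse):
    """Squash-merge *drop* into *keep*."""
    a, b = fine.nodes[keep], fine.nodes[drop]
    kind_a = a.get("element", a.get("label"))
    kind_b = b.get("element", b.get("label"))
    if kind_a != kind_b or a.get("aromatic", False) != b.get("aromatic", False):
        raise ResolutionError(
            f"cannot squash-merge mismatched atoms {keep} and {drop} "
            f"({kind_a}, aromatic={a.get('aromatic', False)} vs "
            f"{kind_b}, aromatic={b.get('aromatic', False)})")
    for key in ("charge", "hcount", "chirality", "isotope"):
        if key in a and key in b and a[key] != b[key]:
            raise ResolutionError(
                f"conflicting '{key}' on squash-merged atoms {keep}/{drop}")
        if key in b:
            a.setdefault(key, b[key])
    if "weight" in a or "weight" in b:
        a["weight"] = max(a.get("weight", 1.0), b.get("weight", 1.0))
    for neighbor in list(fine.neighbors(drop)):
        data = dict(fine[drop][neighbor])
        if fine.has_edge(keep, neighbor):
            LOGGER.warning("parallel bond after squash merge; keeping max order")
            fine[keep][neighbor]["order"] = max(
                fine[keep][neighbor].get("order", 1), data.get("order", 1))
        else:
            if data.get("stereo_from") == drop:
                data["stereo_from"] = keep
            if "written" in data:
                data["written"] = tuple(keep if x == drop else x
                                        for x in data["written"])
            fine.add_edge(keep, neighbor, **data)
    membership.setdefault(keep, {}).update(membership.pop(drop, {}))
    for descs in descs_by_coarse.values():
        for desc in descs:
            if desc.host == drop:
                desc.host = keep
    fine.remove_node(drop)


def resolve_layer(coarse, fragments, dialect=OPEN_SMILES):
    """Refine *coarse* by one level using the given fragment dictionary."""
    fine = G.new_graph()
    membership = {}
    pruned = virtual_nodes(coarse)
    skip = set(pruned)
    descs_by_coarse = {}
    for node in coarse.nodes:
        if node in skip:
            continue
        data = coarse.nodes[node]
        if data.get("is_wildcard"):
            raise WildcardError(
                f"coarse node {node} is an unresolved wildcard; "
                "use MoleculeResolver.enumerate_variants()")
        label = data.get("label")
        if label not in fragments:
            raise ResolutionError(f"no fragment named '{label}' for coarse node {node}")
        descs_by_coarse[node] = _instantiate(fine, fragments[label], node, membership)

    consumed_ledger = []
    merges = 0
    for u, v, data in G.ordered_edges(coarse, data=True):
        order = data.get("order", 1)
        if order == 0 or u in skip or v in skip:
            continue
        first, second = data.get("written", (u, v))
        for repeat in range(order):
            match = None
            for desc_a in scan_order(descs_by_coarse[first]):
                if desc_a.consumed:
                    continue
                for desc_b in scan_order(descs_by_coarse[second]):
                    if desc_b.consumed or not desc_a.compatible(desc_b):
                        continue
                    match = (desc_a, desc_b)
                    break
                if match:
                    break
            if match is None:
                remaining_a = [d.to_string() for d in descs_by_coarse[first]
                               if not d.consumed]
                remaining_b = [d.to_string() for d in descs_by_coarse[second]
                               if not d.consumed]
                raise ResolutionError(
                    f"no compatible descriptor pair for coarse edge ({first}, {second}) "
                    f"match {repeat + 1}/{order}: "
                    f"'{coarse.nodes[first].get('label')}' offers {remaining_a}, "
                    f"'{coarse.nodes[second].get('label')}' offers {remaining_b}")
            desc_a, desc_b = match
            desc_a.consumed = desc_b.consumed = True
            if desc_a.kind == "!":
                _merge_atoms(fine, desc_a.host, desc_b.host, membership, descs_by_coarse)
                merges += 1
                consumed_ledger.append(
                    dict(coarse_edge=(first, second), kind="squash",
                         descriptors=(desc_a.to_string(), desc_b.to_string()),
                         atom=desc_a.host))
            else:
                aromatic = (desc_a.bond_order == 1
                            and fine.nodes[desc_a.host].get("aromatic", False)
                            and fine.nodes[desc_b.host].get("aromatic", False))
                G.add_edge(fine, desc_a.host, desc_b.host,
                           order=desc_a.bond_order, aromatic=aromatic)
                consumed_ledger.append(
                    dict(coarse_edge=(first, second), kind="bond",
                         descriptors=(desc_a.to_string(), desc_b.to_string()),
                         fine_edge=(desc_a.host, desc_b.host),
                         order=desc_a.bond_order))

    leftover = [d for descs in descs_by_coarse.values() for d in descs
                if not d.consumed]
    return ResolutionLayer(coarse=coarse, fine=fine, membership=membership,
                           consumed=consumed_ledger, pruned=pruned,
                           merges=merges, leftover=leftover)


def _validate_stereo(molecule):
    for u, v, data in molecule.edges(data=True):
        if data.get("stereo"):
            near_double = any(
                molecule[x][nbr].get("order", 1) == 2
                for x in (u, v) for nbr in molecule.neighbors(x))
            if not near_double:
                raise ResolutionError(
                    f"cis/trans mark on bond ({u}, {v}) is not adjacent to a double bond")
    for node, data in molecule.nodes(data=True):
        if data.get("chirality"):
            # hydrogens are interchangeable: collapse them to one neighbor
            neighbors = list(molecule.neighbors(node))
            distinct = len([n for n in neighbors
                            if molecule.nodes[n].get("element") != "H"])
            if any(molecule.nodes[n].get("element") == "H" for n in neighbors):
                distinct += 1
            if distinct < 3:
                raise ResolutionError(
                    f"atom {node} is annotated chiral but has fewer than 3 "
                    "distinct neighbors")


def resolve_all(layers, *, validate=True):
    """Resolve every layer; returns a :class:`ResolvedMolecule`.

    Hydrogen completion and aromaticity normalization run only on the final
    layer and only if it is atomic.
    """
    if layers.base is None:
        raise ResolutionError(
            "string has no base graph; use MoleculeSampler for fragment-only strings")
    _reject_selections(layers)
    current = layers.base
    done = []
    for k, (fragments, dialect) in enumerate(
            zip(layers.fragment_layers, layers.dialects)):
        try:
            layer = resolve_layer(current, fragments, dialect)
        except ResolutionError as err:
            raise ResolutionError(f"layer {k + 1}: {err}") from None
        done.append(layer)
        current = layer.fine
    if done and layers.dialects[-1] == OPEN_SMILES:
        molecule = done[-1].fine
        normalize_aromaticity(molecule)
        for heavy, hydrogen in complete_hydrogens(molecule, done[-1].leftover):
            done[-1].membership[hydrogen] = dict(done[-1].membership.get(heavy, {}))
        if validate:
            _validate_stereo(molecule)
    return ResolvedMolecule(layers=done, base=layers.base)


# ---------------------------------------------------------------------------
# wildcard / selection handling

def _selection_points(layers):
    points = []
    if layers.base is not None:
        for node, data in layers.base.nodes(data=True):
            if data.get("is_wildcard"):
                tokens = data.get("annotations", {}).get("s")
                if not tokens:
                    raise WildcardError(f"wildcard node {node} has no selection list")
                points.append(("base", None, None, node, tokens))
    for k, fragments in enumerate(layers.fragment_layers):
        for name, fragment in fragments.items():
            for node, data in fragment.graph.nodes(data=True):
                if data.get("element") == "*" and "select" in data:
                    tokens = data["select"]
                    if not tokens or tokens == [""]:
                        raise WildcardError(
                            f"wildcard atom {node} in '{name}' has an empty selection")
                    points.append(("fragment", k, name, node, tokens))
                elif data.get("is_wildcard"):
                    tokens = data.get("annotations", {}).get("s")
                    if not tokens:
                        raise WildcardError(
                            f"wildcard node {node} in '{name}' has no selection list")
                    points.append(("fragment", k, name, node, tokens))
    return points


def _reject_selections(layers):
    if _selection_points(layers):
        raise WildcardError(
            "string contains selection wildcards; "
            "use enumerate_variants() or variant(index)")


def copy_layers(layers):
    base = G.copy_graph(layers.base) if layers.base is not None else None
    fragment_layers = []
    for fragments in layers.fragment_layers:
        fragment_layers.append({
            name: replace(frag, graph=G.copy_graph(frag.graph),
                          descriptors=[replace(d) for d in frag.descriptors])
            for name, frag in fragments.items()})
    return LayerSpec(base=base, fragment_layers=fragment_layers,
                     dialects=list(layers.dialects))


def _contract_node(graph, node, descriptors=None):
    """Remove *node*; reconnect its (at most two) neighbors."""
    neighbors = G.ordered_neighbors(graph, node)
    if len(neighbors) > 2:
        raise WildcardError(
            f"cannot delete wildcard {node}: more than two neighbors")
    if len(neighbors) == 2:
        a, b = neighbors
        if not graph.has_edge(a, b):
            order = max(graph[node][a].get("order", 1),
                        graph[node][b].get("order", 1))
            index = min(graph[node][a].get("index", 0),
                        graph[node][b].get("index", 0))
            graph.add_edge(a, b, order=order, index=index, written=(a, b))
    if descriptors is not None:
        descriptors[:] = [d for d in descriptors if d.host != node]
    graph.remove_node(node)


def _apply_choice(layers, point, token):
    where, k, name, node, _ = point
    if where == "base":
        graph, descriptors = layers.base, None
    else:
        fragment = layers.fragment_layers[k][name]
        graph, descriptors = fragment.graph, fragment.descriptors
    if token == "0":
        _contract_node(graph, node, descriptors)
        return
    data = graph.nodes[node]
    if where == "base" or "label" in data:
        data["label"] = token
        data["is_wildcard"] = False
        data.get("annotations", {}).pop("s", None)
    else:
        data["element"] = token.capitalize()
        data["aromatic"] = token[0].islower()
        data.pop("select", None)


def enumerate_variants(layers, *, validate=True, limit=None):
    """Yield every concrete molecule over the Cartesian product of selections.

    Selection token ``"0"`` deletes the wildcard and contracts its bonds.
    The same fragment-level choice applies to every copy of that fragment.
    """
    points = _selection_points(layers)
    if not points:
        yield resolve_all(layers, validate=validate)
        return
    produced = 0
    for combo in itertools.product(*(tokens for *_, tokens in points)):
        if limit is not None and produced >= limit:
            return
        work = copy_layers(layers)
        for point, token in zip(points, combo):
            _apply_choice(work, point, token)
        yield resolve_all(work, validate=validate)
        produced += 1


class MoleculeResolver:
    """Resolve a multi-resolution string into its stack of graphs.

    Parameters
    ----------
    source:
        A full string, or an already-parsed :class:`LayerSpec`.
    last_dialect:
        Dialect of the final fragment layer (``"open_smiles"`` by default,
        ``"cg_graph"`` for purely coarse stacks).
    """

    def __init__(self, source, *, last_dialect=OPEN_SMILES):
        if isinstance(source, LayerSpec):
            self.layers = source
        else:
            self.layers = parse_cgsmiles(source, last_dialect=last_dialect)

    def resolve(self, *, validate=True):
        return resolve_all(self.layers, validate=validate)

    def enumerate_variants(self, *, validate=True, limit=None):
        return enumerate_variants(self.layers, validate=validate, limit=limit)

    def variant(self, index, *, validate=True):
        for i, resolved in enumerate(self.enumerate_variants(validate=validate)):
            if i == index:
                return resolved
        raise WildcardError(f"variant index {index} out of range")


def permute_edges(coarse, permutation):
    """Copy of *coarse* with edge insertion order replaced by *permutation*.

    *permutation* is a sequence over ``range(n_edges)`` giving the new rank of
    each edge (in current order).  Used to probe edge-order sensitivity.
    """
    edges = G.ordered_edges(coarse, data=True)
    if sorted(permutation) != list(range(len(edges))):
        raise ValueError("not a permutation of the edge indices")
    out = G.copy_graph(coarse)
    for (u, v, _), rank in zip(edges, permutation):
        out[u][v]["index"] = rank
    return out


def resolve(text, *, last_dialect=OPEN_SMILES, validate=True):
    """Convenience one-shot: parse and resolve *text*."""
    return MoleculeResolver(text, last_dialect=last_dialect).resolve(validate=validate)
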