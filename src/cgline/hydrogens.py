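"""Hydrogen completion on the fully assembled atomic graph.

Hydrogens are assigned only once the whole molecule is connected: first,
every bonding descriptor left unconsumed becomes one hydrogen on its host
atom where the element's valence allows it; then atoms without an explicit
``H`` count are filled to the smallest standard valence (OpenSMILES organic
subset rules).  Explicitly written hydrogens (e.g. weight-annotated ones)
are left untouched, as are wildcards and charged atoms without an explicit
count.  Over-valent atoms receive no hydrogens and a warning is logged.
"""

import logging

from . import graph as G
from .descriptors import scan_order
from .elements import DEFAULT_VALENCES, implicit_hydrogens

LOGGER = logging.getLogger(__name__)


def _bond_order_sum(graph, node):
    return sum(d.get("order", 1) for _, _, d in graph.edges(node, data=True))


def complete_hydrogens(graph, leftover_descriptors=()):
    """Add explicit hydrogen atoms in place.

    Returns a list of ``(heavy_atom, hydrogen)`` pairs so callers can extend
    membership maps (hydrogens inherit their heavy neighbor's beads).
    """
    if graph.graph.get("_h_complete"):
        return []
    added = []

    def add_hydrogen(heavy):
        hydrogen = G.add_node(graph, element="H", aromatic=False)
        G.add_edge(graph, heavy, hydrogen, order=1)
        added.append((heavy, hydrogen))

    # unconsumed bonding descriptors become hydrogens where applicable
    for desc in scan_order([d for d in leftover_descriptors if not d.consumed]):
        host = desc.host
        if host is None or host not in graph:
            continue
        data = graph.nodes[host]
        element = data.get("element")
        valences = DEFAULT_VALENCES.get(element)
        if not valences:
            LOGGER.warning("unconsumed descriptor %s on %s atom ignored",
                           desc.to_string(), element)
            continue
        occupied = _bond_order_sum(graph, host) + data.get("hcount", 0)
        if occupied + 1 <= max(valences):
            add_hydrogen(host)
        else:
            LOGGER.warning("no room for a hydrogen from descriptor %s on atom %s",
                           desc.to_string(), host)

    # standard-valence completion
    for node in list(graph.nodes):
        data = graph.nodes[node]
        element = data.get("element")
        if element in (None, "H", "*"):
            continue
        if "hcount" in data:
            count = data["hcount"]
        elif data.get("charge", 0) != 0:
            continue
        else:
            count = implicit_hydrogens(element, _bond_order_sum(graph, node))
            if count == 0 and _bond_order_sum(graph, node) > max(
                    DEFAULT_VALENCES.get(element, (0,))):
                LOGGER.warning("atom %s (%s) exceeds its standard valence",
                               node, element)
        for _ in range(count):
            add_hydrogen(node)
    graph.graph["_h_complete"] = True
    return added
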