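"""Parser for the coarse-graph dialect.

The dialect adapts SMILES to arbitrary graphs: bracketed nodes
(``[#label;annotations]``), linear chaining, parenthesised branches,
ring-closure markers (``%`` consumes *all* following digits), bond-order
symbols ``. - = # $`` for orders 0-4, a multiplication operator ``|n`` and
key-value annotations.  Edge order of first appearance is preserved because
descriptor matching during resolution walks edges in that order.
"""

import re

from . import graph as G
from .descriptors import BondingDescriptor, KINDS, parse_descriptor_token
from .errors import ParseError

BOND_ORDERS = {".": 0, "-": 1, "=": 2, "#": 3, "$": 4}
ORDER_SYMBOLS = {0: ".", 1: "", 2: "=", 3: "#", 4: "$"}

_LABEL_RE = re.compile(r"^[A-Za-z0-9]+$")
_NUMBER_RE = re.compile(r"^[+-]?\d+(\.\d+)?$")

# token types
NODE, DESCRIPTOR, BOND, RING, OPEN, CLOSE, MULTIPLY = (
    "NODE", "DESCRIPTOR", "BOND", "RING", "OPEN", "CLOSE", "MULTIPLY")


def tokenize(text):
    """Split coarse-dialect *text* into (type, value, position) triples."""
    tokens = []
    i, n = 0, len(text)
    while i < n:
        char = text[i]
        if char.isspace():
            raise ParseError("whitespace is not allowed inside a resolution block",
                             position=i, text=text)
        if char == "[":
            end = text.find("]", i)
            if end < 0:
                raise ParseError("unbalanced square bracket", position=i, text=text)
            body = text[i + 1:end]
            if not body:
                raise ParseError("empty bracket", position=i, text=text)
            if body[0] in KINDS:
                tokens.append((DESCRIPTOR, body, i))
            elif body[0] == "#" or body[0] == "*":
                tokens.append((NODE, body, i))
            else:
                raise ParseError(f"expected '#', '*' or a bonding descriptor, got '[{body}]'",
                                 position=i, text=text)
            i = end + 1
        elif char in BOND_ORDERS:
            tokens.append((BOND, char, i))
            i += 1
        elif char == "(":
            tokens.append((OPEN, char, i))
            i += 1
        elif char == ")":
            tokens.append((CLOSE, char, i))
            i += 1
        elif char.isdigit():
            tokens.append((RING, int(char), i))
            i += 1
        elif char == "%":
            j = i + 1
            while j < n and text[j].isdigit():
                j += 1
            if j == i + 1:
                raise ParseError("'%' must be followed by digits", position=i, text=text)
            tokens.append((RING, int(text[i + 1:j]), i))
            i = j
        elif char == "|":
            j = i + 1
            while j < n and text[j].isdigit():
                j += 1
            if j == i + 1:
                raise ParseError("'|' must be followed by an integer factor",
                                 position=i, text=text)
            tokens.append((MULTIPLY, int(text[i + 1:j]), i))
            i = j
        else:
            raise ParseError(f"unexpected character '{char}'", position=i, text=text)
    return tokens


def parse_number(value, pos, text):
    if not _NUMBER_RE.match(value):
        raise ParseError(f"expected a number, got '{value}'", position=pos, text=text)
    num = float(value)
    return int(num) if num.is_integer() else num


def parse_annotations(parts, positional_keys, pos, text):
    """Parse ``;``-separated annotation strings into a dict.

    *positional_keys* gives the convention for unkeyed values: (q, w) on
    coarse nodes, (w, x) on atoms.  A value may not contain '=' or ';'.
    """
    annotations = {}
    slot = 0
    for part in parts:
        if not part:
            raise ParseError("empty annotation", position=pos, text=text)
        if "=" in part:
            key, _, value = part.partition("=")
            if "=" in value:
                raise ParseError("annotation values may not contain '='",
                                 position=pos, text=text)
        else:
            while slot < len(positional_keys) and positional_keys[slot] in annotations:
                slot += 1
            if slot >= len(positional_keys):
                raise ParseError(
                    f"too many positional annotations (convention is {positional_keys})",
                    position=pos, text=text)
            key, value = positional_keys[slot], part
            slot += 1
        if not key or not value:
            raise ParseError(f"malformed annotation '{part}'", position=pos, text=text)
        if key in annotations:
            raise ParseError(f"duplicate annotation key '{key}'", position=pos, text=text)
        if key == "q":
            annotations[key] = parse_number(value, pos, text)
        elif key == "w":
            number = parse_number(value, pos, text)
            if number < 0:
                raise ParseError("weights must be non-negative", position=pos, text=text)
            annotations[key] = number
        elif key == "x":
            if value not in ("R", "S"):
                raise ParseError("chirality must be 'R' or 'S'", position=pos, text=text)
            annotations[key] = value
        elif key == "s":
            annotations[key] = value.split(",")
        else:
            annotations[key] = value
    return annotations


def _parse_node_body(body, pos, text):
    """Content of a ``[...]`` node bracket -> (label, is_wildcard, annotations)."""
    parts = body.split(";")
    head = parts[0]
    if head == "*":
        label, wildcard = "", True
    elif head.startswith("#"):
        label, wildcard = head[1:], False
        if not _LABEL_RE.match(label):
            raise ParseError(f"invalid node label '{label}'", position=pos, text=text)
    else:  # pragma: no cover - tokenizer already filtered
        raise ParseError(f"invalid node '{body}'", position=pos, text=text)
    annotations = parse_annotations(parts[1:], ("q", "w"), pos, text)
    if "s" in annotations and not wildcard:
        raise ParseError("selection annotations are only valid on wildcards",
                         position=pos, text=text)
    return label, wildcard, annotations


class _Branch:
    __slots__ = ("anchor", "nodes")

    def __init__(self, anchor):
        self.anchor = anchor
        self.nodes = []


def parse_cg_graph(text, *, allow_descriptors=False, max_multiplication=10 ** 6):
    """Parse coarse-dialect *text* into a molecule graph.

    Returns the graph, or ``(graph, descriptors)`` when *allow_descriptors*
    is set (used for fragment bodies written in the coarse dialect).
    """
    tokens = tokenize(text)
    graph = G.new_graph()
    anchor = None
    pending_order = None
    just_opened = True            # at string start descriptors attach forward
    forward_descs = []
    descriptors = []
    open_markers = {}             # marker -> FIFO of (node, pending order)
    inbound_order = {}            # node -> order of its chain edge
    open_on_node = {}             # node -> set of its open ring markers
    branch_stack = []
    last_entity = None            # ('node', id) | ('branch', (...)) | None

    def make_edge(u, v, order, pos):
        if u == v:
            raise ParseError("self-loops are not allowed", position=pos, text=text)
        if graph.has_edge(u, v):
            raise ParseError(
                "duplicate edge; use a bond order to express multiple connections",
                position=pos, text=text)
        G.add_edge(graph, u, v, order=order)

    for ttype, value, pos in tokens:
        if ttype == NODE:
            label, wildcard, annotations = _parse_node_body(value, pos, text)
            node = G.add_node(graph, label=label, is_wildcard=wildcard,
                              annotations=annotations)
            for desc in forward_descs:
                desc.host = node
                descriptors.append(desc)
            forward_descs = []
            if anchor is not None:
                order = 1 if pending_order is None else pending_order
                make_edge(anchor, node, order, pos)
                inbound_order[node] = order
            pending_order = None
            for branch in branch_stack:
                branch.nodes.append(node)
            anchor = node
            just_opened = False
            last_entity = ("node", node)
        elif ttype == DESCRIPTOR:
            if not allow_descriptors:
                raise ParseError("bonding descriptors are not allowed in a base graph",
                                 position=pos, text=text)
            try:
                desc = parse_descriptor_token(value, position=len(descriptors) + len(forward_descs))
            except ValueError as err:
                raise ParseError(str(err), position=pos, text=text) from None
            if anchor is None:
                desc.prefix = True
                if pending_order is not None:
                    desc.bond_order = pending_order
                    pending_order = None
                forward_descs.append(desc)
            else:
                desc.host = anchor
                if pending_order is not None:
                    desc.bond_order = pending_order
                    pending_order = None
                descriptors.append(desc)
            last_entity = None
        elif ttype == BOND:
            if pending_order is not None:
                raise ParseError("two consecutive bond symbols", position=pos, text=text)
            if forward_descs and anchor is None:
                forward_descs[-1].bond_order = BOND_ORDERS[value]
            else:
                pending_order = BOND_ORDERS[value]
            last_entity = None
        elif ttype == RING:
            if anchor is None:
                raise ParseError("ring marker before any node", position=pos, text=text)
            # a marker only closes against a NONconsecutive node; against an
            # adjacent one it opens in parallel (allows immediate reuse)
            queue = open_markers.setdefault(value, [])
            partner = next((entry for entry in queue
                            if entry[0] != anchor
                            and not graph.has_edge(entry[0], anchor)), None)
            if partner is not None:
                queue.remove(partner)
                if not queue:
                    del open_markers[value]
                other, other_order = partner
                open_on_node[other].discard(value)
                if other_order is not None and pending_order is not None \
                        and other_order != pending_order:
                    raise ParseError(
                        f"conflicting bond orders on ring marker {value}",
                        position=pos, text=text)
                order = pending_order if pending_order is not None else other_order
                make_edge(other, anchor, 1 if order is None else order, pos)
            else:
                queue.append((anchor, pending_order))
                open_on_node.setdefault(anchor, set()).add(value)
            pending_order = None
        elif ttype == OPEN:
            if anchor is None:
                raise ParseError("branch before any node", position=pos, text=text)
            if pending_order is not None:
                raise ParseError("bond symbol may not precede '('", position=pos, text=text)
            branch_stack.append(_Branch(anchor))
            just_opened = True
            last_entity = None
        elif ttype == CLOSE:
            if not branch_stack:
                raise ParseError("unmatched ')'", position=pos, text=text)
            if pending_order is not None:
                raise ParseError("dangling bond symbol before ')'", position=pos, text=text)
            branch = branch_stack.pop()
            anchor = branch.anchor
            just_opened = False
            last_entity = ("branch", branch)
        elif ttype == MULTIPLY:
            if value < 1:
                raise ParseError("multiplication factor must be >= 1", position=pos, text=text)
            if value > max_multiplication:
                raise ParseError(
                    f"multiplication factor {value} exceeds the limit {max_multiplication}",
                    position=pos, text=text)
            if last_entity is None:
                raise ParseError("'|' must follow a node or a closed branch",
                                 position=pos, text=text)
            kind, payload = last_entity
            if kind == "node":
                node = payload
                if open_on_node.get(node):
                    raise ParseError("cannot multiply a node with an open ring marker",
                                     position=pos, text=text)
                order = inbound_order.get(node, 1)
                previous = node
                data = dict(graph.nodes[node])
                for _ in range(value - 1):
                    clone = G.add_node(graph, **{**data,
                                                 "annotations": dict(data["annotations"])})
                    make_edge(previous, clone, order, pos)
                    inbound_order[clone] = order
                    for branch in branch_stack:
                        branch.nodes.append(clone)
                    previous = clone
                anchor = previous
            else:
                branch = payload
                unit = [branch.anchor] + branch.nodes
                for entries in open_markers.values():
                    if any(host in branch.nodes for host, _ in entries):
                        raise ParseError(
                            "cannot multiply a branch with an open ring marker",
                            position=pos, text=text)
                order = inbound_order.get(branch.anchor, 1)
                previous_bp = branch.anchor
                unit_edges = [(u, v, d) for u, v, d in graph.edges(unit, data=True)
                              if u in unit and v in unit]
                for _ in range(value - 1):
                    mapping = {}
                    for old in unit:
                        data = dict(graph.nodes[old])
                        mapping[old] = G.add_node(
                            graph, **{**data, "annotations": dict(data["annotations"])})
                        for b in branch_stack:
                            b.nodes.append(mapping[old])
                    for u, v, d in unit_edges:
                        G.add_edge(graph, mapping[u], mapping[v], order=d.get("order", 1))
                    make_edge(previous_bp, mapping[branch.anchor], order, pos)
                    inbound_order[mapping[branch.anchor]] = order
                    previous_bp = mapping[branch.anchor]
                anchor = previous_bp
            last_entity = None
        else:  # pragma: no cover
            raise AssertionError(ttype)

    if branch_stack:
        raise ParseError("unmatched '('", text=text)
    if open_markers:
        raise ParseError(f"unclosed ring markers: {sorted(open_markers)}", text=text)
    if pending_order is not None:
        raise ParseError("dangling bond symbol at end of input", text=text)
    if forward_descs:
        raise ParseError("bonding descriptor with no host node", text=text)
    if graph.number_of_nodes() == 0:
        raise ParseError("empty graph", text=text)

    if allow_descriptors:
        return graph, descriptors
    return graph
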