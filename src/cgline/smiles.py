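"""OpenSMILES-subset parser for atomic fragment bodies.

Covers the organic subset, bracket atoms (isotope, element, explicit H count,
charge), branches, ring closures, bond symbols including ``:`` (aromatic) and
``/ \\`` (cis/trans marks), plus the notation's extensions: bracketed bonding
descriptors, ``w``/``x``/``s`` annotations (positional convention ``(w, x)``)
and ``%`` ring markers consuming all following digits.

Two deliberate deviations from strict OpenSMILES:

* Hydrogen completion is deferred until the full molecule is assembled, so a
  bracket atom without an explicit ``H`` count is valence-filled later just
  like an organic-subset atom (write ``[CH0]`` to suppress).  Charged atoms
  without an explicit count receive no implicit hydrogens.
* ``@``/``@@`` chirality is parsed but ignored with a warning; chirality in
  this notation is annotated explicitly as ``x=R/S`` because the local,
  order-dependent SMILES form does not survive fragment assembly.
"""

import logging
import re

from . import graph as G
from .descriptors import KINDS, parse_descriptor_token
from .elements import AROMATIC_ELEMENTS, ONE_LETTER, TWO_LETTER
from .errors import ParseError
from .graph_parser import parse_annotations

LOGGER = logging.getLogger(__name__)

BOND_ORDERS = {"-": 1, "=": 2, "#": 3, "$": 4}
_AROMATIC_ORGANIC = {"b", "c", "n", "o", "p", "s"}
_ALIPHATIC_ORGANIC = {"B", "C", "N", "O", "P", "S", "F", "I"}

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?|as|se|[bcnops*])")


def _parse_bracket_atom(body, pos, text):
    """Parse the inside of an atom bracket into a node-attribute dict."""
    attrs = {"bracket": True}     # written form remembered for the writer
    i = 0
    match = re.match(r"\d+", body)
    if match:
        attrs["isotope"] = int(match.group())
        i = match.end()
    match = _ELEMENT_RE.match(body, i)
    if not match:
        raise ParseError(f"invalid element in '[{body}]'", position=pos, text=text)
    symbol = match.group()
    i = match.end()
    if symbol == "*":
        attrs["element"] = "*"
        attrs["aromatic"] = False
    elif symbol.islower():
        element = symbol.capitalize()
        if element not in AROMATIC_ELEMENTS:
            raise ParseError(f"element '{element}' cannot be aromatic",
                             position=pos, text=text)
        attrs["element"] = element
        attrs["aromatic"] = True
    else:
        if len(symbol) == 2 and symbol not in TWO_LETTER:
            raise ParseError(f"unknown element '{symbol}'", position=pos, text=text)
        if len(symbol) == 1 and symbol not in ONE_LETTER:
            raise ParseError(f"unknown element '{symbol}'", position=pos, text=text)
        attrs["element"] = symbol
        attrs["aromatic"] = False
    while i < len(body) and body[i] in "@":
        LOGGER.warning("ignoring '@' chirality in '[%s]'; annotate x=R/S instead", body)
        i += 1 if not body.startswith("@@", i) else 2
    if i < len(body) and body[i] == "H" and attrs["element"] != "H":
        i += 1
        match = re.match(r"\d+", body[i:])
        if match:
            attrs["hcount"] = int(match.group())
            i += match.end()
        else:
            attrs["hcount"] = 1
    if i < len(body) and body[i] in "+-":
        sign = 1 if body[i] == "+" else -1
        i += 1
        match = re.match(r"\d+", body[i:])
        if match:
            attrs["charge"] = sign * int(match.group())
            i += match.end()
        else:
            magnitude = 1
            while i < len(body) and body[i] == ("+" if sign > 0 else "-"):
                magnitude += 1
                i += 1
            attrs["charge"] = sign * magnitude
    if i < len(body) and body[i] == ":":
        match = re.match(r"\d+", body[i + 1:])
        if not match:
            raise ParseError(f"invalid atom class in '[{body}]'", position=pos, text=text)
        i += 1 + match.end()
    if i < len(body):
        if body[i] != ";":
            raise ParseError(f"unexpected '{body[i:]}' in '[{body}]'",
                             position=pos, text=text)
        parts = body[i + 1:].split(";")
        annotations = parse_annotations(parts, ("w", "x"), pos, text)
        for key, value in annotations.items():
            if key == "w":
                attrs["weight"] = float(value)
            elif key == "x":
                attrs["chirality"] = value
            elif key == "s":
                if attrs["element"] != "*":
                    raise ParseError("selection annotations are only valid on wildcard atoms",
                                     position=pos, text=text)
                attrs["select"] = value
            else:
                raise ParseError(
                    f"annotation '{key}' is not supported on atoms (use w, x or s)",
                    position=pos, text=text)
    return attrs


def parse_atomic_fragment(text, *, allow_descriptors=True):
    """Parse an atomic-dialect fragment body.

    Returns ``(graph, descriptors)``.  Hydrogens are *not* added and aromatic
    flags are taken verbatim; both are normalized once the full molecule is
    assembled.
    """
    graph = G.new_graph()
    descriptors = []
    forward_descs = []
    anchor = None
    pending = None                # (order, aromatic, stereo) of the next bond
    just_opened = True
    open_markers = {}             # marker -> (node, pending bond)
    branch_stack = []
    position = 0                  # descriptor sequence counter

    def new_atom(attrs, pos):
        nonlocal anchor, pending, just_opened
        node = G.add_node(graph, **attrs)
        for desc in forward_descs:
            desc.host = node
            descriptors.append(desc)
        forward_descs.clear()
        if anchor is not None:
            _bond(anchor, node, pending, pos)
        anchor = node
        pending = None
        just_opened = False

    def _bond(u, v, bond, pos):
        if graph.has_edge(u, v) or u == v:
            raise ParseError("duplicate bond or self-loop", position=pos, text=text)
        if bond is None:
            aromatic = graph.nodes[u]["aromatic"] and graph.nodes[v]["aromatic"]
            G.add_edge(graph, u, v, order=1, aromatic=aromatic)
        else:
            order, aromatic, stereo = bond
            attrs = {"aromatic": aromatic}
            if stereo:
                attrs.update(stereo=stereo, stereo_from=u)
            G.add_edge(graph, u, v, order=order, **attrs)

    i, n = 0, len(text)
    while i < n:
        char = text[i]
        if char.isspace():
            raise ParseError("whitespace is not allowed in a fragment body",
                             position=i, text=text)
        if char == "[":
            end = text.find("]", i)
            if end < 0:
                raise ParseError("unbalanced square bracket", position=i, text=text)
            body = text[i + 1:end]
            if body and body[0] in KINDS:
                if not allow_descriptors:
                    raise ParseError("bonding descriptors are not allowed here",
                                     position=i, text=text)
                try:
                    desc = parse_descriptor_token(body, position=position)
                except ValueError as err:
                    raise ParseError(str(err), position=i, text=text) from None
                position += 1
                if pending is not None:
                    desc.bond_order = pending[0]
                    pending = None
                if anchor is None:
                    desc.prefix = True
                    forward_descs.append(desc)
                else:
                    # like a BigSMILES pseudo-atom: bonds to the preceding
                    # atom, also inside a branch ("C([$])C")
                    desc.host = anchor
                    descriptors.append(desc)
            else:
                attrs = _parse_bracket_atom(body, i, text)
                new_atom(attrs, i)
            i = end + 1
        elif text.startswith(("Cl", "Br"), i):
            new_atom({"element": text[i:i + 2], "aromatic": False}, i)
            i += 2
        elif char in _ALIPHATIC_ORGANIC:
            new_atom({"element": char, "aromatic": False}, i)
            i += 1
        elif char in _AROMATIC_ORGANIC:
            new_atom({"element": char.upper(), "aromatic": True}, i)
            i += 1
        elif char == "*":
            new_atom({"element": "*", "aromatic": False}, i)
            i += 1
        elif char in BOND_ORDERS:
            if pending is not None:
                raise ParseError("two consecutive bond symbols", position=i, text=text)
            if forward_descs and anchor is None:
                forward_descs[-1].bond_order = BOND_ORDERS[char]
            else:
                pending = (BOND_ORDERS[char], False, None)
            i += 1
        elif char == ":":
            pending = (1, True, None)
            i += 1
        elif char in "/\\":
            pending = (1, False, char)
            i += 1
        elif char == ".":
            if pending is not None:
                raise ParseError("bond symbol before '.'", position=i, text=text)
            anchor = None
            just_opened = True
            i += 1
        elif char == "(":
            if anchor is None:
                raise ParseError("branch before any atom", position=i, text=text)
            if pending is not None:
                raise ParseError("bond symbol may not precede '('", position=i, text=text)
            branch_stack.append(anchor)
            just_opened = True
            i += 1
        elif char == ")":
            if not branch_stack:
                raise ParseError("unmatched ')'", position=i, text=text)
            if pending is not None:
                raise ParseError("dangling bond symbol before ')'", position=i, text=text)
            anchor = branch_stack.pop()
            just_opened = False
            i += 1
        elif char.isdigit() or char == "%":
            if char == "%":
                match = re.match(r"\d+", text[i + 1:])
                if not match:
                    raise ParseError("'%' must be followed by digits", position=i, text=text)
                marker = int(match.group())
                i += 1 + match.end()
            else:
                marker = int(char)
                i += 1
            if anchor is None:
                raise ParseError("ring marker before any atom", position=i, text=text)
            if marker in open_markers:
                other, other_bond = open_markers.pop(marker)
                bond = pending if pending is not None else other_bond
                if pending is not None and other_bond is not None \
                        and pending[0] != other_bond[0]:
                    raise ParseError(f"conflicting bond orders on ring marker {marker}",
                                     position=i, text=text)
                _bond(other, anchor, bond, i)
                pending = None
            else:
                open_markers[marker] = (anchor, pending)
                pending = None
        else:
            raise ParseError(f"unexpected character '{char}'", position=i, text=text)

    if branch_stack:
        raise ParseError("unmatched '('", text=text)
    if open_markers:
        raise ParseError(f"unclosed ring markers: {sorted(open_markers)}", text=text)
    if pending is not None:
        raise ParseError("dangling bond symbol at end of input", text=text)
    if forward_descs:
        raise ParseError("bonding descriptor with no host atom", text=text)
    if graph.number_of_nodes() == 0:
        raise ParseError("empty fragment body", text=text)
    return graph, descriptors
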