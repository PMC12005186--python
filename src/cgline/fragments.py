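"""Splitting full strings into resolution layers and parsing fragment lists.

A full string is a sequence of brace-enclosed blocks joined by periods:
the first block is the base graph (coarsest resolution), every further block
is a fragment dictionary mapping coarser node labels to finer subgraphs.
Fragment bodies are written either in the coarse-graph dialect or in the
OpenSMILES-based atomic dialect; all layers except possibly the last use the
coarse dialect, the last layer's dialect is declared by the caller.

A string may omit the base graph (a fragment-list-only string); such strings
describe statistical polymers and are handled by the sampler.
"""

import re
from dataclasses import dataclass, field

from . import smiles
from . import graph_parser
from .descriptors import BondingDescriptor
from .errors import ParseError

CG_GRAPH = "cg_graph"
OPEN_SMILES = "open_smiles"

_NAME_RE = re.compile(r"^[A-Za-z0-9]+$")


@dataclass
class Fragment:
    """A named finer-resolution subgraph with its bonding descriptors."""
    name: str
    dialect: str
    graph: "object"                      # networkx Graph (see cgline.graph)
    descriptors: list = field(default_factory=list)
    source: str = ""                     # body text as written


@dataclass
class LayerSpec:
    """A parsed multi-resolution string.

    ``base`` is the coarsest graph (None for fragment-list-only strings);
    ``fragment_layers`` is a list of dicts name -> Fragment, coarsest first;
    ``dialects`` records each fragment layer's dialect.
    """
    base: "object"
    fragment_layers: list
    dialects: list

    @property
    def sampler_only(self):
        return self.base is None


def split_layers(text):
    """Split a full string into its brace-enclosed blocks.

    Returns the list of block contents in order.  Periods inside braces are
    untouched; any text outside braces other than separating periods is an
    error.
    """
    blocks = []
    i, n = 0, len(text)
    expect_block = True
    while i < n:
        char = text[i]
        if char == "{":
            if not expect_block:
                raise ParseError("missing '.' between resolution blocks",
                                 position=i, text=text)
            end = text.find("}", i)
            if end < 0:
                raise ParseError("unbalanced '{'", position=i, text=text)
            if "{" in text[i + 1:end]:
                raise ParseError("nested braces", position=i, text=text)
            blocks.append(text[i + 1:end])
            i = end + 1
            expect_block = False
        elif char == "." and not expect_block:
            expect_block = True
            i += 1
        elif char.isspace():
            i += 1
        else:
            raise ParseError(f"unexpected text outside braces: '{char}'",
                             position=i, text=text)
    if expect_block and blocks:
        raise ParseError("trailing '.' without a following block", text=text)
    if not blocks:
        raise ParseError("no brace-enclosed resolution block found", text=text)
    return blocks


def _split_fragments(layer_text):
    """Split a fragment-list block on top-level commas (bracket-aware)."""
    entries, depth, start = [], 0, 0
    for i, char in enumerate(layer_text):
        if char == "[":
            depth += 1
        elif char == "]":
            depth -= 1
            if depth < 0:
                raise ParseError("unbalanced ']'", position=i, text=layer_text)
        elif char == "," and depth == 0:
            entries.append((start, layer_text[start:i]))
            start = i + 1
    entries.append((start, layer_text[start:]))
    return entries


def parse_fragment_list(layer_text, dialect=OPEN_SMILES):
    """Parse one fragment-dictionary block into ``{name: Fragment}``."""
    if dialect not in (CG_GRAPH, OPEN_SMILES):
        raise ParseError(f"unknown dialect '{dialect}'")
    fragments = {}
    for pos, entry in _split_fragments(layer_text):
        if not entry.startswith("#"):
            raise ParseError("fragment entry must start with '#'",
                             position=pos, text=layer_text)
        name, sep, body = entry[1:].partition("=")
        if not sep:
            raise ParseError(f"fragment '#{name}' is missing '='",
                             position=pos, text=layer_text)
        if not _NAME_RE.match(name):
            raise ParseError(f"invalid fragment name '{name}'",
                             position=pos, text=layer_text)
        if name in fragments:
            raise ParseError(f"duplicate fragment name '{name}'",
                             position=pos, text=layer_text)
        if not body:
            raise ParseError(f"fragment '#{name}' has an empty body",
                             position=pos, text=layer_text)
        if dialect == OPEN_SMILES:
            graph, descriptors = smiles.parse_atomic_fragment(body)
        else:
            graph, descriptors = graph_parser.parse_cg_graph(
                body, allow_descriptors=True)
        fragments[name] = Fragment(name=name, dialect=dialect, graph=graph,
                                   descriptors=descriptors, source=body)
    return fragments


def parse_cgsmiles(text, *, last_dialect=OPEN_SMILES, base_present=None):
    """Parse a full multi-resolution string into a :class:`LayerSpec`.

    *last_dialect* declares the dialect of the final fragment layer (all
    earlier fragment layers are coarse-dialect by construction).  When
    *base_present* is None the first block is taken to be a base graph unless
    it looks like a fragment list (starts with ``#``), which covers
    fragment-list-only sampler strings.
    """
    blocks = split_layers(text)
    if base_present is None:
        # a base graph always opens with a bracketed node; a fragment list
        # opens with '#NAME='
        base_present = not blocks[0].startswith("#")
    base = None
    frag_blocks = blocks
    if base_present:
        base = graph_parser.parse_cg_graph(blocks[0])
        frag_blocks = blocks[1:]
    fragment_layers, dialects = [], []
    for k, block in enumerate(frag_blocks):
        dialect = last_dialect if k == len(frag_blocks) - 1 else CG_GRAPH
        fragment_layers.append(parse_fragment_list(block, dialect))
        dialects.append(dialect)
    return LayerSpec(base=base, fragment_layers=fragment_layers, dialects=dialects)
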