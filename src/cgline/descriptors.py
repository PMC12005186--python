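"""Bonding descriptors: the unit of inter-fragment assembly.

Four connector kinds exist. ``$`` pairs with any ``$`` of equal label;
``>`` pairs only with ``<`` (and vice versa); ``!`` (the squash connector)
pairs only with ``!`` and merges the two host atoms into one. A bond-order
symbol written between host and descriptor sets the chemical order of the
created bond; both partners must declare the same order.
"""

import re
from dataclasses import dataclass, field

KINDS = ("$", ">", "<", "!")

_LABEL_RE = re.compile(r"^[A-Za-z0-9]*$")


@dataclass
class BondingDescriptor:
    kind: str                      # one of $ > < !
    label: str = ""                # alphanumeric, may be empty
    bond_order: int = 1            # order of the bond created on match
    host: int | None = None        # node id carrying the descriptor
    written_position: int = 0      # token sequence number within the fragment
    prefix: bool = False           # written before its host atom
    consumed: bool = False

    def compatible(self, other):
        """True if this descriptor may pair with *other*."""
        if self.consumed or other.consumed:
            return False
        if self.label != other.label or self.bond_order != other.bond_order:
            return False
        if self.kind == "$":
            return other.kind == "$"
        if self.kind == "!":
            return other.kind == "!"
        if self.kind == ">":
            return other.kind == "<"
        if self.kind == "<":
            return other.kind == ">"
        return False

    def to_string(self):
        return f"[{self.kind}{self.label}]"


def parse_descriptor_token(body, position=0):
    """Parse the inside of a bracket known to hold a descriptor.

    *body* is e.g. ``"$a"``, ``">1"``, ``"!"``. Returns a BondingDescriptor
    or raises ValueError for a malformed label.
    """
    kind, label = body[0], body[1:]
    if kind not in KINDS or not _LABEL_RE.match(label):
        raise ValueError(f"malformed bonding descriptor '[{body}]'")
    return BondingDescriptor(kind=kind, label=label, written_position=position)


def scan_order(descriptors):
    """Descriptors in matching scan order.

    The scan is (host-node written order) x (descriptor written order): node
    ids are allocated in written order, so sorting on (host, written_position)
    reproduces it. A descriptor written before its host (prefix form) still
    belongs to that host's slot.
    """
    return sorted(descriptors, key=lambda d: (d.host, d.written_position))
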