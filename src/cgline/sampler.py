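"""Stochastic growth of molecules from fragment-only strings.

A fragment list without a base graph describes a statistical (co)polymer.
The sampler turns it into concrete molecules with a documented stochastic
process:

1. the first repeat unit is drawn from the composition distribution;
2. while the target is unreached, one unconsumed bonding descriptor of the
   growing molecule is picked uniformly at random, a partner fragment type is
   drawn from the composition restricted (and renormalized) to types offering
   a compatible descriptor, and the new unit is connected through the
   partner's first compatible descriptor in written order;
3. growth stops exactly at ``target_node_count``, or at the first crossing of
   ``target_molar_mass``; descriptors still open become hydrogens once the
   molecule is resolved to atoms.

Fragment molar masses count the written atoms plus the hydrogens a fully
connected (interior) unit would carry.  The per-step probability of a
fragment type is therefore proportional to its composition fraction times
the availability of a compatible descriptor; reaction probabilities beyond
this are not part of the notation.
"""

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import graph as G
from .descriptors import scan_order
from .elements import ATOMIC_MASSES, implicit_hydrogens
from .errors import SamplerError
from .fragments import OPEN_SMILES, LayerSpec, parse_cgsmiles
from .resolver import resolve_all


@dataclass
class SamplerConfig:
    target_node_count: int | None = None
    target_molar_mass: float | None = None
    composition: dict | None = None      # fragment name -> fraction; sums to 1
    seed: int = 0
    max_attempts: int = 1000

    def validate(self, names):
        if (self.target_node_count is None) == (self.target_molar_mass is None):
            raise SamplerError(
                "specify exactly one of target_node_count / target_molar_mass")
        target = self.target_node_count or self.target_molar_mass
        if target <= 0:
            raise SamplerError("target must be positive")
        if self.composition is None:
            return {name: 1.0 / len(names) for name in names}
        unknown = set(self.composition) - set(names)
        if unknown:
            raise SamplerError(f"composition names unknown: {sorted(unknown)}")
        composition = {name: float(self.composition.get(name, 0.0)) for name in names}
        if any(f < 0 for f in composition.values()):
            raise SamplerError("fractions must be non-negative")
        if abs(sum(composition.values()) - 1.0) > 1e-9:
            raise SamplerError("fractions must sum to 1")
        return composition


def fragment_molar_mass(fragment):
    """Mass of one interior repeat unit (written atoms + completion H)."""
    mass = 0.0
    graph = fragment.graph
    hosts = {}
    for desc in fragment.descriptors:
        hosts[desc.host] = hosts.get(desc.host, 0) + desc.bond_order
    for node, data in graph.nodes(data=True):
        element = data.get("element", "H")
        mass += ATOMIC_MASSES.get(element, 0.0)
        if element in ("H", "*") or "hcount" in data and not data["hcount"]:
            continue
        bondsum = sum(d.get("order", 1) for _, _, d in graph.edges(node, data=True))
        bondsum += hosts.get(node, 0)          # descriptor sites are bonded
        count = data.get("hcount",
                         implicit_hydrogens(element, bondsum))
        mass += count * ATOMIC_MASSES["H"]
    return mass


class MoleculeSampler:
    """Grow concrete molecules from a fragment dictionary.

    *source* is a fragment-only string (``{#A=...,#B=...}``), a
    :class:`LayerSpec` without base graph, or a plain ``{name: Fragment}``
    dict.  Extra fragment layers after the first are applied during
    resolution.
    """

    def __init__(self, source, *, last_dialect=OPEN_SMILES):
        if isinstance(source, str):
            source = parse_cgsmiles(source, last_dialect=last_dialect,
                                    base_present=False)
        if isinstance(source, LayerSpec):
            if source.base is not None:
                raise SamplerError("sampler input must not contain a base graph")
            self.layers = source
        else:
            self.layers = LayerSpec(base=None, fragment_layers=[dict(source)],
                                    dialects=[last_dialect])
        self.fragments = self.layers.fragment_layers[0]
        for name, fragment in self.fragments.items():
            if not fragment.descriptors:
                raise SamplerError(f"fragment '{name}' has no bonding descriptor")

    # -- growth -----------------------------------------------------------

    def _compatible_types(self, desc, composition):
        out = []
        for name, fraction in composition.items():
            if fraction <= 0:
                continue
            if any(desc.compatible(replace(d, consumed=False))
                   for d in self.fragments[name].descriptors):
                out.append(name)
        return out

    def sample_graph(self, config):
        """Run the growth loop; returns the generated base graph."""
        composition = config.validate(list(self.fragments))
        rng = np.random.default_rng(config.seed)
        names = [n for n, f in composition.items() if f > 0]
        weights = np.array([composition[n] for n in names])
        weights = weights / weights.sum()

        masses = {name: fragment_molar_mass(frag)
                  for name, frag in self.fragments.items()}
        base = G.new_graph()
        open_descs = []                 # (node, descriptor copy)

        def add_unit(name, via=None):
            node = G.add_node(base, label=name, is_wildcard=False, annotations={})
            descs = [replace(d, host=node, consumed=False)
                     for d in scan_order(self.fragments[name].descriptors)]
            if via is not None:
                chosen, partner_pool = via
                partner = next(d for d in descs if chosen.compatible(d))
                partner.consumed = True
                chosen.consumed = True
                G.add_edge(base, chosen.host, node, order=1)
            open_descs.extend(d for d in descs if not d.consumed)
            return node

        start = str(rng.choice(names, p=weights))
        add_unit(start)
        count, mass = 1, masses[start]

        def reached():
            if config.target_node_count is not None:
                return count >= config.target_node_count
            return mass >= config.target_molar_mass

        attempts = 0
        while not reached():
            live = [d for d in open_descs
                    if not d.consumed and self._compatible_types(d, composition)]
            if not live:
                census = {}
                for d in open_descs:
                    if not d.consumed:
                        census[d.to_string()] = census.get(d.to_string(), 0) + 1
                raise SamplerError(
                    f"growth deadlock at {count} units: no open descriptor has a "
                    f"compatible partner (remaining: {census})")
            chosen = live[rng.integers(len(live))]
            pool = self._compatible_types(chosen, composition)
            pool_weights = np.array([composition[n] for n in pool])
            pool_weights = pool_weights / pool_weights.sum()
            name = str(rng.choice(pool, p=pool_weights))
            add_unit(name, via=(chosen, pool))
            open_descs[:] = [d for d in open_descs if not d.consumed]
            count += 1
            mass += masses[name]
            attempts += 1
            if attempts > config.max_attempts and not reached():
                raise SamplerError(
                    f"target not reached after {config.max_attempts} growth steps")
        return base

    def sample_molecule(self, config):
        """Grow one molecule and resolve it; returns (base graph, resolved)."""
        base = self.sample_graph(config)
        spec = LayerSpec(base=base, fragment_layers=self.layers.fragment_layers,
                         dialects=self.layers.dialects)
        return base, resolve_all(spec)

    def sample_string(self, config):
        """Grow one molecule and return it as a full multi-resolution string."""
        from .writer import write_full
        base = self.sample_graph(config)
        spec = LayerSpec(base=base, fragment_layers=self.layers.fragment_layers,
                         dialects=self.layers.dialects)
        return write_full(spec)


def composition_report(base_graphs):
    """Empirical fragment fractions (with standard errors) over samples."""
    rows = []
    names = sorted({d["label"] for g in base_graphs for _, d in g.nodes(data=True)})
    per_sample = {name: [] for name in names}
    for g in base_graphs:
        total = g.number_of_nodes()
        counts = {name: 0 for name in names}
        for _, data in g.nodes(data=True):
            counts[data["label"]] += 1
        for name in names:
            per_sample[name].append(counts[name] / total)
    for name in names:
        values = np.asarray(per_sample[name])
        rows.append(dict(fragment=name,
                         fraction=values.mean(),
                         stderr=values.std(ddof=1) / np.sqrt(len(values))
                         if len(values) > 1 else float("nan"),
                         n_samples=len(values)))
    return pd.DataFrame(rows)
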