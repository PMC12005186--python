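"""Reading and writing the package's file formats.

* molecule libraries: TSV with columns ``name`` and ``cgsmiles``; lines
  starting with ``;`` are comments (``#`` collides with the notation);
* interaction tables: square TSV matrix (see :mod:`cgline.fingerprint`);
* graph export: JSON node-link or GraphML (annotation dicts are serialized
  to JSON strings for GraphML, which only supports scalar attributes);
* fingerprints: CSV, one row per solute.
"""

import json

import networkx as nx
import pandas as pd

from .errors import CGLineError


def read_library(path):
    """Read a (name, cgsmiles) library; returns a DataFrame."""
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith(";"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise CGLineError(
                    f"{path}:{lineno}: expected 'name<TAB>cgsmiles'")
            rows.append({"name": parts[0].strip(), "cgsmiles": parts[1].strip()})
    if rows and rows[0]["name"].lower() == "name":
        rows = rows[1:]
    return pd.DataFrame(rows)


def write_library(frame, path):
    with open(path, "w") as handle:
        handle.write("; molecule library: name<TAB>cgsmiles\n")
        for _, row in frame.iterrows():
            handle.write(f"{row['name']}\t{row['cgsmiles']}\n")


def _scalarize(value):
    if isinstance(value, (str, int, float, bool)):
        return value
    return json.dumps(value, sort_keys=True)


def graph_to_node_link(graph):
    """JSON-serializable node-link representation of any resolution graph."""
    data = {"nodes": [], "links": []}
    for node, attrs in graph.nodes(data=True):
        entry = {"id": node}
        entry.update({k: v for k, v in attrs.items()})
        data["nodes"].append(entry)
    for u, v, attrs in graph.edges(data=True):
        entry = {"source": u, "target": v}
        entry.update({k: list(v2) if isinstance(v2, tuple) else v2
                      for k, v2 in attrs.items()})
        data["links"].append(entry)
    return data


def write_graph(graph, path, fmt="json"):
    if fmt == "json":
        with open(path, "w") as handle:
            json.dump(graph_to_node_link(graph), handle, indent=1)
    elif fmt == "graphml":
        flat = nx.Graph()
        for node, attrs in graph.nodes(data=True):
            flat.add_node(node, **{k: _scalarize(v) for k, v in attrs.items()})
        for u, v, attrs in graph.edges(data=True):
            flat.add_edge(u, v, **{k: _scalarize(v) for k, v in attrs.items()})
        nx.write_graphml(flat, path)
    else:
        raise CGLineError(f"unknown graph format '{fmt}'")


def write_fingerprints(rows, path):
    """Write fingerprint vectors as CSV; *rows* is {name: FingerprintVector}."""
    records = []
    for name, vector in rows.items():
        record = {"name": name}
        flat = vector.as_array()
        for i, value in enumerate(flat[:-1]):
            block, idx = divmod(i, vector.counts.shape[1])
            record[f"block{block}_type{idx}"] = int(value)
        record["volume"] = flat[-1]
        records.append(record)
    pd.DataFrame(records).to_csv(path, index=False)
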