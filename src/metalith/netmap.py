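"""Merged chemical-similarity / reaction-pair metabolite networks.

Two edge layers connect the identified metabolites of a study:

* a *similarity* layer from Tanimoto coefficients over binary substructure
  fingerprints — an edge wherever similarity exceeds 0.5, plus one
  *similarity_fallback* edge from each otherwise-unconnected compound to its
  chemically closest neighbor;
* an *rpair* layer from curated reactant pairs (substrate-product pairs of
  enzymatic reactions, "main" class), giving a single-step reaction network.

The merged graph keeps both edge types between a pair when both layers
connect it. Differential statistics are painted onto nodes (size for the
magnitude of change, direction for up/down, a 4-level intensity for the
ANOVA p-value band) and the result is exported as a Cytoscape SIF edge list
plus a node-attribute TSV.

Fingerprints are plain fixed-length bit vectors (default length 881, the
public substructure-key length); computing them from structures is a caller
concern, keeping cheminformatics dependencies out of the core.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .study_io import ReactionPairTable

__all__ = [
    "DEFAULT_FP_LENGTH",
    "NetworkError",
    "Fingerprint",
    "MetaboliteNetwork",
    "tanimoto",
    "similarity_edges",
    "rpair_edges",
    "merge_networks",
    "map_statistics",
    "write_sif",
    "read_sif",
    "write_node_attributes",
]

DEFAULT_FP_LENGTH = 881

EDGE_TYPES = ("rpair", "similarity", "similarity_fallback")

Edge = tuple[str, str, str]  # (id_a, id_b, edge_type), id_a < id_b


class NetworkError(Exception):
    pass


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary substructure fingerprint."""

    bits: tuple

    def __post_init__(self) -> None:
        if not all(b in (0, 1) for b in self.bits):
            raise NetworkError("fingerprint bits must be 0/1")

    @classmethod
    def from_bits(cls, bits: Iterable[int]) -> "Fingerprint":
        return cls(bits=tuple(int(b) for b in bits))

    @classmethod
    def from_string(cls, s: str) -> "Fingerprint":
        return cls(bits=tuple(int(c) for c in s.strip()))

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def popcount(self) -> int:
        return sum(self.bits)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=bool)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a AND b| / |a OR b|; 0 by convention when both fingerprints are empty."""
    if len(a) != len(b):
        raise NetworkError(f"fingerprint length mismatch: {len(a)} vs {len(b)}")
    av, bv = a.as_array(), b.as_array()
    union = int(np.logical_or(av, bv).sum())
    if union == 0:
        return 0.0
    return float(np.logical_and(av, bv).sum() / union)


def _norm(a: str, b: str, etype: str) -> Edge:
    return (a, b, etype) if a <= b else (b, a, etype)


def similarity_edges(
    fps: Mapping[str, Fingerprint], threshold: float = 0.5
) -> set[Edge]:
    """Similarity layer over all fingerprint pairs.

    An edge of type ``similarity`` for every pair with Tanimoto strictly
    above ``threshold``. Every node left without such an edge gets one
    ``similarity_fallback`` edge to its most similar neighbor (ties broken
    by lexicographic id; reciprocal fallbacks deduplicate; a node whose best
    similarity is 0 stays isolated — there is no "closest" structure).
    """
    ids = sorted(fps)
    if len(ids) < 2:
        warnings.warn("similarity_edges needs >= 2 fingerprints; returning empty set",
                      stacklevel=2)
        return set()
    sim: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            sim[(a, b)] = tanimoto(fps[a], fps[b])
    edges: set[Edge] = {
        _norm(a, b, "similarity") for (a, b), s in sim.items() if s > threshold
    }
    connected = {x for a, b, _ in edges for x in (a, b)}
    for node in ids:
        if node in connected:
            continue
        best_id, best_s = None, 0.0
        for other in ids:
            if other == node:
                continue
            s = sim[(node, other)] if node < other else sim[(other, node)]
            # iterating ids in sorted order + strict ">" keeps the
            # lexicographically smallest id on ties
            if s > best_s:
                best_id, best_s = other, s
        if best_id is not None and best_s > 0:
            edges.add(_norm(node, best_id, "similarity_fallback"))
    return edges


def rpair_edges(
    study_ids: Iterable[str],
    rpairs: ReactionPairTable,
    id_resolver: Mapping[str, str],
) -> tuple[set[Edge], dict]:
    """Single-step reaction layer: an ``rpair`` edge for every main reactant
    pair whose both compounds resolve to identified study metabolites.

    ``id_resolver`` maps compound references (e.g. compound-database ids) to
    study metabolite ids. Unresolvable or out-of-study references are not
    fatal; they are tallied in the returned report.
    """
    present = set(study_ids)
    edges: set[Edge] = set()
    unresolved = 0
    absent = 0
    for ref_a, ref_b, _cls in rpairs.pairs:
        a = id_resolver.get(ref_a)
        b = id_resolver.get(ref_b)
        if a is None or b is None:
            unresolved += 1
            continue
        if a not in present or b not in present:
            absent += 1
            continue
        if a == b:
            continue
        edges.add(_norm(a, b, "rpair"))
    report = {
        "n_pairs": rpairs.n_pairs,
        "n_edges": len(edges),
        "n_unresolved": unresolved,
        "n_absent": absent,
    }
    return edges, report


NEUTRAL_ATTRS = {
    "ratio": math.nan,
    "p": math.nan,
    "direction": "neutral",
    "size": None,  # filled with the minimum size on mapping
    "intensity": 0,
}


@dataclass
class MetaboliteNetwork:
    """Typed-edge metabolite graph with per-node statistical attributes."""

    nodes: dict[str, dict] = field(default_factory=dict)
    edges: set[Edge] = field(default_factory=set)

    def validate(self) -> None:
        for a, b, etype in self.edges:
            if a == b:
                raise NetworkError(f"self-edge on {a!r}")
            if etype not in EDGE_TYPES:
                raise NetworkError(f"unknown edge type {etype!r}")
            for x in (a, b):
                if x not in self.nodes:
                    raise NetworkError(f"edge endpoint {x!r} not in node set")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiGraph()
        for node, attrs in self.nodes.items():
            g.add_node(node, **attrs)
        for a, b, etype in self.edges:
            g.add_edge(a, b, key=etype, edge_type=etype)
        return g


def merge_networks(
    sim_edges: set[Edge], rxn_edges: set[Edge], nodes: Iterable[str]
) -> MetaboliteNetwork:
    """Union of the two layers; a pair present in both keeps both typed edges."""
    node_set = {n: dict(NEUTRAL_ATTRS) for n in nodes}
    net = MetaboliteNetwork(nodes=node_set, edges=set(sim_edges) | set(rxn_edges))
    net.validate()
    return net


# p-value bands mapped to the 4 intensity levels (strongest first)
INTENSITY_BANDS = ((0.001, 3), (0.01, 2), (0.05, 1))


def map_statistics(
    net: MetaboliteNetwork,
    results: Sequence,
    size_range: tuple[float, float] = (20.0, 80.0),
    log2_cap: float = 3.0,
) -> MetaboliteNetwork:
    """Paint differential statistics onto the node attributes.

    * ``size``: |log2(ratio)| mapped linearly into ``size_range`` and clipped
      at ``log2_cap`` (default 3, i.e. an 8-fold change saturates the scale);
    * ``direction``: "up" if ratio > 1, "down" if < 1, "neutral" at 1;
    * ``intensity``: 0..3 for the p-value bands (>=0.05, <0.05, <0.01, <0.001).

    Nodes without a result keep neutral attributes at the minimum size.
    """
    lo, hi = size_range
    if not lo < hi:
        raise NetworkError("size_range must be increasing")
    out = MetaboliteNetwork(
        nodes={n: dict(a) for n, a in net.nodes.items()}, edges=set(net.edges)
    )
    for attrs in out.nodes.values():
        if attrs.get("size") is None:
            attrs["size"] = lo
    for r in results:
        if r.metabolite_id not in out.nodes:
            continue
        ratio, p = r.ratio, r.p
        if not math.isnan(ratio) and ratio <= 0:
            raise NetworkError(f"nonpositive ratio for {r.metabolite_id!r}")
        attrs = out.nodes[r.metabolite_id]
        attrs["ratio"] = ratio
        attrs["p"] = p
        if math.isnan(ratio) or ratio == 1.0:
            attrs["direction"] = "neutral"
            attrs["size"] = lo
        else:
            attrs["direction"] = "up" if ratio > 1 else "down"
            mag = min(abs(math.log2(ratio)), log2_cap)
            attrs["size"] = lo + (hi - lo) * mag / log2_cap
        level = 0
        if not math.isnan(p):
            for cut, lv in INTENSITY_BANDS:
                if p < cut:
                    level = lv
                    break
        attrs["intensity"] = level
    return out


# ---------------------------------------------------------------------------
# Cytoscape exports


def write_sif(net: MetaboliteNetwork, path) -> None:
    """One ``id_a <tab> edge_type <tab> id_b`` line per edge, sorted by
    (type, id_a, id_b) so output is deterministic."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, etype in sorted(net.edges, key=lambda e: (e[2], e[0], e[1])):
            fh.write(f"{a}\t{etype}\t{b}\n")


def read_sif(path) -> set[Edge]:
    edges: set[Edge] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise NetworkError(f"malformed SIF line {lineno}: {line!r}")
            a, etype, b = fields
            edges.add(_norm(a, b, etype))
    return edges


def write_node_attributes(net: MetaboliteNetwork, path) -> None:
    """TSV of id, size, direction, intensity, ratio, p (Cytoscape-importable)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tsize\tdirection\tintensity\tratio\tp\n")
        for node in sorted(net.nodes):
            a = net.nodes[node]
            size = a.get("size")
            ratio = a.get("ratio", math.nan)
            p = a.get("p", math.nan)
            fh.write(
                f"{node}\t{'' if size is None else f'{size:g}'}\t"
                f"{a.get('direction', 'neutral')}\t{a.get('intensity', 0)}\t"
                f"{'' if math.isnan(ratio) else f'{ratio:g}'}\t"
                f"{'' if math.isnan(p) else f'{p:g}'}\n"
            )
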