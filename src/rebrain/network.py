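"""Query-centric drug-repurposing networks and priority lists.

Given a reference drug and a catalog of profiles, the network collects all
candidates that survive the molecular-weight cut and whose masked profile
distance to the reference stays below a threshold.  Component knockout
(removing a pathway component from the mask) and knock-in (restoring it)
reshape the distance geometry before the network is built.  Candidates are
ranked by ascending distance; each row also reports the profile-regression
R2 and slope against the reference plus the strict R2 > 0.6 significance
call used for the final repurposing assessment.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .profiles import DEFAULT_MW_MAX, ProfileSet, filter_by_mw
from .registry import COMPONENT_IDS, validate_component_ids
from .similarity import euclidean_distance, pair_regression, significance_flag

__all__ = [
    "DEFAULT_TOP_K",
    "NetworkQuery",
    "RepurposeNetwork",
    "PriorityRow",
    "PriorityList",
    "build_query_network",
    "prioritize",
    "apply_knockout",
    "apply_knockin",
    "export_network",
]

DEFAULT_TOP_K = 9  # length of the ranked repurposing shortlist


@dataclass(frozen=True)
class NetworkQuery:
    """Parameters of one repurposing query."""

    reference_id: str
    mw_max: float = DEFAULT_MW_MAX
    distance_max: float = math.inf
    mask: frozenset[str] = field(default_factory=lambda: frozenset(COMPONENT_IDS))
    top_k: int = DEFAULT_TOP_K
    edge_mode: str = "star"

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not (self.mw_max > 0):
            raise ValueError("mw_max must be positive")
        if self.distance_max < 0:
            raise ValueError("distance_max must be nonnegative")
        if self.edge_mode not in ("star", "mutual"):
            raise ValueError(f"edge_mode must be 'star' or 'mutual', got {self.edge_mode!r}")
        object.__setattr__(self, "mask", validate_component_ids(self.mask))


@dataclass(frozen=True)
class RepurposeNetwork:
    """The reference-centred graph for one query."""

    graph: nx.Graph
    query: NetworkQuery

    @property
    def node_ids(self) -> list[str]:
        return list(self.graph.nodes)


@dataclass(frozen=True)
class PriorityRow:
    rank: int
    drug_id: str
    name: str
    distance: float
    r2: float
    weight: float
    significant: bool


@dataclass(frozen=True)
class PriorityList:
    """Ranked repurposing shortlist (reference excluded, ties broken by name, id)."""

    reference_id: str
    rows: tuple[PriorityRow, ...]

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rank": r.rank,
                    "drug_id": r.drug_id,
                    "name": r.name,
                    "distance": r.distance,
                    "r2": r.r2,
                    "weight": r.weight,
                    "significant": r.significant,
                }
                for r in self.rows
            ],
            columns=["rank", "drug_id", "name", "distance", "r2", "weight", "significant"],
        )

    def to_tsv(self, path: str | Path) -> Path:
        self.to_dataframe().to_csv(path, sep="\t", index=False)
        return Path(path)


def apply_knockout(query: NetworkQuery, components: Iterable[str]) -> NetworkQuery:
    """Remove pathway components from the query mask (in-silico knockout)."""
    components = frozenset(components)
    if not components:
        return query
    for cid in sorted(components):
        if cid not in COMPONENT_IDS:
            raise KeyError(f"unknown component id: {cid!r}")
    remaining = query.mask - components
    if not remaining:
        raise ValueError("knockout would empty the component mask; keep at least one component")
    return replace(query, mask=remaining)


def apply_knockin(query: NetworkQuery, components: Iterable[str]) -> NetworkQuery:
    """Restore pathway components to the query mask (in-silico knock-in)."""
    components = validate_component_ids(components)
    return replace(query, mask=query.mask | components)


def _reference_stats(profile_set: ProfileSet, query: NetworkQuery):
    """Per-candidate (distance, r2, weight) to the reference, under the mask."""
    if query.reference_id not in profile_set:
        raise KeyError(f"reference drug {query.reference_id!r} not found in catalog")
    ref_vec = profile_set.profile(query.reference_id).vector(query.mask)
    regression_ok = len(query.mask) >= 2
    stats = {}
    for did in profile_set:
        vec = profile_set.profile(did).vector(query.mask)
        dist = euclidean_distance(ref_vec, vec)
        if regression_ok:
            r2, weight, _ = pair_regression(ref_vec, vec)
        else:
            r2, weight = 0.0, 0.0
        stats[did] = (dist, r2, weight)
    return stats


def build_query_network(profile_set: ProfileSet, query: NetworkQuery) -> RepurposeNetwork:
    """Build the reference-centred repurposing graph.

    Candidate pool = MW-filtered catalog plus the reference itself; nodes
    are candidates with masked distance to the reference <= distance_max.
    ``star`` mode draws reference-candidate edges only; ``mutual`` mode
    additionally links candidate pairs within distance_max of each other.
    """
    ref = query.reference_id
    pool = filter_by_mw(profile_set, query.mw_max)
    pool_ids = set(pool.ids()) | {ref}
    stats = _reference_stats(profile_set, query)

    kept = [
        did
        for did in profile_set  # keeps catalog order
        if did in pool_ids and (did == ref or stats[did][0] <= query.distance_max)
    ]

    g = nx.Graph()
    for did in kept:
        rec = profile_set.record(did)
        dist, r2, weight = stats[did]
        g.add_node(
            did,
            name=rec.name,
            molecular_weight=rec.molecular_weight,
            distance=dist,
            r2=r2,
            weight=weight,
            is_reference=did == ref,
        )
    for did in kept:
        if did != ref:
            g.add_edge(ref, did, distance=stats[did][0], r2=stats[did][1])
    if query.edge_mode == "mutual":
        cands = [d for d in kept if d != ref]
        for i, a in enumerate(cands):
            va = profile_set.profile(a).vector(query.mask)
            for b in cands[i + 1 :]:
                vb = profile_set.profile(b).vector(query.mask)
                d_ab = euclidean_distance(va, vb)
                if d_ab <= query.distance_max:
                    r2_ab = pair_regression(va, vb).r2 if len(query.mask) >= 2 else 0.0
                    g.add_edge(a, b, distance=d_ab, r2=r2_ab)
    return RepurposeNetwork(graph=g, query=query)


def prioritize(profile_set: ProfileSet, query: NetworkQuery) -> PriorityList:
    """Rank candidates by ascending masked distance to the reference.

    Deterministic: ties are broken by (distance, lowercase name, drug_id).
    At most ``query.top_k`` rows; the reference never appears.
    """
    net = build_query_network(profile_set, query)
    ref = query.reference_id
    rows = []
    for did in net.node_ids:
        if did == ref:
            continue
        attrs = net.graph.nodes[did]
        rows.append((attrs["distance"], attrs["name"].lower(), did, attrs))
    rows.sort(key=lambda t: (t[0], t[1], t[2]))
    ranked = tuple(
        PriorityRow(
            rank=i + 1,
            drug_id=did,
            name=attrs["name"],
            distance=attrs["distance"],
            r2=attrs["r2"],
            weight=attrs["weight"],
            significant=significance_flag(attrs["r2"]),
        )
        for i, (_, _, did, attrs) in enumerate(rows[: query.top_k])
    )
    return PriorityList(reference_id=ref, rows=ranked)


def export_network(net: RepurposeNetwork, fmt: str, path: str | Path) -> Path:
    """Write the network as GraphML or JSON node-link, with all attributes."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net.graph, path)
    elif fmt == "json_node_link":
        payload = nx.node_link_data(net.graph, edges="edges")
        path.write_text(json.dumps(payload, indent=2))
    else:
        raise ValueError(f"unknown export format {fmt!r}; use 'graphml' or 'json_node_link'")
    return path
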