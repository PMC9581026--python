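"""Differentially interacting proteins (DIPs) and hub-centered modules.

A DIP is a protein incident to at least ``min_edges`` distinct differential
interactions; its module is the star subnetwork of those interactions,
named by prefixing the hub symbol with "m" (mMYC is the module around MYC).
Catalogs from two independently analyzed datasets can be intersected to
keep only hubs whose modules share interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .differential import DifferentialPPI

DEFAULT_MIN_EDGES = 5


@dataclass(frozen=True)
class DIPModule:
    """A hub protein with its incident differential interactions.

    ``directions`` maps each edge to the set of directions ("activated",
    "repressed") in which it was called; an edge may carry both.
    """

    hub: str
    members: frozenset[str]
    edges: frozenset[tuple[str, str]]
    directions: dict[tuple[str, str], frozenset[str]] = field(hash=False)

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.members):
            raise ValueError("a star module has exactly one edge per member")
        for e in self.edges:
            if self.hub not in e:
                raise ValueError(f"edge {e} not incident to hub {self.hub}")

    @property
    def name(self) -> str:
        return f"m{self.hub}"

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class ModuleCatalog:
    """Named map of hub -> module, tagged with its dataset of origin."""

    modules: dict[str, DIPModule]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, module in self.modules.items():
            if name != module.name:
                raise ValueError(f"catalog key {name!r} != module name {module.name!r}")

    def hubs(self) -> set[str]:
        return {m.hub for m in self.modules.values()}

    def __len__(self) -> int:
        return len(self.modules)


def _partner(edge: tuple[str, str], hub: str) -> str:
    return edge[1] if edge[0] == hub else edge[0]


def build_modules(
    dppis: list[DifferentialPPI], min_edges: int = DEFAULT_MIN_EDGES
) -> ModuleCatalog:
    """Build a module around every protein incident to >= min_edges dPPI edges.

    Distinct edges are counted: an edge called in both directions counts
    once toward the hub threshold, and its module annotation carries both
    directions.
    """
    incident: dict[str, dict[tuple[str, str], set[str]]] = {}
    for call in dppis:
        for node in call.edge:
            incident.setdefault(node, {}).setdefault(call.edge, set()).add(
                call.direction
            )
    modules: dict[str, DIPModule] = {}
    for hub, edge_dirs in incident.items():
        if len(edge_dirs) < min_edges:
            continue
        edges = frozenset(edge_dirs)
        module = DIPModule(
            hub=hub,
            members=frozenset(_partner(e, hub) for e in edges),
            edges=edges,
            directions={e: frozenset(d) for e, d in edge_dirs.items()},
        )
        modules[module.name] = module
    return ModuleCatalog(modules)


def intersect_catalogs(
    a: ModuleCatalog,
    b: ModuleCatalog,
    require_direction_agreement: bool = True,
) -> ModuleCatalog:
    """Common modules of two catalogs, keeping only shared interactions.

    A hub survives iff it is a hub in both catalogs and its two modules
    share at least one edge; the common module's edge set is the
    intersection. By default an edge is shared only if the two datasets
    agree on at least one direction for it (an interaction activated in one
    dataset and repressed in the other is not a shared signature); set
    ``require_direction_agreement=False`` to intersect on edges alone.

    Because hubs are thresholded before intersection, a common module may
    retain fewer shared edges than the hub threshold.
    """
    common: dict[str, DIPModule] = {}
    for name in sorted(set(a.modules) & set(b.modules)):
        ma, mb = a.modules[name], b.modules[name]
        edges = {}
        for e in ma.edges & mb.edges:
            dirs = ma.directions[e] & mb.directions[e]
            if require_direction_agreement:
                if dirs:
                    edges[e] = dirs
            else:
                edges[e] = ma.directions[e] | mb.directions[e]
        if not edges:
            continue
        hub = ma.hub
        common[name] = DIPModule(
            hub=hub,
            members=frozenset(_partner(e, hub) for e in edges),
            edges=frozenset(edges),
            directions=edges,
        )
    prov = " & ".join(p for p in (a.provenance, b.provenance) if p)
    return ModuleCatalog(common, provenance=prov)


def module_summary(catalog: ModuleCatalog) -> pd.DataFrame:
    """Per-module size and hub-sharing table.

    ``hub_sharing_degree`` counts the other modules in which a module's hub
    appears as a member — the quantity scaled by node color in hub-overlap
    network figures.
    """
    rows = []
    for name, module in sorted(catalog.modules.items()):
        sharing = sum(
            1
            for other_name, other in catalog.modules.items()
            if other_name != name and module.hub in other.members
        )
        rows.append(
            {"module": name, "hub": module.hub, "n_edges": len(module.edges),
             "hub_sharing_degree": sharing}
        )
    return pd.DataFrame(
        rows, columns=["module", "hub", "n_edges", "hub_sharing_degree"]
    )
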