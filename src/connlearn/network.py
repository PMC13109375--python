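"""The core learning network: regions, hemispheres, and edge catalogues.

The network has five regions of interest — dorsal anterior cingulate (ACC),
amygdala (AMY), cerebellar nuclei (CEB), hippocampus (HIP) and ventromedial
prefrontal cortex (PFC) — in each hemisphere, ten nodes in total. Connections
among cerebral regions are ipsilateral (same hemisphere); every connection
involving the cerebellar nuclei instead pairs CEB with a *contralateral*
cerebral region, because cerebellar output crosses at the level of the
brainstem. This yields 20 undirected edges (used for functional and
structural connectivity) and 40 directed edges (both orientations, used for
effective connectivity).

Node labels carry a lowercase hemisphere prefix (``lHIP``, ``rCEB``);
undirected edges are serialized ``lHIP-lAMY`` and directed edges
``lHIP->lAMY``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

REGIONS = ("ACC", "AMY", "CEB", "HIP", "PFC")
CEREBRAL = ("ACC", "AMY", "HIP", "PFC")
HEMISPHERES = ("L", "R")

#: node labels in canonical order: left hemisphere regions, then right
NODES = tuple(f"{h.lower()}{r}" for h in HEMISPHERES for r in REGIONS)


def node_label(region: str, hemisphere: str) -> str:
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"unknown hemisphere {hemisphere!r}; expected L or R")
    return f"{hemisphere.lower()}{region}"


def split_node(node: str) -> tuple[str, str]:
    """Return (region, hemisphere) for a node label like ``lHIP``."""
    hemi, region = node[0].upper(), node[1:]
    if hemi not in HEMISPHERES or region not in REGIONS:
        raise ValueError(f"malformed node label {node!r}")
    return region, hemi


def edge_label(a: str, b: str, directed: bool = False) -> str:
    if directed:
        return f"{a}->{b}"
    return f"{min(a, b)}-{max(a, b)}"


def parse_edge(label: str) -> tuple[str, str, bool]:
    """Parse an edge label; returns (source, target, directed)."""
    if "->" in label:
        a, b = label.split("->")
        directed = True
    elif "-" in label:
        a, b = label.split("-")
        directed = False
    else:
        raise ValueError(f"malformed edge label {label!r}")
    for node in (a, b):
        split_node(node)  # validates
    return a, b, directed


@dataclass(frozen=True)
class EdgeSet:
    """Catalogue of the network's undirected and directed edges.

    ``undirected`` holds 20 node pairs (sorted within pair); ``directed``
    holds the 40 ordered pairs obtained by taking both orientations of each
    undirected edge.
    """

    undirected: tuple[tuple[str, str], ...]
    directed: tuple[tuple[str, str], ...] = field(default=())

    def __post_init__(self):
        if not self.directed:
            directed = tuple(
                pair for (a, b) in self.undirected for pair in ((a, b), (b, a))
            )
            object.__setattr__(self, "directed", directed)

    @property
    def undirected_labels(self) -> list[str]:
        return [edge_label(a, b) for a, b in self.undirected]

    @property
    def directed_labels(self) -> list[str]:
        return [edge_label(a, b, directed=True) for a, b in self.directed]

    def labels(self, modality: str) -> list[str]:
        """Edge labels used as predictors for a connectivity modality."""
        if modality in ("FC", "SC"):
            return self.undirected_labels
        if modality == "EC":
            return self.directed_labels
        raise ValueError(f"unknown modality {modality!r}")

    def __len__(self) -> int:
        return len(self.undirected)


def default_edge_set() -> EdgeSet:
    """The 20-edge catalogue of the 10-node core learning network.

    Cerebral-cerebral edges pair same-hemisphere regions (6 pairs per
    hemisphere); CEB edges pair each cerebellar node with the four
    contralateral cerebral regions (8 edges).
    """
    edges: list[tuple[str, str]] = []
    for h in HEMISPHERES:
        for r1, r2 in combinations(CEREBRAL, 2):
            a, b = node_label(r1, h), node_label(r2, h)
            edges.append((min(a, b), max(a, b)))
    for h, other in (("L", "R"), ("R", "L")):
        ceb = node_label("CEB", h)
        for r in CEREBRAL:
            cer = node_label(r, other)
            edges.append((min(ceb, cer), max(ceb, cer)))
    return EdgeSet(undirected=tuple(edges))


def n_directed_edges(n_regions_per_hemisphere: int) -> int:
    """Directed edge count for a hypothetical network of n regions per
    hemisphere under the same pairing rules: 2 * (n^2 - n)."""
    n = n_regions_per_hemisphere
    return 2 * (n * n - n)
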