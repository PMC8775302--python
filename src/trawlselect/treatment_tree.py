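"""Treatment trees: gear designs connected stepwise by single modifications.

A treatment tree starts at a reference gear design (for the Basque fleet,
the regulated small top panel with the diamond codend, SMP_TS + CD_D) and
steps outward through the remaining designs; every arrow applies exactly one
design modification:

* increase SMP size (small -> large),
* move the SMP to the bottom panel (top -> bottom),
* remove the SMP (regardless of its size/position),
* change codend mesh geometry (diamond -> square).

Each edge carries a delta-selectivity comparison of treatment vs baseline;
each node can carry its selection curve or projected catch profile.  Size,
position and presence are treated as independent axes, so the forward
single-modification graph over the ten designs is a DAG rooted at the
reference in which every design is reachable.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .bootstrap_inference import CurveBand, DeltaCurveResult
from .catch_patterns import RetainedPopulation
from .data_model import GearDesignLabel

__all__ = [
    "MODIFICATIONS",
    "TreatmentTree",
    "TreeStructureError",
    "enumerate_modifications",
    "build_treatment_tree",
    "render_tree",
    "tree_to_dict",
]

#: Forward modification labels (direction: away from the reference design).
MODIFICATIONS = (
    "increase_smp_size",
    "move_smp_to_bottom",
    "remove_smp",
    "change_codend_geometry",
)


class TreeStructureError(ValueError):
    """Raised when a design set cannot form a connected treatment tree."""


def enumerate_modifications(a: GearDesignLabel, b: GearDesignLabel) -> list[str]:
    """Atomic design differences between two gears (empty when identical).

    Removing/adding the panel counts as a single modification whatever its
    size and position; when both gears carry a panel, size and position
    differences count separately.  The number of modifications is symmetric
    in the arguments; the labels encode the a -> b direction.
    """
    mods = []
    if a.smp_present != b.smp_present:
        mods.append("remove_smp" if a.smp_present else "add_smp")
    elif a.smp_present and b.smp_present:
        if a.smp_size != b.smp_size:
            mods.append("increase_smp_size" if a.smp_size == "S" else "decrease_smp_size")
        if a.smp_position != b.smp_position:
            mods.append("move_smp_to_bottom" if a.smp_position == "T" else "move_smp_to_top")
    if a.codend != b.codend:
        mods.append("change_codend_geometry")
    return mods


def _forward_modification(a: GearDesignLabel, b: GearDesignLabel) -> str | None:
    """The single forward modification turning a into b, if there is one."""
    mods = enumerate_modifications(a, b)
    if len(mods) != 1:
        return None
    mod = mods[0]
    if mod == "change_codend_geometry" and not (a.codend == "CD_D" and b.codend == "CD_S"):
        return None  # geometry steps run diamond -> square, away from the reference
    return mod if mod in MODIFICATIONS else None


@dataclass(frozen=True)
class TreatmentTree:
    """Gear designs as nodes, single forward modifications as directed edges."""

    reference: GearDesignLabel
    nodes: tuple[GearDesignLabel, ...]
    edges: tuple[tuple[GearDesignLabel, GearDesignLabel, str], ...]

    @property
    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for a, b, mod in self.edges:
            g.add_edge(a, b, modification=mod)
        return g

    def depth(self, node: GearDesignLabel) -> int:
        return nx.shortest_path_length(self.graph, self.reference, node)


def build_treatment_tree(
    designs: Iterable[GearDesignLabel], reference: GearDesignLabel
) -> TreatmentTree:
    """Connect a design set stepwise from the reference design.

    Edges are exactly the ordered pairs that differ by one forward
    modification.  Nodes and edges are ordered breadth-first from the
    reference with lexicographic tie-breaking, so the layout is reproducible.
    Raises :class:`TreeStructureError` if the reference is missing or some
    design cannot be reached stepwise (orphans are listed).
    """
    designs = sorted(set(designs), key=str)
    if reference not in designs:
        raise TreeStructureError(f"reference design {reference} not among the designs")

    edges = [
        (a, b, mod)
        for a in designs
        for b in designs
        if a != b and (mod := _forward_modification(a, b)) is not None
    ]
    adjacency: dict[GearDesignLabel, list[tuple[GearDesignLabel, str]]] = {d: [] for d in designs}
    for a, b, mod in edges:
        adjacency[a].append((b, mod))

    # breadth-first ordering from the reference, lexicographic within a level
    order: list[GearDesignLabel] = []
    seen = {reference}
    queue = deque([reference])
    ordered_edges: list[tuple[GearDesignLabel, GearDesignLabel, str]] = []
    while queue:
        node = queue.popleft()
        order.append(node)
        for nbr, mod in sorted(adjacency[node], key=lambda t: str(t[0])):
            ordered_edges.append((node, nbr, mod))
            if nbr not in seen:
                seen.add(nbr)
                queue.append(nbr)
    orphans = [d for d in designs if d not in seen]
    if orphans:
        raise TreeStructureError(
            "designs not reachable stepwise from the reference: "
            + ", ".join(str(d) for d in orphans)
        )
    return TreatmentTree(reference=reference, nodes=tuple(order), edges=tuple(ordered_edges))


def tree_to_dict(tree: TreatmentTree) -> dict:
    """JSON-ready export of the tree structure (nodes, edges, modifications)."""
    return {
        "reference": str(tree.reference),
        "nodes": [str(n) for n in tree.nodes],
        "edges": [
            {"baseline": str(a), "treatment": str(b), "modification": mod}
            for a, b, mod in tree.edges
        ],
    }


# ---------------------------------------------------------------------------
# Rendering


def _layered_positions(tree: TreatmentTree) -> dict[GearDesignLabel, tuple[float, float]]:
    depths: dict[int, list[GearDesignLabel]] = {}
    for node in tree.nodes:
        depths.setdefault(tree.depth(node), []).append(node)
    pos = {}
    for depth, nodes in depths.items():
        for i, node in enumerate(nodes):
            pos[node] = (float(depth), -(i - (len(nodes) - 1) / 2.0))
    return pos


def render_tree(
    tree: TreatmentTree,
    panels: str,
    out: str | Path,
    *,
    node_artifacts: Mapping[GearDesignLabel, object] | None = None,
    edge_artifacts: Mapping[tuple[GearDesignLabel, GearDesignLabel], DeltaCurveResult] | None = None,
    mcrs: float | None = None,
    reference_artifact: object | None = None,
) -> Path:
    """Render the treatment tree with per-node / per-edge data panels.

    ``panels`` selects what each box shows: ``"delta"`` draws one panel per
    edge (delta curve, CI band, zero line, significant ranges shaded);
    ``"selectivity"`` one :class:`CurveBand` panel per node; ``"catch_profile"``
    one :class:`RetainedPopulation` panel per node.  A missing artifact raises
    ``KeyError`` naming the node or edge.  The MCRS is drawn as a vertical
    reference line when given.  Returns the written path.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if panels not in ("delta", "selectivity", "catch_profile"):
        raise ValueError(f"unknown panel kind {panels!r}")
    if panels == "delta":
        items = [((a, b), f"{a} → {b}\n[{mod}]") for a, b, mod in tree.edges]
        artifacts = edge_artifacts or {}
    else:
        items = [(node, str(node)) for node in tree.nodes]
        artifacts = node_artifacts or {}
    for key, _ in items:
        if key not in artifacts:
            raise KeyError(f"no {panels} artifact for {key}")

    n = len(items)
    ncols = min(4, max(1, n))
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.6 * ncols, 2.6 * nrows), squeeze=False)
    for ax in axes.flat[n:]:
        ax.set_axis_off()
    for ax, (key, title) in zip(axes.flat, items):
        art = artifacts[key]
        if panels == "delta":
            ax.axhline(0.0, color="0.4", lw=0.8)
            ax.fill_between(art.lengths, art.lo, art.hi, color="0.8")
            ax.plot(art.lengths, art.delta, color="k")
            for lo_l, hi_l in art.significant_ranges:
                ax.axvspan(lo_l, hi_l, color="tab:blue", alpha=0.15)
            ax.set_ylim(-1.05, 1.05)
            ax.set_ylabel("Δr(l)")
        elif panels == "selectivity":
            ax.fill_between(art.lengths, art.lo, art.hi, color="0.8")
            ax.plot(art.lengths, art.mean, color="k")
            if reference_artifact is not None and key != tree.reference:
                ax.plot(reference_artifact.lengths, reference_artifact.mean, "g--", lw=1)
            ax.set_ylim(-0.02, 1.02)
            ax.set_ylabel("r(l)")
        else:
            if art.lo is not None:
                ax.fill_between(art.lengths, art.lo, art.hi, color="0.8")
            ax.plot(art.lengths, art.n, color="k")
            if reference_artifact is not None and key != tree.reference:
                ax.plot(reference_artifact.lengths, reference_artifact.n, "g--", lw=1)
            ax.set_ylabel("retained")
        if mcrs is not None:
            ax.axvline(mcrs, color="r", ls=":", lw=1)
        ax.set_title(title, fontsize=8)
        ax.set_xlabel("length (cm)")
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out)
    plt.close(fig)
    return out
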