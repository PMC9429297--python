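"""Minimal per-network drawing helper for visual inspection."""

from __future__ import annotations

from .io_model import PatientNetwork

__all__ = ["draw_network"]


def draw_network(net: PatientNetwork, path) -> None:
    """Draw one network (spring layout, arrows for direction) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(sorted(net.nodes))
    g.add_edges_from(sorted(net.links))
    pos = nx.spring_layout(g, seed=0)
    fig, ax = plt.subplots(figsize=(6, 6))
    nx.draw_networkx(
        g, pos=pos, ax=ax, node_size=200, font_size=6, arrows=True, node_color="#8ecae6"
    )
    ax.set_title(f"{net.group_id} / {net.year}")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
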