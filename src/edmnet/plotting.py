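"""Minimal plotting helpers for networks and temperature-sensitivity smooths."""
from __future__ import annotations


def plot_network(edges, ax=None, node_copies: dict | None = None):
    """Draw the retained interaction network (edge colour = TE)."""
    import matplotlib.pyplot as plt
    import networkx as nx

    from .sensitivity import to_graph

    g = to_graph(edges, node_copies=node_copies)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    pos = nx.spring_layout(g, seed=0)
    te = [d["te"] for _, _, d in g.edges(data=True)]
    sizes = None
    if node_copies:
        sizes = [100 + 400 * node_copies.get(n, 0) / max(node_copies.values())
                 for n in g.nodes]
    nx.draw_networkx(g, pos=pos, ax=ax, node_size=sizes or 300,
                     edge_color=te, edge_cmap=plt.cm.viridis,
                     node_color="#86b4d4", font_size=7, arrows=True)
    ax.set_axis_off()
    return ax


def plot_strength_fit(fit, ax=None, show_ci: bool = True):
    """Fitted |IS| smooth against its predictor with the 95% band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(fit.grid, fit.mean, color="C0")
    if show_ci:
        ax.fill_between(fit.grid, fit.ci_low, fit.ci_high, alpha=0.25, color="C0")
    ax.set_xlabel(fit.predictor)
    ax.set_ylabel("|interaction strength|")
    ax.set_title(f"{fit.direction}-strength, p={fit.p_smooth:.3g} ({fit.sign_class})")
    return ax
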