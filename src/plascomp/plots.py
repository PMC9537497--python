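"""Optional figure output: circular ring plot and linear synteny plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ranking import RingMatrix
from .synteny import SyntenyChain


def ring_plot(
    matrix: RingMatrix,
    path,
    family_colors: dict[str, str] | None = None,
) -> None:
    """Polar ring plot: one ring per target (rank order, outermost
    first), one sector per query CDS; blank sectors mean no homologue.
    ``family_colors`` maps target id -> color (e.g. by host family)."""
    n = len(matrix.query_cds_order)
    if n == 0 or not matrix.rows:
        raise ValueError("empty ring matrix")
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    width = 2 * np.pi / n
    n_rows = len(matrix.rows)
    for r, (tid, cells) in enumerate(matrix.rows):
        radius = 1.0 - r / (n_rows + 1)
        color = (family_colors or {}).get(tid, f"C{r % 10}")
        present = [t for t, c in zip(theta, cells) if c is not None]
        ax.bar(
            present,
            height=0.8 / (n_rows + 1),
            width=width,
            bottom=radius,
            color=color,
            edgecolor="none",
            align="edge",
        )
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title("per-CDS homologue presence (outermost = rank 1)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def synteny_plot(chain: SyntenyChain, path) -> None:
    """Two gene tracks with ribbons connecting chained homologue pairs."""
    n = chain.chain_len
    fig, ax = plt.subplots(figsize=(max(6, n), 2.5))
    for i, (q, t) in enumerate(chain.pairs):
        ti = i if chain.orientation == "same" else n - 1 - i
        ax.plot([i, ti], [1, 0], color="C0", alpha=0.6)
        ax.annotate(q, (i, 1.05), rotation=45, fontsize=7)
        ax.annotate(t, (ti, -0.15), rotation=45, fontsize=7)
    ax.set_ylim(-0.5, 1.6)
    ax.axis("off")
    ax.set_title(
        f"{chain.cluster_id or 'cluster'} vs {chain.target_id}: "
        f"{n} genes, {chain.orientation}"
    )
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
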