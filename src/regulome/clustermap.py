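"""Hierarchical clustering of the z-matrix and clustered-heatmap rendering.

Both axes of the regulome are clustered independently with agglomerative
UPGMA (unweighted average linkage) on Euclidean distances between z-score
profiles, so diseases with similar TF-association profiles end up adjacent
and vice versa.  Undefined z cells (zero null variance) are imputed as 0
for the distance computation only — they carry no differential signal —
and rendered in a distinct missing-data grey.

Determinism: axis labels are sorted lexicographically before linkage, so
the tree is invariant to input ordering; leaf ordering places the tighter
(lower merge height) subtree first, ties broken by smallest leaf label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .enrichment import RegulomeMatrix

__all__ = ["LinkageTree", "ClusterMap", "cluster_axis", "cut_tree", "render_heatmap"]


@dataclass
class LinkageTree:
    """A UPGMA clustering of one axis.

    ``labels`` index the leaves as referenced by ``merges`` (scipy linkage
    format: each row merges two clusters at a height, recording the new
    cluster's size); ``leaf_order`` is the display permutation.
    """

    labels: list[str]
    merges: np.ndarray  # (n-1, 4) scipy linkage matrix; empty for a single leaf
    leaf_order: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> np.ndarray:
        return self.merges[:, 2] if self.merges.size else np.empty(0)

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = self.n_leaves
        if n == 1:
            return f"{self.labels[0]}:0;"
        height = {i: 0.0 for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.merges):
            height[n + i] = float(h)

        def node(i: int) -> str:
            if i < n:
                return self.labels[i]
            a, b = int(self.merges[i - n, 0]), int(self.merges[i - n, 1])
            h = height[i]
            return (
                f"({node(a)}:{h - height[a]:g},{node(b)}:{h - height[b]:g})"
            )

        return node(2 * n - 2) + ";"


@dataclass
class ClusterMap:
    matrix: RegulomeMatrix
    row_tree: LinkageTree
    col_tree: LinkageTree
    z_cap: float = 8.0

    def __post_init__(self) -> None:
        T, D = self.matrix.counts.shape
        if self.row_tree.n_leaves != T or self.col_tree.n_leaves != D:
            raise ValueError("trees do not match matrix dimensions")
        if self.z_cap <= 0:
            raise ValueError("z_cap must be positive")


def _ordered_leaves(Z: np.ndarray, labels: list[str]) -> list[str]:
    """Leaf order with the tighter subtree first; ties by smallest label."""
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    for i, row in enumerate(Z):
        height[n + i] = float(row[2])

    def min_label(i: int) -> str:
        return min(labels[j] for j in leaves(i))

    def leaves(i: int) -> list[int]:
        if i < n:
            return [i]
        a, b = int(Z[i - n, 0]), int(Z[i - n, 1])
        ca, cb = (a, b)
        if (height[a], min_label(a)) > (height[b], min_label(b)):
            ca, cb = b, a
        return leaves(ca) + leaves(cb)

    return [labels[j] for j in leaves(2 * n - 2)]


def cluster_axis(matrix: RegulomeMatrix, axis: Literal["rows", "cols"]) -> LinkageTree:
    """UPGMA on Euclidean distances between the axis's z-profiles.

    NaN z values are imputed as 0 for the distance computation.  Heights of
    an average-linkage tree are non-decreasing (no inversions), which is
    asserted on every run.
    """
    z = np.nan_to_num(matrix.z, nan=0.0)
    if axis == "rows":
        profiles, labels = z, list(matrix.row_names)
    elif axis == "cols":
        profiles, labels = z.T, list(matrix.col_names)
    else:
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    order = np.argsort(np.array(labels, dtype=object))
    labels = [labels[i] for i in order]
    profiles = profiles[order]
    if len(labels) == 1:
        return LinkageTree(labels, np.empty((0, 4)), list(labels))
    Z = linkage(pdist(profiles, metric="euclidean"), method="average")
    heights = Z[:, 2]
    assert np.all(np.diff(heights) >= -1e-9), "average-linkage height inversion"
    return LinkageTree(labels, Z, _ordered_leaves(Z, labels))


def cut_tree(
    tree: LinkageTree, k: int | None = None, height: float | None = None
) -> dict[str, int]:
    """Cut the tree into flat clusters, by count k or by merge height.

    Returns label -> cluster id, ids numbered by first appearance along
    ``leaf_order`` (so cluster 1 is leftmost in the rendered map).
    """
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    n = tree.n_leaves
    if k is not None and not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if n == 1 or k == 1:
        return {lab: 1 for lab in tree.labels}
    if k is not None:
        raw = fcluster(tree.merges, t=k, criterion="maxclust")
    else:
        raw = fcluster(tree.merges, t=height, criterion="distance")
    by_label = dict(zip(tree.labels, (int(c) for c in raw)))
    remap: dict[int, int] = {}
    for lab in tree.leaf_order:
        remap.setdefault(by_label[lab], len(remap) + 1)
    return {lab: remap[c] for lab, c in by_label.items()}


# ---------------------------------------------------------------------------
# Rendering


def _diverging_cmap():
    """Cyan -> blue -> black -> red -> yellow, black anchored at z = 0."""
    from matplotlib.colors import LinearSegmentedColormap

    return LinearSegmentedColormap.from_list(
        "regulome",
        [(0.0, "#00ffff"), (0.25, "#0000cc"), (0.5, "#000000"),
         (0.75, "#cc0000"), (1.0, "#ffff00")],
    )


def _plot_dendrogram(ax, tree: LinkageTree, orientation: str) -> None:
    """Draw the tree aligned with the tree's own leaf_order.

    Drawn by hand (rather than scipy's dendrogram) so the leaves line up
    exactly with the heatmap's deterministic ordering.
    """
    n = tree.n_leaves
    Z = tree.merges
    pos = {tree.labels.index(lab): float(i) for i, lab in enumerate(tree.leaf_order)}
    height = {i: 0.0 for i in range(n)}

    def coord(i: int) -> float:
        if i in pos:
            return pos[i]
        a, b = int(Z[i - n, 0]), int(Z[i - n, 1])
        pos[i] = (coord(a) + coord(b)) / 2
        return pos[i]

    for i, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        xa, xb = coord(a), coord(b)
        ha, hb = height[a], height[b]
        height[n + i] = float(h)
        xs = [xa, xa, xb, xb]
        ys = [ha, h, h, hb]
        if orientation == "top":
            ax.plot(xs, ys, color="#444444", linewidth=0.8)
        else:
            ax.plot(ys, xs, color="#444444", linewidth=0.8)
    coord(2 * n - 2)
    if orientation == "top":
        ax.set_xlim(-0.5, n - 0.5)
    else:
        ax.set_ylim(n - 0.5, -0.5)
        ax.invert_xaxis()
    ax.set_axis_off()


def render_heatmap(
    cm: ClusterMap,
    out_path: str | Path,
    format: Literal["png", "svg", "html"] = "png",
) -> Path:
    """Write the clustered heatmap.

    z is clipped at ±z_cap on a diverging scale with black at 0; cells with
    undefined z are grey; significance dots mark flagged cells; dendrograms
    are drawn on both margins.  The HTML output embeds the full per-cell
    table (observed, expected, z, p) as JSON with hover detail.
    """
    out_path = Path(out_path)
    mat = cm.matrix
    row_order = [mat.row_names.index(lab) for lab in cm.row_tree.leaf_order]
    col_order = [mat.col_names.index(lab) for lab in cm.col_tree.leaf_order]
    z = mat.z[np.ix_(row_order, col_order)]
    if format == "html":
        _render_html(cm, z, row_order, col_order, out_path)
        return out_path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    T, D = z.shape
    fig = plt.figure(figsize=(max(6, 0.25 * D + 3), max(5, 0.25 * T + 3)))
    gs = fig.add_gridspec(
        2, 2, width_ratios=[1, 4], height_ratios=[1, 4], wspace=0.02, hspace=0.02
    )
    ax_col = fig.add_subplot(gs[0, 1])
    ax_row = fig.add_subplot(gs[1, 0])
    ax_hm = fig.add_subplot(gs[1, 1])
    if cm.col_tree.merges.size:
        _plot_dendrogram(ax_col, cm.col_tree, "top")
    else:
        ax_col.set_axis_off()
    if cm.row_tree.merges.size:
        _plot_dendrogram(ax_row, cm.row_tree, "left")
    else:
        ax_row.set_axis_off()
    cmap = _diverging_cmap()
    cmap.set_bad("#888888")
    shown = np.ma.masked_invalid(np.clip(z, -cm.z_cap, cm.z_cap))
    im = ax_hm.imshow(
        shown, cmap=cmap, vmin=-cm.z_cap, vmax=cm.z_cap, aspect="auto",
        interpolation="nearest",
    )
    if mat.sig_over is not None:
        so = mat.sig_over[np.ix_(row_order, col_order)]
        su = mat.sig_under[np.ix_(row_order, col_order)]
        ys, xs = np.nonzero(so | su)
        ax_hm.scatter(xs, ys, s=12, facecolors="white", edgecolors="black",
                      linewidths=0.5, zorder=3)
    ax_hm.set_xticks(range(D))
    ax_hm.set_xticklabels(cm.col_tree.leaf_order, rotation=90, fontsize=6)
    ax_hm.set_yticks(range(T))
    ax_hm.set_yticklabels(cm.row_tree.leaf_order, fontsize=6)
    ax_hm.yaxis.tick_right()
    fig.colorbar(im, ax=ax_hm, fraction=0.03, pad=0.08, label="z")
    fig.savefig(out_path, format=format, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out_path


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
 body {{ font-family: sans-serif; }}
 td.cell {{ width: 14px; height: 14px; padding: 0; }}
 td.lab {{ font-size: 9px; white-space: nowrap; }}
 #detail {{ position: fixed; bottom: 0; left: 0; background: #eee;
            padding: 4px 8px; font-size: 12px; }}
</style></head>
<body>
<h2>{title}</h2>
<table id="hm" cellspacing="0">{table_rows}</table>
<div id="detail">hover a cell for detail</div>
<script>
const cells = {cells_json};
document.querySelectorAll('td.cell').forEach(td => {{
  td.addEventListener('mouseover', () => {{
    const c = cells[+td.dataset.i];
    document.getElementById('detail').textContent =
      `${{c.tf}} x ${{c.disease}}: observed=${{c.observed}} expected=${{c.expected}} ` +
      `z=${{c.z}} p_over=${{c.p_over}} p_under=${{c.p_under}}`;
  }});
}});
</script>
</body></html>
"""


def _render_html(cm, z_ordered, row_order, col_order, out_path: Path) -> None:
    mat = cm.matrix
    cmap = _diverging_cmap()
    cells = []
    rows_html = []
    i = 0
    header = "<tr><td></td>" + "".join(
        f'<td class="lab">{lab}</td>' for lab in cm.col_tree.leaf_order
    ) + "</tr>"
    rows_html.append(header)
    for ri, rlab in zip(row_order, cm.row_tree.leaf_order):
        tds = [f'<td class="lab">{rlab}</td>']
        for ci, clab in zip(col_order, cm.col_tree.leaf_order):
            zv = mat.z[ri, ci]
            if np.isnan(zv):
                color = "#888888"
            else:
                frac = (np.clip(zv, -cm.z_cap, cm.z_cap) + cm.z_cap) / (2 * cm.z_cap)
                r, g, b, _ = cmap(float(frac))
                color = f"#{int(r*255):02x}{int(g*255):02x}{int(b*255):02x}"
            cells.append(
                {
                    "tf": rlab,
                    "disease": clab,
                    "observed": int(mat.counts.observed[ri, ci]),
                    "expected": round(float(mat.expected[ri, ci]), 4),
                    "z": None if np.isnan(zv) else round(float(zv), 4),
                    "p_over": round(float(mat.p_over[ri, ci]), 6),
                    "p_under": round(float(mat.p_under[ri, ci]), 6),
                }
            )
            tds.append(
                f'<td class="cell" data-i="{i}" style="background:{color}"></td>'
            )
            i += 1
        rows_html.append("<tr>" + "".join(tds) + "</tr>")
    html = _HTML_TEMPLATE.format(
        title=f"Regulome ({mat.null_model} null)",
        table_rows="\n".join(rows_html),
        cells_json=json.dumps(cells),
    )
    out_path.write_text(html)
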