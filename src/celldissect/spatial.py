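"""Spatial re-integration: map class-level proteome results back onto the image.

Cell classes are dissected and measured as class-level proteomes, so
pathway-level scores exist per class, not per cell.  This module parses
the per-class cell-geometry XML exports, computes centroids, attaches the
class's pathway scores to every cell of that class, and renders the
"tissue heat map": cell centroids colored by a selected annotation term's
z-scored class score.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .lmd import read_cutplan_xml

__all__ = [
    "read_geometry_xml",
    "class_pathway_scores",
    "build_overlay",
    "render_tissue_heatmap",
]

logger = logging.getLogger(__name__)


def _read_generic_polygon_xml(path) -> list[tuple[int, np.ndarray]]:
    """Minimal generic dialect: <cells><cell id="..."><point x="..." y="..."/>...</cells>."""
    root = ET.parse(path).getroot()
    cells = []
    for el in root.iter():
        if el.tag.lower() != "cell":
            continue
        cid = int(el.get("id", len(cells) + 1))
        pts = np.array(
            [[float(p.get("x")), float(p.get("y"))] for p in el if p.tag.lower() == "point"]
        )
        if len(pts) >= 3:
            cells.append((cid, pts))
    return cells


def read_geometry_xml(files_by_class: dict[int, object]) -> pd.DataFrame:
    """Aggregate per-class cell-geometry XML exports into one table.

    ``files_by_class`` maps class label → path of that class's geometry
    file, either in the package's LMD contour dialect or in a minimal
    generic polygon dialect.  Object ids are compounded with the class, so
    ids may repeat across files.  Returns one row per cell with columns
    class_label, object_id, centroid_x_um, centroid_y_um, area_um2,
    vertices (object column of (n, 2) arrays).
    """
    rows = []
    for class_label, path in files_by_class.items():
        root_tag = ET.parse(path).getroot().tag
        if root_tag == "ImageData":
            contours, _, _ = read_cutplan_xml(path)
            cells = [(c.object_id, c.vertices) for c in contours]
        else:
            cells = _read_generic_polygon_xml(path)
        for cid, verts in cells:
            closed = np.vstack([verts, verts[:1]])
            x, y = closed[:, 0], closed[:, 1]
            cross = x[:-1] * y[1:] - x[1:] * y[:-1]
            area = cross.sum() / 2.0
            if area == 0:
                raise ValueError(f"degenerate polygon (cell {cid}) in {path}")
            cx = ((x[:-1] + x[1:]) * cross).sum() / (6.0 * area)
            cy = ((y[:-1] + y[1:]) * cross).sum() / (6.0 * area)
            rows.append(
                {
                    "class_label": class_label,
                    "object_id": cid,
                    "centroid_x_um": cx,
                    "centroid_y_um": cy,
                    "area_um2": abs(area),
                    "vertices": verts,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["class_label", "object_id", "centroid_x_um", "centroid_y_um", "area_um2", "vertices"],
    )


def class_pathway_scores(
    class_matrix: pd.DataFrame, terms: dict[str, set[str]], zscore: bool = True
) -> pd.DataFrame:
    """Median-per-annotation class scores, z-scored across classes.

    ``class_matrix`` is proteins × classes (one quantified proteome per
    cell class).  For each term, the score of a class is the median level
    of the term's quantified member proteins in that class; scores are
    then z-scored across classes per term (sample sd), which is the color
    scale of the tissue heat map.  Terms with no quantified members get no
    row.  With ``zscore=False`` raw medians are returned (alternative
    whole-slide normalizations can then be applied by the caller).
    """
    rows = {}
    for term, members in terms.items():
        present = class_matrix.index.intersection(list(members))
        if present.empty:
            logger.warning("term %r has no quantified member proteins; skipped", term)
            continue
        med = class_matrix.loc[present].median(axis=0)
        if zscore:
            sd = med.std(ddof=1)
            med = (med - med.mean()) / sd if sd > 0 else med * 0.0
        rows[term] = med
    return pd.DataFrame(rows).T  # terms × classes


def build_overlay(geometry: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Join per-cell geometry with per-class term scores.

    ``scores`` is terms × classes (from :func:`class_pathway_scores`).
    Every cell inherits the scores of its class; classes absent from the
    score table get NaN (explicit missing marker).  Returns the per-cell
    overlay with one ``score:<term>`` column per term.
    """
    overlay = geometry[["object_id", "class_label", "centroid_x_um", "centroid_y_um"]].copy()
    for term in scores.index:
        per_class = scores.loc[term]
        overlay[f"score:{term}"] = overlay["class_label"].map(per_class.to_dict())
    return overlay


def render_tissue_heatmap(
    overlay: pd.DataFrame,
    term: str,
    ax: plt.Axes | None = None,
    point_size: float = 12.0,
    cmap: str = "RdBu_r",
    missing_color: str = "0.7",
):
    """Scatter cell centroids colored by one term's class z-score.

    The color scale is a symmetric diverging map centered at 0.  Cells of
    classes without a score for the term are drawn in a neutral "no data"
    color and reported in the log.  Returns ``(figure, table)`` where
    ``table`` has columns (x, y, class, score) exactly as plotted.
    """
    col = f"score:{term}"
    if col not in overlay.columns:
        raise KeyError(f"unknown term {term!r}")
    table = overlay.rename(
        columns={"centroid_x_um": "x", "centroid_y_um": "y", "class_label": "class"}
    )[["x", "y", "class", col]].rename(columns={col: "score"})
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 6))
    else:
        fig = ax.figure
    have = table["score"].notna()
    if (~have).any():
        logger.warning(
            "%d cells (classes %s) have no score for %r; drawn in no-data color",
            (~have).sum(), sorted(table.loc[~have, "class"].unique()), term,
        )
        ax.scatter(table.loc[~have, "x"], table.loc[~have, "y"], s=point_size,
                   color=missing_color, label="no data")
    vmax = float(np.nanmax(np.abs(table["score"]))) if have.any() else 1.0
    vmax = vmax if vmax > 0 else 1.0
    sc = ax.scatter(
        table.loc[have, "x"], table.loc[have, "y"], c=table.loc[have, "score"],
        s=point_size, cmap=cmap, vmin=-vmax, vmax=vmax,
    )
    fig.colorbar(sc, ax=ax, label=f"{term} (z-score)")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    ax.invert_yaxis()  # image convention: y downward
    ax.set_title(term)
    return fig, table
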