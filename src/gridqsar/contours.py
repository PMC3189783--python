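"""stdev*coeff contour maps from a fitted PLS field model.

At every retained lattice column the product of the PLS regression
coefficient (in original descriptor units) and the column's standard
deviation marks how strongly local field variation drives predicted
activity; filtered-out columns are zero.  Favoured/disfavoured level sets
are taken at percentiles of the nonzero value distribution (80/20 by
default, the customary display levels), and connected regions (6-neighbour
lattice connectivity) are reported with the nearest substituent-position
label of a reference compound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .fields import FieldBlock, GridSpec
from .molecule import Molecule3D
from .pls import PLSModel

__all__ = [
    "ContourMap",
    "Region",
    "stdev_coeff_map",
    "contour_levels",
    "connected_regions",
    "substituent_report",
]


@dataclass
class ContourMap:
    """Lattice of coefficient * column-sd values with optional level sets."""

    field_kind: str
    grid: GridSpec
    values: np.ndarray  # flat, one per lattice point
    favored_level: Optional[float] = None
    disfavored_level: Optional[float] = None
    favored_points: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    disfavored_points: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def values_3d(self) -> np.ndarray:
        return self.values.reshape(self.grid.dims)


def stdev_coeff_map(model: PLSModel, block: FieldBlock) -> ContourMap:
    """Coefficient x standard-deviation lattice for one field block.

    The model must have been fitted on descriptors that include this
    block's retained columns (provenance is checked through the stored
    field kinds and lattice column indices).
    """
    if model.column_field_kinds is None or model.column_grid_indices is None:
        raise ValueError("model carries no column provenance; refit with metadata")
    sel = np.flatnonzero(model.column_field_kinds == block.field_kind)
    if sel.size == 0:
        raise ValueError(
            f"model was not fitted on any {block.field_kind!r} columns"
        )
    cols = np.asarray(model.column_grid_indices[sel], int)
    if cols.max() >= block.grid.n_points:
        raise ValueError("model/block provenance mismatch: column index beyond grid")
    sds = block.matrix.std(axis=0, ddof=0)
    values = np.zeros(block.grid.n_points)
    values[cols] = model.coef_raw[sel] * sds[cols]
    return ContourMap(field_kind=block.field_kind, grid=block.grid, values=values)


def contour_levels(
    cmap: ContourMap, favored_pct: float = 80.0, disfavored_pct: float = 20.0
) -> ContourMap:
    """Populate favoured/disfavoured levels and index sets in place.

    Levels are percentiles of the *nonzero* value distribution; the
    favoured set collects points at or above the favoured level, the
    disfavoured set points at or below the disfavoured level.  An all-zero
    map yields empty sets.
    """
    nz = cmap.values[cmap.values != 0.0]
    if nz.size == 0:
        import warnings

        warnings.warn(f"all-zero {cmap.field_kind} map; empty contour sets", stacklevel=2)
        cmap.favored_level = cmap.disfavored_level = None
        cmap.favored_points = np.array([], dtype=int)
        cmap.disfavored_points = np.array([], dtype=int)
        return cmap
    cmap.favored_level = float(np.percentile(nz, favored_pct))
    cmap.disfavored_level = float(np.percentile(nz, disfavored_pct))
    nonzero = cmap.values != 0.0
    cmap.favored_points = np.flatnonzero(nonzero & (cmap.values >= cmap.favored_level))
    cmap.disfavored_points = np.flatnonzero(
        nonzero & (cmap.values <= cmap.disfavored_level)
    )
    return cmap


@dataclass
class Region:
    """A connected component of a contour level set."""

    kind: str  # "favored" | "disfavored"
    point_indices: np.ndarray
    peak_value: float
    centroid: np.ndarray  # Cartesian
    nearest_label: Optional[str] = None
    nearest_distance: float = float("nan")


def connected_regions(cmap: ContourMap) -> List[Region]:
    """Split both level sets into 6-connected lattice components."""
    regions: List[Region] = []
    pts = cmap.grid.points()
    structure = ndimage.generate_binary_structure(3, 1)  # faces only
    for kind, idx in (
        ("favored", cmap.favored_points),
        ("disfavored", cmap.disfavored_points),
    ):
        if idx.size == 0:
            continue
        mask = np.zeros(cmap.grid.n_points, bool)
        mask[idx] = True
        labels, n = ndimage.label(mask.reshape(cmap.grid.dims), structure=structure)
        flat_labels = labels.reshape(-1)
        for lab in range(1, n + 1):
            members = np.flatnonzero(flat_labels == lab)
            vals = cmap.values[members]
            peak = vals[np.argmax(np.abs(vals))]
            regions.append(
                Region(
                    kind=kind,
                    point_indices=members,
                    peak_value=float(peak),
                    centroid=pts[members].mean(axis=0),
                )
            )
    return regions


def substituent_report(
    cmap: ContourMap,
    ref: Molecule3D,
    anchors: Optional[Dict[str, np.ndarray]] = None,
) -> Tuple[List[Region], str]:
    """Annotate contour regions with the nearest substituent site of ``ref``.

    ``anchors`` may override the label -> position map; by default the
    reference molecule's recorded anchor atoms are used.  Returns the
    annotated regions and a plain-text report.
    """
    if anchors is None:
        if not ref.anchors:
            anchors = {}
        else:
            anchors = {lbl: ref.coords[i] for lbl, i in ref.anchors.items()}
    regions = connected_regions(cmap)
    labels = list(anchors)
    positions = np.array([anchors[l] for l in labels]) if labels else np.empty((0, 3))
    pts = cmap.grid.points()
    lines = [f"# {cmap.field_kind} contour regions ({len(regions)})"]
    for i, reg in enumerate(regions):
        if labels:
            d = np.linalg.norm(
                pts[reg.point_indices][:, None, :] - positions[None, :, :], axis=2
            )
            flat = np.argmin(d)
            _, j = np.unravel_index(flat, d.shape)
            reg.nearest_label = labels[j]
            reg.nearest_distance = float(d.min())
        lines.append(
            f"{i:3d} {reg.kind:11s} n_points={reg.point_indices.size:4d} "
            f"peak={reg.peak_value:+.4f} nearest={reg.nearest_label} "
            f"dist={reg.nearest_distance:.2f} A"
        )
    if not regions:
        lines.append("(no contour regions)")
    return regions, "\n".join(lines)
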