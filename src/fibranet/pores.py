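"""Pore identification, pore-area statistics and porosity.

Pores are 4-connected background components (against 8-connected fibers,
the standard duality that stops diagonal leak-through).  Components that
touch the frame border are partial pores: they are flagged, kept in the
pore list, and excluded from the complete-pore statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import BinaryMask

__all__ = [
    "Pore",
    "PoreSummary",
    "find_pores",
    "pore_statistics",
    "porosity",
    "summarize_layers",
    "DEFAULT_BIN_WIDTH_UM2",
    "DEFAULT_SMALL_CUTOFF_UM2",
    "DEFAULT_DOMINANT_CENTER_UM2",
]

DEFAULT_SMALL_CUTOFF_UM2 = 5.5
DEFAULT_DOMINANT_CENTER_UM2 = 2.75
#: bin width 5.5/3: the first three bins then span [0, 5.5) exactly and the
#: second bin is centred at 2.75 μm²
DEFAULT_BIN_WIDTH_UM2 = DEFAULT_SMALL_CUTOFF_UM2 / 3.0


@dataclass
class Pore:
    label: int
    area_um2: float
    touches_border: bool
    centroid_px: tuple[float, float]


@dataclass
class PoreSummary:
    """Complete-pore statistics of one mask (Table-style row)."""

    total_full_pores: int
    fraction_dominant: float | None
    fraction_small: float | None
    porosity: float | None
    bin_edges_um2: np.ndarray
    counts: np.ndarray


def find_pores(mask: BinaryMask) -> list[Pore]:
    """Label 4-connected background components with areas in μm²."""
    bg = ~mask.grid
    lab, n = ndimage.label(bg, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n == 0:
        return []
    border_labels = set(np.unique(lab[0, :])) | set(np.unique(lab[-1, :]))
    border_labels |= set(np.unique(lab[:, 0])) | set(np.unique(lab[:, -1]))
    border_labels.discard(0)
    areas = ndimage.sum_labels(bg, lab, index=np.arange(1, n + 1))
    centroids = ndimage.center_of_mass(bg, lab, index=np.arange(1, n + 1))
    px2 = mask.pixel_size**2
    return [
        Pore(
            label=k,
            area_um2=float(areas[k - 1] * px2),
            touches_border=k in border_labels,
            centroid_px=tuple(centroids[k - 1]),
        )
        for k in range(1, n + 1)
    ]


def pore_statistics(
    pores: list[Pore],
    *,
    bin_width_um2: float = DEFAULT_BIN_WIDTH_UM2,
    small_cutoff_um2: float = DEFAULT_SMALL_CUTOFF_UM2,
    dominant_bin_center_um2: float = DEFAULT_DOMINANT_CENTER_UM2,
) -> PoreSummary:
    """Histogram complete pores and report dominant/small fractions.

    With zero complete pores the fractions are missing (``None``), never 0.
    """
    areas = np.array([p.area_um2 for p in pores if not p.touches_border])
    total = len(areas)
    if total == 0:
        return PoreSummary(
            total_full_pores=0,
            fraction_dominant=None,
            fraction_small=None,
            porosity=None,
            bin_edges_um2=np.array([0.0, bin_width_um2]),
            counts=np.array([0]),
        )
    n_bins = max(int(np.ceil(areas.max() / bin_width_um2)), 1)
    edges = np.arange(n_bins + 1) * bin_width_um2
    counts, _ = np.histogram(areas, bins=edges)
    dom_bin = int(dominant_bin_center_um2 // bin_width_um2)
    frac_dom = float(counts[dom_bin] / total) if dom_bin < len(counts) else 0.0
    frac_small = float((areas < small_cutoff_um2).sum() / total)
    return PoreSummary(
        total_full_pores=total,
        fraction_dominant=frac_dom,
        fraction_small=frac_small,
        porosity=None,
        bin_edges_um2=edges,
        counts=counts,
    )


def porosity(mask: BinaryMask) -> float:
    """Background area fraction of the full frame."""
    return float(1.0 - mask.grid.mean())


def summarize_layers(per_layer_values: dict[str, dict[str, list[float]]]) -> pd.DataFrame:
    """Aggregate per-image statistic vectors into per-layer means.

    ``per_layer_values`` maps layer label → {statistic name → list of
    per-image values}.  Returns a tidy frame with one row per (layer,
    statistic) carrying the value vector and its mean; ragged vectors are
    averaged over whatever is available.
    """
    rows = []
    for layer, stats in per_layer_values.items():
        for stat, values in stats.items():
            vals = [v for v in values if v is not None]
            rows.append(
                {
                    "layer": layer,
                    "statistic": stat,
                    "values": list(vals),
                    "n_images": len(vals),
                    "mean": float(np.mean(vals)) if vals else None,
                }
            )
    return pd.DataFrame(rows)
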