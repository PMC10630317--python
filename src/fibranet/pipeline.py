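"""End-to-end orchestration: mask → descriptors, curves → moduli, layers → report."""

from __future__ import annotations

from dataclasses import asdict

import numpy as np

from . import fiber_typing, network, pores
from .errors import FitRejectedError, InsufficientDataError
from .indentation import analyze_curve
from .report import LayerDescriptors
from .segmentation import BinaryMask

__all__ = ["analyze_mask", "analyze_layer"]


def analyze_mask(mask: BinaryMask, *, k_max: int = fiber_typing.DEFAULT_K_MAX,
                 seed: int = 0, fit_types: bool = True) -> LayerDescriptors:
    """All image-derived descriptors of one mask as a LayerDescriptors bundle."""
    sk, stats, radii = network.analyze_network(mask)
    pore_list = pores.find_pores(mask)
    summary = pores.pore_statistics(pore_list)
    ftypes = {}
    if fit_types and len(radii) >= fiber_typing.MIN_SAMPLES_PER_COMPONENT:
        sd_floor = 0.5 * mask.pixel_size
        model = fiber_typing.select_components(
            radii, k_max=k_max, seed=seed, sd_floor=sd_floor
        )
        ftypes = {
            "n_components": model.n_components,
            "means": model.means.tolist(),
            "sds": model.sds.tolist(),
            "weights": model.weights.tolist(),
            "aic": model.aic,
        }
    return LayerDescriptors(
        label="",
        crosslink_density=stats.crosslink_density,
        network_density=stats.network_density,
        mean_segment_length=stats.mean_segment_length,
        porosity=pores.porosity(mask),
        pore_summary={
            "total_full_pores": summary.total_full_pores,
            "fraction_dominant": summary.fraction_dominant,
            "fraction_small": summary.fraction_small,
        },
        fiber_types=ftypes,
    )


def analyze_layer(label: str, mask: BinaryMask, curves=(), *, R_um: float = 92.03,
                  poisson_ratio: float = 0.0, seed: int = 0,
                  k_max: int = fiber_typing.DEFAULT_K_MAX) -> LayerDescriptors:
    """Descriptors plus per-indent moduli for one layer."""
    desc = analyze_mask(mask, k_max=k_max, seed=seed)
    desc.label = label
    e_values = []
    for curve in curves:
        try:
            fit = analyze_curve(curve, R_um, poisson_ratio=poisson_ratio)
        except (FitRejectedError, InsufficientDataError):
            continue
        if fit.accepted and np.isfinite(fit.E_kPa):
            e_values.append(float(fit.E_kPa))
    desc.E_kPa = e_values
    return desc
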