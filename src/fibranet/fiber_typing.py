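"""Dominant fiber-type identification by 1-D Gaussian mixtures with AIC.

The fiber-radius histogram of a layered network is multimodal; each mode is
one dominant fiber type (mean radius, spread, mixing weight).  The number
of types is chosen by minimising the Akaike information criterion
``AIC = 2p − 2·logL`` with ``p = 3K − 1`` free parameters for K components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .errors import InsufficientDataError

__all__ = ["FiberTypeModel", "fit_mixture", "select_components", "model_density",
           "export_histogram"]

#: minimum samples per component required to attempt an EM fit
MIN_SAMPLES_PER_COMPONENT = 10

DEFAULT_K_MAX = 6
DEFAULT_N_INIT = 5

#: default sd floor (μm): half the default pixel size, preventing
#: delta-collapse on discretised radii
DEFAULT_SD_FLOOR = 0.0165


@dataclass
class FiberTypeModel:
    """A fitted 1-D Gaussian mixture over fiber radii, sorted by mean."""

    n_components: int
    means: np.ndarray  # μm, ascending
    sds: np.ndarray  # μm
    weights: np.ndarray  # sum to 1
    log_likelihood: float  # total over the sample
    aic: float
    seed: int

    def __post_init__(self) -> None:
        order = np.argsort(self.means)
        self.means = np.asarray(self.means, dtype=float)[order]
        self.sds = np.asarray(self.sds, dtype=float)[order]
        self.weights = np.asarray(self.weights, dtype=float)[order]
        assert abs(self.weights.sum() - 1.0) < 1e-9
        assert (self.sds > 0).all()


def _as_column(radii) -> np.ndarray:
    values = getattr(radii, "values", radii)
    return np.asarray(values, dtype=float).reshape(-1, 1)


def fit_mixture(radii, k: int, seed: int = 0, *, n_init: int = DEFAULT_N_INIT,
                sd_floor: float = DEFAULT_SD_FLOOR) -> FiberTypeModel:
    """EM-fit a K-component mixture to radius samples.

    Reported sds are floored at ``sd_floor`` so degenerate (all-equal or
    heavily discretised) inputs yield a usable model rather than a silent
    near-delta component.
    """
    x = _as_column(radii)
    n = len(x)
    if n < MIN_SAMPLES_PER_COMPONENT * k:
        raise InsufficientDataError(
            f"need at least {MIN_SAMPLES_PER_COMPONENT * k} samples for k={k}, got {n}"
        )
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=n_init,
        random_state=seed,
        reg_covar=1e-12,
        max_iter=500,
    ).fit(x)
    sds = np.sqrt(gm.covariances_.reshape(-1))
    return FiberTypeModel(
        n_components=k,
        means=gm.means_.reshape(-1),
        sds=np.maximum(sds, sd_floor),
        weights=gm.weights_,
        log_likelihood=float(gm.score(x) * n),
        aic=float(gm.aic(x)),
        seed=seed,
    )


def select_components(radii, k_max: int = DEFAULT_K_MAX, seed: int = 0,
                      *, n_init: int = DEFAULT_N_INIT,
                      sd_floor: float = DEFAULT_SD_FLOOR) -> FiberTypeModel:
    """Fit k = 1..k_max and return the AIC-minimising model.

    Values of k that would leave fewer than 10 samples per component are
    skipped; at least k = 1 must be feasible.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    x = _as_column(radii)
    k_feasible = min(k_max, len(x) // MIN_SAMPLES_PER_COMPONENT)
    if k_feasible < 1:
        raise InsufficientDataError(
            f"need at least {MIN_SAMPLES_PER_COMPONENT} samples, got {len(x)}"
        )
    best = None
    for k in range(1, k_feasible + 1):
        model = fit_mixture(x, k, seed=seed + k, n_init=n_init, sd_floor=sd_floor)
        if best is None or model.aic < best.aic:
            best = model
    return best


def model_density(model: FiberTypeModel, grid: np.ndarray) -> np.ndarray:
    """Mixture pdf evaluated on ``grid`` (μm)."""
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    for m, s, w in zip(model.means, model.sds, model.weights):
        out += w * np.exp(-0.5 * ((grid - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
    return out


def export_histogram(radii, model: FiberTypeModel, n_bins: int = 40) -> pd.DataFrame:
    """Histogram + fitted-density table (bin_center, count, model_density)."""
    values = np.asarray(getattr(radii, "values", radii), dtype=float)
    counts, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame(
        {
            "bin_center": centers,
            "count": counts,
            "model_density": model_density(model, centers),
        }
    )
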