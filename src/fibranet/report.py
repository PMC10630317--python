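"""Layer aggregation, derived ratios and the structure–property correlation.

Combines per-layer microstructural descriptors with per-layer moduli into
gradient summaries: percent changes along the growth direction, the
dimensionless contact-validity ratios, and the modulus-vs-crosslink-density
correlation.  With only a handful of layers the correlation is reported as
rank correlation + slope with significance explicitly "not assessed".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sstats

__all__ = [
    "LayerDescriptors",
    "percent_change",
    "dimensionless_ratios",
    "correlate_structure_property",
    "HERTZ_VALIDITY_THRESHOLD",
]

#: probe-to-mesh size ratio above which indentation of a fibrous network
#: deforms elastically without densification (strict inequality)
HERTZ_VALIDITY_THRESHOLD = 12.0


@dataclass
class LayerDescriptors:
    """Per-layer bundle of structural descriptors and moduli."""

    label: str
    crosslink_density: float | None = None  # ρ_b, μm⁻²
    network_density: float | None = None  # ρ, μm/μm²
    mean_segment_length: float | None = None  # l_c, μm
    porosity: float | None = None
    pore_summary: dict = field(default_factory=dict)
    fiber_types: dict = field(default_factory=dict)
    E_kPa: list[float] = field(default_factory=list)  # per accepted indent

    @property
    def E_mean(self) -> float | None:
        return float(np.mean(self.E_kPa)) if self.E_kPa else None

    @property
    def E_sd(self) -> float | None:
        return float(np.std(self.E_kPa, ddof=1)) if len(self.E_kPa) > 1 else None

    def to_json(self) -> str:
        d = asdict(self)
        d["E_mean"] = self.E_mean
        d["E_sd"] = self.E_sd
        return json.dumps(d, default=float, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LayerDescriptors":
        d = json.loads(text)
        d.pop("E_mean", None)
        d.pop("E_sd", None)
        return cls(**d)


def percent_change(old_value: float, new_value: float) -> float:
    """``100·(old − new)/old``: positive means a decrease from old to new.

    Rounding is left to the presentation layer.
    """
    if old_value == 0:
        raise ValueError("percent change undefined for old_value = 0")
    return 100.0 * (old_value - new_value) / old_value


def dimensionless_ratios(R_um: float, l_c_um: float, radii_um=()):
    """Contact-validity ratios for a fibrous network under a spherical probe.

    Returns a dict with ``R_over_lc`` (probe radius over mesh size),
    ``r_over_lc`` ((min, max) fiber radius over mesh size, when radii are
    given) and the strict ``hertz_valid`` verdict ``R/l_c > 12``.
    """
    if R_um <= 0 or l_c_um <= 0:
        raise ValueError("R and l_c must be positive")
    r_over = None
    radii = np.asarray(radii_um, dtype=float)
    if radii.size:
        if (radii <= 0).any():
            raise ValueError("radii must be positive")
        r_over = (float(radii.min() / l_c_um), float(radii.max() / l_c_um))
    ratio = R_um / l_c_um
    return {
        "R_over_lc": float(ratio),
        "r_over_lc": r_over,
        "hertz_valid": bool(ratio > HERTZ_VALIDITY_THRESHOLD),
    }


def _monotone_verdict(values: np.ndarray) -> str:
    diffs = np.diff(values)
    if (diffs < 0).all():
        return "decreasing"
    if (diffs > 0).all():
        return "increasing"
    return "non-monotone"


def correlate_structure_property(layers: list[LayerDescriptors]) -> dict:
    """Modulus-vs-ρ_b and ρ_b-vs-1/l_c correlations across layers.

    Requires ≥ 3 layers with both quantities present.  Rank correlations
    are Spearman; identical descriptor values make the correlation
    undefined and it is reported as missing.  Significance is deliberately
    not assessed at these sample sizes.
    """
    usable = [
        ly for ly in layers
        if ly.crosslink_density is not None and ly.E_mean is not None
    ]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 layers with ρ_b and E, got {len(usable)}")
    rho_b = np.array([ly.crosslink_density for ly in usable])
    e = np.array([ly.E_mean for ly in usable])

    def _spearman(x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return None
        r = sstats.spearmanr(x, y).statistic
        return None if np.isnan(r) else float(r)

    slope = None
    if np.ptp(rho_b) > 0:
        slope = float(sstats.linregress(rho_b, e).slope)

    report = {
        "labels": [ly.label for ly in usable],
        "E_vs_crosslink_rank_corr": _spearman(rho_b, e),
        "E_vs_crosslink_slope": slope,
        "E_monotonicity": _monotone_verdict(e),
        "crosslink_monotonicity": _monotone_verdict(rho_b),
        "significance": "not assessed (n=%d)" % len(usable),
    }
    lcs = np.array(
        [ly.mean_segment_length if ly.mean_segment_length else np.nan for ly in usable]
    )
    if not np.isnan(lcs).any():
        report["crosslink_vs_inverse_lc_rank_corr"] = _spearman(rho_b, 1.0 / lcs)
    else:
        report["crosslink_vs_inverse_lc_rank_corr"] = None
    return report


def plot_gradient(layers: list[LayerDescriptors], path) -> None:
    """E-vs-ρ_b scatter with per-layer error bars (optional matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    for ly in layers:
        if ly.crosslink_density is None or ly.E_mean is None:
            continue
        ax.errorbar(ly.crosslink_density, ly.E_mean, yerr=ly.E_sd, fmt="o",
                    capsize=3)
        ax.annotate(ly.label, (ly.crosslink_density, ly.E_mean),
                    textcoords="offset points", xytext=(5, 5))
    ax.set_xlabel(r"crosslink density $\rho_b$ ($\mu m^{-2}$)")
    ax.set_ylabel("elastic modulus E (kPa)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
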