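"""Force–indentation curve analysis.

Moduli are estimated from the loading stage via the contact-point-free
derivative form of the Hertz sphere-on-half-space model: the loading curve
``F = (4/3)·E*·√R·d^1.5`` implies ``dF/du = K·F^n`` with ``n = 1/3`` and
``K = 2·(3/4)^(1/3)·E*^(2/3)·R^(1/3)``, so fitting the (F, dF/du) cloud on a
log–log scale yields E* without locating the initial point of contact.

Units are μm for depth, μN for force, kPa for moduli.  The single unit
conversion lives in :data:`KPA_PER_UN_PER_UM2` (μN/μm² = MPa = 1000 kPa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import savgol_coeffs, savgol_filter

from .errors import FitRejectedError, FormatError, InsufficientDataError

__all__ = [
    "IndentationCurve",
    "HertzFit",
    "parse_curve",
    "detect_pop_ins",
    "derivative_estimate",
    "fit_power_law",
    "modulus_from_fit",
    "hertz_prefactor",
    "analyze_curve",
    "KPA_PER_UN_PER_UM2",
]

#: μN/μm² (= MPa) expressed in kPa — the one unit-conversion constant.
KPA_PER_UN_PER_UM2 = 1000.0

#: Hertz exponent for dF/du vs F of a spherical indenter.
HERTZ_EXPONENT = 1.0 / 3.0

STAGE_LOAD, STAGE_DWELL, STAGE_UNLOAD = "load", "dwell", "unload"


@dataclass
class IndentationCurve:
    """A three-stage (load / dwell / unload) force–indentation record."""

    time: np.ndarray  # s, strictly increasing
    depth: np.ndarray  # μm
    force: np.ndarray  # μN
    stage: np.ndarray | None = None  # per-sample labels
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if not (len(self.time) == len(self.depth) == len(self.force)):
            raise FormatError("time, depth and force must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise FormatError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    def stage_mask(self, label: str) -> np.ndarray:
        if self.stage is None:
            raise ValueError("stages not labelled; call label_stages() first")
        return self.stage == label

    @property
    def d_max(self) -> float:
        return float(self.depth.max())

    def substrate_ratio(self) -> float | None:
        """d_max / sample thickness, if thickness metadata (mm) is present."""
        t_f_mm = self.meta.get("thickness_mm")
        if t_f_mm is None:
            return None
        return self.d_max / (t_f_mm * 1000.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "depth_um": self.depth, "force_uN": self.force}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def label_stages(curve: IndentationCurve, rate_fraction: float = 0.25,
                 smooth_samples: int = 5) -> IndentationCurve:
    """Label samples load/dwell/unload from the sign of the depth rate.

    The rate is median-filtered over ``smooth_samples`` points and compared
    against ``rate_fraction`` of the peak absolute rate (hysteresis
    threshold), so sensor jitter around the dwell does not flicker labels.
    """
    rate = np.gradient(curve.depth, curve.time)
    if smooth_samples > 1:
        k = smooth_samples | 1
        pad = k // 2
        padded = np.pad(rate, pad, mode="edge")
        rate = np.array(
            [np.median(padded[i:i + k]) for i in range(len(rate))]
        )
    thr = rate_fraction * np.abs(rate).max()
    stage = np.full(len(curve), STAGE_DWELL, dtype=object)
    stage[rate > thr] = STAGE_LOAD
    stage[rate < -thr] = STAGE_UNLOAD
    curve.stage = stage.astype(str)
    return curve


def parse_curve(path_or_frame, meta: dict | None = None) -> IndentationCurve:
    """Read a ``time_s,depth_um,force_uN`` CSV and label its stages."""
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame
    else:
        df = pd.read_csv(path_or_frame)
    required = ["time_s", "depth_um", "force_uN"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"curve CSV missing columns: {missing}; expected {required}")
    curve = IndentationCurve(
        time=df["time_s"].to_numpy(),
        depth=df["depth_um"].to_numpy(),
        force=df["force_uN"].to_numpy(),
        meta=dict(meta or {}),
    )
    return label_stages(curve)


def _loading_slice(curve: IndentationCurve) -> np.ndarray:
    if curve.stage is None:
        label_stages(curve)
    idx = np.flatnonzero(curve.stage_mask(STAGE_LOAD))
    if idx.size == 0:
        raise InsufficientDataError("curve has no loading stage")
    # use the first contiguous loading run
    breaks = np.flatnonzero(np.diff(idx) > 1)
    if breaks.size:
        idx = idx[: breaks[0] + 1]
    return idx


def detect_pop_ins(curve: IndentationCurve, *, floor_uN: float = 1.0,
                   sigma_mult: float = 3.0) -> list[tuple[float, float]]:
    """Detect sudden force drops during loading.

    An event is a run of samples where the force decreases while depth
    increases, with total drop exceeding ``max(sigma_mult × noise sd,
    floor_uN)``.  The noise sd is estimated robustly (MAD of the detrended
    first difference).  Returns ``(depth μm, force drop μN)`` pairs.
    """
    idx = _loading_slice(curve)
    f_raw = curve.force[idx]
    d = curve.depth[idx]
    # median-filter the trace so sensor noise cannot fake a drop; a real
    # pop-in is a persistent step, which the filter preserves
    k = min(7, len(f_raw) | 1)
    f = ndimage.median_filter(f_raw, size=k, mode="nearest")
    df_raw = np.diff(f_raw)
    mad = np.median(np.abs(df_raw - np.median(df_raw)))
    sigma_step = 1.4826 * mad  # sd of the raw force increment incl. noise
    thr = max(sigma_mult * sigma_step, floor_uN)
    df = np.diff(f)

    events: list[tuple[float, float]] = []
    i = 0
    while i < len(df):
        if df[i] < 0:
            j = i
            while j + 1 < len(df) and df[j + 1] < 0:
                j += 1
            drop = f[i] - f[j + 1]
            if drop > thr:
                events.append((float(d[i]), float(drop)))
            i = j + 1
        else:
            i += 1
    return events


def derivative_estimate(curve: IndentationCurve, *, window_um: float = 2.0,
                        polyorder: int = 3):
    """Local-polynomial (Savitzky–Golay) estimate of dF/du on the loading stage.

    Returns ``(F, dF/du)`` arrays with half a window trimmed from each end.
    Requires an (approximately) uniform depth grid, which holds for
    constant-rate loading.
    """
    idx = _loading_slice(curve)
    if idx.size < 20:
        raise InsufficientDataError(
            f"need >= 20 loading samples for derivative estimate, got {idx.size}"
        )
    d = curve.depth[idx]
    f = curve.force[idx]
    step = float(np.median(np.diff(d)))
    if step <= 0:
        raise InsufficientDataError("loading depth is not increasing")
    win = max(int(round(window_um / step)) | 1, polyorder + 2 | 1)
    win = min(win, len(f) if len(f) % 2 else len(f) - 1)
    f_smooth = savgol_filter(f, win, polyorder)
    dfdu = savgol_filter(f, win, polyorder, deriv=1, delta=step)
    half = win // 2
    sl = slice(half, len(f) - half) if len(f) > 2 * half else slice(None)
    # propagate the sensor noise through the derivative filter: the output
    # noise sd is the input sd times the filter's L2 gain
    d2 = np.diff(f, n=2)  # second difference cancels the smooth trend
    sigma_f = 1.4826 * np.median(np.abs(d2 - np.median(d2))) / np.sqrt(6.0)
    gain = float(np.sqrt(np.sum(savgol_coeffs(win, polyorder, deriv=1, delta=step) ** 2)))
    return f_smooth[sl], dfdu[sl], sigma_f * gain


def fit_power_law(F: np.ndarray, dFdu: np.ndarray,
                  window: tuple[float, float] = (5.0, 30.0),
                  sigma_dFdu: float = 0.0):
    """Least-squares fit of ``log(dF/du) = log K + n·log F`` inside a force window.

    When the derivative noise sd ``sigma_dFdu`` is known, the log samples
    get a second-order Jensen bias correction (+σ_rel²/2) and inverse-
    variance weights, which removes the systematic downward pull of noisy
    low-force samples.  Returns ``(K, n, diagnostics)`` where diagnostics
    carries the residual RMS, the number of points used and a
    Hertz-anchored prefactor.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("fit window must satisfy F_min < F_max")
    sel = (F >= lo) & (F <= hi) & (F > 0) & (dFdu > 0)
    n_sel = int(sel.sum())
    if n_sel < 10:
        raise InsufficientDataError(
            f"only {n_sel} samples inside the {window} μN window (need >= 10)"
        )
    x = np.log(F[sel])
    y = np.log(dFdu[sel])
    n, logk = np.polyfit(x, y, 1)
    if sigma_dFdu > 0:
        # weights and Jensen correction must use the *predicted* derivative,
        # not the noisy samples, or up-fluctuations get upweighted
        rel = sigma_dFdu / np.exp(logk + n * x)
        y_corr = y + 0.5 * rel**2
        n, logk = np.polyfit(x, y_corr, 1, w=1.0 / np.maximum(rel, 1e-12))
        y = y_corr
    resid = y - (logk + n * x)
    # prefactor re-anchored at the window centre assuming the Hertz
    # exponent: the fitted line is best determined at the pivot, so this
    # decouples the modulus from slope noise while n stays a free quality
    # gate (identical to K when n = 1/3 exactly)
    log_pivot = float(np.mean(x))
    k_hertz = float(np.exp(logk + (n - HERTZ_EXPONENT) * log_pivot))
    diagnostics = {
        "n_points_used": n_sel,
        "residual_rms": float(np.sqrt(np.mean(resid**2))),
        "K_hertz_anchored": k_hertz,
    }
    return float(np.exp(logk)), float(n), diagnostics


def hertz_prefactor(E_star_kPa: float, R_um: float) -> float:
    """Forward map E* (kPa) → K of ``dF/du = K·F^(1/3)`` (μm/μN units)."""
    e = E_star_kPa / KPA_PER_UN_PER_UM2  # μN/μm²
    return 2.0 * (0.75) ** (1.0 / 3.0) * e ** (2.0 / 3.0) * R_um ** (1.0 / 3.0)


@dataclass
class HertzFit:
    """Result of the derivative-form Hertz fit for one curve."""

    K: float
    n: float
    E_star_kPa: float
    E_kPa: float
    poisson_ratio: float
    fit_window_uN: tuple[float, float]
    n_points_used: int
    residual_rms: float
    accepted: bool
    flags: list[str] = field(default_factory=list)
    pop_ins: list[tuple[float, float]] = field(default_factory=list)


def modulus_from_fit(K: float, n: float, R_um: float, poisson_ratio: float = 0.0,
                     *, n_tolerance: float = 0.1) -> tuple[float, float]:
    """Invert the fitted prefactor to moduli: ``E* = K^(3/2)·(6R)^(-1/2)``.

    The fit is rejected (no modulus emitted) when the free exponent strays
    more than ``n_tolerance`` from the Hertz value 1/3.  Returns
    ``(E*, E)`` in kPa with ``E = E*·(1 − ν²)``.
    """
    if abs(n - HERTZ_EXPONENT) > n_tolerance:
        raise FitRejectedError(
            f"exponent n={n:.4f} deviates from 1/3 by more than {n_tolerance}"
        )
    if not 0.0 <= poisson_ratio < 0.5:
        raise ValueError("poisson_ratio must be in [0, 0.5)")
    e_star = K**1.5 / np.sqrt(6.0 * R_um)  # μN/μm²
    e_star_kpa = e_star * KPA_PER_UN_PER_UM2
    return float(e_star_kpa), float(e_star_kpa * (1.0 - poisson_ratio**2))


def analyze_curve(
    curve: IndentationCurve,
    R_um: float,
    *,
    poisson_ratio: float = 0.0,
    window: tuple[float, float] = (5.0, 30.0),
    derivative_window_um: float = 1.0,
    n_tolerance: float = 0.1,
    popin_policy: str = "truncate",
) -> HertzFit:
    """Full per-curve pipeline: pop-in scan → derivative → power-law → moduli.

    ``popin_policy``: ``truncate`` caps the fit window below the force at
    the first pop-in; ``reject`` raises when a pop-in lies inside the
    window; ``ignore`` fits regardless.
    """
    if curve.stage is None:
        label_stages(curve)
    flags: list[str] = []
    events = detect_pop_ins(curve)
    lo, hi = window
    if events:
        idx = _loading_slice(curve)
        first_depth = events[0][0]
        f_at = float(np.interp(first_depth, curve.depth[idx], curve.force[idx]))
        if f_at < hi:
            if popin_policy == "reject":
                raise FitRejectedError(
                    f"pop-in at F≈{f_at:.1f} μN inside the fit window"
                )
            if popin_policy == "truncate":
                hi = max(f_at, lo * 1.5)
                flags.append("window_truncated_at_pop_in")
            else:
                flags.append("pop_in_inside_window")

    F, dFdu, sigma_d = derivative_estimate(curve, window_um=derivative_window_um)
    K, n, diag = fit_power_law(F, dFdu, window=(lo, hi), sigma_dFdu=sigma_d)
    try:
        e_star, e = modulus_from_fit(
            diag["K_hertz_anchored"], n, R_um, poisson_ratio, n_tolerance=n_tolerance
        )
        accepted = True
    except FitRejectedError:
        e_star = e = float("nan")
        accepted = False
        flags.append("exponent_out_of_tolerance")
    return HertzFit(
        K=K,
        n=n,
        E_star_kPa=e_star,
        E_kPa=e,
        poisson_ratio=poisson_ratio,
        fit_window_uN=(lo, hi),
        n_points_used=diag["n_points_used"],
        residual_rms=diag["residual_rms"],
        accepted=accepted,
        flags=flags,
        pop_ins=events,
    )
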