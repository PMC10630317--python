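"""Synthetic fiber-network images and indentation curves with analytic truth.

Fibers are straight capsules (segments with round caps); curvature adds
nothing to the descriptors under test.  Every generated artifact carries a
:class:`GroundTruth` so downstream estimators can be validated without any
external data.  All randomness flows from the spec's ``seed`` through
``numpy.random.default_rng``: identical spec + seed ⇒ bit-identical output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import geometry
from .errors import ConfigurationError
from .indentation import (
    IndentationCurve,
    KPA_PER_UN_PER_UM2,
    STAGE_DWELL,
    STAGE_LOAD,
    STAGE_UNLOAD,
)
from .segmentation import BinaryMask, Micrograph

__all__ = [
    "NetworkSpec",
    "GroundTruth",
    "IndentationSpec",
    "GradientSpec",
    "LayerSample",
    "generate_fiber_network",
    "rasterize_area_fraction",
    "generate_indentation_curve",
    "generate_layer_series",
    "hertz_force",
]

#: default pixel size (μm/px): the thinnest default fiber type (0.17 μm
#: radius) then spans ~10 px across, safely above the few-pixels-per-diameter
#: resolution floor where distance-transform radii degrade.
DEFAULT_PIXEL_SIZE = 0.033

DEFAULT_RADIUS_MIXTURE = ((0.17, 0.015, 0.5), (0.34, 0.03, 0.5))


@dataclass
class NetworkSpec:
    """Configuration for one synthetic fiber-network image."""

    image_width_px: int = 512
    image_height_px: int = 512
    pixel_size: float = DEFAULT_PIXEL_SIZE
    n_fibers: int = 40
    radius_mixture: tuple = DEFAULT_RADIUS_MIXTURE
    fiber_length_range: tuple[float, float] = (5.0, 30.0)
    uniform_orientation: bool = True
    depth_layers: int = 3
    seed: int = 0
    # rendering controls (grayscale only; the mask is intensity-independent)
    background_intensity: int = 50
    fiber_intensity: int = 200
    depth_dim_factor: float = 0.72

    def __post_init__(self) -> None:
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ConfigurationError("image dimensions must be positive")
        if not self.pixel_size > 0:
            raise ConfigurationError("pixel_size must be positive")
        if self.n_fibers < 0:
            raise ConfigurationError("n_fibers must be non-negative")
        w = sum(c[2] for c in self.radius_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ConfigurationError(f"mixture weights must sum to 1, got {w}")
        for mean, sd, _ in self.radius_mixture:
            if mean <= 0 or sd <= 0:
                raise ConfigurationError("mixture means and sds must be positive")
        lo, hi = self.fiber_length_range
        if lo > hi:
            raise ConfigurationError("fiber_length_range must satisfy min <= max")
        if self.depth_layers < 1:
            raise ConfigurationError("depth_layers must be >= 1")

    @property
    def frame_um(self) -> tuple[float, float]:
        """(width, height) of the frame in μm."""
        return (
            self.image_width_px * self.pixel_size,
            self.image_height_px * self.pixel_size,
        )


@dataclass
class GroundTruth:
    """Analytic truth attached to a generated network image.

    ``fiber_segments`` are ``((x1, y1), (x2, y2), radius)`` in μm; centerline
    crossings are counted only strictly inside the frame, mirroring the
    edge-exclusion convention of the descriptor pipeline; ``true_total_length``
    sums the in-frame portion of each centerline.
    """

    fiber_segments: list
    true_crosslink_count: int
    true_total_length: float
    true_radii: list
    true_area_fraction: float
    frame_um: tuple[float, float] = (0.0, 0.0)
    radius_mixture: tuple = ()

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=float, indent=2)


def _draw_radii(rng: np.random.Generator, mixture, n: int) -> np.ndarray:
    comps = rng.choice(len(mixture), size=n, p=[c[2] for c in mixture])
    means = np.array([mixture[k][0] for k in comps])
    sds = np.array([mixture[k][1] for k in comps])
    radii = rng.normal(means, sds)
    # resample the (rare) non-physical tails rather than clipping the shape
    bad = radii <= means * 0.2
    while bad.any():
        radii[bad] = rng.normal(means[bad], sds[bad])
        bad = radii <= means * 0.2
    return radii


def generate_fiber_network(spec: NetworkSpec):
    """Render a random capsule network.

    Returns ``(Micrograph, BinaryMask, GroundTruth)``.  The mask is the
    exact rasterised union of the capsules; the grayscale image paints each
    fiber at an intensity set by its depth layer (topmost brightest),
    mimicking electron-micrograph depth cueing, over a uniform background.
    """
    rng = np.random.default_rng(spec.seed)
    w_um, h_um = spec.frame_um
    shape = (spec.image_height_px, spec.image_width_px)

    radii = _draw_radii(rng, spec.radius_mixture, spec.n_fibers)
    centers = rng.uniform([0, 0], [w_um, h_um], size=(spec.n_fibers, 2))
    if spec.uniform_orientation:
        angles = rng.uniform(0.0, np.pi, size=spec.n_fibers)
    else:
        angles = rng.normal(0.0, 0.3, size=spec.n_fibers) % np.pi
    lengths = rng.uniform(*spec.fiber_length_range, size=spec.n_fibers)
    layers = rng.integers(0, spec.depth_layers, size=spec.n_fibers)

    segments = []
    total_len = 0.0
    for c, a, L, r in zip(centers, angles, lengths, radii):
        half = 0.5 * L * np.array([np.cos(a), np.sin(a)])
        p1, p2 = tuple(c - half), tuple(c + half)
        segments.append((p1, p2, float(r)))
        clipped = geometry.clip_segment_to_frame(p1, p2, w_um, h_um)
        if clipped is not None:
            total_len += geometry.segment_length(*clipped)

    mask = np.zeros(shape, dtype=bool)
    gray = np.full(shape, spec.background_intensity, dtype=np.uint8)
    # paint deepest layers first so shallower fibers overwrite them
    order = np.argsort(-layers, kind="stable")
    for i in order:
        p1, p2, r = segments[i]
        intensity = int(round(spec.fiber_intensity * spec.depth_dim_factor ** layers[i]))
        geometry.paint_capsule(gray, p1, p2, r, spec.pixel_size, value=intensity)
        geometry.paint_capsule(mask, p1, p2, r, spec.pixel_size, value=True)

    gt = GroundTruth(
        fiber_segments=segments,
        true_crosslink_count=geometry.count_interior_intersections(segments, w_um, h_um),
        true_total_length=total_len,
        true_radii=[float(r) for r in radii],
        true_area_fraction=float(mask.mean()),
        frame_um=(w_um, h_um),
        radius_mixture=spec.radius_mixture,
    )
    micrograph = Micrograph(grid=gray, pixel_size=spec.pixel_size,
                            source=f"synthetic:seed={spec.seed}")
    bmask = BinaryMask(grid=mask, pixel_size=spec.pixel_size, provenance="automatic",
                       meta={"generator": "synthetic"})
    return micrograph, bmask, gt


def rasterize_area_fraction(segments_with_radii, shape_px, pixel_size: float,
                            supersample_factor: int = 4) -> float:
    """Area fraction of the capsule union on a supersampled pixel grid."""
    if supersample_factor < 1:
        raise ConfigurationError("supersample_factor must be >= 1")
    if not segments_with_radii:
        return 0.0
    fine = geometry.capsule_union_mask(
        segments_with_radii, shape_px, pixel_size, supersample=supersample_factor
    )
    return float(fine.mean())


def hertz_force(depth_um, E_star_kPa: float, R_um: float,
                contact_offset_um: float = 0.0):
    """Hertz loading force (μN): ``F = (4/3)·E*·√R·(d − d₀)^1.5`` above contact."""
    d = np.asarray(depth_um, dtype=float) - contact_offset_um
    d = np.where(d > 0.0, d, 0.0)
    e = E_star_kPa / KPA_PER_UN_PER_UM2  # μN/μm²
    return (4.0 / 3.0) * e * np.sqrt(R_um) * d**1.5


@dataclass
class IndentationSpec:
    """Configuration for one synthetic three-stage indentation curve."""

    E_sample_kPa: float = 55.1
    poisson_ratio: float = 0.0
    R_indenter_um: float = 92.03
    d_max_um: float = 70.0
    load_rate_um_s: float = 3.0
    dwell_time_s: float = 50.0
    unload_rate_um_s: float = 1.0
    contact_offset_um: float = 0.0
    noise_sd_uN: float = 0.0
    popin_events: tuple = ()  # (depth μm, force-drop μN)
    sample_rate_hz: float = 100.0
    thickness_mm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.E_sample_kPa > 0:
            raise ConfigurationError("E_sample must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ConfigurationError("poisson_ratio must be in [0, 0.5)")
        if not self.d_max_um > 0:
            raise ConfigurationError("d_max must be positive")
        if self.noise_sd_uN < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.d_max_um <= self.contact_offset_um:
            raise ConfigurationError("d_max must exceed contact_offset")

    @property
    def E_star_kPa(self) -> float:
        return self.E_sample_kPa / (1.0 - self.poisson_ratio**2)


def generate_indentation_curve(spec: IndentationSpec) -> IndentationCurve:
    """Simulate a load → dwell → unload record with Hertzian elasticity.

    Pop-in events appear as step force drops at the requested loading
    depths; the accumulated drop is carried through dwell and unload so the
    trace stays continuous.  Gaussian force noise of sd ``noise_sd_uN`` is
    added to every sample.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.sample_rate_hz

    t_load = spec.d_max_um / spec.load_rate_um_s
    t_unload = spec.d_max_um / spec.unload_rate_um_s
    n_load = int(round(t_load / dt))
    n_dwell = int(round(spec.dwell_time_s / dt))
    n_unload = int(round(t_unload / dt))

    t = np.arange(n_load + n_dwell + n_unload + 1) * dt
    depth = np.empty_like(t)
    depth[: n_load + 1] = np.linspace(0.0, spec.d_max_um, n_load + 1)
    depth[n_load + 1 : n_load + n_dwell + 1] = spec.d_max_um
    depth[n_load + n_dwell + 1 :] = np.linspace(
        spec.d_max_um, 0.0, n_unload + 1
    )[1:]

    stage = np.empty(len(t), dtype=object)
    stage[: n_load + 1] = STAGE_LOAD
    stage[n_load + 1 : n_load + n_dwell + 1] = STAGE_DWELL
    stage[n_load + n_dwell + 1 :] = STAGE_UNLOAD

    force = hertz_force(depth, spec.E_star_kPa, spec.R_indenter_um,
                        spec.contact_offset_um)
    # cumulative pop-in drops: applied from the event depth onward (loading),
    # then carried through the rest of the record
    total_drop = 0.0
    loading = np.arange(len(t)) <= n_load
    for event_depth, drop in spec.popin_events:
        after = loading & (depth >= event_depth)
        force[after] -= drop
        total_drop += drop
    force[~loading] -= total_drop
    np.maximum(force, 0.0, out=force)
    if spec.noise_sd_uN > 0:
        force = force + rng.normal(0.0, spec.noise_sd_uN, size=len(t))

    return IndentationCurve(
        time=t,
        depth=depth,
        force=force,
        stage=stage.astype(str),
        meta={
            "R_indenter_um": spec.R_indenter_um,
            "d_max_um": spec.d_max_um,
            "thickness_mm": spec.thickness_mm,
            "load_rate_um_s": spec.load_rate_um_s,
            "unload_rate_um_s": spec.unload_rate_um_s,
            "E_sample_kPa": spec.E_sample_kPa,
            "E_star_kPa": spec.E_star_kPa,
            "contact_offset_um": spec.contact_offset_um,
            "stage_bounds": (int(n_load), int(n_load + n_dwell)),
            "popin_events": [tuple(e) for e in spec.popin_events],
        },
    )


def generate_sparse_network(
    spec: NetworkSpec,
    *,
    min_crossing_sep_um: float = 3.0,
    min_crossing_angle_deg: float = 40.0,
    clearance_um: float = 0.6,
    border_margin_um: float = 1.2,
    max_attempts_per_fiber: int = 200,
    stop_at_crossings: int | None = None,
):
    """Rejection-sampled network on which every crossing is unambiguous.

    Fibers are added one at a time; a candidate is rejected when it crosses
    an accepted fiber at a shallow angle, produces a crossing closer than
    ``min_crossing_sep_um`` to another crossing or ``border_margin_um`` to
    the frame edge, or passes a non-crossing fiber closer than the capsule
    radii plus ``clearance_um`` (near-misses would fuse in the raster).
    Such networks satisfy the sparse precondition under which skeleton
    junction detection is expected to be exact.  Returns the same triple as
    :func:`generate_fiber_network`.
    """
    rng = np.random.default_rng(spec.seed)
    w_um, h_um = spec.frame_um
    min_angle = np.radians(min_crossing_angle_deg)

    accepted: list[tuple] = []  # (p1, p2, r, angle)
    crossings: list[tuple[float, float]] = []
    while len(accepted) < spec.n_fibers and not (
        stop_at_crossings is not None and len(crossings) >= stop_at_crossings
    ):
        placed = False
        for _ in range(max_attempts_per_fiber):
            r = float(_draw_radii(rng, spec.radius_mixture, 1)[0])
            c = rng.uniform([0, 0], [w_um, h_um])
            a = rng.uniform(0.0, np.pi)
            L = rng.uniform(*spec.fiber_length_range)
            half = 0.5 * L * np.array([np.cos(a), np.sin(a)])
            p1, p2 = tuple(c - half), tuple(c + half)
            new_crossings = []
            ok = True
            for q1, q2, r2, a2 in accepted:
                pt = geometry.segment_intersection_point(p1, p2, q1, q2)
                if pt is None:
                    if geometry.segment_min_distance(p1, p2, q1, q2) < r + r2 + clearance_um:
                        ok = False
                        break
                    continue
                # reject near-endpoint crossings: a fiber tip grazing another
                # fiber rasterises as an ambiguous T, not a clean X
                t_p = geometry.segment_length(p1, pt) / geometry.segment_length(p1, p2)
                t_q = geometry.segment_length(q1, pt) / geometry.segment_length(q1, q2)
                if not (0.08 < t_p < 0.92 and 0.08 < t_q < 0.92):
                    ok = False
                    break
                dang = abs(((a - a2) + np.pi / 2) % np.pi - np.pi / 2)
                inside = (
                    border_margin_um < pt[0] < w_um - border_margin_um
                    and border_margin_um < pt[1] < h_um - border_margin_um
                )
                if dang < min_angle or not inside:
                    ok = False
                    break
                new_crossings.append(pt)
            if ok:
                pool = crossings + new_crossings
                for i, pa in enumerate(new_crossings):
                    others = crossings + new_crossings[:i] + new_crossings[i + 1 :]
                    if any(
                        np.hypot(pa[0] - pb[0], pa[1] - pb[1]) < min_crossing_sep_um
                        for pb in others
                    ):
                        ok = False
                        break
            if ok:
                accepted.append((p1, p2, r, a))
                crossings.extend(new_crossings)
                placed = True
                break
        if not placed:
            if stop_at_crossings is None:
                warnings.warn(
                    f"sparse placement stalled at {len(accepted)}/{spec.n_fibers} fibers",
                    stacklevel=2,
                )
            break

    shape = (spec.image_height_px, spec.image_width_px)
    mask = np.zeros(shape, dtype=bool)
    gray = np.full(shape, spec.background_intensity, dtype=np.uint8)
    total_len = 0.0
    segments = []
    for p1, p2, r, _ in accepted:
        segments.append((p1, p2, r))
        geometry.paint_capsule(gray, p1, p2, r, spec.pixel_size,
                               value=spec.fiber_intensity)
        geometry.paint_capsule(mask, p1, p2, r, spec.pixel_size, value=True)
        clipped = geometry.clip_segment_to_frame(p1, p2, w_um, h_um)
        if clipped is not None:
            total_len += geometry.segment_length(*clipped)
    gt = GroundTruth(
        fiber_segments=segments,
        true_crosslink_count=len(crossings),
        true_total_length=total_len,
        true_radii=[s[2] for s in segments],
        true_area_fraction=float(mask.mean()),
        frame_um=(w_um, h_um),
        radius_mixture=spec.radius_mixture,
    )
    micrograph = Micrograph(grid=gray, pixel_size=spec.pixel_size,
                            source=f"synthetic-sparse:seed={spec.seed}")
    bmask = BinaryMask(grid=mask, pixel_size=spec.pixel_size,
                       provenance="automatic", meta={"generator": "synthetic-sparse"})
    return micrograph, bmask, gt


@dataclass
class GradientSpec:
    """A monotone growth gradient across ``n_layers`` sections (L-1 oldest)."""

    n_layers: int = 3
    crosslink_density_range: tuple[float, float] = (0.079, 0.027)  # μm⁻², old → young
    modulus_range: tuple[float, float] = (55.1, 26.5)  # kPa, old → young
    network_spec: NetworkSpec = field(
        # short fibers pack to higher crossing densities before the
        # constraint sampler stalls
        default_factory=lambda: NetworkSpec(n_fibers=200, fiber_length_range=(3.0, 9.0))
    )
    indentation_spec: IndentationSpec = field(default_factory=IndentationSpec)
    curves_per_layer: int = 5
    density_tolerance: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ConfigurationError("n_layers must be >= 2")
        for rng_ in (self.crosslink_density_range, self.modulus_range):
            if not all(np.isfinite(v) and v > 0 for v in rng_):
                raise ConfigurationError("gradient ranges must be finite and positive")

    def layer_targets(self) -> list[tuple[str, float, float]]:
        """Per-layer (label, ρ_b target, E target), linearly interpolated."""
        fr = np.linspace(0.0, 1.0, self.n_layers)
        rho = self.crosslink_density_range
        mod = self.modulus_range
        return [
            (
                f"L-{i + 1}",
                float(rho[0] + f * (rho[1] - rho[0])),
                float(mod[0] + f * (mod[1] - mod[0])),
            )
            for i, f in zip(range(self.n_layers), fr)
        ]


@dataclass
class LayerSample:
    """One generated layer: image, mask, truth, indentation curves, targets."""

    label: str
    micrograph: Micrograph
    mask: BinaryMask
    ground_truth: GroundTruth
    curves: list
    target_crosslink_density: float
    target_modulus_kPa: float
    achieved_crosslink_density: float


def _generate_layer_network(base: NetworkSpec, target_density: float, seed: int,
                            tolerance: float):
    """One constraint-sampled network tuned to a crosslink-density target.

    Fibers are added until the analytic crossing count reaches
    ``target_density × frame area`` (or placement stalls, in which case a
    best-effort network is returned with a warning).  Constraint sampling
    keeps every crossing individually resolvable by the skeleton stage.
    """
    w_um, h_um = base.frame_um
    area = w_um * h_um
    target_count = int(round(target_density * area))
    spec = NetworkSpec(**{**asdict(base), "seed": seed})
    out = generate_sparse_network(
        spec,
        min_crossing_sep_um=1.2,
        min_crossing_angle_deg=25.0,
        clearance_um=0.4,
        border_margin_um=0.8,
        stop_at_crossings=target_count,
    )
    density = out[2].true_crosslink_count / area
    if abs(density - target_density) / target_density > tolerance:
        warnings.warn(
            f"crosslink-density target {target_density:.4f} μm⁻² not met within "
            f"{tolerance:.0%} (achieved {density:.4f}); returning best effort",
            stacklevel=2,
        )
    return out, density


def generate_layer_series(gspec: GradientSpec) -> list[LayerSample]:
    """Generate the full gradient: one image + curve set per layer.

    Layer targets interpolate monotonically between the range endpoints
    (L-1 = oldest, highest ρ_b and E).  The fiber budget per layer is
    driven by the analytic crossing count against the layer's ρ_b target.
    """
    master = np.random.default_rng(gspec.seed)
    layers: list[LayerSample] = []
    for label, rho_target, e_target in gspec.layer_targets():
        net_seed = int(master.integers(2**31))
        (micro, mask, gt), achieved = _generate_layer_network(
            gspec.network_spec, rho_target, net_seed, gspec.density_tolerance
        )
        curves = []
        for _ in range(gspec.curves_per_layer):
            ispec = IndentationSpec(**{
                **asdict(gspec.indentation_spec),
                "E_sample_kPa": e_target,
                "seed": int(master.integers(2**31)),
            })
            curves.append(generate_indentation_curve(ispec))
        layers.append(
            LayerSample(
                label=label,
                micrograph=micro,
                mask=mask,
                ground_truth=gt,
                curves=curves,
                target_crosslink_density=rho_target,
                target_modulus_kPa=e_target,
                achieved_crosslink_density=achieved,
            )
        )
    return layers
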