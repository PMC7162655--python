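"""Synthetic LSFM-like retina phantoms with exhaustive ground truth.

Generates the geometric/statistical structure that the downstream
measurements assume: a curved retinal surface (spherical cap at mouse-eye
scale) carrying a tubular superficial vascular plexus, an anisotropic
flat-mount compression distortion, protruding neovascular tufts with
known volume / nuclei / stalk connections / tunnels / curved-nucleus
fractions, layered nuclei sheets (ONL-like slabs), and scripted
time-lapse filopodia and moving actin bundles.

All coordinates are physical µm in ``(z, y, x)`` order matching the array
axes; the vitreous side is +z.  Rendering is binary-mask-first: objects
are rasterized into boolean masks, Gaussian-blurred (PSF-like), and
additive Gaussian noise is applied on top — the simplest model that makes
thresholding non-trivial.  Every stochastic draw flows from one
``numpy.random.default_rng(seed)``, so identical (spec, seed) pairs give
bit-identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volio import Volume


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

class PlaneSurface:
    """Flat reference surface z = z0 (already-flat or unbent tissue)."""

    def __init__(self, z0_um: float):
        self.z0 = float(z0_um)

    def z_of(self, y, x):
        return np.broadcast_arrays(np.asarray(y, float), np.asarray(x, float))[0] * 0 + self.z0

    def normal_at(self, y, x):
        y = np.asarray(y, float)
        n = np.zeros(np.broadcast_shapes(y.shape, np.shape(x)) + (3,))
        n[..., 0] = 1.0
        return n

    def height_above(self, points_zyx) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_zyx, float))
        return p[..., 0] - self.z0

    def height_grid(self, shape, spacing) -> np.ndarray:
        z = np.arange(shape[0]) * spacing[0]
        return np.broadcast_to(
            (z - self.z0)[:, None, None], shape
        ).copy()


class SphericalCapSurface:
    """Spherical cap emulating the curved retinal cup (default R=1700 µm).

    The sphere centre sits below the volume so that the cap bulges
    toward +z (the vitreous).  Signed height above the surface is the
    exact signed distance ``|p - c| - R``.
    """

    def __init__(self, radius_um: float = 1700.0, apex_zyx: Sequence[float] = (30.0, 64.0, 64.0)):
        self.R = float(radius_um)
        self.apex = np.asarray(apex_zyx, float)
        self.center = self.apex - np.array([self.R, 0.0, 0.0])

    def z_of(self, y, x):
        y = np.asarray(y, float)
        x = np.asarray(x, float)
        rho2 = (y - self.center[1]) ** 2 + (x - self.center[2]) ** 2
        return self.center[0] + np.sqrt(np.maximum(self.R**2 - rho2, 0.0))

    def normal_at(self, y, x):
        y = np.asarray(y, float)
        x = np.asarray(x, float)
        z = self.z_of(y, x)
        p = np.stack(np.broadcast_arrays(z, y, x), axis=-1)
        v = p - self.center
        return v / np.linalg.norm(v, axis=-1, keepdims=True)

    def height_above(self, points_zyx) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_zyx, float))
        return np.linalg.norm(p - self.center, axis=-1) - self.R

    def height_grid(self, shape, spacing) -> np.ndarray:
        z = np.arange(shape[0])[:, None, None] * spacing[0]
        y = np.arange(shape[1])[None, :, None] * spacing[1]
        x = np.arange(shape[2])[None, None, :] * spacing[2]
        d = np.sqrt(
            (z - self.center[0]) ** 2
            + (y - self.center[1]) ** 2
            + (x - self.center[2]) ** 2
        )
        return d - self.R


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    background: float = 0.05          # constant offset
    sigma: float = 0.02               # additive Gaussian SD
    blur_um: tuple[float, float, float] = (0.7, 0.7, 0.7)  # PSF-like blur

    def __post_init__(self):
        if any(b < 0 for b in self.blur_um):
            raise ValueError("blur sigma must be >= 0")


@dataclass
class VesselSpec:
    points_zyx_um: np.ndarray          # centerline control points, (N, 3) µm
    radius_um: float

    def __post_init__(self):
        self.points_zyx_um = np.atleast_2d(np.asarray(self.points_zyx_um, float))
        if self.radius_um <= 0:
            raise ValueError("vessel radius must be > 0")


@dataclass
class TuftSpec:
    anchor_yx_um: tuple[float, float]
    n_nuclei: int
    n_connections: int = 1
    n_tunnels: int = 0
    curved_nuclei_fraction: float = 0.0
    target_volume_um3: float = 1.0e4
    protrusion_height_um: float = 40.0

    def __post_init__(self):
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if self.n_connections < 1:
            raise ValueError("n_connections must be >= 1")
        if not (0 <= self.n_tunnels <= 2):
            raise ValueError("n_tunnels outside the supported range 0..2")
        if not (0.0 <= self.curved_nuclei_fraction <= 1.0):
            raise ValueError("curved_nuclei_fraction must be in [0, 1]")
        if self.target_volume_um3 <= 0 or self.protrusion_height_um <= 0:
            raise ValueError("target volume and protrusion height must be > 0")


@dataclass
class SceneSpec:
    seed: int = 0
    volume_shape: tuple[int, int, int] = (64, 128, 128)   # (z, y, x) voxels
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    surface: object = None
    vessels: list[VesselSpec] = field(default_factory=list)
    tufts: list[TuftSpec] = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing must be strictly positive")
        if self.surface is None:
            ny, nx = self.volume_shape[1], self.volume_shape[2]
            apex_z = 0.45 * self.volume_shape[0] * self.spacing_um[0]
            self.surface = SphericalCapSurface(
                1700.0,
                apex_zyx=(apex_z, ny * self.spacing_um[1] / 2, nx * self.spacing_um[2] / 2),
            )


@dataclass
class GroundTruth:
    """One record per generated object; arrays carried alongside.

    ``vessel_mask`` / ``nuclei_mask`` are the clean (pre-blur, pre-noise)
    binary channels; ``tuft_labels`` labels each tuft body+stalks.
    """

    surface: object = None
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    vessels: list[dict] = field(default_factory=list)
    tufts: list[dict] = field(default_factory=list)
    filopodia: list[dict] = field(default_factory=list)
    bundles: list[dict] = field(default_factory=list)
    layers: dict = field(default_factory=dict)
    compression_applied: float = 1.0
    unbent: bool = False
    vessel_mask: np.ndarray | None = None
    nuclei_mask: np.ndarray | None = None
    tuft_labels: np.ndarray | None = None

    def to_json_dict(self) -> dict:
        """JSON-serializable summary (arrays and surface objects dropped)."""
        def _clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items() if k != "centerline"}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        return {
            "spacing_um": list(self.spacing_um),
            "compression_applied": self.compression_applied,
            "unbent": self.unbent,
            "vessels": _clean(self.vessels),
            "tufts": _clean(self.tufts),
            "filopodia": _clean(self.filopodia),
            "bundles": _clean(self.bundles),
            "layers": _clean(self.layers),
        }


# ---------------------------------------------------------------------------
# rasterization primitives
# ---------------------------------------------------------------------------

def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, float))
    if len(pts) == 1:
        return pts
    segs = np.diff(pts, axis=0)
    seglen = np.linalg.norm(segs, axis=1)
    total = seglen.sum()
    if total == 0:
        return pts[:1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    t = np.linspace(0, total, n)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    out = np.empty((n, 3))
    for i, ti in enumerate(t):
        k = min(np.searchsorted(cum, ti, side="right") - 1, len(segs) - 1)
        frac = (ti - cum[k]) / seglen[k] if seglen[k] > 0 else 0.0
        out[i] = pts[k] + frac * segs[k]
    return out


def _bbox_slices(lo_um, hi_um, spacing, shape, pad_um):
    sl = []
    for ax in range(3):
        lo = int(np.floor((lo_um[ax] - pad_um) / spacing[ax]))
        hi = int(np.ceil((hi_um[ax] + pad_um) / spacing[ax])) + 1
        sl.append(slice(max(lo, 0), min(hi, shape[ax])))
    return tuple(sl)


def _grid_points(slices, spacing):
    axes = [np.arange(s.start, s.stop) * sp for s, sp in zip(slices, spacing)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()]), zz.shape


def rasterize_tube(mask: np.ndarray, spacing, points_um, radius_um: float) -> None:
    """OR a tube of circular cross-section around a polyline into ``mask``."""
    pts = _resample_polyline(points_um, min(spacing) / 3.0)
    sl = _bbox_slices(pts.min(0), pts.max(0), spacing, mask.shape, radius_um + 2 * max(spacing))
    if any(s.start >= s.stop for s in sl):
        return
    grid, gshape = _grid_points(sl, spacing)
    d, _ = cKDTree(pts).query(grid, workers=-1)
    mask[sl] |= (d <= radius_um).reshape(gshape)


def rasterize_ellipsoid(mask, spacing, center_um, semiaxes_um) -> None:
    c = np.asarray(center_um, float)
    a = np.asarray(semiaxes_um, float)
    sl = _bbox_slices(c - a, c + a, spacing, mask.shape, 2 * max(spacing))
    if any(s.start >= s.stop for s in sl):
        return
    grid, gshape = _grid_points(sl, spacing)
    q = (grid - c) / a
    mask[sl] |= (np.sum(q * q, axis=1) <= 1.0).reshape(gshape)


def rasterize_torus(
    mask, spacing, center_um, ring_radius_um, tube_radius_um,
    axis=(0.0, 0.0, 1.0), axis_stretch: float = 1.0,
) -> None:
    """Solid torus; ring lies in the plane perpendicular to ``axis``.

    ``axis_stretch`` scales the solid along its axis (volume scales
    linearly) without touching the ring plane, so the tunnel survives.
    """
    c = np.asarray(center_um, float)
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    ext = ring_radius_um + tube_radius_um + tube_radius_um * axis_stretch
    sl = _bbox_slices(c - ext, c + ext, spacing, mask.shape, 2 * max(spacing))
    if any(s.start >= s.stop for s in sl):
        return
    grid, gshape = _grid_points(sl, spacing)
    q = grid - c
    q_ax = q @ a
    q_perp = q - np.outer(q_ax, a)
    rho = np.linalg.norm(q_perp, axis=1)
    d2 = (rho - ring_radius_um) ** 2 + (q_ax / axis_stretch) ** 2
    mask[sl] |= (d2 <= tube_radius_um**2).reshape(gshape)


def render_channel(mask: np.ndarray, spacing, noise: NoiseSpec, rng) -> np.ndarray:
    """Blur a binary mask and add background + Gaussian noise (float32)."""
    sigma_vox = [b / s for b, s in zip(noise.blur_um, spacing)]
    img = ndimage.gaussian_filter(mask.astype(np.float32), sigma=sigma_vox)
    img += noise.background
    if noise.sigma > 0:
        img += rng.normal(0.0, noise.sigma, size=img.shape).astype(np.float32)
    return np.clip(img, 0.0, None).astype(np.float32)


# ---------------------------------------------------------------------------
# plexus volumes
# ---------------------------------------------------------------------------

def plexus_vessel_grid(
    surface,
    extent_yx_um: tuple[float, float],
    pitch_um: float = 22.0,
    radius_um: float = 2.5,
    margin_um: float = 6.0,
) -> list[VesselSpec]:
    """A rectilinear capillary-like grid draped on the surface."""
    ey, ex = extent_yx_um
    vessels = []
    for y in np.arange(margin_um, ey - margin_um + 1e-9, pitch_um):
        xs = np.linspace(margin_um, ex - margin_um, 24)
        pts = np.column_stack([surface.z_of(np.full_like(xs, y), xs), np.full_like(xs, y), xs])
        vessels.append(VesselSpec(pts, radius_um))
    for x in np.arange(margin_um, ex - margin_um + 1e-9, pitch_um):
        ys = np.linspace(margin_um, ey - margin_um, 24)
        pts = np.column_stack([surface.z_of(ys, np.full_like(ys, x)), ys, np.full_like(ys, x)])
        vessels.append(VesselSpec(pts, radius_um))
    return vessels


def make_plexus_volume(spec: SceneSpec) -> tuple[Volume, GroundTruth]:
    """Render the vessel channel of a plexus scene.

    Tube cross-sections are circular with the specified radius before any
    distortion; the ground truth records each vessel's radius and the
    local surface normal at each control point.
    """
    rng = np.random.default_rng(spec.seed)
    for v in spec.vessels:
        if v.radius_um < 2 * max(spec.spacing_um):
            raise ValueError(
                f"vessel radius {v.radius_um} µm unresolvable at spacing {spec.spacing_um}"
            )
    mask = np.zeros(spec.volume_shape, dtype=bool)
    truth = GroundTruth(surface=spec.surface, spacing_um=spec.spacing_um)
    for v in spec.vessels:
        rasterize_tube(mask, spec.spacing_um, v.points_zyx_um, v.radius_um)
        normals = spec.surface.normal_at(v.points_zyx_um[:, 1], v.points_zyx_um[:, 2])
        truth.vessels.append(
            {
                "radius_um": v.radius_um,
                "control_points_zyx_um": v.points_zyx_um.copy(),
                "normals_zyx": np.atleast_2d(normals),
                "expected_width_um": 2 * v.radius_um,
                "expected_depth_um": 2 * v.radius_um,
            }
        )
    img = render_channel(mask, spec.spacing_um, spec.noise, rng)
    vol = Volume(img[None], spec.spacing_um, axes="CZYX", channel_names=["vessels"])
    truth.vessel_mask = mask
    return vol, truth


# ---------------------------------------------------------------------------
# flat-mount distortion
# ---------------------------------------------------------------------------

def _distortion_forward_points(points_zyx, surface, compression, unbend, z_flat):
    """Forward map of physical points under unbend + z-compression."""
    p = np.atleast_2d(np.asarray(points_zyx, float)).copy()
    zs = surface.z_of(p[:, 1], p[:, 2])
    ref = np.full(len(p), z_flat) if unbend else zs
    p[:, 0] = ref + (p[:, 0] - zs) * compression
    return p


def apply_flatmount_distortion(
    volume: Volume,
    truth: GroundTruth,
    compression: float,
    unbend: bool = False,
) -> tuple[Volume, GroundTruth]:
    """Emulate confocal flat-mounting: optional unbending of the curved
    surface to a flat plane, then scaling the along-surface-normal (z)
    axis by ``compression``.

    Ground truth is updated so that the expected post-distortion depth is
    ``compression ×`` the true diameter while the width is unchanged;
    control points, masks and the surface model are transformed
    consistently.  ``compression=1, unbend=False`` is the identity.
    """
    if not (0.0 < compression <= 1.0):
        raise ValueError("compression must be in (0, 1]")
    surface = truth.surface
    spacing = volume.spacing
    shape_zyx = volume.data.shape[-3:]
    if compression == 1.0 and not unbend:
        new_truth = replace(truth)
        return Volume(volume.data.copy(), spacing, volume.axes, volume.channel_names), new_truth

    y = np.arange(shape_zyx[1]) * spacing[1]
    x = np.arange(shape_zyx[2]) * spacing[2]
    yy, xx = np.meshgrid(y, x, indexing="ij")
    zs = surface.z_of(yy, xx)                      # (ny, nx) µm
    z_flat = float(np.median(zs))
    zp = np.arange(shape_zyx[0])[:, None, None] * spacing[0]
    ref = z_flat if unbend else zs[None]
    src_z = zs[None] + (zp - ref) / compression     # inverse map, µm
    src_idx_z = src_z / spacing[0]
    idx_y, idx_x = np.meshgrid(
        np.arange(shape_zyx[1]), np.arange(shape_zyx[2]), indexing="ij"
    )
    coords = [
        np.broadcast_to(src_idx_z, (shape_zyx[0],) + idx_y.shape),
        np.broadcast_to(idx_y[None], (shape_zyx[0],) + idx_y.shape),
        np.broadcast_to(idx_x[None], (shape_zyx[0],) + idx_x.shape),
    ]

    def _warp(arr, order=1):
        return ndimage.map_coordinates(
            arr.astype(np.float32), coords, order=order, mode="constant", cval=0.0
        )

    data = volume.data
    if volume.axes == "ZYX":
        new_data = _warp(data)
    else:
        lead = data.shape[: data.ndim - 3]
        flat = data.reshape((-1,) + shape_zyx)
        new_data = np.stack([_warp(ch) for ch in flat]).reshape(data.shape)

    new_truth = GroundTruth(
        surface=PlaneSurface(z_flat) if unbend else surface,
        spacing_um=truth.spacing_um,
        compression_applied=truth.compression_applied * compression,
        unbent=truth.unbent or unbend,
        layers=dict(truth.layers),
        filopodia=list(truth.filopodia),
        bundles=list(truth.bundles),
    )
    for v in truth.vessels:
        rec = dict(v)
        rec["control_points_zyx_um"] = _distortion_forward_points(
            v["control_points_zyx_um"], surface, compression, unbend, z_flat
        )
        rec["expected_depth_um"] = v["expected_depth_um"] * compression
        if new_truth.unbent:
            n = np.zeros_like(np.atleast_2d(v["normals_zyx"]))
            n[:, 0] = 1.0
            rec["normals_zyx"] = n
        new_truth.vessels.append(rec)
    for t in truth.tufts:
        rec = dict(t)
        rec["protrusion_height_um"] = t["protrusion_height_um"] * compression
        if "nuclei" in t:
            rec["nuclei"] = [
                {
                    **n,
                    "centroid_zyx_um": _distortion_forward_points(
                        n["centroid_zyx_um"], surface, compression, unbend, z_flat
                    )[0],
                }
                for n in t["nuclei"]
            ]
        new_truth.tufts.append(rec)
    for name in ("vessel_mask", "nuclei_mask"):
        m = getattr(truth, name)
        if m is not None:
            setattr(new_truth, name, _warp(m) >= 0.5)
    if truth.tuft_labels is not None:
        new_truth.tuft_labels = _warp(truth.tuft_labels, order=0).astype(
            truth.tuft_labels.dtype
        )
    return Volume(new_data, spacing, volume.axes, volume.channel_names), new_truth


# ---------------------------------------------------------------------------
# tufts
# ---------------------------------------------------------------------------

#: geometry constants for tuft assembly (µm)
STALK_TOP_HEIGHT = 12.0      # body bottom sits this high above the plexus
STALK_RADIUS = 2.0
NUCLEUS_RADIUS = 1.6
NUCLEUS_ARM = 4.5            # half-length of straight capsules
CURVED_ARC_LENGTH = 14.0     # centreline length of C-shaped curved nuclei
CURVED_TURN_DEG = 170.0      # total tangent turn of the C shape
NUCLEUS_GAP = 2.5            # min surface-to-surface gap between nuclei
MIN_TUNNEL_RADIUS = 3.5


def _tuft_body_mask(shape, spacing, anchor_zyx, spec: TuftSpec, rng) -> np.ndarray:
    """Rasterize one tuft body (above the stalk top) per its topology."""
    he = spec.protrusion_height_um - STALK_TOP_HEIGHT
    if he <= 6:
        raise ValueError("protrusion height too small for a tuft body")
    body = np.zeros(shape, dtype=bool)
    cz = anchor_zyx[0] + STALK_TOP_HEIGHT + he / 2.0
    center = np.array([cz, anchor_zyx[1], anchor_zyx[2]])
    if spec.n_tunnels == 0:
        c_semi = he / 2.0
        ab = math.sqrt(3.0 * spec.target_volume_um3 / (4.0 * math.pi * c_semi))
        rasterize_ellipsoid(body, spacing, center, (c_semi, ab, ab))
        return body
    # torus-based bodies: ring in the (z, y) plane (axis along x) so the
    # tunnel is visible from the side, as in the imaged tufts
    n_lobes = spec.n_tunnels
    v_lobe = spec.target_volume_um3 / n_lobes
    half = he / 2.0
    r_t = min(he / 3.0, (half - MIN_TUNNEL_RADIUS) / 2.0)
    if r_t <= 1.5:
        raise ValueError("tuft too small to carry a tunnel")
    R = half - r_t  # hole radius R - r_t >= MIN_TUNNEL_RADIUS by construction
    v_base = 2 * math.pi**2 * R * r_t**2
    stretch = max(0.6, v_lobe / v_base)
    if n_lobes == 1:
        rasterize_torus(body, spacing, center, R, r_t, axis=(0, 0, 1), axis_stretch=stretch)
    else:
        for sgn in (-1.0, 1.0):
            c = center + np.array([0.0, sgn * R, 0.0])
            rasterize_torus(body, spacing, c, R, r_t, axis=(0, 0, 1), axis_stretch=stretch)
    return body


def _segment_min_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 3D segments (closed form)."""
    u, v, w = p1 - p0, q1 - q0, p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    s = np.clip((b * t - d) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    return float(np.linalg.norm((p0 + s * u) - (q0 + t * v)))


def _place_nuclei(body: np.ndarray, spacing, spec: TuftSpec, rng) -> list[dict]:
    """Rejection-sample capsule nuclei fully inside the body mask.

    Curved nuclei are C-shaped tubes following a circular arc
    (``CURVED_ARC_LENGTH`` µm of centreline turning ``CURVED_TURN_DEG``
    in total, emulating the dramatically bent nuclei seen in tufts);
    flat ones are straight capsules.  Centrelines keep a
    surface-to-surface gap of ``NUCLEUS_GAP`` so the rendered blobs stay
    separable.
    """
    edt = ndimage.distance_transform_edt(body, sampling=spacing)
    cand = np.argwhere(edt >= NUCLEUS_RADIUS + 1.0)
    if len(cand) == 0:
        raise RuntimeError("tuft body too thin to host nuclei")
    cand_um = cand * np.asarray(spacing)
    n_curved = int(round(spec.curved_nuclei_fraction * spec.n_nuclei))
    placed: list[dict] = []
    min_sep = 2 * NUCLEUS_RADIUS + NUCLEUS_GAP

    def _fits(poly):
        samples = _resample_polyline(poly, 0.8)
        idx = np.round(samples / spacing).astype(int)
        if (idx < 0).any() or (idx >= np.array(body.shape)).any():
            return False
        if np.any(edt[idx[:, 0], idx[:, 1], idx[:, 2]] < NUCLEUS_RADIUS + 0.6):
            return False
        c_new = poly.mean(axis=0)
        reach = CURVED_ARC_LENGTH + min_sep
        for other in placed:
            op = other["centerline"]
            if np.linalg.norm(c_new - op.mean(axis=0)) > reach:
                continue
            for i in range(len(poly) - 1):
                for j in range(len(op) - 1):
                    if (
                        _segment_min_distance(poly[i], poly[i + 1], op[j], op[j + 1])
                        < min_sep
                    ):
                        return False
        return True

    tree = cKDTree(cand_um)

    def _local_frame(c):
        """Main/secondary axes of the interior core near c: nuclei align
        with the local vessel direction like real endothelial nuclei."""
        idx = tree.query_ball_point(c, 10.0)
        if len(idx) < 8:
            return None
        pts_local = cand_um[idx] - cand_um[idx].mean(axis=0)
        _, vecs = np.linalg.eigh(np.cov(pts_local.T))
        return vecs[:, 2], vecs[:, 1]

    for k in range(spec.n_nuclei):
        curved = k < n_curved
        ok = False
        for attempt in range(6000):
            c = cand_um[rng.integers(len(cand_um))]
            frame = _local_frame(c) if attempt < 4000 else None
            if frame is not None:
                u = frame[0] + 0.25 * rng.normal(size=3)
            else:
                u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            if curved:
                e = (frame[1] if frame is not None else rng.normal(size=3)) + 0.25 * rng.normal(size=3)
                e -= (e @ u) * u
                e /= np.linalg.norm(e)
                theta = math.radians(CURVED_TURN_DEG)
                rho = CURVED_ARC_LENGTH / theta
                ts = np.linspace(-theta / 2, theta / 2, 11)
                poly = np.stack(
                    [c + rho * math.sin(t) * u + rho * (1 - math.cos(t)) * e for t in ts]
                )
            else:
                poly = np.array([c - NUCLEUS_ARM * u, c + NUCLEUS_ARM * u])
            if _fits(poly):
                placed.append(
                    {
                        "centerline": poly,
                        "curved": curved,
                        "centroid_zyx_um": poly.mean(axis=0),
                    }
                )
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place nucleus {k + 1}/{spec.n_nuclei}; tuft volume too small"
            )
    return placed


def _stalk_anchors(body: np.ndarray, spacing, surface, n: int, rng) -> np.ndarray:
    """Pick n well-separated (y, x) stalk positions under the body."""
    heights = surface.height_above(
        np.argwhere(body) * np.asarray(spacing)
    )
    vox = np.argwhere(body)
    low = vox[heights <= STALK_TOP_HEIGHT + 8.0]
    if len(low) == 0:
        low = vox
    foot = np.unique(low[:, 1:], axis=0) * np.asarray(spacing[1:])
    chosen = [foot[len(foot) // 2]]
    for _ in range(n - 1):
        d = np.min(
            np.linalg.norm(foot[:, None, :] - np.asarray(chosen)[None], axis=-1), axis=1
        )
        best = int(np.argmax(d))
        if d[best] < 7.0:
            raise RuntimeError("tuft footprint too small for requested connections")
        chosen.append(foot[best])
    return np.asarray(chosen)


def make_tuft_volume(spec: SceneSpec) -> tuple[Volume, GroundTruth]:
    """Render a two-channel tuft scene (vessels + nuclei) with ground truth.

    Each tuft is a blob/coil protruding above the plexus with exactly
    ``n_connections`` tube stalks crossing the plexus interface and first
    Betti number equal to ``n_tunnels``; the nuclei channel carries
    exactly ``n_nuclei`` separable blobs per tuft.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.volume_shape, spec.spacing_um
    vessel = np.zeros(shape, dtype=bool)
    nuclei = np.zeros(shape, dtype=bool)
    labels = np.zeros(shape, dtype=np.int16)
    truth = GroundTruth(surface=spec.surface, spacing_um=spacing)
    for v in spec.vessels:
        rasterize_tube(vessel, spacing, v.points_zyx_um, v.radius_um)
    voxvol = float(np.prod(spacing))
    for i, t in enumerate(spec.tufts, start=1):
        zy = spec.surface.z_of(t.anchor_yx_um[0], t.anchor_yx_um[1])
        anchor = np.array([float(zy), t.anchor_yx_um[0], t.anchor_yx_um[1]])
        body = _tuft_body_mask(shape, spacing, anchor, t, rng)
        placed = _place_nuclei(body, spacing, t, rng)
        stalk = np.zeros(shape, dtype=bool)
        for yx in _stalk_anchors(body, spacing, spec.surface, t.n_connections, rng):
            z0 = spec.surface.z_of(yx[0], yx[1]) - 3.0
            col = body[:, int(round(yx[0] / spacing[1])), int(round(yx[1] / spacing[2]))]
            nz = np.nonzero(col)[0]
            z1 = (nz[0] * spacing[0] + 3.0) if len(nz) else anchor[0] + STALK_TOP_HEIGHT + 3.0
            rasterize_tube(
                stalk, spacing,
                np.array([[z0, yx[0], yx[1]], [z1, yx[0], yx[1]]]),
                STALK_RADIUS,
            )
        tuft_mask = body | stalk
        vessel |= tuft_mask
        labels[tuft_mask] = i
        for n in placed:
            rasterize_tube(nuclei, spacing, n["centerline"], NUCLEUS_RADIUS)
        truth.tufts.append(
            {
                "tuft_id": i,
                "anchor_zyx_um": anchor,
                "n_nuclei": t.n_nuclei,
                "n_connections": t.n_connections,
                "n_tunnels": t.n_tunnels,
                "curved_nuclei_fraction": t.curved_nuclei_fraction,
                "n_curved_nuclei": sum(n["curved"] for n in placed),
                "protrusion_height_um": t.protrusion_height_um,
                "realized_volume_um3": float(body.sum()) * voxvol,
                "nuclei": [
                    {
                        "centroid_zyx_um": n["centroid_zyx_um"],
                        "curved": bool(n["curved"]),
                        "centerline": n["centerline"],
                    }
                    for n in placed
                ],
            }
        )
    img_v = render_channel(vessel, spacing, spec.noise, rng)
    img_n = render_channel(nuclei, spacing, replace(spec.noise, blur_um=(0.5, 0.5, 0.5)), rng)
    vol = Volume(
        np.stack([img_v, img_n]), spacing, axes="CZYX", channel_names=["vessels", "nuclei"]
    )
    truth.vessel_mask = vessel
    truth.nuclei_mask = nuclei
    truth.tuft_labels = labels
    return vol, truth


# ---------------------------------------------------------------------------
# time lapse
# ---------------------------------------------------------------------------

@dataclass
class FilopodiumScript:
    """Base point + per-frame length along a fixed direction."""

    base_zyx_um: np.ndarray
    direction_zyx: np.ndarray
    lengths_um: np.ndarray
    id: object = None

    def __post_init__(self):
        self.base_zyx_um = np.asarray(self.base_zyx_um, float)
        d = np.asarray(self.direction_zyx, float)
        self.direction_zyx = d / np.linalg.norm(d)
        self.lengths_um = np.asarray(self.lengths_um, float)

    def tip_positions(self) -> np.ndarray:
        return self.base_zyx_um[None] + self.lengths_um[:, None] * self.direction_zyx[None]


@dataclass
class BundleScript:
    """Per-frame positions of one moving actin-rich bundle."""

    positions_zyx_um: np.ndarray
    id: object = None

    def __post_init__(self):
        self.positions_zyx_um = np.atleast_2d(np.asarray(self.positions_zyx_um, float))

    def path_length(self) -> float:
        return float(
            np.linalg.norm(np.diff(self.positions_zyx_um, axis=0), axis=1).sum()
        )


def make_timelapse(
    filopodia: Sequence[FilopodiumScript],
    bundles: Sequence[BundleScript] = (),
    volume_shape=(32, 64, 64),
    spacing_um=(1.0, 1.0, 1.0),
    dt_min: float = 1.0,
    seed: int = 0,
    noise: NoiseSpec | None = None,
    epsilon_um: float = 0.5,
    render: bool = True,
) -> tuple[Volume | None, "pd.DataFrame", GroundTruth]:
    """Render a 4D stack plus the exact track table for scripted objects.

    Ground-truth kinematics are computed from the scripts in closed form
    (max of the length script, the ε-rule lifetime, mean signed rates,
    cumulative step sums), independent of any rendering.
    """
    import pandas as pd

    if dt_min <= 0:
        raise ValueError("dt_min must be > 0 (frame interval is constant by contract)")
    n_frames = 0
    for f in filopodia:
        n_frames = max(n_frames, len(f.lengths_um))
    for b in bundles:
        n_frames = max(n_frames, len(b.positions_zyx_um))
    if n_frames == 0:
        raise ValueError("no scripted objects")
    rng = np.random.default_rng(seed)
    noise = noise or NoiseSpec(background=0.03, sigma=0.01, blur_um=(0.5, 0.5, 0.5))

    rows = []
    truth = GroundTruth(spacing_um=spacing_um)
    for k, f in enumerate(filopodia):
        fid = f.id if f.id is not None else f"filo_{k}"
        tips = f.tip_positions()
        for fr, p in enumerate(tips):
            rows.append((fid, fr, p[2], p[1], p[0]))
        L = f.lengths_um
        alive = L > epsilon_um
        appear = int(np.argmax(alive)) if alive.any() else None
        if appear is None:
            raise ValueError(f"filopodium {fid}: never exceeds epsilon")
        dead_after = np.nonzero(~alive[appear:])[0]
        disappear = appear + int(dead_after[0]) if dead_after.size else len(L)
        rates = np.diff(L) / dt_min
        pos, neg = rates[rates > 0], rates[rates < 0]
        truth.filopodia.append(
            {
                "id": fid,
                "base_zyx_um": f.base_zyx_um,
                "lengths_um": L,
                "max_length_um": float(L[appear:disappear].max()),
                "lifetime_min": float((disappear - appear) * dt_min),
                "censored": not dead_after.size,
                "extension_speed_um_min": float(pos.mean()) if pos.size else 0.0,
                "retraction_speed_um_min": float(np.abs(neg).mean()) if neg.size else 0.0,
            }
        )
    for k, b in enumerate(bundles):
        bid = b.id if b.id is not None else f"bundle_{k}"
        for fr, p in enumerate(b.positions_zyx_um):
            rows.append((bid, fr, p[2], p[1], p[0]))
        n = len(b.positions_zyx_um)
        truth.bundles.append(
            {
                "id": bid,
                "path_length_um": b.path_length(),
                "duration_min": float((n - 1) * dt_min),
                "average_speed_um_min": b.path_length() / ((n - 1) * dt_min) if n > 1 else 0.0,
            }
        )
    tracks_df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um", "z_um"])
    tracks_df = tracks_df.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)

    vol = None
    if render:
        frames = []
        for fr in range(n_frames):
            m = np.zeros(volume_shape, dtype=bool)
            for f in filopodia:
                if fr < len(f.lengths_um) and f.lengths_um[fr] > 0:
                    tip = f.base_zyx_um + f.lengths_um[fr] * f.direction_zyx
                    rasterize_tube(m, spacing_um, np.array([f.base_zyx_um, tip]), 0.9)
                elif fr < len(f.lengths_um):
                    rasterize_ellipsoid(m, spacing_um, f.base_zyx_um, (1.2, 1.2, 1.2))
            for b in bundles:
                if fr < len(b.positions_zyx_um):
                    rasterize_ellipsoid(
                        m, spacing_um, b.positions_zyx_um[fr], (1.5, 1.5, 1.5)
                    )
            frames.append(render_channel(m, spacing_um, noise, rng))
        vol = Volume(np.stack(frames), spacing_um, axes="TZYX")
    return vol, tracks_df, truth


# --- study-condition cohorts (scripted kinematics, no rendering) -----------

#: printed study conditions for the filopodia cohorts
FILOPODIA_CONDITIONS = {
    "p5": {"mean_max_length_um": 14.84, "n": 67},
    "oir": {"mean_max_length_um": 4.3, "n": 23},
}
BUNDLE_MEAN_SPEED_UM_MIN = 2.56


def filopodia_cohort(
    condition: str,
    rng: np.random.Generator,
    n: int | None = None,
    dt_min: float = 1.0,
) -> list[FilopodiumScript]:
    """Scripted filopodia for one condition (``p5`` or ``oir``).

    Each filopodium grows linearly from zero to its own max length,
    dwells briefly, and retracts to zero; max lengths scatter around the
    condition mean with 20% relative SD.
    """
    cond = FILOPODIA_CONDITIONS[condition]
    n = n if n is not None else cond["n"]
    scripts = []
    for k in range(n):
        L = max(1.0, rng.normal(cond["mean_max_length_um"], 0.2 * cond["mean_max_length_um"]))
        rate = max(0.8, rng.normal(2.0, 0.4))                   # µm/min
        n_up = max(1, int(round(L / (rate * dt_min))))
        up = np.linspace(0.0, L, n_up + 1)
        dwell = np.full(int(rng.integers(0, 3)), L)
        down = np.linspace(L, 0.0, n_up + 1)[1:]
        lengths = np.concatenate([[0.0], up, dwell, down, [0.0]])
        base = rng.uniform(10, 50, size=3)
        d = rng.normal(size=3)
        scripts.append(
            FilopodiumScript(base, d, lengths, id=f"{condition}_{k}")
        )
    return scripts


def bundle_cohort(
    rng: np.random.Generator,
    n: int = 18,
    dt_min: float = 1.0,
) -> list[BundleScript]:
    """Scripted actin-bundle random walks with per-bundle constant speed
    drawn around the observed 2.56 µm/min average."""
    scripts = []
    for k in range(n):
        speed = max(0.3, rng.normal(BUNDLE_MEAN_SPEED_UM_MIN, 0.5))
        n_frames = int(rng.integers(8, 41))                     # 7–40 min videos
        steps = rng.normal(size=(n_frames - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        steps *= speed * dt_min
        pos = np.concatenate([[rng.uniform(10, 50, size=3)], steps]).cumsum(axis=0)
        scripts.append(BundleScript(pos, id=f"bundle_{k}"))
    return scripts


# --- tuft population (study conditions) ------------------------------------

#: class-conditional population parameters: many small/medium tufts, few
#: large ones; volume rises roughly linearly with nuclei up to ~10 then
#: plateaus within the medium class; connections roughly constant within
#: a class and jumping ~2.5-fold (volume ~3-fold) past the 20-nuclei
#: boundary.  Absolute volume scale is the generator's own choice.
TUFT_CLASS_PARAMS = {
    "small": {"plateau_volume_um3": 6.0e3, "protrusion_um": 28.0, "connections": (1, 2)},
    "medium": {"plateau_volume_um3": 3.3e4, "protrusion_um": 42.0, "connections": (2, 2, 2, 3)},
    "large": {"plateau_volume_um3": 1.0e5, "protrusion_um": 55.0, "connections": (4, 5, 5, 6)},
}


def tuft_population(
    rng: np.random.Generator,
    n: int = 30,
    class_counts: tuple[int, int, int] = (8, 16, 6),
) -> list[TuftSpec]:
    """Sample a tuft cohort spanning all three size classes.

    ``class_counts`` gives (small, medium, large) counts and must sum to
    ``n``.  Curved-nuclei fractions are ~one half in small/medium tufts
    and a roughly constant *count* (~8) in large tufts; tunnels appear
    in the girthier tufts (some mediums and larges).
    """
    ns, nm, nl = class_counts
    if ns + nm + nl != n:
        raise ValueError("class counts must sum to n")
    specs = []
    nuclei_counts = (
        [int(rng.integers(2, 4)) for _ in range(ns)]
        + [int(rng.integers(4, 21)) for _ in range(nm)]
        + [int(rng.integers(21, 31)) for _ in range(nl)]
    )
    for k, n_nuc in enumerate(nuclei_counts):
        if n_nuc < 4:
            cls = "small"
        elif n_nuc <= 20:
            cls = "medium"
        else:
            cls = "large"
        p = TUFT_CLASS_PARAMS[cls]
        plateau = p["plateau_volume_um3"]
        if cls == "small":
            vol = plateau * (n_nuc / 3.0)
        elif cls == "medium":
            vol = plateau * (min(n_nuc, 10) / 10.0)
        else:
            vol = plateau
        vol *= float(rng.lognormal(0.0, 0.12))
        if cls == "small":
            tunnels = 0
        elif cls == "medium":
            tunnels = int(rng.choice([0, 0, 1, 1, 2])) if n_nuc >= 8 else 0
        else:
            tunnels = int(rng.choice([0, 1, 1, 2]))
        # feasibility floor: enough interior to host the nuclei (tunnel
        # bodies are thinner-walled, so need more volume per nucleus)
        vol = max(vol, (2000.0 if tunnels else 1700.0) * n_nuc)
        frac = 0.5 if cls != "large" else min(1.0, 8.0 / n_nuc)
        specs.append(
            TuftSpec(
                anchor_yx_um=(60.0, 60.0),
                n_nuclei=n_nuc,
                n_connections=int(rng.choice(p["connections"])),
                n_tunnels=tunnels,
                curved_nuclei_fraction=frac,
                target_volume_um3=vol,
                protrusion_height_um=p["protrusion_um"] * float(rng.normal(1.0, 0.05)),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# layered (ONL-like) volumes
# ---------------------------------------------------------------------------

def make_layered_volume(
    density_per_um2: float,
    thickness_um: float,
    volume_shape=(96, 128, 128),
    spacing_um=(1.0, 1.0, 1.0),
    surface=None,
    base_height_um: float = 8.0,
    nucleus_radius_um: float = 2.5,
    seed: int = 0,
    noise: NoiseSpec | None = None,
) -> tuple[Volume, GroundTruth]:
    """A curved slab of nuclei at a requested areal density.

    Nuclei are spheres placed by a uniform point process over the (y, x)
    footprint — ``round(density × area)`` of them, so the ground-truth
    density is exact — at random depths within the slab.  A warning flag
    is set in the ground truth when placements overlap (density too high
    for the blob size).
    """
    if density_per_um2 < 0 or thickness_um <= 0:
        raise ValueError("density must be >= 0 and thickness > 0")
    rng = np.random.default_rng(seed)
    spacing = tuple(float(s) for s in spacing_um)
    if surface is None:
        surface = SphericalCapSurface(
            1700.0,
            apex_zyx=(
                base_height_um,
                volume_shape[1] * spacing[1] / 2,
                volume_shape[2] * spacing[2] / 2,
            ),
        )
    ext_y = volume_shape[1] * spacing[1]
    ext_x = volume_shape[2] * spacing[2]
    area = ext_y * ext_x
    n = int(round(density_per_um2 * area))
    nuclei = np.zeros(volume_shape, dtype=bool)
    centers = []
    for _ in range(n):
        y = rng.uniform(0, ext_y)
        x = rng.uniform(0, ext_x)
        zlo = surface.z_of(y, x) + nucleus_radius_um
        zhi = surface.z_of(y, x) + thickness_um - nucleus_radius_um
        z = rng.uniform(zlo, max(zhi, zlo + 1e-6))
        centers.append((z, y, x))
        rasterize_ellipsoid(nuclei, spacing, (z, y, x), (nucleus_radius_um,) * 3)
    centers = np.asarray(centers).reshape(-1, 3)
    overlap = False
    if len(centers) > 1:
        d, _ = cKDTree(centers).query(centers, k=2)
        overlap = bool(np.any(d[:, 1] < 2 * nucleus_radius_um))

    hgrid = surface.height_grid(volume_shape, spacing)
    slab = (hgrid >= 0) & (hgrid <= thickness_um)
    noise = noise or NoiseSpec()
    img_n = render_channel(nuclei, spacing, noise, rng)
    img_l = render_channel(slab, spacing, noise, rng)
    vol = Volume(
        np.stack([img_n, img_l]), spacing, axes="CZYX", channel_names=["nuclei", "layer"]
    )
    truth = GroundTruth(surface=surface, spacing_um=spacing)
    truth.nuclei_mask = nuclei
    truth.layers = {
        "density_per_um2": (len(centers) / area) if area > 0 else 0.0,
        "n_nuclei": int(len(centers)),
        "area_um2": area,
        "thickness_um": float(thickness_um),
        "overlap_warning": overlap,
        "centers_zyx_um": centers,
    }
    return vol, truth
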