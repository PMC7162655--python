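"""Vessel segmentation, centreline graphs, plexus planes and
plane-referenced diameter measurements.

The distortion analysis compares, for the same vessel site, the diameter
measured in the local tangent plane of the superficial plexus ("width",
the in-plane chord perpendicular to the vessel axis) with the diameter
along the plane normal ("depth").  In flat-mounted confocal stacks those
directions coincide with XY and Z; in light-sheet stacks the tissue sits
at an arbitrary orientation, so the plexus plane is fitted locally from
the surrounding centreline network and used as the reference frame.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

_OFFSETS26 = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
)


@dataclass
class VesselMask:
    mask: np.ndarray
    spacing: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def volume_um3(self) -> float:
        return float(self.mask.sum()) * float(np.prod(self.spacing))


@dataclass
class SkeletonGraph:
    """Simplified medial-axis graph: junction/end nodes + edge polylines.

    ``points_um`` holds every skeleton voxel in µm (used for plane
    fitting); ``graph`` is a networkx multigraph whose edges carry
    ``polyline`` (µm points) and ``length_um``.
    """

    graph: nx.MultiGraph
    points_um: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def nodes_um(self) -> np.ndarray:
        return np.array([self.graph.nodes[n]["pos_um"] for n in self.graph.nodes])

    def edges(self):
        return [
            (u, v, d["polyline"], d["length_um"])
            for u, v, d in self.graph.edges(data=True)
        ]

    def node_degree(self, n) -> int:
        return self.graph.degree(n)


@dataclass
class PlexusPlane:
    """Local tangent-plane model of the superficial plexus."""

    anchor_um: np.ndarray
    normal: np.ndarray
    fit_radius_um: float
    fit_residual_um: float

    def __post_init__(self):
        self.anchor_um = np.asarray(self.anchor_um, float)
        n = np.asarray(self.normal, float)
        self.normal = n / np.linalg.norm(n)

    def height_above(self, points_zyx) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_zyx, float))
        return (p - self.anchor_um) @ self.normal

    def height_grid(self, shape, spacing) -> np.ndarray:
        z = np.arange(shape[0])[:, None, None] * spacing[0]
        y = np.arange(shape[1])[None, :, None] * spacing[1]
        x = np.arange(shape[2])[None, None, :] * spacing[2]
        return (
            (z - self.anchor_um[0]) * self.normal[0]
            + (y - self.anchor_um[1]) * self.normal[1]
            + (x - self.anchor_um[2]) * self.normal[2]
        )


@dataclass
class DiameterMeasurement:
    site_um: np.ndarray
    width_um: float
    depth_um: float
    modality: str = "lsfm"

    @property
    def aspect_ratio(self) -> float:
        """W / D; > 1 means wider than deep (flattened)."""
        return self.width_um / self.depth_um


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_vessels(
    volume,
    channel: str | int = 0,
    method: str = "otsu",
    threshold: float = 0.5,
    min_component_um3: float = 0.0,
) -> VesselMask:
    """Threshold a channel into a binary vessel mask with size cleanup."""
    from .volio import Volume

    if isinstance(volume, Volume):
        img = volume.channel(channel)
        spacing = volume.spacing
    else:
        img = np.asarray(volume)
        spacing = (1.0, 1.0, 1.0)
    img = np.asarray(img, float)
    if method == "otsu":
        if img.max() == img.min():
            raise ValueError("no vessels found: channel is constant")
        thr = threshold_otsu(img)
        mask = img > thr
    elif method == "fixed_threshold":
        thr = float(threshold)
        mask = img >= thr
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    if min_component_um3 > 0 and mask.any():
        voxvol = float(np.prod(spacing))
        lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        keep = np.nonzero(sizes * voxvol >= min_component_um3)[0] + 1
        mask = np.isin(lab, keep)
    if not mask.any():
        raise ValueError("no vessels found after segmentation/cleanup")
    return VesselMask(
        mask=mask,
        spacing=spacing,
        provenance={"method": method, "threshold": float(thr),
                    "min_component_um3": min_component_um3},
    )


# ---------------------------------------------------------------------------
# skeleton graph
# ---------------------------------------------------------------------------

def skeletonize_mask(mask_or_vm, spacing=None, prune_um: float = 4.0) -> SkeletonGraph:
    """3D medial-axis skeleton converted to a junction/edge graph.

    Degree-2 chain voxels are contracted into edge polylines with
    spacing-aware lengths; spur edges shorter than ``prune_um`` that end
    in a free tip are removed (skeletonization artefacts at junctions).
    """
    if isinstance(mask_or_vm, VesselMask):
        mask, spacing = mask_or_vm.mask, mask_or_vm.spacing
    else:
        mask = np.asarray(mask_or_vm, bool)
        spacing = tuple(spacing) if spacing is not None else (1.0, 1.0, 1.0)
    if not mask.any():
        raise ValueError("cannot skeletonize an empty mask")
    skel = skeletonize(mask)
    coords = np.argwhere(skel)
    sp = np.asarray(spacing, float)
    index = {tuple(c): i for i, c in enumerate(coords)}
    # voxel-level adjacency (26-neighborhood)
    vg = nx.Graph()
    vg.add_nodes_from(range(len(coords)))
    for i, c in enumerate(coords):
        for off in _OFFSETS26:
            j = index.get(tuple(c + off))
            if j is not None and j > i:
                vg.add_edge(i, j, w=float(np.linalg.norm(off * sp)))

    pos_um = coords * sp
    graph = nx.MultiGraph()

    def _add_node(i):
        if not graph.has_node(i):
            graph.add_node(i, pos_um=pos_um[i])

    visited_edges = set()
    junction = {i for i in vg.nodes if vg.degree(i) != 2}
    for comp in nx.connected_components(vg):
        comp_junc = junction & comp
        if not comp_junc:
            # pure cycle or isolated voxel: pick an arbitrary anchor node
            start = min(comp)
            comp_junc = {start}
            junction.add(start)
        for n0 in comp_junc:
            _add_node(n0)
            for nb in vg.neighbors(n0):
                key = (min(n0, nb), max(n0, nb))
                if key in visited_edges:
                    continue
                chain = [n0, nb]
                prev, cur = n0, nb
                while cur not in junction:
                    nxt = [m for m in vg.neighbors(cur) if m != prev]
                    if not nxt:
                        break
                    prev, cur = cur, nxt[0]
                    chain.append(cur)
                for a, b in zip(chain[:-1], chain[1:]):
                    visited_edges.add((min(a, b), max(a, b)))
                end = chain[-1]
                _add_node(end)
                poly = pos_um[chain]
                length = float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())
                graph.add_edge(n0, end, polyline=poly, length_um=length)

    # prune short free-tip spurs (junction artefacts)
    changed = True
    while changed and prune_um > 0:
        changed = False
        for u, v, k, d in list(graph.edges(keys=True, data=True)):
            if d["length_um"] >= prune_um or u == v:
                continue
            du, dv = graph.degree(u), graph.degree(v)
            if du == 1 and dv > 2:
                graph.remove_edge(u, v, k)
                graph.remove_node(u)
                changed = True
            elif dv == 1 and du > 2:
                graph.remove_edge(u, v, k)
                graph.remove_node(v)
                changed = True
    return SkeletonGraph(graph=graph, points_um=pos_um, spacing=spacing)


# ---------------------------------------------------------------------------
# plexus plane
# ---------------------------------------------------------------------------

def fit_plexus_plane(
    skeleton: SkeletonGraph,
    site_um,
    fit_radius_um: float = 30.0,
    exclude_mask: np.ndarray | None = None,
    reference_direction=(1.0, 0.0, 0.0),
    min_points: int = 10,
) -> PlexusPlane:
    """Fit the local plexus tangent plane at a site.

    The plane passes through the centroid of skeleton points within
    ``fit_radius_um`` of the site; its normal is the direction of least
    variance of those points (PCA), oriented toward the vitreous-side
    ``reference_direction`` (+z by default).  Off-plexus voxels (e.g.
    tufts) can be excluded by mask.
    """
    site = np.asarray(site_um, float)
    pts = skeleton.points_um
    sel = np.linalg.norm(pts - site, axis=1) <= fit_radius_um
    if exclude_mask is not None:
        sp = np.asarray(skeleton.spacing)
        idx = np.round(pts / sp).astype(int)
        idx = np.clip(idx, 0, np.array(exclude_mask.shape) - 1)
        sel &= ~exclude_mask[idx[:, 0], idx[:, 1], idx[:, 2]]
    pts = pts[sel]
    if len(pts) < min_points:
        raise ValueError(
            f"plexus neighborhood too sparse: {len(pts)} skeleton points "
            f"within {fit_radius_um} µm (need >= {min_points})"
        )
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    normal = evecs[:, 0]
    ref = np.asarray(reference_direction, float)
    if normal @ ref < 0:
        normal = -normal
    residual = float(np.sqrt(np.mean(((pts - centroid) @ normal) ** 2)))
    return PlexusPlane(
        anchor_um=centroid, normal=normal,
        fit_radius_um=fit_radius_um, fit_residual_um=residual,
    )


# ---------------------------------------------------------------------------
# diameters
# ---------------------------------------------------------------------------

def _chord_through(img: np.ndarray, spacing, site_um, direction, level=0.5,
                   step_um=0.25, max_um=100.0) -> float:
    """Length of the chord of ``img >= level`` through ``site`` along
    ±``direction``, with linear subvoxel localization of the 0.5 crossing."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    sp = np.asarray(spacing, float)

    def _half(sign):
        n = int(max_um / step_um)
        t = np.arange(n + 1) * step_um
        pts = site_um[None] + sign * t[:, None] * d[None]
        idx = (pts / sp).T
        vals = ndimage.map_coordinates(img, idx, order=1, mode="constant", cval=0.0)
        below = np.nonzero(vals < level)[0]
        if not below.size:
            return float(t[-1])
        k = below[0]
        if k == 0:
            return 0.0
        v0, v1 = vals[k - 1], vals[k]
        frac = (v0 - level) / (v0 - v1) if v0 != v1 else 0.0
        return float(t[k - 1] + frac * step_um)

    img = np.asarray(img, float)
    return _half(+1.0) + _half(-1.0)


def local_vessel_axis(skeleton: SkeletonGraph, site_um, window_um: float = 8.0) -> np.ndarray:
    """Tangent direction of the skeleton edge nearest to the site."""
    site = np.asarray(site_um, float)
    best, best_d = None, np.inf
    for _, _, poly, _ in skeleton.edges():
        d = np.linalg.norm(poly - site, axis=1)
        k = int(np.argmin(d))
        if d[k] < best_d:
            best_d, best = d[k], (poly, k)
    if best is None:
        raise ValueError("skeleton has no edges near the site")
    poly, k = best
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(poly, axis=0), axis=1))])
    sel = np.abs(arc - arc[k]) <= window_um
    seg = poly[sel]
    if len(seg) < 2:
        lo, hi = max(k - 1, 0), min(k + 2, len(poly))
        seg = poly[lo:hi]
    axis = seg[-1] - seg[0]
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("degenerate vessel axis at site")
    return axis / norm


def measure_diameters(
    mask_or_vm,
    site_um,
    plane: PlexusPlane,
    skeleton: SkeletonGraph,
    spacing=None,
    modality: str = "lsfm",
    min_axis_angle_deg: float = 15.0,
    width_mode: str = "perpendicular",
    chord_image: np.ndarray | None = None,
    level: float = 0.5,
) -> DiameterMeasurement:
    """Plane-referenced width and depth of the vessel at a site.

    Depth is the chord of the mask through the site along the plexus
    normal; width is the chord along the in-plane direction
    perpendicular to the local vessel axis (``normal × axis``).  With
    ``width_mode="max_inplane"`` the maximal in-plane chord over
    directions perpendicular to the normal is reported instead (the
    alternative reading of an XY measurement).

    Chords localize the ``level``-crossing of the linearly interpolated
    mask; passing the pre-threshold intensity as ``chord_image`` keeps
    genuinely subvoxel edge localization.
    """
    if isinstance(mask_or_vm, VesselMask):
        img, spacing = mask_or_vm.mask.astype(float), mask_or_vm.spacing
    else:
        img = np.asarray(mask_or_vm, float)
        spacing = tuple(spacing) if spacing is not None else (1.0, 1.0, 1.0)
    if chord_image is not None:
        img = np.asarray(chord_image, float)
    site = np.asarray(site_um, float)
    normal = plane.normal
    axis = local_vessel_axis(skeleton, site)
    cosang = abs(float(axis @ normal))
    if cosang > np.cos(np.deg2rad(min_axis_angle_deg)):
        raise ValueError(
            "segment not measurable against this plane: vessel axis within "
            f"{min_axis_angle_deg}° of the plane normal"
        )
    depth = _chord_through(img, spacing, site, normal, level=level)
    if width_mode == "perpendicular":
        wdir = np.cross(normal, axis)
        wdir /= np.linalg.norm(wdir)
        width = _chord_through(img, spacing, site, wdir, level=level)
    elif width_mode == "max_inplane":
        u = np.cross(normal, axis)
        u /= np.linalg.norm(u)
        v = np.cross(normal, u)
        width = max(
            _chord_through(
                img, spacing, site, np.cos(t) * u + np.sin(t) * v, level=level
            )
            for t in np.linspace(0, np.pi, 18, endpoint=False)
        )
    else:
        raise ValueError(f"unknown width_mode {width_mode!r}")
    if width <= 0 or depth <= 0:
        raise ValueError("site is outside the vessel mask (zero chord)")
    return DiameterMeasurement(site_um=site, width_um=width, depth_um=depth, modality=modality)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def unpaired_ttest(x, y, equal_var: bool = True) -> dict:
    """Two-sample unpaired t-test (Student by default, Welch optional)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 measurements per group")
    degenerate = x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean()
    if degenerate:
        warnings.warn("degenerate t-test: both groups constant and equal")
        df = len(x) + len(y) - 2 if equal_var else float(len(x) + len(y) - 2)
        return {"t": 0.0, "df": float(df), "p": 1.0, "degenerate": True}
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return {
        "t": float(res.statistic),
        "df": float(res.df),
        "p": float(res.pvalue),
        "degenerate": False,
    }


def compare_distortion(
    lsfm: list[DiameterMeasurement],
    confocal: list[DiameterMeasurement],
) -> dict:
    """Group means and unpaired t-tests (Student and Welch) on depth and
    on the W/D aspect ratio between the two imaging modalities."""
    def _summ(ms):
        w = np.array([m.width_um for m in ms])
        d = np.array([m.depth_um for m in ms])
        return {
            "n": len(ms),
            "mean_width_um": float(w.mean()),
            "mean_depth_um": float(d.mean()),
            "mean_aspect": float((w / d).mean()),
            "_w": w,
            "_d": d,
        }

    a, b = _summ(lsfm), _summ(confocal)
    report = {
        "lsfm": {k: v for k, v in a.items() if not k.startswith("_")},
        "confocal": {k: v for k, v in b.items() if not k.startswith("_")},
        "tests": {},
    }
    for metric, (xa, xb) in {
        "depth_um": (a["_d"], b["_d"]),
        "aspect": (a["_w"] / a["_d"], b["_w"] / b["_d"]),
    }.items():
        report["tests"][metric] = {
            "student": unpaired_ttest(xa, xb, equal_var=True),
            "welch": unpaired_ttest(xa, xb, equal_var=False),
        }
    return report
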