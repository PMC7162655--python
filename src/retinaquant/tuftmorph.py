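"""Pathological tuft morphometrics, topology and nucleus–Golgi polarity.

In the oxygen-induced retinopathy model, vessels sprout into the vitreous
as bulbous "tufts" above the superficial plexus.  This module detects
tufts as connected vessel components protruding past a height threshold
above the plexus reference, and quantifies per tuft: volume (voxel
integration), endothelial nuclei (blob detection with watershed
splitting, plus a principal-curve curvature criterion for "curved"
nuclei), the number of stalk connections to the plexus, the protrusion
depth along the plexus normal, a small/medium/large size class on nuclei
count, and the number of tunnels through the tuft (first Betti number of
the voxel complex — the "knotted" morphology).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import euler_number
from skimage.morphology import skeletonize
from skimage.segmentation import watershed

from .vesselgeom import SkeletonGraph

#: size-class boundaries on nuclei count: < 4 small, 4–20 medium, > 20 large
SMALL_BELOW = 4
LARGE_ABOVE = 20


@dataclass
class NucleusRecord:
    centroid_um: np.ndarray
    arc_length_um: float
    chord_um: float
    max_turning_angle_deg: float
    curved: bool = False
    degenerate: bool = False

    @property
    def bend_ratio(self) -> float:
        return self.arc_length_um / self.chord_um if self.chord_um > 0 else 1.0


@dataclass
class TuftRecord:
    label: int
    volume_um3: float
    n_nuclei: int
    n_curved_nuclei: int
    n_connections: int
    n_tunnels: int
    depth_um: float
    size_class: str


@dataclass
class PolarityVector:
    nucleus_um: np.ndarray
    golgi_um: np.ndarray
    vector: np.ndarray
    angle_deg: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_tufts(
    vessel_mask: np.ndarray,
    plexus,
    spacing,
    min_height_um: float = 10.0,
    min_volume_um3: float = 50.0,
) -> np.ndarray:
    """Label connected vessel components protruding above the plexus.

    ``plexus`` is any model exposing ``height_grid(shape, spacing)``
    (a fitted plane or a generator surface).  Voxels whose signed height
    exceeds ``min_height_um`` are kept, labelled with 26-connectivity,
    and components smaller than ``min_volume_um3`` discarded.
    """
    if plexus is None:
        raise ValueError("no plexus model supplied")
    mask = np.asarray(vessel_mask, bool)
    heights = plexus.height_grid(mask.shape, spacing)
    above = mask & (heights > min_height_um)
    labels, n = ndimage.label(above, structure=np.ones((3, 3, 3)))
    if n == 0:
        return labels
    voxvol = float(np.prod(spacing))
    sizes = ndimage.sum_labels(above, labels, index=np.arange(1, n + 1)) * voxvol
    keep = np.nonzero(sizes >= min_volume_um3)[0] + 1
    out = np.zeros_like(labels)
    for new, old in enumerate(keep, start=1):
        out[labels == old] = new
    return out


def tuft_volume(label_mask: np.ndarray, spacing) -> float:
    """Voxel-integrated volume in µm³ (foreground voxels only; interior
    cavities are not filled)."""
    m = np.asarray(label_mask, bool)
    if not m.any():
        raise ValueError("empty tuft label")
    return float(m.sum()) * float(np.prod(spacing))


def tuft_depth(label_mask: np.ndarray, plexus, spacing) -> float:
    """Protrusion extent along the plexus normal: the maximum signed
    height of tuft voxels above the plexus surface (tufts are anchored at
    the plexus, so this is their length perpendicular to it)."""
    m = np.asarray(label_mask, bool)
    if not m.any():
        raise ValueError("empty tuft label")
    pts = np.argwhere(m) * np.asarray(spacing, float)
    return float(plexus.height_above(pts).max())


def classify_tuft(n_nuclei: int) -> str:
    """Size class from nuclei count: <4 small, 4–20 medium, >20 large."""
    n = int(n_nuclei)
    if n < 1:
        raise ValueError("a tuft has at least one nucleus")
    if n < SMALL_BELOW:
        return "small"
    if n <= LARGE_ABOVE:
        return "medium"
    return "large"


# ---------------------------------------------------------------------------
# nuclei
# ---------------------------------------------------------------------------

def _principal_curve(nuc_mask: np.ndarray, spacing) -> tuple[np.ndarray, float, float, float]:
    """Skeletonize one nucleus and walk its longest geodesic.

    Returns (path_um, arc_length, chord, max_turning_angle_deg).
    """
    sp = np.asarray(spacing, float)
    skel = skeletonize(nuc_mask)
    coords = np.argwhere(skel)
    if len(coords) < 3:
        c = (np.argwhere(nuc_mask) * sp).mean(axis=0)
        return c[None], 0.0, 0.0, 0.0
    import networkx as nx

    index = {tuple(c): i for i, c in enumerate(coords)}
    g = nx.Graph()
    g.add_nodes_from(range(len(coords)))
    offs = np.array(
        [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
         if (a, b, c) != (0, 0, 0)]
    )
    for i, c in enumerate(coords):
        for off in offs:
            j = index.get(tuple(c + off))
            if j is not None and j > i:
                g.add_edge(i, j, w=float(np.linalg.norm(off * sp)))
    # longest shortest-path via double sweep from an arbitrary node
    start = 0
    dist = nx.single_source_dijkstra_path_length(g, start, weight="w")
    a = max(dist, key=dist.get)
    dist_a, paths_a = nx.single_source_dijkstra(g, a, weight="w")
    b = max(dist_a, key=dist_a.get)
    path = np.asarray(paths_a[b])
    pts = coords[path] * sp
    # light moving-average smoothing suppresses voxel staircase without
    # rounding genuine bends away
    if len(pts) >= 3:
        kernel = np.ones(3) / 3.0
        padded = np.vstack([pts[:1], pts, pts[-1:]])
        pts = np.column_stack(
            [np.convolve(padded[:, k], kernel, mode="valid") for k in range(3)]
        )
    # the medial skeleton stops ~1 radius short of the blob tips; extend
    # both ends along the local tangent until leaving the mask
    shape = np.array(nuc_mask.shape)
    if len(pts) >= 3:
        for at_end in (False, True):
            tang = (pts[-1] - pts[max(-4, -len(pts))]) if at_end else (pts[0] - pts[min(3, len(pts) - 1)])
            norm = np.linalg.norm(tang)
            if norm == 0:
                continue
            tang /= norm
            p = (pts[-1] if at_end else pts[0]).copy()
            ext = []
            for _ in range(24):
                p = p + 0.5 * sp.min() * tang
                idx = np.round(p / sp).astype(int)
                if (idx < 0).any() or (idx >= shape).any() or not nuc_mask[tuple(idx)]:
                    break
                ext.append(p.copy())
            if ext:
                pts = np.vstack([pts, ext]) if at_end else np.vstack([ext[::-1], pts])
    seg = np.diff(pts, axis=0)
    arc = float(np.linalg.norm(seg, axis=1).sum())
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    # turning angle between ~3 µm secants on either side of each point
    cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(seg, axis=1))])
    max_turn = 0.0
    w = 3.0
    for i in range(len(pts)):
        j = int(np.searchsorted(cum, cum[i] - w))
        k = int(np.searchsorted(cum, cum[i] + w))
        k = min(k, len(pts) - 1)
        if j < i < k:
            v1 = pts[i] - pts[j]
            v2 = pts[k] - pts[i]
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 > 0 and n2 > 0:
                cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
                max_turn = max(max_turn, float(np.degrees(np.arccos(cosang))))
    return pts, arc, chord, max_turn


def detect_nuclei(
    nuclear_channel: np.ndarray,
    spacing,
    within_label: np.ndarray | None = None,
    threshold: float | str = "otsu",
    min_volume_um3: float = 10.0,
    split_touching: bool = False,
    h_maxima_um: float = 0.8,
    dilate_within_um: float = 3.0,
) -> list[NucleusRecord]:
    """Blob-detect nuclei, optionally restricted to (a dilation of) one
    tuft label.

    With ``split_touching`` a distance-transform watershed seeded at
    h-maxima divides blobs that merge through a thin neck (two round
    nuclei in contact).  It is off by default: on strongly elongated or
    bent nuclei the EDT ridge is shallow and the watershed over-splits,
    so it should be enabled only where merged round blobs are expected.
    """
    img = np.asarray(nuclear_channel, float)
    sp = np.asarray(spacing, float)
    if threshold == "otsu":
        if img.max() == img.min():
            warnings.warn("empty nuclear channel")
            return []
        thr = threshold_otsu(img)
    else:
        thr = float(threshold)
    binary = img >= thr
    if within_label is not None:
        sel = np.asarray(within_label, bool)
        it = max(1, int(round(dilate_within_um / sp.min())))
        sel = ndimage.binary_dilation(sel, np.ones((3, 3, 3)), iterations=it)
        binary &= sel
    if not binary.any():
        warnings.warn("no nuclei detected")
        return []
    labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3)))
    if split_touching and n:
        # h-maxima of the distance transform as markers: a blob splits
        # only where the EDT dips by more than h between summits, so
        # elongated or bent single nuclei (flat EDT ridge) stay whole
        # while touching nuclei separated by a neck are divided
        from skimage.morphology import h_maxima

        edt = ndimage.distance_transform_edt(binary, sampling=sp)
        summits = h_maxima(edt, h_maxima_um)
        markers, nm = ndimage.label(summits, structure=np.ones((3, 3, 3)))
        if nm > n:
            labels = watershed(-edt, markers, mask=binary)
    voxvol = float(np.prod(sp))
    records = []
    for lab in range(1, labels.max() + 1):
        m = labels == lab
        vol = m.sum() * voxvol
        if vol < min_volume_um3:
            continue
        pts, arc, chord, max_turn = _principal_curve(m, sp)
        centroid = (np.argwhere(m) * sp).mean(axis=0)
        degenerate = arc < 2 * sp.min()
        records.append(
            NucleusRecord(
                centroid_um=centroid,
                arc_length_um=arc,
                chord_um=chord,
                max_turning_angle_deg=max_turn,
                degenerate=degenerate,
            )
        )
    if not records:
        warnings.warn("no nuclei above the size filter")
    return records


def classify_nucleus_curvature(
    record: NucleusRecord,
    bend_threshold: float = 1.2,
    angle_threshold_deg: float = 60.0,
) -> str:
    """"curved" iff arc/chord > bend_threshold OR the maximum turning
    angle exceeds the angle threshold; degenerate (sub-voxel) nuclei are
    flat by definition."""
    if record.degenerate:
        record.curved = False
        return "flat"
    curved = (
        record.bend_ratio > bend_threshold
        or record.max_turning_angle_deg > angle_threshold_deg
    )
    record.curved = bool(curved)
    return "curved" if curved else "flat"


# ---------------------------------------------------------------------------
# connections
# ---------------------------------------------------------------------------

def count_connections(
    skeleton: SkeletonGraph,
    tuft_label: np.ndarray,
    plexus,
    min_height_um: float = 10.0,
) -> int:
    """Number of distinct skeleton edges crossing the iso-height surface
    between the tuft and the rest of the network.

    A crossing counts when an edge polyline passes through height
    ``min_height_um`` with its above-side inside the tuft label.  A
    detached tuft yields 0 with a warning.
    """
    label = np.asarray(tuft_label, bool)
    sp = np.asarray(skeleton.spacing, float)
    shape = np.array(label.shape)

    def _in_label(pts):
        idx = np.clip(np.round(pts / sp).astype(int), 0, shape - 1)
        return label[idx[:, 0], idx[:, 1], idx[:, 2]]

    crossings = 0
    for _, _, poly, _ in skeleton.edges():
        h = plexus.height_above(poly)
        above = h > min_height_um
        if above.all() or not above.any():
            continue
        flips = np.nonzero(np.diff(above.astype(int)) != 0)[0]
        inside = _in_label(poly)
        for f in flips:
            hi = f if above[f] else f + 1
            # walk along the above side until we leave/land in the label
            side = poly[hi:] if above[f + 1] else poly[: f + 1][::-1]
            side_in = _in_label(side) if len(side) else np.array([False])
            if side_in.any():
                crossings += 1
    if crossings == 0:
        warnings.warn("tuft appears detached from the plexus (0 crossings)")
    return crossings


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def tuft_topology(label_mask: np.ndarray) -> int:
    """Number of tunnels through the tuft: the first Betti number.

    Uses the fixed 26-connectivity foreground / 6-connectivity background
    convention: b1 = b0 + b2 − χ, with b0 the number of 26-connected
    foreground components, b2 the number of enclosed background
    cavities, and χ the Euler characteristic of the voxel complex.
    """
    m = np.asarray(label_mask, bool)
    if not m.any():
        raise ValueError("empty mask has no topology")
    border = (
        m[0].any() or m[-1].any()
        or m[:, 0].any() or m[:, -1].any()
        or m[:, :, 0].any() or m[:, :, -1].any()
    )
    if border:
        raise ValueError("pad required: mask touches the volume border")
    _, b0 = ndimage.label(m, structure=np.ones((3, 3, 3)))
    bg_lab, n_bg = ndimage.label(~m, structure=ndimage.generate_binary_structure(3, 1))
    b2 = n_bg - 1  # all non-enclosed background is one component (no border contact)
    chi = euler_number(m, connectivity=3)
    b1 = b0 + b2 - chi
    return int(b1)


# ---------------------------------------------------------------------------
# regressions, fold changes, polarity
# ---------------------------------------------------------------------------

def regress_morphometrics(records, x_field: str, y_field: str) -> RegressionResult:
    """Ordinary least squares y ~ x with intercept over tuft records."""
    xs = np.array([getattr(r, x_field) for r in records], float)
    ys = np.array([getattr(r, y_field) for r in records], float)
    if len(xs) < 3:
        raise ValueError("need >= 3 records for a regression")
    if np.var(ys) == 0:
        return RegressionResult(0.0, float(ys.mean()), 0.0, len(xs))
    res = stats.linregress(xs, ys)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(xs),
    )


def class_fold_change(records, field: str, boundary: int = LARGE_ABOVE) -> float:
    """mean(field | large) / mean(field | medium) across the nuclei-count
    boundary (the sharp transition when tufts exceed ~20 nuclei)."""
    large = [getattr(r, field) for r in records if r.n_nuclei > boundary]
    medium = [
        getattr(r, field) for r in records if SMALL_BELOW <= r.n_nuclei <= boundary
    ]
    if not large or not medium:
        raise ValueError("both sides of the class boundary must be non-empty")
    return float(np.mean(large) / np.mean(medium))


def nucleus_golgi_polarity(
    nuclei_um,
    golgi_um,
    reference_direction,
) -> list[PolarityVector]:
    """Pair each nucleus with its nearest Golgi body and report the
    polarity vector and its angle to a reference direction (0–180°).

    The pairing is unconstrained nearest-neighbour: one Golgi body may
    serve several nuclei.
    """
    nuclei = np.atleast_2d(np.asarray(nuclei_um, float))
    golgi = np.atleast_2d(np.asarray(golgi_um, float))
    if len(nuclei) == 0 or len(golgi) == 0:
        raise ValueError("need at least one nucleus and one golgi centroid")
    ref = np.asarray(reference_direction, float)
    nref = np.linalg.norm(ref)
    if nref == 0:
        raise ValueError("reference direction must be normalizable")
    ref = ref / nref
    tree = cKDTree(golgi)
    _, idx = tree.query(nuclei)
    out = []
    for nuc, gi in zip(nuclei, idx):
        g = golgi[gi]
        v = g - nuc
        nv = np.linalg.norm(v)
        unit = v / nv if nv > 0 else ref
        ang = float(np.degrees(np.arccos(np.clip(unit @ ref, -1.0, 1.0))))
        out.append(PolarityVector(nucleus_um=nuc, golgi_um=g, vector=unit, angle_deg=ang))
    return out
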