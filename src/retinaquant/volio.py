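"""Volume / track / table I/O and run configuration.

All downstream code works in physical micrometres with 0-based voxel
indices and a fixed ``(t?, c?, z, y, x)`` axis order; this module is the
only place where on-disk conventions (TIFF metadata, CSV dialects, XLSX
sheets) are translated into that frame.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .trackkin import Track

log = logging.getLogger(__name__)

#: canonical axis orders, innermost-last
_VALID_AXES = ("ZYX", "CZYX", "TZYX", "TCZYX")


@dataclass
class Volume:
    """A voxel grid with physical spacing.

    ``data`` is indexed ``(t?, c?, z, y, x)`` according to ``axes``;
    ``spacing`` is µm per voxel for the three spatial axes, ordered
    ``(z, y, x)``.  The physical coordinate of index ``i`` along a
    spatial axis is ``i * spacing`` (µm).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    axes: str = "ZYX"
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if self.axes not in _VALID_AXES:
            raise ValueError(f"axes must be one of {_VALID_AXES}, got {self.axes!r}")
        if self.data.ndim != len(self.axes):
            raise ValueError(
                f"data has {self.data.ndim} dims but axes is {self.axes!r}"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.channel_names is not None and "C" in self.axes:
            nc = self.data.shape[self.axes.index("C")]
            if len(self.channel_names) != nc:
                raise ValueError("channel_names length does not match C axis")

    @property
    def n_channels(self) -> int:
        return self.data.shape[self.axes.index("C")] if "C" in self.axes else 1

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel as a ZYX (or TZYX) array."""
        if "C" not in self.axes:
            if name_or_index in (0, None) or (
                self.channel_names and name_or_index == self.channel_names[0]
            ):
                return self.data
            raise KeyError(f"volume has no channel axis; cannot select {name_or_index!r}")
        if isinstance(name_or_index, str):
            if not self.channel_names or name_or_index not in self.channel_names:
                raise KeyError(
                    f"unknown channel {name_or_index!r}; have {self.channel_names}"
                )
            idx = self.channel_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        return np.take(self.data, idx, axis=self.axes.index("C"))


def write_volume(path: str | Path, volume: Volume) -> Path:
    """Write an OME-TIFF with spacing (µm) and channel names in metadata."""
    path = Path(path)
    sz, sy, sx = volume.spacing
    metadata = {
        "axes": volume.axes,
        "PhysicalSizeZ": sz,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeY": sy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeX": sx,
        "PhysicalSizeXUnit": "µm",
    }
    if volume.channel_names:
        metadata["Channel"] = {"Name": list(volume.channel_names)}
    # content-derived UUID keeps identical volumes byte-identical on disk
    import hashlib

    digest = hashlib.md5(volume.data.tobytes()).hexdigest()
    metadata["UUID"] = (
        f"urn:uuid:{digest[:8]}-{digest[8:12]}-{digest[12:16]}-"
        f"{digest[16:20]}-{digest[20:32]}"
    )
    tifffile.imwrite(
        path, volume.data, ome=True, metadata=metadata, photometric="minisblack"
    )
    return path


def read_volume(
    path: str | Path,
    spacing: Sequence[float] | None = None,
    axes: str | None = None,
) -> Volume:
    """Read a TIFF/OME-TIFF into a :class:`Volume`.

    Spacing is taken from OME metadata when present, else from the
    ``spacing`` argument (config fallback), else defaults to 1.0 µm per
    axis with a logged warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        file_axes = series.axes.upper().replace("S", "C").replace("Q", "")
        meta_spacing = None
        channel_names = None
        if tf.ome_metadata:
            try:
                from xml.etree import ElementTree as ET

                root = ET.fromstring(tf.ome_metadata)
                ns = {"ome": root.tag.split("}")[0].strip("{")}
                pix = root.find(".//ome:Pixels", ns)
                if pix is not None:
                    vals = [
                        pix.get(f"PhysicalSize{ax}") for ax in ("Z", "Y", "X")
                    ]
                    if all(v is not None for v in vals):
                        meta_spacing = tuple(float(v) for v in vals)
                    chans = pix.findall("ome:Channel", ns)
                    names = [c.get("Name") for c in chans]
                    if names and all(n is not None for n in names):
                        channel_names = list(names)
            except Exception:  # pragma: no cover - defensive
                log.warning("failed to parse OME metadata in %s", path)

    if data.ndim < 3:
        raise ValueError(f"{path} is not a volume (got {data.ndim} dims)")
    vol_axes = axes or file_axes
    if vol_axes not in _VALID_AXES:
        if axes is None and data.ndim == 3:
            # plain z-stacks without metadata: assume ZYX
            vol_axes = "ZYX"
        else:
            raise ValueError(
                f"ambiguous axes {vol_axes!r} for {path}; pass axes= explicitly"
            )
    if meta_spacing is not None:
        use_spacing = meta_spacing
    elif spacing is not None:
        use_spacing = tuple(float(s) for s in spacing)
    else:
        log.warning("%s has no spacing metadata and none supplied; assuming 1 µm", path)
        use_spacing = (1.0, 1.0, 1.0)
    return Volume(data=data, spacing=use_spacing, axes=vol_axes, channel_names=channel_names)


# ---------------------------------------------------------------------------
# track tables
# ---------------------------------------------------------------------------

#: header of the native track CSV dialect
TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um", "z_um"]


def write_tracks(path: str | Path, tracks: Sequence[Track]) -> Path:
    rows = []
    for tr in tracks:
        for f, p in zip(tr.frames, tr.positions):
            rows.append((tr.id, int(f), p[0], p[1], p[2]))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df.to_csv(path, index=False)
    return Path(path)


def read_tracks(
    path: str | Path,
    dialect: str = "native",
    pixel_size_um: float = 1.0,
    dt_min: float = 1.0,
) -> list[Track]:
    """Read a track CSV into a list of :class:`~retinaquant.trackkin.Track`.

    ``dialect="native"`` expects columns ``track_id,frame,x_um,y_um,z_um``
    (positions already in µm).  ``dialect="imagej_manual_tracking"``
    accepts the Fiji Manual Tracking export ("Track n°", "Slice n°",
    "X", "Y") with positions in pixels, converted by ``pixel_size_um``.
    """
    if dialect not in ("native", "imagej_manual_tracking"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: empty track file")
        return []
    if dialect == "native":
        missing = [c for c in TRACK_COLUMNS[:4] if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        tid_col, frame_col = "track_id", "frame"
        xyz = np.column_stack(
            [
                df["x_um"].to_numpy(float),
                df["y_um"].to_numpy(float),
                df["z_um"].to_numpy(float) if "z_um" in df else np.zeros(len(df)),
            ]
        )
    else:
        def _find(keys: tuple[str, ...]) -> str:
            for c in df.columns:
                name = str(c).strip().lower()
                if any(name.startswith(k) for k in keys):
                    return c
            raise ValueError(f"{path}: no column matching {keys}; found {list(df.columns)}")

        tid_col = _find(("track",))
        frame_col = _find(("slice", "frame"))
        xc, yc = _find(("x",)), _find(("y",))
        try:
            zc = _find(("z",))
            zvals = df[zc].to_numpy(float)
        except ValueError:
            zvals = np.zeros(len(df))
        xyz = np.column_stack(
            [df[xc].to_numpy(float), df[yc].to_numpy(float), zvals]
        ) * float(pixel_size_um)

    tracks = []
    for tid, sub in df.groupby(tid_col, sort=True):
        idx = sub.index.to_numpy()
        frames = sub[frame_col].to_numpy(int)
        order = np.argsort(frames, kind="stable")
        frames = frames[order]
        if len(np.unique(frames)) != len(frames):
            raise ValueError(f"{path}: duplicate (track, frame) rows for track {tid}")
        pos = xyz[np.searchsorted(df.index.to_numpy(), idx)][order]
        tracks.append(Track(id=tid, frames=frames, positions=pos, dt_min=dt_min))
    return tracks


# ---------------------------------------------------------------------------
# source-data spreadsheets
# ---------------------------------------------------------------------------

#: default column mapping per figure key; each maps normalized output
#: column -> candidate header substrings (case-insensitive) in the XLSX.
SOURCE_TABLE_SCHEMAS: dict[str, dict[str, tuple[str, ...]]] = {
    "fig3_vessels": {
        "vessel_id": ("vessel", "id"),
        "width_um": ("width", "w "),
        "depth_um": ("depth", "d "),
        "modality": ("modality", "method", "microscope"),
    },
    "fig4_bundles": {
        "bundle_id": ("bundle", "track", "id"),
        "distance_um": ("distance", "path"),
        "duration_min": ("duration", "time"),
        "speed_um_min": ("speed", "velocity"),
    },
    "fig5_tufts": {
        "tuft_id": ("tuft", "id"),
        "volume_um3": ("volume",),
        "n_nuclei": ("nuclei", "nucleus"),
        "n_connections": ("connection",),
    },
    "fig7_filopodia": {
        "filopodium_id": ("filopod", "id"),
        "max_length_um": ("max", "length"),
        "lifetime_min": ("lifetime", "time"),
        "condition": ("condition", "group", "genotype"),
    },
}


def read_source_table(
    path: str | Path,
    figure_key: str,
    column_map: dict[str, str] | None = None,
    sheet: int | str = 0,
) -> pd.DataFrame:
    """Load a deposited source-data spreadsheet into a normalized long table.

    ``column_map`` overrides the heuristic header matching with explicit
    ``normalized_name -> header`` pairs (the deposited files' headers are
    not standardized, so the mapping is configurable).
    Required measurement columns that cannot be located raise a
    ``ValueError`` listing the columns that were found.
    """
    if figure_key not in SOURCE_TABLE_SCHEMAS:
        raise ValueError(
            f"unknown figure_key {figure_key!r}; known: {sorted(SOURCE_TABLE_SCHEMAS)}"
        )
    df = pd.read_excel(path, sheet_name=sheet)
    schema = SOURCE_TABLE_SCHEMAS[figure_key]
    out = {}
    lowered = {str(c).strip().lower(): c for c in df.columns}
    for norm, candidates in schema.items():
        if column_map and norm in column_map:
            if column_map[norm] not in df.columns:
                raise ValueError(
                    f"{path}: mapped column {column_map[norm]!r} for {norm!r} absent; "
                    f"found {list(df.columns)}"
                )
            out[norm] = df[column_map[norm]]
            continue
        hit = None
        for low, orig in lowered.items():
            if any(cand in low for cand in candidates):
                hit = orig
                break
        if hit is not None:
            out[norm] = df[hit]
    optional = {"modality", "condition", "speed_um_min", "lifetime_min"}
    required = [k for k in schema if not k.endswith("_id") and k not in optional]
    missing = [k for k in required if k not in out]
    if missing:
        raise ValueError(
            f"{path}: could not locate columns for {missing}; found {list(df.columns)}"
        )
    res = pd.DataFrame(out)
    res.insert(0, "figure_key", figure_key)
    return res


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

#: every recognized configuration key with its documented default
CONFIG_DEFAULTS: dict[str, object] = {
    "spacing_um": (1.0, 1.0, 1.0),      # voxel size (z, y, x)
    "dt_min": 1.0,                       # frame interval for time lapses
    "seed": 0,                           # master RNG seed
    "segmentation_method": "otsu",       # {otsu, fixed_threshold}
    "segmentation_threshold": 0.5,       # used by fixed_threshold
    "min_component_um3": 30.0,           # segmentation cleanup
    "plane_fit_radius_um": 30.0,         # plexus plane neighborhood
    "tuft_min_height_um": 10.0,          # height above plexus to call a tuft
    "tuft_min_volume_um3": 50.0,
    "nucleus_bend_threshold": 1.2,       # arc/chord ratio for "curved"
    "nucleus_angle_threshold_deg": 60.0,
    "class_boundary_small": 4,           # n_nuclei < 4 -> small
    "class_boundary_large": 20,          # n_nuclei > 20 -> large
    "filopodium_epsilon_um": 0.5,        # alive threshold for lifetime
    "onl_slice_stride": 50,
    "onl_min_particle_um2": 4.0,
    "out_dir": "results",
}


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(CONFIG_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(CONFIG_DEFAULTS)
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key: str):
        return self.values[key]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls(values=data)

    def to_dict(self) -> dict:
        return dict(self.values)
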