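"""Image stacks, ROIs, projections and result tables.

All pixel coordinates in this package are 0-based with ``x`` increasing
rightward (array axis 1) and ``y`` increasing downward (array axis 0);
pixel centers sit at integer coordinates.  Conversions between pixels and
micrometres are centralized in :func:`um_to_px` / :func:`px_to_um` so that
every downstream module shares one convention.

Z ranges are expressed in micrometres and are half-open ``[start, stop)``
so that consecutive sections tile a stack without double counting.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

AXES = "CTZYX"


class ConfigurationError(ValueError):
    """Required acquisition metadata is missing and no override was given."""


class InsufficientDataError(ValueError):
    """Too few observations to define the requested quantity."""


def um_to_px(value_um: float, pixel_size_um: float) -> float:
    """Convert a length in micrometres to pixels."""
    return float(value_um) / float(pixel_size_um)


def px_to_um(value_px: float, pixel_size_um: float) -> float:
    """Convert a length in pixels to micrometres."""
    return float(value_px) * float(pixel_size_um)


# ---------------------------------------------------------------------------
# ImageStack


@dataclass
class ImageStack:
    """A multichannel image stack with acquisition geometry.

    Parameters
    ----------
    pixels
        Intensity array whose dimensions are named by ``axes``.
    axes
        String naming each array axis; an ordered subset of ``"CTZYX"``
        ending in ``"YX"`` (singleton axes may be present or dropped).
    pixel_size_um
        Isotropic XY pixel size in micrometres per pixel.
    z_step_um
        Spacing between Z slices in micrometres (``None`` for single-plane).
    frame_interval_min
        Time between frames in minutes (``None`` for non-timelapse data).
    """

    pixels: np.ndarray
    axes: str = "YX"
    pixel_size_um: float = 1.0
    z_step_um: float | None = None
    frame_interval_min: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != len(self.axes):
            raise ValueError(
                f"axes {self.axes!r} does not match array with "
                f"{self.pixels.ndim} dimensions"
            )
        if not self.axes.endswith("YX"):
            raise ValueError("axes must end with 'YX'")
        seen = [a for a in AXES if a in self.axes]
        if "".join(seen) != self.axes or len(set(self.axes)) != len(self.axes):
            raise ValueError(f"axes must be an ordered subset of {AXES!r}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if np.any(np.asarray(self.pixels, dtype=float) < 0):
            raise ValueError("pixel intensities must be non-negative")

    # -- axis helpers -------------------------------------------------
    def as_5d(self) -> np.ndarray:
        """Return the pixel array expanded to the full (C, T, Z, Y, X) shape."""
        arr = self.pixels
        for i, ax in enumerate(AXES):
            if ax not in self.axes:
                arr = np.expand_dims(arr, i)
        return arr

    def axis_len(self, ax: str) -> int:
        if ax not in AXES:
            raise ValueError(f"unknown axis {ax!r}")
        if ax not in self.axes:
            return 1
        return self.pixels.shape[self.axes.index(ax)]

    @property
    def n_channels(self) -> int:
        return self.axis_len("C")

    @property
    def n_frames(self) -> int:
        return self.axis_len("T")

    @property
    def n_slices(self) -> int:
        return self.axis_len("Z")

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[-2], self.pixels.shape[-1]

    @property
    def z_extent_um(self) -> float:
        """Physical Z extent: one z-step per slice (slices tile the stack)."""
        if self.n_slices <= 1:
            return 0.0 if self.z_step_um is None else float(self.z_step_um)
        if self.z_step_um is None:
            raise ConfigurationError("z_step_um required for multi-slice stack")
        return self.n_slices * float(self.z_step_um)

    def plane(self, channel: int = 0, t: int = 0, z: int = 0) -> np.ndarray:
        """Extract one 2D (Y, X) plane."""
        return self.as_5d()[channel, t, z]


def read_image_stack(
    path: str | Path,
    *,
    axes: str | None = None,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
    frame_interval_min: float | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF file into an :class:`ImageStack`.

    Axis names, pixel size, Z spacing and frame interval are taken from the
    file metadata (ImageJ/OME tags and TIFF resolution tags); keyword
    overrides win over metadata.  A missing pixel size with no override
    raises :class:`ConfigurationError`.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            file_axes = series.axes
            ij = tif.imagej_metadata or {}
            page = tif.pages[0]
            tags = page.tags
            # pixel size only from metadata that states a unit: ImageJ tiffs
            # record unit + resolution tag, OME-TIFF records PhysicalSizeX
            # (µm by default); a bare resolution tag defaults to (1, 1) in
            # many writers and is not trusted.
            ps_meta = None
            if ij.get("unit", "") in ("um", "micron", "µm") and "XResolution" in tags:
                num, den = tags["XResolution"].value
                if num:
                    ps_meta = den / num
            elif tif.ome_metadata:
                m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', tif.ome_metadata)
                if m:
                    ps_meta = float(m.group(1))
    except (OSError, ValueError, IndexError) as exc:
        raise OSError(f"cannot read image stack from {path}: {exc}") from exc

    # Normalize axes: map S (samples) to C, drop Q/other singletons.
    norm_axes = []
    keep = []
    for i, ax in enumerate(file_axes):
        ax = "C" if ax == "S" else ax
        if ax in AXES and ax not in norm_axes:
            norm_axes.append(ax)
            keep.append(i)
        elif data.shape[i] == 1:
            data = np.squeeze(data, axis=len(keep))
        else:
            raise OSError(f"unsupported axis {ax!r} in {path}")
    # Reorder to canonical subset order of CTZYX.
    order = [norm_axes.index(a) for a in AXES if a in norm_axes]
    data = np.transpose(data, order)
    inferred_axes = "".join(a for a in AXES if a in norm_axes)
    if axes is not None:
        inferred_axes = axes
        if data.ndim != len(axes):
            data = data.reshape([1] * (len(axes) - data.ndim) + list(data.shape))

    ps = pixel_size_um if pixel_size_um is not None else ps_meta
    if ps is None:
        raise ConfigurationError(
            f"{path} carries no pixel size; pass pixel_size_um explicitly"
        )
    zs = z_step_um if z_step_um is not None else ij.get("spacing")
    fi = frame_interval_min
    if fi is None and "finterval" in ij:
        fi = float(ij["finterval"]) / 60.0  # ImageJ stores seconds
    return ImageStack(
        pixels=data,
        axes=inferred_axes,
        pixel_size_um=float(ps),
        z_step_um=None if zs is None else float(zs),
        frame_interval_min=None if fi is None else float(fi),
    )


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as an ImageJ-compatible TIFF."""
    path = Path(path)
    arr = stack.as_5d()  # C, T, Z, Y, X
    if arr.dtype == np.float64:
        arr = arr.astype(np.float32)  # ImageJ TIFF has no float64
    data = np.transpose(arr, (1, 2, 0, 3, 4))  # ImageJ wants TZCYX
    meta: dict = {"axes": "TZCYX", "unit": "um"}
    if stack.z_step_um is not None:
        meta["spacing"] = float(stack.z_step_um)
    if stack.frame_interval_min is not None:
        meta["finterval"] = float(stack.frame_interval_min) * 60.0
    ps = float(stack.pixel_size_um)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / ps, 1.0 / ps),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# Projections


def _z_slice_indices(stack: ImageStack, z_range_um: tuple[float, float] | None) -> np.ndarray:
    nz = stack.n_slices
    if z_range_um is None:
        return np.arange(nz)
    start, stop = map(float, z_range_um)
    if nz > 1 or stack.z_step_um is not None:
        if stack.z_step_um is None:
            raise ConfigurationError("z_step_um required to select a µm z-range")
        step = float(stack.z_step_um)
    else:
        step = 1.0
    z_pos = np.arange(nz) * step  # slice i spans [i*step, (i+1)*step)
    if start < -1e-9 or stop > nz * step + 1e-9:
        raise ValueError(
            f"z_range_um [{start}, {stop}) outside stack extent [0, {nz * step})"
        )
    idx = np.nonzero((z_pos >= start - 1e-9) & (z_pos < stop - 1e-9))[0]
    if idx.size == 0:
        raise ValueError(f"z_range_um [{start}, {stop}) selects no slices")
    return idx


def max_intensity_projection(
    stack: ImageStack,
    channel: int = 0,
    z_range_um: tuple[float, float] | None = None,
    t: int = 0,
) -> np.ndarray:
    """Maximum intensity projection over a half-open µm Z range.

    Slice ``i`` occupies ``[i*z_step, (i+1)*z_step)`` µm; a slice is included
    when its start position falls inside ``z_range_um``.  With
    ``z_range_um=None`` all slices are projected.
    """
    idx = _z_slice_indices(stack, z_range_um)
    planes = stack.as_5d()[channel, t]
    return planes[idx].max(axis=0)


def distinct_projection_pair(
    stack: ImageStack,
    channel: int = 0,
    section_um: float = 5.0,
    t: int = 0,
    placement: tuple[float, float] = (0.25, 0.60),
) -> tuple[np.ndarray, np.ndarray]:
    """Two non-overlapping maximum intensity projections of equal thickness.

    Sampling two separated sections of a spheroid avoids measuring the same
    cells twice.  The stack itself does not say where those sections were
    taken, so the default placement starts them at fixed fractions of the Z
    extent (25% and 60%), shifted down as needed so both sections fit and do
    not overlap.
    """
    extent = stack.z_extent_um
    s = float(section_um)
    if extent < 2 * s:
        raise ValueError(
            f"stack Z extent {extent} µm too thin for two {s} µm sections"
        )
    start2 = min(placement[1] * extent, extent - s)
    start1 = min(placement[0] * extent, start2 - s)
    if start1 < 0:
        raise ValueError("placement fractions leave no room for section 1")
    mip1 = max_intensity_projection(stack, channel, (start1, start1 + s), t)
    mip2 = max_intensity_projection(stack, channel, (start2, start2 + s), t)
    return mip1, mip2


# ---------------------------------------------------------------------------
# ROIs

ROI_KINDS = ("point", "rectangle", "polygon", "line")


@dataclass
class Roi:
    """A point, rectangle, polygon or line annotation in pixel coordinates.

    Rectangles are stored as two corner vertices and are half-open pixel
    boxes: corners ``(x0, y0), (x1, y1)`` select ``image[y0:y1, x0:x1]``, so
    a 10 × 10 pixel square has corners 10 apart.
    """

    kind: str
    vertices: list[tuple[float, float]]
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ROI_KINDS:
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        n = len(self.vertices)
        if n < 1:
            raise ValueError("ROI needs at least one vertex")
        if self.kind == "rectangle" and n != 2:
            raise ValueError("rectangle ROI needs exactly 2 corner vertices")
        if self.kind == "line" and n != 2:
            raise ValueError("line ROI needs exactly 2 vertices")
        if self.kind == "point" and n != 1:
            raise ValueError("point ROI needs exactly 1 vertex")

    def rectangle_slices(self) -> tuple[slice, slice]:
        """(row, column) slices selecting the half-open rectangle box."""
        if self.kind != "rectangle":
            raise ValueError("not a rectangle ROI")
        (x0, y0), (x1, y1) = self.vertices
        x0, x1 = sorted((x0, x1))
        y0, y1 = sorted((y0, y1))
        return slice(int(round(y0)), int(round(y1))), slice(int(round(x0)), int(round(x1)))

    def mean_intensity(self, image: np.ndarray) -> float:
        """Mean pixel intensity inside a rectangle ROI."""
        rows, cols = self.rectangle_slices()
        patch = image[rows, cols]
        if patch.size == 0:
            raise ValueError("rectangle ROI selects no pixels")
        return float(patch.mean())


def write_rois(rois: Sequence[Roi], path: str | Path) -> None:
    records = [
        {"kind": r.kind, "vertices": [list(v) for v in r.vertices], "label": r.label}
        for r in rois
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def read_rois(path: str | Path) -> list[Roi]:
    records = json.loads(Path(path).read_text())
    return [
        Roi(kind=r["kind"], vertices=[tuple(v) for v in r["vertices"]], label=r.get("label", ""))
        for r in records
    ]


# ---------------------------------------------------------------------------
# Force-curve tables (TSV + JSON sidecar)


def write_force_curve(curve, path: str | Path) -> None:
    """Write a force curve as TSV (z_nm, force_nN) with a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({"z_nm": curve.z_nm, "force_nN": curve.force_nN})
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "direction": curve.direction,
        "probe_radius_um": curve.probe_radius_um,
        "spring_constant_N_per_m": curve.spring_constant_N_per_m,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_force_curve(path: str | Path):
    """Read a force curve written by :func:`write_force_curve`."""
    from .afm import ForceCurve

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return ForceCurve(
        z_nm=df["z_nm"].to_numpy(float),
        force_nN=df["force_nN"].to_numpy(float),
        direction=meta.get("direction", "extension"),
        probe_radius_um=float(meta.get("probe_radius_um", 5.0)),
        spring_constant_N_per_m=meta.get("spring_constant_N_per_m"),
    )


# ---------------------------------------------------------------------------
# Result tables

RESULT_COLUMNS = ["spheroid_id", "condition", "compartment", "metric", "value", "units"]


@dataclass
class ResultTable:
    """Long-format measurement records shared by all pipeline stages."""

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=RESULT_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in RESULT_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"result table missing columns {missing}")
        values = pd.to_numeric(self.records["value"], errors="coerce")
        if len(values) and not np.all(np.isfinite(values)):
            raise ValueError("result table contains non-finite values")

    def add(
        self,
        spheroid_id: str,
        condition: str,
        compartment: str,
        metric: str,
        value: float,
        units: str = "",
    ) -> "ResultTable":
        if not np.isfinite(value):
            raise ValueError(f"non-finite value for metric {metric!r}")
        row = pd.DataFrame(
            [[spheroid_id, condition, compartment, metric, float(value), units]],
            columns=RESULT_COLUMNS,
        )
        if self.records.empty:
            return replace(self, records=row)
        return replace(self, records=pd.concat([self.records, row], ignore_index=True))

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ResultTable":
        return cls(records=pd.read_csv(path))
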