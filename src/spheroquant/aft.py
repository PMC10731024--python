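"""Alignment by Fourier Transform (AFT): local fiber orientation and order.

A fibrous image is divided into overlapping square windows (default 25 px
with 50% overlap).  Each window's dominant orientation is read from its
Fourier power spectrum: an oriented texture concentrates spectral power
along the axis perpendicular to the fibers, so the fiber angle is the
principal axis of the spectrum's second-moment tensor rotated by 90°.

Co-alignment is scored with the 2D nematic order parameter

    S = ⟨cos 2θ_ij⟩ = 2(⟨cos² θ_ij⟩ − 1/2)

averaged over the angle differences θ_ij between a central reference
vector and its neighbors in an n×n window neighborhood (default 5×5, i.e.
24 neighbors).  S → 1 for perfectly co-aligned neighborhoods, 0 for random
orientations, −1 for perpendicular ones.

Radial alignment relative to a spheroid center is scored per angular
sector as ⟨cos 2φ⟩ with φ the deviation of each fiber from the local
radial direction: +1 = radial, −1 = circumferential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class OrientationField:
    """Grid of local fiber angles with the window geometry that produced it.

    ``angles[i, j]`` is the orientation (radians in [0, π), measured from +x
    with y downward) of the window centered at ``(centers_x[i, j],
    centers_y[i, j])``; ``valid`` flags windows with enough spectral power
    to carry a meaningful orientation.
    """

    angles: np.ndarray
    centers_x: np.ndarray
    centers_y: np.ndarray
    window_px: int
    overlap: float
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float) % np.pi
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.angles.shape == self.valid.shape == np.shape(self.centers_x)):
            raise ValueError("angles, centers and valid must share one grid shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.angles.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": np.ravel(self.centers_x),
                "y": np.ravel(self.centers_y),
                "angle_rad": np.ravel(self.angles),
                "valid": np.ravel(self.valid),
            }
        )


@dataclass
class OrderResult:
    """Per-window nematic order map and its scalar summaries."""

    S_map: np.ndarray  # NaN where the neighborhood does not fit or is invalid
    S_summary: float  # median over defined windows
    S_mean: float
    neighborhood: int
    n_defined: int


def _window_positions(length: int, window: int, step: int) -> np.ndarray:
    if length < window:
        raise ValueError(f"image extent {length} px smaller than window {window} px")
    return np.arange(0, length - window + 1, step)


def compute_orientation_field(
    image: np.ndarray,
    window_px: int = 25,
    overlap: float = 0.5,
    min_power_frac: float = 0.05,
) -> OrientationField:
    """Local fiber orientation per overlapping window via the power spectrum.

    Each window is mean-subtracted, tapered with a raised-cosine (Hann)
    window to suppress edge artifacts, and Fourier transformed.  The
    orientation reported is the principal axis of the power spectrum's
    second-moment tensor rotated by 90° (spectral elongation is
    perpendicular to the fibers).  Windows whose total spectral power falls
    below ``min_power_frac`` of the strongest window are marked invalid.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    step = max(1, int(round(window_px * (1.0 - overlap))))
    ys = _window_positions(image.shape[0], window_px, step)
    xs = _window_positions(image.shape[1], window_px, step)

    taper1d = np.hanning(window_px)
    taper = np.outer(taper1d, taper1d)
    fy = np.fft.fftfreq(window_px)[:, None]
    fx = np.fft.fftfreq(window_px)[None, :]

    # Stack all windows and batch the FFT.
    patches = np.empty((len(ys), len(xs), window_px, window_px), dtype=float)
    for i, y0 in enumerate(ys):
        for j, x0 in enumerate(xs):
            patches[i, j] = image[y0 : y0 + window_px, x0 : x0 + window_px]
    patches -= patches.mean(axis=(2, 3), keepdims=True)
    spec = np.abs(np.fft.fft2(patches * taper)) ** 2
    spec[..., 0, 0] = 0.0  # suppress residual zero-frequency power

    power = spec.sum(axis=(2, 3))
    mxx = (spec * fx**2).sum(axis=(2, 3))
    myy = (spec * fy**2).sum(axis=(2, 3))
    mxy = (spec * fx * fy).sum(axis=(2, 3))
    # Major axis of the spectral second-moment tensor, rotated 90°.
    with np.errstate(invalid="ignore"):
        major = 0.5 * np.arctan2(2.0 * mxy, mxx - myy)
    angles = (major + np.pi / 2.0) % np.pi
    angles[power <= 0] = 0.0

    valid = power >= min_power_frac * power.max() if power.max() > 0 else np.zeros_like(power, bool)
    half = window_px / 2.0
    centers_x, centers_y = np.meshgrid(xs + half, ys + half)
    return OrientationField(
        angles=angles,
        centers_x=centers_x,
        centers_y=centers_y,
        window_px=window_px,
        overlap=overlap,
        valid=valid,
    )


def order_parameter(field: OrientationField, neighborhood: int = 5) -> OrderResult:
    """Neighborhood nematic order parameter S = ⟨cos 2θ_ij⟩ per window.

    S is defined at windows where the full ``neighborhood × neighborhood``
    block fits inside the grid and every member window is valid; θ_ij is the
    angle between the central reference vector and each of the
    ``neighborhood² − 1`` neighbors.  The scalar summary is the median of
    the per-window map (the mean is also reported).  If no window admits a
    complete neighborhood the result is empty (NaN summaries), not an error.
    """
    if neighborhood < 3 or neighborhood % 2 == 0:
        raise ValueError("neighborhood must be an odd integer >= 3")
    ny, nx = field.shape
    h = neighborhood // 2
    S_map = np.full((ny, nx), np.nan)
    if ny >= neighborhood and nx >= neighborhood:
        theta = field.angles
        acc = np.zeros((ny - 2 * h, nx - 2 * h))
        ok = np.ones((ny - 2 * h, nx - 2 * h), dtype=bool)
        center = theta[h : ny - h, h : nx - h]
        count = 0
        for dy in range(-h, h + 1):
            for dx in range(-h, h + 1):
                nb_valid = field.valid[h + dy : ny - h + dy, h + dx : nx - h + dx]
                ok &= nb_valid
                if dy == 0 and dx == 0:
                    continue
                nb = theta[h + dy : ny - h + dy, h + dx : nx - h + dx]
                acc += np.cos(2.0 * (center - nb))
                count += 1
        S_inner = acc / count
        S_inner[~ok] = np.nan
        S_map[h : ny - h, h : nx - h] = S_inner
    defined = np.isfinite(S_map)
    n_def = int(defined.sum())
    if n_def == 0:
        return OrderResult(S_map, float("nan"), float("nan"), neighborhood, 0)
    return OrderResult(
        S_map,
        float(np.nanmedian(S_map)),
        float(np.nanmean(S_map)),
        neighborhood,
        n_def,
    )


def radial_alignment(
    field: OrientationField,
    center: tuple[float, float],
    n_sectors: int = 8,
) -> np.ndarray:
    """Per-sector radial order ⟨cos 2φ⟩ about a center point.

    Windows are binned into ``n_sectors`` angular sectors about ``center``
    (sector 0 centered on +x, proceeding by increasing image-coordinate
    angle, i.e. through +y); φ is the angle between each window's fiber
    orientation and its radial direction.  +1 means fibers point along the
    radius, −1 circumferential, 0 random.  Empty sectors yield NaN.
    """
    cx, cy = center
    dx = field.centers_x - cx
    dy = field.centers_y - cy
    pos_angle = np.arctan2(dy, dx) % (2 * np.pi)
    sector_width = 2 * np.pi / n_sectors
    sector = np.round(pos_angle / sector_width).astype(int) % n_sectors
    radial_dir = np.arctan2(dy, dx)  # axial comparison below handles mod π
    cos2phi = np.cos(2.0 * (field.angles - radial_dir))
    out = np.full(n_sectors, np.nan)
    for s in range(n_sectors):
        sel = (sector == s) & field.valid
        if np.any(sel):
            out[s] = float(cos2phi[sel].mean())
    return out
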