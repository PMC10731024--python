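"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one class of raw data the measurement chain
consumes — fibrous collagen texture, actin speckle timelapses, stained
two-compartment cells, nuclei fields, invading spheroid masks, Hertzian
indentation curves, junction ridges — and returns a :class:`GroundTruth`
record from which the expected downstream metric can be computed without
re-reading the image.

All generators are deterministic: identical parameters and seed reproduce
their output bit-exactly.  Rendering is 2D; three-dimensional stacks are
emulated as (stacks of) 2D sections because every downstream quantity is
computed on 2D projections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, special
from skimage.draw import disk as draw_disk
from skimage.draw import line_aa

from .afm import ForceCurve
from .aft import OrientationField
from .core_io import ImageStack, Roi
from .ratios import CellSample


@dataclass
class GroundTruth:
    """Generator provenance: name, parameter map and seed."""

    generator: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            return v

        Path(path).write_text(
            json.dumps(
                {"generator": self.generator, "seed": self.seed, "params": _clean(self.params)},
                indent=1,
            )
        )


def _rng(seed: int | None) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Fiber fields (collagen texture)


def sample_axial_angles(
    kappa: float, mean_angle: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw fiber orientations on [0, π) from a von Mises on doubled angles.

    Fiber orientation is axial (θ and θ+π are the same fiber), so dispersion
    is parameterized on the doubled-angle circle: 2θ ~ VM(2·mean, κ).  The
    expected axial alignment to the mean is E[cos 2(θ−mean)] = I₁(κ)/I₀(κ).
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if np.isinf(kappa):
        return np.full(n, mean_angle % np.pi)
    if kappa == 0:
        return rng.uniform(0.0, np.pi, n)
    doubled = rng.vonmises(2.0 * mean_angle, kappa, n)
    return (doubled / 2.0) % np.pi


def expected_axial_order(kappa: float) -> float:
    """Closed-form E[cos 2Δθ] = I₁(κ)/I₀(κ) for von Mises axial dispersion."""
    if np.isinf(kappa):
        return 1.0
    if kappa == 0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


def gen_fiber_field(
    kappa: float,
    mean_angle: float = 0.0,
    n_fibers: int = 800,
    image_px: int = 512,
    pixel_size_um: float = 0.5,
    fiber_len_px: float = 60.0,
    intensity: float = 200.0,
    seed: int | None = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render anti-aliased fiber segments with von Mises angular dispersion.

    Angles are measured from +x with y downward (image convention).  Segment
    centers are uniform over the image; each segment is drawn with
    anti-aliased lines at the given intensity on a dark background.
    """
    rng = _rng(seed)
    angles = sample_axial_angles(kappa, mean_angle, n_fibers, rng)
    cx = rng.uniform(0, image_px, n_fibers)
    cy = rng.uniform(0, image_px, n_fibers)
    img = np.zeros((image_px, image_px), dtype=float)
    half = fiber_len_px / 2.0
    segments = []
    for x, y, th in zip(cx, cy, angles):
        dx, dy = np.cos(th) * half, np.sin(th) * half
        r0, c0 = int(round(y - dy)), int(round(x - dx))
        r1, c1 = int(round(y + dy)), int(round(x + dx))
        rr, cc, val = line_aa(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < image_px) & (cc >= 0) & (cc < image_px)
        img[rr[keep], cc[keep]] += val[keep] * intensity
        segments.append((x, y, th))
    gt = GroundTruth(
        "gen_fiber_field",
        {
            "kappa": kappa,
            "mean_angle": mean_angle,
            "n_fibers": n_fibers,
            "image_px": image_px,
            "pixel_size_um": pixel_size_um,
            "fiber_len_px": fiber_len_px,
            "expected_order": expected_axial_order(kappa),
            "angles": angles,
            "segments": np.array(segments),
        },
        seed,
    )
    return img, gt


def gen_orientation_field(
    kappa: float,
    mean_angle: float = 0.0,
    shape: tuple[int, int] = (20, 20),
    window_px: int = 25,
    overlap: float = 0.5,
    seed: int | None = 0,
) -> tuple[OrientationField, GroundTruth]:
    """Draw an orientation-vector field directly, with i.i.d. window angles.

    Bypasses image rendering: each grid vector is an independent draw from
    the axial von Mises.  Useful for exercising the order-parameter stage
    against its exact sampling distribution (κ=0 gives E[S] = 0 exactly).
    """
    rng = _rng(seed)
    ny, nx = shape
    angles = sample_axial_angles(kappa, mean_angle, ny * nx, rng).reshape(ny, nx)
    step = max(1, int(round(window_px * (1.0 - overlap))))
    half = window_px / 2.0
    xs = half + step * np.arange(nx)
    ys = half + step * np.arange(ny)
    centers_x, centers_y = np.meshgrid(xs, ys)
    fld = OrientationField(
        angles=angles,
        centers_x=centers_x,
        centers_y=centers_y,
        window_px=window_px,
        overlap=overlap,
        valid=np.ones(shape, dtype=bool),
    )
    gt = GroundTruth(
        "gen_orientation_field",
        {
            "kappa": kappa,
            "mean_angle": mean_angle,
            "shape": list(shape),
            "expected_order": expected_axial_order(kappa),
        },
        seed,
    )
    return fld, gt


# ---------------------------------------------------------------------------
# Speckle frame pairs (actin flow)


def gen_flow_pair(
    displacement_um: tuple[float, float] | np.ndarray = (1.0, 0.0),
    speckle_sigma_px: float = 1.0,
    noise_sd: float = 0.0,
    image_px: int = 256,
    pixel_size_um: float = 0.16,
    seed: int | None = 0,
) -> tuple[tuple[np.ndarray, np.ndarray], GroundTruth]:
    """A speckle frame pair related by a known displacement.

    Frame A is smoothed uniform speckle; frame B is frame A resampled by the
    displacement (cubic-spline interpolation, sub-pixel capable) plus
    additive Gaussian noise.  ``displacement_um`` is either a constant
    (dx, dy) vector or a dense per-pixel field of shape (H, W, 2) in µm.
    """
    rng = _rng(seed)
    a = ndimage.gaussian_filter(rng.uniform(0, 255, (image_px, image_px)), speckle_sigma_px)
    disp = np.asarray(displacement_um, dtype=float)
    if disp.shape == (2,):
        dx_px, dy_px = disp / pixel_size_um
        # value at (y, x) in B comes from (y - dy, x - dx) in A
        b = ndimage.shift(a, (dy_px, dx_px), order=3, mode="reflect")
    elif disp.ndim == 3 and disp.shape[:2] == a.shape and disp.shape[2] == 2:
        yy, xx = np.mgrid[0:image_px, 0:image_px].astype(float)
        coords = np.stack([yy - disp[..., 1] / pixel_size_um, xx - disp[..., 0] / pixel_size_um])
        b = ndimage.map_coordinates(a, coords, order=3, mode="reflect")
    else:
        raise ValueError("displacement_um must be a 2-vector or an (H, W, 2) field")
    if noise_sd > 0:
        a = a + rng.normal(0, noise_sd, a.shape)
        b = b + rng.normal(0, noise_sd, b.shape)
    gt = GroundTruth(
        "gen_flow_pair",
        {
            "displacement_um": disp,
            "noise_sd": noise_sd,
            "image_px": image_px,
            "pixel_size_um": pixel_size_um,
        },
        seed,
    )
    return (a, b), gt


# ---------------------------------------------------------------------------
# Two-compartment cells (N:C ratio)


def gen_nc_cells(
    nc_ratio: float,
    background: float = 50.0,
    noise_sd: float = 0.0,
    n_cells: int = 20,
    cyto_intensity: float = 100.0,
    cyto_radius_px: int = 22,
    nuc_radius_px: int = 9,
    pixel_size_um: float = 0.5,
    seed: int | None = 0,
) -> tuple[ImageStack, list[CellSample], GroundTruth]:
    """Cells drawn as cytoplasm disks with brighter/dimmer nuclear cores.

    Channel 0 is the signal channel: cytoplasm at ``cyto_intensity +
    background``, nucleus at ``nc_ratio·cyto_intensity + background``.
    Channel 1 is a DAPI-like channel marking nuclei.  Each cell comes with
    one 10×10 px nuclear square and two 10×10 px cytoplasmic squares, the
    sampling scheme the ratio stage consumes.
    """
    if nc_ratio <= 0:
        raise ValueError("nc_ratio must be positive")
    rng = _rng(seed)
    pitch = 2 * cyto_radius_px + 6
    n_side = int(np.ceil(np.sqrt(n_cells)))
    size = n_side * pitch + pitch
    signal = np.full((size, size), background, dtype=float)
    dapi = np.zeros((size, size), dtype=float)
    samples: list[CellSample] = []
    nuc_intensity = nc_ratio * cyto_intensity
    for i in range(n_cells):
        gy, gx = divmod(i, n_side)
        cx = pitch // 2 + 3 + gx * pitch + cyto_radius_px
        cy = pitch // 2 + 3 + gy * pitch + cyto_radius_px
        rr, cc = draw_disk((cy, cx), cyto_radius_px, shape=signal.shape)
        signal[rr, cc] = background + cyto_intensity
        rr, cc = draw_disk((cy, cx), nuc_radius_px, shape=signal.shape)
        signal[rr, cc] = background + nuc_intensity
        dapi[rr, cc] = 200.0
        nuc = Roi("rectangle", [(cx - 5, cy - 5), (cx + 5, cy + 5)], label=f"cell{i}_nuc")
        off = nuc_radius_px + 5 + 1
        cy1 = Roi("rectangle", [(cx - off - 5, cy - 5), (cx - off + 5, cy + 5)], f"cell{i}_cyt1")
        cy2 = Roi("rectangle", [(cx + off - 5, cy - 5), (cx + off + 5, cy + 5)], f"cell{i}_cyt2")
        samples.append(
            CellSample(
                nuclear_roi=nuc,
                cytoplasm_rois=[cy1, cy2],
                spheroid_id="synthetic",
            )
        )
    if noise_sd > 0:
        signal = np.clip(signal + rng.normal(0, noise_sd, signal.shape), 0, None)
    stack = ImageStack(
        pixels=np.stack([signal, dapi]), axes="CYX", pixel_size_um=pixel_size_um
    )
    gt = GroundTruth(
        "gen_nc_cells",
        {
            "nc_ratio": nc_ratio,
            "background": background,
            "noise_sd": noise_sd,
            "n_cells": n_cells,
            "cyto_intensity": cyto_intensity,
            "pixel_size_um": pixel_size_um,
        },
        seed,
    )
    return stack, samples, gt


# ---------------------------------------------------------------------------
# Nuclei fields


def gen_nuclei(
    mode: str = "hexagonal",
    spacing_um: float = 10.0,
    density_per_um2: float | None = None,
    region_um: float = 100.0,
    nucleus_radius_um: float = 3.0,
    pixel_size_um: float = 0.5,
    intensity: float = 200.0,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """A DAPI-like nuclei image plus ground-truth centroids (µm).

    ``hexagonal`` places nuclei on a triangular lattice with the given
    nearest-neighbor spacing; ``poisson`` scatters them with the given
    density (expected count = density × area).  Nuclei are rendered as
    Gaussian blobs of the given radius.
    """
    rng = _rng(seed)
    if mode == "hexagonal":
        pts = []
        row_h = spacing_um * np.sqrt(3) / 2.0
        n_rows = int(region_um / row_h) + 1
        n_cols = int(region_um / spacing_um) + 1
        for r in range(n_rows):
            x0 = (spacing_um / 2.0) if r % 2 else 0.0
            for c in range(n_cols):
                x, y = x0 + c * spacing_um, r * row_h
                if x <= region_um and y <= region_um:
                    pts.append((x, y))
        centroids = np.array(pts)
    elif mode == "poisson":
        if density_per_um2 is None:
            raise ValueError("poisson mode requires density_per_um2")
        n = rng.poisson(density_per_um2 * region_um**2)
        centroids = rng.uniform(0, region_um, (n, 2))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    size = int(np.ceil(region_um / pixel_size_um)) + 1
    img = np.zeros((size, size), dtype=float)
    sigma_px = nucleus_radius_um / pixel_size_um / 2.0
    for x, y in centroids:
        cx, cy = x / pixel_size_um, y / pixel_size_um
        ix, iy = int(round(cx)), int(round(cy))
        if 0 <= iy < size and 0 <= ix < size:
            img[iy, ix] += 1.0
    img = ndimage.gaussian_filter(img, sigma_px)
    if img.max() > 0:
        img *= intensity / img.max()
    gt = GroundTruth(
        "gen_nuclei",
        {
            "mode": mode,
            "spacing_um": spacing_um,
            "density_per_um2": density_per_um2,
            "region_um": region_um,
            "pixel_size_um": pixel_size_um,
            "centroids_um": centroids,
        },
        seed,
    )
    return img, centroids, gt


# ---------------------------------------------------------------------------
# Spheroid invasion series


def gen_spheroid_series(
    radius_um: float = 100.0,
    growth_per_day: float = 0.25,
    n_lobes: int = 0,
    lobe_cells: float = 4.0,
    cell_area_um2: float = 200.0,
    n_filopodia: int = 0,
    filopodia_len_um: float = 10.0,
    n_timepoints: int = 5,
    image_um: float = 512.0,
    pixel_size_um: float = 1.0,
    intensity: float = 200.0,
    lobe_angles: np.ndarray | None = None,
    filopodia_angles: np.ndarray | None = None,
    seed: int | None = 0,
) -> tuple[list[dict], GroundTruth]:
    """A daily timelapse of an invading spheroid, one record per timepoint.

    Each record holds ``mask`` (binary body + lobes), ``image`` (intensity
    rendering with filopodia spurs), and the analytic ``area_um2`` of the
    drawn geometry.  The body is a disk whose radius grows by
    ``growth_per_day`` per timepoint; ``n_lobes`` broad protrusion lobes
    (half-disks of ``lobe_cells``·``cell_area_um2``) sit on the boundary;
    filopodia are 1-px-wide radial spurs outside the body.
    """
    rng = _rng(seed)
    size = int(round(image_um / pixel_size_um))
    c = size / 2.0
    series = []
    if lobe_angles is None:
        lobe_angles = rng.uniform(0, 2 * np.pi, n_lobes)
    else:
        lobe_angles = np.asarray(lobe_angles, dtype=float)
    if filopodia_angles is None:
        filo_angles = rng.uniform(0, 2 * np.pi, n_filopodia)
    else:
        filo_angles = np.asarray(filopodia_angles, dtype=float)
    lobe_r_um = np.sqrt(2.0 * lobe_cells * cell_area_um2 / np.pi)  # half-disk lobe
    for t in range(n_timepoints):
        r_um = radius_um * (1.0 + growth_per_day * t)
        r_px = r_um / pixel_size_um
        mask = np.zeros((size, size), dtype=bool)
        rr, cc = draw_disk((c, c), r_px, shape=mask.shape)
        mask[rr, cc] = True
        area_um2 = np.pi * r_um**2
        for ang in lobe_angles:
            lx = c + r_px * np.cos(ang)
            ly = c + r_px * np.sin(ang)
            rr, cc = draw_disk((ly, lx), lobe_r_um / pixel_size_um, shape=mask.shape)
            mask[rr, cc] = True
        image = mask.astype(float) * intensity
        for ang in filo_angles:
            x0 = c + (r_px + 1) * np.cos(ang)
            y0 = c + (r_px + 1) * np.sin(ang)
            x1 = c + (r_px + 1 + filopodia_len_um / pixel_size_um) * np.cos(ang)
            y1 = c + (r_px + 1 + filopodia_len_um / pixel_size_um) * np.sin(ang)
            rr, cc, val = line_aa(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
            keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
            image[rr[keep], cc[keep]] = np.maximum(image[rr[keep], cc[keep]], val[keep] * intensity)
        series.append({"mask": mask, "image": image, "area_um2": area_um2, "radius_um": r_um})
    gt = GroundTruth(
        "gen_spheroid_series",
        {
            "radius_um": radius_um,
            "growth_per_day": growth_per_day,
            "n_lobes": n_lobes,
            "lobe_cells": lobe_cells,
            "cell_area_um2": cell_area_um2,
            "n_filopodia": n_filopodia,
            "filopodia_len_um": filopodia_len_um,
            "pixel_size_um": pixel_size_um,
            "relative_area": [(1.0 + growth_per_day * t) ** 2 for t in range(n_timepoints)],
            "lobe_angles": lobe_angles,
            "filo_angles": filo_angles,
        },
        seed,
    )
    return series, gt


# ---------------------------------------------------------------------------
# Hertzian force curves


def hertz_force_nN(
    indentation_nm: np.ndarray,
    modulus_pa: float,
    probe_radius_um: float = 5.0,
    poisson_ratio: float = 0.5,
) -> np.ndarray:
    """Hertz spherical-indenter force F = (4/3)·E/(1−ν²)·√R·δ^{3/2}, in nN."""
    delta_m = np.maximum(np.asarray(indentation_nm, dtype=float), 0.0) * 1e-9
    r_m = probe_radius_um * 1e-6
    f_n = (4.0 / 3.0) * (modulus_pa / (1.0 - poisson_ratio**2)) * np.sqrt(r_m) * delta_m**1.5
    return f_n * 1e9


def gen_force_curve(
    modulus_pa: float,
    probe_radius_um: float = 5.0,
    poisson_ratio: float = 0.5,
    contact_z_nm: float = 2000.0,
    baseline_slope: float = 0.0,
    noise_sd: float = 0.0,
    spring_constant_N_per_m: float = 0.013,
    max_indent_nm: float = 1000.0,
    pre_z_nm: float = 4000.0,
    n_points: int = 1024,
    seed: int | None = 0,
) -> tuple[ForceCurve, GroundTruth]:
    """An extension force curve with a flat baseline and a Hertzian ramp.

    Post-contact forces follow the Hertz spherical model; the piezo position
    includes cantilever deflection (z = contact + δ + F/k), so the curve is
    exactly what a soft cantilever with the given spring constant records.
    The pre-contact baseline spans ``pre_z_nm`` (most of a real curve is
    baseline); ``baseline_slope`` (nN per nm) tilts it and ``noise_sd``
    (nN) adds Gaussian force noise.  Samples are allocated proportionally
    to the z span of each segment.
    """
    rng = _rng(seed)
    f_max = hertz_force_nN(max_indent_nm, modulus_pa, probe_radius_um, poisson_ratio)
    post_span = max_indent_nm + f_max / spring_constant_N_per_m
    n_pre = max(10, int(round(n_points * pre_z_nm / (pre_z_nm + post_span))))
    n_post = max(50, n_points - n_pre)
    z_pre = np.linspace(contact_z_nm - pre_z_nm, contact_z_nm, n_pre, endpoint=False)
    f_pre = baseline_slope * (z_pre - contact_z_nm)
    delta = np.linspace(0.0, max_indent_nm, n_post)
    f_post = hertz_force_nN(delta, modulus_pa, probe_radius_um, poisson_ratio)
    # deflection = F/k: nN / (N/m) = nm
    z_post = contact_z_nm + delta + f_post / spring_constant_N_per_m
    z = np.concatenate([z_pre, z_post])
    f = np.concatenate([f_pre, f_post])
    if noise_sd > 0:
        f = f + rng.normal(0, noise_sd, f.shape)
    curve = ForceCurve(
        z_nm=z,
        force_nN=f,
        direction="extension",
        probe_radius_um=probe_radius_um,
        spring_constant_N_per_m=spring_constant_N_per_m,
    )
    gt = GroundTruth(
        "gen_force_curve",
        {
            "modulus_pa": modulus_pa,
            "probe_radius_um": probe_radius_um,
            "poisson_ratio": poisson_ratio,
            "contact_z_nm": contact_z_nm,
            "baseline_slope": baseline_slope,
            "noise_sd": noise_sd,
            "spring_constant_N_per_m": spring_constant_N_per_m,
            "max_indent_nm": max_indent_nm,
        },
        seed,
    )
    return curve, gt


# ---------------------------------------------------------------------------
# Junction ridge images


def gen_junction_image(
    peak_amplitude: float = 100.0,
    peak_width_um: float = 0.5,
    background: float = 20.0,
    image_px: int = 128,
    pixel_size_um: float = 0.2,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> tuple[np.ndarray, Roi, GroundTruth]:
    """A vertical Gaussian ridge emulating a cell–cell junction.

    Intensity is ``background + A·exp(−(x−x₀)²/2w²)`` with the ridge at the
    image center.  Also returns a horizontal line ROI crossing the ridge
    perpendicular to it, starting 5 µm to its left, for linescan tests.
    """
    rng = _rng(seed)
    x_um = np.arange(image_px) * pixel_size_um
    x0 = x_um[image_px // 2]
    profile = background + peak_amplitude * np.exp(-((x_um - x0) ** 2) / (2 * peak_width_um**2))
    img = np.tile(profile, (image_px, 1))
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, img.shape)
    y_mid = image_px // 2
    half_px = 5.0 / pixel_size_um
    line = Roi(
        "line",
        [(image_px // 2 - half_px, y_mid), (image_px // 2 + half_px, y_mid)],
        label="junction",
    )
    gt = GroundTruth(
        "gen_junction_image",
        {
            "peak_amplitude": peak_amplitude,
            "peak_width_um": peak_width_um,
            "background": background,
            "pixel_size_um": pixel_size_um,
            "ridge_x_um": x0,
            "fwhm_um": 2.0 * np.sqrt(2.0 * np.log(2.0)) * peak_width_um,
        },
        seed,
    )
    return img, line, gt
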