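"""Nuclear:cytoplasmic signal ratios and compartment assignment.

Signaling activity of ERK and YAP is read out from their subcellular
localization: both translocate to the nucleus when active, so activity is
proxied by the background-corrected nuclear/cytoplasmic intensity ratio.
The kinase translocation reporter (KTR) is exported from the nucleus upon
activation, so its readout is the reciprocal cytoplasmic/nuclear ratio.

Each cell is sampled with one 10×10 px square in the nucleus and two in
the cytoplasm; the ratio is (mean nuclear − background) divided by the
mean of the two cytoplasmic means minus background.  Cells are assigned to
the spheroid's outer shell (in contact with the matrix) or inner core by
distance to the spheroid boundary, and a sampling plan (≥24 cells per
compartment from ≥2 distinct projections per spheroid) can be enforced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import Roi

logger = logging.getLogger(__name__)

INNER, OUTER = "inner", "outer"


@dataclass
class CellSample:
    """One cell's sampling squares plus its per-cell annotations."""

    nuclear_roi: Roi
    cytoplasm_rois: list[Roi]
    compartment: str | None = None  # "inner" | "outer"
    ki67: str = "unknown"  # "positive" | "negative" | "unknown"
    spheroid_id: str = ""
    projection_id: str = ""

    def __post_init__(self) -> None:
        if self.nuclear_roi.kind != "rectangle":
            raise ValueError("nuclear ROI must be a rectangle")
        if len(self.cytoplasm_rois) != 2 or any(
            r.kind != "rectangle" for r in self.cytoplasm_rois
        ):
            raise ValueError("exactly two rectangular cytoplasm ROIs required")
        if self.compartment not in (None, INNER, OUTER):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.ki67 not in ("positive", "negative", "unknown"):
            raise ValueError(f"unknown ki67 flag {self.ki67!r}")


@dataclass
class RatioMeasurement:
    """One dimensionless ratio with its orientation and the background used."""

    value: float
    direction: str  # "N_over_C" | "C_over_N"
    background: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.value) and self.value > 0):
            raise ValueError("ratio must be finite and positive")
        if self.direction not in ("N_over_C", "C_over_N"):
            raise ValueError(f"unknown direction {self.direction!r}")


def _compartment_means(image: np.ndarray, sample: CellSample) -> tuple[float, float]:
    nuc = sample.nuclear_roi.mean_intensity(image)
    cyt = float(np.mean([r.mean_intensity(image) for r in sample.cytoplasm_rois]))
    return nuc, cyt


def nc_ratio(
    image: np.ndarray, sample: CellSample, background: float
) -> RatioMeasurement | None:
    """Background-corrected nuclear:cytoplasmic ratio for one cell.

    value = (mean nuclear − background) / (mean of two cytoplasmic means −
    background).  A non-positive denominator makes the measurement
    degenerate: it is excluded (returns ``None``) and logged rather than
    clipped, because clipping would bias group means.
    """
    nuc, cyt = _compartment_means(image, sample)
    denom = cyt - background
    num = nuc - background
    if denom <= 0 or num <= 0:
        logger.warning(
            "degenerate ratio for %s (nuc=%.3g cyt=%.3g bg=%.3g); excluded",
            sample.nuclear_roi.label or sample.spheroid_id,
            nuc,
            cyt,
            background,
        )
        return None
    return RatioMeasurement(value=num / denom, direction="N_over_C", background=background)


def ktr_ratio(
    image: np.ndarray, sample: CellSample, background: float
) -> RatioMeasurement | None:
    """Cytoplasmic:nuclear ratio (KTR orientation) on the same squares."""
    m = nc_ratio(image, sample, background)
    if m is None:
        return None
    return RatioMeasurement(value=1.0 / m.value, direction="C_over_N", background=background)


def measure_samples(
    image: np.ndarray,
    samples: list[CellSample],
    background: float,
    mode: str = "nc",
) -> tuple[list[RatioMeasurement], int]:
    """Measure every sample; returns (measurements, n_excluded)."""
    fn = nc_ratio if mode == "nc" else ktr_ratio
    out = []
    excluded = 0
    for s in samples:
        m = fn(image, s, background)
        if m is None:
            excluded += 1
        else:
            out.append(m)
    return out, excluded


def boundary_distance_um(
    spheroid_mask: np.ndarray, pixel_size_um: float
) -> np.ndarray:
    """Per-pixel Euclidean distance (µm) to the nearest off-mask pixel."""
    return ndimage.distance_transform_edt(np.asarray(spheroid_mask, bool)) * pixel_size_um


def assign_compartment(
    cell_centroids: np.ndarray,
    spheroid_mask: np.ndarray,
    boundary_depth_um: float = 15.0,
    pixel_size_um: float = 1.0,
) -> list[str | None]:
    """Classify cells as outer (within ``boundary_depth_um`` of the matrix
    boundary) or inner; centroids outside the mask yield ``None`` (flagged).

    Distance to the boundary is the Euclidean distance transform of the
    mask, i.e. the distance to the nearest off-spheroid pixel.  The default
    depth of 15 µm is roughly one cell radius, operationalizing "cells in
    contact with the ECM".
    """
    dist = boundary_distance_um(spheroid_mask, pixel_size_um)
    out: list[str | None] = []
    for x, y in np.asarray(cell_centroids, dtype=float).reshape(-1, 2):
        iy, ix = int(round(y)), int(round(x))
        if not (0 <= iy < dist.shape[0] and 0 <= ix < dist.shape[1]) or dist[iy, ix] == 0:
            logger.warning("centroid (%.1f, %.1f) outside spheroid mask; excluded", x, y)
            out.append(None)
        else:
            out.append(OUTER if dist[iy, ix] <= boundary_depth_um else INNER)
    return out


@dataclass
class SamplingReport:
    """Per-spheroid audit of the minimum-measurement sampling plan."""

    spheroid_id: str
    n_inner: int
    n_outer: int
    n_projections: int
    deficiencies: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.deficiencies


def enforce_sampling_plan(
    samples: list[CellSample],
    min_per_compartment: int = 24,
    min_projections: int = 2,
) -> list[SamplingReport]:
    """Audit samples against the plan: ≥24 per compartment from ≥2 distinct
    projections, per spheroid.  Violations are reported by name, and the
    spheroid flagged, rather than raising."""
    reports = []
    for sid in sorted({s.spheroid_id for s in samples}):
        group = [s for s in samples if s.spheroid_id == sid]
        n_inner = sum(1 for s in group if s.compartment == INNER)
        n_outer = sum(1 for s in group if s.compartment == OUTER)
        projections = {s.projection_id for s in group}
        defs = []
        if n_inner < min_per_compartment:
            defs.append(f"inner compartment has {n_inner} < {min_per_compartment} samples")
        if n_outer < min_per_compartment:
            defs.append(f"outer compartment has {n_outer} < {min_per_compartment} samples")
        if len(projections) < min_projections:
            defs.append(
                f"samples drawn from {len(projections)} < {min_projections} distinct projections"
            )
        reports.append(SamplingReport(sid, n_inner, n_outer, len(projections), defs))
    return reports


def ki67_association(
    ratios: list[float],
    ki67_flags: list[str],
) -> dict:
    """Split per-cell ratios by Ki-67 status and compare the two groups.

    Returns the positive/negative ratio lists and a two-group comparison
    (delegated to :func:`spheroquant.stats.compare_groups`); if either group
    is empty the comparison is skipped with a notice.
    """
    from . import stats

    pos = [r for r, k in zip(ratios, ki67_flags) if k == "positive"]
    neg = [r for r, k in zip(ratios, ki67_flags) if k == "negative"]
    result: dict = {"positive": pos, "negative": neg, "comparison": None, "notice": None}
    if not pos or not neg:
        result["notice"] = "one Ki-67 group is empty; comparison skipped"
        return result
    result["comparison"] = stats.compare_groups({"ki67_positive": pos, "ki67_negative": neg})
    return result
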