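"""Hertz-model fitting of spherical-indenter AFM force curves.

A force-distance curve records cantilever force against piezo extension.
After locating the contact point, the indentation depth is

    δ = (z − z_contact) − F/k

where F/k is the cantilever deflection (spring constant k); the Young's
modulus follows from the Hertz spherical-contact model

    F = (4/3) · E/(1−ν²) · √R · δ^{3/2}

fitted by least squares on the deepest fraction of the extension curve
(default: the top 10% of the indentation range, which avoids shallow
regions where the probe is still breaking through softer layers of the
meshwork).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import InsufficientDataError


class NoContactError(RuntimeError):
    """The force never rises above the baseline: no contact detected."""


@dataclass
class ForceCurve:
    """One indentation curve: piezo position (nm) vs force (nN)."""

    z_nm: np.ndarray
    force_nN: np.ndarray
    direction: str = "extension"  # "extension" | "retraction"
    probe_radius_um: float = 5.0
    spring_constant_N_per_m: float | None = 0.013

    def __post_init__(self) -> None:
        self.z_nm = np.asarray(self.z_nm, dtype=float)
        self.force_nN = np.asarray(self.force_nN, dtype=float)
        if self.z_nm.shape != self.force_nN.shape or self.z_nm.ndim != 1:
            raise ValueError("z and force must be 1D arrays of equal length")
        if self.direction not in ("extension", "retraction"):
            raise ValueError(f"unknown direction {self.direction!r}")
        dz = np.diff(self.z_nm)
        if len(dz) and not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotone within a curve")
        if not np.all(np.isfinite(self.force_nN)):
            raise ValueError("forces must be finite")

    def ascending(self) -> "ForceCurve":
        """The same curve ordered by increasing z."""
        if len(self.z_nm) < 2 or self.z_nm[1] > self.z_nm[0]:
            return self
        return ForceCurve(
            self.z_nm[::-1].copy(),
            self.force_nN[::-1].copy(),
            self.direction,
            self.probe_radius_um,
            self.spring_constant_N_per_m,
        )


@dataclass
class HertzFit:
    """Result of a Hertz-model fit on one extension curve."""

    modulus_pa: float
    contact_z_nm: float
    poisson_ratio: float
    fit_fraction: float
    residual_rms_nN: float
    n_fit_points: int

    def __post_init__(self) -> None:
        if not self.modulus_pa > 0:
            raise ValueError("modulus must be positive")


def find_contact_point(
    curve: ForceCurve,
    baseline_fraction: float = 0.5,
    threshold_sd: float = 3.0,
    min_run: int = 5,
    refine: bool = True,
) -> float:
    """Contact point of an extension curve from baseline statistics.

    A line is fitted to the first ``baseline_fraction`` of the curve; the
    crossing is the first z where the force exceeds that baseline by
    ``threshold_sd`` baseline residual standard deviations and stays above
    for at least ``min_run`` consecutive samples.  Because a δ^{3/2}
    contact rises gently, a pure threshold crossing lands systematically
    late under noise, so by default the estimate is refined by
    extrapolating the Hertzian ramp back to zero excess force: for a
    spherical indenter F^{2/3} is linear in (z − F/k), and its root is the
    contact point.  Raises :class:`NoContactError` when no crossing exists.
    """
    c = curve.ascending()
    n = len(c.z_nm)
    nb = max(3, int(n * baseline_fraction))
    coeffs = np.polyfit(c.z_nm[:nb], c.force_nN[:nb], 1)
    baseline = np.polyval(coeffs, c.z_nm)
    resid_sd = float(np.std(c.force_nN[:nb] - baseline[:nb]))
    scale = max(abs(c.force_nN).max(), 1.0)
    thr = max(threshold_sd * resid_sd, 1e-9 * scale)
    excess = c.force_nN - baseline
    above = excess > thr
    run = 0
    sustained = above.copy()
    for i in range(n - 1, -1, -1):
        run = run + 1 if above[i] else 0
        sustained[i] = run >= min_run
    idx = np.nonzero(sustained)[0]
    if idx.size == 0:
        raise NoContactError("force never exceeds the baseline threshold")
    z_cross = float(c.z_nm[idx[0]])
    if not refine:
        return z_cross
    sel = np.zeros(n, dtype=bool)
    sel[idx[0] :] = excess[idx[0] :] > thr
    if sel.sum() < 3:
        return z_cross
    k = c.spring_constant_N_per_m
    x = c.z_nm[sel] - (c.force_nN[sel] / k if k else 0.0)
    y = excess[sel] ** (2.0 / 3.0)
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        return z_cross
    z0 = float(-intercept / slope)
    # accept the refinement only if it lands at or before the crossing,
    # within the sampled z range
    if c.z_nm[0] <= z0 <= z_cross:
        return z0
    return z_cross


def hertz_fit(
    curve: ForceCurve,
    contact_z_nm: float,
    probe_radius_um: float | None = None,
    poisson_ratio: float = 0.5,
    fit_fraction: float = 0.10,
    fit_by: str = "depth",
) -> HertzFit:
    """Least-squares Hertz fit on the top fraction of the extension curve.

    The indentation is deflection-corrected when the curve carries a spring
    constant (δ = z − z₀ − F/k), otherwise uncorrected with a warning.
    ``fit_by='depth'`` selects samples in the deepest ``fit_fraction`` of
    the indentation range (the default reading of "top 10%");
    ``fit_by='force'`` selects the top fraction by force instead.  E is
    obtained by a through-origin least-squares fit of F against δ^{3/2}.
    """
    if curve.direction != "extension":
        raise ValueError("Hertz fit uses the extension curve only")
    c = curve.ascending()
    r_um = probe_radius_um if probe_radius_um is not None else c.probe_radius_um
    post = c.z_nm > contact_z_nm
    if post.sum() < 10:
        raise InsufficientDataError("need at least 10 post-contact samples")
    z = c.z_nm[post]
    f = c.force_nN[post]
    k = c.spring_constant_N_per_m
    if k:
        delta = (z - contact_z_nm) - f / k  # nN / (N/m) = nm
    else:
        warnings.warn("no spring constant; skipping cantilever deflection correction")
        delta = z - contact_z_nm
    good = delta > 0
    delta, f = delta[good], f[good]
    if fit_by == "depth":
        sel = delta >= (1.0 - fit_fraction) * delta.max()
    elif fit_by == "force":
        sel = f >= (1.0 - fit_fraction) * f.max()
    else:
        raise ValueError(f"unknown fit_by {fit_by!r}")
    if sel.sum() < 5:
        raise InsufficientDataError("fewer than 5 samples in the fit window")
    d_m = delta[sel] * 1e-9
    f_n = f[sel] * 1e-9
    x = d_m**1.5
    a = float(x @ f_n / (x @ x))  # F = a · δ^{3/2}
    modulus = 0.75 * a * (1.0 - poisson_ratio**2) / np.sqrt(r_um * 1e-6)
    resid = f_n - a * x
    return HertzFit(
        modulus_pa=float(modulus),
        contact_z_nm=float(contact_z_nm),
        poisson_ratio=poisson_ratio,
        fit_fraction=fit_fraction,
        residual_rms_nN=float(np.sqrt(np.mean(resid**2)) * 1e9),
        n_fit_points=int(sel.sum()),
    )


def fit_curve(
    curve: ForceCurve,
    probe_radius_um: float | None = None,
    poisson_ratio: float = 0.5,
    fit_fraction: float = 0.10,
    **contact_kwargs,
) -> HertzFit:
    """Convenience: contact-point estimation followed by the Hertz fit."""
    z0 = find_contact_point(curve, **contact_kwargs)
    return hertz_fit(
        curve,
        z0,
        probe_radius_um=probe_radius_um,
        poisson_ratio=poisson_ratio,
        fit_fraction=fit_fraction,
    )
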