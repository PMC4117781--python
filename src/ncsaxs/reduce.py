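"""2-D detector reduction: q-calibration, azimuthal averaging,
normalization and buffer subtraction.

A photon-counting detector ~1 m from the sample images the scattering;
each pixel at radial distance r from the beam center maps to momentum
transfer q = (4 pi / lambda) sin(atan(r/L)/2).  Unmasked pixels are
averaged in q-annuli with the counting-statistics error model sigma =
stdev / sqrt(N_pixels); profiles are normalized by the beam monitor and
buffer-subtracted in quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .scatter import ScatteringProfile

__all__ = [
    "DetectorImage",
    "ReductionGeometry",
    "q_of_pixel",
    "azimuthal_average",
    "normalize_and_subtract",
    "average_repeats",
    "drift_statistics",
]


@dataclass
class DetectorImage:
    counts: np.ndarray
    mask: np.ndarray | None = None  # True = use pixel
    exposure: float = 0.017
    beam_monitor: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D grid")
        if self.mask is None:
            self.mask = np.ones(self.counts.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask shape mismatch")
        if np.any(self.counts[self.mask] < 0):
            raise ValueError("counts must be >= 0 where unmasked")
        if self.exposure <= 0:
            raise ValueError("exposure must be > 0")


@dataclass(frozen=True)
class ReductionGeometry:
    """Beamline geometry: pixels -> scattering vector."""

    beam_center: tuple[float, float] = (97.0, 97.0)  # (row, col), pixel
    pixel_size: float = 0.172        # mm (PILATUS-class pixel)
    sample_detector_distance: float = 1000.0  # mm
    wavelength: float = 1.17         # A

    def __post_init__(self) -> None:
        if self.sample_detector_distance <= 0:
            raise ValueError("distance must be > 0")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")

    def radius_grid(self, shape: tuple[int, int]) -> np.ndarray:
        """Radial distance (mm) of each pixel center from the beam."""
        rows, cols = np.indices(shape)
        dr = (rows - self.beam_center[0]) * self.pixel_size
        dc = (cols - self.beam_center[1]) * self.pixel_size
        return np.hypot(dr, dc)


def q_of_pixel(geometry: ReductionGeometry, pixel: tuple[float, float]) -> float:
    """q (1/A) of one (row, col) pixel: (4 pi / lambda) sin(theta) with
    2 theta = atan(r / L)."""
    dr = (pixel[0] - geometry.beam_center[0]) * geometry.pixel_size
    dc = (pixel[1] - geometry.beam_center[1]) * geometry.pixel_size
    r = float(np.hypot(dr, dc))
    two_theta = np.arctan2(r, geometry.sample_detector_distance)
    return float(4.0 * np.pi / geometry.wavelength * np.sin(two_theta / 2.0))


def _q_grid_of(img_shape, geometry, n_bins=None):
    rr = geometry.radius_grid(img_shape)
    qq = (4.0 * np.pi / geometry.wavelength
          * np.sin(0.5 * np.arctan2(rr, geometry.sample_detector_distance)))
    if n_bins is None:
        # bin width = one-pixel resolution at the detector edge
        redge = rr.max()
        qedge = qq.max()
        dq = qedge - (4.0 * np.pi / geometry.wavelength * np.sin(
            0.5 * np.arctan2(redge - geometry.pixel_size,
                             geometry.sample_detector_distance)))
        n_bins = max(int(qedge / dq), 8)
    return qq, np.linspace(0.0, qq.max() * (1 + 1e-9), n_bins + 1)


def azimuthal_average(img: DetectorImage, geometry: ReductionGeometry,
                      qedges: np.ndarray | None = None,
                      n_bins: int | None = None) -> ScatteringProfile:
    """Mean counts per q-annulus with sigma = stdev / sqrt(N_pixels).

    Empty annuli are omitted; a fully masked image raises.
    """
    qq, default_edges = _q_grid_of(img.counts.shape, geometry, n_bins)
    edges = default_edges if qedges is None else np.asarray(qedges, float)
    m = img.mask
    if not np.any(m):
        raise ValueError("no unmasked pixels")
    qv = qq[m]
    cv = img.counts[m]
    idx = np.digitize(qv, edges) - 1
    nb = len(edges) - 1
    valid = (idx >= 0) & (idx < nb)
    idx, qv, cv = idx[valid], qv[valid], cv[valid]
    npix = np.bincount(idx, minlength=nb)
    tot = np.bincount(idx, weights=cv, minlength=nb)
    tot2 = np.bincount(idx, weights=cv ** 2, minlength=nb)
    qtot = np.bincount(idx, weights=qv, minlength=nb)
    occ = npix > 0
    mean = tot[occ] / npix[occ]
    var = tot2[occ] / npix[occ] - mean ** 2
    sig = np.sqrt(np.clip(var, 0.0, None) / npix[occ])
    qc = qtot[occ] / npix[occ]
    keep = qc > 0
    return ScatteringProfile(qc[keep], mean[keep], sig[keep],
                             meta={"exposure": img.exposure,
                                   "monitor": img.beam_monitor})


def normalize_and_subtract(sample: ScatteringProfile,
                           buffer: ScatteringProfile,
                           sample_monitor: float = 1.0,
                           buffer_monitor: float = 1.0) -> ScatteringProfile:
    """Monitor-normalized buffer subtraction with quadrature errors."""
    if sample_monitor <= 0 or buffer_monitor <= 0:
        raise ValueError("beam monitors must be > 0")
    if len(sample) != len(buffer) or not np.allclose(sample.q, buffer.q):
        raise ValueError("sample and buffer must share a q-grid")
    I = sample.I / sample_monitor - buffer.I / buffer_monitor
    sig = np.hypot(sample.sigma / sample_monitor,
                   buffer.sigma / buffer_monitor)
    meta = dict(sample.meta)
    meta["buffer_subtracted"] = True
    return ScatteringProfile(sample.q, I, sig, meta=meta)


def average_repeats(profiles: list[ScatteringProfile]) -> ScatteringProfile:
    """Inverse-variance-weighted mean of repeat profiles.

    A single profile is returned unchanged.  Mutually inconsistent
    repeats (pointwise chi^2 >> 1) trigger a warning.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    if len(profiles) == 1:
        return profiles[0]
    q0 = profiles[0].q
    for p in profiles[1:]:
        if len(p.q) != len(q0) or not np.allclose(p.q, q0):
            raise ValueError("profiles must share a q-grid")
    I = np.column_stack([p.I for p in profiles])
    S = np.column_stack([p.sigma for p in profiles])
    if np.all(S > 0):
        w = 1.0 / S ** 2
        mean = np.sum(I * w, axis=1) / np.sum(w, axis=1)
        sig = np.sqrt(1.0 / np.sum(w, axis=1))
        chi2 = np.mean((I - mean[:, None]) ** 2 / S ** 2)
        if chi2 > 4.0:
            warnings.warn(f"repeats are mutually inconsistent "
                          f"(mean chi^2 = {chi2:.1f})", stacklevel=2)
    else:
        mean = I.mean(axis=1)
        sig = S.mean(axis=1) / np.sqrt(I.shape[1])
    return ScatteringProfile(q0, mean, sig, meta=dict(profiles[0].meta))


def drift_statistics(profiles: list[ScatteringProfile]) -> np.ndarray:
    """Radiation-damage monitor: correlation of each profile with the
    first.  Values decaying from 1 indicate exposure-dependent change;
    reported, never auto-rejected."""
    ref = profiles[0].I
    out = []
    for p in profiles:
        a = ref - ref.mean()
        b = p.I - p.I.mean()
        denom = np.sqrt((a @ a) * (b @ b))
        out.append(float(a @ b / denom) if denom > 0 else np.nan)
    return np.asarray(out)
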