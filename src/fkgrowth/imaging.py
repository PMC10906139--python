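"""ADC imaging preprocessing: from apparent-diffusion-coefficient maps to
normalized tumor-cell-density maps and tumor segmentations.

The central quantity is the normalized tumor cell density ``nbar`` in [0, 1],
obtained from an ADC map through the linear inverse relationship

    nbar(x) = (ADC_h - ADC(x)) / (ADC_h - ADC_min),

truncated to 0 above the healthy-tissue value ``ADC_h`` and to 1 below the
minimum intratumoral value ``ADC_min`` (fixed at ``0.25 * ADC_h``).  Tumor
cores are segmented as the sub-region of the gross tumor with ADC below 70 %
of ``ADC_h`` and then expanded by a small metric margin so the final tumor
mask reaches into near-healthy ADC values.

A hyperbolic-tangent model links the continuous Gleason-score scale to the
ADC ratio ``ADC/ADC_h``; it motivates both the 70 % core threshold and the
0.25 lower asymptote and can be refit to (GS, ADC-ratio) points.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import nibabel as nib
from scipy import ndimage
from scipy.optimize import curve_fit

__all__ = [
    "ImageVolume",
    "Segmentation",
    "AdcCalibration",
    "GsAdcModel",
    "ScanSeries",
    "resample_isotropic",
    "estimate_healthy_adc",
    "adc_to_density",
    "density_to_adc",
    "fit_gs_adc_model",
    "segment_tumor_core",
    "expand_margin",
    "load_gs_adc_points",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ImageVolume:
    """A 3D scalar field on a regular grid with isotropic voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values (ADC in arbitrary consistent units, or dimensionless
        normalized density).
    spacing : float
        Isotropic voxel edge length in mm.
    origin : ndarray, shape (3,)
        Physical offset of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(self.spacing) ** 3

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag([self.spacing] * 3 + [1.0])
        affine[:3, 3] = self.origin
        return nib.Nifti1Image(self.data.astype(np.float32), affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, path) -> "ImageVolume":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0], rtol=1e-4):
            raise ValueError(f"anisotropic voxels {zooms}; resample first")
        return cls(
            data=np.asarray(img.get_fdata(), dtype=float),
            spacing=float(zooms[0]),
            origin=np.asarray(img.affine[:3, 3], dtype=float),
        )


@dataclass
class Segmentation:
    """A boolean mask aligned with an :class:`ImageVolume` grid."""

    mask: np.ndarray
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def volume_cc(self, spacing: float) -> float:
        """Mask volume in cc for the given isotropic spacing (mm)."""
        return self.n_voxels * spacing**3 / 1000.0

    def save(self, path, spacing: float, origin=None) -> None:
        affine = np.diag([spacing] * 3 + [1.0])
        if origin is not None:
            affine[:3, 3] = origin
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine), str(path))

    @classmethod
    def from_nifti(cls, path, label: str = "unlabeled") -> "Segmentation":
        img = nib.load(str(path))
        return cls(mask=np.asarray(img.get_fdata()) > 0.5, label=label)


@dataclass
class AdcCalibration:
    """Constants of the ADC <-> density conversion.

    ``adc_h`` is the mean ADC of healthy prostate tissue; ``ratio_min`` fixes
    the minimum intratumoral ADC as a fraction of ``adc_h`` (lower asymptote
    of the GS-ADC tanh model); ``core_ratio`` is the tumor-core threshold as
    a fraction of ``adc_h``.
    """

    adc_h: float = 1.0
    ratio_min: float = 0.25
    core_ratio: float = 0.70

    def __post_init__(self) -> None:
        if not self.adc_h > 0:
            raise ValueError("adc_h must be positive")
        if not 0 < self.ratio_min < self.core_ratio < 1:
            raise ValueError(
                f"require 0 < ratio_min < core_ratio < 1, got "
                f"({self.ratio_min}, {self.core_ratio})"
            )

    @property
    def adc_min(self) -> float:
        return self.ratio_min * self.adc_h


@dataclass
class ScanSeries:
    """Ordered per-patient scans: times (days), ADC maps, masks, densities.

    ``times[0]`` defines the patient's relative time origin; the density map
    of the first scan is the initial condition of the growth model.
    """

    times: np.ndarray
    prostate: Segmentation
    adc: list[ImageVolume] | None = None
    gross_masks: list[Segmentation] | None = None
    tumor_masks: list[Segmentation] | None = None
    density: list[ImageVolume] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 1:
            raise ValueError("times must be a nonempty 1D sequence")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("scan times must be strictly increasing")

    @property
    def n_scans(self) -> int:
        return len(self.times)

    def truncated(self, n_scans: int) -> "ScanSeries":
        """A copy keeping only the first ``n_scans`` scans."""
        def cut(x):
            return None if x is None else x[:n_scans]
        return ScanSeries(
            times=self.times[:n_scans],
            prostate=self.prostate,
            adc=cut(self.adc),
            gross_masks=cut(self.gross_masks),
            tumor_masks=cut(self.tumor_masks),
            density=cut(self.density),
        )


# ---------------------------------------------------------------------------
# resampling and ROI statistics
# ---------------------------------------------------------------------------

def resample_isotropic(
    vol: ImageVolume, target_spacing: float, order: int = 1
) -> ImageVolume:
    """Resample a volume to a new isotropic spacing.

    Scalar maps use trilinear interpolation (``order=1``); masks should be
    resampled with ``order=0`` (nearest neighbor).  The output grid keeps the
    input origin and covers the same physical extent.
    """
    if not target_spacing > 0:
        raise ValueError(f"target_spacing must be positive, got {target_spacing}")
    if order not in (0, 1):
        raise ValueError("order must be 0 (nearest) or 1 (trilinear)")
    ratio = vol.spacing / target_spacing
    if np.isclose(ratio, 1.0):
        return ImageVolume(vol.data.copy(), vol.spacing, vol.origin.copy())
    new_shape = tuple(
        int(np.floor((n - 1) * ratio)) + 1 for n in vol.data.shape
    )
    coords = np.meshgrid(
        *[np.arange(n) / ratio for n in new_shape], indexing="ij"
    )
    out = ndimage.map_coordinates(
        vol.data, np.stack(coords), order=order, mode="nearest"
    )
    return ImageVolume(out, target_spacing, vol.origin.copy())


def estimate_healthy_adc(adc: ImageVolume, roi: Segmentation) -> float:
    """Mean ADC over a healthy-tissue region of interest (ADC_h estimate)."""
    if adc.data.shape != roi.mask.shape:
        raise ValueError("ROI grid does not match the ADC volume")
    if roi.n_voxels == 0:
        raise ValueError("empty healthy-tissue ROI")
    return float(adc.data[roi.mask].mean())


# ---------------------------------------------------------------------------
# ADC <-> density conversion
# ---------------------------------------------------------------------------

def adc_to_density(adc, cal: AdcCalibration | None = None):
    """Convert ADC values to normalized tumor cell density in [0, 1].

    Values above ``adc_h`` map to 0 and below ``adc_min`` to 1 (truncation
    avoids negative densities and densities above carrying capacity).
    Accepts scalars or arrays.
    """
    cal = cal or AdcCalibration()
    adc = np.asarray(adc, dtype=float)
    nbar = (cal.adc_h - adc) / (cal.adc_h - cal.adc_min)
    out = np.clip(nbar, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def density_to_adc(nbar, cal: AdcCalibration | None = None):
    """Inverse of :func:`adc_to_density` on [0, 1] (used by the synthetic
    generator to manufacture ADC maps from simulated density)."""
    cal = cal or AdcCalibration()
    nbar = np.asarray(nbar, dtype=float)
    if np.any(nbar < -1e-12) or np.any(nbar > 1 + 1e-12):
        raise ValueError("nbar must lie in [0, 1]")
    adc = cal.adc_h - np.clip(nbar, 0.0, 1.0) * (cal.adc_h - cal.adc_min)
    return float(adc) if adc.ndim == 0 else adc


# ---------------------------------------------------------------------------
# GS-ADC hyperbolic tangent model
# ---------------------------------------------------------------------------

@dataclass
class GsAdcModel:
    """Decreasing tanh map from the continuous Gleason scale to ADC/ADC_h.

    f(GS) = (upper + lower)/2 - (upper - lower)/2 * tanh(slope * (GS - midpoint))

    with the asymptotes pinned at ``upper`` (healthy tissue, 1.0) and
    ``lower`` (maximal cellularity, the calibration's ``ratio_min``).
    GS values in (0, 2) represent healthy/pretumoral tissue.
    """

    slope: float
    midpoint: float
    upper: float = 1.0
    lower: float = 0.25
    rss: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("slope must be positive")
        if not self.lower < self.upper:
            raise ValueError("lower asymptote must be below upper")

    def __call__(self, gs):
        gs = np.asarray(gs, dtype=float)
        mid = 0.5 * (self.upper + self.lower)
        amp = 0.5 * (self.upper - self.lower)
        out = mid - amp * np.tanh(self.slope * (gs - self.midpoint))
        return float(out) if out.ndim == 0 else out

    def density(self, gs, cal: AdcCalibration | None = None):
        """Composite map GS -> normalized density through the conversion."""
        cal = cal or AdcCalibration(adc_h=1.0, ratio_min=self.lower)
        return adc_to_density(self(gs) * cal.adc_h, cal)


def fit_gs_adc_model(
    gs_values: Sequence[float],
    adc_ratios: Sequence[float],
    lower: float = 0.25,
    upper: float = 1.0,
) -> GsAdcModel:
    """Least-squares fit of the two free tanh parameters (slope, midpoint).

    The asymptotes are held fixed; at least three distinct GS values are
    required.
    """
    gs = np.asarray(gs_values, dtype=float)
    ratios = np.asarray(adc_ratios, dtype=float)
    if gs.shape != ratios.shape or gs.ndim != 1:
        raise ValueError("gs_values and adc_ratios must be equal-length 1D")
    if len(gs) < 3:
        raise ValueError("need at least 3 points to fit the tanh model")
    if np.ptp(gs) == 0:
        raise ValueError("degenerate fit: all GS values identical")

    mid, amp = 0.5 * (upper + lower), 0.5 * (upper - lower)

    def f(x, slope, midpoint):
        return mid - amp * np.tanh(slope * (x - midpoint))

    p0 = (1.0, float(np.mean(gs)))
    popt, _ = curve_fit(f, gs, ratios, p0=p0, maxfev=20000)
    slope, midpoint = float(popt[0]), float(popt[1])
    if slope < 0:  # tanh is odd: flip to the canonical decreasing branch
        slope = -slope
    rss = float(np.sum((f(gs, slope, midpoint) - ratios) ** 2))
    return GsAdcModel(slope=slope, midpoint=midpoint, upper=upper,
                      lower=lower, rss=rss)


def load_gs_adc_points():
    """Load the packaged synthetic (GS, ADC-ratio) literature-style points.

    Returns ``(gs, adc_ratio)`` arrays.  These points are a synthetic
    stand-in with the qualitative shape of published GS-specific mean ADC
    ratios (monotone decrease, plateau at high GS); see the CSV header.
    """
    ref = importlib.resources.files("fkgrowth").joinpath(
        "data/gs_adc_points_synthetic.csv"
    )
    raw = np.genfromtxt(ref.open("rb"), delimiter=",", names=True)
    return np.atleast_1d(raw["gs"]), np.atleast_1d(raw["adc_ratio"])


# ---------------------------------------------------------------------------
# tumor segmentation steps
# ---------------------------------------------------------------------------

def segment_tumor_core(
    adc: ImageVolume, gross: Segmentation, cal: AdcCalibration
) -> Segmentation:
    """Tumor core: gross-tumor voxels with ADC strictly below
    ``core_ratio * adc_h`` (default 70 % of the healthy value)."""
    if adc.data.shape != gross.mask.shape:
        raise ValueError("gross mask grid does not match the ADC volume")
    mask = gross.mask & (adc.data < cal.core_ratio * cal.adc_h)
    return Segmentation(mask=mask, label="tumor_core")


def _ball_structure(margin_mm: float, spacing: float) -> np.ndarray:
    r = int(np.floor(margin_mm / spacing + 1e-9))
    if r == 0:
        return np.ones((1, 1, 1), dtype=bool)
    ax = np.arange(-r, r + 1)
    ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
    return (ii**2 + jj**2 + kk**2) * spacing**2 <= margin_mm**2 + 1e-9


def expand_margin(
    core: Segmentation,
    gross: Segmentation,
    margin_mm: float,
    spacing: float,
) -> Segmentation:
    """Dilate the tumor core by a Euclidean ball of radius ``margin_mm`` and
    clip to the gross tumor, producing the final tumor segmentation."""
    if margin_mm < 0:
        raise ValueError("margin must be nonnegative")
    if core.mask.shape != gross.mask.shape:
        raise ValueError("core and gross masks live on different grids")
    if np.any(core.mask & ~gross.mask):
        raise ValueError("core must be contained in the gross segmentation")
    if margin_mm == 0 or core.n_voxels == 0:
        return Segmentation(core.mask.copy(), label="tumor_final")
    structure = _ball_structure(margin_mm, spacing)
    dilated = ndimage.binary_dilation(core.mask, structure=structure)
    return Segmentation(mask=dilated & gross.mask, label="tumor_final")
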