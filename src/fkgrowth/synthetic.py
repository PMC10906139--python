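"""Self-contained synthetic cohorts emulating longitudinal prostate mpMRI.

Each synthetic patient carries an ellipsoidal prostate mask (volumes in the
18.5-67.3 cc range), a focal tumor seeded as a compactly-supported smooth
bump, true Fisher-Kolmogorov parameters drawn log-uniformly from the
calibrated ranges, three scans at interscan intervals of 0.5-2.6 years
whose density evolves by the forward model, ADC-ratio maps produced by
inverting the linear ADC-density relationship (ADC_h = 1 in ratio units)
plus optional additive Gaussian noise, gross tumor masks dilated from the
true tumor support, and Gleason-like risk labels tied to the true mean
proliferation activity so the classifier stage has a learnable ground
truth.

The generator is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging import (AdcCalibration, ImageVolume, ScanSeries, Segmentation,
                      density_to_adc)
from .biomarkers import GsObservation, biomarker_panel
from .solver import DensityState, GrowthParams, SimulationGrid, simulate

__all__ = [
    "CohortSpec",
    "SyntheticPatient",
    "make_prostate",
    "seed_tumor",
    "generate_patient",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

DAYS_PER_YEAR = 365.0


@dataclass
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Parameter ranges mirror the study population: prostate volumes
    18.5-67.3 cc, interscan gaps 0.5-2.6 years, three scans per patient,
    and (D, rho) spanning the envelope of the calibrated patient values.
    ``a_p_cutoff`` sets the true mean-proliferation-activity level above
    which a scan is labelled higher-risk (Gleason >= 3+4-like).
    """

    n_patients: int = 10
    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: float = 1.5           # mm
    dt: float = 1.0                # days
    prostate_volume_range: tuple[float, float] = (18.5, 67.3)   # cc
    d_range: tuple[float, float] = (5.35e-4, 5.35e-3)           # mm^2/day
    rho_range: tuple[float, float] = (7.8e-4, 5.2e-3)           # 1/day
    n_scans: int = 3
    gap_range_years: tuple[float, float] = (0.5, 2.6)
    tumor_radius_range: tuple[float, float] = (4.0, 7.0)        # mm
    peak_nbar_range: tuple[float, float] = (0.7, 0.9)
    noise_sigma: float = 0.02      # additive Gaussian on the ADC ratio
    nbar_th: float = 0.15
    a_p_cutoff: float = 4.0e-4     # 1/day
    gross_margin_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scans != 3:
            raise ValueError("the emulated protocol has three scans")
        for name in ("prostate_volume_range", "d_range", "rho_range",
                     "gap_range_years", "tumor_radius_range",
                     "peak_nbar_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")


@dataclass
class SyntheticPatient:
    """A generated patient: truth plus its imaging-level representation."""

    patient_id: str
    true_params: GrowthParams
    series: ScanSeries
    gs_observations: list[GsObservation]
    true_density: list[np.ndarray] = field(default_factory=list)
    adc_h: float = 1.0
    spacing: float = 1.5
    dt: float = 1.0


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

_AXIS_RATIOS = (1.15, 1.0, 0.85)  # mildly oblate, fixed across the cohort


def make_prostate(volume_cc: float, shape: tuple[int, int, int],
                  spacing: float) -> Segmentation:
    """Ellipsoidal prostate mask of the requested volume (within 2 %).

    Semi-axes follow fixed anatomical-looking ratios; a bisection on the
    overall scale corrects voxelization error.
    """
    target_mm3 = volume_cc * 1000.0
    ratios = np.array(_AXIS_RATIOS)
    # continuum solution: V = 4/3 pi (s r0)(s r1)(s r2)
    s0 = (target_mm3 / (4.0 / 3.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
    center = (np.array(shape) - 1) / 2.0
    coords = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")

    def count(scale: float) -> int:
        semi = scale * ratios / spacing  # in voxel units
        q = sum(((c - c0) / a) ** 2
                for c, c0, a in zip(coords, center, semi))
        return int(np.sum(q <= 1.0))

    target_vox = target_mm3 / spacing**3
    if count(s0 * 1.05) < 1:
        raise ValueError("requested prostate volume too small for the grid")
    semi_max = s0 * 1.1 * ratios.max() / spacing
    if np.any(s0 * 1.1 * ratios / spacing >= (np.array(shape) - 1) / 2.0):
        raise ValueError(
            f"prostate of {volume_cc} cc does not fit a {shape} grid at "
            f"{spacing} mm spacing (semi-axis {semi_max:.1f} voxels)")

    lo, hi = 0.9 * s0, 1.1 * s0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if count(mid) < target_vox:
            lo = mid
        else:
            hi = mid
    scale = 0.5 * (lo + hi)
    semi = scale * ratios / spacing
    q = sum(((c - c0) / a) ** 2 for c, c0, a in zip(coords, center, semi))
    mask = q <= 1.0
    achieved = mask.sum() * spacing**3 / 1000.0
    if abs(achieved - volume_cc) / volume_cc > 0.02:
        raise ValueError(
            f"voxelized prostate volume {achieved:.2f} cc misses the "
            f"requested {volume_cc:.2f} cc by more than 2 %")
    return Segmentation(mask=mask, label="prostate")


def seed_tumor(prostate: Segmentation, center, radius_mm: float,
               peak_nbar: float, spacing: float) -> DensityState:
    """Focal initial tumor: smooth bump of compact support.

    nbar(r) = peak * exp(1 - 1/(1 - (r/R)^2)) for r < R, 0 outside, so the
    initial density is exactly zero beyond ``radius_mm`` (the measured map
    of the first scan then captures the full tumor).
    """
    if not 0 < peak_nbar <= 1:
        raise ValueError("peak_nbar must lie in (0, 1]")
    if not radius_mm > 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float)
    ci = tuple(int(round(c)) for c in center)
    if not prostate.mask[ci]:
        raise ValueError("tumor center lies outside the prostate")
    coords = np.meshgrid(*[np.arange(n) for n in prostate.mask.shape],
                         indexing="ij")
    r2 = sum(((c - c0) * spacing) ** 2 for c, c0 in zip(coords, center))
    s2 = np.clip(r2 / radius_mm**2, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        profile = np.where(s2 < 1.0,
                           np.exp(1.0 - 1.0 / np.maximum(1.0 - s2, 1e-300)),
                           0.0)
    nbar = peak_nbar * profile * prostate.mask
    return DensityState(nbar=nbar, t=0.0)


# ---------------------------------------------------------------------------
# patient and cohort generation
# ---------------------------------------------------------------------------

def _uniform(rng, lohi):
    return float(rng.uniform(*lohi))


def _log_uniform(rng, lohi):
    return float(np.exp(rng.uniform(np.log(lohi[0]), np.log(lohi[1]))))


def generate_patient(spec: CohortSpec, rng: np.random.Generator,
                     patient_id: str = "P00") -> SyntheticPatient:
    """Draw one synthetic patient and forward-simulate its scans."""
    volume_cc = _uniform(rng, spec.prostate_volume_range)
    prostate = make_prostate(volume_cc, spec.shape, spec.spacing)
    grid = SimulationGrid(prostate.mask, spec.spacing, spec.dt)

    true = GrowthParams(d=_log_uniform(rng, spec.d_range),
                        rho=_log_uniform(rng, spec.rho_range),
                        nbar_th=spec.nbar_th)

    # tumor seed: offset from the prostate center, guaranteed interior
    center = (np.array(spec.shape) - 1) / 2.0
    radius = _uniform(rng, spec.tumor_radius_range)
    peak = _uniform(rng, spec.peak_nbar_range)
    offset_dir = rng.standard_normal(3)
    offset_dir /= np.linalg.norm(offset_dir)
    semi_mm = (volume_cc * 1000.0 * 3.0 /
               (4.0 * np.pi * np.prod(_AXIS_RATIOS))) ** (1 / 3)
    offset_mm = 0.35 * semi_mm * min(_AXIS_RATIOS)
    tumor_center = center + offset_dir * offset_mm / spec.spacing
    initial = seed_tumor(prostate, tumor_center, radius, peak, spec.spacing)

    gaps = [_uniform(rng, spec.gap_range_years) * DAYS_PER_YEAR
            for _ in range(spec.n_scans - 1)]
    times = np.concatenate([[0.0], np.cumsum(gaps)])

    states = [initial] + simulate(initial, grid, true, times[1:])

    cal = AdcCalibration(adc_h=1.0)
    adc_vols, gross_masks, tumor_masks = [], [], []
    true_density, gs_obs = [], []
    struct = _ball_offsets(spec.gross_margin_mm, spec.spacing)
    for state in states:
        nbar = state.nbar
        true_density.append(nbar.copy())
        adc = density_to_adc(nbar, cal)
        if spec.noise_sigma > 0:
            adc = adc + spec.noise_sigma * rng.standard_normal(adc.shape)
            adc = np.clip(adc, 1e-6, 1.2)
        adc_vols.append(ImageVolume(adc, spec.spacing))
        support = nbar > 0.02
        gross = ndimage.binary_dilation(support, structure=struct)
        gross_masks.append(Segmentation(gross & prostate.mask, "gross_tumor"))
        tumor_masks.append(Segmentation(nbar >= spec.nbar_th, "tumor_true"))
        panel = biomarker_panel(state, grid, true)
        risk = "higher_risk" if panel.a_p > spec.a_p_cutoff else "lower_risk"
        gs = (3, 4) if risk == "higher_risk" else (3, 3)
        gs_obs.append(GsObservation(time=state.t, primary=gs[0],
                                    secondary=gs[1]))

    series = ScanSeries(times=times, prostate=prostate, adc=adc_vols,
                        gross_masks=gross_masks, tumor_masks=tumor_masks,
                        density=[ImageVolume(d, spec.spacing)
                                 for d in true_density])
    return SyntheticPatient(
        patient_id=patient_id, true_params=true, series=series,
        gs_observations=gs_obs, true_density=true_density,
        adc_h=1.0, spacing=spec.spacing, dt=spec.dt,
    )


def _ball_offsets(margin_mm: float, spacing: float) -> np.ndarray:
    r = max(int(np.floor(margin_mm / spacing + 1e-9)), 0)
    ax = np.arange(-r, r + 1)
    ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
    return (ii**2 + jj**2 + kk**2) * spacing**2 <= margin_mm**2 + 1e-9


def generate_cohort(spec: CohortSpec) -> list[SyntheticPatient]:
    """Generate ``spec.n_patients`` patients reproducibly from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    return [generate_patient(spec, rng, patient_id=f"P{i:02d}")
            for i in range(spec.n_patients)]


# ---------------------------------------------------------------------------
# cohort directory I/O (NIfTI volumes + scans.json + cohort.csv manifest)
# ---------------------------------------------------------------------------

def write_cohort(cohort: list[SyntheticPatient], out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pat in cohort:
        pdir = out_dir / pat.patient_id
        pdir.mkdir(exist_ok=True)
        s = pat.series
        s.prostate.save(pdir / "prostate_mask.nii.gz", pat.spacing)
        meta = {
            "patient_id": pat.patient_id,
            "adc_h": pat.adc_h,
            "spacing_mm": pat.spacing,
            "dt_days": pat.dt,
            "times_days": s.times.tolist(),
            "true_params": {"d": pat.true_params.d,
                            "rho": pat.true_params.rho},
            "gs_observations": [
                {"time_days": g.time, "primary": g.primary,
                 "secondary": g.secondary, "risk": g.risk}
                for g in pat.gs_observations
            ],
        }
        for i in range(s.n_scans):
            s.adc[i].save(pdir / f"adc_{i}.nii.gz")
            s.gross_masks[i].save(pdir / f"gross_{i}.nii.gz", pat.spacing)
        with open(pdir / "scans.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
        rows.append((pat.patient_id, s.n_scans,
                     s.prostate.volume_cc(pat.spacing)))
    with open(out_dir / "cohort.csv", "w") as fh:
        fh.write("patient_id,n_scans,prostate_volume_cc\n")
        for pid, n, v in rows:
            fh.write(f"{pid},{n},{v:.6f}\n")
    return out_dir


def read_cohort(cohort_dir) -> list[dict]:
    """Read a cohort directory back as a list of per-patient dicts with
    keys ``patient_id, adc_h, spacing, dt, series, gs_observations,
    true_params`` (``series.density`` is left unset: preprocessing fills
    it from the ADC maps)."""
    cohort_dir = Path(cohort_dir)
    patients = []
    for pdir in sorted(p for p in cohort_dir.iterdir() if p.is_dir()):
        meta_path = pdir / "scans.json"
        if not meta_path.exists():
            continue
        meta = json.loads(meta_path.read_text())
        prostate = Segmentation.from_nifti(pdir / "prostate_mask.nii.gz",
                                           "prostate")
        times = np.asarray(meta["times_days"], dtype=float)
        adc = [ImageVolume.from_nifti(pdir / f"adc_{i}.nii.gz")
               for i in range(len(times))]
        gross = [Segmentation.from_nifti(pdir / f"gross_{i}.nii.gz",
                                         "gross_tumor")
                 for i in range(len(times))]
        series = ScanSeries(times=times, prostate=prostate, adc=adc,
                            gross_masks=gross)
        gs_obs = [GsObservation(time=g["time_days"], primary=g["primary"],
                                secondary=g["secondary"])
                  for g in meta["gs_observations"]]
        patients.append({
            "patient_id": meta["patient_id"],
            "adc_h": float(meta["adc_h"]),
            "spacing": float(meta["spacing_mm"]),
            "dt": float(meta["dt_days"]),
            "series": series,
            "gs_observations": gs_obs,
            "true_params": meta.get("true_params"),
        })
    return patients
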