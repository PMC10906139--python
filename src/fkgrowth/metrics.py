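"""Global and local model-data agreement metrics.

Global: tumor volume V_T and total tumor cell volume V_N (cc), computed on
the tumor region Omega_T = {nbar >= nbar_th} with nbar_th = 0.15, compared
patientwise across a cohort via Pearson (PCC) and Lin concordance (CCC)
correlation coefficients.  Local: Dice similarity coefficient of the tumor
regions plus RMSE/PCC/CCC of the density maps over the union of the
measured and simulated tumor regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np

__all__ = [
    "tumor_region",
    "tumor_volume",
    "total_cell_volume",
    "dice",
    "local_agreement",
    "cohort_concordance",
    "pearson",
    "concordance",
    "AgreementReport",
]

NBAR_TH = 0.15


def tumor_region(nbar: np.ndarray, nbar_th: float = NBAR_TH) -> np.ndarray:
    """Boolean tumor region Omega_T: voxels with nbar >= nbar_th."""
    return np.asarray(nbar) >= nbar_th


def tumor_volume(nbar: np.ndarray, spacing: float,
                 nbar_th: float = NBAR_TH) -> float:
    """V_T: volume of the tumor region, in cc."""
    return float(tumor_region(nbar, nbar_th).sum()) * spacing**3 / 1000.0


def total_cell_volume(nbar: np.ndarray, spacing: float,
                      nbar_th: float = NBAR_TH) -> float:
    """V_N: integral of nbar over the tumor region, in cc.  V_N <= V_T."""
    region = tumor_region(nbar, nbar_th)
    return float(np.asarray(nbar)[region].sum()) * spacing**3 / 1000.0


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|a&b|/(|a|+|b|); 1 if both empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks live on different grids")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN (with a warning) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        warnings.warn("Pearson correlation undefined for constant input",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def concordance(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient
    2*cov(x,y) / (var(x) + var(y) + (mean(x) - mean(y))^2).

    Satisfies |CCC| <= |PCC|; penalizes location and scale bias.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    denom = vx + vy + (x.mean() - y.mean()) ** 2
    if denom == 0:
        return 1.0 if np.allclose(x, y) else 0.0
    return float(2.0 * sxy / denom)


class LocalAgreement(NamedTuple):
    rmse: float
    pcc: float
    ccc: float


def local_agreement(meas: np.ndarray, model: np.ndarray,
                    support: np.ndarray) -> LocalAgreement:
    """Voxelwise RMSE/PCC/CCC of two density maps over a support mask
    (by convention the union of measured and simulated tumor regions)."""
    meas = np.asarray(meas, dtype=float)
    model = np.asarray(model, dtype=float)
    support = np.asarray(support).astype(bool)
    if not (meas.shape == model.shape == support.shape):
        raise ValueError("maps and support live on different grids")
    if support.sum() == 0:
        raise ValueError("empty evaluation support")
    x, y = meas[support], model[support]
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    return LocalAgreement(rmse=rmse, pcc=pearson(x, y), ccc=concordance(x, y))


def cohort_concordance(x, y) -> tuple[float, float]:
    """(PCC, CCC) of patientwise scalar pairs, e.g. measured vs modeled V_T."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length cohorts of size >= 3")
    return pearson(x, y), concordance(x, y)


@dataclass
class AgreementReport:
    """Per-patient, per-scan agreement row (volumes in cc, time in days)."""

    patient: str
    scenario: str
    scan_index: int
    time_days: float
    v_t_meas: float
    v_t_model: float
    v_n_meas: float
    v_n_model: float
    dsc: float
    rmse: float
    pcc: float
    ccc: float

    def to_dict(self) -> dict:
        return asdict(self)
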