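"""Model-based biomarkers of higher-risk prostate cancer and their
statistical evaluation.

Six candidate markers are computed from a personalized simulation at a time
point: prostate volume V_P (cc), tumor volume V_T (cc), total tumor cell
volume V_N (cc), mean normalized density nbar_mean = V_N / V_T, total tumor
index N_T = V_N / V_P, and mean proliferation activity
A_p = (1/V_T) * int_{Omega_T} rho * nbar * (1 - nbar) dx (1/day).

Subgroups (Gleason 3+3 "lower risk" vs >= 3+4 "higher risk") are compared
with Wilcoxon rank-sum / signed-rank tests computed by exact enumeration at
small sample sizes, and markers are turned into uni-/bivariate logistic
classifiers evaluated by trapezoidal-rule ROC analysis with the optimal
operating point at minimum distance to the (0, 1) corner.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from .metrics import tumor_region
from .solver import DensityState, GrowthParams, SimulationGrid

__all__ = [
    "BiomarkerPanel",
    "GsObservation",
    "RiskClassifier",
    "prostate_volume",
    "biomarker_panel",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "fit_logistic",
    "roc_analysis",
    "risk_trajectory",
]

EXACT_N_MAX = 12       # exact enumeration limit for both Wilcoxon tests
COEF_CAP = 30.0        # IRLS stops and flags separation past this norm
RISK_LABELS = ("lower_risk", "higher_risk")


# ---------------------------------------------------------------------------
# biomarker panel
# ---------------------------------------------------------------------------

@dataclass
class BiomarkerPanel:
    """Candidate marker values at one time point (volumes in cc)."""

    v_p: float
    v_t: float
    v_n: float
    nbar_mean: float
    n_t: float
    a_p: float
    time: float = 0.0
    gs_label: str = "none"

    def feature(self, name: str) -> float:
        if name not in ("v_p", "v_t", "v_n", "nbar_mean", "n_t", "a_p"):
            raise KeyError(f"unknown biomarker {name!r}")
        return getattr(self, name)


@dataclass
class GsObservation:
    """A histopathologic Gleason observation; risk follows the 3+3 vs
    >= 3+4 rule."""

    time: float
    primary: int
    secondary: int

    def __post_init__(self) -> None:
        if self.primary not in (3, 4, 5) or self.secondary not in (3, 4, 5):
            raise ValueError("Gleason patterns must be 3, 4 or 5")

    @property
    def risk(self) -> str:
        return "lower_risk" if (self.primary, self.secondary) == (3, 3) \
            else "higher_risk"


def prostate_volume(grid: SimulationGrid) -> float:
    """V_P: prostate-mask volume in cc."""
    return grid.prostate_volume_cc()


def biomarker_panel(state: DensityState, grid: SimulationGrid,
                    params: GrowthParams,
                    gs_label: str = "none") -> BiomarkerPanel:
    """Evaluate the six candidate markers on a density state.

    With an empty tumor region all tumor markers are zero.
    """
    voxvol = grid.voxel_volume
    v_p = grid.prostate_volume_cc()
    region = tumor_region(state.nbar, params.nbar_th) & grid.mask
    n_vox = int(region.sum())
    if n_vox == 0:
        return BiomarkerPanel(v_p=v_p, v_t=0.0, v_n=0.0, nbar_mean=0.0,
                              n_t=0.0, a_p=0.0, time=state.t,
                              gs_label=gs_label)
    vals = state.nbar[region]
    v_t = n_vox * voxvol / 1000.0
    v_n = float(vals.sum()) * voxvol / 1000.0
    a_p = float(params.rho * np.mean(vals * (1.0 - vals)))
    return BiomarkerPanel(
        v_p=v_p, v_t=v_t, v_n=v_n,
        nbar_mean=v_n / v_t, n_t=v_n / v_p, a_p=a_p,
        time=state.t, gs_label=gs_label,
    )


# ---------------------------------------------------------------------------
# Wilcoxon tests (exact enumeration at small n)
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    return _sps.rankdata(values, method="average")


def _tail_p(dist: np.ndarray, observed: float, alternative: str) -> float:
    """Tail probability of ``observed`` under the enumerated null ``dist``."""
    eps = 1e-9
    p_less = float(np.mean(dist <= observed + eps))
    p_greater = float(np.mean(dist >= observed - eps))
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    if alternative == "two_sided":
        return min(1.0, 2.0 * min(p_less, p_greater))
    raise ValueError(f"unknown alternative {alternative!r}")


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided") -> float:
    """Rank-sum (Mann-Whitney) test p-value; ``alternative`` refers to the
    location of ``x`` relative to ``y``.

    Exact permutation enumeration (midranks for ties) when the combined
    sample size is <= 12, normal approximation with tie correction
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    n1, n = len(x), len(pooled)
    w = float(ranks[:n1].sum())

    if n <= EXACT_N_MAX:
        dist = np.array([
            sum(ranks[i] for i in combo)
            for combo in itertools.combinations(range(n), n1)
        ])
        return _tail_p(dist, w, alternative)

    # normal approximation with midrank tie correction
    n2 = n - n1
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1.0)))
    if var == 0:
        return 1.0
    if alternative == "less":
        z = (w - mu + 0.5) / math.sqrt(var)
        return float(_sps.norm.cdf(z))
    if alternative == "greater":
        z = (w - mu - 0.5) / math.sqrt(var)
        return float(_sps.norm.sf(z))
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    return float(2.0 * _sps.norm.sf(z))


def wilcoxon_signed_rank(x, y, alternative: str = "two_sided") -> float:
    """Paired signed-rank test p-value (``alternative`` on x - y); zero
    differences dropped.  Exact sign enumeration for <= 12 nonzero pairs,
    normal approximation with tie correction otherwise.  Returns 1.0 when
    all differences are zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = _midranks(np.abs(d))
    w_pos = float(ranks[d > 0].sum())

    if n <= EXACT_N_MAX:
        dist = np.array([
            sum(ranks[i] for i in range(n) if signs & (1 << i))
            for signs in range(2**n)
        ])
        # positive differences (x > y) push w_pos up
        flip = {"less": "less", "greater": "greater",
                "two_sided": "two_sided"}[alternative]
        return _tail_p(dist, w_pos, flip)

    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie = np.sum(counts**3 - counts)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie / 48.0
    if alternative == "less":
        z = (w_pos - mu + 0.5) / math.sqrt(var)
        return float(_sps.norm.cdf(z))
    if alternative == "greater":
        z = (w_pos - mu - 0.5) / math.sqrt(var)
        return float(_sps.norm.sf(z))
    z = (abs(w_pos - mu) - 0.5) / math.sqrt(var)
    return float(2.0 * _sps.norm.sf(z))


# ---------------------------------------------------------------------------
# logistic risk classifier and ROC analysis
# ---------------------------------------------------------------------------

@dataclass
class RiskClassifier:
    """Fitted logistic risk model with its ROC analysis.

    ``coef`` is (intercept, w_1[, w_2]); scores are probabilities of the
    higher-risk class.  ``optimal_point`` is (sensitivity, specificity,
    probability threshold) at the ROC vertex closest to the (0, 1) corner.
    """

    features: tuple[str, ...]
    coef: np.ndarray
    separated: bool = False
    fpr: np.ndarray = field(default_factory=lambda: np.array([]))
    tpr: np.ndarray = field(default_factory=lambda: np.array([]))
    auc: float = float("nan")
    optimal_point: tuple[float, float, float] = (np.nan, np.nan, np.nan)

    def linear_score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.coef[0] + X @ self.coef[1:]

    def predict_proba(self, X) -> np.ndarray:
        z = self.linear_score(X)
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

    def panel_proba(self, panel: BiomarkerPanel) -> float:
        x = np.array([[panel.feature(f) for f in self.features]])
        return float(self.predict_proba(x)[0])

    def to_dict(self) -> dict:
        sens, spec, thr = self.optimal_point
        return {
            "features": list(self.features),
            "coef": [float(c) for c in self.coef],
            "separated": bool(self.separated),
            "auc": float(self.auc),
            "roc": {"fpr": self.fpr.tolist(), "tpr": self.tpr.tolist()},
            "optimal_point": {"sensitivity": float(sens),
                              "specificity": float(spec),
                              "threshold": float(thr)},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fpr, self.tpr, marker=".", label=f"AUC = {self.auc:.2f}")
        ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
        sens, spec, _ = self.optimal_point
        ax.plot(1 - spec, sens, "o", c="crimson", label="optimal point")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax


def _irls_logistic(X: np.ndarray, y: np.ndarray,
                   cap: float = COEF_CAP,
                   tol: float = 1e-10, max_iter: int = 200):
    """Maximum-likelihood logistic fit by iteratively reweighted least
    squares; stops with ``separated=True`` when coefficients exceed ``cap``
    in infinity norm (quasi-separation)."""
    n, k = X.shape
    A = np.column_stack([np.ones(n), X])
    beta = np.zeros(k + 1)
    ll_old = -np.inf
    separated = False
    for _ in range(max_iter):
        z = np.clip(A @ beta, -500, 500)
        p = 1.0 / (1.0 + np.exp(-z))
        W = np.maximum(p * (1 - p), 1e-12)
        grad = A.T @ (y - p)
        H = (A * W[:, None]).T @ A + 1e-10 * np.eye(k + 1)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(beta)) > cap:
            beta = beta * (cap / np.max(np.abs(beta)))
            separated = True
            break
        ll = float(np.sum(y * z - np.log1p(np.exp(z))))
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return beta, separated


def fit_logistic(panels, labels=None, features=("a_p",),
                 cap: float = COEF_CAP) -> RiskClassifier:
    """Fit a 1- or 2-marker logistic risk classifier on biomarker panels
    and attach its ROC analysis.

    ``labels`` defaults to the panels' ``gs_label`` fields; both classes
    must be present with at least two observations each.
    """
    features = tuple(features)
    if not 1 <= len(features) <= 2:
        raise ValueError("classifiers use one or two markers")
    X = np.array([[p.feature(f) for f in features] for p in panels])
    if labels is None:
        labels = [p.gs_label for p in panels]
    y = np.array([1.0 if lab == "higher_risk" else 0.0 for lab in labels])
    for cls in (0.0, 1.0):
        if np.sum(y == cls) < 2:
            raise ValueError("need at least two observations per risk class")
    # standardize internally for IRLS conditioning; report raw-scale coefs
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    beta_std, separated = _irls_logistic((X - mu) / sd, y, cap=cap)
    w = beta_std[1:] / sd
    coef = np.concatenate([[beta_std[0] - np.sum(mu * w)], w])

    clf = RiskClassifier(features=features, coef=coef, separated=separated)
    scores = clf.predict_proba(X)
    fpr, tpr, auc, opt = roc_analysis(scores, y)
    clf.fpr, clf.tpr, clf.auc, clf.optimal_point = fpr, tpr, auc, opt
    return clf


def roc_analysis(scores, labels):
    """ROC curve, trapezoidal AUC and the optimal operating point.

    Higher score implies a higher-risk call.  Thresholds sweep the distinct
    scores (plus +inf for the (0, 0) endpoint); the optimal point is the
    ROC vertex at minimum Euclidean distance to (fpr, tpr) = (0, 1), ties
    broken toward higher sensitivity.

    Returns ``(fpr, tpr, auc, (sensitivity, specificity, threshold))``.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    pos, neg = np.sum(y == 1), np.sum(y == 0)
    if pos == 0 or neg == 0:
        raise ValueError("ROC analysis needs both classes present")
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    fpr = np.empty(len(thresholds))
    tpr = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        call = scores >= thr
        tpr[i] = np.sum(call & (y == 1)) / pos
        fpr[i] = np.sum(call & (y == 0)) / neg
    auc = float(np.trapezoid(tpr, fpr))
    d2 = fpr**2 + (1.0 - tpr) ** 2
    best = np.lexsort((-tpr, d2))[0]  # min distance, then max sensitivity
    optimal = (float(tpr[best]), float(1.0 - fpr[best]),
               float(thresholds[best]))
    return fpr, tpr, auc, optimal


def risk_trajectory(states, grid: SimulationGrid, params: GrowthParams,
                    classifier: RiskClassifier):
    """Classifier probability along a simulated density trajectory.

    Returns ``(times, probabilities, crossing_time)`` where
    ``crossing_time`` is the first time the probability reaches the optimal
    operating threshold (None if never).
    """
    times, probs = [], []
    for state in states:
        panel = biomarker_panel(state, grid, params)
        times.append(state.t)
        probs.append(classifier.panel_proba(panel))
    times = np.asarray(times)
    probs = np.asarray(probs)
    thr = classifier.optimal_point[2]
    crossing = None
    if np.isfinite(thr):
        above = np.nonzero(probs >= thr)[0]
        if len(above):
            crossing = float(times[above[0]])
    return times, probs, crossing
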