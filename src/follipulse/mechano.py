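"""Cortical F-actin / nuclear-YAP quantification and the telogen-anagen state score.

In quiescent (telogen) hair germs, cortical F-actin is strong and YAP sits in
the cytoplasm; at anagen onset the cortex weakens and YAP moves into nuclei.
Per cell we carry two numbers: a cortical F-actin score from a line profile
crossing the cell boundary, and the nuclear/cytoplasmic YAP intensity ratio.

Two statistics operate on these records:

* a seeded permutation test for the inverse correlation between the two
  (rank-based statistic, shuffle one variable, add-one p-value), and
* a combined state score z(YAP ratio) - z(F-actin) whose sign calls
  anagen (> 0) versus telogen (< 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, InsufficientDataError, ValidationError

STATE_TELOGEN = "telogen"
STATE_ANAGEN = "anagen"


@dataclass
class IntensityProfile:
    """Intensity sampled along a line from cell interior out across the membrane."""

    positions_um: np.ndarray
    intensities_au: np.ndarray

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensities_au = np.asarray(self.intensities_au, dtype=float)
        if self.positions_um.size != self.intensities_au.size:
            raise ValidationError("positions and intensities must match in length")
        if self.positions_um.size < 10:
            raise ValidationError("line profiles need at least 10 samples")
        if np.any(self.intensities_au < 0):
            raise ValidationError("intensities must be non-negative")


@dataclass(frozen=True)
class CellMechRecord:
    cell_id: str
    stage: str  # telogen | anagen
    factin_au: float
    yap_ratio: float

    def __post_init__(self) -> None:
        if self.yap_ratio <= 0:
            raise ValidationError("yap_ratio must be positive")


@dataclass(frozen=True)
class CorrelationTestResult:
    statistic: float
    n_resamples: int
    p_value: float
    seed: int
    statistic_kind: str
    alternative: str


@dataclass(frozen=True)
class StateCalibration:
    """Pooled means/SDs used to standardize both variables."""

    factin_mean: float
    factin_sd: float
    yap_mean: float
    yap_sd: float


@dataclass(frozen=True)
class StateScore:
    score: float
    predicted_state: str  # telogen | anagen | unassigned
    z_factin: float
    z_yap: float


def cortical_score(
    profile: IntensityProfile,
    boundary_fraction: float = 0.2,
    interior_window: tuple[float, float] = (0.3, 0.7),
) -> float:
    """Peak boundary intensity minus median interior intensity (a.u.).

    The boundary window is the outer ``boundary_fraction`` of the line at the
    membrane end; the interior window defaults to the central 40%.
    """
    n = profile.intensities_au.size
    n_boundary = max(int(round(boundary_fraction * n)), 1)
    lo = int(interior_window[0] * n)
    hi = int(interior_window[1] * n)
    if hi <= lo or n_boundary >= n:
        raise ValidationError("profile too short for the configured windows")
    boundary = profile.intensities_au[n - n_boundary :]
    interior = profile.intensities_au[lo:hi]
    return float(boundary.max() - np.median(interior))


def yap_nuclear_ratio(nuclear_au: float, cytoplasmic_au: float) -> float:
    """Nuclear / cytoplasmic YAP intensity."""
    if cytoplasmic_au <= 0:
        raise ValidationError("cytoplasmic intensity must be positive")
    return float(nuclear_au) / float(cytoplasmic_au)


def _correlation(x: np.ndarray, y: np.ndarray, kind: str) -> float:
    if kind == "spearman":
        x, y = sps.rankdata(x), sps.rankdata(y)
    elif kind != "pearson":
        raise ValidationError("statistic must be 'spearman' or 'pearson'")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


def permutation_inverse_correlation(
    records,
    n_resamples: int = 1000,
    seed: int = 0,
    statistic: str = "spearman",
    alternative: str = "less",
) -> CorrelationTestResult:
    """Permutation test for (inverse) correlation between F-actin and YAP ratio.

    The YAP column is shuffled ``n_resamples`` times against the F-actin
    column; with the default one-sided alternative "less" the p-value is
    (1 + #{r_perm <= r_obs}) / (n_resamples + 1), so p >= 1/(n_resamples+1).
    """
    factin = np.array([r.factin_au for r in records], dtype=float)
    yap = np.array([r.yap_ratio for r in records], dtype=float)
    if factin.size < 5:
        raise InsufficientDataError("need at least 5 records")
    if np.all(factin == factin[0]) or np.all(yap == yap[0]):
        raise DegenerateInputError("constant variable: correlation undefined")

    if statistic == "spearman":
        x, y = sps.rankdata(factin), sps.rankdata(yap)
    else:
        x, y = factin, yap
    r_obs = _correlation(x, y, "pearson")

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(y, (n_resamples, 1)), axis=1)
    xc = x - x.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    num = pc @ xc
    den = np.sqrt(np.einsum("ij,ij->i", pc, pc) * np.dot(xc, xc))
    r_perm = num / den

    if alternative == "less":
        extreme = int(np.sum(r_perm <= r_obs))
    elif alternative == "greater":
        extreme = int(np.sum(r_perm >= r_obs))
    elif alternative == "two-sided":
        extreme = int(np.sum(np.abs(r_perm) >= abs(r_obs)))
    else:
        raise ValidationError("alternative must be less/greater/two-sided")
    p = (1 + extreme) / (n_resamples + 1)
    return CorrelationTestResult(r_obs, n_resamples, p, seed, statistic, alternative)


def fit_state_calibration(records) -> StateCalibration:
    """Pooled means/SDs of both variables from labeled reference cells."""
    factin = np.array([r.factin_au for r in records], dtype=float)
    yap = np.array([r.yap_ratio for r in records], dtype=float)
    if factin.size < 2:
        raise InsufficientDataError("calibration needs at least 2 records")
    sd_f, sd_y = factin.std(ddof=1), yap.std(ddof=1)
    if sd_f == 0 or sd_y == 0:
        raise DegenerateInputError("constant variable: cannot standardize")
    return StateCalibration(float(factin.mean()), float(sd_f), float(yap.mean()), float(sd_y))


def combined_state_score(record: CellMechRecord, calibration: StateCalibration) -> StateScore:
    """score = z(YAP ratio) - z(F-actin); > 0 -> anagen, < 0 -> telogen."""
    if calibration is None:
        raise ValidationError("missing calibration")
    z_f = (record.factin_au - calibration.factin_mean) / calibration.factin_sd
    z_y = (record.yap_ratio - calibration.yap_mean) / calibration.yap_sd
    score = z_y - z_f
    state = STATE_ANAGEN if score > 0 else STATE_TELOGEN if score < 0 else "unassigned"
    return StateScore(float(score), state, float(z_f), float(z_y))


def _fit_logistic(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Two-feature logistic regression (anagen = 1) by Newton iterations."""
    design = np.column_stack([np.ones(len(labels)), x])
    beta = np.zeros(design.shape[1])
    for _ in range(50):
        p = 1.0 / (1.0 + np.exp(-design @ beta))
        w = np.clip(p * (1 - p), 1e-9, None)
        hessian = design.T @ (design * w[:, None]) + 1e-6 * np.eye(design.shape[1])
        step = np.linalg.solve(hessian, design.T @ (labels - p))
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def evaluate_state_classifier(records, model: str = "score") -> dict[str, object]:
    """Leave-one-out accuracy and confusion counts.

    model="score" uses the standardized difference score (default);
    model="logistic" fits a two-feature logistic regression instead.
    """
    records = list(records)
    stages = {r.stage for r in records}
    if len(stages) < 2:
        raise ValidationError("evaluation needs both telogen and anagen cells")
    if model not in ("score", "logistic"):
        raise ValidationError("model must be 'score' or 'logistic'")
    features = np.array([[r.factin_au, r.yap_ratio] for r in records])
    labels = np.array([1.0 if r.stage == STATE_ANAGEN else 0.0 for r in records])
    confusion = {(a, b): 0 for a in sorted(stages) for b in sorted(stages) + ["unassigned"]}
    correct = 0
    for i, rec in enumerate(records):
        rest = records[:i] + records[i + 1 :]
        if model == "score":
            cal = fit_state_calibration(rest)
            pred = combined_state_score(rec, cal).predicted_state
        else:
            mask = np.arange(len(records)) != i
            beta = _fit_logistic(features[mask], labels[mask])
            p = 1.0 / (1.0 + np.exp(-(beta[0] + features[i] @ beta[1:])))
            pred = STATE_ANAGEN if p > 0.5 else STATE_TELOGEN if p < 0.5 else "unassigned"
        confusion[(rec.stage, pred)] = confusion.get((rec.stage, pred), 0) + 1
        if pred == rec.stage:
            correct += 1
    return {
        "accuracy": correct / len(records),
        "n": len(records),
        "confusion": confusion,
        "model": model,
    }
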