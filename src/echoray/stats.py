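"""Hand-implemented evaluation statistics: ROC analysis and Welch's t-test.

ROC analysis computes the AUC by Mann-Whitney pair counting (ties count 1/2),
its standard error by the Hanley-McNeil formula, and a cut-off maximising the
Youden index (sensitivity + specificity - 1) over candidate thresholds taken
at midpoints between adjacent distinct pooled values, with +-infinity
sentinels; ties in the Youden index are broken toward higher specificity.

Welch's t-test compares two groups without assuming equal variances:

    t  = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b)

with Welch-Satterthwaite degrees of freedom and a two-sided p-value from the
t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from echoray.errors import DomainError


@dataclass(frozen=True)
class TwoGroupSample:
    """Two groups of measurements of a common quantity."""

    group_a: tuple[float, ...]
    group_b: tuple[float, ...]
    label_a: str = "a"
    label_b: str = "b"
    units: str = ""

    def __post_init__(self):
        for name, grp in (("group_a", self.group_a), ("group_b", self.group_b)):
            if len(grp) == 0:
                raise DomainError(f"{name} must be nonempty")
            if not all(np.isfinite(v) for v in grp):
                raise DomainError(f"{name} contains non-finite values")


@dataclass(frozen=True)
class RocResult:
    """ROC summary: AUC with SE/CI, Youden-optimal cut-off, Se/Sp (fractions)."""

    auc: float
    se: float
    ci95: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str


def _score(values: np.ndarray, direction: str) -> np.ndarray:
    if direction == "greater":
        return values
    if direction == "less":
        return -values
    raise DomainError(f"direction must be 'greater' or 'less', got {direction!r}")


def roc_analysis(
    cases: Sequence[float],
    controls: Sequence[float],
    direction: str = "greater",
) -> RocResult:
    """ROC analysis of a continuous marker separating cases from controls.

    ``direction`` states which way the marker moves in cases: ``"greater"``
    if cases are expected higher, ``"less"`` if lower (e.g. a strain measure
    that becomes more negative with disease).  The reported cut-off is on the
    original scale of the marker.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise DomainError("both groups must be nonempty")

    cs = _score(cases, direction)
    ct = _score(controls, direction)
    n1, n0 = len(cs), len(ct)

    # Mann-Whitney pair counting: case scored above control wins, ties half
    diff = cs[:, None] - ct[None, :]
    auc = float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (n1 * n0))

    # Hanley-McNeil standard error
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    se = float(np.sqrt(max(var, 0.0)))
    ci95 = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))

    # Youden-optimal cut-off over midpoints of adjacent distinct pooled scores
    pooled = np.unique(np.concatenate([cs, ct]))
    candidates = np.concatenate([[-np.inf], (pooled[:-1] + pooled[1:]) / 2.0, [np.inf]])
    best = None
    for c in candidates:
        sens = float(np.mean(cs > c))
        spec = float(np.mean(ct <= c))
        youden = sens + spec - 1.0
        if best is None or youden > best[0] + 1e-12 or (
            abs(youden - best[0]) <= 1e-12 and spec > best[2]
        ):
            best = (youden, sens, spec, c)
    _, sensitivity, specificity, cutoff_score = best

    # map the score-scale cut-off back to the marker's original scale
    cutoff = cutoff_score if direction == "greater" else -cutoff_score
    return RocResult(auc, se, ci95, float(cutoff), sensitivity, specificity, direction)


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample comparison: t statistic, degrees of freedom, two-sided p."""

    t: float
    df: float
    p: float


def welch_test(sample: TwoGroupSample) -> WelchResult:
    """Welch's unequal-variance t-test on a :class:`TwoGroupSample`."""
    a = np.asarray(sample.group_a, dtype=float)
    b = np.asarray(sample.group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DomainError("each group needs at least 2 values for a variance estimate")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    num = a.mean() - b.mean()
    denom2 = va / na + vb / nb
    if denom2 == 0:
        # both groups constant: identical means give t = 0, p = 1
        if num == 0:
            return WelchResult(0.0, float(na + nb - 2), 1.0)
        t = np.inf if num > 0 else -np.inf
        return WelchResult(float(t), float(na + nb - 2), 0.0)
    t = num / np.sqrt(denom2)
    df = denom2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))
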