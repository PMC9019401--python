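"""qPCR amplification model and ELISA standard-series handling.

PCR amplification is exponential below a plateau: after n cycles the product
count is Y_n = X * (1 + E)^n, with initial template count X and per-cycle
efficiency E in [0, 1].  The exponential regime only holds for a limited
number of cycles (typically 20-30); beyond ``plateau_cycle`` the product
count is capped at its plateau value.

Relative expression between conditions is the standard 2^-ddCt double
difference of threshold cycles, assuming efficiency-2 amplification.

ELISA standards are serial dilution series: a top standard repeatedly diluted
by a fixed factor, terminated by a blank (concentration 0).  Sample
concentrations are recovered by monotone log-linear interpolation between the
bracketing standards of a measured response curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from echoray.errors import CalibrationError, ConfigurationError, DomainError


@dataclass(frozen=True)
class AmplificationModel:
    """Exponential PCR amplification with a hard plateau cap.

    Parameters
    ----------
    x0
        Initial template molecule count X (> 0).
    efficiency
        Per-cycle fractional gain E in [0, 1] (E = 1 is perfect doubling).
    plateau_cycle
        Cycle beyond which no further amplification occurs (default 30).
    """

    x0: float
    efficiency: float
    plateau_cycle: int = 30

    def __post_init__(self):
        if self.x0 <= 0:
            raise DomainError(f"x0 must be > 0, got {self.x0}")
        if not 0 <= self.efficiency <= 1:
            raise DomainError(f"efficiency must be in [0, 1], got {self.efficiency}")
        if self.plateau_cycle < 1:
            raise DomainError(f"plateau_cycle must be >= 1, got {self.plateau_cycle}")


def amplify(model: AmplificationModel, n: int) -> float:
    """Expected product count after n cycles: Y_n = X * (1 + E)^min(n, plateau).

    Satisfies the per-cycle recursion Y_n = Y_{n-1} * (1 + E) below the
    plateau and is constant beyond it.
    """
    if n < 0 or int(n) != n:
        raise DomainError(f"cycle count must be a non-negative integer, got {n}")
    eff_cycles = min(int(n), model.plateau_cycle)
    # iterated product rather than a power so the per-cycle recursion holds
    # bitwise in floating point; the cycle count is small by construction
    y = model.x0
    for _ in range(eff_cycles):
        y *= 1.0 + model.efficiency
    return y


def fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,control - Ct_ref,control);
    returns 2^-ddCt (1 when the normalised threshold cycles match).
    """
    cts = (ct_target_case, ct_ref_case, ct_target_control, ct_ref_control)
    if not all(np.isfinite(c) for c in cts):
        raise DomainError(f"all Ct values must be finite, got {cts}")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))


@dataclass(frozen=True)
class StandardSeries:
    """An ELISA standard series: concentrations strictly decreasing, ending in a blank 0."""

    analyte: str
    concentrations: tuple[float, ...]

    def __post_init__(self):
        c = self.concentrations
        if len(c) < 2:
            raise ConfigurationError("a standard series needs at least one standard plus a blank")
        if c[-1] != 0:
            raise ConfigurationError(f"series must end in a blank 0, got {c[-1]}")
        non_blank = c[:-1]
        if any(x <= 0 for x in non_blank):
            raise ConfigurationError("non-blank standards must be > 0")
        if any(b <= a for a, b in zip(non_blank[1:], non_blank[:-1])):
            raise ConfigurationError(f"concentrations must be strictly decreasing: {non_blank}")

    @property
    def non_blank(self) -> tuple[float, ...]:
        return self.concentrations[:-1]


def standard_series(
    analyte: str, top: float, dilution_factor: float = 2.0, levels: int = 7
) -> StandardSeries:
    """Geometric serial-dilution series [top, top/f, ..., top/f^(levels-1), 0].

    For non-geometric panels use :class:`StandardSeries` directly with the
    explicit concentration list.
    """
    if top <= 0:
        raise ConfigurationError(f"top standard must be > 0, got {top}")
    if dilution_factor <= 1:
        raise ConfigurationError(f"dilution_factor must be > 1, got {dilution_factor}")
    if levels < 1:
        raise ConfigurationError(f"levels must be >= 1, got {levels}")
    concs = tuple(top / dilution_factor**i for i in range(levels)) + (0.0,)
    return StandardSeries(analyte, concs)


@dataclass(frozen=True)
class CalibrationResult:
    """Back-calculated concentration and a range flag."""

    concentration: float
    flag: str  # "ok", "below_blank", "above_range", "below_range"


def calibrate(
    series: StandardSeries,
    standard_responses: Sequence[float],
    sample_response: float,
) -> CalibrationResult:
    """Back-calculate a concentration from a measured standard curve.

    The responses must be strictly monotone in concentration over the
    non-blank standards.  Interpolation is log-linear (log concentration vs.
    log response) between the bracketing standards, so a response at the
    geometric midpoint of two standards' responses maps to the geometric
    midpoint of their concentrations.  Responses at a standard return that
    standard's concentration exactly; responses below the blank return 0
    flagged ``below_blank``; responses above the top standard are flagged
    ``above_range`` (the value is the log-linear extrapolation capped at the
    top standard); responses between the blank and the lowest standard are
    interpolated linearly in concentration and flagged ``below_range``.
    """
    responses = np.asarray(standard_responses, dtype=float)
    concs = np.asarray(series.concentrations, dtype=float)
    if responses.shape != concs.shape:
        raise CalibrationError(
            f"expected {len(concs)} responses (one per standard incl. blank), got {len(responses)}"
        )
    nb_resp = responses[:-1]  # highest concentration first
    nb_conc = concs[:-1]
    diffs = np.diff(nb_resp)
    if np.all(diffs < 0):
        increasing = True  # responses increase with concentration
    elif np.all(diffs > 0):
        increasing = False
    else:
        i = int(np.argmax(diffs >= 0) if diffs[0] < 0 else np.argmax(diffs <= 0))
        raise CalibrationError(
            "standard responses are not strictly monotone in concentration: "
            f"levels {i} and {i + 1} have responses {nb_resp[i]} and {nb_resp[i + 1]}"
        )
    blank_resp = float(responses[-1])

    # orient so that signal increases with concentration
    sign = 1.0 if increasing else -1.0
    s = sign * sample_response
    s_nb = sign * nb_resp  # decreasing with index (conc decreasing)
    s_blank = sign * blank_resp

    if s < s_blank:
        return CalibrationResult(0.0, "below_blank")
    if s > s_nb[0]:
        return CalibrationResult(float(nb_conc[0]), "above_range")
    # exact node matches (including the blank)
    exact = np.isclose(s, s_nb, rtol=0, atol=0)
    if exact.any():
        return CalibrationResult(float(nb_conc[int(np.argmax(exact))]), "ok")
    if s == s_blank:
        return CalibrationResult(0.0, "ok")
    if s < s_nb[-1]:
        # between blank and lowest standard: linear in concentration
        frac = (s - s_blank) / (s_nb[-1] - s_blank)
        return CalibrationResult(float(frac * nb_conc[-1]), "below_range")
    # bracketing standards, log-log interpolation
    # s_nb is decreasing; find i with s_nb[i+1] <= s <= s_nb[i]
    i = int(np.searchsorted(-s_nb, -s, side="left")) - 1
    lo_r, hi_r = s_nb[i + 1], s_nb[i]
    lo_c, hi_c = nb_conc[i + 1], nb_conc[i]
    if lo_r <= 0 or s <= 0:
        # non-positive signal cannot be log-interpolated; fall back to linear
        frac = (s - lo_r) / (hi_r - lo_r)
        return CalibrationResult(float(lo_c + frac * (hi_c - lo_c)), "ok")
    frac = (np.log(s) - np.log(lo_r)) / (np.log(hi_r) - np.log(lo_r))
    conc = np.exp(np.log(lo_c) + frac * (np.log(hi_c) - np.log(lo_c)))
    return CalibrationResult(float(conc), "ok")
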