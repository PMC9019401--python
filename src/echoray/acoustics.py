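"""Acoustic kernels: impedance, reflection, transmittance, depth attenuation.

The model
---------
Acoustic impedance is Q = rho * V.  At an interface between media with
impedances Q1, Q2 the specular reflection coefficient is the squared
impedance-mismatch ratio K = ((Q2 - Q1) / (Q2 + Q1))^2, and the diffuse
variant multiplies it by cos^n(theta) for incidence angle theta.

When the medium is given as an attenuation field delta(x) instead of
impedance, the gradient of delta plays the role of the impedance jump:

* reflection   R(x) = max(0, d . grad/|grad|) * (|grad| / (2 max delta))^n
* transmission t(x) = 1 - (|grad| / (2 max delta))^2
* attenuation  I(L)/I0 = exp(- int_0^L (|grad(x + s d)| / (2 max delta))^2 ds)

with d the unit beam direction and max delta the volume-wide maximum (cached
on the volume).  The cosine factor is clamped at zero so back-facing
interfaces do not reflect toward the probe.  The transmittance keeps the
squared normaliser for every n; only the reflection kernel carries the
exponent.  The attenuation integral is discretised with the midpoint rule at
the ray step, sampling grad delta by trilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from echoray.errors import DomainError
from echoray.volume import AttenuationVolume

#: Gradient magnitudes below this are treated as exactly zero (no interface).
GRAD_EPS = 1e-12


@dataclass(frozen=True)
class MediumPoint:
    """Local acoustic properties: density rho (kg/m^3), sound speed v (m/s)."""

    rho: float
    v: float

    def __post_init__(self):
        if self.rho < 0 or self.v < 0:
            raise DomainError(f"rho and v must be >= 0, got rho={self.rho}, v={self.v}")

    @property
    def q(self) -> float:
        """Acoustic impedance Q = rho * v (kg m^-2 s^-1)."""
        return self.rho * self.v


@dataclass(frozen=True)
class Ray:
    """A marching ray: origin (mm), unit direction, step increment lambda (mm)."""

    origin: tuple[float, float, float]
    direction: tuple[float, float, float]
    step: float = 0.25

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise DomainError(f"direction must be a unit vector, got norm {np.linalg.norm(d)}")
        if self.step <= 0:
            raise DomainError(f"step must be > 0, got {self.step}")

    def at(self, depth: float | np.ndarray) -> np.ndarray:
        """Physical point(s) at the given depth(s) along the ray."""
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        depth = np.asarray(depth, dtype=float)
        return o + depth[..., None] * d if depth.ndim else o + depth * d


@dataclass
class RayState:
    """Running state along a march: both ratios start at 1 and never increase."""

    depth: float = 0.0
    intensity_ratio: float = 1.0
    cumulative_transmittance: float = 1.0


def acoustic_impedance(rho: float, v: float) -> float:
    """Q = rho * v; impedance of a medium with density rho and sound speed v."""
    if rho < 0 or v < 0:
        raise DomainError(f"rho and v must be >= 0, got rho={rho}, v={v}")
    return rho * v


def specular_reflection(q1: float, q2: float) -> float:
    """Specular reflection coefficient K = ((Q2 - Q1) / (Q2 + Q1))^2.

    Symmetric in its arguments, 0 for matched impedance, in [0, 1).
    """
    if q1 < 0 or q2 < 0:
        raise DomainError(f"impedances must be >= 0, got ({q1}, {q2})")
    if q1 + q2 == 0:
        raise DomainError("q1 + q2 must be > 0")
    return ((q2 - q1) / (q2 + q1)) ** 2


def diffuse_reflection(q1: float, q2: float, theta: float, n: float) -> float:
    """Diffuse reflection R = cos^n(theta) * ((Q2 - Q1) / (Q2 + Q1))^2.

    The exponent n models how strongly the reflectance at a tissue interface
    falls off with incidence angle; theta is in radians on [0, pi/2].
    """
    if not 0 <= theta <= np.pi / 2:
        raise DomainError(f"theta must be in [0, pi/2], got {theta}")
    if n < 0:
        raise DomainError(f"n must be >= 0, got {n}")
    return float(np.cos(theta) ** n) * specular_reflection(q1, q2)


def _normalized_gradient_terms(
    volume: AttenuationVolume, positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(gradient vectors, |grad|/(2 max delta)) at physical positions."""
    grads = volume.sample_gradient(positions)
    mags = np.linalg.norm(grads, axis=1)
    if volume.max_delta <= 0:
        raise DomainError("volume max_delta must be > 0 for acoustic kernels")
    return grads, mags / (2.0 * volume.max_delta)


def gradient_reflection(
    volume: AttenuationVolume,
    position,
    direction,
    n: float = 1.0,
) -> float:
    """Reflection toward the probe from the local attenuation gradient.

    R = (d . grad/|grad|) * (|grad| / (2 max delta))^n, clamped below at 0.
    Zero wherever the gradient vanishes, is orthogonal to the beam, or faces
    away from it.
    """
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    grads, norm_mag = _normalized_gradient_terms(volume, pos)
    grad = grads[0]
    mag = float(np.linalg.norm(grad))
    if mag < GRAD_EPS:
        return 0.0
    d = np.asarray(direction, dtype=float)
    cosine = float(np.dot(d, grad) / mag)
    if cosine <= 0.0:
        return 0.0
    return cosine * float(norm_mag[0]) ** n


def transmittance(volume: AttenuationVolume, position) -> float:
    """Interface transmittance t = 1 - (|grad delta| / (2 max delta))^2.

    Equals 1 in homogeneous regions; 0 at the extreme |grad| = 2 max delta.
    """
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    _, norm_mag = _normalized_gradient_terms(volume, pos)
    return float(np.clip(1.0 - norm_mag[0] ** 2, 0.0, 1.0))


def attenuation_ratio(volume: AttenuationVolume, ray: Ray, depth: float) -> float:
    """Remaining intensity fraction I/I0 after travelling ``depth`` mm.

    exp(- int_0^depth (|grad delta| / (2 max delta))^2 ds), midpoint rule at
    the ray step (final partial step shortened to land exactly on ``depth``).
    """
    if depth < 0:
        raise DomainError(f"depth must be >= 0, got {depth}")
    if depth == 0:
        return 1.0
    _check_segment_inside(volume, ray, depth)
    integral = _attenuation_integral(volume, ray, 0.0, depth)
    return float(np.exp(-integral))


def _check_segment_inside(volume: AttenuationVolume, ray: Ray, depth: float) -> None:
    for probe in (0.0, depth):
        if not volume.contains(ray.at(probe)):
            raise DomainError(
                f"ray segment exits the volume at depth {probe:.4g} mm "
                f"(requested [0, {depth:.4g}] mm)"
            )


def _attenuation_integral(
    volume: AttenuationVolume, ray: Ray, start: float, stop: float
) -> float:
    """Midpoint-rule integral of (|grad|/(2 max delta))^2 over [start, stop]."""
    length = stop - start
    if length <= 0:
        return 0.0
    n_full = int(length // ray.step)
    seg_lengths = [ray.step] * n_full
    remainder = length - n_full * ray.step
    if remainder > 1e-12:
        seg_lengths.append(remainder)
    seg_lengths = np.asarray(seg_lengths)
    edges = start + np.concatenate([[0.0], np.cumsum(seg_lengths)])
    mids = (edges[:-1] + edges[1:]) / 2.0
    positions = ray.at(mids)
    _, norm_mag = _normalized_gradient_terms(volume, positions)
    return float(np.sum(norm_mag**2 * seg_lengths))
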