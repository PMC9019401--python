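"""Beam marching and B-mode rendering.

Each beam is marched through the attenuation volume at a fixed step.  At
sample k the echo amplitude combines the three acoustic factors:

    incident_k = attenuation_ratio(depth_k) * prod_{j<k} t_j
    echo_k     = incident_k * R_k

i.e. the beam is attenuated by the depth integral and loses a further factor
t at every interface it has already crossed; the echo is the reflected share
of what arrives.  Gray mapping is log compression,

    gray = clamp(round(scale * log(1 + gain * echo)), 0, 255),

followed by the acoustic-shadow rule: wherever the pure attenuation ratio
I/I0 has fallen below ``shadow_threshold`` (default 0.92) the pixel is
overwritten with ``gray_floor`` (default 50).  The shadow mask is returned
with the image so the rule stays testable even when log mapping happens to
land on the floor value by coincidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import imageio.v3 as iio
import numpy as np

from echoray.acoustics import Ray, _attenuation_integral, _normalized_gradient_terms, GRAD_EPS
from echoray.errors import ConfigurationError, FormatError
from echoray.volume import AttenuationVolume


@dataclass(frozen=True)
class ScanGeometry:
    """A linear probe array: parallel beams on a regular lateral grid.

    ``beam_origins`` is an (N, 3) array of physical starting points (mm),
    ``direction`` the shared unit beam direction.
    """

    beam_origins: np.ndarray
    direction: tuple[float, float, float]
    samples_per_beam: int
    step: float

    def __post_init__(self):
        origins = np.atleast_2d(np.asarray(self.beam_origins, dtype=float))
        object.__setattr__(self, "beam_origins", origins)
        if origins.shape[0] < 1 or origins.shape[1] != 3:
            raise ConfigurationError("beam_origins must be a non-empty (N, 3) array")
        if self.samples_per_beam < 1:
            raise ConfigurationError("samples_per_beam must be >= 1")
        if self.step <= 0:
            raise ConfigurationError("step must be > 0")
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ConfigurationError("direction must be a unit vector")

    @property
    def beam_count(self) -> int:
        return self.beam_origins.shape[0]

    @classmethod
    def linear_array(
        cls,
        volume: AttenuationVolume,
        beam_count: int,
        samples_per_beam: int,
        step: float,
        margin_mm: float = 0.0,
    ) -> "ScanGeometry":
        """Parallel beams along the depth axis (axis 2), spread laterally on axis 0.

        Beams start on the shallow face and are centered in the axis-1 extent.
        """
        if beam_count < 1:
            raise ConfigurationError("beam_count must be >= 1")
        shape = np.array(volume.shape)
        extent = (shape - 1) * volume.spacing
        xs = np.linspace(margin_mm, extent[0] - margin_mm, beam_count)
        y = extent[1] / 2.0
        origins = np.column_stack(
            [volume.origin[0] + xs,
             np.full(beam_count, volume.origin[1] + y),
             np.full(beam_count, volume.origin[2])]
        )
        return cls(origins, (0.0, 0.0, 1.0), samples_per_beam, step)


@dataclass
class EchoProfile:
    """Per-sample records along one beam.

    ``intensity_ratio`` is the pure depth-attenuation ratio I/I0; the incident
    intensity additionally multiplies the cumulative interface transmittance.
    ``exited`` flags a march truncated at the volume boundary.
    """

    depths: np.ndarray
    reflection: np.ndarray
    transmittance: np.ndarray
    intensity_ratio: np.ndarray
    cumulative_transmittance: np.ndarray
    echo: np.ndarray
    exited: bool = False

    def __len__(self) -> int:
        return len(self.depths)

    @property
    def incident_intensity(self) -> np.ndarray:
        return self.intensity_ratio * self.cumulative_transmittance


@dataclass(frozen=True)
class GrayMap:
    """Log-compression gray mapping plus the acoustic-shadow floor rule."""

    gain: float = 1000.0
    scale: float = 40.0
    shadow_threshold: float = 0.92
    gray_floor: int = 50
    reflection_exponent: float = 1.0

    def __post_init__(self):
        if not 0 < self.shadow_threshold <= 1:
            raise ConfigurationError("shadow_threshold must be in (0, 1]")
        if not 0 <= self.gray_floor <= 255:
            raise ConfigurationError("gray_floor must be in [0, 255]")
        if self.gain < 0 or self.scale < 0:
            raise ConfigurationError("gain and scale must be >= 0")

    def to_gray(self, echo: np.ndarray) -> np.ndarray:
        g = np.rint(self.scale * np.log1p(self.gain * np.asarray(echo)))
        return np.clip(g, 0, 255).astype(np.uint8)


@dataclass
class BModeImage:
    """Rendered 8-bit image: axes (beam index, depth sample), plus shadow mask."""

    gray: np.ndarray
    shadow_mask: np.ndarray
    gray_floor: int
    shadow_threshold: float


def march_ray(volume: AttenuationVolume, ray: Ray, samples: int, n: float = 1.0) -> EchoProfile:
    """March a ray, recording the acoustic factors at depths k*step, k=1..samples.

    If the ray leaves the volume before the requested sample count, the
    profile is truncated and flagged via ``exited``.
    """
    depths = (np.arange(samples) + 1) * ray.step
    inside = np.array([volume.contains(ray.at(d)) for d in depths])
    exited = not inside.all()
    if exited:
        keep = int(np.argmin(inside))  # first outside sample
        depths = depths[:keep]
    k = len(depths)
    if k == 0:
        empty = np.array([])
        return EchoProfile(empty, empty, empty, empty, empty, empty, exited=True)

    positions = ray.at(depths)
    grads, norm_mag = _normalized_gradient_terms(volume, positions)
    mags = np.linalg.norm(grads, axis=1)
    d = np.asarray(ray.direction, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosine = np.where(mags >= GRAD_EPS, grads @ d / np.where(mags > 0, mags, 1.0), 0.0)
    reflection = np.clip(cosine, 0.0, None) * norm_mag**n
    reflection[mags < GRAD_EPS] = 0.0
    trans = np.clip(1.0 - norm_mag**2, 0.0, 1.0)

    # attenuation ratio accumulated incrementally over successive segments
    seg_integrals = np.array(
        [_attenuation_integral(volume, ray, depths[i] - ray.step, depths[i]) for i in range(k)]
    )
    intensity_ratio = np.exp(-np.cumsum(seg_integrals))

    # transmittance of interfaces strictly shallower than sample k
    cum_trans = np.concatenate([[1.0], np.cumprod(trans)[:-1]])
    echo = intensity_ratio * cum_trans * reflection
    return EchoProfile(depths, reflection, trans, intensity_ratio, cum_trans, echo, exited=exited)


def render_bmode(
    volume: AttenuationVolume,
    geometry: ScanGeometry,
    mapping: GrayMap | None = None,
) -> BModeImage:
    """Render an 8-bit B-mode image: one row per beam, one column per depth sample."""
    if mapping is None:
        mapping = GrayMap()
    if geometry.beam_count < 1:
        raise ConfigurationError("geometry has no beams")

    gray = np.zeros((geometry.beam_count, geometry.samples_per_beam), dtype=np.uint8)
    shadow = np.zeros_like(gray, dtype=bool)
    for b in range(geometry.beam_count):
        ray = Ray(tuple(geometry.beam_origins[b]), geometry.direction, geometry.step)
        profile = march_ray(volume, ray, geometry.samples_per_beam, n=mapping.reflection_exponent)
        k = len(profile)
        gray[b, :k] = mapping.to_gray(profile.echo)
        mask = profile.intensity_ratio < mapping.shadow_threshold
        gray[b, :k][mask] = mapping.gray_floor
        shadow[b, :k] = mask
    return BModeImage(gray, shadow, mapping.gray_floor, mapping.shadow_threshold)


def write_image(image: BModeImage | np.ndarray, path: str | Path) -> None:
    """Write an 8-bit single-channel image as PNG or PGM (lossless)."""
    path = Path(path)
    if path.suffix.lower() not in {".png", ".pgm"}:
        raise FormatError(f"unsupported image extension {path.suffix!r} (use .png or .pgm)")
    gray = image.gray if isinstance(image, BModeImage) else np.asarray(image)
    iio.imwrite(path, gray.astype(np.uint8))


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit single-channel PNG/PGM back as a uint8 array."""
    path = Path(path)
    if path.suffix.lower() not in {".png", ".pgm"}:
        raise FormatError(f"unsupported image extension {path.suffix!r} (use .png or .pgm)")
    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        raise FormatError(f"expected 8-bit image, got dtype {arr.dtype} in {path.name}")
    if arr.ndim != 2:
        raise FormatError(f"expected single-channel image, got shape {arr.shape}")
    return arr


def load_scan_config(path: str | Path) -> dict:
    """Read a JSON scan/mapping configuration document."""
    return json.loads(Path(path).read_text())
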