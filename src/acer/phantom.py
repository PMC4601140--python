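r"""Seeded synthetic prostate phantom and simulated coil-corrected acquisition.

The generator emulates the imaging chain the reconstruction assumes:

1. a piecewise-constant ground truth ``G`` — a prostate ellipse in a
   signal-free background, with hypointense lesions and a urethra disc
   (geometry modelled on a CIRS-style multi-modality prostate training
   phantom: ~5.0 x 4.5 cm gland, three 0.5-1.0 cm lesions, 0.7 cm
   urethra);
2. an endorectal-coil sensitivity field ``B(s) = gamma(d(s))`` decaying
   with distance from the coil surface;
3. uniform complex Gaussian noise of per-channel std ``sigma0`` added to
   the sensitised signal, whose magnitude is Rician
   ``(nu = B G, Phi = sigma0)`` — stationary noise before correction;
4. pre-calibration coil-intensity correction by exact division with the
   sensitivity, ``V = magnitude / B``, which uniformises the signal but
   amplifies noise away from the coil: the corrected background noise
   scale is ``sigma0 / gamma(d)``.

All randomness flows from a single seeded generator.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coil import CoilModel, distance_map, snr_gain
from .errors import ConfigurationError, DomainError, InvalidParameterError
from .image import ImageRecord, as_image

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "simulate_acquisition",
    "apply_precalibration_correction",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise parameters of the synthetic phantom.

    All geometry is expressed in physical mm (converted to pixels via
    ``spacing``); intensities are arbitrary non-negative units.
    """

    shape: tuple[int, int] = (256, 256)
    spacing: tuple[float, float] = (0.3, 0.3)
    prostate_center_mm: tuple[float, float] = (51.5, 38.4)
    prostate_axes_mm: tuple[float, float] = (22.5, 25.0)  # semi-axes (row, col)
    prostate_intensity: float = 160.0
    lesion_offsets_mm: tuple[tuple[float, float], ...] = ((-10.0, -12.0), (-6.0, 11.0), (9.0, -2.0))
    lesion_radius_mm: float = 3.5
    lesion_intensity: float = 100.0
    urethra_offset_mm: tuple[float, float] = (-12.0, 0.0)
    urethra_diameter_mm: float = 7.0
    urethra_intensity: float = 60.0
    background_intensity: float = 0.0
    sigma0: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prostate_intensity", "lesion_intensity", "urethra_intensity",
                     "background_intensity"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.sigma0 <= 0:
            raise InvalidParameterError("sigma0 must be > 0")
        if self.lesion_radius_mm <= 0 or self.urethra_diameter_mm <= 0:
            raise InvalidParameterError("structure sizes must be > 0")
        h, w = self.shape
        fov = ((h - 1) * self.spacing[0], (w - 1) * self.spacing[1])
        cr, cc = self.prostate_center_mm
        ar, ac = self.prostate_axes_mm
        if cr - ar < 0 or cr + ar > fov[0] or cc - ac < 0 or cc + ac > fov[1]:
            raise DomainError("prostate ellipse extends outside the image")
        for dr, dc in self.lesion_offsets_mm:
            margin = self.lesion_radius_mm / min(ar, ac)
            if np.hypot(dr / ar, dc / ac) + margin > 1.0:
                raise DomainError(f"lesion at offset ({dr}, {dc}) mm is not inside the prostate")
        ur, uc = self.urethra_offset_mm
        if np.hypot(ur / ar, uc / ac) + self.urethra_diameter_mm / (2 * min(ar, ac)) > 1.0:
            raise DomainError("urethra disc is not inside the prostate")

    @classmethod
    def default(cls, **overrides) -> "PhantomSpec":
        """Full-resolution phantom: 256x256 at 0.3 mm."""
        return cls(**overrides)

    @classmethod
    def small(cls, **overrides) -> "PhantomSpec":
        """Canonical desk-scale phantom: 128x128 at 0.6 mm, same anatomy."""
        overrides.setdefault("shape", (128, 128))
        overrides.setdefault("spacing", (0.6, 0.6))
        return cls(**overrides)


def make_phantom(spec: PhantomSpec) -> ImageRecord:
    """Deterministic piecewise-constant ground-truth image ``G``."""
    h, w = spec.shape
    rows = np.arange(h)[:, None] * spec.spacing[0]
    cols = np.arange(w)[None, :] * spec.spacing[1]
    g = np.full(spec.shape, float(spec.background_intensity))

    cr, cc = spec.prostate_center_mm
    ar, ac = spec.prostate_axes_mm
    inside = ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2 <= 1.0
    g[inside] = spec.prostate_intensity
    for dr, dc in spec.lesion_offsets_mm:
        disc = np.hypot(rows - (cr + dr), cols - (cc + dc)) <= spec.lesion_radius_mm
        g[disc] = spec.lesion_intensity
    ur, uc = spec.urethra_offset_mm
    disc = np.hypot(rows - (cr + ur), cols - (cc + uc)) <= spec.urethra_diameter_mm / 2.0
    g[disc] = spec.urethra_intensity
    return ImageRecord(g, spacing=spec.spacing)


def sensitivity_field(shape: tuple[int, int], spacing, coil: CoilModel) -> np.ndarray:
    """Coil sensitivity ``B(s) = gamma(d(s))`` on the pixel grid."""
    return snr_gain(distance_map(shape, spacing, coil), coil)


def simulate_acquisition(
    G: ImageRecord | np.ndarray,
    coil: CoilModel,
    sigma0: float,
    seed: int,
) -> ImageRecord:
    """Uncorrected magnitude image with stationary complex Gaussian noise.

    Per pixel the two quadrature channels are ``B G + N(0, sigma0)``
    and ``N(0, sigma0)``; the returned magnitude is therefore Rician
    with location ``B(s) G(s)`` and scale ``sigma0`` everywhere.
    """
    if sigma0 <= 0:
        raise InvalidParameterError("sigma0 must be > 0")
    rec = as_image(G).validate_magnitude()
    b = sensitivity_field(rec.shape, rec.spacing, coil)
    rng = np.random.default_rng(seed)
    re = b * rec.data + rng.normal(0.0, sigma0, rec.shape)
    im = rng.normal(0.0, sigma0, rec.shape)
    return ImageRecord(np.hypot(re, im), spacing=rec.spacing)


def apply_precalibration_correction(
    uncorrected: ImageRecord | np.ndarray,
    coil: CoilModel,
) -> ImageRecord:
    """Divide by the known sensitivity field, as a scanner-side
    pre-calibration correction would.

    The corrected background noise scale becomes ``sigma0 / gamma(d)``
    and thus grows with distance from the coil.
    """
    rec = as_image(uncorrected).validate_magnitude()
    b = sensitivity_field(rec.shape, rec.spacing, coil)
    if np.any(b <= 0):
        raise ConfigurationError(
            "sensitivity field reaches zero; use a coil model with floor_gain > 0"
        )
    return ImageRecord(rec.data / b, spacing=rec.spacing)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture_suite(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write the canonical small test set to ``out_dir``.

    Produces ground truth, uncorrected and corrected images (NIfTI with
    PNG previews), the coil configuration, ROI specifications (a
    near-coil prostate region and a far noise-only background region)
    and a manifest recording every generation parameter and file hash.
    Regenerating with the same seed reproduces the files byte for byte.
    """
    from .config import dump_config
    from .fileio import write_image
    from .reconstruct import SamplerConfig

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = PhantomSpec.small(seed=seed)
    coil = CoilModel(coil_type="rigid", surface="bottom-edge")
    g = make_phantom(spec)
    unc = simulate_acquisition(g, coil, spec.sigma0, seed)
    cor = apply_precalibration_correction(unc, coil)

    paths: dict[str, Path] = {}
    for name, rec in (("ground_truth", g), ("uncorrected", unc), ("corrected", cor)):
        paths[name] = out / f"{name}.nii"
        write_image(rec, paths[name])
        paths[f"{name}_png"] = out / f"{name}.png"
        write_image(rec, paths[f"{name}_png"])

    paths["coil_config"] = out / "coil_config.yaml"
    dump_config(paths["coil_config"], coil=coil, sampler=SamplerConfig())

    regions = {
        "prostate_region": {"rect": [90, 68, 16, 16], "comment": "homogeneous gland, near coil"},
        "background_region": {"rect": [6, 8, 20, 40], "comment": "noise-only, far from coil"},
        "rect_convention": "[row, col, height, width], 0-based",
    }
    paths["regions"] = out / "regions.json"
    paths["regions"].write_text(json.dumps(regions, indent=2, sort_keys=True))

    manifest = {
        "seed": seed,
        "sigma0": spec.sigma0,
        "shape": list(spec.shape),
        "spacing_mm": list(spec.spacing),
        "coil": {
            "coil_type": coil.coil_type,
            "surface": coil.surface,
            "surface_gain": coil.surface_gain,
            "decay_length_mm": coil.decay_length_mm,
            "cutoff_mm": coil.cutoff_mm,
            "floor_gain": coil.floor_gain,
        },
        "files": {k: _sha256(p) for k, p in sorted(paths.items())},
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
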