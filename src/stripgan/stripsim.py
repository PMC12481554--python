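"""Procedural lateral-flow-immunoassay strip image simulator.

An LFIA strip shows two transverse colored bands on a pale nitrocellulose
membrane: a control line that must always develop, and a test line whose
darkness grows with analyte concentration.  The simulator renders strips
with exactly that statistical structure — a fixed band geometry, a
concentration-dependent test-line contrast following a saturating binding
curve, a directional multiplicative lighting gradient (nuisance variable),
and additive per-pixel sensor noise — so the whole downstream pipeline
(preprocessing, generative augmentation, QC, classification) is testable
end to end.

Five analyte levels (0, 0.25, 0.5, 0.75, 1.0 μg/mL) are grouped into three
classes: blank (0), low (0.25, 0.5) and high (0.75, 1.0).

Geometry: the control line sits at 30% of image height, the test line at
60%, each band 4% of height thick; these fractions are fixed so line
cropping is deterministic and the simulator can report ground-truth line
rows.  Default render size is 3×660×50, the pipeline's standardized raw
strip resolution; tests use small sizes for speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import (
    CLASSES,
    CONC_TO_CLASS,
    CONCENTRATIONS,
    LabeledDataset,
    Record,
)

#: saturating binding curve: concentration (μg/mL) → mean test-line contrast
CONTRAST_CURVE: dict[float, float] = {
    0.0: 0.0, 0.25: 0.35, 0.5: 0.50, 0.75: 0.65, 1.0: 0.80,
}

_CLASS_TO_CONCS = {
    "blank": (0.0,),
    "low": (0.25, 0.5),
    "high": (0.75, 1.0),
}


class ParameterError(ValueError):
    """Raised for non-finite or out-of-range strip parameters."""


@dataclass(frozen=True)
class StripParams:
    """Latent description of one simulated strip."""

    class_label: str
    concentration: float
    test_contrast: float
    control_contrast: float
    lighting_angle: float
    noise_sd: float
    seed: int

    def __post_init__(self):
        vals = (self.concentration, self.test_contrast, self.control_contrast,
                self.lighting_angle, self.noise_sd)
        if not all(math.isfinite(v) for v in vals):
            raise ParameterError("non-finite strip parameter")
        if self.concentration not in CONC_TO_CLASS:
            raise ParameterError(
                f"concentration must be one of {CONCENTRATIONS}")
        if CONC_TO_CLASS[self.concentration] != self.class_label:
            raise ParameterError(
                f"concentration {self.concentration} belongs to class "
                f"{CONC_TO_CLASS[self.concentration]!r}, "
                f"not {self.class_label!r}")
        if not 0.0 <= self.test_contrast <= 1.0:
            raise ParameterError("test_contrast must be in [0, 1]")
        if self.concentration == 0.0 and self.test_contrast != 0.0:
            raise ParameterError("blank strips must have zero test contrast")
        if not 0.0 < self.control_contrast <= 1.0:
            raise ParameterError("control_contrast must be in (0, 1]")
        if not 0.0 <= self.lighting_angle < 360.0:
            raise ParameterError("lighting_angle must be in [0, 360)")
        if self.noise_sd < 0.0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SimProfile:
    """Rendering profile: geometry, optics and noise of the simulated capture.

    Attributes
    ----------
    control_row_frac, test_row_frac : float
        Fractional row positions of the band centers.
    band_frac : float
        Band thickness as a fraction of image height.
    lighting_amplitude : float
        Peak relative brightness change of the multiplicative ramp (±15%
        by default).
    noise_sd : float
        Standard deviation of the additive Gaussian pixel noise.
    contrast_jitter : float
        Relative per-strip jitter applied to the binding-curve contrast.
    heavy_tailed_noise : bool
        Replace Gaussian noise with Student-t (df=3) scaled to the same sd.
    """

    control_row_frac: float = 0.30
    test_row_frac: float = 0.60
    band_frac: float = 0.04
    lighting_amplitude: float = 0.15
    noise_sd: float = 0.02
    control_contrast: float = 0.85
    contrast_jitter: float = 0.15
    background: tuple[float, float, float] = (0.84, 0.82, 0.79)
    band_tint: tuple[float, float, float] = (0.15, 0.55, 0.55)
    heavy_tailed_noise: bool = False

    def band_rows(self, height: int) -> tuple[slice, slice]:
        """Row slices of the control and test bands for a given height."""
        half = max(1, round(self.band_frac * height / 2))
        c = round(self.control_row_frac * height)
        t = round(self.test_row_frac * height)
        return (slice(max(0, c - half), min(height, c + half)),
                slice(max(0, t - half), min(height, t + half)))


DEFAULT_PROFILE = SimProfile()

#: profile for small square renders (e.g. 16×16) where the default 4% band
#: thickness would fall below one pixel row
TOY_PROFILE = SimProfile(band_frac=0.15)
#: default raw render size (channels × height × width)
DEFAULT_HEIGHT = 660
DEFAULT_WIDTH = 50


def render_strip(params: StripParams, height: int = DEFAULT_HEIGHT,
                 width: int = DEFAULT_WIDTH,
                 profile: SimProfile = DEFAULT_PROFILE) -> np.ndarray:
    """Render one strip as a 3×height×width float image in [0, 1].

    Identical ``params`` (including seed) give bit-identical pixels.
    """
    if height < 16 or width < 8:
        raise ParameterError("height must be >= 16 and width >= 8")
    bg = np.asarray(profile.background, dtype=np.float64)
    tint = np.asarray(profile.band_tint, dtype=np.float64)
    img = np.broadcast_to(bg[:, None, None], (3, height, width)).copy()

    ctrl, test = profile.band_rows(height)
    img[:, ctrl, :] -= params.control_contrast * tint[:, None, None]
    img[:, test, :] -= params.test_contrast * tint[:, None, None]

    # multiplicative lighting ramp along the lighting direction
    if profile.lighting_amplitude:
        theta = math.radians(params.lighting_angle)
        yy = np.linspace(-1.0, 1.0, height)[:, None]
        xx = np.linspace(-1.0, 1.0, width)[None, :]
        proj = yy * math.cos(theta) + xx * math.sin(theta)
        peak = np.abs(proj).max()
        if peak > 0:
            proj = proj / peak
        img *= 1.0 + profile.lighting_amplitude * proj[None, :, :]

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        if profile.heavy_tailed_noise:
            t = rng.standard_t(df=3, size=img.shape)
            img += params.noise_sd * t / math.sqrt(3.0)  # var of t(3) is 3
        else:
            img += rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def band_contrast(img: np.ndarray,
                  profile: SimProfile = DEFAULT_PROFILE) -> float:
    """Empirical test-line contrast: background minus test-band mean.

    Background is measured between the two bands, away from both, so the
    statistic is robust to the lighting ramp's global tilt.
    """
    height = img.shape[1]
    ctrl, test = profile.band_rows(height)
    lo, hi = ctrl.stop, test.start
    pad = max(1, (hi - lo) // 4)
    background = img[:, lo + pad:hi - pad, :]
    band = img[:, test, :]
    return float(background.mean() - band.mean())


def sample_params(class_label: str, rng: np.random.Generator,
                  profile: SimProfile = DEFAULT_PROFILE) -> StripParams:
    """Draw one strip's latent parameters for a class."""
    if class_label not in CLASSES:
        raise ParameterError(f"unknown class {class_label!r}")
    conc = float(rng.choice(_CLASS_TO_CONCS[class_label]))
    jitter = profile.contrast_jitter
    test_c = CONTRAST_CURVE[conc] * (1.0 + rng.uniform(-jitter, jitter))
    ctrl_c = profile.control_contrast * (1.0 + rng.uniform(-jitter, jitter) / 2)
    return StripParams(
        class_label=class_label,
        concentration=conc,
        test_contrast=float(np.clip(test_c, 0.0, 1.0)),
        control_contrast=float(np.clip(ctrl_c, 1e-6, 1.0)),
        lighting_angle=float(rng.uniform(0.0, 360.0)),
        noise_sd=profile.noise_sd,
        seed=int(rng.integers(0, 2**31)),
    )


def sample_dataset(n_per_class: int, seed: int,
                   profile: SimProfile = DEFAULT_PROFILE,
                   height: int = DEFAULT_HEIGHT,
                   width: int = DEFAULT_WIDTH) -> LabeledDataset:
    """Render a class-balanced dataset of ``3 * n_per_class`` strips.

    Concentrations within the low and high classes are drawn uniformly from
    their two member levels; lighting angles uniformly on [0, 360).  Fully
    reproducible from ``seed``.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for class_label in CLASSES:
        for i in range(n_per_class):
            params = sample_params(class_label, rng, profile)
            img = render_strip(params, height, width, profile)
            ctrl, test = profile.band_rows(height)
            records.append(Record(
                image=img,
                label=class_label,
                provenance="real",
                meta={
                    "concentration": params.concentration,
                    "seed": params.seed,
                    "lighting_angle": params.lighting_angle,
                    "test_contrast": params.test_contrast,
                    "control_row": (ctrl.start + ctrl.stop) // 2,
                    "test_row": (test.start + test.stop) // 2,
                },
            ))
    return LabeledDataset(records)
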