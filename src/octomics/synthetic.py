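"""Synthetic OCT-like cohort generator.

Emulates a cohort of anti-VEGF-treated diabetic macular edema (DME)
eyes: each eye gets a B-scan-like 2D image with a horizontal
inner-retina band mask, a latent texture phenotype (class), clinical
covariates, and binary outcomes (residual/recurrent DME and poor
vision) linked to the class.

Texture motifs are chosen so the texture features the downstream
analysis relies on are discriminative: dark elliptical cysts, bright
hyperreflective foci, a smooth layered reflectivity profile with
class-specific disruption, and additive Gaussian noise. Intensities are
generated in [0, 1] and quantized to 8-bit; all feature math downstream
operates on the 8-bit values, mirroring JPG-era inputs.

The default cohort configuration mirrors the published 234-eye study
structure: four phenotypes at proportions (0.52, 0.19, 0.14, 0.15) with
cluster-linked outcome prevalences (RDME 59/69/59/34%, poor vision
57/60/66/29%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .features.image import BScanImage, InputError, ROIMask
from .outcomes import classify_residual_dme, POOR_VISION_LOGMAR


@dataclass
class ClassTextureParams:
    """Per-phenotype texture generator settings."""

    cyst_density: float = 2.0          # expected cysts per 1000 masked px^2
    cyst_radius_px: tuple[float, float] = (2.0, 6.0)
    focus_density: float = 1.0         # hyperreflective foci per 1000 masked px^2
    layer_disruption: float = 0.05     # SD of smooth within-band modulation
    base_reflectivity_mean: float = 0.55
    base_reflectivity_sd: float = 0.05
    cmt_baseline_median_um: float = 420.0


@dataclass
class SyntheticCohortConfig:
    n_eyes: int = 234
    n_classes: int = 4
    class_proportions: tuple[float, ...] = (0.52, 0.19, 0.14, 0.15)
    image_size: tuple[int, int] = (128, 128)
    pixel_spacing_mm: float = 0.011
    class_params: tuple[ClassTextureParams, ...] = ()
    rdme_probs: tuple[float, ...] = (0.59, 0.69, 0.59, 0.34)
    poor_vision_probs: tuple[float, ...] = (0.57, 0.60, 0.66, 0.29)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eyes < self.n_classes or self.n_eyes <= 0:
            raise InputError("need n_eyes >= n_classes >= 1")
        props = np.asarray(self.class_proportions, dtype=float)
        if len(props) != self.n_classes or abs(props.sum() - 1.0) > 1e-12 or (props < 0).any():
            raise InputError("class_proportions must be a simplex vector of length n_classes")
        for p in (*self.rdme_probs, *self.poor_vision_probs):
            if not 0.0 <= p <= 1.0:
                raise InputError("outcome probabilities must lie in [0, 1]")
        if min(self.image_size) <= 0 or self.pixel_spacing_mm <= 0:
            raise InputError("image size and spacing must be positive")
        if not self.class_params:
            self.class_params = _default_class_params(self.n_classes)
        if len(self.class_params) != self.n_classes:
            raise InputError("one ClassTextureParams per class required")


def _default_class_params(n_classes: int) -> tuple[ClassTextureParams, ...]:
    """Moderately separated phenotypes along cyst load and reflectivity."""
    cmt = (420.0, 510.0, 540.0, 300.0)
    base = []
    for c in range(n_classes):
        base.append(ClassTextureParams(
            cyst_density=(1.5, 4.0, 6.0, 0.5)[c % 4],
            cyst_radius_px=((2, 6), (3, 8), (3, 9), (2, 4))[c % 4],
            focus_density=(1.0, 2.5, 4.0, 0.3)[c % 4],
            layer_disruption=(0.05, 0.08, 0.12, 0.03)[c % 4],
            base_reflectivity_mean=(0.50, 0.58, 0.64, 0.44)[c % 4],
            cmt_baseline_median_um=cmt[c % 4],
        ))
    return tuple(base)


def high_separation_config(n_eyes: int = 120, seed: int = 0) -> SyntheticCohortConfig:
    """Preset with strongly separated phenotypes (planted-cluster recovery)."""
    params = (
        ClassTextureParams(cyst_density=0.0, focus_density=0.0,
                           layer_disruption=0.01, base_reflectivity_mean=0.25),
        ClassTextureParams(cyst_density=3.0, focus_density=1.0,
                           layer_disruption=0.05, base_reflectivity_mean=0.45),
        ClassTextureParams(cyst_density=8.0, focus_density=4.0,
                           layer_disruption=0.10, base_reflectivity_mean=0.62),
        ClassTextureParams(cyst_density=16.0, cyst_radius_px=(4.0, 9.0),
                           focus_density=8.0, layer_disruption=0.18,
                           base_reflectivity_mean=0.82),
    )
    return SyntheticCohortConfig(
        n_eyes=n_eyes, n_classes=4, class_proportions=(0.25, 0.25, 0.25, 0.25),
        class_params=params, noise_sd=0.01, seed=seed,
        rdme_probs=(0.59, 0.69, 0.59, 0.34), poor_vision_probs=(0.57, 0.60, 0.66, 0.29),
    )


def null_config(n_eyes: int = 120, seed: int = 0) -> SyntheticCohortConfig:
    """Preset with identical class parameters (no real structure)."""
    params = tuple(ClassTextureParams() for _ in range(4))
    return SyntheticCohortConfig(
        n_eyes=n_eyes, n_classes=4, class_proportions=(0.25, 0.25, 0.25, 0.25),
        class_params=params, noise_sd=0.05, seed=seed,
    )


@dataclass
class ClinicalRecord:
    eye_id: str
    age: float
    sex: str
    dm_duration: float
    hba1c: float
    cmt_baseline_um: float
    cmt_post_um: float
    bcva_logmar_baseline: float
    bcva_logmar_6mo: float
    dr_stage: str
    medication: str
    recurrence_within_6mo: bool


@dataclass
class EndpointLabels:
    rdme: bool
    vision_poor: bool


@dataclass
class SyntheticEye:
    eye_id: str
    true_class: int
    image: BScanImage
    mask: ROIMask
    clinical: ClinicalRecord
    endpoints: EndpointLabels


def generate_bscan(class_params: ClassTextureParams, size=(128, 128),
                   spacing_mm: float = 0.011, rng: np.random.Generator | None = None):
    """Render one B-scan-like image plus its inner-retina band mask.

    The mask is a horizontal band covering >= 10% of the image; the band
    carries a smooth layered reflectivity profile, dark elliptical
    cysts, and bright punctate foci. Intensities lie in [0, 1].
    """
    if min(size) <= 0 or spacing_mm <= 0:
        raise InputError("size and spacing must be positive")
    rng = rng or np.random.default_rng()
    h, w = size
    p = class_params

    # band position/thickness vary slightly eye to eye (edema swells the band)
    band_top = int(h * (0.25 + 0.04 * rng.uniform(-1.0, 1.0)))
    band_bot = int(h * (0.75 + 0.04 * rng.uniform(-1.0, 1.0)))
    mask = np.zeros((h, w), dtype=bool)
    mask[band_top:band_bot, :] = True

    rows = np.arange(h, dtype=float)
    # layered background: base + two smooth sinusoidal "layers" across depth
    profile = (p.base_reflectivity_mean
               + 0.12 * np.sin(2 * np.pi * (rows - band_top) / max(band_bot - band_top, 1))
               + 0.06 * np.sin(6 * np.pi * rows / h))
    img = np.tile(profile[:, None], (1, w))
    img += rng.normal(0.0, p.base_reflectivity_sd)

    # smooth layer-disruption field
    if p.layer_disruption > 0:
        rough = rng.normal(0.0, 1.0, size=(h, w))
        smooth = ndimage.gaussian_filter(rough, sigma=4.0)
        sd = smooth.std()
        if sd > 0:
            img += p.layer_disruption * smooth / sd

    area_factor = mask.sum() / 1000.0
    yy, xx = np.mgrid[0:h, 0:w]
    n_cysts = rng.poisson(p.cyst_density * area_factor)
    for _ in range(int(n_cysts)):
        cy = rng.uniform(band_top, band_bot)
        cx = rng.uniform(0, w)
        ry = rng.uniform(*p.cyst_radius_px)
        rx = ry * rng.uniform(0.8, 1.6)
        ell = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        img[ell] *= 0.25  # dark fluid-filled space

    n_foci = rng.poisson(p.focus_density * area_factor)
    for _ in range(int(n_foci)):
        fy = int(rng.uniform(band_top, band_bot))
        fx = int(rng.uniform(0, w))
        img[max(0, fy - 1):fy + 2, max(0, fx - 1):fx + 2] = 0.95

    img = np.clip(img, 0.0, 1.0)
    image = BScanImage(pixels=img, spacing_mm=(spacing_mm, spacing_mm))
    return image, ROIMask(pixels=mask)


def link_outcomes(true_class: int, rdme_probs, poor_vision_probs,
                  rng: np.random.Generator, cmt_baseline_median_um: float = 420.0):
    """Draw outcome labels for one eye and synthesize consistent CMT/BCVA.

    RDME and poor vision are independent Bernoulli draws at the
    class-specific probabilities. Baseline/post CMT are synthesized so
    the four-band residual rule reproduces the drawn RDME label
    exactly (recurrence is kept False); 6-month logMAR is drawn on the
    matching side of the 20/63 threshold.
    """
    k = true_class - 1
    for probs in (rdme_probs, poor_vision_probs):
        if not 0.0 <= probs[k] <= 1.0:
            raise InputError("probability outside [0, 1]")
    rdme = bool(rng.random() < rdme_probs[k])
    poor = bool(rng.random() < poor_vision_probs[k])

    cmt_base = float(np.clip(rng.lognormal(np.log(cmt_baseline_median_um), 0.22), 220, 900))
    thr = _residual_threshold(cmt_base)
    if rdme:  # reduction below the band threshold (possibly worsening)
        reduction = rng.uniform(-0.10, thr * 0.999)
    else:
        reduction = rng.uniform(thr * 1.001, 0.70)
    cmt_post = cmt_base * (1.0 - reduction)
    assert classify_residual_dme(cmt_base, cmt_post) == rdme

    if poor:
        logmar_6mo = float(rng.uniform(POOR_VISION_LOGMAR, 1.3))
    else:
        logmar_6mo = float(rng.uniform(0.0, POOR_VISION_LOGMAR * 0.95))
    return EndpointLabels(rdme=rdme, vision_poor=poor), cmt_base, cmt_post, logmar_6mo


def _residual_threshold(cmt_baseline_um: float) -> float:
    if cmt_baseline_um <= 400:
        return 0.10
    if cmt_baseline_um <= 500:
        return 0.15
    if cmt_baseline_um <= 600:
        return 0.20
    return 0.25


def generate_cohort(config: SyntheticCohortConfig) -> list[SyntheticEye]:
    """Generate the full synthetic cohort, deterministic given the seed.

    Class labels are assigned by largest-remainder apportionment of the
    class proportions (so equal proportions with divisible n give exact
    balance), then shuffled.
    """
    rng = np.random.default_rng(config.seed)
    counts = _apportion(config.n_eyes, np.asarray(config.class_proportions))
    classes = np.repeat(np.arange(1, config.n_classes + 1), counts)
    rng.shuffle(classes)

    eyes: list[SyntheticEye] = []
    meds = ("ranibizumab", "conbercept", "aflibercept")
    for i, cls in enumerate(classes):
        p = config.class_params[cls - 1]
        image, mask = generate_bscan(p, config.image_size, config.pixel_spacing_mm, rng)
        px = image.pixels
        if config.noise_sd > 0:
            px = np.clip(px + rng.normal(0.0, config.noise_sd, px.shape), 0.0, 1.0)
        # quantize to 8-bit: downstream feature math sees the stored values
        px8 = np.round(px * 255.0).astype(np.uint8)
        image = BScanImage(pixels=px8, spacing_mm=image.spacing_mm, id=f"eye{i:04d}")

        endpoints, cmt_b, cmt_p, logmar6 = link_outcomes(
            int(cls), config.rdme_probs, config.poor_vision_probs, rng,
            cmt_baseline_median_um=p.cmt_baseline_median_um)
        clinical = ClinicalRecord(
            eye_id=f"eye{i:04d}",
            age=float(np.clip(rng.normal(59.3, 9.9), 25, 90)),
            sex=("male", "female")[int(rng.random() < 0.46)],
            dm_duration=float(np.clip(rng.gamma(4.0, 2.5), 0.5, 40)),
            hba1c=float(np.clip(rng.normal(7.4, 1.0), 5.0, 13.0)),
            cmt_baseline_um=cmt_b,
            cmt_post_um=cmt_p,
            bcva_logmar_baseline=float(np.clip(rng.normal(0.5, 0.25), 0.0, 1.6)),
            bcva_logmar_6mo=logmar6,
            dr_stage=("NPDR", "PDR")[int(rng.random() < 0.24)],
            medication=meds[rng.integers(0, 3)],
            recurrence_within_6mo=False,
        )
        eyes.append(SyntheticEye(eye_id=clinical.eye_id, true_class=int(cls),
                                 image=image, mask=mask, clinical=clinical,
                                 endpoints=endpoints))
    return eyes


def _apportion(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n items to the proportions."""
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def cohort_clinical_table(eyes: list[SyntheticEye]):
    """Cohort manifest + clinical table as a DataFrame."""
    import pandas as pd

    rows = []
    for e in eyes:
        c = e.clinical
        rows.append({
            "eye_id": e.eye_id, "true_class": e.true_class,
            "age": c.age, "sex": c.sex, "dm_duration": c.dm_duration,
            "hba1c": c.hba1c,
            "cmt_baseline_um": c.cmt_baseline_um, "cmt_post_um": c.cmt_post_um,
            "bcva_logmar_baseline": c.bcva_logmar_baseline,
            "bcva_logmar_6mo": c.bcva_logmar_6mo,
            "dr_stage": c.dr_stage, "medication": c.medication,
            "rdme": int(e.endpoints.rdme), "vision_poor": int(e.endpoints.vision_poor),
        })
    return pd.DataFrame(rows).set_index("eye_id")
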