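"""Synthetic radiograph textures, study frames and longitudinal cohorts.

The clinical radiographs behind the corticalization analysis are not
publicly deposited, so this module provides statistically controlled
stand-ins for every stage of the pipeline:

* :func:`generate_texture_patch` — Gaussian-random-field gray-level
  patches emulating three radiographic tissue classes: heterogeneous
  mid-density trabecular bone (short correlation length, high contrast),
  bright homogeneous corticalized bone (long correlation length, low
  contrast) and dark homogeneous bone-loss/soft-tissue regions.
* :func:`generate_study_frame` — a full 476 x 620 intraoral-radiograph
  canvas at the 70 um/pixel protocol geometry, with a dark implant
  silhouette, a corticalized peri-implant band and a distant trabecular
  reference region, each carrying a protocol-sized 1500-pixel ROI.
* :func:`generate_cohort` — longitudinal implant cohorts with
  zero-inflated marginal bone loss, moment-matched truncated-normal
  corticalization indices, a weak linear CI-MBL coupling and signed
  covariate effects, returning the ground truth for recovery tests.

The texture model is a smoothed-Gaussian-field proxy, not a physical bone
model; the analysis only consumes gray-level statistics, so matching the
qualitative run-length/entropy contrast between tissue classes is what
matters. All randomness flows from a single user-supplied seed through
named generators; there is no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special, stats as sps
from scipy.ndimage import gaussian_filter

from .cohort import (
    CATEGORICAL_LEVELS,
    CohortRecord,
    DESIGN_FEATURES,
    NUMERIC_COVARIATES,
    PROSTHETIC_FEATURES,
)
from .errors import ParameterError
from .io import RadiographImage, RoiSpec
from .texture import GlcmParams  # noqa: F401  (re-exported for convenience)

__all__ = [
    "TextureParams",
    "CohortSimConfig",
    "generate_texture_patch",
    "generate_study_frame",
    "generate_cohort",
]

#: Per-tissue-class texture defaults: (correlation length px, mean gray
#: level, contrast SD). Sensor noise is shared.
TISSUE_DEFAULTS: dict[str, tuple[float, float, float]] = {
    "trabecular": (4.0, 120.0, 40.0),
    "cortical": (12.0, 190.0, 12.0),
    "soft_tissue": (8.0, 60.0, 8.0),
}

#: Population mean/SD used to draw and standardize patient covariates.
COVARIATE_POPULATION: dict[str, tuple[float, float]] = {
    "age_y": (47.0, 13.0),
    "height_m": (1.70, 0.09),
    "weight_kg": (75.0, 19.0),
    "bmi": (26.0, 4.0),
    "tsh_mu_l": (1.73, 1.07),
    "calcium_mmol_dl": (2.39, 0.61),
    "triglycerides_mmol_l": (1.24, 0.57),
}


@dataclass
class TextureParams:
    """Parameters of one synthetic tissue patch.

    Unset fields fall back to the class defaults in
    :data:`TISSUE_DEFAULTS`. ``correlation_length_px`` is the FWHM of the
    Gaussian smoothing kernel of the underlying random field (the typical
    structure size in pixels); ``contrast_sd`` the gray-level SD of the
    structured component; ``sensor_noise_sd`` the SD of additive
    uncorrelated detector noise.
    """

    tissue_class: str = "trabecular"
    correlation_length_px: float | None = None
    mean_level: float | None = None
    contrast_sd: float | None = None
    sensor_noise_sd: float = 3.0
    patch_shape: tuple[int, int] = (100, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_DEFAULTS:
            raise ParameterError(
                f"unknown tissue_class {self.tissue_class!r}; "
                f"use one of {tuple(TISSUE_DEFAULTS)}"
            )
        corr, mean, contrast = TISSUE_DEFAULTS[self.tissue_class]
        if self.correlation_length_px is None:
            self.correlation_length_px = corr
        if self.mean_level is None:
            self.mean_level = mean
        if self.contrast_sd is None:
            self.contrast_sd = contrast
        if not self.correlation_length_px > 0:
            raise ParameterError("correlation_length_px must be positive")
        if self.contrast_sd < 0 or self.sensor_noise_sd < 0:
            raise ParameterError("contrast_sd and sensor_noise_sd must be >= 0")
        if not (0 <= self.mean_level <= 255):
            raise ParameterError("mean_level must lie in [0, 255]")
        r, c = self.patch_shape
        if r < 2 or c < 2:
            raise ParameterError("patch_shape must be at least 2 x 2")


#: Conversion from a correlation length (kernel FWHM) to the Gaussian sigma.
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def _field(rng: np.random.Generator, shape: tuple[int, int], corr: float) -> np.ndarray:
    """Unit-variance, zero-mean Gaussian random field.

    ``corr`` is the full width at half maximum of the smoothing kernel, so
    a correlation length of 12 px means structures roughly 12 px across.
    """
    raw = gaussian_filter(
        rng.standard_normal(shape), sigma=corr * _FWHM_TO_SIGMA, mode="reflect"
    )
    raw -= raw.mean()
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def generate_texture_patch(params: TextureParams) -> RadiographImage:
    """Render one 8-bit tissue patch; identical seeds give identical pixels."""
    rng = np.random.default_rng(params.seed)
    f = _field(rng, params.patch_shape, params.correlation_length_px)
    img = params.mean_level + params.contrast_sd * f
    if params.sensor_noise_sd > 0:
        img = img + rng.normal(0.0, params.sensor_noise_sd, params.patch_shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return RadiographImage(
        pixels=img,
        bit_depth=8,
        image_id=f"{params.tissue_class}_s{params.seed}",
    )


# Frame layout (rows, cols), chosen so both ROIs are protocol-sized
# 30 x 50 = 1500-pixel rectangles: the peri-implant ROI sits inside the
# corticalized band flanking the implant neck, the reference ROI in
# distant trabecular bone.
FRAME_SHAPE = (476, 620)
_IMPLANT_RECT = (60, 290, 420, 330)
_NECK_RECT = (60, 280, 92, 340)
_CORTICAL_BAND = (90, 330, 170, 400)
_PERI_ROI_RECT = (110, 340, 140, 390)
_REF_ROI_RECT = (330, 80, 360, 130)


def generate_study_frame(seed: int) -> tuple[RadiographImage, list[RoiSpec]]:
    """One synthetic intraoral frame plus its peri-implant/reference ROIs.

    The canvas is 476 x 620 pixels at 70 um pixel pitch: trabecular
    background, a dark implant silhouette with a wider neck platform, and
    a corticalized band along the implant neck. Both returned ROIs resolve
    to exactly 1500 pixels.
    """
    ss = np.random.SeedSequence([int(seed), 476620])
    bg_seed, cort_seed, imp_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))

    frame = generate_texture_patch(
        TextureParams(tissue_class="trabecular", patch_shape=FRAME_SHAPE, seed=bg_seed)
    ).pixels.astype(np.float64)

    r0, c0, r1, c1 = _CORTICAL_BAND
    band = generate_texture_patch(
        TextureParams(
            tissue_class="cortical", patch_shape=(r1 - r0, c1 - c0), seed=cort_seed
        )
    ).pixels
    frame[r0:r1, c0:c1] = band

    imp_rng = np.random.default_rng(imp_seed)
    for rect, value in ((_IMPLANT_RECT, 18.0), (_NECK_RECT, 14.0)):
        r0, c0, r1, c1 = rect
        frame[r0:r1, c0:c1] = value + imp_rng.normal(0.0, 2.0, (r1 - r0, c1 - c0))

    image = RadiographImage(
        pixels=np.clip(np.rint(frame), 0, 255).astype(np.uint8),
        bit_depth=8,
        image_id=f"frame_{seed}",
    )
    specs = [
        RoiSpec(roi_id=f"f{seed}_peri", label="peri_implant", rect=_PERI_ROI_RECT),
        RoiSpec(roi_id=f"f{seed}_ref", label="reference", rect=_REF_ROI_RECT),
    ]
    return image, specs


# ---------------------------------------------------------------------------
# Longitudinal cohort simulation


def _hazard(alpha: float) -> float:
    """Standard-normal hazard phi(a)/(1 - Phi(a)), numerically stable."""
    return math.sqrt(2.0 / math.pi) / special.erfcx(alpha / math.sqrt(2.0))


def _truncated_normal_params(mean: float, sd: float) -> tuple[float, float, float]:
    """Parent (alpha, loc, scale) of a (0, inf)-truncated normal whose
    realized mean and SD equal the targets. Requires mean/sd > 1 (the
    exponential limit); near that limit the left-truncation point sits far
    into the parent distribution."""
    if mean <= 0 or sd <= 0:
        raise ParameterError("truncated-normal targets must be positive")
    ratio = mean / sd

    def excess(alpha: float) -> float:
        lam = _hazard(alpha)
        m = lam - alpha
        v = 1.0 - lam * m
        return m / math.sqrt(v) - ratio

    lo, hi = -12.0, 50.0
    if excess(hi) > 0:
        raise ParameterError(
            f"mean/sd ratio {ratio:.3f} too close to 1 for a truncated normal"
        )
    from scipy.optimize import brentq

    alpha = float(brentq(excess, lo, hi, xtol=1e-12))
    lam = _hazard(alpha)
    v = 1.0 - lam * (lam - alpha)
    scale = sd / math.sqrt(v)
    loc = -alpha * scale
    return alpha, loc, scale


def _draw_zero_truncated(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draws from the moment-matched (0, inf)-truncated normal."""
    alpha, loc, scale = _truncated_normal_params(mean, sd)
    return sps.truncnorm.rvs(alpha, np.inf, loc=loc, scale=scale, size=size, random_state=rng)


#: Default per-timepoint CI mean/SD (unitless).
DEFAULT_CI_MEAN_SD = {"initial": (200.0, 146.0), "y5": (282.0, 182.0), "y10": (261.0, 168.0)}
#: Default fraction of implants with exactly zero MBL per timepoint.
DEFAULT_MBL_ZERO_FRACTION = {"initial": 0.867, "y5": 0.544, "y10": 0.444}
#: Default MBL mean/SD (mm) in the affected (MBL > 0) subgroup.
DEFAULT_MBL_POSITIVE = {"initial": (1.93, 1.85), "y5": (1.91, 1.26), "y10": (2.67, 2.04)}
#: Default population CI-MBL Pearson correlation targeted per timepoint.
DEFAULT_CI_MBL_CC = {"initial": 0.0, "y5": 0.11, "y10": 0.12}
#: Default signed covariate contributions to CI (per 1 population SD).
DEFAULT_COVARIATE_EFFECTS = {
    "tsh_mu_l": 10.0,
    "calcium_mmol_dl": -10.0,
    "age_y": 8.0,
    "weight_kg": -8.0,
}
#: Default design-feature / prosthetic option frequencies.
DEFAULT_FEATURE_FREQUENCIES: dict[str, dict[str, float]] = {
    "titanium_alloy": {"grade5": 0.84, "grade4": 0.16},
    "level": {"bone": 0.91, "subcrestal": 0.07, "tissue": 0.02},
    "connection_type": {"internal": 0.98, "custom": 0.02},
    "connection_shape": {
        "internal_hexagon": 0.70,
        "conical": 0.27,
        "one_piece_abutment": 0.02,
        "internal_octagon": 0.01,
    },
    "neck_microthreads": {"yes": 0.78, "no": 0.22},
    "body_shape": {"tapered": 0.91, "straight": 0.09},
    "body_threads": {
        "reverse_buttress": 0.50,
        "square": 0.31,
        "v_shape": 0.15,
        "buttress": 0.02,
        "no_threads": 0.02,
    },
    "apex_shape": {"dome": 0.62, "flat": 0.32, "cone": 0.06},
    "apex_hole": {"no_hole": 0.97, "round": 0.03},
    "apex_groove": {"yes": 0.93, "no": 0.07},
    "prosthetic": {
        "splinted_crowns": 0.35,
        "single_crown": 0.33,
        "bridge": 0.25,
        "overdenture": 0.07,
    },
    "platform_switching": {"no": 0.81, "yes": 0.19},
    "sex": {"female": 0.55, "male": 0.45},
    "smoking": {"no": 0.75, "yes": 0.25},
    "jaw": {"mandible": 0.52, "maxilla": 0.48},
    "arch_location": {"posterior": 0.65, "anterior": 0.35},
    "augmented": {"no": 0.80, "yes": 0.20},
}


@dataclass
class CohortSimConfig:
    """Configuration of the longitudinal cohort simulator.

    Per-timepoint CI draws come from moment-matched truncated normals, so
    the configured mean/SD are the marginal moments of the generated
    (non-negative) CI. MBL is zero-inflated: a point mass at 0 mm plus a
    moment-matched positive component. ``ci_mbl_slope`` (CI units per mm)
    linearly couples CI to the centred MBL; when left ``None`` it is
    derived per timepoint from ``ci_mbl_target_cc`` so the population
    Pearson correlation matches the target. Covariate effects add the
    stated CI shift per population SD of the covariate; their variance and
    the coupling variance are removed from the base CI draw so the
    marginal moments stay at the configured values.
    """

    n_implants: int = 100
    timepoints: tuple[str, ...] = ("initial", "y5", "y10")
    ci_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CI_MEAN_SD)
    )
    mbl_zero_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MBL_ZERO_FRACTION)
    )
    mbl_mean_sd_given_positive: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MBL_POSITIVE)
    )
    ci_mbl_slope: dict[str, float] | float | None = None
    ci_mbl_target_cc: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CI_MBL_CC)
    )
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    design_feature_frequencies: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FEATURE_FREQUENCIES.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_implants < 1:
            raise ParameterError(f"n_implants must be >= 1, got {self.n_implants}")
        unknown_tp = set(self.timepoints) - {"initial", "y5", "y10"}
        if unknown_tp or not self.timepoints:
            raise ParameterError(f"invalid timepoints {self.timepoints}")
        for tp in self.timepoints:
            m, s = self.ci_mean_sd[tp]
            if m <= 0 or s < 0:
                raise ParameterError(f"ci_mean_sd[{tp}] must have mean > 0, sd >= 0")
            z = self.mbl_zero_fraction[tp]
            if not 0.0 <= z <= 1.0:
                raise ParameterError(f"mbl_zero_fraction[{tp}] must lie in [0, 1]")
            mp, sp = self.mbl_mean_sd_given_positive[tp]
            if mp <= 0 or sp < 0:
                raise ParameterError(
                    f"mbl_mean_sd_given_positive[{tp}] must have mean > 0, sd >= 0"
                )
        for cov in self.covariate_effects:
            if cov not in NUMERIC_COVARIATES:
                raise ParameterError(f"unknown covariate {cov!r} in covariate_effects")
        for feat, freqs in self.design_feature_frequencies.items():
            if feat not in CATEGORICAL_LEVELS:
                raise ParameterError(f"unknown feature {feat!r} in frequencies")
            bad = set(freqs) - set(CATEGORICAL_LEVELS[feat])
            if bad:
                raise ParameterError(f"unknown options {sorted(bad)} for feature {feat!r}")
            if any(f < 0 for f in freqs.values()) or sum(freqs.values()) <= 0:
                raise ParameterError(f"invalid frequencies for feature {feat!r}")

    def mbl_overall_moments(self, tp: str) -> tuple[float, float]:
        """Mean and SD of the zero-inflated MBL marginal at a timepoint."""
        z = self.mbl_zero_fraction[tp]
        mp, sp = self.mbl_mean_sd_given_positive[tp]
        mean = (1.0 - z) * mp
        var = (1.0 - z) * (sp**2 + mp**2) - mean**2
        return mean, math.sqrt(max(var, 0.0))

    def slope(self, tp: str) -> float:
        """Effective CI-MBL slope at a timepoint (CI units per mm)."""
        if isinstance(self.ci_mbl_slope, dict):
            return float(self.ci_mbl_slope.get(tp, 0.0))
        if self.ci_mbl_slope is not None:
            return float(self.ci_mbl_slope)
        cc = self.ci_mbl_target_cc.get(tp, 0.0)
        _, sd_mbl = self.mbl_overall_moments(tp)
        if sd_mbl == 0:
            return 0.0
        _, sd_ci = self.ci_mean_sd[tp]
        return cc * sd_ci / sd_mbl


def _draw_categorical(
    rng: np.random.Generator, freqs: dict[str, float], size: int
) -> np.ndarray:
    opts = sorted(freqs)
    p = np.array([freqs[o] for o in opts], dtype=float)
    p = p / p.sum()
    return rng.choice(opts, size=size, p=p)


def generate_cohort(config: CohortSimConfig) -> tuple[list[CohortRecord], dict]:
    """Simulate a longitudinal implant cohort.

    Returns the records plus a ground-truth dictionary (configured
    moments, effective slopes, covariate effects) for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_implants

    features: dict[str, np.ndarray] = {}
    for feat in DESIGN_FEATURES + PROSTHETIC_FEATURES + (
        "sex",
        "smoking",
        "jaw",
        "arch_location",
        "augmented",
    ):
        freqs = config.design_feature_frequencies.get(feat)
        if freqs is None:
            freqs = DEFAULT_FEATURE_FREQUENCIES[feat]
        features[feat] = _draw_categorical(rng, freqs, n)
    technique = np.where(
        features["augmented"] == "yes",
        _draw_categorical(
            rng,
            {"bone_chips": 0.4, "bone_substitute": 0.3, "sinus_lift": 0.3},
            n,
        ),
        "none",
    )
    features["augmentation_technique"] = technique

    covs: dict[str, np.ndarray] = {}
    m, s = COVARIATE_POPULATION["age_y"]
    covs["age_y"] = np.clip(rng.normal(m, s, n), 18.0, 95.0)
    m, s = COVARIATE_POPULATION["height_m"]
    covs["height_m"] = np.clip(rng.normal(m, s, n), 1.4, 2.1)
    m, s = COVARIATE_POPULATION["weight_kg"]
    covs["weight_kg"] = np.clip(rng.normal(m, s, n), 40.0, 160.0)
    covs["bmi"] = covs["weight_kg"] / covs["height_m"] ** 2
    m, s = COVARIATE_POPULATION["tsh_mu_l"]
    covs["tsh_mu_l"] = np.clip(rng.normal(m, s, n), 0.05, None)
    m, s = COVARIATE_POPULATION["calcium_mmol_dl"]
    covs["calcium_mmol_dl"] = np.clip(rng.normal(m, s, n), 0.5, None)
    m, s = COVARIATE_POPULATION["triglycerides_mmol_l"]
    covs["triglycerides_mmol_l"] = np.clip(rng.normal(m, s, n), 0.1, None)

    cov_term = np.zeros(n)
    var_cov = 0.0
    for cov_name, effect in config.covariate_effects.items():
        pm, ps = COVARIATE_POPULATION[cov_name]
        cov_term += effect * (covs[cov_name] - pm) / ps
        var_cov += effect**2

    ci_cols: dict[str, np.ndarray] = {}
    mbl_cols: dict[str, np.ndarray] = {}
    slopes: dict[str, float] = {}
    for tp in config.timepoints:
        z = config.mbl_zero_fraction[tp]
        mp, sp = config.mbl_mean_sd_given_positive[tp]
        affected = rng.random(n) >= z
        mbl = np.zeros(n)
        n_pos = int(affected.sum())
        if n_pos:
            if sp > 0:
                mbl[affected] = _draw_zero_truncated(mp, sp, n_pos, rng)
            else:
                mbl[affected] = mp
        mbl_cols[tp] = mbl

        m_ci, s_ci = config.ci_mean_sd[tp]
        slope = config.slope(tp)
        slopes[tp] = slope
        mean_mbl, sd_mbl = config.mbl_overall_moments(tp)
        var_base = s_ci**2 - (slope * sd_mbl) ** 2 - var_cov
        if var_base <= 0:
            raise ParameterError(
                f"configured CI SD at {tp!r} too small for the coupling/covariate variance"
            )
        base = _draw_zero_truncated(m_ci, math.sqrt(var_base), n, rng)
        ci = base + slope * (mbl - mean_mbl) + cov_term
        ci_cols[tp] = np.maximum(ci, 0.0)

    records = []
    width = len(str(n))
    for i in range(n):
        kwargs = {"implant_id": f"imp{i:0{width}d}"}
        for feat, arr in features.items():
            kwargs[feat] = str(arr[i])
        for cov_name, arr in covs.items():
            kwargs[cov_name] = float(arr[i])
        for tp in config.timepoints:
            kwargs[f"ci_{tp}"] = float(ci_cols[tp][i])
            kwargs[f"mbl_{tp}"] = float(mbl_cols[tp][i])
        records.append(CohortRecord(**kwargs))

    ground_truth = {
        "seed": config.seed,
        "n_implants": n,
        "timepoints": list(config.timepoints),
        "ci_mean_sd": {tp: list(config.ci_mean_sd[tp]) for tp in config.timepoints},
        "mbl_zero_fraction": {tp: config.mbl_zero_fraction[tp] for tp in config.timepoints},
        "mbl_mean_sd_given_positive": {
            tp: list(config.mbl_mean_sd_given_positive[tp]) for tp in config.timepoints
        },
        "mbl_overall_mean_sd": {
            tp: list(config.mbl_overall_moments(tp)) for tp in config.timepoints
        },
        "ci_mbl_slope": slopes,
        "ci_mbl_target_cc": {
            tp: config.ci_mbl_target_cc.get(tp, 0.0) for tp in config.timepoints
        },
        "covariate_effects": dict(config.covariate_effects),
    }
    return records, ground_truth
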