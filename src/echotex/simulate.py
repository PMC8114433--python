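"""Synthetic ultrasound-like ROIs and synthetic cohorts with known effect sizes.

The image generator emulates what matters for second-order texture
statistics of muscle: a speckle field with a controllable correlation
length, plus bright elongated streaks standing in for hyperechoic
fat/fibrous infiltration. A single latent ``heterogeneity`` parameter in
[0, 1] moves an ROI from homogeneous "healthy" texture (high ASM/IDM,
low entropy) to heavily infiltrated texture (the reverse), and raises
mean echo intensity at the same time — so EI and entropy are positively
associated across ROIs, as observed on real muscle.

The cohort generator draws a latent muscle-quality score q per subject,
renders each subject's ROI at heterogeneity decreasing in q, computes
texture features from the rendered pixels, and generates function-test
scores tied to q with noise calibrated so that the realized Spearman
correlation between the anchor feature (entropy by default) and each
test converges to a requested target. Missingness is injected MCAR
(uniform) or MAR (probability rising with observed age).

Neither generator attempts physical B-mode realism (no beam physics,
attenuation or anatomy); see the package docs for what that implies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import expit

from . import reference
from .texture import GLCMFeatureExtractor

__all__ = ["ConfigError", "ImageSimConfig", "CohortSimConfig",
           "SimulatedCohort", "simulate_roi", "simulate_cohort"]


class ConfigError(ValueError):
    """Invalid or infeasible simulation configuration."""


@dataclass(frozen=True)
class ImageSimConfig:
    """Parameters of one synthetic speckle ROI.

    Parameters
    ----------
    height, width : int
        ROI size in pixels (>= 8).
    base_level : float
        Mean gray level of uninfiltrated muscle (0-255).
    speckle_scale : float
        Correlation length of the speckle field, pixels (> 0).
    speckle_amplitude : float
        Relative speckle contrast; 0 gives a noise-free field.
    heterogeneity : float
        0 = homogeneous muscle, 1 = heavy bright infiltration.
    infiltration_brightness : float
        Peak gray-level offset of an infiltration streak.
    n_streaks : int
        Streak count at heterogeneity 1 (scales down linearly).
    seed : int
        Generator seed; same config + seed is bit-reproducible.
    """

    height: int = 50
    width: int = 50
    base_level: float = 60.0
    speckle_scale: float = 1.5
    speckle_amplitude: float = 0.35
    heterogeneity: float = 0.0
    infiltration_brightness: float = 80.0
    n_streaks: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ConfigError(f"image must be at least 8x8, got "
                              f"{self.height}x{self.width}")
        if not 0.0 <= self.heterogeneity <= 1.0:
            raise ConfigError(f"heterogeneity must be in [0, 1], got "
                              f"{self.heterogeneity}")
        if self.speckle_scale <= 0:
            raise ConfigError("speckle_scale must be positive")
        if not 0 <= self.base_level <= 255:
            raise ConfigError("base_level must be in [0, 255]")


def simulate_roi(config: ImageSimConfig) -> np.ndarray:
    """Render one synthetic muscle ROI as a uint8 array.

    Speckle: the envelope sqrt(g1^2 + g2^2) of two independent smoothed
    Gaussian fields (a Rayleigh-like multiplicative texture), scaled to
    ``speckle_amplitude`` relative contrast around ``base_level``.
    Infiltration: ``round(n_streaks * heterogeneity)`` bright elongated
    Gaussian streaks with random position and orientation, brightness
    growing with heterogeneity.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    img = np.full((h, w), float(config.base_level))

    if config.speckle_amplitude > 0:
        g1 = gaussian_filter(rng.standard_normal((h, w)), config.speckle_scale)
        g2 = gaussian_filter(rng.standard_normal((h, w)), config.speckle_scale)
        env = np.hypot(g1, g2)
        env = env / env.mean()  # unit-mean multiplicative field
        img = config.base_level * (1.0 + config.speckle_amplitude * (env - 1.0))
    else:
        # keep the stream position deterministic w.r.t. amplitude
        rng.standard_normal((h, w))
        rng.standard_normal((h, w))

    het = config.heterogeneity
    k = int(round(config.n_streaks * het))
    if k > 0:
        rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
        for _ in range(k):
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, w)
            theta = rng.uniform(0, math.pi)
            length = rng.uniform(0.3, 0.8) * max(h, w)
            width_sd = rng.uniform(1.0, 3.0)
            gain = rng.uniform(0.7, 1.3)
            u = (rows - cy) * math.cos(theta) + (cols - cx) * math.sin(theta)
            v = -(rows - cy) * math.sin(theta) + (cols - cx) * math.cos(theta)
            profile = np.exp(-0.5 * (u / (length / 2.0)) ** 2
                             - 0.5 * (v / width_sd) ** 2)
            bright = config.infiltration_brightness * (0.3 + 0.7 * het) * gain
            img += bright * profile

    return np.clip(np.round(img), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class CohortSimConfig:
    """Parameters of one synthetic cohort.

    ``target_rho`` sets the Spearman correlation between the computed
    ``anchor_feature`` and each function test: either one float applied
    to every test, or a mapping test-name -> rho. Signs are taken
    literally (a negative value yields an anticorrelated test). The
    default reproduces the magnitude pattern of the published entropy
    row (|rho| 0.08-0.28).

    Demographic and lab distributions default to the published cohort
    summary (means/SDs); they are independent of the latent quality
    unless a downstream analysis couples them.
    """

    n_subjects: int = 90
    target_rho: float | Mapping[str, float] = field(
        default_factory=lambda: dict(reference.REFERENCE_RHO["entropy"]))
    anchor_feature: str = "entropy"
    missing_rate: float = 0.0
    missing_mechanism: str = "MCAR"
    demographics: Mapping[str, tuple | float] = field(
        default_factory=lambda: dict(reference.COHORT_SUMMARY))
    image: ImageSimConfig = field(default_factory=ImageSimConfig)
    heterogeneity_span: float = 1.0
    levels: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ConfigError("need at least 3 subjects")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise ConfigError(f"unknown missing mechanism "
                              f"{self.missing_mechanism!r}")
        for t, r in self._rho_map().items():
            if t not in reference.TEST_NAMES:
                raise ConfigError(f"unknown function test {t!r}")
            if abs(r) >= 0.95:
                raise ConfigError(f"|target_rho| for {t} must be < 0.95")
        if self.anchor_feature not in reference.FEATURE_NAMES:
            raise ConfigError(f"unknown anchor feature "
                              f"{self.anchor_feature!r}")

    def _rho_map(self) -> dict[str, float]:
        if isinstance(self.target_rho, Mapping):
            return dict(self.target_rho)
        return {t: float(self.target_rho) for t in reference.TEST_NAMES}


@dataclass
class SimulatedCohort:
    """A generated cohort: observed table, missingness mask, ground truth.

    ``data`` holds NaN where a value is missing; ``mask`` is True there.
    ``latent`` carries the per-subject latent quality q, the rendered
    heterogeneity, and the complete (pre-masking) values — the sidecar
    ground truth for recovery tests.
    """

    data: pd.DataFrame
    mask: pd.DataFrame
    latent: pd.DataFrame
    config: CohortSimConfig

    @property
    def n_subjects(self) -> int:
        return len(self.data)


_MASKABLE = ("bmi", "egfr", "hb", "albumin",
             "iswt", "gait_speed", "tuag", "sts60", "hgs")

def _normal_scores(x: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


def _solve_score_mix(anchor_ranks: np.ndarray, q: np.ndarray,
                     eps: np.ndarray, target: float, r_fq: float,
                     test_name: str) -> np.ndarray:
    """Mix latent q and noise so the realized Spearman hits ``target``.

    The score is s(w) = w*q + sqrt(1-w^2)*eps; the mixing weight w is
    solved numerically: the realized rank correlation with the already
    *measured* anchor feature is a monotone (step) function of w, so a
    bracketing root find lands within rank granularity of the target.
    """

    def realized(w: float) -> float:
        s = w * q + math.sqrt(max(1.0 - w * w, 0.0)) * eps
        return float(np.corrcoef(anchor_ranks, stats.rankdata(s))[0, 1])

    w_max = 0.999
    lo, hi = (-w_max, w_max) if r_fq > 0 else (w_max, -w_max)
    if not min(realized(lo), realized(hi)) <= target <= \
            max(realized(lo), realized(hi)):
        raise ConfigError(
            f"target rho {target} for {test_name} infeasible: anchor-"
            f"latent coupling is only {r_fq:.3f}")
    w = brentq(lambda v: realized(v) - target,
               min(lo, hi), max(lo, hi), xtol=1e-4, maxiter=200)
    return w * q + math.sqrt(max(1.0 - w * w, 0.0)) * eps


def simulate_cohort(config: CohortSimConfig) -> SimulatedCohort:
    """Generate a cohort whose texture features come from rendered pixels.

    Latent quality q ~ N(0,1) drives per-subject ROI heterogeneity
    (Phi(-q), worse quality = more infiltration) and, through a
    calibrated Gaussian-copula link, every function-test score. Texture
    features are then *measured* from the rendered ROI, not drawn from a
    distribution, so feature noise has the same origin as in a real
    analysis: finite-ROI sampling of the texture.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    rho_map = config._rho_map()

    q = rng.standard_normal(n)
    het = stats.norm.cdf(-q / config.heterogeneity_span)
    seeds = rng.integers(0, 2**31 - 1, size=n)

    rois = []
    for i in range(n):
        cfg_i = ImageSimConfig(
            height=config.image.height, width=config.image.width,
            base_level=config.image.base_level,
            speckle_scale=config.image.speckle_scale,
            speckle_amplitude=config.image.speckle_amplitude,
            heterogeneity=float(het[i]),
            infiltration_brightness=config.image.infiltration_brightness,
            n_streaks=config.image.n_streaks,
            seed=int(seeds[i]))
        rois.append(simulate_roi(cfg_i))

    feats = GLCMFeatureExtractor(levels=config.levels).fit_transform(rois)
    columns = ["asm", "entropy", "idm", "correlation", "contrast",
               "echo_intensity"]
    feat_df = pd.DataFrame(feats, columns=columns)

    anchor = feat_df[config.anchor_feature].to_numpy()
    r_fq = float(np.corrcoef(_normal_scores(anchor), q)[0, 1])
    if abs(r_fq) < 1e-6:
        raise ConfigError("anchor feature carries no latent signal; "
                          "increase heterogeneity contrast")
    anchor_ranks = stats.rankdata(anchor)

    demo = dict(config.demographics)
    tests = {}
    for t in reference.TEST_NAMES:
        target = rho_map.get(t)
        mean, sd = demo[t]
        if target is None:
            s = rng.standard_normal(n)
        else:
            eps = rng.standard_normal(n)
            s = _solve_score_mix(anchor_ranks, q, eps, float(target),
                                 r_fq, t)
        tests[t] = np.maximum(mean + sd * s, 0.0)

    age = demo["age"][0] + demo["age"][1] * rng.standard_normal(n)
    sex = np.where(rng.random(n) < demo["male_fraction"], "male", "female")
    eth_draw = rng.random(n)
    wf = demo["white_fraction"]
    ethnicity = np.where(eth_draw < wf, "white",
                         np.where(eth_draw < wf + 0.2, "south_asian",
                                  "other"))
    bmi = np.maximum(demo["bmi"][0] + demo["bmi"][1] * rng.standard_normal(n),
                     12.0)
    egfr = np.maximum(demo["egfr"][0]
                      + demo["egfr"][1] * rng.standard_normal(n), 4.0)
    hb = np.maximum(demo["hb"][0] + demo["hb"][1] * rng.standard_normal(n),
                    40.0)
    albumin = np.maximum(demo["albumin"][0]
                         + demo["albumin"][1] * rng.standard_normal(n), 15.0)
    htn = rng.random(n) < demo["hypertension_fraction"]
    dm = rng.random(n) < demo["diabetes_fraction"]

    data = pd.DataFrame({
        "subject_id": [f"S{i:05d}" for i in range(n)],
        "age": age, "sex": sex, "ethnicity": ethnicity,
        "bmi": bmi, "egfr": egfr, "hb": hb, "albumin": albumin,
        "hypertension": htn, "diabetes": dm,
        **{c: feat_df[c].to_numpy() for c in columns},
        **tests,
    })

    latent = pd.DataFrame({
        "subject_id": data["subject_id"],
        "latent_quality": q,
        "heterogeneity": het,
        "image_seed": seeds,
        **{f"true_{t}": tests[t] for t in reference.TEST_NAMES},
    })

    mask = pd.DataFrame(False, index=data.index, columns=data.columns)
    if config.missing_rate > 0:
        rate = config.missing_rate
        if config.missing_mechanism == "MCAR":
            p_subject = np.full(n, rate)
        else:  # MAR: older subjects more likely to miss assessments
            z_age = (age - age.mean()) / age.std()
            slope = 1.5

            def marginal(intercept: float) -> float:
                return float(expit(intercept + slope * z_age).mean()) - rate

            a = brentq(marginal, -20.0, 20.0)
            p_subject = expit(a + slope * z_age)
        for col in _MASKABLE:
            hit = rng.random(n) < p_subject
            mask[col] = hit
            data.loc[hit, col] = np.nan

    return SimulatedCohort(data=data, mask=mask, latent=latent,
                           config=config)
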