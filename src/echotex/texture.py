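"""Gray-level co-occurrence matrices (GLCM) and Haralick-style texture features.

A GLCM for displacement (dr, dc) counts ordered pixel pairs
``(p, p + (dr, dc))`` whose gray levels are (i, j); normalizing by the
number of in-bounds pairs gives the joint probability p(i, j). Second-order
features summarize this joint distribution:

* ASM (energy)     ``sum p(i,j)^2``          — high for uniform texture
* entropy          ``-sum p log p``          — textural disorder
* IDM (homogeneity)``sum p / (1 + (i-j)^2)`` — near-diagonal mass
* contrast         ``sum (i-j)^2 p``         — neighbor gray dispersion
* correlation      covariance of (i, j) under p, normalized per variant

The default displacement set is the four unit vectors
``[0 1], [-1 1], [-1 0], [-1 -1]`` (distance 1; the standard
0/45/90/135-degree set), and features are averaged over the four
directions so that no single orientation dominates.

Because the pair differences (i - j) are unchanged when every gray level
shifts by a constant, ASM/entropy/IDM/contrast (and the mean-centered
correlation) are invariant to constant brightness offsets — unlike echo
intensity, which tracks them one-for-one. That robustness to scanner
brightness settings is the point of using second-order statistics here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .imaging import echo_intensity

__all__ = [
    "DisplacementVector", "DEFAULT_DISPLACEMENTS", "FEATURE_NAMES",
    "CooccurrenceMatrix", "MarginalStats", "TextureFeatures",
    "DegenerateInputError", "quantize", "compute_glcm", "glcm_features",
    "averaged_features", "GLCMFeatureExtractor",
]

FEATURE_NAMES = ("asm", "entropy", "idm", "correlation", "contrast")


class DegenerateInputError(ValueError):
    """ROI too small for the displacement (no valid pixel pairs)."""


@dataclass(frozen=True)
class DisplacementVector:
    """Pixel offset (drow, dcol) defining one co-occurrence direction."""

    drow: int
    dcol: int
    label: str = ""

    def __post_init__(self) -> None:
        if (self.drow, self.dcol) == (0, 0):
            raise ValueError("displacement must be nonzero")


#: The four-direction, distance-1 set used throughout: 0, 45, 90 and 135
#: degrees in matrix (row, col) coordinates.
DEFAULT_DISPLACEMENTS: tuple[DisplacementVector, ...] = (
    DisplacementVector(0, 1, "0deg"),
    DisplacementVector(-1, 1, "45deg"),
    DisplacementVector(-1, 0, "90deg"),
    DisplacementVector(-1, -1, "135deg"),
)


@dataclass(frozen=True)
class MarginalStats:
    """Means and SDs of the row/column marginals of a GLCM."""

    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float


@dataclass(frozen=True)
class TextureFeatures:
    """The five GLCM features plus first-order echo intensity.

    ``correlation`` is NaN when undefined (zero marginal variance, e.g. a
    constant ROI); ``correlation_defined`` makes the marker explicit.
    """

    asm: float
    entropy: float
    idm: float
    correlation: float
    contrast: float
    echo_intensity: float = math.nan

    @property
    def correlation_defined(self) -> bool:
        return not math.isnan(self.correlation)

    def as_array(self) -> np.ndarray:
        return np.array([self.asm, self.entropy, self.idm,
                         self.correlation, self.contrast,
                         self.echo_intensity])


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Pair counts and probabilities for one displacement.

    ``counts[i, j]`` is the number of ordered pairs with gray(i) at the
    source pixel and gray(j) at the displaced pixel; ``probs`` sums to 1.
    """

    counts: np.ndarray
    displacement: DisplacementVector
    levels: int
    symmetric: bool = False
    n_pairs: int = field(init=False, default=0)
    probs: np.ndarray = field(init=False, default=None)

    def __post_init__(self) -> None:
        n = int(self.counts.sum())
        object.__setattr__(self, "n_pairs", n)
        object.__setattr__(self, "probs", self.counts / n if n else
                           np.zeros_like(self.counts, dtype=float))

    def marginal_stats(self) -> MarginalStats:
        px = self.probs.sum(axis=1)
        py = self.probs.sum(axis=0)
        lev = np.arange(self.levels, dtype=np.float64)
        mu_x = float(px @ lev)
        mu_y = float(py @ lev)
        sigma_x = float(math.sqrt(max(px @ lev**2 - mu_x**2, 0.0)))
        sigma_y = float(math.sqrt(max(py @ lev**2 - mu_y**2, 0.0)))
        return MarginalStats(mu_x, mu_y, sigma_x, sigma_y)


def quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width rebinning of 8-bit gray levels into ``levels`` bins.

    ``levels=256`` is the identity on uint8 input; bin k covers gray
    values in [256k/levels, 256(k+1)/levels).
    """
    if not 2 <= levels <= 256:
        raise ValueError(f"levels must be in [2, 256], got {levels}")
    arr = np.asarray(gray)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("gray levels must lie in [0, 255]")
    if levels == 256:
        return arr.astype(np.int64)
    return (arr.astype(np.int64) * levels) // 256


def _pair_views(q: np.ndarray, disp: DisplacementVector):
    """Aligned views (source, displaced) of all in-bounds pairs."""
    h, w = q.shape
    dr, dc = disp.drow, disp.dcol
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        return None, None
    src = q[r0:r1, c0:c1]
    dst = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    return src, dst


def compute_glcm(roi: np.ndarray, disp: DisplacementVector, *,
                 levels: int = 256, symmetric: bool = False) -> CooccurrenceMatrix:
    """Count gray-level pairs of ``roi`` at displacement ``disp``.

    Pairs whose displaced pixel falls outside the ROI are skipped.
    ``symmetric=True`` additionally counts each transposed pair, as in the
    symmetric Haralick formulation; the default counts ordered pairs only.
    """
    q = quantize(roi, levels)
    src, dst = _pair_views(q, disp)
    if src is None or src.size == 0:
        raise DegenerateInputError(
            f"ROI {q.shape} has no valid pairs for displacement "
            f"({disp.drow}, {disp.dcol})")
    codes = src.ravel() * levels + dst.ravel()
    counts = np.bincount(codes, minlength=levels * levels)
    if symmetric:
        counts = counts + np.bincount(dst.ravel() * levels + src.ravel(),
                                      minlength=levels * levels)
    counts = counts.reshape(levels, levels)
    return CooccurrenceMatrix(counts=counts, displacement=disp,
                              levels=levels, symmetric=symmetric)


def _features_from_counts(counts: np.ndarray, n_pairs: float,
                          correlation_variant: str,
                          log_base: float | None) -> TextureFeatures:
    # Sparse triplets keep the sums bit-identical under diagonal
    # translation of the matrix (constant gray offset of the ROI).
    ii, jj = np.nonzero(counts)
    p = counts[ii, jj] / n_pairs
    d = (ii - jj).astype(np.float64)
    asm = float(p @ p)
    ent = float(-(p @ np.log(p)))
    if log_base is not None:
        ent /= math.log(log_base)
    idm = float(p @ (1.0 / (1.0 + d * d)))
    con = float(p @ (d * d))
    # Correlation on indices re-centered at the minimum occupied level:
    # shift-invariant by construction (covariance and variances are
    # unchanged by per-variable offsets).
    x = (ii - ii.min()).astype(np.float64)
    y = (jj - jj.min()).astype(np.float64)
    mu_x, mu_y = float(p @ x), float(p @ y)
    var_x = float(p @ (x * x)) - mu_x * mu_x
    var_y = float(p @ (y * y)) - mu_y * mu_y
    cov = float(p @ (x * y)) - mu_x * mu_y
    if correlation_variant == "haralick":
        denom = math.sqrt(max(var_x, 0.0)) * math.sqrt(max(var_y, 0.0))
    elif correlation_variant == "walker":
        denom = var_x * var_y
    else:
        raise ValueError(
            f"correlation_variant must be 'walker' or 'haralick', "
            f"got {correlation_variant!r}")
    cor = cov / denom if denom > 0 else math.nan
    return TextureFeatures(asm=asm, entropy=ent, idm=idm,
                           correlation=cor, contrast=con)


def glcm_features(matrix: CooccurrenceMatrix, *,
                  correlation_variant: str = "walker",
                  log_base: float | None = None) -> TextureFeatures:
    """The five texture features of one co-occurrence matrix.

    Parameters
    ----------
    correlation_variant : {"walker", "haralick"}
        ``"haralick"`` normalizes the covariance by sigma_x * sigma_y
        (Pearson form, values in [-1, 1]); ``"walker"`` (default)
        normalizes by the product of the *variances*, giving the much
        smaller magnitudes characteristic of the ImageJ texture plugin
        this pipeline models.
    log_base : float, optional
        Entropy log base; natural log when None.
    """
    if matrix.n_pairs == 0:
        raise DegenerateInputError("empty co-occurrence matrix")
    return _features_from_counts(matrix.counts, matrix.n_pairs,
                                 correlation_variant, log_base)


def averaged_features(roi: np.ndarray,
                      disps: tuple[DisplacementVector, ...] = DEFAULT_DISPLACEMENTS,
                      *, levels: int = 256,
                      correlation_variant: str = "walker",
                      averaging: str = "feature",
                      symmetric: bool = False,
                      log_base: float | None = None,
                      with_ei: bool = True) -> TextureFeatures:
    """Direction-averaged texture features of one ROI.

    ``averaging="feature"`` (default) computes the five features per
    displacement and arithmetic-means them; ``averaging="matrix"``
    averages the probability matrices first and computes features once.
    Displacements with no valid pairs are skipped; if all are degenerate
    a :class:`DegenerateInputError` is raised. An undefined correlation in
    any direction makes the averaged correlation NaN.
    """
    if averaging not in ("feature", "matrix"):
        raise ValueError(f"averaging must be 'feature' or 'matrix', "
                         f"got {averaging!r}")
    mats = []
    for disp in disps:
        try:
            mats.append(compute_glcm(roi, disp, levels=levels,
                                     symmetric=symmetric))
        except DegenerateInputError:
            continue
    if not mats:
        raise DegenerateInputError("all displacements degenerate for this ROI")
    if averaging == "feature":
        feats = [glcm_features(m, correlation_variant=correlation_variant,
                               log_base=log_base) for m in mats]
        arr = np.array([[f.asm, f.entropy, f.idm, f.correlation, f.contrast]
                        for f in feats])
        asm, ent, idm, cor, con = arr.mean(axis=0)
        out = TextureFeatures(asm=float(asm), entropy=float(ent),
                              idm=float(idm), correlation=float(cor),
                              contrast=float(con))
    else:
        mean_probs = np.mean([m.probs for m in mats], axis=0)
        out = _features_from_counts(mean_probs, 1.0,
                                    correlation_variant, log_base)
    if with_ei:
        out = replace(out, echo_intensity=echo_intensity(roi))
    return out


class GLCMFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transform a batch of gray ROIs into texture-feature rows.

    Output columns are ``asm, entropy, idm, correlation, contrast`` and,
    when ``include_ei`` is set, ``echo_intensity``. Stateless apart from
    parameter validation; provided so texture extraction composes with
    scikit-learn pipelines.

    Parameters
    ----------
    levels : int
        Gray-level quantization (default 256 = native 8-bit).
    correlation_variant : {"walker", "haralick"}
    averaging : {"feature", "matrix"}
    symmetric : bool
        Count unordered (transposed) pairs as well.
    log_base : float or None
        Entropy log base (None = natural log).
    include_ei : bool
        Append first-order echo intensity as a sixth column.
    """

    def __init__(self, levels: int = 256,
                 correlation_variant: str = "walker",
                 averaging: str = "feature",
                 symmetric: bool = False,
                 log_base: float | None = None,
                 include_ei: bool = True):
        self.levels = levels
        self.correlation_variant = correlation_variant
        self.averaging = averaging
        self.symmetric = symmetric
        self.log_base = log_base
        self.include_ei = include_ei

    def fit(self, X, y=None):
        quantize(np.zeros((2, 2), dtype=np.uint8), self.levels)  # validates
        if self.correlation_variant not in ("walker", "haralick"):
            raise ValueError(f"bad correlation_variant "
                             f"{self.correlation_variant!r}")
        if self.averaging not in ("feature", "matrix"):
            raise ValueError(f"bad averaging {self.averaging!r}")
        self.n_features_out_ = 6 if self.include_ei else 5
        return self

    def transform(self, X) -> np.ndarray:
        """``X``: iterable of 2-D gray arrays (or one (n, H, W) stack)."""
        if not hasattr(self, "n_features_out_"):
            self.fit(X)
        rows = []
        for roi in X:
            f = averaged_features(
                np.asarray(roi), levels=self.levels,
                correlation_variant=self.correlation_variant,
                averaging=self.averaging, symmetric=self.symmetric,
                log_base=self.log_base, with_ei=self.include_ei)
            row = f.as_array()
            rows.append(row if self.include_ei else row[:5])
        return np.asarray(rows)

    def get_feature_names_out(self, input_features=None):
        names = list(FEATURE_NAMES)
        if self.include_ei:
            names.append("echo_intensity")
        return np.asarray(names, dtype=object)
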