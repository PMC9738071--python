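"""Gray-level texture features and the corticalization index.

The analysis pipeline prepares one ROI and derives three features from it:

1.  The ROI is intensity-normalized to the window ``[mu - 3*sigma,
    mu + 3*sigma]`` (``mu``, ``sigma`` from the raw ROI pixels) and
    quantized to ``Ng = 2**bits`` gray levels (6 bits, 64 levels, by
    default).
2.  *Mean optical density* — the mean of the normalized-histogram levels,
    ``sum_i i * p(i)``.
3.  *Difference entropy* (``DifEntr``) — the common-logarithm Shannon
    entropy of the co-occurrence difference histogram ``p_{x-y}(k)`` at a
    5-pixel spacing, averaged over the four lattice directions
    0°/45°/90°/135°.
4.  *Long-run emphasis* (``LngREmph``) — ``sum k^2 p(i,k) / sum p(i,k)``
    over the gray-level run-length matrix, averaged over the same four
    directions.

The corticalization index combines them as

    ``CI = mean_od * LngREmph_avg / DifEntr_avg``

so that bright, homogeneous, long-run (corticalized) bone scores high and
heterogeneous trabecular bone scores low.

Quantization boundaries are decided in exact integer arithmetic (see
:func:`normalize_and_quantize`), which makes the normalized levels — and
therefore every downstream feature — exactly invariant under integer
affine rescaling ``x -> a*x + b`` (``a > 0``) of the raw pixels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    EmptyRoiError,
    InsufficientExtentError,
    ParameterError,
    UndefinedCIWarning,
)
from .io import RadiographImage, RoiSpec, resolve_roi

__all__ = [
    "NormalizedRoi",
    "GlcmParams",
    "DifferenceHistogram",
    "RunLengthMatrix",
    "TextureFeatures",
    "normalize_and_quantize",
    "quantize_value",
    "first_order_mean",
    "glcm_difference_histogram",
    "difference_entropy",
    "run_length_matrix",
    "long_run_emphasis",
    "directional_average",
    "corticalization_index",
    "analyze_roi",
]


@dataclass
class GlcmParams:
    """Co-occurrence parameters: spacing and lattice directions.

    ``distance`` is the pixel spacing ``d``; the default directions are the
    standard four at Chebyshev distance ``d``: 0° ``(0, d)``, 45°
    ``(-d, d)``, 90° ``(-d, 0)`` and 135° ``(-d, -d)``.
    """

    distance: int = 5
    directions: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ParameterError(f"distance must be >= 1, got {self.distance}")
        if self.directions is None:
            d = self.distance
            self.directions = ((0, d), (-d, d), (-d, 0), (-d, -d))

    def run_directions(self) -> tuple[tuple[int, int], ...]:
        """Primitive (unit-step) versions of the directions, for run lengths."""
        out = []
        for dr, dc in self.directions:  # type: ignore[union-attr]
            g = math.gcd(abs(dr), abs(dc))
            out.append((dr // g, dc // g))
        return tuple(out)


@dataclass
class NormalizedRoi:
    """An ROI quantized to levels ``1..ng`` on a cropped grid.

    ``levels`` is an int array over the ROI bounding box, ``mask`` marks
    ROI membership; pixels outside the mask carry level 0 and never enter
    any statistic. ``origin`` locates the crop in the source image.
    """

    levels: np.ndarray
    mask: np.ndarray
    ng: int
    origin: tuple[int, int] = (0, 0)
    source_mu: float = float("nan")
    source_sigma: float = float("nan")
    degenerate: bool = False

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def masked_levels(self) -> np.ndarray:
        return self.levels[self.mask]

    @classmethod
    def from_levels(cls, levels: np.ndarray, ng: int, mask: np.ndarray | None = None) -> "NormalizedRoi":
        """Build directly from a level grid (levels in ``1..ng``)."""
        levels = np.asarray(levels)
        if mask is None:
            mask = np.ones(levels.shape, dtype=bool)
        return cls(levels=levels, mask=mask, ng=ng)


@dataclass
class DifferenceHistogram:
    """Normalized histogram of absolute level differences ``p_{x-y}(k)``."""

    probs: np.ndarray  # length ng, sums to 1
    pair_count: int
    offset: tuple[int, int] = (0, 0)


@dataclass
class RunLengthMatrix:
    """Run counts ``p(i, k)``: gray level ``i`` (rows) by run length ``k``."""

    counts: np.ndarray  # shape (ng, max_len)
    direction: tuple[int, int] = (0, 1)

    @property
    def total_runs(self) -> int:
        return int(self.counts.sum())


@dataclass
class TextureFeatures:
    """The three primary features plus the corticalization index.

    Directional features carry one value per direction; ``*_avg`` is their
    arithmetic mean. ``ci`` is NaN when the ROI is texture-free (zero
    difference entropy); ``ci_defined`` flags that case.
    """

    mean_od: float
    difentr_dir: tuple[float, ...]
    difentr_avg: float
    lngremph_dir: tuple[float, ...]
    lngremph_avg: float
    ci: float
    degenerate: bool = False

    @property
    def ci_defined(self) -> bool:
        return not math.isnan(self.ci)


# ---------------------------------------------------------------------------
# Normalization / quantization


def quantize_value(x: float, mu: float, sigma: float, ng: int = 64) -> int:
    """Quantize one raw value given window statistics (scalar reference form).

    ``level = clamp(floor((x - lo) / (hi - lo) * ng), 0, ng - 1) + 1`` with
    ``lo = mu - 3*sigma``, ``hi = mu + 3*sigma``. A zero-spread window maps
    everything to level 1.
    """
    if sigma == 0:
        return 1
    t = (x - (mu - 3.0 * sigma)) / (6.0 * sigma)
    return int(min(max(math.floor(t * ng), 0), ng - 1)) + 1


def _ge_c_sqrt(a: int, c: int, d: int) -> bool:
    """Exact integer decision of ``a >= c * sqrt(d)`` (``d >= 0``)."""
    if c == 0 or d == 0:
        return a >= 0
    if c > 0:
        return a >= 0 and a * a >= c * c * d
    # c < 0: rhs <= 0
    if a >= 0:
        return True
    return a * a <= c * c * d


def normalize_and_quantize(
    image: RadiographImage, roi: np.ndarray, bits: int = 6
) -> NormalizedRoi:
    """Window an ROI to ``mu +/- 3*sigma`` and quantize to ``2**bits`` levels.

    ``mu`` and ``sigma`` (population SD) come from the raw ROI pixels. The
    mapping is ``level = clamp(floor((x - lo)/(hi - lo) * Ng), 0, Ng-1) + 1``
    with ``lo = mu - 3*sigma``, ``hi = mu + 3*sigma``. Boundary decisions
    are made in exact integer arithmetic from the pixel sums, so integer
    affine rescaling of the raw data leaves the levels bit-identical.
    A constant ROI (``sigma = 0``) maps every pixel to level 1 and sets
    ``degenerate``.
    """
    roi = np.asarray(roi)
    if roi.ndim != 2 or roi.shape[1] != 2 or len(roi) == 0:
        raise EmptyRoiError("ROI pixel set must be a non-empty (n, 2) array")
    if bits < 1:
        raise ParameterError(f"bits must be >= 1, got {bits}")
    ng = 2**bits
    rows, cols = roi[:, 0], roi[:, 1]
    vals = image.pixels[rows, cols].astype(np.int64)
    n = len(vals)
    s1 = int(vals.sum())
    s2 = int(np.dot(vals, vals))
    disc = n * s2 - s1 * s1  # n^2 * sigma^2, exact integer
    mu = s1 / n
    sigma = math.sqrt(disc) / n if disc > 0 else 0.0

    r0, c0 = int(rows.min()), int(cols.min())
    shape = (int(rows.max()) - r0 + 1, int(cols.max()) - c0 + 1)
    grid = np.zeros(shape, dtype=np.int32)
    mask = np.zeros(shape, dtype=bool)
    mask[rows - r0, cols - c0] = True

    if disc <= 0:
        grid[rows - r0, cols - c0] = 1
        return NormalizedRoi(grid, mask, ng, (r0, c0), mu, 0.0, degenerate=True)

    # level(x) = 1 + #{m in 1..ng-1 : ng * (x - lo) >= m * (hi - lo)}
    #          = 1 + #{m : ng*(n*x - s1) >= (6m - 3*ng) * sqrt(disc)}
    a_vals = ng * (n * vals - s1)  # int64; |a| <= ng * n * xmax, well inside int64
    c_vals = 6 * np.arange(1, ng) - 3 * ng
    thresholds = c_vals * math.sqrt(disc)  # ascending
    lev = np.searchsorted(thresholds, a_vals.astype(np.float64), side="right")
    # re-decide boundary cases exactly (float tie within 0.5 of a threshold)
    idx_lo = np.clip(lev - 1, 0, len(thresholds) - 1)
    idx_hi = np.clip(lev, 0, len(thresholds) - 1)
    near = (
        np.abs(a_vals - thresholds[idx_lo]) < 0.5
    ) | (np.abs(a_vals - thresholds[idx_hi]) < 0.5)
    if near.any():
        d_int = int(disc)
        for i in np.flatnonzero(near):
            a = int(a_vals[i])
            lev[i] = sum(_ge_c_sqrt(a, int(c), d_int) for c in c_vals)
    grid[rows - r0, cols - c0] = lev + 1
    return NormalizedRoi(grid, mask, ng, (r0, c0), mu, sigma, degenerate=False)


# ---------------------------------------------------------------------------
# First-order feature


def first_order_mean(nroi: NormalizedRoi) -> float:
    """Mean optical density: ``sum_i i * p(i)`` over the level histogram.

    Numerically identical to the mean of the per-pixel levels.
    """
    if nroi.n_pixels == 0:
        raise EmptyRoiError("normalized ROI is empty")
    return float(nroi.masked_levels().mean())


# ---------------------------------------------------------------------------
# Co-occurrence difference histogram and difference entropy


def _shifted_views(arr: np.ndarray, dr: int, dc: int) -> tuple[np.ndarray, np.ndarray]:
    """Views of ``arr`` at positions p and p+(dr,dc), both in bounds."""
    h, w = arr.shape
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        empty = arr[:0, :0]
        return empty, empty
    return arr[r0:r1, c0:c1], arr[r0 + dr : r1 + dr, c0 + dc : c1 + dc]


def glcm_difference_histogram(
    nroi: NormalizedRoi, offset: tuple[int, int]
) -> DifferenceHistogram:
    """Difference histogram ``p_{x-y}(k)`` of the co-occurrence matrix.

    Pairs are counted symmetrically (both ``+offset`` and ``-offset``,
    ordered) and only when both members lie inside the ROI mask — a pair
    never bridges non-ROI pixels. ``k = |level_i - level_j|`` ranges over
    ``0..ng-1``.
    """
    dr, dc = offset
    if (dr, dc) == (0, 0):
        raise ParameterError("offset must be non-zero")
    a, b = _shifted_views(nroi.levels, dr, dc)
    ma, mb = _shifted_views(nroi.mask, dr, dc)
    valid = ma & mb
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise InsufficientExtentError(
            f"no pixel pair at offset {offset} lies fully inside the ROI"
        )
    diffs = np.abs(a[valid] - b[valid])
    counts = np.bincount(diffs, minlength=nroi.ng)[: nroi.ng]
    # symmetric counting doubles every tally and the pair count; p is unchanged
    probs = counts / n_valid
    return DifferenceHistogram(probs=probs, pair_count=2 * n_valid, offset=(dr, dc))


def difference_entropy(dh: DifferenceHistogram) -> float:
    """Shannon entropy (common logarithm) of the difference histogram.

    ``-sum_k p(k) log10 p(k)`` with ``0 * log 0 := 0``; bounded by
    ``log10(ng)``.
    """
    p = dh.probs[dh.probs > 0]
    return float(-(p * np.log10(p)).sum())


# ---------------------------------------------------------------------------
# Run-length matrix and long-run emphasis


def _line_starts(shape: tuple[int, int], dr: int, dc: int):
    """Starting points of all lattice lines of direction (dr, dc)."""
    h, w = shape
    starts = []
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if not (0 <= pr < h and 0 <= pc < w):
                starts.append((r, c))
    return starts


def run_length_matrix(nroi: NormalizedRoi, offset: tuple[int, int]) -> RunLengthMatrix:
    """Maximal equal-level runs along lines of the given direction.

    The offset is reduced to its primitive lattice step. A run breaks
    wherever the next lattice point leaves the ROI mask, so runs are
    confined to the ROI even for non-rectangular geometries.
    """
    dr, dc = offset
    if (dr, dc) == (0, 0):
        raise ParameterError("offset must be non-zero")
    g = math.gcd(abs(dr), abs(dc))
    dr, dc = dr // g, dc // g
    if nroi.n_pixels == 0:
        raise EmptyRoiError("normalized ROI is empty")
    levels, mask = nroi.levels, nroi.mask
    h, w = levels.shape
    run_counts: dict[tuple[int, int], int] = {}
    for r0, c0 in _line_starts((h, w), dr, dc):
        r, c = r0, c0
        cur_level = -1
        cur_len = 0
        while 0 <= r < h and 0 <= c < w:
            if mask[r, c]:
                lv = int(levels[r, c])
                if lv == cur_level:
                    cur_len += 1
                else:
                    if cur_len:
                        key = (cur_level, cur_len)
                        run_counts[key] = run_counts.get(key, 0) + 1
                    cur_level, cur_len = lv, 1
            else:
                if cur_len:
                    key = (cur_level, cur_len)
                    run_counts[key] = run_counts.get(key, 0) + 1
                cur_level, cur_len = -1, 0
            r += dr
            c += dc
        if cur_len:
            key = (cur_level, cur_len)
            run_counts[key] = run_counts.get(key, 0) + 1
    max_len = max((k for (_, k) in run_counts), default=1)
    counts = np.zeros((nroi.ng, max_len), dtype=np.int64)
    for (lv, k), n in run_counts.items():
        counts[lv - 1, k - 1] = n
    return RunLengthMatrix(counts=counts, direction=(dr, dc))


def long_run_emphasis(rlm: RunLengthMatrix) -> float:
    """``sum_{i,k} k^2 p(i,k) / sum_{i,k} p(i,k)``; at least 1."""
    total = rlm.counts.sum()
    if total == 0:
        raise EmptyRoiError("run-length matrix holds no runs")
    k = np.arange(1, rlm.counts.shape[1] + 1, dtype=np.float64)
    return float((rlm.counts.sum(axis=0) * k**2).sum() / total)


# ---------------------------------------------------------------------------
# Aggregation


def directional_average(values: Sequence[float]) -> float:
    """Arithmetic mean of the four directional feature values."""
    vals = np.asarray(values, dtype=float)
    if vals.shape != (4,):
        raise ParameterError(f"expected exactly 4 directional values, got {vals.shape}")
    if not np.all(np.isfinite(vals)):
        raise ParameterError("directional values must be finite")
    return float(vals.mean())


def corticalization_index(
    mean_od: float, lngremph_avg: float, difentr_avg: float
) -> float:
    """``CI = mean_od * LngREmph_avg / DifEntr_avg``.

    Long uniform runs of dense bone drive the numerator up; chaotic
    trabecular arrangement (high difference entropy) drives the score
    down. Returns NaN — with an :class:`UndefinedCIWarning` — when the
    difference entropy is zero (texture-free ROI).
    """
    if difentr_avg == 0:
        warnings.warn(
            "difference entropy is zero; corticalization index undefined",
            UndefinedCIWarning,
            stacklevel=2,
        )
        return float("nan")
    return mean_od * lngremph_avg / difentr_avg


def analyze_roi(
    image: RadiographImage,
    roi: RoiSpec | np.ndarray,
    params: GlcmParams | None = None,
    bits: int = 6,
    mean_on_raw: bool = False,
) -> TextureFeatures:
    """Full pipeline for one ROI: normalize, quantize, features, CI.

    ``roi`` may be an :class:`~periocort.io.RoiSpec` or an already-resolved
    ``(n, 2)`` pixel array. ``mean_on_raw=True`` computes the mean optical
    density from the raw gray values instead of the normalized levels (the
    default keeps all features on the one prepared ROI).
    """
    params = params or GlcmParams()
    pixels = resolve_roi(image, roi) if isinstance(roi, RoiSpec) else np.asarray(roi)
    nroi = normalize_and_quantize(image, pixels, bits=bits)
    if mean_on_raw:
        mean_od = float(image.pixels[pixels[:, 0], pixels[:, 1]].mean())
    else:
        mean_od = first_order_mean(nroi)
    difentr = tuple(
        difference_entropy(glcm_difference_histogram(nroi, off))
        for off in params.directions  # type: ignore[union-attr]
    )
    lngremph = tuple(
        long_run_emphasis(run_length_matrix(nroi, off)) for off in params.run_directions()
    )
    difentr_avg = directional_average(difentr)
    lngremph_avg = directional_average(lngremph)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UndefinedCIWarning)
        ci = corticalization_index(mean_od, lngremph_avg, difentr_avg)
    return TextureFeatures(
        mean_od=mean_od,
        difentr_dir=difentr,
        difentr_avg=difentr_avg,
        lngremph_dir=lngremph,
        lngremph_avg=lngremph_avg,
        ci=ci,
        degenerate=nroi.degenerate,
    )
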