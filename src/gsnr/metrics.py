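"""Empirical detectability metrics on envelope images and ROI masks.

The measurements here operate on pre-log-compression B-mode envelope data:
Smith-style contrast ``Cpsi`` (on intensity), the contrast ratio ``CR`` (on
envelope means), a rank-based empirical gCNR estimator, resolution-cell
counting, and the two detectability scores

    SNR  = Cpsi     * sqrt(M) * sqrt(N)     (classic, DAS-specific)
    gSNR = f(gCNR)  * sqrt(M) * sqrt(N)     (transformation robust)

with M the number of speckle resolution cells inside the lesion ROI and N
the number of independently compounded images (1 unless stated otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import analytic

__all__ = [
    "EnvelopeImage",
    "RoiSet",
    "DetectabilityResult",
    "cpsi_empirical",
    "cr_empirical",
    "gcnr_ecdf",
    "gcnr_hist_oracle",
    "resolution_cell_area",
    "count_cells",
    "snr",
    "gsnr",
]

#: Minimum number of pixels required in each ROI for a meaningful estimate.
MIN_REGION_PIXELS = 10


@dataclass
class EnvelopeImage:
    """2-D envelope (pre-log) image with physical pixel spacing.

    Rows are axial (depth), columns lateral.  ``dz``/``dx`` are the axial and
    lateral pixel spacings in mm.  Pixel values are nonnegative amplitudes.
    """

    pixels: np.ndarray
    dz: float
    dx: float
    label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("pixel values must be finite and >= 0")
        if self.dz <= 0 or self.dx <= 0:
            raise ValueError("pixel spacings must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in mm^2."""
        return self.dz * self.dx

    def with_pixels(self, pixels: np.ndarray, label: str | None = None) -> "EnvelopeImage":
        return EnvelopeImage(pixels, self.dz, self.dx, self.label if label is None else label)


@dataclass
class RoiSet:
    """Lesion and background masks plus the true-lesion provenance.

    The two masks must be congruent boolean grids, disjoint, each nonempty,
    and matched in pixel count to within 5% so that both regions contribute
    comparable sample sizes to the distribution estimates.
    """

    lesion_mask: np.ndarray
    background_mask: np.ndarray
    true_radius: float
    roi_fraction: float = 0.8
    dz: float = field(default=1.0)
    dx: float = field(default=1.0)

    def __post_init__(self) -> None:
        self.lesion_mask = np.asarray(self.lesion_mask, dtype=bool)
        self.background_mask = np.asarray(self.background_mask, dtype=bool)
        if self.lesion_mask.shape != self.background_mask.shape:
            raise ValueError("masks must have identical shapes")
        if np.any(self.lesion_mask & self.background_mask):
            raise ValueError("lesion and background masks must be disjoint")
        n_l = int(self.lesion_mask.sum())
        n_b = int(self.background_mask.sum())
        if n_l == 0 or n_b == 0:
            raise ValueError("both masks must be nonempty")
        if abs(n_l - n_b) / n_l > 0.05:
            raise ValueError(
                f"mask pixel counts differ by more than 5%: lesion={n_l}, background={n_b}"
            )
        if not (0.0 < self.roi_fraction <= 1.0):
            raise ValueError("roi_fraction must lie in (0, 1]")
        if self.dz <= 0 or self.dx <= 0:
            raise ValueError("pixel spacings must be > 0")

    @property
    def lesion_area(self) -> float:
        """Lesion-ROI area in mm^2 (pixel count times pixel area)."""
        return float(self.lesion_mask.sum()) * self.dz * self.dx


@dataclass(frozen=True)
class DetectabilityResult:
    """One detectability score with its ingredients and Rose verdict."""

    cpsi_or_f: float
    gcnr: float | None
    M: float
    N: int
    score: float
    rose_pass: bool

    def __post_init__(self) -> None:
        expected = self.cpsi_or_f * np.sqrt(self.M) * np.sqrt(self.N)
        if abs(self.score - expected) > 1e-12 * max(1.0, abs(expected)):
            raise ValueError("score is inconsistent with cpsi_or_f*sqrt(M)*sqrt(N)")


def _region_samples(img: EnvelopeImage, roi: RoiSet, min_pixels: int):
    if roi.lesion_mask.shape != img.shape:
        raise ValueError("ROI masks are not congruent with the image")
    lesion = img.pixels[roi.lesion_mask]
    background = img.pixels[roi.background_mask]
    if lesion.size < min_pixels or background.size < min_pixels:
        raise ValueError(f"each region needs at least {min_pixels} pixels")
    return lesion, background


def cpsi_empirical(
    img: EnvelopeImage,
    roi: RoiSet,
    signed: bool = False,
    min_pixels: int = MIN_REGION_PIXELS,
) -> float:
    """Smith-style contrast on intensity data: |I_L - I_B| / sqrt(I_L^2 + I_B^2).

    Intensities are the mean squared envelope over each mask.  The magnitude
    convention keeps the value in [0, 1]; ``signed=True`` preserves the sign
    (negative for hypoechoic lesions).
    """
    lesion, background = _region_samples(img, roi, min_pixels)
    il = float(np.mean(lesion**2))
    ib = float(np.mean(background**2))
    if ib == 0.0 and il == 0.0:
        raise ValueError("both regions are identically zero; contrast undefined")
    value = (il - ib) / np.hypot(il, ib)
    return float(value if signed else abs(value))


def cr_empirical(
    img: EnvelopeImage, roi: RoiSet, min_pixels: int = MIN_REGION_PIXELS
) -> tuple[float, float]:
    """Contrast ratio of mean envelope values, as (linear ratio, dB).

    CR = mean(envelope_L) / mean(envelope_B); the dB form uses the amplitude
    convention 20*log10(CR).
    """
    lesion, background = _region_samples(img, roi, min_pixels)
    mb = float(np.mean(background))
    if mb == 0.0:
        raise ValueError("background mean is zero; contrast ratio undefined")
    ratio = float(np.mean(lesion)) / mb
    db = 20.0 * np.log10(ratio) if ratio > 0 else -np.inf
    return ratio, float(db)


def gcnr_ecdf(x, y) -> float:
    """gCNR from empirical CDFs: the extremal span of H = F - G.

    The population identity gCNR = sum(H_max) - sum(H_min) runs over the
    local extrema of the CDF difference, which sit at the crossings of the
    two densities.  On raw pooled samples every interleaving of the two
    sample sets creates a spurious O(1/n) extremum of the empirical step
    function, so the plug-in extrema sum is evaluated as

        gCNR = max(H, 0).max() + max(-H, 0).max()

    over the pooled support.  For distributions whose densities cross at
    most twice in the interior -- which covers Rayleigh pairs and every
    monotone transform of them -- this equals the population extrema sum,
    while remaining stable against sampling noise.  The estimator is exactly
    rank-based: any strictly monotone transform applied jointly to both
    samples leaves it unchanged.  Identical samples give 0, samples with
    disjoint supports give 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample set needs at least 2 values")
    support = np.unique(np.concatenate([x, y]))
    fx = np.searchsorted(np.sort(x), support, side="right") / x.size
    gy = np.searchsorted(np.sort(y), support, side="right") / y.size
    h = fx - gy
    value = max(h.max(), 0.0) + max(-h.min(), 0.0)
    return float(min(max(value, 0.0), 1.0))


def gcnr_hist_oracle(x, y, n_bins: int = 100) -> float:
    """Brute-force gCNR = 1 - OVL via shared-bin histograms.

    Both samples are binned on a common grid spanning the pooled range and
    the overlap is the summed bin-wise minimum of the two probability mass
    functions.  Serves as an independent cross-check of :func:`gcnr_ecdf`.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if lo == hi:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    p, _ = np.histogram(x, bins=edges)
    q, _ = np.histogram(y, bins=edges)
    ovl = np.minimum(p / x.size, q / y.size).sum()
    return float(1.0 - ovl)


def resolution_cell_area(res_lat: float, res_ax: float) -> float:
    """Elliptical resolution-cell area Sc = pi * (res_lat/2) * (res_ax/2), mm^2."""
    if res_lat <= 0 or res_ax <= 0:
        raise ValueError("resolution lengths must be > 0")
    return float(np.pi * (res_lat / 2.0) * (res_ax / 2.0))


def count_cells(roi: RoiSet, sc: float) -> float:
    """Number of resolution cells in the lesion ROI, M = S / Sc."""
    if sc <= 0:
        raise ValueError("resolution cell area must be > 0")
    return roi.lesion_area / sc


def _check_score_inputs(contrast: float, m: float, n: int) -> None:
    if not 0.0 <= contrast <= 1.0:
        raise ValueError(f"contrast term must lie in [0, 1], got {contrast}")
    if m <= 0:
        raise ValueError("M must be > 0")
    if int(n) != n or n < 1:
        raise ValueError("N must be an integer >= 1")


def snr(cpsi: float, m: float, n: int = 1) -> DetectabilityResult:
    """Classic detectability score SNR = Cpsi * sqrt(M) * sqrt(N)."""
    _check_score_inputs(cpsi, m, n)
    score = float(cpsi * np.sqrt(m) * np.sqrt(n))
    return DetectabilityResult(
        cpsi_or_f=float(cpsi),
        gcnr=None,
        M=float(m),
        N=int(n),
        score=score,
        rose_pass=bool(score >= analytic.rose_threshold()),
    )


def gsnr(gcnr: float, m_tilde: float, n: int = 1, f_mode: str = "gompertz") -> DetectabilityResult:
    """Robust detectability score gSNR = f(gCNR) * sqrt(M~) * sqrt(N).

    ``f_mode`` selects the gCNR -> Cpsi bridge: ``'gompertz'`` (published
    coefficients, the practical default) or ``'exact'`` (numeric inverse of
    the analytic relation).  ``m_tilde`` should come from a transformation
    robust resolution estimate.
    """
    if f_mode == "gompertz":
        f_value = float(np.clip(analytic.f_gompertz(gcnr), 0.0, 1.0))
    elif f_mode == "exact":
        f_value = analytic.f_exact(gcnr)
    else:
        raise ValueError("f_mode must be 'gompertz' or 'exact'")
    _check_score_inputs(f_value, m_tilde, n)
    score = float(f_value * np.sqrt(m_tilde) * np.sqrt(n))
    return DetectabilityResult(
        cpsi_or_f=f_value,
        gcnr=float(gcnr),
        M=float(m_tilde),
        N=int(n),
        score=score,
        rose_pass=bool(score >= analytic.rose_threshold()),
    )
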