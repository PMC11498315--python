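"""Resolution-cell estimation for detectability scores.

Five ways of measuring the lateral/axial resolution that feed the
resolution-cell area Sc = pi*(res_lat/2)*(res_ax/2):

* raw PSF FWHM (the classic choice, valid for plain delay-and-sum data but
  manipulable by gray-level transforms);
* FWHM after histogram matching the image back to a DAS reference;
* Sparrow's two-point criterion (transform invariant: a dip between two
  points cannot be created or removed by a monotone map);
* speckle autocovariance length (intensity autocovariance FWHM);
* autoinformation length (mutual-information decay, exactly rank invariant).

Sparrow and autoinformation systematically predict smaller cells than the
FWHM even for DAS, so a DAS-derived calibration scalar per axis maps each
method onto the DAS FWHM scale before use in a detectability score.

Half maximum is applied to envelope amplitude, i.e. the -6 dB two-way
display convention; intensity-domain FWHM users should square first.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .metrics import EnvelopeImage

__all__ = [
    "ResolutionEstimate",
    "TwoPointSeries",
    "fwhm_profile",
    "psf_fwhm",
    "histogram_match",
    "matched_psf_fwhm",
    "sparrow_limit",
    "autocov_length",
    "autoinfo_length",
    "calibrate_to_das_fwhm",
]

_METHODS = ("fwhm", "fwhm_matched", "sparrow", "autocorr", "autoinfo")


@dataclass(frozen=True)
class ResolutionEstimate:
    """Per-method lateral/axial resolution lengths (mm) with calibration state."""

    method: str
    lateral: float
    axial: float
    scaled: bool = False
    calibration_lateral: float = 1.0
    calibration_axial: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.lateral <= 0 or self.axial <= 0:
            raise ValueError("resolution lengths must be > 0")


@dataclass
class TwoPointSeries:
    """Stack of two-point envelope images at increasing separations.

    ``stack[i]`` is the envelope image with the two points separated by
    ``separations[i]`` mm along ``axis``; both points are centered about the
    image midpoint and lie on the sampling grid.
    """

    stack: list
    separations: np.ndarray
    axis: str
    noise_snr_db: float = np.inf

    def __post_init__(self) -> None:
        self.separations = np.asarray(self.separations, dtype=float)
        if self.axis not in ("lateral", "axial"):
            raise ValueError("axis must be 'lateral' or 'axial'")
        if len(self.stack) != self.separations.size or self.separations.size < 3:
            raise ValueError("need >= 3 separations, one image each")
        if np.any(np.diff(self.separations) <= 0):
            raise ValueError("separations must be strictly increasing")


def fwhm_profile(values, spacing: float) -> float:
    """Full width at half maximum of a 1-D profile, in physical units.

    The global peak must be interior; the two half-maximum crossings nearest
    the peak are located by linear interpolation between samples.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 3:
        raise ValueError("profile must be 1-D with >= 3 samples")
    peak = int(np.argmax(values))
    if peak == 0 or peak == values.size - 1:
        raise ValueError("profile peak lies at the edge; FWHM undefined")
    half = values[peak] / 2.0

    def _cross(idx_from, step):
        i = idx_from
        while 0 <= i + step < values.size:
            j = i + step
            if values[j] <= half:
                # linear interpolation between samples i (above) and j (below)
                frac = (values[i] - half) / (values[i] - values[j])
                return i + step * frac
            i = j
        raise ValueError("no half-maximum crossing on one side of the peak")

    left = _cross(peak, -1)
    right = _cross(peak, +1)
    return float((right - left) * spacing)


def psf_fwhm(psf: EnvelopeImage) -> tuple[float, float]:
    """(lateral, axial) FWHM in mm of a single-peak PSF image.

    Profiles are the row and column through the brightest pixel.
    """
    pix = psf.pixels
    if pix.max() <= pix.min():
        raise ValueError("flat image has no PSF peak")
    r, c = np.unravel_index(int(np.argmax(pix)), pix.shape)
    lateral = fwhm_profile(pix[r, :], psf.dx)
    axial = fwhm_profile(pix[:, c], psf.dz)
    return lateral, axial


def histogram_match(
    src: EnvelopeImage,
    ref: EnvelopeImage,
    apply_to: EnvelopeImage | None = None,
    rescale_apply: bool = False,
) -> EnvelopeImage:
    """Monotone quantile map from ``src``'s value distribution to ``ref``'s.

    The map sends each quantile of ``src`` to the same quantile of ``ref``
    and is applied pointwise to ``apply_to`` (``src`` itself by default).
    Because a pointwise monotone gray-level transform permutes no ranks, the
    map exactly inverts such transforms up to quantization: matching a
    transformed speckle region back to its DAS reference recovers the DAS
    distribution.

    The map is learned from speckle statistics, so values of ``apply_to``
    outside the source range (a bright point target, say) would saturate at
    the reference extremes.  ``rescale_apply=True`` first scales ``apply_to``
    so its maximum coincides with the source maximum; for the power-law
    transform family the map is itself a power law, so this rescaling leaves
    the mapped shape -- and hence any width measurement -- unchanged.
    """
    src_vals = np.sort(src.pixels.ravel())
    if src_vals[0] == src_vals[-1]:
        raise ValueError("source image is constant; quantile map is degenerate")
    quantiles = np.linspace(0.0, 1.0, src_vals.size)
    ref_at_q = np.quantile(ref.pixels.ravel(), quantiles)
    target = src if apply_to is None else apply_to
    values = target.pixels
    if rescale_apply and values.max() > 0:
        values = values * (src_vals[-1] / values.max())
    mapped = np.interp(values, src_vals, ref_at_q)
    return target.with_pixels(mapped, label=f"{target.label}->matched({ref.label})")


def matched_psf_fwhm(
    psf: EnvelopeImage, src_speckle: EnvelopeImage, ref_speckle: EnvelopeImage
) -> tuple[float, float]:
    """PSF FWHM after histogram matching to the DAS reference.

    The quantile map is derived from homogeneous speckle of the transformed
    image (``src_speckle``) against the DAS reference speckle, then applied
    to the transformed PSF image (peak rescaled into the speckle range).
    """
    matched = histogram_match(src_speckle, ref_speckle, apply_to=psf, rescale_apply=True)
    return psf_fwhm(matched)


def _two_point_profile(img: EnvelopeImage, separation: float, axis: str):
    """Profile through the two point positions, and their pixel indices."""
    nz, nx = img.shape
    if axis == "lateral":
        profile = img.pixels[nz // 2, :]
        spacing = img.dx
    else:
        profile = img.pixels[:, nx // 2]
        spacing = img.dz
    center = profile.size // 2
    half = separation / 2.0 / spacing
    i1 = int(round(center - half))
    i2 = int(round(center + half))
    return profile, i1, i2


def _has_strict_local_min(values) -> bool:
    """Strict interior local minimum after compressing equal-value plateaus."""
    v = np.asarray(values, dtype=float)
    keep = np.ones(v.size, dtype=bool)
    keep[1:] = v[1:] != v[:-1]
    v = v[keep]
    if v.size < 3:
        return False
    return bool(np.any((v[1:-1] < v[:-2]) & (v[1:-1] < v[2:])))


def _has_interior_minimum(profile, i1: int, i2: int, fit_quartic: bool) -> bool:
    """True when a dip exists strictly between the two point positions.

    Just above the resolution limit the two maxima migrate inward from the
    point positions, so the test scans the window between the points for a
    strict local minimum rather than comparing against the endpoint values.
    """
    if i2 - i1 < 2:
        return False
    if fit_quartic:
        margin = max(1, int(round(0.2 * (i2 - i1))))
        lo = max(0, i1 - margin)
        hi = min(profile.size, i2 + margin + 1)
        x = np.arange(lo, hi, dtype=float)
        coeffs = np.polyfit(x - x.mean(), profile[lo:hi], 4)
        xf = np.linspace(i1, i2, 20 * (i2 - i1) + 1)
        yf = np.polyval(coeffs, xf - x.mean())
    else:
        yf = profile[i1 : i2 + 1]
    return _has_strict_local_min(yf)


def sparrow_limit(series: TwoPointSeries, fit_quartic: bool = False) -> float:
    """Sparrow resolution limit: smallest separation showing an interior dip.

    For each separation the profile through both points is scanned for a
    local minimum strictly between the peaks; with additive noise a quartic
    least-squares fit over the peak-to-peak window (plus 20% margin) smooths
    spurious minima, mirroring standard practice.  The scan must bracket the
    limit: no dip at the smallest separation, a dip at the largest.  A scan
    where every separation already shows a dip (the filtered
    delay-multiply-and-sum pathology) or none does raises a
    ``ValueError('resolution limit outside scan range')`` rather than
    returning a number.
    """
    detected = []
    for img, sep in zip(series.stack, series.separations):
        profile, i1, i2 = _two_point_profile(img, sep, series.axis)
        detected.append(_has_interior_minimum(profile, i1, i2, fit_quartic))
    detected = np.asarray(detected, dtype=bool)
    if detected.all() or not detected.any():
        raise ValueError("resolution limit outside scan range")
    return float(series.separations[int(np.argmax(detected))])


def _lag_curve_fwhm(curve, spacing: float) -> float:
    """Full width of a symmetric, lag-0-normalized curve at half maximum."""
    below = np.nonzero(curve < 0.5)[0]
    if below.size == 0:
        raise ValueError("curve never falls below half maximum; patch too small")
    j = int(below[0])
    if j == 0:
        return float(spacing)  # drops immediately: width below one lag
    frac = (curve[j - 1] - 0.5) / (curve[j - 1] - curve[j])
    half_width = (j - 1 + frac) * spacing
    return float(2.0 * half_width)


def autocov_length(speckle: EnvelopeImage, axis: str, max_lag_frac: float = 0.25) -> float:
    """Speckle correlation length: FWHM of the intensity autocovariance, mm.

    The mean-removed intensity autocovariance along ``axis`` (averaged over
    the perpendicular lines, lags up to a quarter of the patch extent) is
    normalized to lag 0 and its full width at half maximum is returned.  For
    a Gaussian PSF this width equals the PSF FWHM.  Invariant under global
    amplitude scaling; NOT invariant under nonlinear gray-level transforms.
    """
    if axis not in ("lateral", "axial"):
        raise ValueError("axis must be 'lateral' or 'axial'")
    intensity = speckle.pixels.astype(float) ** 2
    if axis == "lateral":
        data = intensity
        spacing = speckle.dx
    else:
        data = intensity.T
        spacing = speckle.dz
    n = data.shape[1]
    max_lag = max(2, int(n * max_lag_frac))
    if n < 16:
        raise ValueError("speckle patch too small along requested axis")
    centered = data - data.mean()
    cov = np.zeros(max_lag + 1)
    for lag in range(max_lag + 1):
        a = centered[:, : n - lag]
        b = centered[:, lag:]
        cov[lag] = np.mean(a * b)
    curve = cov / cov[0]
    return _lag_curve_fwhm(curve, spacing)


def _mutual_information(a_bins, b_bins, n_bins: int) -> float:
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (a_bins, b_bins), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    mask = joint > 0
    outer = np.outer(pa, pb)
    return float(np.sum(joint[mask] * np.log(joint[mask] / outer[mask])))


def autoinfo_length(
    speckle: EnvelopeImage,
    axis: str,
    threshold: float = 0.1,
    n_bins: int = 16,
    max_lag_frac: float = 0.25,
) -> float:
    """Autoinformation length: mutual-information decay of pixel pairs, mm.

    Pixels are rank-binned into ``n_bins`` equal-mass quantile classes and
    the mutual information between pairs at each integer lag along ``axis``
    is computed from the joint class histogram, then normalized by the lag-1
    value.  The length is twice the first lag where the normalized value
    drops below ``threshold`` (full-width convention, linearly
    interpolated).  Rank binning makes the measure exactly invariant under
    strictly monotone gray-level transforms.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if axis not in ("lateral", "axial"):
        raise ValueError("axis must be 'lateral' or 'axial'")
    data = speckle.pixels if axis == "lateral" else speckle.pixels.T
    spacing = speckle.dx if axis == "lateral" else speckle.dz
    n = data.shape[1]
    if n < 16:
        raise ValueError("speckle patch too small along requested axis")
    # rank-quantile class labels, computed once for the whole patch
    flat = data.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(flat.size)
    labels = (ranks * n_bins // flat.size).reshape(data.shape).astype(np.intp)
    max_lag = max(2, int(n * max_lag_frac))
    mi = np.zeros(max_lag + 1)
    for lag in range(1, max_lag + 1):
        a = labels[:, : n - lag].ravel()
        b = labels[:, lag:].ravel()
        # Under independence 2N*MI ~ chi^2 with (n_bins-1)^2 dof; subtract
        # the Miller-Madow bias and zero out values within the null noise.
        bias = (n_bins - 1) ** 2 / (2.0 * a.size)
        null_sd = (n_bins - 1) * np.sqrt(2.0) / (2.0 * a.size)
        raw = _mutual_information(a, b, n_bins)
        mi[lag] = raw - bias if raw >= bias + 2.0 * null_sd else 0.0
    if mi[1] <= 0:
        return float(2.0 * spacing)  # already independent at lag 1
    curve = mi / mi[1]
    below = np.nonzero(curve[1:] < threshold)[0]
    if below.size == 0:
        raise ValueError("autoinformation never falls below threshold; patch too small")
    j = int(below[0]) + 1  # first lag (>=1 indexing) below threshold
    if j == 1:
        lag_at = 1.0
    else:
        frac = (curve[j - 1] - threshold) / (curve[j - 1] - curve[j])
        lag_at = (j - 1) + frac
    return float(2.0 * lag_at * spacing)


def calibrate_to_das_fwhm(
    estimates: dict[str, ResolutionEstimate],
    das_fwhm: ResolutionEstimate,
    das_key: str = "DAS",
) -> dict[str, ResolutionEstimate]:
    """Scale one method's raw lengths so DAS lands on its FWHM value.

    All estimates must share the same method.  Per axis the scalar is
    ``das_fwhm_length / das_method_length`` and is applied uniformly to every
    beamformer, so the DAS scaled value equals the DAS FWHM by construction
    and relative comparisons between beamformers are preserved.
    """
    if das_key not in estimates:
        raise ValueError(f"estimates must include the DAS reference key {das_key!r}")
    methods = {e.method for e in estimates.values()}
    if len(methods) != 1:
        raise ValueError(f"all estimates must share one method, got {sorted(methods)}")
    das_raw = estimates[das_key]
    if das_raw.lateral <= 0 or das_raw.axial <= 0:
        raise ValueError("zero-length DAS estimate cannot be calibrated")
    s_lat = das_fwhm.lateral / das_raw.lateral
    s_ax = das_fwhm.axial / das_raw.axial
    return {
        key: replace(
            est,
            lateral=est.lateral * s_lat,
            axial=est.axial * s_ax,
            scaled=True,
            calibration_lateral=s_lat,
            calibration_axial=s_ax,
        )
        for key, est in estimates.items()
    }
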