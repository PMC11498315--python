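"""Gray-level transforms and channel-domain beamformers.

The power transform ``DAS^n`` on the envelope is the canonical example of a
metric-manipulating operation: it is clinically a no-op (a dynamic-range
remap) yet moves intensity-based contrast and raw-FWHM resolution.  The
channel-domain methods -- plain delay-and-sum (DAS), generalized coherence
factor (GCF) weighting, minimum-variance (Capon) apodization with subarray
smoothing and diagonal loading, and filtered delay-multiply-and-sum
(F-DMAS) -- operate on delayed per-channel samples produced by the
:mod:`gsnr.synth` simulator.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import firwin, hilbert

from .metrics import EnvelopeImage
from .synth import ChannelData

__all__ = [
    "das_transform",
    "das_sum",
    "gcf_weight",
    "mv_output",
    "dmas_combine",
    "fdmas_scanline",
    "delay_channels",
    "das_image",
    "gcf_image",
    "mv_image",
    "fdmas_image",
]


def das_transform(img: EnvelopeImage, n: float) -> EnvelopeImage:
    """Pointwise power of the envelope, |S|^n (n > 0).

    n = 1 is the identity; n = 2 and n = 0.5 are the squared and square-root
    dynamic-range transforms.  Any rank-based metric (gCNR, Sparrow,
    autoinformation) is invariant under this family.
    """
    if n <= 0:
        raise ValueError("power must be > 0")
    label = img.label if n == 1 else f"{img.label}^{n:g}"
    return img.with_pixels(img.pixels**n, label=label)


def das_sum(snapshot) -> float:
    """Plain unapodized channel sum."""
    return float(np.sum(snapshot))


def gcf_weight(snapshot, m0: int = 5) -> float:
    """Generalized coherence factor of one aperture snapshot, in [0, 1].

    Ratio of the spectral energy in the low-frequency region of the
    across-aperture discrete spectrum -- DC plus ``m0`` bins on each side --
    to the total energy.  A constant snapshot gives exactly 1; an all-zero
    snapshot is defined as 0.
    """
    snapshot = np.asarray(snapshot, dtype=float)
    n = snapshot.size
    if n <= 2 * m0:
        raise ValueError("channel count must exceed 2*m0")
    spectrum = np.abs(np.fft.fft(snapshot)) ** 2
    total = spectrum.sum()
    if total == 0.0:
        return 0.0
    low = spectrum[0] + spectrum[1 : m0 + 1].sum() + spectrum[n - m0 :].sum()
    return float(low / total)


def mv_output(snapshot, subarray_len: int, delta: float | None = None) -> float:
    """Minimum-variance (Capon) beamformed sample from one snapshot.

    Spatial smoothing averages the covariance over sliding subarrays of
    length L; diagonal loading eps = delta*tr(R) with delta = 1/(10 L) keeps
    the inversion well conditioned.  The distortionless constraint w'a = 1
    (a = ones) means a constant snapshot is returned unchanged, and L = 1
    reduces exactly to the channel mean.
    """
    x = np.asarray(snapshot, dtype=float)
    n = x.size
    L = int(subarray_len)
    if not 1 <= L <= n:
        raise ValueError("subarray length must satisfy 1 <= L <= channels")
    if delta is None:
        delta = 1.0 / (10.0 * L)
    k = n - L + 1
    subs = np.lib.stride_tricks.sliding_window_view(x, L)  # [k, L]
    r = subs.T @ subs / k
    trace = np.trace(r)
    if trace == 0.0:
        return 0.0
    r_loaded = r + delta * trace * np.eye(L)
    a = np.ones(L)
    w = np.linalg.solve(r_loaded, a)
    w /= a @ w
    return float(np.mean(subs @ w))


def dmas_combine(delayed: np.ndarray) -> np.ndarray:
    """Pairwise delay-multiply coupling: sum_{i<j} sign(s_i s_j) sqrt(|s_i s_j|).

    Computed per sample through the identity
    ``((sum s_hat)^2 - sum s_hat^2)/2`` with ``s_hat = sign(s) sqrt(|s|)``.
    For two identical nonnegative channels the single pair reduces to the
    channel itself; K identical channels scale the output by K(K-1)/2.
    """
    delayed = np.asarray(delayed, dtype=float)
    if delayed.ndim != 2 or delayed.shape[0] < 2:
        raise ValueError("delayed data must be [channels >= 2, samples]")
    s_hat = np.sign(delayed) * np.sqrt(np.abs(delayed))
    return (s_hat.sum(axis=0) ** 2 - (s_hat**2).sum(axis=0)) / 2.0


def fdmas_scanline(
    delayed: np.ndarray, fc: float, fs: float, numtaps: int = 95, envelope: bool = True
) -> np.ndarray:
    """Filtered delay-multiply-and-sum of delayed channels along one line.

    The pairwise mixing of :func:`dmas_combine` moves signal energy to DC
    and to twice the carrier; a linear-phase band-pass centered on 2*fc
    (passband 2*fc +/- fc/2) keeps only the second-harmonic component, and
    the envelope is taken from the analytic signal (``envelope=False``
    returns the filtered RF).  Requires fs > 4*fc.
    """
    if fs <= 4.0 * fc:
        raise ValueError("sampling rate too low to represent the 2*fc component")
    y = dmas_combine(delayed)
    # the linear-phase FIR cannot usefully exceed the scanline length
    numtaps = min(numtaps, 2 * (y.size // 4) + 1)
    if numtaps < 9:
        raise ValueError("scanline too short for the 2*fc band-pass filter")
    band = [2.0 * fc - fc / 2.0, 2.0 * fc + fc / 2.0]
    taps = firwin(numtaps, band, pass_zero=False, fs=fs)
    filtered = np.convolve(y, taps, mode="same")
    if not envelope:
        return filtered
    return np.abs(hilbert(filtered))


# ---------------------------------------------------------------------------
# image-domain wrappers over ChannelData
# ---------------------------------------------------------------------------


def delay_channels(cd: ChannelData, z_grid: np.ndarray) -> np.ndarray:
    """Geometric delay-and-sample: per-pixel aperture snapshots.

    Returns an array [beams, elements, len(z_grid)] of channel samples
    aligned to each (beam, depth) pixel by the two-way focused-transmit plus
    receive-path delay, using linear interpolation along the recorded time
    axis.
    """
    geom = cd.geometry
    z_grid = np.asarray(z_grid, dtype=float)
    c_mm = geom.sound_speed * 1e3
    out = np.zeros((geom.n_beams, geom.n_elements, z_grid.size))
    ex_rel = geom.element_x(0.0)  # aperture is centered on each beam
    d_tx = geom.focus + np.sign(z_grid - geom.focus) * np.abs(z_grid - geom.focus)
    for ei, exr in enumerate(ex_rel):
        d_rx = np.sqrt(exr**2 + z_grid**2)
        tau = (d_tx + d_rx) / c_mm
        for bi in range(geom.n_beams):
            out[bi, ei] = np.interp(tau, cd.time, cd.data[bi, ei], left=0.0, right=0.0)
    return out


def _scanlines_to_image(lines: np.ndarray, z_grid: np.ndarray, geom, envelope: bool = True):
    dz = float(z_grid[1] - z_grid[0])
    pixels = np.abs(hilbert(lines, axis=1)).T if envelope else lines.T
    return EnvelopeImage(pixels, dz=dz, dx=geom.beam_spacing, label="")


def das_image(cd: ChannelData, z_grid: np.ndarray) -> EnvelopeImage:
    """Unapodized delay-and-sum image, envelope via the analytic signal."""
    delayed = delay_channels(cd, z_grid)
    lines = delayed.sum(axis=1)  # [beams, nz]
    img = _scanlines_to_image(lines, z_grid, cd.geometry)
    img.label = "DAS"
    return img


def gcf_image(cd: ChannelData, z_grid: np.ndarray, m0: int = 5) -> EnvelopeImage:
    """Coherence-factor-weighted DAS image."""
    delayed = delay_channels(cd, z_grid)
    nb, _, nz = delayed.shape
    lines = np.zeros((nb, nz))
    for bi in range(nb):
        for zi in range(nz):
            snap = delayed[bi, :, zi]
            lines[bi, zi] = gcf_weight(snap, m0) * snap.sum()
    img = _scanlines_to_image(lines, z_grid, cd.geometry)
    img.label = "GCF"
    return img


def mv_image(cd: ChannelData, z_grid: np.ndarray, subarray_len: int | None = None) -> EnvelopeImage:
    """Minimum-variance image; subarray length defaults to half the aperture."""
    delayed = delay_channels(cd, z_grid)
    nb, ne, nz = delayed.shape
    L = subarray_len or max(1, ne // 2)
    lines = np.zeros((nb, nz))
    for bi in range(nb):
        for zi in range(nz):
            lines[bi, zi] = mv_output(delayed[bi, :, zi], L)
    img = _scanlines_to_image(lines, z_grid, cd.geometry)
    img.label = "MV"
    return img


def fdmas_image(cd: ChannelData, z_grid: np.ndarray) -> EnvelopeImage:
    """Filtered delay-multiply-and-sum image.

    The delayed data are resampled onto the depth grid, so the effective
    sampling rate handed to the band-pass is c/(2*dz).
    """
    geom = cd.geometry
    delayed = delay_channels(cd, z_grid)
    dz_m = float(z_grid[1] - z_grid[0]) * 1e-3
    fs_eff = geom.sound_speed / (2.0 * dz_m)
    lines = np.stack([fdmas_scanline(delayed[bi], geom.fc, fs_eff) for bi in range(delayed.shape[0])])
    img = _scanlines_to_image(lines, z_grid, geom, envelope=False)
    img.label = "F-DMAS"
    return img
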