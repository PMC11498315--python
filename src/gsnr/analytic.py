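"""Closed-form speckle-contrast relations for Rayleigh-distributed envelopes.

For fully developed speckle the envelope amplitude in a homogeneous region is
Rayleigh distributed and the intensity (squared envelope) is exponential.  A
hypoechoic lesion and its background are then fully described by the two
Rayleigh scale parameters ``sigma_lesion`` and ``sigma_background``, or
equivalently by the intensity ratio

    R = CR^2 = sigma_lesion^2 / sigma_background^2.

This module provides the exact bridges between the three contrast measures
used for lesion detectability:

* ``Cpsi`` -- Smith-style normalized intensity contrast,
  ``|I_L - I_B| / sqrt(I_L^2 + I_B^2)``;
* ``CR^2`` -- the intensity ratio itself;
* ``gCNR`` -- one minus the overlap of the two envelope distributions.

For Rayleigh pairs all three are deterministic functions of one another, so
gCNR (which is invariant under monotone gray-level transforms) can stand in
for Cpsi inside a detectability score.  The bridge ``f(gCNR) = Cpsi`` has no
closed form; an exact numeric inverse and a compact four-parameter Gompertz
approximation are provided, along with Rose-criterion utilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "RayleighPair",
    "ContrastTriple",
    "GompertzCoefficients",
    "PRINTED_GOMPERTZ",
    "cpsi_from_cr2",
    "cr2_from_cpsi",
    "rayleigh_pdf_intersection",
    "gcnr_from_cr2",
    "gcnr_from_cpsi",
    "f_exact",
    "f_gompertz",
    "refit_gompertz",
    "rose_threshold",
    "min_contrast_curves",
    "analytic_curve_table",
]

# Relative guard band around R = 1 inside which the analytic limit (zero
# contrast) is returned instead of evaluating the indeterminate forms.
_R_GUARD = 1e-9


@dataclass(frozen=True)
class RayleighPair:
    """Scale parameters of the lesion and background envelope distributions."""

    sigma_lesion: float
    sigma_background: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma_lesion) and self.sigma_lesion > 0):
            raise ValueError("sigma_lesion must be finite and > 0")
        if not (np.isfinite(self.sigma_background) and self.sigma_background > 0):
            raise ValueError("sigma_background must be finite and > 0")

    @property
    def cr2(self) -> float:
        """Intensity ratio R = sigma_L^2 / sigma_B^2."""
        return (self.sigma_lesion / self.sigma_background) ** 2

    @property
    def rate_lesion(self) -> float:
        """Exponential rate of the lesion intensity, 1/(2 sigma_L^2)."""
        return 1.0 / (2.0 * self.sigma_lesion**2)

    @property
    def rate_background(self) -> float:
        return 1.0 / (2.0 * self.sigma_background**2)


@dataclass(frozen=True)
class ContrastTriple:
    """Mutually consistent (Cpsi, CR^2, gCNR) values for one Rayleigh pair."""

    cpsi: float
    cr2: float
    gcnr: float


@dataclass(frozen=True)
class GompertzCoefficients:
    """Coefficients of f(g) = a + b*exp(-exp(-c*(g - d)))."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if self.b * self.c <= 0:
            raise ValueError("b*c must be positive for a monotone increasing map")

    def __call__(self, gcnr):
        g = np.asarray(gcnr, dtype=float)
        out = self.a + self.b * np.exp(-np.exp(-self.c * (g - self.d)))
        return float(out) if np.isscalar(gcnr) else out

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


#: Published Gompertz approximation of the gCNR -> Cpsi bridge.
PRINTED_GOMPERTZ = GompertzCoefficients(a=-0.5506, b=1.627, c=3.181, d=0.0247)


def _check_cr2(cr2: float) -> float:
    cr2 = float(cr2)
    if not np.isfinite(cr2) or cr2 <= 0:
        raise ValueError(f"intensity ratio must be finite and > 0, got {cr2}")
    return cr2


def cpsi_from_cr2(cr2: float, signed: bool = False) -> float:
    """Normalized intensity contrast for an intensity ratio R = sigma_L^2/sigma_B^2.

    With exponential intensities, mean intensities are proportional to the
    squared Rayleigh scales, so

        Cpsi = (R - 1) / sqrt(R^2 + 1).

    By default the magnitude is returned (Cpsi in [0, 1]); ``signed=True``
    keeps the sign (negative for hypoechoic lesions, R < 1).
    """
    cr2 = _check_cr2(cr2)
    value = (cr2 - 1.0) / np.hypot(cr2, 1.0)
    return float(value if signed else abs(value))


def cr2_from_cpsi(cpsi: float, branch: str = "hypo") -> float:
    """Invert the Cpsi(R) relation.

    Both R and 1/R produce the same |Cpsi|; ``branch='hypo'`` returns the
    root R <= 1 (hypoechoic lesion), ``branch='hyper'`` the root R >= 1.
    ``cpsi=1`` is the anechoic limit and maps to exactly 0 on the hypo branch.
    """
    cpsi = float(cpsi)
    if branch not in ("hypo", "hyper"):
        raise ValueError("branch must be 'hypo' or 'hyper'")
    if not np.isfinite(cpsi) or not 0.0 <= cpsi <= 1.0:
        raise ValueError(f"cpsi must lie in [0, 1], got {cpsi}")
    if cpsi == 1.0:
        if branch == "hypo":
            return 0.0
        raise ValueError("cpsi = 1 has no finite hyperechoic root")
    # (R - 1)^2 = c^2 (R^2 + 1)  ->  u R^2 - 2 R + u = 0 with u = 1 - c^2.
    # The R <= 1 root (1 - sqrt(1 - u^2))/u is rationalized to u/(1 + c*sqrt(2 - c^2)),
    # which is free of cancellation at both ends of the domain.
    u = 1.0 - cpsi**2
    root = u / (1.0 + cpsi * np.sqrt(2.0 - cpsi**2))
    return float(root if branch == "hypo" else 1.0 / root)


def rayleigh_pdf_intersection(pair: RayleighPair) -> float:
    """Interior crossing point x0 of the two Rayleigh PDFs.

    Solving pdf_L(x0) = pdf_B(x0) gives

        x0^2 = 4 sigma_L^2 sigma_B^2 ln(sigma_B^2/sigma_L^2)
               / (2 sigma_B^2 - 2 sigma_L^2),

    which is symmetric under swapping the two scales.  Equal scales have no
    unique interior crossing.
    """
    sl2 = pair.sigma_lesion**2
    sb2 = pair.sigma_background**2
    if np.isclose(sl2, sb2, rtol=_R_GUARD, atol=0.0):
        raise ValueError("identical scale parameters: PDFs have no unique crossing")
    x0sq = 4.0 * sl2 * sb2 * np.log(sb2 / sl2) / (2.0 * sb2 - 2.0 * sl2)
    return float(np.sqrt(x0sq))


def gcnr_from_cr2(cr2: float) -> float:
    """Exact gCNR of two Rayleigh distributions with intensity ratio R.

    The CDF difference H = CDF_L - CDF_B has a single interior extremum at
    the PDF crossing x0, and gCNR = |H(x0)|.  Substituting x0 yields

        gCNR = | R^(-R/(R-1)) - R^(-1/(R-1)) |,

    symmetric under R <-> 1/R, zero at R = 1 and approaching 1 in the
    anechoic limit.  A guard band around R = 1 returns the limit 0 instead of
    evaluating the indeterminate form.
    """
    cr2 = _check_cr2(cr2)
    if abs(cr2 - 1.0) <= _R_GUARD:
        return 0.0
    log_r = np.log(cr2)
    q = log_r / (cr2 - 1.0)
    return float(abs(np.exp(-cr2 * q) - np.exp(-q)))


def gcnr_from_cpsi(cpsi: float) -> float:
    """Exact gCNR for a given |Cpsi| (inverse of the bridge f).

    Composition of :func:`cr2_from_cpsi` and :func:`gcnr_from_cr2`; the
    branch choice is immaterial because gCNR is symmetric in R <-> 1/R.
    Monotone increasing on [0, 1] with endpoints 0 -> 0 and 1 -> 1.
    """
    cpsi = float(cpsi)
    if not np.isfinite(cpsi) or not 0.0 <= cpsi <= 1.0:
        raise ValueError(f"cpsi must lie in [0, 1], got {cpsi}")
    if cpsi == 1.0:
        return 1.0
    return gcnr_from_cr2(cr2_from_cpsi(cpsi, branch="hypo"))


def f_exact(gcnr: float, xtol: float = 1e-14) -> float:
    """Exact bridge f(gCNR) = Cpsi, by bracketed root finding.

    ``gcnr_from_cpsi`` is continuous and strictly increasing on [0, 1], so
    the inverse is found by Brent's method on that bracket (no closed form
    exists).  Residual |gcnr_from_cpsi(f(g)) - g| < 1e-10.
    """
    gcnr = float(gcnr)
    if not np.isfinite(gcnr) or not 0.0 <= gcnr <= 1.0:
        raise ValueError(f"gcnr must lie in [0, 1], got {gcnr}")
    if gcnr == 0.0:
        return 0.0
    if gcnr == 1.0:
        return 1.0
    return float(brentq(lambda c: gcnr_from_cpsi(c) - gcnr, 0.0, 1.0, xtol=xtol))


def f_gompertz(gcnr, coeffs: GompertzCoefficients = PRINTED_GOMPERTZ):
    """Gompertz approximation of the bridge f(gCNR) = Cpsi.

    With the published coefficients the approximation stays within a few
    parts in a thousand of :func:`f_exact` over the whole [0, 1] range, which
    is far below the sampling noise of any empirical gCNR estimate.
    """
    g = np.asarray(gcnr, dtype=float)
    if np.any(~np.isfinite(g)) or np.any(g < 0.0) or np.any(g > 1.0):
        raise ValueError("gcnr values must lie in [0, 1]")
    return coeffs(gcnr)


def refit_gompertz(
    n_grid: int = 1000,
    grid: str = "gcnr",
    minimax_polish: bool = False,
) -> GompertzCoefficients:
    """Refit the four-parameter Gompertz bridge on the exact relation.

    Pairs (gCNR, Cpsi) are generated from the exact analytic chain and the
    Gompertz form is fit by nonlinear least squares.  ``grid`` selects how
    the pairs are sampled: ``'gcnr'`` (default) spaces them uniformly in the
    independent variable gCNR, ``'cpsi'`` uniformly in Cpsi.  The fit is
    deterministic given the grid.  ``minimax_polish=True`` follows the least
    squares solution with an iteratively reweighted pass that minimizes the
    worst-case deviation instead of the mean square.

    Raises ``RuntimeError`` with solver diagnostics on non-convergence.
    """
    if n_grid < 100:
        raise ValueError("n_grid must be >= 100")
    if grid == "gcnr":
        gs = np.linspace(0.0, 1.0, n_grid)
        cs = np.array([f_exact(g) for g in gs])
    elif grid == "cpsi":
        cs = np.linspace(0.0, 1.0, n_grid)
        gs = np.array([gcnr_from_cpsi(c) for c in cs])
    else:
        raise ValueError("grid must be 'gcnr' or 'cpsi'")

    def residuals(p):
        a, b, c, d = p
        return a + b * np.exp(-np.exp(-c * (gs - d))) - cs

    x0 = np.array(PRINTED_GOMPERTZ.as_tuple())
    sol = least_squares(residuals, x0, method="lm", max_nfev=20000)
    if not sol.success:
        raise RuntimeError(f"Gompertz fit did not converge: {sol.message}")
    p = sol.x
    if minimax_polish:
        # Soft-minimax continuation: raise the residual exponent so the fit
        # is progressively dominated by the largest deviations.
        for power in (4, 8, 16, 32, 64):
            sol = least_squares(
                lambda q: np.abs(residuals(q)) ** (power / 2.0),
                p,
                method="lm",
                max_nfev=20000,
            )
            if sol.success:
                p = sol.x
    return GompertzCoefficients(*[float(v) for v in p])


def rose_threshold() -> float:
    """Rose-criterion detectability threshold on the speckle SNR scale, 5/sqrt(2)."""
    return 5.0 / np.sqrt(2.0)


def min_contrast_curves(m_values, threshold: float | None = None):
    """Minimum detectable contrast per resolution-cell count M.

    For a detectability score Cpsi*sqrt(M) to reach ``threshold`` (the Rose
    threshold by default), the contrast must satisfy
    ``cpsi >= threshold/sqrt(M)`` (clipped at the anechoic bound 1); the
    matching gCNR threshold follows through the exact bridge inverse.

    Returns an array of (M, cpsi_min, gcnr_min) rows.
    """
    if threshold is None:
        threshold = rose_threshold()
    threshold = float(threshold)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    m_values = np.atleast_1d(np.asarray(m_values, dtype=float))
    if np.any(m_values <= 0):
        raise ValueError("M values must be > 0")
    cpsi_min = np.minimum(threshold / np.sqrt(m_values), 1.0)
    gcnr_min = np.array([gcnr_from_cpsi(c) for c in cpsi_min])
    return np.column_stack([m_values, cpsi_min, gcnr_min])


def analytic_curve_table(n: int = 1000, cr_db_range: tuple[float, float] = (-40.0, 0.0)):
    """(CR_dB, cpsi, gcnr) samples of the exact Rayleigh relations.

    CR here is the envelope-mean ratio, so CR_dB = 20*log10(sigma_L/sigma_B)
    and the intensity ratio is R = 10^(CR_dB/10).  Returns a structured
    array-like list of :class:`ContrastTriple` plus the dB grid, convenient
    for tabulating the contrast curves.
    """
    cr_db = np.linspace(cr_db_range[0], cr_db_range[1], n)
    rows = []
    for db in cr_db:
        r = 10.0 ** (db / 10.0)
        rows.append(ContrastTriple(cpsi=cpsi_from_cr2(r), cr2=r, gcnr=gcnr_from_cr2(r)))
    return cr_db, rows
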