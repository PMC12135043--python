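"""Langmuir monolayer analysis.

Compression isotherms π(A) of an insoluble amphiphile film report on film
elasticity through the compression modulus

    Cs⁻¹ = −A (∂π/∂A)_T        [mN m⁻¹]

whose interior minima mark first-order phase transitions (the liquid-expanded
to liquid-condensed plateau of a saturated phospholipid appears as a dip of
Cs⁻¹ near the plateau pressure).  Constant-area insertion experiments, where a
solute is injected under a pre-compressed film, follow pseudo-first-order
kinetics

    Δπ(t) = Δπ_max (1 − e^{−β t})

and the line Δπ_max versus the initial pressure π₀ extrapolates to the
exclusion surface pressure at its abscissa intercept — the highest film
pressure at which the solute still penetrates the monolayer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Isotherm",
    "ModulusCurve",
    "InsertionTrace",
    "KineticsFit",
    "ExclusionResult",
    "compression_modulus",
    "detect_transition",
    "fit_insertion_kinetics",
    "exclusion_pressure",
]


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class Isotherm:
    """Surface pressure vs. molecular area record of one compression.

    Parameters
    ----------
    area_per_molecule : array, Å² molecule⁻¹ (all > 0)
    surface_pressure : array, mN m⁻¹
    temperature : °C
    label : free text (film composition, subphase)
    """

    area_per_molecule: np.ndarray
    surface_pressure: np.ndarray
    temperature: float = 24.0
    label: str = ""

    def __post_init__(self):
        self.area_per_molecule = _as_1d(self.area_per_molecule, "area_per_molecule")
        self.surface_pressure = _as_1d(self.surface_pressure, "surface_pressure")
        if self.area_per_molecule.shape != self.surface_pressure.shape:
            raise ValueError("area and pressure series must have equal length")
        if self.area_per_molecule.size < 5:
            raise ValueError("an isotherm needs at least 5 points")
        if np.any(self.area_per_molecule <= 0):
            raise ValueError("molecular areas must be strictly positive")

    def __len__(self) -> int:
        return self.area_per_molecule.size


@dataclass
class ModulusCurve:
    """Elastic compression modulus Cs⁻¹ as a function of surface pressure."""

    surface_pressure: np.ndarray  # mN m⁻¹
    cs_inverse: np.ndarray  # mN m⁻¹

    def __post_init__(self):
        self.surface_pressure = _as_1d(self.surface_pressure, "surface_pressure")
        self.cs_inverse = _as_1d(self.cs_inverse, "cs_inverse")
        if self.surface_pressure.shape != self.cs_inverse.shape:
            raise ValueError("series must have equal length")


@dataclass
class InsertionTrace:
    """Constant-area surface-pressure increase after solute injection.

    ``time`` starts at zero and is strictly increasing; ``delta_pi`` is the
    pressure increase over the initial pressure ``pi_zero``.
    """

    time: np.ndarray  # s
    delta_pi: np.ndarray  # mN m⁻¹
    pi_zero: float  # mN m⁻¹
    label: str = ""

    def __post_init__(self):
        self.time = _as_1d(self.time, "time")
        self.delta_pi = _as_1d(self.delta_pi, "delta_pi")
        if self.time.shape != self.delta_pi.shape:
            raise ValueError("time and delta_pi must have equal length")
        if self.time[0] != 0.0:
            raise ValueError("time axis must start at 0")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class KineticsFit:
    """Pseudo-first-order fit Δπ(t) = Δπ_max (1 − e^{−βt})."""

    delta_pi_max: float  # mN m⁻¹
    beta: float  # s⁻¹
    rms_residual: float  # mN m⁻¹
    delta_pi_max_stderr: float = float("nan")
    beta_stderr: float = float("nan")


@dataclass
class ExclusionResult:
    """OLS line Δπ_max = slope·π₀ + intercept and its abscissa intercept."""

    slope: float
    intercept: float  # mN m⁻¹
    pi_exclusion: float  # mN m⁻¹; NaN when undefined
    defined: bool = True


def _local_poly_derivative(x: np.ndarray, y: np.ndarray, window: int, order: int):
    """Smoothed y and dy/dx from moving-window polynomial fits.

    Handles non-uniform x (a π-gridded isotherm has a non-uniform area grid).
    Windows are index-centred and clipped at the series ends, which reduces to
    one-sided fits there.
    """
    n = x.size
    half = window // 2
    y_s = np.empty(n)
    dy = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        if hi - lo < order + 2:  # widen clipped end windows
            lo = max(0, hi - (order + 2))
            hi = min(n, lo + order + 2)
        xs = x[lo:hi] - x[i]  # centre for conditioning
        coef = np.polyfit(xs, y[lo:hi], order)
        y_s[i] = coef[-1]
        dy[i] = coef[-2]
    return y_s, dy


def compression_modulus(
    iso: Isotherm, smooth_window: int = 11, smooth_order: int = 3
) -> ModulusCurve:
    """Elastic compression modulus Cs⁻¹(π) = −A (∂π/∂A)_T of an isotherm.

    The isotherm is sorted by decreasing area (the compression direction);
    π(A) is smoothed with a local polynomial (window of ``smooth_window``
    points, order ``smooth_order``) and differentiated analytically from the
    local fits.  The curve is returned on an ascending-π (descending-A) grid.

    Raises
    ------
    ValueError
        If the area grid has duplicates after sorting, the window is shorter
        than ``smooth_order + 2`` or even, or the isotherm has fewer points
        than the window.
    """
    if smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd")
    if smooth_window < smooth_order + 2:
        raise ValueError("smooth_window must be at least smooth_order + 2")
    if len(iso) < smooth_window:
        raise ValueError(
            f"isotherm has {len(iso)} points, fewer than smooth_window={smooth_window}"
        )
    order = np.argsort(iso.area_per_molecule)[::-1]  # decreasing area
    area = iso.area_per_molecule[order]
    pi = iso.surface_pressure[order]
    if np.any(np.diff(area) >= 0):
        raise ValueError("area grid is non-monotone (duplicate areas) after sorting")
    pi_s, dpi_da = _local_poly_derivative(area, pi, smooth_window, smooth_order)
    cs_inv = -area * dpi_da
    return ModulusCurve(surface_pressure=pi_s, cs_inverse=cs_inv)


def detect_transition(
    mc: ModulusCurve,
    search_range: tuple[float, float],
    min_prominence: float = 0.05,
) -> float | None:
    """Surface pressure of the interior Cs⁻¹ minimum inside ``search_range``.

    Returns the π of the lowest Cs⁻¹ point strictly inside the searched slice
    (ties broken toward lower π).  Returns ``None`` when the minimum sits on
    the slice boundary (Cs⁻¹ monotone over the range) or when the dip is not
    prominent: a transition minimum must undercut both range edges by at
    least the fraction ``min_prominence``, which rejects flat or merely
    noisy curves.
    """
    lo, hi = search_range
    if not lo < hi:
        raise ValueError("empty search range")
    mask = (mc.surface_pressure >= lo) & (mc.surface_pressure <= hi)
    if mask.sum() < 3:
        raise ValueError("search range contains fewer than 3 curve points")
    idx = np.nonzero(mask)[0]
    pi = mc.surface_pressure[idx]
    cs = mc.cs_inverse[idx]
    asc = np.argsort(pi, kind="stable")
    pi, cs = pi[asc], cs[asc]
    i_min = int(np.argmin(cs))  # first occurrence = lowest π on ties
    if i_min == 0 or i_min == cs.size - 1:
        return None
    edge = min(cs[0], cs[-1])
    if cs[i_min] > (1.0 - min_prominence) * edge:
        return None
    return float(pi[i_min])


def _first_order(t, dpi_max, beta):
    return dpi_max * (1.0 - np.exp(-beta * t))


def fit_insertion_kinetics(trace: InsertionTrace) -> KineticsFit:
    """Least-squares fit of the pseudo-first-order insertion model.

    Initial guesses: the plateau is seeded from the mean of the final tenth
    of the trace, the rate from the initial slope divided by that plateau.
    All points (including t = 0) enter an unweighted fit.  Warns when the
    trace is shorter than 2/β, where the plateau is poorly constrained.
    """
    t, y = trace.time, trace.delta_pi
    if t.size < 10:
        raise ValueError("insertion fit needs at least 10 points")
    tail = max(3, t.size // 10)
    dpi0 = float(np.mean(y[-tail:]))
    if dpi0 == 0.0:
        dpi0 = float(np.max(np.abs(y))) or 1.0
    head = max(2, min(5, t.size))
    slope0 = np.polyfit(t[:head], y[:head], 1)[0]
    beta0 = abs(slope0 / dpi0) if slope0 and dpi0 else 1.0 / t[-1]
    beta0 = min(max(beta0, 1e-8), 1e6)
    try:
        popt, pcov = curve_fit(
            _first_order,
            t,
            y,
            p0=(dpi0, beta0),
            bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"insertion kinetics fit did not converge: {err}") from err
    dpi_max, beta = map(float, popt)
    resid = y - _first_order(t, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    perr = np.sqrt(np.diag(pcov))
    if t[-1] < 2.0 / beta:
        warnings.warn(
            f"trace spans {t[-1]:.3g} s < 2/beta = {2.0 / beta:.3g} s; "
            "plateau poorly constrained",
            stacklevel=2,
        )
    return KineticsFit(
        delta_pi_max=dpi_max,
        beta=beta,
        rms_residual=rms,
        delta_pi_max_stderr=float(perr[0]),
        beta_stderr=float(perr[1]),
    )


def exclusion_pressure(points) -> ExclusionResult:
    """Exclusion surface pressure from the Δπ_max vs. π₀ regression.

    ``points`` is a sequence of (π₀, Δπ_max) pairs.  Ordinary least squares
    gives slope and intercept; the exclusion pressure is the abscissa
    intercept −intercept/slope, defined only for a negative slope (insertion
    must vanish at high film pressure).
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (n, 2) pairs of (pi_zero, delta_pi_max)")
    pi0, dmax = arr[:, 0], arr[:, 1]
    if np.unique(pi0).size < 2:
        raise ValueError("need at least 2 distinct initial pressures")
    slope, intercept = np.polyfit(pi0, dmax, 1)
    if slope >= 0:
        return ExclusionResult(float(slope), float(intercept), float("nan"), defined=False)
    return ExclusionResult(float(slope), float(intercept), float(-intercept / slope), True)
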