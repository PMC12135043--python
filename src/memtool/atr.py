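"""Polarized ATR-FTIR linear dichroism and molecular orientation.

A thin film at the internally reflecting face of a high-index prism is probed
by the evanescent wave.  For a film much thinner than the penetration depth

    d_p = λ / (2π √(n1² sin²β − n2²)),

the dichroic ratio R = A_p/A_s of one vibrational band, together with the
relative squared interfacial field amplitudes (Ex², Ey², Ez²), yields an
order parameter of the band's transition dipole moment (TDM) about the
surface normal,

    S_dip = (Ex² − R·Ey² + Ez²) / (Ex² − R·Ey² − 2·Ez²),

under uniaxial symmetry about the normal, and from it the effective dipole
angle θ_dip = arccos √((2 S_dip + 1)/3).  Because the symmetric and
antisymmetric CH₂ stretching TDMs are mutually orthogonal and both
perpendicular to the acyl-chain axis, the chain tilt follows from

    cos²θ_tilt + cos²θ_sym + cos²θ_asym = 1.

Band areas come from a joint pseudo-Voigt deconvolution of the p- and
s-polarized spectra sharing centers, widths and shapes across polarizations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np

__all__ = [
    "OpticalConfig",
    "FieldIntensities",
    "PolarizedSpectrum",
    "BandModel",
    "OrientationResult",
    "TiltResult",
    "penetration_depth",
    "interface_field_intensities",
    "pseudo_voigt",
    "pseudo_voigt_area",
    "deconvolve_bands",
    "dichroic_ratio",
    "order_parameter_from_ratio",
    "dipole_angle",
    "orientation_from_ratio",
    "chain_tilt_from_tdm_angles",
]

# defaults for a silicon prism against a D2O electrolyte at 60° incidence
DEFAULT_N1 = 3.42
DEFAULT_N2 = 1.42
DEFAULT_INCIDENCE_DEG = 60.0


@dataclass(frozen=True)
class OpticalConfig:
    """Interface optics of an internal-reflection experiment.

    ``n1`` is the dense incidence medium (prism), ``n2`` the rare medium
    beyond the interface, ``beta_inc`` the incidence angle in degrees and
    ``wavenumber`` the band position in cm⁻¹.  ``n_film`` optionally enables
    the three-phase thin-film correction of the normal field component.
    """

    n1: float = DEFAULT_N1
    n2: float = DEFAULT_N2
    beta_inc: float = DEFAULT_INCIDENCE_DEG
    wavenumber: float = 2900.0
    n_film: float | None = None

    def __post_init__(self):
        if not (self.n1 > self.n2 > 0):
            raise ValueError("require n1 > n2 > 0")
        if not (0.0 < self.beta_inc < 90.0):
            raise ValueError("incidence angle must be in (0, 90) degrees")
        if self.wavenumber <= 0:
            raise ValueError("wavenumber must be positive")
        if self.n_film is not None and self.n_film <= 0:
            raise ValueError("n_film must be positive")

    @property
    def evanescent(self) -> bool:
        """True when the incidence angle exceeds the critical angle."""
        return self.n1 * np.sin(np.radians(self.beta_inc)) > self.n2


@dataclass(frozen=True)
class FieldIntensities:
    """Relative squared interfacial field amplitudes (dimensionless)."""

    ex2: float
    ey2: float
    ez2: float

    def __post_init__(self):
        if min(self.ex2, self.ey2, self.ez2) < 0:
            raise ValueError("squared field amplitudes must be non-negative")


@dataclass
class PolarizedSpectrum:
    """p- and s-polarized absorbance on a shared wavenumber grid."""

    wavenumber: np.ndarray  # cm⁻¹, strictly monotone (either direction)
    absorbance_p: np.ndarray
    absorbance_s: np.ndarray

    def __post_init__(self):
        self.wavenumber = np.asarray(self.wavenumber, float)
        self.absorbance_p = np.asarray(self.absorbance_p, float)
        self.absorbance_s = np.asarray(self.absorbance_s, float)
        if not (
            self.wavenumber.shape == self.absorbance_p.shape == self.absorbance_s.shape
        ):
            raise ValueError("wavenumber and absorbance series must have equal length")
        for name in ("wavenumber", "absorbance_p", "absorbance_s"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")
        d = np.diff(self.wavenumber)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be strictly monotone")

    def window(self, lo: float, hi: float) -> "PolarizedSpectrum":
        """Slice to wavenumbers in [lo, hi], returned on an ascending grid."""
        mask = (self.wavenumber >= lo) & (self.wavenumber <= hi)
        if mask.sum() < 2:
            raise ValueError("window contains fewer than 2 grid points")
        order = np.argsort(self.wavenumber[mask])
        return PolarizedSpectrum(
            self.wavenumber[mask][order],
            self.absorbance_p[mask][order],
            self.absorbance_s[mask][order],
        )


def pseudo_voigt(x, amplitude, center, fwhm, frac):
    """Height-normalized pseudo-Voigt: (1−frac)·Gaussian + frac·Lorentzian."""
    u = (np.asarray(x, float) - center) / fwhm
    gauss = np.exp(-4.0 * np.log(2.0) * u**2)
    lorentz = 1.0 / (1.0 + 4.0 * u**2)
    return amplitude * ((1.0 - frac) * gauss + frac * lorentz)


def pseudo_voigt_area(amplitude, fwhm, frac):
    """Analytic integral of the height-normalized pseudo-Voigt."""
    gauss_area = 0.5 * np.sqrt(np.pi / np.log(2.0))
    return amplitude * fwhm * ((1.0 - frac) * gauss_area + frac * np.pi / 2.0)


@dataclass
class BandModel:
    """A set of pseudo-Voigt bands shared between the two polarizations.

    Centers, widths (FWHM) and Gaussian/Lorentzian mixing are common to p and
    s (same vibration, different projection); amplitudes are per-polarization
    peak heights.  Baselines are polynomial coefficients in ascending order,
    evaluated in (wavenumber − reference) for conditioning.
    """

    centers: np.ndarray  # cm⁻¹
    fwhms: np.ndarray  # cm⁻¹
    fracs: np.ndarray  # Lorentzian fraction in [0, 1]
    amplitudes_p: np.ndarray
    amplitudes_s: np.ndarray
    baseline_p: np.ndarray | None = None
    baseline_s: np.ndarray | None = None
    baseline_ref: float = 0.0

    def __post_init__(self):
        for name in ("centers", "fwhms", "fracs", "amplitudes_p", "amplitudes_s"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        n = self.centers.size
        if not all(
            getattr(self, name).size == n
            for name in ("fwhms", "fracs", "amplitudes_p", "amplitudes_s")
        ):
            raise ValueError("per-band parameter arrays must have equal length")
        if np.any(self.fwhms <= 0):
            raise ValueError("band widths must be positive")
        if np.any(self.amplitudes_p < 0) or np.any(self.amplitudes_s < 0):
            raise ValueError("band amplitudes must be non-negative")
        if np.any((self.fracs < 0) | (self.fracs > 1)):
            raise ValueError("shape mixing fractions must lie in [0, 1]")

    @property
    def n_bands(self) -> int:
        return self.centers.size

    @property
    def areas_p(self) -> np.ndarray:
        return pseudo_voigt_area(self.amplitudes_p, self.fwhms, self.fracs)

    @property
    def areas_s(self) -> np.ndarray:
        return pseudo_voigt_area(self.amplitudes_s, self.fwhms, self.fracs)

    def evaluate(self, wavenumber, polarization: str) -> np.ndarray:
        """Model absorbance (bands + baseline) for one polarization."""
        x = np.asarray(wavenumber, float)
        amps = self.amplitudes_p if polarization == "p" else self.amplitudes_s
        y = np.zeros_like(x)
        for a, c, w, f in zip(amps, self.centers, self.fwhms, self.fracs):
            y += pseudo_voigt(x, a, c, w, f)
        base = self.baseline_p if polarization == "p" else self.baseline_s
        if base is not None:
            y += np.polynomial.polynomial.polyval(x - self.baseline_ref, base)
        return y


@dataclass(frozen=True)
class OrientationResult:
    """Dichroic ratio with the derived TDM order parameter and angle."""

    dichroic_ratio: float
    s_dip: float  # in [−0.5, 1]
    theta_dip: float  # degrees in [0, 90]


@dataclass(frozen=True)
class TiltResult:
    """Acyl-chain tilt from the two orthogonal CH₂-stretch TDM angles."""

    theta_tilt: float  # degrees
    theta_sym: float  # degrees (input retained)
    theta_asym: float  # degrees (input retained)


def _check_evanescent(cfg: OpticalConfig) -> None:
    if not cfg.evanescent:
        raise ValueError(
            "below critical angle: n1·sin(beta) = "
            f"{cfg.n1 * np.sin(np.radians(cfg.beta_inc)):.4g} <= n2 = {cfg.n2:.4g}"
        )


def penetration_depth(cfg: OpticalConfig) -> float:
    """Evanescent-wave penetration depth in nm.

    d_p = λ / (2π √(n1² sin²β − n2²)) with λ = 10⁷/wavenumber nm.
    """
    _check_evanescent(cfg)
    lam_nm = 1.0e7 / cfg.wavenumber
    beta = np.radians(cfg.beta_inc)
    return float(lam_nm / (2.0 * np.pi * np.sqrt(cfg.n1**2 * np.sin(beta) ** 2 - cfg.n2**2)))


def interface_field_intensities(cfg: OpticalConfig) -> FieldIntensities:
    """Relative squared field amplitudes at the totally reflecting interface.

    Two-phase (thick-film) approximation with n21 = n2/n1:

        Ey² = [2cosβ / √(1−n21²)]²
        Ex² = [2cosβ √(sin²β−n21²)]² / [(1−n21²)((1+n21²)sin²β − n21²)]
        Ez² = [2cosβ sinβ]²          / [(1−n21²)((1+n21²)sin²β − n21²)]

    When ``cfg.n_film`` is set, the three-phase thin-film mode rescales the
    normal field amplitude by (n2/n_film)² — continuity of the normal
    displacement across the film — i.e. Ez² by (n2/n_film)⁴.
    """
    _check_evanescent(cfg)
    beta = np.radians(cfg.beta_inc)
    sb2 = np.sin(beta) ** 2
    cb = np.cos(beta)
    n21sq = (cfg.n2 / cfg.n1) ** 2
    ey2 = (2.0 * cb) ** 2 / (1.0 - n21sq)
    denom = (1.0 - n21sq) * ((1.0 + n21sq) * sb2 - n21sq)
    ex2 = (2.0 * cb) ** 2 * (sb2 - n21sq) / denom
    ez2 = (2.0 * cb) ** 2 * sb2 / denom
    if cfg.n_film is not None:
        ez2 *= (cfg.n2 / cfg.n_film) ** 4
    return FieldIntensities(float(ex2), float(ey2), float(ez2))


def deconvolve_bands(
    spec: PolarizedSpectrum,
    seeds: BandModel,
    window: tuple[float, float],
    baseline_order: int = 1,
    min_fwhm: float = 0.1,
    center_window: float = 8.0,
) -> BandModel:
    """Joint pseudo-Voigt deconvolution of the p and s spectra.

    Centers, widths and shape fractions are shared between polarizations;
    amplitudes are independent; each polarization gets its own polynomial
    baseline of order ``baseline_order`` (0, 1 or 2).  Seed centers come
    from known band assignments, so each center may move at most
    ``center_window`` cm⁻¹ from its seed (and each width at most 3× its
    seed) — this keeps weak shoulder bands from migrating under strong
    neighbours.  Returns the fitted :class:`BandModel` (areas follow
    analytically from the parameters).

    Raises
    ------
    ValueError
        If a seed center lies outside the window or the grid does not cover
        the window.
    RuntimeError
        On non-convergence (reporting the final residual) or when a band
        collapses toward zero width.
    """
    lo, hi = sorted(window)
    if baseline_order not in (0, 1, 2):
        raise ValueError("baseline_order must be 0, 1 or 2")
    if np.any((seeds.centers < lo) | (seeds.centers > hi)):
        raise ValueError("all seed centers must lie inside the fit window")
    step = float(np.median(np.abs(np.diff(spec.wavenumber))))
    if spec.wavenumber.min() > lo + step or spec.wavenumber.max() < hi - step:
        raise ValueError("spectrum grid does not cover the fit window")
    sub = spec.window(lo, hi)
    x = sub.wavenumber
    xref = 0.5 * (lo + hi)
    n = seeds.n_bands
    scale = max(np.ptp(sub.absorbance_p), np.ptp(sub.absorbance_s), 1e-12)

    params = lmfit.Parameters()
    for i in range(n):
        c0 = float(seeds.centers[i])
        params.add(f"c{i}", value=c0, min=max(lo, c0 - center_window),
                   max=min(hi, c0 + center_window))
        w0 = float(seeds.fwhms[i])
        params.add(f"w{i}", value=w0, min=min_fwhm, max=min(3.0 * w0, hi - lo))
        params.add(f"f{i}", value=float(np.clip(seeds.fracs[i], 0, 1)), min=0.0, max=1.0)
        # unseeded amplitudes start from the local baseline-corrected signal
        j = int(np.argmin(np.abs(x - c0)))
        local = max(
            float(sub.absorbance_p[j] - np.median(sub.absorbance_p)), 0.05 * scale
        )
        local_s = max(
            float(sub.absorbance_s[j] - np.median(sub.absorbance_s)), 0.05 * scale
        )
        params.add(f"ap{i}", value=float(seeds.amplitudes_p[i]) or local, min=0.0)
        params.add(f"as{i}", value=float(seeds.amplitudes_s[i]) or local_s, min=0.0)
    for j in range(baseline_order + 1):
        params.add(f"bp{j}", value=0.0)
        params.add(f"bs{j}", value=0.0)

    def _model(p, pol):
        y = np.zeros_like(x)
        for i in range(n):
            amp = p[f"ap{i}"] if pol == "p" else p[f"as{i}"]
            y += pseudo_voigt(x, amp, p[f"c{i}"], p[f"w{i}"], p[f"f{i}"])
        coefs = [p[f"bp{j}"] if pol == "p" else p[f"bs{j}"] for j in range(baseline_order + 1)]
        return y + np.polynomial.polynomial.polyval(x - xref, coefs)

    def _residual(p):
        return np.concatenate(
            [_model(p, "p") - sub.absorbance_p, _model(p, "s") - sub.absorbance_s]
        )

    result = lmfit.minimize(_residual, params, method="leastsq")
    rms = float(np.sqrt(np.mean(result.residual**2)))
    if not result.success:
        raise RuntimeError(
            f"band deconvolution did not converge ({result.message}); final residual RMS = {rms:.3g}"
        )
    p = result.params.valuesdict()
    fwhms = np.array([p[f"w{i}"] for i in range(n)])
    if np.any(fwhms <= min_fwhm * 1.001):
        bad = [i for i in range(n) if fwhms[i] <= min_fwhm * 1.001]
        raise RuntimeError(f"band(s) {bad} collapsed to zero width during the fit")
    return BandModel(
        centers=np.array([p[f"c{i}"] for i in range(n)]),
        fwhms=fwhms,
        fracs=np.array([p[f"f{i}"] for i in range(n)]),
        amplitudes_p=np.array([p[f"ap{i}"] for i in range(n)]),
        amplitudes_s=np.array([p[f"as{i}"] for i in range(n)]),
        baseline_p=np.array([p[f"bp{j}"] for j in range(baseline_order + 1)]),
        baseline_s=np.array([p[f"bs{j}"] for j in range(baseline_order + 1)]),
        baseline_ref=xref,
    )


def dichroic_ratio(bands: BandModel, index: int = 0) -> float:
    """R = integrated p-area / integrated s-area of one fitted band."""
    area_s = float(bands.areas_s[index])
    if area_s <= 0:
        raise ValueError(f"band {index} has zero s-polarized area; R undefined")
    return float(bands.areas_p[index]) / area_s


def order_parameter_from_ratio(
    r: float, fields: FieldIntensities, clamp_tol: float = 1e-6
) -> float:
    """TDM order parameter from the dichroic ratio.

    S_dip = (Ex² − R·Ey² + Ez²) / (Ex² − R·Ey² − 2·Ez²), valid under uniaxial
    symmetry about the interface normal.  Values outside [−0.5, 1] by less
    than ``clamp_tol`` are clamped with a warning; beyond that the optics and
    the ratio are inconsistent and an error is raised.
    """
    u = fields.ex2 - r * fields.ey2
    denom = u - 2.0 * fields.ez2
    if denom == 0.0:
        raise ValueError("zero denominator in the order-parameter expression")
    s = (u + fields.ez2) / denom
    if not (-0.5 <= s <= 1.0):
        if -0.5 - clamp_tol <= s <= 1.0 + clamp_tol:
            warnings.warn(
                f"S_dip = {s!r} marginally outside [-0.5, 1]; clamped", stacklevel=2
            )
            s = float(np.clip(s, -0.5, 1.0))
        else:
            raise ValueError(
                f"inconsistent optics/ratio: S_dip = {s:.6g} outside [-0.5, 1]"
            )
    return float(s)


def dipole_angle(s_dip: float) -> float:
    """Effective TDM angle θ_dip = arccos √((2 S + 1)/3), in degrees."""
    if not (-0.5 - 1e-12 <= s_dip <= 1.0 + 1e-12):
        raise ValueError("order parameter must lie in [-0.5, 1]")
    s_dip = float(np.clip(s_dip, -0.5, 1.0))
    return float(np.degrees(np.arccos(np.sqrt((2.0 * s_dip + 1.0) / 3.0))))


def orientation_from_ratio(r: float, fields: FieldIntensities) -> OrientationResult:
    """Convenience chain: dichroic ratio → S_dip → θ_dip."""
    s = order_parameter_from_ratio(r, fields)
    return OrientationResult(dichroic_ratio=float(r), s_dip=s, theta_dip=dipole_angle(s))


def chain_tilt_from_tdm_angles(
    theta_sym: float, theta_asym: float, tol: float = 1e-9
) -> TiltResult:
    """Acyl-chain tilt from the two orthogonal CH₂-stretch TDM angles.

    The symmetric and antisymmetric CH₂ stretching TDMs and the chain axis
    form an orthogonal triad, so their direction cosines to the normal
    satisfy cos²θ_tilt + cos²θ_sym + cos²θ_asym = 1.
    """
    for name, val in (("theta_sym", theta_sym), ("theta_asym", theta_asym)):
        if not (0.0 <= val <= 90.0):
            raise ValueError(f"{name} must lie in [0, 90] degrees")
    radicand = (
        1.0
        - np.cos(np.radians(theta_sym)) ** 2
        - np.cos(np.radians(theta_asym)) ** 2
    )
    if radicand < -tol:
        raise ValueError(
            "non-orthogonal TDM inputs: cos^2(theta_sym) + cos^2(theta_asym) > 1"
        )
    radicand = max(radicand, 0.0)
    tilt = float(np.degrees(np.arccos(np.sqrt(radicand))))
    return TiltResult(theta_tilt=tilt, theta_sym=float(theta_sym), theta_asym=float(theta_asym))
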