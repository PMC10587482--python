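"""Photobleaching and relocalization kinetics.

Normalization of FRAP/FLIP/relocalization intensity traces, weighted
single-exponential fitting y(t) = y0 + A·exp(−(t − x0)/τ), conversion of a
FRAP half-time to a diffusion coefficient with the corrected Soumpasis
relation D = (r_e² + r_n²)/(8·τ½), and Stokes–Einstein forward/inverse
predictions D = k_B·T/(6π·η·r) for vesicle-sized particles in cytoplasm.

Times are in seconds, distances in μm (Soumpasis) or nm (particle
diameters), D in μm² s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

__all__ = [
    "RecoveryCurve",
    "ExpFit",
    "FrapGeometry",
    "PhysicalParams",
    "normalize_curve",
    "fit_exponential",
    "soumpasis_D",
    "half_time_from_tau",
    "stokes_einstein_D",
    "diameter_from_D",
    "capture_apparent_D",
    "APPARENT_D_FORMULAS",
]

BOLTZMANN = 1.380649e-23  # J/K
#: cytoplasmic viscosity of a HeLa cell, Pa s
CYTOPLASM_VISCOSITY = 4.4e-2
#: imaging temperature (37 °C), K
BODY_TEMPERATURE = 310.0


@dataclass
class RecoveryCurve:
    """Normalized intensity trace (pre-bleach level = 1)."""

    times: np.ndarray
    intensity: np.ndarray
    sd: np.ndarray | None = None
    n: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")


@dataclass
class ExpFit:
    """Single-exponential fit y0 + A·exp(−(t − x0)/τ).

    A < 0 describes recovery toward the plateau y0 (FRAP,
    relocalization); A > 0 describes loss (FLIP). ``immobile_fraction``
    is only meaningful for FRAP-type recoveries.
    """

    y0: float
    A: float
    x0: float
    tau: float
    immobile_fraction: float | None = None
    stderr: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.y0 + self.A * np.exp(-(t - self.x0) / self.tau)

    @property
    def half_time(self) -> float:
        return half_time_from_tau(self.tau)


def normalize_curve(
    raw: np.ndarray,
    background: np.ndarray | float,
    prebleach_frames: int,
    times: np.ndarray | None = None,
    sd: np.ndarray | None = None,
    n: int = 1,
) -> RecoveryCurve:
    """Background-subtract and normalize to the pre-bleach mean.

    ``(raw − background)`` is divided by the mean of its first
    ``prebleach_frames`` samples, so the pre-bleach level maps to 1.
    """
    if prebleach_frames < 1:
        raise ValueError("prebleach_frames must be >= 1")
    raw = np.asarray(raw, dtype=float)
    corrected = raw - np.asarray(background, dtype=float)
    ref = float(corrected[:prebleach_frames].mean())
    if ref <= 0:
        raise ValueError(
            f"pre-bleach mean after background subtraction is {ref:.4g} (must be > 0)"
        )
    if times is None:
        times = np.arange(len(raw), dtype=float)
    scaled_sd = None if sd is None else np.asarray(sd, dtype=float) / ref
    return RecoveryCurve(times=times, intensity=corrected / ref, sd=scaled_sd, n=n)


def _exp_model(t, y0, A, tau, x0):
    return y0 + A * np.exp(-(t - x0) / tau)


def fit_exponential(
    curve: RecoveryCurve,
    weighted: bool = False,
    x0: float | None = None,
    y_prebleach: float = 1.0,
) -> ExpFit:
    """Weighted least-squares single-exponential fit of a recovery curve.

    The time origin ``x0`` defaults to the curve's first sample. Weights
    are 1/sd per time point when ``weighted`` (FRAP convention). For
    recoveries (A < 0) the immobile fraction
    1 − (y0 − y_bleach)/(y_pre − y_bleach) is reported, with y_bleach the
    fitted value at x0.
    """
    if len(curve.times) < 5:
        raise ValueError("need >= 5 points to fit")
    if weighted and curve.sd is None:
        raise ValueError("weighted fit requires per-point sd")
    t = curve.times
    y = curve.intensity
    if np.ptp(y) < 1e-9:
        raise RuntimeError(
            f"flat curve (range {np.ptp(y):.3g}): no exponential component to fit"
        )
    if x0 is None:
        x0 = float(t[0])

    model = Model(_exp_model)
    span = float(t[-1] - t[0])
    y0_guess = float(y[-1])
    a_guess = float(y[0] - y[-1])
    params = model.make_params(
        y0=y0_guess, A=a_guess if a_guess != 0 else 0.1, tau=max(span / 3.0, 1e-6)
    )
    params["x0"].set(value=x0, vary=False)
    params["tau"].set(min=1e-9)
    weights = None
    if weighted:
        sd = np.where(curve.sd > 0, curve.sd, np.nanmin(curve.sd[curve.sd > 0]))
        weights = 1.0 / sd
    result = model.fit(y, params, t=t, weights=weights)
    if not result.success:
        raise RuntimeError(f"exponential fit failed: {result.message}; "
                           f"residual norm {np.linalg.norm(result.residual):.3g}")
    p = result.params
    y0_fit, a_fit, tau_fit = p["y0"].value, p["A"].value, p["tau"].value
    if abs(a_fit) < 1e-12:
        raise RuntimeError("degenerate fit: amplitude collapsed to zero "
                           f"(A = {a_fit:.3g}, data range {np.ptp(y):.3g})")
    immobile = None
    if a_fit < 0:
        y_bleach = y0_fit + a_fit
        denom = y_prebleach - y_bleach
        if abs(denom) > 1e-12:
            immobile = 1.0 - (y0_fit - y_bleach) / denom
    stderr = {k: (p[k].stderr if p[k].stderr is not None else np.nan)
              for k in ("y0", "A", "tau")}
    return ExpFit(y0=float(y0_fit), A=float(a_fit), x0=float(x0),
                  tau=float(tau_fit), immobile_fraction=immobile, stderr=stderr)


@dataclass(frozen=True)
class FrapGeometry:
    """Bleach-spot geometry: nominal radius r_n and effective post-bleach
    radius r_e (both μm, r_e ≥ r_n)."""

    r_n: float
    r_e: float | None = None

    def __post_init__(self) -> None:
        if self.r_e is None:
            object.__setattr__(self, "r_e", self.r_n)
        if self.r_n <= 0 or self.r_e < self.r_n:
            raise ValueError("need r_e >= r_n > 0")


def half_time_from_tau(tau: float) -> float:
    """Half-time of an exponential process: t½ = τ·ln 2."""
    return tau * math.log(2.0)


def soumpasis_D(geometry: FrapGeometry, t_half: float) -> float:
    """Corrected Soumpasis diffusion coefficient D = (r_e² + r_n²)/(8·τ½)."""
    if t_half <= 0:
        raise ValueError("t_half must be > 0")
    return (geometry.r_e**2 + geometry.r_n**2) / (8.0 * t_half)


@dataclass(frozen=True)
class PhysicalParams:
    """Stokes–Einstein inputs: temperature (K), viscosity (Pa s) and
    particle radius (m)."""

    r: float
    T: float = BODY_TEMPERATURE
    eta: float = CYTOPLASM_VISCOSITY
    k_B: float = BOLTZMANN

    def __post_init__(self) -> None:
        if min(self.r, self.T, self.eta, self.k_B) <= 0:
            raise ValueError("all physical parameters must be positive")


def stokes_einstein_D(params: PhysicalParams) -> float:
    """D = k_B·T/(6π·η·r), returned in μm² s⁻¹."""
    d_si = params.k_B * params.T / (6.0 * math.pi * params.eta * params.r)
    return d_si * 1e12  # m² s⁻¹ → μm² s⁻¹


def stokes_einstein_D_from_diameter(
    diameter_nm: float, T: float = BODY_TEMPERATURE, eta: float = CYTOPLASM_VISCOSITY
) -> float:
    """Convenience wrapper taking a particle diameter in nm."""
    return stokes_einstein_D(PhysicalParams(r=diameter_nm * 1e-9 / 2.0, T=T, eta=eta))


def diameter_from_D(
    D: float, T: float = BODY_TEMPERATURE, eta: float = CYTOPLASM_VISCOSITY
) -> float:
    """Invert Stokes–Einstein: particle diameter in nm for D in μm² s⁻¹."""
    if D <= 0:
        raise ValueError("D must be > 0")
    r_m = BOLTZMANN * T / (6.0 * math.pi * eta * D * 1e-12)
    return 2.0 * r_m * 1e9


#: named formulas for a rough capture-limited apparent D from a mean
#: travel distance L (μm) and capture half-time t½ (s)
APPARENT_D_FORMULAS = {
    "msd3d": lambda L, t: L**2 / (6.0 * t),
    "msd2d": lambda L, t: L**2 / (4.0 * t),
    "msd1d": lambda L, t: L**2 / (2.0 * t),
}


def capture_apparent_D(
    mean_distance: float, t_half: float, formula: str = "msd3d"
) -> tuple[float, str]:
    """Apparent diffusion coefficient from a mean capture distance.

    Treats the half-time of a capture process as the time to diffuse the
    mean distance L to the target, under the named dimensional MSD
    scaling (default ``"msd3d"``: D = L²/(6·t)). Returns (D, formula).
    These are order-of-magnitude estimates; the choice of formula is
    reported alongside the value.
    """
    if mean_distance <= 0 or t_half <= 0:
        raise ValueError("mean_distance and t_half must be > 0")
    if formula not in APPARENT_D_FORMULAS:
        raise ValueError(
            f"unknown formula {formula!r}; options: {sorted(APPARENT_D_FORMULAS)}"
        )
    return APPARENT_D_FORMULAS[formula](mean_distance, t_half), formula
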