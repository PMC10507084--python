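"""Electrode-skin equivalent-circuit impedance: forward model, synthetic
spectra, and nonlinear least-squares fitting.

The lumped model is a series electrode resistance R_e followed by two
parallel RC pairs — the stratum-corneum/sweat-gland pair (R_s, C_s) and
the electrode interface pair (charge-transfer resistance R_d, interfacial
capacitance C_d):

    Z(f) = R_e + R_s / (1 + j 2 pi f R_s C_s) + R_d / (1 + j 2 pi f R_d C_d)

|Z| falls monotonically from R_e + R_s + R_d at DC to R_e at high
frequency.  The two RC pairs are exchangeable in the model, so fitted
parameters are canonicalized by corner frequency: the pair with the
LOWER corner 1/(2 pi R C) is reported as (R_d, C_d) — the interfacial
pair dominates at low frequency for gel electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CircuitParams",
    "ImpedanceSpectrum",
    "FitResult",
    "circuit_impedance",
    "synth_impedance",
    "fit_circuit",
    "nyquist",
    "bode",
]

_PARAM_NAMES = ("R_e", "R_s", "C_s", "R_d", "C_d")


@dataclass(frozen=True)
class CircuitParams:
    """Five-element equivalent circuit (ohms and farads)."""

    R_e: float = 1e3         # electrode series resistance
    R_s: float = 10e3        # stratum corneum / sweat gland resistance
    C_s: float = 50e-9       # stratum corneum capacitance (corner ~318 Hz)
    R_d: float = 22e3        # charge-transfer resistance (gel interface)
    C_d: float = 95e-9       # interfacial capacitance (corner ~76 Hz)

    def __post_init__(self) -> None:
        # zero resistances are legal in fixtures (a zero-ohm branch vanishes)
        for name in ("R_e", "R_s", "R_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("C_s", "C_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _PARAM_NAMES], dtype=float)

    def canonical(self) -> "CircuitParams":
        """Order the RC pairs so (R_d, C_d) has the lower corner frequency."""
        f_s = 1.0 / (2 * np.pi * self.R_s * self.C_s) if self.R_s > 0 else np.inf
        f_d = 1.0 / (2 * np.pi * self.R_d * self.C_d) if self.R_d > 0 else np.inf
        if f_d <= f_s:
            return self
        return CircuitParams(self.R_e, self.R_d, self.C_d, self.R_s, self.C_s)


@dataclass
class ImpedanceSpectrum:
    """Sampled complex impedance vs frequency."""

    freqs: np.ndarray  # Hz, strictly increasing, positive
    Z: np.ndarray      # complex ohms

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.Z = np.asarray(self.Z, dtype=complex)
        if self.freqs.shape != self.Z.shape:
            raise ValueError("freqs and Z must have equal length")
        if np.any(self.freqs <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")


def circuit_impedance(p: CircuitParams, f) -> np.ndarray | complex:
    """Z(f) of the five-element circuit; f in Hz (scalar or array)."""
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0):
        raise ValueError("frequency must be positive")
    jw = 1j * 2 * np.pi * f_arr
    z = p.R_e + p.R_s / (1 + jw * p.R_s * p.C_s) + p.R_d / (1 + jw * p.R_d * p.C_d)
    return z if np.ndim(f) else complex(z)


def synth_impedance(
    params: CircuitParams,
    freqs=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ImpedanceSpectrum:
    """Forward-model spectrum with optional multiplicative Gaussian noise
    (relative sd ``noise_sd``) on the real and imaginary parts; seeded."""
    if freqs is None:
        freqs = np.logspace(0, 3, 30)  # 1-1000 Hz
    freqs = np.asarray(freqs, dtype=float)
    z = np.asarray(circuit_impedance(params, freqs))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        z = z.real * (1 + noise_sd * rng.standard_normal(z.size)) + 1j * z.imag * (
            1 + noise_sd * rng.standard_normal(z.size)
        )
    return ImpedanceSpectrum(freqs=freqs, Z=z)


def nyquist(spec: ImpedanceSpectrum) -> tuple[np.ndarray, np.ndarray]:
    """(Re Z, -Im Z) pairs, the electrochemists' complex-plane plot."""
    return spec.Z.real.copy(), -spec.Z.imag.copy()


def bode(spec: ImpedanceSpectrum) -> tuple[np.ndarray, np.ndarray]:
    """(|Z|, phase in degrees) vs the spectrum's frequencies."""
    return np.abs(spec.Z), np.degrees(np.angle(spec.Z))


@dataclass
class FitResult:
    params: CircuitParams
    residual_norm: float
    ci: dict[str, tuple[float, float]]  # per-parameter ~95 % interval
    n_points: int


class FitError(RuntimeError):
    def __init__(self, message: str, best: CircuitParams | None = None, residual: float = np.nan):
        super().__init__(message)
        self.best = best
        self.residual = residual


def _auto_init(spec: ImpedanceSpectrum) -> CircuitParams:
    """Data-driven start: R_e from the high-frequency magnitude, the DC
    excess split 80/20 between the two RC branches, corners from the two
    strongest-curvature points of log|Z| (fallback: band thirds)."""
    mag = np.abs(spec.Z)
    r_e = max(mag[-1], 1e-3)
    dc_excess = max(mag[0] - r_e, 10 * r_e)
    r_d, r_s = 0.8 * dc_excess, max(0.2 * dc_excess, 1e-3)
    logf, logm = np.log10(spec.freqs), np.log10(np.maximum(mag, 1e-30))
    corners: list[float] = []
    if len(logf) >= 5:
        curv = np.abs(np.gradient(np.gradient(logm, logf), logf))
        order = np.argsort(curv)[::-1]
        for idx in order:
            f_c = spec.freqs[idx]
            if all(abs(np.log10(f_c / c)) > 0.3 for c in corners):
                corners.append(float(f_c))
            if len(corners) == 2:
                break
    if len(corners) < 2:
        f_lo, f_hi = spec.freqs[0], spec.freqs[-1]
        corners = [float(f_lo * (f_hi / f_lo) ** (1 / 3)), float(f_lo * (f_hi / f_lo) ** (2 / 3))]
    f_d, f_s = sorted(corners)  # lower corner -> interfacial pair
    c_d = 1.0 / (2 * np.pi * r_d * f_d)
    c_s = 1.0 / (2 * np.pi * r_s * f_s)
    return CircuitParams(r_e, r_s, c_s, r_d, c_d)


def fit_circuit(spec: ImpedanceSpectrum, init: CircuitParams | str = "auto") -> FitResult:
    """Least-squares fit of the equivalent circuit to a spectrum.

    Minimizes the summed squared RELATIVE error of the real and imaginary
    parts (|Z| spans decades, so absolute residuals would let the
    low-frequency points dominate).  Positivity is enforced by optimizing
    log-parameters; the returned parameters are canonicalized by corner
    frequency.  Approximate 95 % confidence intervals come from the local
    curvature (Gauss-Newton J^T J) in log space.
    """
    n = len(spec.freqs)
    if 2 * n <= 5:
        raise FitError(f"{n} frequencies give {2 * n} data values; 5 parameters are under-determined")
    p0 = _auto_init(spec) if isinstance(init, str) else init
    scale = np.abs(spec.Z)

    def residuals(logp: np.ndarray) -> np.ndarray:
        p = np.exp(logp)
        model = circuit_impedance(CircuitParams(*p), spec.freqs)
        return np.concatenate([(model.real - spec.Z.real) / scale, (model.imag - spec.Z.imag) / scale])

    x0 = np.log(np.maximum(p0.as_array(), 1e-12))
    sol = least_squares(residuals, x0, method="lm", max_nfev=20000)
    if not sol.success or not np.all(np.isfinite(sol.x)):
        best = CircuitParams(*np.exp(sol.x)) if np.all(np.isfinite(sol.x)) else None
        raise FitError(f"fit did not converge: {sol.message}", best=best,
                       residual=float(np.linalg.norm(sol.fun)))
    p_hat = np.exp(sol.x)
    resid_norm = float(np.linalg.norm(sol.fun))

    # ~95 % CI from the Jacobian at the solution, back-transformed from log space
    dof = max(2 * n - 5, 1)
    s2 = resid_norm**2 / dof
    JtJ = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(JtJ)
        se_log = np.minimum(np.sqrt(np.maximum(np.diag(cov), 0)), 300.0)
    except np.linalg.LinAlgError:
        se_log = np.full(5, np.nan)
    fitted = CircuitParams(*p_hat)
    lo = p_hat * np.exp(-1.96 * se_log)
    hi = p_hat * np.exp(+1.96 * se_log)
    raw_ci = dict(zip(_PARAM_NAMES, zip(lo, hi)))

    canon = fitted.canonical()
    if canon is not fitted:  # pairs swapped -> swap their intervals too
        raw_ci["R_s"], raw_ci["R_d"] = raw_ci["R_d"], raw_ci["R_s"]
        raw_ci["C_s"], raw_ci["C_d"] = raw_ci["C_d"], raw_ci["C_s"]
    ci = {k: (float(a), float(b)) for k, (a, b) in raw_ci.items()}
    return FitResult(params=canon, residual_norm=resid_norm, ci=ci, n_points=n)
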