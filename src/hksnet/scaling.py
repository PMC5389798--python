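"""Extensivity classification and Lyapunov-spectrum invariance constants.

H_KS is extensive when it grows linearly with the network size N, i.e.
H_KS = sigma * N + nu.  For a growing family whose intra-degree sum scales
as S ~ N^(theta+1), extensivity is maintained by rescaling the intra
coupling eps ~ N^(-theta) (and gamma*zeta constant for the inter part).
The invariance of the normalised Lyapunov-spectrum curve is governed by the
constants

    C  = dbar / omega_max,      C1 = eps * omega_max,
    C2 = C1 * (C - 1) + 1,

where dbar is the mean intra-degree and omega_max the largest Laplacian
eigenvalue of a layer; C2 equals the spectral average
(1/N1) sum_i (C1 * omega_i / omega_max + 1 - C1) identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .netgen import LayerGraph

__all__ = [
    "ScalingResult",
    "InvarianceConstants",
    "fit_hks_scaling",
    "epsilon_rescaling",
    "invariance_constants",
    "extensivity_condition_residual",
    "eq18_residual",
    "case_spectrum_eps_inverse_N",
    "write_scaling_report",
]

EXTENSIVE = "extensive"
SUB_EXTENSIVE = "sub_extensive"
SUPER_EXTENSIVE = "super_extensive"


@dataclass
class ScalingResult:
    """(N, H_KS) series with the linear fit H_KS = sigma*N + nu and the
    log-log exponent theta_hat of H_KS ~ N^(theta+1)."""

    sizes: np.ndarray
    hks_values: np.ndarray
    slope: float
    intercept: float
    slope_stderr: float
    r_squared: float
    theta_hat: float
    classification: str


def fit_hks_scaling(
    sizes, hks, theta_tol: float = 0.1, r2_min: float = 0.95
) -> ScalingResult:
    """OLS fit of H_KS against N plus a log-log exponent fit.

    Classified extensive iff |theta_hat| <= theta_tol and the linear fit has
    R^2 >= r2_min; otherwise sub-/super-extensive by the sign of theta_hat.
    A family with some H_KS <= 0 (entropy collapsed) cannot be log-fitted
    and is reported sub-extensive with theta_hat = nan.
    """
    sizes = np.asarray(sizes, dtype=float)
    hks = np.asarray(hks, dtype=float)
    if sizes.size < 3:
        raise ValueError("need at least 3 sizes for a scaling fit")
    if np.any(np.diff(sizes) <= 0):
        raise ValueError("sizes must be strictly increasing")
    lin = stats.linregress(sizes, hks)
    r2 = float(lin.rvalue**2)
    if np.all(hks > 0):
        loglog = stats.linregress(np.log(sizes), np.log(hks))
        theta_hat = float(loglog.slope) - 1.0
        if abs(theta_hat) <= theta_tol and r2 >= r2_min:
            cls = EXTENSIVE
        elif theta_hat > theta_tol:
            cls = SUPER_EXTENSIVE
        elif theta_hat < -theta_tol:
            cls = SUB_EXTENSIVE
        else:
            cls = SUB_EXTENSIVE if theta_hat < 0 else SUPER_EXTENSIVE
    else:
        theta_hat = float("nan")
        cls = SUB_EXTENSIVE
    return ScalingResult(
        sizes=sizes,
        hks_values=hks,
        slope=float(lin.slope),
        intercept=float(lin.intercept),
        slope_stderr=float(lin.stderr),
        r_squared=r2,
        theta_hat=theta_hat,
        classification=cls,
    )


def epsilon_rescaling(theta: float, N: int, base: float) -> float:
    """Coupling rescaling eps(N) = base * N^(-theta) that keeps H_KS
    extensive when S ~ N^(theta+1)."""
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return base * float(N) ** (-theta)


@dataclass
class InvarianceConstants:
    """Constants governing the collapse of the normalised Lyapunov spectrum."""

    C: float
    C1: float
    C2: float
    zeta: float
    lhs_average: float  # independently computed spectral average of C2


def invariance_constants(layer: LayerGraph, epsilon: float, zeta: float = 0.0) -> InvarianceConstants:
    """Compute C = dbar/omega_max, C1 = eps*omega_max, C2 = C1(C-1)+1, and
    independently the spectral average that C2 equals identically."""
    wmax = layer.omega_max
    if wmax <= 0:
        raise ValueError("degenerate layer: omega_max = 0 (no edges)")
    C = layer.mean_degree / wmax
    C1 = epsilon * wmax
    C2 = C1 * (C - 1.0) + 1.0
    lhs = float(np.mean(C1 * layer.omega / wmax + 1.0 - C1))
    return InvarianceConstants(C=C, C1=C1, C2=C2, zeta=zeta, lhs_average=lhs)


def extensivity_condition_residual(
    layer: LayerGraph, epsilon: float, gamma: float, l12: int,
    sigma: float, nu: float, N: int,
) -> float:
    """Residual of the extensivity condition
    eps * sum(omega_i) + gamma * l12 = sigma * N + nu; near-zero across a
    growing family means the family is extensive."""
    return float(epsilon * layer.omega.sum() + gamma * l12 - (sigma * N + nu))


def eq18_residual(
    N: int, epsilon: float, mean_degree: float, omega_max: float,
    sigma: float, nu: float,
) -> float:
    """Residual of the convenience form of the extensivity condition:
    eps * dbar * N/2 + (N/4)(1 - eps * omega_max) = sigma * N + nu."""
    return float(
        epsilon * mean_degree * N / 2.0
        + (N / 4.0) * (1.0 - epsilon * omega_max)
        - (sigma * N + nu)
    )


def case_spectrum_eps_inverse_N(omega, N: int) -> tuple[np.ndarray, np.ndarray]:
    """Exponent branches of the eps = 1/N case study,
    lambda_{2i-1} = log(2 - omega_i/N) and
    lambda_{2i}   = log(1 - (omega_i - omega_max)/N),
    for spectrum-density diagnostics."""
    omega = np.asarray(omega, dtype=float)
    wmax = omega[-1]
    branch_odd = np.log(2.0 - omega / N)
    branch_even = np.log(1.0 - (omega - wmax) / N)
    return branch_odd, branch_even


def write_scaling_report(path_prefix, result: ScalingResult) -> None:
    """JSON report plus a TSV companion (N, H_KS) for plotting."""
    prefix = Path(path_prefix)
    report = {
        "sizes": result.sizes.tolist(),
        "hks": result.hks_values.tolist(),
        "sigma": result.slope,
        "sigma_stderr": result.slope_stderr,
        "nu": result.intercept,
        "r2": result.r_squared,
        "theta_hat": result.theta_hat,
        "class": result.classification,
    }
    Path(str(prefix) + ".json").write_text(json.dumps(report, indent=2) + "\n")
    lines = ["N\thks"] + [
        f"{int(n)}\t{h:.12g}" for n, h in zip(result.sizes, result.hks_values)
    ]
    Path(str(prefix) + ".tsv").write_text("\n".join(lines) + "\n")
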