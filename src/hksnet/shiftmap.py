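"""Analytic Lyapunov theory of the coupled shift-map multiplex.

The discrete model iterates the coupled doubling map

    x_{n+1} = (2 x_n - L x_n) mod 1,

whose Jacobian ``2I - L`` is constant, so each Lyapunov exponent is
``lambda_i = log|2 - mu_i|`` with ``mu_i`` the supra-Laplacian eigenvalues.
For mirror multiplexes (two identical layers, each node linked alpha times
to its mirror) the eigenvalues pair up as

    mu_{2i-1} = eps * omega_i,   mu_{2i} = eps * omega_i + 2 * gamma * alpha,

giving closed forms for H_KS = sum of positive exponents and first-order
Taylor approximations in the weak-coupling regime:

    single layer      H_KS ~ N1 log 2 - (eps/2) S
    multiplex         H_KS ~ N  log 2 - (eps/2) S' - gamma l12        (S' = 2S)
    mixed-sign (u<0)  H_KS ~ (N-u) log 2 - (eps/2) S
                            - eps/(2(1-gamma*alpha)) sum_{i<=N1-u} omega_i
                            + (N1-u) log(1-gamma*alpha)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .netgen import SupraLaplacian

__all__ = [
    "DegenerateSpectrumError",
    "LyapunovSpectrum",
    "TaylorHKS",
    "les_from_supra",
    "les_from_layer",
    "hks_taylor_single",
    "hks_taylor_multiplex",
    "hks_taylor_mixed",
    "count_negative_les",
    "all_les_positive",
    "iterate_map",
    "map_largest_le_numeric",
    "linear_flow_les",
    "write_spectrum",
]

LOG2 = float(np.log(2.0))


class DegenerateSpectrumError(ValueError):
    """Raised when some mu_i = 2 exactly, so log|2 - mu_i| diverges.

    Perturb the couplings (eps, gamma) slightly to lift the degeneracy.
    """


@dataclass
class LyapunovSpectrum:
    """Descending Lyapunov exponents with derived H_KS and negative count u.

    Exponents with lambda <= 0 (zeros included, matching the "log|.| <= 0"
    convention) are counted in ``n_negative``; H_KS sums the strictly
    positive ones.
    """

    exponents: np.ndarray
    hks: float
    n_negative: int
    size: int

    @classmethod
    def from_exponents(cls, exponents: np.ndarray) -> "LyapunovSpectrum":
        lam = np.sort(np.asarray(exponents, dtype=float))[::-1]
        return cls(
            exponents=lam,
            hks=float(lam[lam > 0].sum()),
            n_negative=int((lam <= 0).sum()),
            size=lam.size,
        )


@dataclass
class TaylorHKS:
    """First-order (Taylor) H_KS approximation and the regime it applies to."""

    value: float
    regime: str  # single_layer | multiplex_all_positive | multiplex_mixed


def _check_degenerate(mu: np.ndarray) -> None:
    if np.any(np.abs(2.0 - mu) < 1e-300):
        raise DegenerateSpectrumError(
            "some eigenvalue mu_i equals 2, so log|2 - mu_i| diverges; "
            "perturb eps or gamma to lift the degeneracy"
        )


def les_from_supra(mu) -> LyapunovSpectrum:
    """Lyapunov spectrum lambda_i = log|2 - mu_i| from supra-Laplacian
    eigenvalues (any multiplex, no mirror structure assumed)."""
    mu = np.asarray(mu, dtype=float)
    _check_degenerate(mu)
    return LyapunovSpectrum.from_exponents(np.log(np.abs(2.0 - mu)))


def _mirror_mu(omega, epsilon: float, gamma: float, alpha: float) -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    return np.concatenate([epsilon * omega, epsilon * omega + 2.0 * gamma * alpha])


def les_from_layer(omega, epsilon: float, gamma: float, alpha: float) -> LyapunovSpectrum:
    """Spectrum of a mirror multiplex from one layer's Laplacian spectrum,
    via the closed-form eigenvalue pairing (equivalent to les_from_supra on
    the assembled supra-Laplacian)."""
    mu = _mirror_mu(omega, epsilon, gamma, alpha)
    _check_degenerate(mu)
    return LyapunovSpectrum.from_exponents(np.log(np.abs(2.0 - mu)))


def _validity_warning(epsilon: float, omega_max: float | None, gamma_alpha: float) -> None:
    if omega_max is not None and epsilon * omega_max > 0.5:
        warnings.warn(
            f"eps*omega_max = {epsilon * omega_max:.3g} > 0.5: first-order "
            "Taylor approximation of H_KS may be inaccurate",
            stacklevel=3,
        )
    if gamma_alpha > 0.5:
        warnings.warn(
            f"gamma*alpha = {gamma_alpha:.3g} > 0.5: first-order Taylor "
            "approximation of H_KS may be inaccurate",
            stacklevel=3,
        )


def hks_taylor_single(n1: int, epsilon: float, S: int, omega_max: float | None = None) -> TaylorHKS:
    """Single-layer weak-coupling estimate H_KS ~ N1 log2 - (eps/2) S."""
    _validity_warning(epsilon, omega_max, 0.0)
    return TaylorHKS(value=n1 * LOG2 - 0.5 * epsilon * S, regime="single_layer")


def hks_taylor_multiplex(
    n: int, epsilon: float, S_prime: int, gamma: float, l12: int,
    omega_max: float | None = None, alpha: float = 0.0,
) -> TaylorHKS:
    """All-positive-exponent multiplex estimate
    H_KS ~ N log2 - (eps/2) S' - gamma l12, with S' = 2S the degree sum of
    the whole multiplex."""
    _validity_warning(epsilon, omega_max, gamma * alpha)
    return TaylorHKS(
        value=n * LOG2 - 0.5 * epsilon * S_prime - gamma * l12,
        regime="multiplex_all_positive",
    )


def hks_taylor_mixed(
    n: int, n1: int, u: int, epsilon: float, S: int, gamma: float, alpha: float, omega
) -> TaylorHKS:
    """Mixed-sign estimate for a mirror multiplex whose inter coupling has
    driven u exponents non-positive (u assumed constant during evolution)."""
    ga = gamma * alpha
    if ga >= 1.0:
        raise ValueError(f"gamma*alpha = {ga:.3g} >= 1: log(1 - gamma*alpha) undefined")
    if not 0 <= u <= n1:
        raise ValueError(f"need 0 <= u <= N1, got u={u}")
    omega = np.asarray(omega, dtype=float)
    _validity_warning(epsilon, float(omega[-1]) if omega.size else None, ga)
    partial = float(omega[: n1 - u].sum())
    value = (
        (n - u) * LOG2
        - 0.5 * epsilon * S
        - epsilon / (2.0 * (1.0 - ga)) * partial
        + (n1 - u) * np.log(1.0 - ga)
    )
    return TaylorHKS(value=float(value), regime="multiplex_mixed")


def count_negative_les(omega, epsilon: float, gamma: float, alpha: float) -> int:
    """Number u of non-positive exponents (|2 - mu_i| <= 1) over both
    branches of the mirror pairing."""
    mu = _mirror_mu(omega, epsilon, gamma, alpha)
    return int((np.abs(2.0 - mu) <= 1.0).sum())


def all_les_positive(omega, epsilon: float, gamma: float, alpha: float) -> bool:
    """True iff every exponent of the mirror multiplex is strictly positive,
    evaluated from the exact condition |2 - mu_i| > 1."""
    return count_negative_les(omega, epsilon, gamma, alpha) == 0


def iterate_map(state, L, steps: int, wrap: bool = True) -> np.ndarray:
    """Iterate x_{n+1} = (2 x_n - L x_n) mod 1 and return the full orbit
    (steps+1, N).  ``wrap=False`` skips the mod (the constant Jacobian makes
    the tangent dynamics, hence all Lyapunov quantities, identical)."""
    mat = L.matrix if isinstance(L, SupraLaplacian) else np.asarray(L, dtype=float)
    x = np.asarray(state, dtype=float)
    if x.shape != (mat.shape[0],):
        raise ValueError(f"state dimension {x.shape} does not match L {mat.shape}")
    jac = 2.0 * np.eye(mat.shape[0]) - mat
    orbit = np.empty((steps + 1, x.size))
    orbit[0] = x
    for n in range(steps):
        x = jac @ x
        if wrap:
            x = np.mod(x, 1.0)
        orbit[n + 1] = x
    return orbit


def map_largest_le_numeric(L, steps: int = 10_000, seed: int = 0) -> float:
    """Finite-time estimate of the largest exponent by propagating a random
    tangent vector through the constant Jacobian 2I - L with
    renormalisation (never by finite differences of the orbit)."""
    mat = L.matrix if isinstance(L, SupraLaplacian) else np.asarray(L, dtype=float)
    jac = 2.0 * np.eye(mat.shape[0]) - mat
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(mat.shape[0])
    v /= np.linalg.norm(v)
    total = 0.0
    for _ in range(steps):
        v = jac @ v
        norm = np.linalg.norm(v)
        total += np.log(norm)
        v /= norm
    return total / steps


def linear_flow_les(C: float, mu) -> np.ndarray:
    """Exponents of the linear flow xdot = C x - L x: lambda_i = C - mu_i."""
    return C - np.asarray(mu, dtype=float)


def write_spectrum(path_prefix, spectrum: LyapunovSpectrum, extra: dict | None = None) -> None:
    """TSV (index, i/N, lambda) plus a JSON sidecar with H_KS and u."""
    prefix = Path(path_prefix)
    lines = ["index\ti_over_N\tlambda"]
    n = spectrum.size
    for i, lam in enumerate(spectrum.exponents, start=1):
        lines.append(f"{i}\t{i / n:.10g}\t{lam:.12g}")
    Path(str(prefix) + ".tsv").write_text("\n".join(lines) + "\n")
    sidecar = {"hks": spectrum.hks, "n_negative": spectrum.n_negative, "size": spectrum.size}
    if extra:
        sidecar.update(extra)
    Path(str(prefix) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")
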