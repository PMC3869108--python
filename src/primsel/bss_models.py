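"""Generative reformulations of four blind source separation models.

Observed signals ``X`` (J trials/signals x T time points) are modelled as a
linear mixture of ``I`` latent source time courses ``S`` with weights ``W``
and i.i.d. Gaussian observation noise:

    X = W S + noise                      (instantaneous: pPCA, ICA, SIM)
    X_jt = sum_i W_ji S_i(t - tau_ji)    (anechoic mixture model, AMM)

The four families differ only in their parameter priors:

* **pPCA** - i.i.d. Gaussian sources N(mu, sigma^2), Gaussian weights.
* **ICA**  - sources from a contrast-augmented maximum-entropy density
  ``p(s) ∝ exp(-(s-mu)^2/(2 sigma^2) + lam * G(s-mu))`` with
  ``G(u) = log cosh(u)``; ``lam`` tilts the Gaussian toward the heavy/light
  tailed densities targeted by negentropy-based ICA.
* **SIM**  - smooth instantaneous mixture: each source row drawn from a
  wave-kernel Gaussian process (cutoff ``f0``); no delays.
* **AMM**  - SIM plus per-(signal, source) delays ``tau_ji`` with an
  exponential prior of mean ``gamma`` (favouring delays sparsely different
  from zero).

All operations here are pure functions of (parameters, hyperparameters,
model spec); fitting lives in :mod:`primsel.inference`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .gp_prior import KernelBundle, gp_log_density

__all__ = [
    "ModelFamily", "SignalMatrix", "ParameterSet", "HyperParams", "ModelSpec",
    "reconstruct_instantaneous", "shift_source", "reconstruct_delayed",
    "log_likelihood", "ica_log_normalizer", "log_prior", "log_cosh",
]

_LOG_2PI = np.log(2.0 * np.pi)


class ModelFamily(str, enum.Enum):
    """Model families, in the canonical (parsimony) tie-break order."""

    PPCA = "ppca"
    ICA = "ica"
    SIM = "sim"
    AMM = "amm"

    @property
    def order(self) -> int:
        return ["ppca", "ica", "sim", "amm"].index(self.value)

    @property
    def has_delays(self) -> bool:
        return self is ModelFamily.AMM

    @property
    def has_kernel(self) -> bool:
        return self in (ModelFamily.SIM, ModelFamily.AMM)


@dataclass
class SignalMatrix:
    """Observed data: J signals/trials sampled at T time points.

    ``per_signal_mean`` records the row means removed at centering so that
    reconstructions can be mapped back to the original signal units.
    """

    values: np.ndarray
    fs: float
    per_signal_mean: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < 1 or self.values.shape[1] < 2:
            raise ValueError(f"need J >= 1 and T >= 2, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal matrix contains non-finite values")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.per_signal_mean is not None:
            self.per_signal_mean = np.asarray(self.per_signal_mean, dtype=float)

    @property
    def n_signals(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def centered(self) -> "SignalMatrix":
        """Remove each signal's mean, recording it for later reconstruction."""
        m = self.values.mean(axis=1)
        return SignalMatrix(self.values - m[:, None], self.fs, per_signal_mean=m)


@dataclass
class ModelSpec:
    """Model index: family, number of sources I and smoothness cutoff f0 (Hz)."""

    family: ModelFamily
    n_sources: int
    f0: float = np.inf

    def __post_init__(self):
        self.family = ModelFamily(self.family)
        if self.n_sources < 1:
            raise ValueError(f"need at least one source, got I={self.n_sources}")
        if not self.family.has_kernel and np.isfinite(self.f0):
            raise ValueError(f"{self.family.value} admits no smoothness cutoff; "
                             f"got f0={self.f0}")

    @property
    def label(self) -> str:
        f0 = "inf" if np.isinf(self.f0) else f"{self.f0:g}"
        return f"{self.family.value}(I={self.n_sources}, f0={f0})"


@dataclass
class ParameterSet:
    """Model parameters Theta = (W, S, tau).

    W: (J, I) mixing weights; S: (I, T) source values on the time grid;
    tau: (J, I) nonnegative delays in samples, identically zero for
    non-anechoic families.
    """

    W: np.ndarray
    S: np.ndarray
    tau: np.ndarray | None = None

    def __post_init__(self):
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        J, I = self.W.shape
        I2, T = self.S.shape
        if I != I2:
            raise ValueError(f"W has {I} sources but S has {I2}")
        if self.tau is None:
            self.tau = np.zeros((J, I))
        self.tau = np.atleast_2d(np.asarray(self.tau, dtype=float))
        if self.tau.shape != (J, I):
            raise ValueError(f"tau shape {self.tau.shape} != (J={J}, I={I})")
        if np.any(self.tau < 0) or np.any(self.tau >= T):
            raise ValueError("delays must lie in [0, T)")

    @property
    def shapes(self):
        return self.W.shape[0], self.S.shape[0], self.S.shape[1]

    def copy(self) -> "ParameterSet":
        return ParameterSet(self.W.copy(), self.S.copy(), self.tau.copy())

    def n_free(self, family: ModelFamily) -> int:
        """dim(Theta): weights + sources (+ delays for AMM)."""
        J, I, T = self.shapes
        return J * I + I * T + (J * I if family.has_delays else 0)


@dataclass
class HyperParams:
    """Hyperparameters Phi shared across families.

    sigma_n: observation noise sd; sigma_w: weight prior sd; mu/sigma:
    source prior mean and sd (sigma doubles as the wave-kernel amplitude
    for SIM/AMM); lam: ICA contrast natural parameter; gamma: mean of the
    exponential delay prior (samples); f0: smoothness cutoff (Hz).
    """

    sigma_n: float
    sigma_w: float
    mu: float = 0.0
    sigma: float = 1.0
    lam: float = 0.0
    gamma: float = 20.0
    f0: float = np.inf

    def __post_init__(self):
        for name in ("sigma_n", "sigma_w", "sigma", "gamma"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


# ---------------------------------------------------------------------------
# reconstruction operators
# ---------------------------------------------------------------------------

def reconstruct_instantaneous(W: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Noise-free instantaneous reconstruction W @ S."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if W.shape[1] != S.shape[0]:
        raise ValueError(f"W has {W.shape[1]} sources but S has {S.shape[0]} rows")
    return W @ S


def _shift_phases(tau, T: int, n_freq: int) -> np.ndarray:
    """rfft-domain multipliers realizing a periodic band-limited shift by tau."""
    tau = np.asarray(tau, dtype=float)
    k = np.arange(n_freq)
    phase = np.exp(-2j * np.pi * np.multiply.outer(tau, k) / T)
    if T % 2 == 0:
        # Nyquist bin must stay real for a real, tau-differentiable output
        phase[..., -1] = np.cos(np.pi * tau)
    return phase


def _transpose_product_phases(tau_a, tau_b, T: int, n_freq: int) -> np.ndarray:
    """rfft multipliers of R(tau_a)^T R(tau_b) (composition of an adjoint
    shift with a shift).  Equals the multiplier of R(tau_b - tau_a) at all
    bins except Nyquist, where the real cos factors do not compose as a
    difference: cos(pi a) cos(pi b) != cos(pi (b - a))."""
    ph = _shift_phases(np.asarray(tau_b, float) - np.asarray(tau_a, float),
                       T, n_freq)
    if T % 2 == 0:
        ph[..., -1] = np.cos(np.pi * np.asarray(tau_a, float)) \
            * np.cos(np.pi * np.asarray(tau_b, float))
    return ph


def _shift_periodic(s: np.ndarray, tau: float) -> np.ndarray:
    """Shift without the [0, T) range check (tau taken modulo T)."""
    s = np.asarray(s, dtype=float)
    T = s.shape[-1]
    F = np.fft.rfft(s)
    return np.fft.irfft(F * _shift_phases(tau, T, F.shape[-1]), n=T)


def shift_source(s: np.ndarray, tau: float) -> np.ndarray:
    """Evaluate source ``s`` at times t - tau under periodic band-limited
    (Whittaker-Shannon) interpolation on the grid.

    Integer ``tau`` reduces to an exact circular shift; fractional shifts
    are differentiable in tau, which the delay optimization relies on.
    """
    s = np.asarray(s, dtype=float)
    T = s.shape[-1]
    if not (0 <= tau < T):
        raise ValueError(f"delay must lie in [0, T={T}), got {tau}")
    return _shift_periodic(s, tau)


def reconstruct_delayed(W: np.ndarray, S: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Anechoic reconstruction: X_hat[j, t] = sum_i W[j,i] * S_i(t - tau[j,i]).

    With ``tau`` identically zero this equals
    :func:`reconstruct_instantaneous` (up to rounding).
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    S = np.atleast_2d(np.asarray(S, dtype=float))
    tau = np.atleast_2d(np.asarray(tau, dtype=float))
    J, I = W.shape
    if S.shape[0] != I:
        raise ValueError(f"W has {I} sources but S has {S.shape[0]} rows")
    if tau.shape != (J, I):
        raise ValueError(f"tau shape {tau.shape} != (J={J}, I={I})")
    T = S.shape[1]
    F = np.fft.rfft(S, axis=-1)                       # (I, n_freq)
    phase = _shift_phases(tau, T, F.shape[-1])        # (J, I, n_freq)
    Fhat = np.einsum("ji,if,jif->jf", W, F, phase)
    return np.fft.irfft(Fhat, n=T, axis=-1)


# ---------------------------------------------------------------------------
# likelihood and priors
# ---------------------------------------------------------------------------

def log_likelihood(X, Xhat, sigma_n: float) -> float:
    """Gaussian i.i.d. log-likelihood of the residual X - Xhat.

    ``-||X - Xhat||_F^2 / (2 sigma_n^2) - (J T / 2) log(2 pi sigma_n^2)``;
    the Frobenius norm enters squared so that this is a proper Gaussian
    log-density.
    """
    if not (sigma_n > 0):
        raise ValueError(f"sigma_n must be positive, got {sigma_n}")
    Xv = X.values if isinstance(X, SignalMatrix) else np.asarray(X, dtype=float)
    Xh = np.asarray(Xhat, dtype=float)
    if Xv.shape != Xh.shape:
        raise ValueError(f"shape mismatch: X {Xv.shape} vs Xhat {Xh.shape}")
    n = Xv.size
    rss = float(np.sum((Xv - Xh) ** 2))
    return -rss / (2.0 * sigma_n ** 2) - 0.5 * n * np.log(2.0 * np.pi * sigma_n ** 2)


def log_cosh(u):
    """Numerically stable log cosh(u), the ICA contrast function G."""
    u = np.asarray(u, dtype=float)
    return np.logaddexp(u, -u) - np.log(2.0)


def ica_log_normalizer(mu: float, sigma: float, lam: float) -> float:
    """log Z(mu, sigma, lam) of the contrast-augmented source density.

    ``Z = integral exp(-(s-mu)^2/(2 sigma^2) + lam*log cosh(s-mu)) ds``,
    evaluated by deterministic adaptive quadrature after substituting
    u = s - mu (the normalizer is translation invariant in mu).
    """
    if not (sigma > 0):
        raise ValueError(f"sigma must be positive, got {sigma}")
    if lam == 0.0:
        return 0.5 * np.log(2.0 * np.pi * sigma ** 2)
    # the exponent -u^2/(2 s^2) + lam*|u| peaks near |u| = |lam| s^2;
    # integrate over a range safely covering both the peak and the tails
    L = 12.0 * sigma + abs(lam) * sigma ** 2

    def exponent(u):
        return -0.5 * (u / sigma) ** 2 + lam * log_cosh(u)

    grid = np.linspace(-L, L, 4001)
    m = float(np.max(exponent(grid)))
    if not np.isfinite(m):
        raise ValueError(f"non-finite ICA prior exponent (sigma={sigma}, lam={lam})")
    val, _ = quad(lambda u: np.exp(exponent(u) - m), -L, L,
                  epsabs=0.0, epsrel=1e-10, limit=400)
    if not (np.isfinite(val) and val > 0):
        raise ValueError("ICA normalizer quadrature failed")
    return m + np.log(val)


def _weight_log_prior(W: np.ndarray, sigma_w: float) -> float:
    return (-0.5 * float(np.sum(W ** 2)) / sigma_w ** 2
            - 0.5 * W.size * np.log(2.0 * np.pi * sigma_w ** 2))


def log_prior(theta: ParameterSet, phi: HyperParams, spec: ModelSpec,
              kernel: KernelBundle | None = None) -> float:
    """Joint log-prior of Theta = (W, S, tau) for the given family.

    Sums (a) the source prior - i.i.d. Gaussian for pPCA, contrast-augmented
    for ICA, wave-kernel GP per source row for SIM/AMM; (b) the i.i.d.
    zero-mean Gaussian weight prior with sd sigma_w; (c) for AMM only, the
    mean-gamma exponential delay prior (1/gamma) exp(-tau/gamma) per delay.

    ``kernel`` is required exactly when the family carries a smoothness
    prior (SIM/AMM).
    """
    fam = spec.family
    if fam.has_kernel and kernel is None:
        raise ValueError(f"{fam.value} requires a kernel precision bundle")
    if not fam.has_kernel and kernel is not None:
        raise ValueError(f"{fam.value} takes no kernel bundle")

    J, I, T = theta.shapes
    total = _weight_log_prior(theta.W, phi.sigma_w)

    if fam is ModelFamily.PPCA:
        u = theta.S - phi.mu
        total += (-0.5 * float(np.sum(u ** 2)) / phi.sigma ** 2
                  - 0.5 * I * T * np.log(2.0 * np.pi * phi.sigma ** 2))
    elif fam is ModelFamily.ICA:
        u = theta.S - phi.mu
        log_z = ica_log_normalizer(phi.mu, phi.sigma, phi.lam)
        total += float(np.sum(-0.5 * (u / phi.sigma) ** 2 + phi.lam * log_cosh(u)))
        total -= I * T * log_z
    else:  # SIM / AMM
        mu_vec = np.full(T, phi.mu)
        for i in range(I):
            total += gp_log_density(theta.S[i], mu_vec, kernel)

    if fam.has_delays:
        total += float(np.sum(-theta.tau / phi.gamma)) - J * I * np.log(phi.gamma)
    return total
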