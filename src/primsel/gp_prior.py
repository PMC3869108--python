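"""Wave-kernel Gaussian-process machinery for temporal smoothness priors.

Band-limited sources are modelled a priori as draws from a stationary GP
whose covariance is the *wave kernel*

    k(t, t') = amplitude * sinc(2 * f0 * |t - t'|),

with the normalized sinc convention sinc(x) = sin(pi x)/(pi x), i.e. the
inverse Fourier transform of an ideal low-pass filter with cutoff ``f0``.
Functions drawn from this prior vary on timescales comparable to 1/f0.

The limit ``f0 = inf`` yields a diagonal covariance (white sources), which
makes the smooth instantaneous mixture nest probabilistic PCA exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, cholesky

__all__ = ["KernelBundle", "wave_kernel", "kernel_matrix", "gp_log_density", "sample_gp"]

_LOG_2PI = np.log(2.0 * np.pi)

#: Relative diagonal jitter of the sampled wave-kernel Gram matrix.  The
#: jitter is not merely a numerical stabilizer: it is the prior variance of
#: out-of-band source fluctuations, i.e. it prices how "soft" the
#: band-limitedness constraint is.  The default 1e-4 * amplitude allows
#: out-of-band wiggles at 1% of the source sd, keeping the smoothness
#: constraint a soft preference (signals such as filtered kinematic
#: trajectories are only approximately band-limited); a much smaller jitter
#: would make the constraint effectively hard and veto such signals.
#: Escalates tenfold on factorization failure, up to 1e-2 * amplitude.
_JITTER_START = 1e-4
_JITTER_MAX = 1e-2


def wave_kernel(dt, f0: float, amplitude: float):
    """Evaluate the wave kernel at time lag ``dt`` (seconds).

    ``amplitude * sinc(2*f0*|dt|)`` with the normalized sinc, equal to
    ``amplitude * sin(2*pi*f0*|dt|) / (2*pi*f0*|dt|)``; the value at
    ``dt = 0`` is ``amplitude`` (removable singularity).
    """
    if not (f0 > 0):
        raise ValueError(f"f0 must be positive, got {f0}")
    if not (amplitude > 0):
        raise ValueError(f"amplitude must be positive, got {amplitude}")
    return amplitude * np.sinc(2.0 * f0 * np.abs(np.asarray(dt, dtype=float)))


@dataclass
class KernelBundle:
    """Gram matrix of the wave kernel on a regular time grid plus its factorization.

    ``K`` is symmetric positive definite after the diagonal jitter; ``chol``
    is its upper Cholesky factor, ``K_inv`` the explicit inverse and
    ``logdet`` the log-determinant.  ``amplitude`` doubles as the source
    prior variance sigma^2 so that the f0 -> inf limit reproduces an i.i.d.
    Gaussian source prior.
    """

    K: np.ndarray
    K_inv: np.ndarray
    logdet: float
    f0: float
    amplitude: float
    jitter: float
    fs: float
    chol: np.ndarray = field(repr=False, default=None)

    @property
    def T(self) -> int:
        return self.K.shape[0]

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return cho_solve((self.chol, False), rhs)

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition K = U diag(lam) U^T (lam ascending)."""
        if not hasattr(self, "_eig"):
            lam, U = np.linalg.eigh(self.K)
            self._eig = (np.maximum(lam, 1e-300), U)
        return self._eig


def kernel_matrix(T: int, fs: float, f0: float, amplitude: float,
                  jitter: float | None = None) -> KernelBundle:
    """Build the T x T wave-kernel Gram matrix on the grid t_m = m/fs.

    ``f0 = inf`` returns a diagonal bundle ``amplitude * I`` (no jitter
    needed).  For finite ``f0`` a diagonal jitter is added, starting at
    ``1e-8 * amplitude`` and escalating tenfold up to ``1e-2 * amplitude``
    until the Cholesky factorization succeeds; the sampled sinc Gram matrix
    is near-singular whenever f0 is well below the Nyquist frequency.
    """
    if T < 1:
        raise ValueError(f"grid length must be >= 1, got {T}")
    if not (amplitude > 0):
        raise ValueError(f"amplitude must be positive, got {amplitude}")
    if np.isinf(f0):
        K = amplitude * np.eye(T)
        inv = np.eye(T) / amplitude
        return KernelBundle(K=K, K_inv=inv, logdet=T * np.log(amplitude),
                            f0=f0, amplitude=amplitude, jitter=0.0, fs=fs,
                            chol=np.sqrt(amplitude) * np.eye(T))
    lags = (np.arange(T)[:, None] - np.arange(T)[None, :]) / fs
    base = wave_kernel(lags, f0, amplitude)

    jitters = ([jitter] if jitter is not None else
               [amplitude * _JITTER_START * 10.0 ** k
                for k in range(int(np.log10(_JITTER_MAX / _JITTER_START)) + 1)])
    last_err = None
    for jit in jitters:
        K = base + jit * np.eye(T)
        try:
            U = cholesky(K, lower=False)
        except np.linalg.LinAlgError as err:  # pragma: no cover - rare
            last_err = err
            continue
        logdet = 2.0 * float(np.sum(np.log(np.diag(U))))
        K_inv = cho_solve((U, False), np.eye(T))
        return KernelBundle(K=K, K_inv=K_inv, logdet=logdet, f0=f0,
                            amplitude=amplitude, jitter=jit, fs=fs, chol=U)
    raise np.linalg.LinAlgError(
        f"wave-kernel Gram matrix not positive definite up to jitter "
        f"{jitters[-1]:.3g} (T={T}, f0={f0}, fs={fs})") from last_err


def gp_log_density(s: np.ndarray, mu_vec: np.ndarray, bundle: KernelBundle) -> float:
    """Multivariate Gaussian log-density of ``s`` under N(mu_vec, K)."""
    s = np.asarray(s, dtype=float)
    mu_vec = np.asarray(mu_vec, dtype=float)
    if s.shape != mu_vec.shape or s.shape[-1] != bundle.T:
        raise ValueError(f"length mismatch: s {s.shape}, mu {mu_vec.shape}, "
                         f"kernel T={bundle.T}")
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(mu_vec))):
        raise ValueError("non-finite input to gp_log_density")
    q = s - mu_vec
    quad = float(q @ bundle.solve(q))
    return -0.5 * quad - 0.5 * bundle.logdet - 0.5 * bundle.T * _LOG_2PI


def sample_gp(T: int, fs: float, f0: float, amplitude: float, mu: float,
              n_draws: int, seed) -> np.ndarray:
    """Draw ``n_draws`` source functions from the GP prior N(mu, K).

    Reproducible: identical ``seed`` gives identical draws.
    """
    bundle = kernel_matrix(T, fs, f0, amplitude)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, T))
    # chol is upper: K = U^T U, so draws = mu + z @ U
    return mu + z @ bundle.chol
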