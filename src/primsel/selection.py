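"""Model-evidence computation and grid-based model selection.

The LAP criterion is a Laplace approximation to the log marginal
likelihood of a fitted model:

    LAP = log-likelihood + log-prior + (F/2) log 2pi - (1/2) log |H|

evaluated at the MAP parameters, where ``H`` is the Hessian of the
negative log joint and ``F = dim(Theta)``.  Larger LAP is better.  It is
compared against BIC = -2(loglik - dim/2 * log N) and
AIC = -2(loglik - dim), both of which are minimized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import circulant

from .bss_models import (HyperParams, ModelFamily, ModelSpec, ParameterSet,
                         SignalMatrix, _shift_phases,
                         _transpose_product_phases, log_likelihood,
                         log_prior, reconstruct_delayed,
                         reconstruct_instantaneous)
from .gp_prior import KernelBundle
from .inference import (FitOptions, FittedModel, _kernel_for, _pack,
                        fit_model, make_objective)

__all__ = [
    "LapScore", "CandidateScore", "SelectionResult",
    "neg_log_joint_hessian", "lap_score", "bic_score", "aic_score",
    "score_fitted", "select_model",
]

#: relative eigenvalue clip for log|H| (degenerate-direction policy)
_EIG_CLIP = 1e-8
#: relative tie tolerance for winner determination
_TIE_TOL = 1e-6
#: finite-difference step (samples) for delay-involving Hessian blocks
_HESS_TAU_STEP = 1e-3


# ---------------------------------------------------------------------------
# Hessian of the negative log joint at the MAP point
# ---------------------------------------------------------------------------

def _hessian_instantaneous(Xv, theta, phi, spec, kernel):
    J, I, T = theta.shapes
    W, S = theta.W, theta.S
    inv_sn2 = 1.0 / phi.sigma_n ** 2
    r = W @ S - Xv
    n_w = J * I
    F = n_w + I * T
    H = np.zeros((F, F))

    # W-W: block diagonal over signals, identical blocks
    A = inv_sn2 * (S @ S.T) + np.eye(I) / phi.sigma_w ** 2
    H[:n_w, :n_w] = np.kron(np.eye(J), A)

    # S-S: likelihood couples sources at equal times; prior adds per family
    B = inv_sn2 * (W.T @ W)
    H_ss = np.kron(B, np.eye(T))
    if spec.family is ModelFamily.PPCA:
        H_ss += np.eye(I * T) / phi.sigma ** 2
    elif spec.family is ModelFamily.ICA:
        u = (S - phi.mu).ravel()
        H_ss += np.diag(1.0 / phi.sigma ** 2
                        - phi.lam * (1.0 - np.tanh(u) ** 2))
    else:  # SIM
        H_ss += np.kron(np.eye(I), kernel.K_inv)
    H[n_w:, n_w:] = H_ss

    # W-S cross terms
    for j in range(J):
        blk = (W[j][None, :, None] * S[:, None, :]
               + np.eye(I)[:, :, None] * r[j][None, None, :])
        H[j * I:(j + 1) * I, n_w:] = inv_sn2 * blk.reshape(I, I * T)
    H[n_w:, :n_w] = H[:n_w, n_w:].T
    return H


def _hessian_amm(Xv, theta, phi, spec, kernel):
    J, I, T = theta.shapes
    W, S, tau = theta.W, theta.S, theta.tau
    inv_sn2 = 1.0 / phi.sigma_n ** 2
    n_w, n_s = J * I, I * T
    F = n_w + n_s + n_w
    H = np.zeros((F, F))

    Fs = np.fft.rfft(S, axis=-1)
    nf = Fs.shape[-1]
    phase = _shift_phases(tau, T, nf)                    # (J, I, nf)
    Sh = np.fft.irfft(Fs[None, :, :] * phase, n=T)       # (J, I, T)
    r = np.einsum("ji,jit->jt", W, Sh) - Xv
    Fr = np.fft.rfft(r, axis=-1)

    # W-W: per-signal Gram of the shifted sources
    for j in range(J):
        blk = inv_sn2 * (Sh[j] @ Sh[j].T) + np.eye(I) / phi.sigma_w ** 2
        H[j * I:(j + 1) * I, j * I:(j + 1) * I] = blk

    # S-S: sum over signals of shifted-source couplings (circulant blocks)
    for i in range(I):
        for k in range(i, I):
            # sum_j W_ji W_jk R_ji^T R_jk, circulant in time
            ph = _transpose_product_phases(tau[:, i], tau[:, k], T, nf)
            col = np.fft.irfft(np.einsum("j,jf->f", W[:, i] * W[:, k], ph), n=T)
            blk = inv_sn2 * circulant(col)
            if i == k:
                blk = blk + kernel.K_inv
            H[n_w + i * T:n_w + (i + 1) * T, n_w + k * T:n_w + (k + 1) * T] = blk
            if k != i:
                H[n_w + k * T:n_w + (k + 1) * T, n_w + i * T:n_w + (i + 1) * T] = blk.T

    # W-S cross terms: rows (j,i), columns (k,:)
    for j in range(J):
        FSh_ji = Fs * phase[j]                           # (I, nf): R_ji S_i
        for i in range(I):
            row = np.zeros((I, T))
            # W_jk * R_jk^T (R_ji S_i) for every k
            row += W[j][:, None] * np.fft.irfft(
                np.conj(phase[j]) * FSh_ji[i][None, :], n=T)
            row[i] += np.fft.irfft(np.conj(phase[j, i]) * Fr[j], n=T)
            H[j * I + i, n_w:n_w + n_s] = inv_sn2 * row.ravel()
    H[n_w:n_w + n_s, :n_w] = H[:n_w, n_w:n_w + n_s].T

    # delay-involving blocks: central differences of the full gradient
    fg = make_objective(Xv, phi, spec, kernel, theta.shapes)
    z = _pack(theta, spec.family)
    h = _HESS_TAU_STEP
    for p in range(n_w):
        zp, zm = z.copy(), z.copy()
        zp[n_w + n_s + p] += h
        zm[n_w + n_s + p] -= h
        col = (fg(zp)[1] - fg(zm)[1]) / (2.0 * h)
        H[:, n_w + n_s + p] = col
        H[n_w + n_s + p, :] = col
    return H


def neg_log_joint_hessian(X: SignalMatrix, theta_star: ParameterSet,
                          phi: HyperParams, spec: ModelSpec,
                          kernel: KernelBundle | None = None) -> np.ndarray:
    """Symmetric F x F Hessian of the negative log joint at the MAP point.

    Analytic blocks for weights and sources (likelihood and prior);
    delay-involving blocks by central finite differences of the gradient.
    """
    if kernel is None:
        kernel = _kernel_for(spec, phi, X.n_times, X.fs)
    Xv = X.values
    if spec.family.has_delays:
        H = _hessian_amm(Xv, theta_star, phi, spec, kernel)
    else:
        H = _hessian_instantaneous(Xv, theta_star, phi, spec, kernel)
    if not np.all(np.isfinite(H)):
        raise ValueError("non-finite entries in Hessian")
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

@dataclass
class LapScore:
    total: float
    loglik: float
    logprior: float
    log_posterior_volume: float


def lap_score(loglik: float, logprior: float, H: np.ndarray) -> LapScore:
    """Laplace-approximation evidence: loglik + logprior + (F/2) log 2pi
    - (1/2) log|H|.

    log|H| is computed from the eigenvalues of H, clipped from below at
    ``1e-8 * max(eig)`` so that residual flat (degenerate) directions do
    not produce an infinite posterior volume.
    """
    H = np.asarray(H, dtype=float)
    F = H.shape[0]
    eig = np.linalg.eigvalsh(0.5 * (H + H.T))
    top = eig[-1]
    if top <= 0:
        raise ValueError("Hessian has no positive eigenvalue; not a minimum")
    logdet = float(np.sum(np.log(np.clip(eig, _EIG_CLIP * top, None))))
    volume = 0.5 * F * np.log(2.0 * np.pi) - 0.5 * logdet
    return LapScore(total=loglik + logprior + volume, loglik=loglik,
                    logprior=logprior, log_posterior_volume=volume)


def bic_score(loglik: float, dim_theta: int, n_points: int) -> float:
    """Bayesian information criterion (minimize): -2(loglik - dim/2 log N)."""
    if n_points < 1:
        raise ValueError(f"n_points must be >= 1, got {n_points}")
    return -2.0 * (loglik - 0.5 * dim_theta * np.log(n_points))


def aic_score(loglik: float, dim_theta: int) -> float:
    """Akaike information criterion (minimize): -2(loglik - dim)."""
    return -2.0 * (loglik - dim_theta)


# ---------------------------------------------------------------------------
# candidate scan
# ---------------------------------------------------------------------------

@dataclass
class CandidateScore:
    spec: ModelSpec
    lap: float = np.nan
    bic: float = np.nan
    aic: float = np.nan
    dim_theta: int = 0
    loglik: float = np.nan
    logprior: float = np.nan
    log_posterior_volume: float = np.nan
    converged: bool = False
    error: str | None = None
    fitted: FittedModel | None = field(default=None, repr=False)

    @property
    def ok(self) -> bool:
        return self.error is None


def score_fitted(X: SignalMatrix, fitted: FittedModel) -> CandidateScore:
    """Compute LAP/BIC/AIC for one fitted candidate."""
    Xc = X.centered() if X.per_signal_mean is None else X
    spec, theta, phi = fitted.spec, fitted.theta_star, fitted.phi
    if spec.family.has_delays:
        Xhat = reconstruct_delayed(theta.W, theta.S, theta.tau)
    else:
        Xhat = reconstruct_instantaneous(theta.W, theta.S)
    ll = log_likelihood(Xc, Xhat, phi.sigma_n)
    lp = log_prior(theta, phi, spec,
                   fitted.kernel if spec.family.has_kernel else None)
    H = neg_log_joint_hessian(Xc, theta, phi, spec, fitted.kernel)
    lap = lap_score(ll, lp, H)
    dim = theta.n_free(spec.family)
    n_points = Xc.values.size
    return CandidateScore(spec=spec, lap=lap.total,
                          bic=bic_score(ll, dim, n_points),
                          aic=aic_score(ll, dim), dim_theta=dim, loglik=ll,
                          logprior=lp,
                          log_posterior_volume=lap.log_posterior_volume,
                          converged=fitted.converged, fitted=fitted)


def _pick_winner(cands: list[CandidateScore], key, maximize: bool):
    ok = [c for c in cands if c.ok and np.isfinite(key(c))]
    if not ok:
        return None
    best = max(ok, key=key) if maximize else min(ok, key=key)
    tol = _TIE_TOL * max(1.0, abs(key(best)))
    tied = [c for c in ok if abs(key(c) - key(best)) <= tol]
    # parsimony tie-break: fewer sources, then the simpler family
    # (pPCA < ICA < SIM < AMM), then the smaller cutoff.  Exact ties occur
    # on noiseless rank-I data, where every family reconstructs perfectly;
    # they resolve to the least-assuming model.
    tied.sort(key=lambda c: (c.spec.n_sources, c.spec.family.order, c.spec.f0))
    return tied[0].spec


@dataclass
class SelectionResult:
    candidates: list[CandidateScore]
    winner_lap: ModelSpec | None
    winner_bic: ModelSpec | None
    winner_aic: ModelSpec | None

    def winner(self, criterion: str) -> ModelSpec | None:
        return getattr(self, f"winner_{criterion}")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"family": c.spec.family.value, "I": c.spec.n_sources,
                 "f0_hz": c.spec.f0, "loglik": c.loglik,
                 "logprior": c.logprior,
                 "logposteriorvol": c.log_posterior_volume, "lap": c.lap,
                 "bic": c.bic, "aic": c.aic, "converged": c.converged,
                 "error": c.error}
                for c in self.candidates]
        return pd.DataFrame(rows)


def candidate_specs(families, I_range, f0_grid) -> list[ModelSpec]:
    """Enumerate the candidate grid.

    pPCA and ICA carry no smoothness cutoff (a single f0 = inf candidate
    per I); SIM and AMM take each finite f0 from the grid.  When the grid
    contains inf and pPCA is among the families, the SIM f0 = inf member
    coincides with pPCA and is scored once (as pPCA).
    """
    fams = sorted({ModelFamily(f) for f in families}, key=lambda f: f.order)
    if not fams or not list(I_range) or not list(f0_grid):
        raise ValueError("families, I_range and f0_grid must be non-empty")
    specs = []
    finite = [f for f in f0_grid if np.isfinite(f)]
    has_inf = any(np.isinf(f) for f in f0_grid)
    for fam in fams:
        for I in I_range:
            if not fam.has_kernel:
                specs.append(ModelSpec(fam, I, np.inf))
            else:
                for f0 in finite:
                    specs.append(ModelSpec(fam, I, float(f0)))
                if has_inf and not (fam is ModelFamily.SIM
                                    and ModelFamily.PPCA in fams):
                    specs.append(ModelSpec(fam, I, np.inf))
    return specs


def select_model(X: SignalMatrix, families, I_range, f0_grid,
                 opts: FitOptions | None = None) -> SelectionResult:
    """Fit and score every (family, I, f0) candidate; return all scores and
    the per-criterion winners.

    Individual fit failures are recorded on their candidate and excluded
    from the winners; they never abort the scan.
    """
    opts = opts or FitOptions()
    Xc = X.centered() if X.per_signal_mean is None else X
    cands = []
    for spec in candidate_specs(families, I_range, f0_grid):
        try:
            fitted = fit_model(Xc, spec, opts)
            cands.append(score_fitted(Xc, fitted))
        except Exception as err:  # noqa: BLE001 - record, never abort the scan
            cands.append(CandidateScore(spec=spec, error=f"{type(err).__name__}: {err}"))
    return SelectionResult(
        candidates=cands,
        winner_lap=_pick_winner(cands, lambda c: c.lap, maximize=True),
        winner_bic=_pick_winner(cands, lambda c: c.bic, maximize=False),
        winner_aic=_pick_winner(cands, lambda c: c.aic, maximize=False),
    )
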