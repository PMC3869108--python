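"""Ground-truth generator for the simulation benchmark.

Emulates kinematic-like trajectories (e.g. joint angles): band-limited
sources obtained by zero-phase Butterworth filtering of Gaussian noise,
mixed either instantaneously (SIM) or with per-(trial, source) delays
(AMM), then corrupted by multiplicative signal-dependent Gaussian noise
whose slope alpha is calibrated to hit a target noise level 1 - R^2.

Benchmark design: 2 families (SIM/AMM) x 2 source cutoffs (5/10 Hz) x
4 source counts (1..4) x 3 noise levels (0/0.15/0.3) = 48 conditions,
each realized for J in {5, 10, 25} trials with 20 replicates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.signal import butter, filtfilt

from .bss_models import (ModelFamily, ParameterSet, SignalMatrix,
                         reconstruct_delayed, reconstruct_instantaneous)

__all__ = [
    "GeneratorRecord", "GroundTruthDataset", "BenchmarkConfig",
    "generate_sources", "generate_mixture", "r_squared",
    "add_signal_dependent_noise", "calibrate_noise_slope",
    "benchmark_conditions", "generate_benchmark", "make_dataset",
    "gait_design_series", "save_dataset", "load_dataset",
]


@dataclass
class GeneratorRecord:
    """Provenance of one synthetic dataset."""

    family: str
    I_true: int
    cutoff_hz: float
    noise_level: float
    J: int
    alpha: float
    achieved_noise: float
    seed: int
    replicate: int = 0
    T: int = 100
    fs: float = 100.0


@dataclass
class GroundTruthDataset:
    X_noisy: SignalMatrix
    X_noiseless: SignalMatrix
    true_params: ParameterSet
    generator: GeneratorRecord


@dataclass
class BenchmarkConfig:
    """Benchmark factorial design; defaults are the study conditions."""

    families: Sequence[str] = ("sim", "amm")
    cutoffs_hz: Sequence[float] = (5.0, 10.0)
    n_sources: Sequence[int] = (1, 2, 3, 4)
    noise_levels: Sequence[float] = (0.0, 0.15, 0.3)
    trial_counts: Sequence[int] = (5, 10, 25)
    replicates: int = 20
    T: int = 100
    fs: float = 100.0
    weight_range: tuple[float, float] = (-10.0, 10.0)
    delay_mean: float = 20.0


def generate_sources(I: int, T: int = 100, fs: float = 100.0, *,
                     cutoff_hz: float, seed) -> np.ndarray:
    """Band-limited sources: i.i.d. standard normal draws low-pass filtered
    by a 6th-order Butterworth applied forward and backward (zero phase).

    With T = 100 at fs = 100 Hz each source spans 1 s.
    """
    if not (0 < cutoff_hz < fs / 2):
        raise ValueError(f"cutoff must lie in (0, fs/2)={fs / 2}, got {cutoff_hz}")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((I, T))
    b, a = butter(6, cutoff_hz / (fs / 2))
    return filtfilt(b, a, raw, axis=-1)


def generate_mixture(S: np.ndarray, J: int, family, seed, *,
                     fs: float = 100.0,
                     weight_range: tuple[float, float] = (-10.0, 10.0),
                     delay_mean: float = 20.0) -> tuple[SignalMatrix, ParameterSet]:
    """Mix sources into J noiseless trials.

    Weights are uniform on ``weight_range``; for AMM, delays are drawn from
    an exponential distribution with mean ``delay_mean`` samples and reduced
    modulo T (shifts are periodic, so delays are equivalent mod T; the
    stored delays always lie in [0, T)).  No noise is added here.
    """
    family = ModelFamily(family)
    if not family.has_kernel:
        raise ValueError(f"generator families are SIM and AMM, got {family.value}")
    S = np.atleast_2d(np.asarray(S, dtype=float))
    I, T = S.shape
    rng = np.random.default_rng(seed)
    W = rng.uniform(*weight_range, size=(J, I))
    if family.has_delays:
        tau = np.mod(rng.exponential(delay_mean, size=(J, I)), T)
        X = reconstruct_delayed(W, S, tau)
    else:
        tau = np.zeros((J, I))
        X = reconstruct_instantaneous(W, S)
    return SignalMatrix(X, fs), ParameterSet(W, S, tau)


def r_squared(X_noiseless, X_noisy) -> float:
    """Multivariate coefficient of determination based on total variation.

    ``1 - ||Xn - Xy||_F^2 / ||Xn - Xbar||_F^2`` where ``Xbar`` repeats the
    across-trial mean time course in every row; the denominator is T times
    the trace of the across-trial covariance of the noiseless data.
    """
    Xn = X_noiseless.values if isinstance(X_noiseless, SignalMatrix) else np.asarray(X_noiseless, float)
    Xy = X_noisy.values if isinstance(X_noisy, SignalMatrix) else np.asarray(X_noisy, float)
    if Xn.shape != Xy.shape:
        raise ValueError(f"shape mismatch: {Xn.shape} vs {Xy.shape}")
    denom = float(np.sum((Xn - Xn.mean(axis=0, keepdims=True)) ** 2))
    if denom == 0.0:
        raise ValueError("noiseless data has zero across-trial variation")
    return 1.0 - float(np.sum((Xn - Xy) ** 2)) / denom


def add_signal_dependent_noise(X, alpha: float, seed):
    """Add Gaussian noise with sd = alpha * |x(t)| element-wise."""
    if alpha < 0:
        raise ValueError(f"alpha must be nonnegative, got {alpha}")
    is_sm = isinstance(X, SignalMatrix)
    Xv = X.values if is_sm else np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    noisy = Xv + rng.standard_normal(Xv.shape) * (alpha * np.abs(Xv))
    return SignalMatrix(noisy, X.fs) if is_sm else noisy


def calibrate_noise_slope(X_noiseless, target_level: float, seed, *,
                          step: float = 0.001, tol: float = 0.01,
                          patience: int = 10, draws_per_step: int | None = None,
                          max_steps: int = 100_000) -> float:
    """Find the noise slope alpha achieving a target noise level 1 - R^2.

    Starting from alpha = 0, increase alpha by ``step``; at each step draw
    fresh noise and compute 1 - R^2 (averaged over ``draws_per_step`` fresh
    draws, which keeps the Monte-Carlo scatter of the level estimate well
    inside the tolerance window).  Stop once the level has stayed within
    ``tol`` of the target for ``patience`` consecutive steps and return
    that alpha.  A target of 0 returns alpha = 0 immediately.
    """
    if not (0 <= target_level < 1):
        raise ValueError(f"target noise level must lie in [0, 1), got {target_level}")
    if target_level == 0.0:
        return 0.0
    rng = np.random.default_rng(seed)
    # expected level is c * alpha^2 with c = sum(x^2) / sum((x - xbar)^2);
    # shrink the increment when the level-vs-alpha slope at the target is so
    # steep that the tolerance window would span fewer steps than `patience`
    Xn = X_noiseless.values if isinstance(X_noiseless, SignalMatrix) else np.asarray(X_noiseless, float)
    c = float(np.sum(Xn ** 2) / np.sum((Xn - Xn.mean(axis=0, keepdims=True)) ** 2))
    slope = 2.0 * np.sqrt(target_level * c)
    step = min(step, 2.0 * tol / (8.0 * patience * slope))
    denom = float(np.sum((Xn - Xn.mean(axis=0, keepdims=True)) ** 2))
    if draws_per_step is None:
        # Monte-Carlo sd of a single-draw level estimate at the target:
        # Var(sum e^2) = 2 sum(alpha^2 x^2)^2; keep the averaged sd <= tol/3
        a2 = target_level / c
        var1 = 2.0 * a2 ** 2 * float(np.sum(Xn ** 4)) / denom ** 2
        draws_per_step = int(np.clip(np.ceil(9.0 * var1 / tol ** 2), 5, 400))
    abs_x = np.abs(Xn)

    def level_at(alpha: float, n_draws: int) -> float:
        z = rng.standard_normal((n_draws,) + Xn.shape)
        rss = np.sum((z * (alpha * abs_x)) ** 2, axis=(1, 2))
        return float(np.mean(rss)) / denom

    # coarse approach with a few draws, then fine steps with the streak rule
    alpha = 0.0
    coarse = max(step, np.sqrt(target_level / c) / 50.0)
    while level_at(alpha + coarse, 5) < target_level - 5 * tol:
        alpha += coarse
    streak = 0
    for _ in range(max_steps):
        alpha += step
        level = level_at(alpha, draws_per_step)
        streak = streak + 1 if abs(level - target_level) <= tol else 0
        if streak >= patience:
            return alpha
        if level > target_level + 10 * tol:
            break
    raise RuntimeError(f"noise calibration failed to stabilize at level "
                       f"{target_level} within {max_steps} steps")


def make_dataset(family, I_true: int, cutoff_hz: float, noise_level: float,
                 J: int, seed, *, replicate: int = 0, T: int = 100,
                 fs: float = 100.0, weight_range=(-10.0, 10.0),
                 delay_mean: float = 20.0) -> GroundTruthDataset:
    """Generate one ground-truth dataset for a single benchmark condition."""
    ss = np.random.SeedSequence(seed)
    s_src, s_mix, s_cal, s_noise = (int(c.generate_state(1)[0] % (2 ** 31))
                                    for c in ss.spawn(4))
    S = generate_sources(I_true, T, fs, cutoff_hz=cutoff_hz, seed=s_src)
    X_clean, truth = generate_mixture(S, J, family, s_mix, fs=fs,
                                      weight_range=weight_range,
                                      delay_mean=delay_mean)
    if noise_level > 0:
        alpha = calibrate_noise_slope(X_clean, noise_level, s_cal)
        X_noisy = add_signal_dependent_noise(X_clean, alpha, s_noise)
    else:
        alpha, X_noisy = 0.0, SignalMatrix(X_clean.values.copy(), fs)
    achieved = 1.0 - r_squared(X_clean, X_noisy)
    rec = GeneratorRecord(family=ModelFamily(family).value, I_true=I_true,
                          cutoff_hz=cutoff_hz, noise_level=noise_level, J=J,
                          alpha=alpha, achieved_noise=achieved, seed=int(seed),
                          replicate=replicate, T=T, fs=fs)
    return GroundTruthDataset(X_noisy, X_clean, truth, rec)


def benchmark_conditions(config: BenchmarkConfig | None = None) -> list[dict]:
    """Enumerate the factorial generator conditions (48 by default)."""
    cfg = config or BenchmarkConfig()
    return [dict(family=f, cutoff_hz=c, I_true=i, noise_level=nl)
            for f in cfg.families for c in cfg.cutoffs_hz
            for i in cfg.n_sources for nl in cfg.noise_levels]


def _child_seed(master_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_benchmark(config: BenchmarkConfig | None, master_seed: int
                       ) -> Iterator[GroundTruthDataset]:
    """Lazily generate the full benchmark.

    Yields one dataset per (condition, J, replicate), with child seeds
    derived deterministically from ``master_seed`` so that any single
    dataset is regenerable in isolation.
    """
    cfg = config or BenchmarkConfig()
    for ci, cond in enumerate(benchmark_conditions(cfg)):
        for J in cfg.trial_counts:
            for rep in range(cfg.replicates):
                seed = _child_seed(master_seed, ci, J, rep)
                yield make_dataset(cond["family"], cond["I_true"],
                                   cond["cutoff_hz"], cond["noise_level"],
                                   J, seed, replicate=rep, T=cfg.T, fs=cfg.fs,
                                   weight_range=cfg.weight_range,
                                   delay_mean=cfg.delay_mean)


def gait_design_series(n_actors: int = 6, n_styles: int = 3,
                       n_repetitions: int = 3, n_flexion_angles: int = 8) -> int:
    """Series count of the gait recording design this generator emulates.

    Six actors walking in three emotional styles, three repetitions each,
    one gait cycle per repetition, eight lower-body flexion angles per
    cycle: 6 * 3 * 3 * 8 = 432 one-dimensional time series.
    """
    return n_actors * n_styles * n_repetitions * n_flexion_angles


# ---------------------------------------------------------------------------
# on-disk layout: signals CSVs + truth arrays + metadata JSON
# ---------------------------------------------------------------------------

def _write_signals_csv(path: Path, values: np.ndarray) -> None:
    header = ",".join(f"t{k}" for k in range(values.shape[1]))
    np.savetxt(path, values, delimiter=",", header=header, comments="")


def save_dataset(ds: GroundTruthDataset, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_signals_csv(out / "signals_noisy.csv", ds.X_noisy.values)
    _write_signals_csv(out / "signals_noiseless.csv", ds.X_noiseless.values)
    np.save(out / "true_W.npy", ds.true_params.W)
    np.save(out / "true_S.npy", ds.true_params.S)
    np.save(out / "true_tau.npy", ds.true_params.tau)
    meta = {"fs_hz": ds.X_noisy.fs, "generator": asdict(ds.generator)}
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
    return out


def load_dataset(path) -> GroundTruthDataset:
    p = Path(path)
    meta = json.loads((p / "metadata.json").read_text())
    fs = meta["fs_hz"]
    noisy = np.loadtxt(p / "signals_noisy.csv", delimiter=",", skiprows=1, ndmin=2)
    clean = np.loadtxt(p / "signals_noiseless.csv", delimiter=",", skiprows=1, ndmin=2)
    truth = ParameterSet(np.load(p / "true_W.npy"), np.load(p / "true_S.npy"),
                         np.load(p / "true_tau.npy"))
    rec = GeneratorRecord(**meta["generator"])
    return GroundTruthDataset(SignalMatrix(noisy, fs), SignalMatrix(clean, fs),
                              truth, rec)
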