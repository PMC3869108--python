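"""Benchmark metrics: model-type classification rate, source-count error
and smoothness-estimation error, aggregated into summary tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bss_models import ModelFamily, ModelSpec
from .selection import SelectionResult
from .synthetic_data import GeneratorRecord

__all__ = [
    "ExperimentRecord", "SmoothnessError", "classification_rate",
    "source_count_error", "smoothness_error", "summarize_experiment",
]

CRITERIA = ("lap", "bic", "aic")


@dataclass
class ExperimentRecord:
    """One benchmark dataset together with its selection outcome."""

    generator: GeneratorRecord
    selection: SelectionResult

    def selected(self, criterion: str) -> ModelSpec | None:
        return self.selection.winner(criterion)


def _check(records, criterion):
    if not records:
        raise ValueError("empty record list")
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}, got {criterion}")


def classification_rate(records: list[ExperimentRecord], criterion: str) -> float:
    """Fraction of records whose selected family equals the generating
    family.  A pPCA or ICA selection counts as incorrect for both SIM and
    AMM generators."""
    _check(records, criterion)
    hits = 0
    for rec in records:
        sel = rec.selected(criterion)
        if sel is not None and sel.family.value == rec.generator.family:
            hits += 1
    return hits / len(records)


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return mean, sd


def source_count_error(records: list[ExperimentRecord], criterion: str
                       ) -> tuple[float, float]:
    """Mean and sd (n-1 denominator) of Delta I = selected I - true I."""
    _check(records, criterion)
    deltas = [rec.selected(criterion).n_sources - rec.generator.I_true
              for rec in records if rec.selected(criterion) is not None]
    if not deltas:
        raise ValueError("no records with a selection")
    return _mean_sd(np.asarray(deltas, dtype=float))


@dataclass
class SmoothnessError:
    mean: float
    sd: float
    n_used: int
    n_excluded: int

    def __iter__(self):  # allow ``mean, sd = smoothness_error(...)``-lite use
        return iter((self.mean, self.sd))


def smoothness_error(records: list[ExperimentRecord], criterion: str,
                     exclude_infinite: bool = True) -> SmoothnessError:
    """Mean and sd of Delta f0 = selected f0 - generating cutoff (Hz).

    Records whose winner carries no finite cutoff (pPCA/ICA, or an
    unsmoothed selection) are excluded from the statistics and reported as
    an exclusion count."""
    _check(records, criterion)
    deltas, excluded = [], 0
    for rec in records:
        sel = rec.selected(criterion)
        if sel is None or np.isinf(sel.f0):
            excluded += 1
            continue
        deltas.append(sel.f0 - rec.generator.cutoff_hz)
    if not deltas:
        raise ValueError("all records excluded from smoothness error")
    if not exclude_infinite and excluded:
        raise ValueError(f"{excluded} records carry no finite cutoff")
    mean, sd = _mean_sd(np.asarray(deltas, dtype=float))
    return SmoothnessError(mean=mean, sd=sd, n_used=len(deltas),
                           n_excluded=excluded)


def summarize_experiment(records: list[ExperimentRecord]) -> dict[str, pd.DataFrame]:
    """Three tables keyed by (J, generator family, noise level, criterion):
    classification rate, Delta I mean +- sd, Delta f0 mean +- sd."""
    if not records:
        raise ValueError("empty record list")
    keys = sorted({(r.generator.J, r.generator.family, r.generator.noise_level)
                   for r in records})
    cls_rows, di_rows, df_rows = [], [], []
    for J, fam, noise in keys:
        subset = [r for r in records
                  if (r.generator.J, r.generator.family,
                      r.generator.noise_level) == (J, fam, noise)]
        for crit in CRITERIA:
            base = {"J": J, "generator": fam, "noise_level": noise,
                    "criterion": crit, "n": len(subset)}
            cls_rows.append({**base,
                             "classification_rate": classification_rate(subset, crit)})
            try:
                m, s = source_count_error(subset, crit)
                di_rows.append({**base, "delta_I_mean": m, "delta_I_sd": s})
            except ValueError:
                pass
            try:
                err = smoothness_error(subset, crit)
                df_rows.append({**base, "delta_f0_mean": err.mean,
                                "delta_f0_sd": err.sd,
                                "n_infinite": err.n_excluded})
            except ValueError:
                pass
    return {"classification": pd.DataFrame(cls_rows),
            "source_count": pd.DataFrame(di_rows),
            "smoothness": pd.DataFrame(df_rows)}
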