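"""Derived observables: peak adoption, consensus times, survival curves."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnsembleSummary",
    "max_adoption",
    "time_to_consensus",
    "survival_metrics",
    "SurvivalCurves",
]


@dataclass
class EnsembleSummary:
    """Across-run aggregation of an ensemble of simulation runs.

    Per-run arrays (``i_max``, ``peak_epoch``, ``extinction_epoch``,
    consensus times) have one entry per replicate; censored values are
    NaN.  ``mean_*`` trajectories are averaged over runs after exact
    padding of frozen tails to the common horizon.  ``mean_survival`` is
    the mean of the per-run normalized curves I(t)/I_max.
    """

    n_runs: int
    n_total: int
    i_max: np.ndarray
    peak_epoch: np.ndarray
    extinction_epoch: np.ndarray
    mean_s: np.ndarray
    mean_i: np.ndarray
    mean_r: np.ndarray
    mean_survival: np.ndarray
    consensus_epochs: dict = field(default_factory=dict)

    @property
    def i_max_mean(self) -> float:
        return float(np.mean(self.i_max))

    @property
    def i_max_sd(self) -> float:
        return float(np.std(self.i_max, ddof=1)) if self.n_runs > 1 else 0.0

    @property
    def i_max_se(self) -> float:
        return self.i_max_sd / np.sqrt(self.n_runs)

    def summary(self) -> dict:
        out = {
            "n_runs": self.n_runs,
            "i_max_mean": self.i_max_mean,
            "i_max_sd": self.i_max_sd,
            "i_max_se": self.i_max_se,
            "peak_epoch_mean": float(np.mean(self.peak_epoch)),
            "extinct_fraction": float(
                np.mean(~np.isnan(self.extinction_epoch))
            ),
        }
        for lvl, times in sorted(self.consensus_epochs.items()):
            ok = ~np.isnan(times)
            out[f"consensus_{lvl}_mean"] = (
                float(np.mean(times[ok])) if ok.any() else float("nan")
            )
            out[f"consensus_{lvl}_censored"] = int(np.sum(~ok))
        return out


def max_adoption(result, n_total: int) -> float:
    """Peak concurrent infected count as a fraction of ``n_total``."""
    if len(result.i) == 0:
        raise ValueError("empty trajectory")
    return result.peak_i / n_total


def time_to_consensus(result, level: float):
    """First epoch at which I/N >= ``level`` (SI runs); None if censored.

    ``level`` must lie in (0, 1].  With a monotone I trajectory (SI
    mode) the returned times are monotone in ``level`` by construction.
    """
    if not 0.0 < level <= 1.0:
        raise ValueError("consensus level must lie in (0, 1]")
    frac = result.i / result.n_total
    hits = np.nonzero(frac >= level)[0]
    return int(hits[0]) if len(hits) else None


@dataclass
class SurvivalCurves:
    """Normalized and raw infected-population decay curves.

    ``normalized[t] = I(t)/I_max`` and ``raw[t] = I(t)/N`` per recorded
    epoch; ``at_checkpoints`` maps requested epochs to the normalized
    value (NaN marks checkpoints beyond the recorded horizon).
    """

    epochs: np.ndarray
    normalized: np.ndarray
    raw: np.ndarray
    at_checkpoints: dict


def survival_metrics(result, checkpoints=(515,)) -> SurvivalCurves:
    """Fraction of the peak infected population remaining over time.

    Works on any object with ``i`` (per-epoch counts), ``peak_i`` and
    ``n_total``.  Post-extinction values are 0 by construction.
    """
    i = np.asarray(result.i, dtype=float)
    if result.peak_i <= 0:
        raise ValueError("run has no infected population to normalize by")
    normalized = i / result.peak_i
    raw = i / result.n_total
    horizon = len(i) - 1
    at = {
        int(t): (float(normalized[int(t)]) if 0 <= t <= horizon else np.nan)
        for t in checkpoints
    }
    return SurvivalCurves(
        epochs=np.arange(len(i)),
        normalized=normalized,
        raw=raw,
        at_checkpoints=at,
    )
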