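"""Resampled nonlinear least-squares fitting of the dispersion model.

The calibration procedure repeatedly fits the four-parameter model to a
random 90% subset of the data (shuffled train/test split), 1000 times by
default, and summarizes the distribution of fitted parameters by its
median and 2.5/97.5 empirical percentiles.  The held-out 10% of each
iteration is predicted with that iteration's parameters; pooling those
pairs across iterations gives an out-of-sample agreement estimate.

Everything is deterministic given ``master_seed``: iteration ``k`` uses
split seed ``(master_seed + k) % 2**31``, so any single iteration can be
reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.model_selection import train_test_split

from .core import PARAMETER_NAMES, PARAMETER_UNITS, ModelParameters, relaxivity
from .dataset import Dataset

__all__ = [
    "FitConfig",
    "FitFailure",
    "ParameterEnsemble",
    "fit_once",
    "resample_fit",
    "summarize_ensemble",
    "pooled_test_predictions",
    "DEFAULT_BOUNDS",
    "DEFAULT_INITIAL_GUESS",
]

#: Optimizer box constraints per parameter (1e-4 scale): Lorentzian amplitude
#: and width non-negative, offset and temperature slope loosely bounded.
DEFAULT_BOUNDS = ((0.0, 100.0), (0.0, 100.0), (-10.0, 10.0), (-1.0, 1.0))
DEFAULT_INITIAL_GUESS = (5.0, 1.0, 1.0, 0.01)

FULL_MASK = (True, True, True, True)


class FitFailure(RuntimeError):
    """The optimizer failed to converge on this subset."""


@dataclass(frozen=True)
class FitConfig:
    """Settings for the resampled fit.

    n_iterations    number of resampling iterations (default 1000)
    train_fraction  fraction of records in each training subset (default 0.9)
    master_seed     seed controlling all shuffled splits and jittered restarts
    initial_guess   optimizer start, full four-vector on the 1e-4 scale
    bounds          per-parameter (lower, upper) boxes, full four-vector
    n_starts        multi-start count; starts beyond the first jitter the
                    initial guess, best residual wins (guards local minima)
    optimizer_tolerance  ftol/xtol passed to the least-squares solver
    """

    n_iterations: int = 1000
    train_fraction: float = 0.9
    master_seed: int = 0
    initial_guess: tuple = DEFAULT_INITIAL_GUESS
    bounds: tuple = DEFAULT_BOUNDS
    n_starts: int = 1
    optimizer_tolerance: float = 1e-10

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction <= 1:
            raise ValueError("train_fraction must be in (0, 1]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass(frozen=True)
class ParameterEnsemble:
    """Fitted parameter vectors from each resampling iteration.

    ``samples`` is (n_successes, k_active); ``heldout_modelled`` /
    ``heldout_measured`` concatenate each iteration's test-set
    predictions and observations (empty when the config left no test
    records).  ``ci_lower <= median <= ci_upper`` holds per parameter.
    """

    samples: np.ndarray
    active_mask: tuple[bool, bool, bool, bool]
    medians: ModelParameters
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    convergence_failures: int
    n_iterations: int
    master_seed: int
    heldout_modelled: np.ndarray
    heldout_measured: np.ndarray

    def parameter_table(self) -> dict:
        """Per-parameter {median, ci_lower, ci_upper, units} summary."""
        names = [n for n, m in zip(PARAMETER_NAMES, self.active_mask) if m]
        med = self.medians.active_values()
        return {
            name: {
                "median": float(m),
                "ci_lower": float(lo),
                "ci_upper": float(hi),
                "units": PARAMETER_UNITS[name],
            }
            for name, m, lo, hi in zip(names, med, self.ci_lower, self.ci_upper)
        }


def _model_residuals(active, mask, b0, temperature, y):
    full = np.zeros(4)
    full[mask] = active
    return full[0] / (1.0 + full[1] * b0**2) + full[2] + full[3] * temperature - y


def fit_once(
    ds: Dataset,
    active_mask: Sequence[bool] = FULL_MASK,
    initial_guess: Sequence[float] = DEFAULT_INITIAL_GUESS,
    bounds: Sequence[tuple] = DEFAULT_BOUNDS,
    tolerance: float = 1e-10,
    _arrays: tuple | None = None,
) -> tuple[ModelParameters, float]:
    """Single bounded nonlinear least-squares fit on a dataset.

    Returns the fitted :class:`ModelParameters` and the residual sum of
    squares on the 1e-4 scale.  Raises ``ValueError`` when the dataset
    has no more records than active parameters (underdetermined) and
    :class:`FitFailure` when the solver does not converge.
    """
    mask = np.asarray(active_mask, dtype=bool)
    if not mask[0]:
        raise ValueError("c1 must always be active")
    if _arrays is not None:
        b0, temperature, y = _arrays
    else:
        b0, temperature, y = ds.b0, ds.temperature, ds.r1ox
    k = int(mask.sum())
    if len(y) <= k:
        raise ValueError(
            f"underdetermined fit: {len(y)} records for {k} free parameters"
        )
    init = np.asarray(initial_guess, dtype=float)[mask]
    lower = np.array([b[0] for b in bounds])[mask]
    upper = np.array([b[1] for b in bounds])[mask]
    init = np.clip(init, lower, upper)
    result = least_squares(
        _model_residuals,
        init,
        bounds=(lower, upper),
        args=(mask, b0, temperature, y),
        ftol=tolerance,
        xtol=tolerance,
    )
    if result.status <= 0:
        raise FitFailure(f"optimizer did not converge: {result.message}")
    params = ModelParameters.from_active(result.x, tuple(mask))
    rss = float(np.sum(result.fun**2))
    return params, rss


def _fit_multistart(cfg, mask, arrays, rng):
    best = None
    for start in range(cfg.n_starts):
        guess = np.asarray(cfg.initial_guess, dtype=float)
        if start > 0:
            guess = guess * rng.uniform(0.5, 2.0, size=4)
        try:
            params, rss = fit_once(
                None, mask, guess, cfg.bounds, cfg.optimizer_tolerance,
                _arrays=arrays,
            )
        except FitFailure:
            continue
        if best is None or rss < best[1]:
            best = (params, rss)
    if best is None:
        raise FitFailure("all starts failed to converge")
    return best


def resample_fit(
    ds: Dataset,
    cfg: FitConfig = FitConfig(),
    active_mask: Sequence[bool] = FULL_MASK,
) -> ParameterEnsemble:
    """Run the full resampled fitting pipeline.

    Each iteration shuffles the records, holds out ``1 - train_fraction``
    of them (ceil rule, so 28 records at 0.9 give a 25/3 split), fits the
    masked model on the training subset and predicts the held-out
    records with the fitted parameters.  Convergence failures are
    dropped and counted; more than 50% failures aborts.
    """
    mask = tuple(bool(m) for m in np.asarray(active_mask, dtype=bool))
    b0, temperature, y = ds.b0, ds.temperature, ds.r1ox
    n = len(y)
    test_size = 1.0 - cfg.train_fraction
    indices = np.arange(n)

    samples: list[np.ndarray] = []
    held_mod: list[np.ndarray] = []
    held_mea: list[np.ndarray] = []
    failures = 0
    for k_iter in range(cfg.n_iterations):
        split_seed = (cfg.master_seed + k_iter) % 2**31
        if cfg.train_fraction < 1.0:
            train_idx, test_idx = train_test_split(
                indices, test_size=test_size, random_state=split_seed, shuffle=True
            )
        else:  # degenerate: train on everything, no held-out records
            train_idx, test_idx = indices, np.array([], dtype=int)
        arrays = (b0[train_idx], temperature[train_idx], y[train_idx])
        rng = np.random.default_rng(split_seed)
        try:
            params, _ = _fit_multistart(cfg, mask, arrays, rng)
        except FitFailure:
            failures += 1
            continue
        samples.append(params.active_values())
        if test_idx.size:
            held_mod.append(
                relaxivity(params, b0=b0[test_idx], temperature=temperature[test_idx])
            )
            held_mea.append(y[test_idx])
        if failures > cfg.n_iterations // 2:
            raise FitFailure(
                f"{failures} of {k_iter + 1} iterations failed to converge; aborting"
            )
    if not samples:
        raise FitFailure("no iteration converged")

    sample_matrix = np.asarray(samples)
    med = np.median(sample_matrix, axis=0)
    lo = np.percentile(sample_matrix, 2.5, axis=0)
    hi = np.percentile(sample_matrix, 97.5, axis=0)
    return ParameterEnsemble(
        samples=sample_matrix,
        active_mask=mask,
        medians=ModelParameters.from_active(med, mask),
        ci_lower=lo,
        ci_upper=hi,
        convergence_failures=failures,
        n_iterations=cfg.n_iterations,
        master_seed=cfg.master_seed,
        heldout_modelled=(
            np.concatenate(held_mod) if held_mod else np.array([], dtype=float)
        ),
        heldout_measured=(
            np.concatenate(held_mea) if held_mea else np.array([], dtype=float)
        ),
    )


def summarize_ensemble(ens: ParameterEnsemble) -> dict:
    """JSON-ready fit report: per-parameter medians/CIs plus run metadata."""
    if ens.samples.size == 0:
        raise ValueError("empty ensemble")
    return {
        "parameters": ens.parameter_table(),
        "active_mask": list(ens.active_mask),
        "n_iterations": ens.n_iterations,
        "convergence_failures": ens.convergence_failures,
        "master_seed": ens.master_seed,
        "scale": "1e-4 s^-1/mmHg",
    }


def pooled_test_predictions(ens: ParameterEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """All (modelled, measured) held-out pairs pooled across iterations."""
    return ens.heldout_modelled, ens.heldout_measured
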