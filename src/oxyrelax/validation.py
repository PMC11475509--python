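"""Agreement statistics for modelled versus measured relaxivity.

Conventions:

* ``r_squared`` is the squared Pearson correlation between modelled and
  measured values — the R^2 of the simple linear regression of one on
  the other, which is what agreement scatter plots annotate.  It is
  blind to sign and to affine miscalibration; ``r_squared_identity``
  (1 - RSS/TSS about the identity line) is available when calibration
  itself is in question.
* Bland-Altman differences are modelled - measured; limits of agreement
  are bias +/- 1.96 * SD of the differences, sample (n-1) SD by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .core import ModelParameters, relaxivity
from .dataset import Dataset

__all__ = [
    "ValidationReport",
    "r_squared",
    "r_squared_identity",
    "mse",
    "bland_altman",
    "validate_predictions",
    "subset_validation",
]


@dataclass(frozen=True)
class ValidationReport:
    """Agreement summary for one modelled/measured comparison.

    Relaxivity units are 1e-4 s^-1/mmHg (squared for ``mse``).
    ``r_squared`` is None when the subset was too small to support it.
    """

    n: int
    r_squared: float | None
    r_squared_identity: float | None
    mse: float
    mean_bias: float
    loa_lower: float
    loa_upper: float
    subset_label: str = "all"

    def to_dict(self) -> dict:
        return asdict(self)


def _paired(modelled, measured, min_n: int = 1):
    modelled = np.asarray(modelled, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if modelled.shape != measured.shape or modelled.ndim != 1:
        raise ValueError("modelled and measured must be equal-length 1-d sequences")
    if modelled.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {modelled.size}")
    return modelled, measured


def r_squared(modelled, measured) -> float:
    """Squared Pearson correlation between modelled and measured values."""
    modelled, measured = _paired(modelled, measured, min_n=3)
    if np.ptp(measured) == 0 or np.ptp(modelled) == 0:
        raise ValueError("R^2 undefined for constant input")
    return float(np.corrcoef(modelled, measured)[0, 1] ** 2)


def r_squared_identity(modelled, measured) -> float:
    """1 - RSS/TSS about the identity line (penalizes miscalibration)."""
    modelled, measured = _paired(modelled, measured, min_n=3)
    tss = float(np.sum((measured - measured.mean()) ** 2))
    if tss == 0:
        raise ValueError("R^2 undefined for constant measured values")
    rss = float(np.sum((modelled - measured) ** 2))
    return 1.0 - rss / tss


def mse(modelled, measured) -> float:
    """Mean squared difference, (1e-4 s^-1/mmHg)^2."""
    modelled, measured = _paired(modelled, measured, min_n=1)
    return float(np.mean((modelled - measured) ** 2))


def bland_altman(modelled, measured, ddof: int = 1) -> tuple[float, float, float]:
    """Mean bias and 95% limits of agreement of modelled - measured.

    Returns ``(bias, loa_lower, loa_upper)`` with
    ``loa = bias +/- 1.96 * SD(differences)``; ``ddof=1`` (sample SD) by
    default, ``ddof=0`` for the population convention.
    """
    modelled, measured = _paired(modelled, measured, min_n=2)
    diff = modelled - measured
    bias = float(diff.mean())
    half_width = 1.96 * float(diff.std(ddof=ddof))
    return bias, bias - half_width, bias + half_width


def validate_predictions(modelled, measured, subset_label: str = "all",
                         min_n_r2: int = 3) -> ValidationReport:
    """Full agreement report; R^2 is suppressed (None) below ``min_n_r2`` pairs."""
    modelled, measured = _paired(modelled, measured, min_n=1)
    if modelled.size >= min_n_r2 and np.ptp(measured) > 0 and np.ptp(modelled) > 0:
        r2 = r_squared(modelled, measured)
        r2_id = r_squared_identity(modelled, measured)
    else:
        warnings.warn(
            f"subset {subset_label!r} has too few or degenerate pairs for R^2; "
            "reporting MSE/bias only",
            stacklevel=2,
        )
        r2 = r2_id = None
    if modelled.size >= 2:
        bias, lo, hi = bland_altman(modelled, measured)
    else:
        bias = float(modelled[0] - measured[0])
        lo = hi = bias
    return ValidationReport(
        n=modelled.size,
        r_squared=r2,
        r_squared_identity=r2_id,
        mse=mse(modelled, measured),
        mean_bias=bias,
        loa_lower=lo,
        loa_upper=hi,
        subset_label=subset_label,
    )


def subset_validation(ds: Dataset, params: ModelParameters,
                      material: str | None = None) -> ValidationReport:
    """Evaluate the model against a dataset, optionally one material only."""
    subset = ds.filter({material}) if material is not None else ds
    if len(subset) == 0:
        raise ValueError(f"no records for material {material!r}")
    modelled = relaxivity(params, b0=subset.b0, temperature=subset.temperature)
    return validate_predictions(
        np.atleast_1d(modelled), subset.r1ox, subset_label=material or "all"
    )
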