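"""AIC comparison of the full dispersion model against nested reductions.

The four-parameter model nests eight variants: the Lorentzian amplitude
C1 is always retained, and each of {C2, C3, CTemp} may be switched off
(fixed at zero).  Dropping C2 collapses the Lorentzian to a constant,
so the "drop-C2-C3-CTemp" variant is a one-parameter flat model.

Each variant is fitted by the same resampling pipeline as the full
model; its AIC is computed from the full-data residual sum of squares at
the variant's ensemble-median parameters, using the Gaussian
least-squares form

    AIC = n * ln(RSS / n) + 2k

where lower is better.  A ``score`` column (-AIC, higher is better) is
reported alongside for readers used to that polarity, as is the
small-sample AICc; ranking is by AIC.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .core import ModelParameters, relaxivity
from .dataset import Dataset
from .fitting import FitConfig, FitFailure, resample_fit
from .validation import mse as _mse
from .validation import r_squared as _r_squared

__all__ = ["ModelVariant", "SelectionReport", "enumerate_variants", "aic", "aicc",
           "compare_models"]

_TOGGLEABLE = ("c2", "c3", "c_temp")
_LABELS = {"c2": "C2", "c3": "C3", "c_temp": "CTemp"}


@dataclass(frozen=True)
class ModelVariant:
    """One nested reduction of the dispersion model."""

    label: str
    mask: tuple[bool, bool, bool, bool]

    @property
    def k(self) -> int:
        return int(sum(self.mask))


@dataclass(frozen=True)
class SelectionReport:
    """Per-variant fit quality and the AIC ranking (best first)."""

    results: dict[str, dict]
    ranking: tuple[str, ...]

    def to_dict(self) -> dict:
        return {"results": self.results, "ranking": list(self.ranking)}


def enumerate_variants() -> list[ModelVariant]:
    """The full model plus every mask deactivating a subset of C2/C3/CTemp."""
    variants = []
    for drop in itertools.chain.from_iterable(
        itertools.combinations(_TOGGLEABLE, r) for r in range(4)
    ):
        mask = (True,) + tuple(name not in drop for name in _TOGGLEABLE)
        label = "full" if not drop else "drop-" + "-".join(_LABELS[d] for d in drop)
        variants.append(ModelVariant(label=label, mask=mask))
    return variants


def aic(rss: float, n: int, k: int) -> float:
    """Gaussian least-squares Akaike information criterion; lower is better.

    A zero RSS (perfect interpolation) returns -inf — the criterion is
    degenerate there and the caller should treat the variant specially.
    """
    if n <= k:
        raise ValueError("need n > k for the least-squares AIC")
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0:
        return -math.inf
    return n * math.log(rss / n) + 2 * k


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected AIC; requires n > k + 1."""
    base = aic(rss, n, k)
    if n <= k + 1:
        raise ValueError("need n > k + 1 for AICc")
    return base + 2 * k * (k + 1) / (n - k - 1)


def compare_models(
    ds: Dataset,
    cfg: FitConfig = FitConfig(),
    variants: list[ModelVariant] | None = None,
) -> SelectionReport:
    """Fit every variant by the resampling pipeline and rank by AIC.

    Variants whose fit fails are kept in the report with an ``error``
    entry and excluded from the ranking.
    """
    if variants is None:
        variants = enumerate_variants()
    n = len(ds)
    y = ds.r1ox
    results: dict[str, dict] = {}
    for variant in variants:
        try:
            ens = resample_fit(ds, cfg, active_mask=variant.mask)
        except (FitFailure, ValueError) as exc:
            results[variant.label] = {"k": variant.k, "error": str(exc)}
            continue
        params = ens.medians
        pred = relaxivity(params, b0=ds.b0, temperature=ds.temperature)
        rss = float(np.sum((pred - y) ** 2))
        score = aic(rss, n, variant.k)
        try:
            r2 = _r_squared(pred, y)
        except ValueError:  # constant predictions (e.g. flat variants)
            r2 = None
        results[variant.label] = {
            "k": variant.k,
            "mask": list(variant.mask),
            "aic": score,
            "score": -score,
            "aicc": aicc(rss, n, variant.k) if n > variant.k + 1 else None,
            "rss": rss,
            "mse": _mse(pred, y),
            "r_squared": r2,
            "parameters": ens.parameter_table(),
        }
    ranked = sorted(
        (label for label, res in results.items() if "aic" in res),
        key=lambda label: results[label]["aic"],
    )
    return SelectionReport(results=results, ranking=tuple(ranked))
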