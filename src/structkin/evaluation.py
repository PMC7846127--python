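"""Estimator evaluation: RMSE summaries, replicates and prediction intervals.

Accuracy of a relatedness-matrix estimate is summarized as a root mean
square error over the unique entries, expressed as a percentage of the mean
relatedness (so errors are interpretable across simulations with different
overall kinship levels).  Genome-wide scalar estimators are evaluated by
replicate experiments: the population structure is held fixed while allele
frequencies and genotypes are redrawn, and the spread of the replicate
estimates yields distribution-free order-statistic prediction intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike

from .model_core import RelatednessMatrix, convert_relatedness
from .simulate import AdmixtureModel, IndepModel, draw_dataset, SimBundle

__all__ = [
    "rmse_relative",
    "mean_relatedness_value",
    "PredictionInterval",
    "prediction_interval",
    "replicate_experiment",
]


def _comparison_entries(M: RelatednessMatrix, include_diagonal: bool) -> np.ndarray:
    """Unique off-diagonal entries (j < k) plus, optionally, the diagonal on
    the inbreeding scale (coancestry-form diagonal)."""
    C = convert_relatedness(M, "coancestry")
    n = C.n
    iu = np.triu_indices(n, k=1)
    parts = [C.values[iu]]
    if include_diagonal:
        parts.append(np.diag(C.values))
    return np.concatenate(parts)


def mean_relatedness_value(M: RelatednessMatrix, include_diagonal: bool = True) -> float:
    """Mean relatedness over the RMSE comparison entry set."""
    return float(_comparison_entries(M, include_diagonal).mean())


def rmse_relative(
    est: RelatednessMatrix | ArrayLike,
    ref: RelatednessMatrix | ArrayLike,
    phi_mean: float,
    *,
    include_diagonal: bool = True,
) -> float:
    """RMSE between two relatedness matrices as a percentage of mean kinship.

    Entries compared: all unique pairs j < k, plus (by default) the diagonal
    on the inbreeding scale -- both matrices are converted to coancestry
    form first, so kinship- and coancestry-form inputs mix freely.  The
    result is ``100 * sqrt(mean((est - ref)^2)) / phi_mean``, with
    ``phi_mean > 0`` the mean relatedness used as the scale.
    """
    if phi_mean <= 0:
        raise ValueError("phi_mean must be positive")
    if not isinstance(est, RelatednessMatrix):
        est = RelatednessMatrix(values=np.asarray(est, float), form="coancestry")
    if not isinstance(ref, RelatednessMatrix):
        ref = RelatednessMatrix(values=np.asarray(ref, float), form="coancestry")
    a = _comparison_entries(est, include_diagonal)
    b = _comparison_entries(ref, include_diagonal)
    if a.shape != b.shape:
        raise ValueError("matrices must have the same size")
    return 100.0 * float(np.sqrt(np.mean((a - b) ** 2))) / phi_mean


@dataclass(frozen=True)
class PredictionInterval:
    """Order-statistic prediction interval [lo, hi] with its confidence."""

    lo: float
    hi: float
    confidence: float

    def contains(self, x: float) -> bool:
        return self.lo <= x <= self.hi


def prediction_interval(values: ArrayLike, j: int = 1) -> PredictionInterval:
    """Distribution-free prediction interval from R independent estimates.

    With order statistics ``X_(1) < ... < X_(R)``, the interval
    ``[X_(j), X_(R+1-j)]`` is a prediction interval for a future draw with
    confidence ``(R + 1 - 2j)/(R + 1)``; R = 39 and j = 1 give 95%.
    """
    v = np.sort(np.asarray(values, dtype=float))
    R = len(v)
    if j < 1 or R < 2 * j:
        raise ValueError("need R >= 2j replicate values")
    return PredictionInterval(
        lo=float(v[j - 1]), hi=float(v[R - j]), confidence=(R + 1 - 2 * j) / (R + 1)
    )


def replicate_experiment(
    model: AdmixtureModel | IndepModel,
    m: int,
    methods: Mapping[str, Callable[[SimBundle], float]],
    R: int = 39,
    rng: np.random.Generator | None = None,
    *,
    keep_iaf: bool = True,
) -> pd.DataFrame:
    """Run R replicate simulations and apply each estimator to every draw.

    The structure (subpopulation differentiations, admixture proportions or
    group sizes) is fixed; ancestral/subpopulation frequencies, IAFs and
    genotypes are redrawn independently per replicate from sub-generators
    spawned off the master generator.  Returns a tidy frame with columns
    ``replicate``, ``method`` and ``estimate``.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for r, child in enumerate(rng.spawn(R)):
        bundle = draw_dataset(model, m, child, keep_iaf=keep_iaf)
        for name, fn in methods.items():
            rows.append({"replicate": r, "method": name, "estimate": float(fn(bundle))})
    return pd.DataFrame(rows)
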