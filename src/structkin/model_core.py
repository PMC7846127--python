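"""Parameter-level population-structure model.

This module works purely with identity-by-descent (IBD) parameters --
inbreeding coefficients, kinship/coancestry matrices and the weights that
define a generalized F_ST -- without ever touching genotype data.

Notation.  All IBD probabilities are defined relative to a reference
(ancestral) population ``T``.  For an individual ``j``:

* ``f_total``  -- total inbreeding, the probability that j's two alleles at a
  random locus are IBD relative to T;
* ``f_local``  -- local (family) inbreeding, relative to j's own local
  subpopulation;
* ``f_structural`` -- inbreeding of j's local subpopulation relative to T
  (the per-individual F_ST).

Wright's partition ties them together: (1 - f_total) =
(1 - f_local) * (1 - f_structural).  The generalized F_ST of a sample is a
weighted mean of the per-individual structural coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "InbreedingTriple",
    "RelatednessMatrix",
    "MeanRelatedness",
    "uniform_weights",
    "check_weights",
    "wright_partition",
    "generalized_fst",
    "convert_relatedness",
    "mean_relatedness",
    "bias_coefficient",
]

Form = Literal["kinship", "coancestry"]

#: relative tolerance used for pure-parameter algebraic invariant checks
PARAM_RTOL = 1e-10


@dataclass(frozen=True)
class InbreedingTriple:
    """Total, local and structural inbreeding of one individual.

    Invariant (Wright's partition):
    ``(1 - f_total) == (1 - f_local) * (1 - f_structural)``.
    """

    f_total: float
    f_local: float
    f_structural: float

    def __post_init__(self) -> None:
        for name in ("f_total", "f_local", "f_structural"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lhs = 1.0 - self.f_total
        rhs = (1.0 - self.f_local) * (1.0 - self.f_structural)
        if abs(lhs - rhs) > PARAM_RTOL * max(1.0, abs(lhs)):
            raise ValueError(
                "inconsistent triple: (1-f_total) != (1-f_local)(1-f_structural)"
            )

    @classmethod
    def from_total_and_local(cls, f_total: float, f_local: float) -> "InbreedingTriple":
        return cls(f_total, f_local, wright_partition(f_total, f_local))


def uniform_weights(n: int) -> NDArray[np.float64]:
    """Uniform weight vector ``w_j = 1/n``."""
    if n < 1:
        raise ValueError("n must be positive")
    return np.full(n, 1.0 / n)


def check_weights(
    w: ArrayLike, n: int | None = None, *, strict: bool = False
) -> NDArray[np.float64]:
    """Validate a weight vector: non-negative (positive if *strict*), sums to 1.

    Returns the validated vector as float64.  Weights off from sum 1 by more
    than 1e-6 raise; tiny drift is renormalized silently.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 1:
        raise ValueError("weights must be a 1-d vector")
    if n is not None and len(w) != n:
        raise ValueError(f"expected {n} weights, got {len(w)}")
    if strict:
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
    elif np.any(w < 0):
        raise ValueError("weights must be non-negative")
    s = w.sum()
    if abs(s - 1.0) > 1e-6:
        raise ValueError(f"weights must sum to 1 (got {s!r})")
    return w / s


def wright_partition(f_total: ArrayLike, f_local: ArrayLike) -> ArrayLike:
    """Structural inbreeding from total and local inbreeding.

    Solves Wright's partition for the structural coefficient:
    ``f_structural = (f_total - f_local) / (1 - f_local)``.

    The result may be negative when ``f_total < f_local``; it is passed
    through unclamped so callers can see inconsistent inputs.

    Parameters
    ----------
    f_total : total inbreeding coefficient(s), in [0, 1].
    f_local : local (pedigree/family) inbreeding coefficient(s), in [0, 1).

    Examples
    --------
    An individual with total inbreeding 0.15 whose parents are first cousins
    (local inbreeding 1/16) has structural inbreeding ~0.093; with
    second-cousin parents (1/64) it rises to ~0.137.
    """
    ft = np.asarray(f_total, dtype=float)
    fl = np.asarray(f_local, dtype=float)
    if np.any(fl >= 1.0):
        raise ValueError("f_local must be < 1")
    if np.any(fl < 0.0) or np.any(ft < 0.0) or np.any(ft > 1.0):
        raise ValueError("inbreeding coefficients must be in [0, 1]")
    out = (ft - fl) / (1.0 - fl)
    return float(out) if out.ndim == 0 else out


def generalized_fst(f_structural: ArrayLike, weights: ArrayLike) -> float:
    """Generalized F_ST: weighted mean of per-individual structural inbreeding.

    ``F_ST = sum_j w_j * f_structural[j]`` with non-negative weights summing
    to one.  With per-subpopulation weights ``1/(K r_u)`` this reduces to the
    unweighted mean of the K subpopulation-specific F_ST values.
    """
    f = np.asarray(f_structural, dtype=float)
    w = check_weights(weights, len(f))
    return float(w @ f)


@dataclass
class RelatednessMatrix:
    """Symmetric n x n relatedness matrix in kinship or coancestry form.

    The two forms share off-diagonal entries (kinship == coancestry between
    distinct individuals); they differ on the diagonal:

    * ``coancestry``: diagonal holds the inbreeding coefficient f_j in [0, 1];
    * ``kinship``:    diagonal holds the self-kinship (1 + f_j)/2 in [1/2, 1].

    ``validate(true_params=True)`` additionally enforces the [0, 1] bounds
    that hold for true IBD probabilities; estimated matrices may legitimately
    contain negative or >1 entries and are only checked for symmetry.
    """

    values: NDArray[np.float64]
    form: Form = "coancestry"
    ids: list[str] | None = None
    reference_label: str = "T"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("relatedness matrix must be square")
        if self.form not in ("kinship", "coancestry"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.ids is not None and len(self.ids) != self.n:
            raise ValueError("ids length does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def validate(self, *, true_params: bool = False, atol: float = 1e-8) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("matrix is not symmetric")
        if true_params:
            d = np.diag(v)
            off = v[~np.eye(self.n, dtype=bool)]
            if off.size and (off.min() < -atol or off.max() > 1 + atol):
                raise ValueError("off-diagonal entries outside [0, 1]")
            lo, hi = (0.5, 1.0) if self.form == "kinship" else (0.0, 1.0)
            if d.size and (d.min() < lo - atol or d.max() > hi + atol):
                raise ValueError(f"diagonal outside [{lo}, {hi}] for {self.form} form")

    def to_form(self, target: Form) -> "RelatednessMatrix":
        return convert_relatedness(self, target)

    def inbreeding(self) -> NDArray[np.float64]:
        """Per-individual inbreeding coefficients from the diagonal."""
        d = np.diag(self.values)
        return 2.0 * d - 1.0 if self.form == "kinship" else d.copy()


def convert_relatedness(M: RelatednessMatrix, target_form: Form) -> RelatednessMatrix:
    """Convert between kinship and coancestry forms.

    Off-diagonal entries are unchanged; the diagonal is mapped through
    f <-> (1 + f)/2.  Converting twice is the identity.
    """
    if target_form not in ("kinship", "coancestry"):
        raise ValueError(f"unknown form {target_form!r}")
    if M.form == target_form:
        return replace(M, values=M.values.copy())
    v = M.values.copy()
    d = np.diag(v).copy()
    if target_form == "kinship":  # f -> (1+f)/2
        np.fill_diagonal(v, (1.0 + d) / 2.0)
    else:  # (1+f)/2 -> f
        np.fill_diagonal(v, 2.0 * d - 1.0)
    return replace(M, values=v, form=target_form)


@dataclass(frozen=True)
class MeanRelatedness:
    """Weighted summaries of a coancestry matrix.

    theta_bar   -- overall weighted mean coancestry sum_jk w_j w_k theta_jk
    theta_bar_j -- per-individual weighted means sum_k w_k theta_jk
    theta_tilde -- mean coancestry *between* individuals (off-diagonal only)
    fst         -- generalized F_ST, the weighted mean of the diagonal
    """

    theta_bar: float
    theta_bar_j: NDArray[np.float64] = field(repr=False)
    theta_tilde: float
    fst: float


def mean_relatedness(M: RelatednessMatrix, weights: ArrayLike) -> MeanRelatedness:
    """Weighted mean coancestry, per-individual means, F_ST and theta-tilde.

    Requires coancestry form (so the diagonal is inbreeding and the weighted
    diagonal mean is the generalized F_ST).  Under uniform weights
    ``theta_tilde = (n * theta_bar - fst) / (n - 1)``, the plain mean of the
    off-diagonal entries; for general weights the weighted off-diagonal
    analogue ``(theta_bar - sum_j w_j^2 theta_jj) / (1 - sum_j w_j^2)`` is
    used, which reduces exactly to the former when weights are uniform.
    """
    if M.form != "coancestry":
        raise ValueError("mean_relatedness requires coancestry form")
    w = check_weights(weights, M.n)
    theta = M.values
    theta_bar_j = theta @ w
    theta_bar = float(w @ theta_bar_j)
    fst = float(w @ np.diag(theta))
    w2 = float(w @ w)
    theta_tilde = (theta_bar - float(w**2 @ np.diag(theta))) / (1.0 - w2)
    return MeanRelatedness(theta_bar, theta_bar_j, theta_tilde, fst)


def bias_coefficient(M: RelatednessMatrix, weights: ArrayLike) -> float:
    """Bias coefficient s = theta_bar / F_ST of a coancestry matrix.

    Quantifies departure from the independent-subpopulations model: s = 1/K
    for K independent equally-weighted subpopulations, up to s = 1 when all
    individuals are equally related (maximal bias of the standard
    estimators).  Requires F_ST > 0.
    """
    mr = mean_relatedness(M, weights)
    if mr.fst <= 0:
        raise ValueError("bias coefficient undefined: F_ST (weighted diagonal mean) is not positive")
    return mr.theta_bar / mr.fst
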