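"""Kinship, inbreeding and coancestry estimators from genotypes or IAFs.

Two estimator families are implemented:

* the *standard* family, which centers genotypes by an estimated ancestral
  allele frequency per locus (the usual GRM-style estimator, plus the stdII /
  stdIII inbreeding variants).  These are consistent only for unstructured
  samples; under structure their limits are complex, pair-specific linear
  distortions of the true kinship (see :mod:`structkin.limits`);

* the *A-statistic* family.  ``A_jk = mean_i (x_ij - 1)(x_ik - 1) - 1`` has
  expectation ``(phi_jk - 1) * v`` with a single shared nuisance scale
  ``v = 4 mean_i p_i (1 - p_i)``, so once the limit of the minimum A is
  estimated (``A_min``, from the least-related pair of subpopulations, whose
  kinship is assumed zero) the rescaling ``phi_hat = 1 - A / A_min`` is a
  consistent kinship estimator for arbitrary structure.  Replacing the
  minimum with the overall average A gives the Weir-Goudet individual
  estimator, which instead targets linearly-transformed kinship.

All genome-wide estimators here are ratio-of-means estimators (numerators
and denominators summed across loci before a single division) except where a
mean-of-ratios form is explicitly requested for comparison.  Dense matrix
products are accumulated in blocks of loci so that n=1000, m=300,000 runs in
a few GB of memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .model_core import RelatednessMatrix, check_weights

__all__ = [
    "AStatMatrix",
    "EstimatedFreqs",
    "estimate_freqs",
    "kinship_std",
    "inbreeding_std",
    "a_statistic",
    "a_min_subpops",
    "kinship_new",
    "inbreeding_new",
    "kinship_wg",
    "coancestry_std_iaf",
]

#: loci per block in the blocked genotype-matrix accumulations
BLOCK_LOCI = 8192


def _as_dosage(X: ArrayLike) -> np.ndarray:
    """Validate a complete dosage matrix (entries in {0, 1, 2})."""
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("genotype matrix must be 2-d (individuals x loci)")
    if np.issubdtype(X.dtype, np.floating):
        if np.any(~np.isin(X, (0.0, 1.0, 2.0))):
            raise ValueError("genotype dosages must be in {0, 1, 2}; missing data "
                             "must be dropped or imputed upstream")
    else:
        if X.min(initial=0) < 0 or X.max(initial=0) > 2:
            raise ValueError("genotype dosages must be in {0, 1, 2}; missing data "
                             "must be dropped or imputed upstream")
    return X


def _locus_blocks(m: int, block: int = BLOCK_LOCI) -> Iterator[slice]:
    for start in range(0, m, block):
        yield slice(start, min(start + block, m))


@dataclass(frozen=True)
class EstimatedFreqs:
    """Weighted ancestral allele-frequency estimates, one per locus."""

    p_hat: NDArray[np.float64]
    weights: NDArray[np.float64]


@dataclass(frozen=True)
class AStatMatrix:
    """Matrix of pairwise A statistics plus the number of loci used.

    Dosage bounds force every entry into [-2, 0]; expectations are
    ``(phi_jk - 1) * v`` for the shared positive scale v, so more-related
    pairs have A closer to 0.
    """

    values: NDArray[np.float64]
    m_loci: int

    @property
    def n(self) -> int:
        return self.values.shape[0]


def estimate_freqs(
    X: ArrayLike,
    weights: ArrayLike,
    *,
    data: Literal["genotypes", "iaf"] = "genotypes",
) -> EstimatedFreqs:
    """Weighted per-locus ancestral allele frequency estimates.

    For genotypes ``p_hat_i = (1/2) sum_j w_j x_ij``; for individual-specific
    allele frequencies (IAFs) the 1/2 is dropped.  Weights must be strictly
    positive and sum to one so that 0 <= p_hat <= 1 and the estimate is
    unbiased for the ancestral frequency.
    """
    X = np.asarray(X)
    w = check_weights(weights, X.shape[0], strict=True)
    if data == "genotypes":
        _as_dosage(X)
        p_hat = 0.5 * (w @ np.asarray(X, dtype=float))
    elif data == "iaf":
        p_hat = w @ np.asarray(X, dtype=float)
    else:
        raise ValueError(f"unknown data kind {data!r}")
    return EstimatedFreqs(p_hat=p_hat, weights=w)


def kinship_std(
    X: ArrayLike,
    weights: ArrayLike | None = None,
    form: Literal["ratio_of_means", "mean_of_ratios"] = "ratio_of_means",
) -> RelatednessMatrix:
    """Standard (GRM-style) kinship estimator, both genome-wide ratio forms.

    ratio_of_means (recommended):
        ``phi_hat_jk = sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) /
        [4 sum_i p_i (1 - p_i)]`` with ``p_i`` the weighted frequency
        estimate.  Converges a.s. (m -> infinity) to a double-centered
        transform of the true kinship, not to the kinship itself, whenever
        the sample is structured.

    mean_of_ratios (for comparison; the GRM convention prevalent in the
        literature): off-diagonal per-locus ratios
        ``(x_ij - 2 p_i)(x_ik - 2 p_i) / [4 p_i (1 - p_i)]`` averaged over
        loci; the diagonal follows the same convention's self-relatedness
        form, ``(1 + f_i)/2`` per locus with
        ``f_i = [x^2 - (1 + 2 p_i) x + 2 p_i^2] / [2 p_i (1 - p_i)]``,
        which avoids the squared-deviation diagonal's heavy tail at rare
        variants.  Loci fixed under ``p_hat`` (p_hat in {0, 1}) are skipped.

    The diagonal estimates self-kinship (1 + f_j)/2; defaults to uniform
    weights.  Raises if every locus is monomorphic under the estimated
    frequencies (zero denominator).
    """
    X = _as_dosage(X)
    n, m = X.shape
    if n < 2 or m < 1:
        raise ValueError("need at least 2 individuals and 1 locus")
    if weights is None:
        weights = np.full(n, 1.0 / n)
    ef = estimate_freqs(X, weights)
    p = ef.p_hat

    S = np.zeros((n, n))
    if form == "ratio_of_means":
        denom = 4.0 * float(np.sum(p * (1.0 - p)))
        if denom <= 0.0:
            raise ZeroDivisionError("all loci monomorphic under estimated frequencies")
        for sl in _locus_blocks(m):
            Xc = np.asarray(X[:, sl], dtype=float) - 2.0 * p[sl]
            S += Xc @ Xc.T
        values = S / denom
    elif form == "mean_of_ratios":
        keep_total = 0
        diag_sum = np.zeros(n)
        for sl in _locus_blocks(m):
            pb = p[sl]
            keep = (pb > 0.0) & (pb < 1.0)
            if not keep.any():
                continue
            keep_total += int(keep.sum())
            pk = pb[keep]
            qk = 1.0 - pk
            Xb = np.asarray(X[:, sl], dtype=float)[:, keep]
            Y = (Xb - 2.0 * pk) / np.sqrt(4.0 * pk * qk)
            S += Y @ Y.T
            f_i = (Xb**2 - (1.0 + 2.0 * pk) * Xb + 2.0 * pk**2) / (2.0 * pk * qk)
            diag_sum += f_i.sum(axis=1)
        if keep_total == 0:
            raise ZeroDivisionError("all loci monomorphic under estimated frequencies")
        values = S / keep_total
        np.fill_diagonal(values, (1.0 + diag_sum / keep_total) / 2.0)
    else:
        raise ValueError(f"unknown form {form!r}")
    return RelatednessMatrix(values=values, form="kinship")


def inbreeding_std(
    X: ArrayLike,
    weights: ArrayLike | None = None,
    variant: Literal["std", "stdII", "stdIII"] = "std",
) -> NDArray[np.float64]:
    """Ratio-of-means inbreeding estimators of the standard family.

    std:    ``2 * diag(kinship_std) - 1``.
    stdII:  ``1 - sum_i x_ij (2 - x_ij) / [2 sum_i p_i (1 - p_i)]``
            (heterozygosity-deficit form; equals 1 for a fully homozygous
            individual regardless of structure).
    stdIII: ``sum_i [x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2] /
            [2 sum_i p_i (1 - p_i)]``.

    All three share the weighted frequency estimates and, although their
    per-individual limits differ, they produce exactly the same plug-in
    F_ST when averaged with matching weights (see
    :func:`structkin.fst.fst_std`).
    """
    X = _as_dosage(X)
    n, m = X.shape
    if weights is None:
        weights = np.full(n, 1.0 / n)
    if variant == "std":
        K = kinship_std(X, weights, form="ratio_of_means")
        return 2.0 * np.diag(K.values) - 1.0
    ef = estimate_freqs(X, weights)
    p = ef.p_hat
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ZeroDivisionError("all loci monomorphic under estimated frequencies")
    Xf = np.asarray(X, dtype=float)
    if variant == "stdII":
        het = (Xf * (2.0 - Xf)).sum(axis=1)
        return 1.0 - het / denom
    if variant == "stdIII":
        num = (Xf**2).sum(axis=1) - Xf @ (1.0 + 2.0 * p) + 2.0 * float(np.sum(p**2))
        return num / denom
    raise ValueError(f"unknown variant {variant!r}")


def a_statistic(X: ArrayLike) -> AStatMatrix:
    """Pairwise A statistics: ``A_jk = mean_i (x_ij - 1)(x_ik - 1) - 1``.

    Includes the diagonal (j == k), needed for inbreeding estimation.
    ``E[A_jk] = (phi_jk - 1) * v`` where ``v = (4/m) sum_i p_i (1 - p_i)``
    is a shared nuisance scale, so A estimates kinship up to one unknown
    positive factor and a shift.
    """
    X = _as_dosage(X)
    n, m = X.shape
    if m == 0:
        raise ValueError("need at least one locus")
    S = np.zeros((n, n))
    for sl in _locus_blocks(m):
        Z = np.asarray(X[:, sl], dtype=float) - 1.0
        S += Z @ Z.T
    return AStatMatrix(values=S / m - 1.0, m_loci=m)


def a_min_subpops(A: AStatMatrix, labels: ArrayLike) -> float:
    """Estimate the limiting minimum A from subpopulation labels.

    Returns the minimum, over all unordered pairs of distinct subpopulations
    (u, v), of the unweighted mean of ``A_jk`` for j in S_u, k in S_v.  This
    consistently estimates ``-v`` (minus the nuisance scale) provided the
    least-related pair of subpopulations has zero kinship across it, which
    pins the reference population T to the MRCA of the sample.

    Requires at least two non-empty subpopulations; with only one group the
    unrelated-pair identification that anchors the estimator is impossible.
    """
    labels = np.asarray(labels)
    if labels.shape != (A.n,):
        raise ValueError("labels must have one entry per individual")
    groups = [np.flatnonzero(labels == g) for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError(
            "a_min_subpops needs >= 2 subpopulations: identifying an unrelated "
            "pair of groups is required to set the kinship scale"
        )
    best = np.inf
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            block = A.values[np.ix_(groups[a], groups[b])]
            best = min(best, float(block.mean()))
    return best


def kinship_new(A: AStatMatrix, a_min: float) -> RelatednessMatrix:
    """Consistent kinship estimator ``phi_hat_jk = 1 - A_jk / a_min``.

    ``a_min`` must be negative (it estimates minus the positive nuisance
    scale); a non-negative value signals that no unrelated pair was found
    and the rescaling is undefined.
    """
    if not a_min < 0:
        raise ValueError(
            "a_min must be negative; a non-negative estimate means no unrelated "
            "pair of subpopulations was identified"
        )
    return RelatednessMatrix(values=1.0 - A.values / a_min, form="kinship")


def inbreeding_new(K_new: RelatednessMatrix) -> NDArray[np.float64]:
    """Inbreeding from the new kinship estimator: ``2 * diag - 1``."""
    if K_new.form != "kinship":
        raise ValueError("expected kinship form")
    return 2.0 * np.diag(K_new.values) - 1.0


def kinship_wg(A: AStatMatrix) -> RelatednessMatrix:
    """Weir-Goudet individual kinship estimator: rescale A by its average.

    ``phi_hat_jk = 1 - A_jk / A_avg`` with ``A_avg`` the unweighted mean of
    the off-diagonal A over unordered pairs.  Targets the linearly
    transformed quantity ``(phi_jk - phi_tilde) / (1 - phi_tilde)`` (with
    phi_tilde the mean pairwise kinship); it recovers IBD probabilities only
    when phi_tilde = 0.
    """
    n = A.n
    if n < 2:
        raise ValueError("need at least 2 individuals")
    off = ~np.eye(n, dtype=bool)
    a_avg = float(A.values[off].mean())
    if a_avg == 0.0:
        raise ZeroDivisionError("average A is zero; rescaling undefined")
    return RelatednessMatrix(values=1.0 - A.values / a_avg, form="kinship")


def coancestry_std_iaf(
    P: ArrayLike, weights: ArrayLike | None = None
) -> RelatednessMatrix:
    """Standard ratio-of-means coancestry estimator from IAFs.

    ``theta_hat_jk = sum_i (pi_ij - p_i)(pi_ik - p_i) / sum_i p_i (1 - p_i)``
    with ``p_i = sum_j w_j pi_ij``.  Even with true individual-specific
    allele frequencies this estimator inherits the same double-centering
    distortion as the genotype-based standard kinship estimator.
    """
    P = np.asarray(P)
    if P.ndim != 2:
        raise ValueError("IAF matrix must be 2-d (individuals x loci)")
    n, m = P.shape
    if weights is None:
        weights = np.full(n, 1.0 / n)
    ef = estimate_freqs(P, weights, data="iaf")
    p = ef.p_hat
    denom = float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ZeroDivisionError("all loci monomorphic under estimated frequencies")
    S = np.zeros((n, n))
    for sl in _locus_blocks(m):
        Pc = np.asarray(P[:, sl], dtype=float) - p[sl]
        S += Pc @ Pc.T
    return RelatednessMatrix(values=S / denom, form="coancestry")
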