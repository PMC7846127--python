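"""Genome-wide F_ST estimators.

Implements the classical method-of-moments estimators derived under the
independent-subpopulations model (Weir-Cockerham, Weir-Hill, Hudson pairwise
and its K-subpopulation generalization "HudsonK"), the idealized
infinite-sample-size estimator they all collapse to, the plug-in estimator
built from the standard kinship estimator, two oracle bias adjustments, and
the consistent estimator built from the new A-statistic kinship estimates.

All classical estimators are ratio-of-means estimators: numerator and
denominator are each summed over loci before the single division, which
guarantees almost-sure convergence to the ratio of expectations as the
number of independent loci grows.  Each result records its numerator and
denominator sums for diagnostics.

Under arbitrary structure the classical estimators converge not to F_ST but
to ``(F_ST - theta_tilde) / (1 - theta_tilde)`` where theta_tilde is the
mean coancestry between the groups being compared -- a downward bias that
vanishes only for truly independent subpopulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .model_core import RelatednessMatrix, check_weights
from .kinship import _as_dosage, _locus_blocks, estimate_freqs

__all__ = [
    "FstEstimate",
    "SubpopPartition",
    "group_sample_stats",
    "fst_indep",
    "fst_wc",
    "fst_wc_from_freqs",
    "fst_weir_hill",
    "fst_weir_hill_from_freqs",
    "fst_hudson_pair",
    "fst_hudson_pair_from_freqs",
    "fst_hudson_k",
    "fst_hudson_k_from_freqs",
    "fst_std",
    "fst_adjust_theta",
    "fst_adjust_s",
    "fst_new",
    "fst_wg_individuals",
]


@dataclass(frozen=True)
class FstEstimate:
    """An F_ST estimate with ratio diagnostics.

    For ratio-of-means methods ``value == numerator_sum / denominator_sum``;
    methods that are not ratios (e.g. the new estimator, a weighted mean of
    inbreeding coefficients) leave the sums as ``nan``.
    """

    value: float
    method: str
    numerator_sum: float = float("nan")
    denominator_sum: float = float("nan")

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class SubpopPartition:
    """Assignment of n individuals to K labeled, non-empty groups."""

    labels: NDArray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def group_names(self) -> NDArray:
        return np.unique(self.labels)

    @property
    def k(self) -> int:
        return len(self.group_names)

    def indices(self) -> list[NDArray[np.intp]]:
        return [np.flatnonzero(self.labels == g) for g in self.group_names]

    @property
    def sizes(self) -> NDArray[np.int64]:
        return np.array([len(ix) for ix in self.indices()], dtype=np.int64)


def _ratio(num: float, den: float, method: str) -> FstEstimate:
    return FstEstimate(value=num / den, method=method,
                       numerator_sum=num, denominator_sum=den)


def group_sample_stats(
    X: ArrayLike, partition: SubpopPartition | ArrayLike
) -> tuple[NDArray, NDArray, NDArray]:
    """Per-group sample allele frequencies and heterozygote fractions.

    Returns ``(freqs, hets, sizes)`` where ``freqs[u, i]`` is the sample
    reference-allele frequency of group u at locus i, ``hets[u, i]`` the
    observed fraction of heterozygotes, and ``sizes`` the group counts.
    """
    X = _as_dosage(X)
    if not isinstance(partition, SubpopPartition):
        partition = SubpopPartition(np.asarray(partition))
    if partition.n != X.shape[0]:
        raise ValueError("partition labels must have one entry per individual")
    idx = partition.indices()
    if any(len(ix) == 0 for ix in idx):
        raise ValueError("every subpopulation must be non-empty")
    freqs = np.empty((len(idx), X.shape[1]))
    hets = np.empty_like(freqs)
    for u, ix in enumerate(idx):
        sub = np.asarray(X[ix, :], dtype=float)
        freqs[u] = sub.mean(axis=0) / 2.0
        hets[u] = (sub == 1.0).mean(axis=0)
    return freqs, hets, partition.sizes.astype(float)


def fst_indep(P: ArrayLike) -> FstEstimate:
    """Idealized F_ST estimator for independent subpopulations.

    Rows of ``P`` are true subpopulation allele frequencies (or IAFs) --
    the infinite-sample-size abstraction in which WC, Weir-Hill and HudsonK
    all coincide:

    ``F_hat = sum_i sigma2_i / sum_i [p_i (1 - p_i) + sigma2_i / n]``

    with ``p_i`` the row-mean frequency and ``sigma2_i`` the unbiased
    (n - 1 denominator) variance across rows.  Consistent for F_ST under
    independent subpopulations; converges to
    ``(F_ST - theta_tilde)/(1 - theta_tilde)`` in general.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("need a 2-d frequency matrix with n >= 2 rows")
    n = P.shape[0]
    p = P.mean(axis=0)
    sig2 = P.var(axis=0, ddof=1)
    num = float(sig2.sum())
    den = float((p * (1.0 - p) + sig2 / n).sum())
    return _ratio(num, den, "indep")


# ---------------------------------------------------------------------------
# Weir-Cockerham


def fst_wc_from_freqs(
    freqs: ArrayLike, sizes: ArrayLike, hets: ArrayLike | None = None
) -> FstEstimate:
    """Weir-Cockerham estimator from per-group sample frequencies.

    ``freqs`` is K x m, ``sizes`` the group sample sizes (floats allowed so
    the infinite-sample behavior can be probed directly), ``hets`` the
    per-group heterozygote fractions (defaults to the Hardy-Weinberg value
    ``2 p (1 - p)``, which only matters through the small-sample terms).
    """
    freqs = np.asarray(freqs, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    K = freqs.shape[0]
    if K < 2 or len(sizes) != K:
        raise ValueError("need K >= 2 groups with matching sizes")
    if np.any(sizes <= 0):
        raise ValueError("every group must be non-empty")
    if np.all(np.isinf(sizes)):
        # infinite sample sizes: sample frequencies are the true group
        # frequencies and every small-sample correction vanishes
        est = fst_indep(freqs)
        return FstEstimate(value=est.value, method="wc",
                           numerator_sum=est.numerator_sum,
                           denominator_sum=est.denominator_sum)
    if hets is None:
        hets = 2.0 * freqs * (1.0 - freqs)
    hets = np.asarray(hets, dtype=float)

    nbar = sizes.mean()
    c2 = float(((sizes - nbar) ** 2).sum() / (nbar**2 * (K - 1)))
    rel = (sizes / nbar)[:, None]
    p_t = (rel * freqs).sum(axis=0) / K
    hbar = (rel * hets).sum(axis=0) / K
    sig2 = (rel * (freqs - p_t) ** 2).sum(axis=0) / (K - 1)

    ptq = p_t * (1.0 - p_t)
    num_i = sig2 - (ptq - (K - 1) / K * sig2 - hbar / 4.0) / (nbar - 1.0)
    den_i = (
        ptq * (1.0 - nbar * c2 / (K * (nbar - 1.0)))
        + sig2 / K * (1.0 + (K - 1.0) * nbar * c2 / (K * (nbar - 1.0)))
        + hbar * c2 / (4.0 * K * (nbar - 1.0))
    )
    return _ratio(float(num_i.sum()), float(den_i.sum()), "wc")


def fst_wc(X: ArrayLike, partition: SubpopPartition | ArrayLike) -> FstEstimate:
    """Weir-Cockerham F_ST from genotypes and a K-group partition."""
    freqs, hets, sizes = group_sample_stats(X, partition)
    return fst_wc_from_freqs(freqs, sizes, hets)


# ---------------------------------------------------------------------------
# Weir-Hill


def fst_weir_hill_from_freqs(freqs: ArrayLike, sizes: ArrayLike) -> FstEstimate:
    """Weir-Hill estimator (biallelic, averaged over loci) from frequencies.

    Weights individuals (hence groups proportionally to their sample sizes):
    ``w_u = n_u / sum n_u`` and ``p_t = sum_u w_u p_u``.  The estimator is

    ``1 - [sum_u n_u (1 - w_u)] * sum_i sum_u w_u 2n_u/(2n_u - 1) p (1-p) /
    sum_i sum_u [n_u (p_u - p_t)^2 + n_u (1 - w_u) p (1-p)]``,

    written below as a single ratio so numerator and denominator sums are
    reported.  For equal sizes going to infinity it reduces exactly to
    :func:`fst_indep`.
    """
    freqs = np.asarray(freqs, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    K = freqs.shape[0]
    if K < 2 or len(sizes) != K:
        raise ValueError("need K >= 2 groups with matching sizes")
    if np.any(sizes <= 0):
        raise ValueError("every group must be non-empty")
    if np.all(np.isinf(sizes)):
        # equal infinite sizes: the estimator collapses to the idealized one
        est = fst_indep(freqs)
        return FstEstimate(value=est.value, method="weir_hill",
                           numerator_sum=est.numerator_sum,
                           denominator_sum=est.denominator_sum)
    w = sizes / sizes.sum()
    p_t = w @ freqs
    pq = freqs * (1.0 - freqs)
    a = float((sizes * (1.0 - w)).sum())
    corr = (w * 2.0 * sizes / (2.0 * sizes - 1.0))[:, None]
    b = float((corr * pq).sum())
    den = float(
        ((sizes[:, None] * (freqs - p_t) ** 2) + (sizes * (1.0 - w))[:, None] * pq).sum()
    )
    return FstEstimate(
        value=1.0 - a * b / den,
        method="weir_hill",
        numerator_sum=den - a * b,
        denominator_sum=den,
    )


def fst_weir_hill(X: ArrayLike, partition: SubpopPartition | ArrayLike) -> FstEstimate:
    """Weir-Hill F_ST from genotypes and a K-group partition."""
    freqs, _, sizes = group_sample_stats(X, partition)
    return fst_weir_hill_from_freqs(freqs, sizes)


# ---------------------------------------------------------------------------
# Hudson pairwise and HudsonK


def fst_hudson_pair_from_freqs(freqs: ArrayLike, sizes: ArrayLike) -> FstEstimate:
    """Hudson pairwise F_ST for exactly two groups, from sample frequencies.

    ``num_i = (p1 - p2)^2 - p1(1-p1)/(2n1 - 1) - p2(1-p2)/(2n2 - 1)``,
    ``den_i = p1(1-p2) + p2(1-p1)``, summed over loci before dividing.
    """
    freqs = np.asarray(freqs, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if freqs.shape[0] != 2 or len(sizes) != 2:
        raise ValueError("Hudson pairwise estimator requires exactly 2 groups")
    if np.any(2.0 * sizes - 1.0 <= 0):
        raise ValueError("group sizes must satisfy 2 n - 1 > 0")
    p1, p2 = freqs
    n1, n2 = sizes
    num_i = (p1 - p2) ** 2 - p1 * (1 - p1) / (2 * n1 - 1) - p2 * (1 - p2) / (2 * n2 - 1)
    den_i = p1 * (1 - p2) + p2 * (1 - p1)
    return _ratio(float(num_i.sum()), float(den_i.sum()), "hudson")


def fst_hudson_pair(X: ArrayLike, partition: SubpopPartition | ArrayLike) -> FstEstimate:
    """Hudson pairwise F_ST from genotypes and a 2-group partition."""
    freqs, _, sizes = group_sample_stats(X, partition)
    return fst_hudson_pair_from_freqs(freqs, sizes)


def fst_hudson_k_from_freqs(freqs: ArrayLike, sizes: ArrayLike) -> FstEstimate:
    """HudsonK: the Hudson estimator generalized to K groups.

    Obtained by averaging pairwise numerators and denominators before the
    division; equals the Weir-Goudet subpopulation F_ST for biallelic loci.
    Groups are weighted equally regardless of sample size:

    ``num_i = sigma2_i - (1/K) sum_u p_u (1 - p_u)/(2 n_u - 1)``,
    ``den_i = p_t (1 - p_t) + sigma2_i / K``

    with ``p_t`` the unweighted group-mean frequency and ``sigma2_i`` the
    (K - 1)-denominator variance of group frequencies.
    """
    freqs = np.asarray(freqs, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    K = freqs.shape[0]
    if K < 2 or len(sizes) != K:
        raise ValueError("need K >= 2 groups with matching sizes")
    if np.any(2.0 * sizes - 1.0 <= 0):
        raise ValueError("group sizes must satisfy 2 n - 1 > 0")
    p_t = freqs.mean(axis=0)
    sig2 = freqs.var(axis=0, ddof=1)
    with np.errstate(divide="ignore"):
        per_group = (freqs * (1.0 - freqs)) / (2.0 * sizes - 1.0)[:, None]
    corr = np.where(np.isinf(sizes)[:, None], 0.0, per_group).mean(axis=0)
    num = float((sig2 - corr).sum())
    den = float((p_t * (1.0 - p_t) + sig2 / K).sum())
    return _ratio(num, den, "hudson_k")


def fst_hudson_k(X: ArrayLike, partition: SubpopPartition | ArrayLike) -> FstEstimate:
    """HudsonK F_ST from genotypes and a K-group partition."""
    freqs, _, sizes = group_sample_stats(X, partition)
    return fst_hudson_k_from_freqs(freqs, sizes)


# ---------------------------------------------------------------------------
# Standard-kinship plug-in and adjustments


def fst_std(
    X: ArrayLike,
    weights: ArrayLike | None = None,
    *,
    data: str = "genotypes",
) -> FstEstimate:
    """Plug-in F_ST from the standard kinship/coancestry estimator.

    Genotypes: ``sum_i sum_j w_j (x_ij - 2 p_i)^2 / [2 sum_i p_i(1-p_i)] - 1``;
    IAFs:      ``sum_i sum_j w_j (pi_ij - p_i)^2 / sum_i p_i(1-p_i)``.

    All three standard inbreeding variants (std, stdII, stdIII) averaged
    with weights matching the frequency estimate give exactly this value.
    Converges to ``(F_ST - mean_kinship)/(1 - mean_kinship)``: downwardly
    biased for any structured sample.
    """
    X = np.asarray(X)
    n = X.shape[0]
    if weights is None:
        weights = np.full(n, 1.0 / n)
    w = check_weights(weights, n, strict=True)
    if data == "genotypes":
        _as_dosage(X)
        p = estimate_freqs(X, w).p_hat
        den = 2.0 * float(np.sum(p * (1.0 - p)))
        if den <= 0.0:
            raise ZeroDivisionError("all loci monomorphic under estimated frequencies")
        num = 0.0
        for sl in _locus_blocks(X.shape[1]):
            dev = (np.asarray(X[:, sl], dtype=float) - 2.0 * p[sl]) ** 2
            num += float(w @ dev.sum(axis=1))
        return FstEstimate(value=num / den - 1.0, method="std",
                           numerator_sum=num - den, denominator_sum=den)
    if data == "iaf":
        p = estimate_freqs(X, w, data="iaf").p_hat
        den = float(np.sum(p * (1.0 - p)))
        if den <= 0.0:
            raise ZeroDivisionError("all loci monomorphic under estimated frequencies")
        num = 0.0
        for sl in _locus_blocks(X.shape[1]):
            dev = (np.asarray(X[:, sl], dtype=float) - p[sl]) ** 2
            num += float(w @ dev.sum(axis=1))
        return _ratio(num, den, "std_iaf")
    raise ValueError(f"unknown data kind {data!r}")


def fst_adjust_theta(fst_std_value: float, theta_bar: float) -> float:
    """Oracle adjustment of the standard plug-in F_ST given mean coancestry.

    ``F' = F_std (1 - theta_bar) + theta_bar`` reverses the limiting bias
    exactly when theta_bar is the true weighted mean coancestry.
    """
    if not 0.0 <= theta_bar < 1.0:
        raise ValueError("theta_bar must be in [0, 1)")
    return fst_std_value * (1.0 - theta_bar) + theta_bar


def fst_adjust_s(fst_std_value: float, s: float) -> float:
    """Oracle adjustment given the bias coefficient s = theta_bar / F_ST.

    ``F'' = F_std / [1 - s (1 - F_std)]``; with uniform weights and
    ``s = 1/n`` this reproduces :func:`fst_indep` exactly, of which it is
    the generalization.
    """
    if not 0.0 < s <= 1.0:
        raise ValueError("s must be in (0, 1]")
    den = 1.0 - s * (1.0 - fst_std_value)
    if abs(den) < 1e-300:
        raise ZeroDivisionError("adjustment denominator is zero")
    return fst_std_value / den


# ---------------------------------------------------------------------------
# New estimator and Weir-Goudet individual-level estimator


def fst_new(K_new: RelatednessMatrix, weights: ArrayLike | None = None) -> FstEstimate:
    """F_ST from the new kinship estimates: weighted mean of ``2 phi_jj - 1``.

    Consistent for the generalized F_ST of locally-outbred individuals when
    the kinship matrix comes from :func:`structkin.kinship.kinship_new`.
    """
    if K_new.form != "kinship":
        raise ValueError("expected kinship form")
    n = K_new.n
    if weights is None:
        weights = np.full(n, 1.0 / n)
    w = check_weights(weights, n)
    value = float(w @ (2.0 * np.diag(K_new.values) - 1.0))
    return FstEstimate(value=value, method="new")


def fst_wg_individuals(K_wg: RelatednessMatrix) -> FstEstimate:
    """Weir-Goudet individual-level F_ST: unweighted mean of ``2 phi_jj - 1``.

    Targets the linearly-transformed value
    ``(F_ST - phi_tilde)/(1 - phi_tilde)``; recovers F_ST only when the mean
    pairwise kinship phi_tilde is zero.
    """
    if K_wg.form != "kinship":
        raise ValueError("expected kinship form")
    value = float(np.mean(2.0 * np.diag(K_wg.values) - 1.0))
    return FstEstimate(value=value, method="wg_individuals")
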