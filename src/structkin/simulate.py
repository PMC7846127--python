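"""Genotype simulators with known IBD structure.

Two generative models are provided, both with exactly known coancestry
matrices so estimator error can be measured against truth:

* **independent subpopulations** -- K non-overlapping groups that evolved
  independently from the ancestral population T, each with its own
  differentiation ``f_u = (u/K) * tau``.  The true coancestry matrix is
  block-diagonal.  The scale ``tau = 2 K F_ST / (K + 1)`` hits a target
  F_ST exactly under per-subpopulation weights ``w_j = 1/(K r_u)``.

* **1D-geography admixture (BN-PSD)** -- K intermediate subpopulations on a
  line with differentiation increasing with position (a serial founder
  effect), whose individuals then spread by random walk.  Each modern
  individual draws ancestry from every intermediate subpopulation with
  Normal-density weights, giving admixture proportions Q and a smooth
  coancestry matrix ``Theta = Q diag(f) Q^T`` with no independent blocks.
  The Normal spread ``sigma`` is tuned by root-finding so the bias
  coefficient ``s = mean coancestry / F_ST`` hits a target (s = 1/2 by
  default, which halves the classical estimators' limits), and ``tau``
  rescales the f's to hit the target F_ST.

Allele frequencies: the ancestral ``p_i ~ Uniform(0.01, 0.5)``; each
intermediate subpopulation draws ``p_iu`` from the Balding-Nichols
distribution ``Beta(p (1/f - 1), (1-p)(1/f - 1))`` (mean p, variance
f p (1-p)); individual-specific frequencies are ``pi_ij = sum_u p_iu q_ju``;
genotypes are ``x_ij ~ Binomial(2, pi_ij)``, independent across loci (no
linkage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import brentq
from scipy.stats import norm

from .model_core import RelatednessMatrix
from .fst import SubpopPartition

__all__ = [
    "SimConfig",
    "AdmixtureModel",
    "IndepModel",
    "SimBundle",
    "draw_ancestral_freqs",
    "draw_bn_freqs",
    "random_subpop_sizes",
    "tau_indep",
    "admix_props_1d",
    "bias_coefficient_sigma",
    "solve_sigma",
    "tau_admix",
    "true_coancestry_admix",
    "draw_iafs",
    "draw_genotypes",
    "assign_subpops_1d",
    "build_admixture_model",
    "build_indep_model",
    "draw_dataset",
    "simulate_indep",
    "simulate_admix",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulation run.

    Defaults are the evaluation conditions used throughout: n = 1000
    individuals, m = 300,000 independent loci, K = 10 subpopulations,
    F_ST = 0.1, bias coefficient target 0.5 (admixture model only), and
    ancestral frequencies uniform on (0.01, 0.5).
    """

    n: int = 1000
    m: int = 300_000
    k: int = 10
    fst: float = 0.1
    s_target: float = 0.5
    p_range: tuple[float, float] = (0.01, 0.5)

    def __post_init__(self) -> None:
        if not (self.n >= self.k >= 2):
            raise ValueError("need n >= K >= 2")
        if self.m < 1:
            raise ValueError("need m >= 1")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")


@dataclass(frozen=True)
class AdmixtureModel:
    """1D-geography admixture structure (fixed across replicate draws)."""

    Q: NDArray[np.float64]  # n x K admixture proportions, rows sum to 1
    f_inter: NDArray[np.float64]  # K intermediate differentiations f_Su
    coords_subpops: NDArray[np.float64]  # x_u
    coords_individuals: NDArray[np.float64]  # y_j
    sigma: float
    tau: float

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    @property
    def k(self) -> int:
        return self.Q.shape[1]


@dataclass(frozen=True)
class IndepModel:
    """Independent-subpopulations structure (fixed across replicate draws)."""

    sizes: NDArray[np.int64]  # r_u, sums to n
    f_inter: NDArray[np.float64]  # f_Su = (u/K) tau
    tau: float

    @property
    def n(self) -> int:
        return int(self.sizes.sum())

    @property
    def k(self) -> int:
        return len(self.sizes)

    @property
    def labels(self) -> NDArray[np.int64]:
        return np.repeat(np.arange(self.k), self.sizes)


@dataclass
class SimBundle:
    """One simulated dataset plus its true parameters."""

    X: NDArray[np.int8]  # n x m dosages
    iaf: NDArray | None  # n x m individual-specific allele frequencies
    p_anc: NDArray[np.float64]  # m ancestral frequencies
    p_subpops: NDArray[np.float64]  # m x K intermediate subpop frequencies
    partition: SubpopPartition
    weights: NDArray[np.float64]
    theta_true: RelatednessMatrix  # coancestry form
    fst: float
    model: AdmixtureModel | IndepModel = field(repr=False)


# ---------------------------------------------------------------------------
# Frequency draws


def draw_ancestral_freqs(
    m: int, p_range: tuple[float, float] = (0.01, 0.5), rng: np.random.Generator | None = None
) -> NDArray[np.float64]:
    """i.i.d. ancestral allele frequencies, uniform on ``p_range``."""
    lo, hi = p_range
    if not 0.0 < lo < hi < 1.0:
        raise ValueError("need 0 < lo < hi < 1")
    rng = np.random.default_rng(rng)
    return rng.uniform(lo, hi, size=m)


def draw_bn_freqs(
    p_anc: NDArray, f: float, rng: np.random.Generator | None = None
) -> NDArray[np.float64]:
    """Balding-Nichols subpopulation frequencies given ancestral frequencies.

    ``Beta(p (1/f - 1), (1-p)(1/f - 1))`` per locus: mean p and variance
    ``f p (1 - p)``.  The degenerate limit f -> 0 returns p exactly.
    """
    p = np.asarray(p_anc, dtype=float)
    if f == 0.0:
        return p.copy()
    if not 0.0 < f < 1.0:
        raise ValueError("f must be in (0, 1) (or exactly 0 for no drift)")
    rng = np.random.default_rng(rng)
    nu = 1.0 / f - 1.0
    return rng.beta(p * nu, (1.0 - p) * nu)


def random_subpop_sizes(
    n: int, k: int, rng: np.random.Generator | None = None
) -> NDArray[np.int64]:
    """Random subpopulation sample sizes summing to n, none below n/(3K).

    Sizes are rounded from a flat Dirichlet draw; draws with any group below
    the floor are rejected, and rounding drift is repaired one individual at
    a time at a random group.
    """
    if k == 1:
        return np.array([n], dtype=np.int64)
    if n < 3 * k:
        raise ValueError("need n >= 3K so the minimum group size is feasible")
    rng = np.random.default_rng(rng)
    floor = n / (3.0 * k)
    while True:
        sizes = np.round(n * rng.dirichlet(np.ones(k))).astype(np.int64)
        if sizes.min() < floor:
            continue
        while (delta := n - int(sizes.sum())) != 0:
            u = rng.integers(k)
            sizes[u] += int(np.sign(delta))
        if sizes.min() >= floor:
            return sizes


# ---------------------------------------------------------------------------
# Calibration of tau and sigma


def tau_indep(fst_target: float, k: int) -> float:
    """Differentiation scale for the independent model: ``2 K F_ST/(K+1)``.

    With ``f_u = (u/K) tau`` the equal-weight subpopulation mean is
    ``tau (K+1)/(2K)``, so this tau hits the target F_ST exactly.
    """
    tau = 2.0 * k * fst_target / (k + 1.0)
    if tau > 1.0:
        raise ValueError(f"target F_ST={fst_target} infeasible for K={k} (tau > 1)")
    return tau


def _coords_1d(n: int, k: int) -> tuple[NDArray, NDArray]:
    x = np.arange(1, k + 1, dtype=float)
    if n == 1:
        y = np.array([(k + 1.0) / 2.0])  # single individual at the midpoint
    else:
        y = 0.5 + (np.arange(n) / (n - 1.0)) * k
    return x, y


def admix_props_1d(n: int, k: int, sigma: float) -> NDArray[np.float64]:
    """Admixture proportions from Normal-density weights on a line.

    Subpopulations sit at ``x_u = u`` (u = 1..K); individuals at
    ``y_j = 1/2 + (j-1) K/(n-1)`` spanning [1/2, K + 1/2].  Row u-weights
    are proportional to the Normal(0, sigma) density of ``|x_u - y_j|`` and
    normalized to sum to one; sigma -> 0 recovers one-hot rows at the
    nearest subpopulation.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x, y = _coords_1d(n, k)
    # log-density with a per-row shift: immune to underflow at small sigma
    logdens = norm.logpdf(np.abs(x[None, :] - y[:, None]), scale=sigma)
    dens = np.exp(logdens - logdens.max(axis=1, keepdims=True))
    return dens / dens.sum(axis=1, keepdims=True)


def bias_coefficient_sigma(sigma: float, n: int, k: int) -> float:
    """Bias coefficient s of the 1D admixture model as a function of sigma.

    With uniform individual weights and ``f_u`` proportional to u, tau
    cancels and ``s = [ (1/n) sum_u u (sum_j q_ju)^2 ] /
    [ sum_u u sum_j q_ju^2 ]`` depends on sigma alone.
    """
    Q = admix_props_1d(n, k, sigma)
    u = np.arange(1, k + 1, dtype=float)
    num = float((u * Q.sum(axis=0) ** 2).sum()) / n
    den = float((u * (Q**2).sum(axis=0)).sum())
    return num / den


def solve_sigma(
    s_target: float, n: int, k: int, bracket: tuple[float, float] = (0.01, 100.0), tol: float = 1e-6
) -> float:
    """Spread sigma achieving a target bias coefficient, by bracketed root find.

    s(sigma) increases smoothly from 1/K (sigma -> 0, independent-like)
    toward 1, so a target in (1/K, 1) has a unique root; s = 1/2 for
    n = 1000, K = 10 is reached near sigma = 1.78.
    """
    lo, hi = bracket
    f = lambda s: bias_coefficient_sigma(s, n, k) - s_target
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"no sign change on bracket {bracket}: s({lo})={flo + s_target:.4f}, "
            f"s({hi})={fhi + s_target:.4f}; target {s_target} unattainable"
        )
    return float(brentq(f, lo, hi, xtol=tol))


def tau_admix(fst_target: float, Q: NDArray, k: int) -> float:
    """Differentiation scale tau achieving a target F_ST for fixed Q.

    ``tau = F_ST / [ (1/K) sum_u u (1/n sum_j q_ju^2) ]``; about 0.901 for
    the sigma that gives s = 1/2 with n = 1000, K = 10.
    """
    Q = np.asarray(Q, dtype=float)
    n = Q.shape[0]
    u = np.arange(1, k + 1, dtype=float)
    den = float((u * (Q**2).sum(axis=0) / n).sum()) / k
    if den <= 0:
        raise ValueError("degenerate admixture proportions")
    tau = fst_target / den
    if tau > 1.0:
        raise ValueError(f"target F_ST={fst_target} infeasible (tau={tau:.3f} > 1)")
    return tau


def true_coancestry_admix(model: AdmixtureModel) -> RelatednessMatrix:
    """True coancestry of the admixture model: ``Theta = Q diag(f) Q^T``."""
    theta = (model.Q * model.f_inter) @ model.Q.T
    return RelatednessMatrix(values=theta, form="coancestry")


def assign_subpops_1d(model: AdmixtureModel) -> SubpopPartition:
    """Geographic clustering: each individual to its nearest subpopulation.

    Ties (an individual exactly between two subpopulations) go to the lower
    index.
    """
    d = np.abs(model.coords_subpops[None, :] - model.coords_individuals[:, None])
    return SubpopPartition(labels=np.argmin(d, axis=1))


# ---------------------------------------------------------------------------
# Model construction and data draws


def build_admixture_model(
    n: int = 1000, k: int = 10, fst: float = 0.1, s_target: float = 0.5
) -> AdmixtureModel:
    """Calibrated 1D admixture structure hitting (F_ST, s) targets."""
    sigma = solve_sigma(s_target, n, k)
    Q = admix_props_1d(n, k, sigma)
    tau = tau_admix(fst, Q, k)
    f_inter = np.arange(1, k + 1, dtype=float) / k * tau
    x, y = _coords_1d(n, k)
    return AdmixtureModel(Q=Q, f_inter=f_inter, coords_subpops=x,
                          coords_individuals=y, sigma=sigma, tau=tau)


def build_indep_model(
    n: int = 1000, k: int = 10, fst: float = 0.1, rng: np.random.Generator | None = None
) -> IndepModel:
    """Independent-subpopulations structure with random group sizes."""
    rng = np.random.default_rng(rng)
    tau = tau_indep(fst, k)
    f_inter = np.arange(1, k + 1, dtype=float) / k * tau
    sizes = random_subpop_sizes(n, k, rng)
    return IndepModel(sizes=sizes, f_inter=f_inter, tau=tau)


def draw_iafs(
    model: AdmixtureModel, p_subpops: NDArray, *, dtype=np.float32
) -> NDArray:
    """Individual-specific allele frequencies ``pi = P_subpops Q^T``.

    ``p_subpops`` is m x K; the result is n x m (float32 by default to keep
    the full evaluation scale within memory).
    """
    return np.asarray(model.Q @ p_subpops.T, dtype=dtype)


def draw_genotypes(P, rng: np.random.Generator | None = None) -> NDArray[np.int8]:
    """Binomial(2, pi) genotype draws from an IAF matrix, blocked over loci."""
    rng = np.random.default_rng(rng)
    P = np.asarray(P)
    n, m = P.shape
    X = np.empty((n, m), dtype=np.int8)
    step = 4096
    for start in range(0, m, step):
        sl = slice(start, min(start + step, m))
        block = np.asarray(P[:, sl], dtype=float)
        u = rng.random((2, n, sl.stop - sl.start))
        X[:, sl] = (u[0] < block).astype(np.int8) + (u[1] < block).astype(np.int8)
    return X


def draw_dataset(
    model: AdmixtureModel | IndepModel,
    m: int,
    rng: np.random.Generator | None = None,
    p_range: tuple[float, float] = (0.01, 0.5),
    *,
    keep_iaf: bool = True,
) -> SimBundle:
    """Draw one dataset (frequencies + genotypes) from a fixed structure.

    Ancestral and subpopulation frequencies are redrawn on every call, so
    repeated calls with the same structure produce independent replicates
    of the same study conditions.
    """
    rng = np.random.default_rng(rng)
    p_anc = draw_ancestral_freqs(m, p_range, rng)
    k = model.k
    p_subpops = np.empty((m, k))
    for u in range(k):
        p_subpops[:, u] = draw_bn_freqs(p_anc, float(model.f_inter[u]), rng)

    if isinstance(model, AdmixtureModel):
        iaf = draw_iafs(model, p_subpops)
        X = draw_genotypes(iaf, rng)
        partition = assign_subpops_1d(model)
        n = model.n
        weights = np.full(n, 1.0 / n)
        theta = true_coancestry_admix(model)
    else:
        labels = model.labels
        iaf = np.asarray(p_subpops.T[labels, :], dtype=np.float32)
        X = draw_genotypes(iaf, rng)
        partition = SubpopPartition(labels=labels)
        # equal subpopulation weight, split evenly within each group
        weights = (1.0 / (model.k * model.sizes.astype(float)))[labels]
        theta = RelatednessMatrix(
            values=_indep_theta(model), form="coancestry"
        )
    mr_fst = float(weights @ np.diag(theta.values))
    return SimBundle(
        X=X,
        iaf=iaf if keep_iaf else None,
        p_anc=p_anc,
        p_subpops=p_subpops,
        partition=partition,
        weights=weights,
        theta_true=theta,
        fst=mr_fst,
        model=model,
    )


def _indep_theta(model: IndepModel) -> NDArray[np.float64]:
    """Block-diagonal coancestry: f_u within each subpopulation, 0 between."""
    labels = model.labels
    same = labels[:, None] == labels[None, :]
    return np.where(same, model.f_inter[labels][None, :], 0.0)


def simulate_indep(
    config: SimConfig, rng: np.random.Generator | None = None, *, keep_iaf: bool = True
) -> SimBundle:
    """Draw genotypes from the independent-subpopulations model."""
    rng = np.random.default_rng(rng)
    model = build_indep_model(config.n, config.k, config.fst, rng)
    return draw_dataset(model, config.m, rng, config.p_range, keep_iaf=keep_iaf)


def simulate_admix(
    config: SimConfig, rng: np.random.Generator | None = None, *, keep_iaf: bool = True
) -> SimBundle:
    """Draw genotypes from the 1D-geography BN-PSD admixture model."""
    rng = np.random.default_rng(rng)
    model = build_admixture_model(config.n, config.k, config.fst, config.s_target)
    return draw_dataset(model, config.m, rng, config.p_range, keep_iaf=keep_iaf)
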