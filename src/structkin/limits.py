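"""Closed-form infinite-loci limits of the analyzed estimators.

Every genome-wide ratio-of-means estimator studied in this package
converges almost surely, as the number of independent loci grows, to a
deterministic function of the true relatedness parameters.  This module
evaluates those limits directly from true kinship/coancestry matrices --
they never see genotypes -- and serves as the oracle against which the
empirical estimators are tested.

All limits are invariant to the choice of reference population T: replacing
``theta' = (theta - r)/(1 - r)`` for any feasible r leaves them unchanged.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .model_core import RelatednessMatrix, check_weights

__all__ = [
    "limit_fst_indep",
    "limit_kinship_std",
    "limit_inbreeding_std",
    "limit_coancestry_std",
    "limit_fst_std",
    "limit_fst_std_from_s",
    "limit_kinship_wg",
    "relative_error_fst_std",
    "shift_reference",
]


def _double_center_limit(values: NDArray, w: NDArray) -> NDArray:
    """(v_jk - vbar_j - vbar_k + vbar) / (1 - vbar) with weighted means."""
    vbar_j = values @ w
    vbar = float(w @ vbar_j)
    if vbar >= 1.0:
        raise ValueError("mean relatedness of 1: limit undefined")
    return (values - vbar_j[:, None] - vbar_j[None, :] + vbar) / (1.0 - vbar)


def limit_fst_indep(Theta: RelatednessMatrix) -> float:
    """Limit of the independent-subpopulations F_ST estimator.

    ``(F_ST - theta_tilde)/(1 - theta_tilde)`` with uniform weights, where
    theta_tilde is the plain mean of the off-diagonal (between-individual)
    coancestry.  Equals F_ST exactly for block-independent structures
    (theta_tilde = 0) and collapses to 0 when all pairs are equally related.
    """
    if Theta.form != "coancestry":
        raise ValueError("expected coancestry form")
    v = Theta.values
    n = Theta.n
    fst = float(np.diag(v).mean())
    off = ~np.eye(n, dtype=bool)
    theta_tilde = float(v[off].mean())
    if theta_tilde >= 1.0:
        raise ValueError("theta_tilde = 1: limit undefined")
    return (fst - theta_tilde) / (1.0 - theta_tilde)


def limit_kinship_std(Phi: RelatednessMatrix, weights: ArrayLike | None = None) -> RelatednessMatrix:
    """Limit matrix of the standard (ratio-of-means) kinship estimator.

    Entrywise ``(phi_jk - phibar_j - phibar_k + phibar)/(1 - phibar)`` with
    weighted row means phibar_j and overall mean phibar, applied to the
    kinship-form matrix (self-kinship on the diagonal).  The limit is a
    pair-specific distortion: zero weighted row/column means by
    construction, hence the characteristic over/under-shoot pattern.
    """
    if Phi.form != "kinship":
        raise ValueError("expected kinship form")
    n = Phi.n
    w = check_weights(weights if weights is not None else np.full(n, 1.0 / n), n)
    return RelatednessMatrix(values=_double_center_limit(Phi.values, w), form="kinship")


def limit_inbreeding_std(
    Phi: RelatednessMatrix, weights: ArrayLike | None = None, variant: str = "std"
) -> NDArray[np.float64]:
    """Limits of the standard inbreeding estimators.

    std:    ``(f_j - 4 phibar_j + 3 phibar)/(1 - phibar)``
    stdII:  ``(f_j - phibar)/(1 - phibar)``
    stdIII: ``(f_j + phibar - 2 phibar_j)/(1 - phibar)``
    """
    if Phi.form != "kinship":
        raise ValueError("expected kinship form")
    n = Phi.n
    w = check_weights(weights if weights is not None else np.full(n, 1.0 / n), n)
    phibar_j = Phi.values @ w
    phibar = float(w @ phibar_j)
    f = 2.0 * np.diag(Phi.values) - 1.0
    if variant == "std":
        num = f - 4.0 * phibar_j + 3.0 * phibar
    elif variant == "stdII":
        num = f - phibar
    elif variant == "stdIII":
        num = f + phibar - 2.0 * phibar_j
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return num / (1.0 - phibar)


def limit_coancestry_std(
    Theta: RelatednessMatrix, weights: ArrayLike | None = None
) -> RelatednessMatrix:
    """Limit of the IAF-based standard coancestry estimator.

    Same double-centering distortion as the genotype version, applied to
    the coancestry-form matrix.
    """
    if Theta.form != "coancestry":
        raise ValueError("expected coancestry form")
    n = Theta.n
    w = check_weights(weights if weights is not None else np.full(n, 1.0 / n), n)
    return RelatednessMatrix(
        values=_double_center_limit(Theta.values, w), form="coancestry"
    )


def limit_fst_std(fst: float, mean_rel: float) -> float:
    """Limit of the plug-in F_ST: ``(F_ST - mean)/(1 - mean)``.

    ``mean_rel`` is the weighted mean kinship (genotype version) or mean
    coancestry (IAF version).
    """
    if mean_rel >= 1.0:
        raise ValueError("mean relatedness of 1: limit undefined")
    return (fst - mean_rel) / (1.0 - mean_rel)


def limit_fst_std_from_s(fst: float, s: float) -> float:
    """Equivalent parameterization by the bias coefficient:
    ``F_ST (1 - s)/(1 - s F_ST)``."""
    return fst * (1.0 - s) / (1.0 - s * fst)


def limit_kinship_wg(Phi: RelatednessMatrix) -> RelatednessMatrix:
    """Limit of the Weir-Goudet individual kinship estimator.

    ``(phi_jk - phi_tilde)/(1 - phi_tilde)`` entrywise, with phi_tilde the
    unweighted mean kinship over unordered distinct pairs.  Equals the true
    kinship iff phi_tilde = 0.
    """
    if Phi.form != "kinship":
        raise ValueError("expected kinship form")
    n = Phi.n
    off = ~np.eye(n, dtype=bool)
    phi_tilde = float(Phi.values[off].mean())
    if phi_tilde >= 1.0:
        raise ValueError("phi_tilde = 1: limit undefined")
    return RelatednessMatrix(
        values=(Phi.values - phi_tilde) / (1.0 - phi_tilde), form="kinship"
    )


def relative_error_fst_std(fst: float, s: float) -> float:
    """Limiting relative error of the plug-in F_ST: ``s (1 - F_ST)/(1 - s F_ST)``.

    Approximately s itself when F_ST << 1 -- the reason s is called the
    bias coefficient.
    """
    return s * (1.0 - fst) / (1.0 - s * fst)


def shift_reference(Theta: RelatednessMatrix, r: float) -> RelatednessMatrix:
    """Re-express relatedness relative to a more recent reference population.

    ``theta' = (theta - r)/(1 - r)`` entrywise (coancestry form), valid for
    0 <= r <= min theta.  Estimator limits are invariant under this shift.
    """
    if Theta.form != "coancestry":
        raise ValueError("expected coancestry form")
    if not 0.0 <= r < 1.0:
        raise ValueError("r must be in [0, 1)")
    return RelatednessMatrix(values=(Theta.values - r) / (1.0 - r), form="coancestry")
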