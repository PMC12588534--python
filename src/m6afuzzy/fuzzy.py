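"""TSK fuzzy antecedents and the lifted fuzzy design matrix.

A first-order Takagi-Sugeno-Kang system with K rules maps an input x ∈ R^d to

    y(x) = Σ_k μ̃_k(x) · (p₀ᵏ + Σ_j p_jᵏ x_j),

where μ̃_k is the normalized firing strength of rule k.  Each rule's IF-part
is a product of per-feature Gaussian memberships

    μ_{A_jᵏ}(x_j) = exp(−(x_j − c_jᵏ)² / δ_jᵏ)

(with the width δ, not δ², in the denominator and no factor ½).  Rule centres
and widths are estimated from a fuzzy c-means (FCM) partition of the training
features:

    c_jᵏ = Σ_i μ_ik x_ij / Σ_i μ_ik,
    δ_jᵏ = h · Σ_i μ_ik (x_ij − c_jᵏ)² / Σ_i μ_ik,

with unexponentiated memberships μ_ik and a manually adjustable width scale h.
FCM iterations themselves use the standard fuzzified μ_ikᵐ weights.

Since y(x) is linear in the consequent parameters once the antecedents are
fixed, each sample lifts to the row x_g = (μ̃₁(x)·(1,x), …, μ̃_K(x)·(1,x)) of
the N × ((1+d)K) fuzzy design matrix; one (1+d)-sized block per rule.  This
block structure is exactly what the block-sparse Bayesian learner exploits.

Firing strengths are accumulated in the log domain with a per-row max
subtraction, so the Eq.-style products of up to d = 37 Gaussians cannot
underflow to an all-zero row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

# Relative width floor: keeps the Gaussian membership defined when a cluster
# collapses onto a constant feature.
WIDTH_FLOOR_REL = 1e-8
WIDTH_FLOOR_ABS = 1e-12


@dataclass
class FcmResult:
    """Fuzzy c-means partition: memberships (N×K, rows sum to 1) and centers (K×d)."""

    memberships: np.ndarray
    centers: np.ndarray
    iterations: int
    converged: bool


@dataclass
class FuzzyAntecedent:
    """Per-rule Gaussian membership parameters: centers and strictly positive widths."""

    centers: np.ndarray  # K × d
    widths: np.ndarray  # K × d, > 0
    h: float

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.widths = np.atleast_2d(np.asarray(self.widths, dtype=float))
        if self.centers.shape != self.widths.shape:
            raise ValueError("centers and widths must have identical shape")
        if np.any(self.widths <= 0):
            raise ValueError("all membership widths must be strictly positive")

    @property
    def n_rules(self) -> int:
        return self.centers.shape[0]

    @property
    def n_features(self) -> int:
        return self.centers.shape[1]


@dataclass
class FuzzyDesign:
    """Lifted design matrix N × ((1+d)·K) with one column block per rule."""

    values: np.ndarray
    block_map: list[slice]
    d: int
    K: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != (1 + self.d) * self.K:
            raise ValueError(
                f"design shape {self.values.shape} inconsistent with "
                f"d={self.d}, K={self.K}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def _as_matrix(X) -> np.ndarray:
    values = getattr(X, "values", X)
    return np.atleast_2d(np.asarray(values, dtype=float))


def fcm(
    X,
    K: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> FcmResult:
    """Fuzzy c-means clustering (standard alternating fixed point).

    Centers are initialized as K distinct rows of X chosen by seeded sampling;
    iteration stops when the maximum center shift drops below ``tol``.  Points
    coinciding exactly with one or more centers get their membership split
    uniformly over those centers.
    """
    Xv = _as_matrix(X)
    N, d = Xv.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > N:
        raise ValueError(f"K={K} rules but only N={N} samples")
    if m <= 1:
        raise ValueError("fuzziness exponent m must exceed 1")
    rng = np.random.default_rng(seed)
    centers = Xv[rng.choice(N, size=K, replace=False)].copy()
    exponent = 1.0 / (m - 1.0)
    u = np.full((N, K), 1.0 / K)
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        dist2 = cdist(Xv, centers, metric="sqeuclidean")
        with np.errstate(divide="ignore"):
            w = dist2 ** (-exponent)
        zero_rows = ~np.all(np.isfinite(w), axis=1)
        u = np.empty_like(w)
        u[~zero_rows] = w[~zero_rows] / w[~zero_rows].sum(axis=1, keepdims=True)
        if np.any(zero_rows):
            hits = dist2[zero_rows] == 0.0
            u[zero_rows] = hits / hits.sum(axis=1, keepdims=True)
        um = u**m
        denom = um.sum(axis=0)
        new_centers = (um.T @ Xv) / denom[:, None]
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        if shift < tol:
            converged = True
            break
    if K > 1:
        center_dists = cdist(centers, centers)
        np.fill_diagonal(center_dists, np.inf)
        if np.min(center_dists) < 1e-12:
            logger.warning("FCM produced tied centers (degenerate input?)")
    return FcmResult(
        memberships=u, centers=centers, iterations=iterations, converged=converged
    )


def estimate_antecedents(X, fcm_result: FcmResult, h: float = 1.0) -> FuzzyAntecedent:
    """Rule centers and widths from an FCM partition (unexponentiated memberships).

    Widths scale linearly with ``h`` and are floored at
    ``1e−8·var_j + 1e−12`` per feature so collapsed clusters stay usable.
    """
    if h <= 0:
        raise ValueError("width coefficient h must be positive")
    Xv = _as_matrix(X)
    u = np.asarray(fcm_result.memberships, dtype=float)
    if u.shape[0] != Xv.shape[0]:
        raise ValueError("membership rows do not match sample count")
    mass = u.sum(axis=0)  # Σ_i μ_ik, per rule
    centers = (u.T @ Xv) / mass[:, None]
    K = u.shape[1]
    widths = np.empty_like(centers)
    for k in range(K):
        sq = (Xv - centers[k]) ** 2
        widths[k] = h * (u[:, k] @ sq) / mass[k]
    col_var = Xv.var(axis=0)
    floor = WIDTH_FLOOR_REL * col_var + WIDTH_FLOOR_ABS
    widths = np.maximum(widths, floor)
    return FuzzyAntecedent(centers=centers, widths=widths, h=h)


def firing_strengths(X, antecedent: FuzzyAntecedent) -> np.ndarray:
    """Normalized rule firing strengths μ̃_k(x_i): an N × K row-stochastic matrix.

    Accumulated in the log domain (sum of per-feature log memberships, per-row
    max subtracted before exponentiation), so 0/0 underflow cannot occur even
    at large d.
    """
    Xv = _as_matrix(X)
    if Xv.shape[1] != antecedent.n_features:
        raise ValueError(
            f"input has {Xv.shape[1]} features, antecedent expects "
            f"{antecedent.n_features}"
        )
    if not np.all(np.isfinite(Xv)):
        raise ValueError("input features contain NaN/inf")
    diff = Xv[:, None, :] - antecedent.centers[None, :, :]
    log_mu = -np.sum(diff**2 / antecedent.widths[None, :, :], axis=2)  # N × K
    log_mu -= log_mu.max(axis=1, keepdims=True)
    w = np.exp(log_mu)
    return w / w.sum(axis=1, keepdims=True)


def build_fuzzy_design(X, antecedent: FuzzyAntecedent) -> FuzzyDesign:
    """Lift features into the fuzzy design matrix: row i = ⊕_k μ̃_k(x_i)·(1, x_i)."""
    Xv = _as_matrix(X)
    strengths = firing_strengths(Xv, antecedent)
    N, d = Xv.shape
    K = antecedent.n_rules
    x_ext = np.hstack([np.ones((N, 1)), Xv])  # (1, x_i)
    values = (strengths[:, :, None] * x_ext[:, None, :]).reshape(N, K * (1 + d))
    block_map = [slice(k * (1 + d), (k + 1) * (1 + d)) for k in range(K)]
    return FuzzyDesign(values=values, block_map=block_map, d=d, K=K)
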