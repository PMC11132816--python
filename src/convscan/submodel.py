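"""Reversible 20-state amino-acid substitution models.

A model is an exchangeability matrix S and stationary frequencies pi,
combined into a rate matrix Q with off-diagonals Q[i,j] = S[i,j]*pi[j],
normalized so branch lengths are in expected substitutions per site.
Transition probabilities come from the matrix exponential, computed through
the symmetrized eigendecomposition B = diag(sqrt(pi)) Q diag(1/sqrt(pi)),
which is symmetric for reversible Q and therefore has real eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from convscan.phylo_io import AMINO_ACIDS, read_paml_dat

N_STATES = 20


@dataclass(frozen=True)
class SubstitutionModel:
    """Normalized reversible amino-acid rate model.

    Attributes
    ----------
    pi : stationary frequencies (sum 1, all positive).
    Q : 20x20 rate matrix, rows summing to 0, -sum(pi_i Q_ii) = 1.
    """

    pi: np.ndarray
    Q: np.ndarray
    # eigendecomposition of the symmetrized generator, cached for expm
    _eigvals: np.ndarray = field(repr=False, default=None)
    _left: np.ndarray = field(repr=False, default=None)   # diag(1/sqrt pi) @ V
    _right: np.ndarray = field(repr=False, default=None)  # V.T @ diag(sqrt pi)

    states: str = AMINO_ACIDS


def build_model(exchangeabilities: np.ndarray, frequencies: np.ndarray) -> SubstitutionModel:
    """Assemble a normalized reversible model from S and pi.

    S must be symmetric (within 1e-9) and nonnegative; pi positive and
    summing to 1 within 1e-6 (renormalized).
    """
    S = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(frequencies, dtype=float)
    k = pi.shape[0] if pi.ndim == 1 else 0
    if S.shape != (k, k) or k < 2:
        raise ValueError(
            f"need a square exchangeability matrix matching the frequency "
            f"vector (amino acids: 20x20 and 20), got {S.shape} and {pi.shape}"
        )
    if np.any(pi <= 0):
        raise ValueError("all stationary frequencies must be positive")
    if abs(pi.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {pi.sum():.8f}, expected 1 within 1e-6")
    if np.max(np.abs(S - S.T)) > 1e-9:
        raise ValueError("exchangeability matrix is not symmetric")
    if np.any(S < 0):
        raise ValueError("exchangeabilities must be nonnegative")
    pi = pi / pi.sum()

    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices(k)] = -Q.sum(axis=1)
    mu = -float(pi @ np.diag(Q))
    if mu <= 0:
        raise ValueError("degenerate model: zero total rate")
    Q = Q / mu

    sqrt_pi = np.sqrt(pi)
    B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
    B = 0.5 * (B + B.T)  # symmetrize away rounding
    eigvals, V = np.linalg.eigh(B)
    left = V / sqrt_pi[:, None]
    right = V.T * sqrt_pi[None, :]
    return SubstitutionModel(pi=pi, Q=Q, _eigvals=eigvals, _left=left, _right=right)


def poisson_model(n_states: int = N_STATES) -> SubstitutionModel:
    """Equal-rate model with uniform frequencies (default: 20 amino acids).

    After normalization every off-diagonal rate is 1/(K-1) and every
    diagonal -1; the transition matrix has the K-state Jukes-Cantor closed
    form. Reduced-alphabet variants exist for exhaustive-enumeration checks.
    """
    S = np.ones((n_states, n_states))
    np.fill_diagonal(S, 0.0)
    pi = np.full(n_states, 1.0 / n_states)
    return build_model(S, pi)


def model_from_spec(model_spec: str) -> SubstitutionModel:
    """Resolve a config string: "poisson" or a path to a PAML .dat file."""
    if model_spec == "poisson":
        return poisson_model()
    S, pi = read_paml_dat(model_spec)
    return build_model(S, pi)


def transition_probabilities(model: SubstitutionModel, t: float) -> np.ndarray:
    """P(t) = expm(Q t): a row-stochastic 20x20 matrix.

    Tiny negative entries from the eigendecomposition are clamped to zero
    and rows renormalized.
    """
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    if t == 0:
        return np.eye(len(model.pi))
    P = model._left @ (np.exp(model._eigvals * t)[:, None] * model._right)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P
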