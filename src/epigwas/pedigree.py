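"""Pedigree additive-relationship matrix and desk-scale BLUP.

This module supplies the correction source for the AGLS pipeline (PTA = half
the pedigree BLUP breeding value), the GLS oracle used to check the
BLUE identity, and the polygenic machinery of the simulator.  Everything is
a dense direct solve and deliberately capped in size: the module exists for
correction, simulation and cross-checking, not national-scale evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Pedigree

MAX_DENSE = 5_000


@dataclass
class AdditiveRelationship:
    """Numerator relationship matrix A over pedigree animals (topological order)."""

    animals: list[str]
    A: np.ndarray

    def index(self, animal: str) -> int:
        return self.animals.index(animal)


@dataclass
class BlupSolution:
    b_hat: np.ndarray  # fixed-effect solutions
    a_hat: np.ndarray  # predicted breeding values, pedigree order of Z columns


def build_A(ped: Pedigree) -> AdditiveRelationship:
    """Tabular (recursive) A matrix; founders non-inbred and unrelated.

    A_xy = 0.5 (A_x,sire(y) + A_x,dam(y)); diag = 1 + 0.5 A_sire,dam.
    Unknown parents contribute zero relationship.
    """
    order = ped.topological_order()
    if len(order) > MAX_DENSE:
        raise ValueError(f"pedigree larger than dense cap ({MAX_DENSE})")
    pos = {a: i for i, a in enumerate(order)}
    parents = {
        r.animal: (r.sire, r.dam) for r in ped.data.itertuples()
    }
    n = len(order)
    A = np.zeros((n, n))
    for i, x in enumerate(order):
        s, d = parents[x]
        si = pos.get(s, -1) if s != Pedigree.UNKNOWN else -1
        di = pos.get(d, -1) if d != Pedigree.UNKNOWN else -1
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
        for j in range(i):
            r = 0.0
            if si >= 0:
                r += 0.5 * A[j, si]
            if di >= 0:
                r += 0.5 * A[j, di]
            A[i, j] = A[j, i] = r
    return AdditiveRelationship(order, A)


def solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    A: np.ndarray,
    lam: float,
) -> BlupSolution:
    """Henderson's mixed model equations, dense direct solve.

    lam = sigma_e^2 / sigma_a^2.  Returns the joint (b_hat, a_hat); singular
    fixed-effect blocks are handled with a generalized inverse, so estimable
    functions of b remain valid.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    Z = np.atleast_2d(np.asarray(Z, float))
    Ainv = np.linalg.inv(A)
    p, q = X.shape[1], Z.shape[1]
    lhs = np.block(
        [
            [X.T @ X, X.T @ Z],
            [Z.T @ X, Z.T @ Z + lam * Ainv],
        ]
    )
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(lhs) @ rhs
    return BlupSolution(sol[:p], sol[p:])


def gls_blue(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> np.ndarray:
    """BLUE of b by explicit generalized least squares with the V inverse.

    b = (X' V^-1 X)^- X' V^-1 y — the identity partner of the MME solution,
    used as the independent oracle for the AGLS approximation.
    """
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    return np.linalg.pinv(XtVX) @ X.T @ Vinv @ np.asarray(y, float)
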