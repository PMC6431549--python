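"""Markov transition matrices for land-cover change.

A :class:`TransitionMatrix` is a row-stochastic class×class matrix estimated
from the cross-tabulation of two co-registered maps; entry ``(i, j)`` is the
probability that a cell of class ``i`` at the start of the period is class
``j`` at its end.  Multi-decade periods are stepped yearly by taking a matrix
root through the eigendecomposition (:func:`annualize`).

Empirical period matrices are frequently *non-embeddable*: no nonnegative
stochastic yearly matrix powers back to them exactly, typically because of
printed zeros or rounding.  The exact real eigen-root then carries small
negative rates.  ``annualize`` keeps that exact root by default (flagging the
matrix as quasi-stochastic and reporting the negative mass) so that the
round-trip ``A**T == P`` holds to machine precision; pass
``enforce_stochastic=True`` to truncate negatives and renormalize instead,
trading round-trip fidelity for a proper probability matrix.  Restricting to
a transition whitelist (:func:`restrict`) folds off-whitelist mass — including
any negative artifacts — into the diagonal and always yields a proper
stochastic matrix, which is what the cellular-automata engine consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnnualizationError, EstimationError
from .raster import TransitionCounts

__all__ = [
    "TransitionMatrix",
    "TransitionWhitelist",
    "estimate_matrix",
    "annualize",
    "project_shares",
    "restrict",
    "read_matrix_csv",
    "write_matrix_csv",
]


@dataclass
class TransitionMatrix:
    """Row-stochastic transition probability matrix over a period.

    ``quasi`` marks a matrix holding small negative rates from annualization
    of a non-embeddable period matrix; ``cleanup_magnitude`` is the total
    absolute negative mass either retained (quasi) or truncated away.
    """

    P: np.ndarray
    period_years: float
    class_order: list[int]
    quasi: bool = False
    cleanup_magnitude: float = 0.0

    _ROW_TOL = 1e-9

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        k = len(self.class_order)
        if self.P.shape != (k, k):
            raise ValueError("matrix shape does not match class_order")
        if not self.period_years > 0:
            raise ValueError("period_years must be positive")
        rowsum = self.P.sum(axis=1)
        if np.abs(rowsum - 1.0).max() > self._ROW_TOL:
            raise ValueError(f"rows must sum to 1 (max dev {np.abs(rowsum-1).max():.2e})")
        floor = -0.01 if self.quasi else -1e-12
        if self.P.min() < floor or self.P.max() > 1 + 1e-12:
            raise ValueError("entries outside [0, 1]")

    @classmethod
    def from_rows(
        cls,
        rows,
        period_years: float,
        class_order: list[int],
        normalize: bool = True,
        atol: float = 5e-4,
    ) -> "TransitionMatrix":
        """Build from printed/loaded rows, renormalizing rounded row sums.

        Row sums may deviate from 1 by up to ``atol`` (printed 4-decimal
        matrices routinely sum to 1.0001); larger deviations raise.
        """
        P = np.asarray(rows, dtype=float)
        rowsum = P.sum(axis=1)
        if np.abs(rowsum - 1.0).max() > atol:
            raise ValueError(
                f"row sums deviate from 1 by {np.abs(rowsum-1).max():.2e} > atol={atol}"
            )
        if normalize:
            P = P / rowsum[:, None]
        return cls(P, period_years, list(class_order))

    def index_of(self, code: int) -> int:
        return self.class_order.index(code)

    def to_frame(self, labels: dict[int, str] | None = None) -> pd.DataFrame:
        names = [labels.get(c, str(c)) if labels else str(c) for c in self.class_order]
        return pd.DataFrame(self.P, index=names, columns=names)


@dataclass
class TransitionWhitelist:
    """Set of allowed (from, to) class-code transitions."""

    allowed: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.allowed = {(int(a), int(b)) for a, b in self.allowed}
        if any(a == b for a, b in self.allowed):
            raise ValueError("whitelist cannot contain self-transitions")

    def __contains__(self, pair) -> bool:
        return (int(pair[0]), int(pair[1])) in self.allowed


def estimate_matrix(tc: TransitionCounts, period_years: float) -> TransitionMatrix:
    """Maximum-likelihood transition matrix: row-normalized crosstab counts.

    A class with zero cells at the start of the period gets an identity
    (pure-persistence) row with a warning — rare classes may be absent from a
    period without invalidating the rest of the matrix.
    """
    counts = np.asarray(tc.counts, dtype=float)
    if counts.sum() == 0:
        raise EstimationError("cannot estimate a transition matrix from all-zero counts")
    rowsum = counts.sum(axis=1)
    P = np.zeros_like(counts)
    for i, total in enumerate(rowsum):
        if total > 0:
            P[i] = counts[i] / total
        else:
            warnings.warn(
                f"class {tc.class_order[i]} has no cells at period start; identity row used",
                stacklevel=2,
            )
            P[i, i] = 1.0
    return TransitionMatrix(P, period_years, list(tc.class_order))


def annualize(m: TransitionMatrix, enforce_stochastic: bool = False) -> TransitionMatrix:
    """Yearly transition matrix: the ``period_years``-th root of ``m.P``.

    Computed by eigendecomposition, taking the principal branch root of each
    eigenvalue.  Eigenvalues on the negative real axis (oscillatory dynamics,
    atypical for diagonally dominant LULC matrices) and numerically
    non-diagonalizable matrices raise :class:`AnnualizationError`.

    By default the exact real root is returned even when it carries small
    negative entries (``quasi=True``; round-trip exact to machine precision).
    With ``enforce_stochastic=True`` negatives are truncated to 0 and rows
    renormalized; the truncated mass is reported in ``cleanup_magnitude`` and
    the round-trip degrades accordingly.
    """
    T = m.period_years
    if T == 1:
        return m
    w, V = np.linalg.eig(m.P)
    on_cut = (w.real <= 0) & (np.abs(w.imag) <= 1e-9)
    if on_cut.any():
        bad = w[on_cut][0]
        raise AnnualizationError(
            f"non-positive eigenvalue {bad.real:.6g}; matrix has no principal real yearly root"
        )
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e12:
        raise AnnualizationError("matrix is numerically non-diagonalizable")
    A_c = V @ np.diag(w.astype(complex) ** (1.0 / T)) @ np.linalg.inv(V)
    if np.abs(A_c.imag).max() > 1e-8:
        raise AnnualizationError("yearly root has a non-negligible imaginary part")
    A = A_c.real
    # row sums of the root are exactly 1 up to numerical noise
    A = A / A.sum(axis=1, keepdims=True)
    neg_mass = float(-np.clip(A, None, 0.0).sum())
    if enforce_stochastic or neg_mass < 1e-10:
        A = np.clip(A, 0.0, None)
        A = A / A.sum(axis=1, keepdims=True)
        return TransitionMatrix(
            A, 1.0, list(m.class_order), quasi=False, cleanup_magnitude=neg_mass
        )
    return TransitionMatrix(
        A, 1.0, list(m.class_order), quasi=True, cleanup_magnitude=neg_mass
    )


def project_shares(m: TransitionMatrix, shares, n_years: int) -> np.ndarray:
    """Aggregate Markov projection: ``shares · Pⁿ`` (classes in matrix order)."""
    if n_years < 0:
        raise ValueError("n_years must be non-negative")
    shares = np.asarray(shares, dtype=float)
    if abs(shares.sum() - 1.0) > 1e-9:
        raise ValueError("shares must sum to 1")
    steps = int(round(n_years / m.period_years))
    return shares @ np.linalg.matrix_power(m.P, steps)


def restrict(m: TransitionMatrix, w: TransitionWhitelist) -> TransitionMatrix:
    """Zero off-whitelist transitions, moving their mass to the diagonal.

    Negative quasi-stochastic artifacts on off-whitelist entries are folded
    into the diagonal as well, so the result is always properly stochastic
    provided whitelisted entries are nonnegative (any negative whitelisted
    entry is clipped to 0 with its mass returned to the diagonal).
    """
    P = m.P.copy()
    k = len(m.class_order)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            pair = (m.class_order[i], m.class_order[j])
            if pair not in w or P[i, j] < 0:
                P[i, i] += P[i, j]
                P[i, j] = 0.0
    P = P / P.sum(axis=1, keepdims=True)
    return TransitionMatrix(P, m.period_years, list(m.class_order))


def write_matrix_csv(m: TransitionMatrix, path, labels: dict[int, str] | None = None) -> None:
    """CSV with class codes as header/index; 6-decimal fixed format."""
    df = m.to_frame(labels)
    df.to_csv(path, float_format="%.6f")


def read_matrix_csv(path, period_years: float, class_order: list[int] | None = None) -> TransitionMatrix:
    df = pd.read_csv(path, index_col=0)
    order = class_order if class_order is not None else [int(c) for c in df.columns]
    return TransitionMatrix.from_rows(df.values, period_years, order, normalize=True, atol=5e-4)
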