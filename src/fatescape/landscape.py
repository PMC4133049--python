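"""Projection-method Hopfield landscape over cell-fate patterns.

Given the ±1 panel Xi (N TFs x p fates) the landscape is built from the
fate correlation matrix A = Xi^T Xi / N and its inverse:

* couplings        J = Xi A^{-1} Xi^T / N        (a rank-p projector),
* overlaps         m_a(S) = (1/N) sum_i xi_i^a S_i,
* projections      a = A^{-1} m                  (least-squares coordinates),
* predictivity     P = Xi A^{-1}                 (a_a(S) = (1/N) P^T S),

and the energy decomposes into a basin term plus three control fields:

    H(S) = -1/2 S^T J S  -  b_opt . S  -  N c . a(S)  -  N a(S)^T D m(S)

The basin term makes every stored fate an equally deep global minimum
(H_basin = -N/2); b_opt models experimental overexpression of chosen TFs,
c biases culture-favored fates, and the (generally asymmetric) signal
matrix D opens directed low-energy paths between fates: D[target, source]
> 0 drives `source` toward `target`.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DimensionMismatchError, SingularCorrelationError, ValidationError
from .panel import FatePanel

DEFAULT_MAX_CONDITION = 1e8


@dataclass(frozen=True)
class CorrelationMatrix:
    """Fate-fate correlation matrix A, its inverse, and the condition number."""

    a: np.ndarray
    a_inv: np.ndarray
    condition_number: float


@dataclass(frozen=True)
class EnergyBreakdown:
    """The four landscape terms and their sum (abstract, unitless energy)."""

    h_basin: float
    h_opt: float
    h_culture: float
    h_dev: float

    @property
    def h_total(self) -> float:
        return self.h_basin + self.h_opt + self.h_culture + self.h_dev


def _as_patterns(panel) -> np.ndarray:
    if isinstance(panel, FatePanel):
        return np.asarray(panel.xi, dtype=float)
    xi = np.asarray(panel, dtype=float)
    if xi.ndim != 2:
        raise DimensionMismatchError("pattern matrix must be 2-D (N x p)")
    return xi


def correlation_matrix(
    panel,
    max_condition: float = DEFAULT_MAX_CONDITION,
    pseudo_inverse: bool = False,
) -> CorrelationMatrix:
    """A_{ab} = (1/N) xi^a . xi^b with its inverse.

    Duplicate or antipodal fates make A singular and are rejected by name;
    a condition number above ``max_condition`` is rejected unless the
    ``pseudo_inverse`` escape hatch is set.
    """
    xi = _as_patterns(panel)
    n, p = xi.shape
    a = xi.T @ xi / n
    names = list(panel.fate_names) if isinstance(panel, FatePanel) else [str(i) for i in range(p)]
    for i in range(p):
        for j in range(i + 1, p):
            if abs(a[i, j]) >= 1.0 - 1e-12:
                kind = "duplicate" if a[i, j] > 0 else "antipodal"
                raise SingularCorrelationError(
                    f"fates {names[i]!r} and {names[j]!r} are {kind}; A is singular"
                )
    cond = float(np.linalg.cond(a))
    if not np.isfinite(cond) or cond > max_condition:
        if not pseudo_inverse:
            raise SingularCorrelationError(
                f"correlation matrix condition number {cond:.3g} exceeds "
                f"{max_condition:.3g}; pass pseudo_inverse=True to override"
            )
        a_inv = np.linalg.pinv(a)
    else:
        a_inv = np.linalg.inv(a)
    return CorrelationMatrix(a=a, a_inv=a_inv, condition_number=cond)


def overlaps(panel, state: np.ndarray) -> np.ndarray:
    """m_a = (1/N) sum_i xi_i^a S_i for one state or a stack of states."""
    xi = _as_patterns(panel)
    s = np.asarray(state, dtype=float)
    if s.shape[-1] != xi.shape[0]:
        raise DimensionMismatchError(
            f"state length {s.shape[-1]} != panel size {xi.shape[0]}"
        )
    return s @ xi / xi.shape[0]


def projections(corr: CorrelationMatrix, m: np.ndarray) -> np.ndarray:
    """a = A^{-1} m: correlation-corrected coordinates in the fate subspace."""
    m = np.asarray(m, dtype=float)
    if m.shape[-1] != corr.a_inv.shape[0]:
        raise DimensionMismatchError("overlap vector does not match correlation matrix")
    return m @ corr.a_inv.T


def interaction_matrix(panel, corr: CorrelationMatrix) -> np.ndarray:
    """Projection-method couplings J = Xi A^{-1} Xi^T / N.

    J is the orthogonal projector onto the fate subspace (scaled ±1
    patterns): symmetric, idempotent, trace p, and J xi^a = xi^a.
    """
    xi = _as_patterns(panel)
    return xi @ corr.a_inv @ xi.T / xi.shape[0]


def predictivity_matrix(panel, corr: CorrelationMatrix) -> np.ndarray:
    """P = Xi A^{-1}, shape (N, p): TF i's weight in fate a's projection.

    Satisfies a(S) = (1/N) P^T S for every state, so a TF's predictivity is
    exactly its leverage on the projection (and on the basin energy) of that
    fate.  Defined without a 1/N prefactor; rankings are scale-invariant.
    """
    xi = _as_patterns(panel)
    return xi @ corr.a_inv


def culture_fields(panel, corr: CorrelationMatrix, c: np.ndarray) -> np.ndarray:
    """Per-TF field equivalent of the per-fate culture bias c.

    b_cult = Xi A^{-1} c, so that -b_cult . S == -N sum_a c_a a_a(S).
    """
    xi = _as_patterns(panel)
    c = np.asarray(c, dtype=float)
    if c.shape != (xi.shape[1],):
        raise DimensionMismatchError(f"culture bias must have length p={xi.shape[1]}")
    return xi @ (corr.a_inv @ c)


def dev_coupling(panel, corr: CorrelationMatrix, d: np.ndarray) -> np.ndarray:
    """Directed signal couplings J_dev = Xi A^{-1} D Xi^T / N.

    Convention: D[target, source] > 0 opens a path from `source` to
    `target` — at S = xi^source the field gains a component along
    xi^target proportional to that entry.  Off-diagonal D makes J_dev
    asymmetric and breaks detailed balance (a pseudo-landscape).
    """
    xi = _as_patterns(panel)
    d = np.asarray(d, dtype=float)
    p = xi.shape[1]
    if d.shape != (p, p):
        raise DimensionMismatchError(f"signal matrix must be {p}x{p}")
    return xi @ corr.a_inv @ d @ xi.T / xi.shape[0]


def total_energy(
    state: np.ndarray,
    panel,
    corr: CorrelationMatrix,
    j: np.ndarray,
    b_opt: Optional[np.ndarray] = None,
    c: Optional[np.ndarray] = None,
    d: Optional[np.ndarray] = None,
) -> EnergyBreakdown:
    """Evaluate the four landscape terms at a ±1 state.

    H_basin = -1/2 S^T J S is bounded below by -N/2, with equality exactly
    on the fate subspace; the control terms vanish for zero fields.
    """
    xi = _as_patterns(panel)
    s = np.asarray(state, dtype=float)
    if s.shape != (xi.shape[0],):
        raise DimensionMismatchError("state length does not match panel")
    n = xi.shape[0]
    h_basin = -0.5 * float(s @ (j @ s))
    h_opt = 0.0
    if b_opt is not None:
        b_opt = np.asarray(b_opt, dtype=float)
        if b_opt.shape != (n,):
            raise DimensionMismatchError("b_opt must have length N")
        h_opt = -float(b_opt @ s)
    m = overlaps(panel, s)
    a_coord = projections(corr, m)
    h_culture = 0.0
    if c is not None:
        c = np.asarray(c, dtype=float)
        if c.shape != (xi.shape[1],):
            raise DimensionMismatchError("c must have length p")
        h_culture = -n * float(c @ a_coord)
    h_dev = 0.0
    if d is not None:
        d = np.asarray(d, dtype=float)
        if d.shape != (xi.shape[1], xi.shape[1]):
            raise DimensionMismatchError("D must be p x p")
        h_dev = -n * float(a_coord @ d @ m)
    return EnergyBreakdown(h_basin, h_opt, h_culture, h_dev)


def local_field(
    state: np.ndarray,
    j: np.ndarray,
    b: Optional[np.ndarray] = None,
    j_dev: Optional[np.ndarray] = None,
    exclude_self: bool = False,
) -> np.ndarray:
    """h_i = sum_j J_ij S_j (+ fields + signal couplings).

    With the full sum and zero fields, h(xi^a) = xi^a exactly (the
    projector identity).  ``exclude_self`` drops each spin's self-coupling
    J_ii S_i; that diagonal-free field is the one the dynamics use — it
    makes the single-flip identity dH = 2 S_i h_i exact and heat-bath
    updates exactly Boltzmann-stationary for symmetric J.
    """
    s = np.asarray(state, dtype=float)
    if s.shape != (j.shape[0],):
        raise DimensionMismatchError("state length does not match couplings")
    m = j if j_dev is None else j + j_dev
    h = m @ s
    if exclude_self:
        h = h - np.diag(m) * s
    if b is not None:
        b = np.asarray(b, dtype=float)
        if b.shape != s.shape:
            raise DimensionMismatchError("field length does not match state")
        h = h + b
    return h


class EpigeneticLandscape(TransformerMixin, BaseEstimator):
    """Scikit-learn estimator for the projection-method fate landscape.

    ``fit`` takes the stored patterns — a :class:`FatePanel` or a (p, N)
    array whose rows are the ±1 fate patterns (sklearn orientation: one
    sample per stored fate) — and precomputes the correlation matrix, its
    inverse, the projector couplings and the predictivity matrix.
    ``transform`` maps ±1 states (n_states, N) to their projection
    coordinates (n_states, p).

    Parameters
    ----------
    max_condition : float, default 1e8
        Reject panels whose fate correlation matrix is worse conditioned.
    pseudo_inverse : bool, default False
        Escape hatch: use the Moore-Penrose inverse instead of rejecting.

    Attributes
    ----------
    xi_ : ndarray (N, p)         stored patterns, TF-major.
    correlation_ : ndarray (p, p), correlation_inv_, condition_number_
    coupling_ : ndarray (N, N)   projector couplings J.
    predictivity_ : ndarray (N, p)
    tf_ids_, fate_names_ : labels (generated if fit from a bare array).
    """

    def __init__(self, max_condition: float = DEFAULT_MAX_CONDITION, pseudo_inverse: bool = False):
        self.max_condition = max_condition
        self.pseudo_inverse = pseudo_inverse

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y=None):
        if isinstance(X, FatePanel):
            panel = X
        else:
            arr = np.asarray(X)
            if arr.ndim != 2:
                raise ValidationError("expected a (p, N) array of fate patterns")
            p, n = arr.shape
            panel = FatePanel(
                tuple(f"TF{i:04d}" for i in range(n)),
                tuple(f"fate{i:02d}" for i in range(p)),
                arr.T,
            )
        self.panel_ = panel
        self.tf_ids_ = panel.tf_ids
        self.fate_names_ = panel.fate_names
        self.xi_ = np.asarray(panel.xi, dtype=float)
        self.n_features_in_ = panel.n_tfs
        corr = correlation_matrix(panel, self.max_condition, self.pseudo_inverse)
        self.corr_ = corr
        self.correlation_ = corr.a
        self.correlation_inv_ = corr.a_inv
        self.condition_number_ = corr.condition_number
        self.coupling_ = interaction_matrix(panel, corr)
        self.predictivity_ = predictivity_matrix(panel, corr)
        return self

    def _check_fitted(self):
        if not hasattr(self, "xi_"):
            raise ValidationError("landscape is not fitted; call fit() first")

    # -- geometry ----------------------------------------------------------
    def overlaps(self, S) -> np.ndarray:
        self._check_fitted()
        return overlaps(self.panel_, S)

    def transform(self, S) -> np.ndarray:
        """Projection coordinates a = A^{-1} m for one state or a stack."""
        self._check_fitted()
        return projections(self.corr_, self.overlaps(S))

    project = transform

    def pattern(self, fate: str) -> np.ndarray:
        self._check_fitted()
        return self.panel_.pattern(fate)

    # -- fields and energies ----------------------------------------------
    def culture_field(self, c) -> np.ndarray:
        self._check_fitted()
        return culture_fields(self.panel_, self.corr_, c)

    def dev_coupling(self, d) -> np.ndarray:
        self._check_fitted()
        return dev_coupling(self.panel_, self.corr_, d)

    def signal_matrix(self, edges: dict) -> np.ndarray:
        """Build D from ``{(target, source): strength}`` by fate name."""
        self._check_fitted()
        p = len(self.fate_names_)
        d = np.zeros((p, p))
        for (target, source), strength in edges.items():
            d[self.panel_.fate_index(target), self.panel_.fate_index(source)] = strength
        return d

    def energy(self, S, b_opt=None, c=None, d=None, j=None) -> EnergyBreakdown:
        self._check_fitted()
        return total_energy(
            S, self.panel_, self.corr_, self.coupling_ if j is None else j,
            b_opt=b_opt, c=c, d=d,
        )

    def local_field(self, S, b_opt=None, c=None, d=None, j=None, exclude_self=False) -> np.ndarray:
        self._check_fitted()
        b = None
        if b_opt is not None or c is not None:
            b = np.zeros(self.n_features_in_)
            if b_opt is not None:
                b = b + np.asarray(b_opt, dtype=float)
            if c is not None:
                b = b + self.culture_field(c)
        j_dev = self.dev_coupling(d) if d is not None else None
        return local_field(
            S, self.coupling_ if j is None else j, b=b, j_dev=j_dev,
            exclude_self=exclude_self,
        )
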