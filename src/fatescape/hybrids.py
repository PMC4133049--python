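"""Hybrid (spurious-attractor-like) classification of expression states.

A random ±1 state has projection a_alpha with mean 0 and variance
(A^{-1})_{alpha alpha} / N on every fate, so a pooled null standard
deviation calibrated from uniform random vectors gives a significance
scale: a query whose |projection| on a fate exceeds a few null sd's
genuinely points into that fate's direction of the subspace.  Partially
reprogrammed cells classified this way look like low-dimensional hybrids —
mixtures of a handful of natural fates — matching the odd-majority-vote
spurious attractors of the underlying Hopfield network.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import EmptyIntersectionError, ValidationError
from .landscape import EpigeneticLandscape
from .panel import FatePanel
from . import preprocess


@dataclass(frozen=True)
class NullCalibration:
    """Projection statistics of uniform random ±1 states."""

    n_draws: int
    mean: np.ndarray        # per fate
    sd: np.ndarray          # per fate
    pooled_mean: float
    pooled_sd: float
    seed: int
    fate_names: tuple

    def closed_form_sd(self, corr_inv: np.ndarray, n_tfs: int) -> np.ndarray:
        """Exact per-fate null sd: sqrt((A^{-1})_aa / N)."""
        return np.sqrt(np.diag(corr_inv) / n_tfs)


@dataclass(frozen=True)
class HybridHit:
    fate: str
    projection: float
    n_sd: float
    strong: bool


@dataclass(frozen=True)
class HybridReport:
    """Fates whose |projection| clears the calibrated null threshold."""

    query_id: str
    hits: tuple
    threshold_sd: float
    null_sd: float

    @property
    def significant_fates(self):
        return tuple(h.fate for h in self.hits)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "query": self.query_id,
                    "fate": h.fate,
                    "projection": h.projection,
                    "n_sd": h.n_sd,
                    "strong": h.strong,
                }
                for h in self.hits
            ]
        )


def projection_null(
    landscape: EpigeneticLandscape,
    n_draws: int = 10_000,
    seed: int = 0,
) -> NullCalibration:
    """Calibrate the projection null from uniform random ±1 vectors."""
    if n_draws < 1000:
        raise ValidationError("need at least 1000 null draws for a stable sd")
    rng = np.random.default_rng(seed)
    n = landscape.n_features_in_
    states = rng.choice([-1.0, 1.0], size=(n_draws, n))
    a = landscape.transform(states)
    return NullCalibration(
        n_draws=n_draws,
        mean=a.mean(axis=0),
        sd=a.std(axis=0),
        pooled_mean=float(a.mean()),
        pooled_sd=float(a.std()),
        seed=seed,
        fate_names=landscape.fate_names_,
    )


def classify_hybrid(
    query_z: pd.Series,
    panel: FatePanel,
    null: Optional[NullCalibration] = None,
    threshold_sd: float = 2.0,
    strong_sd: float = 3.0,
    per_fate: bool = False,
    n_draws: int = 10_000,
    seed: int = 0,
    query_id: Optional[str] = None,
) -> HybridReport:
    """Classify one expression profile as a hybrid of natural fates.

    The query (continuous z-scores indexed by gene) is intersected with the
    panel TFs; if the intersection is proper, the panel, correlation matrix
    and null are rebuilt on the common genes (cross-platform rule).  The
    query is binarized and fates with |projection| >= threshold_sd x the
    pooled null sd are reported, sign preserved, sorted by |projection|;
    hits at >= strong_sd are flagged.  ``per_fate`` thresholds each fate on
    its own null sd instead of the pooled one.
    """
    ids = [t for t in panel.tf_ids if t in query_z.index]
    if not ids:
        raise EmptyIntersectionError("query shares no genes with the panel")
    restricted = len(ids) < panel.n_tfs
    work_panel = panel.restrict(ids) if restricted else panel
    landscape = EpigeneticLandscape().fit(work_panel)
    if null is None or restricted:
        null = projection_null(landscape, n_draws=n_draws, seed=seed)
    s = np.where(query_z.loc[list(work_panel.tf_ids)].to_numpy() >= 0, 1.0, -1.0)
    a = landscape.transform(s)
    scale = null.sd if per_fate else np.full(a.shape, null.pooled_sd)
    n_sd = np.abs(a) / scale
    order = np.argsort(-np.abs(a), kind="stable")
    hits = tuple(
        HybridHit(
            fate=landscape.fate_names_[k],
            projection=float(a[k]),
            n_sd=float(n_sd[k]),
            strong=bool(n_sd[k] >= strong_sd),
        )
        for k in order
        if n_sd[k] >= threshold_sd
    )
    return HybridReport(
        query_id=query_id or (query_z.name if query_z.name else "query"),
        hits=hits,
        threshold_sd=threshold_sd,
        null_sd=float(null.pooled_sd),
    )


def mixture_state(panel: FatePanel, fate_subset: Sequence[str]) -> np.ndarray:
    """Odd-majority-vote mixture of a subset of fate patterns.

    Odd subset size guarantees no per-TF ties; size 1 degenerates to the
    pattern itself.  These mixtures are the classic spurious attractors of
    Hopfield networks with (near-)orthogonal patterns.
    """
    subset = list(fate_subset)
    if len(subset) % 2 == 0 or len(subset) < 1:
        raise ValidationError("mixture subsets must have odd size >= 1")
    idx = [panel.fate_index(f) for f in subset]
    votes = np.asarray(panel.xi, dtype=int)[:, idx].sum(axis=1)
    return np.sign(votes).astype(np.int8)


@dataclass(frozen=True)
class Attractor:
    state: np.ndarray
    energy: float
    projections: np.ndarray
    label: str


def enumerate_attractors(
    landscape: EpigeneticLandscape,
    b_opt: Optional[np.ndarray] = None,
    max_mixture_size: int = 7,
) -> list:
    """All fixed points of zero-noise sign dynamics, for N <= 20.

    A state is a fixed point iff every spin agrees with its (self-coupling
    excluded) local field, zero field resolving to +1.  Each attractor is
    labeled pure / sign_flip / mixture (odd-majority vote of stored fates,
    either sign) / other.
    """
    from .dynamics import all_states  # local import to avoid a cycle

    n = landscape.n_features_in_
    if n > 20:
        raise ValidationError("exhaustive attractor enumeration limited to N <= 20")
    j = np.array(landscape.coupling_)
    jz = j.copy()
    np.fill_diagonal(jz, 0.0)
    b = np.zeros(n) if b_opt is None else np.asarray(b_opt, dtype=float)

    xi = landscape.xi_
    p = xi.shape[1]
    mixtures = {}
    for size in range(3, min(p, max_mixture_size) + 1, 2):
        for subset in combinations(landscape.fate_names_, size):
            mx = mixture_state(landscape.panel_, subset)
            mixtures[mx.tobytes()] = subset
            mixtures[(-mx).tobytes()] = subset

    out = []
    chunk = 1 << 14
    for start in range(0, 2**n, chunk):
        codes = np.arange(start, min(start + chunk, 2**n))
        bits = (codes[:, None] >> np.arange(n)) & 1
        states = np.where(bits == 1, 1.0, -1.0)
        h = states @ jz.T + b
        stable = ((states * h > 0) | ((h == 0) & (states > 0))).all(axis=1)
        for s in states[stable]:
            e = -0.5 * float(s @ (j @ s))
            a = landscape.transform(s)
            key = s.astype(np.int8)
            label = "other"
            for k in range(p):
                if np.array_equal(s, xi[:, k]):
                    label = "pure"
                elif np.array_equal(s, -xi[:, k]):
                    label = "sign_flip"
            if label == "other" and key.tobytes() in mixtures:
                label = "mixture"
            out.append(Attractor(state=key, energy=e, projections=a, label=label))
    return out


class HybridClassifier(BaseEstimator):
    """Estimator wrapping null calibration + hybrid classification.

    ``fit`` takes the natural-fate panel (a :class:`FatePanel` or a (p, N)
    pattern array), builds the landscape and calibrates the projection
    null; ``predict`` returns the highest-projecting fate per query column,
    and :meth:`report` the full per-query hybrid reports.
    """

    def __init__(
        self,
        threshold_sd: float = 2.0,
        strong_sd: float = 3.0,
        n_draws: int = 10_000,
        per_fate: bool = False,
        random_state: int = 0,
    ):
        self.threshold_sd = threshold_sd
        self.strong_sd = strong_sd
        self.n_draws = n_draws
        self.per_fate = per_fate
        self.random_state = random_state

    def fit(self, X, y=None):
        landscape = EpigeneticLandscape().fit(X)
        self.landscape_ = landscape
        self.panel_ = landscape.panel_
        self.null_ = projection_null(
            landscape, n_draws=self.n_draws, seed=self.random_state
        )
        self.n_features_in_ = landscape.n_features_in_
        return self

    def report(self, queries: pd.DataFrame) -> list:
        """Hybrid reports for each query column (genes x queries z-scores)."""
        if not hasattr(self, "landscape_"):
            raise ValidationError("classifier is not fitted")
        return [
            classify_hybrid(
                queries[col],
                self.panel_,
                null=self.null_,
                threshold_sd=self.threshold_sd,
                strong_sd=self.strong_sd,
                per_fate=self.per_fate,
                n_draws=self.n_draws,
                seed=self.random_state,
                query_id=str(col),
            )
            for col in queries.columns
        ]

    def predict(self, queries: pd.DataFrame) -> np.ndarray:
        """Top-projecting fate per query (empty string if nothing significant)."""
        return np.array(
            [r.hits[0].fate if r.hits else "" for r in self.report(queries)],
            dtype=object,
        )
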