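"""Expression preprocessing: rank-based normal scores, binarization, consensus.

Gene expression is positive and approximately log-normal, so the pipeline
works on rank statistics: each array (column) is converted to a rank order,
ranks to midpoint percentiles, percentiles to standard-normal quantiles, and
the resulting scores are re-standardized with the biased (divide-by-G)
variance so every column has mean 0 and Euclidean norm sqrt(G).  A positive
score means "above the median of this array", which is what the downstream
±1 binarization encodes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    ConstantColumnError,
    EmptyIntersectionError,
    GeneMismatchError,
    NonFiniteDataError,
    NonPositiveDataError,
    ValidationError,
)
from .panel import FatePanel

HM_CATEGORIES = ("K4", "K27", "bivalent", "none")


@dataclass(frozen=True)
class RawExpressionTable:
    """Positive expression values (genes x samples) plus a sample→fate map."""

    values: pd.DataFrame
    fate_of_sample: Mapping[str, str]

    def __post_init__(self):
        missing = [s for s in self.values.columns if s not in self.fate_of_sample]
        if missing:
            raise ValidationError(f"samples without a fate annotation: {missing}")


def normal_scores(values: np.ndarray, standardize: bool = True) -> np.ndarray:
    """Rank-based inverse-normal transform of one expression column.

    Ties receive average ranks; percentiles use the midpoint convention
    (rank - 0.5)/G, which keeps quantiles finite and is symmetric around the
    median.  With ``standardize`` the scores are re-centered and rescaled by
    the biased (1/G) standard deviation, giving sum 0 and sum of squares G.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValidationError("normal_scores expects a 1-D column")
    if x.size < 2:
        raise ValidationError("need at least 2 genes per column")
    if not np.isfinite(x).all():
        raise NonFiniteDataError("expression column contains NaN or infinite values")
    if (x <= 0).any():
        raise NonPositiveDataError("expression values must be strictly positive")
    if np.all(x == x[0]):
        raise ConstantColumnError("column is constant; ranks are undefined")
    ranks = stats.rankdata(x, method="average")
    z = stats.norm.ppf((ranks - 0.5) / x.size)
    if standardize:
        z = (z - z.mean()) / z.std()  # biased estimator: ddof=0
    return z


def rank_to_zscore(raw) -> pd.DataFrame:
    """Convert a positive expression table (genes x samples) to normal scores.

    Accepts a :class:`RawExpressionTable` or a bare DataFrame.  Each column
    is transformed independently; the output is monotone in the input within
    each column and invariant under strictly monotone column transforms.
    """
    df = raw.values if isinstance(raw, RawExpressionTable) else raw
    if df.index.duplicated().any():
        raise GeneMismatchError("duplicate gene ids; aggregate probes upstream")
    out = {}
    for col in df.columns:
        try:
            out[col] = normal_scores(df[col].to_numpy())
        except ValidationError as exc:
            raise type(exc)(f"column {col!r}: {exc}") from None
    return pd.DataFrame(out, index=df.index)


def binarize(z) -> "pd.DataFrame | np.ndarray":
    """Map normal scores to ±1 TF states: z > 0 → +1, z < 0 → −1, z = 0 → +1.

    The z = 0 tie rule is fixed (+1) so runs are reproducible.
    """
    arr = z.to_numpy() if isinstance(z, pd.DataFrame) else np.asarray(z, dtype=float)
    if not np.isfinite(arr).all():
        raise NonFiniteDataError("binarize requires finite z-scores")
    b = np.where(arr >= 0, 1, -1).astype(np.int8)
    if isinstance(z, pd.DataFrame):
        return pd.DataFrame(b, index=z.index, columns=z.columns)
    return b


def consensus_patterns(
    binary: pd.DataFrame,
    z: pd.DataFrame,
    fate_of_sample: Mapping[str, str],
) -> FatePanel:
    """Majority-vote consensus of replicate ±1 calls, one pattern per fate.

    Exact vote ties are broken by the sign of the mean continuous score
    across the tied replicates (a zero mean resolves to +1).
    """
    if not binary.index.equals(z.index) or not binary.columns.equals(z.columns):
        raise GeneMismatchError("binary and continuous tables must share genes and samples")
    missing = [s for s in binary.columns if s not in fate_of_sample]
    if missing:
        raise ValidationError(f"samples without fate annotation: {missing}")
    fates = list(dict.fromkeys(fate_of_sample[s] for s in binary.columns))
    cols = {}
    for fate in fates:
        samples = [s for s in binary.columns if fate_of_sample[s] == fate]
        votes = binary[samples].to_numpy().sum(axis=1)
        consensus = np.sign(votes)
        tied = consensus == 0
        if tied.any():
            mean_z = z[samples].to_numpy()[tied].mean(axis=1)
            consensus[tied] = np.where(mean_z >= 0, 1, -1)
        cols[fate] = consensus.astype(np.int8)
    return FatePanel(tuple(binary.index), tuple(fates), np.column_stack([cols[f] for f in fates]))


def filter_nondifferential(panel: FatePanel):
    """Drop TFs that are always on or always off in every fate.

    Returns ``(filtered_panel, removed_ids)``; survivor order is preserved.
    On the original study data this step reduces 1715 TFs to 1337.
    """
    xi = np.asarray(panel.xi)
    constant = np.all(xi == xi[:, [0]], axis=1)
    removed = [t for t, c in zip(panel.tf_ids, constant) if c]
    if constant.all():
        raise ValidationError("every TF is constant across fates; nothing differential")
    kept = [t for t, c in zip(panel.tf_ids, constant) if not c]
    return panel.restrict(kept), removed


def intersect_panels(panel: FatePanel, query_genes: Sequence[str]):
    """Restrict a panel to the TFs present in ``query_genes``.

    Returns ``(restricted_panel, index_map)`` where ``index_map[i]`` is the
    row of the original panel that became row ``i``.  Any correlation or
    coupling matrix must be rebuilt on the restricted panel (the study's
    cross-platform analyses use the N = 1329 common TFs with a rebuilt A).
    """
    qset = set(query_genes)
    idx = np.array([i for i, t in enumerate(panel.tf_ids) if t in qset], dtype=int)
    if idx.size == 0:
        raise EmptyIntersectionError("panels share no gene identifiers")
    restricted = panel.restrict([panel.tf_ids[i] for i in idx])
    return restricted, idx


def hm_conditional_profile(
    z_column: pd.Series,
    hm_calls: pd.Series,
    bin_edges: Sequence[float],
) -> pd.DataFrame:
    """P(histone mark | expression z-bin) from matched call and score tables.

    Rows are z-score bins, columns the mark categories (K4, K27, bivalent,
    none) plus a gene count; occupied rows sum to 1, empty bins are kept as
    NaN rows (flagged by count 0), never fabricated.
    """
    shared = z_column.index.intersection(hm_calls.index)
    if len(shared) == 0:
        raise GeneMismatchError("no shared genes between expression and HM calls")
    bad = set(hm_calls.loc[shared].unique()) - set(HM_CATEGORIES)
    if bad:
        raise ValidationError(f"unknown histone-mark categories: {sorted(bad)}")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or (np.diff(edges) <= 0).any():
        raise ValidationError("bin_edges must be increasing with at least two edges")
    z = z_column.loc[shared].to_numpy()
    which = np.digitize(z, edges) - 1
    labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    counts = pd.DataFrame(0, index=labels, columns=list(HM_CATEGORIES), dtype=float)
    inside = (which >= 0) & (which < len(labels))
    for b, mark in zip(which[inside], hm_calls.loc[shared].to_numpy()[inside]):
        counts.loc[labels[b], mark] += 1
    total = counts.sum(axis=1)
    probs = counts.div(total, axis=0)  # empty bins become NaN, deliberately
    probs["n_genes"] = total.astype(int)
    return probs


class RankNormalScores(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer applying the rank→normal-scores map.

    Follows the sklearn orientation: rows are samples (arrays), columns are
    genes, and each *row* is transformed independently — the transpose of
    the genes-x-samples tables used elsewhere in this package.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("expected a 2-D array of samples x genes")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.vstack([normal_scores(row) for row in X])


def preprocess_pipeline(raw: RawExpressionTable):
    """Full chain raw → z-scores → ±1 calls → consensus panel → differential panel.

    Returns ``(panel, z_by_fate, removed_ids)`` where ``z_by_fate`` averages
    the continuous scores over replicates of each fate (the expression input
    to reprogramming scores).
    """
    z = rank_to_zscore(raw)
    calls = binarize(z)
    panel = consensus_patterns(calls, z, raw.fate_of_sample)
    panel, removed = filter_nondifferential(panel)
    fate_cols = {}
    for fate in panel.fate_names:
        samples = [s for s in z.columns if raw.fate_of_sample[s] == fate]
        fate_cols[fate] = z[samples].mean(axis=1)
    z_by_fate = pd.DataFrame(fate_cols).loc[list(panel.tf_ids)]
    return panel, z_by_fate, removed
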