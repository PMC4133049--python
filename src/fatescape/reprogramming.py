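"""Ranking transcription factors as reprogramming candidates.

A TF is a good overexpression candidate for a target fate when it is both
highly expressed there (continuous z-score) and highly predictive of that
fate (its weight in the fate's projection).  The product of the two — the
reprogramming score — ranks candidates: top of the list for
overexpression, bottom for knockout.  A label-permutation tail probability
quantifies how surprising it is that a known protocol's TFs all sit in the
top k; it converges to the hypergeometric closed form C(k, s)/C(N, s).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import comb

from .errors import GeneMismatchError, ValidationError
from .landscape import EpigeneticLandscape


def _quadrant(z, p):
    return ("+" if z >= 0 else "-") + ("+" if p >= 0 else "-")


def reprogramming_scores(
    z_by_fate: pd.DataFrame,
    landscape: EpigeneticLandscape,
) -> pd.DataFrame:
    """Long table of (tf, fate, zscore, predictivity, score, quadrant).

    ``z_by_fate`` holds the continuous per-fate expression z-scores (genes
    x fates) and must cover exactly the landscape's TFs; the score is the
    elementwise product zscore x predictivity.
    """
    tf_ids = list(landscape.tf_ids_)
    if set(z_by_fate.index) != set(tf_ids):
        raise GeneMismatchError(
            "expression table TFs do not match the landscape panel"
        )
    missing = [f for f in landscape.fate_names_ if f not in z_by_fate.columns]
    if missing:
        raise ValidationError(f"expression table lacks fates: {missing}")
    z = z_by_fate.loc[tf_ids, list(landscape.fate_names_)].to_numpy(dtype=float)
    p = landscape.predictivity_
    rows = []
    for k, fate in enumerate(landscape.fate_names_):
        for i, tf in enumerate(tf_ids):
            rows.append(
                (tf, fate, z[i, k], p[i, k], z[i, k] * p[i, k], _quadrant(z[i, k], p[i, k]))
            )
    return pd.DataFrame(
        rows, columns=["tf", "fate", "zscore", "predictivity", "score", "quadrant"]
    )


def rank_candidates(
    table: pd.DataFrame,
    fate: str,
    k: int,
    direction: str = "overexpress",
) -> pd.DataFrame:
    """Top-k candidates for one fate, by signed reprogramming score.

    ``direction`` "overexpress" ranks descending (most positive score
    first), "knockout" ascending.  Ties break lexicographically by TF id,
    so the ordering is deterministic and independent of input row order.
    """
    if direction not in ("overexpress", "knockout"):
        raise ValidationError("direction must be 'overexpress' or 'knockout'")
    sub = table[table["fate"] == fate]
    if sub.empty:
        raise ValidationError(f"unknown fate {fate!r}")
    if k > len(sub):
        raise ValidationError(f"k={k} exceeds the {len(sub)} available TFs")
    ascending = direction == "knockout"
    ordered = sub.sort_values(
        ["score", "tf"], ascending=[ascending, True], kind="stable"
    ).reset_index(drop=True)
    out = ordered.head(k).copy()
    out.insert(0, "rank", np.arange(1, k + 1))
    return out


@dataclass(frozen=True)
class PermutationTail:
    """Monte-Carlo and closed-form probability of a set surviving in the top k."""

    frequency: float
    closed_form: float
    n_perm: int
    n_success: int

    @property
    def standard_error(self) -> float:
        p = self.closed_form
        return float(np.sqrt(p * (1 - p) / self.n_perm))


def hypergeometric_tail(n_tfs: int, k: int, set_size: int) -> float:
    """P(all ``set_size`` members land in the top k under random relabeling).

    C(k, s) / C(N, s); for the study's N = 1337, k = 50, s = 4 this is
    ~1.7e-6, the one-in-a-million level seen in the original permutation
    experiment.
    """
    if set_size > k or k > n_tfs:
        raise ValidationError("need set_size <= k <= N")
    return float(comb(k, set_size, exact=True) / comb(n_tfs, set_size, exact=True))


def permutation_tail_probability(
    table: pd.DataFrame,
    fate: str,
    tf_set: Sequence[str],
    k: int,
    n_perm: int,
    seed: int = 0,
) -> PermutationTail:
    """How often all of ``tf_set`` stays in the top k after label permutation.

    Scores stay attached to their positions while TF labels are randomly
    permuted; the Monte-Carlo frequency is returned together with the
    hypergeometric closed form for cross-checking.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be at least 1")
    ranked = rank_candidates(table, fate, k=len(table[table["fate"] == fate]))
    tfs = ranked["tf"].to_numpy()
    n = len(tfs)
    members = np.array([np.flatnonzero(tfs == t) for t in tf_set]).ravel()
    if len(members) != len(tf_set):
        raise ValidationError("tf_set contains TFs absent from the table")
    if k > n:
        raise ValidationError("k exceeds the number of TFs")
    topk = np.zeros(n, dtype=bool)
    topk[:k] = True  # ranked is already ordered by score
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if topk[perm[members]].all():
            hits += 1
    return PermutationTail(
        frequency=hits / n_perm,
        closed_form=hypergeometric_tail(n, k, len(tf_set)),
        n_perm=n_perm,
        n_success=hits,
    )
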