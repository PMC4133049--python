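"""Synthetic fate panels, replicate expression tables, and hybrid queries.

The generator emulates the statistical structure of the real inputs:

* lineage-correlated ±1 fate patterns — patterns evolve along a tree, each
  edge flipping a fraction f of each sign class, so fates at tree distance
  d correlate as (1 - 2f)^d (a star topology over a hidden root gives a
  near-orthogonal panel for f near 0.5, a chain gives a graded lineage).
  Patterns are balanced (half the TFs on): binarization of real arrays is
  a median split, so real consensus patterns are balanced by construction,
  and the balance-preserving flips keep the planted panel recoverable by
  that same median split;
* log-normal replicate expression consistent with the patterns — per-gene
  baseline plus ±Delta/2 on/off shift plus Gaussian noise, all in log
  space, exponentiated to positive values;
* hybrid query profiles — odd-majority-vote mixtures of chosen fates,
  pushed through the same expression-noise model.

All outputs are pure functions of (spec, seed).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SingularCorrelationError, ValidationError
from .landscape import DEFAULT_MAX_CONDITION, correlation_matrix
from .panel import FatePanel
from .preprocess import RawExpressionTable
from .hybrids import mixture_state


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the generator.

    n_tfs, n_fates : panel dimensions (N > p required downstream).
    flip_prob : per-edge, per-TF flip probability f in (0, 0.5); star
        topology pairwise correlation is (1-2f)^2.
    topology : "star" (hidden root, every fate one edge away) or "chain"
        (fate k is the child of fate k-1; fate 0 is the root pattern).
    replicates : arrays per fate.
    delta : on/off mean log-expression separation (z-score units of the
        log-normal model); delta/sigma >= 4 gives near-perfect recovery.
    sigma : per-measurement log-space noise sd.
    baseline_sd : per-gene baseline log-expression sd, giving genes
        distinct typical ranks while staying small against delta/2.
    seed : RNG seed.
    """

    n_tfs: int = 1000
    n_fates: int = 10
    flip_prob: float = 0.4
    topology: str = "star"
    replicates: int = 3
    delta: float = 2.0
    sigma: float = 0.5
    baseline_sd: float = 0.15
    seed: int = 0
    max_condition: float = DEFAULT_MAX_CONDITION
    max_retries: int = 10

    def __post_init__(self):
        if not 0 < self.flip_prob < 0.5:
            raise ValidationError("flip_prob must lie strictly in (0, 0.5)")
        if self.topology not in ("star", "chain"):
            raise ValidationError("topology must be 'star' or 'chain'")
        if self.delta < 0 or self.sigma < 0 or self.baseline_sd < 0:
            raise ValidationError("delta, sigma and baseline_sd must be nonnegative")
        if self.n_fates < 1 or self.n_tfs <= self.n_fates or self.replicates < 1:
            raise ValidationError("need n_tfs > n_fates >= 1 and replicates >= 1")


def _tf_ids(n):
    return tuple(f"TF{i:04d}" for i in range(n))


def _fate_names(p):
    return tuple(f"fate{i:02d}" for i in range(p))


def _balanced_root(rng, n):
    pat = np.concatenate([np.ones(n - n // 2, dtype=np.int8), -np.ones(n // 2, dtype=np.int8)])
    rng.shuffle(pat)
    return pat


def _balanced_flip(rng, parent, f):
    """Flip a fraction f of each sign class, preserving the on/off balance.

    Per-TF marginal flip probability is f, so the parent-child correlation
    is (1 - 2f) exactly in expectation; flipping equal counts on each side
    keeps every pattern median-splittable like real consensus patterns.
    """
    child = parent.copy()
    for sign in (1, -1):
        members = np.flatnonzero(parent == sign)
        m = int(round(f * members.size))
        if m:
            child[rng.choice(members, size=m, replace=False)] *= -1
    return child


def synth_fate_panel(spec: SyntheticSpec) -> FatePanel:
    """Draw a lineage-correlated, balanced ±1 panel passing the condition gate.

    Regenerates (bounded retries) when the fate correlation matrix fails
    the gate — e.g. when f is so small that fates collapse onto each other.
    """
    rng = np.random.default_rng(spec.seed)
    last_error = None
    for _ in range(spec.max_retries):
        root = _balanced_root(rng, spec.n_tfs)
        if spec.topology == "chain":
            cols = [root]
            parent = root
            for _ in range(spec.n_fates - 1):
                parent = _balanced_flip(rng, parent, spec.flip_prob)
                cols.append(parent)
        else:  # star: hidden root, every fate one edge away
            cols = [
                _balanced_flip(rng, root, spec.flip_prob)
                for _ in range(spec.n_fates)
            ]
        xi = np.column_stack(cols)
        panel = FatePanel(_tf_ids(spec.n_tfs), _fate_names(spec.n_fates), xi)
        try:
            correlation_matrix(panel, max_condition=spec.max_condition)
            return panel
        except SingularCorrelationError as exc:
            last_error = exc
    raise SingularCorrelationError(
        f"no valid panel in {spec.max_retries} attempts "
        f"(N={spec.n_tfs}, p={spec.n_fates}, f={spec.flip_prob}, "
        f"topology={spec.topology}): last failure: {last_error}"
    )


def synth_replicates(panel: FatePanel, spec: SyntheticSpec) -> RawExpressionTable:
    """Log-normal replicate expression consistent with a ±1 panel.

    log-expression = gene baseline + (delta/2) * xi + Normal(0, sigma),
    exponentiated.  Sample names are ``<fate>_r<j>``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n, p = panel.n_tfs, panel.n_fates
    baseline = rng.normal(0.0, spec.baseline_sd, size=n)
    xi = np.asarray(panel.xi, dtype=float)
    cols, names, fate_of = {}, [], {}
    for k, fate in enumerate(panel.fate_names):
        for r in range(spec.replicates):
            name = f"{fate}_r{r}"
            log_e = baseline + 0.5 * spec.delta * xi[:, k] + rng.normal(0.0, spec.sigma, size=n)
            cols[name] = np.exp(log_e)
            names.append(name)
            fate_of[name] = fate
    values = pd.DataFrame(cols, index=list(panel.tf_ids))[names]
    return RawExpressionTable(values=values, fate_of_sample=fate_of)


def synth_hybrid_profiles(
    panel: FatePanel,
    fate_subsets: Sequence[Sequence[str]],
    spec: SyntheticSpec,
) -> RawExpressionTable:
    """Noisy expression profiles of planted odd-majority hybrid states.

    One sample per subset, named ``hyb_<fate>+<fate>+...``; classification
    of the output should recover exactly the planted constituents.
    """
    rng = np.random.default_rng(spec.seed + 2)
    baseline = rng.normal(0.0, spec.baseline_sd, size=panel.n_tfs)
    cols, fate_of = {}, {}
    for subset in fate_subsets:
        mix = mixture_state(panel, subset).astype(float)
        name = "hyb_" + "+".join(subset)
        log_e = baseline + 0.5 * spec.delta * mix + rng.normal(0.0, spec.sigma, size=panel.n_tfs)
        cols[name] = np.exp(log_e)
        fate_of[name] = name
    values = pd.DataFrame(cols, index=list(panel.tf_ids))
    return RawExpressionTable(values=values, fate_of_sample=fate_of)


def spec_from_json(obj: dict) -> SyntheticSpec:
    """Build a spec from a plain dict (the CLI's JSON config)."""
    known = {f for f in SyntheticSpec.__dataclass_fields__}
    unknown = set(obj) - known
    if unknown:
        raise ValidationError(f"unknown synthetic-spec fields: {sorted(unknown)}")
    return SyntheticSpec(**obj)
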