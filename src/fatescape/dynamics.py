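"""Stochastic (Glauber) and deterministic dynamics on the fate landscape.

Time is counted in single-TF updates; one sweep is N updates.  Updates are
asynchronous: a uniformly random TF is chosen and resampled from the
heat-bath probability P(S_i = +1) = e^{beta h_i} / (e^{beta h_i} +
e^{-beta h_i}), with the self-coupling excluded from h_i so that, for
symmetric couplings and no signal term, the chain is exactly reversible
with respect to exp(-beta H).  Periodic "burst" noise — sign-flipping a
fixed fraction of TFs every few sweeps — mimics division-associated
epigenetic errors.  No mapping from update count to wall-clock biology is
attempted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import DimensionMismatchError, ValidationError
from .landscape import EpigeneticLandscape


@dataclass(frozen=True)
class DynamicsConfig:
    """Knobs of a Glauber run.

    beta : effective inverse noise (0 = coin flips, large = sign updates).
    n_sweeps : run length; 1 sweep = N single-TF updates.
    burst_fraction : fraction of TFs sign-flipped in each noise burst
        (0.02 in the basin-stability experiments; 0 disables bursts).
    burst_period_sweeps : sweeps between bursts.
    record_every : recording cadence, in sweeps.
    seed : RNG seed; trajectories are pure functions of (inputs, seed).
    """

    beta: float = 4.0
    n_sweeps: int = 50
    burst_fraction: float = 0.02
    burst_period_sweeps: int = 10
    record_every: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.beta < 0:
            raise ValidationError("beta must be nonnegative")
        if not 0 <= self.burst_fraction <= 1:
            raise ValidationError("burst_fraction must lie in [0, 1]")
        if self.burst_period_sweeps < 1 or self.record_every < 1 or self.n_sweeps < 0:
            raise ValidationError("sweep counts must be positive")


@dataclass(frozen=True)
class Trajectory:
    """Recorded states with their overlap/projection coordinates and energy."""

    times: np.ndarray          # update counts at each record
    states: np.ndarray         # (T, N) int8 ±1
    overlaps: np.ndarray       # (T, p)
    projections: np.ndarray    # (T, p)
    energies: np.ndarray       # (T,)
    fate_names: tuple

    def to_frame(self) -> pd.DataFrame:
        cols = {"update_index": self.times, "energy": self.energies}
        for k, f in enumerate(self.fate_names):
            cols[f"overlap_{f}"] = self.overlaps[:, k]
        for k, f in enumerate(self.fate_names):
            cols[f"projection_{f}"] = self.projections[:, k]
        return pd.DataFrame(cols)


def glauber_update_probability(h, beta: float):
    """Probability that the resampled spin is +1 given its local field."""
    if beta < 0:
        raise ValidationError("beta must be nonnegative")
    h = np.asarray(h, dtype=float)
    if not np.isfinite(h).all():
        raise ValidationError("local field must be finite")
    out = expit(2.0 * beta * h)
    return float(out) if out.ndim == 0 else out


def _check_state(s0, n):
    s0 = np.asarray(s0)
    if s0.shape != (n,) or not np.isin(s0, (-1, 1)).all():
        raise ValidationError("initial state must be a length-N ±1 vector")
    return s0.astype(float)


def _effective_operator(landscape, j=None, b_opt=None, c=None, d=None):
    """Total couplings (basin + signal) and total per-TF field."""
    m = np.array(landscape.coupling_ if j is None else j, dtype=float)
    if d is not None:
        m = m + landscape.dev_coupling(d)
    n = m.shape[0]
    b = np.zeros(n)
    if b_opt is not None:
        b_opt = np.asarray(b_opt, dtype=float)
        if b_opt.shape != (n,):
            raise DimensionMismatchError("b_opt must have length N")
        b = b + b_opt
    if c is not None:
        b = b + landscape.culture_field(c)
    return m, b


def simulate(
    s0,
    landscape: EpigeneticLandscape,
    config: DynamicsConfig,
    j: Optional[np.ndarray] = None,
    b_opt=None,
    c=None,
    d=None,
) -> Trajectory:
    """Asynchronous Glauber run from a ±1 state, with optional burst noise.

    ``j`` overrides the landscape couplings (e.g. a diluted, asymmetric
    matrix); ``b_opt``/``c``/``d`` switch on the three control fields.
    """
    j_eff = np.array(landscape.coupling_ if j is None else j, dtype=float)
    m, b = _effective_operator(landscape, j, b_opt, c, d)
    n = m.shape[0]
    s = _check_state(s0, n)
    rng = np.random.default_rng(config.seed)
    diag = np.diag(m).copy()
    n_burst = int(round(config.burst_fraction * n))

    records = [s.copy()]
    times = [0]
    idx_all = rng.integers(0, n, size=config.n_sweeps * n) if config.n_sweeps else np.empty(0, int)
    u_all = rng.random(config.n_sweeps * n) if config.n_sweeps else np.empty(0)
    two_beta = 2.0 * config.beta
    for sweep in range(config.n_sweeps):
        if (
            n_burst > 0
            and sweep > 0
            and sweep % config.burst_period_sweeps == 0
        ):
            flip = rng.choice(n, size=n_burst, replace=False)
            s[flip] = -s[flip]
        base = sweep * n
        for t in range(n):
            i = idx_all[base + t]
            h = m[i] @ s - diag[i] * s[i] + b[i]
            p_plus = 1.0 / (1.0 + np.exp(-two_beta * h)) if config.beta > 0 else 0.5
            s[i] = 1.0 if u_all[base + t] < p_plus else -1.0
        if (sweep + 1) % config.record_every == 0:
            records.append(s.copy())
            times.append((sweep + 1) * n)

    states = np.array(records)
    mm = landscape.overlaps(states)
    aa = landscape.transform(states)
    # energy per record, matching EnergyBreakdown term by term
    energies = -0.5 * np.einsum("ti,ij,tj->t", states, j_eff, states) - states @ b
    if d is not None:
        d_arr = np.asarray(d, dtype=float)
        energies = energies - n * np.einsum("tp,pq,tq->t", aa, d_arr, mm)
    return Trajectory(
        times=np.array(times),
        states=states.astype(np.int8),
        overlaps=mm,
        projections=aa,
        energies=energies,
        fate_names=landscape.fate_names_,
    )


@dataclass(frozen=True)
class RelaxResult:
    state: np.ndarray
    converged: bool
    two_cycle: bool
    n_sweeps: int
    sweep_states: Optional[np.ndarray] = None


def deterministic_relax(
    s0,
    landscape: EpigeneticLandscape,
    max_sweeps: int = 100,
    j: Optional[np.ndarray] = None,
    b_opt=None,
    c=None,
    d=None,
    seed: int = 0,
    record: bool = False,
) -> RelaxResult:
    """Zero-noise limit: sweeps of sign(h) updates in randomized order.

    Stops when a full sweep changes nothing (converged) or when a 2-cycle
    is detected (possible for asymmetric couplings).  A zero field resolves
    to +1, matching the binarization tie rule.
    """
    m, b = _effective_operator(landscape, j, b_opt, c, d)
    n = m.shape[0]
    s = _check_state(s0, n)
    rng = np.random.default_rng(seed)
    diag = np.diag(m).copy()
    prev = None
    prev2 = None
    history = [s.copy()] if record else None
    for sweep in range(max_sweeps):
        changed = False
        for i in rng.permutation(n):
            h = m[i] @ s - diag[i] * s[i] + b[i]
            new = 1.0 if h >= 0 else -1.0
            if new != s[i]:
                s[i] = new
                changed = True
        if record:
            history.append(s.copy())
        if not changed:
            return RelaxResult(
                s.astype(np.int8), True, False, sweep + 1,
                np.array(history, dtype=np.int8) if record else None,
            )
        if prev2 is not None and np.array_equal(s, prev2) and not np.array_equal(s, prev):
            return RelaxResult(
                s.astype(np.int8), False, True, sweep + 1,
                np.array(history, dtype=np.int8) if record else None,
            )
        prev2, prev = prev, s.copy()
    return RelaxResult(
        s.astype(np.int8), False, False, max_sweeps,
        np.array(history, dtype=np.int8) if record else None,
    )


def dilute_coupling(j: np.ndarray, fraction: float, seed: int) -> np.ndarray:
    """Randomly zero ``round(fraction * N^2)`` coupling entries.

    Entries are chosen uniformly over the whole matrix without symmetry
    pairing, so the result is generically asymmetric and breaks detailed
    balance (a pseudo-landscape).
    """
    if not 0 <= fraction < 1:
        raise ValidationError("dilution fraction must lie in [0, 1)")
    out = np.array(j, dtype=float)
    n2 = out.size
    k = int(round(fraction * n2))
    if k:
        rng = np.random.default_rng(seed)
        flat = rng.choice(n2, size=k, replace=False)
        out.flat[flat] = 0.0
    return out


def switch_fate(
    source: str,
    signal: dict,
    landscape: EpigeneticLandscape,
    config: DynamicsConfig,
) -> Trajectory:
    """Start at a named fate and drive it with a developmental signal.

    ``signal`` maps (target, source) fate-name pairs to strengths; the run
    starts at the source pattern and success is read off the final-state
    projections.
    """
    s0 = landscape.pattern(source)
    d = landscape.signal_matrix(signal)
    return simulate(s0, landscape, config, d=d)


def glauber_state_counts(
    j: np.ndarray,
    b: np.ndarray,
    beta: float,
    n_updates: int,
    burn_in: int,
    seed: int,
) -> np.ndarray:
    """Visit counts over all 2^N states of a long Glauber run (N <= 20).

    The chain uses the self-coupling-excluded field, so for symmetric J the
    stationary law is exactly the Boltzmann distribution of
    H = -1/2 S^T J S - b.S (up to the constant diagonal term).
    """
    n = j.shape[0]
    if n > 20:
        raise ValidationError("exhaustive state tracking limited to N <= 20")
    if beta < 0:
        raise ValidationError("beta must be nonnegative")
    rng = np.random.default_rng(seed)
    s = rng.choice([-1.0, 1.0], size=n)
    jz = np.array(j, dtype=float)
    np.fill_diagonal(jz, 0.0)
    code = int(sum(1 << i for i in range(n) if s[i] > 0))
    counts = np.zeros(2**n, dtype=np.int64)
    two_beta = 2.0 * beta
    chunk = 100_000
    done = 0
    from math import exp

    jrows = [jz[i] for i in range(n)]
    while done < n_updates:
        size = min(chunk, n_updates - done)
        idx = rng.integers(0, n, size=size)
        u = rng.random(size)
        for t in range(size):
            i = idx[t]
            h = jrows[i] @ s + b[i]
            p_plus = 1.0 / (1.0 + exp(-two_beta * h))
            new = 1.0 if u[t] < p_plus else -1.0
            if new != s[i]:
                s[i] = new
                code ^= 1 << i
            if done + t >= burn_in:
                counts[code] += 1
        done += size
    return counts


def boltzmann_distribution(j: np.ndarray, b: np.ndarray, beta: float) -> np.ndarray:
    """Exact Boltzmann law over all 2^N states, indexed by bit code (N <= 20)."""
    n = j.shape[0]
    if n > 20:
        raise ValidationError("exhaustive enumeration limited to N <= 20")
    states = all_states(n)
    jz = np.array(j, dtype=float)
    np.fill_diagonal(jz, 0.0)
    energies = -0.5 * np.einsum("ti,ij,tj->t", states, jz, states) - states @ b
    w = np.exp(-beta * (energies - energies.min()))
    return w / w.sum()


def all_states(n: int) -> np.ndarray:
    """All 2^n ±1 states; row index is the bit code (bit i set ⇔ S_i = +1)."""
    codes = np.arange(2**n, dtype=np.int64)
    bits = (codes[:, None] >> np.arange(n)) & 1
    return np.where(bits == 1, 1.0, -1.0)
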