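"""Exact continuous-time Markov chain of the particle-anchor-matrix system.

The state of a single nanoparticulate is the pair ``(n, s)``: ``n`` anchors
bound to the particle, ``s`` of which simultaneously crosslink it to the
matrix (``0 <= s <= n <= N``).  Six reaction channels connect the states:

====================  ==========================  =========================
transition            rate                        meaning
====================  ==========================  =========================
(n,s) -> (n+1,s)      (N-n) k_on                  free anchor binds particle
(n,0) -> (n+1,1)      (N-n) k_on'                 matrix-bound anchor
                                                  captures the free particle
                                                  (only from s = 0)
(n,s) -> (n-1,s)      (n-s) k_off                 non-crosslinking anchor
                                                  releases particle
(n,s) -> (n-1,s-1)    s k_off                     crosslinking anchor
                                                  releases particle
(n,s) -> (n,s+1)      g(s) (n-s) a_on             particle-bound anchor
                                                  binds matrix
(n,s) -> (n,s-1)      s a_off                     crosslink releases matrix
====================  ==========================  =========================

with ``g(0) = D_P/D_A`` (the complex must diffuse to the matrix, at the
particle's mobility) and ``g(s>=1) = C`` (intra-complex binding).  The
particle diffuses freely only while ``s = 0``, so the long-run fraction of
time spent with ``s = 0`` is exactly ``D_eff/D_P``.  This module builds the
generator and solves the stationary distribution densely; it is the exact
oracle against which the closed-form reduction and the stochastic
simulations are checked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import TrappingParameters, smoluchowski_rates


@dataclass(frozen=True)
class ChainSpec:
    """Enumerated (n, s) state space and transition-rate generator."""

    N: int
    states: tuple[tuple[int, int], ...]
    generator: np.ndarray
    k_on: float
    k_on_prime: float
    k_off: float
    a_on: float
    a_off: float
    C: float
    D_P: float
    D_A: float

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def index(self) -> dict[tuple[int, int], int]:
        return {st: i for i, st in enumerate(self.states)}

    @property
    def free_mask(self) -> np.ndarray:
        """Boolean mask of states with s == 0 (freely diffusing)."""
        return np.array([s == 0 for (_, s) in self.states])

    def transition_table(self) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
        """Per-state (targets, cumulative rates, total exit rate) for simulation."""
        targets, cumrates = [], []
        total = np.empty(self.n_states)
        for i in range(self.n_states):
            row = self.generator[i].copy()
            row[i] = 0.0
            nz = np.flatnonzero(row)
            targets.append(nz)
            cumrates.append(np.cumsum(row[nz]))
            total[i] = row[nz].sum()
        return targets, cumrates, total

    def to_dataframe(self) -> pd.DataFrame:
        """Nonzero transitions as a tidy table (n, s, n_to, s_to, rate)."""
        rows = []
        for i, (n, s) in enumerate(self.states):
            for j in np.flatnonzero(self.generator[i]):
                if i == j:
                    continue
                n2, s2 = self.states[j]
                rows.append((n, s, n2, s2, self.generator[i, j]))
        return pd.DataFrame(rows, columns=["n", "s", "n_to", "s_to", "rate"])


@dataclass(frozen=True)
class StationaryResult:
    """Stationary distribution of the chain and the resulting D_eff/D_P."""

    spec: ChainSpec
    pi: np.ndarray
    prob_free: float
    absorbing: bool = False
    note: str = ""

    @property
    def d_eff_ratio(self) -> float:
        return self.prob_free

    def to_dataframe(self) -> pd.DataFrame:
        n, s = zip(*self.spec.states)
        return pd.DataFrame({"n": n, "s": s, "probability": self.pi})

    def marginal_s_given_n(self, n: int) -> np.ndarray:
        """Conditional stationary distribution of s given n (length n+1)."""
        out = np.zeros(n + 1)
        for i, (ni, si) in enumerate(self.spec.states):
            if ni == n:
                out[si] = self.pi[i]
        tot = out.sum()
        if tot == 0:
            raise ValueError(f"state n={n} has zero stationary probability")
        return out / tot


def enumerate_states(N: int) -> tuple[tuple[int, int], ...]:
    """All (n, s) with 0 <= s <= n <= N; (N+1)(N+2)/2 states."""
    return tuple((n, s) for n in range(N + 1) for s in range(n + 1))


def build_chain(p: TrappingParameters) -> ChainSpec:
    """Assemble the generator matrix of the (n, s) chain for parameters ``p``."""
    if p.N < 0:
        raise ValueError("N must be >= 0")
    if p.D_A <= 0:
        raise ValueError("D_A must be > 0 (g(0) = D_P/D_A)")
    k_on, k_on_prime = smoluchowski_rates(p)
    states = enumerate_states(p.N)
    index = {st: i for i, st in enumerate(states)}
    G = np.zeros((len(states), len(states)))

    def g(s: int) -> float:
        return p.D_P / p.D_A if s == 0 else p.C

    for (n, s) in states:
        i = index[(n, s)]
        if n < p.N:
            G[i, index[(n + 1, s)]] += (p.N - n) * k_on
            if s == 0:
                G[i, index[(n + 1, 1)]] += (p.N - n) * k_on_prime
        if n > 0:
            if n - s > 0:
                G[i, index[(n - 1, s)]] += (n - s) * p.k_off
            if s > 0:
                G[i, index[(n - 1, s - 1)]] += s * p.k_off
        if s < n:
            G[i, index[(n, s + 1)]] += g(s) * (n - s) * p.a_on
        if s > 0:
            G[i, index[(n, s - 1)]] += s * p.a_off
    np.fill_diagonal(G, G.diagonal() - G.sum(axis=1))
    return ChainSpec(
        N=p.N, states=states, generator=G,
        k_on=k_on, k_on_prime=k_on_prime, k_off=p.k_off,
        a_on=p.a_on, a_off=p.a_off, C=p.C, D_P=p.D_P, D_A=p.D_A,
    )


def stationary(spec: ChainSpec) -> StationaryResult:
    """Solve pi G = 0, sum(pi) = 1 by a dense least-squares null-space solve.

    With ``k_off = 0`` the particle can never shed anchors, so any trapping
    is permanent; the long-run answer is reported explicitly instead of a
    stationary vector of the (then reducible) chain.
    """
    if spec.k_off == 0 and spec.N > 0 and (spec.k_on > 0 or spec.k_on_prime > 0):
        return _absorbing_limit(spec)
    A = np.vstack([spec.generator.T, np.ones(spec.n_states)])
    b = np.zeros(spec.n_states + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    prob_free = float(pi[spec.free_mask].sum())
    return StationaryResult(spec=spec, pi=pi, prob_free=prob_free)


def _absorbing_limit(spec: ChainSpec) -> StationaryResult:
    """Long-run free fraction when anchor release is impossible (k_off = 0).

    The particle accumulates anchors until n = N and stays there; the
    long-run behavior is the stationary s-distribution of the birth-death
    subchain at n = N (all mass at s with no escape when a_off = 0 too).
    """
    N = spec.N
    pi = np.zeros(spec.n_states)
    index = spec.index
    if spec.a_off == 0 and (spec.a_on > 0 or spec.k_on_prime > 0):
        # crosslinks, once formed, are permanent: particle ends at s >= 1
        pi[index[(N, N if spec.a_on > 0 else 1)]] = 1.0
        prob_free = 0.0
        note = "k_off = 0 and a_off = 0: trapping is absorbing; D_eff -> 0"
    else:
        # birth-death in s at n = N
        w = np.zeros(N + 1)
        w[0] = 1.0
        if spec.a_on > 0:  # a_off > 0 here, else the branch above applied
            for s in range(N):
                g = spec.D_P / spec.D_A if s == 0 else spec.C
                w[s + 1] = w[s] * g * (N - s) * spec.a_on / ((s + 1) * spec.a_off)
        w /= w.sum()
        for s in range(N + 1):
            pi[index[(N, s)]] = w[s]
        prob_free = float(w[0])
        note = "k_off = 0: chain absorbs into n = N; reporting the s-subchain there"
    warnings.warn(note, stacklevel=3)
    return StationaryResult(spec=spec, pi=pi, prob_free=prob_free, absorbing=True, note=note)


def d_eff_exact(p: TrappingParameters) -> float:
    """D_eff/D_P from the exact stationary free-state probability."""
    return stationary(build_chain(p)).prob_free
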