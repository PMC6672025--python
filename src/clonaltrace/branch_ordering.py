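"""Temporal ordering of mutations within a clone-tree branch.

Mutations arising earlier on a branch are carried by more cells, so
within a branch their VAFs tend to be higher in every sample.  Each pair
of mutations is scored per sample (1 / 0 / 0.5 for higher / lower / tied
VAF), the scores are summed into a wins matrix, and a Bradley-Terry
model with a Gamma(a, ·) prior on the abilities (a = 1.1) is fitted by a
minorize-maximize iteration.  P(v1 occurred before v2) = pi1/(pi1+pi2);
abilities express confidence in the ordering, not time intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

DEFAULT_PRIOR_SHAPE = 1.1


@dataclass
class WinsMatrix:
    """Pairwise win tallies over all samples for one branch's mutations."""

    labels: list[str]
    W: np.ndarray  # (m, m), zero diagonal
    branch: str | None = None

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        m = len(self.labels)
        if self.W.shape != (m, m):
            raise ValueError("wins matrix shape does not match labels")
        if (self.W < 0).any():
            raise ValueError("wins matrix must be non-negative")
        if np.abs(np.diag(self.W)).max(initial=0.0) > 0:
            raise ValueError("wins matrix must have a zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.labels, columns=self.labels)


@dataclass
class AbilityVector:
    """Fitted Bradley-Terry abilities, normalized to sum to len(labels)."""

    labels: list[str]
    pi: np.ndarray
    a: float = DEFAULT_PRIOR_SHAPE
    converged: bool = True
    n_iter: int = 0

    def __getitem__(self, label: str) -> float:
        return float(self.pi[self.labels.index(label)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.pi, index=self.labels, name="ability")


def pairwise_wins(vafs: pd.DataFrame, branch: str | None = None) -> WinsMatrix:
    """Wins matrix from a mutations x samples VAF table.

    Per sample, the earlier-looking mutation of a pair scores 1, the
    other 0; exact VAF ties score 0.5 each.  Samples where either VAF is
    undefined (NaN, e.g. zero depth) are skipped for that pair.
    W_jk sums the scores of mutation j against mutation k over samples;
    the diagonal is zero.
    """
    if vafs.shape[0] < 2:
        raise ValueError("need at least 2 mutations to compare")
    x = vafs.to_numpy(dtype=float)
    defined = ~np.isnan(x)
    both = defined[:, None, :] & defined[None, :, :]  # (m, m, n)
    with np.errstate(invalid="ignore"):
        gt = (x[:, None, :] > x[None, :, :]) & both
        eq = (x[:, None, :] == x[None, :, :]) & both
    W = gt.sum(axis=2) + 0.5 * eq.sum(axis=2)
    np.fill_diagonal(W, 0.0)
    return WinsMatrix(labels=list(vafs.index), W=W, branch=branch)


def log_posterior(W: np.ndarray, pi: np.ndarray, a: float = DEFAULT_PRIOR_SHAPE) -> float:
    """Unnormalized log-posterior of abilities under the wins model.

    sum_{j != k} W_jk log(pi_j / (pi_j + pi_k)) + (a - 1) sum_j log pi_j,
    evaluated at the given (typically sum-normalized) abilities.
    """
    pi = np.asarray(pi, dtype=float)
    s = pi[:, None] + pi[None, :]
    with np.errstate(divide="ignore"):
        ll = W * (np.log(pi)[:, None] - np.log(s))
    np.fill_diagonal(ll, 0.0)
    return float(ll.sum() + (a - 1.0) * np.log(pi).sum())


def fit_bt_map(
    W: WinsMatrix | np.ndarray,
    a: float = DEFAULT_PRIOR_SHAPE,
    tol: float = 1e-10,
    max_iter: int = 20_000,
) -> AbilityVector:
    """MAP Bradley-Terry abilities by a sum-constrained MM iteration.

    Maximizes the log-posterior over abilities constrained to sum to the
    number of mutations (abilities are identified only up to scale; the
    prior shape ``a`` > 1 keeps the maximizer finite and the comparison
    graph effectively connected).  Each sweep maximizes the standard MM
    surrogate exactly on the constraint set via a one-dimensional
    Lagrange root-solve, so the log-posterior never decreases.
    """
    if isinstance(W, WinsMatrix):
        labels, Wm = W.labels, W.W
    else:
        Wm = np.asarray(W, dtype=float)
        labels = [f"v{i + 1}" for i in range(Wm.shape[0])]
    if (Wm < 0).any():
        raise ValueError("wins matrix must be non-negative")
    if a <= 1.0:
        raise ValueError("prior shape a must exceed 1 for a proper MAP")
    m = Wm.shape[0]
    if m == 1:
        return AbilityVector(labels=labels, pi=np.array([1.0]), a=a)

    alpha = (a - 1.0) + Wm.sum(axis=1)  # prior pseudo-wins + observed wins
    N = Wm + Wm.T  # comparisons per pair
    pi = np.full(m, 1.0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s = pi[:, None] + pi[None, :]
        np.fill_diagonal(s, 1.0)
        beta = (N / s).sum(axis=1)

        def gap(lam):
            return (alpha / (beta + lam)).sum() - m

        # gap() is strictly decreasing on (-min beta, inf); alpha > 0 makes
        # gap(lo) -> +inf at the left end and gap(hi) <= 0 by construction
        lo = -beta.min() + 1e-12
        hi = alpha.sum() / m - beta.min() + 1e-12
        lam = brentq(gap, lo, hi, xtol=1e-14, rtol=8.9e-16)
        new = alpha / (beta + lam)
        new *= m / new.sum()
        delta = np.abs(new - pi) / np.maximum(pi, 1e-300)
        pi = new
        if delta.max() < tol:
            converged = True
            break
    return AbilityVector(labels=labels, pi=pi, a=a, converged=converged, n_iter=it)


def order_probability(pi_1: float, pi_2: float) -> float:
    """P(v1 occurred before v2) = pi1 / (pi1 + pi2)."""
    if pi_1 <= 0 or pi_2 <= 0:
        raise ValueError("abilities must be positive")
    return pi_1 / (pi_1 + pi_2)


def rank_mutations(abilities: AbilityVector, tie_tol: float = 0.0) -> pd.DataFrame:
    """Descending-ability ranks (rank 1 = earliest), with tie groups.

    Mutations with exactly equal abilities share a tie group and the same
    rank; within a tie group the input (coordinate) order is kept for
    display only.  The result is invariant to the input order of
    mutations.
    """
    order = sorted(range(len(abilities.labels)),
                   key=lambda i: (-abilities.pi[i], abilities.labels[i]))
    rows = []
    rank = 0
    tie_group = -1
    prev = None
    for display_pos, i in enumerate(order, start=1):
        ability = float(abilities.pi[i])
        if prev is None or abs(prev - ability) > tie_tol:
            rank = display_pos
            tie_group += 1
        rows.append((abilities.labels[i], rank, ability, tie_group))
        prev = ability
    df = pd.DataFrame(rows, columns=["mutation", "rank", "ability", "tie_group"])
    tied = df.groupby("tie_group")["mutation"].transform("count") > 1
    df["tied"] = tied
    return df


def order_branch(
    vafs: pd.DataFrame,
    branch: str | None = None,
    a: float = DEFAULT_PRIOR_SHAPE,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Full per-branch ordering: wins -> MAP abilities -> ranked timeline.

    Returns a timeline table (branch, rank, mutation, ability, and the
    maximum pairwise ordering probability against any other mutation).
    A single-mutation branch yields an empty table: there is nothing to
    order.
    """
    if vafs.shape[0] < 2:
        return pd.DataFrame(columns=["branch", "rank", "mutation", "ability",
                                     "max_pair_probability", "tied"])
    wins = pairwise_wins(vafs, branch=branch)
    abilities = fit_bt_map(wins, a=a, tol=tol)
    ranked = rank_mutations(abilities)
    pi = abilities.pi
    probs = pi[:, None] / (pi[:, None] + pi[None, :])
    np.fill_diagonal(probs, 0.0)
    max_prob = {abilities.labels[i]: float(probs[i].max()) for i in range(len(pi))}
    ranked["max_pair_probability"] = ranked["mutation"].map(max_prob)
    ranked.insert(0, "branch", branch if branch is not None else "")
    return ranked[["branch", "rank", "mutation", "ability", "max_pair_probability", "tied"]]


def write_timeline(timelines: pd.DataFrame, path) -> Path:
    path = Path(path)
    timelines.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
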