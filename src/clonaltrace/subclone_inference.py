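"""Subclonal deconvolution: small-tree search, binomial fractions, BIC.

A clone tree places each somatic mutation on the edge above one clone;
the mutation is then carried by every clone in the subtree below that
edge.  Given per-sample clone fractions P (rows: normal + clones,
columns sum to 1), the expected VAF of a mutation is its carried copy
count (multiplicity 1) over the local average copy number (2 at diploid
sites, the bulk total from the CNV bundle inside curated segments),
times the summed carrier fractions.  Observed alt counts are binomial
at that expected VAF.

Fitting alternates exact per-mutation edge re-assignment with
projected-gradient ascent of P on per-sample simplexes, from multiple
seeded restarts (k-means on VAF profiles seeds the assignment).  The
number of subclones is chosen by a BIC elbow rule: the smallest K after
which adding a clone yields only a marginal BIC increase.  Mutations
withheld from tree building are assigned post hoc by maximum
likelihood, with hypothetical zero-length ancestor edges permitted
above any set of sibling subtrees.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ConfigurationError, ContractViolation

NORMAL = "normal"

VAF_FLOOR = 1e-6
VAF_CEIL = 1.0 - 1e-6


@dataclass
class FitConfig:
    """Settings for the subclone fit and model selection."""

    K_range: tuple[int, int] = (1, 5)
    restarts: int = 10
    max_iter: int = 200
    tol: float = 1e-6
    elbow_fraction: float = 0.05
    seed: int = 0
    dedup_topologies: bool = True

    def __post_init__(self):
        lo, hi = self.K_range
        if not (1 <= lo <= hi <= 6):
            raise ConfigurationError("K_range must lie within [1, 6]")
        if self.tol <= 0:
            raise ConfigurationError("tol must be positive")


@dataclass
class CloneTree:
    """A fitted clone tree: topology, mutation placement, fractions, score."""

    K: int
    parents: dict[str, str]
    assignments: dict[str, str]  # mutation id -> edge (child-clone key)
    P: pd.DataFrame  # (K+1) x N, row 0 "normal", columns sum to 1
    log_likelihood: float = float("-inf")
    bic: float = float("-inf")
    converged: bool = True
    n_modeled: int = 0
    ll_trace: list[float] = field(default_factory=list, repr=False)

    @property
    def clones(self) -> list[str]:
        return sorted(self.parents)

    @property
    def samples(self) -> list[str]:
        return list(self.P.columns)

    def children(self, node: str) -> list[str]:
        return sorted(c for c, p in self.parents.items() if p == node)

    def subtree(self, clone: str) -> frozenset[str]:
        out, stack = set(), [clone]
        while stack:
            node = stack.pop()
            out.add(node)
            stack.extend(self.children(node))
        return frozenset(out)

    def edge_mutations(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {c: [] for c in self.clones}
        for m, e in sorted(self.assignments.items()):
            out[e].append(m)
        return out

    def validate(self) -> None:
        cols = self.P.sum(axis=0)
        if not np.allclose(cols, 1.0, atol=1e-9):
            raise ConfigurationError("P columns must sum to 1")
        if ((self.P < -1e-12) | (self.P > 1 + 1e-12)).any().any():
            raise ConfigurationError("P entries must lie in [0, 1]")
        for m, e in self.assignments.items():
            if e not in self.parents:
                raise ConfigurationError(f"mutation {m} assigned to unknown edge {e}")

    def to_json(self) -> str:
        return json.dumps({
            "K": self.K,
            "parents": self.parents,
            "assignments": self.assignments,
            "P": {"index": list(self.P.index), "columns": list(self.P.columns),
                  "values": self.P.round(10).to_numpy().tolist()},
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "converged": self.converged,
            "n_modeled": self.n_modeled,
        }, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CloneTree":
        doc = json.loads(text)
        P = pd.DataFrame(doc["P"]["values"], index=doc["P"]["index"],
                         columns=doc["P"]["columns"])
        return cls(K=doc["K"], parents=doc["parents"], assignments=doc["assignments"],
                   P=P, log_likelihood=doc["log_likelihood"], bic=doc["bic"],
                   converged=doc["converged"], n_modeled=doc["n_modeled"])


# ---------------------------------------------------------------------------
# topology enumeration


def _parent_vectors(K: int):
    """All acyclic parent assignments over clone1..cloneK rooted at normal."""
    clones = [f"clone{i + 1}" for i in range(K)]
    options = [NORMAL] + clones
    for combo in itertools.product(options, repeat=K):
        parents = dict(zip(clones, combo))
        if any(parents[c] == c for c in clones):
            continue
        ok = True
        for c in clones:
            seen, node = set(), c
            while node != NORMAL:
                if node in seen:
                    ok = False
                    break
                seen.add(node)
                node = parents[node]
            if not ok:
                break
        if ok:
            yield parents


def _shape_hash(parents: Mapping[str, str]) -> str:
    """Canonical form of the rooted tree shape (labels ignored)."""
    children: dict[str, list[str]] = {}
    for c, p in parents.items():
        children.setdefault(p, []).append(c)

    def canon(node: str) -> str:
        return "(" + ",".join(sorted(canon(c) for c in children.get(node, []))) + ")"

    return canon(NORMAL)


def enumerate_topologies(K: int, dedup: bool = False,
                         sample: int | None = None, seed: int = 0) -> list[dict[str, str]]:
    """Rooted labeled clone-tree topologies on K clones with a normal root.

    Exhaustive for K <= 5 (there are (K+1)**(K-1) labeled trees);
    ``dedup=True`` keeps one representative per unlabeled shape, which
    suffices when clone labels are exchangeable (as in fitting).  For
    K > 5 pass ``sample`` to draw random topologies instead.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > 5 and sample is None:
        raise ValueError("exhaustive enumeration supports K <= 5; "
                         "pass sample=<n> to use sampling mode")
    if sample is not None:
        from .synthetic_tumor import _random_rooted_tree
        rng = np.random.default_rng(seed)
        seen, out = set(), []
        for _ in range(sample * 20):
            parents = _random_rooted_tree(K, rng)
            key = _shape_hash(parents) if dedup else tuple(sorted(parents.items()))
            if key not in seen:
                seen.add(key)
                out.append(parents)
            if len(out) >= sample:
                break
        return out
    out, seen = [], set()
    for parents in _parent_vectors(K):
        if dedup:
            key = _shape_hash(parents)
            if key in seen:
                continue
            seen.add(key)
        out.append(parents)
    return out


# ---------------------------------------------------------------------------
# likelihood machinery


def _carrier_matrix(parents: Mapping[str, str], clones: Sequence[str]) -> np.ndarray:
    """(E, K) indicator: edge above clone e is carried by clone k."""
    children: dict[str, list[str]] = {}
    for c, p in parents.items():
        children.setdefault(p, []).append(c)
    K = len(clones)
    idx = {c: i for i, c in enumerate(clones)}
    C = np.zeros((K, K))
    for e, clone in enumerate(clones):
        stack = [clone]
        while stack:
            node = stack.pop()
            C[e, idx[node]] = 1.0
            stack.extend(children.get(node, []))
    return C


def _inverse_total_cn(matrix, bundle, samples: Sequence[str]) -> np.ndarray:
    """(M, N) per-mutation, per-sample 1/average-copies factor.

    Diploid mutations get 1/2; mutations inside a curated segment get
    1/(W_M + W_m) for that sample, clamped away from zero.
    """
    M = len(matrix.variants)
    N = len(samples)
    inv = np.full((M, N), 0.5)
    if bundle is None or not bundle.segments:
        return inv
    total = (bundle.wm + bundle.wmin).clip(lower=0.5)
    seg_of = bundle.Y.to_numpy().argmax(axis=1)
    n_seg = len(bundle.segments)
    for vi in range(M):
        si = seg_of[vi]
        if si < n_seg:
            label = bundle.Y.columns[si]
            for ni, s in enumerate(samples):
                inv[vi, ni] = 1.0 / float(total.loc[label, s])
    return inv


def expected_vaf(tree: CloneTree, bundle, variant_index: int, sample: str,
                 matrix=None) -> float:
    """Expected VAF of one assigned mutation in one sample."""
    if matrix is None:
        raise ConfigurationError("matrix required to resolve mutation ids")
    mid = matrix.variant_label(variant_index)
    edge = tree.assignments.get(mid)
    if edge is None:
        raise ContractViolation(f"mutation {mid} is not assigned to an edge")
    carriers = sorted(tree.subtree(edge))
    ccf = float(tree.P.loc[carriers, sample].sum())
    inv = _inverse_total_cn(matrix, bundle, tree.samples)
    ni = tree.samples.index(sample)
    return float(np.clip(inv[variant_index, ni] * ccf, VAF_FLOOR, VAF_CEIL))


def _loglik_edges(alt, depth, inv_t, ccf_edges):
    """(M, E) binomial log-likelihood of each mutation on each edge.

    ``ccf_edges`` is (E, N); ``inv_t`` is (M, N).  The binomial constant
    is omitted (identical for every edge and K).
    """
    p = np.clip(inv_t[:, None, :] * ccf_edges[None, :, :], VAF_FLOOR, VAF_CEIL)
    return (alt[:, None, :] * np.log(p)
            + (depth - alt)[:, None, :] * np.log1p(-p)).sum(axis=2)


def _project_columns_to_simplex(P: np.ndarray) -> np.ndarray:
    """Euclidean projection of each column onto the probability simplex."""
    K, N = P.shape
    out = np.empty_like(P)
    for j in range(N):
        v = P[:, j]
        u = np.sort(v)[::-1]
        css = np.cumsum(u) - 1.0
        rho = np.flatnonzero(u - css / np.arange(1, K + 1) > 0)[-1]
        theta = css[rho] / (rho + 1.0)
        out[:, j] = np.maximum(v - theta, 0.0)
    return out


def _binom_constant(alt, depth) -> float:
    return float((gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)).sum())


def fit_clone_fractions(
    parents: Mapping[str, str],
    matrix,
    bundle=None,
    config: FitConfig | None = None,
    mutations: Sequence[str] | None = None,
) -> CloneTree:
    """Fit clone fractions and mutation placement for a fixed topology.

    Coordinate ascent: (a) each mutation is re-assigned to the edge
    maximizing its summed binomial log-likelihood given P; (b) P is
    improved by projected-gradient ascent on per-sample simplexes given
    the assignments (steps are only accepted when the total
    log-likelihood does not decrease, so the objective is monotone).
    The best of ``config.restarts`` seeded restarts is returned, with
    the full-likelihood value (binomial constants included) and its BIC
    BIC = logL - 0.5 * (K*N) * log(modeled mutations * N).
    """
    config = config or FitConfig()
    clones = sorted(parents)
    K = len(clones)
    samples = matrix.tumor_samples
    N = len(samples)
    sample_idx = [matrix.sample_index(s) for s in samples]

    all_ids = [matrix.variant_label(i) for i in range(len(matrix.variants))]
    if mutations is None:
        mutations = all_ids
    keep = [all_ids.index(m) for m in mutations]
    alt = matrix.alt_counts[np.ix_(keep, sample_idx)].astype(float)
    depth = matrix.depth[np.ix_(keep, sample_idx)].astype(float)
    M = len(keep)
    if M < 1:
        raise ValueError("need at least one mutation to fit")

    inv_t_full = _inverse_total_cn(matrix, bundle, samples)
    inv_t = inv_t_full[keep]
    C = _carrier_matrix(parents, clones)  # (E=K, K)
    const = _binom_constant(alt, depth)

    with np.errstate(invalid="ignore", divide="ignore"):
        vaf_obs = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)

    def total_ll(P_clones, assign_idx):
        ccf_edges = C @ P_clones  # (E, N)
        p = np.clip(inv_t * ccf_edges[assign_idx], VAF_FLOOR, VAF_CEIL)
        return float((alt * np.log(p) + (depth - alt) * np.log1p(-p)).sum())

    rng_master = np.random.default_rng(config.seed)

    # Initialization: k-means clusters of VAF profiles are mapped onto the
    # K edges.  Every cluster -> edge permutation is scored by the
    # likelihood of the tree-consistent P implied by the cluster-mean
    # CCFs (p_clone = ccf_edge - sum of child-edge ccfs); restarts walk
    # the permutations from best to worst, then fall back to random
    # starts.  This makes the labeled global optimum reachable even when
    # several edges have similar subtree sizes.
    child_idx = [[clones.index(c) for c, p in parents.items() if p == clone]
                 for clone in clones]
    inits: list[tuple[np.ndarray, np.ndarray]] = []
    if M >= K > 1:
        from sklearn.cluster import KMeans
        km = KMeans(n_clusters=K, n_init=3, random_state=int(config.seed % (2**31)))
        labels = km.fit_predict(vaf_obs)
        cluster_mean = np.stack([
            vaf_obs[labels == k].mean(axis=0) if (labels == k).any() else np.zeros(N)
            for k in range(K)
        ])
        scored = []
        for perm in itertools.permutations(range(K)):
            perm = np.asarray(perm)
            # perm[cluster] = edge; ccf of edge e = 2 * mean VAF of its cluster
            ccf = np.empty((K, N))
            ccf[perm] = 2.0 * np.clip(cluster_mean, 0.0, 0.5)
            P0 = np.stack([ccf[e] - sum(ccf[c] for c in child_idx[e])
                           for e in range(K)])
            P0 = np.clip(P0, 1e-4, 1.0)
            total = P0.sum(axis=0)
            over = total > 0.999
            P0[:, over] *= 0.999 / total[over]
            scored.append((total_ll(P0, perm[labels]), P0, perm[labels]))
        scored.sort(key=lambda t: -t[0])
        inits = [(P0, a) for _, P0, a in scored]

    best = None
    for restart in range(max(config.restarts, 1)):
        rng = np.random.default_rng(rng_master.integers(0, 2**31))
        if restart < len(inits):
            P_clones, assign_idx = inits[restart][0].copy(), inits[restart][1].copy()
        else:
            assign_idx = rng.integers(0, K, size=M)
            P_clones = rng.dirichlet(np.ones(K + 1), size=N).T[1:]  # (K, N)

        ll = total_ll(P_clones, assign_idx)
        trace = [ll]
        converged = False
        step = 0.05
        for _ in range(config.max_iter):
            # (b) projected-gradient ascent on P given assignments
            for _inner in range(8):
                ccf_edges = C @ P_clones
                p = np.clip(inv_t * ccf_edges[assign_idx], VAF_FLOOR, VAF_CEIL)
                g_site = inv_t * (alt / p - (depth - alt) / (1.0 - p))  # (M, N)
                g_edges = np.zeros((K, N))
                np.add.at(g_edges, assign_idx, g_site)
                grad = C.T @ g_edges  # (K, N) wrt clone rows
                gnorm = np.abs(grad).max()
                if gnorm < 1e-12:
                    break
                improved = False
                s = step
                for _bt in range(25):
                    # project the full (normal + clones) column; normal has zero grad
                    cand_full = np.vstack([1.0 - P_clones.sum(axis=0), P_clones])
                    cand_full[1:] += s * grad / gnorm
                    cand_full = _project_columns_to_simplex(cand_full)
                    cand = cand_full[1:]
                    cand_ll = total_ll(cand, assign_idx)
                    if cand_ll > ll + 1e-12:
                        P_clones, ll = cand, cand_ll
                        improved = True
                        step = min(s * 1.5, 0.5)
                        break
                    s *= 0.5
                if not improved:
                    break
            # (a) exact edge re-assignment given P
            ll_me = _loglik_edges(alt, depth, inv_t, C @ P_clones)
            assign_idx = ll_me.argmax(axis=1)
            ll_new = total_ll(P_clones, assign_idx)
            trace.append(ll_new)
            if ll_new < ll - 1e-6 * max(abs(ll), 1.0):  # pragma: no cover
                raise AssertionError("coordinate ascent decreased the log-likelihood")
            if abs(ll_new - ll) < config.tol * max(abs(ll), 1.0):
                ll = ll_new
                converged = True
                break
            ll = ll_new
        if best is None or ll > best[0]:
            best = (ll, P_clones.copy(), assign_idx.copy(), converged, trace)

    ll, P_clones, assign_idx, converged, trace = best
    P_full = np.vstack([1.0 - P_clones.sum(axis=0), P_clones])
    P_full = np.clip(P_full, 0.0, 1.0)
    P_full /= P_full.sum(axis=0, keepdims=True)
    P = pd.DataFrame(P_full, index=[NORMAL] + clones, columns=samples)
    full_ll = ll + const
    bic = full_ll - 0.5 * (K * N) * math.log(max(M * N, 2))
    tree = CloneTree(
        K=K, parents=dict(parents),
        assignments={mutations[i]: clones[assign_idx[i]] for i in range(M)},
        P=P, log_likelihood=full_ll, bic=bic, converged=converged,
        n_modeled=M, ll_trace=[t + const for t in trace],
    )
    tree.validate()
    return tree


def fit_best_topology(K: int, matrix, bundle=None, config: FitConfig | None = None,
                      mutations: Sequence[str] | None = None) -> CloneTree:
    """Best fit over all clone-tree shapes with K clones."""
    config = config or FitConfig()
    topologies = enumerate_topologies(K, dedup=config.dedup_topologies)
    best = None
    for ti, parents in enumerate(topologies):
        sub = FitConfig(K_range=config.K_range, restarts=config.restarts,
                        max_iter=config.max_iter, tol=config.tol,
                        elbow_fraction=config.elbow_fraction,
                        seed=(config.seed * 1_000_003 + ti) % (2**31),
                        dedup_topologies=config.dedup_topologies)
        fit = fit_clone_fractions(parents, matrix, bundle, sub, mutations)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    return best


def select_model(fits: Mapping[int, CloneTree] | Sequence[CloneTree],
                 config: FitConfig | None = None) -> CloneTree:
    """BIC elbow selection of the number of subclones.

    Scanning K upward, the first step whose BIC increase falls below
    ``elbow_fraction`` of the previous step's increase marks the elbow;
    the model before that step is selected.  With no elbow, the
    BIC-maximal K wins.  BIC ties and non-increases resolve toward the
    smallest K (the penalty grows with K at fixed data).
    """
    config = config or FitConfig()
    if not isinstance(fits, Mapping):
        fits = {f.K: f for f in fits}
    ks = sorted(fits)
    if len(ks) == 1:
        return fits[ks[0]]
    bic = {k: fits[k].bic for k in ks}
    deltas = {ks[i]: bic[ks[i]] - bic[ks[i - 1]] for i in range(1, len(ks))}
    prev_delta = None
    for k in ks[1:]:
        d = deltas[k]
        if d <= 0:
            return fits[ks[ks.index(k) - 1]]
        if prev_delta is not None and prev_delta > 0 and d < config.elbow_fraction * prev_delta:
            return fits[ks[ks.index(k) - 1]]
        prev_delta = d
    return fits[max(ks, key=lambda k: (bic[k], -k))]


def fit_and_select(matrix, bundle=None, config: FitConfig | None = None,
                   mutations: Sequence[str] | None = None) -> tuple[CloneTree, dict[int, CloneTree]]:
    """Fit every K in the configured range and select the model."""
    config = config or FitConfig()
    lo, hi = config.K_range
    fits = {K: fit_best_topology(K, matrix, bundle, config, mutations)
            for K in range(lo, hi + 1)}
    return select_model(fits, config), fits


def topology_automorphisms(parents: Mapping[str, str]) -> list[dict[str, str]]:
    """Clone relabelings that leave the rooted topology unchanged."""
    clones = sorted(parents)
    out = []
    for perm in itertools.permutations(clones):
        mp = dict(zip(clones, perm))
        mp[NORMAL] = NORMAL
        if all(parents[mp[c]] == mp[parents[c]] for c in clones):
            out.append({c: mp[c] for c in clones})
    return out


def fraction_rmse(truth_fractions: pd.DataFrame, truth_parents: Mapping[str, str],
                  fit: CloneTree) -> float:
    """RMSE between fitted and true clone fractions.

    Minimized over topology automorphisms: clones in symmetric positions
    (e.g. sibling leaves) are exchangeable in the likelihood, so their
    labels carry no information.
    """
    clones = sorted(truth_parents)
    P_true = truth_fractions.loc[[NORMAL] + clones].to_numpy()
    best = np.inf
    for mp in topology_automorphisms(truth_parents):
        rows = [NORMAL] + [mp[c] for c in clones]
        P_fit = fit.P.loc[rows, truth_fractions.columns].to_numpy()
        best = min(best, float(np.sqrt(((P_fit - P_true) ** 2).mean())))
    return best


# ---------------------------------------------------------------------------
# post-hoc assignment and reporting


def _candidate_edges(tree: CloneTree) -> dict[str, frozenset[str]]:
    """Real edges plus hypothetical ancestor edges above sibling subtrees."""
    cands = {c: tree.subtree(c) for c in tree.clones}
    for node in [NORMAL] + tree.clones:
        kids = tree.children(node)
        if len(kids) < 2:
            continue
        for r in range(2, len(kids) + 1):
            for combo in itertools.combinations(kids, r):
                carriers = frozenset().union(*(tree.subtree(c) for c in combo))
                key = "ancestor(" + "+".join(sorted(combo)) + ")"
                if carriers not in cands.values():
                    cands[key] = carriers
    return cands


def posthoc_assign(tree: CloneTree, matrix, mutations: Sequence[str],
                   bundle=None, noise_rate: float = 1e-3) -> pd.DataFrame:
    """Maximum-likelihood post-hoc placement of residual mutations.

    Each mutation is scored on every real edge and on hypothetical
    zero-length ancestor edges above any set of sibling subtrees; the
    best edge and its log-likelihood margin over the runner-up are
    reported.  A mutation whose best edge does not beat a flat
    sequencing-noise model (binomial at ``noise_rate``) is left
    unassigned — in particular one with zero depth everywhere.
    """
    samples = tree.samples
    sample_idx = [matrix.sample_index(s) for s in samples]
    all_ids = [matrix.variant_label(i) for i in range(len(matrix.variants))]
    keep = [all_ids.index(m) for m in mutations]
    alt = matrix.alt_counts[np.ix_(keep, sample_idx)].astype(float)
    depth = matrix.depth[np.ix_(keep, sample_idx)].astype(float)
    inv_t = _inverse_total_cn(matrix, bundle, samples)[keep]

    cands = _candidate_edges(tree)
    names = list(cands)
    ccf = np.stack([tree.P.loc[sorted(cands[name]), samples].sum(axis=0).to_numpy()
                    for name in names])  # (E, N)
    ll = _loglik_edges(alt, depth, inv_t, ccf)  # (M, E)
    p0 = np.clip(noise_rate, VAF_FLOOR, VAF_CEIL)
    ll_null = (alt * np.log(p0) + (depth - alt) * np.log1p(-p0)).sum(axis=1)

    rows = []
    for i, mid in enumerate(mutations):
        order = np.argsort(ll[i])[::-1]
        best, runner = order[0], (order[1] if len(order) > 1 else order[0])
        assigned = ll[i, best] > ll_null[i]
        rows.append({
            "mutation": mid,
            "edge": names[best] if assigned else None,
            "log_likelihood": float(ll[i, best]),
            "margin": float(ll[i, best] - ll[i, runner]),
            "beats_noise": bool(assigned),
        })
    return pd.DataFrame(rows)


def prevalence_report(tree: CloneTree) -> pd.DataFrame:
    """Per-sample composition in percent (normal row included, sums to 100)."""
    pct = 100.0 * tree.P
    pct.loc["total"] = pct.sum(axis=0)
    return pct


def write_prevalence(tree: CloneTree, out_prefix) -> tuple[Path, Path]:
    out_prefix = Path(out_prefix)
    table = prevalence_report(tree)
    tsv = out_prefix.with_suffix(".tsv")
    js = out_prefix.with_suffix(".json")
    table.to_csv(tsv, sep="\t", float_format="%.4f")
    js.write_text(json.dumps(
        {s: {c: round(float(table.loc[c, s]), 4) for c in table.index if c != "total"}
         for s in table.columns}, indent=1, sort_keys=True) + "\n")
    return tsv, js
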