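"""Synthetic multi-region tumor cohorts with known clonal ground truth.

Every downstream stage of the pipeline (variant matrix, sample phylogeny,
CNV curation, subclone inference, branch ordering) is exercised against
cohorts produced here, so the generator records complete ground truth:
the clone tree, the temporal order of mutations on every branch, the
per-sample clone-fraction matrix, and any copy-number events.

The default parameters emulate the structure of a rapid-autopsy cohort:
one matched normal plus 11 tumor samples, ~292 unique somatic mutations
of which 7 are truncal, four subclones with one clone dominant in the
pretreatment sample, one clone private to a single autopsy sample, one
clone appearing only at autopsy, a truncal 21.9-Mb one-copy gain on
chromosome 8q, and ~231x mean sequencing depth.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

TRUTH_SCHEMA_VERSION = "1.0"

NORMAL = "normal"

#: Approximate lengths of autosomes (hg19-scale), used to draw mutation
#: coordinates.  Only relative sizes matter for the simulation.
CHROM_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566,
}

#: The truncal copy gain carried by the default preset: a 21.9-Mb
#: single-copy gain of the major allele on chromosome 8q.
TRUNCAL_GAIN = ("8", 124_448_804, 146_364_022, 2, 1, True)

#: Canonical sample names for the emulated cohort: one pretreatment
#: biopsy, one postprogression biopsy, and nine autopsy samples.
FIGURE3C_SAMPLES = [
    "pretreatment", "postprogression",
    "liver_1", "liver_2", "liver_3", "liver_4", "liver_5", "liver_6",
    "lymph_aorta_esophagus", "lymph_left_kidney", "omentum",
]

#: Mean composition (rows: normal + clones, columns: samples) behind the
#: "figure3c" preset.  Structural zeros are exact: clone 1 is present only
#: in liver_1 and the postprogression biopsy, clone 4 only at autopsy and
#: not in liver_1.
FIGURE3C_MEANS = pd.DataFrame(
    {
        "pretreatment":          [0.06, 0.00, 0.89, 0.05, 0.00],
        "postprogression":       [0.18, 0.07, 0.45, 0.30, 0.00],
        "liver_1":               [0.10, 0.20, 0.40, 0.30, 0.00],
        "liver_2":               [0.12, 0.00, 0.50, 0.22, 0.16],
        "liver_3":               [0.15, 0.00, 0.45, 0.25, 0.15],
        "liver_4":               [0.10, 0.00, 0.55, 0.20, 0.15],
        "liver_5":               [0.14, 0.00, 0.42, 0.24, 0.20],
        "liver_6":               [0.12, 0.00, 0.48, 0.22, 0.18],
        "lymph_aorta_esophagus": [0.15, 0.00, 0.45, 0.22, 0.18],
        "lymph_left_kidney":     [0.13, 0.00, 0.50, 0.21, 0.16],
        "omentum":               [0.16, 0.00, 0.44, 0.22, 0.18],
    },
    index=[NORMAL, "clone1", "clone2", "clone3", "clone4"],
)

#: Clone-tree topology of the preset: the basal clone3 carries the truncal
#: mutations; clone1 (the resistance-mutation clone) sits below clone2's
#: lineage; clone4 diverged early from the basal clone.
FIGURE3C_PARENTS = {
    "clone3": NORMAL,
    "clone2": "clone3",
    "clone1": "clone2",
    "clone4": "clone3",
}

#: Per-edge mutation counts for the preset (truncal basal edge 7, the
#: private clone-1 branch 111, total 292 unique mutations).
FIGURE3C_EDGE_SIZES = {"clone3": 7, "clone2": 89, "clone1": 111, "clone4": 85}


@dataclass
class SimulationTruth:
    """Ground truth for one simulated cohort.

    ``parents`` maps each clone to its parent (clones plus the ``normal``
    root form a rooted tree); ``branch_mutations`` maps the edge above
    each clone to the ordered list of mutation ids that arose on it (list
    order = true temporal order); ``fractions`` is the (normal + clones)
    x samples composition matrix; ``cnv_truth`` lists
    (chrom, start, end, major, minor, truncal) events with 1-based
    inclusive coordinates.
    """

    parents: dict[str, str]
    branch_mutations: dict[str, list[str]]
    fractions: pd.DataFrame | None = None
    cnv_truth: list[tuple] = field(default_factory=list)
    seed: int = 0
    schema_version: str = TRUTH_SCHEMA_VERSION

    @property
    def clones(self) -> list[str]:
        return sorted(self.parents)

    @property
    def K(self) -> int:
        return len(self.parents)

    def children(self, node: str) -> list[str]:
        return sorted(c for c, p in self.parents.items() if p == node)

    def subtree(self, clone: str) -> frozenset[str]:
        """Clones at or below ``clone`` — the carriers of its edge mutations."""
        out, stack = set(), [clone]
        while stack:
            node = stack.pop()
            out.add(node)
            stack.extend(self.children(node))
        return frozenset(out)

    def mutation_edge(self) -> dict[str, str]:
        """Mapping mutation id -> edge (keyed by child clone)."""
        return {m: e for e, ms in self.branch_mutations.items() for m in ms}

    def validate(self) -> None:
        clones = set(self.parents)
        if NORMAL in clones:
            raise ConfigurationError("the normal root cannot be a clone")
        for clone, parent in self.parents.items():
            if parent != NORMAL and parent not in clones:
                raise ConfigurationError(f"unknown parent {parent!r} of {clone!r}")
        # acyclicity: every clone must reach the root
        for clone in clones:
            seen, node = set(), clone
            while node != NORMAL:
                if node in seen:
                    raise ConfigurationError(f"cycle through clone {node!r}")
                seen.add(node)
                node = self.parents[node]
        seen_muts: set[str] = set()
        for edge, muts in self.branch_mutations.items():
            if edge not in clones:
                raise ConfigurationError(f"mutations on unknown edge {edge!r}")
            dup = seen_muts.intersection(muts)
            if dup:
                raise ConfigurationError(f"mutations on several edges: {sorted(dup)[:3]}")
            seen_muts.update(muts)
        if self.fractions is not None:
            cols = self.fractions.sum(axis=0)
            if not np.allclose(cols, 1.0, atol=1e-9):
                raise ConfigurationError("per-sample compositions must sum to 1")

    def topology_hash(self) -> str:
        payload = json.dumps(
            {"parents": dict(sorted(self.parents.items())),
             "branch_mutations": {k: list(v) for k, v in sorted(self.branch_mutations.items())}},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self) -> str:
        doc = {
            "schema_version": self.schema_version,
            "seed": int(self.seed),
            "parents": self.parents,
            "branch_mutations": self.branch_mutations,
            "fractions": None if self.fractions is None else {
                "index": list(self.fractions.index),
                "columns": list(self.fractions.columns),
                "values": self.fractions.to_numpy().tolist(),
            },
            "cnv_truth": [list(ev) for ev in self.cnv_truth],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        doc = json.loads(text)
        fractions = None
        if doc.get("fractions"):
            f = doc["fractions"]
            fractions = pd.DataFrame(f["values"], index=f["index"], columns=f["columns"])
        return cls(
            parents=doc["parents"],
            branch_mutations={k: list(v) for k, v in doc["branch_mutations"].items()},
            fractions=fractions,
            cnv_truth=[tuple(ev) for ev in doc.get("cnv_truth", [])],
            seed=doc.get("seed", 0),
            schema_version=doc.get("schema_version", TRUTH_SCHEMA_VERSION),
        )


def _random_rooted_tree(K: int, rng: np.random.Generator) -> dict[str, str]:
    """Uniform labeled rooted tree on K clones plus the normal root.

    Drawn via a random Pruefer sequence over the K+1 labels, then rooted at
    normal; there are (K+1)**(K-1) such trees.
    """
    labels = [NORMAL] + [f"clone{i + 1}" for i in range(K)]
    n = K + 1
    if n == 2:
        return {labels[1]: NORMAL}
    import heapq

    prufer = rng.integers(0, n, size=n - 2)
    degree = np.ones(n, dtype=int)
    for v in prufer:
        degree[v] += 1
    edges = []
    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    for v in prufer:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, int(v)))
        degree[leaf] -= 1
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, int(v))
    last = [i for i in range(n) if degree[i] == 1]
    edges.append((last[0], last[1]))
    # orient away from the root (index 0)
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    parents: dict[str, str] = {}
    stack = [0]
    seen = {0}
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                parents[labels[nb]] = labels[node]
                stack.append(nb)
    return parents


def _edge_order(parents: Mapping[str, str]) -> list[str]:
    """Edges (keyed by child clone) in breadth-first, name-sorted order."""
    children: dict[str, list[str]] = {}
    for c, p in parents.items():
        children.setdefault(p, []).append(c)
    order, frontier = [], sorted(children.get(NORMAL, []))
    while frontier:
        order.extend(frontier)
        frontier = sorted(c for node in frontier for c in children.get(node, []))
    return order


def simulate_clone_tree(
    K: int,
    n_mutations: int,
    seed: int,
    n_truncal: int = 7,
    require_truncal: bool = False,
    edge_sizes: Sequence[int] | None = None,
) -> SimulationTruth:
    """Draw a clone-tree topology and distribute mutations over its edges.

    The topology is uniform over rooted labeled trees on ``K`` clones with
    a fixed normal root.  Mutations are multinomially distributed over the
    ``K`` edges with every edge receiving at least one; when the root has a
    single child, ``n_truncal`` mutations are reserved for that basal edge
    (truncal mutations only exist when a unique basal edge does).  Passing
    ``edge_sizes`` fixes the per-edge counts (breadth-first edge order)
    instead.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if n_mutations < K:
        raise ValueError(f"need n_mutations >= K, got {n_mutations} < {K}")
    rng = np.random.default_rng(seed)
    parents = _random_rooted_tree(K, rng)
    if require_truncal:
        children_of_root = [c for c, p in parents.items() if p == NORMAL]
        tries = 0
        while len(children_of_root) != 1:
            parents = _random_rooted_tree(K, rng)
            children_of_root = [c for c, p in parents.items() if p == NORMAL]
            tries += 1
            if tries > 10_000:  # pragma: no cover
                raise RuntimeError("failed to draw a single-basal-edge topology")
    edges = _edge_order(parents)

    if edge_sizes is not None:
        if len(edge_sizes) != K or sum(edge_sizes) != n_mutations or min(edge_sizes) < 1:
            raise ValueError("edge_sizes must have K positive entries summing to n_mutations")
        counts = np.asarray(edge_sizes, dtype=int)
    else:
        root_children = [c for c, p in parents.items() if p == NORMAL]
        basal = root_children[0] if len(root_children) == 1 else None
        counts = np.ones(K, dtype=int)
        remaining = n_mutations - K
        reserved = 0
        if basal is not None and n_truncal > 0:
            reserved = min(max(n_truncal - 1, 0), remaining)
            counts[edges.index(basal)] += reserved
            remaining -= reserved
        if remaining > 0:
            counts += rng.multinomial(remaining, np.full(K, 1.0 / K))

    width = max(4, len(str(n_mutations)))
    mut_ids = [f"m{i + 1:0{width}d}" for i in range(n_mutations)]
    branch_mutations: dict[str, list[str]] = {}
    cursor = 0
    for edge, c in zip(edges, counts):
        branch_mutations[edge] = mut_ids[cursor:cursor + int(c)]
        cursor += int(c)
    truth = SimulationTruth(parents=parents, branch_mutations=branch_mutations, seed=int(seed))
    truth.validate()
    return truth


def figure3c_truth(seed: int = 0) -> SimulationTruth:
    """Ground-truth skeleton of the emulated rapid-autopsy cohort."""
    n = sum(FIGURE3C_EDGE_SIZES.values())
    width = max(4, len(str(n)))
    mut_ids = [f"m{i + 1:0{width}d}" for i in range(n)]
    branch_mutations, cursor = {}, 0
    for edge in _edge_order(FIGURE3C_PARENTS):
        size = FIGURE3C_EDGE_SIZES[edge]
        branch_mutations[edge] = mut_ids[cursor:cursor + size]
        cursor += size
    truth = SimulationTruth(
        parents=dict(FIGURE3C_PARENTS),
        branch_mutations=branch_mutations,
        cnv_truth=[TRUNCAL_GAIN],
        seed=int(seed),
    )
    truth.validate()
    return truth


def simulate_clone_fractions(
    truth: SimulationTruth,
    n_samples: int,
    concentration: float = 2.0,
    seed: int = 0,
    preset: str | None = None,
    sample_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw the (normal + clones) x samples composition matrix.

    Each sample's composition is a Dirichlet draw over normal plus the K
    clones.  ``preset="figure3c"`` instead centres the Dirichlet on the
    emulated cohort's prevalence pattern (structural zeros stay exactly
    zero: the autopsy-only clone is absent from both biopsies, the rare
    resistance clone is present only in liver_1/postprogression).
    ``concentration`` is the total Dirichlet mass per sample.
    """
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    rows = [NORMAL] + truth.clones
    if preset == "figure3c":
        if truth.K != 4:
            raise ConfigurationError("the figure3c preset requires K=4 clones")
        if n_samples != len(FIGURE3C_SAMPLES):
            raise ConfigurationError(
                f"the figure3c preset defines {len(FIGURE3C_SAMPLES)} samples")
        means = FIGURE3C_MEANS.loc[rows]
        cols = {}
        for sample in FIGURE3C_SAMPLES:
            mean = means[sample].to_numpy()
            frac = np.zeros_like(mean)
            nz = mean > 0
            frac[nz] = rng.dirichlet(concentration * mean[nz] + 1e-12)
            cols[sample] = frac
        fractions = pd.DataFrame(cols, index=rows)
    elif preset is None:
        names = list(sample_names) if sample_names else [f"sample_{i + 1}" for i in range(n_samples)]
        if len(names) != n_samples:
            raise ConfigurationError("sample_names length must equal n_samples")
        draws = rng.dirichlet(np.full(len(rows), concentration), size=n_samples).T
        fractions = pd.DataFrame(draws, index=rows, columns=names)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    truth.fractions = fractions
    truth.validate()
    return fractions


def _mixture_total_cn(event, tumor_fraction: float) -> float:
    """Average copies per cell at a truncal CNV in a bulk sample."""
    _, _, _, major, minor, _ = event[:6]
    t = major + minor
    return 2.0 * (1.0 - tumor_fraction) + t * tumor_fraction


def simulate_read_counts(
    truth: SimulationTruth,
    depth_mean: float = 231.0,
    seed: int = 0,
    overdispersion: float | None = None,
    error_rate: float = 0.0,
):
    """Draw per-site, per-sample allelic depths for the simulated cohort.

    For a mutation on edge ``e`` the carriers are the clones in the subtree
    below ``e``; its expected VAF in sample ``i`` is the carried copy count
    (multiplicity fixed at 1) divided by the average copies per cell (2 for
    diploid sites, the purity-weighted mixture total for sites inside a
    truncal CNV), times the summed carrier fractions.  Depth is Poisson
    with mean ``depth_mean`` (negative binomial when ``overdispersion`` —
    the NB shape parameter — is given) and alt counts are binomial.  The
    normal sample has expected VAF 0 apart from the optional flat
    sequencing error rate.
    """
    from .variant_matrix import CohortVariantMatrix, SomaticVariant, build_presence_sets

    if depth_mean <= 0:
        raise ValueError(f"depth_mean must be positive, got {depth_mean}")
    if truth.fractions is None:
        raise ConfigurationError("truth has no clone fractions; run simulate_clone_fractions first")
    rng = np.random.default_rng(seed)

    mut_edge = truth.mutation_edge()
    mut_ids = sorted(mut_edge)
    chroms = list(CHROM_LENGTHS)
    lengths = np.array([CHROM_LENGTHS[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    bases = np.array(list("ACGT"))
    variants = []
    seen_pos: set[tuple[str, int]] = set()
    for mid in mut_ids:
        while True:
            ci = rng.choice(len(chroms), p=probs)
            pos = int(rng.integers(1, CHROM_LENGTHS[chroms[ci]] + 1))
            if (chroms[ci], pos) not in seen_pos:
                seen_pos.add((chroms[ci], pos))
                break
        ref, alt = rng.choice(bases, size=2, replace=False)
        variants.append(SomaticVariant(chrom=chroms[ci], pos=pos, ref=str(ref), alt=str(alt)))
    order = sorted(range(len(variants)), key=lambda i: variants[i].sort_key())
    variants = [variants[i] for i in order]
    mut_ids = [mut_ids[i] for i in order]

    tumor_samples = list(truth.fractions.columns)
    samples = [NORMAL] + tumor_samples
    frac = truth.fractions
    tumor_total = frac.drop(index=NORMAL).sum(axis=0)

    M, S = len(variants), len(samples)
    exp_vaf = np.zeros((M, S))
    for vi, (var, mid) in enumerate(zip(variants, mut_ids)):
        carriers = truth.subtree(mut_edge[mid])
        ccf = frac.loc[sorted(carriers)].sum(axis=0)
        event = next(
            (ev for ev in truth.cnv_truth
             if ev[5] and ev[0] == var.chrom and ev[1] <= var.pos <= ev[2]),
            None,
        )
        for si, sample in enumerate(tumor_samples, start=1):
            denom = 2.0 if event is None else _mixture_total_cn(event, float(tumor_total[sample]))
            exp_vaf[vi, si] = float(ccf[sample]) / denom
    if error_rate > 0:
        exp_vaf = exp_vaf * (1 - error_rate) + (1 - exp_vaf) * error_rate
    exp_vaf = np.clip(exp_vaf, 0.0, 1.0)

    if overdispersion is None:
        depth = rng.poisson(depth_mean, size=(M, S))
    else:
        if overdispersion <= 0:
            raise ValueError("overdispersion (NB shape) must be positive")
        p = overdispersion / (overdispersion + depth_mean)
        depth = rng.negative_binomial(overdispersion, p, size=(M, S))
    alt = rng.binomial(depth, exp_vaf)
    ref = depth - alt

    matrix = CohortVariantMatrix(
        variants=variants,
        samples=samples,
        normal_sample=NORMAL,
        alt_counts=alt.astype(np.int64),
        ref_counts=ref.astype(np.int64),
        variant_ids=mut_ids,
    )
    build_presence_sets(matrix)
    matrix.expected_vaf = exp_vaf
    return matrix


def expected_vaf_matrix(truth: SimulationTruth, variants=None) -> pd.DataFrame:
    """Noise-free expected VAFs (diploid sites) per mutation and tumor sample."""
    if truth.fractions is None:
        raise ConfigurationError("truth has no clone fractions")
    mut_edge = truth.mutation_edge()
    rows = {}
    for mid in sorted(mut_edge):
        carriers = truth.subtree(mut_edge[mid])
        rows[mid] = 0.5 * truth.fractions.loc[sorted(carriers)].sum(axis=0)
    return pd.DataFrame(rows).T


def simulate_figure3c_cohort(
    seed: int = 0,
    depth_mean: float = 231.0,
    concentration: float = 150.0,
    error_rate: float = 0.0,
):
    """One-call cohort emulation: preset truth, fractions, and read counts."""
    ss = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    truth = figure3c_truth(seed=int(seed))
    simulate_clone_fractions(
        truth, n_samples=len(FIGURE3C_SAMPLES), concentration=concentration,
        seed=int(ss[0]), preset="figure3c",
    )
    matrix = simulate_read_counts(
        truth, depth_mean=depth_mean, seed=int(ss[1]), error_rate=error_rate)
    return truth, matrix


def simulate_het_snps(
    n_snps: int,
    samples: Sequence[str],
    cnv_truth: Iterable[tuple] = (),
    depth_mean: float = 200.0,
    rdep: Mapping[str, float] | float = 1.0,
    purity: Mapping[str, float] | float = 1.0,
    seed: int = 0,
    chrom: str = "8",
    chrom_length: int | None = None,
):
    """Germline-heterozygous-SNP allelic counts for CNV work.

    Positions are uniform over one chromosome.  Outside CNV regions both
    parental alleles have one copy (BAF 1/2, depth ratio rdep); inside a
    (major, minor) region the bulk totals and B-allele fractions follow
    the purity-weighted mixture.  Phase is random per SNP, as in real
    unphased data, so only the mirrored BAF is informative.
    """
    from .cnv_segments import HetSnpCounts

    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    length = chrom_length or CHROM_LENGTHS.get(chrom, 150_000_000)
    pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_snps, replace=False))

    if not isinstance(rdep, Mapping):
        rdep = {s: float(rdep) for s in samples}
    if not isinstance(purity, Mapping):
        purity = {s: float(purity) for s in samples}

    normal_depth = rng.poisson(depth_mean, size=n_snps)
    normal_a = rng.binomial(normal_depth, 0.5)

    events = [ev for ev in cnv_truth if ev[0] == chrom]
    t_site = np.full(n_snps, 2.0)
    f_site = np.full(n_snps, 0.5)
    tumor = {}
    for sample in samples:
        rho = purity[sample]
        t_mix = np.full(n_snps, 2.0)
        f_mix = np.full(n_snps, 0.5)
        for ev in events:
            _, start, end, major, minor = ev[:5]
            inside = (pos >= start) & (pos <= end)
            t = 2.0 * (1 - rho) + (major + minor) * rho
            f = ((1 - rho) + major * rho) / t
            t_mix[inside] = t
            f_mix[inside] = f
        d = rng.poisson(depth_mean * rdep[sample] * t_mix / 2.0)
        phase = rng.random(n_snps) < 0.5
        eff_f = np.where(phase, f_mix, 1 - f_mix)
        a = rng.binomial(d, eff_f)
        tumor[sample] = (a.astype(np.int64), (d - a).astype(np.int64))
    return HetSnpCounts(
        chrom=np.full(n_snps, chrom, dtype=object),
        pos=pos.astype(np.int64),
        normal_a=normal_a.astype(np.int64),
        normal_b=(normal_depth - normal_a).astype(np.int64),
        tumor=tumor,
    )


def simulate_ordered_branch(
    n_mutations: int = 20,
    n_samples: int = 11,
    sigma: float = 0.02,
    vaf_high: float = 0.40,
    vaf_low: float = 0.10,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """A branch timeline with a VAF-rank signal for ordering recovery.

    The true temporal order induces linearly decreasing VAFs from
    ``vaf_high`` (earliest) to ``vaf_low`` (latest) in every sample, with
    i.i.d. Gaussian noise of standard deviation ``sigma`` added per
    mutation and sample.  Returns the VAF matrix and the true order
    (earliest first).
    """
    rng = np.random.default_rng(seed)
    ids = [f"v{i + 1:03d}" for i in range(n_mutations)]
    base = np.linspace(vaf_high, vaf_low, n_mutations)
    vafs = base[:, None] + rng.normal(0.0, sigma, size=(n_mutations, n_samples))
    vafs = np.clip(vafs, 1e-4, 0.999)
    cols = [f"sample_{i + 1}" for i in range(n_samples)]
    return pd.DataFrame(vafs, index=ids, columns=cols), ids


def write_fixture(truth: SimulationTruth, matrix, out_dir) -> dict[str, Path]:
    """Write a cohort fixture: multi-sample VCF, truth JSON, manifest TSV.

    The VCF is plain-text v4.2 with GT and AD FORMAT fields and
    round-trips losslessly through :func:`clonaltrace.variant_matrix.read_cohort`.
    Nothing is written if the cohort is empty.
    """
    if not matrix.variants or not matrix.samples:
        raise ValueError("refusing to write an empty cohort fixture")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = out_dir / "cohort.vcf"
    truth_path = out_dir / "truth.json"
    manifest_path = out_dir / "manifest.tsv"

    contigs = sorted({v.chrom for v in matrix.variants},
                     key=lambda c: (len(c), c) if c.isdigit() else (99, c))
    lines = [
        "##fileformat=VCFv4.2",
        "##source=clonaltrace-synthetic",
        f"##clonaltrace_truth_schema={truth.schema_version}",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for c in contigs:
        lines.append(f"##contig=<ID={c},length={CHROM_LENGTHS.get(c, 250_000_000)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.samples))
    ids = matrix.variant_ids or ["."] * len(matrix.variants)
    for vi, var in enumerate(matrix.variants):
        fields = [var.chrom, str(var.pos), ids[vi], var.ref, var.alt, ".", "PASS", ".", "GT:AD:DP"]
        for si in range(len(matrix.samples)):
            a = int(matrix.alt_counts[vi, si])
            r = int(matrix.ref_counts[vi, si])
            gt = "0/1" if a > 0 else "0/0"
            fields.append(f"{gt}:{r},{a}:{r + a}")
        lines.append("\t".join(fields))
    vcf_path.write_text("\n".join(lines) + "\n")

    truth_path.write_text(truth.to_json() + "\n")
    rows = ["sample\trole"]
    for s in matrix.samples:
        rows.append(f"{s}\t{'normal' if s == matrix.normal_sample else 'tumor'}")
    manifest_path.write_text("\n".join(rows) + "\n")
    return {"vcf": vcf_path, "truth": truth_path, "manifest": manifest_path}
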