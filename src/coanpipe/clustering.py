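"""Coancestry-matrix clustering in the fineSTRUCTURE style.

The coancestry matrix rows, rescaled by a c-factor into effective independent
chunk counts, are modelled as multinomial draws whose donor-side composition
is shared by all members of a cluster (exchangeability within clusters);
integrating the composition against a symmetric Dirichlet prior gives a
closed-form Dirichlet-multinomial marginal likelihood for any partition.
The same partition clusters both axes of a square matrix. The partition
prior is uniform over the number of clusters K and uniform over set
partitions with exactly K blocks.

A Markov chain Monte Carlo sampler (Gibbs single-individual reassignment
plus Metropolis-Hastings split/merge proposals) explores the partition
posterior; the number of clusters is an output, not an input. A greedy
agglomerative pass then builds a hierarchical tree by repeatedly applying
the pairwise merge with the smallest posterior decrease.

The external-sharing variant clusters recipients purely on their copying
from external donor groups: the rectangular matrix X is embedded in a square
block matrix whose donor-donor block carries calibration constants g_k (the
group-k block mean matching the group-k mean of X), with all other blocks
zero so recipient-recipient copying cannot contribute; donor groups are held
fixed during the MCMC (force-file semantics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .panel import CoancestryMatrix

__all__ = [
    "Partition",
    "ClusterTree",
    "MCMCTrace",
    "BlockMatrix",
    "scale_to_counts",
    "default_c_factor",
    "partition_log_marginal",
    "cluster_mcmc",
    "build_merge_tree",
    "assignment_certainty",
    "select_tree_level",
    "build_external_sharing_matrix",
    "cluster_on_external_sharing",
]


@dataclass
class Partition:
    """Cluster label per individual; labels are contiguous 1..K."""

    ids: list
    labels: np.ndarray  # (n,) int, values 1..K

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.ids):
            raise ValueError("labels and ids must align")
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
            raise ValueError("labels must be contiguous 1..K")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    def members(self, k: int) -> list:
        return [self.ids[i] for i in np.flatnonzero(self.labels == k)]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters + 1)[1:]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "cluster": self.labels})


@dataclass
class MCMCTrace:
    """Thinned partition samples with their log posteriors."""

    samples: list  # list of (n,) label arrays (0-based internal labels)
    log_posterior: list
    seed: int
    n_burn: int
    n_sample: int
    thin: int

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise ValueError("degenerate trace: fewer than 2 retained samples")
        if not np.all(np.isfinite(self.log_posterior)):
            raise ValueError("non-finite log posterior in trace")


@dataclass
class ClusterTree:
    """Greedy merge tree above a leaf partition.

    ``merges`` lists (cluster_a, cluster_b, score) in merge order, where
    cluster ids are leaf labels 1..K for leaves and K+1, K+2, ... for
    internal nodes; ``score`` is the (clamped non-negative) decrease in log
    posterior caused by the merge.
    """

    leaf_partition: Partition
    merges: list

    def __post_init__(self) -> None:
        K = self.leaf_partition.n_clusters
        if len(self.merges) != K - 1:
            raise ValueError("tree must have exactly K-1 merges")
        if any(s < 0 for _, _, s in self.merges):
            raise ValueError("merge scores must be non-negative")

    def partition_at_level(self, level: int) -> Partition:
        """Partition with ``level`` clusters (1 = root, K = leaves)."""
        K = self.leaf_partition.n_clusters
        if not 1 <= level <= K:
            raise ValueError(f"level must be in 1..{K}")
        parent = {}
        for step, (a, b, _) in enumerate(self.merges[: K - level]):
            parent[a] = K + 1 + step
            parent[b] = K + 1 + step

        def root(x):
            while x in parent:
                x = parent[x]
            return x

        raw = np.array([root(l) for l in self.leaf_partition.labels])
        _, canon = np.unique(raw, return_inverse=True)
        return Partition(self.leaf_partition.ids, canon + 1)

    def newick(self) -> str:
        """Newick string; merge scores annotate internal branch lengths."""
        K = self.leaf_partition.n_clusters
        node = {k: f"c{k}" for k in range(1, K + 1)}
        for step, (a, b, score) in enumerate(self.merges):
            nid = K + 1 + step
            node[nid] = f"({node[a]},{node[b]}):{score:.6g}"
        root_id = K + len(self.merges)
        body = node[root_id] if K > 1 else node[1]
        # root branch annotation is meaningless; strip it
        if K > 1:
            body = body.rsplit(":", 1)[0]
        return body + ";"


@dataclass
class BlockMatrix:
    """(N+M) x (N+M) external-sharing matrix C = [[0, X], [0, Y]].

    Y is zero except the within-donor-group diagonal blocks, whose entries
    all equal the calibration constant g_k (self-pairs included), chosen so
    the group-k mean of Y equals the group-k mean of X.
    """

    values: np.ndarray
    recipients: list
    donors: list
    donor_group_of: dict
    g_k: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        N, M = len(self.recipients), len(self.donors)
        if self.values.shape != (N + M, N + M):
            raise ValueError("block matrix shape must be (N+M, N+M)")
        if np.any(self.values[:, :N] != 0):
            raise ValueError("recipient-side columns must be zero")
        Y = self.values[N:, N:]
        groups = [self.donor_group_of[d] for d in self.donors]
        for i, gi in enumerate(groups):
            for_j = np.array(groups) == gi
            if np.any(Y[i, ~for_j] != 0):
                raise ValueError("Y must be zero outside donor-group blocks")

    @property
    def X(self) -> np.ndarray:
        return self.values[: len(self.recipients), len(self.recipients) :]

    @property
    def ids(self) -> list:
        return list(self.recipients) + list(self.donors)


def default_c_factor(lengths: CoancestryMatrix, counts: CoancestryMatrix) -> float:
    """Mean chunk-size heuristic: total painted length / total chunk count,
    so that 1/c-scaled rows approximate effective independent chunk counts."""
    tot_counts = counts.values.sum()
    if tot_counts <= 0:
        raise ValueError("chunk-count matrix sums to zero")
    return float(lengths.values.sum() / tot_counts)


def scale_to_counts(values: np.ndarray, c_factor: float) -> np.ndarray:
    """Rescale rows by 1/c and round (half-even) to effective counts,
    adjusting each row's largest entry so the row total is preserved."""
    if c_factor <= 0:
        raise ValueError("c_factor must be > 0")
    scaled = values / c_factor
    m = np.round(scaled)  # numpy rounds half to even
    target = np.round(scaled.sum(axis=1))
    diff = target - m.sum(axis=1)
    idx = np.argmax(m, axis=1)
    for i, d in enumerate(diff):
        m[i, idx[i]] = max(m[i, idx[i]] + d, 0.0)
    return m


@lru_cache(maxsize=64)
def _log_stirling2_row(n: int) -> tuple:
    """log S(n, k) for k = 0..n (Stirling numbers of the second kind)."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # S(0,0)=1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        for k in range(1, m + 1):
            new[k] = np.logaddexp(np.log(k) + row[k], row[k - 1])
        row = new
    return tuple(row)


class _PartitionModel:
    """Two-level partition likelihood over an effective-counts matrix.

    Each row is a multinomial over the n donor columns. Under partition z
    (shared by rows and columns), a copy from row-cluster a lands in
    column-cluster b with probability theta_ab and is then allocated
    uniformly among b's members, so the per-row column probabilities are
    theta_ab / |b|. The cluster-level compositions theta_a are integrated
    against a flat Dirichlet prior, giving

        log ML(a) = sum_{i in a} coeff_i - sum_b T_ab log|b|
                    + lgam(K b0) - lgam(K b0 + N_a)
                    + sum_b [lgam(b0 + T_ab) - lgam(b0)]

    with T_ab the aggregated counts. The category space is always the full
    set of n columns, so marginals of different partitions are comparable;
    the uniform-allocation term is what penalizes merging columns with
    heterogeneous copying patterns.

    The Dirichlet base measure is proportional to column-cluster size
    (b_b = beta0 |b| / n), i.e. the aggregation of a flat measure over
    individual columns; the total concentration beta0 is then independent
    of K, so adding a cluster does not re-price every other cluster's
    marginal through the prior dimension.
    """

    def __init__(self, counts: np.ndarray, beta: float = 1.0):
        self.m = np.asarray(counts, dtype=float)
        self.n = self.m.shape[0]
        self.beta = beta
        self._const = float(
            gammaln(self.m.sum(axis=1) + 1).sum() - gammaln(self.m + 1).sum()
        )
        self._ls2 = np.array(_log_stirling2_row(self.n))

    def log_marginal(self, labels0: np.ndarray) -> float:
        """Log marginal likelihood of all rows under the partition.

        A row cannot copy from itself, so its own column-cluster allocates
        uniformly over |b| - 1 members rather than |b|.
        """
        K = int(labels0.max()) + 1
        Z = np.zeros((self.n, K))
        Z[np.arange(self.n), labels0] = 1.0
        A = self.m @ Z  # (n, K) per-row counts by column cluster
        T = Z.T @ A  # (K, K) aggregated counts
        sizes = Z.sum(axis=0)
        N_a = T.sum(axis=1)
        b0 = self.beta
        bcol = b0 * sizes / self.n  # size-proportional base measure
        ll = self._const
        ll -= float((T * np.log(sizes)[None, :]).sum())
        own = A[np.arange(self.n), labels0]
        sz = sizes[labels0]
        big = sz > 1
        ll += float(
            (own[big] * (np.log(sz[big]) - np.log(sz[big] - 1))).sum()
        )
        ll += (gammaln(b0) - gammaln(b0 + N_a)).sum()
        ll += (gammaln(T + bcol[None, :]) - gammaln(bcol)[None, :]).sum()
        return float(ll)

    def log_prior(self, labels0: np.ndarray) -> float:
        K = int(labels0.max()) + 1
        return float(-np.log(self.n) - self._ls2[K])

    def log_posterior(self, labels0: np.ndarray) -> float:
        return self.log_marginal(labels0) + self.log_prior(labels0)


def _canonical0(labels: np.ndarray) -> np.ndarray:
    """Relabel to 0..K-1 in order of first appearance."""
    out = np.empty_like(labels)
    mapping = {}
    for i, l in enumerate(labels):
        if l not in mapping:
            mapping[l] = len(mapping)
        out[i] = mapping[l]
    return out


def _as_count_model(matrix, c_factor: float, beta: float = 1.0) -> _PartitionModel:
    if isinstance(matrix, BlockMatrix):
        values = matrix.values
    elif isinstance(matrix, CoancestryMatrix):
        if matrix.kind != "square":
            raise ValueError(
                "square coancestry or block matrix required for clustering"
            )
        values = matrix.values
    else:
        values = np.asarray(matrix, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("clustering input must be square")
    return _PartitionModel(scale_to_counts(values, c_factor), beta=beta)


def _full_labels(matrix, labels: np.ndarray) -> np.ndarray:
    """For a block matrix given recipient-only labels, append the fixed
    donor-group clusters after the recipient clusters."""
    if isinstance(matrix, BlockMatrix) and len(labels) == len(matrix.recipients):
        groups = [matrix.donor_group_of[d] for d in matrix.donors]
        order = list(dict.fromkeys(groups))
        K = int(labels.max()) + 1
        donor_labels = np.array([K + order.index(g) for g in groups])
        return np.concatenate([labels, donor_labels])
    return labels


def partition_log_marginal(matrix, partition, c_factor: float) -> float:
    """Log marginal likelihood of a partition for a (square or block)
    coancestry matrix under the Dirichlet-multinomial model."""
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(
        partition
    )
    labels0 = _canonical0(labels)
    model = _as_count_model(matrix, c_factor)
    return model.log_marginal(_full_labels(matrix, labels0))


def _gibbs_sweep(model, labels, free_idx, free_cluster_ids, rng):
    """One random-order Gibbs sweep over the free individuals.

    ``free_cluster_ids`` restricts candidate clusters (plus one fresh
    cluster) to those the free individuals may occupy.
    """
    for i in rng.permutation(free_idx):
        current = labels[i]
        # candidate labels: clusters currently occupied by free individuals,
        # plus a brand-new cluster
        occupied = sorted(set(labels[free_idx]))
        candidates = [k for k in occupied if k in free_cluster_ids or k == current]
        fresh = labels.max() + 1
        candidates.append(fresh)
        logp = np.empty(len(candidates))
        for j, k in enumerate(candidates):
            labels[i] = k
            logp[j] = model.log_posterior(_canonical0(labels))
        probs = np.exp(logp - logsumexp(logp))
        choice = candidates[rng.choice(len(candidates), p=probs)]
        labels[i] = choice
        if choice == fresh:
            free_cluster_ids.add(fresh)
    return labels


def _split_merge(model, labels, free_idx, free_cluster_ids, rng):
    """One Metropolis-Hastings split-or-merge proposal among free clusters."""
    free_clusters = sorted(set(labels[free_idx]) & free_cluster_ids)
    K = len(free_clusters)
    do_split = rng.random() < 0.5
    cur_post = model.log_posterior(_canonical0(labels))
    if do_split:
        splittable = [k for k in free_clusters if np.sum(labels[free_idx] == k) >= 2]
        if not splittable:
            return labels, False
        k = splittable[rng.integers(len(splittable))]
        members = [i for i in free_idx if labels[i] == k]
        while True:
            side = rng.random(len(members)) < 0.5
            if 0 < side.sum() < len(side):
                break
        prop = labels.copy()
        new_id = labels.max() + 1
        for i, s in zip(members, side):
            if s:
                prop[i] = new_id
        m = len(members)
        log_q_fwd = -np.log(len(splittable)) + np.log(2.0) - np.log(2.0**m - 2.0)
        log_q_rev = -np.log((K + 1) * K / 2.0)
    else:
        if K < 2:
            return labels, False
        a, b = rng.choice(K, size=2, replace=False)
        ka, kb = free_clusters[a], free_clusters[b]
        prop = labels.copy()
        prop[prop == kb] = ka
        merged_size = int(np.sum(labels[free_idx] == ka) + np.sum(labels[free_idx] == kb))
        n_splittable_rev = sum(
            1
            for kk in set(prop[free_idx])
            if np.sum(prop[free_idx] == kk) >= 2
        )
        log_q_fwd = -np.log(K * (K - 1) / 2.0)
        log_q_rev = (
            -np.log(max(n_splittable_rev, 1))
            + np.log(2.0)
            - np.log(2.0**merged_size - 2.0)
        )
    prop_post = model.log_posterior(_canonical0(prop))
    log_acc = prop_post - cur_post + log_q_rev - log_q_fwd
    if np.log(rng.random()) < log_acc:
        if do_split:
            free_cluster_ids.add(int(prop.max()))
        return prop, True
    return labels, False


def _hill_climb(model, labels, free_idx, free_cluster_ids):
    """Deterministic single-move ascent to a local posterior optimum."""
    best = model.log_posterior(_canonical0(labels))
    improved = True
    while improved:
        improved = False
        for i in free_idx:
            current = labels[i]
            occupied = sorted(set(labels[free_idx]) & free_cluster_ids)
            fresh = labels.max() + 1
            for k in occupied + [fresh]:
                if k == current:
                    continue
                labels[i] = k
                post = model.log_posterior(_canonical0(labels))
                if post > best + 1e-10:
                    best = post
                    current = k
                    improved = True
                    if k == fresh:
                        free_cluster_ids.add(fresh)
                else:
                    labels[i] = current
    return labels


def cluster_mcmc(
    matrix,
    c_factor: float,
    n_burn: int = 200,
    n_sample: int = 300,
    thin: int = 5,
    seed: int = 0,
    init_labels: np.ndarray | None = None,
    _fixed: tuple | None = None,
) -> tuple[MCMCTrace, Partition]:
    """MCMC over partitions; returns the trace and the MAP partition.

    The MAP is the best-posterior state visited, refined by a deterministic
    single-move hill climb. The number of clusters is inferred.
    """
    if n_burn <= 0 or n_sample <= 0 or thin <= 0:
        raise ValueError("iteration counts must be positive")
    model = _as_count_model(matrix, c_factor)
    n = model.n
    rng = np.random.default_rng(seed)

    if _fixed is None:
        free_idx = np.arange(n)
        # all-singletons start: coalescing similar individuals by single
        # Gibbs moves mixes far better than splitting out of one cluster
        labels = np.arange(n) if init_labels is None else np.asarray(
            init_labels, dtype=int
        ).copy()
        free_cluster_ids = set(labels.tolist())
    else:
        free_idx, labels, free_cluster_ids = _fixed
        labels = labels.copy()
        free_cluster_ids = set(free_cluster_ids)

    best_labels = labels.copy()
    best_post = model.log_posterior(_canonical0(labels))
    samples, logps = [], []
    total = n_burn + n_sample
    for it in range(total):
        labels = _gibbs_sweep(model, labels, free_idx, free_cluster_ids, rng)
        labels, _ = _split_merge(model, labels, free_idx, free_cluster_ids, rng)
        post = model.log_posterior(_canonical0(labels))
        if post > best_post:
            best_post = post
            best_labels = labels.copy()
        if it >= n_burn and (it - n_burn) % thin == 0:
            samples.append(_canonical0(labels[free_idx]).copy())
            logps.append(post)
    trace = MCMCTrace(samples, logps, seed, n_burn, n_sample, thin)

    best_labels = _hill_climb(model, best_labels.copy(), free_idx, free_cluster_ids)
    map_labels0 = _canonical0(best_labels[free_idx])
    ids = getattr(matrix, "recipients", None)
    if ids is None:
        ids = [str(i) for i in range(n)]
    if isinstance(matrix, BlockMatrix):
        ids = matrix.recipients
    elif isinstance(matrix, CoancestryMatrix):
        ids = matrix.recipients
    map_partition = Partition([ids[i] for i in range(len(free_idx))], map_labels0 + 1)
    return trace, map_partition


def build_merge_tree(partition: Partition, matrix, c_factor: float) -> ClusterTree:
    """Greedy agglomeration: repeatedly apply the pairwise merge with the
    smallest posterior decrease; ties broken by the smallest cluster-id pair."""
    if partition.n_clusters < 2:
        return ClusterTree(partition, [])
    model = _as_count_model(matrix, c_factor)
    K = partition.n_clusters
    labels = _full_labels(matrix, partition.labels - 1)
    # node id per active cluster (leaf ids 1..K)
    active = {k: k + 1 for k in range(K)}  # internal cluster idx -> node id
    cluster_of = labels.copy()
    merges = []
    next_node = K + 1
    while len(active) > 1:
        cur_post = model.log_posterior(_canonical0(cluster_of))
        best = None
        for a in sorted(active):
            for b in sorted(active):
                if b <= a:
                    continue
                trial = cluster_of.copy()
                trial[trial == b] = a
                post = model.log_posterior(_canonical0(trial))
                if best is None or post > best[0] + 1e-12:
                    best = (post, a, b)
        post, a, b = best
        merges.append((active[a], active[b], max(0.0, cur_post - post)))
        cluster_of[cluster_of == b] = a
        active[a] = next_node
        del active[b]
        next_node += 1
    return ClusterTree(partition, merges)


def assignment_certainty(
    trace: MCMCTrace,
    final: Partition,
    tree: ClusterTree | None = None,
    level: int | None = None,
) -> pd.DataFrame:
    """Per-individual, per-cluster assignment certainty in [0, 1].

    For each MCMC sample, the overlap between final cluster k and the
    individual's sampled cluster (|intersection| / |sampled cluster|),
    averaged over samples; rows sum to 1. With ``tree`` and ``level`` the
    certainty is aggregated by summing over the clusters merged at that
    level.
    """
    target = final if tree is None or level is None else tree.partition_at_level(level)
    n = len(target.ids)
    Kf = target.n_clusters
    F = np.zeros((n, Kf))
    F[np.arange(n), target.labels - 1] = 1.0
    acc = np.zeros((n, Kf))
    for s in trace.samples:
        Ks = int(s.max()) + 1
        M = np.zeros((n, Ks))
        M[np.arange(n), s] = 1.0
        sizes = M.sum(axis=0)
        acc += M @ ((M.T @ F) / sizes[:, None])
    acc /= len(trace.samples)
    cols = [f"cluster_{k}" for k in range(1, Kf + 1)]
    return pd.DataFrame(acc, index=target.ids, columns=cols)


def select_tree_level(tree: ClusterTree, rule: str, threshold: int) -> int:
    """Deterministic tree-level choice (level = number of clusters).

    "all-greater-than": finest level at which every cluster is larger than
    ``threshold``. "first-large-merge": the level at which the first merge
    between two clusters each larger than ``threshold`` occurs. Falls back
    to the root (level 1) with a warning when unsatisfiable.
    """
    K = tree.leaf_partition.n_clusters
    if rule == "all-greater-than":
        for level in range(K, 0, -1):
            sizes = tree.partition_at_level(level).sizes()
            if np.all(sizes > threshold):
                return level
        warnings.warn("no level satisfies the size rule; returning the root")
        return 1
    if rule == "first-large-merge":
        # walk merges from the leaves; sizes of merging nodes
        size_of = {}
        part = tree.leaf_partition
        for k in range(1, K + 1):
            size_of[k] = int(np.sum(part.labels == k))
        for step, (a, b, _) in enumerate(tree.merges):
            if size_of[a] > threshold and size_of[b] > threshold:
                return K - step
            size_of[K + 1 + step] = size_of[a] + size_of[b]
        warnings.warn("no merge between two large clusters; returning the root")
        return 1
    raise ValueError(f"unknown rule: {rule!r}")


def build_external_sharing_matrix(
    X: CoancestryMatrix, donor_group_of: dict
) -> BlockMatrix:
    """Embed the rectangular external-sharing matrix X into the square block
    matrix C = [[0, X], [0, Y]]; every group-k entry of Y (self-pairs
    included) equals g_k = mean of the group-k entries of X."""
    for d in X.donors:
        if d not in donor_group_of:
            raise ValueError(f"donor without a group label: {d}")
    N, M = X.shape
    groups = np.array([donor_group_of[d] for d in X.donors])
    C = np.zeros((N + M, N + M))
    C[:N, N:] = X.values
    g_k = {}
    for g in dict.fromkeys(groups):
        cols = np.flatnonzero(groups == g)
        g_k[g] = float(X.values[:, cols].mean())
        block = np.ix_(N + cols, N + cols)
        C[block] = g_k[g]
    return BlockMatrix(C, X.recipients, X.donors, dict(donor_group_of), g_k)


def cluster_on_external_sharing(
    block: BlockMatrix,
    c_factor: float,
    n_burn: int = 200,
    n_sample: int = 300,
    thin: int = 5,
    seed: int = 0,
) -> tuple[MCMCTrace, Partition]:
    """Cluster recipients on their donor-group sharing only; donor groups are
    fixed (never split or merged), so splits and merges happen among
    recipients alone."""
    N = len(block.recipients)
    M = len(block.donors)
    groups = [block.donor_group_of[d] for d in block.donors]
    order = list(dict.fromkeys(groups))
    labels = np.empty(N + M, dtype=int)
    labels[:N] = np.arange(N)  # recipients start as singletons
    for j, g in enumerate(groups):
        labels[N + j] = N + order.index(g)
    free_idx = np.arange(N)
    free_cluster_ids = set(range(N))
    trace, part = cluster_mcmc(
        block,
        c_factor,
        n_burn=n_burn,
        n_sample=n_sample,
        thin=thin,
        seed=seed,
        _fixed=(free_idx, labels, free_cluster_ids),
    )
    return trace, part
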