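"""Population-level statistics.

Four pieces, in the order the analysis runs:

* PCA of the (already z-scaled) analysis variables — eigendecomposition
  of the correlation matrix — with a two-stage retention rule: discard
  components explaining <10% of the variance, then keep the smallest
  prefix reaching a cumulative target (75% for song-level analyses, 80%
  for element-level ones).
* Permuted discriminant function analysis (pDFA) for population
  discriminability with repeated measures: songs are nested in
  individuals, so significance comes from reassigning whole individuals
  to populations. The observed statistic averages balanced
  train/held-out splits (a fixed number of songs per individual is drawn
  for training; the remaining songs of the same individuals are
  cross-classified by a linear discriminant classifier); the null repeats
  the identical procedure on each permuted dataset, making observed and
  null exchangeable under the no-population-effect hypothesis.
* Pairwise squared Mahalanobis distances D^2 between population centroids
  under the pooled within-population covariance of the retained principal
  component scores.
* Monte-Carlo Mantel tests between distance matrices (one-sided,
  "greater", matching the isolation-by-distance direction; r reported
  with r^2 alongside) and average-linkage (UPGMA) dendrograms exported
  as Newick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    loadings: np.ndarray           # variables x components, orthonormal columns
    scores: np.ndarray             # rows x components
    variance_fraction: np.ndarray  # non-increasing, sums to <= 1


def pca(X: np.ndarray) -> PCAResult:
    """PCA via the correlation matrix of z-scaled data.

    Components are sorted by decreasing variance; each component's sign is
    fixed so its largest-magnitude loading is positive. Components beyond
    the numerical rank are dropped with a warning.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than variables")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in input")
    corr = (X.T @ X) / (n - 1)  # X z-scaled => this is the correlation matrix
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    total = w.sum()
    rank = int((w > 1e-10 * max(w.max(), 1.0)).sum())
    if rank < p:
        warnings.warn(f"rank-deficient input: keeping {rank} of {p} components")
        w, v = w[:rank], v[:, :rank]
    # sign convention: largest-|loading| entry positive
    for k in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, k])))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
    return PCAResult(loadings=v, scores=X @ v, variance_fraction=w / total)


def retain_components(variance_fractions, cumulative_target: float,
                      min_fraction: float = 0.10) -> int:
    """Two-stage retention: drop <10% components, then reach the target.

    From the components whose variance fraction is at least
    ``min_fraction`` (a prefix, fractions being non-increasing), keep the
    smallest number whose cumulative fraction reaches
    ``cumulative_target``; if they cannot, keep all of them and warn.
    """
    f = np.asarray(variance_fractions, dtype=float)
    eligible = f[f >= min_fraction]
    if eligible.size == 0:
        raise ValueError("no components reach the minimum variance fraction")
    cum = np.cumsum(eligible)
    hit = np.nonzero(cum >= cumulative_target)[0]
    if hit.size == 0:
        warnings.warn("eligible components cannot reach the cumulative target; keeping all")
        return int(eligible.size)
    return int(hit[0] + 1)


# ---------------------------------------------------------------------------
# pDFA
# ---------------------------------------------------------------------------

@dataclass
class PDFAResult:
    observed_correct_pct: float          # cross-classified held-out songs
    resubstitution_correct_pct: float    # training songs, for reference
    null_correct_pct: np.ndarray
    p_value: float
    confusion: np.ndarray                # population x population, rows sum to 100
    populations: list = field(default_factory=list)
    n_selection: int = 0
    #: per permutation, the population assigned to each individual (audit trail)
    permuted_assignments: np.ndarray | None = None
    individuals: list = field(default_factory=list)


def _balanced_rate(X, y_pop, groups_idx, k, rng,
                   confusion=None, pop_index=None):
    """One balanced draw: k train songs per individual, classify the rest."""
    train, test = [], []
    for idx in groups_idx:
        sel = rng.permutation(len(idx))
        train.append(idx[sel[:k]])
        if len(idx) > k:
            test.append(idx[sel[k:]])
    train = np.concatenate(train)
    lda = LinearDiscriminantAnalysis()
    lda.fit(X[train], y_pop[train])
    resub = float(np.mean(lda.predict(X[train]) == y_pop[train]))
    if test:
        test = np.concatenate(test)
        pred = lda.predict(X[test])
        rate = float(np.mean(pred == y_pop[test]))
        if confusion is not None:
            for t, p in zip(y_pop[test], pred):
                confusion[pop_index[t], pop_index[p]] += 1
    else:
        rate = resub
    return rate, resub


def pdfa(X, populations, individuals, n_permutations: int = 1000,
         n_selections: int = 100, seed=None) -> PDFAResult:
    """Permuted DFA over individuals nested in populations.

    The balanced selection size is the corpus-wide minimum per-individual
    song count; in a perfectly balanced corpus (every individual at the
    minimum) it drops to half that count so a held-out set exists. The
    null permutes whole individuals across populations (group sizes
    preserved) and recomputes the identical statistic;
    p = (#{null >= observed} + 1) / (n_permutations + 1).
    """
    X = np.asarray(X, dtype=float)
    pops = np.asarray(populations)
    indivs = np.asarray(individuals)
    if np.ptp(X, axis=0).min() == 0:
        raise ValueError("constant feature column")
    uniq_pops = sorted(set(pops.tolist()))
    if len(uniq_pops) < 2:
        raise ValueError("need at least 2 populations")
    pop_index = {p: i for i, p in enumerate(uniq_pops)}

    uniq_ind, ind_codes = np.unique(indivs, return_inverse=True)
    groups_idx = [np.nonzero(ind_codes == g)[0] for g in range(len(uniq_ind))]
    group_pop = np.array([pops[idx[0]] for idx in groups_idx], dtype=object)
    for g, idx in enumerate(groups_idx):
        if len(set(pops[idx].tolist())) != 1:
            raise ValueError(f"individual {uniq_ind[g]!r} spans populations")
    pops_of_groups = {}
    for p in uniq_pops:
        members = [g for g in range(len(uniq_ind)) if group_pop[g] == p]
        if len(members) < 2:
            raise ValueError(f"population {p!r} has fewer than 2 individuals")
        pops_of_groups[p] = members

    counts = np.array([len(idx) for idx in groups_idx])
    k = int(counts.min())
    if counts.max() == k:  # perfectly balanced: split so a held-out set exists
        k = max(1, k // 2)

    rng = np.random.default_rng(seed)
    confusion = np.zeros((len(uniq_pops), len(uniq_pops)))
    y = pops.copy()
    obs_rates, resub_rates = [], []
    for _ in range(n_selections):
        r, rs = _balanced_rate(X, y, groups_idx, k, rng,
                               confusion=confusion, pop_index=pop_index)
        obs_rates.append(r)
        resub_rates.append(rs)
    observed = float(np.mean(obs_rates)) * 100
    resub = float(np.mean(resub_rates)) * 100

    null = np.empty(n_permutations)
    n_groups = len(groups_idx)
    stored = np.empty((n_permutations, n_groups), dtype=object)
    for b in range(n_permutations):
        perm = rng.permutation(n_groups)
        y_perm = np.empty(len(pops), dtype=object)
        for g, pg in enumerate(perm):
            y_perm[groups_idx[g]] = group_pop[pg]
        stored[b] = group_pop[perm]
        rates = [_balanced_rate(X, y_perm, groups_idx, k, rng)[0]
                 for _ in range(n_selections)]
        null[b] = np.mean(rates)
    p = (np.sum(null * 100 >= observed) + 1) / (n_permutations + 1)

    row_sums = confusion.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    confusion = 100 * confusion / row_sums
    return PDFAResult(observed_correct_pct=observed,
                      resubstitution_correct_pct=resub,
                      null_correct_pct=null * 100, p_value=float(p),
                      confusion=confusion, populations=uniq_pops,
                      n_selection=k, permuted_assignments=stored,
                      individuals=list(uniq_ind))


# ---------------------------------------------------------------------------
# Mahalanobis distances between population centroids
# ---------------------------------------------------------------------------

def pairwise_mahalanobis(scores, populations):
    """Squared Mahalanobis distances D^2 between population centroids.

    D^2(g, h) = (mu_g - mu_h)' S_pooled^-1 (mu_g - mu_h), with S_pooled
    the within-population covariance pooled over groups with n - G
    degrees of freedom. Returns ``(names, D2 matrix)``.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    pops = np.asarray(populations)
    names = sorted(set(pops.tolist()))
    if len(names) < 2:
        raise ValueError("need at least 2 populations")
    n, d = X.shape
    mus, pooled = [], np.zeros((d, d))
    for p in names:
        g = X[pops == p]
        mus.append(g.mean(axis=0))
        if len(g) > 1:
            pooled += (len(g) - 1) * np.cov(g, rowvar=False).reshape(d, d)
    pooled /= (n - len(names))
    if np.linalg.cond(pooled) > 1e12:
        raise ValueError(
            "singular pooled covariance: principal-component scores are "
            "collinear within populations")
    chol = np.linalg.cholesky(pooled)
    D2 = np.zeros((len(names), len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            diff = mus[i] - mus[j]
            z = np.linalg.solve(chol, diff)
            D2[i, j] = D2[j, i] = float(z @ z)
    return names, D2


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    r_squared: float
    p_value: float
    n_permutations: int


def mantel(d1, d2, n_permutations: int = 999, seed=None) -> MantelResult:
    """Monte-Carlo Mantel test, one-sided (greater).

    Pearson correlation of the lower-triangle entries; the null applies
    the same random relabelling to the rows and columns of the second
    matrix; p = (#{r_perm >= r_obs} + 1) / (n_permutations + 1).
    """
    A = np.asarray(d1, dtype=float)
    B = np.asarray(d2, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square with matching shapes")
    for M in (A, B):
        if not np.allclose(M, M.T):
            raise ValueError("distance matrices must be symmetric")
    n = A.shape[0]
    if n < 4:
        warnings.warn("fewer than 4 labels: permutation distribution is degenerate")
    tri = np.tril_indices(n, k=-1)
    a = A[tri]

    def corr_with(Bp):
        b = Bp[tri]
        # degenerate label sets (warned above) make corrcoef noisy; the
        # resulting nan r is the honest answer
        with np.errstate(invalid="ignore", divide="ignore"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(np.corrcoef(a, b)[0, 1])

    r_obs = corr_with(B)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if corr_with(B[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return MantelResult(r=r_obs, r_squared=r_obs ** 2, p_value=float(p),
                        n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# dendrograms
# ---------------------------------------------------------------------------

def cluster_dendrogram(dist, labels):
    """Average-linkage (UPGMA) tree; returns (linkage matrix, Newick string)."""
    D = np.asarray(dist, dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    tree = hierarchy.to_tree(Z)

    def newick(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length / 2:.6g}"
        left = newick(node.left, node.dist)
        right = newick(node.right, node.dist)
        return f"({left},{right}):{length / 2:.6g}"

    # heights are merge distances; branch lengths halve them (ultrametric)
    def newick_root(node):
        left = newick(node.left, node.dist)
        right = newick(node.right, node.dist)
        return f"({left},{right});"

    return Z, newick_root(tree)
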