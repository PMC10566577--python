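"""Phylogenetic-signal machinery: trees, Mantel tests, K_mult, CLR-PCA.

The central question is whether mutation-spectrum divergence between species
tracks their phylogenetic divergence.  Two complementary statistics are used:

* the **Mantel test** — Pearson correlation between the off-diagonal entries
  of two labeled distance matrices, with significance from jointly permuting
  the rows and columns of one matrix.  Under Brownian trait evolution the
  expected trait divergence scales with the square root of cophenetic
  distance, so the phylogenetic matrix is square-rooted before testing.
* **K_mult** — the multivariate generalization of Blomberg's K: the ratio of
  observed trait dispersion to the dispersion expected under Brownian motion
  on the tree (expectation 1 under Brownian motion), with a tip-shuffling
  permutation p-value.

Permutation p-values use the bias-corrected estimator (b+1)/(N+1), whose
attainable floor is 1/(N+1) — e.g. 1e-5 at 99,999 permutations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .containers import PhyloDistances, SpectrumTable

__all__ = [
    "read_tree",
    "cophenetic_matrix",
    "brownian_covariance",
    "mantel_test",
    "partial_mantel",
    "k_mult",
    "scalar_distance_matrix",
    "watterson_theta",
    "clr_pca",
    "bonferroni_threshold",
    "MantelResult",
    "KmultResult",
    "PCAResult",
]


def read_tree(newick: str) -> dendropy.Tree:
    """Parse a Newick tree (from a string or a file path)."""
    if "(" not in newick:
        with open(newick) as fh:
            newick = fh.read()
    return dendropy.Tree.get(data=newick, schema="newick")


def _leaf_labels(tree: dendropy.Tree) -> list:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("leaf labels are not unique")
    return labels


def _check_branch_lengths(tree: dendropy.Tree) -> None:
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            raise ValueError("negative branch length")


def cophenetic_matrix(tree, sqrt: bool = False) -> PhyloDistances:
    """Leaf-pairwise path-length distances; optionally elementwise sqrt.

    Square-rooting matches the Brownian-motion expectation that trait
    divergence grows with the square root of shared-path distance.
    """
    if isinstance(tree, str):
        tree = read_tree(tree)
    _check_branch_lengths(tree)
    labels = _leaf_labels(tree)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
        D[i, j] = D[j, i] = d
    out = PhyloDistances(labels, D, kind="cophenetic")
    return out.sqrt() if sqrt else out


def brownian_covariance(tree) -> tuple[list, np.ndarray]:
    """Brownian tip covariance C: C_ij = shared root-to-MRCA path length.

    Computed as (d_i + d_j - D_ij)/2 from root-to-leaf depths d and the
    cophenetic matrix D.
    """
    if isinstance(tree, str):
        tree = read_tree(tree)
    _check_branch_lengths(tree)
    labels = _leaf_labels(tree)
    depth = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depth[leaf.taxon.label] = d
    D = cophenetic_matrix(tree).reorder(labels).values
    d = np.array([depth[l] for l in labels])
    C = (d[:, None] + d[None, :] - D) / 2.0
    return labels, C


# --------------------------------------------------------------------------
# Mantel machinery


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str
    seed: object = None

    @property
    def p_floor(self) -> float:
        """Minimum attainable p for this permutation count: 1/(n_perm+1)."""
        return 1.0 / (self.n_perm + 1)

    def __str__(self) -> str:
        return (f"Mantel r = {self.r:.4f}, p = {self.p:.3g} "
                f"({self.n_perm} permutations, tail={self.tail})")


def _aligned(D1: PhyloDistances, D2: PhyloDistances):
    if set(D1.labels) != set(D2.labels):
        raise ValueError("distance matrices are labeled with different sets")
    return D1.values, D2.reorder(D1.labels).values


def _offdiag_corr(x: np.ndarray, y: np.ndarray) -> float:
    # pearson on the upper-triangle entries
    xm, ym = x - x.mean(), y - y.mean()
    denom = math.sqrt((xm @ xm) * (ym @ ym))
    if denom == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    return float(xm @ ym / denom)


def mantel_test(D1: PhyloDistances, D2: PhyloDistances, n_perm: int = 9999,
                tail: str = "greater", seed=None) -> MantelResult:
    """Permutation Mantel test between two labeled distance matrices.

    ``r`` is the Pearson correlation of the upper-triangle entries.  The null
    distribution jointly permutes the rows and columns of ``D2``; the
    one-sided upper-tail p-value is (1 + #{r* >= r}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    A, B = _aligned(D1, D2)
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    a = A[iu]
    r_obs = _offdiag_corr(a, B[iu])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        null[i] = _offdiag_corr(a, B[np.ix_(perm, perm)][iu])
    p = _perm_p(r_obs, null, tail)
    return MantelResult(r_obs, p, n_perm, tail, seed)


def mantel_exact(D1: PhyloDistances, D2: PhyloDistances,
                 tail: str = "greater") -> MantelResult:
    """Exact Mantel p by enumerating all n! label permutations (small n)."""
    A, B = _aligned(D1, D2)
    n = A.shape[0]
    if n > 8:
        raise ValueError("exact enumeration is limited to n <= 8 labels")
    iu = np.triu_indices(n, k=1)
    a = A[iu]
    r_obs = _offdiag_corr(a, B[iu])
    null = np.array([_offdiag_corr(a, B[np.ix_(p, p)][iu])
                     for p in itertools.permutations(range(n))])
    # all n! permutations enumerated: p is the exact null tail fraction
    if tail == "greater":
        p = float(np.mean(null >= r_obs - 1e-12))
    elif tail == "less":
        p = float(np.mean(null <= r_obs + 1e-12))
    else:
        p = float(np.mean(np.abs(null) >= abs(r_obs) - 1e-12))
    return MantelResult(r_obs, p, len(null) - 1, tail)


def _perm_p(obs: float, null: np.ndarray, tail: str) -> float:
    if tail == "greater":
        b = int(np.sum(null >= obs - 1e-12))
    elif tail == "less":
        b = int(np.sum(null <= obs + 1e-12))
    else:
        b = int(np.sum(np.abs(null) >= abs(obs) - 1e-12))
    return (b + 1) / (len(null) + 1)


def _residual_matrix(Y: PhyloDistances, X: PhyloDistances) -> PhyloDistances:
    """Off-diagonal least-squares residuals of Y ~ X, as a symmetric matrix."""
    A, B = _aligned(Y, X)
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    y, x = A[iu], B[iu]
    beta, alpha = np.polyfit(x, y, 1)
    res = y - (alpha + beta * x)
    R = np.zeros_like(A)
    R[iu] = res
    R = R + R.T
    return PhyloDistances(Y.labels, R, kind="residual")


def partial_mantel(D_spec: PhyloDistances, D_covariate: PhyloDistances,
                   D_phylo: PhyloDistances, n_perm: int = 9999,
                   seed=None) -> MantelResult:
    """Phylogenetically aware Mantel test.

    Regresses both the spectrum-distance and covariate-distance matrices on
    the phylogenetic distance matrix (ordinary least squares over off-diagonal
    entries) and runs a permutation Mantel test between the two residual
    matrices.  Asks whether the covariate explains spectrum divergence beyond
    what the phylogeny explains.
    """
    R_spec = _residual_matrix(D_spec, D_phylo)
    R_cov = _residual_matrix(D_covariate.reorder(R_spec.labels), D_phylo)
    return mantel_test(R_spec, R_cov, n_perm=n_perm, tail="greater", seed=seed)


# --------------------------------------------------------------------------
# K_mult


@dataclass(frozen=True)
class KmultResult:
    k_mult: float
    p: float
    n_perm: int
    seed: object = None

    def __str__(self) -> str:
        return f"K_mult = {self.k_mult:.4f}, p = {self.p:.3g}"


def _kmult_stat(Y: np.ndarray, Cinv: np.ndarray, trC: float,
                ones: np.ndarray) -> float:
    n = Y.shape[0]
    s = ones @ Cinv @ ones
    a = (Cinv @ Y).sum(axis=0) / s           # phylogenetic (GLS) mean
    E = Y - a
    num = float(np.sum(E * E))
    den = float(np.sum(E * (Cinv @ E)))
    if den == 0:
        raise ValueError("degenerate trait matrix")
    expected = (trC - n / s) / (n - 1)
    return (num / den) / expected


def k_mult(tree, traits: SpectrumTable | pd.DataFrame, n_perm: int = 999,
           seed=None) -> KmultResult:
    """Multivariate Blomberg's K for a species x traits matrix on a tree.

    K_mult = [sum_traits (Y-a)'(Y-a) / sum_traits (Y-a)'C^-1(Y-a)]
             / [(tr(C) - n/(1'C^-1 1)) / (n-1)]
    with C the Brownian tip covariance and a the GLS phylogenetic mean; the
    expectation under Brownian motion is 1.  The p-value shuffles tip labels
    (upper tail).  ``n_perm=0`` skips the permutation p-value.
    """
    df = traits.data if isinstance(traits, SpectrumTable) else traits
    labels, C = brownian_covariance(tree)
    missing = set(labels) - set(df.index)
    if missing:
        raise ValueError(f"traits missing for leaves {sorted(missing)}")
    Y = df.loc[labels].to_numpy(dtype=float)
    n = len(labels)
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular Brownian covariance matrix") from err
    trC = float(np.trace(C))
    ones = np.ones(n)
    obs = _kmult_stat(Y, Cinv, trC, ones)
    if n_perm == 0:
        return KmultResult(obs, float("nan"), 0, seed)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _kmult_stat(Y[rng.permutation(n)], Cinv, trC, ones)
    return KmultResult(obs, _perm_p(obs, null, "greater"), n_perm, seed)


# --------------------------------------------------------------------------
# covariates, diversity, PCA


def scalar_distance_matrix(values: dict, kind: str = "scalar_abs_diff"
                           ) -> PhyloDistances:
    """|v_i - v_j| distance matrix from one scalar per species."""
    labels = list(values)
    v = np.array([values[l] for l in labels], dtype=float)
    if np.any(np.isnan(v)):
        raise ValueError("missing covariate values")
    return PhyloDistances(labels, np.abs(v[:, None] - v[None, :]), kind=kind)


def watterson_theta(n_chromosomes: int, n_segregating: int,
                    L_accessible: float) -> float:
    """Watterson's theta per site: S / (a_n * L), a_n = sum_{i<n} 1/i."""
    if n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes")
    if L_accessible <= 0:
        raise ValueError("accessible length must be positive")
    a_n = sum(1.0 / i for i in range(1, n_chromosomes))
    return n_segregating / (a_n * L_accessible)


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fractions: np.ndarray


def clr_pca(table: SpectrumTable) -> PCAResult:
    """PCA (column-centered SVD) of CLR-transformed spectra.

    Deterministic up to sign; the sign of each component is fixed so its
    largest-magnitude loading is positive.  Variance fractions sum to 1.
    """
    if table.stage != "clr":
        raise ValueError("clr_pca expects a CLR-transformed table")
    X = table.data.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows for a PCA")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    var = S ** 2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    pcs = [f"PC{i+1}" for i in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(U * S, index=table.data.index, columns=pcs),
        loadings=pd.DataFrame(Vt.T, index=table.data.columns, columns=pcs),
        variance_fractions=frac,
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise corrected per-test threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
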