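"""Spectrum normalization and Aitchison (compositional) geometry.

Cross-species spectrum comparison requires removing differences that come
from genome composition and diversity rather than from mutation rates:

1. **Rescale** each species' counts to a common reference k-mer composition:
   ``x_rescaled = x * (t_m,ref / T_ref) / (t_m,A / T_A)`` where ``t_m`` are
   accessible-genome ancestral k-mer target counts and ``T`` their sum.
   Pairwise CLR distances are invariant to which reference composition is
   chosen, as long as it is shared.
2. **Downsample** all rows to a common SNP count with one multinomial draw
   (defaults to the minimum row total — the lowest-diversity species).
3. **Pseudocount** (+1 by default) so the log-ratio transforms are finite.
4. **CLR/ILR transform** into real coordinates where Euclidean distance is
   the Aitchison distance used throughout.

The stages must be applied in this order; ``SpectrumTable.provenance``
enforces it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.linalg import helmert
from scipy.spatial.distance import pdist, squareform

from .containers import PhyloDistances, SpectrumTable, TargetCounts
from .types import CPG_LABEL, MutationType, SpectrumSchema

__all__ = [
    "ancestral_targets",
    "rescale_counts",
    "downsample_multinomial",
    "add_pseudocount",
    "to_proportions",
    "clr",
    "ilr",
    "ilr_basis",
    "aitchison_distance_matrix",
    "cosine_similarity",
]


def ancestral_targets(schema: SpectrumSchema, targets: TargetCounts) -> pd.Series:
    """Per-type ancestral target counts t_m aligned to a schema.

    ``targets`` may be counted at a larger (or equal) k than the schema; its
    k-mers are then marginalized onto each type's ancestral context.  The
    1-mer+CpG and minus-CpG schemas need ``targets.k >= 3`` so the 3' base of
    the central C is observable.
    """
    k, K = schema.k, targets.k
    if K < k:
        raise ValueError(f"targets counted at k={K} cannot serve a k={k} schema")
    needs_cpg = schema.k == 1 and schema.cpg_policy in ("separate", "excluded")
    if needs_cpg and K < 3:
        raise ValueError("CpG-aware 1-mer schemas need targets counted at k >= 3")
    if schema.folded:
        raise ValueError("target counts are defined for unfolded schemas")

    h, H = k // 2, K // 2
    ctx = {}   # (central k-window, cpg flag or None) -> target count
    for kmer, t in targets.counts.items():
        window = kmer[H - h:H + h + 1]
        cpg = (kmer[H] == "C" and H + 1 < K and kmer[H + 1] == "G") if needs_cpg else None
        key = (window, cpg)
        ctx[key] = ctx.get(key, 0) + int(t)

    out = {}
    for lab in schema.labels:
        if lab == CPG_LABEL:
            out[lab] = ctx.get(("C", True), 0)
            continue
        t = MutationType.from_label(lab)
        if needs_cpg:
            if t.central_base == "C" and t.derived_base == "T":
                # plain C>T class: non-CpG contexts only once CpG is split off
                out[lab] = ctx.get((t.ancestral_kmer, False), 0)
            else:
                out[lab] = (ctx.get((t.ancestral_kmer, True), 0)
                            + ctx.get((t.ancestral_kmer, False), 0))
        else:
            out[lab] = ctx.get((t.ancestral_kmer, None), 0)
    return pd.Series(out, dtype=float)[list(schema.labels)]


def rescale_counts(x: SpectrumTable, targets_own: TargetCounts,
                   targets_ref: TargetCounts) -> SpectrumTable:
    """Rescale counts to the reference genome's k-mer composition.

    Every row (all rows share ``targets_own``; use one table per species) is
    multiplied type-wise by ``(t_m,ref / T_ref) / (t_m,own / T_own)``.  Output
    counts are real-valued; only a subsequent multinomial downsampling
    re-integerizes.  Types absent from the reference targets are dropped with
    a warning; a positive count over a zero own-target is an impossible
    observation and raises.
    """
    if x.stage != "raw":
        raise ValueError("rescaling applies to raw counts")
    t_own = ancestral_targets(x.schema, targets_own)
    t_ref = ancestral_targets(x.schema, targets_ref)
    T_own, T_ref = t_own.sum(), t_ref.sum()

    data = x.data.astype(float).copy()
    bad = (t_own == 0) & (data > 0).any(axis=0)
    if bad.any():
        raise ValueError(
            f"types with zero own-genome target but nonzero counts: "
            f"{list(data.columns[bad])[:5]}")
    drop = data.columns[(t_ref == 0).values]
    if len(drop):
        warnings.warn(f"dropping {len(drop)} types absent from the reference "
                      f"targets", stacklevel=2)
        data = data.drop(columns=drop)
        t_own, t_ref = t_own.drop(drop), t_ref.drop(drop)
    factor = (t_ref / T_ref) / (t_own / T_own).replace(0, np.nan)
    data = data * factor.fillna(0.0)
    return x.with_stage(data, "rescaled")


def downsample_multinomial(s: SpectrumTable, n_target: int | None = None,
                           seed=None) -> SpectrumTable:
    """One seeded multinomial draw of size ``n_target`` per row.

    Probabilities are the row fractions.  ``n_target=None`` uses the floor of
    the minimum row total (the lowest-diversity sample's SNP count).
    """
    if not s.is_counts():
        raise ValueError("downsampling applies to count tables")
    totals = s.row_totals()
    if (totals <= 0).any():
        raise ValueError("cannot downsample an all-zero row")
    if n_target is None:
        n_target = int(np.floor(totals.min()))
    rng = np.random.default_rng(seed)
    probs = s.data.div(totals, axis=0).to_numpy()
    out = np.vstack([rng.multinomial(n_target, p) for p in probs])
    return s.with_stage(pd.DataFrame(out, index=s.data.index,
                                     columns=s.data.columns), "downsampled")


def add_pseudocount(s: SpectrumTable, c: float = 1) -> SpectrumTable:
    """Add ``c`` to every cell so zero categories survive the log transforms."""
    if not s.is_counts():
        raise ValueError("pseudocount applies to count tables")
    return s.with_stage(s.data.astype(float) + c, "pseudocounted")


def to_proportions(s: SpectrumTable) -> SpectrumTable:
    if not s.is_counts():
        raise ValueError("already transformed")
    return s.with_stage(s.data.div(s.row_totals(), axis=0), "proportions")


def _clr_rows(mat: np.ndarray) -> np.ndarray:
    if np.any(mat <= 0):
        raise ValueError("CLR requires strictly positive entries "
                         "(apply a pseudocount first)")
    logm = np.log(mat)
    return logm - logm.mean(axis=1, keepdims=True)


def clr(p) -> np.ndarray | SpectrumTable:
    """Centered log-ratio: clr_i = ln(p_i) - mean_j ln(p_j).

    Accepts a 1-D composition, a 2-D array of row compositions, or a
    ``SpectrumTable`` (counts or proportions; counts are scale-invariant under
    CLR so no prior closure is needed).  Output rows sum to zero.
    """
    if isinstance(p, SpectrumTable):
        if p.stage in ("clr", "ilr"):
            raise ValueError("table is already log-ratio transformed")
        out = _clr_rows(p.data.to_numpy(dtype=float))
        return p.with_stage(pd.DataFrame(out, index=p.data.index,
                                         columns=p.data.columns), "clr")
    arr = np.asarray(p, dtype=float)
    one = arr.ndim == 1
    out = _clr_rows(np.atleast_2d(arr))
    return out[0] if one else out


def ilr_basis(dim: int) -> np.ndarray:
    """Orthonormal Helmert-type contrast basis, shape (dim-1, dim)."""
    return helmert(dim, full=False)


def ilr(p, basis: np.ndarray | None = None):
    """Isometric log-ratio coordinates: clr projected onto an orthonormal
    contrast basis.  Euclidean ILR distance equals the Aitchison distance."""
    if isinstance(p, SpectrumTable):
        if p.stage in ("clr", "ilr"):
            raise ValueError("table is already log-ratio transformed")
        dim = p.data.shape[1]
        V = ilr_basis(dim) if basis is None else _check_basis(basis, dim)
        out = _clr_rows(p.data.to_numpy(dtype=float)) @ V.T
        cols = [f"ilr{i+1}" for i in range(dim - 1)]
        df = pd.DataFrame(out, index=p.data.index, columns=cols)
        return p.with_stage(df, "ilr")
    arr = np.atleast_2d(np.asarray(p, dtype=float))
    V = ilr_basis(arr.shape[1]) if basis is None else _check_basis(basis, arr.shape[1])
    out = _clr_rows(arr) @ V.T
    return out[0] if np.asarray(p).ndim == 1 else out


def _check_basis(V: np.ndarray, dim: int) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if V.shape != (dim - 1, dim):
        raise ValueError(f"basis must have shape ({dim-1}, {dim})")
    if not (np.allclose(V @ V.T, np.eye(dim - 1), atol=1e-10)
            and np.allclose(V.sum(axis=1), 0, atol=1e-10)):
        raise ValueError("basis is not an orthonormal zero-sum contrast basis")
    return V


def aitchison_distance_matrix(s: SpectrumTable) -> PhyloDistances:
    """Pairwise Aitchison distances (Euclidean distance between CLR rows)."""
    if s.stage == "clr":
        rows = s.data.to_numpy(dtype=float)
    elif s.stage == "ilr":
        rows = s.data.to_numpy(dtype=float)  # isometric: same distances
    else:
        rows = _clr_rows(s.data.to_numpy(dtype=float))
    return PhyloDistances(list(s.data.index), squareform(pdist(rows)),
                          kind="aitchison")


def cosine_similarity(u, v) -> float:
    """u.v / (|u||v|); raises on zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))
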