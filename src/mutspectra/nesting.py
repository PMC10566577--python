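"""Conditional context-dependence test.

A k-mer spectrum inherits phylogenetic signal from its nested (k-2)-mer
spectrum, so a significant Mantel test at k=5 does not by itself show that
the *extra* flanking bases matter.  The test here builds control spectra in
which the dependence of mutation rate on the outer bases is erased: within
every (k-2)-mer equivalence class, the class's observed count total is
redistributed over its member k-mer types by a multinomial draw whose
probabilities are the species' genomic target fractions of each member k-mer.
The (k-2)-mer marginals are preserved exactly, so the controls carry all the
nested signal and none of the extended-context signal.  The empirical Mantel
correlation is then compared against the control distribution:
p = (1 + #{controls with r* >= r_obs}) / (n_control + 1).

Controls are pushed through the identical downstream chain (pseudocount, CLR,
Aitchison distance, Mantel r) as the empirical spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PhyloDistances, SpectrumTable, TargetCounts
from .normalize import _clr_rows
from .phylo import _offdiag_corr
from .types import MutationType

__all__ = ["equivalence_classes", "randomize_within_classes",
           "nested_signal_test", "NestedSignalResult"]


def equivalence_classes(schema) -> pd.Series:
    """Map each k-mer type label to its nested (k-2)-mer class label."""
    k = schema.k
    if k < 3:
        raise ValueError("equivalence classes need k >= 3")
    if schema.folded or schema.cpg_policy != "merged":
        raise ValueError("classes are defined on unfolded merged-policy schemas")
    h = k // 2
    out = {}
    for lab in schema.labels:
        t = MutationType.from_label(lab)
        inner = t.ancestral_kmer[1:-1]
        out[lab] = MutationType(inner, t.derived_base).label if k > 3 else \
            MutationType(t.ancestral_kmer[h], t.derived_base).label
    return pd.Series(out)


def _class_setup(s: SpectrumTable, targets: dict | TargetCounts):
    """Per-species within-class target probabilities and class index arrays."""
    labels = list(s.data.columns)
    classes = equivalence_classes(s.schema)[labels]
    class_names = list(dict.fromkeys(classes))
    class_id = np.array([class_names.index(c) for c in classes])
    species = list(s.data.index)
    if isinstance(targets, TargetCounts):
        targets = {sp: targets for sp in species}
    t = np.zeros((len(species), len(labels)))
    for i, sp in enumerate(species):
        tc = targets[sp]
        if tc.k != s.schema.k:
            raise ValueError("target counts k does not match the spectrum k")
        t[i] = [tc.get(MutationType.from_label(l).ancestral_kmer) for l in labels]
    # normalize targets within each class per species
    probs = np.zeros_like(t)
    for c in range(len(class_names)):
        m = class_id == c
        tot = t[:, m].sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs[:, m] = np.where(tot > 0, t[:, m] / tot, 0.0)
    return class_id, len(class_names), probs


def _randomize_batch(X: np.ndarray, class_id: np.ndarray, n_classes: int,
                     probs: np.ndarray, rng, size: int) -> np.ndarray:
    """``size`` control tables at once; shape (size, n_species, n_types)."""
    S, M = X.shape
    out = np.zeros((size, S, M))
    for c in range(n_classes):
        m = np.flatnonzero(class_id == c)
        for i in range(S):
            p = probs[i, m]
            tot = int(np.rint(X[i, m].sum()))
            if p.sum() == 0:
                # zero genomic target for the whole class: leave counts as-is
                out[:, i, m] = X[i, m]
                continue
            if len(m) == 1:
                out[:, i, m[0]] = tot
            else:
                out[:, i, m] = rng.multinomial(tot, p / p.sum(), size=size)
    return out


def randomize_within_classes(s: SpectrumTable, targets, seed=None
                             ) -> SpectrumTable:
    """One control spectrum table with extended-context effects erased."""
    if not s.is_counts():
        raise ValueError("randomization applies to count tables")
    class_id, n_classes, probs = _class_setup(s, targets)
    rng = np.random.default_rng(seed)
    X = s.data.to_numpy(dtype=float)
    out = _randomize_batch(X, class_id, n_classes, probs, rng, size=1)[0]
    return SpectrumTable(pd.DataFrame(out, index=s.data.index,
                                      columns=s.data.columns),
                         s.schema, s.provenance)


@dataclass
class NestedSignalResult:
    r_observed: float
    null_r: np.ndarray
    p: float
    n_control: int
    seed: object = None

    def null_quantiles(self, q=(0.025, 0.5, 0.975)) -> np.ndarray:
        return np.quantile(self.null_r, q)

    def __str__(self) -> str:
        lo, med, hi = self.null_quantiles()
        return (f"observed r = {self.r_observed:.4f}; control r median "
                f"{med:.4f} [{lo:.4f}, {hi:.4f}]; p = {self.p:.3g} "
                f"({self.n_control} controls)")


def nested_signal_test(s: SpectrumTable, targets, D_phylo: PhyloDistances,
                       n_control: int = 5000, pseudocount: float = 1.0,
                       seed=None) -> NestedSignalResult:
    """Does the k-mer spectrum carry signal beyond its (k-2)-mer marginals?

    ``s`` holds per-species counts at the stage the empirical Mantel test
    consumes (typically rescaled and downsampled); ``targets`` maps species to
    their own-genome :class:`TargetCounts` (or one shared set).  ``D_phylo``
    should hold square-rooted cophenetic distances.
    """
    if n_control < 1:
        raise ValueError("n_control must be >= 1")
    if not s.is_counts():
        raise ValueError("the test consumes count tables")
    labels = list(s.data.index)
    D = D_phylo.reorder(labels).values
    iu = np.triu_indices(len(labels), k=1)
    d = D[iu]

    def chain_r(X: np.ndarray) -> float:
        Z = _clr_rows(X + pseudocount)
        sq = (Z * Z).sum(axis=1)
        G = Z @ Z.T
        D2 = np.maximum(sq[:, None] + sq[None, :] - 2 * G, 0.0)
        return _offdiag_corr(np.sqrt(D2)[iu], d)

    X = s.data.to_numpy(dtype=float)
    r_obs = chain_r(X)

    class_id, n_classes, probs = _class_setup(s, targets)
    rng = np.random.default_rng(seed)
    null = np.empty(n_control)
    batch = 250
    done = 0
    while done < n_control:
        b = min(batch, n_control - done)
        ctrl = _randomize_batch(X, class_id, n_classes, probs, rng, size=b)
        Z = _clr_rows(ctrl.reshape(b * X.shape[0], -1) + pseudocount)
        Z = Z.reshape(b, X.shape[0], -1)
        sq = (Z * Z).sum(axis=2)
        G = Z @ Z.transpose(0, 2, 1)
        D2 = np.maximum(sq[:, :, None] + sq[:, None, :] - 2 * G, 0.0)
        dist = np.sqrt(D2)[:, iu[0], iu[1]]
        dm = dist - dist.mean(axis=1, keepdims=True)
        ym = d - d.mean()
        denom = np.sqrt((dm * dm).sum(axis=1) * (ym @ ym))
        null[done:done + b] = (dm @ ym) / denom
        done += b
    p = (1 + int(np.sum(null >= r_obs - 1e-12))) / (n_control + 1)
    return NestedSignalResult(r_obs, null, p, n_control, seed)
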