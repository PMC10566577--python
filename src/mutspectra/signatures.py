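"""Mutational-signature models for species-level spectra.

A mutational signature is a probability distribution over mutation types
attributed to one mutagenic process; a species' spectrum is modeled as a
multinomial draw from an exposure-weighted mixture of signatures.  Exposures
are estimated by maximum likelihood with an EM algorithm; optionally one
additional "novel" signature, shared across species, is estimated jointly
with the exposures (block EM with seeded restarts).

Also built here are the three human reproductive-aging signatures derived
from parental-age regressions of trio data: for each non-CpG 1-mer class c
the expected maternally/paternally transmitted mutation count at parental
age a is y_c(a) = m_c * a + b_c; the maternal (paternal) age signature
normalizes the slopes m_c, and the "young parent" signature normalizes
y_c,mat(13) + y_c,pat(13), i.e. the expected load of offspring of parents
reproducing at puberty (taken as age 13 in humans).

Usage follows the Model/Results convention::

    model = SignatureModel(counts_table, signature_set)
    res = model.fit()                       # exposures to fixed signatures
    res = model.fit(extract_novel=True)     # + one novel signature
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import PhyloDistances, SpectrumTable
from .normalize import aitchison_distance_matrix, cosine_similarity
from .phylo import MantelResult, mantel_test
from .types import (CPG_LABEL, MutationType, SpectrumSchema, collapse_strand,
                    is_cpg_transition)

__all__ = [
    "Signature",
    "SignatureSet",
    "read_signatures_tsv",
    "read_aging_table",
    "build_aging_signatures",
    "strip_cpg",
    "SignatureModel",
    "SignatureFitResults",
    "reconstruction_metrics",
]


@dataclass(frozen=True)
class Signature:
    """A named probability vector over a schema's mutation types."""

    name: str
    probs: pd.Series

    def __post_init__(self):
        p = self.probs.astype(float)
        if (p < 0).any():
            raise ValueError(f"signature {self.name!r} has negative entries")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"signature {self.name!r} does not sum to 1")
        object.__setattr__(self, "probs", p)

    @classmethod
    def from_weights(cls, name: str, weights: pd.Series) -> "Signature":
        w = weights.astype(float)
        if (w < 0).any():
            neg = list(w.index[w < 0])
            raise ValueError(
                f"signature {name!r}: negative weights for {neg}; cannot "
                "normalize to a probability vector")
        tot = w.sum()
        if tot <= 0:
            raise ValueError(f"signature {name!r}: all weights zero")
        return cls(name, w / tot)


class SignatureSet:
    """An ordered collection of signatures over one shared label universe."""

    def __init__(self, signatures):
        self.signatures = list(signatures)
        labels = [tuple(s.probs.index) for s in self.signatures]
        if len(set(labels)) > 1:
            raise ValueError("signatures are defined over different type sets")

    @property
    def names(self) -> list:
        return [s.name for s in self.signatures]

    @property
    def labels(self) -> list:
        return list(self.signatures[0].probs.index)

    def matrix(self, labels=None) -> np.ndarray:
        labels = self.labels if labels is None else list(labels)
        return np.vstack([s.probs.reindex(labels).to_numpy()
                          for s in self.signatures])

    def __len__(self):
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures)

    def __getitem__(self, name: str) -> Signature:
        for s in self.signatures:
            if s.name == name:
                return s
        raise KeyError(name)


def _canonical_label(label: str) -> str:
    """Accept 'ACA>AAA' or COSMIC 'A[C>A]A' labels; strand-collapse both."""
    if "[" in label:
        left, rest = label.split("[")
        sub, right = rest.split("]")
        anc_c, der_c = sub.split(">")
        anc = left + anc_c + right
        der = der_c
    else:
        anc, _, derk = label.partition(">")
        der = derk[len(derk) // 2]
    return collapse_strand(anc, der).label


def read_signatures_tsv(path, names=None) -> SignatureSet:
    """Read COSMIC-style signature columns keyed by mutation-type labels.

    The first column holds 96-type labels in either ``ACA>AAA`` or COSMIC
    ``A[C>A]A`` style (pyrimidine- or purine-centered; both are collapsed to
    the canonical strand).  Remaining columns are signatures.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = [_canonical_label(l) for l in df.index]
    schema = SpectrumSchema(len(df.index[0].partition(">")[0]))
    df = df.reindex(list(schema.labels)).fillna(0.0)
    cols = names if names is not None else list(df.columns)
    return SignatureSet([Signature.from_weights(c, df[c]) for c in cols])


# --------------------------------------------------------------------------
# reproductive-aging signatures

AGING_COLUMNS = ("maternal_slope", "maternal_intercept",
                 "paternal_slope", "paternal_intercept")


def read_aging_table(path) -> pd.DataFrame:
    """Parental-age regression coefficients per non-CpG 1-mer class.

    TSV columns: ``class`` (1-mer labels, any strand convention),
    ``maternal_slope``, ``maternal_intercept``, ``paternal_slope``,
    ``paternal_intercept`` — mutations per year of parental age and mutations
    at age zero, respectively.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index("class")
    df.index = [collapse_strand(l[0], l[2]).label for l in df.index]
    missing = [c for c in AGING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"aging table lacks columns {missing}")
    expected = set(SpectrumSchema(1, "excluded").labels)
    if set(df.index) != expected:
        raise ValueError(
            f"aging table classes {sorted(df.index)} do not cover the six "
            f"non-CpG 1-mer classes {sorted(expected)}")
    return df[list(AGING_COLUMNS)].astype(float)


def build_aging_signatures(table: pd.DataFrame,
                           puberty_age: float = 13.0) -> SignatureSet:
    """Maternal, paternal and young-parent signatures from regression slopes.

    maternal_c = m_c,mat / sum(m_mat); paternal analogous;
    young_parent_c = (y_c,mat(puberty) + y_c,pat(puberty)) normalized, with
    y_c(a) = m_c * a + b_c.
    """
    labels = list(SpectrumSchema(1, "excluded").labels)
    t = table.loc[labels]
    maternal = Signature.from_weights("maternal_age", t["maternal_slope"])
    paternal = Signature.from_weights("paternal_age", t["paternal_slope"])
    young = (t["maternal_slope"] * puberty_age + t["maternal_intercept"]
             + t["paternal_slope"] * puberty_age + t["paternal_intercept"])
    return SignatureSet([maternal, paternal,
                         Signature.from_weights("young_parent", young)])


def strip_cpg(s: SpectrumTable, sigs: SignatureSet
              ) -> tuple[SpectrumTable, SignatureSet]:
    """Remove CpG-transition types from a spectrum and a signature set.

    CpG polymorphisms are depleted relative to de novo data (purifying
    selection, homoplasy, mismapping), so signature fits exclude them; the
    remaining signature mass is renormalized to sum to 1.  Idempotent.
    """
    schema = s.schema
    if schema.k == 1:
        if schema.cpg_policy == "excluded":
            return s, sigs
        if schema.cpg_policy != "separate":
            raise ValueError("1-mer CpG stripping needs the 'separate' policy")
        keep = [l for l in s.data.columns if l != CPG_LABEL]
        new_schema = SpectrumSchema(1, "excluded", schema.folded)
    else:
        keep = [l for l in s.data.columns
                if not is_cpg_transition(MutationType.from_label(l))]
        if keep == list(s.data.columns):
            return s, sigs
        new_schema = SpectrumSchema(schema.k, "excluded", schema.folded)
    table = SpectrumTable(s.data[keep], new_schema, s.provenance)
    new_sigs = SignatureSet([
        Signature.from_weights(sig.name, sig.probs.reindex(keep).dropna())
        for sig in sigs])
    return table, new_sigs


# --------------------------------------------------------------------------
# exposure fitting


class SignatureModel:
    """Multinomial signature-mixture model for per-species spectrum counts.

    Parameters
    ----------
    spectra : SpectrumTable
        Species x types counts (raw, rescaled or downsampled; counts are
        rescaled to the signature-reference genome composition upstream when
        external signature catalogs are used).
    signatures : SignatureSet
        Fixed signatures over the same type universe.
    """

    def __init__(self, spectra: SpectrumTable, signatures: SignatureSet):
        if not spectra.is_counts():
            raise ValueError("the model consumes count tables")
        if list(spectra.data.columns) != signatures.labels:
            raise ValueError("spectrum and signature type universes differ")
        self.spectra = spectra
        self.signatures = signatures
        self._X = spectra.data.to_numpy(dtype=float)
        if np.any(self._X < 0):
            raise ValueError("negative counts")

    def fit(self, extract_novel: bool = False, max_iter: int = 10000,
            tol: float = 1e-10, n_restarts: int = 10, seed=None
            ) -> "SignatureFitResults":
        """Maximum-likelihood exposures via EM.

        With ``extract_novel`` a single additional signature shared across
        species is estimated by block EM (exposure updates alternating with
        novel-signature updates); ``n_restarts`` seeded random
        initializations are run and the best log-likelihood kept.  The
        log-likelihood is non-decreasing across iterations in either mode.
        """
        X = self._X
        S = self.signatures.matrix()
        zero_cols = (S.sum(axis=0) == 0) & (X.sum(axis=0) > 0)
        if not extract_novel and np.any(zero_cols):
            raise ValueError(
                "types with observed counts have zero probability under every "
                f"signature: {list(self.spectra.data.columns[zero_cols])[:5]}")
        if extract_novel:
            if X.shape[0] < 2:
                raise ValueError("novel-signature extraction needs >= 2 species")
            best = None
            root = np.random.default_rng(seed)
            for _ in range(max(1, n_restarts)):
                out = _em(X, S, novel=True, max_iter=max_iter, tol=tol,
                          rng=np.random.default_rng(root.integers(2 ** 31)))
                if best is None or out["llf"] > best["llf"]:
                    best = out
            out = best
        else:
            out = _em(X, S, novel=False, max_iter=max_iter, tol=tol, rng=None)
        return SignatureFitResults(self, out, seed)


def _em(X, S_fixed, novel, max_iter, tol, rng):
    n_sp, M = X.shape
    K = S_fixed.shape[0]
    if novel:
        nov = rng.dirichlet(np.ones(M))
        S = np.vstack([S_fixed, nov])
        E = rng.dirichlet(np.ones(K + 1), size=n_sp)
    else:
        S = S_fixed
        E = np.full((n_sp, K), 1.0 / K)
    N = X.sum(axis=1, keepdims=True)
    llf_prev = -np.inf
    llf = llf_prev
    history = []
    tiny = 1e-300
    for it in range(1, max_iter + 1):
        P = E @ S
        llf = float(np.sum(X * np.log(np.maximum(P, tiny))))
        history.append(llf)
        if llf - llf_prev < tol * max(1.0, abs(llf)) and it > 1:
            break
        llf_prev = llf
        R = X / np.maximum(P, tiny)              # n_sp x M
        E = E * (R @ S.T)
        E /= np.maximum(N, tiny)
        E = np.maximum(E, 0)
        E /= E.sum(axis=1, keepdims=True)
        if novel:
            # expected counts attributed to the novel component, summed
            # over species, renormalized
            w = (X * (E[:, -1:] * S[-1][None, :])
                 / np.maximum(E @ S, tiny)).sum(axis=0)
            if w.sum() > 0:
                S = np.vstack([S_fixed, w / w.sum()])
    return {"exposures": E, "S": S, "novel": novel, "llf": llf,
            "n_iter": len(history), "history": np.asarray(history),
            "converged": len(history) < max_iter}


@dataclass
class SignatureFitResults:
    """Estimated exposures, reconstructions and diagnostics of a fit."""

    model: SignatureModel
    _out: dict = field(repr=False)
    seed: object = None

    def __post_init__(self):
        names = list(self.model.signatures.names)
        if self._out["novel"]:
            names = names + ["novel"]
        self.signature_names = names
        self.exposures = pd.DataFrame(self._out["exposures"],
                                      index=self.model.spectra.data.index,
                                      columns=names)
        if self._out["novel"]:
            nov = pd.Series(self._out["S"][-1],
                            index=self.model.spectra.data.columns)
            self.novel_signature = Signature("novel", nov / nov.sum())
            fixed = self.model.signatures.matrix()
            sims = {s.name: cosine_similarity(nov.to_numpy(), row)
                    for s, row in zip(self.model.signatures, fixed)}
            self.novel_similarity = pd.Series(sims)
            close = self.novel_similarity.max()
            if close > 0.999:
                warnings.warn(
                    "novel signature degenerated onto a fixed signature "
                    f"(cosine {close:.4f})", stacklevel=2)
        else:
            self.novel_signature = None
            self.novel_similarity = None

    # --- core quantities --------------------------------------------------
    @property
    def llf(self) -> float:
        return self._out["llf"]

    @property
    def converged(self) -> bool:
        return self._out["converged"]

    @property
    def llf_history(self) -> np.ndarray:
        return self._out["history"]

    @property
    def reconstructed(self) -> SpectrumTable:
        """Reconstructed per-species spectra as proportions."""
        P = self._out["exposures"] @ self._out["S"]
        df = pd.DataFrame(P, index=self.model.spectra.data.index,
                          columns=self.model.spectra.data.columns)
        return SpectrumTable(df, self.model.spectra.schema,
                             self.model.spectra.provenance + ("proportions",))

    def observed_proportions(self) -> pd.DataFrame:
        X = self.model.spectra.data
        return X.div(X.sum(axis=1), axis=0)

    def cosine_similarities(self) -> pd.Series:
        obs = self.observed_proportions()
        rec = self.reconstructed.data
        return pd.Series({sp: cosine_similarity(obs.loc[sp], rec.loc[sp])
                          for sp in obs.index})

    def residuals(self) -> pd.DataFrame:
        """Observed minus reconstructed proportions; rows sum to zero."""
        return self.observed_proportions() - self.reconstructed.data

    # --- downstream tests -------------------------------------------------
    def reconstructed_signal_test(self, D_phylo: PhyloDistances,
                                  n_perm: int = 9999, seed=None,
                                  floor: float = 1e-12) -> MantelResult:
        """Mantel test of reconstructed-spectrum Aitchison distances against
        (square-rooted) phylogenetic distances — do the reconstructions
        retain the empirical phylogenetic signal?"""
        rec = self.reconstructed
        data = rec.data
        if (data.to_numpy() <= 0).any():
            warnings.warn("zero reconstructed proportions floored before CLR",
                          stacklevel=2)
            data = data.clip(lower=floor)
            rec = SpectrumTable(data, rec.schema, rec.provenance)
        D_rec = aitchison_distance_matrix(rec)
        return mantel_test(D_rec, D_phylo, n_perm=n_perm, seed=seed)

    def summary(self) -> str:
        lines = ["Signature exposure fit (multinomial EM)",
                 "=" * 46,
                 f"species: {len(self.exposures)}   types: "
                 f"{self.model.spectra.data.shape[1]}   signatures: "
                 f"{', '.join(self.signature_names)}",
                 f"log-likelihood: {self.llf:.2f}   iterations: "
                 f"{self._out['n_iter']}   converged: {self.converged}",
                 "",
                 "Exposures:",
                 self.exposures.round(4).to_string(),
                 "",
                 "Reconstruction cosine similarity:",
                 self.cosine_similarities().round(4).to_string()]
        if self.novel_signature is not None:
            lines += ["", "Novel-signature cosine similarity to fixed "
                      "signatures:", self.novel_similarity.round(4).to_string()]
        return "\n".join(lines)


def reconstruction_metrics(fit: SignatureFitResults,
                           observed: SpectrumTable | None = None):
    """(per-species cosine similarity, residual matrix) for a fit.

    ``observed`` defaults to the model's own spectra; providing a table
    cross-checks a fit against an alternative observation set.
    """
    if observed is None:
        return fit.cosine_similarities(), fit.residuals()
    obs = observed.data.div(observed.data.sum(axis=1), axis=0)
    rec = fit.reconstructed.data
    cos = pd.Series({sp: cosine_similarity(obs.loc[sp], rec.loc[sp])
                     for sp in obs.index})
    return cos, obs - rec
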