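"""k-mer mutation-type universe: strand collapsing, folding, CpG partitions.

A mutation type is an ancestral k-mer (odd k) together with a derived base that
replaces the central base.  Types are strand-collapsed so that the central
ancestral base is always A or C; e.g. the 1-mer spectrum has the six classes
A>C, A>G, A>T, C>A, C>G, C>T.  Context-expanded spectra annotate the central
substitution with (k-1)/2 flanking bases on each side: 96 types at k=3,
1,536 at k=5, 24,576 at k=7.

Type labels serialize as ``"TAC>TGC"`` — the ancestral k-mer, ``>``, and the
derived k-mer differing only at the center.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

__all__ = [
    "MutationType",
    "SpectrumSchema",
    "reverse_complement",
    "collapse_strand",
    "enumerate_types",
    "is_cpg_transition",
    "fold_type",
    "central_1mer",
    "CPG_LABEL",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = "ACGT"
#: the extra class label used by the 1-mer + CpG ("separate") spectrum
CPG_LABEL = "CpG>TpG"
#: central-substitution ordering used everywhere (canonical strand: A or C)
CENTRAL_ORDER = ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T")
SUPPORTED_K = (1, 3, 5, 7)


def reverse_complement(kmer: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    if not set(kmer) <= set("ACGTN"):
        bad = sorted(set(kmer) - set("ACGTN"))
        raise ValueError(f"non-IUPAC characters in k-mer: {bad}")
    return kmer.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=False)
class MutationType:
    """A strand-collapsed k-mer substitution.

    Parameters
    ----------
    ancestral_kmer : str
        Odd-length DNA string; the central base is the mutating site.
    derived_base : str
        The base replacing the central one; must differ from it.
    """

    ancestral_kmer: str
    derived_base: str

    def __post_init__(self):
        k = len(self.ancestral_kmer)
        if k % 2 == 0 or k not in SUPPORTED_K:
            raise ValueError(f"k must be odd and one of {SUPPORTED_K}, got {k}")
        if not set(self.ancestral_kmer) <= set(_BASES):
            raise ValueError(f"invalid ancestral k-mer {self.ancestral_kmer!r}")
        if self.derived_base not in _BASES:
            raise ValueError(f"invalid derived base {self.derived_base!r}")
        if self.derived_base == self.central_base:
            raise ValueError("derived base equals the central ancestral base")

    @property
    def k(self) -> int:
        return len(self.ancestral_kmer)

    @property
    def central_base(self) -> str:
        return self.ancestral_kmer[self.k // 2]

    @property
    def derived_kmer(self) -> str:
        h = self.k // 2
        return self.ancestral_kmer[:h] + self.derived_base + self.ancestral_kmer[h + 1:]

    @property
    def label(self) -> str:
        return f"{self.ancestral_kmer}>{self.derived_kmer}"

    @classmethod
    def from_label(cls, label: str) -> "MutationType":
        anc, _, der = label.partition(">")
        if not der or len(anc) != len(der):
            raise ValueError(f"malformed mutation-type label {label!r}")
        return cls(anc, der[len(der) // 2])

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def collapse_strand(anc_kmer: str, derived_base: str) -> MutationType:
    """Canonicalize a substitution so the central ancestral base is A or C.

    If the central base is G or T the ancestral k-mer is reverse-complemented
    and the derived base complemented; otherwise the input is returned as is.
    Idempotent by construction.
    """
    k = len(anc_kmer)
    if k % 2 == 0:
        raise ValueError("ancestral k-mer must have odd length")
    center = anc_kmer[k // 2]
    if center == "N":
        raise ValueError("central base is N; cannot strand-collapse")
    if center in "AC":
        return MutationType(anc_kmer, derived_base)
    return MutationType(reverse_complement(anc_kmer),
                        derived_base.translate(_COMPLEMENT))


@dataclass(frozen=True)
class SpectrumSchema:
    """Defines the column universe of a spectrum table.

    Parameters
    ----------
    k : int
        Context size (1, 3, 5 or 7).
    cpg_policy : str
        ``"merged"`` — CpG transitions kept inside C>T (the plain spectrum);
        ``"separate"`` — at k=1, CpG>TpG split out as a 7th class (for k >= 3
        the CpG context is already visible so the universe is unchanged);
        ``"excluded"`` — CpG-transition types removed ("minus-CpG" spectrum).
    folded : bool
        Merge each type with its reverse substitution (X>Y with Y>X) to
        remove sensitivity to ancestral-allele misidentification.
    """

    k: int
    cpg_policy: str = "merged"
    folded: bool = False

    def __post_init__(self):
        if self.k not in SUPPORTED_K:
            raise ValueError(f"unsupported k={self.k}; expected one of {SUPPORTED_K}")
        if self.cpg_policy not in ("merged", "separate", "excluded"):
            raise ValueError(f"unknown cpg_policy {self.cpg_policy!r}")

    @property
    def labels(self) -> tuple:
        """Ordered, deterministic tuple of type labels for this schema."""
        return _schema_labels(self.k, self.cpg_policy, self.folded)

    def __len__(self) -> int:
        return len(self.labels)


def enumerate_types(schema: SpectrumSchema) -> list:
    """All type labels of a schema, in canonical order.

    The order sorts by central substitution (A>C, A>G, A>T, C>A, C>G, C>T)
    and then lexicographically by context, so external 96-type signature files
    align after strand mapping.  Folded schemas return the canonical (minimal)
    label of each fold orbit; the 1-mer+CpG schema appends ``CpG>TpG`` last
    (a class label with no single MutationType representation).
    """
    return list(schema.labels)


@lru_cache(maxsize=None)
def _base_labels(k: int) -> tuple:
    h = (k - 1) // 2
    labels = []
    for sub in CENTRAL_ORDER:
        anc_c, der_c = sub[0], sub[2]
        for flanks in sorted("".join(p) for p in product(_BASES, repeat=k - 1)):
            anc = flanks[:h] + anc_c + flanks[h:]
            labels.append(MutationType(anc, der_c).label)
    return tuple(labels)


@lru_cache(maxsize=None)
def _schema_labels(k: int, cpg_policy: str, folded: bool) -> tuple:
    labels = _base_labels(k)
    if cpg_policy == "excluded" and k >= 3:
        labels = tuple(lab for lab in labels
                       if not is_cpg_transition(MutationType.from_label(lab)))
    if folded:
        seen, out = set(), []
        for lab in labels:
            f = fold_type(MutationType.from_label(lab))
            if f not in seen:
                seen.add(f)
                out.append(f)
        labels = tuple(out)
    if cpg_policy == "separate" and k == 1:
        labels = labels + (CPG_LABEL,)
    return labels


def is_cpg_transition(t: MutationType) -> bool:
    """True iff the central substitution is C>T with a G immediately 3'.

    Requires k >= 3 so the 3' flanking base is part of the type itself; 1-mer
    classification reads a 3-mer window and handles CpG before projecting.
    """
    if t.k < 3:
        raise ValueError("CpG detection needs the 3' base; use a k >= 3 window")
    h = t.k // 2
    return (t.central_base == "C" and t.derived_base == "T"
            and t.ancestral_kmer[h + 1] == "G")


def fold_type(t: MutationType) -> str:
    """Label of the fold orbit of ``t``.

    Folding merges each type X>Y with the strand-collapsed form of the reverse
    substitution Y>X (context carried along), removing dependence on which
    allele is called ancestral.  The orbit label is the minimum of the two
    member labels under the canonical ordering, so folding is idempotent on
    labels.
    """
    partner = collapse_strand(t.derived_kmer, t.central_base)
    order = {lab: i for i, lab in enumerate(_base_labels(t.k))}
    return min(t.label, partner.label, key=order.__getitem__)


def central_1mer(t: MutationType) -> MutationType:
    """The nested 1-mer substitution of any k-mer type."""
    return MutationType(t.central_base, t.derived_base)
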