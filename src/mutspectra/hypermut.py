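"""Motif hypermutability scan.

For one species at a time (raw counts, no rescaling or downsampling — no
cross-species comparison happens here), every k-mer mutation type's rate
(count over genomic target size) is compared against the rate of its central
1-mer class with a two-sided Fisher's exact test.  The per-species benchmark
is the fold enrichment of CpG>TpG transitions over the background C>T rate
(classically ~7-9x); types that are Bonferroni-significant, are not CpG
transitions, and exceed that benchmark are the "super-CpG" hypermutable
motifs.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import fisher_exact

from .containers import SpectrumTable, TargetCounts
from .phylo import bonferroni_threshold
from .types import MutationType, is_cpg_transition

__all__ = ["EnrichmentRecord", "fisher_scan", "cpg_enrichment_threshold",
           "flag_super_cpg"]


@dataclass(frozen=True)
class EnrichmentRecord:
    type_label: str
    count: int
    target: int
    background_count: int
    background_target: int
    fold: float
    p: float
    significant: bool
    is_cpg: bool


def _one_row(s: SpectrumTable):
    if not s.is_counts():
        raise ValueError("the scan consumes raw count tables")
    if s.schema.folded or s.schema.cpg_policy != "merged":
        raise ValueError("the scan expects an unfolded merged-policy spectrum")
    if s.data.shape[0] != 1:
        raise ValueError("provide one species at a time")
    return s.data.iloc[0]


def _class_totals(s: SpectrumTable, targets: TargetCounts):
    """Per central-substitution totals of counts, and per central-base target
    totals (shared by the three substitutions of one ancestral base)."""
    if targets.k != s.schema.k:
        raise ValueError("targets k does not match the spectrum k")
    row = _one_row(s)
    h = s.schema.k // 2
    x_class: dict = {}
    for lab, x in row.items():
        t = MutationType.from_label(lab)
        key = f"{t.central_base}>{t.derived_base}"
        x_class[key] = x_class.get(key, 0) + int(x)
    t_base: dict = {}
    for kmer, t in targets.counts.items():
        t_base[kmer[h]] = t_base.get(kmer[h], 0) + int(t)
    return row, x_class, t_base


def fisher_scan(s: SpectrumTable, targets: TargetCounts,
                alpha: float = 0.05, alternative: str = "two-sided") -> list:
    """Fisher's exact test of every type against its 1-mer class.

    The 2x2 table is [[x_k, t_k - x_k], [x_b, t_b - x_b]] with the background
    b the central 1-mer class *excluding* the focal k-mer (no
    self-comparison); the reported fold enrichment uses the full 1-mer rate,
    (x_k/t_k) / (x_1/t_1), matching how enrichment is usually plotted.
    The default two-sided p sums hypergeometric probabilities of tables at
    most as probable as the observed one; ``alternative`` may also be
    ``"greater"`` or ``"less"``.  Bonferroni correction is over the number of
    types tested (t_k > 0).
    """
    row, x_class, t_base = _class_totals(s, targets)
    tested = []
    for lab, x in row.items():
        t = MutationType.from_label(lab)
        t_k = targets.get(t.ancestral_kmer)
        if t_k == 0:
            continue
        if x > t_k:
            raise ValueError(f"{lab}: count {x} exceeds target size {t_k}")
        tested.append((lab, t, int(x), t_k))
    thresh = bonferroni_threshold(alpha, len(tested)) if tested else alpha
    records = []
    for lab, t, x_k, t_k in tested:
        key = f"{t.central_base}>{t.derived_base}"
        x_1, t_1 = x_class[key], t_base[t.central_base]
        x_b, t_b = x_1 - x_k, t_1 - t_k
        _, p = fisher_exact([[x_k, t_k - x_k], [x_b, t_b - x_b]],
                            alternative=alternative)
        fold = 0.0 if x_k == 0 else (x_k / t_k) / (x_1 / t_1)
        records.append(EnrichmentRecord(
            type_label=lab, count=x_k, target=t_k, background_count=x_b,
            background_target=t_b, fold=fold, p=float(p),
            significant=p < thresh,
            is_cpg=is_cpg_transition(t) if t.k >= 3 else False))
    return records


def cpg_enrichment_threshold(s: SpectrumTable, targets: TargetCounts) -> float:
    """Species-specific CpG>TpG mutability over the background C>T rate.

    Aggregate CpG-transition rate (summed counts over summed CpG-context
    targets) divided by the background C>T rate, i.e. the rate of C>T
    mutations at non-CpG contexts.  A genome in which CpG transitions run at
    f times the background therefore recovers a threshold of f.
    """
    if s.schema.k < 3:
        raise ValueError("CpG contexts need a k >= 3 spectrum")
    row, x_class, t_base = _class_totals(s, targets)
    h = s.schema.k // 2
    x_cpg = t_cpg = 0
    for lab, x in row.items():
        t = MutationType.from_label(lab)
        if is_cpg_transition(t):
            x_cpg += int(x)
    for kmer, t in targets.counts.items():
        if kmer[h] == "C" and kmer[h + 1] == "G":
            t_cpg += int(t)
    x_ct, t_c = x_class.get("C>T", 0), t_base.get("C", 0)
    x_bg, t_bg = x_ct - x_cpg, t_c - t_cpg
    if x_bg <= 0:
        raise ValueError("no background C>T counts; CpG threshold undefined")
    if t_cpg == 0:
        raise ValueError("no CpG-context targets")
    return (x_cpg / t_cpg) / (x_bg / t_bg)


def flag_super_cpg(records: list, threshold: float) -> list:
    """Bonferroni-significant non-CpG-transition types at or above the
    species' CpG>TpG fold-enrichment benchmark."""
    return [r for r in records
            if r.significant and not r.is_cpg and r.fold >= threshold]
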