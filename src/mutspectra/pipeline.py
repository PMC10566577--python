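"""Spectrum extraction: VCF + reference/ancestral FASTA + BED masks -> counts.

The unit of observation is a biallelic SNP polarized against an ancestral
FASTA: the derived allele is whichever VCF allele differs from the ancestral
base (sites whose ancestral base matches neither allele are dropped).  A SNP
is classified into a strand-collapsed k-mer mutation type read from the
*ancestral* sequence, provided its full k-window lies inside the accessible
genome (chromosome minus all exclusion masks) and contains no N.  Variants
shared among individuals are assigned to exactly one randomly chosen carrier
so no mutation is counted twice.

Target counts — the number of accessible positions carrying each ancestral
k-mer — are collected under the identical window rule, so type-specific
rates x_m / t_m are internally consistent.

Coordinates: BED is 0-based half-open, VCF 1-based, everything internal
0-based.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from pyfaidx import Fasta

from .containers import AccessibleRegions, SpectrumTable, TargetCounts
from .types import (CPG_LABEL, MutationType, SpectrumSchema, collapse_strand,
                    fold_type, is_cpg_transition)

__all__ = [
    "load_masks_and_subtract",
    "count_targets",
    "classify_variants",
    "aggregate_species",
    "project_to_smaller_k",
]

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _collapse_code_map(k: int) -> np.ndarray:
    """Map each k-mer integer code to its strand-collapsed code."""
    n = 4 ** k
    codes = np.arange(n)
    digits = np.empty((k, n), dtype=np.int64)
    c = codes.copy()
    for j in range(k - 1, -1, -1):       # digit j = base at position j
        digits[j] = c % 4
        c //= 4
    center = digits[k // 2]
    rc = np.zeros(n, dtype=np.int64)
    for j in range(k):                   # reverse complement arithmetic
        rc = rc * 4 + (3 - digits[k - 1 - j])
    return np.where(center >= 2, rc, codes)


def _code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def load_masks_and_subtract(reference, masks) -> AccessibleRegions:
    """Accessible regions = each chromosome minus the union of all masks.

    ``reference`` is a FASTA path or ``pyfaidx.Fasta``; ``masks`` a list of
    BED paths (0-based half-open).  BED records naming chromosomes absent
    from the FASTA are skipped with a warning; malformed lines raise.
    """
    fasta = reference if isinstance(reference, Fasta) else Fasta(str(reference))
    lengths = {name: len(fasta[name]) for name in fasta.keys()}
    masked: dict = {c: [] for c in lengths}
    for path in masks:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed BED line")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                if start < 0 or end < start:
                    raise ValueError(f"{path}:{lineno}: invalid interval")
                if chrom not in lengths:
                    warnings.warn(f"{path}:{lineno}: chromosome {chrom!r} not "
                                  f"in FASTA; skipping", stacklevel=2)
                    continue
                masked[chrom].append((start, min(end, lengths[chrom])))

    regions = AccessibleRegions()
    for chrom, L in lengths.items():
        ivs = sorted(masked[chrom])
        # merge overlapping masks, then complement against [0, L)
        starts, ends, pos = [], [], 0
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        for s, e in merged:
            if s > pos:
                starts.append(pos)
                ends.append(s)
            pos = max(pos, e)
        if pos < L:
            starts.append(pos)
            ends.append(L)
        regions.add(chrom, starts, ends)
    return regions


def count_targets(ancestral, regions: AccessibleRegions, k: int,
                  label: str = "genome") -> TargetCounts:
    """Strand-collapsed ancestral k-mer counts over the accessible genome.

    A position is counted when its full k-window fits inside one accessible
    interval and contains no N.  Counting is invariant to reverse
    complementation of the input because of the central-base collapse.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    fasta = ancestral if isinstance(ancestral, Fasta) else Fasta(str(ancestral))
    cmap = _collapse_code_map(k)
    weights = 4 ** np.arange(k - 1, -1, -1)
    acc = np.zeros(4 ** k, dtype=np.int64)
    for chrom in regions.chroms():
        seq = str(fasta[chrom][:]).upper()
        starts, ends = regions.intervals[chrom]
        for s, e in zip(starts, ends):
            if e - s < k:
                continue
            arr = _encode(seq[s:e]).astype(np.int64)
            nwin = len(arr) - k + 1
            codes = np.zeros(nwin, dtype=np.int64)
            invalid = np.zeros(nwin, dtype=bool)
            for j in range(k):
                col = arr[j:j + nwin]
                invalid |= col > 3
                codes = codes * 4 + np.where(col > 3, 0, col)
            acc += np.bincount(cmap[codes[~invalid]], minlength=4 ** k)
    nz = np.nonzero(acc)[0]
    counts = pd.Series({_code_to_kmer(int(c), k): int(acc[c]) for c in nz},
                       dtype=np.int64).sort_index()
    return TargetCounts(label, k, counts)


def classify_variants(vcf_path, ancestral, regions: AccessibleRegions,
                      schema: SpectrumSchema, individuals=None,
                      seed=None) -> SpectrumTable:
    """Per-individual spectrum counts from a VCF of biallelic SNPs.

    Each qualifying SNP adds one count to the row of a single uniformly
    chosen carrier of the derived allele.  A SNP is skipped when it is not a
    biallelic SNP, fails FILTER, its window leaves the accessible region or
    touches an N, or the ancestral base matches neither REF nor ALT.
    """
    fasta = ancestral if isinstance(ancestral, Fasta) else Fasta(str(ancestral))
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if individuals is None:
        individuals = samples
    idx = []
    for name in individuals:
        if name not in samples:
            raise ValueError(f"sample {name!r} not present in the VCF")
        idx.append(samples.index(name))

    k = schema.k
    cpg_aware = schema.cpg_policy in ("separate", "excluded")
    win = max(k, 3) if (k == 1 and cpg_aware) else k
    wh = win // 2
    rng = np.random.default_rng(seed)
    labels = list(schema.labels)
    counts = pd.DataFrame(0, index=list(individuals), columns=labels,
                          dtype=np.int64)
    contigs = set(fasta.keys())

    for v in vcf:
        if v.FILTER is not None:          # cyvcf2: None means PASS / '.'
            continue
        alts = v.ALT
        if len(alts) != 1 or len(v.REF) != 1 or len(alts[0]) != 1:
            continue
        ref, alt = v.REF.upper(), alts[0].upper()
        if ref not in "ACGT" or alt not in "ACGT":
            continue
        if v.CHROM not in contigs:
            raise ValueError(f"contig {v.CHROM!r} missing from ancestral FASTA")
        pos0 = v.POS - 1
        if not regions.window_accessible(v.CHROM, pos0 - wh, pos0 + wh + 1):
            continue
        window = str(fasta[v.CHROM][pos0 - wh:pos0 + wh + 1]).upper()
        if len(window) != win or "N" in window:
            continue
        anc_base = window[wh]
        if anc_base not in (ref, alt):
            continue
        derived = alt if anc_base == ref else ref

        win3 = window[wh - 1:wh + 2] if win >= 3 else None
        cpg = (is_cpg_transition(collapse_strand(win3, derived))
               if win3 is not None else False)
        if k == 1:
            if cpg_aware and cpg and schema.cpg_policy == "excluded":
                continue
            if cpg_aware and cpg:
                label = CPG_LABEL
            else:
                t = collapse_strand(anc_base, derived)
                label = fold_type(t) if schema.folded else t.label
        else:
            t = collapse_strand(window[wh - k // 2:wh + k // 2 + 1], derived)
            if schema.cpg_policy == "excluded" and is_cpg_transition(t):
                continue
            label = fold_type(t) if schema.folded else t.label

        gts = v.genotypes
        derived_code = 0 if derived == ref else 1
        carriers = [i for i in idx
                    if derived_code in (gts[i][0], gts[i][1])]
        if not carriers:
            continue
        chosen = carriers[0] if len(carriers) == 1 else int(rng.choice(carriers))
        counts.loc[samples[chosen], label] += 1
    return SpectrumTable(counts, schema, ("raw",))


def aggregate_species(per_individual: SpectrumTable,
                      label: str = "species") -> SpectrumTable:
    """Column-wise sum of per-individual rows into one species row."""
    summed = per_individual.data.sum(axis=0).to_frame(label).T
    return SpectrumTable(summed, per_individual.schema,
                         per_individual.provenance)


def stack_species(tables: dict) -> SpectrumTable:
    """Stack one-species tables (shared schema) into a species x types table."""
    items = list(tables.items())
    schema = items[0][1].schema
    rows = []
    for name, t in items:
        if t.schema != schema:
            raise ValueError("schema mismatch between species tables")
        rows.append(t.data.sum(axis=0).rename(name))
    return SpectrumTable(pd.DataFrame(rows), schema, items[0][1].provenance)


def project_to_smaller_k(s: SpectrumTable, k_target: int,
                         cpg_policy: str | None = None) -> SpectrumTable:
    """Marginalize flanking bases: sum k-mer counts onto their nested
    (smaller-k) types.  Totals are preserved (except under an ``excluded``
    target policy, which drops CpG transitions)."""
    k = s.schema.k
    if k_target >= k:
        raise ValueError(f"target k={k_target} must be smaller than k={k}")
    if s.schema.folded or s.schema.cpg_policy != "merged":
        raise ValueError("projection is defined for unfolded merged-policy tables")
    if cpg_policy is None:
        cpg_policy = "merged"
    if k_target == 1 and cpg_policy in ("separate", "excluded") and k < 3:
        raise ValueError("CpG-aware projection needs k >= 3")
    target_schema = SpectrumSchema(k_target, cpg_policy, folded=False)
    h, ht = k // 2, k_target // 2
    mapping = {}
    for lab in s.data.columns:
        t = MutationType.from_label(lab)
        cpg = is_cpg_transition(t)
        if cpg_policy == "excluded" and cpg:
            continue
        if k_target == 1 and cpg_policy == "separate" and cpg:
            mapping[lab] = CPG_LABEL
        else:
            anc = t.ancestral_kmer[h - ht:h + ht + 1]
            mapping[lab] = MutationType(anc, t.derived_base).label
    cols = {lab: [] for lab in target_schema.labels}
    for src, dst in mapping.items():
        cols[dst].append(src)
    data = pd.DataFrame(
        {dst: s.data[srcs].sum(axis=1) if srcs else 0.0
         for dst, srcs in cols.items()},
        index=s.data.index)[list(target_schema.labels)]
    if s.is_counts():
        data = data.astype(s.data.dtypes.iloc[0])
    return SpectrumTable(data, target_schema, s.provenance)
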