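"""Synthetic data with the statistical structure the analysis assumes.

Everything the pipeline consumes can be generated here: a reference /
ancestral FASTA pair with exclusion masks, per-species VCFs whose SNPs are
drawn from k-mer mutation-rate compositions that evolve by Brownian motion in
CLR space along a phylogeny, scalar covariates (phylogenetically correlated
or exchangeable), and signature-mixture spectra.  Every generator is
deterministic given its seed and returns exact truth bookkeeping so
downstream tests compare against truth, never against figures.

The default 13-leaf tree mirrors the shape of a typical mammal panel: four
clades (six primate-like taxa, two rodent-like taxa on a long internal
branch, two cetacean-like and three carnivoran-like taxa), branch lengths in
expected substitutions per site.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd

from .containers import AccessibleRegions, SpectrumTable
from .phylo import read_tree
from .types import MutationType, SpectrumSchema

__all__ = [
    "DEFAULT_TREE",
    "simulate_reference_and_ancestral",
    "evolve_spectra_on_tree",
    "emit_vcf",
    "simulate_signature_mixture",
    "simulate_covariates",
    "write_fasta",
    "write_bed",
]

#: 13 leaves, 4 clades, long internal branch to the rodent-like pair
DEFAULT_TREE = (
    "(((((pri1:0.010,pri2:0.010):0.006,(pri3:0.013,pri4:0.013):0.003):0.008,"
    "(pri5:0.020,pri6:0.020):0.007):0.025,"
    "((cet1:0.016,cet2:0.016):0.022,"
    "(car1:0.012,(car2:0.006,car3:0.006):0.007):0.024):0.018):0.012,"
    "(rod1:0.021,rod2:0.021):0.150);"
)

_COMP = str.maketrans("ACGT", "TGCA")


def write_fasta(path, sequences: dict, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bed(path, chrom: str, intervals) -> None:
    with open(path, "w") as fh:
        for s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def simulate_reference_and_ancestral(length: int, seed=None,
                                     base_weights=(0.29, 0.21, 0.21, 0.29),
                                     substitution_fraction: float = 0.01,
                                     mask_fraction: float = 0.10,
                                     chrom: str = "chr1"):
    """An ancestral sequence, a derived reference, and exclusion masks.

    The reference equals the ancestral sequence except at a random
    ``substitution_fraction`` of positions (substituted uniformly among the
    other bases); masks are non-overlapping random intervals covering about
    ``mask_fraction`` of the chromosome.

    Returns ``(reference, ancestral, mask_intervals)``; write with
    :func:`write_fasta` / :func:`write_bed`.
    """
    w = np.asarray(base_weights, dtype=float)
    if w.min() < 0 or w.sum() <= 0:
        raise ValueError("invalid base composition weights")
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    anc = rng.choice(4, size=length, p=w)
    ref = anc.copy()
    n_sub = int(round(substitution_fraction * length))
    if n_sub:
        pos = rng.choice(length, size=n_sub, replace=False)
        ref[pos] = (ref[pos] + rng.integers(1, 4, size=n_sub)) % 4
    masks = []
    if mask_fraction > 0:
        target = int(mask_fraction * length)
        covered = 0
        taken = np.zeros(length, dtype=bool)
        tries = 0
        while covered < target and tries < 10000:
            tries += 1
            span = int(rng.integers(50, 200))
            s = int(rng.integers(0, max(1, length - span)))
            if taken[s:s + span].any():
                continue
            taken[s:s + span] = True
            masks.append((s, s + span))
            covered += span
        masks.sort()
    return "".join(bases[ref]), "".join(bases[anc]), masks


def _clr_to_composition(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def evolve_spectra_on_tree(tree, root_composition: pd.Series,
                           sigma2: float, seed=None) -> pd.DataFrame:
    """Brownian motion of a mutation-rate composition in CLR space.

    Each branch adds independent N(0, sigma2 * branch_length) increments per
    CLR coordinate, projected onto the zero-sum subspace; leaf CLR vectors
    map back to the simplex by softmax (the exact inverse CLR on that
    subspace).  Expected squared Aitchison distance between two leaves is
    proportional to their cophenetic distance.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    p0 = root_composition.astype(float)
    if (p0 <= 0).any():
        raise ValueError("root composition must be strictly positive")
    p0 = p0 / p0.sum()
    z0 = np.log(p0.to_numpy())
    z0 = z0 - z0.mean()
    if isinstance(tree, str):
        tree = read_tree(tree)
    rng = np.random.default_rng(seed)
    D = len(p0)
    values = {tree.seed_node: z0}
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            z = values[node]
        else:
            bl = node.edge.length or 0.0
            eps = rng.normal(0.0, np.sqrt(sigma2 * bl), size=D)
            eps -= eps.mean()
            z = values[node.parent_node] + eps
            values[node] = z
        if node.is_leaf():
            out[node.taxon.label] = _clr_to_composition(z)
    return pd.DataFrame(out, index=list(p0.index)).T


def _accessible_positions_by_kmer(anc: str, ref: str,
                                  regions: AccessibleRegions,
                                  chrom: str, k: int) -> dict:
    """Collapsed ancestral k-mer -> candidate SNP positions (0-based).

    A candidate position has its full k-window inside one accessible
    interval, an N-free ancestral window, and reference equal to ancestral at
    the center (so REF can be set to the ancestral base)."""
    h = k // 2
    pools: dict = {}
    starts, ends = regions.intervals[chrom]
    for s, e in zip(starts, ends):
        for pos in range(s + h, e - h):
            win = anc[pos - h:pos + h + 1]
            if "N" in win or ref[pos] != anc[pos]:
                continue
            center = win[h]
            key = win if center in "AC" else win.translate(_COMP)[::-1]
            pools.setdefault(key, []).append(pos)
    return pools


def emit_vcf(path, anc: str, ref: str, regions: AccessibleRegions,
             composition: pd.Series, n_individuals: int, n_snps: int,
             seed=None, chrom: str = "chr1", planted_motifs: dict | None = None,
             max_retries: int = 100) -> pd.Series:
    """Write a minimal VCF of ``n_snps`` biallelic SNPs drawn from a k-mer
    mutation-type composition; returns the exact truth counts per type.

    ``composition`` is indexed by unfolded merged-policy type labels;
    ``planted_motifs`` maps type labels to fold multipliers applied to their
    rate before renormalization.  Each SNP is placed at an unused accessible
    position whose ancestral context matches the sampled type (contexts on
    the reverse strand receive the complemented derived allele), and its
    derived allele is given to 1..n_individuals random carriers.
    """
    labels = list(composition.index)
    k = len(labels[0].partition(">")[0])
    schema = SpectrumSchema(k)
    if labels != list(schema.labels):
        raise ValueError("composition must cover the full merged k schema")
    rng = np.random.default_rng(seed)
    weights = composition.to_numpy(dtype=float).copy()
    if planted_motifs:
        for lab, fold in planted_motifs.items():
            weights[labels.index(lab)] *= fold
    weights = weights / weights.sum()

    pools = _accessible_positions_by_kmer(anc, ref, regions, chrom, k)
    for key in pools:
        rng.shuffle(pools[key])
    anc_of = {lab: MutationType.from_label(lab).ancestral_kmer for lab in labels}

    # types sharing an ancestral k-mer draw from one finite position pool;
    # allocate iteratively, moving overflow to types with spare capacity
    by_kmer: dict = {}
    for i, lab in enumerate(labels):
        by_kmer.setdefault(anc_of[lab], []).append(i)
    counts = np.zeros(len(labels), dtype=np.int64)
    remaining = n_snps
    resampled = 0
    for _ in range(max_retries):
        if remaining == 0:
            break
        cap = {kmer: len(pools.get(kmer, ())) - int(counts[idxs].sum())
               for kmer, idxs in by_kmer.items()}
        w = np.array([weights[i] if cap[anc_of[labels[i]]] > 0 else 0.0
                      for i in range(len(labels))])
        if w.sum() == 0:
            raise ValueError("insufficient genomic targets for the requested "
                             "number of SNPs")
        draw = rng.multinomial(remaining, w / w.sum())
        remaining = 0
        for kmer, idxs in by_kmer.items():
            want = int(draw[idxs].sum())
            if want <= cap[kmer]:
                counts[idxs] += draw[idxs]
                continue
            over = want - cap[kmer]
            remaining += over
            resampled += over
            for i in sorted(idxs, key=lambda i: -draw[i]):
                cut = min(draw[i], over)
                draw[i] -= cut
                over -= cut
                if over == 0:
                    break
            counts[idxs] += draw[idxs]
    else:
        raise ValueError("could not place all requested SNPs")
    if resampled:
        warnings.warn(f"{resampled} requested SNPs lacked genomic targets "
                      "and were resampled among remaining types",
                      stacklevel=2)

    records = []  # (pos, ref_base, alt_base, label)
    used: dict = {key: 0 for key in pools}
    for i, lab in enumerate(labels):
        t = MutationType.from_label(lab)
        kmer = t.ancestral_kmer
        for _ in range(int(counts[i])):
            pos = pools[kmer][used[kmer]]
            used[kmer] += 1
            h = k // 2
            center = anc[pos]
            derived = t.derived_base if center in "AC" \
                else t.derived_base.translate(_COMP)
            records.append((pos, center, derived, lab))
    records.sort()

    samples = [f"ind{j+1}" for j in range(n_individuals)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={len(anc)}>\n")
        fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for pos, ref_base, alt_base, _ in records:
            n_car = int(rng.integers(1, n_individuals + 1))
            carriers = set(rng.choice(n_individuals, size=n_car, replace=False))
            gts = ["0/1" if j in carriers else "0/0"
                   for j in range(n_individuals)]
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref_base}\t{alt_base}\t.\t"
                     f"PASS\t.\tGT\t" + "\t".join(gts) + "\n")

    truth = pd.Series(0, index=labels, dtype=np.int64)
    for _, _, _, lab in records:
        truth[lab] += 1
    return truth


def simulate_signature_mixture(signatures, exposures, n_counts: int,
                               seed=None) -> SpectrumTable:
    """Multinomial spectrum counts from exposure-weighted signature mixtures.

    ``exposures``: DataFrame (species x signature names) or Series for a
    single sample; rows must lie on the simplex.
    """
    if isinstance(exposures, pd.Series):
        exposures = exposures.to_frame().T
    if list(exposures.columns) != signatures.names:
        raise ValueError("exposure columns must match signature names")
    E = exposures.to_numpy(dtype=float)
    if np.any(E < 0) or not np.allclose(E.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("exposures must be non-negative and sum to 1")
    S = signatures.matrix()
    rng = np.random.default_rng(seed)
    P = E @ S
    counts = np.vstack([rng.multinomial(n_counts, p / p.sum()) for p in P])
    labels = signatures.labels
    k = len(labels[0].partition(">")[0]) if ">" in labels[0] else 1
    # infer the schema from the label universe
    for policy in ("merged", "separate", "excluded"):
        schema = SpectrumSchema(k, policy)
        if list(schema.labels) == labels:
            break
    else:
        raise ValueError("signature labels do not match any known schema")
    return SpectrumTable(pd.DataFrame(counts, index=exposures.index,
                                      columns=labels), schema, ("raw",))


def simulate_covariates(tree, mode: str = "brownian", sigma2: float = 1.0,
                        seed=None, root_value: float = 0.0) -> dict:
    """One scalar per species: Brownian on the tree, or exchangeable iid."""
    if isinstance(tree, str):
        tree = read_tree(tree)
    rng = np.random.default_rng(seed)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if mode == "independent":
        return {l: float(v) for l, v in
                zip(leaves, rng.normal(0.0, np.sqrt(sigma2), len(leaves)))}
    if mode != "brownian":
        raise ValueError(f"unknown mode {mode!r}")
    values = {tree.seed_node: root_value}
    out = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            bl = node.edge.length or 0.0
            values[node] = values[node.parent_node] + rng.normal(
                0.0, np.sqrt(sigma2 * bl))
        if node.is_leaf():
            out[node.taxon.label] = float(values[node])
    return out
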