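"""In-memory containers shared across the pipeline.

``SpectrumTable`` wraps a pandas DataFrame of per-individual or per-species
mutation-type counts (or their transformed descendants) together with its
schema and a provenance trail recording which normalization stages have been
applied.  ``TargetCounts`` holds accessible-genome ancestral k-mer counts (the
denominators of context-specific mutation rates).  ``AccessibleRegions`` is
the masked-genome interval set, and ``PhyloDistances`` a labeled symmetric
distance matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import SpectrumSchema

__all__ = ["SpectrumTable", "TargetCounts", "AccessibleRegions", "PhyloDistances"]

# normalization stages in their mandatory order of application
_STAGE_ORDER = ("raw", "rescaled", "downsampled", "pseudocounted",
                "proportions", "clr", "ilr")


@dataclass
class SpectrumTable:
    """Rows of mutation-type values keyed by individual or species.

    ``provenance`` is the tuple of pipeline stages applied so far, starting at
    ``("raw",)``.  Transform helpers in :mod:`mutspectra.normalize` append to
    it and refuse out-of-order application.
    """

    data: pd.DataFrame
    schema: SpectrumSchema
    provenance: tuple = ("raw",)

    def __post_init__(self):
        if "ilr" not in self.provenance:
            expected = list(self.schema.labels)
            if list(self.data.columns) != expected:
                # allow column subsets only if they are in schema order
                cols = [c for c in expected if c in set(self.data.columns)]
                if list(self.data.columns) != cols:
                    raise ValueError("columns do not follow the schema ordering")
        bad = [s for s in self.provenance if s not in _STAGE_ORDER]
        if bad:
            raise ValueError(f"unknown provenance stages {bad}")

    @property
    def stage(self) -> str:
        return self.provenance[-1]

    @property
    def labels(self) -> list:
        return list(self.data.index)

    def is_counts(self) -> bool:
        return self.stage in ("raw", "rescaled", "downsampled", "pseudocounted")

    def with_stage(self, data: pd.DataFrame, stage: str) -> "SpectrumTable":
        """New table with ``stage`` appended; enforces the pipeline order."""
        if _STAGE_ORDER.index(stage) <= _STAGE_ORDER.index(self.stage):
            raise ValueError(
                f"stage {stage!r} cannot follow {self.stage!r}; the pipeline "
                f"order is {' -> '.join(_STAGE_ORDER)}")
        return SpectrumTable(data, self.schema, self.provenance + (stage,))

    def row_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    # --- plain-text round trip -------------------------------------------
    def to_tsv(self, path) -> None:
        header = {"k": self.schema.k, "cpg_policy": self.schema.cpg_policy,
                  "folded": self.schema.folded, "provenance": list(self.provenance)}
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            self.data.to_csv(fh, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path) -> "SpectrumTable":
        with open(path) as fh:
            header = json.loads(fh.readline().lstrip("#"))
            data = pd.read_csv(fh, sep="\t", index_col="sample")
        schema = SpectrumSchema(header["k"], header["cpg_policy"], header["folded"])
        return cls(data, schema, tuple(header["provenance"]))


@dataclass
class TargetCounts:
    """Ancestral k-mer counts t_m over the accessible genome of one assembly.

    ``counts`` is indexed by strand-collapsed ancestral k-mer; ``total`` is
    T = sum(t_m), the number of accessible positions whose full k-window is
    accessible and N-free.
    """

    label: str
    k: int
    counts: pd.Series

    def __post_init__(self):
        if (self.counts < 0).any():
            raise ValueError("negative target counts")
        self.counts = self.counts.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def get(self, kmer: str) -> int:
        return int(self.counts.get(kmer, 0))

    def to_tsv(self, path) -> None:
        header = {"label": self.label, "k": self.k}
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            self.counts.rename("count").to_csv(fh, sep="\t", index_label="kmer")

    @classmethod
    def from_tsv(cls, path) -> "TargetCounts":
        with open(path) as fh:
            header = json.loads(fh.readline().lstrip("#"))
            s = pd.read_csv(fh, sep="\t", index_col="kmer")["count"]
        return cls(header["label"], header["k"], s)


@dataclass
class AccessibleRegions:
    """Per-chromosome sorted, non-overlapping half-open 0-based intervals."""

    intervals: dict = field(default_factory=dict)  # chrom -> (starts, ends) arrays

    def add(self, chrom: str, starts, ends) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if np.any(ends <= starts) or np.any(np.diff(starts) <= 0):
            raise ValueError("intervals must be sorted, non-empty, non-overlapping")
        if starts.size > 1 and np.any(starts[1:] < ends[:-1]):
            raise ValueError("intervals overlap")
        self.intervals[chrom] = (starts, ends)

    def chroms(self):
        return list(self.intervals)

    def total_length(self, chrom: str | None = None) -> int:
        if chrom is not None:
            s, e = self.intervals[chrom]
            return int((e - s).sum())
        return sum(self.total_length(c) for c in self.intervals)

    def window_accessible(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) lies entirely inside one accessible interval."""
        if chrom not in self.intervals:
            return False
        starts, ends = self.intervals[chrom]
        i = np.searchsorted(starts, start, side="right") - 1
        return i >= 0 and end <= ends[i]


@dataclass
class PhyloDistances:
    """Labeled symmetric distance matrix with zero diagonal."""

    labels: list
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    def reorder(self, labels) -> "PhyloDistances":
        idx = [self.labels.index(l) for l in labels]
        return PhyloDistances(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) entries, row-major."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def sqrt(self) -> "PhyloDistances":
        return PhyloDistances(self.labels, np.sqrt(self.values),
                              f"sqrt_{self.kind}")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels,
                     columns=self.labels).to_csv(path, sep="\t", index_label="")

    @classmethod
    def from_tsv(cls, path, kind="generic") -> "PhyloDistances":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.values, kind)
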