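"""Per-sample and between-sample microbiome computation.

Count tables are handled as ASV-level sample x taxon integer matrices.
Composition is analysed on the simplex via the centred log-ratio (CLR)
transform, so between-sample dissimilarity is the Aitchison distance
(Euclidean distance between CLR vectors), a proper metric on compositions.
Alpha diversity (richness, Shannon in nats) is computed on a single seeded
rarefaction draw; rare-taxon filtering and aerotolerance stratification
operate on the unrarefied counts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = [
    "CountTable",
    "TaxonAnnotation",
    "rarefy",
    "alpha_diversity",
    "filter_taxa",
    "clr_transform",
    "aitchison_distances",
    "subset_by_aerotolerance",
]

AEROTOLERANCE_CLASSES = ("aerotolerant", "anaerobic", "unknown")


class CountTable:
    """Sample x taxon matrix of nonnegative integer read counts."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates or data.columns.has_duplicates:
            raise ValueError("duplicate sample or taxon IDs in count table")
        arr = data.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            data = data.round().astype(np.int64)
        if (data.to_numpy() < 0).any():
            raise ValueError("counts must be >= 0")
        self.data = data.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def select_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.data.loc[list(sample_ids)])

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def __repr__(self) -> str:  # pragma: no cover
        n, m = self.shape
        return f"CountTable({n} samples x {m} taxa)"


class TaxonAnnotation:
    """taxon_id -> (genus, aerotolerance class) lookup.

    The aerotolerance class is assigned at the genus level (aerotolerant =
    aerobic + facultatively anaerobic; anaerobic; unknown) and inherited by
    every ASV of that genus.
    """

    def __init__(self, data: pd.DataFrame):
        if not {"genus", "aerotolerance"}.issubset(data.columns):
            raise ValueError("annotation needs 'genus' and 'aerotolerance' columns")
        bad = set(data["aerotolerance"].unique()) - set(AEROTOLERANCE_CLASSES)
        if bad:
            raise ValueError(f"unknown aerotolerance classes: {sorted(bad)}")
        if data.index.has_duplicates:
            raise ValueError("duplicate taxon IDs in annotation")
        self.data = data

    def classes_for(self, taxon_ids) -> pd.Series:
        missing = [t for t in taxon_ids if t not in self.data.index]
        if missing:
            raise KeyError(f"taxa without aerotolerance annotation: {missing[:5]}"
                           f"{'...' if len(missing) > 5 else ''}")
        return self.data.loc[list(taxon_ids), "aerotolerance"]

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="taxon_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TaxonAnnotation":
        return cls(pd.read_csv(path, sep="\t", index_col="taxon_id"))


def rarefy(table: CountTable, depth: int = 8000,
           rng: np.random.Generator | None = None,
           seed: int | None = None) -> CountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are removed (not padded). Taxa that
    end up all-zero are retained; column pruning is a separate step.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = table.counts
    totals = counts.sum(axis=1)
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    out = np.empty((int(keep.sum()), counts.shape[1]), dtype=np.int64)
    for i, row_idx in enumerate(np.flatnonzero(keep)):
        row = counts[row_idx]
        if totals[row_idx] == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    kept_ids = [table.sample_ids[i] for i in np.flatnonzero(keep)]
    return CountTable(pd.DataFrame(out, index=pd.Index(kept_ids, name="sample_id"),
                                   columns=table.data.columns.copy()))


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Richness (taxa with count > 0) and Shannon diversity (nats) per sample."""
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"all-zero sample(s): {[table.sample_ids[i] for i in zero]}")
    p = counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    richness = (counts > 0).sum(axis=1)
    return pd.DataFrame({"richness": richness, "shannon": shannon},
                        index=table.data.index.copy())


def filter_taxa(table: CountTable, min_total: int = 50,
                min_prevalence: float = 0.05) -> CountTable:
    """Drop rare taxa: total reads < ``min_total`` across all samples, or
    present (count > 0) in fewer than ``min_prevalence`` of samples.

    Both thresholds are evaluated on the input table and applied jointly, so
    the result does not depend on filter order. Prevalence is retained-if
    >= ``min_prevalence`` (fraction of samples).
    """
    counts = table.counts
    totals = counts.sum(axis=0)
    prevalence = (counts > 0).mean(axis=0)
    keep = (totals >= min_total) & (prevalence >= min_prevalence)
    if not keep.any():
        raise ValueError("all taxa removed by abundance/prevalence filters")
    return CountTable(table.data.loc[:, keep])


def clr_transform(table: CountTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centred log-ratio transform: ln(c + pseudocount) minus the row mean.

    Every row of the result sums to zero (within numerical tolerance). A zero
    pseudocount is only valid when all counts are positive.
    """
    c = table.counts.astype(float) + pseudocount
    if (c <= 0).any():
        raise ValueError("nonpositive values after pseudocount; use pseudocount > 0 "
                         "for tables containing zeros")
    logc = np.log(c)
    clr = logc - logc.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.data.index.copy(),
                        columns=table.data.columns.copy())


def aitchison_distances(clr: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Aitchison distances: Euclidean distance between CLR rows."""
    vals = clr.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("CLR matrix must be finite")
    dm = squareform(pdist(vals, metric="euclidean"), checks=False)
    return DistanceMatrix(dm, ids=[str(s) for s in clr.index])


def subset_by_aerotolerance(table: CountTable, annot: TaxonAnnotation,
                            which: str) -> CountTable:
    """Retain taxa of one aerotolerance class ('aerotolerant' or 'anaerobic').

    Unknown-class taxa are excluded from both subsets. The caller is expected
    to re-filter and re-CLR-transform the subset (re-closure): the CLR of a
    subcomposition differs from a subset of the full-table CLR values.
    """
    if which not in ("aerotolerant", "anaerobic"):
        raise ValueError("which must be 'aerotolerant' or 'anaerobic'")
    classes = annot.classes_for(table.taxon_ids)
    keep = (classes == which).to_numpy()
    if not keep.any():
        raise ValueError(f"no taxa in class '{which}'")
    return CountTable(table.data.loc[:, keep])
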