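"""Data model, TSV I/O and preprocessing for genotype/phenotype benchmarks.

The in-memory containers are thin wrappers around pandas/numpy objects:

* :class:`GenotypeMatrix` — samples × markers, haploid ``{0,1}`` or diploid
  ``{-1,0,1}`` coding, with a marker map (chromosome, genetic position) and
  NaN-encoded missing values.
* :class:`PhenotypeTable` — per-trait response vectors (samples × traits),
  optionally replicated, with NaN-encoded missingness.
* :class:`GeneAnnotation` — gene intervals in 0-based half-open coordinates
  on the same axis as the marker map.

Preprocessing implements the conventions common in genomic-selection work:
missing-genotype imputation (column mean, or heterozygote for diploid data),
sliding-window LD pruning on pairwise r², replicate averaging, and per-trait
standardization to mean 0 / unit (n−1) variance.

File formats are plain TSV: genotypes as a sample × marker table with marker
ids in the header and sample ids in the first column; the map as a 3-column
TSV (marker, chromosome, position); phenotypes as a sample × trait table;
annotations as BED-like 4-column TSV (chromosome, start, end, gene id).
Missing values are written as ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

HAPLOID = "haploid01"
DIPLOID = "diploid-1,0,1"

_ALPHABETS = {HAPLOID: {0.0, 1.0}, DIPLOID: {-1.0, 0.0, 1.0}}


class DataFormatError(ValueError):
    """Raised when a file or matrix violates the documented format."""


@dataclass
class GenotypeMatrix:
    """Samples × markers genotype table with marker map metadata.

    ``values`` is a float array with NaN for missing entries. ``mapping`` is a
    DataFrame indexed by marker id with columns ``chromosome`` and
    ``position`` (genetic position, Morgans for simulated data).
    """

    values: np.ndarray
    coding: str
    sample_ids: list[str]
    marker_ids: list[str]
    mapping: pd.DataFrame | None = None
    pedigree: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataFormatError("genotype values must be 2-D")
        if self.values.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise DataFormatError("genotype shape does not match id lists")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise DataFormatError("duplicate marker ids")
        if self.coding not in _ALPHABETS:
            raise DataFormatError(f"unknown coding {self.coding!r}")
        self._check_alphabet()

    def _check_alphabet(self) -> None:
        allowed = _ALPHABETS[self.coding]
        vals = self.values[~np.isnan(self.values)]
        bad = ~np.isin(vals, sorted(allowed))
        if bad.any():
            offender = vals[bad][0]
            raise DataFormatError(
                f"value {offender!r} outside alphabet for coding {self.coding}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.marker_ids)

    def subset_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            pedigree=None,
        )

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {m: j for j, m in enumerate(self.marker_ids)}
        cols = [pos[m] for m in marker_ids]
        mapping = self.mapping.loc[list(marker_ids)] if self.mapping is not None else None
        return replace(
            self,
            values=self.values[:, cols],
            marker_ids=list(marker_ids),
            mapping=mapping,
        )


@dataclass
class PhenotypeTable:
    """Per-trait phenotype vectors with NaN missingness.

    ``traits`` is a samples × traits DataFrame. ``replicates``, when present,
    is a long DataFrame (sample, trait, replicate, value) that
    :func:`average_replicates` collapses into ``traits``.
    """

    traits: pd.DataFrame
    normalized: bool = False
    replicates: pd.DataFrame | None = None

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    def vector(self, trait: str) -> pd.Series:
        return self.traits[trait]


@dataclass
class GeneAnnotation:
    """Gene intervals, 0-based half-open, sorted by (chromosome, start)."""

    intervals: pd.DataFrame  # columns: gene_id, chromosome, start, end

    def __post_init__(self) -> None:
        df = self.intervals
        if (df["start"] >= df["end"]).any():
            raise DataFormatError("annotation interval with start >= end")
        self.intervals = df.sort_values(["chromosome", "start"], kind="stable").reset_index(
            drop=True
        )

    def for_chromosome(self, chrom: str) -> pd.DataFrame:
        return self.intervals[self.intervals["chromosome"] == chrom]


# ---------------------------------------------------------------------------
# File I/O


def read_genotypes(path, coding: str, map_path=None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    mapping = read_map(map_path) if map_path is not None else None
    G = GenotypeMatrix(
        values=df.to_numpy(dtype=float),
        coding=coding,
        sample_ids=[str(s) for s in df.index],
        marker_ids=[str(m) for m in df.columns],
        mapping=mapping,
    )
    return G


def write_genotypes(G: GenotypeMatrix, path, map_path=None) -> None:
    df = G.to_frame()
    df.index.name = "sample"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")
    if map_path is not None and G.mapping is not None:
        write_map(G.mapping, map_path)


def read_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chromosome": str})
    return df.set_index("marker")


def write_map(mapping: pd.DataFrame, path) -> None:
    out = mapping.reset_index()
    out.columns = ["marker", "chromosome", "position"]
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return PhenotypeTable(traits=df)


def write_phenotypes(P: PhenotypeTable, path) -> None:
    out = P.traits.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chromosome", "start", "end", "gene_id"],
        dtype={"chromosome": str, "gene_id": str},
    )
    return GeneAnnotation(intervals=df[["gene_id", "chromosome", "start", "end"]])


def write_annotation(ann: GeneAnnotation, path) -> None:
    ann.intervals[["chromosome", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Preprocessing


def impute(G: GenotypeMatrix, strategy: str = "column-mean") -> GenotypeMatrix:
    """Fill missing genotypes; observed entries are never altered.

    ``column-mean`` replaces NaN with the per-marker mean of observed values
    (the convention in the rice genomic-selection literature). ``heterozygote``
    replaces NaN with 0 (the aA class) and is only defined for diploid coding.
    """
    vals = G.values.copy()
    mask = np.isnan(vals)
    if not mask.any():
        return G
    if strategy == "column-mean":
        counts = (~mask).sum(axis=0)
        if (counts == 0).any():
            j = int(np.argmax(counts == 0))
            raise DataFormatError(
                f"marker {G.marker_ids[j]!r} is entirely missing; no column mean defined"
            )
        col_means = np.nanmean(vals, axis=0)
        vals[mask] = np.broadcast_to(col_means, vals.shape)[mask]
    elif strategy == "heterozygote":
        if G.coding != DIPLOID:
            raise DataFormatError("heterozygote imputation requires diploid coding")
        vals[mask] = 0.0
    else:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    # column means need not lie in the discrete alphabet, so skip revalidation
    return _bypass_alphabet(G, vals)


def _bypass_alphabet(G: GenotypeMatrix, vals: np.ndarray) -> GenotypeMatrix:
    out = GenotypeMatrix.__new__(GenotypeMatrix)
    out.values = vals
    out.coding = G.coding
    out.sample_ids = list(G.sample_ids)
    out.marker_ids = list(G.marker_ids)
    out.mapping = G.mapping
    out.pedigree = G.pedigree
    return out


def ld_prune(
    G: GenotypeMatrix, window: int = 50, step: int = 5, r2_threshold: float = 0.02
) -> list[str]:
    """Greedy sliding-window LD pruning on squared Pearson correlation.

    Within each window of ``window`` markers (advanced by ``step``), marker
    pairs with r² above the threshold are broken by removing the
    later-positioned marker; the retained set is returned in original marker
    order. Constant markers have undefined correlation and are treated as
    r² = 0 with everything (never removed for correlation).
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not 0 < r2_threshold < 1:
        raise ValueError("r2_threshold must be in (0,1)")
    vals = G.values
    if np.isnan(vals).any():
        raise DataFormatError("impute before LD pruning")
    p = G.n_markers
    removed = np.zeros(p, dtype=bool)
    sd = vals.std(axis=0)
    start = 0
    while True:
        end = min(start + window, p)
        idx = [j for j in range(start, end) if not removed[j] and sd[j] > 0]
        for a_pos in range(len(idx)):
            a = idx[a_pos]
            if removed[a]:
                continue
            for b in idx[a_pos + 1 :]:
                if removed[b]:
                    continue
                r = np.corrcoef(vals[:, a], vals[:, b])[0, 1]
                if r * r > r2_threshold:
                    removed[b] = True
        if end == p:
            break
        start += step
    return [m for j, m in enumerate(G.marker_ids) if not removed[j]]


def average_replicates(P: PhenotypeTable) -> PhenotypeTable:
    """Collapse replicated measurements to per-sample means (missing ignored)."""
    if P.replicates is None:
        return P
    wide = (
        P.replicates.groupby(["sample", "trait"])["value"].mean().unstack("trait")
    )
    return PhenotypeTable(traits=wide, normalized=False)


def normalize_phenotypes(P: PhenotypeTable) -> PhenotypeTable:
    """Standardize each trait over observed entries to mean 0, (n−1) variance 1."""
    out = P.traits.copy()
    for trait in out.columns:
        col = out[trait]
        obs = col.dropna()
        if obs.nunique() < 2:
            raise DataFormatError(f"trait {trait!r} is constant; cannot normalize")
        out[trait] = (col - obs.mean()) / obs.std(ddof=1)
    return PhenotypeTable(traits=out, normalized=True, replicates=P.replicates)
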