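"""Marker-fusion representations driven by a gene annotation.

Because markers inside one linkage block are nearly redundant, blocks of
markers can be fused into single binary attributes with minimal information
loss. Two schemes are provided:

* **gene + intergenic** — one attribute per gene containing at least one
  marker (value 1 for a sample iff the majority of the gene's markers are 1)
  plus one attribute per maximal intergenic run of markers, fused the same
  way. Partially and fully overlapping genes are treated as separate
  attributes, so a marker under two genes contributes to both.
* **gene + flanks** — the chromosome is divided into regions, each holding
  one gene plus half of the gaps to its two neighbours; genes fully nested
  inside another gene are dropped. Markers in each region are fused by
  majority vote.

Majority ties (even marker count, split vote) resolve to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import HAPLOID, GeneAnnotation, GenotypeMatrix


@dataclass
class FusionScheme:
    mode: str  # gene+intergenic | gene+flanks
    members: dict[str, list[str]]  # fused attribute id -> constituent markers
    provenance: dict[str, tuple[str, float, float]]  # id -> (chrom, start, end)


def _require_haploid(G: GenotypeMatrix) -> None:
    if G.coding != HAPLOID:
        raise ValueError("fusion is defined for haploid 0/1 coding only")
    if G.mapping is None:
        raise ValueError("fusion requires a marker map")
    if np.isnan(G.values).any():
        raise ValueError("impute missing genotypes before fusion")


def _majority(values: np.ndarray) -> np.ndarray:
    # value 1 iff strictly more than half of the member markers are 1
    return (values.mean(axis=1) > 0.5).astype(float)


def _assemble(
    G: GenotypeMatrix, mode: str, groups: list[tuple[str, str, float, float, list[int]]]
) -> tuple[GenotypeMatrix, FusionScheme]:
    cols, ids, members, prov, map_rows = [], [], {}, {}, []
    for fid, chrom, start, end, marker_idx in groups:
        if not marker_idx:
            continue
        cols.append(_majority(G.values[:, marker_idx]))
        ids.append(fid)
        members[fid] = [G.marker_ids[j] for j in marker_idx]
        prov[fid] = (chrom, start, end)
        map_rows.append((fid, chrom, (start + end) / 2.0))
    fused = GenotypeMatrix(
        values=np.column_stack(cols) if cols else np.zeros((G.n_samples, 0)),
        coding=HAPLOID,
        sample_ids=list(G.sample_ids),
        marker_ids=ids,
        mapping=pd.DataFrame(
            map_rows, columns=["marker", "chromosome", "position"]
        ).set_index("marker"),
    )
    return fused, FusionScheme(mode=mode, members=members, provenance=prov)


def fuse_gene_intergenic(
    G: GenotypeMatrix, annotation: GeneAnnotation
) -> tuple[GenotypeMatrix, FusionScheme]:
    """Majority-fused attributes for genes and intergenic runs (exhaustive).

    Every marker belongs to at least one fused attribute: its gene(s), or the
    intergenic run between the union of gene intervals (chromosome ends
    included).
    """
    _require_haploid(G)
    chrom_arr = G.mapping.loc[G.marker_ids, "chromosome"].to_numpy()
    pos_arr = G.mapping.loc[G.marker_ids, "position"].to_numpy()
    groups = []
    for chrom in pd.unique(chrom_arr):
        marker_idx = np.flatnonzero(chrom_arr == chrom)
        marker_pos = pos_arr[marker_idx]
        genes = annotation.for_chromosome(chrom)
        for _, g in genes.iterrows():
            inside = (marker_pos >= g["start"]) & (marker_pos < g["end"])
            groups.append(
                (g["gene_id"], chrom, g["start"], g["end"], list(marker_idx[inside]))
            )
        # intergenic runs: complement of the union of gene intervals
        covered = np.zeros(len(marker_pos), dtype=bool)
        for _, g in genes.iterrows():
            covered |= (marker_pos >= g["start"]) & (marker_pos < g["end"])
        bounds = sorted(
            set(genes["start"]).union(genes["end"])
        )
        edges = np.asarray([-np.inf] + bounds + [np.inf])
        run_of = np.searchsorted(edges, marker_pos, side="right")
        for run_id in np.unique(run_of[~covered]):
            in_run = (~covered) & (run_of == run_id)
            lo = edges[run_id - 1] if np.isfinite(edges[run_id - 1]) else marker_pos[in_run].min()
            hi = edges[run_id] if np.isfinite(edges[run_id]) else marker_pos[in_run].max()
            groups.append(
                (f"intergenic_{chrom}_{run_id}", chrom, float(lo), float(hi),
                 list(marker_idx[in_run]))
            )
    return _assemble(G, "gene+intergenic", groups)


def fuse_gene_flanks(
    G: GenotypeMatrix, annotation: GeneAnnotation
) -> tuple[GenotypeMatrix, FusionScheme]:
    """One region per non-nested gene spanning to the midpoints of its gaps."""
    _require_haploid(G)
    chrom_arr = G.mapping.loc[G.marker_ids, "chromosome"].to_numpy()
    pos_arr = G.mapping.loc[G.marker_ids, "position"].to_numpy()
    chrom_len = {c: pos_arr[chrom_arr == c].max() for c in pd.unique(chrom_arr)}
    groups = []
    for chrom in pd.unique(chrom_arr):
        marker_idx = np.flatnonzero(chrom_arr == chrom)
        marker_pos = pos_arr[marker_idx]
        genes = annotation.for_chromosome(chrom).reset_index(drop=True)
        if genes.empty:
            continue
        # drop genes fully nested within another gene
        nested = []
        for i, gi in genes.iterrows():
            for j, gj in genes.iterrows():
                if i != j and gj["start"] <= gi["start"] and gi["end"] <= gj["end"] and (
                    gj["start"] < gi["start"] or gi["end"] < gj["end"]
                ):
                    nested.append(i)
                    break
        kept = genes.drop(index=nested).sort_values("start").reset_index(drop=True)
        for i, g in kept.iterrows():
            left = 0.0 if i == 0 else (kept.loc[i - 1, "end"] + g["start"]) / 2.0
            right = (
                chrom_len[chrom] + 1e-9
                if i == len(kept) - 1
                else (g["end"] + kept.loc[i + 1, "start"]) / 2.0
            )
            inside = (marker_pos >= left) & (marker_pos < right)
            groups.append(
                (f"region_{g['gene_id']}", chrom, float(left), float(right),
                 list(marker_idx[inside]))
            )
    return _assemble(G, "gene+flanks", groups)
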