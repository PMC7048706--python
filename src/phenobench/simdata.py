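"""Synthetic genotype/phenotype generator for biparental crosses.

The generator emulates the data layout of a classical two-parent cross
experiment: haploid segregants whose chromosomes are random patchworks of
contiguous parental blocks, with crossovers following a Haldane
(no-interference) model — crossover points are a Poisson process with rate 1
per Morgan along each chromosome. Each chromosome independently starts from
either parent with probability 1/2, so every marker has expected allele-1
proportion 0.5 and adjacent markers are correlated through linkage.

Traits are built from an explicit genetic architecture (additive marker
effects plus optional pairwise products for epistasis); the environmental
noise variance is calibrated on the realized genetic scores so that the
realized heritability matches the requested h² on the generated sample, and
the returned phenotype is standardized to mean 0, unit (n−1) variance.

``simulate_structured_population`` extends the same meiosis machinery to
multi-generation random-mating populations from several founders, producing
crop-like relatedness structure in either haploid {0,1} or diploid {−1,0,1}
coding.

All randomness flows from one master seed through named child streams
(meiosis, noise, missingness, annotation), so a stored seed regenerates a
population bit-identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import DIPLOID, HAPLOID, GeneAnnotation, GenotypeMatrix, PhenotypeTable


class MapValidationError(ValueError):
    """Raised for an inconsistent genome map."""


def child_rng(seed: int, purpose: str, *extra: int) -> np.random.Generator:
    """Deterministic per-purpose child stream derived from a master seed."""
    tag = zlib.crc32(purpose.encode()) % (2**31)
    ss = np.random.SeedSequence([int(seed), tag, *[int(e) for e in extra]])
    return np.random.default_rng(ss)


@dataclass
class GenomeMap:
    """Chromosome lengths (Morgans) and monotone marker positions.

    ``positions`` maps chromosome name -> strictly increasing array of
    genetic positions in Morgans within [0, length].
    """

    chromosomes: list[tuple[str, float]]  # (name, length in Morgans)
    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise MapValidationError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length < 0:
                raise MapValidationError(f"chromosome {name} has negative length")
            pos = np.asarray(self.positions[name], dtype=float)
            if pos.size == 0:
                raise MapValidationError(f"chromosome {name} has no markers")
            if (np.diff(pos) <= 0).any():
                raise MapValidationError(f"positions not strictly increasing on {name}")
            if pos[0] < 0 or pos[-1] > length:
                raise MapValidationError(f"marker outside chromosome {name}")
            self.positions[name] = pos

    @classmethod
    def regular(
        cls, n_chromosomes: int = 5, length: float = 1.0, markers_per_chromosome: int = 40
    ) -> "GenomeMap":
        """Evenly spaced markers; convenient default map for simulations."""
        chroms, positions = [], {}
        for i in range(n_chromosomes):
            name = f"chr{i + 1}"
            chroms.append((name, length))
            if markers_per_chromosome == 1:
                positions[name] = np.array([length / 2.0])
            else:
                positions[name] = np.linspace(0, length, markers_per_chromosome)
        return cls(chromosomes=chroms, positions=positions)

    @property
    def n_markers(self) -> int:
        return sum(len(self.positions[c]) for c, _ in self.chromosomes)

    def marker_table(self) -> pd.DataFrame:
        rows = []
        for name, _ in self.chromosomes:
            for k, pos in enumerate(self.positions[name]):
                rows.append((f"{name}_m{k + 1}", name, pos))
        return pd.DataFrame(rows, columns=["marker", "chromosome", "position"]).set_index(
            "marker"
        )


@dataclass
class TraitArchitecture:
    """Additive and pairwise-epistatic marker effects plus heritability."""

    name: str
    additive: dict[int, float]
    interactions: dict[tuple[int, int], float] = field(default_factory=dict)
    h2: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.h2 <= 1):
            raise ValueError("h2 must be in (0, 1]")
        if not self.additive and not self.interactions:
            raise ValueError("architecture must have at least one nonzero effect")
        pairs = set()
        for i, j in self.interactions:
            if i == j:
                raise ValueError("interaction pair must involve two distinct markers")
            key = (min(i, j), max(i, j))
            if key in pairs:
                raise ValueError("duplicate interaction pair")
            pairs.add(key)


def _meiosis_gamete(
    hap_a: np.ndarray, hap_b: np.ndarray, positions: np.ndarray, length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete from two parental haplotypes of one chromosome.

    Crossovers are a Poisson process with rate 1/Morgan; the gamete starts on
    either haplotype with probability 1/2 and switches at each crossover.
    """
    n_co = rng.poisson(length) if length > 0 else 0
    start = rng.integers(2)
    if n_co == 0:
        return hap_a.copy() if start == 0 else hap_b.copy()
    breaks = np.sort(rng.uniform(0, length, size=n_co))
    # phase at each marker = start + number of crossovers before the marker
    phase = (start + np.searchsorted(breaks, positions, side="right")) % 2
    return np.where(phase == 0, hap_a, hap_b)


def simulate_cross(map: GenomeMap, n_segregants: int, seed: int) -> GenotypeMatrix:
    """Haploid segregants of a two-parent cross, coded 0/1 by parent of origin."""
    if n_segregants < 1:
        raise ValueError("n_segregants must be >= 1")
    rng = child_rng(seed, "meiosis")
    blocks = []
    for name, length in map.chromosomes:
        pos = map.positions[name]
        zeros = np.zeros(len(pos))
        ones = np.ones(len(pos))
        chrom = np.empty((n_segregants, len(pos)))
        for i in range(n_segregants):
            chrom[i] = _meiosis_gamete(zeros, ones, pos, length, rng)
        blocks.append(chrom)
    values = np.hstack(blocks)
    table = map.marker_table()
    return GenotypeMatrix(
        values=values,
        coding=HAPLOID,
        sample_ids=[f"seg{i + 1}" for i in range(n_segregants)],
        marker_ids=list(table.index),
        mapping=table,
    )


def genetic_score(G: GenotypeMatrix, arch: TraitArchitecture) -> np.ndarray:
    """The noiseless genetic value Σβ·g + Σγ·g_i·g_j for each sample."""
    p = G.n_markers
    for idx in list(arch.additive) + [i for pair in arch.interactions for i in pair]:
        if not 0 <= idx < p:
            raise ValueError(f"marker index {idx} outside genotype matrix")
    score = np.zeros(G.n_samples)
    for idx, beta in arch.additive.items():
        score += beta * G.values[:, idx]
    for (i, j), gamma in arch.interactions.items():
        score += gamma * G.values[:, i] * G.values[:, j]
    return score


def simulate_trait(G: GenotypeMatrix, arch: TraitArchitecture, seed: int) -> np.ndarray:
    """Phenotype vector with realized heritability h², standardized to (0, 1).

    Noise variance is calibrated on the realized genetic score of this sample
    so that var(genetic)/var(total) equals h² exactly in expectation on the
    generated data; with h² = 1 the trait is a deterministic function of G.
    """
    score = genetic_score(G, arch)
    var_g = score.var(ddof=1)
    if var_g == 0:
        raise ValueError("architecture produces a constant genetic score on this sample")
    if arch.h2 == 1:
        y = score
    else:
        var_e = var_g * (1 - arch.h2) / arch.h2
        rng = child_rng(seed, "noise")
        y = score + rng.normal(0.0, np.sqrt(var_e), size=len(score))
    return (y - y.mean()) / y.std(ddof=1)


def inject_missing(y: np.ndarray, rate: float, seed: int) -> np.ndarray:
    """Uniform-at-random missingness in a phenotype vector (NaN-coded)."""
    out = np.asarray(y, dtype=float).copy()
    if rate > 0:
        rng = child_rng(seed, "missingness")
        out[rng.random(len(out)) < rate] = np.nan
    return out


def simulate_structured_population(
    n_founders: int,
    n_generations: int,
    map: GenomeMap,
    n_lines: int,
    ploidy_coding: str = HAPLOID,
    seed: int = 0,
    breeding_pool: int | None = None,
) -> GenotypeMatrix:
    """Random-mating population descended from founder haplotypes.

    Founder 0 is all-zeros and founder 1 all-ones (so a two-founder,
    one-generation population is distributed exactly as ``simulate_cross``);
    further founders are i.i.d. Bernoulli(1/2) haplotypes. Each generation
    draws two distinct random parents per line and produces one recombinant
    gamete per parent; haploid output keeps one gamete, diploid output sums
    the two gametes coded {−1,0,1} for {aa,aA,AA}. The pedigree of the final
    generation is attached for kinship checks.

    ``breeding_pool`` is the size of intermediate generations (default
    ``max(2 · n_founders, 12)``): a modest parent pool, as in a breeding
    program, so that the final lines share recent ancestors and the
    population carries real relatedness structure.
    """
    if n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = child_rng(seed, "meiosis")
    table = map.marker_table()
    p = len(table)
    founders = np.empty((n_founders, p))
    founders[0] = 0.0
    founders[1] = 1.0
    if n_founders > 2:
        founders[2:] = rng.integers(2, size=(n_founders - 2, p)).astype(float)

    chrom_slices = []
    off = 0
    for name, length in map.chromosomes:
        k = len(map.positions[name])
        chrom_slices.append((name, length, slice(off, off + k)))
        off += k

    def gamete(hap_a: np.ndarray, hap_b: np.ndarray) -> np.ndarray:
        out = np.empty(p)
        for name, length, sl in chrom_slices:
            out[sl] = _meiosis_gamete(
                hap_a[sl], hap_b[sl], map.positions[name], length, rng
            )
        return out

    # population state: diploid genomes of shape (size, 2, p); founders enter
    # as fully homozygous lines (doubled haplotypes)
    pop = np.stack([founders, founders], axis=1)
    pedigree = None
    if breeding_pool is None:
        breeding_pool = max(2 * n_founders, 12)
    for gen in range(n_generations):
        size = n_lines if gen == n_generations - 1 else breeding_pool
        nxt = np.empty((size, 2, p))
        parents = np.empty((size, 2), dtype=int)
        for i in range(size):
            a, b = rng.choice(len(pop), size=2, replace=False)
            parents[i] = (a, b)
            nxt[i, 0] = gamete(pop[a, 0], pop[a, 1])
            nxt[i, 1] = gamete(pop[b, 0], pop[b, 1])
        pop = nxt
        pedigree = pd.DataFrame(parents, columns=["parent_a", "parent_b"])

    if ploidy_coding == HAPLOID:
        # a haploid line is one more gamete of the final diploid genome, so a
        # two-founder single-generation population reduces to simulate_cross
        values = np.empty((len(pop), p))
        for i in range(len(pop)):
            values[i] = gamete(pop[i, 0], pop[i, 1])
    elif ploidy_coding == DIPLOID:
        values = pop[:, 0, :] + pop[:, 1, :] - 1.0
    else:
        raise ValueError(f"unknown coding {ploidy_coding!r}")
    G = GenotypeMatrix(
        values=values,
        coding=ploidy_coding,
        sample_ids=[f"line{i + 1}" for i in range(len(values))],
        marker_ids=list(table.index),
        mapping=table,
        pedigree=pedigree,
    )
    return G


def simulate_annotation(
    map: GenomeMap,
    n_genes: int,
    seed: int,
    overlap_fraction: float = 0.0,
    nested_fraction: float = 0.0,
) -> GeneAnnotation:
    """Gene intervals on the map's coordinate axis, mostly non-overlapping.

    Genes are laid out per chromosome on an even grid with random jitter so
    that by default no two intervals overlap. A fraction of genes can be made
    to partially overlap their left neighbour, and another fraction to be
    fully nested inside the previous gene, to exercise fusion edge rules.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = child_rng(seed, "annotation")
    chroms = [(name, length) for name, length in map.chromosomes if length > 0]
    if not chroms:
        raise MapValidationError("annotation requires a chromosome of positive length")
    rows = []
    gid = 0
    # distribute genes round-robin across chromosomes
    per_chrom = [0] * len(chroms)
    for g in range(n_genes):
        per_chrom[g % len(chroms)] += 1
    for (name, length), k in zip(chroms, per_chrom):
        if k == 0:
            continue
        slot = length / k
        prev = None
        for s in range(k):
            lo = s * slot
            width = slot * rng.uniform(0.3, 0.6)
            start = lo + slot * rng.uniform(0.05, 0.3)
            end = min(start + width, length)
            if prev is not None and rng.random() < nested_fraction:
                ps, pe = prev
                start = ps + (pe - ps) * 0.25
                end = ps + (pe - ps) * 0.75
            elif prev is not None and rng.random() < overlap_fraction:
                ps, pe = prev
                start = ps + (pe - ps) * 0.5  # straddles the previous gene's end
                end = min(start + width, length)
            if end <= start:
                end = min(start + slot * 0.1, length)
            rows.append((f"gene{gid + 1}", name, start, end))
            gid += 1
            prev = (start, end)
    return GeneAnnotation(
        intervals=pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])
    )


def simulate_population(
    map: GenomeMap,
    n_segregants: int,
    architectures: list[TraitArchitecture],
    seed: int,
    missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Convenience bundle: one cross plus one phenotype per architecture."""
    G = simulate_cross(map, n_segregants, seed)
    cols = {}
    for t, arch in enumerate(architectures):
        y = simulate_trait(G, arch, seed=seed + 1000 * (t + 1))
        cols[arch.name] = inject_missing(y, missing_rate, seed=seed + 1000 * (t + 1))
    P = PhenotypeTable(traits=pd.DataFrame(cols, index=G.sample_ids), normalized=True)
    return G, P
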