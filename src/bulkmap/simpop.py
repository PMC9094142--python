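"""Synthetic biparental populations and phenotype-selected sequencing pools.

Simulates the statistical structure a bulked-segregant analysis assumes:
an F2 (and selfed F2:3) population derived from two fully inbred parents,
a single completely penetrant dominant locus, phenotype-selected bulks,
and depth-sampled pooled allele counts.

Meiosis uses a no-interference crossover model: the per-gamete crossover
count is Poisson with mean equal to the chromosome map length in Morgans,
and crossover positions are uniform — the model under which map distances
follow Haldane's function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

#: canonical genotype codes: A = P1 homozygote, H = het, B = P2 homozygote
DOSAGE_TO_CODE = np.array(["A", "H", "B"])


@dataclass
class GenomeModel:
    """Single-chromosome marker panel with a constant recombination rate.

    Every simulated SNP is fixed-different between the two parents:
    parent P1 carries the ref allele and parent P2 the alt allele at all
    sites (dosage counts the P2/alt allele).
    """

    chrom_name: str
    length_bp: int
    cm_per_mb: float
    snp_positions: np.ndarray
    ref_alleles: np.ndarray = field(default=None)  # type: ignore[assignment]
    alt_alleles: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.snp_positions = np.asarray(self.snp_positions, dtype=np.int64)
        if self.cm_per_mb < 0:
            raise ValueError("cm_per_mb must be >= 0")
        if self.snp_positions.size == 0:
            raise ValueError("need at least one SNP position")
        if np.any(np.diff(self.snp_positions) <= 0):
            raise ValueError("snp_positions must be strictly increasing")
        if self.snp_positions[0] < 1 or self.snp_positions[-1] > self.length_bp:
            raise ValueError("snp_positions must lie in [1, length_bp]")
        if self.ref_alleles is None:
            # deterministic default alphabet; real runs use random_genome()
            self.ref_alleles = np.full(self.n_snps, "A")
            self.alt_alleles = np.full(self.n_snps, "T")
        self.ref_alleles = np.asarray(self.ref_alleles)
        self.alt_alleles = np.asarray(self.alt_alleles)
        if len(self.ref_alleles) != self.n_snps or len(self.alt_alleles) != self.n_snps:
            raise ValueError("allele arrays must match snp_positions length")
        if np.any(self.ref_alleles == self.alt_alleles):
            raise ValueError("ref and alt alleles must differ at every SNP")

    @property
    def n_snps(self) -> int:
        return len(self.snp_positions)

    @property
    def morgans(self) -> float:
        """Total map length: (length_bp / 1e6) * cm_per_mb / 100."""
        return self.length_bp * self.cm_per_mb / 1e8

    def snp_index_at(self, position_bp: int) -> int:
        """Index of the SNP at ``position_bp`` (exact match required)."""
        i = int(np.searchsorted(self.snp_positions, position_bp))
        if i >= self.n_snps or self.snp_positions[i] != position_bp:
            raise ValueError(f"no SNP at position {position_bp}")
        return i


@dataclass(frozen=True)
class CausalLocus:
    """A single, completely penetrant dominant locus."""

    position_bp: int
    dominant_parent: str = "P2"
    dominant_phenotype: str = "black"
    recessive_phenotype: str = "yellow"

    def __post_init__(self) -> None:
        if self.dominant_parent not in ("P1", "P2"):
            raise ValueError("dominant_parent must be 'P1' or 'P2'")

    def phenotype_of(self, dosage: int) -> str:
        """Phenotype from the P2-allele dosage at the locus (0/1/2)."""
        has_dominant = dosage >= 1 if self.dominant_parent == "P2" else dosage <= 1
        return self.dominant_phenotype if has_dominant else self.recessive_phenotype


@dataclass
class Plant:
    """One individual; haplotypes are per-SNP P2-allele indicators (0/1).

    Haplotypes are kept (not just dosages) because selfing an F2 plant
    requires phase. ``hap1``/``hap2`` may be ``None`` for externally
    constructed plants, in which case gamete simulation refuses
    heterozygous genotypes.
    """

    id: str
    hap1: np.ndarray | None
    hap2: np.ndarray | None
    phenotype: str = ""
    generation: str = "F2"

    @property
    def dosage(self) -> np.ndarray:
        if self.hap1 is None or self.hap2 is None:
            raise ValueError(f"plant {self.id} has no haplotype data")
        return self.hap1 + self.hap2


def random_genome(
    n_snps: int = 5000,
    length_bp: int = 25_000_000,
    cm_per_mb: float = 3.0,
    chrom_name: str = "chr1",
    rng: np.random.Generator | int | None = 0,
    include_positions: tuple[int, ...] = (),
) -> GenomeModel:
    """Draw a desk-scale genome: uniform SNP positions, random allele pairs.

    ``include_positions`` forces specific positions (e.g. the causal locus)
    into the panel.
    """
    rng = np.random.default_rng(rng)
    if n_snps > length_bp:
        raise ValueError("n_snps cannot exceed length_bp")
    # rejection sampling of distinct positions avoids materialising the
    # full 1..length_bp population
    pos = np.unique(rng.integers(1, length_bp + 1, size=int(n_snps * 1.1) + 8))
    while len(pos) < n_snps:
        extra = rng.integers(1, length_bp + 1, size=n_snps)
        pos = np.unique(np.concatenate([pos, extra]))
    pos = rng.permutation(pos)[:n_snps]
    pos = np.union1d(pos, np.asarray(include_positions, dtype=np.int64))
    ref_idx = rng.integers(0, 4, size=len(pos))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(pos))) % 4
    return GenomeModel(
        chrom_name=chrom_name,
        length_bp=length_bp,
        cm_per_mb=cm_per_mb,
        snp_positions=np.sort(pos),
        ref_alleles=_BASES[ref_idx],
        alt_alleles=_BASES[alt_idx],
    )


def f1_plant(genome: GenomeModel, plant_id: str = "F1") -> Plant:
    """The F1 of two inbred parents: one full P1 and one full P2 haplotype."""
    zeros = np.zeros(genome.n_snps, dtype=np.uint8)
    ones = np.ones(genome.n_snps, dtype=np.uint8)
    return Plant(id=plant_id, hap1=zeros, hap2=ones, generation="F1")


def simulate_gamete(
    parent: Plant,
    genome: GenomeModel,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """One meiotic product of ``parent`` (per-SNP P2-allele indicator).

    Crossover count ~ Poisson(map length in Morgans); crossover positions
    uniform on the chromosome; the gamete alternates between the parent's
    two haplotypes at each crossover, starting from a random haplotype.
    """
    rng = np.random.default_rng(rng)
    if parent.hap1 is None or parent.hap2 is None:
        raise ValueError(
            f"plant {parent.id}: cannot simulate gametes from unphased "
            "heterozygous genotypes; haplotypes are required"
        )
    n_xo = rng.poisson(genome.morgans)
    start = rng.integers(0, 2)
    if n_xo == 0:
        source = np.full(genome.n_snps, start)
    else:
        xo_pos = rng.uniform(1, genome.length_bp, size=n_xo)
        n_before = np.searchsorted(np.sort(xo_pos), genome.snp_positions)
        source = (start + n_before) % 2
    out = np.where(source == 0, parent.hap1, parent.hap2)
    return out.astype(np.uint8)


def make_f2(
    n: int,
    genome: GenomeModel,
    locus: CausalLocus,
    rng: np.random.Generator | int | None = None,
    id_prefix: str = "F2",
) -> list[Plant]:
    """An F2 population: each plant is the union of two independent F1 gametes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    f1 = f1_plant(genome)
    causal_idx = genome.snp_index_at(locus.position_bp)
    plants = []
    for i in range(n):
        h1 = simulate_gamete(f1, genome, rng)
        h2 = simulate_gamete(f1, genome, rng)
        phen = locus.phenotype_of(int(h1[causal_idx]) + int(h2[causal_idx]))
        plants.append(
            Plant(id=f"{id_prefix}_{i + 1}", hap1=h1, hap2=h2, phenotype=phen,
                  generation="F2")
        )
    return plants


def make_f23_screen(
    f2_parents: list[Plant],
    n_offspring_total: int,
    genome: GenomeModel,
    locus: CausalLocus,
    flank_left_bp: int,
    flank_right_bp: int,
    rng: np.random.Generator | int | None = None,
) -> list[Plant]:
    """Self F2 plants heterozygous across a flanking-marker interval.

    Parents not heterozygous at *both* flanking markers are excluded with
    a warning; offspring are distributed round-robin over the remainder.
    """
    rng = np.random.default_rng(rng)
    li = genome.snp_index_at(flank_left_bp)
    ri = genome.snp_index_at(flank_right_bp)
    kept: list[Plant] = []
    for p in f2_parents:
        d = p.dosage
        if d[li] == 1 and d[ri] == 1:
            kept.append(p)
        else:
            logger.warning(
                "F2:3 screen: parent %s is not heterozygous across "
                "[%d, %d]; excluded", p.id, flank_left_bp, flank_right_bp
            )
    if not kept:
        raise ValueError("no F2 parent is heterozygous across the flanking interval")
    causal_idx = genome.snp_index_at(locus.position_bp)
    offspring = []
    for i in range(n_offspring_total):
        parent = kept[i % len(kept)]
        h1 = simulate_gamete(parent, genome, rng)
        h2 = simulate_gamete(parent, genome, rng)
        phen = locus.phenotype_of(int(h1[causal_idx]) + int(h2[causal_idx]))
        offspring.append(
            Plant(id=f"F23_{i + 1}", hap1=h1, hap2=h2, phenotype=phen,
                  generation="F2:3")
        )
    return offspring


@dataclass(frozen=True)
class PoolSpec:
    """Size, target depth and phenotype selector of one sequencing bulk."""

    n_plants: int
    mean_depth: float
    phenotype_selector: str

    def __post_init__(self) -> None:
        if self.n_plants <= 0:
            raise ValueError("n_plants must be > 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")


def pool_allele_counts(
    plants: list[Plant],
    spec: PoolSpec,
    genome: GenomeModel,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Depth-sampled ``(ref_depth, alt_depth)`` arrays for one bulk.

    Pool alt frequency p = (sum of dosages) / (2 n); per-site depth is
    Poisson(mean_depth) — zero-depth sites are emitted so downstream
    filters are exercised — and alt reads are Binomial(depth, p).
    """
    rng = np.random.default_rng(rng)
    selected = [p for p in plants if p.phenotype == spec.phenotype_selector]
    if len(selected) < spec.n_plants:
        raise ValueError(
            f"pool '{spec.phenotype_selector}' needs {spec.n_plants} plants "
            f"but only {len(selected)} have that phenotype "
            f"(short by {spec.n_plants - len(selected)})"
        )
    idx = rng.choice(len(selected), size=spec.n_plants, replace=False)
    dosages = np.stack([selected[i].dosage for i in idx])
    p = dosages.sum(axis=0) / (2 * spec.n_plants)
    depth = rng.poisson(spec.mean_depth, size=genome.n_snps)
    alt = rng.binomial(depth, p)
    return (depth - alt).astype(np.int64), alt.astype(np.int64)


def make_pools(
    plants: list[Plant],
    spec_low: PoolSpec,
    spec_high: PoolSpec,
    genome: GenomeModel,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Pooled-variant table for the two bulks.

    ``low`` is the recessive-phenotype bulk and ``high`` the dominant one,
    matching the downstream delta orientation (delta = low - high index).
    """
    rng = np.random.default_rng(rng)
    low_ref, low_alt = pool_allele_counts(plants, spec_low, genome, rng)
    high_ref, high_alt = pool_allele_counts(plants, spec_high, genome, rng)
    return pd.DataFrame(
        {
            "chrom": genome.chrom_name,
            "pos": genome.snp_positions,
            "ref": genome.ref_alleles,
            "alt": genome.alt_alleles,
            "low_ref": low_ref,
            "low_alt": low_alt,
            "high_ref": high_ref,
            "high_alt": high_alt,
        }
    )


def genotype_matrix_frame(
    plants: list[Plant],
    genome: GenomeModel,
    marker_positions: list[int],
    marker_names: list[str] | None = None,
    trait_locus: CausalLocus | None = None,
) -> pd.DataFrame:
    """Plants x markers codes (A/H/B), optionally plus an A/C trait column.

    The trait column codes the recessive phenotype as A (recessive
    homozygote class) and the dominant phenotype as C ("not A").
    """
    if marker_names is None:
        marker_names = [f"M{i + 1}" for i in range(len(marker_positions))]
    cols = {}
    idxs = [genome.snp_index_at(p) for p in marker_positions]
    for name, i in zip(marker_names, idxs):
        cols[name] = [DOSAGE_TO_CODE[p.dosage[i]] for p in plants]
    if trait_locus is not None:
        cols["trait"] = [
            "A" if p.phenotype == trait_locus.recessive_phenotype else "C"
            for p in plants
        ]
    return pd.DataFrame(cols, index=pd.Index([p.id for p in plants], name="plant_id"))
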