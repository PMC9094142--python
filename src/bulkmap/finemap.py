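"""Recombinant screening and substitution mapping of a dominant locus.

Plants whose genotype class changes between two flanking markers carry a
crossover inside the interval; the genotypes and phenotypes of those
recombinants exclude sub-regions incompatible with a completely
penetrant dominant locus, narrowing the candidate interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .intervals import GenomicInterval
from .linkage import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RecombinantPlant:
    """One recombinant: ordered A/H/B genotypes plus a phenotype label."""

    id: str
    genotypes: tuple[str, ...]  # aligned with the marker list in use
    phenotype: str


def screen_recombinants(
    matrix: GenotypeMatrix,
    flank_left: str,
    flank_right: str,
    phenotypes: dict[str, str],
    markers: list[str] | None = None,
) -> list[RecombinantPlant]:
    """Plants whose genotype class differs between the two flanking markers.

    ``phenotypes`` maps plant id to phenotype label. Plants missing (U) at
    either flank are skipped with a log entry. ``markers`` selects and
    orders the genotype columns carried on each returned recombinant
    (default: all codominant markers ordered by physical position).
    """
    for m in (flank_left, flank_right):
        if m not in matrix.data.columns:
            raise ValueError(f"flanking marker '{m}' not in matrix")
        if matrix.codings[m] != "codominant":
            raise ValueError(f"flanking marker '{m}' must be codominant")
    if markers is None:
        markers = [
            m for m in matrix.markers
            if matrix.codings[m] == "codominant" and matrix.positions.get(m) is not None
        ]
        markers.sort(key=lambda m: matrix.positions[m])
    recombinants: list[RecombinantPlant] = []
    n_skipped = 0
    for plant_id, row in matrix.data.iterrows():
        g_left, g_right = row[flank_left], row[flank_right]
        if g_left == "U" or g_right == "U":
            logger.info("screen_recombinants: plant %s missing at a flank; skipped",
                        plant_id)
            n_skipped += 1
            continue
        if g_left != g_right:
            recombinants.append(
                RecombinantPlant(
                    id=str(plant_id),
                    genotypes=tuple(row[m] for m in markers),
                    phenotype=phenotypes.get(str(plant_id), ""),
                )
            )
    logger.info(
        "screen_recombinants: %d recombinant / %d scored / %d skipped",
        len(recombinants), len(matrix.data) - n_skipped, n_skipped,
    )
    return recombinants


def _compatible_mask(
    plant: RecombinantPlant,
    n_markers: int,
    recessive_hom: str,
    dominant_phenotype: str,
) -> list[bool]:
    """Per-marker compatibility of the locus position with one plant.

    A recessive-phenotype plant is homozygous recessive at the locus, so
    every marker where it carries a dominant allele (H or the dominant
    homozygote) is excluded. A dominant-phenotype plant carries at least
    one dominant allele, so only its recessive-homozygote markers are
    excluded (het regions are uninformative under dominance).
    """
    if len(plant.genotypes) != n_markers:
        raise ValueError(f"plant {plant.id}: genotype/marker length mismatch")
    is_recessive_pheno = plant.phenotype != dominant_phenotype
    mask = []
    for g in plant.genotypes:
        if g == "U":
            mask.append(True)
        elif is_recessive_pheno:
            mask.append(g == recessive_hom)
        else:
            mask.append(g != recessive_hom)
    return mask


def _plant_bounds(
    plant: RecombinantPlant,
    marker_positions: list[int],
    mask: list[bool],
    current: GenomicInterval,
    boundary: str,
) -> tuple[int, int]:
    """The sub-interval of ``current`` one plant allows the locus to occupy.

    The locus may sit at any compatible marker or inside a gap adjacent
    to one (the unobserved crossover can fall anywhere within a
    transition gap), so the plant's bound is set by its *innermost
    excluding markers*: the closest incompatible markers flanking the
    span of compatible markers. ``boundary="marker"`` reports the
    excluding marker positions themselves (sound: the locus lies strictly
    between them); ``boundary="midpoint"`` splits the transition gaps at
    their midpoints (tighter, but can clip the true locus).
    """
    n = len(marker_positions)
    first = next(i for i in range(n) if mask[i])
    last = next(i for i in reversed(range(n)) if mask[i])
    if not all(mask[first: last + 1]):
        # compatible markers are non-contiguous (double crossover or
        # genotyping noise); the enclosing span is a sound superset
        logger.warning(
            "refine_interval: plant %s has non-contiguous compatible "
            "markers; using their enclosing span", plant.id
        )
    lo, hi = current.start, current.end
    if first > 0:
        left_excl = marker_positions[first - 1]
        lo = (
            left_excl if boundary == "marker"
            else (left_excl + marker_positions[first]) // 2
        )
    if last < n - 1:
        right_excl = marker_positions[last + 1]
        hi = (
            right_excl if boundary == "marker"
            else (marker_positions[last] + right_excl + 1) // 2
        )
    return lo, hi


def refine_interval(
    recombinants: list[RecombinantPlant],
    marker_positions: list[int],
    current: GenomicInterval,
    dominant_hom: str = "B",
    dominant_phenotype: str = "black",
    boundary: str = "marker",
) -> GenomicInterval:
    """Narrow ``current`` to the sub-interval compatible with all recombinants.

    ``marker_positions`` (1-based, strictly increasing, inside ``current``)
    align with each recombinant's genotype tuple. ``dominant_hom`` names
    the homozygote class (A or B) carrying the dominant allele. Each
    recombinant restricts the locus to the region between its innermost
    excluding markers (see :func:`_plant_bounds`); the refined interval
    is the intersection of those regions with ``current``, so it is
    independent of input order and can only shrink as recombinants are
    added.

    An empty intersection raises ``ValueError`` naming the conflicting
    plants — a signal of phenotyping/genotyping error or non-monogenic
    inheritance.
    """
    if dominant_hom not in ("A", "B"):
        raise ValueError("dominant_hom must be 'A' or 'B'")
    if boundary not in ("marker", "midpoint"):
        raise ValueError("boundary must be 'marker' or 'midpoint'")
    if sorted(marker_positions) != list(marker_positions) or len(
        set(marker_positions)
    ) != len(marker_positions):
        raise ValueError("marker positions must be strictly increasing")
    for p in marker_positions:
        if not current.contains(p):
            raise ValueError(f"marker position {p} outside current interval")
    if not recombinants:
        return current

    recessive_hom = "A" if dominant_hom == "B" else "B"
    n = len(marker_positions)
    lo, hi = current.start, current.end
    bounds = {}
    for plant in recombinants:
        mask = _compatible_mask(plant, n, recessive_hom, dominant_phenotype)
        if not any(mask):
            raise ValueError(
                f"plant {plant.id}: no marker position is compatible with "
                "its genotype and phenotype"
            )
        p_lo, p_hi = _plant_bounds(plant, marker_positions, mask, current,
                                   boundary)
        bounds[plant.id] = (p_lo, p_hi)
        lo, hi = max(lo, p_lo), min(hi, p_hi)

    if lo > hi:
        conflicting = sorted(
            pid for pid, (p_lo, p_hi) in bounds.items()
            if p_lo > hi or p_hi < lo
        )
        raise ValueError(
            "recombinants exclude every position in the interval; "
            f"check plants: {', '.join(conflicting) or 'all'}"
        )
    return GenomicInterval(
        current.chrom, lo, hi,
        confidence_level=current.confidence_level,
        sign=current.sign,
    )
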