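"""Candidate-gene layer: CDS handling, variant effects, haplotypes, qPCR.

Variant coordinates are 1-based positions within the *spliced* CDS. A
genomic<->CDS converter is provided for gene models read from exon
coordinates. Translation uses the standard genetic code via Biopython.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID = set("ACGT")


@dataclass
class GeneModel:
    """A protein-coding gene: exon structure plus spliced CDS sequence.

    ``exons`` are 1-based inclusive genomic intervals in genomic order;
    for minus-strand genes the spliced CDS is the reverse complement of
    the concatenated exon sequence.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        self.cds = self.cds.upper()
        for i, ch in enumerate(self.cds):
            if ch not in _VALID:
                raise ValueError(f"non-ACGT character '{ch}' at CDS position {i + 1}")
        if len(self.cds) % 3 != 0:
            raise ValueError(f"CDS length {len(self.cds)} is not a multiple of 3")
        exon_len = sum(e - s + 1 for s, e in self.exons)
        if exon_len != len(self.cds):
            raise ValueError(
                f"exon lengths sum to {exon_len} but CDS has {len(self.cds)} bases"
            )
        last = None
        for s, e in self.exons:
            if e < s or (last is not None and s <= last):
                raise ValueError("exons must be ordered, non-overlapping intervals")
            last = e

    @classmethod
    def from_genomic(
        cls,
        gene_id: str,
        chrom: str,
        strand: str,
        exons: list[tuple[int, int]],
        genomic_seq: str,
        seq_offset: int = 1,
    ) -> "GeneModel":
        """Splice a CDS out of a genomic sequence starting at ``seq_offset``."""
        parts = [
            genomic_seq[s - seq_offset: e - seq_offset + 1] for s, e in exons
        ]
        cds = "".join(parts).upper()
        if strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cls(gene_id, chrom, strand, exons, cds)

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Genomic coordinate of a 1-based spliced-CDS position."""
        if not 1 <= cds_pos <= len(self.cds):
            raise ValueError(f"cds_pos {cds_pos} outside CDS of length {len(self.cds)}")
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        remaining = cds_pos
        for s, e in exons:
            length = e - s + 1
            if remaining <= length:
                return s + remaining - 1 if self.strand == "+" else e - remaining + 1
            remaining -= length
        raise AssertionError("unreachable")

    def genomic_to_cds(self, pos: int) -> int:
        """1-based spliced-CDS position of a genomic coordinate (exonic only)."""
        offset = 0
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        for s, e in exons:
            if s <= pos <= e:
                within = pos - s + 1 if self.strand == "+" else e - pos + 1
                return offset + within
            offset += e - s + 1
        raise ValueError(f"position {pos} is not exonic in {self.gene_id}")


@dataclass(frozen=True)
class CdsVariant:
    """A single-base coding change at a 1-based spliced-CDS position."""

    name: str
    cds_pos: int
    ref_base: str
    alt_base: str


@dataclass(frozen=True)
class VariantEffect:
    variant: str
    codon_index: int  # 1-based codon number
    codon_position: int  # 1, 2 or 3 within the codon
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    synonymous: bool


def splice_and_translate(model: GeneModel, to_stop: bool = True) -> str:
    """Translate the spliced CDS with the standard genetic code.

    Translation stops at the first stop codon when ``to_stop`` is set; a
    stop before the final codon triggers a warning, as does a CDS not
    beginning with ATG.
    """
    if not model.cds.startswith("ATG"):
        warnings.warn(f"{model.gene_id}: CDS does not start with ATG", stacklevel=2)
    full = str(Seq(model.cds).translate())
    stop_at = full.find("*")
    if 0 <= stop_at < len(full) - 1:
        warnings.warn(
            f"{model.gene_id}: internal stop codon at codon {stop_at + 1}",
            stacklevel=2,
        )
    return full.split("*")[0] if to_stop else full


def annotate_variant(model: GeneModel, variant: CdsVariant) -> VariantEffect:
    """Codon arithmetic plus re-translation of the substituted codon."""
    pos = variant.cds_pos
    if not 1 <= pos <= len(model.cds):
        raise ValueError(
            f"{variant.name}: cds_pos {pos} outside CDS of length {len(model.cds)}"
        )
    if model.cds[pos - 1] != variant.ref_base.upper():
        raise ValueError(
            f"{variant.name}: reference CDS has '{model.cds[pos - 1]}' at "
            f"position {pos}, variant claims '{variant.ref_base}'"
        )
    codon_index = (pos - 1) // 3 + 1
    codon_position = (pos - 1) % 3 + 1
    start = (codon_index - 1) * 3
    ref_codon = model.cds[start: start + 3]
    alt_codon = (
        ref_codon[: codon_position - 1]
        + variant.alt_base.upper()
        + ref_codon[codon_position:]
    )
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return VariantEffect(
        variant=variant.name,
        codon_index=codon_index,
        codon_position=codon_position,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        synonymous=ref_aa == alt_aa,
    )


def apply_variants(cds: str, variants: list[CdsVariant]) -> str:
    """Alternative CDS with every variant's alt base substituted."""
    seq = list(cds)
    for v in variants:
        if seq[v.cds_pos - 1] != v.ref_base.upper():
            raise ValueError(f"{v.name}: ref mismatch at {v.cds_pos}")
        seq[v.cds_pos - 1] = v.alt_base.upper()
    return "".join(seq)


# --------------------------------------------------------------------------
# haplotype grouping


def _haplotype_key(alleles: pd.Series) -> tuple[str, bool]:
    """Collapse per-variant calls ("C" or "C/T") to a haplotype key.

    Homozygous samples yield the plain allele string; heterozygous ones
    the unordered pair of the two phased-by-column haplotypes.
    """
    first, second = [], []
    for call in alleles:
        parts = str(call).split("/")
        if len(parts) == 1:
            parts = [parts[0], parts[0]]
        if len(parts) != 2:
            raise ValueError(f"malformed allele call '{call}'")
        first.append(parts[0].upper())
        second.append(parts[1].upper())
    h1, h2 = "-".join(first), "-".join(second)
    if h1 == h2:
        return h1, False
    return "|".join(sorted([h1, h2])), True


def classify_haplotypes(
    calls: pd.DataFrame,
    phenotypes: pd.Series | dict,
) -> tuple[pd.DataFrame, float]:
    """Group samples by haplotype and score phenotype concordance.

    ``calls`` is samples x variants with entries like ``"C"`` (homozygous)
    or ``"C/T"`` (heterozygous); ``phenotypes`` maps sample id to a label.
    Samples with missing calls are excluded with a log entry. Concordance
    is the fraction of samples whose phenotype matches the majority
    phenotype of their haplotype group (heterozygous pairs form their own
    groups, consistent with a dominant phenotype expectation).

    Returns ``(per_sample_table, concordance)``.
    """
    if calls.index.has_duplicates:
        dupes = calls.index[calls.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    phenotypes = pd.Series(phenotypes)
    rows = []
    for sample, alleles in calls.iterrows():
        if alleles.isna().any() or (alleles.astype(str) == "").any():
            logger.info("classify_haplotypes: sample %s has missing calls; excluded",
                        sample)
            continue
        key, het = _haplotype_key(alleles)
        rows.append(
            {
                "sample": sample,
                "haplotype": key,
                "zygosity": "heterozygous" if het else "homozygous",
                "phenotype": phenotypes.get(sample, ""),
            }
        )
    table = pd.DataFrame(rows).set_index("sample")
    majority = {}
    for hap, sub in table.groupby("haplotype"):
        majority[hap] = Counter(sub["phenotype"]).most_common(1)[0][0]
    table["group_phenotype"] = table["haplotype"].map(majority)
    table["concordant"] = table["phenotype"] == table["group_phenotype"]
    concordance = float(table["concordant"].mean()) if len(table) else float("nan")
    return table, concordance


def relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Delta-delta-Ct fold change: 2**-((Tt - Tr) - (Ct - Cr))."""
    values = (ct_target_sample, ct_ref_sample, ct_target_calibrator,
              ct_ref_calibrator)
    if not all(np.isfinite(v) for v in values):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return float(2.0 ** (-ddct))


# --------------------------------------------------------------------------
# packaged demonstration gene


_FILL_CODONS = ["GCT", "GAT", "AAA", "TGG", "CAT", "GTT", "CCA", "TCA",
                "GGA", "ATC", "GAG", "TTC"]


def example_gene_model() -> tuple[GeneModel, list[CdsVariant]]:
    """A synthetic two-exon PPO-like gene with four known coding variants.

    The CDS is 1,344 bp (exons of 482 and 862 bp separated by a 1,570 bp
    intron, 448 codons including the stop). Four variants at spliced-CDS
    positions 670 (C>T, Leu->Phe), 822 (G>T, synonymous), 887 (C>T,
    Ser->Phe) and 931 (G>A, Glu->Lys) distinguish the recessive
    (C-G-C-G) and dominant (T-T-T-A) haplotypes.
    """
    n_codons = 1344 // 3
    codons = [_FILL_CODONS[i % len(_FILL_CODONS)] for i in range(n_codons)]
    codons[0] = "ATG"
    codons[223] = "CTT"  # CDS 670-672; C670T -> TTT (Leu -> Phe)
    codons[273] = "CCG"  # CDS 820-822; G822T -> CCT (Pro, synonymous)
    codons[295] = "TCT"  # CDS 886-888; C887T -> TTT (Ser -> Phe)
    codons[310] = "GAA"  # CDS 931-933; G931A -> AAA (Glu -> Lys)
    codons[-1] = "TAA"
    cds = "".join(codons)
    gene_start = 100_001
    exon1 = (gene_start, gene_start + 482 - 1)
    intron_end = exon1[1] + 1570
    exon2 = (intron_end + 1, intron_end + 862)
    model = GeneModel(
        gene_id="ppo_demo", chrom="chr1", strand="+",
        exons=[exon1, exon2], cds=cds,
    )
    variants = [
        CdsVariant("snp670", 670, "C", "T"),
        CdsVariant("snp822", 822, "G", "T"),
        CdsVariant("snp887", 887, "C", "T"),
        CdsVariant("snp931", 931, "G", "A"),
    ]
    return model, variants
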