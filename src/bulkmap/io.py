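"""Readers and writers for the pipeline's interchange formats.

TSV is the canonical format; minimal VCF (allele depths per pool sample),
BED and GFF3 are supported at the edges. Every writer prepends a
provenance header (tool version, parameter hash, seed) so reruns with
identical seeds produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam
import yaml

from . import __version__
from .bsaindex import POOL_COLUMNS
from .intervals import GenomicInterval
from .linkage import GenotypeMatrix

logger = logging.getLogger(__name__)


def params_hash(params: dict) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def provenance_lines(params: dict | None = None, seed: int | None = None) -> list[str]:
    params = params or {}
    lines = [f"#bulkmap_version={__version__}"]
    if seed is not None:
        lines.append(f"#seed={seed}")
    lines.append(f"#config_hash={params_hash(params)}")
    for k in sorted(params):
        lines.append(f"#param:{k}={params[k]}")
    return lines


def _write_table(df: pd.DataFrame, path, params: dict | None, seed: int | None,
                 index: bool = False) -> None:
    buf = _io.StringIO()
    for line in provenance_lines(params, seed):
        buf.write(line + "\n")
    df.to_csv(buf, sep="\t", index=index)
    Path(path).write_text(buf.getvalue())


# --------------------------------------------------------------------------
# pooled-variant tables


def write_pooled_tsv(records: pd.DataFrame, path, params: dict | None = None,
                     seed: int | None = None) -> None:
    write_cols = [c for c in records.columns if c in POOL_COLUMNS]
    _write_table(records[write_cols], path, params, seed)


def read_pooled_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in POOL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df.sort_values(["chrom", "pos"], ignore_index=True)


def write_pooled_vcf(
    records: pd.DataFrame,
    path,
    low_sample: str = "recessive_bulk",
    high_sample: str = "dominant_bulk",
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Minimal VCF with per-pool AD (ref,alt) sample fields."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=bulkmap {__version__}",
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths for the ref and alt alleles">',
    ]
    for chrom in pd.unique(records["chrom"]):
        length = (
            chrom_lengths[chrom]
            if chrom_lengths
            else int(records.loc[records["chrom"] == chrom, "pos"].max())
        )
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
        f"\t{low_sample}\t{high_sample}"
    )
    for row in records.itertuples(index=False):
        lines.append(
            f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tAD"
            f"\t{row.low_ref},{row.low_alt}\t{row.high_ref},{row.high_alt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_pooled_vcf(
    path,
    low_sample: str | None = None,
    high_sample: str | None = None,
) -> pd.DataFrame:
    """Parse a two-pool VCF with AD fields into the pooled-variant table.

    Multiallelic records are skipped (count logged). By default the first
    sample column is the low (recessive) pool and the second the high
    (dominant) pool.
    """
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) < 2:
            raise ValueError(f"{path}: need two pool sample columns, found {samples}")
        low = low_sample or samples[0]
        high = high_sample or samples[1]
        for s in (low, high):
            if s not in samples:
                raise ValueError(f"{path}: sample '{s}' not in VCF ({samples})")
        rows = []
        n_multi = 0
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_multi += 1
                continue
            try:
                ad_low = rec.samples[low]["AD"]
                ad_high = rec.samples[high]["AD"]
                low_ref, low_alt = int(ad_low[0]), int(ad_low[1])
                high_ref, high_alt = int(ad_high[0]), int(ad_high[1])
            except (KeyError, TypeError, IndexError) as exc:
                raise ValueError(
                    f"{path}: malformed AD field at {rec.chrom}:{rec.pos}"
                ) from exc
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": int(rec.pos),
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "low_ref": low_ref,
                    "low_alt": low_alt,
                    "high_ref": high_ref,
                    "high_alt": high_alt,
                }
            )
    if n_multi:
        logger.info("read_pooled_vcf: skipped %d multiallelic records", n_multi)
    df = pd.DataFrame(rows, columns=POOL_COLUMNS)
    return df.sort_values(["chrom", "pos"], ignore_index=True)


# --------------------------------------------------------------------------
# BED


def write_bed(intervals: list[GenomicInterval], path) -> None:
    lines = []
    for iv in intervals:
        chrom, start, end, name = iv.to_bed_fields()
        lines.append(f"{chrom}\t{start}\t{end}\t{name}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed(path) -> list[GenomicInterval]:
    intervals = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{i}: BED line has fewer than 3 fields")
        name = fields[3] if len(fields) > 3 else "."
        intervals.append(
            GenomicInterval.from_bed_fields(
                fields[0], int(fields[1]), int(fields[2]), name
            )
        )
    return intervals


# --------------------------------------------------------------------------
# genotype matrices


def write_genotype_matrix(matrix: GenotypeMatrix, path,
                          params: dict | None = None,
                          seed: int | None = None) -> None:
    buf = _io.StringIO()
    for line in provenance_lines(params, seed):
        buf.write(line + "\n")
    for m in matrix.markers:
        pos = matrix.positions.get(m)
        buf.write(
            f"##marker={m};pos={'NA' if pos is None else pos};"
            f"coding={matrix.codings[m]}\n"
        )
    matrix.data.to_csv(buf, sep="\t")
    Path(path).write_text(buf.getvalue())


def read_genotype_matrix(path) -> GenotypeMatrix:
    positions: dict[str, int | None] = {}
    codings: dict[str, str] = {}
    body_lines = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("##marker="):
            fields = dict(
                token.split("=", 1) for token in line[2:].split(";")
            )
            name = fields["marker"]
            positions[name] = None if fields["pos"] == "NA" else int(fields["pos"])
            codings[name] = fields["coding"]
        elif line.startswith("#"):
            continue
        else:
            body_lines.append(line)
    df = pd.read_csv(_io.StringIO("\n".join(body_lines)), sep="\t",
                     index_col=0, dtype=str)
    for col in df.columns:
        bad = df[col].isna()
        if bad.any():
            raise ValueError(
                f"{path}: empty genotype cell for marker '{col}' "
                f"(plants: {df.index[bad].tolist()[:5]})"
            )
    return GenotypeMatrix(data=df, positions=positions, codings=codings)


# --------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """End-to-end pipeline parameters; everything stochastic is seeded."""

    seed: int = 0
    out_dir: str = "bulkmap_out"
    # genome geometry
    chrom_name: str = "chr1"
    length_bp: int = 25_000_000
    n_snps: int = 5000
    cm_per_mb: float = 3.0
    causal_pos: int = 14_750_000
    dominant_phenotype: str = "black"
    recessive_phenotype: str = "yellow"
    # populations
    n_f2_bsa: int = 200
    n_f2_linkage: int = 147
    n_f23: int = 2975
    # pools
    pool_size: int = 30
    mean_depth: float = 60.0
    # bsa stage
    window_bp: int = 1_000_000
    step_bp: int = 100_000
    min_depth: int = 7
    low_cut: float = 0.3
    high_cut: float = 0.7
    filter_mode: str = "both"
    n_boot_reps: int = 10_000
    call_level: float = 0.95
    window_ci_method: str = "mean_bounds"
    # linkage stage
    n_linkage_markers: int = 18
    linkage_span_bp: int = 3_000_000
    lod_min: float = 3.0
    r_max: float = 0.4
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.causal_pos <= self.length_bp:
            raise ValueError("causal_pos must lie on the chromosome")
        if self.step_bp <= 0 or self.window_bp <= 0:
            raise ValueError("window_bp and step_bp must be > 0")
        if self.call_level not in (0.95, 0.99):
            raise ValueError("call_level must be 0.95 or 0.99")
        if self.pool_size <= 0 or self.mean_depth <= 0:
            raise ValueError("pool_size and mean_depth must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k != "extra"
        }
        out.update(self.extra)
        return out
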