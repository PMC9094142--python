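"""Genomic interval arithmetic with 1-based inclusive coordinates.

All mapping stages in this package narrow a :class:`GenomicInterval`. The
internal convention is 1-based inclusive on both ends (``length_bp =
end - start + 1``); BED export converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, inclusive chromosome interval.

    Parameters
    ----------
    chrom :
        Chromosome / pseudochromosome name.
    start, end :
        1-based inclusive boundaries, ``1 <= start <= end``.
    confidence_level :
        Confidence level of the call that produced this interval
        (e.g. 0.95), or ``None`` for intervals not derived from a test.
    sign :
        +1 for a positive delta peak, -1 for a negative peak, 0 otherwise.
    """

    chrom: str
    start: int
    end: int
    confidence_level: float | None = None
    sign: int = 0

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def length_kb(self, ndigits: int = 1) -> float:
        return round(self.length_bp / 1e3, ndigits)

    def length_mb(self, ndigits: int = 1) -> float:
        return round(self.length_bp / 1e6, ndigits)

    def contains(self, pos: int, chrom: str | None = None) -> bool:
        if chrom is not None and chrom != self.chrom:
            return False
        return self.start <= pos <= self.end

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if self.chrom != other.chrom:
            return None
        lo, hi = max(self.start, other.start), min(self.end, other.end)
        if lo > hi:
            return None
        return replace(self, start=lo, end=hi)

    def to_bed_fields(self) -> tuple[str, int, int, str]:
        """BED conversion: 0-based half-open ``(chrom, start-1, end, name)``."""
        sign = {1: "+peak", -1: "-peak", 0: "."}[self.sign]
        level = "NA" if self.confidence_level is None else f"{self.confidence_level:g}"
        return self.chrom, self.start - 1, self.end, f"ci={level};{sign}"

    @classmethod
    def from_bed_fields(
        cls, chrom: str, bed_start: int, bed_end: int, name: str = "."
    ) -> "GenomicInterval":
        level: float | None = None
        sign = 0
        for token in name.split(";"):
            if token.startswith("ci=") and token[3:] != "NA":
                level = float(token[3:])
            elif token == "+peak":
                sign = 1
            elif token == "-peak":
                sign = -1
        return cls(chrom, bed_start + 1, bed_end, confidence_level=level, sign=sign)
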