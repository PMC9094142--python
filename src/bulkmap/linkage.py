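"""Two-point F2 linkage: recombination-fraction ML, LOD, grouping, Haldane.

Genotype columns use codes A (parent-1 homozygote), H (heterozygote),
B (parent-2 homozygote), C (dominant class, "not A") and U (missing).
The estimator builds the coupling-phase F2 joint-genotype table from
gamete frequencies ((1-r)/2, r/2), collapses classes according to each
column's coding, and maximises the multinomial log-likelihood over
r in [0, 0.5]. LOD = log10 L(r_hat) / L(0.5).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

CODOMINANT = "codominant"
DOMINANT = "dominant"

#: collapsed class labels and the F2 genotypes (P2-allele dosage) they merge
_CLASSES = {
    CODOMINANT: {"A": (0,), "H": (1,), "B": (2,)},
    DOMINANT: {"A": (0,), "C": (1, 2)},
}

UNLINKED_CM = math.inf


@dataclass
class GenotypeMatrix:
    """Plants x markers code table plus marker metadata.

    ``data`` is indexed by plant id; ``positions`` maps marker name to its
    1-based physical position (trait columns may carry ``None``);
    ``codings`` maps marker name to ``"codominant"`` or ``"dominant"``.
    """

    data: pd.DataFrame
    positions: dict[str, int | None]
    codings: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in self.data.columns:
            coding = self.codings.setdefault(m, CODOMINANT)
            if coding not in _CLASSES:
                raise ValueError(f"marker {m}: unknown coding '{coding}'")
            allowed = set(_CLASSES[coding]) | {"U"}
            bad = set(self.data[m].unique()) - allowed
            if bad:
                raise ValueError(
                    f"marker {m} ({coding}): invalid codes {sorted(bad)}"
                )
            self.positions.setdefault(m, None)

    @property
    def markers(self) -> list[str]:
        return list(self.data.columns)

    def column(self, marker: str) -> pd.Series:
        return self.data[marker]


@dataclass(frozen=True)
class TwoPointResult:
    marker1: str
    marker2: str
    r_hat: float
    lod: float
    cm: float  # Haldane distance; inf means unlinked (r_hat ~ 0.5)
    n: int

    @property
    def unlinked(self) -> bool:
        return not math.isfinite(self.cm)


def f2_joint_table(r: float) -> np.ndarray:
    """3x3 coupling-phase F2 joint genotype probabilities.

    Entry (i, j) is P(dosage_locus1 = i, dosage_locus2 = j) for an F2
    plant, from two independent gametes with haplotype frequencies
    (1-r)/2 for parental and r/2 for recombinant types.
    """
    # gamete haplotypes over (locus1 allele, locus2 allele)
    q = {
        (0, 0): (1 - r) / 2,
        (1, 1): (1 - r) / 2,
        (0, 1): r / 2,
        (1, 0): r / 2,
    }
    table = np.zeros((3, 3))
    for (a1, b1), p1 in q.items():
        for (a2, b2), p2 in q.items():
            table[a1 + a2, b1 + b2] += p1 * p2
    return table


def _collapsed_table(r: float, coding1: str, coding2: str) -> np.ndarray:
    full = f2_joint_table(r)
    c1 = _CLASSES[coding1]
    c2 = _CLASSES[coding2]
    out = np.zeros((len(c1), len(c2)))
    for i, g1 in enumerate(c1.values()):
        for j, g2 in enumerate(c2.values()):
            out[i, j] = full[np.ix_(g1, g2)].sum()
    return out


def _class_counts(
    col1: pd.Series, col2: pd.Series, coding1: str, coding2: str
) -> np.ndarray:
    keep = (col1 != "U") & (col2 != "U")
    c1 = list(_CLASSES[coding1])
    c2 = list(_CLASSES[coding2])
    counts = np.zeros((len(c1), len(c2)), dtype=np.int64)
    ct = pd.crosstab(col1[keep], col2[keep])
    for i, a in enumerate(c1):
        for j, b in enumerate(c2):
            if a in ct.index and b in ct.columns:
                counts[i, j] = int(ct.at[a, b])
    return counts


def _loglik(counts: np.ndarray, r: float, coding1: str, coding2: str) -> float:
    probs = _collapsed_table(r, coding1, coding2)
    with np.errstate(divide="ignore"):
        lp = np.log(probs)
    mask = counts > 0
    if np.any(np.isneginf(lp[mask])):
        return -math.inf
    return float(np.sum(counts[mask] * lp[mask]))


def estimate_rf(
    col1: pd.Series,
    col2: pd.Series,
    coding1: str = CODOMINANT,
    coding2: str = CODOMINANT,
    name1: str | None = None,
    name2: str | None = None,
) -> TwoPointResult:
    """ML recombination fraction and LOD for one marker pair.

    Missing codes (U) are dropped pairwise. All plants falling in a
    single joint class leaves r undefined and raises ``ValueError``.
    """
    counts = _class_counts(col1, col2, coding1, coding2)
    n = int(counts.sum())
    if n == 0:
        raise ValueError("no jointly scored plants")
    if (counts > 0).sum() == 1:
        raise ValueError("all plants fall in a single joint class; r undefined")
    if n < 20:
        warnings.warn(
            f"only {n} jointly scored plants; r estimate is unreliable",
            stacklevel=2,
        )

    def nll(r: float) -> float:
        return -_loglik(counts, r, coding1, coding2)

    res = minimize_scalar(
        nll, bounds=(1e-9, 0.5 - 1e-9), method="bounded",
        options={"xatol": 1e-8},
    )
    candidates = [(float(res.x), -res.fun)]
    for r0 in (0.0, 0.5):
        candidates.append((r0, _loglik(counts, r0, coding1, coding2)))
    r_hat, ll_hat = max(candidates, key=lambda t: t[1])
    if abs(r_hat) < 1e-6:
        r_hat = 0.0
    ll_null = _loglik(counts, 0.5, coding1, coding2)
    lod = max((ll_hat - ll_null) / math.log(10), 0.0)
    cm = haldane_cm(r_hat) if r_hat < 0.5 - 1e-9 else UNLINKED_CM
    return TwoPointResult(
        marker1=name1 or str(col1.name),
        marker2=name2 or str(col2.name),
        r_hat=r_hat,
        lod=lod,
        cm=cm,
        n=n,
    )


def haldane_cm(r: float) -> float:
    """Haldane map distance: cM = -50 ln(1 - 2r), for r in [0, 0.5)."""
    if r < 0:
        raise ValueError("recombination fraction must be >= 0")
    if r >= 0.5:
        raise ValueError("r >= 0.5 has no finite Haldane distance")
    return -50.0 * math.log1p(-2.0 * r)


def haldane_r(cm: float) -> float:
    """Inverse Haldane map function: r = (1 - exp(-cM/50)) / 2."""
    if cm < 0:
        raise ValueError("map distance must be >= 0")
    return (1.0 - math.exp(-cm / 50.0)) / 2.0


def group_markers(
    results: list[TwoPointResult], lod_min: float = 3.0, r_max: float = 0.4
) -> list[set[str]]:
    """Single-linkage grouping: linked means LOD >= lod_min and r < r_max."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for res in results:
        find(res.marker1)
        find(res.marker2)
        if res.lod >= lod_min and res.r_hat < r_max:
            union(res.marker1, res.marker2)
    groups: dict[str, set[str]] = {}
    for m in parent:
        groups.setdefault(find(m), set()).add(m)
    return sorted(groups.values(), key=lambda s: sorted(s)[0])


def trait_map(
    matrix: GenotypeMatrix, trait_column: str = "trait"
) -> pd.DataFrame:
    """Per-marker Haldane distance and LOD to the trait, in physical order.

    Markers whose column is entirely missing are excluded with a log
    entry. Co-segregating markers (r_hat = 0) are flagged.
    """
    if trait_column not in matrix.data.columns:
        raise ValueError(f"no trait column '{trait_column}'")
    if matrix.codings[trait_column] != DOMINANT:
        raise ValueError("trait column must use the dominant (A/C) coding")
    trait = matrix.column(trait_column)
    rows = []
    markers = [m for m in matrix.markers if m != trait_column]
    markers.sort(key=lambda m: (matrix.positions.get(m) is None,
                                matrix.positions.get(m) or 0))
    for m in markers:
        col = matrix.column(m)
        if (col == "U").all():
            logger.info("trait_map: marker %s is all-missing; excluded", m)
            continue
        res = estimate_rf(
            col, trait, matrix.codings[m], DOMINANT, name1=m, name2=trait_column
        )
        rows.append(
            {
                "marker": m,
                "pos_bp": matrix.positions.get(m),
                "r_hat": res.r_hat,
                "cm_to_trait": res.cm,
                "lod": res.lod,
                "n": res.n,
                "cosegregating": res.r_hat == 0.0,
            }
        )
    return pd.DataFrame(rows)
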