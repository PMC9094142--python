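"""Chi-square goodness-of-fit tests for phenotype segregation ratios."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class SegregationResult:
    observed: tuple[int, ...]
    expected: tuple[float, ...]
    expected_ratio: tuple[float, ...]
    chi2: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "observed": ":".join(str(o) for o in self.observed),
            "ratio": ":".join(f"{r:g}" for r in self.expected_ratio),
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
        }


def chi_square_gof(
    observed,
    ratio,
    continuity_correction: bool = False,
) -> SegregationResult:
    """Test observed class counts against an expected segregation ratio.

    ``expected_i = total * ratio_i / sum(ratio)``; the statistic is
    ``sum((O - E)^2 / E)`` with ``df = classes - 1`` and an upper-tail
    chi-square p-value. No continuity correction is applied by default;
    ``continuity_correction=True`` switches to the Yates statistic
    ``sum((|O - E| - 0.5)^2 / E)``.
    """
    obs = np.asarray(observed, dtype=float)
    rat = np.asarray(ratio, dtype=float)
    if obs.ndim != 1 or rat.ndim != 1 or len(obs) != len(rat):
        raise ValueError("observed and ratio must be 1-D and the same length")
    if len(obs) < 2:
        raise ValueError("need at least two phenotype classes")
    if np.any(obs < 0):
        raise ValueError("observed counts must be >= 0")
    if np.any(rat <= 0):
        raise ValueError("ratio terms must be > 0")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total observed count must be > 0")

    expected = total * rat / rat.sum()
    if np.any(expected < 1):
        warnings.warn(
            "some expected class counts are < 1; the chi-square "
            "approximation is unreliable",
            stacklevel=2,
        )
    dev = np.abs(obs - expected)
    if continuity_correction:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float(np.sum(dev**2 / expected))
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return SegregationResult(
        observed=tuple(int(o) for o in obs),
        expected=tuple(float(e) for e in expected),
        expected_ratio=tuple(float(r) for r in rat),
        chi2=chi2,
        df=df,
        p_value=p,
    )
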