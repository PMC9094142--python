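"""SNP-index / delta-SNP-index profiling with a simulated null envelope.

The per-pool SNP-index of a site is ``alt_depth / (ref_depth + alt_depth)``
and ``delta = index_low - index_high`` where *low* is the recessive-phenotype
bulk and *high* the dominant one. Sites are filtered on depth and
informativeness, windowed means are profiled along the chromosome, and
significance is assessed against empirical quantiles of a null model in
which both bulks are random draws from an F2 (1/4 : 1/2 : 1/4 genotype
sampling followed by binomial read sampling at the observed depths).
Contiguous significant windows merge into candidate intervals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

#: pooled-variant table columns; low = recessive bulk, high = dominant bulk
POOL_COLUMNS = ["chrom", "pos", "ref", "alt",
                "low_ref", "low_alt", "high_ref", "high_alt"]

_DEPTH_COLS = ["low_ref", "low_alt", "high_ref", "high_alt"]


def compute_snp_index(records: pd.DataFrame) -> pd.DataFrame:
    """Attach per-pool indices, depths and delta to a pooled-variant table.

    Pools with zero depth get an undefined (NaN) index and
    ``pass_filter=False``.
    """
    missing = [c for c in POOL_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"pooled-variant table is missing columns: {missing}")
    for c in _DEPTH_COLS:
        if (records[c] < 0).any():
            raise ValueError(f"negative depths in column '{c}'")
    out = records.copy()
    depth_low = out["low_ref"] + out["low_alt"]
    depth_high = out["high_ref"] + out["high_alt"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["index_low"] = np.where(depth_low > 0, out["low_alt"] / depth_low, np.nan)
        out["index_high"] = np.where(
            depth_high > 0, out["high_alt"] / depth_high, np.nan
        )
    out["depth_low"] = depth_low
    out["depth_high"] = depth_high
    out["delta"] = out["index_low"] - out["index_high"]
    out["pass_filter"] = (depth_low > 0) & (depth_high > 0)
    return out


def filter_snps(
    records: pd.DataFrame,
    min_depth: int = 7,
    low_cut: float = 0.3,
    high_cut: float = 0.7,
    mode: str = "both",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the depth and index-informativeness filters.

    A SNP is excluded when either pool's depth is below ``min_depth``, or
    when its index falls below ``low_cut`` / above ``high_cut`` in *both*
    pools (``mode="both"``, default) or in *either* pool
    (``mode="either"``). Returns the passing subset and per-rule removal
    counts.
    """
    if mode not in ("both", "either"):
        raise ValueError("mode must be 'both' or 'either'")
    if "index_low" not in records.columns:
        records = compute_snp_index(records)
    fail_depth = (records["depth_low"] < min_depth) | (
        records["depth_high"] < min_depth
    )
    low_l = records["index_low"] < low_cut
    low_h = records["index_high"] < low_cut
    high_l = records["index_low"] > high_cut
    high_h = records["index_high"] > high_cut
    if mode == "both":
        fail_low = low_l & low_h
        fail_high = high_l & high_h
    else:
        fail_low = low_l | low_h
        fail_high = high_l | high_h
    fail = fail_depth | fail_low.fillna(False) | fail_high.fillna(False)
    counts = {
        "input": int(len(records)),
        "removed_depth": int(fail_depth.sum()),
        "removed_index_low": int((fail_low & ~fail_depth).sum()),
        "removed_index_high": int((fail_high & ~fail_depth).sum()),
        "passed": int((~fail).sum()),
    }
    logger.info("filter_snps: %s", counts)
    out = records.loc[~fail].copy()
    out["pass_filter"] = True
    return out, counts


def sliding_windows(
    records: pd.DataFrame,
    chrom_lengths: dict[str, int] | int,
    window_bp: int = 1_000_000,
    step_bp: int = 100_000,
) -> pd.DataFrame:
    """Windowed unweighted means of the per-SNP statistics.

    Windows start at 1, 1+step, ... while the start lies on the
    chromosome; terminal windows are truncated at the chromosome end.
    Windows without passing SNPs are emitted with ``n_snps=0`` and NaN
    means. ``records`` must be sorted by (chrom, pos) and already
    filtered.
    """
    if step_bp <= 0:
        raise ValueError("step_bp must be > 0")
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    if "index_low" not in records.columns:
        records = compute_snp_index(records)
    rows = []
    for chrom, sub in records.groupby("chrom", sort=True):
        if isinstance(chrom_lengths, dict):
            if chrom not in chrom_lengths:
                raise ValueError(f"no chromosome length for '{chrom}'")
            clen = int(chrom_lengths[chrom])
        else:
            clen = int(chrom_lengths)
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"records on '{chrom}' are not sorted by pos")
        idx_low = sub["index_low"].to_numpy()
        idx_high = sub["index_high"].to_numpy()
        delta = sub["delta"].to_numpy()
        starts = np.arange(1, clen + 1, step_bp, dtype=np.int64)
        ends = np.minimum(starts + window_bp - 1, clen)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        for s, e, a, b in zip(starts, ends, lo, hi):
            n = int(b - a)
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(s),
                    "end": int(e),
                    "n_snps": n,
                    "mean_index_low": float(np.mean(idx_low[a:b])) if n else np.nan,
                    "mean_index_high": float(np.mean(idx_high[a:b])) if n else np.nan,
                    "mean_delta": float(np.mean(delta[a:b])) if n else np.nan,
                }
            )
    win = pd.DataFrame(rows)
    for c in ("ci95_lo", "ci95_hi", "ci99_lo", "ci99_hi"):
        win[c] = np.nan
    return win


def _simulate_null_pool_freqs(
    n_plants: int, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Null pool alt frequencies: n genotypes from (1/4, 1/2, 1/4)."""
    counts = rng.multinomial(n_plants, [0.25, 0.5, 0.25], size=n_reps)
    return (counts[:, 1] + 2 * counts[:, 2]) / (2 * n_plants)


def bootstrap_null_ci(
    pool_sizes: tuple[int, int],
    depth_pairs,
    n_reps: int = 10_000,
    levels: tuple[float, ...] = (0.95, 0.99),
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Empirical null delta quantiles for each distinct depth pair.

    For every replicate and pool, genotypes of ``n`` plants are drawn from
    the F2 law (1/4, 1/2, 1/4), the pool alt frequency formed, alt reads
    drawn Binomial(depth, p) and the delta of the two pool indices
    computed. Linear-interpolation quantiles at the symmetric tails of
    each ``level`` are cached per distinct ``(depth_low, depth_high)``
    pair. Zero depth in either pool yields NaN bounds.
    """
    n_low, n_high = pool_sizes
    if n_low < 1 or n_high < 1:
        raise ValueError("pool sizes must be >= 1")
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    rng = np.random.default_rng(rng)
    pairs = pd.DataFrame(depth_pairs, columns=["depth_low", "depth_high"])
    uniq = pairs.drop_duplicates().to_numpy(dtype=np.int64)

    # one shared set of genotype-sampling draws across depth pairs: the
    # null quantile per pair conditions only on depths, so reuse is sound
    # and keeps the table O(unique pairs x reps)
    p_low = _simulate_null_pool_freqs(n_low, n_reps, rng)
    p_high = _simulate_null_pool_freqs(n_high, n_reps, rng)

    qs: list[float] = []
    for lev in levels:
        tail = (1 - lev) / 2
        qs += [tail, 1 - tail]

    rows = []
    ok = (uniq[:, 0] > 0) & (uniq[:, 1] > 0)
    if ok.any():
        d_ok = uniq[ok]
        alt_low = rng.binomial(d_ok[:, [0]], p_low[None, :])
        alt_high = rng.binomial(d_ok[:, [1]], p_high[None, :])
        delta = alt_low / d_ok[:, [0]] - alt_high / d_ok[:, [1]]
        quants = np.quantile(delta, qs, axis=1, method="linear")
    j = 0
    for i, (dl, dh) in enumerate(uniq):
        row: dict = {"depth_low": int(dl), "depth_high": int(dh)}
        if dl > 0 and dh > 0:
            for k, lev in enumerate(levels):
                tag = f"ci{int(round(lev * 100))}"
                row[f"{tag}_lo"] = float(quants[2 * k, j])
                row[f"{tag}_hi"] = float(quants[2 * k + 1, j])
            j += 1
        else:
            for lev in levels:
                tag = f"ci{int(round(lev * 100))}"
                row[f"{tag}_lo"] = np.nan
                row[f"{tag}_hi"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index(["depth_low", "depth_high"])


def attach_snp_ci(records: pd.DataFrame, ci_table: pd.DataFrame) -> pd.DataFrame:
    """Join per-depth-pair null CI bounds onto the per-SNP table."""
    out = records.merge(
        ci_table.reset_index(), on=["depth_low", "depth_high"], how="left"
    )
    out.index = records.index
    return out


def attach_window_ci(
    windows: pd.DataFrame,
    records_with_ci: pd.DataFrame,
    method: str = "mean_bounds",
    pool_sizes: tuple[int, int] | None = None,
    n_reps: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Populate window CI columns.

    ``method="mean_bounds"`` (default): each window bound is the
    arithmetic mean of its member SNPs' per-depth null bounds —
    conservative and depth-aware. ``method="window_mean_null"``: the
    bounds are quantiles of null-simulated window mean deltas (genotype
    draws shared across member SNPs within a replicate, read draws
    independent), which is tighter.
    """
    if method not in ("mean_bounds", "window_mean_null"):
        raise ValueError("unknown window CI method: " + method)
    out = windows.copy()
    ci_cols = ["ci95_lo", "ci95_hi", "ci99_lo", "ci99_hi"]
    ci_cols = [c for c in ci_cols if c in records_with_ci.columns]
    if method == "window_mean_null":
        if pool_sizes is None:
            raise ValueError("window_mean_null requires pool_sizes")
        rng = np.random.default_rng(rng)
    for chrom, sub in records_with_ci.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        mask = out["chrom"] == chrom
        for i in out.index[mask]:
            a = np.searchsorted(pos, out.at[i, "start"], side="left")
            b = np.searchsorted(pos, out.at[i, "end"], side="right")
            if b <= a:
                continue
            if method == "mean_bounds":
                for c in ci_cols:
                    out.at[i, c] = float(sub[c].iloc[a:b].mean())
            else:
                dl = sub["depth_low"].to_numpy()[a:b]
                dh = sub["depth_high"].to_numpy()[a:b]
                keep = (dl > 0) & (dh > 0)
                if not keep.any():
                    continue
                dl, dh = dl[keep], dh[keep]
                n_low, n_high = pool_sizes
                p_low = _simulate_null_pool_freqs(n_low, n_reps, rng)
                p_high = _simulate_null_pool_freqs(n_high, n_reps, rng)
                alt_low = rng.binomial(dl[:, None], p_low[None, :])
                alt_high = rng.binomial(dh[:, None], p_high[None, :])
                deltas = (alt_low / dl[:, None] - alt_high / dh[:, None]).mean(axis=0)
                out.at[i, "ci95_lo"], out.at[i, "ci95_hi"] = np.quantile(
                    deltas, [0.025, 0.975]
                )
                out.at[i, "ci99_lo"], out.at[i, "ci99_hi"] = np.quantile(
                    deltas, [0.005, 0.995]
                )
    return out


def delta_profile(
    records: pd.DataFrame,
    pool_sizes: tuple[int, int],
    chrom_lengths: dict[str, int] | int,
    window_bp: int = 1_000_000,
    step_bp: int = 100_000,
    min_depth: int = 7,
    low_cut: float = 0.3,
    high_cut: float = 0.7,
    filter_mode: str = "both",
    n_reps: int = 10_000,
    levels: tuple[float, ...] = (0.95, 0.99),
    window_ci_method: str = "mean_bounds",
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Full profile: index -> filter -> windows -> null CIs.

    Returns ``(per_snp_table, per_window_table, filter_counts)``.
    """
    rng = np.random.default_rng(rng)
    snps = compute_snp_index(records)
    passing, counts = filter_snps(
        snps, min_depth=min_depth, low_cut=low_cut, high_cut=high_cut,
        mode=filter_mode,
    )
    ci_table = bootstrap_null_ci(
        pool_sizes,
        passing[["depth_low", "depth_high"]].to_numpy(),
        n_reps=n_reps,
        levels=levels,
        rng=rng,
    )
    passing = attach_snp_ci(passing, ci_table)
    windows = sliding_windows(passing, chrom_lengths, window_bp, step_bp)
    windows = attach_window_ci(
        windows, passing, method=window_ci_method, pool_sizes=pool_sizes, rng=rng
    )
    return passing, windows, counts


def call_candidate_regions(
    windows: pd.DataFrame, level: float = 0.95
) -> list[GenomicInterval]:
    """Merge significant windows into signed candidate intervals.

    A window is significant when its mean delta lies outside its null CI
    at ``level``. Overlapping or adjacent significant windows of the same
    sign merge; each interval spans the first merged window start to the
    last merged window end.
    """
    tag = f"ci{int(round(level * 100))}"
    lo_c, hi_c = f"{tag}_lo", f"{tag}_hi"
    if lo_c not in windows.columns or hi_c not in windows.columns:
        raise ValueError(f"windows table has no CI columns for level {level}")
    w = windows.sort_values(["chrom", "start"])
    sig_pos = (w["n_snps"] > 0) & (w["mean_delta"] > w[hi_c])
    sig_neg = (w["n_snps"] > 0) & (w["mean_delta"] < w[lo_c])
    intervals: list[GenomicInterval] = []
    cur: dict | None = None
    for (_, row), pos_f, neg_f in zip(w.iterrows(), sig_pos, sig_neg):
        if not (pos_f or neg_f):
            continue
        sign = 1 if pos_f else -1
        if (
            cur is not None
            and row["chrom"] == cur["chrom"]
            and row["start"] <= cur["end"] + 1
            and sign == cur["sign"]
        ):
            cur["end"] = max(cur["end"], int(row["end"]))
        else:
            if cur is not None:
                intervals.append(
                    GenomicInterval(
                        cur["chrom"], cur["start"], cur["end"],
                        confidence_level=level, sign=cur["sign"],
                    )
                )
            cur = {
                "chrom": row["chrom"],
                "start": int(row["start"]),
                "end": int(row["end"]),
                "sign": sign,
            }
    if cur is not None:
        intervals.append(
            GenomicInterval(
                cur["chrom"], cur["start"], cur["end"],
                confidence_level=level, sign=cur["sign"],
            )
        )
    return intervals


def plot_delta_profile(windows: pd.DataFrame, path, level: float = 0.95) -> None:
    """Basic delta-SNP-index profile figure (one panel per chromosome)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tag = f"ci{int(round(level * 100))}"
    chroms = list(windows["chrom"].unique())
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(9, 2.8 * len(chroms)), squeeze=False
    )
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = windows[windows["chrom"] == chrom]
        mid = (sub["start"] + sub["end"]) / 2e6
        ax.plot(mid, sub["mean_delta"], lw=1.2, color="k", label="mean delta")
        ax.plot(mid, sub[f"{tag}_hi"], lw=0.8, color="tab:blue", label=f"{tag} bounds")
        ax.plot(mid, sub[f"{tag}_lo"], lw=0.8, color="tab:blue")
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_xlabel(f"{chrom} position (Mb)")
        ax.set_ylabel("delta SNP-index")
        ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
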