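"""Delta SNP-index bulked-segregant mapping (QTL-seq style).

Per-SNP indices (alt-read fraction per bulk), sliding-window smoothing,
simulation-based null confidence bands, and candidate-interval calling.
Sign convention, stated in all outputs: delta = high (trait-mutant) bulk
minus low bulk, with the mutant-parent allele as alt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def compute_delta_index(counts: pd.DataFrame, min_depth: int = 10) -> pd.DataFrame:
    """Per-SNP table of ``index_high``, ``index_low`` and ``delta``.

    SNPs with total depth below ``min_depth`` in either bulk (including
    zero-depth SNPs) are dropped; the returned frame carries the number
    dropped in ``.attrs["n_dropped"]``.
    """
    df = counts.copy()
    depth_high = df["ref_depth_high"] + df["alt_depth_high"]
    depth_low = df["ref_depth_low"] + df["alt_depth_low"]
    keep = (depth_high >= max(min_depth, 1)) & (depth_low >= max(min_depth, 1))
    n_dropped = int((~keep).sum())
    df = df[keep].copy()
    df["index_high"] = df["alt_depth_high"] / (df["alt_depth_high"] + df["ref_depth_high"])
    df["index_low"] = df["alt_depth_low"] / (df["alt_depth_low"] + df["ref_depth_low"])
    df["delta"] = df["index_high"] - df["index_low"]
    df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    df.attrs["n_dropped"] = n_dropped
    return df


def smooth_profile(
    snp_table: pd.DataFrame,
    window: int = 2_000_000,
    step: int = 50_000,
    chrom_len: int | None = None,
) -> pd.DataFrame:
    """Sliding-window unweighted means of per-SNP deltas.

    Window count per chromosome is ``floor((L - window)/step) + 1``; windows
    containing no SNPs are emitted with ``n_snps = 0`` and null delta.
    """
    if not window >= step > 0:
        raise ValueError("need window >= step > 0")
    rows = []
    for chrom, sub in snp_table.groupby("chrom", sort=True):
        L = chrom_len if chrom_len is not None else int(sub["pos"].max()) + 1
        n_windows = max(0, (L - window) // step) + 1
        pos = sub["pos"].to_numpy()
        for w in range(n_windows):
            ws, we = w * step, w * step + window
            mask = (pos >= ws) & (pos < we)
            n = int(mask.sum())
            rows.append(
                {
                    "chrom": chrom,
                    "window_start": ws,
                    "window_end": we,
                    "mean_index_high": sub.loc[mask, "index_high"].mean() if n else np.nan,
                    "mean_index_low": sub.loc[mask, "index_low"].mean() if n else np.nan,
                    "delta": sub.loc[mask, "delta"].mean() if n else np.nan,
                    "n_snps": n,
                }
            )
    return pd.DataFrame(rows)


def null_ci(
    depths,
    n_high: int,
    n_low: int,
    pop_type: str = "F2",
    n_sim: int = 10_000,
    alpha: float = 0.01,
    seed: int = 0,
) -> dict[int, tuple[float, float]]:
    """Simulated null band of the per-SNP delta index, per sequencing depth.

    Unselected bulks: each bulk's allele frequency is the mean of
    ``2 * n_bulk`` alleles drawn from F2 individuals sampled 1:2:1, followed
    by binomial read sampling at the given depth.  Returns
    ``{depth: (alpha/2 quantile, 1 - alpha/2 quantile)}``.
    """
    if pop_type != "F2":
        raise ValueError("only F2 bulks are supported")
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    bands = {}
    for depth in depths:
        deltas = np.empty(n_sim)
        # genotype alt-dosage per individual: 0/1/2 with probs 1/4, 1/2, 1/4
        dos_high = rng.binomial(2, 0.5, size=(n_sim, n_high))
        dos_low = rng.binomial(2, 0.5, size=(n_sim, n_low))
        p_high = dos_high.sum(axis=1) / (2 * n_high)
        p_low = dos_low.sum(axis=1) / (2 * n_low)
        idx_high = rng.binomial(depth, p_high) / depth
        idx_low = rng.binomial(depth, p_low) / depth
        deltas = idx_high - idx_low
        lo, hi = np.quantile(deltas, [alpha / 2, 1 - alpha / 2])
        bands[int(depth)] = (float(lo), float(hi))
    return bands


@dataclass
class CandidateInterval:
    chrom: str
    start: int
    end: int
    n_windows: int
    peak_window_start: int
    peak_delta: float


def call_intervals(
    profile: pd.DataFrame,
    ci_high: float,
    min_run: int = 5,
    merge_gap: int = 2,
) -> list[CandidateInterval]:
    """Maximal runs of windows whose delta exceeds the null band.

    Runs of at least ``min_run`` consecutive above-band windows are reported;
    runs separated by at most ``merge_gap`` windows are merged first.  Each
    interval reports its peak window and peak delta.
    """
    out: list[CandidateInterval] = []
    if profile.empty:
        return out
    for chrom, sub in profile.groupby("chrom", sort=True):
        sub = sub.sort_values("window_start").reset_index(drop=True)
        above = (sub["delta"] > ci_high).fillna(False).to_numpy()
        runs = []
        i = 0
        while i < len(above):
            if above[i]:
                j = i
                while j + 1 < len(above) and above[j + 1]:
                    j += 1
                runs.append([i, j])
                i = j + 1
            else:
                i += 1
        merged = []
        for run in runs:
            if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
                merged[-1][1] = run[1]
            else:
                merged.append(run)
        for i0, i1 in merged:
            if i1 - i0 + 1 < min_run:
                continue
            block = sub.iloc[i0: i1 + 1]
            peak = block.loc[block["delta"].idxmax()]
            out.append(
                CandidateInterval(
                    chrom=str(chrom),
                    start=int(block["window_start"].iloc[0]),
                    end=int(block["window_end"].iloc[-1]),
                    n_windows=i1 - i0 + 1,
                    peak_window_start=int(peak["window_start"]),
                    peak_delta=float(peak["delta"]),
                )
            )
    return out


def intervals_to_bed(intervals, path=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "name": [f"candidate_{i + 1}" for i in range(len(intervals))],
            "score": [round(iv.peak_delta, 4) for iv in intervals],
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", header=False, index=False)
    return df
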