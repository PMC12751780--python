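"""Runs of homozygosity: sliding-window detection, length bins and F_ROH.

The detector follows the PLINK ``--homozyg`` scheme: a 50-SNP window is
"eligible" when it holds at most 3 heterozygous and 5 missing calls; a SNP
enters a candidate run when the fraction of eligible windows covering it
reaches the hit threshold; candidate runs are split at heterozygous calls and
at large inter-SNP gaps, then kept if they satisfy the length, SNP-count and
density conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, HaplotypePanel

ROH_BINS = ((0.5e6, 1e6, "0.5-1Mb"), (1e6, 2e6, "1-2Mb"),
            (2e6, 4e6, "2-4Mb"), (4e6, np.inf, ">4Mb"))


@dataclass
class ROHParams:
    """Detection parameters; the window conditions are the printed criteria,
    the remaining thresholds are the PLINK defaults."""

    window_snps: int = 50
    max_het_per_window: int = 3
    max_missing_per_window: int = 5
    density_kb_per_snp: float = 50.0
    window_hit_threshold: float = 0.05
    min_len_bp: int = 500_000
    min_snps: int = 50
    max_gap_bp: int = 1_000_000

    def __post_init__(self):
        for f, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"ROH parameter {f} must be positive")


def _candidate_mask(genos: np.ndarray, params: ROHParams) -> np.ndarray:
    """Per-SNP flag: covered by an eligible-window fraction >= threshold."""
    m = genos.size
    w = params.window_snps
    het = (genos == 1).astype(np.int64)
    mis = (genos == MISSING).astype(np.int64)
    if m < w:
        return np.zeros(m, dtype=bool)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    starts = np.arange(m - w + 1)
    eligible = ((chet[starts + w] - chet[starts] <= params.max_het_per_window)
                & (cmis[starts + w] - cmis[starts] <= params.max_missing_per_window))
    celig = np.concatenate([[0], np.cumsum(eligible)])
    i = np.arange(m)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, m - w)
    n_cover = hi - lo + 1
    n_elig = celig[hi + 1] - celig[lo]
    return n_elig / n_cover >= params.window_hit_threshold


def detect_roh_sample(genos, positions, params: ROHParams | None = None):
    """ROH segments for one sample: list of (start_bp, end_bp, n_snps, length).

    Positions are 1-based SNP coordinates (must be sorted); a segment spans
    its first to last SNP inclusive.
    """
    params = params or ROHParams()
    genos = np.asarray(genos)
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size > 1 and np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be sorted and unique")
    cand = _candidate_mask(genos, params)
    # split candidate stretches at heterozygous SNPs and at large gaps
    cand = cand & (genos != 1)
    segs = []
    i = 0
    m = genos.size
    while i < m:
        if not cand[i]:
            i += 1
            continue
        j = i
        while (j + 1 < m and cand[j + 1]
               and positions[j + 1] - positions[j] <= params.max_gap_bp):
            j += 1
        start, end = positions[i], positions[j]
        n_snps = int(np.sum(genos[i:j + 1] != MISSING))
        length = int(end - start)
        if (length >= params.min_len_bp and n_snps >= params.min_snps
                and length / max(n_snps, 1) <= params.density_kb_per_snp * 1000.0):
            segs.append((int(start), int(end), n_snps, length))
        i = j + 1
    return segs


def detect_roh(panel: HaplotypePanel, params: ROHParams | None = None) -> pd.DataFrame:
    """ROH segments for every sample of a panel.

    Returns a DataFrame `sample chrom start_bp end_bp n_snps length_bp`.
    """
    params = params or ROHParams()
    g = panel.genotypes()
    rows = []
    for i, sample in enumerate(panel.sample_ids):
        for start, end, n_snps, length in detect_roh_sample(g[i], panel.positions, params):
            rows.append((sample, panel.chrom, start, end, n_snps, length))
    return pd.DataFrame(rows, columns=["sample", "chrom", "start_bp", "end_bp",
                                       "n_snps", "length_bp"])


def bin_roh(segments: pd.DataFrame) -> pd.DataFrame:
    """Counts and summed lengths per sample in the four length bins.

    Bins are left-closed/right-open: [0.5,1), [1,2), [2,4), [4,∞) Mb.
    """
    samples = sorted(segments["sample"].unique()) if len(segments) else []
    rows = []
    for s in samples:
        sub = segments[segments["sample"] == s]
        row = {"sample": s}
        for lo, hi, name in ROH_BINS:
            sel = sub[(sub["length_bp"] >= lo) & (sub["length_bp"] < hi)]
            row[f"n_{name}"] = len(sel)
            row[f"len_{name}"] = int(sel["length_bp"].sum())
        rows.append(row)
    cols = ["sample"] + [f"{p}_{n}" for _, _, n in ROH_BINS for p in ("n", "len")]
    return pd.DataFrame(rows, columns=cols if rows else cols)


def froh(segments: pd.DataFrame, autosome_len_bp: int, samples=None) -> pd.Series:
    """Per-sample F_ROH = Σ ROH length / autosome length, in [0, 1]."""
    if autosome_len_bp <= 0:
        raise ValueError("autosome length must be positive")
    totals = segments.groupby("sample")["length_bp"].sum() if len(segments) else pd.Series(dtype=float)
    if samples is not None:
        totals = totals.reindex(samples, fill_value=0)
    return totals / autosome_len_bp
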