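"""Candidate-region logic: empirical tails, consensus calls, gene reports.

Windows in the top 1% of the genome-wide empirical distribution of a scan
statistic are outliers; a window supported by at least two of {CLR (upper
tail), θπ (lower tail), iHS window summary (upper tail)} is a consensus sweep
candidate.  Cross-population candidates are the intersection of the F_ST and
XP-EHH top 1% sets.  The di statistic sums standardized pairwise F_ST values
of a focal population against every other population.  Candidate genes are
windows' overlapping annotations, and each gene's ancestral origin is the
label of the retained excess-ancestry segments it overlaps.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .panel import HaplotypePanel
from .stats import WindowedStat


def empirical_top(stat: WindowedStat | pd.DataFrame, q=0.01, tail="upper"):
    """Flag windows in the empirical q-tail; ties at the threshold included.

    Missing windows are excluded from both numerator and denominator.
    Returns (flags boolean array aligned to the windows, threshold).
    """
    values = stat.values if isinstance(stat, WindowedStat) else np.asarray(stat, dtype=float)
    ok = np.isfinite(values)
    n = int(ok.sum())
    if n == 0:
        return np.zeros(values.size, dtype=bool), np.nan
    if n < 100:
        warnings.warn(f"only {n} non-missing windows; a {q:.0%} tail is noisy",
                      stacklevel=2)
    vals = values[ok]
    if tail == "upper":
        thr = np.quantile(vals, 1.0 - q)
        flags = ok & (values >= thr)
    elif tail == "lower":
        thr = np.quantile(vals, q)
        flags = ok & (values <= thr)
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    if np.all(vals == vals[0]):
        warnings.warn("all window values tie at the threshold; every window flagged",
                      stacklevel=2)
    return flags, float(thr)


def map_clr_to_windows(clr_table: pd.DataFrame, grid) -> np.ndarray:
    """Attribute each CLR grid point to every sliding window containing it.

    A window's value is the maximum CLR over the grid points it contains
    (NaN when it contains none).
    """
    vals = np.full(grid.n_windows, np.nan)
    sub = clr_table[clr_table["chrom"].astype(str) == str(grid.chrom)]
    pos0 = sub["grid_pos"].to_numpy() - 1
    clr = sub["clr"].to_numpy(dtype=float)
    for w in range(grid.n_windows):
        inside = (pos0 >= grid.starts[w]) & (pos0 < grid.ends[w]) & np.isfinite(clr)
        if inside.any():
            vals[w] = clr[inside].max()
    return vals


def consensus_sweeps(clr_w, pi_w, ihs_w, q=0.01) -> pd.DataFrame:
    """Windows supported by ≥2 of CLR (upper), θπ (lower) and iHS (upper) tails.

    All three inputs must live on the same window grid (WindowedStat, or a
    plain value array for pre-mapped CLR).
    """
    grids = [s.grid for s in (clr_w, pi_w, ihs_w) if isinstance(s, WindowedStat)]
    for g in grids[1:]:
        if (g.chrom != grids[0].chrom or not np.array_equal(g.starts, grids[0].starts)):
            raise ValueError("statistics must share one window grid")
    grid = grids[0]
    f_clr, _ = empirical_top(clr_w, q, "upper")
    f_pi, _ = empirical_top(pi_w, q, "lower")
    f_ihs, _ = empirical_top(ihs_w, q, "upper")
    n_methods = f_clr.astype(int) + f_pi.astype(int) + f_ihs.astype(int)
    df = grid.to_frame()
    df["clr_top"] = f_clr
    df["pi_low"] = f_pi
    df["ihs_top"] = f_ihs
    df["methods_passing"] = n_methods
    df["consensus"] = n_methods >= 2
    return df


def crosspop_candidates(fst_w, xpehh_w, q=0.01) -> np.ndarray:
    """Intersection of the F_ST and XP-EHH upper q-tails (boolean per window)."""
    f1, _ = empirical_top(fst_w, q, "upper")
    f2, _ = empirical_top(xpehh_w, q, "upper")
    return f1 & f2


def di_statistic(fst_by_pop: dict) -> pd.DataFrame:
    """Akey's di: per site, the sum of standardized pairwise F_ST values.

    ``fst_by_pop`` maps each comparison population's name to the focal
    population's per-site F_ST against it.  Standardization uses each pair's
    genome-wide mean and SD; pairs with zero SD are dropped with a warning.
    """
    if len(fst_by_pop) < 2:
        raise ValueError("di needs at least 2 comparison populations")
    z_sum = None
    used = []
    for pop, fst in fst_by_pop.items():
        fst = np.asarray(fst, dtype=float)
        mu = np.nanmean(fst)
        sd = np.nanstd(fst, ddof=0)
        if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, abs(mu)):
            warnings.warn(f"pairwise F_ST to {pop} has zero SD; pair dropped",
                          stacklevel=2)
            continue
        z = (fst - mu) / sd
        z_sum = z if z_sum is None else z_sum + z
        used.append(pop)
    if not used:
        raise ValueError("no population pair had positive F_ST variance")
    return pd.DataFrame({"di": z_sum, "n_pops": len(used)})


def genes_in_windows(flagged: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Genes overlapping (≥1 bp) any flagged window, with supporting windows.

    ``flagged`` needs columns chrom/start/end (0-based half-open).
    """
    gchroms = set(genes["chrom"].astype(str))
    wchroms = set(flagged["chrom"].astype(str))
    if flagged.shape[0] and genes.shape[0] and not (gchroms & wchroms):
        raise ValueError(f"no chromosome names in common: windows {sorted(wchroms)} "
                         f"vs genes {sorted(gchroms)}")
    rows = []
    for _, g in genes.iterrows():
        sub = flagged[flagged["chrom"].astype(str) == str(g["chrom"])]
        hits = sub[(sub["start"] < g["end"]) & (sub["end"] > g["start"])]
        if len(hits):
            rows.append({"gene": g["name"], "chrom": g["chrom"],
                         "start": g["start"], "end": g["end"],
                         "n_windows": len(hits),
                         "windows": ";".join(f"{s}-{e}" for s, e
                                             in zip(hits["start"], hits["end"]))})
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end",
                                       "n_windows", "windows"])


def assign_origin(genes: pd.DataFrame, excess_segments: pd.DataFrame,
                  labels=("taurine-like", "indicine-like")) -> pd.Series:
    """Ancestral origin per gene from retained excess-ancestry segments.

    ``excess_segments`` needs chrom/start/end/label (label values 0/1 indexing
    ``labels``, or the label strings themselves) and should contain only
    retained segments.  Overlap with both labels gives "mixed"; none, "none".
    """
    out = []
    for _, g in genes.iterrows():
        sub = excess_segments[excess_segments["chrom"].astype(str) == str(g["chrom"])]
        hits = sub[(sub["start"] < g["end"]) & (sub["end"] > g["start"])]
        found = set()
        for lab in hits["label"]:
            found.add(labels[int(lab)] if not isinstance(lab, str) else lab)
        if not found:
            out.append("none")
        elif len(found) == 1:
            out.append(found.pop())
        else:
            out.append("mixed")
    return pd.Series(out, index=genes.index, name="origin")


def report_variant_freqs(panels_by_pop: dict, positions) -> pd.DataFrame:
    """Derived-allele frequency of chosen sites in each population.

    Missing genotypes are excluded site-wise (the denominator is the
    non-missing allele count); sites absent from a panel get NaN.
    """
    positions = np.asarray(positions)
    out = {"pos": positions}
    for pop, panel in panels_by_pop.items():
        freqs = np.full(positions.size, np.nan)
        idx = np.searchsorted(panel.positions, positions)
        ok = (idx < panel.n_sites) & (panel.positions[np.minimum(idx, panel.n_sites - 1)]
                                      == positions)
        f = panel.allele_freq()
        freqs[ok] = f[idx[ok]]
        out[pop] = freqs
    return pd.DataFrame(out)
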