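"""Haplotype-based selection scans: EHH, iHS and XP-EHH.

EHH(x) around a core SNP is the probability that two randomly drawn
haplotypes from an allele class are identical over the interval from the core
to offset x.  iHH is the trapezoidal integral of EHH over genetic distance on
both sides of the core, truncated where EHH drops below a cutoff; iHS is the
standardized log-ratio ln(iHH_ancestral / iHH_derived).  XP-EHH compares the
pooled iHH of two populations at the same site.

Conventions follow the selscan/Voight defaults: EHH truncation 0.05, maximum
inter-SNP gap 200 kb (the core site is skipped when exceeded), derived-allele
frequency cutoff 0.05, and standardization within 50 equal-occupancy
frequency bins (iHS) or genome-wide (XP-EHH).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .panel import MISSING, HaplotypePanel
from .stats import WindowedStat, WindowGrid

EHH_CUTOFF = 0.05
MAX_GAP_BP = 200_000
MIN_DAF = 0.05
N_STD_BINS = 50


def _homozygosity(counts: np.ndarray, denom: float) -> float:
    return float(np.sum(counts * (counts - 1) / 2.0) / denom)


def ehh_curve(panel: HaplotypePanel, core_site: int, allele: int) -> "EHHCurve":
    """Full EHH decay curve around a core site for one allele class (no truncation)."""
    panel.require_phased("EHH")
    H = panel.alleles
    cls = np.flatnonzero(H[:, core_site] == allele)
    if cls.size < 2:
        raise ValueError("allele class needs at least 2 haplotypes")
    offs, vals = [0], [1.0]
    for step in (-1, 1):
        groups = np.zeros(cls.size, dtype=np.int64)
        denom = cls.size * (cls.size - 1) / 2.0
        i = core_site
        while 0 <= i + step < panel.n_sites:
            i += step
            key = groups * 2 + H[cls, i]
            _, groups = np.unique(key, return_inverse=True)
            e = _homozygosity(np.bincount(groups), denom)
            offs.append(int(panel.positions[i] - panel.positions[core_site]))
            vals.append(e)
    order = np.argsort(offs)
    return EHHCurve(core_site, allele, np.asarray(offs)[order],
                    np.asarray(vals)[order])


@dataclass
class EHHCurve:
    core_site: int
    allele: int
    offsets_bp: np.ndarray
    ehh: np.ndarray


@njit(cache=True)
def _side_ihh_nb(H, rows, core, step, pos_bp, pos_cm, cutoff, max_gap_bp):
    """One-sided iHH (cM units) for the haplotypes in `rows`.

    Returns -1.0 when an inter-SNP gap exceeds max_gap_bp (core site must be
    skipped); integration runs until EHH < cutoff or the chromosome end.
    """
    n = rows.size
    denom = n * (n - 1) / 2.0
    groups = np.zeros(n, dtype=np.int64)
    relabel = np.empty(2 * n, dtype=np.int64)
    counts = np.empty(n, dtype=np.int64)
    ehh_prev = 1.0
    area = 0.0
    i = core
    m = pos_bp.shape[0]
    while 0 <= i + step < m:
        j = i + step
        if abs(pos_bp[j] - pos_bp[i]) > max_gap_bp:
            return -1.0
        relabel[:] = -1
        ng = 0
        for q in range(n):
            key = groups[q] * 2 + H[rows[q], j]
            if relabel[key] < 0:
                relabel[key] = ng
                ng += 1
            groups[q] = relabel[key]
        counts[:ng] = 0
        for q in range(n):
            counts[groups[q]] += 1
        hom = 0.0
        for q in range(ng):
            hom += counts[q] * (counts[q] - 1) / 2.0
        e = hom / denom
        area += 0.5 * (ehh_prev + e) * abs(pos_cm[j] - pos_cm[i])
        ehh_prev = e
        i = j
        if e < cutoff:
            break
    return area


def _side_ihh(H, rows, core, step, pos_bp, pos_cm,
              cutoff=EHH_CUTOFF, max_gap_bp=MAX_GAP_BP):
    out = _side_ihh_nb(np.ascontiguousarray(H), np.asarray(rows, dtype=np.int64),
                       core, step, np.asarray(pos_bp, dtype=np.int64),
                       np.asarray(pos_cm, dtype=np.float64),
                       float(cutoff), float(max_gap_bp))
    return None if out < 0 else float(out)


def _site_cm(panel, gmap):
    if gmap is None:
        return panel.positions * 1e-6  # uniform 1 cM/Mb
    return np.asarray(gmap.cm(panel.chrom, panel.positions), dtype=float)


def ihs_raw(panel: HaplotypePanel, gmap=None, min_daf=MIN_DAF,
            cutoff=EHH_CUTOFF, max_gap_bp=MAX_GAP_BP) -> pd.DataFrame:
    """Unstandardized iHS table for one chromosome.

    Ancestral states come from the panel's AA annotation; sites without one
    are polarized as reference-ancestral and flagged in the ``polarized``
    column.  Sites with DAF outside [min_daf, 1−min_daf], an allele class of
    < 2 haplotypes, a zero integral, or a gap violation get NaN with a reason.
    """
    panel.require_phased("iHS")
    H = panel.alleles
    if (H == MISSING).any():
        raise ValueError("iHS requires complete (non-missing) haplotypes")
    anc = panel.ancestral
    pos_cm = _site_cm(panel, gmap)
    rows = []
    for s in range(panel.n_sites):
        a_state = 0 if anc is None or anc[s] == MISSING else int(anc[s])
        polarized = not (anc is None or anc[s] == MISSING)
        der = H[:, s] != a_state
        daf = der.mean()
        rec = {"chrom": panel.chrom, "pos": int(panel.positions[s]), "daf": daf,
               "ihh_a": np.nan, "ihh_d": np.nan, "ihs_raw": np.nan,
               "polarized": polarized, "reason": ""}
        if not (min_daf <= daf <= 1 - min_daf):
            rec["reason"] = "daf"
            rows.append(rec)
            continue
        cls_d = np.flatnonzero(der)
        cls_a = np.flatnonzero(~der)
        if cls_d.size < 2 or cls_a.size < 2:
            rec["reason"] = "class_size"
            rows.append(rec)
            continue
        ihh = {}
        ok = True
        for name, cls in (("a", cls_a), ("d", cls_d)):
            left = _side_ihh(H, cls, s, -1, panel.positions, pos_cm, cutoff, max_gap_bp)
            right = _side_ihh(H, cls, s, +1, panel.positions, pos_cm, cutoff, max_gap_bp)
            if left is None or right is None:
                rec["reason"] = "gap"
                ok = False
                break
            ihh[name] = left + right
        if not ok:
            rows.append(rec)
            continue
        rec["ihh_a"], rec["ihh_d"] = ihh["a"], ihh["d"]
        if ihh["a"] <= 0 or ihh["d"] <= 0:
            rec["reason"] = "zero_ihh"
        else:
            rec["ihs_raw"] = np.log(ihh["a"] / ihh["d"])
        rows.append(rec)
    return pd.DataFrame(rows)


def standardize_ihs(table: pd.DataFrame, n_bins=N_STD_BINS) -> pd.DataFrame:
    """Standardize raw iHS within equal-occupancy derived-frequency bins.

    Within each bin the standardized scores have mean 0 and SD 1 exactly.
    Bins with fewer than 2 scored sites stay NaN.
    """
    out = table.copy()
    out["ihs"] = np.nan
    ok = out["ihs_raw"].notna()
    if ok.sum() < 2:
        return out
    n_bins = max(1, min(n_bins, ok.sum() // 2))
    bins = pd.qcut(out.loc[ok, "daf"], q=n_bins, duplicates="drop")
    raw = out.loc[ok, "ihs_raw"]
    grouped = raw.groupby(bins, observed=True)
    mu = grouped.transform("mean")
    sd = grouped.transform("std", ddof=0)
    out.loc[ok, "ihs"] = (raw - mu) / sd.replace(0.0, np.nan)
    return out


def ihs(panels, gmap=None, min_daf=MIN_DAF, n_bins=N_STD_BINS,
        cutoff=EHH_CUTOFF, max_gap_bp=MAX_GAP_BP) -> pd.DataFrame:
    """Genome-wide standardized iHS: raw scores per chromosome, one shared
    frequency-bin standardization across all of them."""
    if isinstance(panels, HaplotypePanel):
        panels = {panels.chrom: panels}
    raw = pd.concat(
        [ihs_raw(p, gmap, min_daf, cutoff, max_gap_bp) for p in panels.values()],
        ignore_index=True)
    return standardize_ihs(raw, n_bins=n_bins)


def xpehh_raw(panel1: HaplotypePanel, panel2: HaplotypePanel, gmap=None,
              cutoff=EHH_CUTOFF, max_gap_bp=MAX_GAP_BP) -> pd.DataFrame:
    """Unstandardized XP-EHH per site: ln(iHH_pop1 / iHH_pop2), all haplotypes
    of each population pooled (no allele-class split)."""
    for p in (panel1, panel2):
        p.require_phased("XP-EHH")
    if not np.array_equal(panel1.positions, panel2.positions):
        raise ValueError("panels must share the site list")
    pos_cm = _site_cm(panel1, gmap)
    rows1 = np.arange(panel1.n_haplotypes)
    rows2 = np.arange(panel2.n_haplotypes)
    rows = []
    for s in range(panel1.n_sites):
        rec = {"chrom": panel1.chrom, "pos": int(panel1.positions[s]),
               "ihh1": np.nan, "ihh2": np.nan, "xpehh_raw": np.nan, "reason": ""}
        vals = {}
        ok = True
        for name, p, rr in (("ihh1", panel1, rows1), ("ihh2", panel2, rows2)):
            left = _side_ihh(p.alleles, rr, s, -1, p.positions, pos_cm, cutoff, max_gap_bp)
            right = _side_ihh(p.alleles, rr, s, +1, p.positions, pos_cm, cutoff, max_gap_bp)
            if left is None or right is None:
                rec["reason"] = "gap"
                ok = False
                break
            vals[name] = left + right
        if not ok:
            rows.append(rec)
            continue
        rec.update(vals)
        if vals["ihh1"] <= 0 or vals["ihh2"] <= 0:
            rec["reason"] = "zero_ihh"
        else:
            rec["xpehh_raw"] = np.log(vals["ihh1"] / vals["ihh2"])
        rows.append(rec)
    return pd.DataFrame(rows)


def xpehh(panels1, panels2, gmap=None, cutoff=EHH_CUTOFF,
          max_gap_bp=MAX_GAP_BP) -> pd.DataFrame:
    """Genome-wide standardized XP-EHH (mean 0, SD 1 over all scored sites)."""
    if isinstance(panels1, HaplotypePanel):
        panels1 = {panels1.chrom: panels1}
        panels2 = {panels2.chrom: panels2}
    raw = pd.concat(
        [xpehh_raw(panels1[c], panels2[c], gmap, cutoff, max_gap_bp)
         for c in panels1],
        ignore_index=True)
    out = raw.copy()
    ok = out["xpehh_raw"].notna()
    vals = out.loc[ok, "xpehh_raw"]
    sd = vals.std(ddof=0)
    out["xpehh"] = np.nan
    if ok.sum() >= 2 and sd > 0:
        out.loc[ok, "xpehh"] = (vals - vals.mean()) / sd
    return out


def window_summary(positions, scores, grid: WindowGrid, rule="frac_extreme",
                   threshold=2.0, min_sites=5) -> WindowedStat:
    """Aggregate per-site scores to windows.

    ``frac_extreme``: fraction of scored sites with |score| > threshold (the
    iHS convention); ``max``: the window's maximum signed score (the XP-EHH
    convention).  Windows with fewer than ``min_sites`` scored sites are
    missing.
    """
    positions = np.asarray(positions)
    scores = np.asarray(scores, dtype=float)
    ok = np.isfinite(scores)
    positions, scores = positions[ok], scores[ok]
    order = np.argsort(positions)
    positions, scores = positions[order], scores[order]
    lo, hi = grid.site_window_matrix(positions)
    counts = hi - lo
    vals = np.full(grid.n_windows, np.nan)
    if rule == "frac_extreme":
        ext = np.concatenate([[0.0], np.cumsum((np.abs(scores) > threshold).astype(float))])
        with np.errstate(invalid="ignore", divide="ignore"):
            v = (ext[hi] - ext[lo]) / counts
        vals = np.where(counts >= min_sites, v, np.nan)
    elif rule == "max":
        for w in range(grid.n_windows):
            if counts[w] >= min_sites:
                vals[w] = scores[lo[w]:hi[w]].max()
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return WindowedStat(grid, vals, counts, f"summary_{rule}")
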