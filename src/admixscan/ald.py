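"""Admixture dating from the decay of weighted ancestry disequilibrium.

For every SNP pair (x, y) in the admixed population, the product of the
genotype-dosage covariance D̂_xy with the weight
w = (p_A,x − p_B,x)(p_A,y − p_B,y) — allele-frequency contrasts between the
two reference panels — measures admixture LD.  Under a single admixture
pulse λ generations ago this quantity decays in genetic distance d as
A·exp(−λ·d) + c, so λ estimates the admixture time in generations.  The
standard error of λ comes from a leave-one-chromosome-out jackknife, and a
generation interval converts generations to years.

Genotype-dosage covariances (not haplotype D) are used so unphased admixed
data can still be dated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .panel import HaplotypePanel

MIN_PAIRS_PER_BIN = 100


@dataclass
class ALDCurve:
    """Binned weighted-LD curve with per-chromosome sums for jackknifing."""

    bin_edges_cm: np.ndarray
    per_chrom: dict  # chrom -> (sum of D̂·w per bin, pair count per bin)

    @property
    def centers_cm(self) -> np.ndarray:
        return (self.bin_edges_cm[:-1] + self.bin_edges_cm[1:]) / 2.0

    def aggregate(self, exclude=None):
        """(values, counts) per bin, optionally excluding one chromosome."""
        nb = self.bin_edges_cm.size - 1
        s = np.zeros(nb)
        c = np.zeros(nb, dtype=np.int64)
        for chrom, (ss, cc) in self.per_chrom.items():
            if chrom == exclude:
                continue
            s += ss
            c += cc
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(c > 0, s / np.maximum(c, 1), np.nan)
        return v, c

    def to_frame(self) -> pd.DataFrame:
        v, c = self.aggregate()
        keep = c >= MIN_PAIRS_PER_BIN
        return pd.DataFrame({"bin_cM": self.centers_cm[keep], "value": v[keep],
                             "n_pairs": c[keep]})


def _chrom_cm(panel, gmap):
    if gmap is None:
        return panel.positions * 1e-6
    return np.asarray(gmap.cm(panel.chrom, panel.positions), dtype=float)


def weighted_ld_curve(admixed, ref_a_freqs, ref_b_freqs, gmap=None,
                      bin_width_cm=0.1, d_max_cm=30.0) -> ALDCurve:
    """Weighted ancestry-LD decay curve over one or more chromosomes.

    Parameters
    ----------
    admixed : HaplotypePanel or dict chrom -> HaplotypePanel
    ref_a_freqs, ref_b_freqs : ndarray or dict chrom -> ndarray
        Reference-panel allele frequencies on the admixed site list.
    """
    if isinstance(admixed, HaplotypePanel):
        chrom = admixed.chrom
        admixed = {chrom: admixed}
        ref_a_freqs = {chrom: np.asarray(ref_a_freqs)}
        ref_b_freqs = {chrom: np.asarray(ref_b_freqs)}
    edges = np.arange(0.0, d_max_cm + bin_width_cm, bin_width_cm)
    nb = edges.size - 1
    per_chrom = {}
    any_pairs = False
    for chrom, panel in admixed.items():
        wa = np.asarray(ref_a_freqs[chrom], dtype=float)
        wb = np.asarray(ref_b_freqs[chrom], dtype=float)
        w = wa - wb
        g = panel.genotypes().astype(float)
        n = g.shape[0]
        gc = g - g.mean(axis=0)
        cm = _chrom_cm(panel, gmap)
        m = cm.size
        sums = np.zeros(nb)
        counts = np.zeros(nb, dtype=np.int64)
        block = 512
        for i0 in range(0, m, block):
            i1 = min(i0 + block, m)
            jmax = int(np.searchsorted(cm, cm[i1 - 1] + d_max_cm, side="right"))
            cov = gc[:, i0:i1].T @ gc[:, i0:jmax] / (n - 1)
            val = cov * np.outer(w[i0:i1], w[i0:jmax])
            d = cm[i0:jmax][None, :] - cm[i0:i1][:, None]
            mask = (d > 0) & (d <= d_max_cm)
            if not mask.any():
                continue
            bins = np.minimum((d[mask] / bin_width_cm).astype(np.int64), nb - 1)
            sums += np.bincount(bins, weights=val[mask], minlength=nb)
            counts += np.bincount(bins, minlength=nb)
            any_pairs = True
        per_chrom[chrom] = (sums, counts)
    if not any_pairs:
        raise ValueError("no usable SNP pairs (no polymorphic shared sites?)")
    return ALDCurve(edges, per_chrom)


@dataclass
class PulseFit:
    """Affine-exponential fit A·exp(−λd) + c to a weighted-LD curve."""

    amplitude: float
    lam: float            # generations
    const: float
    d_min_cm: float
    d_max_cm: float
    se_lam: float
    n_chrom: int
    significant: bool

    def summary(self) -> dict:
        return {"amplitude": self.amplitude, "lambda_generations": self.lam,
                "constant": self.const, "fit_range_cM": [self.d_min_cm, self.d_max_cm],
                "jackknife_se": self.se_lam, "n_chromosomes": self.n_chrom,
                "significant": self.significant}


def _model(d_cm, A, lam, c):
    return A * np.exp(-lam * d_cm / 100.0) + c


def _fit_bins(centers, values) -> tuple[float, float, float]:
    c0 = float(np.mean(values[-max(3, values.size // 10):]))
    resid = values - c0
    pos = resid > 0
    if pos.sum() >= 3:
        slope, intercept = np.polyfit(centers[pos] / 100.0, np.log(resid[pos]), 1)
        lam0 = float(np.clip(-slope, 1.0, 999.0))
        a0 = float(np.exp(intercept))
    else:
        lam0, a0 = 50.0, max(float(values[0] - c0), 1e-9)
    try:
        popt, _ = curve_fit(_model, centers, values, p0=[a0, lam0, c0],
                            bounds=([0.0, 1e-6, -np.inf], [np.inf, 1000.0, np.inf]),
                            maxfev=20_000)
    except RuntimeError as err:
        raise RuntimeError(
            f"single-pulse fit failed to converge (init A={a0:.3g}, "
            f"lambda={lam0:.3g}, c={c0:.3g})") from err
    return tuple(float(x) for x in popt)


def fit_single_pulse(curve: ALDCurve, d_min_cm=0.5, d_max_cm=None,
                     min_pairs=MIN_PAIRS_PER_BIN) -> PulseFit:
    """Nonlinear least-squares single-pulse fit with chromosome jackknife.

    Bins below ``d_min_cm`` are excluded to keep short-range background LD
    out of the fit; bins with fewer than ``min_pairs`` pairs are dropped.
    """
    d_max_cm = d_max_cm or float(curve.bin_edges_cm[-1])
    centers = curve.centers_cm

    def usable(values, counts):
        keep = ((centers >= d_min_cm) & (centers <= d_max_cm)
                & (counts >= min_pairs) & np.isfinite(values))
        return centers[keep], values[keep]

    v, c = curve.aggregate()
    x, y = usable(v, c)
    if x.size < 10:
        raise ValueError(f"only {x.size} usable bins beyond d_min; need >= 10")
    A, lam, const = _fit_bins(x, y)
    resid_sd = float(np.std(y - _model(x, A, lam, const)))
    significant = A > 2.0 * resid_sd

    chroms = list(curve.per_chrom)
    se = 0.0
    if len(chroms) >= 2:
        lams = []
        for chrom in chroms:
            vi, ci = curve.aggregate(exclude=chrom)
            xi, yi = usable(vi, ci)
            try:
                lams.append(_fit_bins(xi, yi)[1])
            except (RuntimeError, ValueError):
                lams.append(np.nan)
        lams = np.asarray(lams, dtype=float)
        ok = np.isfinite(lams)
        g = ok.sum()
        if g >= 2:
            se = float(np.sqrt((g - 1) / g * np.sum((lams[ok] - lams[ok].mean()) ** 2)))
    return PulseFit(A, lam, const, d_min_cm, d_max_cm, se, len(chroms), significant)


def generations_to_years(lam, se=0.0, generation_interval_years=5.0):
    """Convert an admixture time in generations (and its SE) to years."""
    if generation_interval_years <= 0:
        raise ValueError("generation interval must be positive")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return lam * generation_interval_years, se * generation_interval_years
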