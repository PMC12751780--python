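"""Reading and writing the pipeline's file formats.

Covers phased VCF 4.2 in/out, GATK-style hard site filters, gene annotation
(BED4 / GFF3), sample→population maps, and genetic maps (bp ↔ cM).

Coordinate conventions: VCF positions are 1-based; all internal interval
arithmetic (windows, genes, tracts) is 0-based half-open.  Reported tables
keep 1-based inclusive coordinates to match VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import MISSING, HaplotypePanel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_vcf(path, region=None, samples=None):
    """Read a phased biallelic-SNP VCF into HaplotypePanels, one per chromosome.

    Only biallelic SNP records are accepted; multiallelic or indel records are
    skipped and counted.  Phased records yield two haplotypes per sample; if
    any heterozygote is unphased the panel is flagged ``phased=False``.

    Parameters
    ----------
    region : tuple (chrom, start_bp, end_bp) or str chrom, optional
        1-based inclusive restriction.
    samples : list of str, optional
        Subset of samples to load.

    Returns
    -------
    dict mapping chromosome name -> HaplotypePanel
    """
    vcf = VCF(str(path), samples=list(samples) if samples else None, gts012=False)
    if samples:
        got = set(vcf.samples)
        miss = [s for s in samples if s not in got]
        if miss:
            raise KeyError(f"samples not in VCF: {miss}")
    sample_ids = list(vcf.samples)
    if region is not None and not isinstance(region, str):
        rchrom, rstart, rend = region
    else:
        rchrom, rstart, rend = region, None, None
    if rchrom is not None and vcf.seqnames and rchrom not in vcf.seqnames:
        raise KeyError(f"region chromosome {rchrom!r} not in VCF header")

    by_chrom: dict[str, dict] = {}
    n_skipped = 0
    for v in vcf:
        if rchrom is not None and v.CHROM != rchrom:
            continue
        if rstart is not None and not (rstart <= v.POS <= rend):
            continue
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        store = by_chrom.setdefault(
            v.CHROM, {"pos": [], "gt": [], "anc": [], "phased": True})
        gts = v.genotypes  # [[a, b, phased], ...]
        row = np.empty(2 * len(sample_ids), dtype=np.int8)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            row[2 * i] = a if a >= 0 else MISSING
            row[2 * i + 1] = b if b >= 0 else MISSING
            if not g[2] and a >= 0 and b >= 0 and a != b:
                store["phased"] = False
        store["pos"].append(v.POS)
        store["gt"].append(row)
        aa = v.INFO.get("AA")
        if aa is None:
            store["anc"].append(MISSING)
        else:
            aa = str(aa).upper()
            store["anc"].append(0 if aa == v.REF else 1 if aa == v.ALT[0] else MISSING)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)

    panels = {}
    for chrom, st in by_chrom.items():
        anc = np.asarray(st["anc"], dtype=np.int8)
        panels[chrom] = HaplotypePanel(
            chrom, np.asarray(st["pos"]), np.asarray(st["gt"]).T,
            sample_ids, phased=st["phased"],
            ancestral=anc if (anc != MISSING).any() else None)
    panels["_n_skipped"] = n_skipped  # bookkeeping for callers that want it
    n_skipped_total = panels.pop("_n_skipped")
    for p in panels.values():
        p.n_skipped_records = n_skipped_total
    return panels


def read_vcf_single(path, region=None, samples=None) -> HaplotypePanel:
    """As :func:`read_vcf` but require exactly one chromosome."""
    panels = read_vcf(path, region=region, samples=samples)
    if len(panels) != 1:
        raise ValueError(f"expected one chromosome, found {sorted(panels)}")
    return next(iter(panels.values()))


def write_vcf(panels, path):
    """Write HaplotypePanels as a phased VCF 4.2 with contig headers and INFO/AA.

    REF is 'A' and ALT is 'G' at every site (synthetic panels carry 0/1
    alleles, not nucleotides); AA records the ancestral allele when known.
    """
    if isinstance(panels, HaplotypePanel):
        panels = {panels.chrom: panels}
    items = sorted(panels.items())
    sample_ids = items[0][1].sample_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, p in items:
            fh.write(f"##contig=<ID={chrom},length={int(p.positions[-1]) + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for chrom, p in items:
            if p.sample_ids != sample_ids:
                raise ValueError("all panels must share samples")
            anc = p.ancestral
            for s in range(p.n_sites):
                if anc is None or anc[s] == MISSING:
                    info = "."
                else:
                    info = "AA=" + ("A" if anc[s] == 0 else "G")
                col = p.alleles[:, s]
                gts = "\t".join(
                    f"{_gt(col[2 * i])}|{_gt(col[2 * i + 1])}"
                    for i in range(p.n_samples))
                fh.write(f"{chrom}\t{p.positions[s]}\t.\tA\tG\t.\tPASS\t{info}\tGT\t{gts}\n")


def _gt(a):
    return "." if a == MISSING else str(int(a))


# ---------------------------------------------------------------------------
# GATK-style hard site filters
# ---------------------------------------------------------------------------

@dataclass
class SiteFilterSpec:
    """Hard-filter thresholds for variant INFO annotations.

    A record is removed iff it violates at least one rule whose annotation is
    present (strict inequalities; values exactly at a threshold are kept).
    The depth rule removes sites whose DP is below ``depth_low_frac`` times or
    above ``depth_high_frac`` times the dataset mean DP.
    """

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    sor_max: float = 3.0
    depth_low_frac: float = 1.0 / 3.0
    depth_high_frac: float = 3.0


_RULES = (
    ("QD", "qd_min", "lt"),        # fail if QD < qd_min
    ("FS", "fs_max", "gt"),        # fail if FS > fs_max
    ("MQ", "mq_min", "lt"),
    ("MQRankSum", "mqranksum_min", "lt"),
    ("ReadPosRankSum", "readposranksum_min", "lt"),
    ("SOR", "sor_max", "gt"),
)


def site_violations(info: dict, spec: SiteFilterSpec, mean_depth=None) -> list:
    """Names of filter rules the site violates. Absent annotations are not applied."""
    bad = []
    for key, attr, sense in _RULES:
        val = info.get(key)
        if val is None:
            continue
        thr = getattr(spec, attr)
        if (sense == "lt" and float(val) < thr) or (sense == "gt" and float(val) > thr):
            bad.append(key)
    dp = info.get("DP")
    if dp is not None and mean_depth is not None and mean_depth > 0:
        dp = float(dp)
        if dp < spec.depth_low_frac * mean_depth or dp > spec.depth_high_frac * mean_depth:
            bad.append("DP")
    return bad


@dataclass
class FilterReport:
    n_input: int = 0
    n_output: int = 0
    removed_by_rule: dict = field(default_factory=dict)
    rules_not_applied: list = field(default_factory=list)


def apply_site_filters(path_in, path_out, spec: SiteFilterSpec | None = None) -> FilterReport:
    """Stream a VCF through the hard filters; surviving records go to path_out.

    Two passes: the first computes the dataset mean DP for the relative depth
    rule; the second filters.  Removal counts are per rule (a record failing
    several rules increments each, but is removed once).
    """
    spec = spec or SiteFilterSpec()
    dps = [v.INFO.get("DP") for v in VCF(str(path_in))]
    dps = [float(d) for d in dps if d is not None]
    mean_depth = float(np.mean(dps)) if dps else None

    rep = FilterReport()
    seen_fields = set()
    vcf = VCF(str(path_in))
    with open(path_out, "w") as out:
        out.write(vcf.raw_header)
        for v in vcf:
            rep.n_input += 1
            info = {k: v.INFO.get(k) for k, _, _ in _RULES}
            info["DP"] = v.INFO.get("DP")
            seen_fields.update(k for k, val in info.items() if val is not None)
            bad = site_violations(info, spec, mean_depth)
            if bad:
                for rule in bad:
                    rep.removed_by_rule[rule] = rep.removed_by_rule.get(rule, 0) + 1
            else:
                out.write(str(v))
                rep.n_output += 1
    all_fields = {k for k, _, _ in _RULES} | {"DP"}
    rep.rules_not_applied = sorted(all_fields - seen_fields)
    for rule in rep.rules_not_applied:
        logger.info("apply_site_filters: annotation %s absent, rule not applied", rule)
    return rep


# ---------------------------------------------------------------------------
# Gene annotation, popmap, genetic map
# ---------------------------------------------------------------------------

def read_genes(path) -> pd.DataFrame:
    """Read gene intervals from BED4 or GFF3 into 0-based half-open records.

    Returns a DataFrame with columns chrom, start, end, name, strand.  GFF3:
    only ``gene`` features are kept; the name is the Name= attribute, falling
    back to ID=.  Format is autodetected from extension, then content.
    """
    path = str(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    is_gff = path.endswith((".gff", ".gff3")) or (
        not path.endswith(".bed") and len(first.rstrip("\n").split("\t")) == 9)
    rows = []
    if is_gff:
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                name = attrs.get("Name", attrs.get("ID", "."))
                rows.append((f[0], int(f[3]) - 1, int(f[4]), name, f[6]))
    else:
        with open(path) as fh:
            for line in fh:
                if line.startswith(("#", "track", "browser")) or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                name = f[3] if len(f) > 3 else "."
                strand = f[5] if len(f) > 5 else "."
                rows.append((f[0], int(f[1]), int(f[2]), name, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    if (df["start"] >= df["end"]).any():
        raise ValueError("gene records must have start < end")
    return df


def read_popmap(path) -> dict:
    """TSV `sample<TAB>population` -> dict sample -> population."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["sample", "population"],
                     comment="#", dtype=str)
    return dict(zip(df["sample"], df["population"]))


class GeneticMap:
    """Piecewise-linear bp→cM map per chromosome; default uniform 1 cM/Mb.

    The uniform default matches the genome-wide average recombination rate in
    cattle and is used (and logged) whenever no map file is supplied.
    """

    DEFAULT_CM_PER_MB = 1.0

    def __init__(self, tables: dict | None = None):
        # tables: chrom -> (bp array, cM array), both strictly increasing
        self.tables = tables or {}
        if not self.tables:
            logger.info("GeneticMap: no map supplied, using uniform 1 cM/Mb")
        for chrom, (bp, cm) in self.tables.items():
            if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) <= 0):
                raise ValueError(f"genetic map for {chrom} is not strictly monotone")

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                         names=["chrom", "bp", "cM"],
                         dtype={"chrom": str, "bp": np.int64, "cM": float})
        tables = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("bp")
            tables[chrom] = (grp["bp"].to_numpy(), grp["cM"].to_numpy())
        return cls(tables)

    def cm(self, chrom, bp):
        """Interpolated cM position(s); linear extrapolation outside the map."""
        bp = np.asarray(bp, dtype=float)
        tab = self.tables.get(chrom)
        if tab is None:
            return bp * self.DEFAULT_CM_PER_MB * 1e-6
        xs, ys = tab
        out = np.interp(bp, xs, ys)
        # linear extrapolation at the edges using boundary slopes
        if xs.size >= 2:
            lo = bp < xs[0]
            hi = bp > xs[-1]
            if np.any(lo):
                slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
                out = np.where(lo, ys[0] + (bp - xs[0]) * slope, out)
            if np.any(hi):
                slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
                out = np.where(hi, ys[-1] + (bp - xs[-1]) * slope, out)
        return out
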