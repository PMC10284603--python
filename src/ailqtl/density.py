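"""Variant quality filtering, density segmentation, and candidate filtering.

A pairwise comparison of two inbred genomes shows long blocks of low or
high SNP density, reflecting shared versus divergent founder haplotypes.
This module filters the variant catalog to high-quality strain-discriminating
calls, tiles the genome into bins to expose the bimodal density pattern,
segments it at a count cutoff, intersects the high-density segments with
QTL support intervals, and filters candidate variants by expression and
predicted impact.

Genomic intervals are 0-based half-open internally; variant positions are
1-based (VCF convention) and converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyranges as pr

logger = logging.getLogger(__name__)

__all__ = [
    "DensityProfile",
    "filter_high_quality",
    "bin_density",
    "sweep_bin_sizes",
    "classify_density",
    "intersect_qtl",
    "expressed_genes",
    "filter_candidates",
    "merge_intervals",
    "intersect_intervals",
    "total_length",
    "qtl_cm_to_bp",
]

ZYGOSITY = {"hom_ref", "het", "hom_alt", "missing"}
MIN_DEPTH = 8
MAX_FDR = 0.10
DEFAULT_BIN = 600_000
DEFAULT_CUTOFF = 1000
IMPACT_CLASSES = {"high_impact", "deleterious_missense", "nonframeshift_deletion"}


# ---------------------------------------------------------------------------
# interval helpers (0-based half-open frames: chrom, start, end)
# ---------------------------------------------------------------------------

def _to_pr(df: pd.DataFrame) -> pr.PyRanges:
    return pr.PyRanges(df.rename(columns={"chrom": "Chromosome", "start": "Start",
                                          "end": "End"}))


def _from_pr(g: pr.PyRanges) -> pd.DataFrame:
    if len(g) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    out = g.df.rename(columns={"Chromosome": "chrom", "Start": "start", "End": "end"})
    out["chrom"] = out["chrom"].astype(str)
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of an interval set: overlapping/adjacent-overlap intervals merged."""
    if df.empty:
        return df[["chrom", "start", "end"]].copy()
    return _from_pr(_to_pr(df).merge())


def intersect_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    if a.empty or b.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return _from_pr(_to_pr(a[["chrom", "start", "end"]]).intersect(_to_pr(b[["chrom", "start", "end"]])))


def total_length(df: pd.DataFrame) -> int:
    """Total covered length after merging overlaps."""
    m = merge_intervals(df)
    return int((m["end"] - m["start"]).sum()) if not m.empty else 0


def _positions_in_intervals(chroms: np.ndarray, pos_1based: np.ndarray,
                            intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask: 1-based positions falling inside 0-based half-open
    intervals (position p occupies [p-1, p))."""
    mask = np.zeros(len(pos_1based), dtype=bool)
    if intervals.empty:
        return mask
    merged = merge_intervals(intervals)
    for chrom, grp in merged.groupby("chrom"):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        p0 = pos_1based[sel] - 1  # 0-based
        idx = np.searchsorted(starts, p0, side="right") - 1
        ok = (idx >= 0) & (p0 < ends[np.clip(idx, 0, None)])
        mask[np.flatnonzero(sel)[ok]] = True
    return mask


# ---------------------------------------------------------------------------
# quality filtering
# ---------------------------------------------------------------------------

def filter_high_quality(variants: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep high-quality strain-discriminating variants.

    A record passes when sequencing depth >= 8, estimated FDR <= 10%, and the
    zygosity pattern is homozygous-alternate in exactly one strain with a
    reference or heterozygous call in the other (so the variant cleanly
    separates the two founder genomes).  Returns the kept frame and counts of
    records rejected per reason (first failing reason, checked in the order
    malformed, depth, fdr, zygosity).
    """
    v = variants.copy()
    reasons = {"malformed": 0, "depth": 0, "fdr": 0, "zygosity": 0}
    za, zb = v["zyg_a"], v["zyg_b"]
    malformed = ~(za.isin(ZYGOSITY) & zb.isin(ZYGOSITY))
    low_depth = v["depth"] < MIN_DEPTH
    high_fdr = v["fdr"] > MAX_FDR
    one_hom_alt = ((za == "hom_alt") & zb.isin({"hom_ref", "het"})) | \
                  ((zb == "hom_alt") & za.isin({"hom_ref", "het"}))
    bad_zyg = ~one_hom_alt
    reasons["malformed"] = int(malformed.sum())
    reasons["depth"] = int((low_depth & ~malformed).sum())
    reasons["fdr"] = int((high_fdr & ~malformed & ~low_depth).sum())
    reasons["zygosity"] = int((bad_zyg & ~malformed & ~low_depth & ~high_fdr).sum())
    kept = v[~(malformed | low_depth | high_fdr | bad_zyg)].reset_index(drop=True)
    logger.info("filter_high_quality: kept %d of %d (%s)", len(kept), len(v), reasons)
    return kept, reasons


# ---------------------------------------------------------------------------
# density binning and segmentation
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    bin_size: int
    bins: pd.DataFrame      # chrom, start, end, width, count
    genome: dict[str, int]
    cutoff: int | None = None


def bin_density(variants: pd.DataFrame, genome: dict[str, int], bin_size: int,
                ) -> DensityProfile:
    """Count variants in non-overlapping ``bin_size`` tiles per chromosome,
    each chromosome tiled from position 0; the terminal partial bin keeps its
    true width."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, length in genome.items():
        starts = np.arange(0, int(length), int(bin_size))
        ends = np.minimum(starts + int(bin_size), int(length))
        sel = variants["chrom"] == chrom if len(variants) else pd.Series([], dtype=bool)
        pos0 = (variants.loc[sel, "pos"].to_numpy() - 1) if len(variants) else np.array([])
        counts = np.histogram(pos0, bins=np.append(starts, ends[-1]))[0] \
            if len(starts) else np.array([], dtype=int)
        for s, e, c in zip(starts, ends, counts):
            rows.append((chrom, int(s), int(e), int(e - s), int(c)))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "width", "count"])
    return DensityProfile(int(bin_size), bins, dict(genome))


def _bimodality_depth(counts: np.ndarray, n_hist: int = 40) -> float:
    """Depth of the antimode between the two largest modes of the per-bin
    count histogram, normalized to [0, 1]; 0 when the histogram is unimodal.

    Counts are histogrammed on a sqrt scale (variant counts are heavily
    right-skewed) and local maxima of the smoothed histogram are the modes.
    """
    if len(counts) == 0 or counts.max() == counts.min():
        return 0.0
    x = np.sqrt(counts.astype(float))
    h, _ = np.histogram(x, bins=n_hist)
    h = np.convolve(h, np.ones(3) / 3.0, mode="same")  # light smoothing
    modes = [i for i in range(len(h))
             if h[i] > 0
             and (i == 0 or h[i] >= h[i - 1])
             and (i == len(h) - 1 or h[i] > h[i + 1])]
    if len(modes) < 2:
        return 0.0
    modes = sorted(modes, key=lambda i: -h[i])[:2]
    lo, hi = sorted(modes)
    antimode = h[lo:hi + 1].min()
    ref = min(h[lo], h[hi])
    return float((ref - antimode) / ref) if ref > 0 else 0.0


def sweep_bin_sizes(variants: pd.DataFrame, genome: dict[str, int],
                    sizes=None) -> pd.DataFrame:
    """Bin-size sweep (default 50 kb to 1.1 Mb in 50 kb steps) with a
    bimodality diagnostic per size; the clearest low/high separation has the
    deepest antimode."""
    if sizes is None:
        sizes = range(50_000, 1_100_001, 50_000)
    rows = []
    for s in sizes:
        prof = bin_density(variants, genome, int(s))
        rows.append((int(s), _bimodality_depth(prof.bins["count"].to_numpy())))
    return pd.DataFrame(rows, columns=["bin_size", "bimodality"])


def classify_density(profile: DensityProfile, cutoff: int = DEFAULT_CUTOFF) -> pd.DataFrame:
    """High-variant-density segments: bins with ``count >= cutoff``
    (inclusive), maximal runs of adjacent high bins merged into one segment.
    """
    profile.cutoff = int(cutoff)
    segs = []
    for chrom, grp in profile.bins.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        high = grp["count"].to_numpy() >= cutoff
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        i = 0
        while i < len(high):
            if high[i]:
                j = i
                while j + 1 < len(high) and high[j + 1]:
                    j += 1
                segs.append((chrom, int(starts[i]), int(ends[j])))
                i = j + 1
            else:
                i += 1
    return pd.DataFrame(segs, columns=["chrom", "start", "end"])


def intersect_qtl(qtl_intervals: pd.DataFrame, segments: pd.DataFrame,
                  ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Restrict QTL support regions to high-density segments.

    Returns the retained interval set and a summary with total Mb before and
    after plus the percent retained
    (``100 * retained_length / qtl_length``).
    """
    if qtl_intervals.empty:
        raise ValueError("empty QTL interval set")
    retained = intersect_intervals(qtl_intervals, segments)
    before = total_length(qtl_intervals)
    after = total_length(retained)
    summary = {
        "total_mb_before": before / 1e6,
        "total_mb_after": after / 1e6,
        "percent_retained": 100.0 * after / before if before else 0.0,
    }
    return retained, summary


# ---------------------------------------------------------------------------
# expression filter and candidate variants
# ---------------------------------------------------------------------------

def expressed_genes(counts: pd.DataFrame, cpm_threshold: float = 1.0,
                    min_samples: int = 2) -> set[str]:
    """Genes with CPM strictly above ``cpm_threshold`` in at least
    ``min_samples`` samples (counts: genes x samples, non-negative)."""
    if counts.shape[1] < min_samples:
        raise ValueError(f"need at least {min_samples} samples")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = lib.index[lib == 0][0]
        raise ValueError(f"sample {bad!r} has zero library size")
    cpm = counts / lib * 1e6
    keep = (cpm > cpm_threshold).sum(axis=1) >= min_samples
    return set(counts.index[keep])


def filter_candidates(
    variants: pd.DataFrame,
    qtl_intervals: pd.DataFrame,
    expressed: set[str],
    segments: pd.DataFrame | None = None,
    impact_classes: set[str] = frozenset(IMPACT_CLASSES),
    strain_names: tuple[str, str] = ("strain_a", "strain_b"),
) -> tuple[pd.DataFrame, dict]:
    """Candidate functional variants under QTL.

    Keeps variants inside the QTL intervals, in expressed genes, with an
    effect class among the retained impact classes (high impact, deleterious
    missense, non-frameshift deletion).  The filters are row-wise predicates,
    so their application order is immaterial.  Each candidate is assigned to
    the strain carrying the homozygous-alternate call.

    The summary reports per-gene variant counts, per-strain variant/gene
    totals, the fraction of candidates inside high-density segments (when
    supplied), and the average number of candidates per QTL interval.
    """
    v = variants.copy()
    in_qtl = _positions_in_intervals(v["chrom"].to_numpy(), v["pos"].to_numpy(),
                                     qtl_intervals)
    keep = in_qtl & v["gene"].isin(expressed).to_numpy() \
        & v["effect_class"].isin(impact_classes).to_numpy()
    cand = v[keep].reset_index(drop=True)
    cand["strain"] = np.where(cand["zyg_a"] == "hom_alt", strain_names[0], strain_names[1])
    summary: dict = {
        "n_candidates": int(len(cand)),
        "n_genes": int(cand["gene"].nunique()),
        "per_gene": cand.groupby("gene").size().to_dict(),
        "per_strain": {
            s: {"variants": int((cand["strain"] == s).sum()),
                "genes": int(cand.loc[cand["strain"] == s, "gene"].nunique())}
            for s in strain_names
        },
        "candidates_per_qtl": (len(cand) / len(qtl_intervals)) if len(qtl_intervals) else 0.0,
    }
    if segments is not None:
        in_high = _positions_in_intervals(cand["chrom"].to_numpy(),
                                          cand["pos"].to_numpy(), segments)
        summary["n_in_high_density"] = int(in_high.sum())
        summary["percent_in_high_density"] = (
            100.0 * in_high.sum() / len(cand) if len(cand) else 0.0)
    return cand, summary


# ---------------------------------------------------------------------------
# cM -> bp conversion of QTL support intervals
# ---------------------------------------------------------------------------

def qtl_cm_to_bp(peaks, marker_physical: pd.DataFrame) -> pd.DataFrame:
    """Convert QTL support intervals from cM to physical coordinates.

    ``marker_physical`` needs columns marker, chrom, cm, bp; within each
    chromosome positions are linearly interpolated between flanking markers
    (the same piecewise-linear machinery as genetic-map conversion).
    Intervals are emitted 0-based half-open.
    """
    rows = []
    by_chrom = {c: g.sort_values("cm") for c, g in marker_physical.groupby("chrom")}
    for pk in peaks:
        g = by_chrom.get(pk.chromosome)
        if g is None:
            raise ValueError(f"no physical positions for chromosome {pk.chromosome!r}")
        cm = g["cm"].to_numpy()
        bp = g["bp"].to_numpy()
        lo = float(np.interp(np.clip(pk.ci_lo, cm[0], cm[-1]), cm, bp))
        hi = float(np.interp(np.clip(pk.ci_hi, cm[0], cm[-1]), cm, bp))
        rows.append((pk.chromosome, int(lo), int(np.ceil(hi)) + 1))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
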