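"""Variant enrichment in genomic features with interval-shuffle nulls.

For a feature class (enhancers, promoters, UTRs, exons, introns) of a gene
set lying under QTL support regions, the observed statistic is the count of
variants overlapping the feature inside the QTL regions, and the normalized
enrichment divides the proportion of QTL variants in the feature by the
proportion of QTL length the feature covers (1 means density as expected
from coverage).  Significance comes from a shuffle null: length-matched
intervals are re-placed uniformly at random inside the QTL regions (minus
an exclusion set), the overlap recounted, and the empirical p is the share
of shuffles with overlap at or above the observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import (
    _positions_in_intervals,
    intersect_intervals,
    merge_intervals,
    total_length,
)

__all__ = [
    "EnrichmentResult",
    "define_promoters",
    "define_enhancers",
    "enrichment",
    "shuffle_null",
]

PROMOTER_UP = 1000    # bp upstream of the TSS
PROMOTER_DOWN = 100   # bp downstream
ENHANCER_WINDOWS_KB = (50, 100, 150, 200, 250)


def define_promoters(tss: pd.DataFrame, chrom_sizes: dict[str, int] | None = None,
                     ) -> pd.DataFrame:
    """Promoter intervals around transcription start sites.

    A plus-strand gene with TSS at p gets ``[p - 1000, p + 100)``; minus
    strand is mirrored (``[p - 100, p + 1000)``).  Intervals are clipped to
    chromosome bounds.  ``tss`` needs columns gene, chrom, tss, strand.
    """
    if tss["strand"].isna().any() or (~tss["strand"].isin(["+", "-"])).any():
        raise ValueError("every TSS needs a strand of '+' or '-'")
    plus = tss["strand"] == "+"
    start = np.where(plus, tss["tss"] - PROMOTER_UP, tss["tss"] - PROMOTER_DOWN)
    end = np.where(plus, tss["tss"] + PROMOTER_DOWN, tss["tss"] + PROMOTER_UP)
    start = np.maximum(start, 0)
    if chrom_sizes is not None:
        limit = tss["chrom"].map(chrom_sizes).to_numpy()
        end = np.minimum(end, limit)
    return pd.DataFrame({"chrom": tss["chrom"].to_numpy(), "start": start.astype(int),
                         "end": end.astype(int), "gene": tss["gene"].to_numpy()})


def _interval_tss_distance(iv: pd.DataFrame, tss: pd.DataFrame) -> np.ndarray:
    """Distance from each interval to the nearest TSS (0 when a TSS falls
    inside the half-open interval)."""
    out = np.full(len(iv), np.inf)
    for chrom, grp in tss.groupby("chrom"):
        sel = (iv["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        t = np.sort(grp["tss"].to_numpy())
        s = iv.loc[sel, "start"].to_numpy()
        e = iv.loc[sel, "end"].to_numpy()
        left = np.searchsorted(t, s, side="left")
        dist = np.full(sel.sum(), np.inf)
        inside = (np.searchsorted(t, e - 1, side="right") - left) > 0
        dist[inside] = 0.0
        prev = np.clip(left - 1, 0, len(t) - 1)
        nxt = np.clip(np.searchsorted(t, e - 1, side="right"), 0, len(t) - 1)
        d_prev = np.where(left > 0, s - t[prev], np.inf)
        d_next = np.where(np.searchsorted(t, e - 1, side="right") < len(t),
                          t[nxt] - (e - 1), np.inf)
        dist = np.minimum(dist, np.minimum(d_prev, d_next))
        out[sel] = dist
    return out


def define_enhancers(h3k4me1: pd.DataFrame, h3k27ac: pd.DataFrame,
                     h3k4me3: pd.DataFrame, tss: pd.DataFrame,
                     window_kb: int) -> pd.DataFrame:
    """Candidate enhancers from histone marks near a gene set's TSS.

    Candidates are the union of H3K4me1+ and H3K27ac+ regions; any candidate
    overlapping an H3K4me3+ region (a promoter signature) is removed, and
    the rest are retained only if they lie within ``window_kb`` kb of a TSS
    of the gene set.
    """
    candidates = merge_intervals(pd.concat(
        [h3k4me1[["chrom", "start", "end"]], h3k27ac[["chrom", "start", "end"]]],
        ignore_index=True))
    if candidates.empty:
        return candidates
    if not h3k4me3.empty:
        hit = intersect_intervals(candidates, h3k4me3)
        if not hit.empty:
            drop = np.zeros(len(candidates), dtype=bool)
            for chrom, grp in hit.groupby("chrom"):
                sel = (candidates["chrom"] == chrom).to_numpy()
                s = candidates.loc[sel, "start"].to_numpy()
                e = candidates.loc[sel, "end"].to_numpy()
                hs = grp["start"].to_numpy()
                he = grp["end"].to_numpy()
                overlap = np.array([bool(((hs < ee) & (he > ss)).any())
                                    for ss, ee in zip(s, e)])
                drop[np.flatnonzero(sel)[overlap]] = True
            candidates = candidates[~drop].reset_index(drop=True)
    if candidates.empty or tss.empty:
        return candidates.iloc[0:0]
    dist = _interval_tss_distance(candidates, tss)
    return candidates[dist <= window_kb * 1000].reset_index(drop=True)


@dataclass
class EnrichmentResult:
    observed: int
    total_variants: int
    normalized_enrichment: float
    flagged: bool = False
    n_shuffles: int | None = None
    seed: int | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    null_ci95: tuple[float, float] | None = None
    exceedances: int | None = None
    p_value: float | None = None


def enrichment(variants: pd.DataFrame, feature: pd.DataFrame,
               qtl_regions: pd.DataFrame) -> EnrichmentResult:
    """Observed overlap and coverage-normalized enrichment of variants in a
    feature within QTL regions.

    ``normalized = (observed / variants-in-QTL) / (len(feature∩QTL) / len(QTL))``.
    An empty feature∩QTL leaves the enrichment undefined (NaN, flagged).
    """
    in_qtl = _positions_in_intervals(variants["chrom"].to_numpy(),
                                     variants["pos"].to_numpy(), qtl_regions)
    vq = variants[in_qtl]
    fq = intersect_intervals(feature, qtl_regions)
    qtl_len = total_length(qtl_regions)
    feat_len = total_length(fq)
    obs = int(_positions_in_intervals(vq["chrom"].to_numpy(), vq["pos"].to_numpy(),
                                      fq).sum()) if len(vq) else 0
    if feat_len == 0 or qtl_len == 0:
        return EnrichmentResult(obs, int(len(vq)), float("nan"), flagged=True)
    if len(vq) == 0:
        return EnrichmentResult(0, 0, float("nan"), flagged=True)
    norm = (obs / len(vq)) / (feat_len / qtl_len)
    return EnrichmentResult(obs, int(len(vq)), float(norm))


def _subtract(space: list[tuple[str, int, int]], block: tuple[str, int, int]):
    chrom, bs, be = block
    out = []
    for c, s, e in space:
        if c != chrom or be <= s or bs >= e:
            out.append((c, s, e))
            continue
        if s < bs:
            out.append((c, s, bs))
        if be < e:
            out.append((c, be, e))
    return out


def _place_intervals(lengths: np.ndarray, space: list[tuple[str, int, int]], rng,
                     ) -> list[tuple[str, int, int]] | None:
    """Place length-matched intervals uniformly at random in the allowed
    space without mutual overlap (longest first); None if infeasible."""
    placed = []
    for L in lengths:
        gaps = [(c, s, e) for c, s, e in space if e - s >= L]
        if not gaps:
            return None
        weights = np.array([e - s - L + 1 for _, s, e in gaps], dtype=float)
        gi = rng.choice(len(gaps), p=weights / weights.sum())
        c, s, e = gaps[gi]
        start = int(s + rng.integers(0, e - s - L + 1))
        placed.append((c, start, start + int(L)))
        space = _subtract(space, (c, start, start + int(L)))
    return placed


def shuffle_null(feature: pd.DataFrame, qtl_regions: pd.DataFrame,
                 exclusions: pd.DataFrame | None, variants: pd.DataFrame,
                 n_shuffles: int = 1000, seed: int = 0,
                 max_retries: int = 10) -> EnrichmentResult:
    """Shuffle-based null for feature/variant overlap inside QTL regions.

    Each replicate re-places intervals length-matched to the observed
    feature∩QTL pieces, uniformly at random within the QTL regions minus
    the exclusions, avoiding overlap among placed intervals, and counts the
    variants they cover.  ``p = (#null >= observed) / N``; the null mean's
    95% CI uses the normal approximation.  The comparison uses raw overlap
    counts, not the normalized enrichment.
    """
    if n_shuffles <= 0:
        raise ValueError("n_shuffles must be positive")
    rng = np.random.default_rng(seed)
    base = enrichment(variants, feature, qtl_regions)
    fq = intersect_intervals(feature, qtl_regions)
    lengths = np.sort((fq["end"] - fq["start"]).to_numpy())[::-1] if not fq.empty \
        else np.array([], dtype=int)

    allowed = merge_intervals(qtl_regions)
    if exclusions is not None and not exclusions.empty:
        space0 = list(allowed.itertuples(index=False, name=None))
        for blk in merge_intervals(exclusions).itertuples(index=False, name=None):
            space0 = _subtract(space0, blk)
    else:
        space0 = list(allowed.itertuples(index=False, name=None))

    in_qtl = _positions_in_intervals(variants["chrom"].to_numpy(),
                                     variants["pos"].to_numpy(), qtl_regions)
    vq = variants[in_qtl]
    chroms = vq["chrom"].to_numpy()
    pos = vq["pos"].to_numpy()

    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        placed = None
        for _ in range(max_retries):
            placed = _place_intervals(lengths, space0, rng)
            if placed is not None:
                break
        if placed is None:
            worst = int(lengths[0]) if len(lengths) else 0
            raise RuntimeError(
                f"cannot place a shuffled interval of length {worst} in the "
                "allowed space; shrink the exclusions or the feature")
        pf = pd.DataFrame(placed, columns=["chrom", "start", "end"])
        null[k] = _positions_in_intervals(chroms, pos, pf).sum()

    exceed = int((null >= base.observed - 1e-12).sum())
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if n_shuffles > 1 else 0.0
    half = 1.96 * sd / np.sqrt(n_shuffles)
    return EnrichmentResult(
        observed=base.observed,
        total_variants=base.total_variants,
        normalized_enrichment=base.normalized_enrichment,
        flagged=base.flagged,
        n_shuffles=int(n_shuffles),
        seed=int(seed),
        null_mean=mean,
        null_sd=sd,
        null_ci95=(mean - half, mean + half),
        exceedances=exceed,
        p_value=exceed / n_shuffles,
    )
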