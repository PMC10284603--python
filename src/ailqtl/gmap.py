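"""Genetic maps and recombination-fraction arithmetic.

Positions are in centimorgans (cM).  The package convention is the Haldane
map function (crossovers form a Poisson process along the chromosome, no
interference), so distances convert to per-meiosis recombination fractions
via ``r = (1 - exp(-2 d / 100)) / 2``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "haldane_r",
    "haldane_cm",
    "expected_recombinant_fraction",
]


def haldane_r(d_cm):
    """Map distance (cM) -> per-meiosis recombination fraction (Haldane)."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cm) else r


def haldane_cm(r):
    """Recombination fraction -> map distance in cM (inverse Haldane)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * r)
    return float(d) if d.ndim == 0 else d


def expected_recombinant_fraction(r, t):
    """Expected recombinant fraction between two loci after t intercross
    generations of an advanced intercross line (AIL).

    Starting from an F2 (``t = 2``), random mating lets recombinants
    accumulate: linkage disequilibrium between the founder alleles decays by
    a factor ``(1 - r)`` per generation, giving

        R_t = 1/2 * [1 - (1 - 2 r) * (1 - r)^(t - 2)]

    which reduces to ``R_2 = r`` and, for small ``r``, grows roughly as
    ``r * t / 2`` -- the map-expansion effect that shrinks AIL support
    intervals ~t/2-fold relative to an F2.

    Parameters
    ----------
    r : float or array
        Per-meiosis recombination fraction, in [0, 0.5].
    t : int
        Intercross generation (F2 = 2).

    Returns
    -------
    float or ndarray
        R_t, bounded above by 0.5 and non-decreasing in t.
    """
    rr = np.asarray(r, dtype=float)
    if np.any((rr < 0) | (rr > 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    if t < 2:
        raise ValueError("AIL generation t must be >= 2")
    out = 0.5 * (1.0 - (1.0 - 2.0 * rr) * (1.0 - rr) ** (t - 2))
    return float(out) if np.isscalar(r) else out


class GeneticMap:
    """Ordered marker positions (cM) per chromosome.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``marker``, ``chrom``, ``cm``.  Positions must be
        non-decreasing within each chromosome and marker names unique;
        duplicated positions are tolerated on input but scan grids are
        built on the deduplicated ordering.
    map_function : str
        Only ``"haldane"`` is implemented.
    """

    def __init__(self, frame: pd.DataFrame, map_function: str = "haldane"):
        required = {"marker", "chrom", "cm"}
        if not required.issubset(frame.columns):
            raise ValueError(f"genetic map needs columns {sorted(required)}")
        if map_function != "haldane":
            raise ValueError("only the Haldane map function is supported")
        frame = frame[["marker", "chrom", "cm"]].copy()
        frame["chrom"] = frame["chrom"].astype(str)
        frame["cm"] = frame["cm"].astype(float)
        if frame["marker"].duplicated().any():
            dup = frame.loc[frame["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker name: {dup!r}")
        frame = frame.sort_values(["chrom", "cm"], kind="stable").reset_index(drop=True)
        self.frame = frame
        self.map_function = map_function
        self._by_chrom = {c: g.reset_index(drop=True) for c, g in frame.groupby("chrom", sort=True)}
        self._marker_row = {m: (c, p) for m, c, p in frame.itertuples(index=False)}

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def markers(self, chrom: str) -> list[str]:
        return list(self._chrom(chrom)["marker"])

    def positions(self, chrom: str) -> np.ndarray:
        return self._chrom(chrom)["cm"].to_numpy()

    def span(self, chrom: str) -> tuple[float, float]:
        pos = self.positions(chrom)
        return float(pos[0]), float(pos[-1])

    def locate(self, marker: str) -> tuple[str, float]:
        """Return (chrom, cM) of a marker; KeyError if absent."""
        return self._marker_row[marker]

    def __contains__(self, marker: str) -> bool:
        return marker in self._marker_row

    def __len__(self) -> int:
        return len(self.frame)

    def _chrom(self, chrom: str) -> pd.DataFrame:
        try:
            return self._by_chrom[str(chrom)]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not on the map") from None
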