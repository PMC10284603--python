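"""Interval mapping for F2 and advanced intercross line (AIL) designs.

The scan walks a grid of positions (default 0.25 cM, snapped to include the
typed markers) and at each position tests a single-QTL model against the
no-QTL null:

* quantitative traits -- a three-component Gaussian mixture (means
  ``mu_QQ, mu_Qq, mu_qq``, common sigma) fitted by EM against a single
  Gaussian, with ``LOD = log10(L1 / L0)``;
* binary traits -- logistic regression on the expected additive dosage and
  heterozygote probability against the intercept-only model, with
  ``LOD = (dev0 - dev1) / (2 ln 10)``.

Genotype probabilities at untyped positions condition on the nearest
informative flanking markers, with recombination fractions expanded to the
AIL scale ``R_t`` (``t = 2`` recovers the standard F2 machinery exactly).
Linked peaks whose 1-LOD support intervals overlap are resolved by
re-scanning with the marker closest to the higher peak included as a fixed
additive + dominance term in both the null and alternative models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gmap import GeneticMap, expected_recombinant_fraction, haldane_r

logger = logging.getLogger(__name__)

__all__ = [
    "LodCurve",
    "QtlPeak",
    "EffectEstimate",
    "normalize_phenotype",
    "convert_map",
    "qtl_genotype_probs",
    "genotype_prob_matrix",
    "scan_quantitative",
    "scan_binary",
    "find_peaks",
    "resolve_linked_peaks",
    "estimate_effects",
]

LN10 = np.log(10.0)
LOD_THRESHOLD_AIL = 2.0      # dense-marker AIL scans
LOD_SIGNIFICANT_F2 = 4.3     # genome-wide F2 significance
LOD_SUGGESTIVE_F2 = 2.8      # genome-wide F2 suggestive linkage
DEFAULT_STEP_CM = 0.25


# ---------------------------------------------------------------------------
# covariate normalization and map conversion
# ---------------------------------------------------------------------------

def normalize_phenotype(phenotypes: pd.DataFrame, trait: str, covariates: list[str]) -> pd.Series:
    """Adjust a trait for covariates prior to linkage.

    Fits an ordinary least-squares model of the trait on the covariates
    (categorical columns are dummy-coded) and returns the residuals
    re-centred at the trait mean, indexed like the retained rows.
    Individuals with missing trait or covariate values are dropped with a
    logged count.
    """
    if not covariates:
        raise ValueError("no covariates supplied; nothing to adjust for")
    cols = [trait, *covariates]
    data = phenotypes[cols]
    kept = data.dropna()
    n_dropped = len(data) - len(kept)
    if n_dropped:
        logger.info("normalize_phenotype(%s): dropped %d individuals with missing values",
                    trait, n_dropped)
    y = kept[trait].to_numpy(dtype=float)
    X = pd.get_dummies(kept[covariates], drop_first=True, dtype=float)
    X.insert(0, "_intercept", 1.0)
    beta, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
    resid = y - X.to_numpy() @ beta
    return pd.Series(resid + y.mean(), index=kept.index, name=trait)


def convert_map(old_positions, anchors) -> np.ndarray:
    """Piecewise-linear conversion between two genetic maps.

    ``anchors`` is a sequence of ``(old_cm, new_cm)`` pairs, strictly
    increasing on both scales.  Queries outside the anchor span raise (no
    extrapolation).
    """
    a = np.asarray(anchors, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 2:
        raise ValueError("anchors must be >= 2 pairs of (old, new) positions")
    old, new = a[:, 0], a[:, 1]
    if np.any(np.diff(old) <= 0) or np.any(np.diff(new) <= 0):
        raise ValueError("anchor positions must be strictly increasing on both scales")
    q = np.asarray(old_positions, dtype=float)
    if np.any((q < old[0]) | (q > old[-1])):
        raise ValueError("query position outside the anchor span; no extrapolation")
    out = np.interp(q, old, new)
    return float(out) if np.isscalar(old_positions) else out


# ---------------------------------------------------------------------------
# conditional genotype probabilities
# ---------------------------------------------------------------------------

def _step(R: float) -> np.ndarray:
    """2x2 allele transition matrix for one AIL 'gamete' across an interval."""
    return np.array([[1.0 - R, R], [R, 1.0 - R]])


def _interval_table(d_left: float | None, d_right: float | None, t: int) -> np.ndarray:
    """P(genotype at scan position | flanking genotypes) as a (3, 3, 3) table
    indexed ``[gL, gR, gS]`` with genotypes counted in Q alleles.

    The two transmitted chromosomes of an individual are treated as
    independent AIL gametes whose allele process along the chromosome is
    Markov with step recombination fractions ``R_t(r)``; the conditional at
    the scan position is the usual flanking-marker enumeration with ``r``
    replaced by ``R_t(r)``.  ``None`` distance means that flank is absent
    (marginalized over).  At ``t = 2`` this is exactly the F2 table.
    """
    if d_left is None and d_right is None:
        prior = np.array([0.25, 0.5, 0.25])
        return np.broadcast_to(prior, (3, 3, 3)).copy()
    RL = expected_recombinant_fraction(haldane_r(d_left), t) if d_left is not None else None
    RR = expected_recombinant_fraction(haldane_r(d_right), t) if d_right is not None else None
    # per-gamete conditional over the scan allele given flank alleles
    # alleles: 1 = Q, 0 = q; gamete prior 1/2 each at any single locus
    gam = np.zeros((2, 2, 2))  # [aL, aR, aS] unnormalized
    for aL in (0, 1):
        for aR in (0, 1):
            for aS in (0, 1):
                w = 1.0
                if RL is not None:
                    w *= _step(RL)[aL, aS]
                if RR is not None:
                    w *= _step(RR)[aS, aR]
                gam[aL, aR, aS] = w
    gam /= gam.sum(axis=2, keepdims=True)
    # joint prior over one gamete's flank alleles
    if RL is not None and RR is not None:
        RLR = RL + RR - 2.0 * RL * RR
        flank_prior = 0.5 * _step(RLR)  # [aL, aR]
    elif RL is not None:
        flank_prior = np.full((2, 2), 0.25)  # aR unobserved dummy
    else:
        flank_prior = np.full((2, 2), 0.25)
    table = np.zeros((3, 3, 3))
    combos = [(aL, aR) for aL in (0, 1) for aR in (0, 1)]
    for aLm, aRm in combos:
        for aLp, aRp in combos:
            w = flank_prior[aLm, aRm] * flank_prior[aLp, aRp]
            gL, gR = aLm + aLp, aRm + aRp
            dist = np.zeros(3)
            for aSm in (0, 1):
                for aSp in (0, 1):
                    dist[aSm + aSp] += gam[aLm, aRm, aSm] * gam[aLp, aRp, aSp]
            table[gL, gR] += w * dist
    sums = table.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        table = np.where(sums > 0, table / sums, 0.0)
    return table


def qtl_genotype_probs(left_call, right_call, d_left, d_right, t: int):
    """Conditional ``(P_QQ, P_Qq, P_qq)`` at a scan position between two
    flanking markers.

    Calls may be given as strings (``"QQ"/"Qq"/"qq"``), as Q-allele counts,
    or ``None``/``-1`` for missing; distances are in cM.  With both flanks
    missing the F-population prior ``(0.25, 0.5, 0.25)`` is returned.  A
    zero distance to an observed flank collapses the probabilities onto the
    observed call.
    """
    names = {"QQ": 2, "Qq": 1, "qq": 0, "NA": -1, None: -1}
    gL = names.get(left_call, left_call)
    gR = names.get(right_call, right_call)
    gL = -1 if gL is None else int(gL)
    gR = -1 if gR is None else int(gR)
    if gL < 0 and gR < 0:
        return (0.25, 0.5, 0.25)
    if gL >= 0 and d_left == 0:
        return tuple(1.0 if k == gL else 0.0 for k in (2, 1, 0))
    if gR >= 0 and d_right == 0:
        return tuple(1.0 if k == gR else 0.0 for k in (2, 1, 0))
    table = _interval_table(d_left if gL >= 0 else None, d_right if gR >= 0 else None, t)
    prior = np.array([0.25, 0.5, 0.25])
    if gL < 0:   # left flank uninformative: table already marginal in gL slot
        p = np.einsum("i,ik->k", prior, table[:, gR, :])
    elif gR < 0:
        p = np.einsum("j,jk->k", prior, table[gL, :, :])
    else:
        p = table[gL, gR]
    p = np.asarray(p, dtype=float)
    p = p / p.sum()
    return (float(p[2]), float(p[1]), float(p[0]))


def genotype_prob_matrix(
    calls: np.ndarray,
    marker_pos: np.ndarray,
    scan_pos: float,
    t: int,
) -> np.ndarray:
    """Genotype probabilities at one scan position for every individual.

    Parameters
    ----------
    calls : (n_markers, n_individuals) int array of Q-allele counts, -1 missing.
    marker_pos : (n_markers,) cM positions, sorted.
    scan_pos : position on the same chromosome.
    t : AIL generation.

    Returns
    -------
    (n_individuals, 3) array ordered ``[P_qq, P_Qq, P_QQ]`` (Q-count order).

    Each individual conditions on its nearest *informative* flanking
    markers, so missing calls fall through to the next marker out; an
    individual with no informative marker on the chromosome receives the
    population prior.
    """
    m, n = calls.shape
    if m == 0:
        return np.tile([0.25, 0.5, 0.25], (n, 1))
    observed = calls >= 0
    # nearest observed marker index at or left/right of each marker slot
    idx = np.arange(m)[:, None]
    left_fill = np.where(observed, idx, -1)
    left_fill = np.maximum.accumulate(left_fill, axis=0)
    right_fill = np.where(observed, idx, m)
    right_fill = np.minimum.accumulate(right_fill[::-1], axis=0)[::-1]

    jL0 = int(np.searchsorted(marker_pos, scan_pos, side="right")) - 1
    jR0 = int(np.searchsorted(marker_pos, scan_pos, side="left"))
    L = left_fill[jL0] if jL0 >= 0 else np.full(n, -1)
    R = right_fill[jR0] if jR0 < m else np.full(n, m)

    probs = np.empty((n, 3))
    key = (L + 1) * (m + 2) + np.where(R >= m, m + 1, R + 1)
    for k in np.unique(key):
        sel = key == k
        i = int(np.flatnonzero(sel)[0])
        jL, jR = int(L[i]), int(R[i])
        has_L, has_R = jL >= 0, jR < m
        if not has_L and not has_R:
            probs[sel] = [0.25, 0.5, 0.25]
            continue
        if has_L and abs(marker_pos[jL] - scan_pos) < 1e-12:
            g = calls[jL, sel]
            probs[sel] = np.eye(3)[g]
            continue
        if has_R and abs(marker_pos[jR] - scan_pos) < 1e-12:
            g = calls[jR, sel]
            probs[sel] = np.eye(3)[g]
            continue
        dL = scan_pos - marker_pos[jL] if has_L else None
        dR = marker_pos[jR] - scan_pos if has_R else None
        table = _interval_table(dL, dR, t)
        gL = calls[jL, sel] if has_L else np.zeros(sel.sum(), int)
        gR = calls[jR, sel] if has_R else np.zeros(sel.sum(), int)
        if not has_L:
            prior = np.array([0.25, 0.5, 0.25])
            sub = np.einsum("i,ijk->jk", prior, table)
            probs[sel] = sub[gR] / sub[gR].sum(axis=1, keepdims=True)
        elif not has_R:
            prior = np.array([0.25, 0.5, 0.25])
            sub = np.einsum("j,ijk->ik", prior, table)
            probs[sel] = sub[gL] / sub[gL].sum(axis=1, keepdims=True)
        else:
            probs[sel] = table[gL, gR]
    return probs


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class LodCurve:
    chromosome: str
    positions: np.ndarray
    lod: np.ndarray
    model: str = "quantitative"            # quantitative | binary | fixed-term
    fixed_marker: str | None = None
    flags: dict[str, list] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chromosome, "cm": self.positions,
                             "lod": self.lod})


@dataclass
class EffectEstimate:
    a_qtl: float
    d_qtl: float
    attributable_pct: float | None = None


@dataclass
class QtlPeak:
    chromosome: str
    position: float
    lod: float
    ci_lo: float
    ci_hi: float
    direction: str | None = None           # normal | cryptic
    effects: EffectEstimate | None = None
    overlapping: bool = False              # support interval overlaps a neighbour's


# ---------------------------------------------------------------------------
# quantitative scan (EM on the mixture likelihood)
# ---------------------------------------------------------------------------

def _scan_grid(positions: np.ndarray, step: float) -> np.ndarray:
    lo, hi = positions[0], positions[-1]
    grid = np.arange(lo, hi + step / 2, step)
    grid = np.unique(np.round(np.concatenate([grid, positions, [hi]]), 6))
    return grid[(grid >= lo - 1e-9) & (grid <= hi + 1e-9)]


def _gaussian_loglik(resid: np.ndarray) -> float:
    n = len(resid)
    s2 = float(resid @ resid) / n
    return -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)


_SIGMA_FLOOR = 1e-8


def _em_mixture(y, probs, C=None, tol=1e-8, max_iter=200, n_starts=4):
    """Maximize the 3-component common-sigma mixture likelihood.

    ``probs``: (n, 3) prior genotype probabilities (Q-count order).
    ``C``: optional covariate matrix (n, c), entering the component means as
    a shared linear term (used for fixed-term scans).

    Returns (loglik, mu (3,), sigma, gamma, converged) for the best of
    ``n_starts`` EM starts.  The first start is a regression on expected
    dosage (Haley-Knott), which begins at or above the nested-null
    likelihood; the mixture surface is multimodal on small samples, so
    additional quantile-based and perturbed starts guard against local
    optima.
    """
    n = len(y)
    x = probs[:, 2] - probs[:, 0]
    z = probs[:, 1]
    Xhk = np.column_stack([np.ones(n), x, z] + ([C] if C is not None else []))
    beta, *_ = np.linalg.lstsq(Xhk, y, rcond=None)
    mu_hk = np.array([beta[0] - beta[1],            # qq
                      beta[0] + beta[2],            # Qq
                      beta[0] + beta[1]])           # QQ
    gamma_hk = beta[3:] if C is not None else np.zeros(0)
    resid = y - Xhk @ beta
    sigma_hk = max(np.sqrt(float(resid @ resid) / n), _SIGMA_FLOOR)

    sd = max(float(y.std()), _SIGMA_FLOOR)
    starts = [(mu_hk, sigma_hk)]
    if n_starts > 1:
        starts.append((np.quantile(y, [0.25, 0.5, 0.75]), sd / 2))
    rng = np.random.default_rng(12345)   # fixed: restarts are deterministic
    while len(starts) < n_starts:
        # the mixture surface has optima with unordered component means, so
        # restarts draw each mean independently across the data range
        mu0 = rng.uniform(y.min() - 0.5 * sd, y.max() + 0.5 * sd, 3)
        starts.append((mu0, sd * rng.uniform(0.25, 1.2)))
    starts.extend(_assignment_starts(y, probs, sd))

    best = None
    for mu0, sigma0 in starts:
        out = _em_once(y, probs, C, np.array(mu0, dtype=float), float(sigma0),
                       gamma_hk.copy(), tol, max_iter)
        if best is None or out[0] > best[0]:
            best = out
    return best


def _assignment_starts(y, probs, sd, max_ambiguous=6, max_n=60):
    """Extra EM starts from hard assignments of genotype-ambiguous
    individuals.

    On small samples the mixture optima correspond to discrete choices of
    which ambiguous individuals (recombinant or partially informative
    flanks) belong to which component; enumerating those choices and
    starting EM from each implied set of class means makes the multi-start
    search effectively exhaustive.  Skipped for larger problems, where the
    surface is well-behaved and the enumeration would be wasted effort.
    """
    n = len(y)
    if n > max_n:
        return []
    hard = probs.argmax(axis=1)
    ambiguous = np.flatnonzero(probs.max(axis=1) < 0.95)
    if len(ambiguous) == 0 or len(ambiguous) > max_ambiguous:
        return []
    starts = []
    grand = float(y.mean())
    for combo in np.ndindex(*([3] * len(ambiguous))):
        assign = hard.copy()
        # restrict each ambiguous individual to classes with nonzero prior
        ok = True
        for i, g in zip(ambiguous, combo):
            if probs[i, g] <= 1e-6:
                ok = False
                break
            assign[i] = g
        if not ok:
            continue
        mu0 = np.full(3, grand)
        for g in range(3):
            sel = assign == g
            if sel.any():
                mu0[g] = float(y[sel].mean())
        resid = y - mu0[assign]
        s0 = max(float(np.sqrt(resid @ resid / n)), _SIGMA_FLOOR)
        starts.append((mu0, s0))
    return starts


def _em_once(y, probs, C, mu, sigma, gamma, tol, max_iter):
    n = len(y)
    offset = C @ gamma if C is not None else np.zeros(n)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        # E-step
        dev = y[:, None] - offset[:, None] - mu[None, :]
        logdens = -0.5 * (dev / sigma) ** 2 - np.log(sigma)
        wk = probs * np.exp(logdens - logdens.max(axis=1, keepdims=True))
        tot = wk.sum(axis=1)
        ll = float(np.sum(np.log(tot) + logdens.max(axis=1))) - 0.5 * n * np.log(2.0 * np.pi)
        w = wk / tot[:, None]
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * (abs(ll_old) + 1.0):
            ll_old = ll
            converged = True
            break
        ll_old = ll
        # M-step
        if C is None:
            wsum = w.sum(axis=0)
            good = wsum > 1e-12
            mu[good] = (w * y[:, None]).sum(axis=0)[good] / wsum[good]
            dev = y[:, None] - mu[None, :]
            sigma = max(np.sqrt(float((w * dev**2).sum()) / n), _SIGMA_FLOOR)
        else:
            c = C.shape[1]
            D = np.zeros((3 + c, 3 + c))
            b = np.zeros(3 + c)
            wsum = w.sum(axis=0)
            D[:3, :3] = np.diag(wsum)
            WC = C * w.sum(axis=1)[:, None]        # each row weight sums to 1
            for g in range(3):
                D[g, 3:] = (C * w[:, g:g + 1]).sum(axis=0)
                D[3:, g] = D[g, 3:]
                b[g] = float(w[:, g] @ y)
            D[3:, 3:] = C.T @ WC
            b[3:] = C.T @ (y * w.sum(axis=1))
            try:
                theta = np.linalg.solve(D + 1e-10 * np.eye(3 + c), b)
            except np.linalg.LinAlgError:
                theta, *_ = np.linalg.lstsq(D, b, rcond=None)
            mu = theta[:3]
            gamma = theta[3:]
            offset = C @ gamma
            dev = y[:, None] - offset[:, None] - mu[None, :]
            sigma = max(np.sqrt(float((w * dev**2).sum()) / n), _SIGMA_FLOOR)
    return ll_old, mu, sigma, gamma, converged


def _fixed_marker_design(genotypes, gmap, fixed_marker, t):
    """Additive + dominance covariate columns for the fixed marker, using
    conditional probabilities for individuals missing its call."""
    chrom, pos = gmap.locate(fixed_marker)
    _, mpos, calls = genotypes.chrom_calls(gmap, chrom)
    probs = genotype_prob_matrix(calls, mpos, pos, t)
    x = probs[:, 2] - probs[:, 0]
    z = probs[:, 1]
    return chrom, np.column_stack([x, z])


def scan_quantitative(
    genotypes,
    y,
    gmap: GeneticMap,
    t: int,
    step: float = DEFAULT_STEP_CM,
    fixed_marker: str | None = None,
    chromosomes: list[str] | None = None,
) -> list[LodCurve]:
    """Maximum-likelihood interval-mapping scan of a quantitative trait.

    Parameters
    ----------
    genotypes : GenotypeMatrix
    y : array-like, one value per individual in ``genotypes``.
    gmap : genetic map covering the genotyped markers.
    t : AIL generation (``t = 2`` gives the classical F2 scan).
    step : grid spacing in cM; the grid is snapped to marker positions.
    fixed_marker : optional marker whose additive + dominance genotype
        enters both null and alternative models, isolating the test
        position from a linked QTL (simplified composite interval mapping).

    Returns one LodCurve per scanned chromosome.  EM non-convergence at a
    position is recorded in ``curve.flags["non_converged"]`` with the
    best-so-far LOD retained.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != genotypes.n_individuals:
        raise ValueError("trait length does not match the genotype matrix")
    if not np.all(np.isfinite(y)):
        raise ValueError("trait values must be finite")
    if np.var(y) == 0:
        raise ValueError("monomorphic trait (zero variance)")

    C = None
    fixed_chrom = None
    if fixed_marker is not None:
        fixed_chrom, C = _fixed_marker_design(genotypes, gmap, fixed_marker, t)

    # null model is shared across positions
    if C is None:
        ll0 = _gaussian_loglik(y - y.mean())
    else:
        X0 = np.column_stack([np.ones(len(y)), C])
        beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
        ll0 = _gaussian_loglik(y - X0 @ beta0)

    curves = []
    for chrom in chromosomes or gmap.chromosomes:
        names, mpos, calls = genotypes.chrom_calls(gmap, chrom)
        if len(names) == 0:
            continue
        grid = _scan_grid(mpos, step)
        lods = np.zeros(len(grid))
        non_conv = []
        for k, p in enumerate(grid):
            probs = genotype_prob_matrix(calls, mpos, float(p), t)
            ll1, _, _, _, ok = _em_mixture(y, probs, C)
            if not ok:
                non_conv.append(float(p))
            lods[k] = max((ll1 - ll0) / LN10, 0.0)
        curves.append(LodCurve(chrom, grid, lods,
                               model="fixed-term" if fixed_marker else "quantitative",
                               fixed_marker=fixed_marker,
                               flags={"non_converged": non_conv} if non_conv else {}))
    return curves


# ---------------------------------------------------------------------------
# binary scan (logistic likelihood ratio)
# ---------------------------------------------------------------------------

_SEPARATION_ETA = 30.0


def _logistic_deviance(y, X):
    """Binomial deviance of a logistic fit; returns (deviance, separated)."""
    import statsmodels.api as sm
    with warnings.catch_warnings(), np.errstate(over="ignore"):
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        except Exception:
            return 0.0, True   # treat a failed fit as separation: capped LR
        dev = float(res.deviance)
        eta = X @ res.params
    separated = dev < 1e-6 or bool(np.abs(eta).max() > _SEPARATION_ETA)
    return dev, separated


def scan_binary(
    genotypes,
    y,
    gmap: GeneticMap,
    t: int,
    step: float = DEFAULT_STEP_CM,
    fixed_marker: str | None = None,
    chromosomes: list[str] | None = None,
    dosage: bool = True,
) -> list[LodCurve]:
    """Logistic-regression linkage scan of a binary trait.

    At each grid position the trait is regressed on the expected additive
    dosage and heterozygote probability (``dosage=False`` substitutes hard
    calls from the most probable genotype); the LOD is the deviance drop
    against the null scaled by ``2 ln 10``.  Complete separation caps the
    deviance improvement at the saturated-model bound and flags the
    position in ``curve.flags["separated"]``.
    """
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("binary trait must be coded 0/1")
    if len(classes) < 2:
        raise ValueError("binary trait has a single class; nothing to map")

    C = None
    if fixed_marker is not None:
        _, C = _fixed_marker_design(genotypes, gmap, fixed_marker, t)

    n = len(y)
    X0 = np.ones((n, 1)) if C is None else np.column_stack([np.ones(n), C])
    dev0, _ = _logistic_deviance(y, X0)

    curves = []
    for chrom in chromosomes or gmap.chromosomes:
        names, mpos, calls = genotypes.chrom_calls(gmap, chrom)
        if len(names) == 0:
            continue
        grid = _scan_grid(mpos, step)
        lods = np.zeros(len(grid))
        separated = []
        for k, p in enumerate(grid):
            probs = genotype_prob_matrix(calls, mpos, float(p), t)
            if dosage:
                x = probs[:, 2] - probs[:, 0]
                z = probs[:, 1]
            else:
                g = probs.argmax(axis=1)
                x = g - 1.0
                z = (g == 1).astype(float)
            X1 = np.column_stack([X0, x, z])
            dev1, sep = _logistic_deviance(y, X1)
            lod = max((dev0 - dev1) / (2.0 * LN10), 0.0)
            if sep:
                lod = dev0 / (2.0 * LN10)   # saturated-model cap
                separated.append(float(p))
            lods[k] = lod
        curves.append(LodCurve(chrom, grid, lods,
                               model="fixed-term" if fixed_marker else "binary",
                               fixed_marker=fixed_marker,
                               flags={"separated": separated} if separated else {}))
    return curves


# ---------------------------------------------------------------------------
# peaks, resolution, effects
# ---------------------------------------------------------------------------

def find_peaks(curve: LodCurve, threshold: float = LOD_THRESHOLD_AIL) -> list[QtlPeak]:
    """Call peaks on a LOD curve with 1-LOD drop-off support intervals.

    A peak is a (plateau-collapsed) local maximum with LOD >= threshold; its
    support interval is the maximal contiguous run around it where
    ``LOD >= peak - 1``.  Peaks whose intervals overlap are flagged for
    linked-peak resolution.
    """
    lod = np.asarray(curve.lod, dtype=float)
    if not np.all(np.isfinite(lod)):
        raise ValueError("LOD curve contains non-finite values")
    pos = np.asarray(curve.positions, dtype=float)
    n = len(lod)
    peaks: list[QtlPeak] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and lod[j + 1] == lod[i]:
            j += 1
        left_ok = i == 0 or lod[i - 1] < lod[i]
        right_ok = j == n - 1 or lod[j + 1] < lod[i]
        if left_ok and right_ok and lod[i] >= threshold:
            k = (i + j) // 2
            lo = k
            while lo > 0 and lod[lo - 1] >= lod[k] - 1.0:
                lo -= 1
            hi = k
            while hi < n - 1 and lod[hi + 1] >= lod[k] - 1.0:
                hi += 1
            peaks.append(QtlPeak(curve.chromosome, float(pos[k]), float(lod[k]),
                                 float(pos[lo]), float(pos[hi])))
        i = j + 1
    for a in range(len(peaks)):
        for b in range(a + 1, len(peaks)):
            if peaks[a].ci_hi >= peaks[b].ci_lo and peaks[b].ci_hi >= peaks[a].ci_lo:
                peaks[a].overlapping = peaks[b].overlapping = True
    return peaks


def resolve_linked_peaks(
    genotypes,
    y,
    gmap: GeneticMap,
    t: int,
    peak_pair: tuple[QtlPeak, QtlPeak],
    threshold: float = LOD_THRESHOLD_AIL,
    step: float = DEFAULT_STEP_CM,
    binary: bool = False,
) -> tuple[str, LodCurve]:
    """Decide whether two overlapping peaks are one QTL or two.

    The typed marker nearest the higher peak (ties broken toward the lower
    cM coordinate) is included as a fixed term and the chromosome is
    re-scanned; the verdict is ``"distinct"`` iff the conditional LOD within
    the lower peak's support interval stays at or above the threshold, and
    ``"single"`` if the lower peak disappears.  Requires a typed marker
    within the higher peak's support interval.
    """
    a, b = peak_pair
    if a.chromosome != b.chromosome:
        raise ValueError("peak pair must lie on one chromosome")
    high, low = (a, b) if a.lod >= b.lod else (b, a)
    chrom = high.chromosome
    names, mpos, _ = genotypes.chrom_calls(gmap, chrom)
    in_ci = [(nm, p) for nm, p in zip(names, mpos) if high.ci_lo <= p <= high.ci_hi]
    if not in_ci:
        raise ValueError("no typed marker within the higher peak's support interval")
    fixed = min(in_ci, key=lambda mp: (abs(mp[1] - high.position), mp[1]))[0]
    scan = scan_binary if binary else scan_quantitative
    curve = scan(genotypes, y, gmap, t, step=step, fixed_marker=fixed,
                 chromosomes=[chrom])[0]
    mask = (curve.positions >= low.ci_lo) & (curve.positions <= low.ci_hi)
    cond_lod = float(curve.lod[mask].max()) if mask.any() else 0.0
    verdict = "distinct" if cond_lod >= threshold else "single"
    return verdict, curve


def estimate_effects(probs: np.ndarray, y, parental_means: tuple[float, float] | None = None,
                     ) -> EffectEstimate:
    """Additive and dominance effects at a scan position.

    Genotype means are probability-weighted:
    ``a_qtl = (mean_QQ - mean_qq) / 2`` (positive when the Q allele raises
    the trait) and ``d_qtl = mean_Qq - (mean_QQ + mean_qq) / 2``.  With
    ``parental_means = (mean_Q_strain, mean_q_strain)`` the additive effect
    is also expressed as a percentage of the parental mean difference
    (the QTL's attributable share of the strain gap).
    """
    y = np.asarray(y, dtype=float)
    probs = np.asarray(probs, dtype=float)
    wsum = probs.sum(axis=0)
    if np.any(wsum < 1e-8):
        raise ValueError("a genotype class has zero expected count at this position")
    means = (probs * y[:, None]).sum(axis=0) / wsum   # [qq, Qq, QQ]
    a = (means[2] - means[0]) / 2.0
    d = means[1] - (means[2] + means[0]) / 2.0
    pct = None
    if parental_means is not None:
        diff = parental_means[0] - parental_means[1]
        if diff == 0:
            raise ValueError("parental means are equal; attributable share undefined")
        pct = 100.0 * a / abs(diff)
    return EffectEstimate(float(a), float(d), None if pct is None else float(pct))


def classify_direction(effect: EffectEstimate, parental_means: tuple[float, float]) -> str:
    """Label a QTL ``"normal"`` when its additive effect pushes the trait in
    the same direction as the parental strain difference (the Q-strain
    allele moving the trait toward the Q-strain mean), ``"cryptic"`` when it
    acts against it."""
    diff = parental_means[0] - parental_means[1]
    return "normal" if effect.a_qtl * diff > 0 else "cryptic"
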