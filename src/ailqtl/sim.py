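"""Synthetic advanced-intercross-line (AIL) cohorts and analysis fixtures.

The simulator reproduces the statistical structure of a two-strain AIL QTL
study: a cascade-mated pedigree of constant size, marker genotypes produced
by gamete-level meiosis under the Haldane map function, quantitative traits
with additive/dominance QTL effects and covariates, a binary trait through a
liability threshold, and the auxiliary fixtures the downstream stages
consume (variant catalogs with blocky density, scored gene networks with a
planted dense community, expression counts with a known expressed set).

Founders are the two fully inbred strains; allele ``Q`` denotes the allele
of the strain with the protective septal phenotype and ``q`` the other.
Genotype calls are stored internally as the count of Q alleles
(``2 = QQ, 1 = Qq, 0 = qq, -1 = missing``).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gmap import GeneticMap, expected_recombinant_fraction, haldane_r

__all__ = [
    "AILDesign",
    "QTLEffect",
    "TraitModel",
    "GenotypeMatrix",
    "SynthFixtures",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_covariates",
    "select_extremes",
    "synth_fixtures",
    "expected_recombinant_fraction",
    "stage_seed",
]

CALL_CODES = {"qq": 0, "Qq": 1, "QQ": 2, "NA": -1}
CODE_CALLS = {v: k for k, v in CALL_CODES.items()}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a deterministic sub-seed (< 2**31) from a global seed and a
    stage name, so every stochastic stage has an independent stream."""
    h = hashlib.sha256(f"{int(seed)}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# designs and trait models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AILDesign:
    """Breeding design: ``n_pairs`` cages per generation, cascade mating,
    two offspring (one of each sex) per pair, intercrossed to generation
    ``t_final`` (F2 = 2)."""

    n_pairs: int = 48
    t_final: int = 14
    offspring_per_pair: int = 2
    seed: int = 0
    mating: str = "cascade"

    def __post_init__(self):
        if self.n_pairs < 2:
            raise ValueError("cascade mating ring needs n_pairs >= 2")
        if self.t_final < 2:
            raise ValueError("t_final must be >= 2 (F2 is generation 2)")
        if self.offspring_per_pair != 2:
            raise ValueError("the design fixes two offspring (one per sex) per pair")
        if self.mating not in ("cascade", "random"):
            raise ValueError("mating must be 'cascade' or 'random'")


@dataclass(frozen=True)
class QTLEffect:
    chrom: str
    pos_cm: float
    a: float          # additive effect of one Q allele
    d: float = 0.0    # dominance deviation of Qq from the homozygote midpoint


@dataclass
class TraitModel:
    """Architecture of one trait.

    ``value = mean + sum_QTL(a*x + d*z) + covariate effects + N(0, residual_sd)``
    with ``x = (#Q alleles) - 1`` and ``z = 1`` for heterozygotes.  If
    ``liability_threshold`` is set the simulated value is an unobserved
    liability and the emitted trait is ``int(liability > threshold)``.
    """

    qtls: list[QTLEffect] = field(default_factory=list)
    residual_sd: float = 1.0
    mean: float = 0.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    liability_threshold: float | None = None

    def __post_init__(self):
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")


class GenotypeMatrix:
    """Marker calls for a cohort, with phased haplotypes kept internally
    when produced by the simulator.

    Attributes
    ----------
    calls : ndarray, shape (n_markers, n_individuals), int8
        Count of Q alleles; -1 for missing.
    markers : list[str]
    individuals : list
    haplotypes : dict[str, ndarray] or None
        Per chromosome, array (n_individuals, 2, n_markers) with allele
        codes (0 = Q, 1 = q); gamete 0 is maternal.
    """

    def __init__(self, calls, markers, individuals, haplotypes=None):
        self.calls = np.asarray(calls, dtype=np.int8)
        self.markers = list(markers)
        self.individuals = list(individuals)
        self.haplotypes = haplotypes
        if self.calls.shape != (len(self.markers), len(self.individuals)):
            raise ValueError("calls shape does not match markers x individuals")
        self._marker_index = {m: i for i, m in enumerate(self.markers)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def marker_calls(self, marker: str) -> np.ndarray:
        return self.calls[self._marker_index[marker]]

    def chrom_calls(self, gmap: GeneticMap, chrom: str):
        """Return (marker positions cM, calls submatrix) for one chromosome,
        restricted to markers present in this matrix."""
        names = [m for m in gmap.markers(chrom) if m in self._marker_index]
        idx = [self._marker_index[m] for m in names]
        pos = np.array([gmap.locate(m)[1] for m in names])
        return names, pos, self.calls[idx]

    def subset(self, individuals) -> "GenotypeMatrix":
        order = {ind: j for j, ind in enumerate(self.individuals)}
        cols = [order[i] for i in individuals]
        haps = None
        if self.haplotypes is not None:
            haps = {c: h[cols] for c, h in self.haplotypes.items()}
        return GenotypeMatrix(self.calls[:, cols], self.markers, list(individuals), haps)

    def to_frame(self) -> pd.DataFrame:
        """Markers x individuals frame with calls in {QQ, Qq, qq, NA}."""
        data = np.vectorize(CODE_CALLS.get)(self.calls)
        return pd.DataFrame(data, index=self.markers, columns=self.individuals)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenotypeMatrix":
        bad = ~frame.isin(list(CALL_CODES))
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"invalid genotype call {frame.iat[r, c]!r} at marker "
                f"{frame.index[r]!r}, individual {frame.columns[c]!r}"
            )
        calls = np.vectorize(CALL_CODES.get, otypes=[np.int8])(frame.to_numpy())
        return cls(calls, frame.index, frame.columns)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(design: AILDesign, n_final: int | None = None) -> pd.DataFrame:
    """Build the AIL pedigree from F2 through the terminal generation.

    Generation 2 seeds ``n_pairs`` cages with one female and one male each
    (their parents are the F1, coded -1).  From F3 onward the cascade
    scheme applies: the pair breeding into cage ``i`` is the female of cage
    ``i`` mated to the male of cage ``i+1`` (wrapping at the last cage), and
    every pair contributes exactly one female and one male, keeping the
    census at ``2 * n_pairs`` and doubling the effective size relative to
    random pairing.

    ``n_final`` optionally expands the terminal generation (the phenotyped
    cohort) beyond two offspring per pair, distributed as evenly as possible
    across pairs with alternating sexes; the breeding generations keep the
    constant-size invariant regardless.

    ``design.mating`` selects the pair formation: ``"cascade"`` is the
    study design above; ``"random"`` draws each pair's dam and sire
    uniformly from the previous generation (the idealized random-mating AIL
    the map-expansion closed form assumes -- the cascade ring mates
    individuals from adjacent cages, which are related, so it accumulates
    slightly fewer recombinant haplotypes than the idealization).

    Returns a frame with columns id, generation, cage, sex, dam, sire.
    The pedigree is fully determined by the design (random mating uses the
    design seed), so identical designs give byte-identical pedigrees.
    """
    n = design.n_pairs
    rng = np.random.default_rng(stage_seed(design.seed, "pedigree"))
    rows = []
    next_id = 0

    def _sizes(gen):
        if gen == design.t_final and n_final is not None:
            if n_final < 1:
                raise ValueError("n_final must be positive")
            return [n_final // n + (1 if c < n_final % n else 0) for c in range(n)]
        return [2] * n

    # generation 2: founder cohort of the intercross phase
    prev_f, prev_m = {}, {}
    g2_sizes = _sizes(2)
    for cage in range(n):
        for k in range(g2_sizes[cage]):
            sex = "F" if k % 2 == 0 else "M"
            rows.append((next_id, 2, cage, sex, -1, -1))
            if sex == "F":
                prev_f[cage] = next_id
            else:
                prev_m[cage] = next_id
            next_id += 1
    for gen in range(3, design.t_final + 1):
        cur_f, cur_m = {}, {}
        per_pair = _sizes(gen)
        if design.mating == "random":
            dam_pool = np.array(sorted(prev_f.values()))
            sire_pool = np.array(sorted(prev_m.values()))
            dams = rng.choice(dam_pool, size=n)
            sires = rng.choice(sire_pool, size=n)
        for cage in range(n):
            if design.mating == "cascade":
                dam = prev_f[cage]
                sire = prev_m[(cage + 1) % n]
            else:
                dam, sire = int(dams[cage]), int(sires[cage])
            for k in range(per_pair[cage]):
                sex = "F" if k % 2 == 0 else "M"
                rows.append((next_id, gen, cage, sex, dam, sire))
                if sex == "F":
                    cur_f[cage] = next_id
                else:
                    cur_m[cage] = next_id
                next_id += 1
        prev_f, prev_m = cur_f, cur_m
    return pd.DataFrame(rows, columns=["id", "generation", "cage", "sex", "dam", "sire"])


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _meiosis_batch(parent_haps: np.ndarray, rec: np.ndarray, rng) -> np.ndarray:
    """One gamete per parent.  parent_haps: (k, 2, m); rec: (m-1,) adjacent
    recombination fractions.  The crossover process is Markov along the
    marker skeleton (exact under Haldane / no interference)."""
    k, _, m = parent_haps.shape
    start = rng.integers(0, 2, size=k)
    if m > 1:
        switch = (rng.random((k, m - 1)) < rec).astype(np.int8)
        chooser = (start[:, None] + np.concatenate(
            [np.zeros((k, 1), dtype=np.int8), np.cumsum(switch, axis=1)], axis=1)) % 2
    else:
        chooser = start[:, None]
    return np.take_along_axis(parent_haps, chooser[:, None, :], axis=1)[:, 0, :]


def simulate_genotypes(
    pedigree: pd.DataFrame,
    panel: pd.DataFrame,
    gmap: GeneticMap | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Drop marker genotypes through the pedigree by simulated meiosis.

    Parameters
    ----------
    pedigree : frame from :func:`simulate_pedigree`.
    panel : frame with columns marker, chrom, cm (the genotyping panel).
    gmap : optional map the panel must lie on; defaults to the panel itself.
        A panel marker on a chromosome absent from the map, or outside the
        map's span, raises.
    seed : seed for the meiosis stream.

    Founders (the implicit F1 parents of generation 2) carry one intact
    Q-strain and one intact q-strain haplotype, so F2 single-marker genotype
    frequencies are 1:2:1 in expectation.
    """
    panel_map = GeneticMap(panel)
    if gmap is not None:
        for m, c, p in panel_map.frame.itertuples(index=False):
            if c not in gmap.chromosomes:
                raise ValueError(f"marker {m!r} lies on chromosome {c!r} absent from the map")
            lo, hi = gmap.span(c)
            if not (lo <= p <= hi):
                raise ValueError(f"marker {m!r} at {p} cM is off the map span [{lo}, {hi}]")
    rng = np.random.default_rng(seed)

    ped = pedigree.sort_values(["generation", "id"], kind="stable")
    ids = ped["id"].to_numpy()
    row_of = {i: j for j, i in enumerate(ids)}
    gens = ped["generation"].to_numpy()
    dam_rows = np.array([row_of.get(d, -1) for d in ped["dam"]])
    sire_rows = np.array([row_of.get(s, -1) for s in ped["sire"]])
    n_ind = len(ids)

    haplotypes: dict[str, np.ndarray] = {}
    markers_all: list[str] = []
    calls_blocks = []
    for chrom in panel_map.chromosomes:
        names = panel_map.markers(chrom)
        pos = panel_map.positions(chrom)
        m = len(pos)
        rec = haldane_r(np.diff(pos))
        H = np.zeros((n_ind, 2, m), dtype=np.int8)
        f1 = np.stack([np.zeros(m, np.int8), np.ones(m, np.int8)])  # Q strand, q strand
        for gen in np.unique(gens):
            sel = np.flatnonzero(gens == gen)
            if gen == 2:
                parents = np.broadcast_to(f1, (len(sel), 2, m))
                H[sel, 0] = _meiosis_batch(parents, rec, rng)
                H[sel, 1] = _meiosis_batch(parents, rec, rng)
            else:
                H[sel, 0] = _meiosis_batch(H[dam_rows[sel]], rec, rng)
                H[sel, 1] = _meiosis_batch(H[sire_rows[sel]], rec, rng)
        haplotypes[chrom] = H
        calls_blocks.append((2 - H.sum(axis=1)).T.astype(np.int8))  # (m, n)
        markers_all.extend(names)
    calls = np.concatenate(calls_blocks, axis=0) if calls_blocks else np.zeros((0, n_ind), np.int8)
    return GenotypeMatrix(calls, markers_all, list(ids), haplotypes)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_covariates(pedigree: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Covariate table for the cohort: sex from the pedigree, age at
    dissection (days) and body weight (g) drawn at magnitudes typical of an
    adult mouse cohort."""
    rng = np.random.default_rng(seed)
    n = len(pedigree)
    return pd.DataFrame({
        "id": pedigree["id"].to_numpy(),
        "sex": (pedigree["sex"] == "M").astype(int).to_numpy(),
        "age": np.round(rng.uniform(70, 130, n)),
        "bw": np.round(rng.normal(25.8, 2.9, n), 2),
        "cage": pedigree["cage"].to_numpy(),
    })


def _qtl_dosage(genotypes: GenotypeMatrix, panel_map: GeneticMap, qtl: QTLEffect):
    """Genotype at the marker nearest a QTL position (x = #Q - 1, z = het)."""
    if qtl.chrom not in panel_map.chromosomes:
        raise ValueError(f"QTL chromosome {qtl.chrom!r} absent from the simulated map")
    names, pos, calls = genotypes.chrom_calls(panel_map, qtl.chrom)
    if len(names) == 0:
        raise ValueError(f"no markers on chromosome {qtl.chrom!r}")
    j = int(np.argmin(np.abs(pos - qtl.pos_cm)))
    g = calls[j].astype(float)
    g[g < 0] = 1.0  # missing -> population mean genotype
    return g - 1.0, (g == 1.0).astype(float)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    models: dict[str, TraitModel],
    panel: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw trait values for every individual in ``genotypes``.

    QTL effects are applied at the panel marker nearest each declared QTL
    position.  Binary traits (models with a liability threshold) emit the
    indicator that the simulated liability exceeds the threshold.
    """
    rng = np.random.default_rng(seed)
    panel_map = GeneticMap(panel)
    n = genotypes.n_individuals
    out = pd.DataFrame({"id": genotypes.individuals})
    if covariates is not None:
        cov = covariates.set_index("id").loc[genotypes.individuals].reset_index()
        for col in cov.columns:
            if col != "id":
                out[col] = cov[col].to_numpy()
    for trait, model in models.items():
        y = np.full(n, model.mean, dtype=float)
        for qtl in model.qtls:
            x, z = _qtl_dosage(genotypes, panel_map, qtl)
            y += qtl.a * x + qtl.d * z
        for col, beta in model.covariate_effects.items():
            if col not in out.columns:
                raise ValueError(f"covariate {col!r} not available for trait {trait!r}")
            y += beta * out[col].to_numpy(dtype=float)
        y += rng.normal(0.0, model.residual_sd, n)
        if model.liability_threshold is not None:
            out[trait] = (y > model.liability_threshold).astype(int)
        else:
            out[trait] = y
    return out


# ---------------------------------------------------------------------------
# sample selection
# ---------------------------------------------------------------------------

def select_extremes(
    phenotypes: pd.DataFrame,
    traits: list[str],
    n_extreme_per_trait: int,
    n_random: int,
    seed: int = 0,
    id_col: str = "id",
) -> pd.DataFrame:
    """Extreme-phenotype selection with random fill.

    For each trait the upper and lower ``n_extreme_per_trait / 2`` tails are
    taken (ties broken by row order, which is deterministic); the union is
    deduplicated, and individuals are then added at random until the total
    reaches ``len(traits) * n_extreme_per_trait + n_random`` -- overlap
    between trait tails is compensated by extra random picks, mirroring a
    selective-genotyping design topped up with random animals.  Random fill
    is balanced across (sex, cage) strata as far as integer counts allow.
    """
    total = len(traits) * n_extreme_per_trait + n_random
    if total > len(phenotypes):
        raise ValueError(f"requested {total} individuals but cohort has {len(phenotypes)}")
    rng = np.random.default_rng(seed)
    chosen: list = []
    chosen_set = set()
    for trait in traits:
        vals = phenotypes[[id_col, trait]].dropna()
        k_lo = n_extreme_per_trait // 2
        k_hi = n_extreme_per_trait - k_lo
        order = vals.sort_values(trait, kind="stable")[id_col].tolist()
        for i in order[:k_lo] + order[::-1][:k_hi]:
            if i not in chosen_set:
                chosen.append(i)
                chosen_set.add(i)
    remaining = phenotypes[~phenotypes[id_col].isin(chosen_set)]
    need = total - len(chosen)
    if need > 0:
        strata_cols = [c for c in ("sex", "cage") if c in phenotypes.columns]
        if strata_cols:
            groups = {
                key: rng.permutation(g[id_col].to_numpy()).tolist()
                for key, g in remaining.groupby(strata_cols, sort=True)
            }
            counts = {key: 0 for key in groups}
            while need > 0 and any(groups.values()):
                key = min((k for k in groups if groups[k]), key=lambda k: (counts[k], k))
                i = groups[key].pop()
                chosen.append(i)
                chosen_set.add(i)
                counts[key] += 1
                need -= 1
        else:
            fill = rng.choice(remaining[id_col].to_numpy(), size=need, replace=False)
            chosen.extend(fill.tolist())
            chosen_set.update(fill.tolist())
    return phenotypes[phenotypes[id_col].isin(chosen_set)].copy()


# ---------------------------------------------------------------------------
# downstream fixtures: variants, features, networks, counts
# ---------------------------------------------------------------------------

@dataclass
class SynthFixtures:
    """Bundle of synthetic inputs for the post-linkage stages, with the
    planted truth recorded in ``metadata``."""

    genome: dict[str, int]
    variants: pd.DataFrame
    high_blocks: pd.DataFrame
    tss: pd.DataFrame
    marks: dict[str, pd.DataFrame]
    edges: pd.DataFrame
    counts: pd.DataFrame
    metadata: dict


def synth_fixtures(
    seed: int = 0,
    genome: dict[str, int] | None = None,
    block_size: int = 3_000_000,
    low_rate_per_600kb: float = 5.0,
    high_rate_per_600kb: float = 2000.0,
    n_genes: int = 400,
    community_size: int = 40,
    p_in: float = 0.25,
    p_out: float = 0.02,
    n_samples: int = 12,
    expressed_fraction: float = 0.7,
) -> SynthFixtures:
    """Generate variant/feature/network/expression fixtures with known truth.

    Variant positions follow a two-component density: the genome is tiled
    into ``block_size`` blocks, a subset of which are "high" (divergent
    founder haplotype) blocks with ``high_rate_per_600kb`` variants per
    600 kb against a low background rate, and the planted block boundaries
    are recorded in the metadata so density segmentation is checkable.  The
    gene network is a stochastic block model with one dense planted
    community; expression counts make a known subset of genes pass the
    CPM > 1 in >= 2 samples rule.
    """
    rng = np.random.default_rng(seed)
    if genome is None:
        genome = {"chr1": 30_000_000, "chr2": 24_000_000}

    gene_spacing = 120_000
    genes, tss_rows = [], []
    for chrom, length in genome.items():
        for k, p in enumerate(range(60_000, int(length), gene_spacing)):
            name = f"{chrom}_g{k:04d}"
            genes.append((name, chrom, p))
            tss_rows.append((name, chrom, p, "+" if k % 2 == 0 else "-"))
    tss = pd.DataFrame(tss_rows, columns=["gene", "chrom", "tss", "strand"])

    # --- variants with blocky density -------------------------------------
    var_rows, block_rows = [], []
    effect_classes = ["high_impact", "deleterious_missense", "nonframeshift_deletion", "other"]
    for chrom, length in genome.items():
        starts = np.arange(0, int(length), block_size)
        high_flags = rng.random(len(starts)) < 0.35
        for s, is_high in zip(starts, high_flags):
            e = min(s + block_size, int(length))
            if is_high:
                block_rows.append((chrom, int(s), int(e)))
            rate = (high_rate_per_600kb if is_high else low_rate_per_600kb) / 600_000.0
            k = rng.poisson(rate * (e - s))
            pos = np.sort(rng.integers(s + 1, e + 1, size=k))  # 1-based
            for p in pos:
                u = rng.random()
                if u < 0.85:
                    zyg = ("hom_alt", "hom_ref") if rng.random() < 0.5 else ("hom_ref", "hom_alt")
                elif u < 0.90:
                    zyg = ("hom_alt", "het") if rng.random() < 0.5 else ("het", "hom_alt")
                elif u < 0.95:
                    zyg = ("het", "het")
                else:
                    zyg = ("hom_alt", "hom_alt")
                gi = min(int(p) // gene_spacing, (int(length) - 60_000) // gene_spacing)
                gene = f"{chrom}_g{gi:04d}"
                var_rows.append((
                    chrom, int(p),
                    int(rng.poisson(30)) if rng.random() > 0.05 else int(rng.integers(0, 8)),
                    float(rng.beta(1, 40)) if rng.random() > 0.04 else float(rng.uniform(0.1, 0.5)),
                    zyg[0], zyg[1],
                    rng.choice(["exonic", "intronic", "splicing", "intergenic"],
                               p=[0.35, 0.4, 0.05, 0.2]),
                    rng.choice(effect_classes, p=[0.05, 0.12, 0.03, 0.8]),
                    gene,
                ))
    variants = pd.DataFrame(var_rows, columns=[
        "chrom", "pos", "depth", "fdr", "zyg_a", "zyg_b",
        "feature", "effect_class", "gene"]).sort_values(
        ["chrom", "pos"], kind="stable").reset_index(drop=True)
    high_blocks = pd.DataFrame(block_rows, columns=["chrom", "start", "end"])

    # --- histone-mark intervals around a subset of TSS ---------------------
    marks = {"H3K4me1": [], "H3K27ac": [], "H3K4me3": []}
    for _, row in tss.iterrows():
        for mark, prob, off in (("H3K4me1", 0.3, 20_000), ("H3K27ac", 0.25, 35_000),
                                ("H3K4me3", 0.2, 500)):
            if rng.random() < prob:
                c = row.tss + int(rng.integers(-off, off + 1))
                w = int(rng.integers(500, 2500))
                marks[mark].append((row.chrom, max(0, c - w), c + w))
    marks = {k: pd.DataFrame(v, columns=["chrom", "start", "end"]) for k, v in marks.items()}

    # --- gene network: SBM with one planted dense community ----------------
    net_genes = [g for g, _, _ in genes][:n_genes]
    planted = net_genes[:community_size]
    edge_rows = []
    for i in range(len(net_genes)):
        for j in range(i + 1, len(net_genes)):
            p = p_in if (i < community_size and j < community_size) else p_out
            u = rng.random()
            if u < p:
                score = int(rng.integers(701, 1000))
            elif u < p + 0.01:
                score = int(rng.integers(150, 701))  # sub-threshold decoys
            else:
                continue
            edge_rows.append((net_genes[i], net_genes[j], score))
    edges = pd.DataFrame(edge_rows, columns=["gene_a", "gene_b", "combined_score"])

    # --- expression counts --------------------------------------------------
    all_genes = [g for g, _, _ in genes]
    n_expr = int(round(expressed_fraction * len(all_genes)))
    expressed = sorted(rng.choice(all_genes, size=n_expr, replace=False).tolist())
    expressed_set = set(expressed)
    counts = np.zeros((len(all_genes), n_samples), dtype=int)
    for gi, g in enumerate(all_genes):
        if g in expressed_set:
            counts[gi] = rng.negative_binomial(5, 5 / (5 + 60.0), size=n_samples)
        elif rng.random() < 0.1:
            counts[gi, rng.integers(0, n_samples)] = 1  # sporadic single read
    counts = pd.DataFrame(counts, index=all_genes,
                          columns=[f"s{j:02d}" for j in range(n_samples)])

    return SynthFixtures(
        genome=dict(genome),
        variants=variants,
        high_blocks=high_blocks,
        tss=tss,
        marks=marks,
        edges=edges,
        counts=counts,
        metadata={
            "seed": int(seed),
            "block_size": int(block_size),
            "planted_high_blocks": block_rows,
            "planted_community": planted,
            "expressed_genes": expressed,
            "low_rate_per_600kb": low_rate_per_600kb,
            "high_rate_per_600kb": high_rate_per_600kb,
        },
    )
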