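"""Readers, writers, configuration, and the end-to-end pipeline.

All tabular formats are TSV with header rows; floats are serialized at six
significant digits so re-runs with the same configuration produce
byte-identical, diff-able outputs.  BED intervals are 0-based half-open;
VCF positions are 1-based (converted at this boundary only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import density as dns
from . import enrich as enr
from . import linkage as lnk
from . import netperm as net
from . import sim
from .gmap import GeneticMap

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "PipelineError",
    "PipelineConfig",
    "read_map", "write_map",
    "read_genotypes", "write_genotypes",
    "read_phenotypes", "write_phenotypes",
    "read_bed", "write_bed",
    "read_vcf_minimal", "read_variants_tsv",
    "read_edges", "read_counts", "read_gene_set",
    "write_lod_curves", "write_peaks",
    "run_pipeline",
]

EXIT_VALIDATION = 2
EXIT_RUNTIME = 3


class ParseError(ValueError):
    """Schema violation in an input file, pointing at file and line."""

    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        return f"{x:.6g}"
    return str(x)


def _write_tsv(df: pd.DataFrame, path) -> None:
    df = df.copy()
    for c in df.columns:
        if pd.api.types.is_float_dtype(df[c]):
            df[c] = df[c].map(_fmt)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genetic maps and genotype/phenotype tables
# ---------------------------------------------------------------------------

def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    for col in ("marker", "chrom", "cm"):
        if col not in df.columns:
            raise ParseError(path, 1, f"missing column {col!r}")
    try:
        return GeneticMap(df)
    except ValueError as e:
        raise ParseError(path, 1, str(e)) from e


def write_map(gmap: GeneticMap, path) -> None:
    _write_tsv(gmap.frame, path)


def read_genotypes(path) -> sim.GenotypeMatrix:
    """Genotype matrix TSV: marker rows, individual columns, calls in
    {QQ, Qq, qq, NA}."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    valid = set(sim.CALL_CODES)
    arr = df.to_numpy()
    for r in range(arr.shape[0]):
        for c in range(arr.shape[1]):
            if arr[r, c] not in valid:
                raise ParseError(path, r + 2,
                                 f"invalid genotype call {arr[r, c]!r} in column "
                                 f"{df.columns[c]!r} (expected QQ/Qq/qq/NA)")
    return sim.GenotypeMatrix.from_frame(df)


def write_genotypes(genotypes: sim.GenotypeMatrix, path) -> None:
    genotypes.to_frame().rename_axis("marker").to_csv(path, sep="\t")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise ParseError(path, 1, "phenotype table needs an 'id' column")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    _write_tsv(df, path)


# ---------------------------------------------------------------------------
# intervals, variants, networks, counts
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """BED (0-based half-open): chrom, start, end[, name]."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, ln, "BED line needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(path, ln, "start/end must be integers") from None
            if end <= start:
                raise ParseError(path, ln, f"end ({end}) must exceed start ({start})")
            if start < 0:
                raise ParseError(path, ln, "negative start coordinate")
            rows.append((parts[0], start, end) + ((parts[3],) if len(parts) > 3 else ()))
    cols = ["chrom", "start", "end"] + (["name"] if rows and len(rows[0]) == 4 else [])
    return pd.DataFrame(rows, columns=cols or ["chrom", "start", "end"])


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


_GT_ZYG = {"0/0": "hom_ref", "0|0": "hom_ref",
           "0/1": "het", "1/0": "het", "0|1": "het", "1|0": "het",
           "1/1": "hom_alt", "1|1": "hom_alt",
           "./.": "missing", ".|.": "missing", ".": "missing"}


def read_vcf_minimal(path) -> pd.DataFrame:
    """Minimal two-sample VCF -> variant table.

    Reads CHROM, POS, INFO keys DP / FDR / FEAT / CLASS / GENE, and the
    first two sample GT fields (strain A, then strain B).  Unknown INFO keys
    are ignored.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 11:
                raise ParseError(path, ln, "expected 9 fixed columns plus two samples")
            chrom, pos = parts[0], parts[1]
            try:
                pos = int(pos)
            except ValueError:
                raise ParseError(path, ln, "POS must be an integer") from None
            info = dict(kv.split("=", 1) for kv in parts[7].split(";") if "=" in kv)
            fmt = parts[8].split(":")
            if "GT" not in fmt:
                raise ParseError(path, ln, "FORMAT lacks GT")
            gi = fmt.index("GT")
            zyg = []
            for s in parts[9:11]:
                gt = s.split(":")[gi]
                if gt not in _GT_ZYG:
                    raise ParseError(path, ln, f"unparseable genotype {gt!r}")
                zyg.append(_GT_ZYG[gt])
            rows.append((chrom, pos, int(info.get("DP", 0)), float(info.get("FDR", 0.0)),
                         zyg[0], zyg[1], info.get("FEAT", "unknown"),
                         info.get("CLASS", "other"), info.get("GENE", "")))
    return pd.DataFrame(rows, columns=["chrom", "pos", "depth", "fdr", "zyg_a", "zyg_b",
                                       "feature", "effect_class", "gene"])


def read_variants_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = {"chrom", "pos", "depth", "fdr", "zyg_a", "zyg_b", "feature",
              "effect_class", "gene"}
    missing = needed - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing columns {sorted(missing)}")
    return df


def read_edges(path) -> net.GeneNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    try:
        return net.GeneNetwork(df)
    except ValueError as e:
        raise ParseError(path, 1, str(e)) from e


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_set(path) -> list[str]:
    with open(path) as fh:
        return [g.strip() for g in fh if g.strip()]


def write_lod_curves(curves_by_trait: dict[str, list[lnk.LodCurve]], path) -> None:
    frames = []
    for trait, curves in curves_by_trait.items():
        for c in curves:
            f = c.to_frame()
            f.insert(0, "trait", trait)
            f.insert(1, "model", c.model)
            frames.append(f)
    _write_tsv(pd.concat(frames, ignore_index=True), path)


def write_peaks(rows: list[dict], path) -> None:
    cols = ["trait", "model", "chrom", "peak_cm", "lod", "ci_lo", "ci_hi",
            "a_qtl", "d_qtl", "attributable_pct", "direction", "verdict"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = ""
    _write_tsv(df[cols], path)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end parameters; defaults are the study's operating values
    (0.25 cM scan step, AIL LOD threshold 2, F2 thresholds 4.3/2.8, 600 kb
    bins at a 1000-variant cutoff, network score > 700 with 100,000
    permutations, 1000 interval shuffles, CPM > 1 in >= 2 samples)."""

    seed: int = 0
    n_pairs: int = 48
    t_final: int = 14
    n_final: int = 400
    step_cm: float = 0.25
    lod_threshold: float = 2.0
    f2_significant: float = 4.3
    f2_suggestive: float = 2.8
    bin_size: int = 600_000
    density_cutoff: int = 1000
    min_score: int = 700
    network_n_perm: int = 100_000
    enrichment_n_shuffles: int = 1000
    cpm_threshold: float = 1.0
    cpm_min_samples: int = 2
    cm_per_mb: float = 0.5
    chromosomes: dict[str, float] = field(default_factory=lambda: {"c1": 60.0, "c2": 50.0})
    marker_spacing_cm: float = 2.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def stamped(self) -> dict:
        d = dataclasses.asdict(self)
        defaults = dataclasses.asdict(PipelineConfig())
        d["_non_default"] = sorted(k for k in d if not k.startswith("_")
                                   and d[k] != defaults.get(k))
        return d


# ---------------------------------------------------------------------------
# end-to-end pipeline on a simulated cohort
# ---------------------------------------------------------------------------

def _default_panel(config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for chrom, length in config.chromosomes.items():
        for k, p in enumerate(np.arange(0.0, length + 1e-9, config.marker_spacing_cm)):
            rows.append((f"{chrom}m{k:03d}", chrom, round(float(p), 6)))
    return pd.DataFrame(rows, columns=["marker", "chrom", "cm"])


def _default_trait_models(config: PipelineConfig) -> dict[str, sim.TraitModel]:
    chroms = list(config.chromosomes)
    c1 = chroms[0]
    c2 = chroms[1] if len(chroms) > 1 else chroms[0]
    fvl_qtl = [sim.QTLEffect(c1, 30.0, 0.35), sim.QTLEffect(c2, 20.0, 0.25)]
    from scipy.stats import norm
    return {
        "fvl": sim.TraitModel(qtls=fvl_qtl, residual_sd=1.0, mean=1.0),
        "fow": sim.TraitModel(qtls=[sim.QTLEffect(c2, 36.0, -0.3, 0.1)],
                              residual_sd=1.0, mean=0.0),
        "hw": sim.TraitModel(qtls=[sim.QTLEffect(c1, 10.0, 0.3)], residual_sd=1.0,
                             mean=0.18,
                             covariate_effects={"sex": 0.5, "bw": 0.02}),
        # liability shares the fvl loci (sign-flipped: low fvl -> high risk);
        # threshold set for ~34% prevalence
        "pfo": sim.TraitModel(qtls=[sim.QTLEffect(c1, 30.0, -0.35),
                                    sim.QTLEffect(c2, 20.0, -0.25)],
                              residual_sd=1.0, mean=0.0,
                              liability_threshold=float(norm.ppf(1 - 0.34))),
    }


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on a simulated cohort and persist the report bundle.

    Stages run in dependency order (simulate, normalize, scan, peaks,
    resolve, density, candidates, network, enrichment); every artifact is
    stamped with the seed and parameters, and identical configurations
    reproduce all outputs byte for byte.  A stage failure aborts with the
    stage name; artifacts already written stay on disk.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.stamped()}
    stage = "simulate"
    try:
        design = sim.AILDesign(config.n_pairs, config.t_final,
                               seed=sim.stage_seed(config.seed, "design"))
        panel = _default_panel(config)
        gmap = GeneticMap(panel)
        ped = sim.simulate_pedigree(design, n_final=config.n_final)
        geno_all = sim.simulate_genotypes(ped, panel, seed=sim.stage_seed(config.seed, "meiosis"))
        terminal = ped[ped["generation"] == config.t_final]
        genotypes = geno_all.subset(terminal["id"].tolist())
        cov = sim.simulate_covariates(terminal, seed=sim.stage_seed(config.seed, "covariates"))
        models = _default_trait_models(config)
        phen = sim.simulate_phenotypes(genotypes, models, panel, covariates=cov,
                                       seed=sim.stage_seed(config.seed, "phenotypes"))
        write_map(gmap, out / "map.tsv")
        write_genotypes(genotypes, out / "genotypes.tsv")
        write_phenotypes(phen, out / "phenotypes.tsv")

        stage = "normalize"
        phen = phen.copy()
        phen["hw_adj"] = lnk.normalize_phenotype(phen, "hw", ["age", "sex", "bw"])

        stage = "scan"
        curves: dict[str, list[lnk.LodCurve]] = {}
        peak_rows: list[dict] = []
        peaks_by_trait: dict[str, list[lnk.QtlPeak]] = {}
        parental = {t: (m.mean + sum(q.a for q in m.qtls),
                        m.mean - sum(q.a for q in m.qtls))
                    for t, m in models.items() if m.liability_threshold is None}
        scan_t = config.t_final
        for trait in ("fvl", "fow", "hw_adj"):
            y = phen[trait].to_numpy()
            curves[trait] = lnk.scan_quantitative(genotypes, y, gmap, scan_t,
                                                  step=config.step_cm)
            peaks_by_trait[trait] = []
            pm = parental.get("hw" if trait == "hw_adj" else trait)
            for curve in curves[trait]:
                for pk in lnk.find_peaks(curve, config.lod_threshold):
                    _, mpos, calls = genotypes.chrom_calls(gmap, curve.chromosome)
                    probs = lnk.genotype_prob_matrix(calls, mpos, pk.position, scan_t)
                    eff = lnk.estimate_effects(probs, y, parental_means=pm)
                    pk.effects = eff
                    if pm is not None:
                        pk.direction = lnk.classify_direction(eff, pm)
                    peaks_by_trait[trait].append(pk)

        stage = "resolve"
        for trait, pks in peaks_by_trait.items():
            y = phen[trait].to_numpy()
            by_chrom: dict[str, list[lnk.QtlPeak]] = {}
            for pk in pks:
                by_chrom.setdefault(pk.chromosome, []).append(pk)
            verdicts: dict[int, str] = {}
            for chrom, group in by_chrom.items():
                for i in range(len(group)):
                    for j in range(i + 1, len(group)):
                        a, b = group[i], group[j]
                        if a.ci_hi >= b.ci_lo and b.ci_hi >= a.ci_lo:
                            v, _ = lnk.resolve_linked_peaks(
                                genotypes, y, gmap, config.t_final, (a, b),
                                threshold=config.lod_threshold, step=config.step_cm)
                            verdicts[id(a)] = verdicts[id(b)] = v
            for pk in pks:
                peak_rows.append({
                    "trait": trait, "model": "quantitative", "chrom": pk.chromosome,
                    "peak_cm": pk.position, "lod": pk.lod, "ci_lo": pk.ci_lo,
                    "ci_hi": pk.ci_hi, "a_qtl": pk.effects.a_qtl,
                    "d_qtl": pk.effects.d_qtl,
                    "attributable_pct": pk.effects.attributable_pct or "",
                    "direction": pk.direction or "",
                    "verdict": verdicts.get(id(pk), ""),
                })

        stage = "binary-scan"
        yb = phen["pfo"].to_numpy()
        curves["pfo"] = lnk.scan_binary(genotypes, yb, gmap, config.t_final,
                                        step=config.step_cm)
        for curve in curves["pfo"]:
            for pk in lnk.find_peaks(curve, config.lod_threshold):
                peak_rows.append({
                    "trait": "pfo", "model": "binary", "chrom": pk.chromosome,
                    "peak_cm": pk.position, "lod": pk.lod, "ci_lo": pk.ci_lo,
                    "ci_hi": pk.ci_hi, "a_qtl": "", "d_qtl": "",
                    "attributable_pct": "", "direction": "", "verdict": "",
                })
        write_lod_curves(curves, out / "lod_curves.tsv")
        write_peaks(peak_rows, out / "peaks.tsv")
        report["n_peaks"] = len(peak_rows)

        stage = "density"
        fx = sim.synth_fixtures(seed=sim.stage_seed(config.seed, "fixtures"))
        hq, rejects = dns.filter_high_quality(fx.variants)
        profile = dns.bin_density(hq, fx.genome, config.bin_size)
        segments = dns.classify_density(profile, config.density_cutoff)
        write_bed(segments, out / "high_density_segments.bed")
        # physical positions for the simulated map: linear cM <-> bp, with the
        # scan chromosomes mapped onto the fixture genome
        qtl_cm = [pk for pks in peaks_by_trait.values() for pk in pks]
        if qtl_cm:
            remap = {c: list(fx.genome)[i % len(fx.genome)]
                     for i, c in enumerate(config.chromosomes)}
            phys = panel.assign(chrom=panel["chrom"].map(remap),
                                bp=(panel["cm"] / config.cm_per_mb * 1e6).astype(int))
            mapped = []
            for pk in qtl_cm:
                q = dataclasses.replace(pk)
                q.chromosome = remap[pk.chromosome]
                mapped.append(q)
            qtl_bp = dns.qtl_cm_to_bp(mapped, phys)
            qtl_bp = dns.merge_intervals(qtl_bp)
        else:
            qtl_bp = pd.DataFrame({"chrom": [list(fx.genome)[0]], "start": [0],
                                   "end": [list(fx.genome.values())[0]]})
        retained, density_summary = dns.intersect_qtl(qtl_bp, segments)
        write_bed(qtl_bp, out / "qtl_regions.bed")
        report["density"] = {"rejected": rejects, **density_summary}

        stage = "candidates"
        expressed = dns.expressed_genes(fx.counts, config.cpm_threshold,
                                        config.cpm_min_samples)
        cands, cand_summary = dns.filter_candidates(hq, qtl_bp, expressed,
                                                    segments=segments)
        _write_tsv(cands, out / "candidates.tsv")
        report["candidates"] = {k: v for k, v in cand_summary.items() if k != "per_gene"}

        stage = "network"
        network = net.GeneNetwork(fx.edges)
        gene_set = fx.metadata["planted_community"]
        background = sorted(set(fx.metadata["expressed_genes"]) & network.nodes)
        perm = net.permutation_test(network, gene_set, background,
                                    n_perm=config.network_n_perm,
                                    seed=sim.stage_seed(config.seed, "netperm"),
                                    min_score=config.min_score)
        sub = net.build_subnetwork(network, gene_set, config.min_score)
        ranking = net.centrality_ranking(sub)
        _write_tsv(ranking, out / "centrality.tsv")
        report["network"] = {
            "observed_edges": perm.observed.n_edges,
            "observed_clustering": perm.observed.avg_clustering,
            "null_mean": perm.null_mean, "null_sd": perm.null_sd,
            "p": perm.p_label,
        }

        stage = "enrichment"
        # promoters of genes whose TSS lies under the QTL regions
        tss_in_qtl = dns._positions_in_intervals(
            fx.tss["chrom"].to_numpy(), fx.tss["tss"].to_numpy() + 1, qtl_bp)
        set_tss = fx.tss[tss_in_qtl] if tss_in_qtl.any() else fx.tss
        promoters = enr.define_promoters(set_tss, fx.genome)
        res = enr.shuffle_null(promoters, qtl_bp, None, hq,
                               n_shuffles=config.enrichment_n_shuffles,
                               seed=sim.stage_seed(config.seed, "enrich"))
        report["enrichment"] = {
            "observed": res.observed,
            "normalized_enrichment": res.normalized_enrichment,
            "null_mean": res.null_mean, "p": res.p_value,
        }
    except Exception as e:
        raise PipelineError(stage, e) from e

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return report


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
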