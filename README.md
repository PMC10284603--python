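# ailqtl

QTL mapping and downstream genomic analysis for **advanced intercross lines
(AIL)** — the breeding design that intercrosses two inbred strains for ten
or more generations to accumulate recombination and fine-map quantitative
trait loci. The package was built around a two-strain mouse study of atrial
septal morphology (flap valve length, foramen ovale width, crescent width)
and patent foramen ovale as a binary trait, but every stage is generic.

It covers, as a tested, reusable pipeline:

* **Cohort simulation** — the cascade-mated AIL pedigree (48 pairs, two
  offspring each, F2→F14), gamete-level meiosis under the Haldane map
  function, additive/dominance traits with covariates, liability-threshold
  binary traits, and extreme-phenotype sample selection.
* **Interval mapping** — maximum-likelihood scans at 0.25 cM steps with
  AIL-expanded recombination fractions
  `R_t = ½[1 − (1−2r)(1−r)^(t−2)]`; a three-component Gaussian-mixture EM
  for quantitative traits and a logistic likelihood-ratio scan for binary
  traits; 1-LOD drop-off support intervals; resolution of linked peaks by
  re-scanning with the marker nearest the higher peak as a fixed term;
  effect sizes `a = (mean_QQ − mean_qq)/2`, `d = mean_Qq − midpoint`, and
  the additive effect as a percentage of the parental strain gap.
* **Variant density** — quality filtering (depth ≥ 8, FDR ≤ 10%,
  strain-discriminating zygosity), genome binning with a bimodality sweep
  (50 kb–1.1 Mb), segmentation at 1000 variants / 600 kb, QTL intersection,
  and candidate filtering by expression (CPM > 1 in ≥ 2 samples) and
  predicted impact.
* **Network analysis** — induced subnetworks at STRING-style combined
  score > 700, permutation nulls for edge count and clustering coefficient,
  betweenness and stress centrality, and Fisher exact tests for hub
  connections and kinase substrates.
* **Feature enrichment** — promoter/enhancer definitions and
  coverage-normalized variant enrichment against an interval-shuffle null.

## Worked example

Simulate an F14 cohort of 400 animals genotyped at 2 cM markers, plant an
additive QTL (a = 0.35 residual SD) at 30 cM, scan, and summarize the peak:

```python
import ailqtl as aq
from ailqtl import studies

panel = studies.default_panel()                 # 31 markers, 2 cM apart
geno, _, _ = studies.simulate_cohort(t=14, n=400, seed=11)
gmap = aq.GeneticMap(panel)
model = {"fvl": aq.TraitModel(qtls=[aq.QTLEffect("1", 30.0, 0.35)],
                              residual_sd=1.0, mean=1.0)}
phen = aq.simulate_phenotypes(geno, model, panel, seed=12)

curve = aq.scan_quantitative(geno, phen["fvl"].to_numpy(), gmap, t=14)[0]
top = max(aq.find_peaks(curve, threshold=2.0), key=lambda p: p.lod)
_, mpos, calls = geno.chrom_calls(gmap, "1")
probs = aq.genotype_prob_matrix(calls, mpos, top.position, 14)
eff = aq.estimate_effects(probs, phen["fvl"].to_numpy(),
                          parental_means=(1.35, 0.65))
print(f"peak at {top.position} cM, LOD {top.lod:.1f}, "
      f"1-LOD interval [{top.ci_lo}, {top.ci_hi}] cM")
print(f"a = {eff.a_qtl:.3f}, d = {eff.d_qtl:.3f}, "
      f"{eff.attributable_pct:.0f}% of the parental gap")
```

prints

```
peak at 29.75 cM, LOD 7.2, 1-LOD interval [29.0, 31.0] cM
a = 0.360, d = 0.010, 51% of the parental gap
```

The scan localizes the planted QTL to a two-centimorgan support interval —
the map-expansion payoff of twelve extra intercross generations — and the
probability-weighted genotype means recover the planted additive effect
(0.36 vs 0.35) with negligible dominance; relative to a parental difference
of 0.70 trait units, this locus alone accounts for about half the strain
gap.

## Command line

Each stage is also exposed as a subcommand over the same functions:

```bash
ailqtl simulate --seed 7 --out cohort/
ailqtl scan --genotypes cohort/genotypes.tsv --phenotypes cohort/phenotypes.tsv \
            --map cohort/map.tsv --trait fvl --t 14 --threshold 2 --out scan/
ailqtl density --variants variants.tsv --genome genome.tsv --bin 600000 --cutoff 1000 --out dens/
ailqtl netperm --edges string.tsv --set degs.txt --background expressed.txt \
               --n 100000 --seed 7 --out net/
ailqtl enrich --features enhancers.bed --qtl qtl.bed --variants variants.tsv \
              --n 1000 --seed 7 --out enr/
ailqtl run-all --seed 7 --out run/      # full pipeline on a simulated cohort
```

Outputs are TSV/BED/JSON, stamped with the seed and parameters; re-running
with the same configuration reproduces every file byte for byte.

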