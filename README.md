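# pnmeth

Tumour subtype discovery and multi-omic integration for methylation-array
cohorts, built around the analysis design used for pancreatic
neuroendocrine tumours (PanNETs): a tumour/normal 450K-style β-value
matrix is quality-filtered, reduced to promoter CpG sites that are
unmethylated in every normal sample and variable across tumours,
dichotomized, and clustered into subtypes; the subtypes are then related to
clinical/genomic covariates, differential methylation, gene expression,
chromosome-arm LOH and an islet-cell signature.

It is aimed at cancer epigenomics analysts who want the full pipeline as
tested, composable library functions (plus a thin `pnmeth` CLI), and at
methodologists who want to probe the operating characteristics of this
class of subtyping procedure on synthetic cohorts with planted ground
truth.

## The method

Let β<sub>ps</sub> ∈ [0,1] be the methylated fraction at CpG probe *p* in
sample *s*. After probe QC (detection *p* > 0.01 or beadcount < 3 in ≥ 5%
of samples; non-CpG, sex-chromosome, SNP-masked and multi-mapping probes
removed), the subtyping cascade keeps probes with:

1. β < 0.3 in **every** normal sample (not methylated in normal tissue),
2. a promoter annotation (TSS1500, TSS200, 5′UTR or 1stExon), and
3. across-tumour SD > 0.20 (*n*−1 denominator).

Retained probes are dichotomized at β ≥ 0.3 (presence/absence of
methylation), tumours are compared with the asymmetric-binary (Jaccard)
distance *d* = (b+c)/(a+b+c) — joint absence ignored — and clustered with
Ward linkage (ward.D2 on the distances; the classic ward.D update is a
config switch), cut at *k* = 3.

Downstream stages: per-probe Welch *t*-tests between subgroup pairs with
Benjamini–Hochberg adjustment per pair and the significance rule
(*q* < 0.05 **and** |Δβ| ≥ 0.20); Fisher / Kruskal–Wallis / rank-sum
subgroup-association tests; CPM + TMM expression normalization and Pearson
correlation of probe methylation with log₂(TMM-CPM + 1); length-weighted
chromosome-arm LOH fraction and median logR summaries with a
LOH-vs-methylation contrast; and nearest-profile scoring against α/β-islet
reference methylation.

The `synthetic_cohort` module generates complete cohorts (β matrix,
annotation, clinical table, segments, counts, islet reference, detection-p
and beadcount matrices) with planted subgroups, DM probes, linked genes
and LOH arms, so every stage can be validated against known truth.

## Worked example

```python
import pnmeth

cohort = pnmeth.simulate_cohort(pnmeth.SimConfig(seed=1))
filtered, report = pnmeth.apply_probe_filters(
    cohort.beta, cohort.detection_p, cohort.beadcount, cohort.annotation)
filtered = pnmeth.drop_incomplete_probes(filtered)
assignment, trace, _ = pnmeth.run_subtyping(filtered, cohort.annotation)
print(trace.counts)
print(pnmeth.truth_recovery_report(cohort, assignment).ari)
```

prints

```
{'input': 4777, 'unmethylated_in_normals': 3775, 'promoter': 1756, 'variable': 687}
1.0
```

QC keeps 4777 of 5000 probes; 3775 of those are unmethylated in all 11
normals, 1756 are promoter probes and 687 survive the SD > 0.20
variability cut (the 600 planted promoter probes plus flip-noise-driven
background probes). Clustering the dichotomized matrix recovers the three
planted subgroups exactly (adjusted Rand index 1.0). Continuing,

```python
dm = pnmeth.pairwise_dm(filtered, assignment.labels)
print(pnmeth.summarize_dm(dm, cohort.annotation).to_dict()["total_sites"])
```

prints `895` significant sites across the three pairwise comparisons.

The same steps are available from the shell:

```sh
pnmeth simulate --seed 1 --out sim/
pnmeth qc --beta sim/beta.tsv --roles sim/roles.tsv --detp sim/detection_p.tsv \
          --beads sim/beadcount.tsv --annot sim/annotation.csv --out qc/
pnmeth subtype --beta qc/beta_filtered.tsv --roles sim/roles.tsv \
               --annot sim/annotation.csv --k 3 --out subtypes/
```

## Layout

- `src/pnmeth/io_formats.py` — readers/writers/validation for every table
- `src/pnmeth/synthetic_cohort.py` — cohort generator with planted truth
- `src/pnmeth/probe_qc.py` — probe exclusion rules
- `src/pnmeth/subtype_discovery.py` — cascade, dichotomization, binary
  distance, Ward clustering
- `src/pnmeth/group_association.py` — Fisher/KW/rank-sum + BH utilities
- `src/pnmeth/differential_methylation.py` — pairwise DM + summaries
- `src/pnmeth/expression_integration.py` — CPM/TMM/correlation/gene reports
- `src/pnmeth/genome_context.py` — arm LOH summaries, LOH-methylation
  contrast, islet signature
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
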