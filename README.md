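# silacq

A tested, reusable SILAC LC-MS quantification pipeline: from per-scan
deisotoped detection tables and peptide identifications to light/heavy
isotope-pair quantification, accurate-mass-and-time (AMT) filtering,
protein-level relative isotope abundance (RIA), differential-expression
calls, hierarchical clustering for heat maps, and hypergeometric term
enrichment.  A ground-truthed synthetic experiment generator emulates
the underlying study design (four sample types — forward mixed, reverse
mixed, and two self-mixed controls — in biological triplicate analyzed
in technical duplicate) so every stage is testable without instrument
data.

## Modules

| module | role |
| --- | --- |
| `silacq.peptide_chem` | tryptic digestion, monoisotopic masses, label mass shifts, the five light/heavy shift classes (R, K, RR, RK, KK) |
| `silacq.synthetic_data` | ground-truthed synthetic experiments: per-scan detection tables, identification tables, manifest, FASTA |
| `silacq.pair_quant` | chromatographic feature building, trapezoidal area integration, shift-class pair matching, RIA |
| `silacq.amt_db` | identification attachment, AMT entry construction, presence/RT-span/wash filters, technical-replicate merging (5 ppm / 5 min) |
| `silacq.protein_quant` | peptide→protein rollup, leave-one-out 2-SD outlier trimming, orientation flipping, per-sample normalization to mean RIA 0.5 |
| `silacq.diff_stats` | per-protein one-way ANOVA (mixed vs control), RIA↔fold transforms, control-distribution fold cutoff, significance calls |
| `silacq.downstream` | hierarchical clustering + heat-map export, hypergeometric enrichment with Benjamini–Hochberg correction |
| `silacq.pipeline` | end-to-end composition of the stages |

## CLI

```sh
# generate a synthetic experiment (optionally override SimConfig fields via YAML)
silacq simulate -o sim/ --seed 1

# detections + identifications + manifest -> pairs, AMT entries,
# protein table, differential results, summary
silacq quantify -d sim/detections.tsv -i sim/identifications.csv \
                -m sim/manifest.tsv -o quant/

# heat-map export (4-column layout; --by-replicate for the 12-column one)
silacq cluster -p quant/protein_samples.tsv -o heatmap --png

# term enrichment of the significant up- or down-regulated set
silacq enrich -r quant/diff_results.tsv -a annotation.tsv -o enrich.tsv --direction up
```

File formats are plain text: detections TSV (`run_id, rt_min,
mono_mass_da, charge, area`), identifications CSV (`run_id, sequence,
charge, mono_mass_da, rt_min, score, accession`), manifest TSV
(`run_id, sample_type, orientation, bio_rep, tech_rep`), FASTA, and a
two-column `term<TAB>accession` annotation table (GMT also accepted).

## Notes

* Label shifts default to the fixed published constants
  (`LabelScheme()`); `LabelScheme.physical()` rebuilds them from
  standard isotope mass differences and agrees within 1e-4 Da.
* Normalization acts in ratio space (a single multiplicative factor on
  light:heavy ratios), which preserves ranks and keeps RIAs inside
  (0, 1).
* The significance screen is two-stage: raw ANOVA p < 0.01 plus an
  empirical fold cutoff derived from the pooled control distribution at
  the 99% confidence level.  No multiple-testing correction is applied
  to the per-protein ANOVA p-values; BH correction is applied to the
  enrichment p-values.
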