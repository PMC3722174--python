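# exondys

Exon-array analysis of tissue-specific transcriptome dysregulation.

Mitochondrial respiratory-chain (RC) disease perturbs the transcriptome
of different tissues in strikingly opposite directions: gene sets that
rise in patient skeletal muscle tend to fall in patient fibroblasts,
UTRs change independently of their gene bodies, AU-rich-element (ARE)
bearing 3'-UTRs are differentially stabilized, and the activity of
nutrient-sensing transcription factors shifts in mirrored patterns.
`exondys` packages the full analysis chain needed to study these
phenomena on probe-level exon-array data — and a synthetic-data
generator that plants every one of those effects with known magnitudes,
so each stage can be validated by parameter recovery.

The pipeline, for a two-tissue, disease-vs-control design:

1. **Normalization** — lowess of each array's log ratio against a
   per-probe median pseudo-array.
2. **Summarization** — the multiplicative expression index
   `PM = θ·φ + ε` fitted per probeset by alternating least squares with
   a robust outlier re-fit (`Σφ² = n` identifiability), then applied
   again over probesets to obtain gene indexes; PCA sample embedding.
3. **Differential expression** — SAM-style moderated statistic
   `d = Δx̄/(s + s₀)` with data-driven s₀, permutation p-values
   (exhaustive when ≤ 10,000 assignments) and permutation FDR, per
   tissue, at gene and probeset level.
4. **Sub-gene events** — smallest-p probeset per gene-region with
   Bonferroni correction; an alternative event needs adjusted p < 0.05
   and either an opposite direction to the gene or a much smaller p;
   Table-style region counts and sense/antisense concordance with
   effective-probeset filtering.
5. **UTR statistics** — the ARE motif ladder (AUUUA → WWWWAUUUAWWWW),
   per-class 3'-UTR change tests, positional (1%-bin) degradation
   profiles with exon adjustment, 5'-UTR baseline association, TOP
   motif detection.
6. **Regulators** — PWM scanning at ≥ 95 % similarity on both strands,
   promoter/intron TF target sets, target-set activity and
   site-interaction Welch tests, running-sum gene-set enrichment,
   hypergeometric over-representation.
7. **Cross-tissue synthesis** — 8-subset classification with the
   inverse-dysregulation fraction, signed-significance correlation
   between tissues, DerSimonian–Laird meta-correlation of gene pairs
   across the four tissue×disease groups, correlation screens.

## Worked example

Simulate a 40-gene dataset and run the whole pipeline:

```sh
exondys simulate --out sim --n-genes 40 --seed 7
exondys run --input sim --out run --seed 7
exondys report --run-dir run
```

The report prints (abridged):

```json
{
 "crosstissue_r": -0.21005373968011515,
 "crosstissue_p": 0.19327900861924366,
 "positional_gradient_muscle": 0.10292408617570782,
 "quadrants": {
  "both_up_down": 3, "both_down_up": 3,
  "both_up_up": 1,  "both_down_down": 3,
  "inverse_fraction": 0.6,
  "n_both_significant": 10
 }
}
```

Reading the numbers: of the 10 genes significantly changed in both
tissues, 6 moved in opposite directions (`inverse_fraction` 0.6 —
exactly the fraction of sign-flipped effects the generator plants by
default), the signed-significance scores of the two tissues correlate
negatively (r = −0.21 over 40 genes; the planted inverse structure at
this small scale), and the positional 3'-UTR gradient in muscle is
+0.10 log2 per unit position — the planted 1.0 gradient diluted by the
10 % of genes that carry it.  The run directory also holds per-tissue
SAM tables, alternative-event calls, Table-style region summaries, ARE
class statistics and TF activity tables, each TSV with a JSON sidecar
recording the config and seed.

The same analyses are available as a library (`exondys.pipeline.analyze`
runs everything in memory; each stage is an importable module — see
`docs/methods.md` for the statistical details).

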