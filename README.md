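# shm-atlas

Tools for mapping the off-target activity of **AID** (activation-induced
deaminase) from targeted deep-sequencing base counts. AID deaminates
deoxycytidines in germinal-center B cells; in mice lacking both uracil
repair pathways (*Ung−/−Msh2−/−*), every unrepaired lesion replicates into a
C→T (or, read on the other strand, G→A) transition, so the raw deamination
footprint becomes directly observable. This package implements that
analysis end to end:

* **Hotspot scanning** of IUPAC motifs (WRC, WRCY, AGCTNT, …) in the
  *deaminated-C frame*: a plus-strand match marks a C, a match of the
  reverse-complemented pattern marks a G whose paired minus-strand C is the
  deaminated base.
* **Mutation profiling** from per-base count tables with germline-SNP
  suppression and depth-weighted frequency formulas:

  ```
  total freq    = total mutations / Σ depth
  C/G freq      = (mutated C + mutated G) / (Σ depth at C + Σ depth at G)
  hotspot freq  = same, restricted to hotspot-frame C and G positions
  ```

* **Target calling**: per region, a one-tailed Fisher exact test of
  transition events vs the AID-null (*Aicda−/−*) control with
  Benjamini–Hochberg FDR control (targets at q ≤ 0.05).
* **Sequence-context analysis** of mutated cytosines (logo composition
  matrices, per-position Fisher/Bonferroni enrichment) and per-motif
  mutability ranking with exact small-sample Mann–Whitney tests — the
  machinery behind identifying AGCTNT-type hotspots.
* **Repair-genotype contrasts** (BER/MMR single knockouts vs the double
  knockout) with control-subtracted frequency matrices and Student t tests.
* **Mutability prediction**: a conditional-inference classification tree
  over gene-level transcriptional features (expression, transcription rate,
  RNAPolII/Spt5 density, chromatin marks, superenhancer and
  convergent-transcription flags), where splits are gated by
  Bonferroni-adjusted rank/Fisher association tests.
* A **synthetic-data generator** that reproduces the statistical structure
  of such an experiment (motif-concentrated deamination, genotype-specific
  repair escape and spectra, Poisson depth, multinomial base calls,
  heterozygous SNPs, sequencing error) so the whole pipeline is testable
  without sequencing data.

Coordinates are 0-based half-open everywhere, including TSV outputs;
substitutions are written ASCII-style (`C>T`). Count tables use the exact
header `region_id  pos  ref  depth  A  C  G  T`.

## Worked example

```python
from shm_atlas import (SimulationConfig, simulate_dataset, mask_snps,
                       summarize_regions, call_targets,
                       site_transition_frequencies, subtract_control,
                       motif_mutability, PRESET_MOTIFS, WRCY_VARIANTS)

cfg = SimulationConfig(n_regions=50, seed=1)           # 50 x 500 bp, 5% true targets
ds = simulate_dataset(cfg, ["UngMsh2_DKO", "Aicda_KO"])

case = mask_snps(ds.counts["UngMsh2_DKO"], ds.snps)    # suppress germline SNPs
ctrl = mask_snps(ds.counts["Aicda_KO"], ds.snps)
results = call_targets(summarize_regions(case), summarize_regions(ctrl))

called = [r for r in results if r.is_target]
print(f"{len(called)} / {len(results)} regions called as AID targets (q <= 0.05)")
for r in called:
    print(f"  {r.region_id}: {r.m_case} vs {r.m_ctrl} transitions "
          f"on ~{r.n_case:,} C/G bases, q = {r.q_value:.2e}")
print("planted truth:", sorted(ds.target_ids))

adjusted = subtract_control(site_transition_frequencies(case),
                            site_transition_frequencies(ctrl))
regions = {r.region_id: r for r in ds.regions}
motifs = [PRESET_MOTIFS["AGCTNT"]] + [PRESET_MOTIFS[v] for v in WRCY_VARIANTS]
ranking = motif_mutability(adjusted, regions, motifs)
print(ranking[["motif_name", "n_sites", "mean_freq"]].head(3).to_string(index=False))
```

prints

```
2 / 50 regions called as AID targets (q <= 0.05)
  r0016: 55 vs 5 transitions on ~115,647 C/G bases, q = 1.12e-10
  r0025: 62 vs 5 transitions on ~126,194 C/G bases, q = 4.07e-12
planted truth: ['r0016', 'r0025']
motif_name  n_sites  mean_freq
    AGCTNT       54   0.000271
      TGCT      172   0.000165
      TGCC      211   0.000155
```

Both planted targets are recovered with no false calls: the double-knockout
replicate accumulates ~10× more C>T/G>A events than the AID-null control in
those regions, and nowhere else. The motif ranking puts AGCTNT (planted at
25× baseline deamination) above every concrete WRCY four-mer (planted at
10×); unmutated motif instances count as zeros, which is why the means sit
well below the per-site hotspot frequencies.

The same steps are available from the shell:

```bash
shm-atlas simulate --outdir demo
shm-atlas call-targets --case demo/counts_UngMsh2_DKO.tsv \
    --control demo/counts_Aicda_KO.tsv --regions demo/regions.bed \
    --fasta demo/regions.fasta --snps demo/snps.bed -o demo/targets.tsv
shm-atlas motifs --case demo/counts_UngMsh2_DKO.tsv \
    --control demo/counts_Aicda_KO.tsv --regions demo/regions.bed \
    --fasta demo/regions.fasta --snps demo/snps.bed --outdir demo/motifs
shm-atlas predict --features features.tsv -o tree.json
```

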