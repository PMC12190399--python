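# phasekin

Methylation-kinetics analysis of nucleosome dynamics in vivo.

Inducible DNA methyltransferases (E. coli Dam for GATC sites, M.SssI for
CG sites) probe chromatin accessibility in living cells: after induction,
each genomic site's methylated fraction rises with pseudo-first-order
kinetics, and the apparent rate constant measures how often that site is
exposed by nucleosome dynamics.  `phasekin` turns per-site methylated
fractions (or raw restriction-fragment intervals) into normalized
accessibility rates and quantifies nucleosome phasing with a decaying
sine wave model.

## The model

Per site, the methylated fraction follows `f(t) = 1 − (1 − f0)·e^(−kt)`,
so `k` is estimated by ordinary least squares on
`ln(1 − f) = −k·t + b`, with fractions capped at 0.99 (past the first
capped point, saturated observations are dropped).  Rates are made
comparable between strains by dividing by an internal control: the median
rate of the non-nucleosomal mitochondrial genome (Dam mode) or the rate
implied by the genome-wide median fraction trajectory (CpG mode).

Averaged over genes aligned on the +1 nucleosome dyad, the normalized
rate profile `y(x)` oscillates with the nucleosome repeat and is fit by

```
y(x) = A·e^(−λx)·sin(ωx + θ) + kx + b ,   x ∈ [−50, 1000] bp
```

whose derived descriptors are the nucleosome spacing `2π/ω`, the initial
amplitude `A`, the per-period decay `e^(−λ·2π/ω)`, the baseline slope per
kb `1000k`, the adjusted mean rate (curve mean over the 1051 integer
offsets of the window), and an adjusted R² `1 − (SSR/SST)(N−1)/(N−7)`.

Downstream analyses include per-gene bias-corrected mean rates (mean
deviation from the population curve, anchored at the population mean),
rate quintiles Q1–Q5 with per-quintile refits, and the kinetics of
TFIIIB (−56..−13), TFIIIC (−2..gene end +10, minus introns) and intron
regions of tRNA genes.

A synthetic-data module generates toy genomes, phased rate landscapes,
time courses and DpnI-style fragments with known ground truth, so every
stage is testable end to end.

## Worked example

```sh
phasekin simulate --n-genes 200 --chrom-length 600000 --interval 128 \
    --n-trna 40 --out sim --seed 11
# wrote synthetic bundle to sim (200 genes, 5358 sites)

phasekin rates --sites sim/sites.bed \
    --fractions sim/frac_t30.bedGraph --fractions sim/frac_t60.bedGraph \
    --fractions sim/frac_t120.bedGraph --fractions sim/frac_t240.bedGraph \
    --times 30,60,120,240 --reference mtdna --out rates.tsv
# reference rate 0.005/min -> rates.tsv

phasekin phase --rates rates.tsv --genes sim/genes.tsv --out-prefix wt_
# spacing 166.3 bp, amplitude 0.39, adj mean rate 0.80, adj R2 1.00

phasekin trna --rates rates.tsv --genes sim/genes.tsv --out-prefix trna_
# TFIIIC/TFIIIB ratio 1.50, intron/TFIIIB ratio 2.00
```

The simulated genome was generated from a wild-type phasing landscape
(spacing 166.3 bp, amplitude 0.39, decay 0.86/period, adjusted mean rate
0.80 relative to mtDNA), and the pipeline recovers exactly those
descriptors from the noise-free time course: the mitochondrial reference
equals the generating control rate (0.005/min), the sine fit returns the
generating spacing/amplitude/mean, and the tRNA class ratios match the
generating TFIIIC:TFIIIB (1.5×) and intron:TFIIIB (2×) rate factors.

The same stages are available as library functions
(`phasekin.kinetics.fit_first_order`, `phasekin.phasing.phase_fit`,
`phasekin.gene_rates.assign_quintiles`, ...) and as one `phasekin run`
pipeline driven by a YAML config.

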