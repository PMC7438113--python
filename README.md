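# germchrom

Quantification of Polycomb (H3K27me3) chromatin domain remodeling in the
*Drosophila* female germline.

Undifferentiated germline stem cells carry a *non-canonical* H3K27me3
distribution — moderate, even coverage of all transcriptionally inactive
chromatin — which is remodeled during nurse-cell differentiation into the
*canonical* pattern of focused enrichment on Polycomb (PcG) domains.
`germchrom` implements the computational layer needed to measure that
transition from sequencing and imaging readouts:

* **4-class genome segmentation** (active / inactive / PcG / Hp1) collapsed
  from a nine-state chromatin model, with overlapping 5 kb bins (500 b
  step), exclusion masks, PRE-summit flagging, and gene classification with
  precedence PcG > active > inactive;
* **spike-in-normalized ChIP enrichment**: per-bin
  `E = (α·RPM_IP + ε)/(RPM_Input + ε)` with
  `α = (spike% Input)/(spike% IP)`, class-stratified densities of log₂ E,
  domain-level enrichment calls and cross-sample sharing, per-class
  fold-change boxplot summaries (notch = 1.58·IQR/√n), peak-centered
  read-depth matrices, and strand-aware TSS-window enrichment;
* **expression trajectories**: TPM, median-of-ratios size factors,
  per-gene log₂ fold changes, and per-class *relative median* fold-change
  trajectories (class median ÷ active-class median, active ≡ 1) with
  bootstrap 95% CIs;
* **reporter induction**: the heat-shock reporter statistic
  `I = [GFP]⁺ʰˢ − mean([GFP]⁻ʰˢ)` per line/stage/genotype, genotype
  contrasts by unpaired two-tailed pooled t-test with */**/N.S. tiers, and
  developmental trajectory tables;
* **a synthetic-data generator** with known ground truth (class-multiplier
  ChIP reads with a derived IP spike fraction, negative-binomial counts
  with class fold effects, Gaussian reporter fluorescence with a
  configurable silencing factor) so every estimator is verified by
  parameter recovery.

See `docs/methods.md` for the statistical details and known limitations.

## Worked example

Simulate a nurse-cell-like ChIP experiment (two 1 Mb chromosomes, 5×10⁵
reads per library, 10% spike-in, per-class IP multipliers
active 0.2 / inactive 2 / PcG 10) and recover the enrichment profile:

```python
import numpy as np
from germchrom import (SyntheticConfig, generate_genome, simulate_chip_pair,
                       make_bins, annotate_bins)
from germchrom.enrichment import SampleLibrary, enrichment_table

cfg = SyntheticConfig(seed=1)
segments, genes = generate_genome(cfg)
ip, inp = simulate_chip_pair(segments, cfg)
lib_ip = SampleLibrary("nc_IP", "IP", ip)
lib_in = SampleLibrary("nc_Input", "Input", inp)
bins = annotate_bins(make_bins({"chr1": 1_000_000, "chr2": 1_000_000}), segments)
table = enrichment_table(lib_ip, lib_in, bins)
print(f"alpha = {table.alpha:.3f}  (input spike {lib_in.spike_fraction:.3f}, "
      f"IP spike {lib_ip.spike_fraction:.3f})")
cls = table.classes()
for c in ("active", "inactive", "PcG"):
    med = np.median(table.enrichment[cls == c])
    print(f"median E  {c:<8s} {med:6.2f}   (n = {(cls == c).sum()} bins)")
```

prints

```
alpha = 2.029  (input spike 0.100, IP spike 0.049)
median E  active     0.20   (n = 1226 bins)
median E  inactive   2.02   (n = 838 bins)
median E  PcG        9.97   (n = 346 bins)
```

The IP library's spike fraction is diluted from 0.100 to 0.049 because
genome-wide IP signal exceeds background; the normalization factor α ≈ 2
restores absolute scale, and the median per-bin enrichment of each class
recovers its configured IP multiplier — PcG bins sit ~10-fold over
background, ~5-fold over inactive chromatin.

The same analyses are available from the shell:

```sh
germchrom simulate --seed 1 --out-dir sim/
germchrom bins sim/segments.bed --chrom-sizes sizes.tsv --out bins.bed
germchrom chip-enrich sim/reads_ip.bed sim/reads_input.bed bins.bed --out enrich.tsv
germchrom domain-calls sim/segments.bed enrich.tsv --out calls.tsv
germchrom run --seed 1 --out-dir out/     # full pipeline + manifest
```

`germchrom run` writes segments, bins, enrichment tables (TSV + bedGraph),
domain calls and sharing summaries, expression fold-change tables, reporter
trajectories/contrasts, and a `manifest.json` with parameters and sha256
digests — two runs with the same config and seed are byte-identical.

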