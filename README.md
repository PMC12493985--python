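# eutromics

Tools for asking how coastal eutrophication reshapes benthic microbial
communities.  The package implements, as one tested pipeline, the standard
computational chain used in estuarine sediment microbiome studies:

* **Trophic status** — the TRIX index for overlying water,
  `TRIX = (log10(Chl-a · aD%O · DIN · P) + 1.5) / 1.2`, and the sediment
  organic-nitrogen / organic-index indicators (`ON = TN × 95%`,
  `OI = TOC × ON`) with their four pollution levels.
* **Community metrics** — observed richness, Chao1, Shannon, Simpson;
  Levins niche breadth `B_j = 1/Σ_i P_ij²` and its community mean Bcom;
  Bray–Curtis dissimilarity, distance–decay regression, mean pairwise
  phylogenetic distance, and FDR-thresholded Spearman co-occurrence
  networks (top-1000 OTUs, ρ > 0.6, q < 0.001).
* **Assembly inference** — the Sloan neutral community model
  `Freq_i = 1 − I(1/N | Nm·p_i, Nm(1−p_i))` fitted for the migration rate m,
  and the βNTI / RC_Bray null-model framework classifying site pairs into
  variable selection, homogeneous selection, dispersal limitation,
  homogenizing dispersal and undominated processes (|βNTI| > 2, |RC| > 0.95).
* **Life-history traits** — community-averaged 16S rRNA copy number, genome
  size and GC from single-copy-marker genome equivalents, codon usage bias
  as the inverse mean ENC′ of ribosomal genes, a calibrated maximal growth
  rate, and transposase content: the r- vs K-strategist toolkit for
  metagenome summaries.
* **Synthetic data** — generators for neutral (Sloan-distributed) and
  selection-structured metacommunities, chemistry within observed regional
  ranges (Yangtze River Estuary vs East China Sea), and genome communities
  with planted traits, so every estimator is testable closed-loop.

See `docs/methods.md` for models, conventions, defaults and limitations.

## Worked example

```python
import numpy as np
from eutromics.simulate import (
    simulate_chemistry, NeutralSimSpec, simulate_neutral_metacommunity,
    SelectionSimSpec, simulate_selection_metacommunity,
)
from eutromics.trophic import assess_water
from eutromics.assembly import fit_neutral_model, bnti, rc_bray, classify_processes

water, sediment = simulate_chemistry("YRE", 5, seed=42)
print(assess_water(water)[["site_id", "trix", "trix_class"]].round(2))

fit = fit_neutral_model(simulate_neutral_metacommunity(
    NeutralSimSpec(n_sites=24, n_taxa=500, n_individuals=20000, m=0.5, seed=42)))
print(f"NCM: m={fit.m:.3f} Nm={fit.nm:.0f} R2={fit.r_squared:.3f}")

table, tree = simulate_selection_metacommunity(
    SelectionSimSpec(n_sites=10, n_taxa=256, mode="homogeneous", seed=42))
z = bnti(table, tree, reps=999, seed=42)
rc = rc_bray(table, reps=999, seed=42)
result = classify_processes(z, rc)
print("median bNTI =", round(np.nanmedian(z.to_numpy()[np.triu_indices(10, 1)]), 2))
print(result.process_fractions)
```

prints

```
site_id  trix trix_class
  YRE00  6.26  eutrophic
  YRE01  6.26  eutrophic
  YRE02  5.97  eutrophic
  YRE03  6.47  eutrophic
  YRE04  6.38  eutrophic
NCM: m=0.562 Nm=11239 R2=0.728
median bNTI = -2.6
{'variable_selection': 0.0, 'homogeneous_selection': 0.822,
 'dispersal_limitation': 0.133, 'homogenizing_dispersal': 0.0,
 'undominated': 0.044}
```

Water drawn inside the eutrophic estuary's observed ranges scores TRIX > 5
(eutrophic) at every site; the neutral-model fit recovers the planted
dispersal parameter (true Nm = 10,000) from the simulated table; and
communities assembled under a shared environmental filter are dominated by
homogeneous selection (βNTI < −2), exactly the regime the simulator planted.

A command-line interface mirrors the library
(`eutromics trophic|diversity|assembly|traits|simulate|all`); every run
writes TSV result tables plus a JSON manifest recording the seed and all
thresholds used.

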