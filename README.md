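# motudelim

Molecular species delimitation for DNA-barcode reference libraries.

Given an aligned COI barcode matrix (fixed length, conventionally the
658-bp Folmer fragment) and a specimen table with morphospecies, genus and
tribe labels, `motudelim` runs the standard battery of distance-based and
tree-based delimitation methods and reconciles their molecular operational
taxonomic units (MOTUs) against the morphological identifications. It is
aimed at taxonomists and barcoding projects who need to ask, for a regional
library: which morphospecies are cleanly recovered as molecular clusters,
which hide deeply divergent (cryptic) lineages, and which pairs share
barcodes?

## Methods implemented

* **K2P / JC69 / p distances** with pairwise deletion. With `P` and `Q` the
  transition (A↔G, C↔T) and transversion mismatch proportions over the
  comparable sites of a pair,
  `d_K2P = −½ ln((1 − 2P − Q) √(1 − 2Q))` and
  `d_JC69 = −¾ ln(1 − 4p/3)`, plus rank-stratified summaries
  (within species / within genus between species / within tribe between
  genera / between tribes).
* **Furthest-neighbor (complete-linkage) MOTU clustering** at a threshold
  *t* (inclusive), a threshold sweep with plateau detection, and the
  conservative 3.6 % headline threshold with a 2.5–3.5 % "integrative
  taxonomy" zone whose excess MOTUs are flagged for morphological review.
* **Automatic barcode gap discovery (ABGD)**: recursive partitioning at the
  gap detected in ranked pairwise distances, over a log-uniform grid of
  prior intraspecific divergences (defaults Pmin = 0.001, Pmax = 0.1,
  10 steps, relative gap width X).
* **Neighbor joining** (Saitou–Nei) with deterministic tie-breaks, midpoint
  or outgroup rooting, newick I/O.
* **Poisson tree processes (PTP)**: two exponential branch-length classes
  (within-species rate λ_W, between-species rate λ_B) on a rooted tree;
  the species partition maximizing the profile log-likelihood is found
  exhaustively on small trees and by a DP-accelerated search on large ones.
* **Reconciliation**: every morphospecies is classified consistent / split
  / shared against any MOTU partition; species with maximum intraspecific
  divergence > 5 % are flagged as cryptic candidates.
* **Synthetic data**: a Kimura-model simulator that generates whole survey
  libraries with controlled intra/interspecific divergence structure and a
  known genealogy, used throughout the test suite.

## Worked example

Simulate a survey-shaped library (421 sequences, 84 morphospecies,
36 genera, 3 tribes) and run the full pipeline:

```python
from motudelim import study_shaped_config, simulate_dataset, run_pipeline

ds = simulate_dataset(study_shaped_config(seed=1))
report = run_pipeline(ds, out_dir="report")
print(report.motu_counts)
print(report.n_by_status(), report.n_consistent(), "/", len(report.classifications))
print([(f.morphospecies, round(f.max_intra, 2)) for f in report.cryptic_flags])
```

prints

```
{'furthest_neighbor@3.6%': 111, 'furthest_neighbor@2.5%': 155,
 'furthest_neighbor@3.5%': 113, 'abgd@P=0.0129': 187, 'ptp': 193}
{'consistent': 41, 'singleton_consistent': 36, 'split': 5, 'singleton_shared': 2} 77 / 84
[('Genus36_sp084', 6.21), ('Genus17_sp040', 5.54), ('Genus19_sp047', 5.05)]
```

Reading this: complete linkage at the 3.6 % threshold finds 111 MOTUs for
the 84 generated morphospecies — the species simulated with moderate
(2–4 %) internal divergence split, exactly the behavior the integrative
zone is meant to catch; 77 of 84 morphospecies are 1:1 consistent with
their MOTU; three species were generated with deep internal divergence and
all three are recovered as cryptic candidates (> 5 % maximum intraspecific
K2P). ABGD and PTP, as more sensitive methods, return finer partitions.
The `report/` directory holds the assignment tables, rank summaries, the
sweep curve, the midpoint-rooted NJ tree, and all flags as TSV/newick.

The same stages are available from the shell:

```sh
motu-delim validate --fasta lib.fasta --meta lib.tsv
motu-delim cluster  --fasta lib.fasta --meta lib.tsv --threshold 3.6 --out motus.tsv
motu-delim sweep    --fasta lib.fasta --meta lib.tsv --grid 0:8:0.1
motu-delim abgd     --fasta lib.fasta --meta lib.tsv --x 1.0
motu-delim njtree   --fasta lib.fasta --meta lib.tsv --root midpoint --out nj.nwk
motu-delim ptp      --tree nj.nwk --out species.tsv
motu-delim run      --fasta lib.fasta --meta lib.tsv --out report/
```

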