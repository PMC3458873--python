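# clinescan

Tools for asking whether geographic clines in allele frequency reflect
diversifying selection or merely demographic history.  Built for population
geneticists analysing one-dimensional transects — many loci (allozymes,
microsatellites, mtDNA, SNPs) typed across populations ordered by latitude —
where secondary contact between formerly isolated lineages can leave neutral
stepped clines that look exactly like selection.

The package provides:

* **Per-locus cline detection.**  For each locus a focal allele (the allele
  with maximal north-south Weir-Cockerham *F*<sub>ST</sub>) is fit with a
  four-parameter "twice-broken-stick" model of frequency vs latitude — two
  plateaus *p*<sub>S</sub>, *p*<sub>N</sub> joined by a linear segment
  between break latitudes *b*<sub>S</sub> < *b*<sub>N</sub> — and compared
  against a horizontal line by a likelihood-ratio test (binomial likelihood
  for count data; an exact F-test variant for least-squares fits).  The fit
  yields each cline's midpoint (*b*<sub>S</sub>+*b*<sub>N</sub>)/2 and slope
  (*p*<sub>N</sub>−*p*<sub>S</sub>)/(*b*<sub>N</sub>−*b*<sub>S</sub>).
* **Genomic Co-Co plots.**  Clinal loci that also show isolation by distance
  (one-sided Mantel test) are embedded at (midpoint, log|slope|); a
  cross-validated 2-D kernel density with 75/95/99% envelopes flags loci
  whose clines are significantly displaced (coincidence) or steeper/
  shallower (concordance) than the genomic consensus.
* **An fdist-style *F*<sub>ST</sub>-outlier scan** against a coalescent
  island-model null (100 demes, 11 sampled, infinite-alleles mutation,
  migration calibrated to a target mean *F*<sub>ST</sub> = 1/(1+4*N*m·(d/(d−1))²)
  inverted at 0.33), with conditional quantile envelopes of *F*<sub>ST</sub>
  given heterozygosity.
* **Neutral secondary-contact simulations**: an ancestor (Ne 100,000) splits
  100,000 generations ago into two isolated relicts, each expanding 10,000
  generations ago into 20 stepping-stone demes (Ne 2,500; 40 demes total)
  exchanging migrants at scaled rate 4*N*m ∈ {0.4, 4, 40} — the sceptic's
  baseline showing how much "selection" a purely neutral history produces.

Estimators follow scikit-learn conventions (`fit`/`predict`,
`get_params`/`set_params`, trailing-underscore fitted attributes) and
compose with sklearn tooling; every operation is also exposed as a plain
function, and a `clinescan` command line wires the workflows end to end.

## Worked example

```python
import numpy as np
from clinescan import (GeneratorSpec, generate_dataset, ClinalScreen,
                       CoCoOutlierDetector, coco_coordinates)

# a synthetic transect: 30 sites on 30-45N, 120 SNPs, half of them clinal
ds, truth = generate_dataset(GeneratorSpec(n_sites=30, n_loci=120,
                                           fraction_clinal=0.5, seed=42))

screen = ClinalScreen(seed=7).fit(ds)          # LRT + Mantel per locus
frame = screen.frame_
print(int(frame.is_clinal.sum()), "clinal,", int(frame.coco_eligible.sum()),
      "Co-Co eligible, median midpoint", round(frame[frame.is_clinal].midpoint.median(), 2))

points = coco_coordinates(frame[frame.coco_eligible])
detector = CoCoOutlierDetector().fit(points)   # CV bandwidth KDE + envelopes
report = detector.report(points)
print(int(report.outlier.sum()), "Co-Co outliers")
```

Output:

```
67 clinal, 61 Co-Co eligible, median midpoint 39.78
4 Co-Co outliers
```

67 of 120 loci are declared clinal — the 60 planted clines (power is ~1 at
these effect sizes) plus a handful of false positives from the unsupervised
break search.  Fitted midpoints concentrate near the planted 38-42°N band
(median 39.78°N).  Of the 61 loci passing both screening criteria, 4 fall
outside the 95% density envelope in (midpoint, log|slope|) space — about the
share expected by construction of the envelope, since this panel contains no
truly exceptional cline.

The same screen applied to *neutral* secondary-contact simulations
(`clinescan simulate --seed 1`, or `clinescan.simulate.percent_clinal`)
classifies roughly 36-50% of loci as clinal depending on dispersal — the
central caution: a strong signal of secondary contact mimics widespread
clinal selection, and the FST-outlier test (`clinescan fdist`) flags many
neutral loci as outliers for the same reason.

## Command line

```bash
clinescan synth --n-loci 200 --seed 1 --out data/       # fixture dataset
clinescan screen data/dataset.csv --seed 2 --out scr/   # per-locus screen
clinescan coco scr/screen.csv --out coco/               # Co-Co plot + outliers
clinescan fdist data/dataset.csv --seed 3 --out fdist/  # FST-outlier scan
clinescan simulate --seed 4 --out sim/                  # secondary-contact study
```

Every run logs its seed and config hash; identical seeds reproduce outputs
byte for byte.

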