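# ploidykit

DNA-ploidy inference for cardiac cell biology: an integrated pipeline that
quantifies nuclear DNA content from confocal DAPI z-stacks, calls ploidy
fractions from DNA-content flow cytometry, and profiles diploid versus
tetraploid cell populations with droplet scRNA-seq — together with seeded
synthetic-data generators that make every stage verifiable by parameter
recovery.

## Who this is for

Labs measuring ploidy of cardiomyocytes and c-kit+ cardiac interstitial
cells (cCICs) in tissue sections or fresh isolates. Polyploidisation is a
hallmark of cardiac stress and development, but in-situ measurements have
no per-cell ground truth; this package pairs each analysis step with a
generator that plants a known 2n/4n/8n composition, so recovery accuracy is
measurable before the method touches real data.

## The core statistic

For a nucleus segmented in a 3-D stack, the DNA-content proxy is the
widest-plane **fluorescence-intensity (FI) statistic**

```
FI = mean(DAPI intensity over the widest x-y ROI) x ROI area (pixels)
```

which is algebraically the DAPI pixel sum over the widest-plane ROI.
Calibration against a known-diploid reference turns FI ratios
r = FI / FI(2n) into classes via windows at the geometric midpoints of the
ideal 1x / 2x / 4x positions: r < 1.5 → 2n, 1.5 ≤ r < 3 → 4n, r ≥ 3 → >4n.
When signal *density* scales with DNA content, E[FI] is proportional to
ploidy; when nuclear *volume* scales instead, the widest-plane statistic
rises only as ploidy^(2/3) — both regimes are simulated, and the 3-D
integrated intensity is provided as the exact comparator.

Flow cytometry uses the same ratio windows after singlet gating (debris cut
below 0.3x the dominant peak; doublets flagged where log(area/width)
exceeds the singlet trend by 3 robust SDs) and KDE peak anchoring on log
area. scRNA-seq follows the standard droplet workflow: cells with < 1000
genes or > 10 % mitochondrial UMIs dropped, genes in < 3 cells dropped,
variable genes by binned dispersion z-score, 12 principal components,
marker-score cell typing (Col3a1 / Cd36 / Cd3e), Wilcoxon + BH differential
expression.

## Worked example

```bash
python examples/02_flow_cytometry_ploidy_calling.py
```

```
gate
singlet    20452
doublet     1101
debris       447

diploid peak position: 199.7 (channel units)
   2n: 54.51 %  (truth 54.51 %)
   4n: 41.89 %  (truth 41.80 %)
  >4n:  3.60 %  (truth 3.69 %)
```

22,000 simulated events at a mixed diploid/tetraploid composition with 5 %
doublets: gating removes the doublets (which would otherwise masquerade as
tetraploid events), the KDE anchors the diploid peak at channel ~200 where
it was planted, and the recovered fractions match the planted truth within
a fraction of a percentage point. The other examples cover image-based
quantification (`01`), scRNA-seq QC + typing (`03`) and the closed-form
assay statistics (`04`).

A thin CLI mirrors the library for shell use, e.g.

```bash
ploidykit simulate-flow --fractions 0.55,0.41,0.04 --n 10000 --seed 1 --out ev.csv
ploidykit flow-call --input ev.csv --anchor 2n
```

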