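# r3d

Analysis toolkit for chromatin-architecture reprogramming: from balanced
Hi-C contact matrices and ATAC peak intensities to A/B compartment calls,
TAD boundaries, chromatin loops, four-class reprogramming-dynamics labels
(Repro / Partial / Hyper / Resis), H3K9me3 ChIP/Input domain marking, and a
donor-vs-method switch taxonomy for comparing nuclear-transfer and iPSC
reprogramming. A synthetic-data module plants ground truth for every stage
so the whole pipeline is testable without downloads.

## Layout

| module | what it does |
| --- | --- |
| `r3d.contact` | load/balance binned matrices (triplet or dense text), expected profiles, O/E maps, contact-decay curves |
| `r3d.compartments` | PC1 compartment calling, saddle strength, switch calling, dynamics classification, NT-vs-iPSC process comparison |
| `r3d.domains` | insulation scores, boundary/TAD calling, aggregate boundary maps, relative TAD intensity (RTI), TAD dynamics |
| `r3d.loops` | donut-style focal loop calling with BH control, APA scoring, loop dynamics |
| `r3d.atac` | peak-matrix normalization, K-means C1–C3 clustering, C4/C5 differential subsets, genomic-context annotation |
| `r3d.integration` | ChIP/Input bin signal, region marking, Wilcoxon group comparisons, expression-by-structure, DEG overlap |
| `r3d.simulate` | truth-first synthetic generator for matrices, PC1/RTI trajectories, peak matrices, ChIP tracks, expression |

## CLI

All file formats are plain text (triplet/dense matrices, BED, BEDPE,
bedGraph, TSV). A few examples:

```sh
r3d simulate --outdir sim/ --seed 1              # synthetic 5-line series
r3d matrix balance --in sim/CC.triplet.tsv --out CC.bal.tsv
r3d matrix decay --in sim/CC.triplet.tsv --out curve.tsv
r3d compartments call --in sim/CC.triplet.tsv --activity sim/activity.txt --out pc1.bedgraph
r3d compartments dynamics --cc sim/CC.triplet.tsv \
    --nt sim/NT5.triplet.tsv --nt sim/NT6.triplet.tsv \
    --f sim/F35.triplet.tsv --f sim/F40.triplet.tsv \
    --activity sim/activity.txt --out dynamics.tsv --delta 0.15
r3d tads call --in tad_matrix.tsv --out tads.bed --res 40000 --window 480000
r3d tads rti --in tad_matrix.tsv --tads tads.bed --out rti.tsv --res 40000
r3d loops call --in loop_matrix.tsv --out loops.bedpe --res 20000 --fdr 0.1
r3d loops apa --in loop_matrix.tsv --loops loops.bedpe --out apa.tsv --k 5
r3d atac differential --peaks sim/peaks.bed --intensity sim/peak_intensity.tsv --out clusters.tsv
r3d mark --track chip.bedgraph --regions regions.tsv --out marked.tsv --ratio-min 2 --frac-min 0.5
```

## Conventions

* Bins are 0-based, half-open `[start, start + resolution)`; BED/BEDPE
  output follows the same convention.
* Compartment state A means oriented PC1 > 0 (sign fixed against a gene
  density or ATAC activity track); exact zero is NA.
* Default resolutions: 200 Kb compartments, 40 Kb insulation/TADs, 20 Kb
  loops (5 Kb supported).
* Dynamics thresholds: trajectory coordinate r = (nt − cc)/(f − cc) with
  delta = 0.15; TAD/loop Static fold = 1.5. All exposed as parameters.
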