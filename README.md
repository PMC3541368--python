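# nucleoshift

Quantitation toolkit for demonstrating agonist-induced nuclear translocation
of G-protein βγ subunits (here the β2 isoform, Gβ2) from two independent
measurement routes — label-free mass spectrometry and confocal microscopy —
plus the downstream bioinformatics that connects the translocated protein to
transcription: docking-motif scanning of transcription factors and
hypergeometric scoring of differential-transcript overlaps.

When a GPCR such as the angiotensin II type-1 receptor (AT1R) is activated,
a share of the cellular Gβ2 pool moves into the nucleus. Measuring that
shift quantitatively requires care on both sides: MS abundances must be
normalized against a spiked-in control peptide, and fluorescence must be
attributed to the nucleus through an explicit, auditable mask. This package
implements those procedures as a tested library, together with a synthetic
data generator that plants known ground truth (elution peaks, nuclear
fractions, motif positions, set overlaps) so the whole pipeline can be
validated end-to-end without instrument data.

## What it computes

**MS quantitation** (`nucleoshift.msquant`). PSM evidence filtering
(inclusive thresholds: ≥15 product ions, ion score ≥30, ≥1 manually
validated signature peptide per protein), spectrum counting, and the
spike-in-normalized extracted-ion-chromatogram fold change

```
fold = (target treated apex / target control apex)
     / (spike-in treated apex / spike-in control apex)
```

where each apex is the chromatogram's "100% abundance" value inside its m/z
window. The worked reference case is a target ratio of 2.47 over a spike-in
ratio of 0.79, i.e. a 3.13-fold nuclear increase. A peptide m/z calculator
(monoisotopic or average) checks that instrument windows actually cover the
monitored peptide.

**Confocal colocalization** (`nucleoshift.imgquant`). Per-slice
threshold-and-binarize of the nuclear-stain (DAPI) channel, plane-by-plane
multiplication of the binary mask with the signal (FITC) channel, and the
nuclear fraction

```
f = Σ signal inside mask / Σ signal        (intensity mode)
f = #signal-positive voxels inside mask / #signal-positive voxels   (pixel mode)
```

with the treated/untreated ratio of fractions as the translocation fold,
per-nucleus statistics via 26-connected components, and 5× z-upsampling for
rendering flattened nuclei.

**Motif scanning** (`nucleoshift.motifscan`). Exact (optionally Hamming)
scanning for the LLTPPG phosphopeptide docking motif that several nuclear
proteins use to engage the central canal of WD40 β-propellers, and
positive/negative classification of a transcription-factor panel.

**Enrichment scoring** (`nucleoshift.enrich`). The network score
`-log10 P(X ≥ k)` for a right-tailed hypergeometric overlap test, computed
in log space so scores of 40+ (p ≈ 1e-41) are exact, and exact three-way
Venn partitioning of differential-transcript ID sets.

**Synthetic ground truth** (`nucleoshift.synthdata`) and a reproducible
orchestrator (`nucleoshift.pipeline`, CLI `nucleoshift`).

## Worked example

`python examples/ms_fold_change.py` simulates the four chromatograms and
prints:

```
target control  apex = 1.003e+06
target treated  apex = 2.476e+06
spike  control  apex = 9.960e+05
spike  treated  apex = 7.841e+05
target ratio      : 2.468   (treated/control, target peptide)
spike-in ratio    : 0.787   (corrects loading/instrument drift)
normalized fold   : 3.14   (planted: 2.47/0.79 = 3.13)
```

The target peptide's abundance roughly doubles-and-a-half while the
spike-in (which should not change) reads 0.79 — dividing by it corrects the
run-to-run loading difference and yields the ~3.1-fold nuclear increase.
`python examples/image_translocation.py` makes the same estimate from
images:

```
untreated planted 0.10  realized 0.1000  recovered 0.1005  (5 nuclei)
treated   planted 0.40  realized 0.4000  recovered 0.3864  (5 nuclei)
translocation fold = 3.84  (planted 0.40/0.10 = 4.0)
```

and `python examples/end_to_end.py` runs every stage under one seed and
confirms the MS and imaging fold estimates agree to within a few percent.
The other examples cover the motif panel (4 of 6 proteins positive, exactly
the planted ones) and the Venn/score bookkeeping (800 and 705 transcripts
sharing 299 → partition 501/406/299).

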