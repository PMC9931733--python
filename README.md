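# aqpolar

Analysis pipeline for studying **aquaporin-4 (Aqp4) mRNA polarization** at
astrocyte endfeet in Visium-style spatial transcriptomics of mouse brain,
with companion tools for astrocyte-endfoot gene screening, gene-set
scoring, and immunofluorescence quantification of AQP4-coated vessels.

## The scientific problem

AQP4 water channels are normally concentrated ("polarized") in astrocyte
endfeet that wrap brain capillaries; loss of this polarization impairs
glymphatic clearance and accompanies Alzheimer's disease. Spatial
transcriptomics can probe the mRNA side of this biology: spots covering
the vessel/blood–brain-barrier (BBB) compartment and spots covering
adjacent astrocytes can be compared to ask how much of a gene's mRNA has
been trafficked toward the endfoot.

The pipeline implements that comparison for a three-group mouse design
(wild-type `WT`, the APP/PS1 Alzheimer's model, and moxibustion-treated
APP/PS1 — `APP/PS1+MOX`):

1. **Gating** — astrocyte (AC) spots are those with *Gfap* > 0 and
   *Aqp4* > 0 outside CSF-facing regions (glia limitans, ependyma, choroid
   plexus); BBB spots have *Pecam1* > 0 and *Flt1* > 0 outside the
   choroid plexus. Spots passing both gates count as BBB.
2. **Pairing** — each AC spot is matched to BBB spots among its six
   hex-lattice neighbours; AC spots with no BBB neighbour are dropped
   ("perivascular AC" remain).
3. **Gene ratio** — for AC count $a$ and adjacent BBB count $b$ of a gene,

   $$\mathrm{ratio} = \max_{b \in \mathrm{neighbours}} \frac{b}{a+b} \in [0,1],$$

   the share of the pair's transcripts on the vessel side — a per-spot
   polarization statistic. Group effects are summarised as fold changes
   of group mean ratios with one-way ANOVA and LSD post-hoc tests.
4. **AEG screening** — astrocyte marker genes (cell-type reference fold
   change > 100 over other vascular cell types) that are endfoot-positive
   (ratio > 0) in more than 60% of perivascular AC are *astrocyte endfoot
   genes*; those whose mean-ratio fold change moves more than 0.15 from 1
   in APP/PS1 are *AD-related AEGs*.
5. **Gene-set scores** — binned-control module scores (e.g. for the
   GO:0090660 cerebrospinal-fluid-circulation set), with thresholded
   group comparisons.
6. **Vessel coating** — in CD31/AQP4 immunofluorescence rasters, vessels
   are CD31-positive components enclosing a lumen; a vessel is
   AQP4-coated when more than a quarter of its perimeter lies near
   top-1%-intensity AQP4 signal.

A first-class synthetic-data module simulates all inputs with known
ground truth (true endfoot share π per gene and group), so every stage is
tested by parameter recovery rather than by fixtures.

## Worked example

```python
from aqpolar import synthdata, gating, polarization

params = synthdata.SynthParams(lattice_rows=60, lattice_cols=60, seed=1)
bundle, truth = synthdata.generate_tissue(params)

cls = gating.gate_spots(bundle)
adjacency = gating.find_adjacent_pairs(cls, bundle)
table = polarization.build_ratio_table(bundle, adjacency, ["Aqp4"])
summary = polarization.summarize_ratios(table, reference_group="WT")
print(summary[["group", "n", "mean_ratio", "fold_change",
               "anova_p", "lsd_p_vs_ref"]].round(4).to_string(index=False))
```

prints

```
      group   n  mean_ratio  fold_change  anova_p  lsd_p_vs_ref
    APP/PS1 122      0.4532       0.6447      0.0           0.0
APP/PS1+MOX 102      0.6160       0.8764      0.0           0.0
         WT 115      0.7030       1.0000      0.0           NaN
```

The generator's wild-type Aqp4 endfoot share is 0.7 with a disease
multiplier of 0.66 and a treatment multiplier of 0.9; the recovered WT
mean ratio (0.703) and fold changes (0.645, 0.876) estimate exactly those
quantities from the simulated counts. The ANOVA/LSD p-values show the
group separation is overwhelming at these sample sizes.

The same stages are available from a shell:

```bash
aqpolar demo --out-dir results/demo --seed 7   # end-to-end run
aqpolar simulate --out bundle --seed 1
aqpolar ratio bundle --out-dir results --gene Aqp4 --reference WT
```

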