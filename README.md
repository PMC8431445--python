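# melcpipe

Single-cell analysis of cyclic multiplex immunofluorescence (MELC) imaging.

MELC (Multi-Epitope-Ligand Cartography) images the same tissue section
through repeated cycles of antibody staining, fluorescence imaging and
photobleaching, yielding one grayscale image per protein marker on the same
cells — here a 20-plex panel on bone-marrow mononuclear cells, built to find
disseminated neuroblastoma tumor cells among hematopoietic and stromal
cells.  Raw cycle images carry systematic artifacts that corrupt per-cell
quantification: fixed illumination patterns, radial vignetting, residual
signal surviving each photobleach, unspecific antibody binding, and
batch-to-batch staining variation.  `melcpipe` turns such an acquisition
into a quantified, clustered single-cell atlas, and ships a simulator that
generates acquisitions with planted ground truth so that every stage can be
validated end to end.

## Pipeline

For an acquisition of cycles *c* with tag images *I_c*, post-bleach images
*B_c*, phase-contrast images *P_c* and calibration images (brightfield *F*,
darkframe *D*):

1. **Correction** (`melcpipe.correction`) — rigid registration of every
   cycle to a reference via phase correlation on *P_c*; flat-field
   correction `(I − D) / (F − D) · mean(F − D)`; bleach subtraction
   `max(I_c − B_{c−1}, 0)`; vignetting correction by a mean-normalized gain
   field estimated from the whole tag stack (per-pixel median + heavy
   Gaussian smoothing), or supplied as a precomputed map.
2. **Segmentation** (`melcpipe.segmentation`) — labeled nucleus mask from
   the nuclear-stain image and labeled cell mask from its phase-contrast
   image (classical baseline: smooth → Otsu → distance-transform watershed;
   externally produced masks, e.g. from a trained network, load in their
   place).  A cell is kept only if a nucleus is reproduced inside it (>50%
   of nucleus pixels); polygon exclusion regions remove artifact areas.
3. **Features** (`melcpipe.features`) — per cell: 6 morphological features
   (cell size/perimeter; nucleus size/perimeter/roundness 4πA/P²/solidity)
   and, per marker, 9 intensity features — mean (ME), total (TO) and mean of
   the top 20% pixels (M20) in nucleus, whole cell and cytoplasm/membrane
   (cell − nucleus).
4. **Normalization** (`melcpipe.normalization`) — division by the paired
   negative-control channel per cell (unspecific secondary binding), then
   division by a per-image background level b estimated from a mutually
   exclusive counterpart marker (batch correction; 1.0 = background).
5. **Feature validation** (`melcpipe.cluster_eval`) — consensus clustering
   (repeated feature subsampling → z-score → t-SNE → Gaussian mixture)
   scored by PAC, concordance CON, mean silhouette MSS and

   MCS = ((1 − PAC) + CON + MSS) / 3,

   plus per-feature ANOVA F-tests (Benjamini–Hochberg) and PCA feature
   contributions.
6. **Atlas** (`melcpipe.atlas`) — t-SNE embedding (perplexity 30), Gaussian
   mean-shift clustering of the embedding, min-max-scaled median cluster
   profiles, complete-linkage sub-clustering, per-sample composition.
7. **Simulator** (`melcpipe.synthetic`) — plants non-overlapping cells
   (elliptical, optionally notched nuclei + cytoplasm rings) with per-type
   marker signatures, renders cycles with vignetting, bleach residuals,
   unspecific binding, batch gain and Poisson/Gaussian noise, and scores
   pipeline outputs against its truth (segmentation F1 at IoU 0.5, adjusted
   Rand index vs planted types, expression correlation).

## Worked example

```bash
cat > config.yaml <<EOF
seed: 0
synthetic: {n_cells: 300, image_size: 560}
correction: {smoothing_scale: 60, min_images: 6}
EOF
melcpipe run --config config.yaml --out out/
```

prints the recovery report of the simulated run:

```json
{
  "ari": 1.0,
  "expression_corr": 0.992,
  "segmentation_f1": 0.987
}
```

meaning: the atlas clusters reproduce the planted cell types exactly
(adjusted Rand index 1.0), measured mean cell intensities correlate with the
planted per-cell expression at r = 0.99, and 98.7% object-level F1 of the
reconciled cell mask at IoU 0.5.  `out/` holds every stage's artifacts:
corrected TIFFs, label masks, the cell table, raw and normalized feature
CSVs (plus FCS export), the t-SNE/cluster atlas, cluster profiles and
composition tables.  Re-running with the same config reproduces the feature
CSVs byte-identically.  Individual stages run as subcommands (`simulate`,
`correct`, `segment`, `features`, `normalize`, `evaluate`, `atlas`), and
`melcpipe panel-info <panel.yaml>` summarizes a panel — the packaged 20-plex
panel reports 20 steps and a 908.1 µm field of view (2018 px × 0.45 µm/px).

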