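# radimm

Radiomic–immunologic correlates of the glioblastoma (GBM) microenvironment.

GBM lesions are spatially heterogeneous on MRI (necrosis, contrast-enhancing
tumor [CET], non-enhancing tumor [nCET], and edema) and immunologically
heterogeneous in their myeloid infiltrate: blood-derived macrophages (BMDM,
CD45⁺/CD33⁺/HLA-DR⁺/CD49d⁺) dominate the tumor center while brain-resident
microglia (MG, CD49d⁻) dominate the margin. Because BMDM are strongly
immunosuppressive, the **BMDM/MG ratio** is a compact index of how
tumor-permissive the microenvironment is — and it can only be measured from
resected tissue. `radimm` implements an analysis chain that asks whether
pre-operative imaging carries a non-invasive surrogate of that index:

1. **Radiomics.** Each of five co-registered images (T1w, Gd⁺ T1w, T2w,
   FLAIR, ADC) is min/max-normalized against normal-appearing intracranial
   tissue, then a fixed 68-feature schema is extracted: per compartment the
   ROI volume and ICV-normalized volume, plus mean, SD and *fractality* of
   the normalized intensity per image. Fractality is the threshold-averaged
   3D box-counting dimension: binarize the ROI at 9 equally spaced levels
   between its intensity extremes and average the least-squares slope of
   log N(s) vs log (1/s) over the level sets.
2. **Dimensionality reduction.** The 17 features of each compartment (and
   all 68 jointly) are z-scored and decomposed by PCA; components up to 80%
   cumulative variance are retained for interpretation. Loading matrices are
   compared across compartments with a structural similarity index (SSIM,
   0–1), and PC scores are cross-correlated.
3. **Immunology.** Specimen-level flow-cytometry frequencies are aggregated
   per subject and sampling site (necrosis / core / margin, defined
   intraoperatively by 5-ALA fluorescence), the BMDM/MG ratio is computed
   from averaged frequencies, and site gradients are tested with
   Kruskal–Wallis and Mann–Whitney.
4. **Correlation.** Pearson correlation between every imaging PC score set
   and the site-wise BMDM/MG ratio over pairwise-complete subjects.

Because no patient data are distributed, a seeded synthetic-cohort
generator produces MR phantoms (nested ellipsoidal compartments with a
per-subject lesion-texture latent) and site-labelled immune frequencies
with a plantable Gaussian-copula coupling between the core-site ratio and
the texture latent — so the whole chain is testable against known ground
truth. See `docs/methods.md` for the model and its limitations.

## Worked example

The numbered drivers under `analysis/` run the default study (62 subjects,
seed 7) and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_extract_features.py
python analysis/03_imaging_pca.py
python analysis/04_immune_profile.py
python analysis/05_correlate.py
```

`03_imaging_pca.py` prints:

```
components needed for 80% of variance: {'necrosis': 6, 'CET': 6, 'nCET': 6, 'edema': 6, 'all': 8}
variance explained by PC1 (%): {'necrosis': 29.6, 'CET': 32.4, 'nCET': 36.8, 'edema': 29.7, 'all': 31.0}
cross-tissue loading similarity: 0.38 - 0.65 (1 = identical loading structure)
```

i.e. ~6 components summarize each compartment, and the modest cross-tissue
loading similarity means the compartments carry non-redundant information.
`05_correlate.py` then recovers the planted signal — and only where it was
planted (the generator couples the *core*-site ratio to lesion texture at
rank correlation −0.4):

```
375 (tissue set, PC, site) rows; 7 significant within the 80%-variance cut:
  necrosis PC1 vs     core ratio: r=-0.35, p=0.00768, n=57
       CET PC1 vs     core ratio: r=-0.33, p=0.0118, n=57
      nCET PC1 vs     core ratio: r=-0.26, p=0.0486, n=57
     edema PC1 vs     core ratio: r=-0.37, p=0.00414, n=57
       all PC1 vs     core ratio: r=-0.35, p=0.00728, n=57
  ...
significant rows per site (coupling is planted at the core only):
core        5
margin      1
necrosis    1
```

Rougher lesion texture (higher SD, lower threshold-averaged box-count
dimension) predicts a higher core BMDM/MG ratio, so the first PC of every
compartment correlates negatively with it at r ≈ −0.3 … −0.4; margin and
necrosis sites stay at chance level. The same functions are available from
the shell via the `radimm` entry point (`simulate`, `extract-features`,
`pca`, `immune-summary`, `correlate`, `report`).

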