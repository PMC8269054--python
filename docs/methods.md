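# Methods

## Scope and data model

`msirisk` analyzes centroided MALDI-MSI peptide data. A dataset is a set of
pixels on a unit grid (physical raster pitch is metadata only), each with a
strictly increasing m/z array and non-negative intensities. Pixel
coordinates are 0-based internally; imzML's 1-based indices are shifted on
read and restored on write. Intensities are stored as float32, m/z as
float64, matching common imzML practice. Group labels are restricted to
`HR` / `nHR` / `unknown`; mapping from clinical "high" versus
"low/intermediate" risk happens when ROI annotations are loaded.

## Preprocessing

**TIC normalization.** Each pixel is scaled so its total ion count equals
the dataset-mean raw TIC. Zero-TIC pixels are left at zero and flagged.
Because the target is the *mean* TIC, a per-pixel multiplicative
perturbation of the input changes the output only by a single global
factor; every downstream statistic used here (rank-based AUC and Wilcoxon,
correlation distance, Pearson correlation, level-scaled PCA) is invariant
to that global factor.

**Peak finding.** Peaks are detected on the dataset-wide mean spectrum
(accumulated on a 0.01 Da grid, padded ≥ 1 Da beyond the outermost signal
so edge peaks remain local maxima), not per pixel — mirroring alignment
across a whole study. Noise reduction is a Gaussian smoothing of the mean
spectrum only (default sigma 0.05 Da); pixel intensities are never
smoothed, preserving quantitation. The noise level is the scaled median
absolute deviation of the mean spectrum's residual against a 1 Da median
filter, floored at a tiny fraction of the maximum to keep the threshold
meaningful for noiseless synthetic input. A peak is a local maximum
exceeding `snr_threshold` (default 3) times that noise level.

**Alignment.** Detected centers are binned into half-open fixed-width
intervals `[c − w/2, c + w/2)` with w = 0.3 Da by default. Centers closer
than one width merge at their intensity-weighted mean, repeatedly, until
all adjacent interval centers are ≥ w apart — so the intervals partition
the axis. The per-pixel interval value is the **maximum** intensity inside
the window ("maximal interval processing"), never a sum or mean.

## Segmentation

Bisecting k-means with correlation distance d(a, b) = 1 − ρ(a, b). Each
spectrum is centered and scaled to unit norm, after which
‖ã − b̃‖² = 2 · d(a, b); standard Lloyd 2-means on the transformed rows
therefore minimizes within-cluster correlation dispersion, and cluster
labels are invariant to per-pixel intensity rescaling. Design choices where
the method is underdetermined:

- *Which cluster to bisect next:* the one with the largest within-cluster
  dispersion (sum of squared distances to its transformed centroid) — the
  standard bisecting criterion.
- *Initialization:* a deterministic farthest-pair start plus
  `n_restarts` (default 10) k-means++-style seeded restarts; the best
  split by dispersion wins. Fixed seeds make results reproducible.
- *Zero-variance spectra:* Pearson is undefined, so they map to the zero
  vector, which sits at distance 1 from everything — a deterministic
  fallback, reported with a warning.
- *Number of clusters:* taken as a parameter. `silhouette_by_k` reports a
  silhouette-versus-k table so "one versus three subpopulations" findings
  can be framed as explicit model selection rather than an implicit
  stopping rule.

Each bisection cannot increase total dispersion (children use their own
optimal centroids), which the dendrogram records and tests assert.

## Screening

The statistical unit is the pixel, as is standard in MSI discovery work;
pixels within a tissue are not independent, so p-values are screening
scores, not population-level inference (pseudoreplication caveat). Groups
are balanced by randomly subsampling an equal number of spectra per group
(with replacement when a group is small) before scoring.

- **AUC** is the Mann–Whitney U statistic divided by n₁n₂, ties counted
  0.5. HR is the positive class, so AUC > 0.5 means higher intensity in
  high-risk tissue. AUC is invariant under strictly monotone intensity
  transforms, and AUC(pos, neg) + AUC(neg, pos) = 1 exactly.
- **Wilcoxon rank-sum** (two-sided) is applied to intervals with AUC > 0.7
  or < 0.3. Small tie-free samples (both groups ≤ 50) use the exact null
  distribution of the rank-sum statistic; larger or tied samples use the
  normal approximation with tie correction — the same policy as R's
  `wilcox.test`. All-equal inputs give p = 1.
- **Candidate rule:** p < 0.001 plus, when ion-image correlation ratios
  are supplied, ratio ≥ 0.30. No multiple-testing correction is applied;
  the fixed p < 0.001 cut *is* the screen, and the null false-flag rate is
  verified by simulation instead. A stricter screen (AUC > 0.8 or < 0.2)
  selects the input set for PCA.
- **PCA** uses level scaling, (x − mean)/mean per interval over included
  pixels, which emphasizes relative changes; zero-mean intervals are
  dropped with a warning. Loadings come from the eigendecomposition of the
  scaled covariance with a deterministic sign convention
  (largest-magnitude loading positive). Five components by default;
  explained-variance fractions are non-increasing and sum to ≤ 1.

## Protein assignment

An MSI interval matches an identified peptide when
|m/z − [Mr+H⁺]| < 0.3 Da (strict) and the identification's MOWSE score is
> 13 (strict). Both masses are singly protonated, so no charge
deconvolution is performed. Per (interval, protein) only the
smallest-deviation row survives, ties broken by the higher score. One
interval may match peptides of different proteins; the multiplicity and
correlation rules arbitrate rather than a uniqueness constraint.

The "correlation ratio" of a member peptide is defined here as its maximum
pairwise Pearson correlation, over ROI pixels pooled across samples,
with the other member intervals of the same protein — the reading that
makes a one-coefficient-per-row report computable. Members below 0.30 are
dropped; a protein is accepted only if ≥ 2 members remain. Zero-variance
ion images yield an undefined coefficient, reported as 0 with a flag.
Shrinking the mass window can only remove matches (monotonicity, tested).

## Risk rules

The classifier is a total function onto
{low, intermediate, high, indeterminate}:

- MYCN amplification ⇒ high at every stage and age. "Mosaic" MYCN is
  treated as not amplified, with a warning.
- Stage 4: ≥ 18 months ⇒ high (also without amplification); < 18 months,
  not amplified ⇒ intermediate. The 18-month cut is compared with ≥ on the
  month scale (ages are carried in years and multiplied by 12).
- Stage 3: 1p deletion/imbalance ⇒ intermediate at any age; 1p normal ⇒
  low below 24 months, intermediate at ≥ 24 months.
- Stages 1/2 and 4s: low with 1p normal (stage 2 with deletion ⇒
  intermediate); combinations the rule grid does not cover — e.g. stage 1
  with 1p deletion, or 4s beyond 18 months — return an explicit
  `indeterminate` rather than a silent default, as does any branch that
  needs an unavailable 1p status.

Cohort validation optionally assumes 1p normal where a branch requires it
and the table omits the column, since clinical summary tables often do.

## Synthetic data generator

The generator emulates the study conditions the pipeline targets, with
defaults chosen once as a realistic small two-group imaging study:

| parameter | default | meaning |
|---|---|---|
| grid | 28 × 28 px | one tissue section per sample |
| samples | 4 per group | HR and nHR |
| m/z range | 800–3200 Da | tryptic peptide detection range |
| peaks | 40 background + 10 discriminative | ≥ 0.6 Da apart |
| effect size | 2.0 | fold change of planted peaks in HR tumor regions |
| subclones | 3 in HR, 1 in nHR | latent spatial subpopulations |
| proteins | 3 × 2 peptides | shared spatial template per protein |
| noise | additive truncated Gaussian, sd 5 a.u. | bases ~ lognormal, median ≈ 100 |
| TIC factor | uniform 0.6–1.6 per pixel | what TIC normalization removes |

Tissue structure comes from thresholded smoothed random fields: a
contiguous tumor-rich blob (~55% of pixels) against stroma, and HR tumor
pixels partitioned into spatially smooth subclones by quantile bands of a
second smooth field (guaranteeing non-empty, pairwise-distinct subclones
whose signatures are multiplicative factors on a dedicated marker-peak
subset shared across HR samples). Protein peptides share one spatial
template per protein, rescaled to mean 1 within each sample's tumor
region; peptides of one protein also share their planted direction and
stromal attenuation, so noiseless same-protein ion images are exactly
proportional (Pearson r = 1) and the pooled tumor-region group-mean ratio
of every planted peak equals the configured effect size exactly in the
noiseless limit. Spectra are emitted directly as centroided peak lists —
the pipeline operates on aligned intervals, so profile-mode peak shapes
would add cost without exercising new logic.

What the generator does **not** emulate: isotope envelopes, matrix
clusters, mass-calibration drift, chemical background, spatial intensity
gradients within compartments, or patient-level biological variance
between samples of one group. Passing recovery tests therefore shows the
statistics behave correctly under the stated noise model, not that the
pipeline is robust to every artifact of real acquisitions.

Because subclones exist only in HR tumors, subclone-marker peaks are
genuinely group-discriminative; a fully null configuration therefore sets
`effect_size=1` *and* `subclone_count_hr=1`.

## Numerical choices and degenerate inputs

- Strict inequalities where thresholds are strict: mass window < 0.3,
  MOWSE > 13, p < 0.001; correlation uses ≥ 0.30.
- Half-open binning intervals make the m/z axis a partition; overlapping
  interval sets are rejected.
- Report-layer rounding (deviations and AUCs to 2 decimals) never feeds
  back into matching decisions.
- Deterministic seeds everywhere; the pipeline derives per-stage seeds
  from one master seed via CRC-tagged `SeedSequence`, so a config + seed
  fully determines all deterministic outputs.
- Problem sizes in the test suite (28 × 28 grids, 4 + 4 samples, ≤ 2500
  null intervals, ≤ 12-spectrum exhaustive oracles) are chosen so the
  oracles stay exhaustive and the planted-recovery checks are
  well-powered at desk scale.

## Known limitations

- Pixel-level testing overstates significance for patient-level claims;
  the package reports it as the method defines it and documents the
  caveat.
- The exact noise-reduction kernel of commercial MSI software is
  proprietary; Gaussian smoothing during peak finding is this package's
  own, stated choice.
- Cohort-scale outcomes (total aligned peak counts, significant-peak
  counts, explained-variance percentages) depend on the acquisition and
  cohort and are not reproduced by synthetic data; the worked-example
  tables cover the deterministic rule-based results instead.
- imzML writing delegates to pyimzml, which stamps a fresh UUID per file;
  reproducibility is at parsed-content level, not byte level.
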