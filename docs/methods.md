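# Methods

`hspcmap` implements a protocol for comparing the CD34+ (hematopoietic stem
and progenitor, HSPC) compartments of bone-marrow samples by multicolor flow
cytometry: pre-gating, biexponential scaling, a merged t-SNE embedding,
gate-based phenotype assignment, and a quantitative sample classification
based on the Pearson correlation of embedding density matrices. This note
records the model assumptions, parameter choices, and numerical conventions
the implementation commits to.

## Pre-gating

Each sample's white-blood-cell events pass through six sequential gates:
an FSC-A/SSC-A scatter polygon, a CD45/SSC-A polygon, doublet exclusion,
dead-cell exclusion, a gate-of-interest (GOI) polygon that removes the
granulocyte cloud, and finally a CD34 positivity threshold. Conventions:

- **Polygon membership** is boundary-inclusive, even-odd rule (shapely on a
  validated simple polygon). The scatter-plane polygons ship as config
  defaults calibrated to the synthetic populations; in a real laboratory
  setting they would be drawn per panel.
- **Doublet rule.** The protocol names the step but not a rule; we use the
  standard FSC-A/FSC-H ratio window: an event is a singlet when
  FSC-A ∈ (1 ± 0.3) × FSC-H. Events with nonpositive FSC-H are dropped.
- **Viability boundary.** Events exactly at the viability-dye threshold
  count as dead (strictly-below retention). The boundary convention is
  arbitrary but must be fixed for reproducibility; we pick the conservative
  side.
- **GOI channel pair.** The gate of interest is a CD34 vs SSC-A polygon by
  default; the protocol's own axes are not specified, and CD34/SSC is the
  conventional plane for separating CD34+ blasts from granulocytes.
- **Cell cap.** After gating, at most 1000 cells per patient enter the
  merged matrix (uniform random subset, order-preserving, seeded). This
  prevents high-cellularity samples from dominating the joint embedding;
  per-patient CD34+ yields realistically span 10² to 2×10⁵.

## Scaling and embedding

Fluorescence is scaled with the inverse hyperbolic sine,
f(x) = asinh(x / c), cofactor c = 150 a.u. per channel. This is the
biexponential display scale in its analytically simplest form: linear for
|x| ≪ c, logarithmic for |x| ≫ c (decades are ln 10 apart), odd, and defined
for negative values. The cofactor is a display-scale choice, not a fitted
parameter; 150 suits the synthetic intensity ranges (positivity cutoff
300 a.u. ≈ 1.44 scaled).

All patients' gated, scaled CD34+ cells are merged into one expression
matrix over the five analysis markers (CD34, CD38, CD45RA, CD123, PD-L1)
with `patient_id` and `group` appended per row, so the joint embedding can
be split back into per-group and per-patient views that share one
coordinate system.

The embedding is Barnes–Hut t-SNE (scikit-learn), perplexity 70,
3000 iterations by default, run on the PCA projection of the scaled markers
capped at 50 components (a no-op with five markers; the cap is kept for
generality). Initialization is the first two principal components rescaled
so PC1 has standard deviation 1e-4 — the established recipe for stabilizing
global structure. PCA component signs follow the largest-|loading|-positive
convention, making the whole pipeline bit-reproducible for a fixed seed
(`n_jobs=1`). Learning rate and exaggeration stay at library defaults and
are recorded in the run log. t-SNE coordinates are unitless; plots omit
axis labels and no distance in the embedding is interpreted metrically.

## Gates on the embedding and phenotype assignment

Polygon gates in (tSNE1, tSNE2) are drawn once on the remission-only view
of a reference embedding and transferred verbatim (identical vertices) to
the combined and active-disease views. Gates must be pairwise disjoint;
ambiguous membership is a hard error, not silently resolved. A watershed
helper proposes candidate gates from local density maxima, but it is
explicitly non-canonical — the analyst's versioned gate set is the input of
record. The shipped `synthetic_reference_gates.yaml` is such a proposal on
a synthetic reference embedding, for illustration only.

Each gate is assigned one phenotype from its gate-level marker means
(not per-cell calls), using scaled-intensity cutoffs:

| CD38 | CD45RA | CD123      | label   |
|------|--------|------------|---------|
| −    | −      | any        | HSC/MPP |
| −    | +      | any        | CLP     |
| +    | −      | −          | MEP     |
| +    | −      | low        | CMP     |
| +    | −      | +          | Other   |
| +    | +      | −          | Other   |
| +    | +      | low or +   | GMP     |

"low" is weakly positive: above the negativity cutoff but at most the
CD123 low-band upper bound (defaults 300 and 2000 a.u. raw). Two closures
the source table leaves open are fixed here: in the CD45RA+ branch CD123
"low" counts as positive (GMP), and CD123 above the low band in the
CD45RA− branch is unnamed, hence "Other". HSC and MPP are merged — they
differ by CD90, which the panel lacks. The CLP rule (CD38− CD45RA+) is kept
as the protocol defines it even though other CLP definitions exist. PD-L1
is summarized but never classifies. Numeric cutoffs are config values; the
defaults are calibrated to the synthetic generator, since the protocol does
not publish its limits.

## Density pictures and Pearson similarity

A t-SNE view is quantified on a fixed grid: 100×100 bins over the combined
embedding's bounding box padded by 2% per side (so every subset shares the
grid and no cell falls outside; boundary cells belong to edge bins). The
raw picture is a 2-D histogram; by default it is blurred with a Gaussian of
1 bin width. The blur is implemented as a *source-normalized* kernel — each
source pixel's kernel is divided by its in-grid mass before convolution —
which keeps the operator linear (pictures of disjoint subsets still add
pixel-wise, exactly) and exactly mass-conserving (entry sum = cell count).
Ordinary reflect or constant padding satisfies only one of those two
properties.

Two pictures A, B with pixel densities A_j, B_j (j = 1..N) are compared by

    r(A,B) = cov_{A,B} / (σ_A σ_B)
    cov_{A,B} = Σ_j A_j B_j − (Σ_j A_j)(Σ_j B_j)/N
    σ_X = sqrt(Σ_j X_j² − (Σ_j X_j)²/N)

computed exactly in this sum form (it matches the textbook product-moment
correlation; the test suite checks agreement to 1e-12 on random pictures).
r(A,A) = 1; complementary-support pictures give r = −1; r is invariant
under positive affine rescaling of either picture, so pictures are compared
unnormalized. A picture with zero pixel variance has no defined
correlation and raises an error rather than returning a value. Plot
rendering (only) normalizes density to the per-plot maximum.

## Leave-one-out classification

For each sample N, reference pictures ∑AD and ∑CR are built from all
active-disease and remission cells *excluding N*; N stays in the joint
embedding (its coordinates have to come from somewhere, and placing new
cells into a frozen map is out of scope). N is called for the group whose
reference correlates higher; |r_CR − r_AD| ≤ 1e-9 is a tie and yields
"unclassified" rather than a forced call. A variant excludes listed
samples from references and records (recomputed on the same embedding), and
a stricter variant re-runs the embedding freshly per held-out evaluation.
Classification robustness is tested, not tuned: calls on separable
synthetic cohorts are unchanged for 64/100/128-bin grids and identical
across three embedding seeds.

## Synthetic cohorts

The generator emulates what the analysis assumes about real marrow samples:

- Each patient is a mixture of populations; every population's fluorescence
  is log-normal per marker (strictly positive, heavy right tail —
  the standard shape of uncompensated intensities), parameterized by
  arithmetic mean and CV.
- Profiles realize the canonical HSPC antigen combinations plus a
  leukemia-like blast population (CD34 dim, strong CD45RA/CD123
  co-expression, high PD-L1) and CD34− lymphocyte/monocyte/granulocyte
  background so the gating steps have real work.
- Default mixtures: the remission CD34+ compartment is 0.7% HSC/MPP,
  1.2% CLP, 9.4% CMP, 11.4% MEP, 44.6% GMP, 32.7% other (the published
  remission composition); the active-disease compartment is enriched for
  CD38− stem-like cells (14%) and contains 30% leukemic blasts. A
  linear interpolation between the two mixtures provides a one-parameter
  group-separation effect size for recovery experiments.
- 5% doublets (FSC-A inflated 1.9×) and 5% dead events (viability-dye
  bright) by default; total events per patient are drawn log-uniformly
  from a configurable range (cellularity spans orders of magnitude).
- Ground-truth population/doublet/dead labels travel in a side channel the
  pipeline never reads.

What the generator does *not* emulate — and therefore what passing tests do
not demonstrate about real data: spillover/compensation, acquisition-time
drift, batch effects, continuous differentiation gradients between
populations (real CD34+ compartments are smears, not well-separated
log-normal islands), and inter-patient variation of population locations.
Synthetic cohorts are easier to classify than patient samples; recovery
results are statements about the protocol's mechanics, not its clinical
accuracy.

## Validation problem sizes

The test suite keeps t-SNE runs small so the whole suite stays fast:
recovery experiments use 12 remission + 9 active-disease patients at
150–250 CD34+ cells each (~4200 cells, perplexity 40, 350 iterations),
swept over five effect sizes × three seeds, plus a three-seed stability
run at full separation; the reusable test embedding is six patients at
150 cells (perplexity 30, 300 iterations). Measured on these conditions:
leave-one-out accuracy is at chance (≈0.59) at zero effect, 1.00 from
effect size 0.25 upward, with 100% call agreement across embedding seeds.

## Known limitations

- FCS support covers list-mode files with uniform parameter width
  (float or unsigned integer); exotic FCS 2.0 variants are out of scope.
- Gates in embedding coordinates are only meaningful for the embedding they
  were drawn on (same inputs, same seed); they are versioned artifacts, not
  transferable calibration.
- The classifier compares whole-sample density patterns; leukemic clones
  outside the CD34+ compartment are invisible to it by construction.
- With five markers the PCA step cannot reduce dimensionality; it exists
  for panel extensions.
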