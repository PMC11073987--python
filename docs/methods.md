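# Methods

This note documents the models behind `ereflow`, the simulation the tests
rest on, the numerical choices, and what passing tests do and do not show.

## Differential expression and abundance

The engine is an empirical-Bayes moderated two-sample t applied to
log2-transformed values: log2(cpm + 1) for transcript counts, and
log2(intensity + 1) for peptide intensities. The offset of 1 bounds the
transform at zero counts. It is deliberately *not* a negative-binomial count
model: a moderated t on transformed values is fully specified, fast, and
calibrated (type-I error ≈ 0.047 at nominal 0.05 on null simulations), at
the cost of some power at very low counts relative to count-likelihood
engines.

**Normalisation.** Plain cpm normalises to column sums, which is what the
cohort ERE metrics use (they are defined on cpm). For differential testing,
however, a strongly asymmetric induced fraction (here ~14% of features at
~4-fold) inflates treated library sizes and drags every null feature down —
a classical compositional artifact. The DE input therefore rescales cpm by
median-of-ratios size factors (median over features of cpm / geometric-mean
cpm across samples, computed over features expressed everywhere). The
correction removes most but not all of the shift (a residual of ~0.2 log2
units remains when the planted fraction is large, because the median of the
mixture is not the median of the null features); the |log2FC| > 1 call
threshold absorbs the remainder, and the recovery tests confirm false
discovery proportion ≤ 0.1 under the planted conditions.

**Variance moderation.** The prior (d0, s0²) is fit by method of moments on
the *log* variance scale: under s² ~ s0² F(d, d0), Var[log s²] =
ψ′(d/2) + ψ′(d0/2) and the mean is a digamma expression; ψ′ is inverted by
Newton iteration. Fitting on the log scale matters here: the peptide branch
imputes missing intensities, which creates a heavy right tail of pooled
variances, and a raw-scale moment fit lets that tail inflate s0² until
well-behaved peptides lose all power. When the spread of log s² does not
exceed chi-square sampling noise, d0 is set effectively infinite and all
features shrink to the common variance.

**Multiple testing** is Benjamini–Hochberg step-up throughout, validated
against a brute-force step-up oracle on all permutations of six p-values.

**Peptide missingness policy.** A peptide is testable if detected in ≥ 2
replicates of at least one condition; remaining missing cells are imputed
with half the minimum observed intensity of that replicate column (a
standard label-free floor imputation for censored-at-detection data).
Treatment-specific peptides are a separate, detection-only call: present in
every treated replicate and in no control replicate.

## ERE metrics

- Class enrichment compares the class composition of an induced-locus set
  against the full annotation's composition; per class, a two-sided exact
  binomial p by the tail-doubling rule (2·min(lower, upper) capped at 1).
- E_p is the per-sample sum of cpm over a fixed locus set; no transform is
  applied before summing.
- H_p counts loci expressed *strictly above* their median across samples
  with non-zero expression of that locus; all-zero loci contribute nothing.
- The median split labels scores ≥ median as "high" (even n: midpoint of the
  two middle order statistics). On 437 distinct values this yields 219 high
  and 218 low — the convention is forced by those group sizes.

## Peptide sequence features

GRAVY uses the Kyte–Doolittle hydropathy table (via Biopython's copy);
aromaticity is the F/W/Y fraction; the DNMT2-target fraction is D/G/V
(aspartate, glycine, valine — the residues whose tRNAs are stabilised by
DNMT2 methylation). The polar set is {S,T,N,Q,C,Y,H,K,R,D,E}
(config-overridable). C-terminal protease classes are tryptic {K,R} vs
chymotryptic-like {F,W,Y,L,M}; peptides ending in anything else are excluded
from the 2×2 Fisher test, and a zero margin degrades to p = 1 with a flag.
The per-residue composition correlation is Spearman of residue frequency
against per-protein up-peptide count, BH-adjusted across the 20 residues.
Group comparisons use Mann–Whitney U, exact when min(n1, n2) ≤ 8 without
ties, otherwise the tie-corrected normal approximation.

## Peptide-to-RNA integration

Candidate databases enumerate every 8–11-mer of the three-frame translation
of expressed transcripts (transcripts are stranded, so three frames suffice;
stop codons and N-containing codons split fragments). A peptide with
multiple candidate sources is attributed to the source with maximal read
support, ties broken canonical > CTA > ERE > other, then lexicographically —
a deliberately conservative rule that never inflates the ERE class.
Concordance classes per differential peptide: rna_up / rna_down /
rna_unchanged (tested but not significant — the post-translational
fraction) / rna_absent (no database source). rphm = r·1e8/T; the screen
flag is strictly rphm > 8.55 per context with no averaging. The 8.55
threshold is an externally established operating point for MAP RNA
expression and is a configuration default here, not a derived quantity.

## Gene-set machinery

ssGSEA ranks genes by decreasing expression within a sample and assigns
rank n to the top gene; in-set weights are rank^alpha with alpha = 0.25, and
ES = sum over positions of (normalised running in-set weight − running
out-of-set fraction). The score is rank-based, hence invariant under any
strictly monotone transform of one sample's values. No "range"
renormalisation is applied by default.

Pre-ranked GSEA uses hit weights |statistic| (exponent 1), miss weights
1/(n−k), ES = signed maximal deviation of the running difference. The null
permutes gene labels (the interface ingests pre-ranked statistics, so
phenotype permutation is not available); p = (1 + #{|null| ≥ |ES|})/(n_perm+1)
is two-sided by magnitude and respects the 1/(n_perm+1) floor;
NES = ES / mean |same-sign null ES|. Under random sets the p-values are
approximately uniform (fraction < 0.05 measured at ~0.04 over 200 sets).

Over-representation is the hypergeometric upper tail P(X ≥ overlap) with BH
across sets. Note that at overlap 0 the upper tail is exactly 1.

Stratification: CD8 score = mean log2(cpm+1) of CD8A and CD8B; ERE axis =
H_p by default (E_p selectable); both axes median-split with the convention
above; GSEA rankings within a stratum use the moderated t of CD8-high vs
CD8-low.

## The synthetic study

The generator plants every effect the analyses are expected to recover:

- **Counts** are negative binomial with mean μ and variance μ + φμ²
  (gamma–Poisson), φ = 0.1 by default; baseline means are log-normal
  (median ≈ 60 counts). Desk scale: 2000 genes + 3000 ERE loci, 3 + 3
  replicates, four cell lines, 437 cohort samples. The ERE class mix is
  LINE 0.35 / SINE 0.45 / LTR 0.15 / Other 0.05, approximating the relative
  abundance of annotated retroelement loci.
- **Planted induction**: all CTA genes (n = 100), 150 non-CTA genes up, 50
  down, and 30% of LINE+LTR loci up, with log2FC ~ N(2, 0.5); SINE loci are
  never planted, which is what the class-enrichment recovery detects. Cell
  lines share one planted truth but respond on nested subsets (sensitivities
  1.0 / 0.75 / 0.55 / 0.4), so DEG and DEM counts co-vary across lines and a
  common induced core exists for the intersection analysis.
- **Proteome**: residue frequencies drawn per protein from a Dirichlet; a
  20% subset is enriched in DNMT2-target residues, with Asp/Gly carrying the
  full enrichment factor (3×) and Val half of it — matching the observed
  ordering in which Asp and Gly correlate most strongly with per-protein
  peptide counts and Val is weaker.
- **Peptides**: 8–11-mers cut from source proteins; true log2FC =
  a·(source RNA log2FC) + (1−a)·e with rna_drive a = 0.3, so most peptide
  changes are post-transcriptional, as observed. The independent effect e is
  drawn for an "affected" subset; peptides from D/G/V-enriched proteins are
  affected three times as often and positively, and for other affected
  peptides the mean of e couples to the peptide's polar-residue excess
  (+4 log2 units per unit excess polar fraction), planting the
  polarity/hydropathy signature of upregulated peptides. Intensities are
  log-normal (log2 scale, mean 12, sd 2) with replicate noise sd 0.3.
- **Detection dropout** is missing-not-at-random:
  P(missing) = clip(detect_dropout_scale, 0, 1) · logistic(mid − log2 I)
  with mid = 10. The knob scales the amplitude of a fixed logistic decay in
  intensity, so detect_dropout_scale → 0 switches missingness off; making
  the knob the logistic slope instead could not satisfy that limit.
- **Cohort**: latent activity A_p ~ N(0,1) per patient; a single coupling
  strength beta_autophagy = 1 scales autophagy-set genes by 2^(+βA_p) and
  the induced-ERE loci by 2^(−βA_p); CD8A/CD8B scale by 2^(−A_p) so CD8
  abundance tracks low autophagy. cpm values carry an O(1e-9) continuous
  jitter so cumulative scores are almost surely distinct.

All randomness flows through `numpy.random.default_rng` (PCG64); a fixed
seed reproduces outputs bit-for-bit.

**What the simulation does not emulate**: mapping ambiguity of repetitive
loci (counts are taken as given), dispersion that shrinks with expression
(φ is constant, which makes well-expressed features noisier than clonal
cell-line data would be — the intersection-recovery test therefore uses
φ = 0.02, the clonal-replicate regime), peptide spectral identification
error, MHC binding preferences, and any methylation mechanism. Passing
recovery tests shows the analysis code detects the structure it is defined
to detect; it does not validate the biology of real cohorts.

## Problem sizes and runtime

Defaults were chosen so the full test battery (including 50-seed null
calibration at 2000 features and the 200-set / 199-permutation GSEA
calibration) runs in well under five minutes, and the acceptance script in
about twenty seconds, while keeping every estimate comfortably away from
small-sample instability.

## Known limitations

- The moderated t underestimates power for features below ~5 counts; a
  count-likelihood engine would do better there.
- Median-of-ratios size factors under-correct when the induced fraction is
  very large (see above); effect-size estimates of null features can carry
  a residual ~0.2 log2 bias in that regime.
- `rphm` read support is summed over a peptide's source transcripts without
  sub-transcript resolution of the coding region.
- The Fisher C-terminus association is planted only indirectly (through the
  polarity coupling, since K/R are polar); with the default desk-scale DEM
  counts it is usually positive but not always significant.
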