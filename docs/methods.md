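# Methods

This note documents the statistics and models `sercodon` implements, the
parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical conventions used
throughout.

## Codon composition metrics

For each gene, the representative CDS is the longest transcript by CDS
length (ties broken by lexicographically smallest transcript id). Codons
are enumerated in frame 0 over the DNA alphabet; RNA-style class labels
(UC[C/U] = TCC/TCT, AG[U/C] = AGT/AGC, UC[G/A] = TCG/TCA) are used in
outputs. All codons are counted, including the initiator and the codons
adjacent to the stop — no positional exclusion is applied, since the
composition metric describes the whole coding sequence.

Class percentages are taken over total Ser codons:
pct_class = 100 · n_class / n_Ser. Genes with no Ser codon are flagged
`defined = False` and excluded from binning and correlation rather than
treated as 0% — a zero-Ser gene carries no information about Ser-codon
preference.

The codon-balance z-score contrasts the two stall-prone classes:

    z = (n_AG[U/C] − n_UC[C/U]) / sqrt(n_AG[U/C] + n_UC[C/U])

This is the binomial-proportion z statistic under a p = 0.5 null (a gene
whose stall-relevant Ser codons split evenly between the boxes scores 0),
with z = 0 defined for genes carrying neither class. The direction is
AG[U/C] minus UC[C/U], so positive scores mark genes leaning on the AGPy
box. Percentage bins are half-open intervals [lo, hi) with the last
closed at 100; the fine scheme uses edges 0, 11, 21, …, 91, 100 with
labels `0-10` … `91-100`, and a coarse scheme separates `0-60`, `61-90`
and `91-100` (the last decile is dominated by very short CDSs with few
Ser codons and behaves differently from the rest).

## Ribosome-density metagenes and pause scores

Footprint alignments are per-transcript (transcript_id, start, end)
intervals in 0-based half-open CDS coordinates, with footprint lengths
gated to 26–34 nt by default (the gel-excised RPF band). Coverage is
full-footprint per-base occupancy by default; an A-site-collapsed mode
(each read contributes one count at 5′ end + offset, default +15) is
available and is the mode in which per-codon dwell ratios are directly
interpretable. Each track is normalized by its own mean per-position
coverage, making transcripts of different expression comparable;
transcripts with fewer than 100 footprints or mean coverage below 0.5
reads/nt are filtered (counts logged) because their normalized tracks are
dominated by shot noise. Normalizing an already-normalized track is a
hard error rather than a no-op, so accidental double normalization cannot
silently re-base a metagene.

The metagene for a codon averages normalized coverage position-by-position
over a window of ±150 nt around every occurrence, pooling all
(occurrence, transcript) pairs with equal weight; positions truncated by a
CDS edge contribute only where defined, and the per-position contributing
count is reported. Occurrences within the first and last 20 codons are
excluded so initiation and termination ramps do not leak into codon-level
signal. The condition contrast is the per-position difference
deprived − rich, summarized by the *pause score*: the mean delta over
relative positions −15…+17, the span a ~33 nt footprint covers when its A
site sits on the codon (configurable). Codons are ranked by descending
pause score with alphabetical tie-breaks.

Differential translation efficiency is deliberately naive: with
pseudocount pc = 0.5,

    TE_cond(g) = ((rpf_g + pc) / Σ(rpf + pc)) / ((rna_g + pc) / Σ(rna + pc))
    Δlog2TE(g) = log2(TE_deprived / TE_rich)

This is a library-normalized double ratio with no dispersion model and no
significance test; output columns are labelled `naive` so it cannot be
mistaken for a model-based estimator.

## Charged tRNA-seq quantification

Periodate oxidation destroys the 3′-terminal ribose of uncharged tRNAs
while the esterified amino acid protects charged ones, so after repair,
ligation and sequencing, a charged mature tRNA reads out with an intact 3′
CCA and an uncharged one ends in CC. Read classification is purely
positional plus terminal-sequence: flush with the mature 3′ end and ending
CCA → charged_mature; one base short ending CC → uncharged_mature;
extending ≥1 nt into the genomically encoded leader or trailer → pre;
anything else → ambiguous (a counted category, excluded from the charging
denominator). Percent charging is 100·nCCA/(nCCA+nCC), undefined (NaN)
when no mature reads were seen. Isoacceptor quantities are sums over
their isodecoders; charged pools are percent charging × mature level
(CPM-normalized when library sizes are given); within-amino-acid ratios
are charged levels over their sum. Alignment, demethylation chemistry and
multi-mapper resolution are upstream concerns — input tables are assumed
uniquely assigned.

## Reporter correction and screen differencing

Per condition, the reporter value is geomean(GFP)/geomean(mCherry) over
cells; the geometric mean is computed as (∏x)^(1/n) with a log-space
fallback when the product over/underflows. The cycloheximide (CHX)
background is subtracted from the normalized per-condition value (not per
cell), and the translational readout is

    ratio(−SG/+SG) = (v_deprived − v_chx) / (v_rich − v_chx)

The ratio is invariant to common rescaling of both channels. When the
rich signal does not exceed background the ratio is undefined and
flagged; negative corrected values are reported as-is with a flag rather
than clipped, since clipping hides background problems. β scores are
consumed from tables (they are estimated upstream by MAGeCK MLE, which
this package does not re-implement); the β difference between two screens
is ranked descending and genes are selected by strict beta_diff > 0.25.

## Proteome coupling

SILAC heavy-channel intensities mark newly synthesized protein; per-gene
log2 fold changes are computed only for proteins quantified on both sides
(missing or zero intensities are dropped with a logged count — imputation
is deliberately not offered because it would inject exactly the structure
the downstream correlation measures). Fold changes are binned by codon
percentage; bin summaries report n, unweighted mean and SEM (NaN for
n < 2), and empty bins with n = 0. The binned correlation is Spearman's r
of bin means against bin midpoints over non-empty bins (unweighted), with
the individual-gene correlation also available — the contrast between the
two is informative because binning suppresses gene-specific regulatory
noise. Trend curves are ordinary least-squares quadratics over retained
bins with explicit label-based exclusion (typically `91-100`); automatic
outlier detection is intentionally not used. Multiple-testing adjustment
is the two-stage Benjamini-Hochberg step-up (first BH pass at α estimates
the number of true nulls m0; BH-adjusted values are rescaled by m0/m),
with plain BH available.

A caution on binned null correlations: with 10 bins, Spearman's r under a
no-effect null follows the exact 10-point rank-permutation distribution,
for which P(|r| < 0.5) ≈ 0.856; sparsely populated extreme bins make
large |r| more likely still, because their noisier means sit at the ends
of the midpoint ranking. Binned correlations on ~10 points are therefore
expected to exceed |r| = 0.5 in a nontrivial fraction of null datasets,
and should be read alongside the per-bin n.

## Synthetic data

Every generator is a pure function of a `SimulationConfig` (seed
included); identical configs give byte-identical outputs, and each
dataset is emitted alongside the ground truth used to construct it.

Transcriptomes: one CDS per gene, ATG + interior + single stop, length
drawn uniformly from 150–450 codons (typical protein-coding range at desk
scale); each interior codon is Ser with probability 0.10 (human Ser usage
is ~8–9% of codons; 0.10 keeps per-gene Ser counts informative at these
lengths), non-Ser codons uniform over the 55 non-Ser sense codons. The
population-average class mix is (⅓, ⅓, ⅓) with per-gene mixes drawn from
a Dirichlet with concentration 3, emulating the gene-to-gene codon-usage
heterogeneity that populates the full 0–100% composition range in real
transcriptomes; a fixed-mix mode is available.

Footprints: for each transcript and condition, A-site codon indices are
drawn with probability proportional to the dwell multiplier of the
codon's class (default: uniform in rich medium, 4× on UC[C/U] under
deprivation — the parental-cell stall regime; moving the multiplier to
AG[U/C] models the processing-deficient switch). A fixed-length 30 nt
read is placed with the A site 15 nt from its 5′ end; placements that
would overhang a CDS end are shifted inward so every footprint keeps full
length while still covering its A-site codon (equivalent to truncation
for every occurrence the metagene measures, given the 20-codon edge
exclusion). This A-site-weighted sampling is a deliberate simplification
of elongation: it creates exactly the at-codon coverage enrichment the
metagene measures, without ribosome transit, collisions, or sequence-
dependent ligation bias.

tRNA-seq: reads per isodecoder are Poisson around level × depth (negative
binomial optionally, for overdispersion), split multinomially into
pre / charged-mature / uncharged-mature by the truth fractions. The
default panel is six Ser isodecoders across the four isoacceptor families
with ~90% charging in rich medium and 70% under deprivation. SILAC:
log2FC(g) = Σ_class β_class · pct_class(g)/100 + N(0, σ²) with σ = 0.3
(typical replicate spread for SILAC ratios), plus lognormal baseline
intensities so the table round-trips through the fold-change reader.
Reporter cells are per-cell lognormal draws constructed so the expected
corrected ratio equals a configurable truth.

What the generators do **not** emulate — and hence what passing recovery
tests do not establish about real data: sequence-dependent cloning and
ligation biases, tRNA modification chemistry and misincorporation
signatures, isoform structure and UTRs, peptide-level quantification
noise, protein degradation, and any coupling between expression level and
codon content.

## Numerical conventions and edge cases

0-based half-open coordinates everywhere; metagene position 0 is the
first nucleotide of the codon. Undefined quantities (zero-Ser profiles,
zero-denominator charging, all-zero pools, constant-vector correlations)
are NaN with explicit flags, never silently 0. Ties are broken
deterministically (alphabetical codons/genes, lexicographic transcript
ids). Filtering is distinct from failure: low-coverage transcripts and
unquantified proteins are dropped with logged counts, while malformed
inputs (frame errors, out-of-bounds alignments, negative counts,
unparseable ids) raise with the offending record named. TSV outputs carry
a `#` header with schema name, version and config hash; floats are
written at full precision and read back losslessly.

## Problem sizes

The bundled protocols run at desk scale, chosen so the complete suite and
the reproduction script finish in about a minute while leaving every
recovery margin wide: 200 genes × 2000 footprints per transcript for
stall recovery (the simulated pause scores exceed the nearest background
codon ~15-fold), 200 binomial replicates at depth 1000 for charging
calibration, and 50 replicates × 1000 genes for the proteome-coupling
sign test.

## Known limitations

The differential-TE estimator is intentionally model-free and should not
be used for per-gene inference; pause scores carry no significance test
(replicate-level comparison is left to standard ANOVA machinery); the
pre-tRNA caller assumes uniquely assigned reads; and the binned Spearman
on ~10 points has the wide null described above. The CLI covers the
simulated end-to-end path and single-stage analyses; multi-sample
designs (replicates, batch structure) are left to the library API.
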