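# Methods

This note documents the models and numerical conventions behind
`aqpscan`, the choices made where the design was genuinely open, and
what the synthetic generators do and do not emulate.

## Coordinates and the spacing convention

All residue positions are 1-based and inclusive; a motif written
`NPA(114)` starts its Asn at residue 114. The NPA–NPA distance is the
count of residues strictly between the two motifs,
`le_pos − lb_pos − 3`. Published aquaporin feature tables rarely define
their distance column; this convention is adopted because it reproduces
the printed distance on every complete row of the packaged canola table
(119/119), and a fixture-wide validator (`validate_table2_fixture`)
enforces it permanently. The choice of indexing the motif's N rather
than its center does not affect spacing arithmetic.

## Physicochemical computations

Molecular mass uses ExPASy average residue masses plus one water;
`X` contributes the mean of the 20 canonical residue masses and flags
the result approximate. The isoelectric point bisects the monotone
Henderson–Hasselbalch net-charge function on pH 0–14 to a 0.01
tolerance (≤ 60 iterations); the pKa constants are the EMBOSS set and
are recorded in the result, because predicted pI shifts by a few tenths
between published pKa sets and no reconciliation with any specific
server is attempted.

## Transmembrane segments

TM helices are called from a centered Kyte–Doolittle window
(default window 19, threshold 1.6): maximal runs of residues whose
window mean reaches the threshold, merged when separated by fewer than
3 residues, discarded under 15 residues. Windows are truncated at the
sequence termini so N-terminal helices (real in the small basic
intrinsic proteins, whose first helix starts within a few residues of
the initiator) are scorable; `X` residues are excluded from window
means. These defaults are exposed in the configuration. This is a
deliberate self-contained stand-in for server-based topology
predictors; it is calibrated for the screening question ("are there
~6 helices?"), not for exact boundary placement.

## Alignment and feature transfer

The global aligner is Needleman–Wunsch with Gotoh affine gaps. A gap of
length k costs `open + (k−1)·extend` (defaults: BLOSUM62, open 10,
extend 1). Traceback is deterministic: on ties, diagonal beats a gap in
the reference, which beats a gap in the query; this makes every
downstream position mapping reproducible. The aligner is verified
against exhaustive enumeration of all alignments for short sequences.
ar/R, Lc and Froger residues of a query are read off at the query
positions aligned to the reference's annotated positions; a reference
position aligned to a gap yields `-`. Extraction uses the best-scoring
reference; alignments under 30% identity set a quality flag.

## Screening and classification

Full-length aquaporins are ~230–300 residues with six helices, so
screening keeps records with length in [150, 450], at least 5 predicted
helices (6 expected; 5 tolerates prediction error at helix boundaries)
and at least one NPA-type motif. Single-motif proteins pass screening
but their missing loop-B/loop-E pair sets a needs-review flag — the
codified version of manual curation of incomplete candidates.
Classification assigns the subfamily/group of the best-scoring
reference; a best score under 40% of that reference's self-alignment
score leaves the query unclassified. This self-score fraction replaces
tool-specific bit-score cutoffs, which are not reproducible outside the
original search engine. Paralog letters (a, b, c …) are assigned within
each (genome, group) set ordered by chromosome, then start coordinate,
then gene id — the ordering on unanchored scaffolds is a package
convention.

## Substrate-specificity rules

The rule table is data (`data/specificity_rules.yaml`), not code: each
rule matches the four ar/R residues (allowed-letter sets), optionally
pins the NPA–NPA spacing, and yields (substrate, tier) predictions;
the first match wins, and undefined filter residues lower all tiers by
one. Silicic acid is special-cased in code as well as data: it is never
predicted unless the filter is exactly G-S-G-R with spacing 108, the
Lsi1-type signature, reflecting the evidence that conserved NPA–NPA
spacing is required for silicon permeability.

## Expression analyses

RPKM is `1e9 · count / (gene_length_bp · library_total)`. The
expressed rule is strict (`> 2` RPKM in at least one library), the
differential rule is `|log2((m_t + 1)/(m_c + 1))| > 2` with the larger
condition mean `≥ 2` RPKM; the pseudocount of 1 handles zeros and is
configurable. Dosage dependency is the Pearson correlation of a gene's
RPKM with the A-genome fraction across genotypes (replicates treated as
independent samples), two-sided t test with n−2 degrees of freedom;
dependent means p < 0.01 **and** r > 0. Co-expression edges must clear
the 5th/95th percentile ranks of the bait's own correlation
distribution (linear-interpolation percentiles, recorded in the
output); a pooled-null option exists because published tools do not
state which null they use. Hierarchical clustering is average linkage
on 1 − r with zero-variance genes excluded and listed.

## Synthetic protein cohorts

Per-group templates are parameterized from the published canola table:
motif variants, typical loop-B positions, spacings, ar/R filters (e.g.
NIP5: NPS/NPV, spacing 108, A-I-G-R) and the TIP Lc letters (TIP1/3 F,
TIP2/4 H, TIP5 Y). Where the literature does not fix a letter the
template chooses one and records it in the truth table: Lc is F outside
the TIPs, and Froger sets are subfamily-typical (PIP QSAFW, TIP TSAYW,
NIP FSAYL, SIP VAAYW). Six 21-residue TM blocks are planted at fixed
offsets around the two motifs; block residues are drawn from I/L/V so a
block always clears the hydropathy threshold, and the short inter-helix
loops are drawn from a hydrophilic set so adjacent blocks never fuse
into one run. Remaining background residues are uniform over the 20
amino acids, which maximizes decoy difficulty; accidental NPA-type
triplets are scrubbed from templates so the planted pair is
unambiguous. Copies are point-mutated at 5% per site with motif, ar/R,
Lc and Froger columns protected; mutations inside TM blocks are
conservative (within the hydrophobic set), mirroring the substitution
constraint of a membrane helix. Decoys cover three failure classes:
fragments, single-motif proteins and hydrophilic non-channels. Gene
models carry group-typical intron counts (3 for PIPs, 11 for SIP1, …).

What this cohort does **not** emulate: real paralog divergence
structure (mutations are i.i.d.), indels, alternative isoforms, or
homology between groups beyond the shared layout — so passing recovery
tests shows the pipeline's operations are correct on sequences whose
ground truth is known, not that real proteome screening is
error-free.

## Synthetic expression matrices

Three designs are emulated: a developing-seed series (4 timepoints × 3
replicates) with a rising TIP3-like and falling PIP1-like trajectory
(log-linear, doubling per two weeks); a drought design (2 tissues ×
control/drought × 3 replicates) with planted fold changes; and an
allopolyploid dosage series using the five genotypes with defined
A-genome fractions (AA = 1, AC = 0.5, AAC = 0.66, CCA = 0.33,
CCAA = 0.5) × 2 replicates. Baselines are lognormal (median 50 RPKM,
log-sd 1); 10% of panel genes are silent (0.2 RPKM). Planted effects
multiply the mean: differential genes gain 2^lfc under treatment (and
are planted on baselines ≥ 5 RPKM, i.e. on expressed genes, so the
pseudocount does not mask the fold change); dosage-dependent genes
scale proportionally with the A fraction (mean ∝ a^slope, slope 1 —
the natural copy-number model; its empirical detection power at
p < 0.01 with n = 10 and noise σ = 0.2 is ≈ 0.95); module genes share a
latent log-normal factor sized for the target pairwise correlation.
Noise is lognormal (σ = 0.2 on the log scale) and counts are Poisson
around the RPKM-implied means (gene lengths 0.8–1.8 kb, 20M-read
libraries).

Each library also contains a constant background transcriptome (600
genes, baselines rescaled so that the library's total RPKM·length mass
is 1e9). This matters twice: recovered RPKM then matches the target
scale (a library whose entire content is 120 genes would inflate RPKM
~13-fold and defeat the >2 RPKM rule), and planted effects on the
panel no longer shift the per-sample totals that RPKM divides by, which
would otherwise compress fold changes and distort dosage slopes. The
analyses evaluate the 120-gene aquaporin panel inside these libraries,
exactly as a panel study evaluates a gene family inside whole
transcriptomes. Not emulated: overdispersion beyond Poisson, mapping
bias, paralog cross-mapping, batch structure.

## Problem sizes and determinism

Default analysis sizes — 16 groups × 3 proteins plus 6 decoys for the
cohort, 120 panel genes + 600 background genes per expression matrix,
200 seeded trials for the selectivity-filter recovery check — were
chosen so each analysis is statistically meaningful at desk scale.
Species-level totals from genome-wide surveys (e.g. 380 aquaporins
across seven genomes, 16 drought differential genes) require the real
proteomes and RNA-seq libraries and are deliberately out of scope; the
package's correctness on those claims is covered by the fixture checks
and recovery tests instead. All generators are deterministic given a
seed (bit-identical outputs); every CLI output embeds the tool version,
configuration hash and seed.

## Known limitations

- The hydropathy scanner is not a topology predictor; helix boundaries
  are approximate and very hydrophilic half-helices (the NPA
  half-helices themselves) are not modeled.
- The classification threshold (40% of reference self-score) is a
  pragmatic proxy validated on the synthetic cohort, not a calibrated
  E-value.
- The specificity rule table encodes evidence classes, not a complete
  physiological mapping; tiers are qualitative.
- The NJ tree is a quality-control device on 1 − identity distances,
  not a substitute for a maximum-likelihood phylogeny with support
  values.
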