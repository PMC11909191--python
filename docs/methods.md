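# Methods

This note documents the models and procedures sorfkit implements, the
parameters that matter, the synthetic data it validates against, and the
design choices made where more than one reasonable convention exists.

## Candidate ORF enumeration

Transcript sequences are assembled by splicing exon blocks from the genome
(reverse-complemented on the minus strand so every transcript reads 5'→3').
On each spliced sequence, every occurrence of an allowed start codon —
ATG, CTG, GTG or TTG by default, reflecting the prevalence of noncanonical
initiation among short ORFs — is extended codon-by-codon to the *first*
in-frame stop (TAA/TAG/TGA). Starts with no downstream in-frame stop are
discarded; nested ORFs sharing a stop are all retained as distinct library
entries.

Conventions that had to be fixed:

- **Coordinates** are 1-based inclusive throughout (the Ensembl GTF
  dialect), so a span printed as 26533546–26533680 has length
  26533680 − 26533546 + 1 = 135.
- **Length** (`length_nt`) includes the stop codon; the peptide excludes
  it. A 135-nt ORF therefore encodes a 44-aa peptide. The identifier is
  `transcriptID_gStart_gStop_lengthNt`, with the length being the
  *spliced* length, not the genomic span, so it is intron-invariant.
- **Minus strand**: the identifier's "start" coordinate is the genomic
  base of the transcript's first ORF base, which is numerically larger
  than the "stop". Because this orientation convention is not externally
  standardized, the catalogue also carries a normalized `(g_min, g_max)`
  span for BED-style consumers.
- **Ambiguous bases**: a codon containing N never matches a start codon
  and never terminates an ORF; it translates to X. This is conservative
  and deterministic — assembly gaps can neither create nor destroy ORFs
  except by forming a literal stop codon.
- **Length filter**: peptides of 6–249 aa are kept by default. The upper
  bound is the defining property of a "short" ORF here (<250 aa); the
  lower bound is the practical floor of tryptic MS detectability and is
  configurable.

### Classification

Each ORF is classified against its transcript's annotated CDS:
`novel_nc` (no CDS on the transcript), `annotated` (coordinates equal the
CDS exactly), `uORF`/`dORF` (entirely 5'/3' of the CDS), `overlap_uORF` /
`overlap_dORF` (straddling the CDS start/stop), `intORF` (strictly inside
the CDS span, different frame), `altORF` (otherwise overlapping). Two
corner cases the category vocabulary does not pin down were resolved as
follows: straddle checks take precedence over frame checks, so an ORF
containing the entire CDS is `overlap_uORF`; and a same-frame ORF strictly
inside the CDS (an N-terminal truncation sharing the CDS stop) falls to
`altORF` rather than `intORF`, keeping `intORF` a strictly
frame-shifted class — which matters because intORF-only peptides are
subject to the canonical-embedding removal below.

### Naming

Identified peptides are named `pepNo.-Type-Gene`: numbering is per host
gene by ascending normalized genomic start, the type code collapses the
categories (u ← uORF/overlap_uORF, d ← dORF/overlap_dORF,
alt ← intORF/altORF, nc ← novel_nc), and a gene with exactly one
identified peptide is labeled `pep` without a number. ORFs on different
isoforms producing the same peptide sequence collapse to one named entry
listing every supporting ORF identifier.

### Decoys

Decoys are whole-entry peptide reversals (`DECOY_` header prefix), the
simplest reproducible choice preserving length and composition. A decoy
colliding with a target sequence is logged and suffix-tagged so it can be
excluded; with realistic libraries collisions are vanishingly rare.

## PSM filtering

The filter cascade is fixed-order and each stage is idempotent:

1. **Ambiguity**: any spectrum matched to two or more *distinct* peptide
   sequences is discarded entirely. A spectrum matching one sequence
   shared by several ORFs is kept — distinctness is sequence-level.
2. **Peptide-level target-decoy FDR** (default 1%): PSMs aggregate to the
   best score per peptide sequence; sweeping thresholds t,
   FDR(t) = (#decoy peptides ≥ t) / (#target peptides ≥ t), converted to
   monotone q-values by a reverse cumulative minimum. No +1 correction
   and no π₀ estimation — the plain ratio is the simplest defensible
   estimator and its calibration is verified by simulation rather than
   assumed. Peptides tied at the threshold score are retained.
3. **Annotated / embedded removal**: peptides supported only by
   `annotated` ORFs are dropped (they are canonical proteins); peptides
   supported only by `intORF`s whose sequence is an exact substring of a
   canonical protein are dropped. The substring test is exact by default;
   I/L equivalence is available behind a flag since isobaric residues are
   indistinguishable by mass.
4. **Redundancy resolution**: ORFs supporting retained peptides are
   grouped into genomic-overlap components per chromosome and strand.
   Within a component, processed in descending length, a longer ORF with
   at least one supporting peptide that is *not* a substring of a shorter
   overlapping ORF's full peptide evicts that shorter ORF ("unique-region
   support"). PSM tables carry no within-protein positions, so "maps
   outside the shorter ORF" is operationalized at the sequence level.
   Components where the condition never fires are retained intact and
   flagged `unresolved_redundant` — the defined rule is silent about
   them, and silently dropping either member would be a stronger claim
   than the evidence supports. Evicted ORFs cannot themselves cause
   further evictions.

A `FilterReport` records input/output counts per stage and enforces that
they never increase. The support summary reports the single-PSM fraction,
the ≥2-PSM fraction and the cross-sample detection fraction of the final
catalogue.

## Screen scoring

Counts are normalized per sequencing column to reads per million and
log2-transformed with a +1 pseudocount (zero-count guides must remain
finite; the pseudocount's effect is negligible above ~10 reads and is the
only departure from exact depth-invariance). A guide's log2 fold change
is mean(final columns) − mean(initial columns) on the normalized scale;
since replicates are averaged before differencing, this equals the mean
of per-replicate LFCs when the design is balanced.

The per-ORF **phenotype score** is the mean LFC of its body-targeting
guides; guides targeting the 1-kb region upstream of the ORF act as
host-RNA knockout controls. Classification uses the dual criterion:
|body| > 1 with |upstream| < 1 is an on-hit (body ≤ −1 pro-proliferative,
body ≥ +1 anti-proliferative); |body| > 1 with |upstream| ≥ 1 is a
host-RNA effect; anything else is a non-hit. ORFs without upstream guides
cannot satisfy the dual criterion and are reported as non-hits with a
flag rather than promoted on partial evidence. The average-LFC statistic
is the scoring core by design; shrinkage-style moderation of fold changes
is deliberately out of scope.

Screen QC checks that essential-gene controls drop out far more than
scrambled controls (one-sided rank-sum on |LFC|, pass at p < 0.01 with a
median ordering check); missing control classes skip QC with a warning.

## Catalogue characterization

Descriptive outputs: start-codon usage fractions over the four allowed
codons, peptide-length distributions stratified by host type (ncRNA vs
mRNA-derived), per-gene peptide counts and category fractions. Covariate
association joins per-ORF phenotypes with externally supplied numeric
covariates (e.g. coding-potential or conservation scores — consumed, never
computed here): Spearman ρ between |phenotype score| and each covariate,
a two-sided rank-sum contrast between hit and non-hit ORFs, and
Benjamini–Hochberg adjustment across the battery, reported alongside the
raw p-values.

## Synthetic data and what it does (not) show

The generators are pure functions of (parameters, seed) and carry their
own coordinate arithmetic, splicing, translation and a naive
scan-to-first-stop enumerator, so planted truth never depends on the
library code it validates.

- **Genome/annotation** (defaults: 2 chromosomes, 6 mRNAs, 4 ncRNAs,
  1–4 exons of 150–450 bp, introns 80–400 bp): mRNAs get an in-frame CDS
  (forced ATG start, forced stop, internal in-frame stops scrubbed) plus
  a planted uORF/dORF where the UTRs have room; ncRNAs get one planted
  sORF. The truth table lists *every* ORF the enumeration rules admit on
  the final sequence, so the library builder can be checked for exact
  set equality.
- **PSM tables** (defaults: 150 truly present peptides, 3 samples,
  detection probability 0.8, true scores Normal(25, 3), null and decoy
  scores Normal(10, 3), 150 false-target and 150 decoy matches, 5% of
  true spectra duplicated against a second peptide): false matches land
  uniformly on the *whole* target library with the same score law as the
  equally many decoy matches. A false hit on a genuinely present peptide
  merges into a true identification and is harmless at the peptide
  level, so the decoy channel upper-bounds the damaging false-target
  channel — the π₀ < 1 mechanism that makes peptide-level decoy FDR
  conservative in real searches, and the reason the uncorrected
  decoy/target ratio controls the realized rate here despite lacking a
  +1 correction. The 3.5-σ separation between the true and null score
  components mimics a well-behaved search; calibration under heavy
  component overlap is exercised separately by the null (μ₁ = μ₀) test.
- **Screen counts**: negative-binomial with variance = μ + φμ²
  (defaults φ = 0.05, 500× coverage, 2 replicates per arm, 4 body +
  2 upstream guides per ORF, 100 scrambles, 50 essential controls planted
  at LFC −3). Final-arm means are μ·2^LFC for planted effects.

What passing these tests does **not** show: real spectra are not
simulated (no mass accuracy, retention time, modifications or chimeric
spectra), search-score distributions are idealized Gaussians, sgRNA
efficacy is uniform, and there is no clonal population dynamics — so the
pipeline's statistical behaviour is validated, not any particular search
engine's or screen's biology.

## Problem sizes and full-scale scope

The default validation runs at desk scale: a ~10-transcript synthetic
genome (a few hundred candidate ORFs), 200 PSM tables of roughly 1000
rows, and a 1000-ORF screen with ~6150 guides. These sizes make every
check exact or tightly calibrated while keeping the whole suite fast.

At full scale — the complete human annotation (Ensembl Hg38 release 103)
searched with a commercial engine against tissue and cell-line MS runs —
the same procedure is reported to yield 11,668,944 candidate ORFs, an
8945-peptide novel catalogue, and 1161 proliferation on-hits. Those
figures require external genome downloads, raw MS data and a licensed
search engine, none of which this package ships; they are full-scale
stretch goals, and the pipeline's correctness on that pathway is
established here by the synthetic property-based checks above (oracle
equality for enumeration, FDR calibration, hand-enumerated filter
ledgers, planted screen-effect recovery) rather than by number matching.

## Known limitations

- GTF only (Ensembl dialect); no GFF3, chromosome aliasing or liftover.
- The redundancy rule's "unique sequence" test is sequence-substring
  based, which is slightly conservative for repetitive peptides that
  occur in both the unique and shared regions of a longer ORF.
- FDR is estimated globally across samples (a per-sample mode would be a
  thin wrapper; the global mode matches a pooled-search workflow).
- The screen scorer does not model guide-level variance or dispersion
  shrinkage; with few guides per ORF the mean-LFC statistic is noisier
  than a moderated estimator would be.
- RPM normalization makes every score relative to library composition:
  if a large fraction of the library is strongly depleted (e.g. many
  essential controls in a small library), null-guide LFCs shift upward
  by the corresponding log2 column-sum ratio. With realistic library
  sizes the shift is a few hundredths of a unit and never crosses the
  ±1 hit thresholds.
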