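# Methods

## Scope and data model

integscape analyses *mapped* integration sites: it consumes site tables
(chrom, position or 8-bp target-site-duplication interval, strand, vector,
fragment count, detection method), a reference genome (FASTA), gene models
(GFF3), arbitrary feature tracks (BED) and per-gene FPKM tables. Read
alignment, raw-read junction calling and mappability computation are out of
scope; mappability enters only as an explicit allowed-region track.

All coordinates are 0-based half-open internally (BED semantics); GFF3 is
converted at the boundary. Two intervals overlap when they share at least
one base. Genomes are uppercase strings over `{A,C,G,T,N}`; `N` never
matches a motif and disqualifies flanking windows from sequence profiling.

## Fragment-count filtering

Fragment counts (number of distinct sequenced fragments supporting a
putative insertion) separate real insertions from PCR/sequencing artifacts.

- *Selected* sets (stable reporter-selected lines): keep NGS sites iff
  `count > 50` (strictly greater). TAIL-/inverse-PCR sites pass
  unconditionally — their support is unambiguous mapping, not fragment
  depth.
- *Unselected* sets (pooled injected embryos, each insert diluted): general
  cut-off `count >= 7`; but a site with a restriction recognition sequence
  of the library enzymes within ±20 bp of its insertion point must reach
  `count >= 50`, because enzyme-adjacent singleton calls are a known
  artifact class of linker-mediated PCR.

Boundary conventions: the unselected thresholds are read inclusively
("lowered the cut-off to 7" = 7 passes), the selected one strictly
("detected with > 50 counts" = 50 fails). Both, the ±20 bp motif window
(the same half-width as the flanking-window geometry), and the enzyme
motifs (MseI `TTAA`, BfaI `CTAG`, Csp6I `GTAC` — the standard REBASE
recognition sequences) are configuration parameters, since different
protocols use different enzymes and depths.

Multi-method deduplication collapses sites on the same chromosome and
strand whose insertion points chain within a 5-bp tolerance (single
linkage), keeping the highest-count record and the union of methods. The
5-bp default absorbs junction-trimming jitter between TAIL and NGS calls;
it is exposed as a parameter. Filtering and merging are idempotent and
order-independent.

## Matched control generation

Controls answer "what would this statistic look like if the vector had no
preference, *given the detection protocol*?". Two modes:

**Uniform mode** (inverse-/TAIL-PCR sets): a pool of 10^6 random 50-bp
locations (optionally restricted to fully-mappable regions) is sampled
without replacement into N = 1000 replicate sets of the experimental size.
Chromosomes are chosen proportional to their number of valid start
positions, so placement is uniform per base.

**Restriction-matched mode** (linker-mediated-PCR NGS sets): a site can
only be recovered if a restriction fragment of usable length spans it, so
distance-to-enzyme-site is a detection covariate. Each experimental site is
keyed by its nearest enzyme occurrence over all three enzymes (absolute bp
from insertion point to motif start, either direction; enzyme ties break by
the configured enzyme order, position ties by lower coordinate). Each
control replicate then places, per site, one point at exactly the key
distance from a uniformly drawn genome-wide occurrence of the same enzyme
(side chosen uniformly; off-chromosome placements are redrawn). Matching is
therefore *constructive* — the control provably carries the key — rather
than rejective; a rejective sampler (draw until the control's own nearest
key matches) is provided for cross-validation on small genomes, where the
two agree on the key invariant. The absolute-distance convention is the
default because the per-site sequencing orientation needed for a signed
convention is rarely recorded; an orientation-aware variant would key on
the downstream side of the insertion strand.

Determinism: every sampler takes an explicit seed; identical inputs and
seed reproduce collections exactly.

## Bootstrap enrichment statistic

For a feature track, with x_exp the experimental overlap count and
x_ctrl_i the count in control replicate i (both by the 1-bp rule, each site
counted at most once):

- fold enrichment = mean over replicates of x_exp / x_ctrl_i, excluding
  replicates with zero count (their number is always reported; if all are
  zero the ratio is undefined and reported as NaN);
- p_enrich = #{i : x_ctrl_i ≥ x_exp} / N, p_deplete = #{i : x_ctrl_i ≤
  x_exp} / N. Ties count toward both (conservative), so p_enrich +
  p_deplete ≥ 1. No add-one correction is applied; the smallest reportable
  value is 0, labelled "< 1/N". The significance threshold applied
  downstream is P = 0.05.

Feature panels are reported without multiplicity adjustment (as is
conventional for this bootstrap design, where each feature is judged
against its own matched null); an optional Benjamini–Hochberg column is
available. Per-chromosome distributions report observed counts against the
control mean ± sd.

Counting uses merged per-chromosome interval arrays with binary search; the
implementation is cross-checked in the test suite against an O(n·m)
all-pairs oracle, exactly, on randomized instances.

## Gene context

Two assignment windows coexist deliberately:

- region/metagene analyses: a site belongs to every gene whose
  strand-oriented window [TSS − 5 kb, TTS] overlaps it; everything else is
  intergenic;
- expression association: genes within ±5 kb of the TSS–TTS span.

All overlapping genes, and all overlapping subregions, are counted.
Exonic sequence splits at the CDS bounds into 5′-UTR / coding exon / 3′-UTR
(strand-aware); non-exonic span is intron; the 5-kb promoter window is
"upstream". An 8-bp duplication interval can legitimately hit several
subregions at once.

Metagene position is measured on the *unspliced* span: 0% at the TSS base,
100% at the TTS base, normalized by (span length − 1) so that both
endpoints are exactly attainable on either strand and the statistic is
strand-equivariant. TSS/TTS profiles bin signed strand-oriented offsets
(negative = upstream of the anchor) within a 1-kb window, one entry per
(site, gene) pair. For duplication intervals the midpoint is the point
coordinate; overlap-based rules still use the full interval.

Expression classes use an FPKM ≥ 1 detection floor (the conventional
threshold; configurable) around a configured zygotic-genome-activation
column index: maternal_only = detected at some pre-ZGA timepoint and at no
post-ZGA one; zygotic_only the converse; maternal_zygotic both; silent
neither. "Overall expression" is the FPKM sum across timepoints. The
association report compares mean/median overall FPKM and class composition
of targeted versus control-targeted genes; genes absent from the table are
counted as silent and tallied.

## Sequence and flexibility profiles

Windows are 48 nt in the insertion orientation (minus-strand windows
reverse-complemented): 20 + 8 + 20 around the target-site duplication for
hAT-family transposons, or 20 before + 28 after a point insertion so that
1-based position 21 is the first integrated base. Windows containing `N` or
running off a chromosome end are excluded and tallied — the positional
averaging assumes complete windows.

Position matrices report per-position base probabilities and information
content, bits = 2 + Σ_b p_b log2 p_b against a uniform background with
0·log 0 = 0. No small-sample correction is applied by default (the matrix
stays a pure function of the frequencies); the standard 3/(2·ln2·n) term is
available for logo-tool parity.

Each window reduces to its 47 overlapping dinucleotide steps; each step is
assigned the mean rigid-body parameters (Twist, Tilt, Roll in degrees;
Shift, Slide, Rise in Å) of that step in crystallographic protein–DNA
complexes — high values mark steps that protein binding readily deforms,
a proxy for local deformability ("flexibility"). The vendored 16-step table
follows the labelling convention in which a GC step has 36.1° Twist and
0.41 Å Slide and a GG step 32.9° and −0.22 Å (the reversed-step labelling
of the crystallographic compilation); these four values are asserted at
import. The table obeys reverse-complement symmetry exactly — Twist, Roll,
Rise and Slide invariant, Tilt and Shift sign-flipped — so pooling a window
set with its reverse complements provably yields midpoint-symmetric
(respectively antisymmetric) profiles, a property the test suite checks to
machine precision.

The flexibility profile is the per-position mean over windows; the control
envelope applies the identical reduction to each replicate control window
set (controls are given the experimental window geometry at their start
coordinate) and records the across-replicate mean and sd. Divergence is
quantified two ways:

- per position: z = (exp − ctrl_mean)/ctrl_sd, plus the empirical fraction
  of replicates at least as deviant (requires ≥ 30 replicates; sd = 0
  positions are flagged);
- per region: the mean profile deviation over a position slice (default
  the central third), standardized by the across-replicate scatter of the
  same region mean.

The region statistic exists because a *window-wide* flexibility preference
spreads its signal thinly over positions. Overlapping steps anti-correlate
(adjacent dinucleotides share a base), so the between-window sd of the
48-bp window-mean Twist (≈ 0.12°) is about three times smaller than step
independence would suggest; a selection shift of a fraction of that sd is
far below the per-position noise floor at realistic set sizes, while the
region mean detects it at high power. Per-position z-scores remain the
right tool for localized signals (e.g. a deformable step at the insertion
point itself).

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, at
desk scale (defaults: 1–2-Mb single-chromosome genomes, tens of genes,
hundreds to thousands of sites — every stage runs in seconds):

- genomes are i.i.d. base draws at a configured GC fraction (default 0.40,
  near the AT-rich genomes of the target organisms);
- gene models are non-overlapping spans (3–15 kb) with 2–6 exons of
  100–500 bp and 100–400-bp UTRs, mirroring vertebrate architecture where
  exons are a small fraction of mostly-intronic spans (the defaults give
  ~3–4% genome-wide exonic coverage); derived tracks (exons, introns, UTRs,
  coding, promoter windows, intergenic) are exactly consistent with the
  models;
- site placement is uniform per base, reweighted multiplicatively inside
  chosen tracks (a planted fold f yields an expected observable enrichment
  of f / (1 + (f−1)·coverage)) and around TSSs; a flexibility tilt accepts
  candidates with probability ∝ exp(β·z), where z is the candidate's
  48-bp window-mean step parameter standardized against 10^4 random
  windows (clipped to ±4 for an exact rejection bound), making β scale-free
  across parameters;
- fragment counts are lognormal (μ = 5.0, σ = 1.2 on the log scale, giving
  the few-to-several-thousand range typical of junction sequencing), with
  an optional fraction of count-1 noise calls planted within 10 bp of
  restriction recognition sites to exercise the stringent filter tier;
- expression tables draw expressed values ≥ 1 and silent values < 1 per
  timepoint according to each gene's planted class, so the threshold
  classifier recovers every class exactly at zero noise.

What the generator does **not** emulate: repeat families and low-complexity
sequence, chromatin tracks with realistic autocorrelation, mappability
structure, PCR chimerism, or sequencing error. Passing recovery tests
therefore demonstrates correctness of the statistical machinery on data
satisfying its assumptions, not robustness to every artifact of real
libraries.

## Pipeline and reproducibility

The `run` pipeline executes filter → controls → enrichment → gene context →
motif → flexibility from one YAML config. A single master seed is expanded
into per-stage seeds by hashing (blake2b of "master:stage", reduced below
2^31), so stages rerun in isolation reproduce full-run outputs byte for
byte. Control collections are persisted as one BED per replicate plus a
JSON manifest (mode, seed, per-site match keys). Flexibility envelopes in
the pipeline use the first 100 control replicates by default — the envelope
mean/sd stabilize well below that — while enrichment uses all N.

The statistical self-check (`scripts/acceptance.py`) and the corresponding
tests run at reduced replicate counts (N = 200 control sets rather than
1000, 200 features, 2-Mb genomes) — sizes chosen so the whole suite runs in
seconds while keeping the empirical P-value resolution (1/N = 0.005) an
order of magnitude below the 0.05 threshold being calibrated.

## Known limitations

- Restriction-matched controls ignore enzyme digestion efficiency and
  fragment-length selection beyond the distance key, and the absolute
  (unsigned) distance convention discards read orientation.
- Empirical P-values are bounded below by 1/N; claims beyond that
  resolution require more replicates, not extrapolation.
- Gene assignment is transcript-model-agnostic (one span per gene);
  isoform-aware UTR boundaries are not represented.
- The step-parameter table is a fixed compilation of protein–DNA complex
  means; it quantifies *average deformed geometry*, not a physical energy
  model, and trinucleotide or tetranucleotide effects are not modelled.
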