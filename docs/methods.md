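# Methods

## The analysis model

4C-seq inverts chromosome conformation capture around one viewpoint: after
cross-linking, primary digestion (DpnII), ligation, secondary digestion
(Csp6I) and re-circularization, inverse PCR with a viewpoint-specific
*reading primer* amplifies the ligated contact partners. Each sequencing
read is therefore primer + the sequence of a captured restriction-fragment
flank. The analysis consequently never maps to the whole genome: the
mapping space is the *frag-end reduced genome*, the set of sequences
directly flanking every primary cut site.

### Frag-end library

Both flanks of every primary fragment that abut a cut site yield a
frag-end (terminal fragment ends at chromosome boundaries yield none).
The stored sequence is the first `extract_len` bases of the fragment read
inward from the cut, truncated at the opposite fragment boundary.
Coordinates are 0-based half-open everywhere; cuts are placed at the motif
start for both enzymes. The secondary enzyme's true cut offset within its
motif is irrelevant here because the pipeline only uses the *presence* of
a secondary site per fragment (fragments without one are flagged *blind*;
they are retained in profiles by default). Frag-ends whose sequence occurs
more than once in the library — or contains `N` — are flagged non-unique
and excluded from read assignment, mirroring the removal of unmappable
frag-ends in alignment-based processing.

`extract_len` defaults to 36 bp, a typical trimmed read length; it is
configurable and nothing downstream depends on its exact value beyond
uniqueness resolution (shorter frag-ends are more often duplicated and
hence discarded, as in real data).

### Read assignment

Reads are synthetic and error-free at this scale, so exact string matching
replaces alignment: a read counts toward frag-end *f* when it begins with
the viewpoint's reading primer and the following bases equal *f*'s
sequence or its reverse complement (frag-end sequences are stored as
plus-strand text read inward from the cut; ligation orientation is
arbitrary, hence both strands match). Reads failing the primer, matching
nothing, or matching a non-unique frag-end are tallied separately;
assigned + discarded always equals the input read count. A
mismatch-tolerance knob is deliberately absent (default 0); the read
simulator produces no sequencing errors and the pipeline has no stage
whose behaviour would change qualitatively with a small mismatch budget.

### Filtering and normalization

The single highest-covered frag-end is removed before normalization (ties:
lowest coordinate, then chromosome name — deterministic). In practice this
is the self-ligation/undigested viewpoint frag-end, whose count would
otherwise dominate the scale factor. All remaining counts (cis and trans)
are then multiplied by s = 10⁶ / (cis sum), so intrachromosomal coverage
sums to exactly one million; s is recorded per replicate.

### Running mean

The displayed contact profile is a centered running mean over 21
consecutive frag-ends, computed per chromosome on coordinate-sorted
frag-ends. Within 10 positions of a chromosome edge the window shrinks
symmetrically to the largest centered window that fits (minimum 1):
mirrored or zero-padded alternatives were rejected because they fabricate
signal where none was measured. Smoothing is linear and, for signal lying
≥10 frag-ends from the edges, mass-conserving. The smoothed track is for
display only; all statistics run on the unsmoothed normalized values.

### Anchor test

Anchors are half-open windows [center − 5,000, center + 5,000) — 10 Kb
total; a frag-end belongs to an anchor iff its cut-site coordinate falls
in the interval (fragment midpoints would shift membership by at most one
fragment and are not used). Per replicate, the normalized coverage of the
member frag-ends is summed; groups are compared with the unpaired
Student's (pooled-variance) two-sample t test, two-sided p on
n₁ + n₂ − 2 df. Welch's variant is available behind a flag but is not the
default, matching standard practice for small equal-size replicate
groups. Zero pooled variance is resolved explicitly (equal means → t = 0,
p = 1; unequal → ±∞, p = 0) rather than returning NaN. Raw p-values are
the primary output — a Benjamini-Hochberg column is appended for
convenience only, since the canonical analysis reports uncorrected p per
pre-specified anchor.

### Allelic expression model

qPCR quantities enter as relative start concentrations; per sample they
are divided by the geometric mean of the reference genes (cTnI and Hprt
for heart tissue in the default simulation), which cancels any per-sample
loading factor exactly. Fold change is the ratio of arithmetic group
means. The two-allele model assigns each allele an activity (wildtype
≡ 1); total output is (a₁ + a₂)/2 of wildtype and the silenced allele's
transcript fraction is min(a)/Σa. A heterozygous deletion that fully
silences its allele — (1, 0) — predicts a 50% reduction with zero
transcript from the silenced allele (monoallelic expression); partial
activities model weaker regulatory elements but no default partial value
is asserted, because per-element residual activity is an empirical
quantity the model cannot derive.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not the biochemistry:

- **Genome** — random sequence at a configurable GC fraction (default
  0.45, vertebrate-like) with primary motifs injected at exponential
  spacings (mean 400 bp, close to the genome-wide density of a 4-cutter)
  and scrubbed from the intervening sequence, so frag-end density is
  controlled. Default shape: one 500 kb viewpoint chromosome plus one
  120 kb trans chromosome — large enough for ~2,500 frag-ends and anchors
  spanning 30–130 kb viewpoint distances, small enough that the full
  read-level Monte-Carlo tests run in about a minute.
- **4C reads** — cis frag-end weight `background_floor + (1 + d/s)^(−α)`
  with s = 2 kb, α = 1, floor = 0.002; trans frag-ends at the floor. The
  power-law-with-shoulder form is a standard phenomenological contact
  decay; the analysis fits no decay model, so only its qualitative shape
  matters. Genotype-specific effect regions multiply weights (default: one
  10 kb region at 60–70 kb from the viewpoint, multiplier 0.5 in the
  second genotype — a heterozygous enhancer deletion). Per replicate,
  20,000 cis and 2,000 trans reads are drawn by weighted sampling with
  replacement from the cis and trans weight vectors respectively, so
  per-compartment totals are exact; each read is primer + frag-end
  sequence at constant quality. Two genotypes × three replicates mirror a
  typical 4C replicate design.
- **Expression** — quantity = baseline × genotype multiplier ×
  log-normal biological noise (CV 0.15) × per-sample log-normal loading
  factor (CV 0.2), n = 5 per genotype; reference genes always carry
  multiplier 1. These CVs are typical of RT-qPCR biological replicates.

What the generator does **not** model: ligation and PCR-duplicate
structure (the pipeline has no duplicate-removal stage, so duplicates
would only rescale counts), sequencing errors (assignment is exact-match),
mappability beyond sequence duplication, and trans-contact enrichment.
Passing tests therefore demonstrate the pipeline's contracts and its
statistical calibration under clean multinomial sampling — not robustness
to PCR artefacts or alignment ambiguity in real libraries.

## Numerical and validation choices

- All randomness flows from one `numpy` `default_rng(seed)`; every
  generator and the end-to-end pipeline are byte-reproducible under a
  fixed seed.
- The running mean uses a cumulative-sum formulation; tests compare it to
  a naive sliding-window oracle at rtol 1e-12.
- The t kernel is validated against an independently coded textbook
  pooled-t closed form (|Δt| < 1e-10 on 1,000 random instances) and
  against `scipy.stats.ttest_ind`.
- Type-I calibration: 200 null Monte-Carlo repetitions of the full
  read-level pipeline (3 vs 3 replicates, 7 anchors) must give an
  empirical p < 0.05 rate inside the 99% binomial band around 0.05.
- Effect recovery: across 50 seeded repetitions of the default scenario
  the perturbed anchor's het/wt mean ratio is compared to 0.5 (±10%) on
  the across-repetition mean — single repetitions carry ~4% sampling CV —
  and p < 0.05 is required in ≥90% of repetitions. Note the recovered
  ratio is biased slightly above the raw multiplier (≈0.506 for these
  defaults) because renormalizing to 10⁶ cis reads redistributes the
  removed contact mass; the bias is bounded by the anchor's share of cis
  coverage and is well inside the tolerance.
- The expression fold-change recovery at n = 5/group averages 25 seeded
  cohorts: a single cohort's estimate has ~8% standard error at the
  default CVs, so the across-cohort mean is the statistically meaningful
  comparison against the configured 0.5.

## Known limitations

- Exact-match assignment cannot process real (error-containing) FASTQ
  data; swapping in an aligner would only change the `assign_reads`
  stage.
- Anchor membership uses frag-end coordinates, so an anchor boundary
  bisecting a fragment assigns each flank independently.
- The t test assumes approximately normal anchor sums; at very low read
  depth (tens of reads per anchor) the calibration test is expected to
  drift.
- `monoallelic_prediction` is a deterministic accounting identity, not an
  inference procedure; it says what expression *would* be under given
  allele activities, and cannot by itself explain intermediate reductions
  (e.g. ~30% for weaker elements) without a measured partial activity.
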