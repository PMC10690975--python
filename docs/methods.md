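# Methods

## The problem

Long third-generation reads (PacBio CLR, ONT) reach tens of kilobases but
carry 5–15% errors, dominated by spurious insertions and deletions; short
next-generation reads are two orders of magnitude more accurate but only a
few hundred bases long.  Hybrid error correction uses the short reads to
clean the long ones.  In samples containing several near-identical genome
copies — strains of one species in a metagenome, haplotypes of a polyploid
— the hard part is not finding disagreements but deciding *which*
disagreements are sequencing errors and which are genuine strain variation:
a corrector that majority-votes across strains "overcorrects", erasing the
very variation downstream assembly needs.

## The two-stage protocol

`haplec` corrects long reads in two stages, each applied iteratively.

**Stage 1 — de Bruijn pre-correction** (`haplec.dbg`).  Canonical k-mers of
the short reads are counted; a k-mer with count ≥ `t_solid` is *solid*.
Maximal solid stretches of a long read are anchors.  For each weak gap
between consecutive anchors, the implicit graph of solid k-mers is searched
(depth-first, within `max_branch` expansions) for paths from the last
anchor k-mer to the first k-mer of the next anchor whose length is within
`max_path_slack` of the observed gap.  With several strains present the
graph contains a bubble per divergent site, so admissible paths come in
haplotype-specific variants.  The gap is replaced by the path strictly
closest, by edit distance, to the read's own gap sequence.  Because errors
elsewhere in the gap penalize all candidate paths equally, the choice is
decided by the read's own bases at the divergent sites — the read is
corrected toward its own haplotype.  When the read is uninformative there
(it erred at the divergent site itself), or more than `max_paths`
candidates exist, the gap is left unchanged; head/tail regions outside the
outermost anchors are never touched; anchor bases are never modified.
This stage removes the bulk of the indel artifacts (on the synthetic
communities, ~10% raw error falls to ~1.5–2% after three passes), which is
what makes the short-to-long alignments of stage 2 trustworthy.

Defaults: `k=21`, `t_solid=3`, `max_branch=5000`, `max_path_slack=10`,
`max_paths=16`, three passes.  These follow common solid-k-mer practice;
the pass count reflects the observation (reproduced by the stage-wise
tests) that improvements stall after about three iterations.

**Stage 2 — phased overlap correction** (`haplec.overlap`, `phasing`,
`poa`).  Each pass:

1. *Mapping.*  A minimizer index (`k=15`, `w=10`) of the current long
   reads is queried with each short read; seed hits are clustered by
   diagonal per (long read, strand), clusters with ≥ 3 seeds are extended
   by banded edit-distance alignment (Myers bit-vector), and alignments
   with more than `max_edit_frac=0.30` edits per aligned base are
   discarded.  Query overhangs past the long-read ends are clipped before
   extension.  Indels are left-shifted within homopolymers so pile columns
   are comparable across reads.  A short read may align to many long reads
   (in a mixed sample the same locus exists on every strain); only the
   best alignment per (short, long) pair is kept.
2. *Pile and phase.*  All alignments onto one target read form its pile.
   Every column where some short read disagrees is classified from support
   counts alone (the target itself is not counted), with "strong" meaning
   ≥ `min_support = 5` reads: strong alternative + weak target support →
   the target carries an error (`TGS_ERROR`); strong support on both sides
   → a haplotype-specific SNP (`HAP_SNP`); weak disagreement (≤ 4 reads) →
   short-read errors (`NGS_ERROR`).  Deletion ("gap") observations are
   classified by the same rules, so indel-type strain variants behave like
   SNPs.  Every short read showing a strongly-supported out-of-phase
   allele at ≥ 1 `HAP_SNP` column is removed from the pile; a read whose
   alignment shows a gap at a base-SNP column is not removed for that
   column alone.  Target errors are *not* edited in place.
3. *Windows and consensus.*  The phase-filtered pile is cut into
   consecutive 500 bp windows; member alignments are sliced at window
   boundaries (clips < 20 bp dropped).  Windows with no evidence of a
   target error (no `TGS_ERROR` column, no strong insertion support) are
   left untouched — where every short read agrees with the target there is
   nothing to do.  Elsewhere the clipped segments are threaded one by one
   into a partial-order graph (match 3, mismatch −5, linear gap −4;
   segments are anchored to target coordinates and aligned within a
   diagonal band of 30, widened automatically when the score indicates a
   misfit); the consensus is the heaviest source-to-sink path and replaces
   the target subread; corrected subreads are concatenated back into the
   full-length read.  Columns before the first / after the last covered
   position keep the target's own sequence.
4. Passes repeat (default 3; the headline protocol uses 5); reads that a
   pass leaves unchanged are at a fixed point — a pass is a deterministic
   function of the read and the short-read set — and are skipped by later
   passes.

### Numerical and degenerate-input choices

* **Consensus objective.**  Edges of the partial-order graph count
  supporting sequences; the consensus path maximizes the sum of
  (weight − 1).  A raw weight sum is gameable: a stray error tail of a
  *single* segment contributes several weight-1 edges whose sum exceeds
  the one well-supported edge it bypasses, purely by being longer.
  Scoring support above the single-sequence baseline removes that bias;
  remaining short (≤ 8 edge) terminal weight-1 runs are trimmed, while
  long weight-1 runs (genuine single-coverage sequence) are kept.  On
  substitution-only windows this consensus provably equals the
  column-majority of the exact multiple alignment, which the tests check
  against an independent brute-force oracle.
* **Segment overhangs.**  Window segments are staggered, so a segment
  routinely extends past the current graph's last column.  The alignment
  is ends-free on the graph side, and the genuine overhang (bounded by
  the distance past the graph's last column) is threaded for free as new
  chain nodes.  Penalizing the overhang instead would bias the dynamic
  program toward chimeric in-graph alignments — with that scoring,
  error-free inputs were not fixed points.
* **Haplotype-SNP columns are final.**  At a `HAP_SNP` column the target
  base is, by construction of the classification, the strongly-supported
  in-phase allele.  The window consensus is therefore not allowed to
  change it: if out-of-phase contamination survives filtering and flips
  such a base, the target's own base is restored.  Without this guard a
  few percent of genuine SNP alleles were lost per protocol run.
* **Filter-induced coverage holes.**  Where the target still carries
  clustered indel errors, per-read gap placement is ambiguous and a few
  adjacent columns can show strong but artifactual allele splits whose
  removal sets jointly cover the whole pile.  A window whose *filtered*
  pile has an interior zero-coverage column is corrected from the
  unfiltered pile instead, with the target subread threaded first as the
  backbone (so exact allele ties resolve toward the target's haplotype).
  Windows whose unfiltered pile also has a hole, or fewer than
  `min_window_cov = 3` segments, keep the target subread.  This rescue
  runs during the first `rescue_passes = 2` overlap passes only: rescued
  regions are alignment-ambiguous by nature and successive passes would
  otherwise keep rewriting them slightly differently without net
  improvement; after the rescue passes such windows pass through
  unchanged.
* **Read ends.**  Short-read support tapers over the first/last tens of
  bases of each long read (seeding and clipping minima); those bases pass
  through uncorrected, which is visible as a small floor in the final
  error rates.  Weak head/tail trimming is deliberately off: the
  evaluator (and any downstream assembler) penalizes lost genome fraction
  more than it rewards slightly cleaner ends.

## The simulator

`haplec.simulate` generates a random ancestor, mutates it independently
per haplotype at the requested per-base divergence (a fraction
`indel_fraction`, default 0.1, of events are 1–3 bp indels, the rest
substitutions), and draws reads per haplotype to a requested coverage:
long reads with Normal(mean, 0.2·mean) lengths truncated at 1 kbp and an
indel-dominated error mix (ins:del:sub = 0.35:0.40:0.25 at 10% by
default), short single-end reads of fixed 250 bp with a
substitution-dominated mix (0.05:0.05:0.90 at 0.3%).  Abundance is
uniform by default with an optional log-normal mode.  Every read carries
its source haplotype and interval, and injected error events are tallied,
so phasing precision and error rates can be scored exactly.  Seeded runs
are bit-reproducible.

What it does **not** emulate: paired-end structure (the phasing logic
never uses pairing), platform-specific error profiles (homopolymer-length
dependent ONT errors, quality-value realism beyond a flat phred), GC or
coverage bias, and real strain phylogenies (every haplotype is
independently derived from one ancestor).  Consequently, passing tests
demonstrate the *logic* of haplotype-aware correction under realistic
error rates and coverages, not performance on any particular instrument's
reads.

## The evaluator

`haplec.evaluate` aligns each (corrected) read to its best haplotype and
strand (minimizer seeding, banded extension, acceptance threshold 35%
edits) and reports: indel errors per 100,000 aligned read bases (events by
default — one 3 bp deletion counts once — with a `count_bases` switch),
mismatches per 100 kbp, and genome fraction (percent of each haplotype
covered by ≥ 1 read alignment).  Each read is assigned to exactly one best
haplotype; reads with no acceptable alignment are counted unaligned.

## Reference experiment sizes

The headline comparison (scripts/acceptance.py) simulates three-strain
communities from a 200 kbp ancestor at 1% per-strain divergence with
10×/10× long/short coverage, corrects the long reads with the full
protocol (3 de Bruijn passes, then 5 overlap passes) and with the
de-Bruijn-only baseline (8 passes), and reports the percentage reduction
in indel and mismatch rates, averaged over three seeds (about 4–5 minutes
per seed on one CPU).  The test suite runs the same comparison at one
seed, adds two further seeds at a 60 kbp ancestor for the stage-wise
monotonicity check, and measures phasing precision and SNP survival on
two-strain fixtures (30–40 kbp, ~2% pairwise divergence).  Typical
outcomes on these fixtures: raw ~6800 indels/100 kbp → ~1800 after the de
Bruijn stage → ~130–230 after the overlap stage, an 85–95% indel
reduction relative to the de-Bruijn-only baseline, with ~80% mismatch
reduction, ≥ 95% of surviving pile members in phase with their target and
≥ 95% of planted haplotype-SNP alleles surviving correction.

## Known limitations

* The de Bruijn stage is a compact solid-k-mer corrector, not a
  re-implementation of any published tool; no claim of parity with
  dedicated pre-correctors is made or tested.
* Best-path gap filling can mis-assign a divergent site when the read's
  own base at that site is itself an error (about 1% of sites at 10%
  read error); downstream phasing does not recover those.
* Columns are classified independently; linkage between nearby SNP
  columns is only exploited implicitly through read-level removal.
* Very low-coverage regions (< `min_window_cov` segments, or single
  coverage at window ends) pass through uncorrected by design.
* The mapper keeps one alignment per (short, long) pair; a short read
  spanning a tandem duplication on the same long read contributes one
  placement only.
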