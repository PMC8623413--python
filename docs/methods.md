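# Methods

## Scaffold classification from sexed k-mer sets

Scaffolds deriving from the Y chromosome are present in male sequencing
reads and absent from female reads. The classifier indexes canonical k-mers
(strand-collapsed: the lexicographic minimum of a k-mer and its reverse
complement, packed 2 bits/base into an int64) of the assembly and of each
read set, then scores each scaffold by

    pct_unmatched = 100 · |valid ∖ female-present| / |valid|

where *valid* k-mers are those occurring exactly once in the whole assembly
(screening repeats shared between the Y and other chromosomes) and observed
at least once in the male reads (screening assembly artifacts).

Parameters and defaults:

* `k = 15` (accepted range 2–31; 15 balances specificity against the read
  length and fits in an int64 with room to spare).
* `min_valid = 20` — scaffolds with fewer valid single-copy k-mers are
  uninformative and reported `unclassified`.
* `cutoff = 60` (%) — a scaffold is `Y` iff `pct_unmatched ≥ cutoff`; the
  tie at exactly the cutoff goes to `Y` so the rule is deterministic. The
  bimodality of real and simulated score distributions makes the result
  robust to the cutoff (summaries report 60 and 80 side by side; the Y
  total is non-increasing in the cutoff).
* `female_min_count = 1`, `male_min_count = 1` — a single supporting read
  counts as presence. A higher female threshold would mask sequencing
  errors; it is exposed as a flag because the right value depends on depth.

Misassembled repetitive scaffolds occupy the valley between the two modes
of the histogram; they are still assigned by the cutoff rather than given a
third class, and the histogram (1% bins) is part of the summary so they
remain visible.

A deliberately naive reference implementation (`ytraffic.reference`)
recomputes the same quantities with explicit Python sets of k-mer strings;
the fast path is required to agree with it exactly on small genomes, and
does (to 0.0 on the 2.2 Mbp validation genome).

## Depth-based segmental-duplication detection

With male and female depth normalized to their autosomal diploid baselines
(median bin depth over confidently autosomal scaffolds — robust to the very
duplications being sought), one hemizygous Y copy of an autosomal region
adds 0.5 to the normalized male track, so *n* copies give ≈ 1 + n/2 while
the female track stays at 1. The caller:

1. bins per-base depth into fixed windows (`bin_bp = 1000`; bin mean = sum
   of per-base depth / actual span, last bin may be shorter);
2. marks bins elevated when normalized male ≥ `min_male_norm = 1.4` and
   normalized female < the same threshold (1.4 leaves headroom below the
   1.5 expected for a single copy while staying well above baseline noise
   at ≥ 20×);
3. merges elevated runs bridging up to `max_gap_bins = 5` cool bins and
   emits runs spanning ≥ `min_len_bp = 10 kb`, bin-aligned;
4. estimates `est_copies = round(2 · (mean male − mean female))` over the
   call, flooring at 1 with a low-confidence flag.

Replacing visual inspection of coverage tracks with this explicit
threshold-run-merge rule is the one place the pipeline substitutes an
algorithm for human judgment; all thresholds are exposed.

Depth never comes from an external aligner: it is accepted as a per-base
TSV (the shape standard depth tools emit) or computed by the internal
placer, which locates error-free reads on the reference by their first
31-mer and verifies by full comparison (first position in reference order
wins on ties). For diverged Y copies, whose reads no longer exact-match,
the simulator's provenance can be projected onto source coordinates
instead; this is how the male-specific SNP check is exercised. A
male-specific SNP site requires an allele with ≥ 3 male reads, ≥ 10% of
male depth, zero female reads and female depth ≥ 5 — so it cannot be
produced by a sequencing error or a thin female pileup.

## Gene-fate classification

A gene copy is **functional** iff its CDS is intact and it contributes
> 10% of its copy group's expression; otherwise it is a **pseudogene**.

* CDS integrity is judged against the reference (source-copy) CDS via
  global alignment with affine gaps (match 1, mismatch −1, open −4,
  extend −1 — ordinary DNA scoring; nothing downstream is sensitive to the
  exact scheme). Indels whose *net* length is not a multiple of 3 shift the
  frame (compensating indels that restore frame count as intact-frame); an
  in-frame stop before the final codon is a premature stop; an empty or
  less-than-half-length candidate is truncated. When several defects
  co-occur the frameshift is reported, with the defect position as the
  reference codon index where the frame first leaves register.
* The expression denominator is the summed TPM of the whole copy group
  (Y + autosomal copies). A pairwise mode (Y copy vs its counterpart only)
  is exposed because the two readings coincide only for two-copy groups;
  group share is the default as the more conservative generalization.
* Copies at ≥ 96% nucleotide identity to their counterpart are flagged
  recent; full-length copy *counting* for catalog tables uses a separate
  ≥ 95% rule. Identity is identical columns / total alignment columns.

Mechanism calls: membership in a called segmental duplication ⇒ DNA
duplication; otherwise ≥ 1 exactly shared CDS-relative intron position with
the outgroup ortholog ⇒ DNA duplication; an intron-less outgroup (or no
outgroup data) ⇒ undetermined. Outgroup introns missing from the Y copy
alone are *not* taken as evidence of an RNA intermediate, because intron
loss is lineage-specific in some groups and would masquerade as
retro-transposition.

## Parsimony mapping and the gain–loss ratio

Each gene is assumed gained on exactly one branch (a single
duplication-to-Y; recurrent gains are out of scope). A scenario consists of
the gain branch plus per-lineage losses of the source copy (wherever a leaf
shows Y or absent) and of the Y copy (wherever an in-clade leaf shows XA or
absent); unknown states are free. Minimal loss sets are computed as the
maximal subtrees whose leaves may all lose the copy and that contain at
least one leaf that must — which is provably minimal and matches exhaustive
enumeration over every (branch × loss-subset × loss-subset) scenario on
all 175 informative state patterns of a 4-leaf tree. Ties among equal-cost
gain branches are broken toward the most recent branch (greatest root
distance) and the alternatives are reported rather than discarded.

Rates: gains ~ Poisson(g · T_gain) with T_gain the summed branch time in
My; losses ~ Poisson(l · T_loss) with T_loss the summed gene-My of
Y residency. Within-branch event times are unknown for scenario-derived
maps, so exposures use midpoint conventions: a gene contributes half its
gain branch, full descendant branches while resident, half of each loss
branch (a quarter when gain and loss fall on the same branch). ML estimates
are ĝ = G/T_gain, l̂ = L/T_loss; the ratio ĝ/l̂ is dimensionless after this
exposure normalization ("per gene per My" on the loss side). The p-value is
a 1-df likelihood-ratio test of g = l; the 95% CI profiles the likelihood
over ρ = g/l (the nuisance rate maximizes in closed form,
l̂(ρ) = (G+L)/(ρT_gain+T_loss)), with bounds solved by Brent's method on
log ρ to 1e-9. Zero observed losses yield a flagged lower-bound estimate
(finite ci_low, infinite ci_high); zero gains the mirror image. Genes whose
source copy is still functional — recent duplications that could yet
resolve either way — can be excluded via an explicit gene list to mirror
paired analyses with and without them.

## The synthetic-data generator

The generator emulates exactly the features the pipeline keys on, with
ground truth emitted as a sidecar (never encoded in sequence headers):

* **Genomes** — i.i.d. nucleotides at the configured GC, with a planted
  library of repeats (six sequences, 0.5–5 kb, capped for small scaffolds)
  shared between Y and autosomal scaffolds so single-copy filtering is
  actually stressed. Outside planted repeats, Y background windows whose
  canonical 15-mers collide with the autosomal scaffolds are re-randomized,
  so with `repeat_fraction = 0` the two classes are provably k-mer-disjoint.
  Same spec ⇒ byte-identical FASTA.
* **Reads** — single-end, fixed length (100 bp default; real library
  layouts vary but pairing adds nothing to the logic under test), uniform
  starts, i.i.d. substitution errors. Autosomes at `depth`; Y at
  `depth · male_fraction / 2` (0 for females, half-depth for males,
  quarter-depth for a 50/50 pool — the hemizygosity arithmetic that also
  gives `expected_y_depth(8.4, 0.5) = 2.1`).
* **Segmental duplications** — mutated copies of a source interval appended
  as new Y scaffolds, with per-copy substitution and 1-bp indel rates and
  full event lists in the truth record; zero rates conserve content
  exactly.
* **Pseudogenization** — per-internal-codon premature stops and 1-bp
  frameshifting indels (start and terminal stop codons exempt), so the
  probability of ≥ 1 stop is exactly 1 − (1 − r)^(codons − 2).
* **Event histories** — per-branch Poisson gains (uniform gain times),
  exponential per-lineage losses propagated down the tree with exact
  residency bookkeeping, so the simulator's event map is its own truth.

What the generator does **not** model — realistic repeat evolution,
quality-score structure, paired ends, coverage biases, alignment ambiguity
from true biological repeats, annotation error — bounds what the validation
shows: passing tests demonstrate the *inference logic* is correct under the
stated model, not that real-data preprocessing (trimming, mapping,
quantification, ortholog assignment) is solved, which is why those steps
are consumed as tabular inputs rather than reimplemented.

## Validation study conditions

Chosen to exercise each stage at a desk-scale size (all figures recomputed
by `scripts/acceptance.py` and asserted in `tests/test_acceptance.py`):

* Scaffold classification: 20 autosomal + 10 Y scaffolds of 75 kb
  (2.25 Mbp), 10% shared repeats, GC 0.45, error-free 10× sexed reads.
  Expected: 100% accuracy on informative scaffolds and exact agreement with
  the string-set reference.
* Duplication recovery: 10 copies of a 200 kb interval of a 1 Mbp scaffold,
  20× reads; boundary error ≤ 1 bin, copy number within ±1.
* Gene fates: 32 copies cycling intact / premature-stop / frameshift /
  silenced (3% share); each disabled copy carries exactly one defect type
  because compensating indel pairs are intact-frame by design and would
  have no well-defined truth label.
* Parsimony: all 175 Y-containing patterns on a balanced 4-leaf tree
  against exhaustive enumeration.
* Estimator: 200 histories on a 5-leaf, 70-My tree at g = 0.5/My,
  l = 0.05/gene-My (true ratio 10), conditioned on ≥ 30 events by
  redrawing; median ratio and 95% CI coverage are checked.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open internally; reports print kb with
size = end − start (no +1). k-mer windows containing non-ACGT symbols are
excluded everywhere. Empty k-mer indexes, scaffolds shorter than k, empty
scenario sets and all-zero expression groups are defined (empty/flagged)
rather than errors; zero baselines, negative rates/depths, mismatched k
between indexes, out-of-scaffold intervals and loss-before-gain scenarios
raise. The profile-CI bracket is expanded in unit steps on log ρ before
root-finding, so the interval is deterministic to solver tolerance.

## Known limitations

* The segdup caller reports bin-aligned coordinates; breakpoint assembly
  and split-read evidence are out of scope.
* The exact-match placer requires error-free reads and fixed read length;
  it is a validation tool, not an aligner.
* Copy-number inversion assumes the diploid source locus is still present
  and collapses intra-Y copy heterogeneity into one mean.
* The parsimony scenario space excludes recurrent gains and
  back-duplications off the Y.
* The estimator conditions on the reconstructed event map; uncertainty in
  the parsimony reconstruction is surfaced as reported ties, not propagated
  into the CI.
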