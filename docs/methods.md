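# Methods

## The experimental design being modelled

A conditional gRNA-array transgene holds an ordered set of guides behind
a single U6 promoter; recombinase activity in each germline stem cell
(GSC) irreversibly commits one guide per array copy, with commitment
probability proportional to a per-guide weight. Cas9 can be restricted to
post-GSC germ cells, so that each offspring of a founder male carries an
independent double-strand-break repair outcome ("independent" mode), or
expressed already in GSCs, in which case a GSC's outcome is inherited by
all of its offspring ("clonal" mode). With two array copies a germ cell
holds one or two distinct guides; two distinct cuts made in the same cell
can resolve as one deletion spanning the inter-cut interval (a *defined*
or inter-target deletion), as independent indels at both sites, or as an
indel at a single site.

Genotyping is by amplicon sequencing: reads over the targeted region are
trimmed, locally aligned, and indel events are extracted and aggregated
per offspring.

## Coordinates, cut sites and event representation

All coordinates are 0-based half-open on the forward strand of each
amplicon. The SpCas9 cut is taken as blunt, 3 bp 5′ of the NGG PAM
(between protospacer positions 17 and 18); only NGG PAMs are accepted.
Guides on different amplicons never form defined deletions — a deletion
spanning two amplicons is handled by supplying the joined sequence as a
single (extended) reference.

An event is a deletion `D`, an insertion `I`, or a large gap `L`. `L`
collects deletions of at least `large_gap_min_bp` (default 40) and any
deletion carrying embedded inserted sequence at its junction. The kind is
assigned by this shared rule in both the simulator's ground truth and the
caller, deliberately: which *mechanism* surfaces a deletion (a CIGAR `D`
run versus a soft-clip rescue) depends on read geometry and is not a
stable property of the allele, so tying `L` to rescue provenance would
make truth comparisons ill-defined. Mid-size deletions genuinely surface
both ways across the reads of one sample.

The same physical edit admits many alignment representations (deletions
shift across flanking repeats; inserted bases matching the reference get
absorbed into flanking matches). Every event — simulated or called — is
therefore reduced to a canonical form: inserted bases matching the
deleted interval's edges are stripped, and the residual pure deletion or
insertion is left-aligned. Equality of event sets is always equality of
canonical forms.

## Simulator

Defaults encode the study conditions the model emulates:

| parameter | default | meaning |
| --- | --- | --- |
| `gsc_count_range` | 12–24 | GSCs per founder male |
| `edit_rate_ceiling` | 0.35 | probability an offspring is edited at all |
| `inter_target_prob` / `double_site_prob` | 0.082 / 0.154 | category draw, conditional on an edit in a germ cell with two distinct active guides |
| `dual_cut_min_separation` | 40 bp | cuts closer than this cannot resolve as one inter-target deletion (steric suppression); such draws fall back to single-site |
| deletion size | geometric extents, mean 4 bp per side, total in [1, 100] | single-site deletions centred on the cut |
| insertion size | geometric, mean 2 bp, random bases | `insertion_prob` = 0.2 of single-site outcomes |
| `l_insertion_prob` | 0.3 | chance an inter-target junction carries inserted bases |
| `founder_count` / `offspring_count` | 16 / 30 | cohort size; offspring per founder |
| reads | 500 per amplicon, 150 bp, error 1e-3 | single-end; fragment starts uniform, lengths geometric (mean 300 bp), short fragments padded with the library adapter |

The category probabilities are conditional on *two distinct* committed
active guides. With two identical equal-weight 4-guide arrays, a quarter
of germ cells commit the same guide twice, so the marginal inter-target
share among all edited offspring is about three quarters of the
configured value; the acceptance script therefore reports the spectrum
conditional on distinct committed pairs, which is the quantity the
parameters define.

Ground-truth consistency is guaranteed by construction: an outcome's
events are redrawn (bounded rejection, ≤100 tries) until the cohort
classifier assigns the drawn category, and the stored category is the
classifier's. This keeps "truth category" and "category recomputed from
truth events" identical for every genotype, at the cost of truncating a
vanishing tail of the indel-size distribution (e.g. a single-site
deletion long enough to reach a neighbouring cut site would be
re-drawn). Clonal mode assigns each GSC a Poisson offspring count (mean
`offspring_count / GSC count`); per-GSC fecundity is otherwise not
modelled.

What the generator does **not** emulate: sequence-dependent repair
spectra (microhomology bias — real single-site deletions are far less
entropic than the geometric model, so absolute unique-allele fractions
run higher here than in real screens, ~97% vs ~20% for the two germline
modes; the *direction* of that contrast, not its magnitude, is the
modelled claim), base-quality structure, PCR chimeras/duplicates,
paired-end geometry, heterozygosity (one allele per offspring), and
female germline or maternal Cas9 carry-over.

## Trimming, alignment, calling

Trimming removes the longest read suffix matching a prefix of the
configured adapter with at least 7 bases of overlap and a mismatch
fraction ≤ 0.1 (budget rounded down); reads shorter than 30 bases after
trimming are discarded. Up to 6 terminal adapter bases are undetectable
by construction; they end as terminal soft-clipped bases downstream and
never reach an event.

Alignment is best-score local (Smith–Waterman, affine gaps) of each read
against each amplicon, keeping the best-scoring amplicon. Scoring
defaults are match +2, mismatch −6, gap open −5, gap extend −3, floor 20
— the penalty shape of a local short-read mapper. The mismatch:gap ratio
matters: with a mild mismatch penalty, one- or two-base junction
insertions score better as mismatched columns than as gaps and the
caller would systematically mis-place junctions. Ties are broken by
leftmost reference start, then fewest gap openings. Two guards make
junction calls representation-stable:

* **Minimum anchor** (`min_anchor`, 12 bp): a terminal match segment
  shorter than this hanging off a gap is folded back into the soft clip.
  Without it, the aligner "creeps" across a large-gap junction whenever
  a few post-junction bases coincidentally match the reference just
  beyond a 1-bp gap (net score gain), yielding phantom micro-deletions.
* **Mismatch fold-back**: mismatched alignment columns immediately
  flanking a deletion are folded into the event as inserted sequence
  before canonicalisation, undoing the aligner's absorption of inserted
  junction bases.

Event extraction walks the CIGAR (`N` is treated as `D`); adjacent gap
runs merge into one junction event. Soft clips of ≥ `min_clip_length`
(15 bp) are re-aligned to the second-pass reference (the same amplicon,
or a supplied extended reference containing it); a unique, same-strand,
colinear placement strictly beyond the primary mapping closes an `L`
event whose unexplained middle bases become the embedded insertion.
Ambiguous (two equal-score placements), inverted, or non-colinear clips
produce no event and are tallied in the run summary. Events identical in
(sample, kind, region, interval, insert) merge with summed support — one
read contributes at most once to an event — and events with support
below `min_support` (10) are discarded; the comparison is strict, so
support 10 survives. Reads supporting the unedited allele are reported
only in the run summary.

## Cohort statistics

A deletion whose endpoints each lie within `window_bp` (20 bp, chosen to
cover the dominant ≤20 bp single-site spectrum while keeping ~100 bp
spaced targets separable) of two distinct cut sites marks an offspring
inter-target; `D` and `L` deletions are treated alike here, for the
provenance reasons above. Otherwise each event is assigned to the
nearest cut site within the window; one implicated guide means
single-site, two mean double-site. Offspring whose events implicate no
guide are single-site when the events form one spatial cluster and are
otherwise flagged ambiguous and excluded from the use matrix and
category proportions. The use matrix increments the diagonal for
single-site offspring and both symmetric cells for two-guide offspring.

Allele identity is the canonical string of the sorted event set;
uniqueness is the fraction of edited offspring whose key occurs exactly
once (within founder, when requested). The reading-frame statistic
reduces each edited offspring's net length change modulo 3 and applies
an asymptotic Pearson χ² test against equal thirds (df = 2, no
continuity correction). Per-base deletion coverage counts each offspring
at most once per position (its intervals are unioned first); maximal
zero-coverage intervals are reported with any cut sites they contain.

## Numerical and reproducibility choices

One seeded NumPy generator drives commitment, outcomes and reads in
order, so a config reproduces byte-identical FASTQ and truth tables. The
test suite and acceptance script use scaled-down cohorts (hundreds of
offspring, 300 reads per amplicon) chosen so that every true event's
expected support comfortably clears the filter (~50 reads at a junction)
while runs complete in about a minute; the statistical checks state
their tolerances in binomial standard errors at the simulated sample
size. The χ² worked example in the tests is validated against an
independent brute-force Pearson computation rather than any quoted
figure.

## Known limitations

* No SNV calling, no base-quality use, no paired-end or UMI support.
* Inversions and trans-placed clips are logged, never called.
* The internal aligner is exact Smith–Waterman per amplicon — fine for
  amplicon panels, not a genome mapper; externally produced SAM can be
  ingested instead.
* Defined deletions across unjoined amplicons require the user to supply
  the joined reference (`extended_reference`).
* Heterozygous offspring (two alleles per sample) are out of scope; all
  statistics are per offspring, one allele assumed.
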