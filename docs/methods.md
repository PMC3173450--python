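# Methods

## Problem setting

SR proteins (serine/arginine-rich splicing factors, with one or two
N-terminal RNA recognition motifs and a C-terminal RS domain) are both
regulators and targets of alternative splicing (AS). Measuring how much AS
an SR gene undergoes from EST/cDNA evidence poses three methodological
problems that this package addresses in sequence:

1. turning a set of transcript-to-genome exon chains into a per-gene splice
   graph and a defensible *count* of AS events of five types;
2. making those counts comparable across organisms (or sub-families) whose
   EST depth differs by orders of magnitude;
3. assembling the gene family in the first place: architecture filters on
   candidate proteins and statistics on the RRM alignment used as the
   phylogenetic marker.

## Splice graph

All coordinates are 0-based half-open, genomic orientation; transcription
orientation enters only in event typing. The union of exons is cut at every
distinct exon boundary into *segments*; junction edges are intron intervals
and adjacency edges connect consecutive segments covered by one exon, each
with per-transcript support sets. Every chain is exactly reconstructible
from its segment path, so the graph loses no evidence. Identical chains are
kept as distinct supporters because the site-choice rules below weight
splice sites by transcript pluralities. There is no minimum junction
support by default (`min_junction_support=1`); when raised, low-support
junctions are ignored as event candidates but transcripts keep their true
structure.

## Event counting rules

Five types are counted per gene; the unit is the supported *pattern* or
*site*, not the supporting read, so re-sequencing the same isoform never
inflates a count.

**Intron retention (IR).** An intron is retention-capable when it lies
entirely inside a single exon of another transcript. Capable introns
observed (retained or spliced) by a common transcript are clustered; each
transcript observing a whole cluster votes the bit vector of introns it
retains, and the count is the number of distinct supported vectors with at
least one retained intron. The all-spliced vector is never an event, so a
locus whose transcripts either splice or retain two introns jointly counts
one event, while three supported retention combinations count three.
Transcripts that only partially overlap a cluster (EST truncation) vote
single-intron patterns where they fully contain the intron — truncation can
therefore hide combinations but never fabricate them.

**Skipped exons (SE).** An internal exon is skip-capable when a single
intron of another transcript spans it while sharing the flanking splice
sites of the skipped block (a block of consecutive cassette exons may be
skipped by one intron). Counting is exactly analogous to IR: distinct
supported skip combinations per cluster of co-observed cassette exons.

**Alternative 5'/3' sites.** Candidate introns — junctions that are neither
retention-capable nor skip-explaining, so one observation is never typed
twice — sharing one boundary are grouped per shared boundary. Within a
group the *prevalent* site at the varying end is the reference: plurality
of supporting transcripts, ties resolved toward the site yielding the
longest intron, residual ties toward the leftmost genomic position (the
last rule is a determinism choice; it is the one place where counting is
not invariant under coordinate reflection). Every non-reference site is
one event. Variation at the transcription-5' end of the intron (the donor;
genomic start on `+`, genomic end on `-`) is Alt5, at the acceptor Alt3.
Transcript terminal boundaries are never alternative sites: ESTs are
routinely 5'/3'-incomplete and their endpoints carry no splice-site
information.

An intron sharing *neither* boundary with any other candidate it overlaps
deviates from the locally prevalent intron at both ends; unless it is
itself the locally prevalent form, it contributes one Alt5 and one Alt3.

**Alt B.** When a deviant donor and a deviant acceptor occur on the same
intron variant and neither deviant end is ever observed independently on
any other intron, the Alt5/Alt3 pair collapses into a single joint event;
each merge reduces both tallies by one. A deviant donor that also appears
with the reference acceptor blocks the merge.

Two properties worth stating precisely. First, IR/SE counts are invariant
under duplicating any transcript (distinct-pattern counting), and *all*
counts are invariant under duplicating every transcript (uniform evidence
scaling). Duplicating a single transcript can, however, change which intron
is the local reference where introns share no boundary, and thereby change
the alt-site tally in either direction — with plurality-based references
this is unavoidable, and it is why only the pattern-based half is asserted
as an invariant. Second, relabeling the strand with coordinates unchanged
swaps Alt5 and Alt3 exactly and leaves IR/SE/AltB untouched, whereas
reflecting coordinates *and* flipping strand is an isomorphism in
transcription space and preserves all five counts up to the leftmost
tie-break.

## Resampling normalization

Deeper EST sampling finds more events, so raw per-organism fractions are
not comparable. The normalization draws a fixed number of ESTs per gene
(`n_est`, default 15) uniformly **without replacement** (with-replacement
draws would duplicate evidence and distort support pluralities), over
`trials` (default 100) trials in `replicates` (default 3) independent
replicates. Genes with fewer than `n_est` chains are omitted and listed,
never kept in denominators; a gene with exactly `n_est` is eligible. The
reported statistics are, per (replicate, group): the mean over trials of
(genes with any AS / genes used), and the mean per-type event count per
gene *experiencing* AS in that trial. Trial-level tallies are retained for
audit.

Randomness uses a master seed spawning per-(replicate, trial, gene)
substreams keyed by a CRC of the gene id, so results are independent of
input order and adding a gene never perturbs another gene's draws. When
`n_est` equals every gene's depth, each draw is the whole EST set and the
normalized fraction equals the plain fraction with zero variance — the
unnormalized census is the limiting case of the same code path.

## SR-protein identification and RRM-alignment statistics

A candidate is accepted when all rules hold, and the verdict names every
rule that failed:

* `evalue` — domain hits with e-value strictly greater than `1e-3` are
  excluded; a protein whose RRM hits all fail the cutoff is rejected for
  that reason (equality is kept).
* `met_start` — the sequence must begin with methionine (guards against
  truncated gene models).
* `rrm_count` — exactly one or two surviving RRM hits.
* `rrm_position` — the RRMs must be N-terminal: three or more RS/SR
  dipeptides strictly before the first RRM mark a reversed architecture.
  This operationalizes "N-terminal RRMs" without a fixed percentage cutoff,
  anchoring it to the observable that actually distinguishes the family
  (an RS region preceding the RRMs).
* `rs_dipeptides` — the region downstream of the last RRM must contain at
  least three non-overlapping RS or SR dipeptides (RS and SR are treated
  interchangeably, as the literature does for RS-domain composition).

Alignment post-processing mirrors the preprocessing used before gene-tree
inference: per-protein N-/C-terminal RRM blocks are concatenated (single-RRM
proteins gap-filled in the C block, with every aligned row checked to degap
to the residues cut by the domain coordinates); columns whose residues come
from at most one sequence — columns that would be gap-only but for a single
unalignable insertion — are removed (idempotent); identical gapped rows are
collapsed to the first-seen representative, with the absorbed ids reported
rather than a hard-coded reduction count, since several duplicate groups
may each absorb members. Column classification treats gaps and `X` as
missing (the protein-parsimony convention): a column with at most one
residue state is constant, one with two or more states each in two or more
sequences is parsimony-informative, and any other variable column is
uninformative. All-missing columns count as constant (nothing varies); the
three classes partition the columns by construction.

## Synthetic data

The generator emulates locus-by-locus EST retrievals: a reference gene with
4–8 exons (80–300 bp) and 60–250 bp introns, one derived isoform per
planted event (retain an intron, skip a cassette exon, shift a donor, an
acceptor, or both ends jointly by 10–50 bp into the flanking exons), and an
EST set of configurable depth (default 8–40, straddling the 15-EST
eligibility threshold) in which a variant isoform is drawn with probability
0.35 and either end may be truncated (default off; geometric number of
whole terminal exons). Default per-type rates (IR 0.3, SE 0.2, Alt3 0.3,
Alt5 0.2, AltB 0.05) mirror the observed prevalence ordering in SR genes —
alternative 3' events most common, joint 3'+5' events rarest.

Planted events occupy disjoint intron/exon slots (an SE event also reserves
its flanking introns), so each contributes exactly one event and the
expected census is exact; a configuration that cannot host its planted
events (for example a single-exon gene with a planted skip) raises a
generation error rather than silently adjusting. Joint-shift isoforms never
expose either deviant end alone, honoring the Alt B pairing condition.
Truncation trims whole terminal exons only, so truncated ESTs are valid
chains that introduce no novel boundaries — which is also why detected
events can only be lost, never invented, under truncation.

What the generator does **not** emulate: sequencing error and chimeric
ESTs, alignment ambiguity at splice sites, within-exon truncation,
non-uniform isoform abundance beyond the single minor-isoform probability,
and genes with several events of the same type. Passing the recovery suite
therefore shows the counting rules are implemented exactly, not that the
pipeline is robust to alignment noise — on real data the upstream spliced
aligner owns that problem.

Protein-family and alignment generators plant violations of exactly one
architecture rule per protein (random regions avoid R/S so no stray
dipeptides arise) and column-class compositions realized row-wise
(informative columns need at least four rows), for cross-validating the
filters and the classifier against known labels.

## Problem sizes and numerical choices

The test suite and the acceptance script run the worked counting examples
(2–7 transcripts), 500 random small loci (≤4 exons, ≤5 transcripts) against
an independent brute-force enumerator, 200-gene recovery cohorts with and
without truncation, a 30-gene × 100-trial × 3-replicate normalization
recovery (a cohort built so a 60% AS fraction is visible in every 15-EST
draw, recovered within three binomial standard errors), and a 48-protein
filter cross-validation; these sizes give exact or tightly bounded
expectations while keeping a full run in seconds. All randomness flows from
explicit integer seeds through `numpy` generators; reports are written
atomically; ties everywhere break deterministically (support, then intron
length, then leftmost position).

## Known limitations

* Gene grouping comes from the input annotation; no transcript clustering
  is performed (chains are assumed pre-assigned to loci, as when ESTs are
  retrieved per gene).
* Mutually exclusive exons and alternative first/last exons are outside the
  five-type taxonomy and are not counted.
* The published 255-sequence RRM alignment is not redistributable here; the
  column-classifier check against its printed 28/267/58 partition runs only
  when that FASTA is supplied at `data/dataset_s1_rrm_alignment.fasta`, and
  the corresponding acceptance test fails loudly otherwise.
* Whether the original normalization sampled with or without replacement is
  not stated in the source material; without replacement is the package's
  choice, for the evidence-duplication reason above.
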