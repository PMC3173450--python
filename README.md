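# srcensus

A splice-graph census of alternative splicing (AS) in SR genes — the
serine/arginine-rich splicing factors with one or two N-terminal RNA
recognition motifs (RRMs) and a C-terminal RS domain. The package is aimed
at comparative transcriptomics of gene families: it takes transcript exon
chains (EST/cDNA alignments) per gene locus, builds per-gene splice graphs,
counts five AS event types under combination-counting rules, and
normalizes the measurements by fixed-depth EST resampling so organisms or
sub-families with wildly different EST coverage can be compared. It also
implements the SR-protein architecture filters and the RRM-alignment
statistics (sparse-column removal, duplicate collapsing, constant /
parsimony-informative / uninformative column classification) used to
assemble such a family, plus a synthetic-data generator that produces every
input with known ground truth.

## The counting model

For a gene with aligned transcripts *T*, the exon union is segmented at
every exon boundary and each transcript traces a path over segments;
introns are junction edges with per-transcript support. Events:

* **IR** — an intron contained in another transcript's exon; retained
  introns co-observed by common transcripts form clusters, and the count is
  the number of distinct supported retention combinations (bit vectors)
  with ≥1 retained intron. Two introns retained only jointly count once.
* **SE** — an internal exon spanned by a single intron sharing the flanking
  splice sites of the skipped block; counted by distinct skip combinations,
  analogously to IR.
* **Alt5 / Alt3** — introns sharing one boundary; the reference at the
  varying end is the *prevalent* splice site (plurality of transcripts,
  ties to the longest intron), and each non-reference site is one event.
  Sidedness follows transcription orientation (5' = donor).
* **AltB** — a deviant donor paired with the same deviant acceptor in all
  transcripts collapses the Alt5/Alt3 pair into one joint event.

Normalization draws a fixed `n_est = 15` chains per gene without
replacement over 100 trials in triplicate and reports the mean fraction of
genes with any AS and the mean per-type events per AS gene; genes below the
depth cutoff are excluded and listed. See `docs/methods.md` for the full
rules, tie-breaks and design rationale.

## Worked example

The shipped fixture `fixtures/panel_b.bed` encodes a locus with two
retained introns supported in three combinations, two alternative donors
and one alternative acceptor at the last junction:

```python
>>> from srcensus import read_exon_chains, count_events
>>> (chains,) = read_exon_chains("fixtures/panel_b.bed", "bed12").values()
>>> counts, events = count_events(chains)
>>> counts.as_tuple()   # (IR, SE, Alt3, Alt5, AltB)
(3, 0, 1, 2, 0)
>>> sorted(e.pattern for e in events if e.type == "IR")
[(0, 1), (1, 0), (1, 1)]
```

Three IR events — the three supported retention combinations over two
introns, not "two retained introns" — plus two alternative donors (Alt5)
and one alternative acceptor (Alt3) against the plurality-supported sites.
The same census from the shell, plus a normalized cohort run:

```
srcensus events --chains fixtures/panel_b.bed --format bed12 --out events.tsv
srcensus simulate --out-dir sim --seed 3 --n-genes 20
srcensus normalize --chains sim/chains.bed --n-est 15 --trials 100 \
    --replicates 3 --seed 17 --out report.tsv
```

`events.tsv` contains one row per gene
(`gene_id  n_transcripts  IR  SE  Alt3  Alt5  AltB  any_AS`), here
`panelB  7  3  0  1  2  0  True`; `report.tsv` holds the per-replicate,
per-group mean AS fraction with its trial spread and the per-type means per
AS gene, with numerators and denominators always printed.

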