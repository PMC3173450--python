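"""Detection and combination-counting of the five alternative-splicing event
types from a per-gene splice graph.

Event taxonomy and counting rules
---------------------------------

* **IR** (intron retention): an intron spliced by some transcripts but lying
  entirely inside a single exon of another. Retained introns observed by
  common transcripts are clustered, each transcript contributes the
  *combination* of introns it retains as a bit vector over the cluster, and
  the count is the number of distinct supported combinations with at least
  one retained intron. The all-spliced combination is never an event: a
  locus whose transcripts either splice both introns or retain both counts
  one IR event, not two.

* **SE** (skipped / cassette exon): an internal exon excluded by a single
  intron of another transcript that shares the flanking splice sites of the
  skipped block. Counting is analogous to IR: distinct supported skip
  combinations per cluster of co-observed cassette exons.

* **Alt 5'/Alt 3'** (alternative donor/acceptor): overlapping introns are
  clustered; per cluster the distinct splice sites on each side are tallied,
  the *prevalent* site (plurality of supporting transcripts, ties resolved
  toward the site yielding the longest intron, then leftmost) is the
  reference, and every non-reference site is one event. Sidedness is defined
  in transcription orientation: the 5' (donor) end of an intron is its
  genomic start on '+' and its genomic end on '-'.

* **Alt B**: a non-reference donor paired with a non-reference acceptor on
  the same intron variant, with neither deviant end ever observed
  independently; the Alt5/Alt3 pair collapses into one Alt B event.

Introns explained by retention and introns explaining a cassette-exon skip
are excluded from alt-site clustering so one observation is never typed
twice. Transcript terminal boundaries (EST start/end positions) are never
treated as alternative sites; only internal splice junctions count.

Truncated (partially overlapping) transcripts vote full combinations only
when they observe a whole cluster; elsewhere they contribute single-intron /
single-exon patterns where they fully contain the intron or exon, so EST
truncation cannot fabricate joint combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

from .errors import ConsistencyError
from .io_formats import ExonChain, Interval
from .splice_graph import SpliceGraph, build_splice_graph, introns_of

EVENT_TYPES = ("IR", "SE", "Alt3", "Alt5", "AltB")


@dataclass(frozen=True)
class ASEvent:
    """One detected alternative-splicing event.

    ``pattern`` is the retained-intron / skipped-exon combination as a bit
    vector over the cluster (IR/SE only); ``ref_site``/``alt_site`` are the
    reference and deviant splice-site positions (Alt3/Alt5 only; AltB carries
    the deviant pair in ``alt_site`` as (donor, acceptor)).
    """

    type: str
    region: Interval
    supporters: frozenset[str]
    pattern: tuple[int, ...] | None = None
    ref_site: int | tuple[int, int] | None = None
    alt_site: int | tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if not self.supporters:
            raise ValueError("an event needs at least one supporting transcript")
        if self.type in ("IR", "SE") and (self.pattern is None or not any(self.pattern)):
            raise ValueError(f"{self.type} event needs a pattern with >=1 set bit")


@dataclass(frozen=True)
class EventCounts:
    """Per-gene tally of the five event types."""

    gene_id: str
    IR: int = 0
    SE: int = 0
    Alt3: int = 0
    Alt5: int = 0
    AltB: int = 0
    n_transcripts: int = 0

    @property
    def total(self) -> int:
        return self.IR + self.SE + self.Alt3 + self.Alt5 + self.AltB

    @property
    def any_AS(self) -> bool:
        return self.total > 0

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.IR, self.SE, self.Alt3, self.Alt5, self.AltB)


# ---------------------------------------------------------------------------
# shared helpers

def _retains(chain: ExonChain, intron: Interval) -> bool:
    d, a = intron
    return any(s <= d and a <= e for s, e in chain.exons)


def _splices(chain: ExonChain, intron: Interval) -> bool:
    return intron in introns_of(chain)


def _clusters(items: Sequence[Hashable], linked) -> list[tuple]:
    """Connected components under a pairwise predicate, in sorted order."""
    items = sorted(items)
    parent = {x: x for x in items}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, x in enumerate(items):
        for y in items[i + 1 :]:
            if linked(x, y):
                parent[find(y)] = find(x)
    groups: dict = {}
    for x in items:
        groups.setdefault(find(x), []).append(x)
    return [tuple(sorted(g)) for _, g in sorted(groups.items())]


def _combination_count(
    cluster: Sequence, statuses: Mapping[str, Sequence[str | None]], kind: str
) -> list[ASEvent]:
    """Count distinct supported bit-vector combinations over one cluster.

    ``statuses[tid][i]`` is 'on' (retained/skipped), 'off' (spliced/included)
    or None (no definite observation of cluster member i by that transcript).
    Transcripts observing the whole cluster vote their full combination;
    others contribute single-member patterns where they are 'on'.
    """
    votes: dict[tuple[int, ...], set[str]] = {}
    for tid, st in statuses.items():
        if all(s is not None for s in st):
            vec = tuple(1 if s == "on" else 0 for s in st)
            if any(vec):
                votes.setdefault(vec, set()).add(tid)
        else:
            for i, s in enumerate(st):
                if s == "on":
                    vec = tuple(1 if j == i else 0 for j in range(len(cluster)))
                    votes.setdefault(vec, set()).add(tid)
    region = (min(iv[0] for iv in cluster), max(iv[1] for iv in cluster))
    return [
        ASEvent(type=kind, region=region, pattern=vec, supporters=frozenset(sup))
        for vec, sup in sorted(votes.items())
    ]


# ---------------------------------------------------------------------------
# intron retention

def detect_retained_introns(graph: SpliceGraph) -> set[Interval]:
    """Junction introns lying entirely inside a single exon of another transcript."""
    chains = graph.chains.values()
    return {
        iv
        for iv in graph.active_junctions()
        if any(_retains(c, iv) for c in chains)
    }


def count_ir_events(graph: SpliceGraph) -> tuple[int, list[ASEvent]]:
    capable = sorted(detect_retained_introns(graph))
    if not capable:
        return 0, []
    chains = [graph.chains[tid] for tid in graph.transcript_ids]

    def observes(c: ExonChain, iv: Interval) -> bool:
        return _retains(c, iv) or _splices(c, iv)

    def linked(iv1: Interval, iv2: Interval) -> bool:
        return any(observes(c, iv1) and observes(c, iv2) for c in chains)

    events: list[ASEvent] = []
    for cluster in _clusters(capable, linked):
        statuses = {
            c.transcript_id: [
                "on" if _retains(c, iv) else "off" if _splices(c, iv) else None
                for iv in cluster
            ]
            for c in chains
        }
        events.extend(_combination_count(cluster, statuses, "IR"))
    return len(events), events


# ---------------------------------------------------------------------------
# cassette exons

@dataclass
class _CassetteIndex:
    """Internal-exon intervals with their observed flanking splice sites."""

    including: dict[Interval, set[str]] = field(default_factory=dict)
    left_donors: dict[Interval, set[int]] = field(default_factory=dict)
    right_acceptors: dict[Interval, set[int]] = field(default_factory=dict)

    @classmethod
    def build(cls, chains: Iterable[ExonChain]) -> "_CassetteIndex":
        idx = cls()
        for c in chains:
            ivs = introns_of(c)
            for k, exon in enumerate(c.exons):
                if k == 0 or k == c.n_exons - 1:
                    continue  # terminal exons have no complete flank pair
                idx.including.setdefault(exon, set()).add(c.transcript_id)
                idx.left_donors.setdefault(exon, set()).add(ivs[k - 1][0])
                idx.right_acceptors.setdefault(exon, set()).add(ivs[k][1])
        return idx

    def skip_intron(self, intron: Interval) -> tuple[Interval, ...]:
        """Candidate exons skipped by ``intron`` with shared block flanks.

        The intron must run from a known donor flanking the leftmost
        contained candidate exon to a known acceptor flanking the rightmost
        one, so a single intron may skip a whole block of cassette exons.
        """
        d, a = intron
        contained = sorted(e for e in self.including if d <= e[0] and e[1] <= a)
        if not contained:
            return ()
        if d in self.left_donors[contained[0]] and a in self.right_acceptors[contained[-1]]:
            return tuple(contained)
        return ()


def count_se_events(graph: SpliceGraph) -> tuple[int, list[ASEvent]]:
    chains = [graph.chains[tid] for tid in graph.transcript_ids]
    idx = _CassetteIndex.build(chains)
    active = graph.active_junctions()

    skipped_by: dict[Interval, set[str]] = {}
    for c in chains:
        for iv in introns_of(c):
            if iv not in active:
                continue
            for exon in idx.skip_intron(iv):
                if c.transcript_id not in idx.including.get(exon, set()):
                    skipped_by.setdefault(exon, set()).add(c.transcript_id)
    capable = sorted(skipped_by)
    if not capable:
        return 0, []

    def status(c: ExonChain, exon: Interval) -> str | None:
        if exon in c.exons:
            return "off"
        if c.transcript_id in skipped_by.get(exon, set()):
            return "on"
        return None

    def linked(e1: Interval, e2: Interval) -> bool:
        return any(status(c, e1) is not None and status(c, e2) is not None for c in chains)

    events: list[ASEvent] = []
    for cluster in _clusters(capable, linked):
        statuses = {c.transcript_id: [status(c, e) for e in cluster] for c in chains}
        events.extend(_combination_count(cluster, statuses, "SE"))
    return len(events), events


# ---------------------------------------------------------------------------
# alternative splice sites

def prevalent_site(
    support: Mapping[int, int], intron_length: Mapping[int, int] | None = None
) -> int:
    """The plurality-supported splice site among candidates at one junction end.

    Ties go to the site yielding the longest intron; a residual tie (equal
    support and equal length) goes to the leftmost genomic position, for
    determinism.
    """
    if not support:
        raise ValueError("prevalent_site needs >=1 candidate site")
    lengths = intron_length or {}
    return min(support, key=lambda s: (-support[s], -lengths.get(s, 0), s))


def _skip_like_introns(graph: SpliceGraph) -> set[Interval]:
    """Introns excluded from alt-site typing because they explain an exon skip.

    An intron that skips a cassette block with shared flanking splice sites
    is already typed as SE; reading its boundaries as alternative sites too
    would double-type the observation.
    """
    idx = _CassetteIndex.build(graph.chains.values())
    return {iv for iv in graph.active_junctions() if idx.skip_intron(iv)}


def count_alt_site_events(graph: SpliceGraph) -> tuple[int, int, list[ASEvent]]:
    """Count Alt5/Alt3 events (before Alt B merging).

    Candidate introns (junctions minus retained and skip-explaining introns)
    sharing one boundary are grouped per shared boundary; the reference at
    the varying end is the prevalent site, and every other site is one
    event. An intron sharing *neither* boundary with any overlapping
    candidate deviates from the locally prevalent intron at both ends and
    yields one Alt5 plus one Alt3 (collapsed later by :func:`merge_altb`) --
    unless it is itself the prevalent form, in which case the other introns
    carry the deviance. Returns (alt5, alt3, events).
    """
    active = graph.active_junctions()
    excluded = detect_retained_introns(graph) | _skip_like_introns(graph)
    cand = {iv: sup for iv, sup in active.items() if iv not in excluded}

    def kind_for(side: int) -> str:
        # genomic start is the donor (5') end on '+', the acceptor on '-'
        if side == 0:
            return "Alt5" if graph.strand == "+" else "Alt3"
        return "Alt3" if graph.strand == "+" else "Alt5"

    events: list[ASEvent] = []

    # shared-boundary groups: introns agreeing at `side`, varying opposite
    for side in (0, 1):
        groups: dict[int, list[Interval]] = {}
        for iv in cand:
            groups.setdefault(iv[side], []).append(iv)
        for shared, ivs in sorted(groups.items()):
            sites = {iv[1 - side]: cand[iv] for iv in ivs}
            if len(sites) < 2:
                continue
            lengths = {s: abs(s - shared) for s in sites}
            ref = prevalent_site({s: len(t) for s, t in sites.items()}, lengths)
            region = (min(iv[0] for iv in ivs), max(iv[1] for iv in ivs))
            for site in sorted(set(sites) - {ref}):
                events.append(
                    ASEvent(
                        type=kind_for(1 - side),
                        region=region,
                        supporters=frozenset(sites[site]),
                        ref_site=ref,
                        alt_site=site,
                    )
                )

    # orphan introns: overlap others but share no boundary with any of them
    shared_start = {s for s, ivs in _boundary_groups(cand, 0).items() if len(ivs) > 1}
    shared_end = {s for s, ivs in _boundary_groups(cand, 1).items() if len(ivs) > 1}
    for iv in sorted(cand):
        if iv[0] in shared_start or iv[1] in shared_end:
            continue
        rivals = [o for o in cand if o != iv and o[0] < iv[1] and iv[0] < o[1]]
        if not rivals:
            continue
        support = {o: len(cand[o]) for o in rivals + [iv]}
        lengths = {o: o[1] - o[0] for o in support}
        ref = min(support, key=lambda o: (-support[o], -lengths[o], o))
        if ref == iv:
            continue  # the orphan itself is the prevalent form here
        for side in (0, 1):
            events.append(
                ASEvent(
                    type=kind_for(side),
                    region=iv,
                    supporters=frozenset(cand[iv]),
                    ref_site=ref[side],
                    alt_site=iv[side],
                )
            )
    alt5 = sum(1 for e in events if e.type == "Alt5")
    alt3 = sum(1 for e in events if e.type == "Alt3")
    return alt5, alt3, events


def _boundary_groups(cand: Mapping[Interval, frozenset], side: int) -> dict[int, list[Interval]]:
    groups: dict[int, list[Interval]] = {}
    for iv in cand:
        groups.setdefault(iv[side], []).append(iv)
    return groups


def merge_altb(
    events: Sequence[ASEvent], graph: SpliceGraph
) -> tuple[int, list[ASEvent]]:
    """Collapse paired deviant donor/acceptor sites into Alt B events.

    A deviant 5' site and a deviant 3' site merge into one Alt B event when
    some intron variant uses both and neither deviant end ever occurs
    independently (on any other intron of the gene); each merge removes one
    Alt5 and one Alt3 event.
    """
    active = graph.active_junctions()
    by_start: dict[int, set[Interval]] = {}
    by_end: dict[int, set[Interval]] = {}
    for iv in active:
        by_start.setdefault(iv[0], set()).add(iv)
        by_end.setdefault(iv[1], set()).add(iv)

    donor_events = {e.alt_site: e for e in events if e.type == "Alt5"}
    acceptor_events = {e.alt_site: e for e in events if e.type == "Alt3"}
    start_side = {  # genomic side each event type lives on, by strand
        "Alt5": 0 if graph.strand == "+" else 1,
        "Alt3": 1 if graph.strand == "+" else 0,
    }

    merged: list[ASEvent] = []
    consumed: set[int] = set()
    kept = list(events)
    for d_site, d_ev in sorted(donor_events.items()):
        s_donor = start_side["Alt5"]
        at_donor = by_start[d_site] if s_donor == 0 else by_end[d_site]
        if len(at_donor) != 1:
            continue  # deviant donor occurs with several acceptors
        (iv,) = at_donor
        a_site = iv[1 - s_donor]
        a_ev = acceptor_events.get(a_site)
        if a_ev is None or id(a_ev) in consumed:
            continue
        at_acceptor = by_end[a_site] if s_donor == 0 else by_start[a_site]
        if at_acceptor != {iv}:
            continue  # deviant acceptor also occurs independently
        merged.append(
            ASEvent(
                type="AltB",
                region=iv,
                supporters=d_ev.supporters | a_ev.supporters,
                ref_site=(d_ev.ref_site, a_ev.ref_site),
                alt_site=(d_site, a_site),
            )
        )
        consumed.update((id(d_ev), id(a_ev)))
    kept = [e for e in kept if id(e) not in consumed]
    return len(merged), kept + merged


# ---------------------------------------------------------------------------
# composition

def count_events(
    chains: Iterable[ExonChain], min_junction_support: int = 1
) -> tuple[EventCounts, list[ASEvent]]:
    """Full five-type event census for one gene's chains.

    Deterministic and invariant under permutations of the input chains.
    """
    chains = list(chains)
    if not chains:
        raise ConsistencyError("count_events needs at least one chain")
    graph = build_splice_graph(chains, min_junction_support=min_junction_support)
    return count_events_on_graph(graph)


def count_events_on_graph(graph: SpliceGraph) -> tuple[EventCounts, list[ASEvent]]:
    n_ir, ir_events = count_ir_events(graph)
    n_se, se_events = count_se_events(graph)
    _, _, alt_events = count_alt_site_events(graph)
    n_altb, alt_events = merge_altb(alt_events, graph)
    counts = EventCounts(
        gene_id=graph.gene_id,
        IR=n_ir,
        SE=n_se,
        Alt3=sum(1 for e in alt_events if e.type == "Alt3"),
        Alt5=sum(1 for e in alt_events if e.type == "Alt5"),
        AltB=n_altb,
        n_transcripts=len(graph.chains),
    )
    return counts, ir_events + se_events + alt_events
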