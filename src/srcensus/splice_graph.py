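"""Per-gene splice graphs built from transcript exon chains.

The construction is the standard one: the union of all exons is cut at every
distinct exon boundary, yielding ordered disjoint exonic *segments*; each
transcript then traces a path over segments. Two kinds of typed edges carry
per-transcript support:

* junction edges -- intron intervals (gaps between consecutive exons of at
  least one chain), keyed by their genomic interval;
* adjacency edges -- consecutive segments covered contiguously by at least
  one transcript (i.e. both segments fall inside one exon of that chain).

Every input chain is exactly reconstructible from its path, so no evidence is
lost in the graph ("support conservation"). Identical chains are kept as
distinct supporters: event counting downstream weights splice sites by
transcript pluralities.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .errors import ConsistencyError
from .io_formats import ExonChain, Interval, _atomic_write


def introns_of(chain: ExonChain) -> tuple[Interval, ...]:
    """Gaps between consecutive exons, in genomic order (empty for one exon)."""
    return tuple((e1, s2) for (_, e1), (s2, _) in zip(chain.exons, chain.exons[1:]))


@dataclass(frozen=True)
class SpliceGraph:
    gene_id: str
    strand: str
    segments: tuple[Interval, ...]
    junctions: Mapping[Interval, frozenset[str]]
    adjacencies: Mapping[tuple[int, int], frozenset[str]]
    paths: Mapping[str, tuple[int, ...]]
    chains: Mapping[str, ExonChain]
    min_junction_support: int = 1

    @property
    def transcript_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.chains))

    def active_junctions(self) -> dict[Interval, frozenset[str]]:
        """Junctions meeting the minimum-support threshold (default: all)."""
        return {
            iv: sup
            for iv, sup in self.junctions.items()
            if len(sup) >= self.min_junction_support
        }

    def reconstruct_chain(self, transcript_id: str) -> ExonChain:
        """Rebuild a transcript's exon chain from its segment path.

        Consecutive path segments that abut genomically belong to one exon
        (introns have positive length), so maximal abutting runs are exons.
        """
        path = self.paths[transcript_id]
        exons: list[Interval] = []
        for idx in path:
            s, e = self.segments[idx]
            if exons and exons[-1][1] == s:
                exons[-1] = (exons[-1][0], e)
            else:
                exons.append((s, e))
        src = self.chains[transcript_id]
        return ExonChain(self.gene_id, transcript_id, src.strand, tuple(exons))

    def to_networkx(self) -> nx.DiGraph:
        """Segment-level DiGraph with typed, support-annotated edges."""
        g = nx.DiGraph(gene_id=self.gene_id, strand=self.strand)
        for i, (s, e) in enumerate(self.segments):
            g.add_node(i, start=s, end=e)
        seg_at_start = {seg[0]: i for i, seg in enumerate(self.segments)}
        seg_at_end = {seg[1]: i for i, seg in enumerate(self.segments)}
        for (i, j), sup in self.adjacencies.items():
            g.add_edge(i, j, kind="adjacency", supporters=sorted(sup))
        for (d, a), sup in self.junctions.items():
            g.add_edge(seg_at_end[d], seg_at_start[a], kind="junction", interval=(d, a), supporters=sorted(sup))
        return g

    def to_json(self) -> str:
        payload = {
            "gene_id": self.gene_id,
            "strand": self.strand,
            "segments": [list(seg) for seg in self.segments],
            "junctions": [
                {"start": d, "end": a, "supporters": sorted(sup)}
                for (d, a), sup in sorted(self.junctions.items())
            ],
            "adjacencies": [
                {"from": i, "to": j, "supporters": sorted(sup)}
                for (i, j), sup in sorted(self.adjacencies.items())
            ],
            "paths": {tid: list(p) for tid, p in sorted(self.paths.items())},
        }
        return json.dumps(payload, indent=1)

    def write_json(self, path) -> None:
        _atomic_write(path, self.to_json() + "\n")

    def to_dot(self) -> str:
        lines = [f'digraph "{self.gene_id}" {{', "  rankdir=LR;", "  node [shape=box];"]
        for i, (s, e) in enumerate(self.segments):
            lines.append(f'  s{i} [label="[{s},{e})"];')
        g = self.to_networkx()
        for u, v, data in g.edges(data=True):
            style = "solid" if data["kind"] == "junction" else "dashed"
            lines.append(f'  s{u} -> s{v} [style={style}, label="{len(data["supporters"])}"];')
        lines.append("}")
        return "\n".join(lines)


def build_splice_graph(
    chains: Iterable[ExonChain], min_junction_support: int = 1
) -> SpliceGraph:
    """Build the splice graph for one gene from >=1 chains.

    All chains must share gene_id and strand. The output is deterministic and
    independent of input order (segments, edges and support sets only depend
    on the set of chains).
    """
    chains = sorted(chains, key=lambda c: c.transcript_id)
    if not chains:
        raise ConsistencyError("cannot build a splice graph from zero chains")
    gene_ids = {c.gene_id for c in chains}
    if len(gene_ids) > 1:
        raise ConsistencyError(f"mixed gene_ids in one graph: {sorted(gene_ids)}")
    strands = {c.strand for c in chains}
    if len(strands) > 1:
        raise ConsistencyError(f"mixed strands for gene {chains[0].gene_id}: {sorted(strands)}")

    boundaries = sorted({x for c in chains for exon in c.exons for x in exon})
    # exon-covered sub-intervals between consecutive boundaries
    covered: list[Interval] = []
    for s, e in zip(boundaries, boundaries[1:]):
        if any(xs <= s and e <= xe for c in chains for xs, xe in c.exons):
            covered.append((s, e))
    segments = tuple(covered)
    seg_index = {seg: i for i, seg in enumerate(segments)}

    junctions: dict[Interval, set[str]] = {}
    adjacencies: dict[tuple[int, int], set[str]] = {}
    paths: dict[str, tuple[int, ...]] = {}
    for c in chains:
        path: list[int] = []
        for xs, xe in c.exons:
            prev = None
            pos = xs
            # segments tiling this exon are consecutive in the segment list
            while pos < xe:
                next_b = boundaries[bisect_right(boundaries, pos)]
                idx = seg_index[(pos, next_b)]
                if prev is not None:
                    adjacencies.setdefault((prev, idx), set()).add(c.transcript_id)
                path.append(idx)
                prev = idx
                pos = next_b
        for iv in introns_of(c):
            junctions.setdefault(iv, set()).add(c.transcript_id)
        paths[c.transcript_id] = tuple(path)

    return SpliceGraph(
        gene_id=chains[0].gene_id,
        strand=chains[0].strand,
        segments=segments,
        junctions={iv: frozenset(s) for iv, s in junctions.items()},
        adjacencies={k: frozenset(s) for k, s in adjacencies.items()},
        paths=paths,
        chains={c.transcript_id: c for c in chains},
        min_junction_support=min_junction_support,
    )
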