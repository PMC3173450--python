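"""Readers and writers for every external representation the pipeline touches.

One coordinate convention is used internally everywhere: 0-based, half-open
genomic intervals. BED12 already uses it and passes through; GTF (1-based,
inclusive) is shifted on read and unshifted on write. Minus-strand chains are
stored in genomic orientation; transcription orientation is applied only when
events are typed.

Gene grouping comes from the input annotation: in BED12 the chromosome field
names the gene locus (each gene's genomic sequence is its own reference, as
when ESTs are aligned locus by locus) and the name field the transcript; in
GTF the ``gene_id``/``transcript_id`` attributes are used.
"""

from __future__ import annotations

import json
import logging
import math
import os
import tempfile
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .errors import AlignmentShapeError, ConsistencyError, FormatError

log = logging.getLogger(__name__)

Interval = tuple[int, int]

_AA = set("ACDEFGHIKLMNPQRSTVWY")
_MSA_ALPHABET = _AA | {"-", "X"}

DOMAIN_KINDS = ("RRM", "ZnK", "other")


@dataclass(frozen=True)
class ExonChain:
    """One transcript's ordered exon intervals on a gene locus.

    Exons are 0-based half-open, sorted, pairwise disjoint and non-abutting
    (a zero-length gap is a merge error upstream, not a valid intron).
    """

    gene_id: str
    transcript_id: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise FormatError(f"{self.transcript_id}: a chain needs at least one exon")
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))
        for s, e in self.exons:
            if e <= s:
                raise FormatError(f"{self.transcript_id}: empty or inverted exon ({s},{e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise FormatError(f"{self.transcript_id}: exons ({s1},{e1}) and ({s2},{e2}) overlap or are unsorted")
            if s2 == e1:
                raise FormatError(f"{self.transcript_id}: exons ({s1},{e1}) and ({s2},{e2}) abut (merge error)")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class DomainHit:
    """An annotated domain on a protein, 1-based inclusive residue coordinates."""

    protein_id: str
    kind: str
    start: int
    end: int
    evalue: float

    def __post_init__(self) -> None:
        if self.kind not in DOMAIN_KINDS:
            raise FormatError(f"{self.protein_id}: unknown domain kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise FormatError(f"{self.protein_id}: bad domain interval [{self.start},{self.end}] (1-based inclusive)")
        if not (self.evalue >= 0 and math.isfinite(self.evalue)):
            raise FormatError(f"{self.protein_id}: e-value must be a finite non-negative number")


@dataclass(frozen=True)
class MsaMatrix:
    """A protein multiple alignment: ordered ids with equal-length gapped rows."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentShapeError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate sequence ids in alignment")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise AlignmentShapeError(f"ragged alignment: row widths {sorted(widths)}")
        bad = set("".join(self.rows)) - _MSA_ALPHABET
        if bad:
            raise FormatError(f"alignment contains non-amino-acid symbols: {sorted(bad)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def select_columns(self, keep: Sequence[int]) -> "MsaMatrix":
        return MsaMatrix(self.ids, tuple("".join(row[j] for j in keep) for row in self.rows))

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(seq_id) from None


def _atomic_write(path: str | os.PathLike, text: str) -> None:
    path = os.fspath(path)
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-srcensus-")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _merge_abutting(exons: list[Interval], where: str) -> list[Interval]:
    merged: list[Interval] = []
    for s, e in sorted(exons):
        if merged and s < merged[-1][1]:
            raise FormatError(f"{where}: overlapping exon blocks ({merged[-1]}, ({s},{e}))")
        if merged and s == merged[-1][1]:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _group_chains(records: Iterable[ExonChain]) -> dict[str, list[ExonChain]]:
    by_gene: dict[str, list[ExonChain]] = {}
    owner: dict[str, str] = {}
    for chain in records:
        prev = owner.get(chain.transcript_id)
        if prev is not None:
            if prev != chain.gene_id:
                raise ConsistencyError(
                    f"transcript {chain.transcript_id!r} spans two gene_ids ({prev!r}, {chain.gene_id!r})"
                )
            raise ConsistencyError(f"duplicate transcript_id {chain.transcript_id!r} in gene {chain.gene_id!r}")
        owner[chain.transcript_id] = chain.gene_id
        by_gene.setdefault(chain.gene_id, []).append(chain)
    return by_gene


# ---------------------------------------------------------------------------
# exon chains: BED12 / GTF

def _parse_bed12_line(lineno: int, line: str) -> ExonChain:
    fields = line.split("\t") if "\t" in line else line.split()
    if len(fields) < 12:
        raise FormatError(f"line {lineno}: BED12 needs 12 fields, got {len(fields)}")
    chrom, chrom_start, chrom_end, name = fields[0], fields[1], fields[2], fields[3]
    strand = fields[5]
    try:
        start, end = int(chrom_start), int(chrom_end)
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-numeric BED12 field ({exc})") from None
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise FormatError(
            f"line {lineno}: blockCount={n_blocks} but {len(sizes)} sizes / {len(starts)} starts"
        )
    if starts[0] != 0:
        raise FormatError(f"line {lineno}: first blockStart must be 0 (UCSC dialect)")
    exons: list[Interval] = []
    for i, (bs, sz) in enumerate(zip(starts, sizes)):
        if sz <= 0:
            raise FormatError(f"line {lineno}: block {i} has non-positive size {sz}")
        if i and bs < starts[i - 1] + sizes[i - 1]:
            raise FormatError(f"line {lineno}: block {i} overlaps or precedes block {i - 1}")
        exons.append((start + bs, start + bs + sz))
    if exons[-1][1] != end:
        raise FormatError(
            f"line {lineno}: last block ends at {exons[-1][1]} but chromEnd is {end}"
        )
    exons = _merge_abutting(exons, f"line {lineno}")
    return ExonChain(gene_id=chrom, transcript_id=name, strand=strand, exons=tuple(exons))


def _read_bed12(path: str | os.PathLike) -> list[ExonChain]:
    chains = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chains.append(_parse_bed12_line(lineno, line))
    return chains


def _read_gtf(path: str | os.PathLike) -> list[ExonChain]:
    try:
        db = gffutils.create_db(
            os.fspath(path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"cannot parse GTF {path}: {exc}") from exc
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        try:
            gene_id = feat.attributes["gene_id"][0]
            tx_id = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise FormatError(f"GTF exon at {feat.seqid}:{feat.start} lacks attribute {exc}") from None
        rec = per_tx.get(tx_id)
        if rec is None:
            rec = per_tx[tx_id] = {"gene": gene_id, "strand": feat.strand, "exons": []}
            order.append(tx_id)
        if rec["gene"] != gene_id:
            raise ConsistencyError(f"transcript {tx_id!r} spans two gene_ids ({rec['gene']!r}, {gene_id!r})")
        if rec["strand"] != feat.strand:
            raise ConsistencyError(f"transcript {tx_id!r} has exons on both strands")
        # GTF is 1-based inclusive; internal convention is 0-based half-open.
        rec["exons"].append((feat.start - 1, feat.end))
    chains = []
    for tx_id in order:
        rec = per_tx[tx_id]
        exons = _merge_abutting(rec["exons"], f"transcript {tx_id}")
        chains.append(ExonChain(rec["gene"], tx_id, rec["strand"], tuple(exons)))
    return chains


def read_exon_chains(path: str | os.PathLike, format: str) -> dict[str, list[ExonChain]]:
    """Read transcript exon chains from BED12 or GTF, grouped by gene_id.

    Returns a mapping gene_id -> chains in input order. Abutting blocks within
    a transcript are merged; a transcript_id appearing under two gene_ids is a
    consistency error.
    """
    if format == "bed12":
        chains = _read_bed12(path)
    elif format == "gtf":
        chains = _read_gtf(path)
    else:
        raise ValueError(f"unknown chain format {format!r} (use 'bed12' or 'gtf')")
    return _group_chains(chains)


def write_exon_chains(chains: Iterable[ExonChain], path: str | os.PathLike, format: str) -> None:
    """Write chains as BED12 (gene as chromosome) or GTF2.2 exon features."""
    lines: list[str] = []
    if format == "bed12":
        for c in chains:
            start, end = c.span
            sizes = ",".join(str(e - s) for s, e in c.exons)
            starts = ",".join(str(s - start) for s, _ in c.exons)
            lines.append(
                "\t".join(
                    [
                        c.gene_id, str(start), str(end), c.transcript_id, "0", c.strand,
                        str(start), str(end), "0", str(c.n_exons), sizes, starts,
                    ]
                )
            )
    elif format == "gtf":
        for c in chains:
            for s, e in c.exons:
                attrs = f'gene_id "{c.gene_id}"; transcript_id "{c.transcript_id}";'
                lines.append(
                    "\t".join(
                        [c.gene_id, "srcensus", "exon", str(s + 1), str(e), ".", c.strand, ".", attrs]
                    )
                )
    else:
        raise ValueError(f"unknown chain format {format!r}")
    _atomic_write(path, "\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# domain tables

_DOMAIN_COLUMNS = ["protein_id", "kind", "start", "end", "evalue"]


def read_domain_table(path: str | os.PathLike) -> list[DomainHit]:
    """Read a TSV of domain hits (protein_id, kind, start, end, evalue).

    Unknown kinds map to ``other`` with a logged warning; a start/end inversion
    or a non-numeric e-value is an error naming the record.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _DOMAIN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: domain table lacks columns {missing}")
    hits: list[DomainHit] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        where = f"{path} row {i} ({row.protein_id})"
        kind = row.kind
        if kind not in DOMAIN_KINDS:
            log.warning("%s: unknown domain kind %r mapped to 'other'", where, kind)
            kind = "other"
        try:
            start, end, evalue = int(row.start), int(row.end), float(row.evalue)
        except (TypeError, ValueError):
            raise FormatError(f"{where}: non-numeric start/end/evalue") from None
        try:
            hits.append(DomainHit(row.protein_id, kind, start, end, evalue))
        except FormatError as exc:
            raise FormatError(f"{where}: {exc}") from None
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | os.PathLike) -> None:
    lines = ["\t".join(_DOMAIN_COLUMNS)]
    for h in hits:
        lines.append(f"{h.protein_id}\t{h.kind}\t{h.start}\t{h.end}\t{h.evalue:g}")
    _atomic_write(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# alignments and event reports

def read_msa(path: str | os.PathLike) -> MsaMatrix:
    """Read an aligned FASTA into an MsaMatrix; ragged rows are rejected."""
    ids, rows = [], []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise FormatError(f"{path}: empty FASTA")
    return MsaMatrix(tuple(ids), tuple(rows))


def write_msa(msa: MsaMatrix, path: str | os.PathLike) -> None:
    chunks = []
    for seq_id, row in zip(msa.ids, msa.rows):
        chunks.append(f">{seq_id}")
        chunks.extend(row[i : i + 60] for i in range(0, len(row), 60))
    _atomic_write(path, "\n".join(chunks) + "\n")


def write_fasta(records: Mapping[str, str], path: str | os.PathLike) -> None:
    chunks = []
    for seq_id, seq in records.items():
        chunks.append(f">{seq_id}")
        chunks.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
    _atomic_write(path, "\n".join(chunks) + "\n")


EVENT_REPORT_COLUMNS = ["gene_id", "n_transcripts", "IR", "SE", "Alt3", "Alt5", "AltB", "any_AS"]


def event_report_frame(counts: Iterable) -> pd.DataFrame:
    """Tabulate per-gene event counts (anything exposing the report attributes)."""
    rows = [
        {col: getattr(c, col) for col in EVENT_REPORT_COLUMNS}
        for c in counts
    ]
    df = pd.DataFrame(rows, columns=EVENT_REPORT_COLUMNS)
    df["any_AS"] = df["any_AS"].astype(bool)
    return df


def write_event_report(counts: Iterable, path: str | os.PathLike, format: str = "tsv") -> None:
    """Write the per-gene five-type tally as TSV or its JSON mirror."""
    df = event_report_frame(counts)
    if format == "tsv":
        _atomic_write(path, df.to_csv(sep="\t", index=False))
    elif format == "json":
        _atomic_write(path, json.dumps(df.to_dict(orient="records"), indent=1) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
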