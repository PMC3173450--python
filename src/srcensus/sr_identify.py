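"""SR-protein candidate filters and RRM-alignment post-processing.

An SR protein has one or two N-terminal RNA recognition motifs (RRMs) and a
C-terminal arginine/serine-rich (RS) domain. The screen applied here keeps a
candidate when all of the following hold:

* domain hits survive an e-value cutoff (1e-3; hits *greater than* the
  threshold are excluded, so equality is kept);
* the sequence begins with methionine (incomplete gene models are dropped);
* it carries exactly one or two RRMs;
* the RRMs are N-terminal: no RS region (>= 3 RS/SR dipeptides) precedes the
  first RRM;
* the region downstream of the last RRM contains at least three
  non-overlapping RS or SR dipeptides (the RS-domain membership criterion).

The alignment utilities mirror the preprocessing used before gene-tree
inference: extracting and concatenating per-protein RRM blocks, removing
columns whose residues come from at most one sequence (single-sequence
insertions), collapsing identical aligned rows to one representative, and
classifying columns as constant / parsimony-informative / uninformative
(gaps and 'X' are treated as missing, as in protein parsimony programs).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ConsistencyError
from .io_formats import DomainHit, MsaMatrix

log = logging.getLogger(__name__)

EVALUE_MAX_DEFAULT = 1e-3
MIN_SR_DIPEPTIDES = 3
RULES = ("evalue", "met_start", "rrm_count", "rrm_position", "rs_dipeptides")

_MISSING = {"-", "X"}


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    hits: tuple[DomainHit, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "hits", tuple(self.hits))
        for h in self.hits:
            if h.end > len(self.sequence):
                raise ConsistencyError(
                    f"{self.id}: hit {h.kind}[{h.start},{h.end}] exceeds length {len(self.sequence)}"
                )

    def rrm_hits(self) -> tuple[DomainHit, ...]:
        return tuple(sorted((h for h in self.hits if h.kind == "RRM"), key=lambda h: h.start))


@dataclass(frozen=True)
class SrVerdict:
    accepted: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.accepted != (len(self.reasons) == 0):
            raise ValueError("accepted verdicts carry no reasons and vice versa")


@dataclass(frozen=True)
class ColumnClassCounts:
    n_columns: int
    n_constant: int
    n_informative: int
    n_uninformative: int

    def __post_init__(self) -> None:
        if self.n_constant + self.n_informative + self.n_uninformative != self.n_columns:
            raise ValueError("column class counts must partition the columns")


def filter_by_evalue(
    hits: Iterable[DomainHit], threshold: float = EVALUE_MAX_DEFAULT
) -> list[DomainHit]:
    """Keep hits with e-value <= threshold (strictly greater ones are excluded)."""
    return [h for h in hits if h.evalue <= threshold]


def count_sr_dipeptides(segment: str) -> int:
    """Non-overlapping occurrences of 'RS' or 'SR' in a residue segment."""
    count = i = 0
    while i < len(segment) - 1:
        if segment[i : i + 2] in ("RS", "SR"):
            count += 1
            i += 2
        else:
            i += 1
    return count


def validate_sr(
    protein: ProteinRecord, evalue_max: float = EVALUE_MAX_DEFAULT
) -> SrVerdict:
    """Apply the SR-family architecture rules; the verdict names every failure."""
    reasons: list[str] = []
    raw_rrms = protein.rrm_hits()
    rrms = tuple(h for h in raw_rrms if h.evalue <= evalue_max)
    if raw_rrms and not rrms:
        reasons.append("evalue")
    if not protein.sequence.startswith("M"):
        reasons.append("met_start")
    if "evalue" not in reasons and len(rrms) not in (1, 2):
        reasons.append("rrm_count")
    if rrms:
        n_prefix = count_sr_dipeptides(protein.sequence[: rrms[0].start - 1])
        if n_prefix >= MIN_SR_DIPEPTIDES:
            reasons.append("rrm_position")
        tail = protein.sequence[rrms[-1].end :]
        if count_sr_dipeptides(tail) < MIN_SR_DIPEPTIDES:
            reasons.append("rs_dipeptides")
    ordered = tuple(r for r in RULES if r in reasons)
    return SrVerdict(accepted=not ordered, reasons=ordered)


# ---------------------------------------------------------------------------
# RRM alignment post-processing

def _degap(row: str) -> str:
    return re.sub(r"-", "", row)


def extract_and_concatenate_rrms(
    proteins: Sequence[ProteinRecord],
    n_term_alignment: MsaMatrix,
    c_term_alignment: MsaMatrix,
) -> MsaMatrix:
    """Concatenate each protein's aligned N-terminal and C-terminal RRM rows.

    Single-RRM proteins occupy only the N-terminal block; their C-terminal
    block is gap-filled. Each aligned row must degap to exactly the RRM
    subsequence cut from the protein, otherwise the alignment and the domain
    coordinates disagree.
    """
    width_c = c_term_alignment.n_cols
    ids, rows = [], []
    for p in proteins:
        rrms = p.rrm_hits()
        if not (1 <= len(rrms) <= 2):
            raise ConsistencyError(f"{p.id}: expected 1 or 2 RRMs, found {len(rrms)}")
        blocks = []
        for aln, hit in zip((n_term_alignment, c_term_alignment), rrms):
            try:
                row = aln.row(p.id)
            except KeyError:
                raise ConsistencyError(f"{p.id}: missing from an RRM block alignment") from None
            expected = p.sequence[hit.start - 1 : hit.end]
            if _degap(row) != expected:
                raise ConsistencyError(
                    f"{p.id}: aligned RRM row does not degap to residues [{hit.start},{hit.end}]"
                )
            blocks.append(row)
        if len(blocks) == 1:
            blocks.append("-" * width_c)
        ids.append(p.id)
        rows.append("".join(blocks))
    return MsaMatrix(tuple(ids), tuple(rows))


def remove_sparse_columns(msa: MsaMatrix) -> MsaMatrix:
    """Drop columns whose residues come from at most one sequence.

    These are the columns that would be gap-only if a single sequence did not
    contribute an unalignable insertion. Idempotent.
    """
    keep = [
        j for j in range(msa.n_cols) if sum(c != "-" for c in msa.column(j)) >= 2
    ]
    return msa.select_columns(keep)


def dedupe_identical(msa: MsaMatrix) -> tuple[MsaMatrix, dict[str, list[str]]]:
    """Collapse identical (gapped) rows to their first-seen representative.

    Returns the reduced alignment and a map representative -> absorbed ids.
    """
    rep_of_row: dict[str, str] = {}
    absorbed: dict[str, list[str]] = {}
    ids, rows = [], []
    for seq_id, row in zip(msa.ids, msa.rows):
        rep = rep_of_row.get(row)
        if rep is None:
            rep_of_row[row] = seq_id
            absorbed[seq_id] = []
            ids.append(seq_id)
            rows.append(row)
        else:
            absorbed[rep].append(seq_id)
    return MsaMatrix(tuple(ids), tuple(rows)), absorbed


def classify_columns(msa: MsaMatrix) -> ColumnClassCounts:
    """Partition columns into constant / parsimony-informative / uninformative.

    States are counted over non-missing residues (gap and 'X' excluded). A
    column is parsimony-informative when at least two states occur in at
    least two sequences each; constant when at most one state is present at
    all; uninformative when variable but not informative.
    """
    if msa.n_rows < 4:
        log.warning(
            "alignment has %d rows; parsimony informativeness is degenerate below 4",
            msa.n_rows,
        )
    n_const = n_inf = n_uninf = 0
    for j in range(msa.n_cols):
        counts: dict[str, int] = {}
        for c in msa.column(j):
            if c not in _MISSING:
                counts[c] = counts.get(c, 0) + 1
        if len(counts) <= 1:
            n_const += 1
        elif sum(1 for v in counts.values() if v >= 2) >= 2:
            n_inf += 1
        else:
            n_uninf += 1
    return ColumnClassCounts(msa.n_cols, n_const, n_inf, n_uninf)


def summarize_alignment(msa: MsaMatrix) -> dict:
    """Row/column shape plus the column-class partition, as plain numbers."""
    cc = classify_columns(msa)
    return {
        "n_sequences": msa.n_rows,
        "n_columns": cc.n_columns,
        "n_constant": cc.n_constant,
        "n_informative": cc.n_informative,
        "n_uninformative": cc.n_uninformative,
    }
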