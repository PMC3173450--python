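"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates what locus-by-locus EST retrievals look like: a
multi-exon reference gene, derived isoforms realizing planted AS events of
each of the five types (retain an intron; skip a cassette exon; shift a
donor; shift an acceptor; shift both ends jointly), and an EST set sampled
from those isoforms with variable depth and 5'/3' truncation. Truncation
trims whole terminal exons, never cutting inside an intron, so truncated
ESTs remain valid chains without inventing novel boundaries. Joint-shift
isoforms never expose either deviant end alone, honoring the pairing
condition that defines an Alt B event.

Planted events occupy disjoint intron/exon slots so each contributes exactly
one event to the expected census; the truth is therefore exact, and on
noise-free full-depth data the detector must reproduce it verbatim (the
central parameter-recovery property of the test suite).

Protein-family and alignment generators plant rule violations (exactly one
rule per protein) and column-class compositions, for cross-validating the SR
filters and the column classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .as_events import EVENT_TYPES, EventCounts
from .errors import GenerationError
from .io_formats import DomainHit, ExonChain, Interval, MsaMatrix
from .sr_identify import RULES, ColumnClassCounts, ProteinRecord

_RATE_DEFAULTS = {"IR": 0.3, "SE": 0.2, "Alt3": 0.3, "Alt5": 0.2, "AltB": 0.05}


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 60
    exon_count: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (60, 250)
    depth: tuple[int, int] = (8, 40)
    event_rates: Mapping[str, float] = field(default_factory=lambda: dict(_RATE_DEFAULTS))
    minor_isoform_prob: float = 0.35
    truncation_prob: float = 0.0
    truncation_extent: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "event_rates", {**_RATE_DEFAULTS, **dict(self.event_rates)})
        unknown = set(self.event_rates) - set(EVENT_TYPES)
        if unknown:
            raise GenerationError(f"unknown event types in rates: {sorted(unknown)}")
        if any(not (0.0 <= r <= 1.0) for r in self.event_rates.values()):
            raise GenerationError("event rates must lie in [0, 1]")
        for name in ("exon_count", "exon_length", "intron_length", "depth"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise GenerationError(f"bad range for {name}: ({lo}, {hi})")
        if self.exon_length[0] < 40 or self.intron_length[0] < 40:
            raise GenerationError("exon and intron lengths must be >= 40 bp to host site shifts")
        if not (0.0 <= self.minor_isoform_prob <= 1.0 and 0.0 <= self.truncation_prob <= 1.0):
            raise GenerationError("probabilities must lie in [0, 1]")
        if not (0.0 < self.truncation_extent <= 1.0):
            raise GenerationError("truncation_extent is a geometric success probability in (0, 1]")


@dataclass(frozen=True)
class PlantedEvent:
    type: str
    slot: int  # intron index for IR/Alt*/AltB, exon index for SE
    isoform_id: str


@dataclass(frozen=True)
class SimTruth:
    gene_id: str
    reference: ExonChain
    events: tuple[PlantedEvent, ...]
    expected: EventCounts


def _rng_for(config: SimConfig, *key: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=tuple(key))
    return np.random.Generator(np.random.PCG64(ss))


def _plan_slots(
    n_exons: int, planted: Sequence[str], rng: np.random.Generator
) -> dict[str, int]:
    """Assign each planted event a disjoint intron (or cassette exon) slot.

    An SE event reserves an internal exon plus both flanking introns; every
    other event reserves one intron. Disjoint slots keep the expected counts
    exactly one per planted event, with no cross-talk between event regions.
    """
    slots: dict[str, int] = {}
    free_introns = set(range(n_exons - 1))
    if "SE" in planted:
        internal = [j for j in range(1, n_exons - 1) if {j - 1, j} <= free_introns]
        if not internal:
            raise GenerationError(f"a {n_exons}-exon gene cannot host a skipped exon")
        j = int(rng.choice(internal))
        slots["SE"] = j
        free_introns -= {j - 1, j}
    for kind in ("IR", "Alt5", "Alt3", "AltB"):
        if kind in planted:
            if not free_introns:
                raise GenerationError(
                    f"a {n_exons}-exon gene cannot host planted events {sorted(planted)}"
                )
            k = int(rng.choice(sorted(free_introns)))
            slots[kind] = k
            free_introns.discard(k)
    return slots


def _min_exons_needed(planted: Sequence[str]) -> int:
    introns = sum(1 for k in planted if k != "SE")
    if "SE" in planted:
        return max(3, introns + 2 + 1)  # SE consumes an internal exon + 2 introns
    return max(2, introns + 1) if planted else 1


def simulate_locus(
    config: SimConfig, gene_index: int
) -> tuple[list[ExonChain], SimTruth]:
    """One gene: the reference isoform plus one isoform per planted event."""
    rng = _rng_for(config, 0, gene_index)
    gene_id = f"g{gene_index:04d}"
    strand = "+" if rng.random() < 0.5 else "-"
    planted = [k for k in EVENT_TYPES if rng.random() < config.event_rates[k]]

    lo, hi = config.exon_count
    n_exons = int(rng.integers(lo, hi + 1))
    need = _min_exons_needed(planted)
    if need > hi:
        raise GenerationError(
            f"{gene_id}: exon count range {config.exon_count} cannot host events {planted}"
        )
    n_exons = max(n_exons, need)

    exons: list[Interval] = []
    pos = 0
    for i in range(n_exons):
        if i:
            pos += int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
        length = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
        exons.append((pos, pos + length))
        pos = exons[-1][1]
    reference = ExonChain(gene_id, f"{gene_id}_iso_ref", strand, tuple(exons))

    slots = _plan_slots(n_exons, planted, rng)

    def shift(delta_cap: int) -> int:
        return int(rng.integers(10, delta_cap + 1))

    isoforms = [reference]
    events: list[PlantedEvent] = []
    counts = {k: 0 for k in EVENT_TYPES}
    for kind in planted:
        slot = slots[kind]
        ex = [list(x) for x in exons]
        if kind == "IR":
            merged = [ex[slot][0], ex[slot + 1][1]]
            ex = ex[:slot] + [merged] + ex[slot + 2 :]
        elif kind == "SE":
            ex = ex[:slot] + ex[slot + 1 :]
        else:
            # transcription-5' end of intron `slot` is its genomic start on '+'
            donor_end = 0 if strand == "+" else 1
            sides = {"Alt5": (donor_end,), "Alt3": (1 - donor_end,), "AltB": (0, 1)}[kind]
            for side in sides:
                if side == 0:  # genomic start: shorten the upstream exon
                    delta = shift(min(50, ex[slot][1] - ex[slot][0] - 10))
                    ex[slot][1] -= delta
                else:  # genomic end: shorten the downstream exon from the left
                    delta = shift(min(50, ex[slot + 1][1] - ex[slot + 1][0] - 10))
                    ex[slot + 1][0] += delta
        iso_id = f"{gene_id}_iso_{kind.lower()}"
        isoforms.append(ExonChain(gene_id, iso_id, strand, tuple(tuple(x) for x in ex)))
        events.append(PlantedEvent(type=kind, slot=slot, isoform_id=iso_id))
        counts[kind] += 1

    expected = EventCounts(gene_id=gene_id, n_transcripts=len(isoforms), **counts)
    truth = SimTruth(gene_id=gene_id, reference=reference, events=tuple(events), expected=expected)
    return isoforms, truth


def simulate_est_set(
    isoforms: Sequence[ExonChain],
    config: SimConfig,
    gene_index: int = 0,
    depth: int | None = None,
) -> list[ExonChain]:
    """Sample an EST set from a gene's isoforms (depth, minor usage, truncation)."""
    if not isoforms:
        raise GenerationError("need at least one isoform")
    rng = _rng_for(config, 1, gene_index)
    if depth is None:
        depth = int(rng.integers(config.depth[0], config.depth[1] + 1))
    reference, variants = isoforms[0], list(isoforms[1:])
    ests: list[ExonChain] = []
    for n in range(depth):
        if variants and rng.random() < config.minor_isoform_prob:
            iso = variants[int(rng.integers(len(variants)))]
        else:
            iso = reference
        exons = list(iso.exons)
        for end5 in (True, False):
            if len(exons) > 1 and rng.random() < config.truncation_prob:
                k = min(int(rng.geometric(config.truncation_extent)), len(exons) - 1)
                trim_left = end5 == (iso.strand == "+")
                exons = exons[k:] if trim_left else exons[: len(exons) - k]
        ests.append(
            ExonChain(iso.gene_id, f"{iso.gene_id}_est{n:03d}", iso.strand, tuple(exons))
        )
    return ests


def simulate_cohort(
    config: SimConfig, fixed_depth: int | None = None
) -> tuple[dict[str, list[ExonChain]], dict[str, SimTruth]]:
    """A whole synthetic cohort: EST chains by gene plus per-gene truth."""
    chains_by_gene: dict[str, list[ExonChain]] = {}
    truth_by_gene: dict[str, SimTruth] = {}
    for i in range(config.n_genes):
        isoforms, truth = simulate_locus(config, i)
        chains_by_gene[truth.gene_id] = simulate_est_set(
            isoforms, config, gene_index=i, depth=fixed_depth
        )
        truth_by_gene[truth.gene_id] = truth
    return chains_by_gene, truth_by_gene


# ---------------------------------------------------------------------------
# protein families

_SAFE_AA = "ACDEFGHIKLNPQTVWY"  # no R/S (would create stray dipeptides), no M


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_SAFE_AA), size=n))


def _rs_tail(rng: np.random.Generator, n_dipeptides: int) -> str:
    parts = []
    for _ in range(n_dipeptides):
        parts.append("RS" if rng.random() < 0.5 else "SR")
        parts.append(_random_aa(rng, int(rng.integers(0, 3))))
    return "".join(parts)


def simulate_protein_family(
    n: int, violation_mix: Mapping[str, float], seed: int
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Proteins that satisfy the SR rules or violate exactly one designated rule.

    ``violation_mix`` maps labels ('valid' or a rule name) to weights; labels
    are allocated proportionally. Returns the records (hits attached) and the
    planted label per protein id.
    """
    labels_pool = list(violation_mix)
    bad = set(labels_pool) - (set(RULES) | {"valid"})
    if bad:
        raise GenerationError(f"unknown rule labels: {sorted(bad)}")
    weights = np.array([violation_mix[l] for l in labels_pool], dtype=float)
    if weights.sum() <= 0:
        raise GenerationError("violation mix weights must sum to a positive value")
    alloc = np.floor(weights / weights.sum() * n).astype(int)
    while alloc.sum() < n:
        alloc[int(np.argmax(weights / weights.sum() * n - alloc))] += 1

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    assigned = [l for l, k in zip(labels_pool, alloc) for _ in range(int(k))]
    rng.shuffle(assigned)

    records: list[ProteinRecord] = []
    labels: dict[str, str] = {}
    for i, label in enumerate(assigned):
        pid = f"P{i:03d}"
        n_rrm = 1 if rng.random() < 0.5 else 2
        tail_dipep = int(rng.integers(4, 9))
        prefix_rs = 0
        evalue = 10.0 ** float(rng.uniform(-20, -6))
        start_res = "M"
        if label == "met_start":
            start_res = "A"
        elif label == "evalue":
            evalue = 1e-2
        elif label == "rrm_count":
            n_rrm = 0 if rng.random() < 0.5 else 3
        elif label == "rrm_position":
            prefix_rs = MIN_PREFIX_RS
        elif label == "rs_dipeptides":
            tail_dipep = 2

        seq = start_res + _random_aa(rng, int(rng.integers(5, 15)))
        if prefix_rs:
            seq += _rs_tail(rng, prefix_rs) + _random_aa(rng, 5)
        hits: list[DomainHit] = []
        for _ in range(max(n_rrm, 0)):
            rrm = _random_aa(rng, int(rng.integers(70, 86)))
            start = len(seq) + 1
            seq += rrm
            hits.append(DomainHit(pid, "RRM", start, len(seq), evalue))
            seq += _random_aa(rng, int(rng.integers(8, 20)))
        if label == "rrm_count" and n_rrm == 0:
            seq += _random_aa(rng, 80)
        seq += _rs_tail(rng, tail_dipep)
        records.append(ProteinRecord(pid, seq, tuple(hits)))
        labels[pid] = label
    return records, labels


MIN_PREFIX_RS = 4  # planted reversed-architecture proteins carry a clear N-terminal RS run


# ---------------------------------------------------------------------------
# alignments with known column classes

_FULL_AA = "ACDEFGHIKLMNPQRSTVWY"


def simulate_msa(
    n_rows: int, class_counts: tuple[int, int, int], seed: int
) -> tuple[MsaMatrix, ColumnClassCounts]:
    """An alignment realizing a requested constant/informative/uninformative mix."""
    n_const, n_inf, n_uninf = class_counts
    if min(class_counts) < 0 or n_rows < 2:
        raise GenerationError("need n_rows >= 2 and non-negative column counts")
    if n_inf > 0 and n_rows < 4:
        raise GenerationError("parsimony-informative columns need at least 4 rows")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    aa = list(_FULL_AA)

    columns: list[str] = []
    for _ in range(n_const):
        columns.append(str(rng.choice(aa)) * n_rows)
    for _ in range(n_inf):
        a, b = rng.choice(aa, size=2, replace=False)
        k = int(rng.integers(2, n_rows - 1))
        col = np.array([a] * k + [b] * (n_rows - k))
        rng.shuffle(col)
        columns.append("".join(col))
    for _ in range(n_uninf):
        if n_rows == 2:
            a, b = rng.choice(aa, size=2, replace=False)
            columns.append(a + b)
        else:
            a, b = rng.choice(aa, size=2, replace=False)
            col = np.array([a] * (n_rows - 1) + [b])
            rng.shuffle(col)
            columns.append("".join(col))
    order = rng.permutation(len(columns))
    rows = tuple(
        "".join(columns[j][i] for j in order) for i in range(n_rows)
    )
    ids = tuple(f"t{i:03d}" for i in range(n_rows))
    return MsaMatrix(ids, rows), ColumnClassCounts(len(columns), n_const, n_inf, n_uninf)
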