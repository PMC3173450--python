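import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracle` importable

from srcensus import ExonChain

FIXTURES = Path(__file__).parent.parent / "fixtures"


@pytest.fixture(scope="session")
def fixtures_dir() -> Path:
    return FIXTURES


@pytest.fixture
def panel_a_chains():
    """Two retained introns supported only jointly: one IR combination."""
    return [
        ExonChain("panelA", "spliced", "+", [(0, 100), (200, 300), (400, 500)]),
        ExonChain("panelA", "retains_both", "+", [(0, 500)]),
    ]


@pytest.fixture
def panel_b_chains():
    """Three retention combinations over two introns, plus two alternative
    donors and one alternative acceptor at the last junction."""
    return [
        ExonChain("panelB", "ref", "+", [(0, 100), (200, 300), (400, 500), (600, 700)]),
        ExonChain("panelB", "retain_i1", "+", [(0, 300), (400, 500), (600, 700)]),
        ExonChain("panelB", "retain_i2", "+", [(0, 100), (200, 500), (600, 700)]),
        ExonChain("panelB", "retain_both", "+", [(0, 500), (600, 700)]),
        ExonChain("panelB", "alt_donor_480", "+", [(0, 100), (200, 300), (400, 480), (600, 700)]),
        ExonChain("panelB", "alt_donor_520", "+", [(0, 100), (200, 300), (400, 520), (600, 700)]),
        ExonChain("panelB", "alt_acceptor_640", "+", [(0, 100), (200, 300), (400, 500), (640, 700)]),
    ]


@pytest.fixture
def panel_c_chains():
    """A deviant donor paired with a deviant acceptor in all transcripts."""
    return [
        ExonChain("panelC", "ref_1", "+", [(0, 100), (200, 300)]),
        ExonChain("panelC", "ref_2", "+", [(0, 100), (200, 300)]),
        ExonChain("panelC", "paired_shift", "+", [(0, 80), (220, 300)]),
    ]


def random_locus(rng: np.random.Generator, gene_id: str = "g", max_exons: int = 4,
                 max_transcripts: int = 5) -> list[ExonChain]:
    """A random small locus over a shared coarse boundary grid.

    Drawing exon boundaries from a small common universe makes transcripts
    share splice sites often, which is what exercises the event rules.
    """
    strand = "+" if rng.random() < 0.5 else "-"
    universe = np.arange(0, 200, 10)
    chains = []
    for t in range(int(rng.integers(1, max_transcripts + 1))):
        m = int(rng.integers(1, max_exons + 1))
        pos = np.sort(rng.choice(universe, size=2 * m, replace=False))
        exons = tuple((int(pos[2 * i]), int(pos[2 * i + 1])) for i in range(m))
        chains.append(ExonChain(gene_id, f"t{t}", strand, exons))
    return chains


def mirror_chains(chains: list[ExonChain], span: int = 10_000) -> list[ExonChain]:
    """Reflect coordinates and flip strand: an isomorphism in transcription
    space (a donor maps to a donor), so every event count is preserved."""
    out = []
    for c in chains:
        flipped = tuple(sorted((span - e, span - s) for s, e in c.exons))
        out.append(ExonChain(c.gene_id, c.transcript_id,
                             "-" if c.strand == "+" else "+", flipped))
    return out


def relabel_strand(chains: list[ExonChain]) -> list[ExonChain]:
    """Flip the strand label only: donor and acceptor ends trade places, so
    Alt5 and Alt3 counts swap while IR/SE/AltB are untouched."""
    return [
        ExonChain(c.gene_id, c.transcript_id,
                  "-" if c.strand == "+" else "+", c.exons)
        for c in chains
    ]
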