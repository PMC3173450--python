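"""Fixed-depth EST resampling so AS measurements are comparable across groups.

Raw EST depth varies by orders of magnitude between organisms, and deeper
sampling finds more events. The normalization draws a fixed number of ESTs
(default 15) per gene, without replacement, over many trials (default 100)
in several independent replicates (default 3), and reports per group (an
organism or a sub-family) the mean fraction of genes with any AS and the
mean per-type event count per AS gene. Genes with fewer ESTs than the draw
size are omitted and listed explicitly, never silently kept in denominators.

Seed discipline: a master seed spawns per-(replicate, trial, gene)
substreams keyed by a stable hash of the gene id, so adding or removing one
gene never perturbs another gene's draws.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .as_events import EVENT_TYPES, count_events
from .io_formats import ExonChain, _atomic_write

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResampleConfig:
    n_est: int = 15
    trials: int = 100
    replicates: int = 3
    seed: int = 0
    min_junction_support: int = 1
    grouping: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.n_est < 2:
            raise ValueError("n_est must be >= 2")
        if self.trials < 1 or self.replicates < 1:
            raise ValueError("trials and replicates must be >= 1")


@dataclass(frozen=True)
class ResampleReport:
    """Trial-level tallies plus per-(replicate, group) aggregates.

    ``trials`` has one row per (replicate, trial, gene); ``summary`` one row
    per (replicate, group). ``excluded`` lists genes below the depth cutoff.
    """

    config: ResampleConfig
    trials: pd.DataFrame
    summary: pd.DataFrame
    excluded: tuple[str, ...]

    def write_tsv(self, path) -> None:
        _atomic_write(path, self.summary.to_csv(sep="\t", index=False))

    def write_trials_tsv(self, path) -> None:
        _atomic_write(path, self.trials.to_csv(sep="\t", index=False))

    def write_json(self, path) -> None:
        payload = {
            "config": {
                "n_est": self.config.n_est,
                "trials": self.config.trials,
                "replicates": self.config.replicates,
                "seed": self.config.seed,
            },
            "excluded": list(self.excluded),
            "summary": self.summary.to_dict(orient="records"),
        }
        _atomic_write(path, json.dumps(payload, indent=1) + "\n")


def eligible_genes(depths: Mapping[str, int], n_est: int) -> set[str]:
    """Genes with at least ``n_est`` aligned ESTs ('fewer than' excludes strictly)."""
    kept = {g for g, d in depths.items() if d >= n_est}
    if not kept:
        log.warning("no gene reaches the required depth of %d ESTs", n_est)
    return kept


def _gene_rng(seed: int, replicate: int, trial: int, gene_id: str) -> np.random.Generator:
    key = zlib.crc32(gene_id.encode())
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(replicate, trial, key))
    return np.random.Generator(np.random.PCG64(ss))


def run_resampling(
    chains_by_gene: Mapping[str, Iterable[ExonChain]], config: ResampleConfig
) -> ResampleReport:
    """Run the resampling normalization over a cohort of genes.

    Per trial and eligible gene, ``n_est`` chains are drawn uniformly without
    replacement and the event census is run on the subsample. Fully
    reproducible for a given seed and gene set, independent of input order.
    """
    normalized = {
        g: sorted(cs, key=lambda c: (c.transcript_id, c.exons))
        for g, cs in chains_by_gene.items()
    }
    depths = {g: len(cs) for g, cs in normalized.items()}
    keep = eligible_genes(depths, config.n_est)
    excluded = tuple(sorted(set(normalized) - keep))
    grouping = dict(config.grouping or {})

    rows = []
    for gene in sorted(keep):
        group = grouping.get(gene, "UG")
        chains = normalized[gene]
        for rep in range(1, config.replicates + 1):
            for trial in range(1, config.trials + 1):
                rng = _gene_rng(config.seed, rep, trial, gene)
                idx = rng.choice(depths[gene], size=config.n_est, replace=False)
                counts, _ = count_events(
                    [chains[i] for i in sorted(idx)],
                    min_junction_support=config.min_junction_support,
                )
                rows.append(
                    {
                        "replicate": rep,
                        "trial": trial,
                        "group": group,
                        "gene_id": gene,
                        **{t: getattr(counts, t) for t in EVENT_TYPES},
                        "any_AS": counts.any_AS,
                    }
                )
    trials = pd.DataFrame(
        rows,
        columns=["replicate", "trial", "group", "gene_id", *EVENT_TYPES, "any_AS"],
    )
    summary = _summarize(trials)
    return ResampleReport(config=config, trials=trials, summary=summary, excluded=excluded)


def _summarize(trials: pd.DataFrame) -> pd.DataFrame:
    """Aggregate trial rows to per-(replicate, group) means.

    The AS fraction is the mean over trials of (genes with AS / genes used);
    per-type means divide by genes with AS in that trial (the 'per gene
    experiencing AS' convention), and trials without AS genes contribute
    nothing to the type means.
    """
    out = []
    if trials.empty:
        return pd.DataFrame(
            columns=["replicate", "group", "n_genes_used", "frac_AS_mean", "frac_AS_sd",
                     *[f"{t}_per_AS_gene" for t in EVENT_TYPES]]
        )
    for (rep, group), sub in trials.groupby(["replicate", "group"], sort=True):
        per_trial = sub.groupby("trial").agg(
            n_genes=("gene_id", "nunique"), n_as=("any_AS", "sum")
        )
        frac = per_trial["n_as"] / per_trial["n_genes"]
        rec = {
            "replicate": rep,
            "group": group,
            "n_genes_used": int(per_trial["n_genes"].iloc[0]),
            "frac_AS_mean": float(frac.mean()),
            "frac_AS_sd": float(frac.std(ddof=1)) if len(frac) > 1 else 0.0,
        }
        as_rows = sub[sub["any_AS"]]
        for t in EVENT_TYPES:
            if as_rows.empty:
                rec[f"{t}_per_AS_gene"] = float("nan")
            else:
                per_trial_mean = as_rows.groupby("trial")[t].mean()
                rec[f"{t}_per_AS_gene"] = float(per_trial_mean.mean())
        out.append(rec)
    return pd.DataFrame(out)
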