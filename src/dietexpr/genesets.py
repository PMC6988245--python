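"""Set-level statistics over per-gene fold changes and module gene lists.

Two tests are provided: a two-sample Welch t-test of a per-gene statistic
(by default a log2 fold change) in a set against the rest of the background
("mean change" is the difference of set and background means), adjusted by
Benjamini-Hochberg; and a one-sided Fisher exact (hypergeometric tail) test
for over-representation of a module's genes in a set, adjusted by
Bonferroni. Collections use GMT semantics (name, description, members).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "set_t_test",
    "fisher_enrichment",
    "run_set_analysis",
    "synthetic_collection",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            sets[name] = set(g for g in parts[2:] if g)
            desc[name] = parts[1]
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def set_t_test(per_gene_stats: pd.Series, gene_set: set[str], background: set[str],
               min_size: int = 10, alternative: str = "two-sided") -> dict | None:
    """Welch two-sample t of a per-gene statistic: set vs rest of background.

    Returns None (with a log entry) when either side is under ``min_size``.
    """
    stats_bg = per_gene_stats[per_gene_stats.index.isin(background)]
    in_set = stats_bg[stats_bg.index.isin(gene_set)]
    rest = stats_bg[~stats_bg.index.isin(gene_set)]
    if len(in_set) < min_size or len(rest) < min_size:
        logger.info("set skipped: %d in set / %d in rest below min size %d",
                    len(in_set), len(rest), min_size)
        return None
    t, p = stats.ttest_ind(in_set, rest, equal_var=False, alternative=alternative)
    return {
        "n": len(in_set),
        "mean_change": float(in_set.mean() - rest.mean()),
        "stat": float(t),
        "p": float(p),
    }


def fisher_enrichment(member_genes: set[str], gene_set: set[str],
                      background: set[str]) -> dict:
    """One-sided over-representation p for the 2x2 table module x set.

    p = P(overlap >= observed) under the hypergeometric null on the
    background universe.
    """
    if not background:
        raise ValueError("empty background")
    if not set(member_genes) <= set(background):
        raise ValueError("member genes must be a subset of the background")
    N = len(background)
    K = len(gene_set & background)
    n = len(member_genes)
    k = len(set(member_genes) & gene_set & background)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return {"n": K, "overlap": k, "mean_change": np.nan,
            "stat": float(k), "p": min(1.0, p)}


def run_set_analysis(per_gene_stats: pd.Series, collection: GeneSetCollection,
                     background: set[str], mode: str = "ttest",
                     member_genes: set[str] | None = None,
                     min_size: int = 10, alternative: str = "two-sided") -> pd.DataFrame:
    """One adjusted result per eligible set, sorted by adjusted p.

    mode "ttest": Welch t of ``per_gene_stats`` per set (BH adjustment).
    mode "fisher": over-representation of ``member_genes`` per set
    (Bonferroni adjustment).
    """
    rows = []
    for name in collection.sets:
        gs = collection.sets[name] & background
        if mode == "ttest":
            res = set_t_test(per_gene_stats, gs, background, min_size, alternative)
        elif mode == "fisher":
            if member_genes is None:
                raise ValueError("fisher mode needs member_genes")
            if len(gs) < min_size:
                logger.info("set %s below min size after background intersection", name)
                res = None
            else:
                res = fisher_enrichment(set(member_genes) & background, gs, background)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if res is not None:
            rows.append({"set": name, **res})
    if not rows:
        logger.warning("no eligible gene set (all below min size %d)", min_size)
        return pd.DataFrame(columns=["set", "n", "mean_change", "stat", "p", "p_adj"])
    out = pd.DataFrame(rows)
    if mode == "ttest":
        from .diffexpr import bh_adjust
        out["p_adj"] = bh_adjust(out["p"])
    else:
        out["p_adj"] = np.minimum(1.0, out["p"] * len(out))
    return out.sort_values("p_adj", kind="stable").reset_index(drop=True)


def synthetic_collection(genes, n_sets: int = 20, set_size: tuple[int, int] = (15, 60),
                         seed: int = 0) -> GeneSetCollection:
    """Random gene sets over a gene universe, for testing and demo pipelines."""
    rng = np.random.default_rng(seed)
    genes = list(genes)
    sets, desc = {}, {}
    for i in range(n_sets):
        size = int(rng.integers(set_size[0], set_size[1] + 1))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        name = f"SET{i + 1:03d}"
        sets[name] = set(members)
        desc[name] = "synthetic random gene set"
    return GeneSetCollection(sets, desc)
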