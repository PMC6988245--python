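"""Shared-reference fold-change concordance and its constrained permutation null.

When two treatment groups are each contrasted against the same reference
group, the two fold-change vectors share the reference group's sampling
noise, so they correlate positively and more than half the genes trend in
the same direction even for random data. This module quantifies observed
concordance (Pearson r and the proportion of genes moving in the same
direction) and calibrates it against a null that reproduces the artifact:
pseudo-groups assembled by drawing an equal number of samples from every
true group, which destroys any real group effect while keeping group sizes
and composition balanced.

Empirical p-values use the add-one rule p = (1 + #{null >= observed}) / (1 + M),
which is never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import compute_lfc
from .preprocess import estimate_size_factors

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationScheme",
    "proportion_same_direction",
    "fold_change_correlation",
    "make_constrained_permutations",
    "empirical_pvalue",
    "run_concordance",
    "ConcordanceTest",
    "ConcordanceResults",
]


@dataclass
class PermutationScheme:
    """Constrained permutation design: M draws, `per_pseudo` samples taken
    from each true diet into every pseudo-diet."""

    n_permutations: int = 100
    per_pseudo: int = 2
    seed: int = 0


def proportion_same_direction(lfc1, lfc2) -> float:
    """(genes up in both + genes down in both) / total genes.

    Genes with an exactly zero fold change in either vector count in the
    denominator only.
    """
    a = np.asarray(lfc1, float)
    b = np.asarray(lfc2, float)
    if a.shape != b.shape:
        raise ValueError("fold-change vectors differ in length")
    if a.size == 0:
        raise ValueError("empty fold-change vectors")
    same = (np.sign(a) == np.sign(b)) & (np.sign(a) != 0)
    return float(same.sum() / a.size)


def fold_change_correlation(lfc1, lfc2) -> float:
    """Pearson correlation of two fold-change vectors; NaN for constant input."""
    a = np.asarray(lfc1, float)
    b = np.asarray(lfc2, float)
    if a.shape != b.shape:
        raise ValueError("fold-change vectors differ in length")
    if a.size <= 2:
        raise ValueError("need more than 2 genes")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("constant fold-change vector; correlation undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def make_constrained_permutations(samples_by_diet: dict[str, list[str]],
                                  scheme: PermutationScheme) -> list[dict[str, list[str]]]:
    """Pseudo-diet assignments: every pseudo-diet gets exactly ``per_pseudo``
    samples from every true diet, drawn without replacement within a draw.

    Returns ``scheme.n_permutations`` dicts keyed by the true diet labels
    (reused as pseudo-diet names), reproducible from ``scheme.seed``.
    """
    diets = list(samples_by_diet)
    need = scheme.per_pseudo * len(diets)
    for d, samp in samples_by_diet.items():
        if len(samp) < need:
            raise ValueError(
                f"diet {d} has {len(samp)} replicates; scheme needs {need}")
    rng = np.random.default_rng(scheme.seed)
    perms = []
    for _ in range(scheme.n_permutations):
        assignment: dict[str, list[str]] = {d: [] for d in diets}
        for d in diets:
            drawn = rng.choice(samples_by_diet[d], size=need, replace=False)
            for k, pseudo in enumerate(diets):
                assignment[pseudo].extend(
                    drawn[k * scheme.per_pseudo:(k + 1) * scheme.per_pseudo])
        perms.append(assignment)
    return perms


def empirical_pvalue(observed: float, null_values, alternative: str = "greater") -> float:
    """Add-one empirical p-value against a permutation null."""
    null = np.asarray(null_values, float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if alternative == "greater":
        extreme = int((null >= observed).sum())
    elif alternative == "less":
        extreme = int((null <= observed).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + extreme) / (1 + null.size)


def run_concordance(counts: pd.DataFrame, meta: pd.DataFrame, tissue: str,
                    scheme: PermutationScheme | None = None,
                    genes: pd.Index | None = None,
                    sizefactors: pd.Series | None = None,
                    pseudocount: float = 0.5,
                    references=None) -> pd.DataFrame:
    """Observed and null concordance for every choice of reference diet.

    For each reference diet the two remaining diets' moderated log2 fold
    changes against it are compared (Pearson r and proportion same
    direction), and the same statistics are recomputed on M constrained
    permutations to yield empirical p-values. Observed statistics do not
    depend on the permutation seed.
    """
    if scheme is None:
        scheme = PermutationScheme()
    meta = meta.set_index("sample_id").loc[list(counts.columns)].reset_index()
    sub = meta[meta["tissue"] == tissue]
    if sub.empty:
        raise ValueError(f"no samples for tissue {tissue!r}")
    counts_t = counts[sub.sample_id.tolist()]
    if genes is not None:
        counts_t = counts_t.loc[counts_t.index.intersection(genes)]
    if sizefactors is None:
        sizefactors = estimate_size_factors(counts_t)
    diets = list(pd.unique(sub["diet"]))
    by_diet = {d: sub.loc[sub.diet == d, "sample_id"].tolist() for d in diets}

    perms = make_constrained_permutations(by_diet, scheme)

    def stats_for(groups: dict[str, list[str]], ref: str) -> tuple[float, float]:
        others = [d for d in diets if d != ref]
        l1 = compute_lfc(counts_t, sizefactors, groups[others[0]], groups[ref],
                         pseudocount)["lfc"].to_numpy()
        l2 = compute_lfc(counts_t, sizefactors, groups[others[1]], groups[ref],
                         pseudocount)["lfc"].to_numpy()
        return fold_change_correlation(l1, l2), proportion_same_direction(l1, l2)

    rows = []
    for ref in (references if references is not None else diets):
        if ref not in diets:
            raise ValueError(f"unknown reference diet {ref!r}")
        others = [d for d in diets if d != ref]
        r_obs, prop_obs = stats_for(by_diet, ref)
        null_r = np.empty(len(perms))
        null_prop = np.empty(len(perms))
        for i, groups in enumerate(perms):
            null_r[i], null_prop[i] = stats_for(groups, ref)
        rows.append({
            "tissue": tissue, "reference": ref,
            "pair": f"{others[0]} vs {others[1]}",
            "r": r_obs, "prop_same": prop_obs,
            "p_emp_r": empirical_pvalue(r_obs, null_r),
            "p_emp_prop": empirical_pvalue(prop_obs, null_prop),
            "null_mean_r": float(np.nanmean(null_r)),
            "null_mean_prop": float(null_prop.mean()),
            "n_genes": len(counts_t), "M": len(perms),
        })
    return pd.DataFrame(rows)


class ConcordanceResults:
    """Per-reference observed/null concordance statistics."""

    def __init__(self, table: pd.DataFrame):
        self.table = table

    def summary(self) -> pd.DataFrame:
        cols = ["tissue", "reference", "pair", "r", "prop_same",
                "p_emp_r", "p_emp_prop", "M"]
        return self.table[cols].copy()


class ConcordanceTest:
    """Shared-reference concordance test for one tissue's samples."""

    def __init__(self, counts: pd.DataFrame, meta: pd.DataFrame, tissue: str,
                 scheme: PermutationScheme | None = None,
                 genes: pd.Index | None = None, pseudocount: float = 0.5):
        self.counts, self.meta, self.tissue = counts, meta, tissue
        self.scheme = scheme or PermutationScheme()
        self.genes, self.pseudocount = genes, pseudocount

    def fit(self) -> ConcordanceResults:
        return ConcordanceResults(run_concordance(
            self.counts, self.meta, self.tissue, self.scheme,
            genes=self.genes, pseudocount=self.pseudocount))
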