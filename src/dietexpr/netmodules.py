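"""Signed weighted co-expression networks, topological overlap, module
detection, eigengenes, merging, resampling robustness, and eigengene ANOVA.

The network is signed: adjacency a_ij = ((1 + cor_ij)/2)^beta, so
anticorrelated genes get near-zero connection strength. Modules are found by
average-linkage hierarchical clustering of the topological overlap
dissimilarity with a static height cut (a documented simplification of the
dynamic hybrid tree cut: same height and minimum-size parameters, exactly
reproducible). Module stability is assessed by rebuilding the network on
resampled replicate subsets and scoring how often each gene rejoins a match
of its full-data module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

__all__ = [
    "NetworkConfig",
    "signed_adjacency",
    "scale_free_fit_index",
    "pick_soft_threshold",
    "topological_overlap",
    "cluster_and_cut",
    "module_eigengene",
    "eigengene_matrix",
    "merge_similar_modules",
    "resample_robustness",
    "RobustnessReport",
    "eigengene_anova",
    "anova_all_modules",
    "CoexpressionNetwork",
    "NetworkResults",
]


@dataclass
class NetworkConfig:
    """Network construction and robustness parameters.

    Defaults follow the conventional signed-WGCNA settings for this design:
    soft power 23 (scale-free fit target r^2 = 0.90), dissimilarity cut
    height 0.95, minimum module size 30, eigengene merge threshold r = 0.9,
    and 100 resamples keeping 4 of 6 replicates per diet x tissue cell with
    the 10% module-match and 50% gene-support rules.
    """

    power: float = 23.0
    candidate_powers: tuple[float, ...] = tuple(range(1, 31))
    target_fit: float = 0.90
    cut_height: float = 0.95
    min_module_size: int = 30
    merge_threshold: float = 0.9
    resamples: int = 100
    kept_replicates: int = 4
    match_fraction: float = 0.10
    support_fraction: float = 0.50
    n_bins: int = 10
    seed: int = 0


def _safe_corr(expr: np.ndarray) -> np.ndarray:
    """Pearson correlation across samples; constant genes -> 0 correlation."""
    sd = expr.std(axis=1)
    const = sd == 0
    if const.any():
        logger.warning("%d constant genes: correlations set to 0", int(const.sum()))
    X = expr - expr.mean(axis=1, keepdims=True)
    denom = np.where(const, 1.0, sd * expr.shape[1])
    X = X / denom[:, None]
    C = (X @ X.T) * expr.shape[1]
    C[const, :] = 0.0
    C[:, const] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def signed_adjacency(expr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """a_ij = ((1 + cor_ij)/2)^beta with unit diagonal, entries in [0, 1]."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    C = _safe_corr(expr.to_numpy(float))
    A = ((1.0 + C) / 2.0) ** beta
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=expr.index, columns=expr.index)


def scale_free_fit_index(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity vector.

    Bins k into ``n_bins`` equal-width intervals, regresses log10(frequency)
    on log10(mean k) over occupied bins, and returns
    (r^2 * sign(-slope), slope). Degenerate (all-equal k) input gives (0, 0)
    with a warning.
    """
    k = np.asarray(k, float)
    if np.ptp(k) == 0:
        logger.warning("all connectivities identical; scale-free fit degenerate")
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        mean_k = k[sel].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(sel.sum() / k.size))
    if len(xs) < 3:
        logger.warning("too few occupied bins for a scale-free fit")
        return 0.0, 0.0
    x, y = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(r2 * np.sign(-slope)), float(slope)


def pick_soft_threshold(expr: pd.DataFrame, candidate_powers=None,
                        target: float = 0.90, n_bins: int = 10) -> tuple[float, pd.DataFrame]:
    """Smallest candidate power whose scale-free fit index reaches ``target``.

    Returns (power, table of per-power fit indices). Falls back to the power
    with maximal fit (with a warning) if none reaches the target.
    """
    if candidate_powers is None:
        candidate_powers = NetworkConfig().candidate_powers
    candidate_powers = list(candidate_powers)
    if len(candidate_powers) < 1:
        raise ValueError("need at least one candidate power")
    rows = []
    for p in candidate_powers:
        A = signed_adjacency(expr, p).to_numpy()
        k = A.sum(axis=0) - 1.0
        fit, slope = scale_free_fit_index(k, n_bins)
        rows.append({"power": p, "fit": fit, "slope": slope, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    reaching = table[table.fit >= target]
    if len(reaching):
        beta = float(reaching.power.iloc[0])
    else:
        beta = float(table.loc[table.fit.idxmax(), "power"])
        logger.warning("no candidate power reaches fit %.2f; using %g (fit %.3f)",
                       target, beta, table.fit.max())
    return beta, table


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with k the connectivity excluding the diagonal and TOM_ii = 1.
    """
    A = adjacency.to_numpy(float)
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    n = A.shape[0]
    k = A.sum(axis=0) - np.diag(A)
    # shared-neighbor sums: (A@A)_ij includes u=i and u=j terms a_ii*a_ij + a_ij*a_jj
    L = A @ A - np.diag(A)[:, None] * A - A * np.diag(A)[None, :]
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (L + A) / denom
    T[~np.isfinite(T)] = 0.0
    np.fill_diagonal(T, 1.0)
    T = np.clip((T + T.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(T, index=adjacency.index, columns=adjacency.columns)


def cluster_and_cut(tom: pd.DataFrame, config: NetworkConfig):
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters smaller than ``min_module_size`` are sent to the unassigned
    label. Module labels M1, M2, ... are ordered by decreasing size.
    Returns (linkage matrix, gene -> label Series).
    """
    D = 1.0 - tom.to_numpy(float)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    raw = hierarchy.fcluster(Z, t=config.cut_height, criterion="distance")
    labels = pd.Series(UNASSIGNED, index=tom.index, dtype=object, name="module")
    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= config.min_module_size].index
    order = sorted(big, key=lambda c: (-sizes[c], c))
    for rank, c in enumerate(order, start=1):
        labels.iloc[np.nonzero(raw == c)[0]] = f"M{rank}"
    return Z, labels


def _standardize(expr: np.ndarray) -> np.ndarray:
    mu = expr.mean(axis=1, keepdims=True)
    sd = expr.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (expr - mu) / sd


def module_eigengene(expr: pd.DataFrame, members) -> tuple[pd.Series, float]:
    """First principal component of the standardized member submatrix.

    Unit norm across samples, oriented so its correlation with the module's
    mean standardized profile is non-negative. Returns (eigengene,
    variance-explained fraction).
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("need at least 2 member genes")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    X = expr.loc[members].to_numpy(float)
    if (X.std(axis=1) == 0).all():
        raise ValueError("all member genes are constant")
    Z = _standardize(X)
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    v = vt[0]
    mean_profile = Z.mean(axis=0)
    orient = float(v @ mean_profile)
    if orient < 0 or (orient == 0 and v[np.argmax(v != 0)] < 0):
        v = -v
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return pd.Series(v, index=expr.columns, name="eigengene"), var_explained


def eigengene_matrix(expr: pd.DataFrame, assignment: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengenes for every non-unassigned module; returns (module x sample, var-explained)."""
    mods = sorted(m for m in assignment.unique() if m != UNASSIGNED)
    rows, ve = {}, {}
    for m in mods:
        eg, v = module_eigengene(expr, assignment.index[assignment == m])
        rows[m], ve[m] = eg, v
    E = pd.DataFrame(rows).T
    E.index.name = "module"
    return E, pd.Series(ve, name="var_explained")


def merge_similar_modules(expr: pd.DataFrame, assignment: pd.Series,
                          threshold: float = 0.9) -> pd.Series:
    """Iteratively merge the module pair with the highest eigengene
    correlation while it exceeds ``threshold``; unassigned never merges.

    The merged module keeps the lexicographically smaller label; eigengenes
    are recomputed after every merge.
    """
    labels = assignment.copy()
    while True:
        mods = sorted(m for m in labels.unique() if m != UNASSIGNED)
        if len(mods) < 2:
            return labels
        E, _ = eigengene_matrix(expr, labels)
        C = np.corrcoef(E.loc[mods].to_numpy())
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] <= threshold:
            return labels
        keep, drop = sorted((mods[i], mods[j]))
        labels[labels == drop] = keep


@dataclass
class RobustnessReport:
    """Gene-level support over resampled networks and the final robust assignment."""

    support: pd.Series
    module_match_counts: pd.Series
    final_assignment: pd.Series
    resamples: int


def _build_modules(expr: pd.DataFrame, config: NetworkConfig) -> pd.Series:
    A = signed_adjacency(expr, config.power)
    T = topological_overlap(A)
    _, labels = cluster_and_cut(T, config)
    if (labels != UNASSIGNED).any():
        labels = merge_similar_modules(expr, labels, config.merge_threshold)
    return labels


def _match_modules(resampled: pd.Series, full: pd.Series, match_fraction: float) -> dict[str, str]:
    """Map each resampled module to a full-data module sharing >= match_fraction
    of the full module's genes; best absolute overlap wins, ties to the
    lexicographically smallest full label."""
    mapping: dict[str, str] = {}
    full_mods = sorted(m for m in full.unique() if m != UNASSIGNED)
    full_sets = {m: set(full.index[full == m]) for m in full_mods}
    for rm in sorted(m for m in resampled.unique() if m != UNASSIGNED):
        rset = set(resampled.index[resampled == rm])
        best, best_ov = None, 0
        for fm in full_mods:
            ov = len(rset & full_sets[fm])
            if ov >= match_fraction * len(full_sets[fm]) and ov > best_ov:
                best, best_ov = fm, ov
        if best is not None:
            mapping[rm] = best
    return mapping


def resample_robustness(expr: pd.DataFrame, meta: pd.DataFrame,
                        config: NetworkConfig,
                        full_assignment: pd.Series) -> RobustnessReport:
    """Module-membership stability over replicate-resampled networks.

    Each resample keeps ``kept_replicates`` of the available replicates in
    every diet x tissue cell, rebuilds the network with identical parameters
    (including merging), and matches resampled modules to full-data modules
    by the configured overlap rule. A gene's support is the fraction of
    resamples in which it lands in a module matched to its full-data module;
    genes below ``support_fraction`` end up unassigned.
    """
    meta = meta.set_index("sample_id").loc[list(expr.columns)].reset_index()
    cells = meta.groupby(["diet", "tissue"])["sample_id"].apply(list)
    if any(len(v) < config.kept_replicates for v in cells):
        raise ValueError("kept_replicates exceeds available replicates in a cell")
    rng = np.random.default_rng(config.seed)
    hits = pd.Series(0, index=expr.index, dtype=int)
    match_counts: dict[str, int] = {}
    for _ in range(config.resamples):
        keep = []
        for samp in cells:
            keep.extend(rng.choice(samp, size=config.kept_replicates, replace=False))
        sub = expr[sorted(keep, key=list(expr.columns).index)]
        labels = _build_modules(sub, config)
        mapping = _match_modules(labels, full_assignment, config.match_fraction)
        for fm in set(mapping.values()):
            match_counts[fm] = match_counts.get(fm, 0) + 1
        matched_to = labels.map(mapping).fillna(UNASSIGNED)
        hits += (matched_to == full_assignment).astype(int)
    support = hits / config.resamples
    final = full_assignment.copy()
    final[(support < config.support_fraction) | (full_assignment == UNASSIGNED)] = UNASSIGNED
    return RobustnessReport(
        support=support.rename("support"),
        module_match_counts=pd.Series(match_counts, dtype=int).sort_index(),
        final_assignment=final,
        resamples=config.resamples,
    )


def eigengene_anova(eigengene: pd.Series, meta: pd.DataFrame) -> pd.DataFrame:
    """Two-way ANOVA (diet, tissue, interaction) on one module eigengene.

    Requires a balanced diet x tissue design (sequential sums of squares then
    equal marginal SS). Drops factors with a single level. Returns a
    DataFrame with term, F, p.
    """
    meta = meta.set_index("sample_id").loc[list(eigengene.index)].reset_index()
    d = pd.DataFrame({"eg": eigengene.to_numpy(), "diet": meta["diet"].to_numpy(),
                      "tissue": meta["tissue"].to_numpy()})
    terms = []
    if d.diet.nunique() > 1:
        terms.append("C(diet)")
    if d.tissue.nunique() > 1:
        terms.append("C(tissue)")
    if len(terms) == 2:
        counts = d.groupby(["diet", "tissue"]).size()
        if counts.nunique() != 1:
            raise ValueError("eigengene ANOVA requires a balanced diet x tissue design")
        formula = "eg ~ C(diet) * C(tissue)"
    elif len(terms) == 1:
        if d.groupby(terms[0][2:-1]).size().nunique() != 1:
            raise ValueError("eigengene ANOVA requires a balanced design")
        formula = f"eg ~ {terms[0]}"
    else:
        raise ValueError("no varying factor for ANOVA")
    fit = smf.ols(formula, data=d).fit()
    tab = sm.stats.anova_lm(fit, typ=1)
    tab = tab.drop(index="Residual")
    name_map = {"C(diet)": "diet", "C(tissue)": "tissue",
                "C(diet):C(tissue)": "diet:tissue"}
    return pd.DataFrame({
        "term": [name_map.get(t, t) for t in tab.index],
        "F": tab["F"].to_numpy(),
        "p": tab["PR(>F)"].to_numpy(),
    })


def anova_all_modules(eigengenes: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Eigengene ANOVA per module with BH adjustment across modules per term."""
    rows = []
    for m in eigengenes.index:
        tab = eigengene_anova(eigengenes.loc[m], meta)
        tab.insert(0, "module", m)
        rows.append(tab)
    out = pd.concat(rows, ignore_index=True)
    out["p_adj"] = np.nan
    for term in out.term.unique():
        sel = out.term == term
        out.loc[sel, "p_adj"] = bh_adjust(out.loc[sel, "p"])
    return out


class NetworkResults:
    """Fitted co-expression network: assignment, eigengenes, ANOVA, robustness."""

    def __init__(self, power, fit_table, assignment, eigengenes, var_explained,
                 anova, robustness=None):
        self.power = power
        self.fit_table = fit_table
        self.assignment = assignment
        self.eigengenes = eigengenes
        self.var_explained = var_explained
        self.anova = anova
        self.robustness = robustness

    def summary(self) -> pd.DataFrame:
        sizes = self.assignment[self.assignment != UNASSIGNED].value_counts().sort_index()
        rows = []
        for m, n in sizes.items():
            row = {"module": m, "n_genes": int(n),
                   "var_explained": float(self.var_explained.get(m, np.nan))}
            if self.anova is not None:
                sub = self.anova[self.anova.module == m]
                for _, r in sub.iterrows():
                    row[f"p_adj[{r.term}]"] = r.p_adj
            rows.append(row)
        rows.append({"module": UNASSIGNED,
                     "n_genes": int((self.assignment == UNASSIGNED).sum()),
                     "var_explained": np.nan})
        return pd.DataFrame(rows)


class CoexpressionNetwork:
    """Signed co-expression network model over an expression matrix."""

    def __init__(self, expr: pd.DataFrame, meta: pd.DataFrame,
                 config: NetworkConfig | None = None, select_power: bool = False):
        self.expr, self.meta = expr, meta
        self.config = config or NetworkConfig()
        self.select_power = select_power

    def fit(self, robustness: bool = False) -> NetworkResults:
        cfg = self.config
        fit_table = None
        if self.select_power:
            beta, fit_table = pick_soft_threshold(
                self.expr, cfg.candidate_powers, cfg.target_fit, cfg.n_bins)
            cfg = NetworkConfig(**{**cfg.__dict__, "power": beta})
        assignment = _build_modules(self.expr, cfg)
        report = None
        if robustness:
            report = resample_robustness(self.expr, self.meta, cfg, assignment)
            assignment = report.final_assignment
        if (assignment != UNASSIGNED).any():
            E, ve = eigengene_matrix(self.expr, assignment)
            anova = anova_all_modules(E, self.meta)
        else:
            E, ve, anova = pd.DataFrame(), pd.Series(dtype=float), None
        return NetworkResults(cfg.power, fit_table, assignment, E, ve, anova, report)
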