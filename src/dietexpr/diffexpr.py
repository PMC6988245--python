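"""Per-gene negative-binomial GLMs, nested likelihood-ratio tests, shrunken
log2 fold changes, and Benjamini-Hochberg adjustment.

The modelling scheme mirrors a four-model hierarchy on a diet x tissue
design with a known batch and one surrogate variable:

    1: SV + batch + tissue
    2: SV + batch + treatment
    3: SV + batch + tissue + treatment
    4: SV + batch + tissue + treatment + tissue:treatment

Contrasts are tested by likelihood ratio: tissue main effect (3 vs 2), diet
main effect (3 vs 1), diet x tissue interaction (4 vs 3). Dispersions are
gene-wise method-of-moments with a floor; log2 fold changes are moderated
group-mean ratios with a pseudocount (a deterministic stand-in for
prior-based shrinkage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import DesignInfo, estimate_size_factors

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
ALPHA_FLOOR = 1e-8

__all__ = [
    "ModelSpec",
    "GeneFit",
    "estimate_dispersion",
    "fit_nb_glm",
    "lrt_nested",
    "bh_adjust",
    "compute_lfc",
    "run_de",
    "DifferentialExpression",
    "DEResults",
]


@dataclass(frozen=True)
class ModelSpec:
    """A named design built from terms of {SV, batch, tissue, treatment, tissue:treatment}."""

    name: str
    terms: tuple[str, ...]

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.terms) <= set(other.terms)


@dataclass
class GeneFit:
    """One gene's NB-GLM fit: coefficients are log2 scale."""

    coef: pd.Series
    fitted: np.ndarray
    alpha: float
    llf: float
    converged: bool
    columns: tuple[str, ...]


def estimate_dispersion(counts: pd.DataFrame, sizefactors: pd.Series,
                        design_cells: pd.Series) -> pd.Series:
    """Method-of-moments NB dispersion per gene, floored at 1e-8.

    Pools the within-cell variance of size-factor-normalized counts across
    the design cells (``design_cells`` labels each sample's cell, e.g.
    diet:tissue), then alpha_g = max(floor, (s2_g - mean_g) / mean_g^2).
    """
    norm = counts.to_numpy(float) / sizefactors.reindex(counts.columns).to_numpy(float)
    cells = pd.Series(design_cells).to_numpy()
    mu = norm.mean(axis=1)
    ss = np.zeros(len(counts))
    dof = 0
    for cell in pd.unique(cells):
        idx = cells == cell
        n_c = int(idx.sum())
        if n_c < 2:
            continue
        sub = norm[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += n_c - 1
    if dof == 0:
        raise ValueError("no design cell has 2 or more samples")
    s2 = ss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, ALPHA_FLOOR)
    n_floor = int((alpha < ALPHA_FLOOR).sum())
    if n_floor:
        logger.info("dispersion floored for %d genes", n_floor)
    return pd.Series(np.maximum(alpha, ALPHA_FLOOR), index=counts.index, name="alpha")


def fit_nb_glm(counts_g: np.ndarray, sizefactors: np.ndarray, design: pd.DataFrame,
               alpha: float) -> GeneFit:
    """Maximize the NB log-likelihood with log link and log-size-factor offsets."""
    X = np.asarray(design, float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    y = np.asarray(counts_g, float)
    if not y.any():
        raise ValueError("all-zero gene cannot be fit")
    model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                   offset=np.log(np.asarray(sizefactors, float)))
    res = model.fit(maxiter=100, tol=1e-8)
    cols = tuple(design.columns)
    return GeneFit(
        coef=pd.Series(res.params / LN2, index=list(cols)),
        fitted=np.asarray(res.fittedvalues),
        alpha=alpha,
        llf=float(res.llf),
        converged=bool(res.converged),
        columns=cols,
    )


def lrt_nested(full: GeneFit, reduced: GeneFit, df: int) -> tuple[float, float]:
    """Likelihood-ratio statistic (clipped at 0) and chi-square upper-tail p."""
    if not set(reduced.columns) <= set(full.columns):
        raise ValueError("models are not nested")
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    return stat, float(stats.chi2.sf(stat, df))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(pvals, float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def compute_lfc(counts: pd.DataFrame, sizefactors: pd.Series,
                samples_a, samples_b, pseudocount: float = 0.5) -> pd.DataFrame:
    """Moderated log2 fold change of group A over group B.

    LFC = log2((mu_A + c) / (mu_B + c)) on mean normalized counts; base mean
    is the mean normalized count over the union of the two groups.
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    if not samples_a or not samples_b:
        raise ValueError("both sample groups must be non-empty")
    if set(samples_a) & set(samples_b):
        raise ValueError("sample groups must be disjoint")
    norm = counts / sizefactors.reindex(counts.columns)
    mu_a = norm[samples_a].mean(axis=1)
    mu_b = norm[samples_b].mean(axis=1)
    lfc = np.log2(mu_a + pseudocount) - np.log2(mu_b + pseudocount)
    base = norm[samples_a + samples_b].mean(axis=1)
    return pd.DataFrame({"lfc": lfc, "base_mean": base})


# ---------------------------------------------------------------------------
# design construction and the four-model scheme

def build_design(meta: pd.DataFrame, terms: tuple[str, ...],
                 surrogate: pd.Series | None = None,
                 diet_ref: str = "C", tissue_ref: str = "B") -> pd.DataFrame:
    """Treatment-coded design matrix for the given terms (reference C / B)."""
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(meta))}
    if "SV" in terms and surrogate is not None:
        sv = surrogate.reindex(meta.sample_id).to_numpy(float)
        if np.linalg.norm(sv) > 0:
            cols["SV"] = sv
    if "batch" in terms:
        for lev in sorted(pd.unique(meta["batch"]))[1:]:
            cols[f"batch[{lev}]"] = (meta["batch"] == lev).to_numpy(float)
    tis_levels = [t for t in pd.unique(meta["tissue"]) if t != tissue_ref]
    diet_levels = [d for d in pd.unique(meta["diet"]) if d != diet_ref]
    if "tissue" in terms:
        for t in tis_levels:
            cols[f"tissue[{t}]"] = (meta["tissue"] == t).to_numpy(float)
    if "treatment" in terms:
        for d in diet_levels:
            cols[f"diet[{d}]"] = (meta["diet"] == d).to_numpy(float)
    if "tissue:treatment" in terms:
        for t in tis_levels:
            for d in diet_levels:
                cols[f"tissue[{t}]:diet[{d}]"] = (
                    ((meta["tissue"] == t) & (meta["diet"] == d)).to_numpy(float))
    return pd.DataFrame(cols, index=meta.sample_id)


def paper_model_specs(meta: pd.DataFrame) -> dict[str, ModelSpec]:
    """The four-model hierarchy, dropping factors with a single level."""
    base = ("SV", "batch") if meta["batch"].nunique() > 1 else ("SV",)
    has_tissue = meta["tissue"].nunique() > 1
    specs = {}
    if has_tissue:
        specs["m1"] = ModelSpec("m1", base + ("tissue",))
        specs["m2"] = ModelSpec("m2", base + ("treatment",))
        specs["m3"] = ModelSpec("m3", base + ("tissue", "treatment"))
        specs["m4"] = ModelSpec("m4", base + ("tissue", "treatment", "tissue:treatment"))
    else:
        specs["m1"] = ModelSpec("m1", base)
        specs["m3"] = ModelSpec("m3", base + ("treatment",))
    return specs


def _fit_matrix(counts, sizefactors, design, alphas):
    """Fit one design to every gene; returns (llf, converged, n_params)."""
    s = sizefactors.reindex(counts.columns).to_numpy(float)
    llf = np.empty(len(counts))
    conv = np.empty(len(counts), dtype=bool)
    K = counts.to_numpy(float)
    a = alphas.reindex(counts.index).to_numpy(float)
    for i in range(len(counts)):
        try:
            fit = fit_nb_glm(K[i], s, design, a[i])
            llf[i], conv[i] = fit.llf, fit.converged
        except (ValueError, np.linalg.LinAlgError):
            llf[i], conv[i] = np.nan, False
    return llf, conv, design.shape[1]


def run_de(counts: pd.DataFrame, meta: pd.DataFrame,
           design_info: DesignInfo | None = None,
           sizefactors: pd.Series | None = None,
           alpha: float = 0.05, pseudocount: float = 0.5,
           diet_ref: str = "C", tissue_ref: str = "B") -> dict:
    """Run the full DE scheme: LRT contrasts plus all pairwise diet LFCs.

    Returns {"tests": DataFrame(gene, contrast, stat, df, p, p_adj),
    "fold_changes": long DataFrame(gene, tissue, pair, reference, lfc,
    base_mean), "sizefactors": Series}.
    """
    meta = meta.set_index("sample_id").loc[list(counts.columns)].reset_index()
    if sizefactors is None:
        sizefactors = estimate_size_factors(counts)
    surrogate = design_info.surrogate if design_info is not None else None
    cells = meta["diet"].astype(str) + ":" + meta["tissue"].astype(str)
    cells.index = meta.sample_id
    alphas = estimate_dispersion(counts, sizefactors, cells.loc[counts.columns])

    specs = paper_model_specs(meta)
    designs = {name: build_design(meta, spec.terms, surrogate, diet_ref, tissue_ref)
               for name, spec in specs.items()}
    fits = {name: _fit_matrix(counts, sizefactors, d, alphas)
            for name, d in designs.items()}

    contrasts = [("treatment-main", "m3", "m1")]
    if "m2" in specs:
        contrasts.append(("tissue-main", "m3", "m2"))
    if "m4" in specs:
        contrasts.append(("interaction", "m4", "m3"))

    rows = []
    for cname, fname, rname in contrasts:
        llf_f, conv_f, k_f = fits[fname]
        llf_r, conv_r, k_r = fits[rname]
        df = k_f - k_r
        stat = np.maximum(0.0, 2.0 * (llf_f - llf_r))
        ok = conv_f & conv_r & np.isfinite(stat)
        n_bad = int((~ok).sum())
        if n_bad:
            logger.info("%s: %d genes excluded (non-converged fits)", cname, n_bad)
        p = np.where(ok, stats.chi2.sf(np.where(ok, stat, 0.0), df), np.nan)
        padj = bh_adjust(p)
        rows.append(pd.DataFrame({
            "gene": counts.index, "contrast": cname,
            "stat": np.where(ok, stat, np.nan), "df": df, "p": p, "p_adj": padj,
        }))
    tests = pd.concat(rows, ignore_index=True)

    fc_rows = []
    diets = list(pd.unique(meta["diet"]))
    for tissue in pd.unique(meta["tissue"]):
        sub = meta[meta["tissue"] == tissue]
        by_diet = {d: sub.loc[sub.diet == d, "sample_id"].tolist() for d in diets}
        for ref in diets:
            for other in diets:
                if other == ref:
                    continue
                tab = compute_lfc(counts, sizefactors, by_diet[other], by_diet[ref],
                                  pseudocount)
                fc_rows.append(pd.DataFrame({
                    "gene": tab.index, "tissue": tissue,
                    "pair": f"{other} vs {ref}", "reference": ref,
                    "lfc": tab["lfc"].to_numpy(), "base_mean": tab["base_mean"].to_numpy(),
                }))
    fold_changes = pd.concat(fc_rows, ignore_index=True)
    return {"tests": tests, "fold_changes": fold_changes, "sizefactors": sizefactors,
            "dispersions": alphas, "fdr": alpha}


class DEResults:
    """Results of a fitted :class:`DifferentialExpression` model."""

    def __init__(self, payload: dict):
        self.tests: pd.DataFrame = payload["tests"]
        self.fold_changes: pd.DataFrame = payload["fold_changes"]
        self.sizefactors: pd.Series = payload["sizefactors"]
        self.dispersions: pd.Series = payload["dispersions"]
        self.fdr: float = payload["fdr"]

    def significant(self, contrast: str = "treatment-main") -> pd.Index:
        t = self.tests
        hit = t[(t.contrast == contrast) & (t.p_adj < self.fdr)]
        return pd.Index(hit.gene.unique())

    def summary(self) -> pd.DataFrame:
        rows = []
        for cname, grp in self.tests.groupby("contrast"):
            rows.append({
                "contrast": cname,
                "n_tested": int(grp.p.notna().sum()),
                "n_significant": int((grp.p_adj < self.fdr).sum()),
                "fdr": self.fdr,
            })
        return pd.DataFrame(rows)


class DifferentialExpression:
    """NB-GLM differential expression model on a counts + design pair."""

    def __init__(self, counts: pd.DataFrame, meta: pd.DataFrame,
                 design_info: DesignInfo | None = None,
                 fdr: float = 0.05, pseudocount: float = 0.5):
        self.counts, self.meta = counts, meta
        self.design_info = design_info
        self.fdr, self.pseudocount = fdr, pseudocount

    @classmethod
    def from_dataframe(cls, counts, meta, **kw):
        return cls(counts, meta, **kw)

    def fit(self) -> DEResults:
        return DEResults(run_de(self.counts, self.meta, self.design_info,
                                alpha=self.fdr, pseudocount=self.pseudocount))
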