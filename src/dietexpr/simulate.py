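"""Synthetic count-data generator.

Emulates a factorial bulk RNA-seq design: three diets (control C, dietary
restriction DR, high sugar HS) crossed with three tissues (body B, head H,
ovary O) and six replicate batches, with negative-binomial counts whose
log2 mean decomposes into a gene baseline, tissue-dominant effects, subtle
diet effects (optionally concordant between DR and HS relative to C),
additive batch offsets, latent-factor gene modules, and per-sample library
depth. Ground truth for every planted quantity is returned alongside the
counts so downstream stages can be tested for recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "TruthTables", "simulate_counts", "write_truth", "read_truth"]

UNASSIGNED = "none"


@dataclass
class SimConfig:
    """Parameters of the simulated experiment.

    All effect scales are log2 units. Defaults state a realistic desk-scale
    bulk experiment: tissue effects dominate (sd 2), diet effects are subtle
    (sd 1 on 20% of genes), batches drift mildly (sd 0.2), and library
    depths span the 0.5-2x range reported for the motivating design.
    """

    n_genes: int = 2000
    diets: Sequence[str] = ("C", "DR", "HS")
    tissues: Sequence[str] = ("B", "H", "O")
    n_replicates: int = 6
    baseline_logmean_mu: float = 5.0
    baseline_logmean_sigma: float = 2.0
    dispersion: float = 0.05
    pi_de: float = 0.2
    effect_size_sd: float = 1.0
    effect_size_fixed: float | None = None
    rho_concord: float = 0.7
    tissue_effect_sd: float = 2.0
    batch_effect_sd: float = 0.2
    interaction_sd: float = 0.3
    module_spec: Sequence[tuple[int, float]] = ()
    library_size_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for name in ("pi_de", "rho_concord"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if sum(size for size, _ in self.module_spec) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be positive and ordered")


@dataclass
class TruthTables:
    """Planted ground truth of a simulation.

    true_lfc columns are "<diet>_<tissue>" log2 fold changes relative to the
    reference diet (first diet label, conventionally C).
    """

    true_lfc: pd.DataFrame
    de_flag: pd.Series
    concord_flag: pd.Series
    module_label: pd.Series
    batch_offset: pd.Series
    sample_depth: pd.Series

    def __post_init__(self) -> None:
        if bool((self.concord_flag & ~self.de_flag).any()):
            raise ValueError("concord_flag set on a gene without de_flag")
        sizes = self.module_label[self.module_label != UNASSIGNED].value_counts()
        if (sizes < 2).any():
            raise ValueError("every labeled module needs at least 2 members")


def _sample_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for tissue in config.tissues:
        for diet in config.diets:
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{tissue}_{diet}_{rep}",
                        "diet": diet,
                        "tissue": tissue,
                        "replicate": rep,
                        "batch": rep,
                    }
                )
    return pd.DataFrame(rows)


def simulate_counts(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, TruthTables]:
    """Draw a count matrix, its sample table, and the planted truth.

    Counts for gene g in sample j are negative binomial with mean
    ``depth_j * 2**(baseline_g + tissue_gt + diet_gdt + batch_b + module term)``
    and dispersion alpha (variance mu + alpha*mu^2). Identical config and
    seed give bitwise-identical output.
    """
    rng = np.random.default_rng(config.seed)
    meta = _sample_table(config)
    n_genes, n_samples = config.n_genes, len(meta)
    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene")
    ref_diet = config.diets[0]

    baseline = rng.normal(config.baseline_logmean_mu, config.baseline_logmean_sigma, n_genes)
    tissue_eff = {
        t: rng.normal(0.0, config.tissue_effect_sd, n_genes) for t in config.tissues
    }

    # planted diet effects: exact counts of DE and concordant genes
    n_de = int(round(config.pi_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    de_flag = np.zeros(n_genes, dtype=bool)
    de_flag[de_idx] = True
    n_conc = int(round(config.rho_concord * n_de))
    conc_idx = rng.permutation(de_idx)[:n_conc]
    concord_flag = np.zeros(n_genes, dtype=bool)
    concord_flag[conc_idx] = True

    alt_diets = [d for d in config.diets if d != ref_diet]
    base_sign = {d: np.zeros(n_genes) for d in alt_diets}
    base_mag = {d: np.zeros(n_genes) for d in alt_diets}
    signs_first = rng.choice([-1.0, 1.0], size=n_genes)
    for i, d in enumerate(alt_diets):
        if config.effect_size_fixed is not None:
            mag = np.full(n_genes, float(config.effect_size_fixed))
        else:
            mag = np.abs(rng.normal(0.0, config.effect_size_sd, n_genes))
        base_mag[d] = np.where(de_flag, mag, 0.0)
        if i == 0:
            base_sign[d] = signs_first
        else:
            base_sign[d] = np.where(concord_flag, signs_first, -signs_first)

    # per-tissue multiplicative perturbation keeps effect signs, adds interaction
    true_lfc = pd.DataFrame(0.0, index=genes,
                            columns=[f"{d}_{t}" for d in alt_diets for t in config.tissues])
    diet_eff = {}
    for d in alt_diets:
        for t in config.tissues:
            pert = np.exp(rng.normal(0.0, config.interaction_sd, n_genes))
            lfc = base_sign[d] * base_mag[d] * pert
            lfc = np.where(de_flag, lfc, 0.0)
            diet_eff[(d, t)] = lfc
            true_lfc[f"{d}_{t}"] = lfc

    batch_offset = rng.normal(0.0, config.batch_effect_sd, config.n_replicates)

    # latent modules: shared standard-normal factor per sample, constant
    # positive loading per module, added on the log2 scale
    module_label = np.full(n_genes, UNASSIGNED, dtype=object)
    module_loading = np.zeros(n_genes)
    module_of_gene = np.full(n_genes, -1)
    free = rng.permutation(n_genes)
    pos = 0
    factors = []
    for m, (size, loading_sd) in enumerate(config.module_spec):
        members = free[pos:pos + size]
        pos += size
        module_label[members] = f"M{m + 1}"
        module_loading[members] = loading_sd
        module_of_gene[members] = m
        factors.append(rng.standard_normal(n_samples))

    lo, hi = config.library_size_range
    depth = np.exp(rng.uniform(np.log(lo), np.log(hi), n_samples))

    log2mu = np.tile(baseline[:, None], (1, n_samples))
    for j, row in meta.iterrows():
        log2mu[:, j] += tissue_eff[row.tissue]
        if row.diet != ref_diet:
            log2mu[:, j] += diet_eff[(row.diet, row.tissue)]
        log2mu[:, j] += batch_offset[row.batch - 1]
        for m in range(len(factors)):
            in_m = module_of_gene == m
            log2mu[in_m, j] += module_loading[in_m] * factors[m][j]

    mu = depth[None, :] * np.exp2(log2mu)
    r = 1.0 / config.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    counts_df = pd.DataFrame(counts, index=genes, columns=meta.sample_id.tolist())
    counts_df.index.name = "gene"
    truth = TruthTables(
        true_lfc=true_lfc,
        de_flag=pd.Series(de_flag, index=genes, name="de_flag"),
        concord_flag=pd.Series(concord_flag, index=genes, name="concord_flag"),
        module_label=pd.Series(module_label, index=genes, name="module"),
        batch_offset=pd.Series(
            batch_offset,
            index=pd.Index(range(1, config.n_replicates + 1), name="batch"),
            name="batch_offset"),
        sample_depth=pd.Series(
            depth, index=pd.Index(meta.sample_id.tolist(), name="sample_id"),
            name="depth"),
    )
    return counts_df, meta, truth


def write_truth(truth: TruthTables, path: str | Path) -> None:
    """Write the truth tables as three TSVs under ``path`` (a directory)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    genes = truth.true_lfc.copy()
    genes.insert(0, "de_flag", truth.de_flag.astype(int))
    genes.insert(1, "concord_flag", truth.concord_flag.astype(int))
    genes.insert(2, "module", truth.module_label)
    genes.index.name = "gene"
    genes.to_csv(path / "truth_genes.tsv", sep="\t")
    truth.batch_offset.rename_axis("batch").to_csv(path / "truth_batches.tsv", sep="\t")
    truth.sample_depth.rename_axis("sample_id").to_csv(path / "truth_samples.tsv", sep="\t")


def read_truth(path: str | Path) -> TruthTables:
    """Read truth tables written by :func:`write_truth` (lossless round trip)."""
    path = Path(path)
    genes = pd.read_csv(path / "truth_genes.tsv", sep="\t", index_col="gene")
    batches = pd.read_csv(path / "truth_batches.tsv", sep="\t", index_col="batch")
    samples = pd.read_csv(path / "truth_samples.tsv", sep="\t", index_col="sample_id")
    lfc_cols = [c for c in genes.columns if c not in ("de_flag", "concord_flag", "module")]
    return TruthTables(
        true_lfc=genes[lfc_cols],
        de_flag=genes["de_flag"].astype(bool).rename("de_flag"),
        concord_flag=genes["concord_flag"].astype(bool).rename("concord_flag"),
        module_label=genes["module"].astype(object).rename("module"),
        batch_offset=batches["batch_offset"],
        sample_depth=samples["depth"],
    )


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["diets"] = list(config.diets)
    d["tissues"] = list(config.tissues)
    d["module_spec"] = [list(m) for m in config.module_spec]
    d["library_size_range"] = list(config.library_size_range)
    return d
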