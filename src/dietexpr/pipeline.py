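"""File formats, configuration, seeding, and the end-to-end orchestrator.

All tabular interchange is TSV; gene-set collections are GMT. A run is
driven by a nested configuration (strict schema: unknown keys rejected) and
a single global seed from which each stochastic stage derives its own
stream, so stages are independently reproducible. Every run writes a JSON
manifest with the config snapshot, per-stage seeds, input digests, and
timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .concordance import PermutationScheme, run_concordance
from .diffexpr import run_de
from .genesets import read_gmt, run_set_analysis, synthetic_collection
from .netmodules import (NetworkConfig, CoexpressionNetwork)
from .preprocess import (estimate_size_factors, estimate_surrogate_variable,
                         filter_low_counts, filter_low_variance,
                         remove_batch_effects, shifted_log_transform)
from .simulate import SimConfig, config_to_dict, simulate_counts, write_truth

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "read_counts", "read_meta",
           "write_table", "derive_seed", "run_all", "DEFAULT_CONFIG"]

META_COLS = ["sample_id", "diet", "tissue", "replicate", "batch"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "dietexpr_run",
    "simulate": {"enabled": True, **{k: v for k, v in
                 dataclasses.asdict(SimConfig()).items() if k != "seed"}},
    "counts": None,   # path to counts TSV when simulate.enabled is false
    "meta": None,     # path to metadata TSV
    "preprocess": {"min_count": 10, "min_samples": 2, "var_threshold": 1.0,
                   "pseudocount": 1.0},
    "de": {"fdr": 0.05, "pseudocount": 0.5},
    "concordance": {"n_permutations": 100, "per_pseudo": 2, "gene_set": "all"},
    "network": {"power": 23.0, "cut_height": 0.95, "min_module_size": 30,
                "merge_threshold": 0.9, "resamples": 100, "kept_replicates": 4,
                "match_fraction": 0.10, "support_fraction": 0.50,
                "robustness": False, "select_power": False},
    "genesets": {"enabled": True, "gmt": None, "mode": "ttest", "min_size": 10,
                 "n_synthetic_sets": 20},
}


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class PipelineConfig:
    """Validated nested configuration; unknown keys are rejected."""

    def __init__(self, overrides: dict | None = None):
        self.data = _merge_strict(DEFAULT_CONFIG, overrides or {}, path="")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must hold a mapping")
        return cls(loaded)

    def __getitem__(self, key):
        return self.data[key]


def _merge_strict(defaults, overrides, path):
    if not isinstance(overrides, dict):
        raise ConfigError(f"section {path or '<root>'} must be a mapping")
    out = {}
    for key, dval in defaults.items():
        if key in overrides:
            oval = overrides[key]
            if isinstance(dval, dict) and isinstance(oval, dict):
                out[key] = _merge_strict(dval, oval, f"{path}.{key}")
            else:
                out[key] = oval
        else:
            out[key] = dval
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config key(s) in {path or '<root>'}: {sorted(unknown)}")
    return out


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: global seed mixed with a stable hash of the stage name."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene x sample integer counts from TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate gene ids: {dup}")
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample ids in counts header")
    arr = df.to_numpy()
    if not ((arr == arr.astype(int)).all() and (arr >= 0).all()):
        raise ValueError("counts must be non-negative integers")
    return df.astype(int)


def read_meta(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV with columns sample_id, diet, tissue, replicate, batch."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing column(s): {missing}")
    if df.sample_id.duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    return df[META_COLS]


def check_samples_match(counts: pd.DataFrame, meta: pd.DataFrame) -> None:
    c, m = set(counts.columns), set(meta.sample_id)
    if c != m:
        only_c, only_m = sorted(c - m), sorted(m - c)
        raise ValueError(
            f"counts/metadata sample mismatch: only in counts {only_c[:5]}, "
            f"only in metadata {only_m[:5]}")


def write_table(df: pd.DataFrame, path: Path, manifest_digest: str = "",
                index: bool = True) -> None:
    """TSV with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(f"# dietexpr v{__version__} manifest={manifest_digest}\n")
        df.to_csv(fh, sep="\t", index=index)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_all(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run simulate (optional) -> preprocess -> de -> concordance -> modules
    -> genesets, writing TSVs and a JSON manifest under the output directory.

    Returns a dict of in-memory stage results; a stage failure aborts after
    recording a partial manifest.
    """
    cfg = config.data
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {
        "version": __version__,
        "config": cfg,
        "seeds": {},
        "inputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
    }
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
    results: dict = {}

    def checkpoint(stage):
        manifest["stages"].append(stage)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    try:
        # --- inputs ---------------------------------------------------
        if cfg["simulate"]["enabled"]:
            sim_seed = derive_seed(seed, "simulate")
            manifest["seeds"]["simulate"] = sim_seed
            sim_kwargs = {k: v for k, v in cfg["simulate"].items() if k != "enabled"}
            sim_kwargs["module_spec"] = [tuple(m) for m in sim_kwargs["module_spec"]]
            simcfg = SimConfig(seed=sim_seed, **sim_kwargs)
            counts, meta, truth = simulate_counts(simcfg)
            write_table(counts, out / "counts.tsv", digest)
            write_table(meta, out / "meta.tsv", digest, index=False)
            write_truth(truth, out / "truth")
            results["truth"] = truth
        else:
            if not cfg["counts"] or not cfg["meta"]:
                raise ConfigError("counts and meta paths required when simulation is off")
            counts = read_counts(cfg["counts"])
            meta = read_meta(cfg["meta"])
            check_samples_match(counts, meta)
            manifest["inputs"] = {"counts": _digest(Path(cfg["counts"])),
                                  "meta": _digest(Path(cfg["meta"]))}
        logger.info("input: %d genes x %d samples", *counts.shape)
        checkpoint("input")

        # --- preprocess -----------------------------------------------
        pp = cfg["preprocess"]
        counts_v = filter_low_variance(counts, pp["var_threshold"])
        counts_f = filter_low_counts(counts_v, pp["min_count"], pp["min_samples"])
        logger.info("filters: %d -> %d -> %d genes",
                    len(counts), len(counts_v), len(counts_f))
        sf = estimate_size_factors(counts_f)
        expr = shifted_log_transform(counts_f, sf, pp["pseudocount"])
        design_info = estimate_surrogate_variable(expr, meta)
        corrected = remove_batch_effects(expr, design_info)
        write_table(sf.to_frame(), out / "size_factors.tsv", digest)
        write_table(design_info.surrogate.to_frame(), out / "surrogate.tsv", digest)
        write_table(corrected, out / "expression_corrected.tsv", digest)
        results.update(counts=counts_f, meta=meta, sizefactors=sf,
                       expr=expr, corrected=corrected, design_info=design_info)
        checkpoint("preprocess")

        # --- differential expression ----------------------------------
        de = run_de(counts_f, meta, design_info, sizefactors=sf,
                    alpha=cfg["de"]["fdr"], pseudocount=cfg["de"]["pseudocount"])
        write_table(de["tests"], out / "de_tests.tsv", digest, index=False)
        write_table(de["fold_changes"], out / "fold_changes.tsv", digest, index=False)
        results["de"] = de
        checkpoint("de")

        # --- concordance per tissue -----------------------------------
        cc = cfg["concordance"]
        conc_tables = []
        sig = None
        if cc["gene_set"] == "de":
            t = de["tests"]
            sig = pd.Index(t[(t.contrast == "treatment-main")
                             & (t.p_adj < cfg["de"]["fdr"])].gene.unique())
        for i, tissue in enumerate(pd.unique(meta["tissue"])):
            scheme = PermutationScheme(
                n_permutations=cc["n_permutations"], per_pseudo=cc["per_pseudo"],
                seed=derive_seed(seed, f"concordance:{tissue}"))
            manifest["seeds"][f"concordance:{tissue}"] = scheme.seed
            conc_tables.append(run_concordance(
                counts_f, meta, tissue, scheme, genes=sig, sizefactors=None,
                pseudocount=cfg["de"]["pseudocount"]))
        conc = pd.concat(conc_tables, ignore_index=True)
        write_table(conc, out / "concordance.tsv", digest, index=False)
        results["concordance"] = conc
        checkpoint("concordance")

        # --- co-expression modules ------------------------------------
        nw = cfg["network"]
        net_seed = derive_seed(seed, "network")
        manifest["seeds"]["network"] = net_seed
        netcfg = NetworkConfig(
            power=nw["power"], cut_height=nw["cut_height"],
            min_module_size=nw["min_module_size"],
            merge_threshold=nw["merge_threshold"], resamples=nw["resamples"],
            kept_replicates=nw["kept_replicates"],
            match_fraction=nw["match_fraction"],
            support_fraction=nw["support_fraction"], seed=net_seed)
        net = CoexpressionNetwork(corrected, meta, netcfg,
                                  select_power=nw["select_power"]).fit(
                                      robustness=nw["robustness"])
        assign = net.assignment.to_frame("module")
        if net.robustness is not None:
            assign["support"] = net.robustness.support
        write_table(assign, out / "modules.tsv", digest)
        if len(net.eigengenes):
            write_table(net.eigengenes, out / "eigengenes.tsv", digest)
        if net.anova is not None:
            write_table(net.anova, out / "eigengene_anova.tsv", digest, index=False)
        results["network"] = net
        checkpoint("modules")

        # --- gene sets -------------------------------------------------
        gs = cfg["genesets"]
        if gs["enabled"]:
            background = set(counts_f.index)
            if gs["gmt"]:
                collection = read_gmt(gs["gmt"])
            else:
                gs_seed = derive_seed(seed, "genesets")
                manifest["seeds"]["genesets"] = gs_seed
                collection = synthetic_collection(
                    sorted(background), gs["n_synthetic_sets"], seed=gs_seed)
            fc = de["fold_changes"]
            first = fc[(fc.tissue == fc.tissue.iloc[0]) & (fc.pair == fc.pair.iloc[0])]
            stats_series = first.set_index("gene")["lfc"]
            table = run_set_analysis(stats_series, collection, background,
                                     mode=gs["mode"], min_size=gs["min_size"])
            write_table(table, out / "geneset_results.tsv", digest, index=False)
            results["genesets"] = table
        checkpoint("genesets")
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        checkpoint("done")
    except Exception:
        manifest["failed"] = True
        checkpoint("FAILED")
        raise
    results["manifest"] = manifest
    return results
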