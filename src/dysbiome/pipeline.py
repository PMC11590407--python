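"""End-to-end orchestration: simulate/load -> diversity -> dysbiosis -> screens.

One config drives a fixed stage order; every intermediate table is
persisted as TSV (matrices, scores, fits) plus a JSON report index with a
provenance block (config hash, seeds, package version) sufficient to
reproduce any output. Reruns with the same config overwrite identical
files.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffabund import cfu_growth_fit, lda_effect_size, loglm_diffabund
from .diversity import alpha_diversity_table, beta_diversity, pairwise_permanova, pcoa, permanova
from .dysbiosis import DysbiosisConfig, dysbiosis_pipeline
from .simulate import build_template, default_design, default_growth_params, simulate_experiment
from .tables import CountTable, rarefy, read_count_table, read_metadata, to_relative

__all__ = ["RunConfig", "AnalysisReport", "run_full_analysis", "load_config"]


@dataclass
class RunConfig:
    """Inputs and knobs of a full analysis run.

    Exactly one of (``counts_path``) or (``simulate``) must be given;
    ``simulate`` is a mapping of template overrides for the synthetic
    generator (may be empty).
    """

    out_dir: str = "results"
    counts_path: str | None = None
    metadata_path: str | None = None
    cfu_path: str | None = None
    simulate: dict | None = None
    seed: int = 0
    rarefaction_depth: int = 5400
    metrics: tuple[str, ...] = ("braycurtis", "jensenshannon")
    ordination_metric: str = "jensenshannon"
    ref_group: str = "CON"
    baseline_timepoint: float = 0.0
    lower_pct: float = 10.0
    upper_pct: float = 90.0
    n_permutations: int = 999
    correlation_focal: str | None = None

    def __post_init__(self) -> None:
        has_paths = self.counts_path is not None
        has_sim = self.simulate is not None
        if has_paths == has_sim:
            raise ValueError("exactly one of counts_path or simulate must be set")
        if has_paths and self.metadata_path is None:
            raise ValueError("counts_path requires metadata_path")
        if self.ordination_metric not in self.metrics:
            raise ValueError("ordination_metric must be among metrics")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["metrics"] = list(self.metrics)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Read a RunConfig from a YAML/JSON key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "metrics" in raw:
        raw["metrics"] = tuple(raw["metrics"])
    return RunConfig(**raw)


@dataclass
class AnalysisReport:
    paths: dict[str, str]
    provenance: dict
    alpha: pd.DataFrame
    permanova_table: pd.DataFrame
    dysbiosis: object
    diffabund: dict[str, pd.DataFrame]
    growth_fits: list
    warnings: list[str] = field(default_factory=list)


def _write_tsv(df: pd.DataFrame, path: Path, index_label="taxon") -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)


def run_full_analysis(config: RunConfig) -> AnalysisReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    notes: list[str] = []

    # ---- stage 0: data
    if config.simulate is not None:
        template = build_template(config.simulate)
        design = default_design()
        dataset = simulate_experiment(template, design, seed=config.seed)
        paths.update(dataset.write(out / "input"))
        counts, metadata, cfu = dataset.counts, dataset.metadata, dataset.cfu
    else:
        counts = read_count_table(config.counts_path)
        metadata = read_metadata(config.metadata_path)
        cfu = pd.read_csv(config.cfu_path, sep="\t") if config.cfu_path else None

    # ---- stage 1: alpha diversity on rarefied counts
    import warnings as _warnings

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        rare = rarefy(counts, depth=config.rarefaction_depth, seed=config.seed)
        notes.extend(str(w.message) for w in caught)
    alpha = alpha_diversity_table(rare)
    _write_tsv(alpha, out / "alpha_diversity.tsv", index_label="sample_id")
    paths["alpha"] = str(out / "alpha_diversity.tsv")
    metadata = metadata.loc[rare.sample_ids]

    # ---- stage 2: beta diversity matrices
    rel = to_relative(rare)
    matrices = {}
    for metric in config.metrics:
        dm = beta_diversity(rel, metric)
        dm.write(out / f"distance_{metric}.tsv")
        paths[f"distance_{metric}"] = str(out / f"distance_{metric}.tsv")
        matrices[metric] = dm

    # ---- stage 3: ordination
    ord_dm = matrices[config.ordination_metric]
    ordination = pcoa(ord_dm)
    _write_tsv(ordination.coordinates, out / "pcoa_coordinates.tsv", index_label="sample_id")
    with open(out / "pcoa_eigenvalues.json", "w") as fh:
        json.dump(
            {
                "metric": config.ordination_metric,
                "eigenvalues": ordination.eigenvalues.tolist(),
                "proportion_explained": ordination.proportion_explained.tolist(),
                "n_negative": ordination.n_negative,
            },
            fh,
            indent=2,
        )
    paths["pcoa_coordinates"] = str(out / "pcoa_coordinates.tsv")
    paths["pcoa_eigenvalues"] = str(out / "pcoa_eigenvalues.json")

    # ---- stage 4: PERMANOVA (time effect, and treatment class per timepoint)
    rng = np.random.default_rng(config.seed)
    rows = []
    time_groups = metadata.loc[ord_dm.ids, "timepoint_h"].astype(str)
    res_time = permanova(
        ord_dm, time_groups, n_permutations=config.n_permutations,
        seed=int(rng.integers(2**31)),
    )
    rows.append(("time", "all", res_time.statistic, res_time.r_squared, res_time.p_value))
    tclass = metadata["treatment"].where(
        metadata["treatment"] == config.ref_group, other="phage"
    )
    per_tp_p = []
    for tp in sorted(metadata["timepoint_h"].unique()):
        ids = metadata.index[metadata["timepoint_h"] == tp]
        sub = ord_dm.filter([i for i in ord_dm.ids if i in set(ids)])
        res = permanova(
            sub, tclass.loc[list(sub.ids)], n_permutations=config.n_permutations,
            seed=int(rng.integers(2**31)),
        )
        rows.append((f"class_at_{tp:g}h", f"{tp:g}", res.statistic, res.r_squared, res.p_value))
        per_tp_p.append(res.p_value)
    from .diffabund import bh_fdr

    perm_table = pd.DataFrame(
        rows, columns=["test", "timepoint_h", "pseudo_f", "r_squared", "p_value"]
    )
    q = np.full(len(perm_table), np.nan)
    q[1:] = bh_fdr(np.array(per_tp_p))
    perm_table["q_value"] = q
    _write_tsv(perm_table.set_index("test"), out / "permanova.tsv", index_label="test")
    paths["permanova"] = str(out / "permanova.tsv")

    # ---- stage 5: dysbiosis scoring (on unrarefied relative abundances)
    dys_cfg = DysbiosisConfig(
        ref_group=config.ref_group,
        baseline_timepoint=config.baseline_timepoint,
        lower_pct=config.lower_pct,
        upper_pct=config.upper_pct,
    )
    report = dysbiosis_pipeline(counts, metadata, dys_cfg)
    _write_tsv(report.samples, out / "dysbiosis_scores.tsv", index_label="sample_id")
    with open(out / "dysbiosis_summary.json", "w") as fh:
        json.dump(
            {
                "thresholds": {
                    "lower": report.thresholds.lower,
                    "upper": report.thresholds.upper,
                    "lower_pct": report.thresholds.lower_pct,
                    "upper_pct": report.thresholds.upper_pct,
                    "baseline_timepoint": report.thresholds.baseline_timepoint,
                },
                "n_clamped": report.n_clamped,
                "groups": [
                    {
                        "treatment": trt,
                        "timepoint_h": tp,
                        "mean": None if pd.isna(row["mean"]) else row["mean"],
                        "sd": None if pd.isna(row["sd"]) else row["sd"],
                        "n": int(row["n"]),
                        "n_dysbiotic": int(row["n_dysbiotic"]),
                    }
                    for (trt, tp), row in report.summary.iterrows()
                ],
            },
            fh,
            indent=2,
        )
    paths["dysbiosis_scores"] = str(out / "dysbiosis_scores.tsv")
    paths["dysbiosis_summary"] = str(out / "dysbiosis_summary.json")

    # ---- stage 6: differential abundance at the final timepoint
    diff_tables: dict[str, pd.DataFrame] = {}
    final_tp = sorted(metadata["timepoint_h"].unique())[-1]
    at_final = metadata[metadata["timepoint_h"] == final_tp]
    ids_ref = [s for s in at_final.index[at_final["treatment"] == config.ref_group] if s in rel.sample_ids]
    ids_phage = [s for s in at_final.index[at_final["treatment"] != config.ref_group] if s in rel.sample_ids]
    if len(ids_ref) >= 3 and len(ids_phage) >= 3:
        sub = rel.select_samples(ids_ref + ids_phage)
        lfc = loglm_diffabund(sub, ids_ref, ids_phage, contrast_name=f"phage_vs_{config.ref_group}_{final_tp:g}h")
        diff_tables["loglm"] = lfc
        _write_tsv(lfc, out / "diffabund_loglm.tsv")
        paths["diffabund_loglm"] = str(out / "diffabund_loglm.tsv")
        classes = pd.Series(
            ["ref"] * len(ids_ref) + ["phage"] * len(ids_phage),
            index=ids_ref + ids_phage,
        )
        lda = lda_effect_size(sub, classes, seed=config.seed)
        diff_tables["lda"] = lda
        _write_tsv(lda, out / "diffabund_lda.tsv")
        paths["diffabund_lda"] = str(out / "diffabund_lda.tsv")
    else:
        notes.append("skipped differential abundance: fewer than 3 samples per class")

    if config.correlation_focal and config.correlation_focal in rel.data.index:
        from .diffabund import taxon_correlation

        corr = taxon_correlation(rel, config.correlation_focal)
        _write_tsv(corr, out / "taxon_correlation.tsv")
        paths["taxon_correlation"] = str(out / "taxon_correlation.tsv")

    # ---- stage 7: CFU growth fits
    fits = []
    if cfu is not None and len(cfu):
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            fits = cfu_growth_fit(cfu, metadata)
            notes.extend(str(w.message) for w in caught)
        fit_df = pd.DataFrame([f.__dict__ for f in fits]).set_index("treatment")
        _write_tsv(fit_df, out / "cfu_growth_fits.tsv", index_label="treatment")
        paths["cfu_growth_fits"] = str(out / "cfu_growth_fits.tsv")

    provenance = {
        "package": "dysbiome",
        "version": __version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "warnings": notes,
    }
    with open(out / "report.json", "w") as fh:
        json.dump({"provenance": provenance, "outputs": paths}, fh, indent=2, sort_keys=True)
    paths["report"] = str(out / "report.json")

    return AnalysisReport(
        paths=paths,
        provenance=provenance,
        alpha=alpha,
        permanova_table=perm_table,
        dysbiosis=report,
        diffabund=diff_tables,
        growth_fits=fits,
        warnings=notes,
    )
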