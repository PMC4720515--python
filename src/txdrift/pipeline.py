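"""End-to-end drift runs: configuration, provenance, and reproduction recipes.

A run is declared by a :class:`RunConfig` (loadable from YAML), executed by
:func:`run_drift_pipeline`, and leaves behind a self-describing output
bundle: the td matrix, drift-variance tables, variance-comparison p-values,
an attenuation report when two arms are present, MDS coordinates, and a
provenance record (effective config, seeds, versions, and per-stage gene and
sample accounting).  Re-running from the stored config with the same inputs
reproduces every output bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .drift import (
    DriftMatrix,
    build_young_reference,
    compute_drift,
    drift_plot_table,
    drift_variance,
    leading_logfc_mds,
)
from .io import (
    DataError,
    ExpressionMatrix,
    cpm_normalize,
    read_annotations,
    read_counts,
    read_gene_sets,
)
from .stats import classify_attenuation, robust_levene


@dataclass
class RunConfig:
    """Declarative description of one drift-analysis run."""

    counts_path: str
    annotations_path: str
    out_dir: str
    ref_age: float = 1.0
    ref_age_is_max: bool = False
    ref_method: str = "pooled_mean"
    holdout_ids: list[str] = field(default_factory=list)
    log_base: float = 2.0
    pseudocount: float = 0.5
    group_by: list[str] = field(default_factory=lambda: ["age", "treatment"])
    gene_sets_path: str | None = None
    set_names: list[str] = field(default_factory=list)
    trim_fraction: float = 0.10
    control_label: str | None = None
    treated_label: str | None = None
    attenuation_rule: str = "mean_abs_td"
    mds_top_n: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _subset_drift(d: DriftMatrix, sample_ids: Sequence[str]) -> DriftMatrix:
    idx = [d.sample_ids.index(s) for s in sample_ids]
    return DriftMatrix(
        gene_ids=list(d.gene_ids),
        sample_ids=list(sample_ids),
        td=d.td[:, idx],
        log_base=d.log_base,
        reference=d.reference,
        pseudocount=d.pseudocount,
    )


def _group_label(ann, group_by: Sequence[str]) -> str:
    return "|".join(str(getattr(ann, g)) for g in group_by)


def run_drift_pipeline(cfg: RunConfig) -> dict:
    """Execute a full drift run and write the output bundle under ``out_dir``.

    Returns the provenance record (also written to ``provenance.json``).
    Every filter is accounted for: genes in = genes used + genes dropped,
    samples in = samples used + samples excluded as reference holdouts.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events: list[dict] = []

    def log(stage: str, **counts) -> None:
        events.append({"stage": stage, **counts})

    counts = read_counts(cfg.counts_path)
    anns = read_annotations(cfg.annotations_path)
    log("read", n_genes=len(counts.gene_ids), n_samples=len(counts.sample_ids))

    cpm = cpm_normalize(counts)
    ref = build_young_reference(
        cpm, anns, cfg.ref_age, cfg.ref_method,  # type: ignore[arg-type]
        holdout_ids=cfg.holdout_ids or None, ref_age_is_max=cfg.ref_age_is_max,
    )
    d = compute_drift(cpm, ref, log_base=cfg.log_base, pseudocount=cfg.pseudocount)
    log(
        "drift",
        n_genes_in=len(cpm.gene_ids),
        n_genes_used=len(d.gene_ids),
        n_genes_dropped=len(cpm.gene_ids) - len(d.gene_ids),
        n_samples_used=len(d.sample_ids),
        n_samples_excluded=len(cpm.sample_ids) - len(d.sample_ids),
        self_referential_samples=d.self_referential_sample_ids,
    )
    d.to_frame().to_csv(out / "td.tsv", sep="\t")

    by_id = {a.sample_id: a for a in anns}
    groups = {s: _group_label(by_id[s], cfg.group_by) for s in d.sample_ids}
    gene_sets = []
    if cfg.gene_sets_path:
        gene_sets = read_gene_sets(cfg.gene_sets_path)
        if cfg.set_names:
            gene_sets = [g for g in gene_sets if g.name in set(cfg.set_names)]

    dv_results = drift_variance(d, groups)
    drift_plot_table(dv_results).to_csv(out / "drift_variance.tsv", sep="\t", index=False)
    for gs in gene_sets:
        tbl = drift_plot_table(drift_variance(d, groups, gene_set=gs))
        tbl.insert(0, "gene_set", gs.name)
        tbl.to_csv(out / f"drift_variance.{gs.name}.tsv", sep="\t", index=False)
    log("variance", n_groups=len(dv_results), n_gene_sets=len(gene_sets))

    # pairwise dispersion comparisons between testable (non-circular) groups
    frame = d.to_frame()
    testable = [r for r in dv_results if not r.self_referential]
    rows = []
    for ra, rb in combinations(testable, 2):
        va = frame[ra.sample_ids].to_numpy().ravel()
        vb = frame[rb.sample_ids].to_numpy().ravel()
        res = robust_levene([va, vb], trim_fraction=cfg.trim_fraction)
        rows.append(
            {"group_a": ra.group_label, "group_b": rb.group_label,
             "W": res.W, "p_value": res.p_value}
        )
    pd.DataFrame(rows).to_csv(out / "levene.tsv", sep="\t", index=False)
    log(
        "levene",
        n_comparisons=len(rows),
        n_groups_excluded_circular=len(dv_results) - len(testable),
    )

    report: dict | None = None
    if cfg.control_label and cfg.treated_label:
        ctrl_ids = [s for s in d.sample_ids if by_id[s].treatment == cfg.control_label]
        trt_ids = [s for s in d.sample_ids if by_id[s].treatment == cfg.treated_label]
        if ctrl_ids and trt_ids:
            res = classify_attenuation(
                _subset_drift(d, ctrl_ids),
                _subset_drift(d, trt_ids),
                {s: by_id[s].age for s in ctrl_ids},
                {s: by_id[s].age for s in trt_ids},
                rule=cfg.attenuation_rule,  # type: ignore[arg-type]
            )
            report = {
                "k_attenuated": res.k_attenuated,
                "n_total": res.n_total,
                "binomial_p": res.binomial_p,
                "rule": res.rule,
                "ages": res.ages_aggregated,
            }
            (out / "attenuation.json").write_text(json.dumps(report, indent=2))
            pd.DataFrame(
                {"gene": list(res.per_gene_calls), "attenuated": list(res.per_gene_calls.values())}
            ).to_csv(out / "attenuation_calls.tsv", sep="\t", index=False)
            log("attenuation", **{k: v for k, v in report.items() if k != "rule"})

    coords, _dist = leading_logfc_mds(cpm, top_n=min(cfg.mds_top_n, len(cpm.gene_ids)))
    coords.to_csv(out / "mds.tsv", sep="\t")
    log("mds", n_samples=len(coords))

    cfg_dict = cfg.to_dict()
    provenance = {
        "package": "txdrift",
        "version": __version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "events": events,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    with (out / "events.jsonl").open("w") as fh:
        for e in events:
            fh.write(json.dumps(e) + "\n")
    return provenance


# ---------------------------------------------------------------------------
# reproduction recipes for the published external data sets
# ---------------------------------------------------------------------------

RECIPES: dict[str, dict] = {
    "worm_timecourse": {
        "description": "Whole-transcriptome drift of water- vs drug-treated "
        "C. elegans over adult days 1-10; young reference = pooled day-1 mean.",
        "requires": {
            "counts.tsv": "RNA-seq gene expression count table (supplementary source data)",
            "annotations.tsv": "sample ages (days), treatment and replicate",
        },
        "config": {"ref_age": 1.0, "ref_method": "pooled_mean",
                   "group_by": ["age", "treatment"],
                   "control_label": "water", "treated_label": "mianserin"},
    },
    "worm_dose_response": {
        "description": "Day-5 drift as a function of drug concentration.",
        "requires": {
            "counts.tsv": "RNA-seq count table of the dose-response cohort",
            "annotations.tsv": "sample dose annotations (uM) at day 5",
        },
        "config": {"ref_age": 1.0, "ref_method": "pooled_mean", "group_by": ["dose"]},
    },
    "worm_delayed_treatment": {
        "description": "Day-10 drift when treatment starts on day 1, 3 or 5.",
        "requires": {
            "counts.tsv": "RNA-seq count table of the delayed-treatment cohort",
            "annotations.tsv": "treatment-start-day annotations",
        },
        "config": {"ref_age": 1.0, "ref_method": "pooled_mean", "group_by": ["treatment"]},
    },
    "worm_microarray_timecourse": {
        "description": "Two-channel microarray aging time course (ages in "
        "hours, binned to days 0/1/2/4/6); expression = ch1netmean / "
        "ch2normalizednetmean per gene before drift.",
        "requires": {
            "ch1netmean.tsv": "channel-1 net mean intensities, genes x samples",
            "ch2normalizednetmean.tsv": "normalized channel-2 net means, genes x samples",
            "annotations.tsv": "sample ages in hours",
        },
        "config": {"ref_age": 8.0, "ref_method": "pooled_mean", "group_by": ["age"]},
        "age_bin_edges_hours": [0, 20, 36, 72, 120, 168],
    },
    "mouse_tissues": {
        "description": "Mouse tissue aging panel pooled into 30/60/100-week "
        "age bins (two sampled ages per bin); one young transcriptome held "
        "out as the reference.",
        "requires": {
            "counts.tsv": "per-tissue expression table, genes x samples",
            "annotations.tsv": "ages in weeks and tissue labels",
        },
        "config": {"ref_age": 13.0, "ref_method": "holdout", "group_by": ["age"]},
        "age_bin_edges_weeks": [0, 30, 60],
    },
    "human_brain": {
        "description": "Human frontal-cortex aging series in 20-year bins; "
        "samples under 30 years held out as the pooled young reference and "
        "excluded from the plots.",
        "requires": {
            "counts.tsv": "expression table, genes x samples",
            "annotations.tsv": "donor ages in years",
        },
        "config": {"ref_method": "holdout", "group_by": ["age"]},
        "age_bin_edges_years": [20, 40, 60, 80, 100],
    },
}


def reproduce_recipe(which: str, data_dir: str | Path, out_dir: str | Path) -> dict:
    """Run one reproduction recipe against externally supplied data.

    The published data sets are not bundled; the recipe fails with a list of
    the files it needs (and what each is) when ``data_dir`` lacks them.
    """
    if which not in RECIPES:
        raise DataError(f"unknown recipe {which!r}; available: {sorted(RECIPES)}")
    recipe = RECIPES[which]
    data_dir = Path(data_dir)
    missing = {f: d for f, d in recipe["requires"].items() if not (data_dir / f).exists()}
    if missing:
        lines = "\n".join(f"  {f}: {d}" for f, d in missing.items())
        raise DataError(
            f"recipe {which!r} needs files missing from {data_dir}:\n{lines}\n"
            "Download the named source data and place them there."
        )
    counts_path = data_dir / "counts.tsv"
    if which == "worm_microarray_timecourse":
        ch1 = read_counts(data_dir / "ch1netmean.tsv")
        ch2 = read_counts(data_dir / "ch2normalizednetmean.tsv")
        if ch1.gene_ids != ch2.gene_ids or ch1.sample_ids != ch2.sample_ids:
            raise DataError("channel matrices must share genes and samples")
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = ch1.values / ch2.values
        if not np.isfinite(ratio).all():
            raise DataError("zero channel-2 intensity produces undefined ratios")
        counts_path = Path(out_dir) / "expression_ratio.tsv"
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        ExpressionMatrix(ch1.gene_ids, ch1.sample_ids, ratio).to_frame().to_csv(
            counts_path, sep="\t"
        )
    cfg = RunConfig(
        counts_path=str(counts_path),
        annotations_path=str(data_dir / "annotations.tsv"),
        out_dir=str(out_dir),
        **recipe["config"],
    )
    if which == "human_brain":
        # young reference = pooled mean of every donor under 30, held out
        anns = read_annotations(cfg.annotations_path)
        cfg.holdout_ids = [a.sample_id for a in anns if a.age < 30]
        cfg.ref_age = 30.0
        cfg.ref_age_is_max = True
    return run_drift_pipeline(cfg)
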