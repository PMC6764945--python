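"""Configuration-driven orchestration of the analysis stages.

A run is described by a flat configuration (key = ``stage.parameter``);
unknown keys are rejected and the fully resolved configuration, along
with its hash, is echoed into the run report so identical inputs yield
identical reports (timestamps excluded from the hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import pandas as pd

from . import __version__, arm_stats, duplex, io, isomir, pulldown, synthetic


class ConfigurationError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A stage failed at run time (CLI exit code 3)."""


#: Flat configuration keys with their defaults. Thresholds default to the
#: standard analysis values: FPKM > 0.1 expression filter, ER > 1.2
#: candidates, |log2FC| > 1 with FDR < 0.001 for the DE flag, >= 14-nt
#: reads with <= 2 mismatches and <= 100 hits, pseudo-count 1 for log2FC.
DEFAULTS: Dict[str, object] = {
    "run.seed": 0,
    "run.stages": "simulate,trends,pulldown,duplex,isomir,survival",
    "simulate.n_patients": 50,
    "simulate.n_arm_pairs": 200,
    "simulate.n_genes": 2000,
    "simulate.n_enriched": 80,
    "simulate.n_reads": 4000,
    "trends.alpha": 0.05,
    "trends.min_fold": 2.0,
    "pulldown.min_fpkm": 0.1,
    "pulldown.er_cutoff": 1.2,
    "pulldown.log2fc_cutoff": 1.0,
    "pulldown.fdr_cutoff": 0.001,
    "pulldown.pseudocount": 0.01,
    "pulldown.log2fc_pseudocount": 1.0,
    "duplex.n_sponge_sites": 6,
    "duplex.spacer_len": 4,
    "isomir.min_len": 14,
    "isomir.max_mm": 2,
    "isomir.max_hits": 100,
    "isomir.entropy_cutoff": 0.5,
    "survival.hazard_beta": 1.0,
    "survival.censor_rate": 0.2,
}

_VALIDATORS = {
    "pulldown.er_cutoff": lambda v: v > 0,
    "pulldown.min_fpkm": lambda v: v >= 0,
    "pulldown.fdr_cutoff": lambda v: 0 < v <= 1,
    "trends.alpha": lambda v: 0 < v < 1,
    "isomir.min_len": lambda v: v >= 1,
    "isomir.max_mm": lambda v: v >= 0,
    "isomir.max_hits": lambda v: v >= 1,
}


def resolve_config(overrides: Optional[Mapping[str, object]] = None) -> Dict[str, object]:
    """Merge overrides into the defaults, rejecting unknown keys and
    out-of-range values."""
    cfg = dict(DEFAULTS)
    for key, value in (overrides or {}).items():
        if key not in cfg:
            raise ConfigurationError(f"unknown configuration key {key!r}")
        cfg[key] = type(cfg[key])(value) if not isinstance(cfg[key], str) else str(value)
    for key, ok in _VALIDATORS.items():
        if not ok(cfg[key]):
            raise ConfigurationError(f"configuration value out of range: {key} = {cfg[key]!r}")
    return cfg


def config_hash(cfg: Mapping[str, object]) -> str:
    blob = json.dumps({k: cfg[k] for k in sorted(cfg)}, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config_file(path) -> Dict[str, object]:
    """Read a flat YAML mapping of ``stage.parameter: value``."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration file must be a flat mapping")
    return resolve_config(raw)


def run(cfg: Mapping[str, object], outdir) -> Dict[str, object]:
    """Execute the selected stages in dependency order and write a report.

    Returns the report dict; all tables are also written as TSVs under
    ``outdir``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s.strip() for s in str(cfg["run.stages"]).split(",") if s.strip()]
    known = {"simulate", "trends", "pulldown", "duplex", "isomir", "survival"}
    unknown = set(stages) - known
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")

    config = synthetic.SimConfig(
        seed=int(cfg["run.seed"]),
        n_patients=int(cfg["simulate.n_patients"]),
        n_arm_pairs=int(cfg["simulate.n_arm_pairs"]),
        n_genes=int(cfg["simulate.n_genes"]),
        n_enriched=int(cfg["simulate.n_enriched"]),
        n_reads=int(cfg["simulate.n_reads"]),
        hazard_beta=float(cfg["survival.hazard_beta"]),
        censor_rate=float(cfg["survival.censor_rate"]),
    )
    report: Dict[str, object] = {
        "version": __version__,
        "config": dict(cfg),
        "config_hash": config_hash(cfg),
        "stages": {},
    }
    outputs: List[str] = []
    t0 = time.time()
    try:
        artifacts: Dict[str, object] = {}
        if "simulate" in stages:
            artifacts["cohort"], artifacts["cohort_truth"] = synthetic.gen_cohort(config)
            artifacts["pulldown"], artifacts["pd_truth"] = synthetic.gen_pulldown(config)
            mats, precs, txs, ref_truth = synthetic.gen_references(config)
            artifacts.update(matures=mats, precursors=precs, transcripts=txs, ref_truth=ref_truth)
            artifacts["reads"], artifacts["read_truth"] = synthetic.gen_small_rna_reads(
                config, precs, mats
            )
            io.write_tsv(artifacts["cohort"], out / "cohort.tsv")
            io.write_tsv(artifacts["pulldown"], out / "pulldown.tsv", index=True)
            io.write_fasta(mats, out / "mature.fa")
            io.write_fasta(dict(zip(precs["mirna_id"], precs["sequence"])), out / "hairpin.fa")
            io.write_tsv(precs[["mirna_id", "precursor_id", "mature_start"]], out / "hairpin_offsets.tsv")
            io.write_fasta(txs, out / "transcripts.fa")
            io.write_fastq(artifacts["reads"], out / "reads.fq")
            truth_df = pd.DataFrame(
                sorted(artifacts["cohort_truth"].trend_labels.items()),
                columns=["pair_id", "trend_label"],
            )
            io.write_tsv(truth_df, out / "cohort_truth.tsv")
            io.write_tsv(ref_truth.site_classes, out / "site_truth.tsv")
            outputs += [
                "cohort.tsv", "pulldown.tsv", "mature.fa", "hairpin.fa",
                "hairpin_offsets.tsv", "transcripts.fa", "reads.fq",
                "cohort_truth.tsv", "site_truth.tsv",
            ]
            report["stages"]["simulate"] = {
                "n_arm_pairs": config.n_arm_pairs,
                "n_genes": config.n_genes,
                "n_reads": config.n_reads,
            }

        if "trends" in stages:
            rule = arm_stats.DeRule(
                alpha=float(cfg["trends.alpha"]), min_fold=float(cfg["trends.min_fold"])
            )
            trends = arm_stats.classify_cohort_trends(artifacts["cohort"], rule)
            summary = arm_stats.arm_trend_summary(trends["trend"])
            io.write_tsv(trends, out / "arm_trends.tsv")
            io.write_tsv(summary.reset_index(), out / "arm_trend_summary.tsv")
            outputs += ["arm_trends.tsv", "arm_trend_summary.tsv"]
            report["stages"]["trends"] = {
                "n_pairs_in": int(len(trends)),
                "proportions": summary["proportion"].to_dict(),
            }

        if "pulldown" in stages:
            table = pulldown.filter_expressed(
                artifacts["pulldown"], float(cfg["pulldown.min_fpkm"])
            )
            er = pulldown.enrichment_ratio(
                table,
                pseudocount=float(cfg["pulldown.pseudocount"]),
                er_cutoff=float(cfg["pulldown.er_cutoff"]),
            )
            lfc = pulldown.log2fc_table(
                table["oe"], table["oe_ctrl"], float(cfg["pulldown.log2fc_pseudocount"])
            )
            records = er.join(lfc)
            records = pulldown.define_potential_targets(records)
            targets = records[records["potential_target"]]
            cmp = pulldown.cdf_shift_test(
                targets["log2fc"], records["log2fc"]
            ) if len(targets) >= 5 else None
            io.write_tsv(records.reset_index(), out / "enrichment.tsv")
            outputs += ["enrichment.tsv"]
            report["stages"]["pulldown"] = {
                "n_genes_in": int(len(artifacts["pulldown"])),
                "n_expressed": int(len(table)),
                "n_candidates": int(records["candidate"].sum()),
                "n_potential_targets": int(len(targets)),
                "ks_p": cmp.p_value if cmp else None,
            }
            artifacts["records"] = records

        if "duplex" in stages:
            frames = []
            for mid, mseq in artifacts["matures"].items():
                design = duplex.design_sponge(
                    mseq,
                    mirna_id=mid,
                    n_sites=int(cfg["duplex.n_sponge_sites"]),
                    spacer_len=int(cfg["duplex.spacer_len"]),
                )
                io.write_fasta({f"{mid}_sponge": design.construct}, out / f"sponge_{mid}.fa")
                outputs.append(f"sponge_{mid}.fa")
            sites = duplex.scan_transcripts(artifacts["matures"], artifacts["transcripts"])
            io.write_tsv(sites, out / "sites.tsv")
            outputs.append("sites.tsv")
            report["stages"]["duplex"] = {
                "n_sites": int(len(sites)),
                "labels": sites["label"].value_counts().to_dict() if len(sites) else {},
            }

        if "isomir" in stages:
            refs = isomir.references_from_tables(artifacts["matures"], artifacts["precursors"])
            kept, fstats = isomir.filter_reads(
                artifacts["reads"],
                min_len=int(cfg["isomir.min_len"]),
                entropy_cutoff=float(cfg["isomir.entropy_cutoff"]),
            )
            calls = isomir.assign_reads(
                kept, refs, max_mm=int(cfg["isomir.max_mm"]), max_hits=int(cfg["isomir.max_hits"])
            )
            profile = isomir.build_profile(calls)
            io.write_tsv(profile.counts.reset_index(), out / "isomir_counts.tsv")
            io.write_tsv(profile.proportions.reset_index(), out / "isomir_proportions.tsv")
            outputs += ["isomir_counts.tsv", "isomir_proportions.tsv"]
            report["stages"]["isomir"] = {
                "n_reads_in": int(fstats["n_in"]),
                "n_reads_kept": int(fstats["n_out"]),
                "n_assigned": int(round(sum(c.weight for c in calls))),
                "mean_proportions": profile.proportions.mean(axis=0).to_dict(),
            }

        if "survival" in stages:
            rng = config.rng()
            patients = [f"P{i:03d}" for i in range(config.n_patients)]
            scores = dict(zip(patients, rng.normal(0.0, 1.0, config.n_patients)))
            surv, _ = synthetic.gen_survival(config, scores, rng=rng)
            groups = arm_stats.median_split_groups(scores)
            surv["group"] = surv["patient_id"].map(groups)
            curves, stat, p = arm_stats.km_logrank(surv)
            io.write_tsv(surv, out / "survival.tsv")
            outputs.append("survival.tsv")
            report["stages"]["survival"] = {
                "n_patients": int(len(surv)),
                "logrank_statistic": stat,
                "logrank_p": p,
            }
    except (ConfigurationError,):
        raise
    except Exception as exc:  # typed stage context for the CLI
        raise StageError(f"stage execution failed: {exc}") from exc

    report["elapsed_s"] = round(time.time() - t0, 3)
    write_report(report, out)
    io.write_manifest(out / "manifest.json", cfg, outputs + ["report.json"])
    return report


def report_hash(report: Mapping[str, object]) -> str:
    """Hash of a report with volatile fields (timings) excluded."""
    stable = {k: v for k, v in report.items() if k not in ("elapsed_s",)}
    return hashlib.sha256(json.dumps(stable, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_report(report: Mapping[str, object], outdir, formats=("json",)) -> None:
    """Write the run report; JSON always, optional TSV/markdown summaries."""
    out = Path(outdir)
    payload = dict(report)
    payload["report_hash"] = report_hash(report)
    (out / "report.json").write_text(json.dumps(payload, indent=2, default=str) + "\n")
    if "tsv" in formats:
        rows = [
            {"stage": stage, **{k: v for k, v in summary.items() if not isinstance(v, dict)}}
            for stage, summary in report["stages"].items()
        ]
        io.write_tsv(pd.DataFrame(rows), out / "report.tsv")
    if "markdown" in formats:
        lines = ["# Run report", "", f"config hash: `{report['config_hash']}`", ""]
        for key, value in sorted(report["config"].items()):
            lines.append(f"- {key} = {value}")
        lines.append("")
        for stage, summary in report["stages"].items():
            lines.append(f"## {stage}")
            for k, v in summary.items():
                lines.append(f"- {k}: {v}")
            lines.append("")
        (out / "report.md").write_text("\n".join(lines))
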