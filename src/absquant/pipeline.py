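"""End-to-end workflow: calibrate -> quantify totals -> integrate -> report.

`run_pipeline` wires the modules together for the common study layout:
a count table, qPCR run + standards CSVs, and optionally a copy-number
table and spike metadata.  Every numeric output lands on disk in plain
text, together with a machine-readable JSON run log recording inputs,
parameters and the seed, so a rerun with the same config is reproducible
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import core, qpcr, tables, validation
from . import __version__

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised with the failing stage's name in the message."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    table: str
    standards: str
    runs: str
    region: str = "V4"
    total_assay: str = "16S_V4"
    copy_table: str | None = None
    spike: str | None = None  # CSV: treatment, nominal_cfu_per_g
    marker_assay: str | None = None
    copy_ratio: float = 7.0
    soil_mass: float = 0.21  # g per extraction
    elution_volume: float = 100.0  # uL
    template_volume: float = 1.0  # uL
    minor_threshold: float = 0.001
    sd_limit: float = 0.5
    eps: float = 0.0
    alpha: float = 0.05
    out_dir: str = "absquant_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return run

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute the workflow; returns a summary dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
    }

    # --- calibrate ---------------------------------------------------------
    @_stage("calibrate")
    def calibrate():
        series = qpcr.read_standards_csv(config.standards)
        curves = {assay: qpcr.fit_standard_curve(s) for assay, s in series.items()}
        for assay, curve in curves.items():
            curve.to_json(out / f"curve_{assay}.json")
        return curves

    curves = calibrate()
    if config.total_assay not in curves:
        raise PipelineError(
            "calibrate", f"no standards for total assay {config.total_assay!r}"
        )

    # --- quantify totals ---------------------------------------------------
    @_stage("quantify")
    def quantify():
        ct_sets = qpcr.read_runs_csv(config.runs)
        per_gram: dict[tuple[str, str], qpcr.CopyQuant] = {}
        for cts in ct_sets:
            if cts.assay not in curves:
                raise PipelineError("quantify", f"no curve for assay {cts.assay!r}")
            quant = qpcr.qc_quantify(cts, curves[cts.assay], sd_limit=config.sd_limit)
            per_gram[(cts.sample, cts.assay)] = qpcr.scale_quant(
                quant,
                elution_volume=config.elution_volume,
                soil_mass=config.soil_mass,
                template_volume=config.template_volume,
            )
        return per_gram

    quants = quantify()
    totals = [
        core.TotalQuant(sample=s, region=config.region, total_copies=q.copies_per_g)
        for (s, assay), q in quants.items()
        if assay == config.total_assay
    ]
    summary["qc_flags"] = {
        f"{s}/{assay}": sorted(q.flags) for (s, assay), q in quants.items() if q.flags
    }

    # --- integrate ---------------------------------------------------------
    @_stage("integrate")
    def do_integrate():
        table = tables.read_feature_table(config.table)
        rel = tables.to_relative(table)
        abs_table = core.integrate(rel, totals, region=config.region)
        if config.copy_table:
            cn = core.CopyNumberTable.from_tsv(config.copy_table)
            genome_table = core.to_genome_equivalents(abs_table, cn)
            genome_table.to_tsv(out / "genome_equivalents.tsv")
        abs_table.to_tsv(out / "absolute_abundance.tsv")
        return rel, abs_table

    rel, abs_table = do_integrate()
    summary["samples"] = list(abs_table.samples)
    summary["totals"] = {
        t.sample: t.total_copies for t in totals if t.region == config.region
    }

    # --- validate (optional) ----------------------------------------------
    if config.spike and config.marker_assay:

        @_stage("validate")
        def validate():
            import pandas as pd

            spike_df = pd.read_csv(config.spike)
            treatments = tuple(
                (str(r["treatment"]), float(r["nominal_cfu_per_g"]))
                for _, r in spike_df.iterrows()
            )
            marker = {
                t: quants[(t, config.marker_assay)].copies_per_g
                for t, _ in treatments
            }
            spike_name = spike_df["taxon"].iloc[0] if "taxon" in spike_df else None
            estimates = {}
            for t, _ in treatments:
                estimates[t] = abs_table.abundance_of(t, spike_name)
            exp = validation.SpikeExperiment(
                treatments=treatments,
                marker_quant=marker,
                ihaaq_estimates={config.region: estimates},
                copy_ratio=config.copy_ratio,
            )
            report = validation.validate_spikein(exp)
            doc = {
                "passed": report.passed,
                "calibration": dataclasses.asdict(report.calibration),
                "agreement": {
                    region: {k: dataclasses.asdict(v) for k, v in fits.items()}
                    for region, fits in report.agreement.items()
                },
            }
            (out / "validation.json").write_text(json.dumps(doc, indent=1))
            return report

        report = validate()
        summary["validation_passed"] = report.passed
        summary["calibration_slope"] = report.calibration.slope
        summary["calibration_r2"] = report.calibration.r2_centered

    # --- summarise ---------------------------------------------------------
    pooled = tables.pool_minor(rel, threshold=config.minor_threshold)
    with open(out / "relative_abundance.tsv", "w", encoding="utf-8") as fh:
        fh.write("#Taxon\t" + "\t".join(pooled.samples) + "\n")
        for j, taxon in enumerate(pooled.taxa):
            row = "\t".join(f"{v:.6g}" for v in pooled.proportions[:, j])
            fh.write(f"{taxon.to_string()}\t{row}\n")

    (out / "run_log.json").write_text(json.dumps(summary, indent=1, default=str))
    logger.info("pipeline complete; outputs in %s", out)
    return summary
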