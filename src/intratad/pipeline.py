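"""End-to-end orchestration with config validation and run manifests.

A single config drives all stages (calibrate -> annotate -> call-tads per
condition -> match-loops -> compare-conditions). Every run directory gets
one manifest recording the config snapshot, input checksums, seeds and
package version; deterministic stages rerun byte-identically from an
identical manifest, and completed stages are skipped on rerun when their
recorded input checksums still match.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .caller import CallerParams, call_tads
from .calibration import SpikeSample, downsample_reads, spike_scale_factors
from .io import (
    read_fimo_tsv,
    read_loops_bedpe,
    read_narrowpeak,
    write_tads_bedpe,
)
from .matching import MatchParams, compare_conditions, match_summary, match_tads

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "load_config", "run_pipeline", "write_manifest"]


class ConfigError(ValueError):
    """The run configuration violates the schema."""


_REQUIRED_INPUTS = ("cohesin_control", "cohesin_patient", "ctcf", "motifs")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def validate_config(cfg: dict) -> None:
    inputs = cfg.get("inputs")
    if not isinstance(inputs, dict):
        raise ConfigError("config missing 'inputs' section")
    for key in _REQUIRED_INPUTS:
        if key not in inputs:
            raise ConfigError(f"config inputs missing required field '{key}'")
        if not Path(inputs[key]).exists():
            raise ConfigError(f"input file for '{key}' not found: {inputs[key]}")
    for key in ("hic_loops", "sample_sheet"):
        if key in inputs and not Path(inputs[key]).exists():
            raise ConfigError(f"input file for '{key}' not found: {inputs[key]}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def caller_params_from_config(cfg: dict) -> CallerParams:
    p = cfg.get("caller", {})
    return CallerParams(
        min_proportion=p.get("min_proportion", 0.40),
        max_span=p.get("max_span", 3_000_000),
        redundancy_overlap=p.get("redundancy_overlap", 0.98),
        motif_pvalue_max=p.get("motif_pvalue_max", 1e-4),
        pairing_rule=p.get("pairing_rule", "balance"),
    )


def match_params_from_config(cfg: dict) -> MatchParams:
    p = cfg.get("matching", {})
    return MatchParams(
        complete_threshold=p.get("complete_threshold", 0.95),
        unchanged_threshold=p.get("unchanged_threshold", 0.75),
        fraction_statistic=p.get("fraction_statistic", "min"),
    )


def write_manifest(outdir: Path, cfg: dict, seed: int, input_paths: dict) -> None:
    manifest = {
        "tool": "intratad",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "config": cfg,
        "input_checksums": {k: _sha256(v) for k, v in input_paths.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _stage_done(outdir: Path, stage: str, checksums: dict) -> bool:
    marker = outdir / f".{stage}.done.json"
    if not marker.exists():
        return False
    try:
        recorded = json.loads(marker.read_text())
    except json.JSONDecodeError:
        return False
    return recorded.get("input_checksums") == checksums


def _mark_stage(outdir: Path, stage: str, checksums: dict) -> None:
    marker = outdir / f".{stage}.done.json"
    marker.write_text(json.dumps({"stage": stage, "input_checksums": checksums}))


def run_pipeline(cfg: dict, outdir, seed: int = 0) -> dict:
    """Run all configured stages; returns the collected summary report.

    Raises :class:`ConfigError` before any computation when the config is
    invalid; on a stage failure, previously written stage outputs remain.
    """
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = cfg["inputs"]
    input_paths = {k: v for k, v in inputs.items() if isinstance(v, str)}
    checksums = {k: _sha256(v) for k, v in input_paths.items() if Path(v).exists()}
    write_manifest(outdir, cfg, seed, input_paths)

    cparams = caller_params_from_config(cfg)
    mparams = match_params_from_config(cfg)
    logger.info(
        "thresholds: min_proportion=%g redundancy=%g complete=%g unchanged=%g",
        cparams.min_proportion,
        cparams.redundancy_overlap,
        mparams.complete_threshold,
        mparams.unchanged_threshold,
    )
    report: dict = {"seed": seed, "version": __version__}

    # ---- calibrate (optional) -------------------------------------------
    if "sample_sheet" in inputs:
        import csv

        factors_path = outdir / "spike_factors.tsv"
        if not _stage_done(outdir, "calibrate", checksums):
            samples = []
            with open(inputs["sample_sheet"]) as fh:
                for row in csv.DictReader(fh, delimiter="\t"):
                    samples.append(
                        SpikeSample(
                            sample_id=row["sample_id"],
                            host_reads=int(row["host_reads"]),
                            spike_reads=int(row["spike_reads"]),
                        )
                    )
            samples = spike_scale_factors(samples)
            with open(factors_path, "w") as fh:
                fh.write("sample_id\thost_reads\tspike_reads\tdownsample_factor\n")
                for s in samples:
                    fh.write(
                        f"{s.sample_id}\t{s.host_reads}\t{s.spike_reads}"
                        f"\t{s.downsample_factor:.6g}\n"
                    )
            _mark_stage(outdir, "calibrate", checksums)
        report["calibrate"] = str(factors_path)

    # ---- call TADs per condition ----------------------------------------
    ctcf = read_narrowpeak(inputs["ctcf"])
    motifs = read_fimo_tsv(inputs["motifs"])
    tads = {}
    for cond in ("control", "patient"):
        cohesin = read_narrowpeak(inputs[f"cohesin_{cond}"])
        called = call_tads(cohesin, ctcf, motifs, cparams)
        tads[cond] = called
        write_tads_bedpe(called, outdir / f"tads_{cond}.bedpe")
        report[f"n_tads_{cond}"] = len(called)
    _mark_stage(outdir, "call_tads", checksums)

    # ---- match against experimental loops (optional) ---------------------
    if "hic_loops" in inputs:
        hic = read_loops_bedpe(
            inputs["hic_loops"], dialect=cfg.get("hic_dialect", "bedpe")
        )
        results = match_tads(tads["control"], hic, mparams)
        summary = match_summary(results, over_threshold=mparams.unchanged_threshold)
        report["hic_match"] = summary
        with open(outdir / "hic_match.tsv", "w") as fh:
            fh.write("query_id\treference_id\tcategory\tsubtype\toverlap_fraction\n")
            for r in results:
                fh.write(
                    f"{r.query_id}\t{r.reference_id or '.'}\t{r.category}"
                    f"\t{r.subtype}\t{r.overlap_fraction:.4f}\n"
                )
        _mark_stage(outdir, "match_loops", checksums)

    # ---- compare conditions ----------------------------------------------
    comparison = compare_conditions(tads["patient"], tads["control"], mparams)
    report["comparison"] = {
        k: v
        for k, v in comparison.items()
        if k.startswith("fraction_") or k == "n"
    }
    with open(outdir / "comparison.tsv", "w") as fh:
        fh.write("tad_id\tlabel\n")
        for tid, label in comparison["labels"]:
            fh.write(f"{tid}\t{label}\n")
    _mark_stage(outdir, "compare_conditions", checksums)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
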