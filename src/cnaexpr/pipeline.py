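"""End-to-end driver: simulate or load inputs, run every stage, write outputs.

Stage order: amplification correction -> median centring -> (enzyme-set
combination) -> segmentation -> gene assignment -> status calls ->
class enrichment -> recurrent-peak detection -> expression calls & FPR ->
copy-number/expression integration.  A manifest (JSON) records the config
hash, input checksums, per-stage timings, warnings and all output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .copy_number import (
    CNThresholds,
    assign_gene_values,
    call_copy_status,
    center_median,
    combine_enzyme_sets,
    correct_amplification,
    deletion_frequency,
    gain_frequency,
    segment_cbs,
)
from .enrichment import ClassBackground, frequency_profile, per_sample_enrichment
from .expression import call_regulation_all, estimate_fpr, summarize_frequency
from .gistic import find_peaks, permutation_significance
from .integration import correlate_all, crosstab_calls, summarize_correlation
from .synthetic import (
    CouplingSpec,
    EventSpec,
    GenomeSpec,
    default_events,
    generate_annotation,
    generate_expression,
    generate_probe_ratios,
    true_gene_ratios,
)

log = logging.getLogger("cnaexpr")

__all__ = ["RunConfig", "run_pipeline", "simulate_inputs"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run; round-trips losslessly through YAML."""

    out_dir: str = "cnaexpr_run"
    # input paths; when simulate=True they are generated into out_dir first
    probe_table: str | None = None
    annotation: str | None = None
    expression: str | None = None
    groups: str | None = None
    simulate: bool = True
    # simulation scale
    n_tumours: int = 8
    n_genes: int = 200
    noise_sd: float = 0.15
    # segmentation
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 200
    cbs_min_width: int = 2
    # thresholds (log2 ratios)
    del_threshold: float = CNThresholds().del_threshold
    gain_threshold: float = CNThresholds().gain_threshold
    homdel_threshold: float = CNThresholds().homdel_threshold
    amp_threshold: float = CNThresholds().amp_threshold
    # expression calls
    fold: float = 2.0
    # enrichment
    enrichment_cutoffs: list = field(default_factory=lambda: list(range(2, 9)))
    # recurrent peaks
    gistic_n_perm: int = 200
    gistic_q: float = 0.25
    # integration
    correlation_cutoff: float = 0.65
    crosstab_k: int = 2
    seed: int = 0

    def thresholds(self) -> CNThresholds:
        return CNThresholds(
            del_threshold=self.del_threshold,
            gain_threshold=self.gain_threshold,
            homdel_threshold=self.homdel_threshold,
            amp_threshold=self.amp_threshold,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not (0 < self.cbs_alpha < 1):
            raise ValueError("cbs_alpha must be in (0, 1)")
        if self.cbs_n_perm < 100:
            raise ValueError("cbs_n_perm must be >= 100")
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        self.thresholds()  # raises if ordering violated
        if not self.simulate:
            for name in ("probe_table", "annotation", "expression", "groups"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"config input {name!r} missing: {p}")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def simulate_inputs(config: RunConfig, out: Path) -> dict:
    """Generate synthetic inputs (plus truth sidecars) into ``out``."""
    genome = GenomeSpec(n_genes=config.n_genes, seed=config.seed)
    ann = generate_annotation(genome)
    events = EventSpec(
        events=default_events(genome, config.n_tumours, seed=config.seed),
        noise_sd=config.noise_sd,
    )
    matrix, truth_seg, _ = generate_probe_ratios(genome, events, seed=config.seed)
    truth_cn = true_gene_ratios(ann, truth_seg)
    coupling = CouplingSpec(n_tumours=config.n_tumours, seed=config.seed)
    expr, truth_reg = generate_expression(ann, truth_cn, coupling)

    paths = {
        "annotation": out / "annotation.tsv",
        "probe_table": out / "probe_ratios.tsv",
        "expression": out / "expression.tsv",
        "groups": out / "groups.tsv",
    }
    pio.write_annotation(ann, paths["annotation"])
    pio.write_probe_table(matrix, paths["probe_table"])
    pio.write_expression(expr, paths["expression"], paths["groups"])
    pio.write_seg(truth_seg, out / "truth_segments.seg")
    truth_reg.to_csv(out / "truth_regulation.tsv", sep="\t")
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "cnaexpr 0.1.0",
        "config_hash": hashlib.sha256(
            yaml.safe_dump(dataclasses.asdict(config)).encode()
        ).hexdigest()[:16],
        "inputs": {},
        "stages": [],
        "outputs": [],
        "warnings": [],
    }

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"].append({"name": name, "t_start": time.time()})

    def done(*outputs):
        manifest["stages"][-1]["seconds"] = round(
            time.time() - manifest["stages"][-1].pop("t_start"), 3
        )
        for o in outputs:
            manifest["outputs"].append(
                {"file": str(o), "stage": manifest["stages"][-1]["name"]}
            )

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if config.simulate:
            stage("simulate")
            paths = simulate_inputs(config, out)
            done(*paths.values())
        else:
            paths = {
                "annotation": Path(config.annotation),
                "probe_table": Path(config.probe_table),
                "expression": Path(config.expression),
                "groups": Path(config.groups),
            }
        manifest["inputs"] = {k: _checksum(Path(v)) for k, v in paths.items()}

        stage("load")
        ann = pio.read_annotation(paths["annotation"])
        matrix = pio.read_probe_table(paths["probe_table"])
        expr = pio.read_expression(paths["expression"], paths["groups"])
        done()

        stage("correct_center")
        if matrix.control_samples:
            matrix = correct_amplification(matrix)
        matrix = center_median(matrix)
        done()

        stage("segment")
        seg = segment_cbs(
            matrix,
            alpha=config.cbs_alpha,
            n_perm=config.cbs_n_perm,
            min_width=config.cbs_min_width,
            seed=config.seed,
        )
        seg_path = out / "segments.seg"
        pio.write_seg(seg, seg_path)
        done(seg_path)

        stage("call_cn")
        genecn = call_copy_status(assign_gene_values(seg, ann), config.thresholds())
        cn_path = out / "gene_cn.tsv"
        pio.write_gene_table(genecn, cn_path)
        done(cn_path)

        stage("enrich")
        universe = genecn.status.index[genecn.status.notna().any(axis=1)]
        tsg = ann.index[ann["role"] == "TSG"]
        tpg = ann.index[ann["role"] == "TPG"]
        bg_tsg = ClassBackground(len(tsg.intersection(universe)), len(universe))
        profile = frequency_profile(
            deletion_frequency(genecn), tsg, bg_tsg, config.enrichment_cutoffs
        )
        per_sample, n_sig = per_sample_enrichment(genecn.status, tsg, bg_tsg, "loss")
        prof_path = out / "tsg_deletion_enrichment.tsv"
        ps_path = out / "per_sample_enrichment.tsv"
        profile.to_csv(prof_path, sep="\t", index=False)
        per_sample.to_csv(ps_path, sep="\t")
        done(prof_path, ps_path)

        stage("gistic")
        peak_paths = []
        peak_genes = {}
        for direction in ("del", "gain"):
            track = permutation_significance(
                genecn, ann, direction,
                n_perm=config.gistic_n_perm, seed=config.seed,
            )
            peaks = find_peaks(track, config.gistic_q, ann, direction)
            p = out / f"peaks_{direction}.tsv"
            peaks.to_csv(p, sep="\t", index=False)
            peak_paths.append(p)
            peak_genes[direction] = sorted(
                {g for row in peaks.get("genes", []) for g in row.split(",") if g}
            )
        done(*peak_paths)

        stage("call_expr")
        reg = call_regulation_all(expr, fold=config.fold)
        freq = summarize_frequency(reg)
        fpr_up, fpr_down = estimate_fpr(expr, fold=config.fold)
        reg_path = out / "regulation_calls.tsv"
        freq_path = out / "regulation_frequency.tsv"
        reg.to_csv(reg_path, sep="\t")
        freq.to_csv(freq_path, sep="\t")
        done(reg_path, freq_path)

        stage("integrate")
        records = correlate_all(genecn, expr.signals)
        summary = summarize_correlation(records, config.correlation_cutoff)
        xtab = crosstab_calls(genecn, freq, k=config.crosstab_k)
        corr_path = out / "correlation.tsv"
        xtab_path = out / "crosstab.tsv"
        records.to_csv(corr_path, sep="\t")
        xtab.to_csv(xtab_path, sep="\t")
        summary_path = out / "summary.json"
        summary_path.write_text(
            json.dumps(
                {
                    "n_samples_significant_tsg_loss": n_sig,
                    "fpr_up": fpr_up,
                    "fpr_down": fpr_down,
                    "correlation": summary,
                    "n_del_peak_genes": len(peak_genes["del"]),
                    "n_gain_peak_genes": len(peak_genes["gain"]),
                },
                indent=2,
            )
        )
        done(corr_path, xtab_path, summary_path)

        manifest["warnings"] = [str(w.message) for w in caught]

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
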