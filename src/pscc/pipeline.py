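"""End-to-end run configuration and orchestration.

``run_pipeline`` executes the counts-level pipeline — GC correction of
case and controls, panel construction, normalization, segmentation,
genotyping — and writes calls (BED + VCF), a segment table, a QC report
and a reproducibility manifest.  Inputs are per-window count TSVs (from
``pscc count`` or the simulator); consistency between counts and windows
is enforced through the windows checksum embedded in each file.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .calling import (
    ALPHA_PT,
    ALPHA_ST,
    MIN_CALL_SIZE_BP,
    call_cnvs,
    report_sample_quality,
)
from .correction import GC_BIN_WIDTH, build_panel, cv_profile, gc_correct, normalize
from .segmentation import BLOCK, MAX_FLANK, P_ENTER, segment_genome
from .windows import DEFAULT_EXPECTED_RC

log = logging.getLogger("pscc")


@dataclass
class RunConfig:
    """Validated parameters for one pipeline run.

    Unknown keys in a YAML config are rejected so typos do not silently
    fall back to defaults.
    """

    case_counts: str = ""
    control_counts: list[str] = field(default_factory=list)
    windows: str | None = None
    panel: str | None = None
    out_dir: str = "pscc_out"
    expected_rc: int = DEFAULT_EXPECTED_RC
    gc_bin: float = GC_BIN_WIDTH
    block: int = BLOCK
    p_enter: float = P_ENTER
    p_genome: float | None = None
    alpha_st: float = ALPHA_ST
    alpha_pt: float = ALPHA_PT
    min_size: int = MIN_CALL_SIZE_BP
    overlap_criterion: float = 0.5
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0 < self.gc_bin <= 0.1):
            raise ValueError("gc_bin must be in (0, 0.1]")
        if self.block < 5:
            raise ValueError("block must be >= 5")
        for name in ("p_enter", "alpha_st", "alpha_pt", "overlap_criterion"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.min_size < 0 or self.expected_rc < 1:
            raise ValueError("min_size and expected_rc must be non-negative")


def run_pipeline(config: RunConfig) -> dict:
    """counts -> gc_correct -> panel -> normalize -> segment -> call.

    Returns a summary dict with the output paths; raises on stage errors
    (the CLI converts these into a nonzero exit status with the stage
    name in the log).
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage=load")
    windows = (
        pio.read_windows_bed(config.windows)
        if config.windows
        else pio.counts_windows(config.case_counts)
    )
    case = pio.read_counts_tsv(config.case_counts, windows=windows)

    log.info("stage=gc_correct")
    case_corr = gc_correct(case, gc_bin_width=config.gc_bin)

    if config.panel:
        log.info("stage=panel (precomputed)")
        panel = pio.read_panel_tsv(config.panel, windows=windows)
    else:
        if len(config.control_counts) < 2:
            raise ValueError("need a panel file or >= 2 control count files")
        log.info("stage=panel (%d controls)", len(config.control_counts))
        controls = [
            gc_correct(pio.read_counts_tsv(p, windows=windows), gc_bin_width=config.gc_bin)
            for p in config.control_counts
        ]
        panel = build_panel(controls)
        pio.write_panel_tsv(panel, windows, out / "panel.tsv")

    log.info("stage=normalize")
    rcr = normalize(case_corr, panel)

    log.info("stage=segment")
    chroms = windows["chrom"].to_numpy()
    segments = segment_genome(
        rcr.values,
        rcr.usable,
        chroms,
        block=config.block,
        p_enter=config.p_enter,
        p_genome=config.p_genome,
    )
    pio.write_segments_tsv(segments, windows, out / "segments.tsv")

    log.info("stage=call")
    calls, results = call_cnvs(
        rcr,
        panel,
        windows,
        alpha_st=config.alpha_st,
        alpha_pt=config.alpha_pt,
        min_size=config.min_size,
        block=config.block,
        p_enter=config.p_enter,
        p_genome=config.p_genome,
    )
    params = {
        f.name: getattr(config, f.name)
        for f in dataclasses.fields(config)
        if f.name not in ("case_counts", "control_counts", "windows", "panel", "out_dir")
    }
    pio.write_calls_bed(calls, out / "calls.bed", params={"sample": case.sample})
    contigs = {
        str(c): int(sub["end"].max()) for c, sub in windows.groupby("chrom", sort=False)
    }
    pio.write_calls_vcf(calls, out / "calls.vcf", contigs=contigs)

    log.info("stage=qc")
    quality = report_sample_quality(results)
    cv_before = cv_profile(case.counts, case.gc, case.usable)
    cv_after = cv_profile(rcr.values, case.gc, rcr.usable)
    qc_path = out / "qc_report.tsv"
    with open(qc_path, "w") as fh:
        fh.write(f"#pscc qc sample={case.sample}\n")
        fh.write(
            f"#segments={quality['n_segments']} sample_quality={quality['n_sample_quality']} "
            f"flagged={quality['flagged']}\n"
        )
        fh.write("metric\tgc_low\tgc_high\tn\tcv\n")
        for row in cv_before.itertuples(index=False):
            fh.write(f"raw\t{row.gc_low:.2f}\t{row.gc_high:.2f}\t{row.n}\t{row.cv:.5g}\n")
        for row in cv_after.itertuples(index=False):
            fh.write(f"rcr\t{row.gc_low:.2f}\t{row.gc_high:.2f}\t{row.n}\t{row.cv:.5g}\n")

    inputs = {config.case_counts: pio.file_checksum(config.case_counts)}
    for p in config.control_counts:
        inputs[p] = pio.file_checksum(p)
    if config.panel:
        inputs[config.panel] = pio.file_checksum(config.panel)
    pio.write_manifest(out / "manifest.json", params, inputs, seed=config.seed)

    log.info("done: %d calls", len(calls))
    return {
        "calls": calls,
        "n_calls": len(calls),
        "quality": quality,
        "out_dir": str(out),
        "outputs": [
            str(out / n)
            for n in ("calls.bed", "calls.vcf", "segments.tsv", "qc_report.tsv", "manifest.json")
        ],
    }
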