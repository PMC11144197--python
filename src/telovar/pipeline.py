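"""Reproducible pipeline orchestration, configuration, and report I/O.

A :class:`PipelineConfig` gathers every threshold and simulation parameter,
round-trips losslessly through YAML/JSON, and drives :func:`run_pipeline`,
which executes the requested stages in dependency order and writes TSV
reports (with JSON mirrors), a log of per-stage read counts and rejection
tallies, and a provenance block (config hash, seed, package version).

All randomness in a pipeline run flows from the single configured seed:
the telomere array, the WGS read simulator, and the terminal-read
simulator use ``seed``, ``seed + 1`` and ``seed + 2`` respectively, so a
recorded config plus seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence

import yaml

from . import __version__
from .composition import CompositionSummary, DetectionConfig, RunLengthTable, compose, run_lengths
from .processivity import ProcessivityResult, estimate_from_table
from .records import PathLike, read_fastq, write_fastq
from .simulate import (
    ModelParams,
    ReadSimParams,
    TerminalSimParams,
    simulate_telomere_array,
    simulate_terminal_reads,
    simulate_wgs_reads,
)
from .terminal import PermutationSpectrum, TerminalFilterConfig, spectrum

logger = logging.getLogger("telovar")

STAGES = ("composition", "processivity", "terminal")

MISSING = "."  # TSV placeholder for undefined values


@dataclass
class PipelineConfig:
    """Full parameterization of a pipeline run."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    terminal: TerminalFilterConfig = field(default_factory=TerminalFilterConfig)
    model: ModelParams = field(default_factory=ModelParams)
    read_sim: ReadSimParams = field(default_factory=ReadSimParams)
    terminal_sim: TerminalSimParams = field(default_factory=TerminalSimParams)
    rho: float = 0.5
    min_runs: int = 5
    n_units: int = 20_000
    input_fastq: Optional[str] = None
    terminal_fastq: Optional[str] = None
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["detection"]["motifs"] = list(d["detection"]["motifs"])
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        d = dict(d)
        if "detection" in d:
            det = dict(d["detection"])
            det["motifs"] = tuple(det.get("motifs", DetectionConfig().motifs))
            d["detection"] = DetectionConfig(**det)
        if "terminal" in d:
            d["terminal"] = TerminalFilterConfig(**d["terminal"])
        if "model" in d:
            d["model"] = ModelParams(**d["model"])
        if "read_sim" in d:
            d["read_sim"] = ReadSimParams(**d["read_sim"])
        if "terminal_sim" in d:
            ts = dict(d["terminal_sim"])
            if "tail_lengths" in ts:
                ts["tail_lengths"] = {int(k): v for k, v in ts["tail_lengths"].items()}
            d["terminal_sim"] = TerminalSimParams(**ts)
        return cls(**d)

    @classmethod
    def load(cls, path: PathLike) -> "PipelineConfig":
        """Load a YAML or JSON configuration file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(data or {})

    def save(self, path: PathLike) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_tsv(path: PathLike, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(header) + "\n")
        for row in rows:
            handle.write("\t".join(_fmt(v) for v in row) + "\n")


def write_json(path: PathLike, obj) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")


def write_composition_report(summary: CompositionSummary, outdir: PathLike) -> None:
    d = summary.as_dict()
    write_tsv(Path(outdir) / "composition.tsv", list(d.keys()), [list(d.values())])
    write_json(Path(outdir) / "composition.json", d)


def write_runlength_report(table: RunLengthTable, outdir: PathLike) -> None:
    rows = [
        (cls, x, n)
        for cls in ("wt", "var")
        for x, n in sorted(table.runs[cls].items())
    ]
    write_tsv(Path(outdir) / "runlengths.tsv", ["class", "run_length", "count"], rows)
    write_json(
        Path(outdir) / "runlengths.json",
        {cls: {str(x): n for x, n in sorted(table.runs[cls].items())} for cls in ("wt", "var")},
    )


def write_processivity_report(result: ProcessivityResult, outdir: PathLike) -> None:
    header = [
        "class", "slope", "intercept", "r_squared", "p_add", "p_x",
        "rho_used", "n_points_fit", "clamped",
    ]
    rows = []
    for cls in ("wt", "var"):
        if cls in result.estimates:
            e = result.estimates[cls]
            rows.append(
                (cls, e.slope, e.intercept, e.r_squared, e.p_add, e.p_x,
                 e.rho_used, e.n_points_fit, e.clamped)
            )
        else:
            rows.append((cls,) + (None,) * 8)
    write_tsv(Path(outdir) / "processivity.tsv", header, rows)
    write_json(
        Path(outdir) / "processivity.json",
        {
            "estimates": {c: e.as_dict() for c, e in result.estimates.items()},
            "failures": result.failures,
        },
    )


def write_terminal_report(spec: PermutationSpectrum, outdir: PathLike) -> None:
    from .terminal import VAR_ROTATIONS, WT_ROTATIONS

    overall = spec.overall_fractions()
    within = spec.within_class_fractions()
    rows = []
    for cls, rotations in (("wt", WT_ROTATIONS), ("var", VAR_ROTATIONS)):
        for r in rotations:
            rows.append(
                (r, cls, spec.counts[r], within.get(cls, {}).get(r), overall.get(r))
            )
    rows.append(("other", "other", spec.other_count, None,
                 spec.other_count / spec.n_passing if spec.n_passing else None))
    write_tsv(
        Path(outdir) / "terminal_spectrum.tsv",
        ["permutation", "class", "count", "within_class_fraction", "overall_fraction"],
        rows,
    )
    write_json(
        Path(outdir) / "terminal_spectrum.json",
        {
            "counts": spec.counts,
            "other_count": spec.other_count,
            "n_reads_total": spec.n_reads_total,
            "n_passing": spec.n_passing,
            "rejections": spec.rejections,
            "class_fractions": spec.class_fractions(),
            "within_class_fractions": within,
        },
    )


def write_provenance(config: PipelineConfig, stages: Sequence[str], outdir: PathLike) -> None:
    write_json(
        Path(outdir) / "provenance.json",
        {
            "tool": "telovar",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": config.config_hash(),
            "stages": list(stages),
        },
    )


def simulate_wgs_to_files(config: PipelineConfig, outdir: PathLike) -> Path:
    """Simulate an array + WGS reads; write FASTQ and ground-truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    array = simulate_telomere_array(config.model, config.n_units, seed=config.seed)
    reads = simulate_wgs_reads(
        array, dataclasses.replace(config.read_sim, seed=config.seed + 1)
    )
    fastq = outdir / "wgs_reads.fastq"
    write_fastq(reads, fastq)
    array.write_truth(outdir / "array_truth.tsv")
    logger.info("simulated %d reads from a %d-unit array", len(reads), array.n_units)
    return fastq


def simulate_terminal_to_files(config: PipelineConfig, outdir: PathLike) -> Path:
    """Simulate C-tail terminal reads; write FASTQ."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads = simulate_terminal_reads(
        dataclasses.replace(config.terminal_sim, seed=config.seed + 2)
    )
    fastq = outdir / "terminal_reads.fastq"
    write_fastq(reads, fastq)
    logger.info("simulated %d terminal reads", len(reads))
    return fastq


def run_pipeline(
    config: PipelineConfig, stages: Sequence[str] = STAGES
) -> Dict[str, object]:
    """Run the requested analysis stages and write reports.

    ``stages`` is a subset of ``{"composition", "processivity",
    "terminal"}``; unknown names raise ``ValueError``. Returns the in-memory
    results keyed by stage.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}; choose from {STAGES}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    results: Dict[str, object] = {}
    try:
        if "composition" in stages or "processivity" in stages:
            if not config.input_fastq:
                raise ValueError("input_fastq is required for composition/processivity")
            summary = compose(read_fastq(config.input_fastq), config.detection)
            table = run_lengths(read_fastq(config.input_fastq), config.detection)
            logger.info(
                "composition: %d/%d reads telomeric, %d bases considered",
                summary.n_reads_telomeric, summary.n_reads_total, summary.bases_considered,
            )
            if summary.n_reads_telomeric == 0:
                logger.warning("composition: no telomeric reads detected")
            if "composition" in stages:
                write_composition_report(summary, outdir)
                write_runlength_report(table, outdir)
                results["composition"] = summary
                results["runlengths"] = table
            if "processivity" in stages:
                proc = estimate_from_table(table, rho=config.rho, min_runs=config.min_runs)
                for cls, reason in proc.failures.items():
                    logger.warning("processivity (%s): %s", cls, reason)
                write_processivity_report(proc, outdir)
                results["processivity"] = proc
        if "terminal" in stages:
            if not config.terminal_fastq:
                raise ValueError("terminal_fastq is required for the terminal stage")
            spec = spectrum(read_fastq(config.terminal_fastq), config.terminal)
            logger.info(
                "terminal: %d/%d reads passing; rejections %s",
                spec.n_passing, spec.n_reads_total, spec.rejections,
            )
            if spec.n_passing == 0:
                logger.warning("terminal: no reads passed the filters")
            write_terminal_report(spec, outdir)
            results["terminal"] = spec
        write_provenance(config, stages, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return results
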