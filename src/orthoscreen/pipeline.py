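"""Pipeline orchestration: simulate/load -> normalize -> screen -> enrich.

A run is described by a :class:`RunConfig` (typically parsed from a
YAML file).  Input is either a block of simulator settings or paths to
on-disk count/metadata/ortholog tables — exactly one of the two.  The
run writes stage profiles, the screen record table, optionally an
enrichment table, and a machine-readable run summary whose counts
mirror the written tables.  Identical config and seed give identical
output tables.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__, io
from .containers import CountMatrix, OrthologMap, ReferenceSpec, StageProfile
from .enrich import enrich, read_gmt
from .normalize import cpm_log2, ordered_sample_matrix, stage_mean_profile, zscale_profile
from .screen import pair_by_name, passing_gene_list, screen, screen_summary
from .simulate import SimConfig, gene_sets_from_truth, simulate_experiment

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message is stage-tagged."""


@dataclass
class DataPaths:
    counts_a: str
    metadata_a: str
    counts_b: str
    metadata_b: str
    stage_order_a: tuple[str, ...]
    stage_order_b: tuple[str, ...]
    ortholog_map: str | None = None  # None -> pair by gene name


@dataclass
class NormalizationOptions:
    pseudocount: float = 1.0
    scale: bool = True
    replicate_mode: str = "stage-mean"  # or "all-samples"

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.replicate_mode not in ("stage-mean", "all-samples"):
            raise ValueError(
                f"replicate_mode must be 'stage-mean' or 'all-samples', got {self.replicate_mode!r}"
            )


@dataclass
class EnrichmentOptions:
    enabled: bool = True
    gmt: str | None = None
    fdr_level: float = 0.05
    min_set: int = 10
    max_set: int = 500
    universe: str = "map"  # or "profiles"
    # used only when no GMT is given in simulation mode: gene sets are
    # derived from the truth table (planted module + random sets)
    n_random_sets: int = 99
    set_size_range: tuple[int, int] = (10, 30)

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must lie in (0, 1)")
        if self.universe not in ("map", "profiles"):
            raise ValueError(f"universe must be 'map' or 'profiles', got {self.universe!r}")


@dataclass
class RunConfig:
    output_dir: str
    seed: int = 0
    simulate: SimConfig | None = None
    data: DataPaths | None = None
    normalization: NormalizationOptions = field(default_factory=NormalizationOptions)
    reference: ReferenceSpec = field(default_factory=lambda: ReferenceSpec("Sox9", "sox9b"))
    enrichment: EnrichmentOptions = field(default_factory=EnrichmentOptions)

    def __post_init__(self) -> None:
        if self.simulate is None and self.data is None:
            raise ValueError("config must provide either a 'simulate' block or a 'data' block")
        if self.simulate is not None and self.data is not None:
            raise ValueError("config may not provide both 'simulate' and 'data' blocks")


_SECTION_FIELDS: dict[str, type] = {
    "simulate": SimConfig,
    "data": DataPaths,
    "normalization": NormalizationOptions,
    "reference": ReferenceSpec,
    "enrichment": EnrichmentOptions,
}
_TOP_KEYS = ("output_dir", "seed", "simulate", "data", "normalization", "reference", "enrichment")


def _check_keys(given: Mapping[str, Any], allowed: tuple[str, ...], where: str, errors: list[str]) -> None:
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            errors.append(f"unknown key {key!r} in {where}{suffix}")


def validate_config(raw: str | Mapping[str, Any]) -> RunConfig:
    """Parse and validate a run configuration (YAML text or mapping).

    All problems are aggregated into a single error; unknown keys are
    rejected with a closest-match suggestion.  Defaults: correlation
    threshold 0.7, FDR level 0.05, pseudocount 1.
    """
    if isinstance(raw, str):
        parsed = yaml.safe_load(raw)
    else:
        parsed = dict(raw)
    if not isinstance(parsed, Mapping):
        raise ValueError("config must be a mapping")
    errors: list[str] = []
    _check_keys(parsed, _TOP_KEYS, "top level", errors)
    sections: dict[str, Any] = {}
    for name, cls in _SECTION_FIELDS.items():
        block = parsed.get(name)
        if block is None:
            continue
        if not isinstance(block, Mapping):
            errors.append(f"section {name!r} must be a mapping")
            continue
        allowed = tuple(f.name for f in dataclasses.fields(cls))
        _check_keys(block, allowed, f"section {name!r}", errors)
        clean = {k: v for k, v in block.items() if k in allowed}
        for key in ("replicates_a", "replicates_b", "stages_a", "stages_b",
                    "stage_order_a", "stage_order_b", "set_size_range",
                    "baseline_range", "null_baseline_range"):
            if key in clean and isinstance(clean[key], list):
                clean[key] = tuple(clean[key])
        try:
            sections[name] = cls(**clean)
        except (TypeError, ValueError) as exc:
            errors.append(f"section {name!r}: {exc}")
    if "output_dir" not in parsed:
        errors.append("missing required key 'output_dir'")
    if parsed.get("simulate") is None and parsed.get("data") is None:
        errors.append("config must provide either a 'simulate' block or a 'data' block")
    data = sections.get("data")
    if data is not None:
        for fname in ("counts_a", "metadata_a", "counts_b", "metadata_b", "ortholog_map"):
            p = getattr(data, fname)
            if p is not None and not Path(p).exists():
                errors.append(f"data file for {fname!r} does not exist: {p}")
    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))
    return RunConfig(
        output_dir=str(parsed["output_dir"]),
        seed=int(parsed.get("seed", 0)),
        simulate=sections.get("simulate"),
        data=sections.get("data"),
        normalization=sections.get("normalization", NormalizationOptions()),
        reference=sections.get("reference", ReferenceSpec("Sox9", "sox9b")),
        enrichment=sections.get("enrichment", EnrichmentOptions()),
    )


def _config_echo(config: RunConfig) -> dict:
    def encode(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [encode(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return encode(config)


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full screen and write all outputs to the run directory.

    Writes ``profiles_a.tsv``/``profiles_b.tsv`` (stage profiles used for
    the correlations), ``screen.tsv`` (one record per ortholog pair),
    ``enrichment.tsv`` when enrichment runs, simulated inputs when in
    simulation mode, and ``run_summary.json``.  Returns the summary.
    Any stage failure aborts with a stage-tagged :class:`PipelineError`
    and the partial summary (status "failed") is still written.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    pkg_logger = logging.getLogger("orthoscreen")
    pkg_logger.addHandler(collector)
    started = datetime.now(timezone.utc).isoformat()
    echo = _config_echo(config)
    summary: dict[str, Any] = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "status": "running",
        "seed": config.seed,
        "started": started,
        "config": echo,
        "config_hash": hashlib.sha256(
            json.dumps(echo, sort_keys=True).encode()
        ).hexdigest(),
        "versions": {
            "orthoscreen": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "counts": {},
        "warnings": [],
    }
    stage = "setup"
    try:
        # ------------------------------------------------ inputs
        if config.simulate is not None:
            stage = "simulate"
            sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
            sim = simulate_experiment(sim_cfg)
            counts_a, counts_b = sim.counts_a, sim.counts_b
            omap, truth = sim.ortholog_map, sim.truth
            io.write_counts(counts_a, out / "counts_a.tsv")
            io.write_metadata(counts_a, out / "metadata_a.tsv")
            io.write_counts(counts_b, out / "counts_b.tsv")
            io.write_metadata(counts_b, out / "metadata_b.tsv")
            io.write_ortholog_map(omap, out / "ortholog_map.tsv")
            io.write_truth(truth, out / "truth.tsv")
            stage_order_a = sim_cfg.stages_a
            stage_order_b = sim_cfg.stages_b
        else:
            stage = "load"
            assert config.data is not None
            d = config.data
            counts_a = io.read_counts(d.counts_a, d.metadata_a, d.stage_order_a)
            counts_b = io.read_counts(d.counts_b, d.metadata_b, d.stage_order_b)
            truth = None
            stage_order_a = tuple(d.stage_order_a)
            stage_order_b = tuple(d.stage_order_b)
            if d.ortholog_map is not None:
                omap = pair_by_name(
                    counts_a.genes, counts_b.genes, mode="table",
                    table=io.read_ortholog_map(d.ortholog_map),
                )
            else:
                omap = pair_by_name(counts_a.genes, counts_b.genes, mode="name")
        summary["counts"]["genes_loaded_a"] = int(counts_a.counts.shape[0])
        summary["counts"]["genes_loaded_b"] = int(counts_b.counts.shape[0])
        summary["counts"]["samples_a"] = int(counts_a.counts.shape[1])
        summary["counts"]["samples_b"] = int(counts_b.counts.shape[1])

        # ------------------------------------------------ normalization
        stage = "normalize"
        norm = config.normalization
        log_a = cpm_log2(counts_a, norm.pseudocount)
        log_b = cpm_log2(counts_b, norm.pseudocount)
        if norm.replicate_mode == "stage-mean":
            prof_a = stage_mean_profile(log_a, counts_a.samples, stage_order_a)
            prof_b = stage_mean_profile(log_b, counts_b.samples, stage_order_b)
        else:
            prof_a = ordered_sample_matrix(log_a, counts_a.samples, stage_order_a)
            prof_b = ordered_sample_matrix(log_b, counts_b.samples, stage_order_b)
        if norm.scale:
            prof_a = zscale_profile(prof_a)
            prof_b = zscale_profile(prof_b)
        io.write_profile(prof_a, out / "profiles_a.tsv")
        io.write_profile(prof_b, out / "profiles_b.tsv")

        # ------------------------------------------------ screen
        stage = "screen"
        records = screen(prof_a, prof_b, omap, config.reference)
        io.write_table(records, out / "screen.tsv")
        summary["counts"].update(screen_summary(records))

        # ------------------------------------------------ enrichment
        stage = "enrich"
        enr = config.enrichment
        run_enrich = enr.enabled and (enr.gmt is not None or truth is not None)
        if run_enrich:
            if enr.gmt is not None:
                collection = read_gmt(enr.gmt)
            else:
                collection = gene_sets_from_truth(
                    truth,
                    n_random_sets=enr.n_random_sets,
                    set_size_range=enr.set_size_range,
                    seed=config.seed,
                )
            query = passing_gene_list(records, "a")
            if enr.universe == "map":
                universe = omap.genes_a()
            else:
                universe = list(prof_a.genes)
            table = enrich(
                query, universe, collection,
                fdr_level=enr.fdr_level, min_set=enr.min_set, max_set=enr.max_set,
            )
            io.write_table(table, out / "enrichment.tsv")
            summary["counts"]["sets_tested"] = int(len(table))
            summary["counts"]["sets_significant"] = int(table["significant"].sum()) if len(table) else 0
        summary["status"] = "ok"
    except Exception as exc:
        summary["status"] = "failed"
        summary["failed_stage"] = stage
        summary["error"] = str(exc)
        raise PipelineError(f"[{stage}] {exc}") from exc
    finally:
        summary["finished"] = datetime.now(timezone.utc).isoformat()
        summary["warnings"] = list(collector.messages)
        pkg_logger.removeHandler(collector)
        (out / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
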