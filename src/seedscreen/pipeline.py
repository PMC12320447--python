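"""End-to-end orchestration: simulate → quantify → enrich → call epitopes.

A run is fully described by a small YAML config (validated against a strict
schema — unknown keys are rejected before any compute) and is reproducible
from that config alone: the RNG seed drives the simulator, and every output
is stamped with the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from . import enrichment as enr
from . import simulate as sim
from .quant import AnchorSpec, load_members, quantify_fastq

log = logging.getLogger("seedscreen")


class ScreenBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_escape_positions: int = 3
    escape_positions: list[int] | None = None
    n_cells: int = 50_000
    read_depth: int = 100_000
    error_rate: float = 0.001


class AnchorBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    upstream: str = sim.DEFAULT_ANCHORS.upstream
    downstream: str = sim.DEFAULT_ANCHORS.downstream


class AnalysisBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pseudocount: float | None = None
    effect_threshold: float = 1.0
    min_fraction_escaping: float = 0.5


class RunConfig(BaseModel):
    """Schema for a full synthetic-screen pipeline run."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 42
    outdir: str = "seedscreen_run"
    screen: ScreenBlock = ScreenBlock()
    anchors: AnchorBlock = AnchorBlock()
    analysis: AnalysisBlock = AnalysisBlock()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full synthetic screen and analysis; returns the run dir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    cfg_hash = config.config_hash()
    try:
        log.info("run config hash %s", cfg_hash)
        (outdir / "config_used.yaml").write_text(
            yaml.safe_dump({"config_hash": cfg_hash, **config.model_dump()})
        )
        anchors = AnchorSpec(config.anchors.upstream, config.anchors.downstream)

        _, members = sim.default_screen_members(seed=config.seed)
        truth = sim.make_screen_truth(
            members,
            seed=config.seed,
            escape_positions=config.screen.escape_positions,
            n_escape_positions=config.screen.n_escape_positions,
            n_cells=config.screen.n_cells,
            read_depth=config.screen.read_depth,
            error_rate=config.screen.error_rate,
        )
        log.info("simulating screen: %d members, escape positions %s",
                 len(members), truth.escape_positions)
        paths = sim.simulate_sort_screen(members, truth, outdir / "reads",
                                         anchors=anchors)

        members = load_members(paths["members"])
        tables = {}
        run_stats = {"config_hash": cfg_hash, "samples": {}}
        for bin_name in ("input", "bin_neg", "bin_pos"):
            tab = quantify_fastq(paths[bin_name], members, anchors,
                                 sample_id=bin_name)
            tab.write(outdir / f"counts_{bin_name}.tsv")
            tables[bin_name] = tab
            run_stats["samples"][bin_name] = tab.stats()
            log.info(
                "%s: reads_in=%d anchored=%d mapped=%d control=%d",
                bin_name, tab.reads_in, tab.reads_anchored, tab.reads_mapped,
                tab.reads_control,
            )

        eps = config.analysis.pseudocount
        enr_pos = enr.fold_enrichment(tables["bin_pos"], tables["input"], eps)
        enr_neg = enr.fold_enrichment(tables["bin_neg"], tables["input"], eps)
        records = enr.conservation_ratio(enr_pos, enr_neg)
        records.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

        profiles = enr.aggregate_by_amino_acid(records)
        profiles.to_csv(outdir / "aa_profiles.tsv", sep="\t", index=False)

        called = enr.call_epitope_positions(
            profiles,
            effect_threshold=config.analysis.effect_threshold,
            min_fraction_escaping=config.analysis.min_fraction_escaping,
        )
        calls = {
            "config_hash": cfg_hash,
            "called_positions": sorted(called),
            "planted_positions": truth.escape_positions,
        }
        (outdir / "epitope_calls.json").write_text(json.dumps(calls, indent=2) + "\n")
        (outdir / "stats.json").write_text(json.dumps(run_stats, indent=2) + "\n")
        log.info("called epitope positions: %s", sorted(called))
        return outdir
    finally:
        log.removeHandler(handler)
        handler.close()
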