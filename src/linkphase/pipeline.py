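"""End-to-end orchestration of the phasing pipeline.

``phase_fragments`` runs molecule splitting, graph partitioning and
per-component assembly on in-memory fragments; ``run_pipeline`` wraps it
with file I/O and optional evaluation against a planted truth.  Components
are processed independently with per-component seeds derived stably from
the master seed and the component's smallest variant index, so results do
not depend on processing order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import blockio
from .components import build_share_graph, recursive_partition
from .core import HaplotypeBlock, SolverConfig, assemble_component
from .fragio import Fragment, VariantSite
from .metrics import EvaluationReport, GroundTruth, evaluate_blocks
from .molsplit import MeanShiftConfig, split_all

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline-wide knobs; defaults are the standard operating point.

    ``mode="fast"`` trades accuracy for speed by lowering the restart
    count to 10 and loosening the SDP gap tolerance to 0.05; the site
    partition into blocks (driven by the components stage) is identical in
    both modes.
    """

    ploidy: int
    nc_threshold: float = 0.03
    molecule_length: float = 50_000.0
    bandwidth: float | None = None  # default: molecule_length / 2
    gap_tol: float = 0.01
    restarts: int = 100
    seed: int = 0
    mode: str = "accurate"  # accurate | fast
    min_component_size: int | None = None  # default: 2 * ploidy
    split_molecules: bool = True

    def effective(self) -> "PipelineConfig":
        cfg = self
        if cfg.mode == "fast":
            cfg = replace(cfg, restarts=10, gap_tol=0.05)
        elif cfg.mode != "accurate":
            raise ValueError(f"unknown mode {cfg.mode!r}")
        if cfg.bandwidth is None:
            cfg = replace(cfg, bandwidth=cfg.molecule_length / 2.0)
        if cfg.min_component_size is None:
            cfg = replace(cfg, min_component_size=2 * cfg.ploidy)
        return cfg


def _component_seed(master: int, anchor: int) -> int:
    """Stable per-component sub-seed, independent of processing order."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(anchor,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineResult:
    blocks: list[HaplotypeBlock]
    fragments_per_block: list[list[Fragment]]
    manifest: dict


def phase_fragments(
    fragments: Sequence[Fragment],
    variants: Sequence[VariantSite],
    config: PipelineConfig,
) -> PipelineResult:
    """Molecule splitting -> components -> per-component assembly."""
    cfg = config.effective()
    manifest: dict = {
        "seed": cfg.seed,
        "ploidy": cfg.ploidy,
        "nc_threshold": cfg.nc_threshold,
        "gap_tol": cfg.gap_tol,
        "restarts": cfg.restarts,
        "mode": config.mode,
        "n_input_fragments": len(fragments),
        "components": [],
    }
    work = list(fragments)
    if cfg.split_molecules:
        ms = MeanShiftConfig(bandwidth=cfg.bandwidth)
        work = split_all(work, variants, ms)
        manifest["n_fragments_after_split"] = len(work)
    by_id = {f.id: f for f in work}
    graph = build_share_graph(work)
    leaves = recursive_partition(
        graph, t=cfg.nc_threshold, min_size=cfg.min_component_size
    )
    # deterministic component order: by smallest first variant index
    def comp_anchor(members: list[str]) -> int:
        return min(by_id[m].first_index for m in members)

    leaves = sorted(leaves, key=lambda ms_: (comp_anchor(ms_), sorted(ms_)[0]))
    blocks: list[HaplotypeBlock] = []
    frags_per_block: list[list[Fragment]] = []
    for ci, members in enumerate(leaves):
        comp_frags = sorted(
            (by_id[m] for m in members), key=lambda f: (f.first_index, f.id)
        )
        entry = {"component": ci, "n_fragments": len(comp_frags)}
        if len(comp_frags) < cfg.ploidy:
            entry["skipped"] = "underdetermined"
            manifest["components"].append(entry)
            logger.info("component %d skipped: %d < K fragments", ci, len(comp_frags))
            continue
        seed = _component_seed(cfg.seed, comp_anchor(members))
        solver_cfg = SolverConfig(
            gap_tol=cfg.gap_tol, restarts=cfg.restarts, seed=seed
        )
        block = assemble_component(
            comp_frags, cfg.ploidy, solver_cfg, component_id=str(ci)
        )
        entry.update(
            seed=seed,
            n_sites=block.n_sites,
            mec=block.mec,
            sdp_gap=block.metadata["sdp_gap"],
        )
        manifest["components"].append(entry)
        blocks.append(block)
        frags_per_block.append(comp_frags)
    return PipelineResult(
        blocks=blocks, fragments_per_block=frags_per_block, manifest=manifest
    )


def run_pipeline(
    fragments: Sequence[Fragment],
    variants: Sequence[VariantSite],
    config: PipelineConfig,
    truth: GroundTruth | None = None,
    out_blocks: str | Path | None = None,
    out_report: str | Path | None = None,
) -> tuple[PipelineResult, EvaluationReport | None]:
    """Phase, optionally evaluate, and optionally write outputs."""
    result = phase_fragments(fragments, variants, config)
    positions = np.asarray([v.position for v in variants])
    report: EvaluationReport | None = None
    if truth is not None:
        report = evaluate_blocks(
            result.blocks, truth, result.fragments_per_block
        )
    if out_blocks is not None:
        blockio.write_blocks(result.blocks, positions, out_blocks)
    if out_report is not None:
        payload = {"manifest": result.manifest}
        if report is not None:
            payload["evaluation"] = report.to_dict()
        with open(out_report, "w") as fh:
            json.dump(payload, fh, indent=2)
    return result, report
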