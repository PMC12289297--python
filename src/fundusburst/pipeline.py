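"""End-to-end pipeline: simulate -> reduce -> qc -> select -> evaluate.

A :class:`PipelineConfig` (YAML round-trippable) drives a deterministic run
producing an artifact tree — phantom/burst images, composites, QC reports,
the selected-records CSV and the bootstrap evaluation JSON — plus a manifest
listing every file with the config hash and global seed, so a run can be
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as fio
from .bootstrap import BootstrapConfig, bootstrap_difference
from .burst_reduce import burst_reduce
from .iqcf import DEFAULT_CUTOFF, iqcf_score
from .study import build_contingency, eligible_paired_records, phi_coefficient, \
    proportion_sufficient, records_from_session
from .synthetic import ArtifactSpec, BurstConfig, generate_phantom, simulate_burst, \
    simulate_session

log = logging.getLogger("fundusburst")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips losslessly through YAML."""

    seed: int = 0
    n_stacks: int = 2
    side_px: int = 192
    vessel_density: float = 0.1
    burst: dict = field(default_factory=lambda: {"n_frames": 8, "noise_sd": 0.01})
    artifacts: dict = field(default_factory=dict)
    iqcf_cutoff: float = DEFAULT_CUTOFF
    n_participants: int = 108
    bootstrap_B: int = 2000
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full flow and return the manifest (also written to disk).

    The manifest contains no timestamps, so identical configs give
    byte-identical manifests.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ValueError(f"output directory {out} is not writable: {exc}") from exc

    logging.basicConfig(level=config.log_level)
    t0 = time.perf_counter()
    manifest: dict = {"config_hash": config.digest(), "seed": config.seed, "files": {}}

    def record(path: Path, seed: int) -> None:
        manifest["files"][str(path.relative_to(out))] = {"seed": seed}

    config.to_yaml(out / "config.yaml")
    record(out / "config.yaml", config.seed)

    # imaging stages
    artifacts = fio.artifact_spec_from_dict(config.artifacts) if config.artifacts \
        else ArtifactSpec()
    for i in range(config.n_stacks):
        stack_seed = config.seed * 10_000 + i
        phantom = generate_phantom(stack_seed, side_px=config.side_px,
                                   vessel_density=config.vessel_density)
        burst_cfg = BurstConfig(**{**config.burst, "seed": stack_seed})
        stack = simulate_burst(phantom, burst_cfg, artifacts)
        stack_dir = out / f"stack_{i:03d}"
        fio.write_stack(stack_dir, stack)
        for f in sorted(stack_dir.iterdir()):
            record(f, stack_seed)
        composite = burst_reduce(stack)
        comp_path = out / f"composite_{i:03d}.png"
        fio.write_image(comp_path, composite.image)
        record(comp_path, stack_seed)
        qc = iqcf_score(composite, stack.fov_mask, cutoff=config.iqcf_cutoff)
        qc_path = out / f"qc_{i:03d}.json"
        fio.write_json(qc_path, {
            "score": qc.score, "cutoff": qc.cutoff, "decision": qc.decision.value,
            "impairment_means": qc.impairment_means,
            "n_frames_used": composite.n_frames_used, "seed": stack_seed,
        })
        record(qc_path, stack_seed)
        log.info("stack %d: score=%.3f decision=%s", i, qc.score, qc.decision.value)

    # statistics stages
    session_seed = config.seed + 1
    session = simulate_session(config.n_participants, seed=session_seed)
    session_path = out / "session.csv"
    session.to_csv(session_path)
    record(session_path, session_seed)

    records = eligible_paired_records(records_from_session(session))
    records_path = out / "records.csv"
    fio.write_records_csv(records_path, records)
    record(records_path, session_seed)

    boot = bootstrap_difference(records, BootstrapConfig(
        B=config.bootstrap_B, seed=config.seed + 2))
    prop_inv = proportion_sufficient(records, "investigational")
    prop_ref = proportion_sufficient(records, "reference")
    grad_records = [r for r in records if r.grader_gradable is not None
                    and r.qc_decision.value != "NA"]
    table = build_contingency(grad_records) if grad_records else None
    phi = None
    if table is not None:
        try:
            phi = phi_coefficient(table)
        except ValueError:
            log.info("phi undefined for this run (zero marginal)")
    eval_path = out / "evaluation.json"
    fio.write_json(eval_path, {
        "proportion_investigational": prop_inv,
        "proportion_reference": prop_ref,
        "difference": {
            "point_estimate": boot.point_estimate,
            "ci_low": boot.ci_low, "ci_high": boot.ci_high,
            "naive_difference": boot.naive_difference,
            "B": boot.config.B, "seed": boot.config.seed,
            "quantile_method": "linear", "n_excluded": boot.n_excluded,
        },
        "contingency": None if table is None else {
            "a": table.a, "b": table.b, "c": table.c, "d": table.d,
            "phi": phi,
            "row_fractions": table.row_fractions(),
            "column_fractions": table.column_fractions(),
        },
        "seed": session_seed,
    })
    record(eval_path, config.seed + 2)

    fio.write_json(out / "manifest.json", manifest)
    log.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    return manifest
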