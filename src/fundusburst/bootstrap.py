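"""Paired cluster (block) bootstrap for the difference in correlated
proportions between the two cameras.

The participant is the cluster unit J.  Each replicate draws J clusters with
replacement; every eye of a drawn cluster enters once per draw, and with it
both cameras' rows, preserving the paired design and original cluster sizes.
The difference in majority-sufficient proportions (investigational minus
reference) is computed per replicate; the point estimate is the 50th
percentile of the B replicate differences and the CI the 2.5%/97.5%
quantiles (default level), with quantiles interpolated linearly between
order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .study import Camera, EyeRecord

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "cluster_resample",
    "bootstrap_difference",
]

QUANTILE_METHOD = "linear"  # interpolation between order statistics


@dataclass(frozen=True)
class BootstrapConfig:
    """Replicate count, seed and CI level for the cluster bootstrap."""

    B: int = 10_000
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError(f"B must be >= 1, got {self.B}")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")


@dataclass
class BootstrapResult:
    """point_estimate is the replicate median; ``replicates`` has length B
    with NaN marking replicates excluded for lacking usable records (counted
    in ``n_excluded``); ``naive_difference`` is the plug-in difference on the
    original data."""

    point_estimate: float
    ci_low: float
    ci_high: float
    replicates: np.ndarray
    naive_difference: float
    n_excluded: int
    config: BootstrapConfig

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point_estimate <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def _cluster_table(records: Sequence[EyeRecord]) -> pd.DataFrame:
    """Per-cluster counts of graded eyes and majority-yes outcomes per camera."""
    rows = [
        {
            "participant_id": r.participant_id,
            "camera": r.camera.value,
            "yes": int(r.majority_sufficient),
        }
        for r in records
        if r.grader_sufficient is not None
    ]
    if not rows:
        raise ValueError("no graded records")
    df = pd.DataFrame(rows)
    agg = (df.groupby(["participant_id", "camera"])
             .agg(k=("yes", "sum"), n=("yes", "size"))
             .unstack("camera", fill_value=0))
    for cam in (Camera.INVESTIGATIONAL.value, Camera.REFERENCE.value):
        for stat in ("k", "n"):
            if (stat, cam) not in agg.columns:
                agg[(stat, cam)] = 0
    return agg


def _check_pairing(records: Sequence[EyeRecord]) -> None:
    seen: dict[tuple[str, str], set[str]] = {}
    graded: dict[tuple[str, str], set[str]] = {}
    for r in records:
        key = (r.participant_id, r.eye)
        seen.setdefault(key, set()).add(r.camera.value)
        if r.grader_sufficient is not None:
            graded.setdefault(key, set()).add(r.camera.value)
    unpaired = sorted(f"{p}/{e}" for (p, e), cams in seen.items() if len(cams) < 2)
    if unpaired:
        raise ValueError(
            "paired design requires both cameras per (participant, eye); "
            f"missing counterpart for: {unpaired}")


def cluster_resample(records: Sequence[EyeRecord], rng: np.random.Generator) -> list[EyeRecord]:
    """One bootstrap resample: J cluster draws with replacement, keeping all
    eyes of each drawn cluster and both cameras' rows per eye."""
    _check_pairing(records)
    clusters: dict[str, list[EyeRecord]] = {}
    for r in records:
        clusters.setdefault(r.participant_id, []).append(r)
    ids = sorted(clusters)
    draws = rng.integers(0, len(ids), size=len(ids))
    out: list[EyeRecord] = []
    for j in draws:
        out.extend(clusters[ids[j]])
    return out


def _per_cluster_arrays(records: Sequence[EyeRecord]):
    agg = _cluster_table(records)
    k_inv = agg[("k", Camera.INVESTIGATIONAL.value)].to_numpy(float)
    n_inv = agg[("n", Camera.INVESTIGATIONAL.value)].to_numpy(float)
    k_ref = agg[("k", Camera.REFERENCE.value)].to_numpy(float)
    n_ref = agg[("n", Camera.REFERENCE.value)].to_numpy(float)
    return k_inv, n_inv, k_ref, n_ref


def bootstrap_difference(
    records: Sequence[EyeRecord] | pd.DataFrame,
    config: BootstrapConfig = BootstrapConfig(),
) -> BootstrapResult:
    """Cluster-bootstrap the difference in majority-sufficient proportions.

    ``records`` is either a list of :class:`~fundusburst.study.EyeRecord`
    (paired structure enforced) or a pre-aggregated frame with columns
    ``participant_id``, ``camera``, ``sufficient`` (bool, one row per graded
    eye image).  A resampled proportion depends on the drawn clusters only
    through their per-cluster counts, so replicates are computed from those
    counts directly; the result is identical to materializing each resample.
    Fixed seed gives a bit-identical result.
    """
    if isinstance(records, pd.DataFrame):
        df = records
        agg = (df.assign(yes=df["sufficient"].astype(int))
                 .groupby(["participant_id", "camera"])
                 .agg(k=("yes", "sum"), n=("yes", "size"))
                 .unstack("camera", fill_value=0))
        k_inv = agg[("k", Camera.INVESTIGATIONAL.value)].to_numpy(float)
        n_inv = agg[("n", Camera.INVESTIGATIONAL.value)].to_numpy(float)
        k_ref = agg[("k", Camera.REFERENCE.value)].to_numpy(float)
        n_ref = agg[("n", Camera.REFERENCE.value)].to_numpy(float)
    else:
        _check_pairing(records)
        k_inv, n_inv, k_ref, n_ref = _per_cluster_arrays(records)
    n_clusters = k_inv.size
    if n_inv.sum() == 0 or n_ref.sum() == 0:
        raise ValueError("both cameras must be represented")

    naive = float(k_inv.sum() / n_inv.sum() - k_ref.sum() / n_ref.sum())

    rng = np.random.default_rng(config.seed)
    # one block of J cluster indices per replicate, drawn together
    idx = rng.integers(0, n_clusters, size=(config.B, n_clusters))
    rk_inv, rn_inv = k_inv[idx].sum(axis=1), n_inv[idx].sum(axis=1)
    rk_ref, rn_ref = k_ref[idx].sum(axis=1), n_ref[idx].sum(axis=1)
    usable = (rn_inv > 0) & (rn_ref > 0)
    reps = np.full(config.B, np.nan)
    reps[usable] = rk_inv[usable] / rn_inv[usable] - rk_ref[usable] / rn_ref[usable]
    valid = reps[usable]
    if valid.size == 0:
        raise ValueError("every replicate lacked records for one camera")

    alpha = 1.0 - config.ci_level
    lo, mid, hi = np.quantile(valid, [alpha / 2.0, 0.5, 1.0 - alpha / 2.0],
                              method=QUANTILE_METHOD)
    return BootstrapResult(
        point_estimate=float(mid), ci_low=float(lo), ci_high=float(hi),
        replicates=reps, naive_difference=naive,
        n_excluded=int(config.B - valid.size), config=config)
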