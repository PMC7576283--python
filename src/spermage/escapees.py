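"""Classification of DMRs as reprogramming escapees.

After fertilization the paternal genome undergoes a genome-wide wave of
demethylation through the pronucleus stages. A region escapes that wave if
its methylation stays high (here >= 30%) and roughly constant (range of
variation < 30%) through the late-pronucleus stage. Boundary conventions:
a minimum exactly at the persistence threshold passes (>=); a range exactly
at the variation threshold fails (<).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import DMR
from .simulate import EmbryoTrajectory

__all__ = ["EscapeeCall", "classify_escapee", "screen_dmrs_for_escapees"]

LATE_PN_STAGE = "zygote_late_PN"


@dataclass(frozen=True)
class EscapeeCall:
    region_id: str
    is_escapee: bool
    min_meth: float
    meth_range: float
    stages_used: tuple[str, ...]


def classify_escapee(
    traj: EmbryoTrajectory,
    persist_threshold: float = 0.30,
    variation_threshold: float = 0.30,
    variation_stat: str = "range",
    final_stage: str = LATE_PN_STAGE,
) -> EscapeeCall:
    """Classify one trajectory, using stages up to and including the
    late-pronucleus stage.

    Escapee iff min methylation >= ``persist_threshold`` and variation
    (range by default, standard deviation with ``variation_stat='sd'``) <
    ``variation_threshold``. Missing (NaN) values are an error: no
    imputation.
    """
    if final_stage in traj.stages:
        n_used = traj.stages.index(final_stage) + 1
    else:
        n_used = len(traj.stages)
    stages = traj.stages[:n_used]
    values = traj.meth[:n_used]
    if any(math.isnan(v) for v in values):
        raise ValueError(f"{traj.region_id}: missing methylation value in trajectory")
    min_meth = min(values)
    meth_range = max(values) - min_meth
    if variation_stat == "range":
        variation = meth_range
    elif variation_stat == "sd":
        mean = sum(values) / len(values)
        variation = math.sqrt(sum((v - mean) ** 2 for v in values) / len(values))
    else:
        raise ValueError(f"unknown variation_stat {variation_stat!r}")
    return EscapeeCall(
        region_id=traj.region_id,
        is_escapee=(min_meth >= persist_threshold) and (variation < variation_threshold),
        min_meth=min_meth,
        meth_range=meth_range,
        stages_used=stages,
    )


def screen_dmrs_for_escapees(
    dmrs: Sequence[DMR],
    trajectories: Sequence[EmbryoTrajectory],
    persist_threshold: float = 0.30,
    variation_threshold: float = 0.30,
    variation_stat: str = "range",
) -> tuple[list[EscapeeCall], dict]:
    """Classify every DMR's trajectory and summarize the escapee set.

    DMRs and trajectories are matched by region id; missing trajectories
    are an error listing the absent ids. The summary reports the escapee
    count and the direction composition of the escapees (in the motivating
    study all escapees were regions gaining methylation with age — reported
    here, never enforced).
    """
    by_id = {t.region_id: t for t in trajectories}
    missing = [d.region_id for d in dmrs if d.region_id not in by_id]
    if missing:
        raise KeyError(f"DMRs without embryo trajectory: {missing}")
    calls = [
        classify_escapee(
            by_id[d.region_id], persist_threshold, variation_threshold, variation_stat
        )
        for d in dmrs
    ]
    direction = {d.region_id: d.direction for d in dmrs}
    escapees = [c for c in calls if c.is_escapee]
    summary = {
        "n_dmrs": len(dmrs),
        "n_escapees": len(escapees),
        "n_escapees_hyper": sum(1 for c in escapees if direction[c.region_id] == "hyper"),
        "n_escapees_hypo": sum(1 for c in escapees if direction[c.region_id] == "hypo"),
    }
    return calls, summary
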