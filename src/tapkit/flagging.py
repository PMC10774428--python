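"""Percentile-threshold fitting, flag assignment, confidence filtering and
ensemble consensus.

Flags are relative to a reference cohort (clinical-stage therapeutics in
the published protocol).  Amber marks a score inside an extreme 5 % tail
of the reference distribution (inclusive boundaries), red a score strictly
beyond the reference minimum/maximum on a flagged side.  Sidedness per
metric: L_tot and PSH are flagged on both tails, PPC and PNC only on the
upper tail, SFvCSP only on the lower tail (large negative = asymmetric
chain charges).

Model-confidence filtering summarises the per-residue backbone predicted
error (PE) over CDRH3 as an RMS value, sqrt(sum PE^2 / L_CDRH3), and
retains structures at or below a threshold, optionally derived as a
percentile of the cohort's own RMS-PE distribution.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .core_model import FvStructure
from .patch_metrics import METRICS, TapProfile
from .regions import assign_regions, cdr_residues


class Flag(enum.IntEnum):
    GREEN = 0
    AMBER = 1
    RED = 2

    def __str__(self) -> str:       # pragma: no cover - cosmetic
        return self.name.lower()


SIDEDNESS: dict[str, str] = {
    "l_tot": "two_sided",
    "psh": "two_sided",
    "ppc": "upper",
    "pnc": "upper",
    "sfvcsp": "lower",
}


@dataclass
class MetricThresholds:
    sidedness: str
    lower_red: Optional[float] = None     # reference minimum (0th pct)
    lower_amber: Optional[float] = None   # 5th pct
    upper_amber: Optional[float] = None   # 95th pct
    upper_red: Optional[float] = None     # reference maximum (100th pct)

    def __post_init__(self) -> None:
        vals = [v for v in (self.lower_red, self.lower_amber,
                            self.upper_amber, self.upper_red) if v is not None]
        if vals != sorted(vals):
            raise ValueError("threshold boundaries out of order")


@dataclass
class ThresholdSet:
    per_metric: dict[str, MetricThresholds]
    reference_n: int = 0

    def to_yaml(self, path: str | Path, header: str = "") -> None:
        payload = {
            "reference_n": self.reference_n,
            "metrics": {
                m: {k: v for k, v in vars(t).items() if v is not None}
                for m, t in self.per_metric.items()
            },
        }
        text = yaml.safe_dump(payload, sort_keys=True)
        Path(path).write_text((f"# {header}\n" if header else "") + text)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdSet":
        payload = yaml.safe_load(Path(path).read_text())
        per_metric = {m: MetricThresholds(**vals)
                      for m, vals in payload["metrics"].items()}
        return cls(per_metric=per_metric, reference_n=payload.get("reference_n", 0))


def fit_thresholds(reference_scores: dict[str, Sequence[float]],
                   method: str = "linear") -> ThresholdSet:
    """Percentile boundaries from per-metric reference score lists.

    0th/100th percentiles are the observed min/max; 5th/95th use sorted
    linear interpolation (numpy's "linear" method) by default.  Only the
    boundaries relevant to each metric's sidedness are populated.
    """
    per_metric: dict[str, MetricThresholds] = {}
    n_ref = 0
    for metric, scores in reference_scores.items():
        arr = np.asarray(list(scores), dtype=float)
        if arr.size == 0:
            raise ValueError(f"empty reference list for {metric}")
        n_ref = max(n_ref, arr.size)
        sided = SIDEDNESS.get(metric, "two_sided")
        t = MetricThresholds(sidedness=sided)
        if sided in ("two_sided", "lower"):
            t.lower_red = float(arr.min())
            t.lower_amber = float(np.percentile(arr, 5, method=method))
        if sided in ("two_sided", "upper"):
            t.upper_amber = float(np.percentile(arr, 95, method=method))
            t.upper_red = float(arr.max())
        per_metric[metric] = t
    return ThresholdSet(per_metric=per_metric, reference_n=n_ref)


def flag_score(score: float, t: MetricThresholds) -> Flag:
    """Amber boundaries are inclusive; red means strictly beyond min/max."""
    if t.sidedness in ("two_sided", "lower"):
        if score < t.lower_red:
            return Flag.RED
        if score <= t.lower_amber:
            return Flag.AMBER
    if t.sidedness in ("two_sided", "upper"):
        if score > t.upper_red:
            return Flag.RED
        if score >= t.upper_amber:
            return Flag.AMBER
    return Flag.GREEN


@dataclass
class FlagReport:
    id: str
    per_metric: dict[str, Flag]
    overall: Flag

    def flag(self, metric: str) -> Flag:
        return self.per_metric[metric]


def assign_flags(profile: TapProfile, thresholds: ThresholdSet) -> FlagReport:
    per_metric = {m: flag_score(profile.metric(m), thresholds.per_metric[m])
                  for m in METRICS if m in thresholds.per_metric}
    overall = max(per_metric.values()) if per_metric else Flag.GREEN
    return FlagReport(id=profile.id, per_metric=per_metric, overall=overall)


# ---------------------------------------------------------------------------
# model-confidence filtering

def cdrh3_rms_predicted_error(structure: FvStructure) -> float:
    """RMS backbone predicted error over CDRH3: sqrt(sum PE^2 / L_CDRH3)."""
    regions = assign_regions(structure)
    loop = cdr_residues(structure, regions, chain_id="H", cdr="CDR3")
    if not loop:
        raise ValueError(f"{structure.id}: empty CDRH3")
    pes = []
    for res in loop:
        if res.predicted_error is None:
            raise ValueError(f"{structure.id}: residue {res.key} has no predicted error")
        pes.append(res.predicted_error)
    return float(np.sqrt(np.mean(np.square(pes))))


def confidence_filter(
    cohort: Sequence[FvStructure],
    threshold: Optional[float] = None,
    percentile: Optional[float] = None,
    exclude_ids: Optional[set[str]] = None,
) -> tuple[list[FvStructure], float]:
    """Retain structures whose CDRH3 RMS predicted error is <= threshold.

    When ``percentile`` is given instead of an absolute threshold, the
    threshold is that percentile of the cohort's RMS-PE values after
    removing ``exclude_ids`` (e.g. antibodies with solved structures, which
    need no model-confidence proxy); the filter itself is then applied to
    the full cohort.  Returns (retained structures, threshold used).
    """
    if (threshold is None) == (percentile is None):
        raise ValueError("give exactly one of threshold or percentile")
    rms = {s.id: cdrh3_rms_predicted_error(s) for s in cohort}
    if percentile is not None:
        exclude_ids = exclude_ids or set()
        pool = [v for sid, v in rms.items() if sid not in exclude_ids]
        if not pool:
            raise ValueError("no structures left to derive the percentile threshold")
        threshold = float(np.percentile(pool, percentile, method="linear"))
    retained = [s for s in cohort if rms[s.id] <= threshold]
    return retained, float(threshold)


# ---------------------------------------------------------------------------
# repeat-run ensembles

@dataclass
class EnsembleReport:
    id: str
    values: dict[str, list[float]]            # metric -> per-run values
    mean: dict[str, float]
    variance: dict[str, float]                # population variance (divisor n)
    per_run_flags: list[FlagReport]
    consensus: dict[str, Flag] = field(default_factory=dict)
    consensus_overall: Flag = Flag.GREEN


def ensemble_profile(profiles: Sequence[TapProfile],
                     thresholds: ThresholdSet) -> EnsembleReport:
    """Aggregate repeat runs of the same antibody; consensus = worst run flag.

    An antibody is formally flagged for a property when any repeat raises
    that flag, so the consensus for each metric is the severity maximum
    over runs.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two repeat profiles")
    ids = {p.id for p in profiles}
    if len(ids) != 1:
        raise ValueError(f"profiles mix antibodies: {sorted(ids)}")
    metrics = [m for m in METRICS if m in thresholds.per_metric]
    values = {m: [p.metric(m) for p in profiles] for m in metrics}
    mean = {m: float(np.mean(v)) for m, v in values.items()}
    variance = {m: float(np.var(v, ddof=0)) for m, v in values.items()}
    per_run = [assign_flags(p, thresholds) for p in profiles]
    consensus = {m: max(r.per_metric[m] for r in per_run) for m in metrics}
    return EnsembleReport(
        id=profiles[0].id, values=values, mean=mean, variance=variance,
        per_run_flags=per_run, consensus=consensus,
        consensus_overall=max(consensus.values()) if consensus else Flag.GREEN,
    )
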