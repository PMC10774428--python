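"""Cohort-level reports: flag rates by group, CDR-length statistics,
gene-usage enrichment among green/red populations, inter-run agreement.

A cohort joins per-antibody profiles and flag reports to metadata (light
locus, V gene, arbitrary group labels) in one pandas table, which then
supports the κ-vs-λ style comparisons: what fraction of each light-chain
class amber-flags for a metric, how CDR lengths differ between groups,
and which germline genes are enriched among red-flagging antibodies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .flagging import Flag, FlagReport, ThresholdSet, assign_flags, ensemble_profile
from .patch_metrics import METRICS, TapProfile

GENE_RATIO_UNDEFINED = math.inf   # sentinel for red:green ratio with 0 green use


@dataclass
class CohortTable:
    """Per-antibody rows (metrics, flags, metadata) with unique ids."""
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame["id"].duplicated().any():
            dupes = self.frame.loc[self.frame["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate antibody ids: {dupes}")

    @property
    def n(self) -> int:
        return len(self.frame)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Metadata CSV with header id,light_locus,v_gene,group (extra columns kept)."""
    df = pd.read_csv(path, comment="#", dtype=str)
    if "id" not in df.columns:
        raise ValueError(f"{path}: metadata CSV needs an 'id' column")
    return df


def gene_family(gene: str) -> str:
    """Family label = text before the first hyphen (IGLV2-14*01 -> IGLV2)."""
    return str(gene).split("-")[0]


def build_cohort_table(
    profiles: Sequence[TapProfile],
    reports: Sequence[FlagReport],
    metadata: Optional[pd.DataFrame] = None,
) -> CohortTable:
    """Join profiles, flag reports and (optionally) a metadata table by id.

    Raises with the offending ids when the metadata join is incomplete.
    """
    by_id = {r.id: r for r in reports}
    rows = []
    for p in profiles:
        r = by_id.get(p.id)
        if r is None:
            raise ValueError(f"no flag report for antibody {p.id}")
        row = {"id": p.id}
        for m in METRICS:
            row[m] = p.metric(m)
            row[f"{m}_flag"] = r.per_metric[m].name.lower() if m in r.per_metric else None
        row["overall_flag"] = r.overall.name.lower()
        row["cdrh3_len"] = p.cdr_lengths.get("CDRH3")
        row["cdrl3_len"] = p.cdr_lengths.get("CDRL3")
        row.update({k: v for k, v in p.metadata.items() if k not in row})
        rows.append(row)
    frame = pd.DataFrame(rows)
    if metadata is not None:
        missing = set(frame["id"]) - set(metadata["id"])
        if missing:
            raise ValueError(f"metadata missing ids: {sorted(missing)}")
        meta_cols = [c for c in metadata.columns if c == "id" or c not in frame.columns]
        frame = frame.merge(metadata[meta_cols], on="id", how="left")
        if "v_gene" in frame.columns:
            frame["v_gene_family"] = frame["v_gene"].map(
                lambda g: gene_family(g) if pd.notna(g) else g)
    return CohortTable(frame=frame)


def flag_rate_by_group(
    table: CohortTable, metric: str, group_key: str,
    mode: str = "amber_only",
) -> dict[str, dict[str, float]]:
    """Per-group percentage of members amber-/red-flagged for ``metric``.

    mode "amber_only" counts exactly-amber members in amber%; mode
    "amber_or_worse" counts amber and red together.  Percentages are
    rounded to 2 decimals.
    """
    if group_key not in table.frame.columns:
        raise KeyError(f"unknown group key {group_key!r}")
    col = f"{metric}_flag"
    out: dict[str, dict[str, float]] = {}
    for group, sub in table.frame.groupby(group_key, dropna=False):
        n = len(sub)
        amber = (sub[col] == "amber").sum()
        red = (sub[col] == "red").sum()
        amber_count = amber + red if mode == "amber_or_worse" else amber
        out[str(group)] = {
            "amber_pct": round(100.0 * amber_count / n, 2),
            "red_pct": round(100.0 * red / n, 2),
            "n": n,
        }
    return out


def length_stats(
    table: CohortTable, region: str, group_key: str, ddof: int = 1,
) -> dict[str, tuple[float, float]]:
    """Mean and standard deviation of a length per group.

    region: "CDRH3", "CDRL3" or "L_tot".  ddof selects the sd convention
    (1 = sample, 0 = population).
    """
    col = {"CDRH3": "cdrh3_len", "CDRL3": "cdrl3_len", "L_tot": "l_tot"}.get(region)
    if col is None:
        raise ValueError(f"unknown region {region!r}")
    out: dict[str, tuple[float, float]] = {}
    for group, sub in table.frame.groupby(group_key, dropna=False):
        vals = sub[col].astype(float).to_numpy()
        out[str(group)] = (float(np.mean(vals)), float(np.std(vals, ddof=ddof)))
    return out


def gene_usage_enrichment(
    table: CohortTable, metric: str, gene_key: str = "v_gene_family",
) -> dict[str, dict[str, float]]:
    """Gene usage fractions among green- vs red-flagged antibodies.

    For each gene label: fraction of the green-flagged population using
    it, fraction of the red-flagged population using it, and the
    red:green usage ratio (``inf`` sentinel when the gene is unused among
    green-flagged antibodies, ``nan`` when unused in both).
    """
    col = f"{metric}_flag"
    green = table.frame[table.frame[col] == "green"]
    red = table.frame[table.frame[col] == "red"]
    genes = sorted(set(table.frame[gene_key].dropna()))
    out: dict[str, dict[str, float]] = {}
    for gene in genes:
        gf = (green[gene_key] == gene).sum() / len(green) if len(green) else 0.0
        rf = (red[gene_key] == gene).sum() / len(red) if len(red) else 0.0
        if gf > 0:
            ratio = rf / gf
        elif rf > 0:
            ratio = GENE_RATIO_UNDEFINED
        else:
            ratio = math.nan
        out[gene] = {"green_fraction": float(gf), "red_fraction": float(rf),
                     "ratio": float(ratio)}
    return out


def interrun_agreement(
    runs: Sequence[Sequence[float]],
    thresholds: ThresholdSet,
    metric: str,
    profiles_by_run: Optional[Sequence[Sequence[TapProfile]]] = None,
) -> dict:
    """Consistency of a metric across repeat runs aligned by antibody.

    Returns Pearson r for every run pair, the mean across antibodies of the
    per-antibody (population) variance, and — when full profiles are
    supplied — the percentage of antibodies whose flag from the first run
    alone differs from the any-run consensus.
    """
    arrays = [np.asarray(r, dtype=float) for r in runs]
    if len(arrays) < 2:
        raise ValueError("need at least two runs")
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("run vectors have mismatched lengths")
    pearson = {}
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            if np.ptp(arrays[i]) == 0 or np.ptp(arrays[j]) == 0:
                pearson[(i, j)] = math.nan      # undefined for constant runs
                continue
            r, _ = stats.pearsonr(arrays[i], arrays[j])
            pearson[(i, j)] = float(r)
    stacked = np.vstack(arrays)                      # runs x antibodies
    mean_variance = float(np.var(stacked, axis=0, ddof=0).mean())

    inconsistency_pct = None
    if profiles_by_run is not None:
        n_diff = 0
        per_ab = list(zip(*profiles_by_run))         # antibody -> tuple of runs
        for runs_of_ab in per_ab:
            single = assign_flags(runs_of_ab[0], thresholds).per_metric[metric]
            consensus = ensemble_profile(list(runs_of_ab), thresholds).consensus[metric]
            if single != consensus:
                n_diff += 1
        inconsistency_pct = round(100.0 * n_diff / len(per_ab), 2)
    return {"pearson_r": pearson, "mean_variance": mean_variance,
            "flag_inconsistency_pct": inconsistency_pct}
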