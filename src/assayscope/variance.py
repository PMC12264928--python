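"""Deviation between repeated measurements of the same protein-compound pair.

A replicate group is the set of pChEMBL values for one (target, compound)
key — optionally further keyed by assay cluster.  The group statistic is the
mean absolute deviation (MAD) about the group mean; groups of size 1 carry
no deviation information and are excluded.  The corpus-level statistic is
the group-size-weighted mean of per-group MADs.  Comparing the overall MAD
with the within-cluster MAD quantifies how much between-assay variance the
clustering explains.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import BioactivityTable
from .errors import DomainError


def mean_absolute_deviation(values: Sequence[float]) -> float:
    """Mean of |x_i - mean(values)|; requires at least 2 values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise DomainError("mean absolute deviation needs at least 2 values")
    if arr.min() == arr.max():  # constant group: exactly 0, no summation noise
        return 0.0
    return float(np.abs(arr - arr.mean()).mean())


def weighted_group_mad(
    table: BioactivityTable | pd.DataFrame,
    keys: Sequence[str] = ("target_accession", "compound_id"),
) -> tuple[float, pd.DataFrame]:
    """Group-size-weighted mean of per-group MADs.

    Returns the statistic and a per-group table (key columns, ``n``,
    ``mad``).  Groups of size 1 are excluded from numerator and weights.
    """
    frame = table.to_frame() if isinstance(table, BioactivityTable) else table
    groups = []
    for key, sub in frame.groupby(list(keys), sort=True):
        if len(sub) < 2:
            continue
        key = key if isinstance(key, tuple) else (key,)
        groups.append(dict(zip(keys, key), n=len(sub),
                           mad=mean_absolute_deviation(sub["pchembl"])))
    if not groups:
        raise DomainError("no replicate group of size >= 2")
    detail = pd.DataFrame(groups)
    stat = float(np.average(detail["mad"], weights=detail["n"]))
    return stat, detail


@dataclass
class DeviationReport:
    """Overall vs within-cluster replicate deviation, in pChEMBL units."""

    overall_weighted_mad: float
    within_cluster_weighted_mad: float | None     # mean over clustering repeats
    within_cluster_sd: float | None               # sd over clustering repeats
    per_repeat: list[float] = field(default_factory=list)
    per_family: dict = field(default_factory=dict)
    n_groups_overall: int = 0
    n_points: int = 0
    n_unjoinable: int = 0
    group_detail: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "overall_weighted_mad": self.overall_weighted_mad,
            "within_cluster_weighted_mad": self.within_cluster_weighted_mad,
            "within_cluster_sd": self.within_cluster_sd,
            "per_repeat": self.per_repeat,
            "per_family": self.per_family,
            "n_groups_overall": self.n_groups_overall,
            "n_points": self.n_points,
            "n_unjoinable": self.n_unjoinable,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def deviation_report(
    table: BioactivityTable,
    models: Sequence | None = None,
    family_labels: Mapping[str, str] | None = None,
    cluster_maps: Sequence[Mapping[str, int]] | None = None,
) -> DeviationReport:
    """Overall and within-cluster replicate deviation.

    The overall statistic groups measurements by (target, compound); the
    within-cluster statistic adds the assay-cluster label to the key and is
    reported as mean +/- sd over the clustering repeats.  Cluster labels come
    either from fitted ``models`` (TopicModelResults, joined on assay_id) or
    from explicit ``cluster_maps``.  Rows whose assay_id resolves to no
    cluster are excluded from the within-cluster statistic, with a count.
    ``family_labels`` (accession -> protein family) adds a per-family
    breakdown of the overall statistic.
    """
    frame = table.to_frame()
    overall, detail = weighted_group_mad(frame)

    per_family: dict[str, dict] = {}
    if family_labels is not None:
        fam = frame["target_accession"].map(dict(family_labels))
        for name, sub in frame.groupby(fam):
            try:
                fam_mad, fam_detail = weighted_group_mad(sub)
                per_family[str(name)] = {"weighted_mad": fam_mad,
                                         "n_groups": len(fam_detail)}
            except DomainError:
                per_family[str(name)] = {"weighted_mad": None, "n_groups": 0}

    maps: list[Mapping[str, int]] = []
    if cluster_maps is not None:
        maps = list(cluster_maps)
    elif models is not None:
        maps = [m.labels_by_assay() for m in models]

    per_repeat: list[float] = []
    n_unjoinable = 0
    for mapping in maps:
        joined = frame.copy()
        joined["cluster"] = joined["assay_id"].map(mapping)
        n_unjoinable = int(joined["cluster"].isna().sum())
        joined = joined.dropna(subset=["cluster"])
        try:
            stat, _ = weighted_group_mad(
                joined, keys=("target_accession", "compound_id", "cluster"))
            per_repeat.append(stat)
        except DomainError:
            warnings.warn("no within-cluster replicate group of size >= 2 in a repeat; "
                          "statistic undefined for that repeat")

    within = float(np.mean(per_repeat)) if per_repeat else None
    within_sd = float(np.std(per_repeat, ddof=1)) if len(per_repeat) > 1 else (
        0.0 if per_repeat else None)
    return DeviationReport(
        overall_weighted_mad=overall,
        within_cluster_weighted_mad=within, within_cluster_sd=within_sd,
        per_repeat=per_repeat, per_family=per_family,
        n_groups_overall=len(detail), n_points=len(frame),
        n_unjoinable=n_unjoinable, group_detail=detail)
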