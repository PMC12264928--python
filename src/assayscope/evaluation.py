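"""Scoring cluster assignments against categorical labels.

Purity and the min-max-scaled *normalized purity*
``(purity - p_modal) / (1 - p_modal)`` are implemented here directly
(normalized purity is 1 for label-pure clusterings and 0 when clustering is
no better than the modal-label baseline).  The entropy- and pair-based
metrics (homogeneity / completeness / V-measure, adjusted mutual
information, Fowlkes-Mallows) delegate to scikit-learn.

Records whose label is missing (None/NaN) are excluded per metric call, not
corpus-wide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .errors import DomainError


def _paired(assignment, categories) -> tuple[np.ndarray, np.ndarray]:
    a = pd.Series(list(assignment))
    c = pd.Series(list(categories))
    if len(a) != len(c):
        raise DomainError("assignment and categories differ in length")
    keep = a.notna() & c.notna()
    if not keep.any():
        raise DomainError("no records with both a cluster and a category")
    return a[keep].to_numpy(), c[keep].to_numpy()


def purity(assignment, categories) -> float:
    """Sum over clusters of the dominant category count, divided by N."""
    a, c = _paired(assignment, categories)
    table = pd.crosstab(a, c)
    return float(table.max(axis=1).sum() / table.values.sum())


def modal_prevalence(categories) -> float:
    c = pd.Series(list(categories)).dropna()
    if c.empty:
        raise DomainError("no labeled records")
    return float(c.value_counts(normalize=True).iloc[0])


def normalized_purity(assignment, categories) -> float:
    """(purity - p_modal) / (1 - p_modal); negative when the clustering is
    worse than always predicting the modal label."""
    a, c = _paired(assignment, categories)
    p_modal = modal_prevalence(c)
    if p_modal >= 1.0:
        raise DomainError("modal category prevalence is 1; normalized purity undefined")
    return (purity(a, c) - p_modal) / (1.0 - p_modal)


def homogeneity_completeness_v(assignment, categories) -> tuple[float, float, float]:
    """Entropy-based homogeneity, completeness and their harmonic mean
    (V-measure); conventions h=1 when H(C)=0 and c=1 when H(K)=0."""
    a, c = _paired(assignment, categories)
    h, comp, v = _skm.homogeneity_completeness_v_measure(c, a)
    return float(h), float(comp), float(v)


def adjusted_mutual_information(assignment, categories) -> float:
    """AMI with arithmetic-mean normalization and the permutation-model
    expectation; a zero denominator (both labelings trivial) is defined as 0."""
    a, c = _paired(assignment, categories)
    if len(pd.unique(a)) == 1 and len(pd.unique(c)) == 1:
        warnings.warn("both labelings are single-class; AMI denominator is 0, returning 0")
        return 0.0
    return float(_skm.adjusted_mutual_info_score(c, a, average_method="arithmetic"))


def fowlkes_mallows(assignment, categories) -> float:
    """Geometric mean of pairwise precision and recall: TP/sqrt((TP+FP)(TP+FN))."""
    a, c = _paired(assignment, categories)
    if len(a) < 2:
        raise DomainError("Fowlkes-Mallows needs at least 2 records")
    score = float(_skm.fowlkes_mallows_score(c, a))
    if score == 0.0:
        warnings.warn("Fowlkes-Mallows denominator or TP count is 0")
    return score


_METRICS = {
    "normalized_purity": normalized_purity,
    "purity": purity,
    "ami": adjusted_mutual_information,
    "fowlkes_mallows": fowlkes_mallows,
}


@dataclass
class EvaluationReport:
    """Long-form metric table: one row per metric x label set x split x repeat."""

    table: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        """Mean +/- sd over repeats for every metric/label-set/split cell."""
        grouped = self.table.groupby(["label_set", "split", "metric"], dropna=False)["value"]
        out = grouped.agg(mean="mean", sd="std", n_repeats="count").reset_index()
        out["sd"] = out["sd"].fillna(0.0)
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        self.aggregate().to_json(path, orient="records", indent=2)


def evaluate_against_labels(
    models: Sequence,
    label_sets: Mapping[str, Sequence],
    split_by: Sequence | None = None,
) -> EvaluationReport:
    """Score each fitted repeat against each label set, optionally per split
    level (e.g. binding vs functional assays scored separately).

    ``models`` are :class:`~assayscope.topics.TopicModelResults`; labels are
    aligned to corpus records.  Metrics on a split level where the label set
    is fully missing are omitted (logged as a warning).
    """
    rows = []
    for repeat, model in enumerate(models):
        assignment = model.record_labels
        split = pd.Series(list(split_by)) if split_by is not None else pd.Series(["all"] * len(assignment))
        for level in sorted(split.dropna().unique()):
            sel = (split == level).to_numpy()
            for name, labels in label_sets.items():
                lab = pd.Series(list(labels))[sel]
                if lab.notna().sum() == 0:
                    warnings.warn(f"label set {name!r} fully missing on split {level!r}; omitted")
                    continue
                assign_sel = pd.Series(assignment)[sel]
                values = {}
                for metric, fn in _METRICS.items():
                    try:
                        values[metric] = fn(assign_sel, lab)
                    except DomainError as exc:
                        warnings.warn(f"{metric} undefined for {name!r}/{level!r}: {exc}")
                try:
                    h, c, v = homogeneity_completeness_v(assign_sel, lab)
                    values.update(homogeneity=h, completeness=c, v_measure=v)
                except DomainError as exc:
                    warnings.warn(f"homogeneity undefined for {name!r}/{level!r}: {exc}")
                for metric, value in values.items():
                    rows.append({"label_set": name, "split": level, "repeat": repeat,
                                 "metric": metric, "value": value,
                                 "n": int(lab.notna().sum())})
    return EvaluationReport(table=pd.DataFrame(
        rows, columns=["label_set", "split", "repeat", "metric", "value", "n"]))
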