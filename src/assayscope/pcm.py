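"""Proteochemometric (PCM) regression with optional assay context.

A PCM model predicts pChEMBL bioactivity from a concatenated feature row:

* molecule block — 2048-bit extended-connectivity fingerprint, radius 3
  (ECFP6), computed on standardized structures;
* protein block — Hellberg z-scales (z1, z2, z3) per aligned position of a
  multiple sequence alignment, gaps encoded as zeros;
* optional assay block — any descriptor family (metadata fingerprint,
  bag-of-words, embedding) keyed by the row's assay context.

Measurements are aggregated to the median pChEMBL per key: per
(compound, target) for the context-free control, additionally per assay
cluster (multitask) or per unique description (assay-descriptor models).
Low-variance and high-correlation feature filters are computed on the
training split only.  The regressor is a gradient-boosted tree ensemble
with a masked squared loss (see :mod:`assayscope.boosting`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .boosting import (BoostingSpec, MaskedBoostingModel, masked_r2,
                       train_multitask, train_single_task)
from .corpus import AssayCorpus, BioactivityTable
from .errors import DomainError, FeaturizationError, ParameterError

# Hellberg z-scales (z1: hydrophilicity, z2: size/bulk, z3: polarity),
# one triple per standard amino acid.
Z_SCALES: dict[str, tuple[float, float, float]] = {
    "A": (0.07, -1.73, 0.09),
    "V": (-2.69, -2.53, -1.29),
    "L": (-4.19, -1.03, -0.98),
    "I": (-4.44, -1.68, -1.03),
    "P": (-1.22, 0.88, 2.23),
    "F": (-4.92, 1.30, 0.45),
    "W": (-4.75, 3.65, 0.85),
    "M": (-2.49, -0.27, -0.41),
    "K": (2.84, 1.41, -3.14),
    "R": (2.88, 2.52, -3.44),
    "H": (2.41, 1.74, 1.11),
    "G": (2.23, -5.36, 0.30),
    "S": (1.96, -1.63, 0.57),
    "T": (0.92, -2.09, -1.40),
    "C": (0.71, -0.97, 4.13),
    "Y": (-1.39, 2.32, 0.01),
    "N": (3.22, 1.45, 0.84),
    "Q": (2.18, 0.53, -1.14),
    "D": (3.64, 1.13, 2.36),
    "E": (3.08, 0.39, -0.07),
}


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class AggregatedDataset:
    """Median-aggregated modeling rows.

    ``mode`` is one of ``control`` (one row per compound-target pair),
    ``cluster`` (pair x assay cluster) or ``description`` (pair x unique
    description); ``context_id`` holds the cluster/description key.
    """

    frame: pd.DataFrame  # compound_id, smiles, target_accession, context_id, pchembl, n_measurements
    mode: str
    provenance: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)

    def to_multitask(self) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, list]:
        """Pivot a cluster-mode dataset into a sparse multitask target matrix.

        Returns (pair frame, Y, mask, task ids); masked entries of Y are NaN.
        """
        if self.mode != "cluster":
            raise ParameterError("multitask pivot requires a cluster-mode dataset")
        pivot = self.frame.pivot_table(index=["compound_id", "target_accession"],
                                       columns="context_id", values="pchembl",
                                       aggfunc="median", sort=True)
        smiles = self.frame.groupby(["compound_id", "target_accession"], sort=True)["smiles"].first()
        pairs = pivot.index.to_frame(index=False)
        pairs["smiles"] = smiles.loc[pivot.index].to_numpy()
        Y = pivot.to_numpy(dtype=float)
        mask = ~np.isnan(Y)
        return pairs, Y, mask, list(pivot.columns)


def aggregate_measurements(
    table: BioactivityTable,
    mode: str = "control",
    assignment: Mapping[str, int] | None = None,
    corpus: AssayCorpus | None = None,
) -> AggregatedDataset:
    """Aggregate measurements to median pChEMBL values.

    ``control`` needs nothing extra; ``cluster`` needs an assay_id -> cluster
    mapping (or a fitted TopicModelResults); ``description`` needs the assay
    corpus to resolve assay_id -> description.  Rows whose assay context
    cannot be resolved are dropped, with a count in the provenance.
    """
    frame = table.to_frame()
    n_dropped = 0
    if mode == "control":
        keys = ["compound_id", "target_accession"]
        frame = frame.assign(context_id=None)
    elif mode == "cluster":
        if assignment is None:
            raise ParameterError("cluster mode requires a cluster assignment")
        mapping = assignment.labels_by_assay() if hasattr(assignment, "labels_by_assay") else dict(assignment)
        frame = frame.assign(context_id=frame["assay_id"].map(mapping))
        n_dropped = int(frame["context_id"].isna().sum())
        frame = frame.dropna(subset=["context_id"])
        frame["context_id"] = frame["context_id"].astype(int)
        keys = ["compound_id", "target_accession", "context_id"]
    elif mode == "description":
        if corpus is None:
            raise ParameterError("description mode requires the assay corpus")
        desc = {r.assay_id: r.description.strip() for r in corpus.records}
        frame = frame.assign(context_id=frame["assay_id"].map(desc))
        n_dropped = int(frame["context_id"].isna().sum())
        frame = frame.dropna(subset=["context_id"])
        keys = ["compound_id", "target_accession", "context_id"]
    else:
        raise ParameterError(f"unknown aggregation mode {mode!r}")

    grouped = frame.groupby(keys, sort=True, dropna=False)
    agg = grouped.agg(pchembl=("pchembl", "median"), smiles=("smiles", "first"),
                      n_measurements=("pchembl", "size")).reset_index()
    if "context_id" not in agg.columns:
        agg["context_id"] = None
    agg = agg[["compound_id", "smiles", "target_accession", "context_id",
               "pchembl", "n_measurements"]]
    return AggregatedDataset(frame=agg, mode=mode, provenance=[{
        "step": "aggregate_measurements", "mode": mode,
        "n_input": len(table), "n_rows": len(agg), "n_unresolved_dropped": n_dropped}])


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def _standardize_mol(smiles: str):
    from rdkit import Chem
    from rdkit.Chem.MolStandardize import rdMolStandardize

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparsable SMILES: {smiles!r}")
    mol = rdMolStandardize.LargestFragmentChooser().choose(mol)
    mol = rdMolStandardize.Uncharger().uncharge(mol)
    return mol


def featurize_molecule(smiles: str, n_bits: int = 2048, radius: int = 3) -> np.ndarray:
    """ECFP6 bit vector of a standardized molecule (salt-stripped,
    charge-neutralized), folded to ``n_bits``."""
    from rdkit.Chem import rdFingerprintGenerator

    mol = _standardize_mol(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprintAsNumPy(mol).astype(np.uint8)


def featurize_molecules(smiles_list: Sequence[str]) -> tuple[np.ndarray, list[int]]:
    """Fingerprint a list of SMILES; returns (matrix, indices of failures).

    Failed rows are all-zero in the matrix and listed in the second return
    value (a row-level rejects report).
    """
    out = np.zeros((len(smiles_list), 2048), dtype=np.uint8)
    rejects: list[int] = []
    cache: dict[str, np.ndarray] = {}
    for i, smi in enumerate(smiles_list):
        if smi not in cache:
            try:
                cache[smi] = featurize_molecule(smi)
            except FeaturizationError:
                cache[smi] = None
        if cache[smi] is None:
            rejects.append(i)
        else:
            out[i] = cache[smi]
    return out, rejects


def read_alignment(path: str | Path) -> dict[str, str]:
    """Read a FASTA multiple sequence alignment into {accession: sequence}."""
    from Bio import SeqIO

    aln = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    lengths = {len(s) for s in aln.values()}
    if len(lengths) > 1:
        raise ParameterError("alignment sequences differ in length")
    return aln


def featurize_protein(alignment: Mapping[str, str] | str | Path, accession: str) -> np.ndarray:
    """z-scale descriptor of an aligned protein: 3 values per alignment
    column; gaps (and unknown residue codes, with a warning) are (0, 0, 0)."""
    aln = alignment if isinstance(alignment, Mapping) else read_alignment(alignment)
    if accession in aln:
        seq = aln[accession]
    else:
        hits = [k for k in aln if accession in k.split("|")]
        if not hits:
            raise ParameterError(f"accession {accession!r} not present in the alignment")
        seq = aln[hits[0]]
    vec = np.zeros(3 * len(seq))
    unknown = set()
    for i, res in enumerate(seq.upper()):
        if res in Z_SCALES:
            vec[3 * i: 3 * i + 3] = Z_SCALES[res]
        elif res not in "-.":
            unknown.add(res)
    if unknown:
        warnings.warn(f"unknown residue codes {sorted(unknown)} treated as gaps")
    return vec


@dataclass
class FeatureMatrix:
    """Concatenated descriptor blocks with recorded boundaries."""

    X: np.ndarray
    blocks: dict[str, tuple[int, int]]  # name -> (start, stop)
    feature_names: list[str] | None = None

    def __post_init__(self):
        stops = sorted(self.blocks.values())
        if stops and (stops[0][0] != 0 or stops[-1][1] != self.X.shape[1] or any(
                stops[i][1] != stops[i + 1][0] for i in range(len(stops) - 1))):
            raise ParameterError("block boundaries must partition the columns")

    def block_of(self, col: int) -> str:
        for name, (start, stop) in self.blocks.items():
            if start <= col < stop:
                return name
        raise IndexError(col)


def build_feature_matrix(
    dataset: AggregatedDataset,
    alignment: Mapping[str, str] | str | Path,
    assay_features: Mapping | None = None,
    assay_block_name: str = "assay",
) -> FeatureMatrix:
    """Assemble molecule ‖ protein (‖ assay) feature rows for a dataset.

    ``assay_features`` maps each row's ``context_id`` to its descriptor
    vector (e.g. an embedded description); required when the dataset has
    assay context and an assay block is wanted.
    """
    frame = dataset.frame
    mol_block, rejects = featurize_molecules(frame["smiles"].tolist())
    if rejects:
        raise FeaturizationError(f"{len(rejects)} rows have unparsable SMILES "
                                 f"(first rows: {rejects[:5]})")
    aln = alignment if isinstance(alignment, Mapping) else read_alignment(alignment)
    prot_cache = {acc: featurize_protein(aln, acc)
                  for acc in frame["target_accession"].unique()}
    prot_block = np.vstack([prot_cache[a] for a in frame["target_accession"]])

    parts = [mol_block.astype(float), prot_block]
    blocks = {"molecule": (0, mol_block.shape[1]),
              "protein": (mol_block.shape[1], mol_block.shape[1] + prot_block.shape[1])}
    if assay_features is not None:
        missing = [c for c in frame["context_id"].unique() if c not in assay_features]
        if missing:
            raise ParameterError(f"assay context ids without features: {missing[:5]}")
        assay_block = np.vstack([np.asarray(assay_features[c], dtype=float)
                                 for c in frame["context_id"]])
        start = blocks["protein"][1]
        blocks[assay_block_name] = (start, start + assay_block.shape[1])
        parts.append(assay_block)
    X = np.hstack(parts)
    return FeatureMatrix(X=X, blocks=blocks)


# ---------------------------------------------------------------------------
# feature filters and splits
# ---------------------------------------------------------------------------

def apply_feature_filters(
    train_features: np.ndarray | FeatureMatrix,
    corr_threshold: float = 0.8,
    var_threshold: float = 0.05,
) -> np.ndarray:
    """Boolean column mask: drop low-variance (< ``var_threshold``) columns,
    then for every remaining pair with |Pearson r| > ``corr_threshold`` drop
    the later column.  Computed on training rows only; apply the returned
    mask to both splits."""
    X = train_features.X if isinstance(train_features, FeatureMatrix) else np.asarray(train_features, dtype=float)
    if X.shape[0] < 2:
        raise ParameterError("feature filters need at least 2 training rows")
    mask = np.var(X, axis=0) >= var_threshold
    surviving = np.nonzero(mask)[0]
    if surviving.size:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X[:, surviving], rowvar=False)
        corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
        keep: list[int] = []
        for j in range(surviving.size):
            if any(abs(corr[j, i]) > corr_threshold for i in keep):
                mask[surviving[j]] = False
            else:
                keep.append(j)
    if not mask.any():
        raise ParameterError("feature filters removed every column")
    return mask


@dataclass
class SplitSpec:
    """Train/test partition of dataset rows."""

    method: str
    test_fraction: float
    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self):
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        overlap = np.intersect1d(self.train_idx, self.test_idx)
        if overlap.size:
            raise ParameterError("train and test indices overlap")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "method": self.method, "test_fraction": self.test_fraction,
            "seed": self.seed, "train_idx": self.train_idx.tolist(),
            "test_idx": self.test_idx.tolist()}, indent=2))


def murcko_scaffold(smiles: str) -> str:
    """Bemis-Murcko scaffold SMILES (empty string for acyclic molecules)."""
    from rdkit.Chem.Scaffolds import MurckoScaffold

    return MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles)


def split_dataset(
    dataset: AggregatedDataset | pd.DataFrame,
    method: str = "random",
    test_fraction: float = 0.1,
    seed: int = 0,
) -> SplitSpec:
    """90/10-style train/test split.

    ``random`` samples rows uniformly; ``scaffold`` assigns whole
    Bemis-Murcko scaffold groups (computed at the molecule level) to the
    test side, in seeded order, until at least ``test_fraction`` of rows is
    reached — no scaffold ever appears on both sides.
    """
    frame = dataset.frame if isinstance(dataset, AggregatedDataset) else dataset
    n = len(frame)
    if n < 10:
        raise ParameterError("need at least 10 rows to split")
    rng = np.random.default_rng(seed)
    if method == "random":
        perm = rng.permutation(n)
        n_test = max(1, int(round(test_fraction * n)))
        return SplitSpec(method, test_fraction, seed, np.sort(perm[n_test:]),
                         np.sort(perm[:n_test]))
    if method != "scaffold":
        raise ParameterError(f"unknown split method {method!r}")

    scaffolds = frame["smiles"].map(murcko_scaffold)
    groups = {s: np.nonzero((scaffolds == s).to_numpy())[0] for s in scaffolds.unique()}
    if len(groups) < 2:
        raise ParameterError("a single scaffold covers all molecules; scaffold split impossible")
    order = list(groups)
    rng.shuffle(order)
    # smallest groups fill the test side first (seeded order among equal
    # sizes), so the realized fraction lands close to the target
    order.sort(key=lambda s: len(groups[s]))
    target = test_fraction * n
    test_rows: list[int] = []
    for s in order:
        if len(test_rows) >= target:
            break
        test_rows.extend(groups[s].tolist())
    test_idx = np.sort(np.asarray(test_rows, dtype=int))
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    if train_idx.size == 0:
        raise ParameterError("scaffold split left no training rows")
    return SplitSpec(method, test_fraction, seed, train_idx, test_idx)


# ---------------------------------------------------------------------------
# evaluation and importance
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """R², RMSE and Kendall's tau-b on a test set (weighted across tasks for
    multitask models)."""

    r2: float
    rmse: float
    kendall_tau: float
    n: int
    per_task: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {"r2": self.r2, "rmse": self.rmse, "kendall_tau": self.kendall_tau, "n": self.n}
        if self.per_task is not None:
            d["per_task"] = self.per_task.to_dict(orient="records")
        return d


def _scalar_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    sst = np.sum((y_true - y_true.mean()) ** 2)
    r2 = 1.0 - float(np.sum((y_true - y_pred) ** 2)) / sst if sst > 0 else float("nan")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    tau = kendalltau(y_true, y_pred, variant="b").statistic
    return r2, rmse, float(tau)


def evaluate_model(
    model: MaskedBoostingModel,
    features_test: np.ndarray,
    targets_test: np.ndarray,
    mask: np.ndarray | None = None,
    task_ids: Sequence | None = None,
) -> MetricsReport:
    """Test-set metrics.  For multitask targets the metrics are computed per
    task on its observed entries and combined as the task-size-weighted
    average; tasks with fewer than 2 test points are excluded (logged)."""
    X = np.asarray(features_test, dtype=float)
    Y = np.asarray(targets_test, dtype=float)
    pred = model.predict(X)
    if Y.ndim == 1:
        r2, rmse, tau = _scalar_metrics(Y, pred[:, 0])
        return MetricsReport(r2=r2, rmse=rmse, kendall_tau=tau, n=len(Y))

    mask = ~np.isnan(Y) if mask is None else np.asarray(mask, dtype=bool)
    rows = []
    for t in range(Y.shape[1]):
        obs = mask[:, t]
        if obs.sum() < 2:
            warnings.warn(f"task {t} has fewer than 2 test points; excluded from the "
                          "weighted average")
            continue
        r2, rmse, tau = _scalar_metrics(Y[obs, t], pred[obs, t])
        rows.append({"task": task_ids[t] if task_ids is not None else t,
                     "r2": r2, "rmse": rmse, "kendall_tau": tau, "n": int(obs.sum())})
    if not rows:
        raise DomainError("no task has enough test points to evaluate")
    per_task = pd.DataFrame(rows)
    w = per_task["n"].to_numpy(dtype=float)
    return MetricsReport(
        r2=float(np.average(per_task["r2"], weights=w)),
        rmse=float(np.average(per_task["rmse"], weights=w)),
        kendall_tau=float(np.average(per_task["kendall_tau"], weights=w)),
        n=int(w.sum()), per_task=per_task)


def aggregate_metrics(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Mean +/- sd over repeated fits (rows: r2, rmse, kendall_tau)."""
    frame = pd.DataFrame([{"r2": r.r2, "rmse": r.rmse, "kendall_tau": r.kendall_tau}
                          for r in reports])
    out = frame.agg(["mean", "std"]).T.rename(columns={"std": "sd"})
    out["sd"] = out["sd"].fillna(0.0)
    return out


def feature_importance(
    model: MaskedBoostingModel,
    features: FeatureMatrix | Mapping[str, tuple[int, int]],
    top_k: int = 30,
) -> tuple[pd.DataFrame, pd.Series]:
    """Ranked per-feature squared-error-reduction gains with block
    attribution, plus the block proportions over the top ``top_k`` features
    (proportions sum to 1)."""
    blocks = features.blocks if isinstance(features, FeatureMatrix) else dict(features)
    gains = model.feature_importances_

    def block_of(col: int) -> str:
        for name, (start, stop) in blocks.items():
            if start <= col < stop:
                return name
        return "unassigned"

    ranked = pd.DataFrame({"feature": np.arange(len(gains)), "gain": gains})
    ranked["block"] = ranked["feature"].map(block_of)
    ranked = ranked.sort_values(["gain", "feature"], ascending=[False, True],
                                ignore_index=True)
    top = ranked.head(top_k)
    counts = top["block"].value_counts()
    proportions = counts / counts.sum() if counts.sum() else counts
    return ranked, proportions


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class PCMModel:
    """Assay-aware PCM regression model.

    Holds the feature matrix and targets; :meth:`fit` applies the
    train-only feature filters, trains the boosting ensemble, and returns a
    :class:`PCMResults` with test metrics and feature importances.

    Parameters
    ----------
    features : FeatureMatrix
    y : 1-D targets (single task) — or —
    Y, mask : 2-D targets with observation mask (multitask)
    spec : BoostingSpec
    """

    def __init__(self, features: FeatureMatrix, y: np.ndarray | None = None,
                 Y: np.ndarray | None = None, mask: np.ndarray | None = None,
                 spec: BoostingSpec | None = None, task_ids: Sequence | None = None):
        if (y is None) == (Y is None):
            raise ParameterError("provide exactly one of y (single task) or Y (multitask)")
        self.features = features
        self.y = None if y is None else np.asarray(y, dtype=float)
        self.Y = None if Y is None else np.asarray(Y, dtype=float)
        if self.Y is not None and mask is None:
            mask = ~np.isnan(self.Y)
        self.mask = mask
        self.spec = spec or BoostingSpec()
        self.task_ids = list(task_ids) if task_ids is not None else None
        n = features.X.shape[0]
        targets_n = len(self.y) if self.y is not None else self.Y.shape[0]
        if n != targets_n:
            raise ParameterError("features and targets are not row-aligned")

    def fit(self, split: SplitSpec, seed: int = 0) -> "PCMResults":
        X = self.features.X
        col_mask = apply_feature_filters(X[split.train_idx])
        X_train, X_test = X[split.train_idx][:, col_mask], X[split.test_idx][:, col_mask]
        if self.y is not None:
            handle = train_single_task(X_train, self.y[split.train_idx], self.spec, seed=seed)
            metrics = evaluate_model(handle, X_test, self.y[split.test_idx])
        else:
            handle = train_multitask(X_train, self.Y[split.train_idx],
                                     self.mask[split.train_idx], self.spec, seed=seed)
            metrics = evaluate_model(handle, X_test, self.Y[split.test_idx],
                                     self.mask[split.test_idx], task_ids=self.task_ids)
        return PCMResults(model=self, handle=handle, split=split, seed=seed,
                          column_mask=col_mask, metrics=metrics)

    def fit_repeats(self, dataset, method: str = "random", n_repeats: int = 3,
                    base_seed: int = 0,
                    test_fraction: float = 0.1) -> list["PCMResults"]:
        """Repeat split+fit with distinct seeds (metrics are then reported as
        mean +/- sd over repeats); ``dataset`` supplies the SMILES for
        scaffold splits."""
        results = []
        for i in range(n_repeats):
            seed = base_seed + i
            split = split_dataset(dataset, method=method,
                                  test_fraction=test_fraction, seed=seed)
            results.append(self.fit(split, seed=seed))
        return results


@dataclass
class PCMResults:
    """Fitted PCM model: realized ensemble, split, metrics, importances."""

    model: PCMModel
    handle: MaskedBoostingModel
    split: SplitSpec
    seed: int
    column_mask: np.ndarray
    metrics: MetricsReport

    @property
    def n_trees(self) -> int:
        return self.handle.n_trees_

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        """Predict for new rows built with the same feature layout."""
        X_new = np.asarray(X_new, dtype=float)
        return self.handle.predict(X_new[:, self.column_mask])

    def feature_importance(self, top_k: int = 30) -> tuple[pd.DataFrame, pd.Series]:
        """Importances mapped back to the original (unfiltered) columns."""
        orig_cols = np.nonzero(self.column_mask)[0]
        gains = self.handle.feature_importances_
        blocks = self.model.features.blocks

        def block_of(col: int) -> str:
            for name, (start, stop) in blocks.items():
                if start <= col < stop:
                    return name
            return "unassigned"

        ranked = pd.DataFrame({"feature": orig_cols, "gain": gains})
        ranked["block"] = ranked["feature"].map(block_of)
        ranked = ranked.sort_values(["gain", "feature"], ascending=[False, True],
                                    ignore_index=True)
        top = ranked.head(top_k)
        counts = top["block"].value_counts()
        return ranked, counts / counts.sum() if counts.sum() else counts

    def summary(self) -> str:
        lines = [
            "PCM boosting results",
            "====================",
            f"tasks:            {1 if self.model.y is not None else self.model.Y.shape[1]}",
            f"split:            {self.split.method} "
            f"(test fraction {self.split.test_fraction}, seed {self.split.seed})",
            f"features kept:    {int(self.column_mask.sum())} / {len(self.column_mask)}",
            f"realized trees:   {self.n_trees} (max {self.model.spec.max_trees})",
            f"test R^2:         {self.metrics.r2:.3f}",
            f"test RMSE:        {self.metrics.rmse:.3f}",
            f"test Kendall tau: {self.metrics.kendall_tau:.3f}",
            f"test n:           {self.metrics.n}",
        ]
        _, proportions = self.feature_importance()
        lines.append("top-30 importance by block: "
                     + ", ".join(f"{b}={p:.2f}" for b, p in proportions.items()))
        return "\n".join(lines)

    def save_metadata(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "spec": self.model.spec.__dict__, "seed": self.seed,
            "realized_trees": self.n_trees,
            "feature_mask": self.column_mask.astype(int).tolist(),
            "metrics": self.metrics.to_dict(),
            "split": {"method": self.split.method,
                      "test_fraction": self.split.test_fraction,
                      "seed": self.split.seed}}, indent=2))
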