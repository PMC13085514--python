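"""Molecular featurization, min-max scaling, variance/correlation feature
selection, and Tanimoto k-NN distances to the training set.

Available feature sets: MACCS keys (166 substructure bits), Avalon
fingerprints, RDKit path-based fingerprints (2048-bit), built-in 2-D
descriptors, and user-supplied precomputed descriptor tables (CSV keyed
by compound id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .core_data import CompoundRecord

logger = logging.getLogger(__name__)

KNOWN_FEATURE_SETS = ("maccs", "avalon", "path_fp_2048", "descriptors_2d", "external_table")

AVALON_N_BITS = 512
PATH_FP_N_BITS = 2048
MORGAN_RADIUS = 2
MORGAN_N_BITS = 2048


class AlignmentError(ValueError):
    """Raised when compound ids cannot be aligned across tables."""


class ScalerStateError(RuntimeError):
    """Raised when applying a scaler that has not been fitted."""


class EmptySelectionError(ValueError):
    """Raised when feature selection removes every feature."""


@dataclass(frozen=True)
class FeatureSetSpec:
    """Which feature sets to compute; ``external_table`` needs a path."""

    names: tuple[str, ...] = ("maccs",)
    external_path: Optional[str] = None

    def __post_init__(self):
        if not self.names:
            raise ValueError("at least one feature set is required")
        unknown = set(self.names) - set(KNOWN_FEATURE_SETS)
        if unknown:
            raise ValueError(f"unknown feature sets: {sorted(unknown)}")
        if "external_table" in self.names and self.external_path is None:
            raise ValueError("external_table requires external_path")


@dataclass
class FeatureMatrix:
    """Dense compound x feature matrix with per-feature provenance.

    ``scaler_state`` holds the per-feature (min, max) fitted on training
    compounds; it is ``None`` until :func:`fit_scale` has been applied.
    """

    compound_ids: list[str]
    feature_names: list[str]  # tagged "<source>:<name>"
    values: np.ndarray
    scaler_state: Optional[np.ndarray] = None  # shape (2, n_features): min, max

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_ids), len(self.feature_names)):
            raise ValueError("values shape does not match ids/names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            compound_ids=list(self.compound_ids),
            feature_names=list(self.feature_names),
            values=self.values.copy(),
            scaler_state=None if self.scaler_state is None else self.scaler_state.copy(),
        )


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    return mol


def _maccs_block(mols) -> tuple[list[str], np.ndarray]:
    # RDKit MACCS bit vectors have 167 positions; bit 0 is unused padding.
    out = np.zeros((len(mols), 166))
    for i, m in enumerate(mols):
        bv = MACCSkeys.GenMACCSKeys(m)
        arr = np.zeros((167,), dtype=np.int8)
        DataStructs.ConvertToNumpyArray(bv, arr)
        out[i] = arr[1:]
    names = [f"maccs:key_{k}" for k in range(1, 167)]
    return names, out


def _avalon_block(mols) -> tuple[list[str], np.ndarray]:
    out = np.zeros((len(mols), AVALON_N_BITS))
    for i, m in enumerate(mols):
        bv = pyAvalonTools.GetAvalonFP(m, nBits=AVALON_N_BITS)
        arr = np.zeros((AVALON_N_BITS,), dtype=np.int8)
        DataStructs.ConvertToNumpyArray(bv, arr)
        out[i] = arr
    names = [f"avalon:bit_{k}" for k in range(AVALON_N_BITS)]
    return names, out


def _path_fp_block(mols) -> tuple[list[str], np.ndarray]:
    out = np.zeros((len(mols), PATH_FP_N_BITS))
    for i, m in enumerate(mols):
        bv = Chem.RDKFingerprint(m, fpSize=PATH_FP_N_BITS)
        arr = np.zeros((PATH_FP_N_BITS,), dtype=np.int8)
        DataStructs.ConvertToNumpyArray(bv, arr)
        out[i] = arr
    names = [f"path_fp_2048:bit_{k}" for k in range(PATH_FP_N_BITS)]
    return names, out


def _descriptor_block(mols) -> tuple[list[str], np.ndarray]:
    desc_names = [name for name, _ in Descriptors.descList]
    out = np.full((len(mols), len(desc_names)), np.nan)
    for i, m in enumerate(mols):
        vals = Descriptors.CalcMolDescriptors(m, missingVal=np.nan)
        out[i] = [vals[name] for name in desc_names]
    return [f"descriptors_2d:{n}" for n in desc_names], out


def _external_block(records, path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    id_col = df.columns[0]
    df = df.set_index(df[id_col].astype(str)).drop(columns=[id_col])
    missing = [r.compound_id for r in records if r.compound_id not in df.index]
    if missing:
        raise AlignmentError(
            f"external table {path} is missing compound ids: {missing}"
        )
    values = df.loc[[r.compound_id for r in records]].to_numpy(dtype=float)
    names = [f"external_table:{c}" for c in df.columns]
    return names, values


def featurize(records: Sequence[CompoundRecord], spec: FeatureSetSpec) -> FeatureMatrix:
    """Compute the (unscaled) feature matrix for *records*.

    Deterministic per SMILES. Columns that are non-finite for any compound
    are dropped with a log entry, so the returned matrix has no missing
    values.
    """
    mols = [_mol(r.smiles) for r in records]
    blocks: list[tuple[list[str], np.ndarray]] = []
    for name in spec.names:
        if name == "maccs":
            blocks.append(_maccs_block(mols))
        elif name == "avalon":
            blocks.append(_avalon_block(mols))
        elif name == "path_fp_2048":
            blocks.append(_path_fp_block(mols))
        elif name == "descriptors_2d":
            blocks.append(_descriptor_block(mols))
        elif name == "external_table":
            blocks.append(_external_block(records, spec.external_path))

    names = [n for block_names, _ in blocks for n in block_names]
    values = np.hstack([vals for _, vals in blocks]) if blocks else np.empty((len(records), 0))

    finite = np.isfinite(values).all(axis=0)
    if not finite.all():
        dropped = [n for n, ok in zip(names, finite) if not ok]
        logger.info("dropping %d incomputable feature columns: %s",
                    len(dropped), dropped[:10])
        values = values[:, finite]
        names = [n for n, ok in zip(names, finite) if ok]

    return FeatureMatrix(
        compound_ids=[r.compound_id for r in records],
        feature_names=names,
        values=values,
    )


def fit_scale(matrix: FeatureMatrix) -> FeatureMatrix:
    """Min-max scale, fitting (min, max) on this (training) matrix.

    Fitted columns span [0, 1] on the training rows; constant columns map
    to 0 by convention.
    """
    mins = matrix.values.min(axis=0)
    maxs = matrix.values.max(axis=0)
    state = np.vstack([mins, maxs])
    out = matrix.copy()
    out.values = _transform(matrix.values, state)
    out.scaler_state = state
    return out


def apply_scale(matrix: FeatureMatrix, scaler_state: np.ndarray) -> FeatureMatrix:
    """Apply a previously fitted min-max scaler. Values outside the
    training range are NOT clipped, so out-of-range inputs land outside
    [0, 1] — deliberately, as an extrapolation signal."""
    if scaler_state is None:
        raise ScalerStateError("scaler has not been fitted (scaler_state is None)")
    if scaler_state.shape[1] != matrix.values.shape[1]:
        raise AlignmentError(
            f"scaler fitted for {scaler_state.shape[1]} features, "
            f"matrix has {matrix.values.shape[1]}"
        )
    out = matrix.copy()
    out.values = _transform(matrix.values, scaler_state)
    out.scaler_state = scaler_state.copy()
    return out


def _transform(values: np.ndarray, state: np.ndarray) -> np.ndarray:
    mins, maxs = state
    span = maxs - mins
    safe = np.where(span == 0, 1.0, span)
    scaled = (values - mins) / safe
    return np.where(span == 0, 0.0, scaled)


@dataclass
class SelectionReport:
    """Per-feature record of the selection pipeline's decisions."""

    table: pd.DataFrame  # columns: feature, source, variance, cluster_id, retained

    @property
    def retained(self) -> list[str]:
        return self.table.loc[self.table["retained"], "feature"].tolist()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def select_features(
    matrix: FeatureMatrix,
    variance_threshold: float = 0.02,
    corr_cut: float = 0.99,
) -> tuple[FeatureMatrix, SelectionReport]:
    """Variance-filter then cluster-deduplicate features.

    1. Drop features with variance < *variance_threshold* (population
       variance on the given, already scaled, rows).
    2. Complete-linkage hierarchical clustering on the distance
       ``1 - |Spearman r|``; the tree is cut at ``1 - corr_cut`` so that
       features with ``|r| >= corr_cut`` are clustered together.
    3. Keep one representative per cluster: the member with the highest
       variance, ties broken by first column order.

    Returns the reduced matrix plus a report of every feature's fate.
    """
    if matrix.shape[0] < 2:
        raise ValueError("feature selection needs at least 2 rows")
    values = matrix.values
    variances = values.var(axis=0)

    n_feat = len(matrix.feature_names)
    cluster_ids = np.full(n_feat, -1)
    retained = np.zeros(n_feat, dtype=bool)

    var_ok = variances >= variance_threshold
    kept_idx = np.flatnonzero(var_ok)
    if kept_idx.size == 0:
        raise EmptySelectionError(
            "variance filter removed all features; lower variance_threshold"
        )

    if kept_idx.size == 1:
        cluster_ids[kept_idx] = 1
        retained[kept_idx] = True
    else:
        corr = spearmanr(values[:, kept_idx]).statistic
        if np.ndim(corr) == 0:  # spearmanr collapses the 2-column case
            corr = np.array([[1.0, float(corr)], [float(corr), 1.0]])
        corr = np.nan_to_num(corr, nan=0.0)
        dist = 1.0 - np.abs(corr)
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        labels = fcluster(
            linkage(squareform(dist, checks=False), method="complete"),
            t=1.0 - corr_cut,
            criterion="distance",
        )
        cluster_ids[kept_idx] = labels
        for lab in np.unique(labels):
            members = kept_idx[labels == lab]
            best = members[np.argmax(variances[members])]
            retained[best] = True

    report = SelectionReport(
        pd.DataFrame(
            {
                "feature": matrix.feature_names,
                "source": [n.split(":", 1)[0] for n in matrix.feature_names],
                "variance": variances,
                "cluster_id": cluster_ids,
                "retained": retained,
            }
        )
    )
    out = FeatureMatrix(
        compound_ids=list(matrix.compound_ids),
        feature_names=[n for n, r in zip(matrix.feature_names, retained) if r],
        values=values[:, retained],
        scaler_state=None
        if matrix.scaler_state is None
        else matrix.scaler_state[:, retained],
    )
    return out, report


def subset_columns(matrix: FeatureMatrix, feature_names: Sequence[str]) -> FeatureMatrix:
    """Project a matrix onto a previously selected feature list."""
    index = {n: i for i, n in enumerate(matrix.feature_names)}
    missing = [n for n in feature_names if n not in index]
    if missing:
        raise AlignmentError(f"matrix lacks selected features: {missing[:10]}")
    cols = [index[n] for n in feature_names]
    return FeatureMatrix(
        compound_ids=list(matrix.compound_ids),
        feature_names=list(feature_names),
        values=matrix.values[:, cols],
        scaler_state=None
        if matrix.scaler_state is None
        else matrix.scaler_state[:, cols],
    )


def _morgan_fps(smiles_list: Sequence[str]):
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=MORGAN_RADIUS, fpSize=MORGAN_N_BITS
    )
    return [gen.GetFingerprint(_mol(s)) for s in smiles_list]


def tanimoto_knn_distance(
    query_smiles: Sequence[str], train_smiles: Sequence[str], k: int = 5
) -> np.ndarray:
    """Distance of each query to the training chemical space.

    ``d = 1 - mean(k largest Tanimoto similarities)`` on Morgan
    fingerprints (radius 2, 2048 bits). Tanimoto between two all-zero
    fingerprints is defined as 0, so d stays in [0, 1].
    """
    if not train_smiles:
        raise ValueError("training set must be non-empty")
    if k > len(train_smiles):
        raise ValueError(f"k={k} exceeds training-set size {len(train_smiles)}")
    train_fps = _morgan_fps(train_smiles)
    query_fps = _morgan_fps(query_smiles)
    out = np.empty(len(query_fps))
    for i, fp in enumerate(query_fps):
        sims = np.array(DataStructs.BulkTanimotoSimilarity(fp, train_fps))
        top = np.sort(sims)[-k:]
        out[i] = 1.0 - top.mean()
    return out
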