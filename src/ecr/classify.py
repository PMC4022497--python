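"""Two-round standardized-PCA + K-means(k=2) interface classifier.

Training works on a labelled matrix of seven interface features (the
coefficient of determination of the energy-centrality fit is dropped: it
contributes little variance).  Round 1 z-scores the features, performs PCA
on their correlation matrix and K-means(k=2) on the (PC1, PC2) scores; the
cluster whose centroid corresponds to larger sum_ddg + n_hot + avg_ddg is
designated the FLIP cluster and its members are predicted FLIP.  Round 2
repeats the whole procedure (fresh standardization, PCA and clustering) on
the remaining interfaces; its FLIP-cluster members are predicted FLIP and
everything else FunC.

New interfaces are *projected*: standardized with the training means/sds,
mapped through the training eigenvectors, and assigned to the nearest
training centroid in (PC1, PC2), round 1 then round 2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .exceptions import DegenerateDataError, FeatureMismatchError, InputError
from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

#: The seven features retained for classification (r2_ddg dropped).
CLASSIFIER_FEATURES = [n for n in FEATURE_NAMES if n != "r2_ddg"]

FLIP = "FLIP"
FUNC = "FunC"

DEFAULT_RESTARTS = 50
DEFAULT_SEED = 1


@dataclass
class FeatureMatrix:
    """An ordered block of interfaces × features, optionally labelled."""

    interface_ids: list[str]
    values: np.ndarray  # (n_interfaces, n_features)
    feature_names: list[str]
    labels: list[str] | None = None  # FLIP / FunC per row
    subcategories: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise InputError("feature matrix shape does not match feature names")
        if len(self.interface_ids) != self.values.shape[0]:
            raise InputError("row count does not match interface ids")
        if not np.all(np.isfinite(self.values)):
            raise InputError("feature matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            interface_ids=[self.interface_ids[i] for i in idx],
            values=self.values[idx],
            feature_names=list(self.feature_names),
            labels=None if self.labels is None else [self.labels[i] for i in idx],
            subcategories=(
                None
                if self.subcategories is None
                else [self.subcategories[i] for i in idx]
            ),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "id", self.interface_ids)
        if self.labels is not None:
            df["category"] = self.labels
        if self.subcategories is not None:
            df["subcategory"] = self.subcategories
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureMatrix":
        meta = [c for c in ("id", "category", "subcategory") if c in df.columns]
        feature_names = [c for c in df.columns if c not in meta]
        return cls(
            interface_ids=(
                df["id"].astype(str).tolist() if "id" in df else [str(i) for i in df.index]
            ),
            values=df[feature_names].to_numpy(dtype=float),
            feature_names=feature_names,
            labels=df["category"].tolist() if "category" in df else None,
            subcategories=df["subcategory"].tolist() if "subcategory" in df else None,
        )


@dataclass
class PCAModel:
    """Standardization parameters plus eigenstructure of one PCA round."""

    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray  # sample (n-1) standard deviations
    eigenvectors: np.ndarray  # columns, orthonormal
    eigenvalues: np.ndarray  # descending

    @property
    def variance_fraction(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def transform(self, values: np.ndarray) -> np.ndarray:
        z = (values - self.means) / self.sds
        return z @ self.eigenvectors


@dataclass
class ClusteringResult:
    assignments: np.ndarray  # cluster index 0/1 per row
    centroids: np.ndarray  # (2, 2) in (PC1, PC2)
    inertia: float
    degenerate: bool = False  # an empty cluster was produced


@dataclass
class RoundModel:
    pca: PCAModel
    clustering: ClusteringResult
    flip_cluster: int


@dataclass
class ClassificationModel:
    round1: RoundModel
    round2: RoundModel | None
    predictions: list[str]  # per training row, order of the training matrix
    round1_member_idx: np.ndarray  # training rows assigned FLIP in round 1
    round2_input_idx: np.ndarray  # training rows passed to round 2
    seed: int
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# PCA


def standardize_and_pca(matrix: FeatureMatrix) -> tuple[PCAModel, np.ndarray]:
    """Correlation-matrix PCA: z-score each feature, eigendecompose, project.

    Returns the fitted :class:`PCAModel` and the score matrix (rows ×
    components).  Eigenvector signs are fixed so the largest-magnitude
    loading of each component is positive (pure convention; assignments are
    invariant to it).
    """
    if matrix.n < 3:
        raise DegenerateDataError("PCA needs at least 3 rows")
    means = matrix.values.mean(axis=0)
    sds = matrix.values.std(axis=0, ddof=1)
    zero_var = np.flatnonzero(sds == 0)
    if zero_var.size:
        names = [matrix.feature_names[i] for i in zero_var]
        raise DegenerateDataError(f"zero-variance feature(s): {names}")
    z = (matrix.values - means) / sds
    corr = (z.T @ z) / (matrix.n - 1)
    eigenvalues, eigenvectors = np.linalg.eigh(corr)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    eigenvectors = eigenvectors[:, order]
    for j in range(eigenvectors.shape[1]):
        col = eigenvectors[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            eigenvectors[:, j] = -col
    model = PCAModel(
        feature_names=list(matrix.feature_names),
        means=means,
        sds=sds,
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
    )
    return model, z @ eigenvectors


def select_features(matrix: FeatureMatrix) -> FeatureMatrix:
    """Drop r2_ddg, keeping the seven classification features.

    Idempotent on already-seven-feature input.  On matrices large enough to
    standardize, warns when PC1+PC2 capture ≤80% of the variance — the
    retained feature set is expected to concentrate variance in two
    components.
    """
    if "r2_ddg" not in matrix.feature_names:
        return matrix
    keep = [i for i, n in enumerate(matrix.feature_names) if n != "r2_ddg"]
    out = FeatureMatrix(
        interface_ids=list(matrix.interface_ids),
        values=matrix.values[:, keep],
        feature_names=[matrix.feature_names[i] for i in keep],
        labels=matrix.labels,
        subcategories=matrix.subcategories,
    )
    if out.n >= 3:
        try:
            model, _ = standardize_and_pca(out)
        except DegenerateDataError:
            return out
        top2 = float(model.variance_fraction[:2].sum())
        if top2 <= 0.80:
            logger.warning(
                "PC1+PC2 capture only %.1f%% of feature variance (expected >80%%)",
                100 * top2,
            )
    return out


# ---------------------------------------------------------------------------
# K-means


def kmeans2(
    scores: np.ndarray, seed: int = DEFAULT_SEED, restarts: int = DEFAULT_RESTARTS
) -> ClusteringResult:
    """K-means with k=2 on (PC1, PC2) scores; best of ``restarts`` seeded inits."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2:
        raise DegenerateDataError("k-means needs at least 2 points")
    km = KMeans(
        n_clusters=2,
        n_init=restarts,
        random_state=seed,
        algorithm="lloyd",
        max_iter=300,
    )
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assignments = km.fit_predict(scores)
    counts = np.bincount(assignments, minlength=2)
    degenerate = bool(np.any(counts == 0))
    if degenerate:
        logger.warning("k-means produced an empty cluster (degenerate data)")
    return ClusteringResult(
        assignments=assignments,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        degenerate=degenerate,
    )


def assign_flip_cluster(
    model: PCAModel,
    clustering: ClusteringResult,
    labels: list[str] | None = None,
    assignments_space_dims: int = 2,
) -> int:
    """Decide which cluster is the FLIP-designated one.

    FLIP interfaces correlate positively with sum_ddg, n_hot and avg_ddg;
    the FLIP cluster is the one whose centroid, mapped back through the PCA
    loadings into standardized feature space, has the larger
    sum_ddg + n_hot + avg_ddg.  Ties break toward larger intcpt_ddg.  With
    ``labels`` the majority label of each cluster decides instead.
    """
    if labels is not None:
        flip_frac = []
        for k in (0, 1):
            members = clustering.assignments == k
            if not members.any():
                flip_frac.append(-1.0)
                continue
            flip_frac.append(
                sum(1 for i in np.flatnonzero(members) if labels[i] == FLIP)
                / members.sum()
            )
        return int(np.argmax(flip_frac))

    back = model.eigenvectors[:, :assignments_space_dims]  # features × dims
    idx = {name: i for i, name in enumerate(model.feature_names)}
    key = [idx["sum_ddg"], idx["n_hot"], idx["avg_ddg"]]
    tie_key = idx["intcpt_ddg"]
    scores = []
    for k in (0, 1):
        z_hat = back @ clustering.centroids[k]
        scores.append((float(z_hat[key].sum()), float(z_hat[tie_key])))
    if scores[0] == scores[1]:
        logger.info("FLIP-cluster designation tie; defaulting to cluster 0")
        return 0
    return int(max((0, 1), key=lambda k: scores[k]))


# ---------------------------------------------------------------------------
# Two-round training and projection


def _fit_round(
    matrix: FeatureMatrix,
    seed: int,
    restarts: int,
    map_by_labels: bool,
) -> RoundModel:
    pca, scores = standardize_and_pca(matrix)
    clustering = kmeans2(scores[:, :2], seed=seed, restarts=restarts)
    flip_cluster = assign_flip_cluster(
        pca, clustering, labels=matrix.labels if map_by_labels else None
    )
    return RoundModel(pca=pca, clustering=clustering, flip_cluster=flip_cluster)


def train_two_round(
    matrix: FeatureMatrix,
    seed: int = DEFAULT_SEED,
    restarts: int = DEFAULT_RESTARTS,
    map_by_labels: bool = False,
) -> ClassificationModel:
    """Fit the full two-round classifier on a seven-feature matrix.

    Round 1 clusters all rows; FLIP-cluster members are predicted FLIP.
    Round 2 re-fits PCA and K-means on the remainder; its FLIP-cluster
    members are predicted FLIP and the rest FunC.  If fewer than 3 rows
    remain for round 2 it is skipped and the remainder predicted FunC.
    """
    if matrix.n < 6:
        raise DegenerateDataError("two-round training needs at least 6 rows")
    if set(matrix.feature_names) != set(CLASSIFIER_FEATURES):
        raise FeatureMismatchError(
            f"expected features {CLASSIFIER_FEATURES}, got {matrix.feature_names}"
        )

    round1 = _fit_round(matrix, seed, restarts, map_by_labels)
    in_flip1 = round1.clustering.assignments == round1.flip_cluster
    round1_member_idx = np.flatnonzero(in_flip1)
    round2_input_idx = np.flatnonzero(~in_flip1)

    predictions = [FUNC] * matrix.n
    for i in round1_member_idx:
        predictions[i] = FLIP

    round2: RoundModel | None = None
    if round2_input_idx.size >= 3:
        sub = matrix.subset(round2_input_idx)
        round2 = _fit_round(sub, seed, restarts, map_by_labels)
        in_flip2 = round2.clustering.assignments == round2.flip_cluster
        for local_i in np.flatnonzero(in_flip2):
            predictions[round2_input_idx[local_i]] = FLIP
    else:
        logger.warning("fewer than 3 rows left for round 2; remainder predicted FunC")

    return ClassificationModel(
        round1=round1,
        round2=round2,
        predictions=predictions,
        round1_member_idx=round1_member_idx,
        round2_input_idx=round2_input_idx,
        seed=seed,
    )


def _nearest_centroid(scores2: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(scores2[:, None, :] - centroids[None, :, :], axis=2)
    return np.argmin(d, axis=1)


def project(
    model: ClassificationModel, matrix: FeatureMatrix
) -> tuple[list[str], dict]:
    """Project new interfaces through the trained rounds.

    Rows are standardized with the *training* means/sds, mapped through the
    round-1 eigenvectors and assigned to the nearest round-1 centroid in
    (PC1, PC2); rows not assigned to the FLIP cluster are re-projected
    through round 2 the same way.  Returns the final FLIP/FunC prediction
    per row plus per-round assignment detail.
    """
    if matrix.feature_names != model.round1.pca.feature_names:
        raise FeatureMismatchError(
            f"model expects features {model.round1.pca.feature_names}, "
            f"got {matrix.feature_names}"
        )
    scores1 = model.round1.pca.transform(matrix.values)[:, :2]
    assign1 = _nearest_centroid(scores1, model.round1.clustering.centroids)
    predictions = [FUNC] * matrix.n
    flip1 = assign1 == model.round1.flip_cluster
    for i in np.flatnonzero(flip1):
        predictions[i] = FLIP

    rest = np.flatnonzero(~flip1)
    assign2 = None
    if model.round2 is not None and rest.size:
        scores2 = model.round2.pca.transform(matrix.values[rest])[:, :2]
        a2 = _nearest_centroid(scores2, model.round2.clustering.centroids)
        assign2 = np.full(matrix.n, -1)
        assign2[rest] = a2
        for local_i in np.flatnonzero(a2 == model.round2.flip_cluster):
            predictions[rest[local_i]] = FLIP

    detail = {"round1_assignments": assign1, "round2_assignments": assign2,
              "round2_rows": rest}
    return predictions, detail


# ---------------------------------------------------------------------------
# Serialization (plain JSON, bit-exact round trip of floats)


def _round_to_dict(rm: RoundModel) -> dict:
    return {
        "feature_names": rm.pca.feature_names,
        "means": rm.pca.means.tolist(),
        "sds": rm.pca.sds.tolist(),
        "eigenvectors": rm.pca.eigenvectors.tolist(),
        "eigenvalues": rm.pca.eigenvalues.tolist(),
        "centroids": rm.clustering.centroids.tolist(),
        "assignments": rm.clustering.assignments.tolist(),
        "inertia": rm.clustering.inertia,
        "degenerate": rm.clustering.degenerate,
        "flip_cluster": rm.flip_cluster,
    }


def _round_from_dict(d: dict) -> RoundModel:
    pca = PCAModel(
        feature_names=list(d["feature_names"]),
        means=np.array(d["means"]),
        sds=np.array(d["sds"]),
        eigenvectors=np.array(d["eigenvectors"]),
        eigenvalues=np.array(d["eigenvalues"]),
    )
    clustering = ClusteringResult(
        assignments=np.array(d["assignments"], dtype=int),
        centroids=np.array(d["centroids"]),
        inertia=float(d["inertia"]),
        degenerate=bool(d["degenerate"]),
    )
    return RoundModel(pca=pca, clustering=clustering, flip_cluster=int(d["flip_cluster"]))


def save_model(model: ClassificationModel, path: str | Path) -> None:
    payload = {
        "format": "ecr-classification-model",
        "version": 1,
        "seed": model.seed,
        "round1": _round_to_dict(model.round1),
        "round2": None if model.round2 is None else _round_to_dict(model.round2),
        "predictions": model.predictions,
        "round1_member_idx": model.round1_member_idx.tolist(),
        "round2_input_idx": model.round2_input_idx.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> ClassificationModel:
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise InputError(f"cannot read model file {path!r}: {exc}") from exc
    if payload.get("format") != "ecr-classification-model":
        raise InputError(f"{path!r} is not an ECR model file")
    return ClassificationModel(
        round1=_round_from_dict(payload["round1"]),
        round2=(
            None if payload["round2"] is None else _round_from_dict(payload["round2"])
        ),
        predictions=list(payload["predictions"]),
        round1_member_idx=np.array(payload["round1_member_idx"], dtype=int),
        round2_input_idx=np.array(payload["round2_input_idx"], dtype=int),
        seed=int(payload["seed"]),
    )
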