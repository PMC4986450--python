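"""Population stratification from CNVR states: random-forest proximity + MDS.

A supervised random forest is trained to predict each sample's population
from its CNVR states; the fraction of trees in which two samples land in the
same terminal node is their proximity. ``1 - proximity`` is a dissimilarity
embedded by classical (Torgerson) metric MDS. Model quality is reported as
an out-of-bag confusion matrix and accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io_formats import SampleManifest


def mtry_rule(n_features: int) -> int:
    """Features tried per tree node: floor(sqrt(n_features)), at least 1."""
    if n_features < 1:
        raise ValueError(f"n_features must be >= 1, got {n_features}")
    return max(1, math.floor(math.sqrt(n_features)))


@dataclass
class ProximityMatrix:
    values: pd.DataFrame          # samples x samples in [0, 1]
    n_trees: int
    mtry: int
    seed: int | None
    oob_only: bool = False

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("proximity matrix must be symmetric")
        if ((v < -1e-12) | (v > 1 + 1e-12)).any():
            raise ValueError("proximities must lie in [0, 1]")

    def to_distance(self) -> pd.DataFrame:
        """Dissimilarity 1 - proximity with an exactly zero diagonal."""
        d = 1.0 - self.values.to_numpy()
        np.fill_diagonal(d, 0.0)
        return pd.DataFrame(d, index=self.values.index,
                            columns=self.values.columns)


@dataclass
class ConfusionMatrix:
    counts: pd.DataFrame          # true label x predicted label

    @property
    def accuracy(self) -> float:
        m = self.counts.to_numpy()
        return float(np.trace(m) / m.sum())


def impute_modal(features: pd.DataFrame) -> pd.DataFrame:
    """Replace missing cells (NaN) by the locus's modal observed state."""
    out = features.copy().astype(float)
    for locus in out.index:
        row = out.loc[locus]
        if row.isna().any():
            observed = row.dropna()
            fill = observed.mode().iloc[0] if len(observed) else 2.0
            out.loc[locus] = row.fillna(fill)
    return out


def fit_forest_proximity(
    features: pd.DataFrame,
    labels: dict[str, str] | pd.Series,
    n_trees: int = 50_000,
    seed: int | None = None,
    oob_proximity: bool = False,
) -> tuple[ProximityMatrix, ConfusionMatrix]:
    """Supervised forest proximity among samples.

    ``features`` is loci x samples (states or allele dosages); ``labels``
    maps sample -> population. Trees are CART with Gini impurity, grown to
    purity on bootstrap resamples, with ``mtry_rule`` features per node.
    proximity(i, j) = fraction of trees whose terminal node contains both i
    and j (over all trees, or over trees where both are out-of-bag when
    ``oob_proximity``). The confusion matrix and accuracy come from
    out-of-bag class votes.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    samples = list(features.columns)
    y = labels.reindex(samples)
    if y.isna().any():
        missing = [s for s in samples if pd.isna(y[s])]
        raise KeyError(f"samples without population label: {missing}")
    if y.nunique() < 2:
        raise ValueError("supervised proximity needs >= 2 populations")
    if len(samples) < 2:
        raise ValueError("need >= 2 samples")

    X = impute_modal(features).to_numpy().T    # samples x features
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features=mtry_rule(X.shape[1]),
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X, y.to_numpy())

    leaves = clf.apply(X)                      # samples x trees
    n = len(samples)
    if oob_proximity:
        import inspect

        from sklearn.ensemble._forest import _generate_unsampled_indices

        # signature gained a sample_weight argument in newer sklearn
        extra = (
            {"sample_weight": None}
            if "sample_weight"
            in inspect.signature(_generate_unsampled_indices).parameters
            else {}
        )
        n_rows = X.shape[0]
        co_oob = np.zeros((n, n))
        same = np.zeros((n, n))
        for t, est in enumerate(clf.estimators_):
            oob_idx = _generate_unsampled_indices(
                est.random_state, n_rows, n_rows, **extra
            )
            mask = np.zeros(n, dtype=bool)
            mask[oob_idx] = True
            pair = np.outer(mask, mask)
            co_oob += pair
            same += pair * (leaves[:, t][:, None] == leaves[:, t][None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            prox = np.where(co_oob > 0, same / np.maximum(co_oob, 1), 0.0)
        np.fill_diagonal(prox, 1.0)
    else:
        prox = np.zeros((n, n))
        chunk = max(1, int(5e7 // (n * n)))    # bound peak memory
        for lo in range(0, n_trees, chunk):
            block = leaves[:, lo:lo + chunk]
            prox += (block[:, None, :] == block[None, :, :]).sum(axis=2)
        prox /= n_trees

    prox_df = pd.DataFrame(prox, index=samples, columns=samples)
    proximity = ProximityMatrix(
        values=prox_df, n_trees=n_trees, mtry=mtry_rule(X.shape[1]),
        seed=seed, oob_only=oob_proximity,
    )

    classes = list(clf.classes_)
    oob_votes = clf.oob_decision_function_
    pred = np.asarray(classes)[np.nanargmax(np.nan_to_num(oob_votes), axis=1)]
    pops = sorted(y.unique())
    counts = pd.DataFrame(0, index=pops, columns=pops)
    for true, p in zip(y.to_numpy(), pred):
        counts.loc[true, p] += 1
    return proximity, ConfusionMatrix(counts)


# ---------------------------------------------------------------------------
# Classical (Torgerson) MDS
# ---------------------------------------------------------------------------

@dataclass
class MDSResult:
    coordinates: pd.DataFrame     # samples x dims
    eigenvalues: np.ndarray       # all eigenvalues, non-increasing
    positive_mass_fraction: float # eigenvalue mass captured by the embedding

    def __post_init__(self) -> None:
        means = self.coordinates.to_numpy().mean(axis=0)
        if not np.allclose(means, 0.0, atol=1e-9):
            raise ValueError("MDS coordinates must be column-centered")
        diffs = np.diff(self.eigenvalues)
        if (diffs > 1e-9 * max(1.0, abs(self.eigenvalues[0]))).any():
            raise ValueError("eigenvalues must be non-increasing")


def classical_mds(distance: pd.DataFrame | np.ndarray, dims: int = 3) -> MDSResult:
    """Torgerson scaling: double-center -squared distances, eigendecompose.

    Coordinates are the top ``dims`` eigenvectors scaled by the square root
    of their (positive) eigenvalues; negative eigenvalues are truncated to
    zero-width axes and reported via ``eigenvalues`` and
    ``positive_mass_fraction``.
    """
    if isinstance(distance, pd.DataFrame):
        labels = list(distance.index)
        D = distance.to_numpy(dtype=float)
    else:
        D = np.asarray(distance, dtype=float)
        labels = [str(i) for i in range(D.shape[0])]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-9):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    if not 1 <= dims <= n:
        raise ValueError(f"dims must be in [1, {n}]")

    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    lam = np.clip(eigvals[:dims], 0.0, None)
    coords = eigvecs[:, :dims] * np.sqrt(lam)[None, :]
    coords -= coords.mean(axis=0, keepdims=True)   # numerically exact centering

    pos_total = float(np.clip(eigvals, 0.0, None).sum())
    captured = float(lam.sum() / pos_total) if pos_total > 0 else 0.0
    frame = pd.DataFrame(
        coords, index=labels, columns=[f"dim{k + 1}" for k in range(dims)]
    )
    return MDSResult(coordinates=frame, eigenvalues=eigvals,
                     positive_mass_fraction=captured)


def population_centroids(
    coordinates: pd.DataFrame, manifest: SampleManifest
) -> pd.DataFrame:
    """Mean MDS coordinates per population."""
    pop = pd.Series({s: manifest.population_of(s) for s in coordinates.index})
    return coordinates.groupby(pop).mean()
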