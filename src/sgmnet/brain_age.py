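"""Brain-age prediction from gray matter voxel intensities.

The model mirrors a widely used voxel-based morphometry pipeline: voxel
intensities inside a shared brain mask are reduced with principal component
analysis (100 components at full scale) and regressed on chronological age
with a linear support-vector regression (nu-SVR, C = 1, nu = 0.5).
Accuracy is assessed with k-fold cross-validation (default 10 folds):
within each fold, both the PCA basis and the regression are fitted on the
training folds only, and predictions are assembled from the held-out folds.
The per-subject brain-predicted age difference is

    brain-PAD = predicted age - chronological age,

positive when a brain "looks older" than its owner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR, NuSVR

from .volume import GrayMatterVolume

__all__ = ["BrainAgeModel", "BrainAgeResults", "vectorize_volumes", "brain_pad"]


def vectorize_volumes(
    volumes: list[GrayMatterVolume], mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stack in-mask voxel intensities into a (n_subjects, n_voxels) table.

    All volumes must share the grid; ``mask`` defaults to the intersection
    of the subjects' masks.  Returns ``(X, constant_columns)`` where the
    flag marks voxels constant across subjects (they carry no signal and a
    downstream PCA ignores them, but they are reported for inspection).
    """
    if not volumes:
        raise ValueError("no volumes given")
    shape = volumes[0].shape
    for v in volumes:
        if v.shape != shape:
            raise ValueError("all volumes must share the same grid shape")
    if mask is None:
        mask = np.logical_and.reduce([v.mask for v in volumes])
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape must match the volume grid")
    x = np.stack([v.intensities[mask] for v in volumes])
    constant = x.std(axis=0) == 0
    if constant.all():
        warnings.warn("every masked voxel is constant across subjects", stacklevel=2)
    return x, constant


def brain_pad(predicted: float | np.ndarray, chronological: float | np.ndarray):
    """Brain-predicted age difference: predicted minus chronological age."""
    return np.asarray(predicted) - np.asarray(chronological)


@dataclass
class BrainAgeModel:
    """Cross-validated PCA + linear support-vector regression of age.

    Parameters
    ----------
    features : ndarray (n_subjects, n_features)
        Voxel intensities (see :func:`vectorize_volumes`).
    ages : ndarray (n_subjects,)
        Chronological ages in years.
    n_components : int
        Number of principal components (100 at full scale; capped at the
        available training rank with a warning).
    folds : int
        Cross-validation folds (default 10).
    svr : {"nu", "eps"}
        ``"nu"`` fits nu-SVR with C and nu below; ``"eps"`` fits
        epsilon-SVR with C and epsilon 0.1.
    basis : {"per_fold", "global"}
        ``"per_fold"`` (default) refits the PCA basis inside every training
        fold, so held-out subjects never influence it; ``"global"`` fits one
        basis on all subjects, replicating pipelines that reduce first and
        cross-validate only the regression.
    standardize : bool
        Z-score features before PCA (off by default; voxel intensities are
        commensurate).
    """

    features: np.ndarray
    ages: np.ndarray
    n_components: int = 100
    folds: int = 10
    C: float = 1.0
    nu: float = 0.5
    svr: str = "nu"
    basis: str = "per_fold"
    standardize: bool = False

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.ages = np.asarray(self.ages, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("features must be 2D (subjects x voxels)")
        if len(self.ages) != self.features.shape[0]:
            raise ValueError("ages and features disagree on subject count")
        if not np.all(np.isfinite(self.ages)):
            raise ValueError("ages must be finite")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.features.shape[0] < self.folds:
            raise ValueError("need at least one subject per fold")
        if self.svr not in ("nu", "eps"):
            raise ValueError("svr must be 'nu' or 'eps'")
        if self.basis not in ("per_fold", "global"):
            raise ValueError("basis must be 'per_fold' or 'global'")

    @classmethod
    def from_volumes(
        cls,
        volumes: list[GrayMatterVolume],
        ages,
        mask: np.ndarray | None = None,
        **kwargs,
    ) -> "BrainAgeModel":
        x, _ = vectorize_volumes(volumes, mask=mask)
        return cls(x, np.asarray(ages, dtype=float), **kwargs)

    # ------------------------------------------------------------------ fit

    def _make_svr(self):
        if self.svr == "nu":
            return NuSVR(kernel="linear", C=self.C, nu=self.nu)
        return SVR(kernel="linear", C=self.C, epsilon=0.1)

    def _reduce(self, train_x: np.ndarray, test_x: np.ndarray):
        cap = min(self.n_components, train_x.shape[0] - 1, train_x.shape[1])
        if cap < self.n_components:
            warnings.warn(
                f"n_components reduced from {self.n_components} to {cap} "
                "(training-fold rank)",
                stacklevel=3,
            )
        pca = PCA(n_components=cap, svd_solver="full")
        return pca.fit_transform(train_x), pca.transform(test_x)

    def fit(self, seed: int = 0) -> "BrainAgeResults":
        """Run the cross-validation loop and pool held-out predictions."""
        x = self.features
        if self.standardize:
            x = StandardScaler().fit_transform(x)
        n = x.shape[0]
        predicted = np.empty(n)
        kf = KFold(n_splits=self.folds, shuffle=True, random_state=int(seed))
        if self.basis == "global":
            pca = PCA(
                n_components=min(self.n_components, n - 1, x.shape[1]),
                svd_solver="full",
            )
            z_all = pca.fit_transform(x)
        for train, test in kf.split(x):
            if self.basis == "per_fold":
                z_train, z_test = self._reduce(x[train], x[test])
            else:
                z_train, z_test = z_all[train], z_all[test]
            reg = self._make_svr()
            reg.fit(z_train, self.ages[train])
            predicted[test] = reg.predict(z_test)
        return BrainAgeResults(model=self, predicted=predicted, seed=int(seed))


@dataclass
class BrainAgeResults:
    """Held-out predictions and accuracy metrics from :meth:`BrainAgeModel.fit`."""

    model: BrainAgeModel
    predicted: np.ndarray
    seed: int
    mae: float = field(init=False)
    rmse: float = field(init=False)
    r: float = field(init=False)

    def __post_init__(self) -> None:
        err = self.predicted - self.model.ages
        self.mae = float(np.abs(err).mean())
        self.rmse = float(np.sqrt((err**2).mean()))
        if np.std(self.model.ages) == 0 or np.std(self.predicted) == 0:
            warnings.warn("degenerate ages or predictions; correlation undefined", stacklevel=2)
            self.r = np.nan
        else:
            self.r = float(np.corrcoef(self.predicted, self.model.ages)[0, 1])

    @property
    def brain_pad(self) -> np.ndarray:
        return brain_pad(self.predicted, self.model.ages)

    def to_frame(self, ids=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "age": self.model.ages,
                "predicted_age": self.predicted,
                "brain_pad": self.brain_pad,
            }
        )
        if ids is not None:
            df.insert(0, "id", list(ids))
        return df

    def metrics(self) -> dict:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "r": self.r,
            "folds": self.model.folds,
            "n_components": self.model.n_components,
            "n_subjects": int(len(self.model.ages)),
            "seed": self.seed,
        }

    def summary(self) -> str:
        m = self.metrics()
        lines = [
            "Brain-age model (PCA + linear SVR, cross-validated)",
            "=" * 51,
            f"subjects            {m['n_subjects']:>10d}",
            f"folds               {m['folds']:>10d}",
            f"components          {m['n_components']:>10d}",
            f"MAE (years)         {m['mae']:>10.3f}",
            f"RMSE (years)        {m['rmse']:>10.3f}",
            f"r(pred, age)        {m['r']:>10.3f}",
            f"mean brain-PAD (y)  {float(np.mean(self.brain_pad)):>10.3f}",
        ]
        return "\n".join(lines)
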