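"""PLS discriminant analysis of the assembly-promoting conformation.

A 0/1 label vector marks frames belonging to the assembly-promoting cluster;
partial-least-squares regression of the flattened, aligned C-alpha
coordinates onto this vector (six components by default) gives a linear
model whose predictivity is measured as the coefficient of determination
R^2 = 1 - SS_res / SS_tot of the continuous predictions on a held-out half
of the shuffled frames.  The fitted label-predictive direction supports
linear interpolation between the class ends (t = 0: non-assembly mean-like
structure, t = 1: assembly-promoting mean-like structure), which turns the
discriminant into an interpretable structural morph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression


class ClassBalanceError(ValueError):
    pass


class RankError(ValueError):
    pass


@dataclass
class DiscriminantModel:
    pls: PLSRegression
    n_components: int
    labels: np.ndarray
    train_mask: np.ndarray
    validation_r2: float
    seed: int
    # linear map structure(t) = intercept + slope * t  (flattened coords)
    _intercept: np.ndarray = None
    _slope: np.ndarray = None
    n_atoms: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.pls.predict(X).ravel()


def fit_plsda(
    X: np.ndarray,
    labels: np.ndarray,
    n_components: int = 6,
    seed: int = 0,
) -> DiscriminantModel:
    """Fit PLS regression of coordinates onto 0/1 class labels.

    ``X``: (n_frames, 3 * n_calpha) aligned flattened coordinates.
    Half of the shuffled frames train the model; validation R^2 is computed
    on the other half from the continuous predictions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ClassBalanceError("labels must be 0/1")
    if len(X) != len(y):
        raise ClassBalanceError("label vector length must equal frame count")
    if n_components > min(X.shape):
        raise RankError(
            f"n_components={n_components} exceeds the data rank bound "
            f"{min(X.shape)}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(X))
    train_idx = perm[: len(X) // 2]
    train_mask = np.zeros(len(X), dtype=bool)
    train_mask[train_idx] = True
    if len(np.unique(y[train_mask])) < 2:
        raise ClassBalanceError("training half contains a single class")

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X[train_mask], y[train_mask])
    y_val = y[~train_mask]
    pred = pls.predict(X[~train_mask]).ravel()
    ss_res = float(np.sum((y_val - pred) ** 2))
    ss_tot = float(np.sum((y_val - y_val.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot

    # Linear coordinate model along the predicted label: regressing X on the
    # in-sample prediction makes structure(t=0)/structure(t=1) approximate
    # the class-conditional mean structures.
    yhat = pls.predict(X[train_mask]).ravel()
    yc = yhat - yhat.mean()
    denom = float(yc @ yc)
    slope = (X[train_mask] - X[train_mask].mean(axis=0)).T @ yc / denom
    intercept = X[train_mask].mean(axis=0) - slope * yhat.mean()

    return DiscriminantModel(
        pls=pls,
        n_components=n_components,
        labels=y.astype(int),
        train_mask=train_mask,
        validation_r2=r2,
        seed=seed,
        _intercept=intercept,
        _slope=slope,
        n_atoms=X.shape[1] // 3,
    )


def interpolate_structures(
    model: DiscriminantModel, t_values
) -> np.ndarray:
    """C-alpha structures along the label-predictive direction.

    Returns (len(t_values), n_calpha, 3); t must lie in [0, 1].
    """
    t = np.asarray(t_values, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("interpolation parameter t must lie in [0, 1]")
    flat = model._intercept[None, :] + t[:, None] * model._slope[None, :]
    return flat.reshape(len(t), model.n_atoms, 3)
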