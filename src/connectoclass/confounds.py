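"""Age/sex confound removal by Gaussian-process regression on controls.

For every feature, a GP regression on (age, sex) is estimated using
*control subjects only* and its fitted mean is subtracted from every
subject's value, so residuals carry no variance explainable by age or sex
and group labels never enter the fit.  The kernel is a sum of linear
(dot-product) and radial-basis components plus observation noise; it
therefore contains exact linear trends as a special case, and in that limit
the residualization coincides with ordinary least squares.

Hyperparameters are shared across features: they are optimized by maximum
marginal likelihood on a seeded subset of up to ``max_opt_features``
feature columns, after which the posterior mean is evaluated for all
features in a single linear solve.  Age is standardized to the fitting
controls' mean/SD; sex is coded {0, 1} (M = 1).

``fit_scope="train_controls"`` (the default used inside cross-validation)
fits on the controls of the training partition only, avoiding test-set
leakage; ``fit_scope="all_controls"`` fits on every control in the table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, DotProduct, WhiteKernel

from .features import FeatureTable

__all__ = ["ConfoundModel", "fit_confound_model", "residualize_confounds"]

MIN_CONTROLS = 10


def _design(ages: np.ndarray, sexes: np.ndarray, age_mean: float, age_sd: float) -> np.ndarray:
    return np.column_stack([(ages - age_mean) / age_sd, sexes.astype(float)])


def _sex_code(sex: np.ndarray) -> np.ndarray:
    return (np.asarray(sex) == "M").astype(float)


@dataclass
class ConfoundModel:
    """Fitted control-sample GP, ready to residualize any subject set."""

    kernel_: object
    x_controls: np.ndarray
    alpha: np.ndarray  # (n_controls, p) solve of (K + noise) against centered Y
    col_mean: np.ndarray  # (p,) control means
    constant_mask: np.ndarray  # (p,) True where the feature had zero variance
    age_mean: float
    age_sd: float

    def predicted_mean(self, ages: np.ndarray, sexes01: np.ndarray) -> np.ndarray:
        x = _design(ages, sexes01, self.age_mean, self.age_sd)
        k_cross = self.kernel_(x, self.x_controls)
        mean = k_cross @ self.alpha + self.col_mean
        mean[:, self.constant_mask] = 0.0  # constant features pass through
        return mean

    def residualize(self, table: FeatureTable) -> FeatureTable:
        ages = table.subjects["age"].to_numpy(dtype=float)
        sexes = _sex_code(table.subjects["sex"].to_numpy())
        return table.with_features(table.features - self.predicted_mean(ages, sexes))


def fit_confound_model(
    table: FeatureTable,
    fit_index: np.ndarray | None = None,
    seed: int = 0,
    max_opt_features: int = 256,
) -> ConfoundModel:
    """Fit the control-only GP on the subjects selected by ``fit_index``.

    ``fit_index`` restricts the candidate pool (e.g. to a CV training
    partition); only its controls enter the fit.  Requires at least
    10 controls in scope.
    """
    subjects = table.subjects
    pool = np.arange(table.n_subjects) if fit_index is None else np.asarray(fit_index)
    controls = pool[subjects["group"].to_numpy()[pool] == "control"]
    if controls.size < MIN_CONTROLS:
        raise ValueError(
            f"need >= {MIN_CONTROLS} control subjects to fit the confound model, "
            f"got {controls.size}"
        )
    ages = subjects["age"].to_numpy(dtype=float)[controls]
    sexes = _sex_code(subjects["sex"].to_numpy()[controls])
    if not np.all(np.isfinite(ages)):
        raise ValueError("control ages must be finite")
    age_mean = float(ages.mean())
    age_sd = float(ages.std()) or 1.0
    x = _design(ages, sexes, age_mean, age_sd)

    y = table.features[controls]
    col_sd = y.std(axis=0)
    constant_mask = col_sd == 0
    if constant_mask.any():
        warnings.warn(
            f"{int(constant_mask.sum())} zero-variance feature(s) passed "
            "through unchanged",
            stacklevel=2,
        )
    col_mean = y.mean(axis=0)
    yc = y - col_mean

    varying = np.flatnonzero(~constant_mask)
    if varying.size == 0:
        # nothing to fit: an identity model with zero predictions
        kernel = WhiteKernel(noise_level=1.0)
        return ConfoundModel(
            kernel_=kernel, x_controls=x, alpha=np.zeros((controls.size, y.shape[1])),
            col_mean=np.zeros(y.shape[1]), constant_mask=constant_mask,
            age_mean=age_mean, age_sd=age_sd,
        )
    rng = np.random.default_rng(seed)
    if varying.size > max_opt_features:
        opt_cols = rng.choice(varying, size=max_opt_features, replace=False)
    else:
        opt_cols = varying
    # scale the optimization targets so the marginal likelihood is not
    # dominated by a few large-variance features
    y_opt = yc[:, opt_cols] / col_sd[opt_cols]

    kernel = (
        ConstantKernel(1.0, (1e-4, 1e4)) * DotProduct(sigma_0=1.0, sigma_0_bounds=(1e-4, 1e4))
        + ConstantKernel(1.0, (1e-4, 1e4)) * RBF(length_scale=1.0, length_scale_bounds=(1e-2, 1e3))
        + WhiteKernel(noise_level=0.5, noise_level_bounds=(1e-8, 1e4))
    )
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=False, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(x, y_opt)
    kernel_ = gp.kernel_

    k_train = kernel_(x)
    k_train[np.diag_indices_from(k_train)] += 1e-10  # numerical jitter
    chol = cho_factor(k_train, lower=True)
    alpha = cho_solve(chol, yc)
    alpha[:, constant_mask] = 0.0
    return ConfoundModel(
        kernel_=kernel_, x_controls=x, alpha=alpha, col_mean=np.where(constant_mask, 0.0, col_mean),
        constant_mask=constant_mask, age_mean=age_mean, age_sd=age_sd,
    )


def residualize_confounds(
    table: FeatureTable,
    fit_scope: str = "all_controls",
    train_index: np.ndarray | None = None,
    seed: int = 0,
    max_opt_features: int = 256,
) -> FeatureTable:
    """Subtract the control-sample GP mean from every subject's features.

    ``fit_scope="all_controls"`` fits on every control in the table;
    ``"train_controls"`` fits only on the controls among ``train_index``
    (required in that case).  Returns a new table; the input is untouched.
    """
    if fit_scope not in ("all_controls", "train_controls"):
        raise ValueError("fit_scope must be 'all_controls' or 'train_controls'")
    if fit_scope == "train_controls":
        if train_index is None:
            raise ValueError("fit_scope='train_controls' requires train_index")
        fit_index = np.asarray(train_index)
    else:
        fit_index = None
    model = fit_confound_model(
        table, fit_index=fit_index, seed=seed, max_opt_features=max_opt_features
    )
    return model.residualize(table)
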