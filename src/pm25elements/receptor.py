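"""PCA / varimax / APCS multiple-regression receptor model.

The apportionment chain is the classical absolute-principal-component-score
construction:

1. column-standardise the concentration matrix;
2. eigendecompose the correlation matrix, retain components with
   eigenvalue > 1, scale loadings as eigenvector * sqrt(eigenvalue);
3. varimax-rotate the retained loadings (Kaiser row normalisation);
4. regression (Thomson) factor scores, shifted by the score of an
   artificial zero-concentration sample (z0_j = -mean_j / sd_j) to give
   absolute scores (APCS);
5. ordinary least squares of every species on the APCS columns; the
   product b_kj * APCS_ik is the contribution of source k to species j in
   sample i, and summed predictions give per-sample measured/predicted
   (M/P) ratios as a goodness check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConcentrationTable, ValidationError


@dataclass
class StandardizedMatrix:
    z: np.ndarray            # n x p, column mean 0 / sd 1
    means: np.ndarray
    sds: np.ndarray
    columns: tuple[str, ...]

    def inverse(self, z: np.ndarray | None = None) -> np.ndarray:
        zz = self.z if z is None else z
        return zz * self.sds + self.means


@dataclass
class PcaModel:
    eigenvalues: np.ndarray          # descending, length p
    loadings: np.ndarray             # p x p unrotated (eigvec * sqrt(eig))
    columns: tuple[str, ...]
    retained: int = 0
    rotated_loadings: np.ndarray | None = None   # p x k
    rotation: np.ndarray | None = None           # k x k
    rotation_iterations: int = 0
    rotation_converged: bool = True

    @property
    def explained_variance_pct(self) -> np.ndarray:
        return self.eigenvalues / len(self.columns) * 100.0

    def rotated_variance_pct(self) -> np.ndarray:
        """Variance share (%) attributed to each rotated component."""
        ssq = (self.rotated_loadings ** 2).sum(axis=0)
        return ssq / len(self.columns) * 100.0


@dataclass
class ApcsModel:
    scores: np.ndarray           # n x k regression factor scores
    zero_scores: np.ndarray      # k
    apcs: np.ndarray             # n x k
    intercepts: np.ndarray | None = None   # p
    coefficients: np.ndarray | None = None  # k x p
    predicted: np.ndarray | None = None     # n x p
    columns: tuple[str, ...] = ()
    source_names: tuple[str, ...] = ()


def standardize(matrix: pd.DataFrame | np.ndarray,
                columns=None) -> StandardizedMatrix:
    """Column z-scores (sample sd, n-1); errors on constant columns."""
    if isinstance(matrix, pd.DataFrame):
        columns = tuple(matrix.columns)
        x = matrix.to_numpy(float)
    else:
        x = np.asarray(matrix, float)
        columns = tuple(columns) if columns is not None else tuple(
            f"x{i}" for i in range(x.shape[1]))
    if not np.isfinite(x).all():
        raise ValidationError("non-finite entries; apply the missing-data "
                              "policy (complete-case) before standardizing")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    bad = [columns[i] for i in np.nonzero(sds == 0)[0]]
    if bad:
        raise ValidationError(f"constant column(s): {bad}")
    return StandardizedMatrix((x - means) / sds, means, sds, columns)


def fit_pca(z: StandardizedMatrix) -> PcaModel:
    """Eigendecomposition of the p x p correlation matrix."""
    n, p = z.z.shape
    if n < 4:
        raise ValidationError("need at least 4 samples")
    corr = z.z.T @ z.z / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    loadings = eigvec * np.sqrt(eigval)
    return PcaModel(eigval, loadings, z.columns)


def retain_components(model: PcaModel) -> int:
    """Number of components with eigenvalue strictly greater than one."""
    k = int((model.eigenvalues > 1.0).sum())
    if k == 0:
        raise ValidationError("no eigenvalue exceeds 1; nothing to retain")
    return k


def varimax_criterion(loadings: np.ndarray) -> float:
    """Sum over components of the variance of the squared loadings."""
    sq = np.asarray(loadings, float) ** 2
    return float((sq.var(axis=0)).sum())


def varimax_rotate(loadings: np.ndarray, tol: float = 1e-6,
                   max_iter: int = 200, kaiser: bool = True
                   ) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Orthogonal varimax rotation.

    Returns (rotated p x k loadings, k x k rotation matrix, iterations,
    converged).  Kaiser row normalisation is applied before and undone
    after the rotation; the varimax criterion is non-decreasing across
    iterations of the SVD algorithm.
    """
    L = np.asarray(loadings, float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k), 0, True
    h = np.sqrt((L ** 2).sum(axis=1)) if kaiser else np.ones(p)
    h = np.where(h == 0, 1.0, h)
    A = L / h[:, None]
    R = np.eye(k)
    d = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        B = A @ R
        u, s, vt = np.linalg.svd(
            A.T @ (B ** 3 - B @ np.diag((B ** 2).sum(axis=0)) / p))
        R = u @ vt
        d_new = s.sum()
        if d_new <= d * (1.0 + tol):
            converged = True
            break
        d = d_new
    if not converged:
        warnings.warn("varimax did not converge; returning best-so-far",
                      RuntimeWarning)
    rotated = (A @ R) * h[:, None]
    # sign convention: largest-magnitude loading of each component positive
    signs = np.sign(rotated[np.abs(rotated).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    rotated *= signs
    R = R * signs
    return rotated, R, it, converged


def rotate_model(model: PcaModel, k: int | None = None,
                 tol: float = 1e-6, max_iter: int = 200) -> PcaModel:
    """Retain k components (eigenvalue > 1 by default) and varimax-rotate,
    ordering rotated components by explained variance."""
    k = retain_components(model) if k is None else k
    L = model.loadings[:, :k]
    rotated, R, iters, conv = varimax_rotate(L, tol=tol, max_iter=max_iter)
    order = np.argsort((rotated ** 2).sum(axis=0))[::-1]
    model.retained = k
    model.rotated_loadings = rotated[:, order]
    model.rotation = R[:, order]
    model.rotation_iterations = iters
    model.rotation_converged = conv
    return model


def apcs_scores(z: StandardizedMatrix, model: PcaModel) -> ApcsModel:
    """Regression-method factor scores plus absolute scores (APCS).

    The artificial zero-concentration sample has z-profile
    z0_j = (0 - mean_j) / sd_j; its factor score is subtracted from every
    sample's score so a zero sample maps to APCS = 0 exactly.
    """
    if model.rotated_loadings is None:
        raise ValidationError("rotate the model before computing scores")
    n = z.z.shape[0]
    corr = z.z.T @ z.z / (n - 1)
    lam = model.rotated_loadings
    try:
        W = np.linalg.solve(corr, lam)        # p x k score coefficients
    except np.linalg.LinAlgError:
        # exact low-rank data (e.g. a noise-free mixture): the loadings lie
        # in the span of the correlation matrix, so the minimum-norm
        # solution is the consistent one
        W = np.linalg.pinv(corr, rcond=1e-10) @ lam
    if not np.isfinite(W).all():
        raise ValidationError("singular correlation matrix")
    scores = z.z @ W
    z0 = -z.means / z.sds
    zero_scores = z0 @ W
    return ApcsModel(scores=scores, zero_scores=zero_scores,
                     apcs=scores - zero_scores, columns=z.columns,
                     source_names=tuple(f"PC{i+1}" for i in range(lam.shape[1])))


def mlr_contributions(apcs_model: ApcsModel, concentrations: pd.DataFrame
                      ) -> ApcsModel:
    """OLS of each species' concentration on the APCS columns.

    Fills intercepts, coefficients (k x p) and predicted concentrations
    (same unit as the input, ng/m3); the source-k contribution to species j
    in sample i is ``coefficients[k, j] * apcs[i, k]``.
    """
    y = concentrations.to_numpy(float)
    n, k = apcs_model.apcs.shape
    if n <= k + 1:
        raise ValidationError("need n > k + 1 samples for the regression")
    X = np.column_stack([np.ones(n), apcs_model.apcs])
    if np.linalg.matrix_rank(X) < k + 1:
        raise ValidationError("rank-deficient APCS design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    apcs_model.intercepts = beta[0]
    apcs_model.coefficients = beta[1:]
    apcs_model.predicted = X @ beta
    apcs_model.columns = tuple(concentrations.columns)
    return apcs_model


def source_contributions(apcs_model: ApcsModel) -> np.ndarray:
    """Per-sample, per-source contribution summed over species (n x k)."""
    return apcs_model.apcs * apcs_model.coefficients.sum(axis=1)


def mp_ratios(apcs_model: ApcsModel, table: ConcentrationTable,
              elements: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per-sample measured/predicted summed-concentration ratios.

    Sums run over the element panel (auxiliary species, if any were added
    to the PCA, are excluded).  Samples with non-positive predicted sums
    are flagged and excluded from site means.
    """
    elements = elements or table.panel.symbols
    idx = [apcs_model.columns.index(e) for e in elements
           if e in apcs_model.columns]
    measured = table.values[[apcs_model.columns[i] for i in idx]].to_numpy(float)
    predicted = apcs_model.predicted[:, idx]
    pred_sum = predicted.sum(axis=1)
    meas_sum = measured.sum(axis=1)
    ok = pred_sum > 0
    mp = np.where(ok, meas_sum / np.where(ok, pred_sum, 1.0), np.nan)
    return pd.DataFrame({"site": table.values["site"],
                         "date": table.values["date"],
                         "MP": mp, "valid": ok})


def site_mean_mp(mp: pd.DataFrame) -> pd.Series:
    return mp[mp["valid"]].groupby("site")["MP"].mean()


def fit_receptor_model(table: ConcentrationTable, k: int | None = None
                       ) -> tuple[PcaModel, ApcsModel, pd.DataFrame]:
    """Full chain on one table: standardise, PCA, rotate, APCS, MLR, M/P."""
    mask = table.matrix().notna().all(axis=1)
    if not mask.all():
        table = ConcentrationTable(table.panel,
                                   table.values[mask].reset_index(drop=True),
                                   table.flags[mask].reset_index(drop=True),
                                   table.unit)
    mat = table.matrix()
    z = standardize(mat)
    model = rotate_model(fit_pca(z), k=k)
    apcs = apcs_scores(z, model)
    apcs = mlr_contributions(apcs, mat)
    mp = mp_ratios(apcs, table)
    return model, apcs, mp
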