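"""CN-anchored covariate residualization of ROI thickness.

Per ROI, an ordinary-least-squares model

    thickness = b0 + b_age*age + b_sex*sex + b_edu*education + b_icv*icv + e

is fitted on cognitively normal (CN) subjects only, and the fitted linear
predictor is then subtracted from every subject's thickness regardless of
diagnosis. Anchoring the fit on CN removes normal-aging and head-size
effects without absorbing disease-related atrophy into the covariate model.

Sex is coded F = 1, M = 0; any consistent coding changes coefficients but
not residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_COVARIATES: tuple[str, ...] = ("age", "sex", "education", "icv")

# subject-table column backing each covariate name
_COVARIATE_SOURCE = {
    "age": "age",
    "sex": "sex",
    "education": "education_years",
    "icv": "icv_mm3",
}


class DesignError(ValueError):
    """Raised for rank-deficient or undersized covariate designs."""


@dataclass(frozen=True)
class GLMFit:
    """Per-ROI OLS coefficients estimated on CN subjects.

    ``coef`` has one row per ROI and columns ``intercept`` plus the covariate
    names; ``resid_sd`` is the per-ROI residual standard deviation on the CN
    fitting set; ``n_cn`` the number of CN rows used.
    """

    coef: pd.DataFrame
    resid_sd: pd.Series
    covariates: tuple[str, ...]
    n_cn: int

    def save(self, path: str | Path) -> None:
        table = self.coef.copy()
        table["resid_sd"] = self.resid_sd
        table["n_cn"] = self.n_cn
        table.to_csv(path, sep="\t", index_label="roi")

    @classmethod
    def load(cls, path: str | Path) -> "GLMFit":
        table = pd.read_csv(path, sep="\t", index_col="roi")
        table.index.name = None
        n_cn = int(table["n_cn"].iloc[0])
        resid_sd = table.pop("resid_sd")
        table = table.drop(columns=["n_cn"])
        covs = tuple(c for c in table.columns if c != "intercept")
        return cls(coef=table, resid_sd=resid_sd, covariates=covs, n_cn=n_cn)


def _design_matrix(
    subjects: pd.DataFrame, covariates: tuple[str, ...]
) -> np.ndarray:
    cols = [np.ones(len(subjects))]
    for cov in covariates:
        src = _COVARIATE_SOURCE.get(cov, cov)
        if src not in subjects.columns:
            raise DesignError(f"covariate {cov!r} (column {src!r}) not in subject table")
        col = subjects[src]
        if cov == "sex" or col.dtype == object:
            vals = (col == "F").to_numpy(float) if cov == "sex" else col.astype(float)
        else:
            vals = col.to_numpy(float)
        cols.append(vals)
    return np.column_stack(cols)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    """Identify and name the first collinear (or constant) column."""
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # walk columns left to right; the first one that fails to raise the rank
    # of the preceding block is the offender
    for j in range(1, X.shape[1]):
        block = X[:, : j + 1]
        if np.linalg.matrix_rank(block) <= np.linalg.matrix_rank(X[:, :j]):
            raise DesignError(
                f"rank-deficient design: column {names[j]!r} is constant or "
                "collinear with earlier columns"
            )
    raise DesignError("rank-deficient design")  # pragma: no cover


def fit_cn_glm(
    thickness: pd.DataFrame,
    subjects: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> GLMFit:
    """OLS fit of every ROI on the covariates, CN rows only.

    Diagnosis labels of non-CN subjects never enter the fit. Raises
    :class:`DesignError` when fewer than ``len(covariates) + 2`` CN subjects
    are available or when the design is rank-deficient (naming the column).
    """
    sub = subjects.set_index("subject_id") if "subject_id" in subjects.columns else subjects
    cn_ids = sub.index[sub["diagnosis"] == "CN"]
    cn_ids = cn_ids.intersection(thickness.index)
    if len(cn_ids) < len(covariates) + 2:
        raise DesignError(
            f"need at least {len(covariates) + 2} CN subjects to fit "
            f"{len(covariates)} covariates, got {len(cn_ids)}"
        )
    cn_sub = sub.loc[cn_ids]
    _require_complete(cn_sub, covariates)
    X = _design_matrix(cn_sub, covariates)
    names = ["intercept", *covariates]
    _check_rank(X, names)
    Y = thickness.loc[cn_ids].to_numpy(float)
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    if not np.all(np.isfinite(beta)):
        raise DesignError("non-finite coefficients in CN fit")
    resid = Y - X @ beta
    dof = max(1, len(cn_ids) - X.shape[1])
    sd = pd.Series(np.sqrt((resid**2).sum(axis=0) / dof), index=thickness.columns)
    coef = pd.DataFrame(beta.T, index=thickness.columns, columns=names)
    return GLMFit(coef=coef, resid_sd=sd, covariates=tuple(covariates), n_cn=len(cn_ids))


def _require_complete(sub: pd.DataFrame, covariates: tuple[str, ...]) -> None:
    missing_ids: list[str] = []
    for cov in covariates:
        src = _COVARIATE_SOURCE.get(cov, cov)
        if src in sub.columns:
            bad = sub.index[sub[src].isna()]
            missing_ids.extend(map(str, bad))
    if missing_ids:
        raise DesignError(
            "missing covariate values for subjects: " + ", ".join(sorted(set(missing_ids)))
        )


def residualize(
    thickness: pd.DataFrame, subjects: pd.DataFrame, fit: GLMFit
) -> pd.DataFrame:
    """Subtract the CN-fitted linear predictor from every subject's thickness.

    Applied to all diagnoses with each subject's own covariate values.
    Returns a table of the same shape as ``thickness`` (mm residuals).
    """
    sub = subjects.set_index("subject_id") if "subject_id" in subjects.columns else subjects
    missing = thickness.index.difference(sub.index)
    if len(missing):
        raise DesignError(
            "subjects without covariate rows: " + ", ".join(map(str, missing))
        )
    sub = sub.loc[thickness.index]
    _require_complete(sub, fit.covariates)
    X = _design_matrix(sub, fit.covariates)
    beta = fit.coef[["intercept", *fit.covariates]].to_numpy(float).T
    predicted = X @ beta
    return thickness - pd.DataFrame(predicted, index=thickness.index, columns=thickness.columns)
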