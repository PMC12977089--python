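"""Phenotype preparation: residualization, rank-based inverse normal
transformation, relative (globally adjusted) measures, and the effective
number of independent phenotypes.

Regional brain measures are prepared in two stages before association
testing: nuisance covariates (age, sex, scanner site, scan quality, genetic
principal components) are regressed out, and the residuals of each measure
are mapped to normal quantiles via their ranks so every downstream linear
model sees a normally distributed response.  "Relative" measures further
remove the matching global measure (total surface area for area parcels,
mean thickness for thickness parcels, intracranial volume for subcortical
volumes), isolating regional effects from overall brain size.

Because regional measures are strongly correlated, a Bonferroni correction
over the raw region count would be conservative; the effective number of
independent phenotypes t_e is estimated from the eigenvalues of the
inter-regional correlation matrix instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_COVARIATES = ("age", "sex", "site", "euler",
                      *(f"pc{i}" for i in range(1, 11)))

#: Modality pairing accepted by :func:`make_relative`.
GLOBAL_FOR_MODALITY = {
    "surface_area": "total_sa",
    "thickness": "mean_ct",
    "subcortical": "icv",
}


@dataclass
class PreparedMeasures:
    """Transformed residual matrix (participants x regions, z-units)."""

    data: pd.DataFrame
    covariates_removed: tuple[str, ...] = ()
    relative: bool = False
    int_applied: bool = False

    @property
    def regions(self) -> list[str]:
        return list(self.data.columns)

    def correlation(self) -> pd.DataFrame:
        return self.data.corr()


def design_matrix(covariates: pd.DataFrame, categorical=("site",)) -> np.ndarray:
    """Intercept + dummy-coded covariate design, with a rank check."""
    cols = [np.ones(len(covariates))]
    names = ["intercept"]
    for c in covariates.columns:
        if c in categorical:
            dummies = pd.get_dummies(covariates[c], prefix=c, drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(dtype=float))
                names.append(dc)
        else:
            cols.append(covariates[c].to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"collinear covariate columns: {bad}")
    return X


def residualize(
    measures: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    categorical=("site",),
) -> PreparedMeasures:
    """Regress nuisance covariates out of every measure column.

    With ``covariates=None`` the measures are simply mean-centered
    (intercept-only model).  Returned columns are orthogonal to every
    covariate column.  Residualization is idempotent.
    """
    if measures.isna().any().any():
        raise ValueError("measures contain missing values")
    if covariates is None or covariates.shape[1] == 0:
        X = np.ones((len(measures), 1))
        removed: tuple[str, ...] = ("intercept",)
    else:
        if covariates.isna().any().any():
            raise ValueError("covariates contain missing values")
        X = design_matrix(covariates, categorical=categorical)
        removed = ("intercept", *covariates.columns)
    Y = measures.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = pd.DataFrame(resid, index=measures.index, columns=measures.columns)
    return PreparedMeasures(data=out, covariates_removed=removed)


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transformation (Blom offsets).

    ``INT(x_i) = Phi^{-1}((r_i - 3/8) / (n + 1/4))`` where ``r_i`` is the
    average rank of ``x_i``.  Order-preserving; ties map to equal values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-d array")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(x) == 0:
        raise ValueError("constant input: ranks undefined")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def transform_measures(prepared: PreparedMeasures) -> PreparedMeasures:
    """Apply the inverse normal transformation column-wise."""
    out = prepared.data.apply(
        lambda col: inverse_normal_transform(col.to_numpy()), raw=False
    )
    return PreparedMeasures(
        data=out,
        covariates_removed=prepared.covariates_removed,
        relative=prepared.relative,
        int_applied=True,
    )


def make_relative(
    measures: PreparedMeasures | pd.DataFrame,
    global_measure,
    modality: str | None = None,
) -> PreparedMeasures:
    """Additionally residualize each region on its matching global measure.

    ``global_measure`` may be a Series/array (already validated by the
    caller) or, when ``modality`` is given, must carry the name matching
    :data:`GLOBAL_FOR_MODALITY` for that modality.
    """
    if isinstance(measures, PreparedMeasures):
        data = measures.data
        removed = measures.covariates_removed
    else:
        data = measures
        removed = ()
    g = np.asarray(global_measure, dtype=float)
    if np.ptp(g) == 0:
        raise ValueError("global measure is constant")
    if modality is not None:
        expected = GLOBAL_FOR_MODALITY.get(modality)
        name = getattr(global_measure, "name", None)
        if expected is None:
            raise ValueError(f"unknown modality {modality!r}")
        if name is not None and name != expected:
            raise ValueError(
                f"modality {modality!r} pairs with {expected!r}, got {name!r}"
            )
    X = np.column_stack([np.ones(len(g)), g])
    Y = data.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = pd.DataFrame(resid, index=data.index, columns=data.columns)
    gname = getattr(global_measure, "name", "global")
    return PreparedMeasures(
        data=out,
        covariates_removed=(*removed, gname or "global"),
        relative=True,
    )


@dataclass
class EffectiveTests:
    """Effective number of independent phenotypes from eigenvalues."""

    t_e: float
    t_e_nyholt: float
    eigenvalues: np.ndarray = field(repr=False)
    method: str = "li-ji"

    @property
    def m(self) -> int:
        return len(self.eigenvalues)


def effective_tests(corr, method: str = "li-ji", tol: float = 1e-6) -> EffectiveTests:
    """Effective number of independent tests from a correlation matrix.

    Li-Ji (default): ``t_e = sum_i [ 1(lam_i >= 1) + (lam_i - floor(lam_i)) ]``.
    Nyholt: ``t_e = 1 + (M - 1) * (1 - Var(lam) / M)`` with the sample
    variance of the eigenvalues.  Both are returned; ``method`` selects
    which populates ``t_e``.

    The input must be symmetric with unit diagonal and positive
    semidefinite within ``tol``.
    """
    C = np.asarray(corr, dtype=float)
    if isinstance(corr, pd.DataFrame):
        C = corr.to_numpy(dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=tol):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(C)
    if lam.min() < -tol:
        raise ValueError("correlation matrix is not positive semidefinite")
    lam = np.clip(lam[::-1], 0.0, None)  # descending
    m = len(lam)

    # snap near-integer eigenvalues so floor() is stable at exact values
    lam_snap = np.where(np.isclose(lam, np.round(lam), atol=1e-9),
                        np.round(lam), lam)
    li_ji = float(np.sum((lam_snap >= 1.0).astype(float)
                         + (lam_snap - np.floor(lam_snap))))
    nyholt = float(1.0 + (m - 1) * (1.0 - np.var(lam, ddof=1) / m)) if m > 1 else 1.0

    if method not in ("li-ji", "nyholt"):
        raise ValueError(f"unknown method {method!r}")
    t_e = li_ji if method == "li-ji" else nyholt
    return EffectiveTests(t_e=t_e, t_e_nyholt=nyholt, eigenvalues=lam, method=method)
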