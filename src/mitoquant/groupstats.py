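"""Hierarchical group comparison: random-intercept LMM and Tukey contrasts.

Per-neuron metrics are compared across the sex x genotype grid while
accounting for repeated measures within animals: a linear mixed model

    y_ij = x_ij' beta + u_animal(i) + e_ij,   u ~ N(0, sigma_u^2),
                                              e ~ N(0, sigma_e^2)

with genotype, sex and their interaction as fixed effects and animal as a
random intercept.  The model is fitted by restricted maximum likelihood,
profiling the variance ratio lambda = sigma_u^2 / sigma_e^2 by 1-D
optimization (the per-group Woodbury identity makes each evaluation O(n)).
Estimated marginal means over the four cells feed all six pairwise
contrasts, with family-wise adjustment from the studentized-range (Tukey)
distribution.  The error degrees of freedom use the containment rule,
``total animals - 4``; this is slightly more conservative than the
Kenward-Roger or Satterthwaite approximations used by some software.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import studentized_range, t as t_dist

from .errors import DesignError, FitError

CELL_ORDER: tuple[tuple[str, str], ...] = (
    ("male", "WT"),
    ("female", "WT"),
    ("male", "KO"),
    ("female", "KO"),
)


@dataclass(frozen=True)
class LMMFit:
    """Random-intercept model fit for one response."""

    response: str
    beta: np.ndarray
    beta_names: tuple[str, ...]
    cov_beta: np.ndarray
    sigma_u: float
    sigma_e: float
    lambda_ratio: float
    reml_loglik: float
    n_obs: int
    n_animals: int
    df_error: int
    cell_rows: np.ndarray  # (4, p) design rows mapping beta -> cell means


def _design(records: pd.DataFrame, response: str):
    required = {"animal_id", "sex", "genotype", response}
    missing = required - set(records.columns)
    if missing:
        raise DesignError(f"records missing columns {sorted(missing)}")
    y = np.asarray(records[response], dtype=float)
    if not np.isfinite(y).all():
        raise DesignError(f"non-finite values in response {response!r}")
    is_female = (records["sex"] == "female").to_numpy(dtype=float)
    is_ko = (records["genotype"] == "KO").to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(y)), is_ko, is_female, is_ko * is_female]
    )
    names = ("intercept", "genotype[KO]", "sex[female]", "genotype:sex")
    animals, groups = np.unique(records["animal_id"], return_inverse=True)
    # every animal must map to one cell
    cells = records.groupby("animal_id", sort=False)[["sex", "genotype"]].nunique()
    if (cells > 1).any().any():
        raise DesignError("an animal maps to more than one sex x genotype cell")
    present = set(zip(records["sex"], records["genotype"]))
    for cell in CELL_ORDER:
        if cell not in present:
            raise DesignError(f"cell {cell} has no animals")
    cell_rows = np.array(
        [
            [1.0, g == "KO", s == "female", (g == "KO") and (s == "female")]
            for s, g in CELL_ORDER
        ],
        dtype=float,
    )
    return y, X, groups, len(animals), names, cell_rows


def _reml_pieces(lam: float, y, X, groups, n_groups):
    """GLS quantities for V = I + lam * Z Z' via the per-group Woodbury form."""
    n, p = X.shape
    counts = np.bincount(groups, minlength=n_groups).astype(float)
    shrink = lam / (1.0 + lam * counts)  # per group

    def vinv(M):
        M = np.atleast_2d(M.T).T
        sums = np.zeros((n_groups, M.shape[1]))
        np.add.at(sums, groups, M)
        return M - (shrink[groups, None] * sums[groups])

    ViX = vinv(X)
    Viy = vinv(y[:, None])[:, 0]
    XtViX = X.T @ ViX
    XtViy = X.T @ Viy
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular fixed-effect design") from exc
    resid = y - X @ beta
    rss_v = float(resid @ vinv(resid[:, None])[:, 0])
    logdet_v = float(np.sum(np.log1p(lam * counts)))
    sign, logdet_xvx = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise FitError("X' V^-1 X not positive definite")
    return beta, XtViX, rss_v, logdet_v, logdet_xvx


def reml_criterion(lam: float, y, X, groups, n_groups) -> float:
    """Profiled REML log-likelihood at variance ratio ``lam`` (up to a constant)."""
    n, p = X.shape
    _, _, rss_v, logdet_v, logdet_xvx = _reml_pieces(lam, y, X, groups, n_groups)
    if rss_v <= 0:
        return -np.inf
    return -0.5 * (
        (n - p) * np.log(rss_v) + logdet_v + logdet_xvx
    )


def fit_lmm(records: pd.DataFrame, response: str) -> LMMFit:
    """Fit the random-intercept model for ``response`` by profiled REML.

    The variance ratio is located by a coarse log-scale grid followed by
    bounded scalar minimization (tolerance well below 1e-8 on lambda), with
    the OLS boundary lambda = 0 always considered.
    """
    y, X, groups, n_animals, names, cell_rows = _design(records, response)
    n, p = X.shape
    if n_animals < 2:
        raise FitError("at least 2 animals are required to separate variance components")

    def neg(loglam):
        return -reml_criterion(np.exp(loglam), y, X, groups, n_animals)

    grid = np.linspace(np.log(1e-8), np.log(1e8), 81)
    vals = np.array([neg(g) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        neg, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-13},
    )
    lam = float(np.exp(res.x))
    ll = -float(res.fun)
    # boundary check: pure OLS (sigma_u = 0)
    ll0 = reml_criterion(0.0, y, X, groups, n_animals)
    if ll0 >= ll:
        lam, ll = 0.0, ll0

    beta, XtViX, rss_v, _, _ = _reml_pieces(lam, y, X, groups, n_animals)
    sigma_e2 = rss_v / (n - p)
    sigma_u2 = lam * sigma_e2
    cov_beta = sigma_e2 * np.linalg.inv(XtViX)
    return LMMFit(
        response=response,
        beta=beta,
        beta_names=names,
        cov_beta=cov_beta,
        sigma_u=float(np.sqrt(sigma_u2)),
        sigma_e=float(np.sqrt(sigma_e2)),
        lambda_ratio=lam,
        reml_loglik=ll,
        n_obs=n,
        n_animals=n_animals,
        df_error=n_animals - 4,
        cell_rows=cell_rows,
    )


def estimated_marginal_means(fit: LMMFit) -> pd.DataFrame:
    """Model-based means of the four sex x genotype cells with SEs."""
    means = fit.cell_rows @ fit.beta
    ses = np.sqrt(np.einsum("ij,jk,ik->i", fit.cell_rows, fit.cov_beta, fit.cell_rows))
    return pd.DataFrame(
        {
            "sex": [c[0] for c in CELL_ORDER],
            "genotype": [c[1] for c in CELL_ORDER],
            "emmean": means,
            "se": ses,
        }
    )


def tukey_contrasts(fit: LMMFit) -> pd.DataFrame:
    """All six pairwise cell contrasts with Tukey family-wise adjustment.

    The adjusted p-value is ``P(q_{4, df} >= sqrt(2) |t|)`` from the
    studentized-range distribution; the unadjusted value is the two-sided
    t probability at the containment degrees of freedom.
    """
    if fit.df_error <= 0:
        raise DesignError(
            f"error degrees of freedom {fit.df_error} <= 0 "
            f"({fit.n_animals} animals for 4 cells)"
        )
    rows = []
    k = len(CELL_ORDER)
    for i, j in itertools.combinations(range(k), 2):
        L = fit.cell_rows[i] - fit.cell_rows[j]
        est = float(L @ fit.beta)
        se = float(np.sqrt(L @ fit.cov_beta @ L))
        tval = est / se if se > 0 else np.inf
        p_unadj = 2 * float(t_dist.sf(abs(tval), fit.df_error))
        p_adj = float(
            studentized_range.sf(abs(tval) * np.sqrt(2.0), k, fit.df_error)
        )
        p_adj = min(max(p_adj, p_unadj), 1.0)
        name_i = f"{CELL_ORDER[i][0]} {CELL_ORDER[i][1]}"
        name_j = f"{CELL_ORDER[j][0]} {CELL_ORDER[j][1]}"
        rows.append(
            {
                "contrast": f"{name_i} - {name_j}",
                "estimate": est,
                "se": se,
                "t": tval,
                "df": fit.df_error,
                "p_unadjusted": p_unadj,
                "p_tukey": p_adj,
            }
        )
    return pd.DataFrame(rows)
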