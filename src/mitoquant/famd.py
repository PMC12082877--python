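"""Factor analysis of mixed data (FAMD).

Joint dimension reduction of quantitative morphometric/integrity metrics and
qualitative sex/genotype labels: quantitative columns enter as in a
correlation PCA, qualitative columns as in multiple correspondence analysis,
normalized so each set of variables carries balanced influence.

Construction: quantitative columns are standardized to mean 0, variance 1
(divisor n, the FactoMineR convention); each qualitative level's indicator
column is divided by the square root of its observed proportion and then
centered.  The singular value decomposition of the combined n x (K + M)
matrix scaled by 1/sqrt(n) yields eigenvalues (squared singular values),
per-variable contributions, quantitative correlation-circle coordinates, and
row factor scores.  Total inertia is K + sum(c_q - 1), so a table with three
quantitative variables and two 2-level qualitative variables has exactly
five nontrivial dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

#: eigenvalues below this fraction of total inertia are numerically null
_NULL_EIGENVALUE_TOL = 1e-10


@dataclass(frozen=True)
class FAMDResult:
    """Eigenstructure of a factor analysis of mixed data."""

    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    cumulative_percent: np.ndarray
    contributions: pd.DataFrame  # variables x dimensions, percent
    quant_correlations: pd.DataFrame  # quantitative variables x dimensions
    row_scores: np.ndarray  # n x dims
    quant_vars: tuple[str, ...]
    quali_vars: tuple[str, ...]

    @property
    def n_dimensions(self) -> int:
        return len(self.eigenvalues)


def famd_dimension_count(
    n_quant: int, category_counts: Sequence[int]
) -> int:
    """Number of nontrivial FAMD dimensions: K + sum(c_q - 1)."""
    if n_quant < 0 or any(c < 2 for c in category_counts):
        raise ConfigError("need n_quant >= 0 and >= 2 categories per variable")
    return n_quant + sum(c - 1 for c in category_counts)


def famd_fit(
    data: pd.DataFrame,
    quant_vars: Sequence[str],
    quali_vars: Sequence[str],
    n_components: int | None = None,
) -> FAMDResult:
    """Fit a FAMD on mixed columns of ``data``.

    ``quant_vars`` must be finite numeric columns with positive variance;
    ``quali_vars`` categorical columns with at least two observed levels.
    Missing values are not supported.  The sign of each dimension is fixed
    by forcing its largest-magnitude quantitative loading (or, lacking
    quantitative variables, its largest-magnitude loading) positive.
    """
    quant_vars = tuple(quant_vars)
    quali_vars = tuple(quali_vars)
    if not quant_vars and not quali_vars:
        raise ConfigError("at least one variable is required")
    n = len(data)
    if n < 2:
        raise ConfigError("need at least 2 rows")

    blocks: list[np.ndarray] = []
    col_var: list[str] = []  # owning variable per processed column
    col_name: list[str] = []
    for v in quant_vars:
        x = np.asarray(data[v], dtype=float)
        if not np.isfinite(x).all():
            raise ConfigError(f"non-finite values in quantitative column {v!r}")
        sd = x.std()  # divisor n
        if sd == 0:
            raise ConfigError(f"zero-variance quantitative column {v!r}")
        blocks.append(((x - x.mean()) / sd)[:, None])
        col_var.append(v)
        col_name.append(v)
    for v in quali_vars:
        levels = pd.unique(data[v])
        if len(levels) < 2:
            raise ConfigError(f"qualitative column {v!r} has a single level")
        for lev in levels:
            ind = (data[v] == lev).to_numpy(dtype=float)
            p = ind.mean()
            z = ind / np.sqrt(p)
            blocks.append((z - z.mean())[:, None])
            col_var.append(v)
            col_name.append(f"{v}={lev}")
    Z = np.hstack(blocks)

    U, S, Vt = np.linalg.svd(Z / np.sqrt(n), full_matrices=False)
    eig = S**2
    total = len(quant_vars) + sum(
        len(pd.unique(data[v])) - 1 for v in quali_vars
    )
    keep = eig > _NULL_EIGENVALUE_TOL * max(total, 1)
    eig, U, S, Vt = eig[keep], U[:, keep], S[keep], Vt[keep]
    if n_components is not None:
        eig, U, S, Vt = (
            eig[:n_components],
            U[:, :n_components],
            S[:n_components],
            Vt[:n_components],
        )
    V = Vt.T  # columns: loadings per dimension

    # sign convention
    n_q = len(quant_vars)
    for s_i in range(V.shape[1]):
        ref = V[:n_q, s_i] if n_q else V[:, s_i]
        j = int(np.argmax(np.abs(ref)))
        if ref[j] < 0:
            V[:, s_i] *= -1
            U[:, s_i] *= -1

    dims = [f"dim{i + 1}" for i in range(len(eig))]
    contrib_cols = 100.0 * V**2  # per processed column, sums to 100 per dim
    contrib = (
        pd.DataFrame(contrib_cols, index=col_var, columns=dims)
        .groupby(level=0, sort=False)
        .sum()
        .reindex(list(quant_vars) + list(quali_vars))
    )
    # correlation of each standardized quantitative column with each dimension
    corr = pd.DataFrame(
        V[:n_q] * S[None, :], index=list(quant_vars), columns=dims
    )
    scores = U * S[None, :] * np.sqrt(n)

    percent = 100.0 * eig / eig.sum()
    return FAMDResult(
        eigenvalues=eig,
        percent_variance=percent,
        cumulative_percent=np.cumsum(percent),
        contributions=contrib,
        quant_correlations=corr,
        row_scores=scores,
        quant_vars=quant_vars,
        quali_vars=quali_vars,
    )


def famd_scores_by_group(
    result: FAMDResult, labels: pd.DataFrame
) -> pd.DataFrame:
    """Dim-1/dim-2 row coordinates tagged with grouping labels.

    ``labels`` must have one row per analyzed individual (typically the
    sex/genotype columns of the input table).
    """
    if len(labels) != result.row_scores.shape[0]:
        raise ConfigError(
            f"label rows ({len(labels)}) do not match scores "
            f"({result.row_scores.shape[0]})"
        )
    out = labels.reset_index(drop=True).copy()
    n_dims = min(2, result.row_scores.shape[1])
    for i in range(n_dims):
        out[f"dim{i + 1}"] = result.row_scores[:, i]
    return out
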