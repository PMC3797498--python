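"""Mantel, partial Mantel, and multiple regression on distance matrices (MRM).

All tests are permutational: the rows and columns of the response distance
matrix are permuted simultaneously (a relabeling of plots), and p-values use
the add-one estimator p = (1 + #{stat_perm >= stat_obs}) / (n_perm + 1), so
p is never 0 and never smaller than 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ecoassembly.data import ValidationError
from ecoassembly.distance import DistanceMatrix

TAILS = ("greater", "two-sided")


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    tail: str


@dataclass(frozen=True)
class MrmResult:
    """OLS on condensed distance vectors with permutational inference."""

    predictor_names: tuple
    coefficients: np.ndarray  # intercept first
    coefficient_p_values: np.ndarray  # permutational, two-sided on |t|; NaN for intercept
    r2: float
    r2_p_value: float
    n_permutations: int


def _aligned_condensed(*mats: DistanceMatrix) -> list[np.ndarray]:
    ids = mats[0].plot_ids
    for m in mats[1:]:
        if m.plot_ids != ids:
            raise ValidationError("distance matrices have different plots or plot order")
    if len(ids) < 4:
        raise ValidationError("need at least 4 plots for a Mantel-type test")
    out = []
    for m in mats:
        v = m.condensed
        if not np.isfinite(v).all():
            raise ValidationError(
                "distance matrix contains non-finite entries; drop degenerate pairs first"
            )
        out.append(v)
    return out


def _check_variance(vec: np.ndarray, name: str) -> None:
    if np.ptp(vec) == 0:
        raise ValidationError(f"condensed {name} has zero variance")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        # residual vector vanished (e.g. partial Mantel of A controlling A)
        return 0.0
    return float(a @ b / denom)


def _permuted_condensed(values: np.ndarray, perm: np.ndarray, iu) -> np.ndarray:
    """Condensed form of the matrix after relabeling plots by ``perm``."""
    return values[perm[iu[0]], perm[iu[1]]]


def _pvalue(obs: float, perms: np.ndarray, tail: str) -> float:
    if tail == "greater":
        k = int(np.sum(perms >= obs - 1e-12))
    elif tail == "two-sided":
        k = int(np.sum(np.abs(perms) >= abs(obs) - 1e-12))
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    return (1 + k) / (len(perms) + 1)


def mantel_test(
    A: DistanceMatrix,
    B: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    tail: str = "greater",
) -> MantelResult:
    """Mantel test: Pearson correlation of two condensed distance matrices.

    Significance by simultaneously permuting the rows and columns of ``A``.
    The default one-sided (greater) tail suits directional hypotheses such as
    turnover increasing with distance; use ``tail="two-sided"`` otherwise.
    """
    a, b = _aligned_condensed(A, B)
    _check_variance(a, "A")
    _check_variance(b, "B")
    r_obs = _pearson(a, b)
    n = A.n
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        r_perm[i] = _pearson(_permuted_condensed(A.values, perm, iu), b)
    return MantelResult(r_obs, _pvalue(r_obs, r_perm, tail), n_perm, tail)


def mantel_exact_p(A: DistanceMatrix, B: DistanceMatrix, tail: str = "greater") -> float:
    """Exact Mantel p-value by enumerating all n! relabelings (tiny n only)."""
    from itertools import permutations

    a, b = _aligned_condensed(A, B)
    r_obs = _pearson(a, b)
    n = A.n
    if n > 7:
        raise ValidationError("exact enumeration is limited to n <= 7")
    iu = np.triu_indices(n, k=1)
    rs = np.array(
        [_pearson(_permuted_condensed(A.values, np.array(p), iu), b) for p in permutations(range(n))]
    )
    if tail == "greater":
        return float(np.mean(rs >= r_obs - 1e-12))
    return float(np.mean(np.abs(rs) >= abs(r_obs) - 1e-12))


def _residualize(v: np.ndarray, c: np.ndarray) -> np.ndarray:
    c = c - c.mean()
    v = v - v.mean()
    denom = c @ c
    if denom == 0:
        return v
    return v - (v @ c / denom) * c


def partial_mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    C: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    tail: str = "greater",
) -> MantelResult:
    """Partial Mantel test: correlation of A and B controlling for C.

    r is the Pearson correlation between the residuals of condensed A on
    condensed C and the residuals of condensed B on condensed C (the
    first-order partial correlation). Permutations relabel the raw ``A``
    matrix before residualization.
    """
    a, b, c = _aligned_condensed(A, B, C)
    _check_variance(a, "A")
    _check_variance(b, "B")
    res_b = _residualize(b, c)
    r_obs = _pearson(_residualize(a, c), res_b)
    n = A.n
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        a_p = _permuted_condensed(A.values, perm, iu)
        r_perm[i] = _pearson(_residualize(a_p, c), res_b)
    return MantelResult(r_obs, _pvalue(r_obs, r_perm, tail), n_perm, tail)


def mrm(
    Y: DistanceMatrix,
    predictors: list[DistanceMatrix],
    n_perm: int = 999,
    seed: int = 0,
) -> MrmResult:
    """Multiple regression of a response distance matrix on predictor
    distance matrices (condensed vectors), with permutational p-values.

    Coefficient significance uses two-sided tests on the t-statistics under
    simultaneous row/column permutation of ``Y``; the overall R^2 test is
    one-sided (greater).
    """
    if not predictors:
        raise ValidationError("mrm needs at least one predictor matrix")
    vecs = _aligned_condensed(Y, *predictors)
    y, xs = vecs[0], vecs[1:]
    _check_variance(y, "Y")
    X = np.column_stack([np.ones_like(y)] + list(xs))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("predictor distance matrices are collinear in condensed form")

    def fit(yv: np.ndarray):
        coef, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ coef
        ss_res = resid @ resid
        ss_tot = ((yv - yv.mean()) ** 2).sum()
        r2 = 1.0 - ss_res / ss_tot
        dof = len(yv) - X.shape[1]
        sigma2 = ss_res / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        t = coef / np.sqrt(np.diag(cov))
        return coef, t, r2

    coef_obs, t_obs, r2_obs = fit(y)
    n = Y.n
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    t_perm = np.empty((n_perm, X.shape[1]))
    r2_perm = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        _, t_perm[i], r2_perm[i] = fit(_permuted_condensed(Y.values, perm, iu))
    k = np.sum(np.abs(t_perm) >= np.abs(t_obs)[None, :] - 1e-12, axis=0)
    p_coef = (1 + k) / (n_perm + 1.0)
    p_coef[0] = np.nan  # intercept is not tested
    names = tuple(f"X{i + 1}" for i in range(len(xs)))
    return MrmResult(
        predictor_names=names,
        coefficients=coef_obs,
        coefficient_p_values=p_coef,
        r2=float(r2_obs),
        r2_p_value=_pvalue(r2_obs, r2_perm, "greater"),
        n_permutations=n_perm,
    )
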