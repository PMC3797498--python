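"""Redundancy analysis (RDA), permutation F-tests, forward selection and
variation partitioning.

RDA is multivariate least squares of a (Hellinger-transformed,
column-centered) community matrix on a predictor matrix, followed by an
eigendecomposition of the fitted values; its R^2 is the fraction of total
community variance captured by the projection. Explained fractions from
predictor sets of different sizes are made comparable with Ezekiel's
adjusted R^2. The variation in community composition is partitioned into a
pure environmental fraction [E|S], a spatially structured environmental
fraction [E&S], a pure spatial fraction [S|E], and an unexplained residual;
the two conditional fractions are testable by reduced-model permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr as _pivoted_qr

from ecoassembly.data import ValidationError

_RANK_TOL = 1e-10


def _as_matrix(obj) -> tuple[np.ndarray, list[str]]:
    if obj is None:
        return np.empty((0, 0)), []
    if isinstance(obj, pd.DataFrame):
        return obj.to_numpy(dtype=float), [str(c) for c in obj.columns]
    arr = np.asarray(obj, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"V{i + 1}" for i in range(arr.shape[1])]


def _center(m: np.ndarray) -> np.ndarray:
    return m - m.mean(axis=0, keepdims=True)


def _basis(m: np.ndarray, names: list[str] | None = None, require_full_rank: bool = True):
    """Orthonormal basis of the column space of an (already centered) matrix.

    Raises listing the dependent columns when ``require_full_rank`` and the
    matrix is rank deficient.
    """
    if m.size == 0 or m.shape[1] == 0:
        return np.empty((m.shape[0], 0))
    q, r, piv = _pivoted_qr(m, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    ref = diag[0] if diag.size and diag[0] > 0 else 1.0
    rank = int(np.sum(diag > _RANK_TOL * ref))
    if require_full_rank and rank < m.shape[1]:
        bad = sorted(piv[rank:])
        labels = [names[i] for i in bad] if names else [str(i) for i in bad]
        raise ValidationError(f"rank-deficient predictors; dependent columns: {labels}")
    return q[:, :rank]


@dataclass(frozen=True)
class RdaResult:
    """Fit of a (partial) redundancy analysis.

    For a partial RDA, ``r2`` is the semipartial fraction: explained sum of
    squares of the conditioned predictors over the *total* sum of squares of
    the response, and ``adj_r2`` is the difference of Ezekiel-adjusted R^2
    between the full (X union W) and conditioning-only (W) models.
    """

    r2: float
    adj_r2: float
    canonical_eigenvalues: np.ndarray
    f_statistic: float
    p_value: float | None
    n: int
    m: int
    q: int = 0  # number of conditioning variables


@dataclass(frozen=True)
class ForwardSelectionStep:
    variable: str
    adj_r2_cum: float
    f_statistic: float
    p_value: float


@dataclass(frozen=True)
class ForwardSelectionResult:
    steps: tuple
    candidate_pool: tuple
    alpha: float
    n_permutations: int
    stopped_by: str  # "alpha" | "double_stop" | "exhausted"

    @property
    def selected(self) -> list[str]:
        return [s.variable for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.variable, s.adj_r2_cum, s.f_statistic, s.p_value) for s in self.steps],
            columns=["variable", "AdjR2Cum", "F", "P"],
        )


@dataclass(frozen=True)
class VariationPartition:
    """Adjusted-R^2 decomposition of community variation.

    The four fractions sum to 1 exactly by construction. The intersection
    [E&S] is not an R^2 of any model and may be negative; it is reported as
    computed, never clamped, and carries no significance test.
    """

    fraction_E_given_S: float
    fraction_intersection: float
    fraction_S_given_E: float
    residual: float
    adj_r2_E: float
    adj_r2_S: float
    adj_r2_total: float
    p_E_given_S: float | None
    p_S_given_E: float | None
    p_total: float | None
    n_permutations: int

    def fractions(self) -> dict:
        return {
            "E|S": self.fraction_E_given_S,
            "E&S": self.fraction_intersection,
            "S|E": self.fraction_S_given_E,
            "residual": self.residual,
        }

    def percents_of_explained(self) -> dict:
        """The three explained fractions as percents of total explained
        variation (the cross-layer comparison view)."""
        total = self.adj_r2_total
        if total <= 0:
            return {"E|S": np.nan, "E&S": np.nan, "S|E": np.nan}
        return {
            "E|S": 100.0 * self.fraction_E_given_S / total,
            "E&S": 100.0 * self.fraction_intersection / total,
            "S|E": 100.0 * self.fraction_S_given_E / total,
        }


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel's adjustment: 1 - (1 - R^2) (n - 1) / (n - m - 1)."""
    if m == 0:
        return float(r2)
    if n <= m + 1:
        raise ValidationError(f"adjusted R^2 undefined for n={n}, m={m} (need n > m + 1)")
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - m - 1))


def rda(Y, X, n_perm: int | None = None, seed: int = 0) -> RdaResult:
    """Redundancy analysis of a response matrix on a predictor matrix.

    Fitted values are the least-squares projection of the column-centered
    response onto the column space of the centered predictors; R^2 is
    SS(fitted) / SS(response) and the canonical eigenvalues decompose the
    fitted variance. With ``n_perm`` set, significance is assessed by a
    permutation F-test (free row permutation of the response).
    """
    y, _ = _as_matrix(Y)
    x, x_names = _as_matrix(X)
    n = y.shape[0]
    m = x.shape[1]
    if x.shape[0] != n:
        raise ValidationError("response and predictors have different numbers of plots")
    if n <= m + 1:
        raise ValidationError(f"n={n} plots cannot support m={m} predictors (need n > m + 1)")
    yc = _center(y)
    q_x = _basis(_center(x), x_names)
    fitted = q_x @ (q_x.T @ yc)
    ss_tot = float(np.sum(yc**2))
    if ss_tot == 0:
        raise ValidationError("response has zero variance")
    ss_fit = float(np.sum(fitted**2))
    r2 = ss_fit / ss_tot
    sing = np.linalg.svd(fitted, compute_uv=False)
    eig = (sing**2) / (n - 1)
    eig = eig[eig > _RANK_TOL * max(eig[0], 1.0)] if eig.size else eig
    f = (ss_fit / m) / ((ss_tot - ss_fit) / (n - m - 1)) if ss_fit < ss_tot else np.inf
    p = None
    if n_perm:
        _, p = permutation_f_test(Y, X, n_perm=n_perm, seed=seed)
    return RdaResult(r2, adjusted_r2(r2, n, m), eig, float(f), p, n, m, 0)


def partial_rda(Y, X, W, n_perm: int | None = None, seed: int = 0) -> RdaResult:
    """Partial RDA: effect of ``X`` on ``Y`` after removing the part of both
    explained by the conditioning variables ``W``.

    Reported ``r2`` is the semipartial fraction of the total response sum of
    squares; ``adj_r2`` is adjR^2(X union W) - adjR^2(W). With ``n_perm``
    set, significance uses reduced-model permutation of the residuals of the
    response on ``W``.
    """
    w, _ = _as_matrix(W)
    if w.shape[1] == 0:
        return rda(Y, X, n_perm=n_perm, seed=seed)
    y, _ = _as_matrix(Y)
    x, x_names = _as_matrix(X)
    n = y.shape[0]
    m, qn = x.shape[1], w.shape[1]
    if n <= m + qn + 1:
        raise ValidationError(f"n={n} plots cannot support m={m} + q={qn} predictors")
    yc = _center(y)
    xc, wc = _center(x), _center(w)
    q_w = _basis(wc, require_full_rank=False)
    y_res = yc - q_w @ (q_w.T @ yc)
    x_res = xc - q_w @ (q_w.T @ xc)
    # columns of X inside span(W) have nothing left to explain: drop them
    orig_norm = np.linalg.norm(xc, axis=0)
    res_norm = np.linalg.norm(x_res, axis=0)
    kept = res_norm > 1e-8 * np.maximum(orig_norm, 1e-30)
    if not kept.any():
        return RdaResult(0.0, 0.0, np.empty(0), 0.0, None, n, m, qn)
    x_res = x_res[:, kept]
    m = int(kept.sum())
    q_x = _basis(x_res, [nm for nm, k in zip(x_names, kept) if k])
    fitted = q_x @ (q_x.T @ y_res)
    ss_tot = float(np.sum(yc**2))
    ss_x = float(np.sum(fitted**2))
    ss_res = float(np.sum(y_res**2)) - ss_x
    r2 = ss_x / ss_tot
    sing = np.linalg.svd(fitted, compute_uv=False)
    eig = (sing**2) / (n - 1)
    eig = eig[eig > _RANK_TOL * max(eig[0], 1.0)] if eig.size else eig
    dof = n - m - qn - 1
    f = (ss_x / m) / (ss_res / dof) if ss_res > 0 else np.inf
    r2_w = float(np.sum((q_w @ (q_w.T @ yc)) ** 2)) / ss_tot
    r2_xw = r2_w + r2
    adj = adjusted_r2(r2_xw, n, m + qn) - adjusted_r2(r2_w, n, qn)
    p = None
    if n_perm:
        _, p = permutation_f_test(Y, X, W, n_perm=n_perm, seed=seed)
    return RdaResult(r2, adj, eig, float(f), p, n, m, qn)


def permutation_f_test(
    Y, X, W=None, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Permutation F-test for (partial) RDA.

    F = (SS_explained / m) / (SS_residual / (n - m - q - 1)). With
    conditioning variables the null distribution permutes the rows of the
    residuals of the response on ``W`` (reduced-model permutation); without
    conditioning it permutes the response rows freely. p uses the add-one
    estimator.
    """
    y, _ = _as_matrix(Y)
    x, x_names = _as_matrix(X)
    w, _ = _as_matrix(W)
    n = y.shape[0]
    m, qn = x.shape[1], w.shape[1]
    if n <= m + qn + 1:
        raise ValidationError(f"n={n} plots cannot support m={m} + q={qn} predictors")
    yc = _center(y)
    xc = _center(x)
    if qn:
        wc = _center(w)
        q_w = _basis(wc, require_full_rank=False)
        y_res = yc - q_w @ (q_w.T @ yc)
        x_res = xc - q_w @ (q_w.T @ xc)
    else:
        q_w = np.empty((n, 0))
        y_res, x_res = yc, xc
    q_x = _basis(x_res, x_names)
    dof = n - m - qn - 1
    ss_yr = float(np.sum(y_res**2))

    def f_of(mat: np.ndarray) -> float:
        # permuted residuals are no longer orthogonal to W: re-residualize,
        # which only changes the total SS (q_x is already orthogonal to q_w)
        ss_x = float(np.sum((q_x.T @ mat) ** 2))
        ss_w = float(np.sum((q_w.T @ mat) ** 2)) if qn else 0.0
        resid = ss_yr - ss_w - ss_x
        if resid <= 0:
            return np.inf
        return (ss_x / m) / (resid / dof)

    f_obs = f_of(y_res)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        # row permutation leaves ss_yr unchanged, so only the projection moves
        if f_of(y_res[rng.permutation(n)]) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return float(f_obs), float(p)


def forward_select(
    Y,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    double_stop: bool = False,
    max_select: int | None = None,
) -> ForwardSelectionResult:
    """Greedy forward selection of predictors for RDA.

    At each step the candidate adding the most explained variance (given the
    already-selected set) is tested by a conditioned permutation F-test;
    selection stops when the best candidate's p exceeds ``alpha`` (or, with
    ``double_stop``, when the cumulative adjusted R^2 would exceed that of
    the full candidate model, or after ``max_select`` variables). Ties are
    broken by candidate order, and the whole procedure is deterministic
    given ``seed``.
    """
    if candidates.shape[1] < 1:
        raise ValidationError("need at least one candidate variable")
    y, _ = _as_matrix(Y)
    n = y.shape[0]
    yc = _center(y)
    ss_tot = float(np.sum(yc**2))
    names = [str(c) for c in candidates.columns]
    cand = _center(candidates.to_numpy(dtype=float))
    full_adj = None
    if double_stop:
        q_full = _basis(cand[:, :], require_full_rank=False)
        r2_full = float(np.sum((q_full.T @ yc) ** 2)) / ss_tot
        full_adj = adjusted_r2(r2_full, n, q_full.shape[1])

    selected: list[int] = []
    steps: list[ForwardSelectionStep] = []
    seed_seq = np.random.SeedSequence(seed)
    stopped_by = "exhausted"
    limit = min(len(names), n - 2)
    if max_select is not None:
        limit = min(limit, max_select)
    while len(selected) < limit:
        q_sel = (
            _basis(cand[:, selected], require_full_rank=False)
            if selected
            else np.empty((n, 0))
        )
        y_res = yc - q_sel @ (q_sel.T @ yc)
        best_j, best_ss = -1, -np.inf
        for j in range(cand.shape[1]):
            if j in selected:
                continue
            u = cand[:, j] - q_sel @ (q_sel.T @ cand[:, j])
            norm = np.linalg.norm(u)
            if norm < 1e-10:  # collinear with the selected set
                continue
            u = u / norm
            ss = float(np.sum((u @ y_res) ** 2))
            if ss > best_ss + 1e-15:
                best_j, best_ss = j, ss
        if best_j < 0:
            break
        step_seed = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
        f, p = permutation_f_test(
            yc,
            cand[:, [best_j]],
            cand[:, selected] if selected else None,
            n_perm=n_perm,
            seed=step_seed,
        )
        if p > alpha:
            stopped_by = "alpha"
            break
        trial = selected + [best_j]
        q_trial = _basis(cand[:, trial], require_full_rank=False)
        r2_cum = float(np.sum((q_trial.T @ yc) ** 2)) / ss_tot
        adj_cum = adjusted_r2(r2_cum, n, len(trial))
        if double_stop and full_adj is not None and adj_cum > full_adj:
            stopped_by = "double_stop"
            break
        selected = trial
        steps.append(ForwardSelectionStep(names[best_j], adj_cum, f, p))
    if stopped_by == "exhausted" and max_select is not None and len(selected) == max_select:
        stopped_by = "max_select"
    return ForwardSelectionResult(
        steps=tuple(steps),
        candidate_pool=tuple(names),
        alpha=alpha,
        n_permutations=n_perm,
        stopped_by=stopped_by,
    )


def variation_partitioning(
    Y, E, S, n_perm: int | None = 999, seed: int = 0
) -> VariationPartition:
    """Partition community variation between environmental and spatial
    predictor blocks using adjusted R^2.

    With a = adjR^2(E union S), b = adjR^2(E), c = adjR^2(S):
    [E|S] = a - c, [S|E] = a - b, [E&S] = b + c - a, residual = 1 - a; the
    four values sum to 1 exactly. Conditional fractions are tested by
    reduced-model partial-RDA permutation; the intersection is not testable.
    """
    e, e_names = _as_matrix(E)
    s, s_names = _as_matrix(S)
    if e.shape[1] == 0 and s.shape[1] == 0:
        raise ValidationError("both predictor blocks are empty")
    y, _ = _as_matrix(Y)
    n = y.shape[0]
    yc = _center(y)
    ss_tot = float(np.sum(yc**2))
    if ss_tot == 0:
        raise ValidationError("response has zero variance")

    def block_adj(mat) -> float:
        # project onto the block's column SPACE: rank-deficient unions (e.g.
        # identical E and S) are handled with m = rank, as in standard usage
        if mat.shape[1] == 0:
            return 0.0
        q = _basis(_center(mat), require_full_rank=False)
        rank = q.shape[1]
        if rank == 0:
            return 0.0
        if n <= rank + 1:
            raise ValidationError(
                f"n={n} plots cannot support a block of rank {rank} (need n > rank + 1)"
            )
        r2 = float(np.sum((q.T @ yc) ** 2)) / ss_tot
        return adjusted_r2(r2, n, rank)

    union = np.hstack([e, s]) if (e.shape[1] and s.shape[1]) else (e if e.shape[1] else s)
    a = block_adj(union)
    b = block_adj(e)
    c = block_adj(s)
    frac_e = a - c
    frac_s = a - b
    inter = b + c - a
    residual = 1.0 - a
    p_e = p_s = p_tot = None
    if n_perm:
        ss1, ss2, ss3 = np.random.SeedSequence(seed).spawn(3)
        to_int = lambda ss: int(ss.generate_state(1)[0] % (2**31))
        _, p_tot = permutation_f_test(y, union, n_perm=n_perm, seed=to_int(ss1))
        if e.shape[1] and s.shape[1]:
            _, p_e = permutation_f_test(y, e, s, n_perm=n_perm, seed=to_int(ss2))
            _, p_s = permutation_f_test(y, s, e, n_perm=n_perm, seed=to_int(ss3))
        elif e.shape[1]:
            p_e = p_tot
        else:
            p_s = p_tot
    return VariationPartition(
        fraction_E_given_S=float(frac_e),
        fraction_intersection=float(inter),
        fraction_S_given_E=float(frac_s),
        residual=float(residual),
        adj_r2_E=float(b),
        adj_r2_S=float(c),
        adj_r2_total=float(a),
        p_E_given_S=p_e,
        p_S_given_E=p_s,
        p_total=p_tot,
        n_permutations=n_perm or 0,
    )
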