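"""LASSO stability selection with a custom regularisation path.

The centrepiece of the prediction analysis: learning scores are regressed on
connectivity predictors (20 undirected edges for FC/SC, 40 directed edges
for EC, plus penalty-exempt age and sex covariates) with an L1 penalty. The
penalty path is the explicit log-equispaced grid

    lambda_max = max_j |sum_i x_ij y_i| / n,
    lambda_k   = exp(log lambda_max + k/(K-1) (log(lambda_max eps) - log lambda_max)),

with K = 1000 values down to lambda_max * eps, eps = 1e-4. A three-step
nested procedure repeats 10-fold cross-validation 100 times; each of the
1000 training fits at its repetition's CV-optimal lambda contributes one
selection vector, and per-edge selection counts are tested against a null
selection rate with exact binomial tail tests and Benjamini-Hochberg FDR.

Companions: ridge / elastic-net / OLS re-fits, Belsley collinearity
diagnostics, and a split-half MSE permutation test of overall performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._cd import cd_gram, cd_path

__all__ = [
    "DesignMatrix",
    "LambdaPath",
    "SelectionResult",
    "build_design",
    "lambda_path",
    "lasso_fit",
    "kkt_check",
    "repeated_cv_selection",
    "estimate_null_selection_rate",
    "selection_binomial_test",
    "selection_maxcount_test",
    "ridge_all_edges",
    "collinearity_diagnostics",
    "split_half_mse_test",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class DesignMatrix:
    """Subjects x predictors design with outcome and penalty metadata."""

    X: np.ndarray
    y: np.ndarray
    labels: list
    penalty_exempt: np.ndarray  # bool per column
    penalty_weights: np.ndarray  # per-column penalty factor (exempt -> 0)
    groups: np.ndarray  # study label per row
    paradigm: np.ndarray
    modality: str = "FC"
    phase: str = "acquisition"
    subject_ids: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def __post_init__(self):
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("design matrix and outcome must not contain NaN")
        if len(self.labels) != self.p or len(set(self.labels)) != self.p:
            raise ValueError("labels must be unique and match the column count")


@dataclass(frozen=True)
class LambdaPath:
    lambda_max: float
    epsilon: float
    K: int
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if len(v) != self.K or np.any(np.diff(v) >= 0):
            raise ValueError("lambda path must hold K strictly decreasing values")


@dataclass
class SelectionResult:
    labels: list
    counts: np.ndarray
    n_models: int
    mean_nonzero_coef: np.ndarray
    optimal_lambdas: np.ndarray  # per repetition
    cv_mse: np.ndarray  # per repetition, at the optimal lambda
    penalty_exempt: np.ndarray
    binomial_p: np.ndarray | None = None
    fdr_significant: np.ndarray | None = None
    p0: float | None = None
    maxcount_p: np.ndarray | None = None
    maxcount_significant: np.ndarray | None = None

    def significant_edges(self) -> list:
        if self.fdr_significant is None:
            raise ValueError("run selection_binomial_test first")
        return [
            lab
            for lab, flag, ex in zip(self.labels, self.fdr_significant, self.penalty_exempt)
            if flag and not ex
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "predictor": self.labels,
                "count": self.counts,
                "selection_rate": self.counts / self.n_models,
                "mean_nonzero_coef": self.mean_nonzero_coef,
                "penalty_exempt": self.penalty_exempt,
            }
        )
        if self.binomial_p is not None:
            df["binomial_p"] = self.binomial_p
            df["fdr_significant"] = self.fdr_significant
        return df


# ---------------------------------------------------------------------------
# design assembly

def build_design(cohort, modality: str, phase: str, scores: pd.DataFrame,
                 ec_weight_mode: str = "penalty") -> DesignMatrix:
    """Assemble the subjects x predictors design for one modality and phase.

    FC/SC contribute one z-scored column per undirected edge (20), EC one per
    directed edge (40) with per-predictor penalty factors proportional to the
    mean posterior variance of the coupling estimate (normalized to mean 1:
    less certain couplings are shrunk harder). Age and sex are appended
    unpenalized. ``scores`` must carry subject_id and z_score for the phase.
    ``ec_weight_mode="none"`` disables the EC uncertainty weighting.

    Subjects missing the modality or a score are dropped (logged via
    warning); fewer than 20 remaining is an error.
    """
    if modality not in ("FC", "SC", "EC"):
        raise ValueError(f"unknown modality {modality!r}")
    conn = cohort.connectivity
    wide = (
        conn[conn.modality == modality]
        .pivot_table(index="subject_id", columns="edge", values="value")
    )
    labels = cohort.edge_set.labels(modality)
    missing_cols = [e for e in labels if e not in wide.columns]
    if missing_cols:
        raise ValueError(f"modality {modality} missing edges: {missing_cols[:5]}")
    wide = wide[labels]
    sc = scores.set_index("subject_id")
    common = wide.dropna().index.intersection(sc.dropna(subset=["z_score"]).index)
    dropped = len(wide.index) - len(common)  # cohort subjects lacking data
    if dropped:
        warnings.warn(
            f"dropping {dropped} subjects missing {modality} values or {phase} scores",
            stacklevel=2,
        )
    if len(common) < 20:
        raise ValueError(f"only {len(common)} subjects with complete data (< 20)")
    sub = cohort.subjects.set_index("subject_id").loc[common]
    Xe = wide.loc[common].to_numpy(dtype=float)
    mu, sd = Xe.mean(axis=0), Xe.std(axis=0)
    sd[sd == 0] = 1.0
    Xe = (Xe - mu) / sd
    cov = sub[["age", "sex"]].to_numpy(dtype=float)
    X = np.column_stack([Xe, cov])
    all_labels = list(labels) + ["age", "sex"]
    exempt = np.array([False] * len(labels) + [True, True])
    weights = np.where(exempt, 0.0, 1.0)
    if modality == "EC" and ec_weight_mode == "penalty":
        pv = (
            conn[(conn.modality == "EC") & conn.subject_id.isin(common)]
            .groupby("edge")
            .posterior_var.mean()
            .reindex(labels)
        )
        if pv.notna().all():
            w = pv.to_numpy()
            weights[: len(labels)] = w / w.mean()
    y = sc.loc[common, "z_score"].to_numpy(dtype=float)
    return DesignMatrix(
        X=X,
        y=y,
        labels=all_labels,
        penalty_exempt=exempt,
        penalty_weights=weights,
        groups=sub["study_id"].to_numpy(),
        paradigm=sub["paradigm"].to_numpy(),
        modality=modality,
        phase=phase,
        subject_ids=np.asarray(common),
    )


# ---------------------------------------------------------------------------
# lambda path and single fits

def lambda_path(X, y, K: int = 1000, epsilon: float = 1e-4,
                penalized: np.ndarray | None = None) -> LambdaPath:
    """The printed log-equispaced penalty grid.

    ``lambda_max = max_j |x_j . y| / n`` over penalized columns, then K
    values equally spaced in log from lambda_max down to lambda_max*epsilon.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.any(y != 0):
        raise ValueError("outcome is identically zero; lambda_max undefined")
    if K < 2:
        raise ValueError("K must be >= 2")
    n = len(y)
    corr = np.abs(X.T @ y) / n
    if penalized is not None:
        corr = corr[np.asarray(penalized, dtype=bool)]
    lam_max = float(corr.max())
    if lam_max == 0:
        raise ValueError("all penalized predictors are orthogonal to y")
    k = np.arange(K)
    values = np.exp(np.log(lam_max) + k / (K - 1) * np.log(epsilon))
    return LambdaPath(lambda_max=lam_max, epsilon=epsilon, K=K, values=values)


def _weights_vector(p, penalty_exempt=None, penalty_weights=None):
    w = np.ones(p)
    if penalty_weights is not None:
        w = np.asarray(penalty_weights, dtype=float).copy()
    if penalty_exempt is not None:
        w[np.asarray(penalty_exempt, dtype=bool)] = 0.0
    return w


def lasso_fit(X, y, lam: float, penalty_exempt=None, penalty_weights=None,
              tol: float = 1e-7, max_iter: int = 100000) -> np.ndarray:
    """Weighted LASSO coefficients at one penalty value.

    Minimizes ``(1/2n)||y - X beta||^2 + lam * sum_j w_j |beta_j|`` by
    cyclic coordinate descent on the Gram matrix; converged when the largest
    coefficient change in a sweep falls below ``tol``. Exempt columns have
    w_j = 0 (never shrunk). No intercept: center/standardize beforehand.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    G = X.T @ X / n
    c = X.T @ y / n
    w = _weights_vector(p, penalty_exempt, penalty_weights)
    beta = np.zeros(p)
    iters = cd_gram(G, c, lam, w, beta, tol, max_iter)
    if iters > max_iter:
        raise ConvergenceError(
            f"coordinate descent did not converge in {max_iter} sweeps "
            f"(lam={lam:.3g}, p={p}, max |beta|={np.abs(beta).max():.3g})"
        )
    return beta


def kkt_check(X, y, beta, lam, penalty_exempt=None, penalty_weights=None,
              tol: float = 1e-6) -> bool:
    """Karush-Kuhn-Tucker optimality check for a weighted LASSO solution."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    g = X.T @ (y - X @ beta) / n
    w = _weights_vector(X.shape[1], penalty_exempt, penalty_weights)
    ok = True
    for j in range(X.shape[1]):
        if w[j] == 0:
            ok &= abs(g[j]) <= tol
        elif beta[j] == 0:
            ok &= abs(g[j]) <= lam * w[j] + tol
        else:
            ok &= abs(g[j] - lam * w[j] * np.sign(beta[j])) <= tol
    return bool(ok)


# ---------------------------------------------------------------------------
# repeated cross-validated selection

def _standardize_train(Xtr, Xte):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    return (Xtr - mu) / sd, (Xte - mu) / sd


def _fold_indices(n, n_folds, rng):
    perm = rng.permutation(n)
    return np.array_split(perm, n_folds)


def repeated_cv_selection(design: DesignMatrix, n_reps: int = 100, n_folds: int = 10,
                          K: int = 1000, epsilon: float = 1e-4, seed=0,
                          rule: str = "min", tol: float = 1e-7,
                          max_iter: int = 100000) -> SelectionResult:
    """Three-step nested LASSO stability selection.

    Per repetition the data are randomly partitioned into ``n_folds`` folds;
    for each fold the full lambda path is fit on the training split (with
    within-fold predictor standardization and outcome centering) and
    evaluated on the held-out fold; the repetition's optimal lambda minimizes
    the mean CV MSE over the shared grid ("min" rule; "1se" optional). Each
    of the ``n_reps * n_folds`` training fits, re-read at the optimal lambda,
    contributes one selection vector (nonzero penalized coefficient =
    selected). Feature selection never touches the held-out fold.
    """
    if design.n < 2 * n_folds:
        raise ValueError(f"need n >= 2 * n_folds = {2 * n_folds}, got {design.n}")
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    rng = np.random.default_rng(seed)
    X, y = design.X, design.y
    p = design.p
    # one grid per design, computed from the full standardized data
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    path = lambda_path(Xs, y - y.mean(), K=K, epsilon=epsilon,
                       penalized=~design.penalty_exempt)
    lams = path.values
    w = np.where(design.penalty_exempt, 0.0, design.penalty_weights)

    counts = np.zeros(p, dtype=int)
    coef_sum = np.zeros(p)
    coef_n = np.zeros(p, dtype=int)
    opt_lams = np.empty(n_reps)
    opt_mse = np.empty(n_reps)
    n_models = 0
    for rep in range(n_reps):
        folds = _fold_indices(design.n, n_folds, rng)
        if min(len(f) for f in folds) < 2:
            folds = _fold_indices(design.n, n_folds, rng)
            if min(len(f) for f in folds) < 2:
                raise ValueError("a fold has < 2 subjects; reduce n_folds")
        sse = np.zeros(K)
        fold_betas = []
        for te in folds:
            tr = np.setdiff1d(np.arange(design.n), te)
            Xtr, Xte = _standardize_train(X[tr], X[te])
            ytr_mean = y[tr].mean()
            ytr = y[tr] - ytr_mean
            G = Xtr.T @ Xtr / len(tr)
            c = Xtr.T @ ytr / len(tr)
            betas, iters = cd_path(G, c, lams, w, tol, max_iter)
            if iters.max() > max_iter:
                raise ConvergenceError("path fit failed to converge")
            pred = Xte @ betas.T + ytr_mean
            sse += ((pred - y[te][:, None]) ** 2).sum(axis=0)
            fold_betas.append(betas)
        mse = sse / design.n
        if rule == "min":
            k_opt = int(np.argmin(mse))
        else:
            k_min = int(np.argmin(mse))
            se = mse.std() / np.sqrt(n_folds)
            ok = np.nonzero(mse <= mse[k_min] + se)[0]
            k_opt = int(ok.min())  # largest lambda within 1 SE
        opt_lams[rep] = lams[k_opt]
        opt_mse[rep] = mse[k_opt]
        for betas in fold_betas:
            b = betas[k_opt]
            sel = (b != 0) & ~design.penalty_exempt
            counts += sel
            coef_sum += np.where(sel, b, 0.0)
            coef_n += sel
            n_models += 1
    mean_nonzero = np.divide(coef_sum, coef_n, out=np.full(p, np.nan),
                             where=coef_n > 0)
    return SelectionResult(
        labels=list(design.labels),
        counts=counts,
        n_models=n_models,
        mean_nonzero_coef=mean_nonzero,
        optimal_lambdas=opt_lams,
        cv_mse=opt_mse,
        penalty_exempt=design.penalty_exempt.copy(),
    )


def estimate_null_selection_rate(design: DesignMatrix, n_runs: int = 20, seed=0,
                                 **cv_kwargs) -> float:
    """Empirical null selection probability p0.

    The outcome is permuted across subjects and the full repeated-CV
    selection is re-run; p0 is the mean per-predictor selection rate over
    penalized predictors and runs. This calibrates the binomial test to the
    data-dependent selection behaviour at the CV-optimal penalty.
    """
    rng = np.random.default_rng(seed)
    rates = []
    from dataclasses import replace

    for r in range(n_runs):
        yperm = rng.permutation(design.y)
        d = replace(design, y=yperm)
        res = repeated_cv_selection(d, seed=rng.integers(2**31), **cv_kwargs)
        pen = ~res.penalty_exempt
        rates.append(res.counts[pen].sum() / (res.n_models * pen.sum()))
    return float(np.mean(rates))


def selection_binomial_test(result: SelectionResult, p0: float,
                            alpha: float = 0.05) -> SelectionResult:
    """Exact one-sided binomial tail tests on selection counts with BH-FDR.

    For each penalized predictor, ``p = P(C >= c | n_models, p0)``;
    Benjamini-Hochberg FDR at level ``alpha`` across penalized predictors.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    from statsmodels.stats.multitest import multipletests

    pen = ~result.penalty_exempt
    pvals = np.full(len(result.labels), np.nan)
    pvals[pen] = stats.binom.sf(result.counts[pen] - 1, result.n_models, p0)
    flags = np.zeros(len(result.labels), dtype=bool)
    if pen.sum():
        rej, _, _, _ = multipletests(pvals[pen], alpha=alpha, method="fdr_bh")
        flags[pen] = rej
    result.binomial_p = pvals
    result.fdr_significant = flags
    result.p0 = float(p0)
    return result


def selection_maxcount_test(design: DesignMatrix, result: SelectionResult,
                            n_runs: int = 20, alpha: float = 0.05, seed=0,
                            **cv_kwargs) -> SelectionResult:
    """Family-wise calibrated selection significance via the permutation null
    of the maximum count.

    The binomial count test assumes the recorded fits are independent trials,
    but within a repetition every edge shares the CV-optimal penalty, so
    under a null outcome whole count vectors jump together and the binomial
    flags grossly over-reject at the family level. Here the outcome is
    permuted ``n_runs`` times, the full selection procedure is re-run, and
    each edge's count is compared against the null distribution of the
    *maximum* penalized count per run (Westfall-Young single-step):
    ``p_j = (1 + #{max null count >= c_j}) / (n_runs + 1)``, which controls
    the family-wise error by construction. ``cv_kwargs`` must match the
    settings used to produce ``result``.
    """
    rng = np.random.default_rng(seed)
    from dataclasses import replace as _replace

    pen = ~result.penalty_exempt
    null_max = np.empty(n_runs)
    for r in range(n_runs):
        d = _replace(design, y=rng.permutation(design.y))
        res = repeated_cv_selection(d, seed=rng.integers(2**31), **cv_kwargs)
        null_max[r] = res.counts[pen].max()
    pvals = np.full(len(result.labels), np.nan)
    pvals[pen] = [
        (1 + np.count_nonzero(null_max >= c)) / (n_runs + 1)
        for c in result.counts[pen]
    ]
    result.maxcount_p = pvals
    result.maxcount_significant = np.where(pen, pvals <= alpha, False)
    return result


# ---------------------------------------------------------------------------
# companion estimators and diagnostics

def ridge_all_edges(design: DesignMatrix, mode: str = "ridge", cv_folds: int = 10,
                    seed=0) -> pd.DataFrame:
    """Companion estimates for every predictor: ridge (CV-chosen L2 penalty),
    elastic net, or OLS.

    Ridge keeps every edge in the model, providing coefficient estimates for
    connections that LASSO zeroes out; these companions also serve the
    robustness comparison of the selection results. Covariates are included
    but, unlike in the LASSO, share the penalty (documented limitation of
    the sklearn backends).
    """
    from sklearn.linear_model import ElasticNetCV, LinearRegression, RidgeCV

    X = (design.X - design.X.mean(axis=0)) / np.where(
        design.X.std(axis=0) == 0, 1.0, design.X.std(axis=0)
    )
    y = design.y
    if mode == "ridge":
        est = RidgeCV(alphas=np.logspace(-3, 3, 50),
                      cv=cv_folds).fit(X, y)
        coefs = est.coef_
    elif mode == "elastic_net":
        est = ElasticNetCV(l1_ratio=0.5, n_alphas=50, cv=cv_folds,
                           random_state=np.random.default_rng(seed).integers(2**31)
                           ).fit(X, y)
        coefs = est.coef_
    elif mode == "ols":
        est = LinearRegression().fit(X, y)
        coefs = est.coef_
    else:
        raise ValueError("mode must be ridge, elastic_net, or ols")
    return pd.DataFrame({"predictor": design.labels, "coef": coefs, "mode": mode})


def collinearity_diagnostics(design: DesignMatrix) -> dict:
    """Belsley-style collinearity diagnostics.

    VIF_j = 1 / (1 - R^2_j) from regressing predictor j on the others
    (exact collinearity is reported as inf, flagged, not raised); tolerance
    = 1/VIF; eigenvalues and condition indices of the scaled cross-product
    matrix; variance-decomposition proportions from its SVD.
    """
    X = design.X
    n, p = X.shape
    if n <= p:
        raise ValueError("collinearity diagnostics need n > p")
    Xs = (X - X.mean(axis=0))
    norms = np.linalg.norm(Xs, axis=0)
    norms[norms == 0] = 1.0
    Xs = Xs / norms
    vif = np.empty(p)
    for j in range(p):
        others = np.delete(Xs, j, axis=1)
        bj, res, rank, _ = np.linalg.lstsq(others, Xs[:, j], rcond=None)
        pred = others @ bj
        ss_res = ((Xs[:, j] - pred) ** 2).sum()
        ss_tot = (Xs[:, j] ** 2).sum()
        r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
        vif[j] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    eig = s**2
    cond_idx = np.sqrt(eig.max() / np.where(eig > 0, eig, np.nan))
    with np.errstate(divide="ignore"):
        phi = (Vt.T**2) / np.where(s**2 > 0, s**2, np.nan)
    var_prop = phi / phi.sum(axis=1, keepdims=True)  # rows: predictors
    return {
        "labels": list(design.labels),
        "vif": vif,
        "tolerance": np.where(np.isinf(vif), 0.0, 1.0 / vif),
        "eigenvalues": eig,
        "condition_indices": cond_idx,
        "variance_proportions": var_prop,
        "flagged": [lab for lab, v in zip(design.labels, vif) if np.isinf(v)],
    }


# ---------------------------------------------------------------------------
# split-half performance permutation test

@dataclass
class SplitHalfResult:
    mse_true: np.ndarray
    mse_surrogate: np.ndarray
    mean_difference: float
    p_value: float
    n_iterations: int


def _cv_lasso_train(X, y, w, K, epsilon, n_folds, rng, tol=1e-7, max_iter=100000):
    """Fit LASSO with internal CV-chosen lambda; returns (beta, mu, sd, y_mean)."""
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    ym = y.mean()
    yc = y - ym
    if not np.any(yc != 0):  # constant outcome: the mean is the model
        return np.zeros(X.shape[1]), mu, sd, ym
    path = lambda_path(Xs, yc, K=K, epsilon=epsilon, penalized=w > 0)
    lams = path.values
    n = len(y)
    folds = _fold_indices(n, n_folds, rng)
    sse = np.zeros(K)
    for te in folds:
        tr = np.setdiff1d(np.arange(n), te)
        Xtr, Xte = _standardize_train(X[tr], X[te])
        ytr = y[tr] - y[tr].mean()
        G = Xtr.T @ Xtr / len(tr)
        c = Xtr.T @ ytr / len(tr)
        betas, _ = cd_path(G, c, lams, w, tol, max_iter)
        pred = Xte @ betas.T + y[tr].mean()
        sse += ((pred - y[te][:, None]) ** 2).sum(axis=0)
    k_opt = int(np.argmin(sse))
    G = Xs.T @ Xs / n
    c = Xs.T @ yc / n
    beta = np.zeros(Xs.shape[1])
    cd_gram(G, c, lams[k_opt], w, beta, tol, max_iter)
    return beta, mu, sd, ym


def split_half_mse_test(design: DesignMatrix, n_iterations: int = 20,
                        subsample_frac: float = 0.5, n_perm: int = 10000,
                        seed=0, K: int = 100, epsilon: float = 1e-4,
                        cv_folds: int = 10) -> SplitHalfResult:
    """Split-half out-of-sample performance with a sign-flip permutation test.

    The data are split in half; a LASSO (internal CV-chosen penalty on the
    log-spaced path) is trained on one half. Each of ``n_iterations``
    Monte-Carlo iterations computes the MSE on a random ``subsample_frac``
    subsample of the test half against the true outcomes, and against an
    outcome-shuffled surrogate subsample that destroys the
    learning-connectivity correspondence. The mean of the paired
    true-minus-surrogate differences is tested two-sided by randomly
    flipping the signs of the differences (add-one convention).

    The sign-flip null treats the iteration differences as exchangeable,
    which holds to good approximation when ``n_iterations`` is small
    relative to the size of the test half (roughly M <= n_test / 10);
    larger M makes the test progressively anticonservative because the
    split-specific offset shared by all iterations then dominates the
    iteration noise. The default (20) keeps the nominal size at n >= 200.
    """
    if design.n < 40:
        raise ValueError("split-half test needs n >= 40")
    rng = np.random.default_rng(seed)
    n = design.n
    w = np.where(design.penalty_exempt, 0.0, design.penalty_weights)
    perm = rng.permutation(n)
    half = n // 2
    tr, te = perm[:half], perm[half:]
    beta, mu, sd, ym = _cv_lasso_train(
        design.X[tr], design.y[tr], w, K, epsilon, cv_folds, rng,
    )
    pred = ((design.X[te] - mu) / sd) @ beta + ym
    y_te = design.y[te]
    k = max(2, int(round(subsample_frac * len(te))))
    mse_true = np.empty(n_iterations)
    mse_surr = np.empty(n_iterations)
    for m in range(n_iterations):
        idx = rng.choice(len(te), size=k, replace=False)
        mse_true[m] = ((pred[idx] - y_te[idx]) ** 2).mean()
        y_shuf = rng.permutation(y_te)
        mse_surr[m] = ((pred[idx] - y_shuf[idx]) ** 2).mean()
    d = mse_true - mse_surr
    obs = d.mean()
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n_iterations))
    null = (signs * d).mean(axis=1)
    p = (1 + np.count_nonzero(np.abs(null) >= abs(obs))) / (n_perm + 1)
    return SplitHalfResult(
        mse_true=mse_true,
        mse_surrogate=mse_surr,
        mean_difference=float(obs),
        p_value=float(p),
        n_iterations=n_iterations,
    )
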