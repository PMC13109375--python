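"""Generalisability and validation battery.

Implements the resampling, permutation, and simulation procedures used to
probe whether selected connectivity predictors generalise:

* hub Monte-Carlo resampling — which regions recur in significant
  connections across 80% subsamples (Poisson regression on appearance
  counts);
* cross-paradigm transfer — train on one paradigm family, test on random
  half-subsamples of the other, against outcome-shuffled surrogates, with a
  sign-flip permutation test on the paired MSE differences;
* leave-one-group-out (LOGO) cross-validation — a fixed predictor set,
  refit by OLS with each study left out in turn, scored by the pooled
  predicted-observed Pearson correlation;
* task-window FC regression — condition-difference functional connectivity
  from BOLD-peak windows of task runs, compared against pseudo-random edge
  sets;
* multivariate-normal simulation — new datasets drawn from the reference
  cohort's estimated covariance, comparing selected vs pseudo-random
  predictors' R^2 (with bootstrap variants);
* Cronbach's alpha for session reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .lassosel import (
    DesignMatrix,
    _cv_lasso_train,
    repeated_cv_selection,
    selection_binomial_test,
)
from .network import split_node

__all__ = [
    "HubResult",
    "TransferResult",
    "LogoResult",
    "hub_resampling",
    "paradigm_transfer_test",
    "logo_crossvalidation",
    "compare_correlations",
    "compare_correlations_dependent",
    "taskfc_regression_test",
    "mvn_simulation_comparison",
    "cronbach_alpha",
]


# ---------------------------------------------------------------------------
# hub Monte-Carlo resampling

@dataclass
class HubResult:
    counts: pd.DataFrame  # resample x region appearance counts (long)
    totals: pd.Series  # total appearances per region
    irr: pd.DataFrame | None  # region, irr, z, p, fdr_significant
    pairwise: pd.DataFrame | None
    n_resamples: int


def hub_resampling(design: DesignMatrix, B: int = 100, subsample_frac: float = 0.8,
                   seed=0, p0: float = 0.5, alpha: float = 0.05,
                   n_reps: int = 5, n_folds: int = 10, K: int = 100,
                   rule: str = "1se", min_completed_frac: float = 0.8) -> HubResult:
    """Monte-Carlo hub analysis.

    Each of ``B`` resamples draws ``subsample_frac`` of the subjects without
    replacement, reruns a reduced repeated-CV LASSO selection, flags
    significant edges (binomial test at ``p0``, BH-FDR), and counts how
    often each region (hemispheres collapsed) appears as an endpoint. A
    Poisson regression of the per-resample region counts on region (log
    link, sum-coded so each region is contrasted with the grand mean rate)
    yields incidence-rate ratios, z and FDR-corrected p-values, plus all
    pairwise region contrasts.

    The internal selections default to the sparser 1-SE penalty rule: under
    80% subsampling the minimum-MSE rule keeps so many predictors nonzero
    that the binomial significance criterion saturates and region counts
    lose contrast.
    """
    if B < 10:
        raise ValueError("B must be >= 10")
    rng = np.random.default_rng(seed)
    n_take = int(round(subsample_frac * design.n))
    regions = sorted({split_node(node)[0]
                      for lab, ex in zip(design.labels, design.penalty_exempt)
                      if not ex
                      for node in lab.replace("->", "-").split("-")})
    rows = []
    completed = 0
    for b in range(B):
        idx = rng.choice(design.n, size=n_take, replace=False)
        sub = replace(design, X=design.X[idx], y=design.y[idx],
                      groups=design.groups[idx], paradigm=design.paradigm[idx],
                      subject_ids=None)
        try:
            res = repeated_cv_selection(sub, n_reps=n_reps, n_folds=n_folds, K=K,
                                        seed=rng.integers(2**31), rule=rule)
        except ValueError:
            continue
        res = selection_binomial_test(res, p0=p0, alpha=alpha)
        completed += 1
        cnt = dict.fromkeys(regions, 0)
        for lab in res.significant_edges():
            for node in lab.replace("->", "-").split("-"):
                cnt[split_node(node)[0]] += 1
        for r in regions:
            rows.append((b, r, cnt[r]))
    if completed < min_completed_frac * B:
        raise RuntimeError(f"only {completed}/{B} resamples completed")
    counts = pd.DataFrame(rows, columns=["resample", "region", "count"])
    totals = counts.groupby("region")["count"].sum()
    irr, pairwise = _poisson_region_model(counts, regions)
    return HubResult(counts=counts, totals=totals, irr=irr, pairwise=pairwise,
                     n_resamples=completed)


def _poisson_region_model(counts: pd.DataFrame, regions: list):
    """Poisson GLM of per-resample counts on region (sum coding)."""
    import statsmodels.api as sm
    from statsmodels.stats.multitest import multipletests

    if counts["count"].sum() == 0:
        return None, None
    y = counts["count"].to_numpy()
    r_idx = pd.Categorical(counts.region, categories=regions).codes
    k = len(regions)
    # sum-coded region effects: last region = -(sum of others)
    Xc = np.zeros((len(y), k - 1))
    for j in range(k - 1):
        Xc[:, j] = (r_idx == j).astype(float) - (r_idx == k - 1).astype(float)
    X = np.column_stack([np.ones(len(y)), Xc])
    model = sm.GLM(y, X, family=sm.families.Poisson())
    fit = model.fit()
    beta = fit.params
    cov = fit.cov_params()
    rows = []
    for j, region in enumerate(regions):
        if j < k - 1:
            contrast = np.zeros(k)
            contrast[j + 1] = 1.0
        else:
            contrast = np.zeros(k)
            contrast[1:] = -1.0
        est = contrast @ beta
        se = float(np.sqrt(contrast @ cov @ contrast))
        z = est / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        rows.append((region, float(np.exp(est)), float(z), float(p)))
    irr = pd.DataFrame(rows, columns=["region", "irr", "z", "p"])
    irr["fdr_significant"] = multipletests(irr.p, method="fdr_bh")[0]
    pair_rows = []
    for i in range(k):
        for j in range(i + 1, k):
            ci = np.zeros(k)
            for idx, sign in ((i, 1.0), (j, -1.0)):
                if idx < k - 1:
                    ci[idx + 1] += sign
                else:
                    ci[1:] += -sign
            est = ci @ beta
            se = float(np.sqrt(ci @ cov @ ci))
            z = est / se if se > 0 else 0.0
            p = 2 * stats.norm.sf(abs(z))
            pair_rows.append((regions[i], regions[j], float(np.exp(est)),
                              float(z), float(p)))
    pairwise = pd.DataFrame(pair_rows, columns=["region_a", "region_b", "irr", "z", "p"])
    pairwise["fdr_significant"] = multipletests(pairwise.p, method="fdr_bh")[0]
    return irr, pairwise


# ---------------------------------------------------------------------------
# cross-paradigm transfer

@dataclass
class TransferResult:
    mse_true: np.ndarray
    mse_surrogate: np.ndarray
    mean_difference: float
    p_value: float


def paradigm_transfer_test(train: DesignMatrix, test: DesignMatrix, M: int = 100,
                           test_frac: float = 0.5, n_perm: int = 10000, seed=0,
                           K: int = 1000, epsilon: float = 1e-4,
                           cv_folds: int = 10) -> TransferResult:
    """Train on one paradigm, test on random half-subsamples of the other.

    One LASSO is fit on the full training paradigm (its own CV-optimal
    penalty on the shared log-spaced path). For each of ``M`` iterations a
    random ``test_frac`` subsample of the held-out paradigm yields a true
    MSE, and an outcome-shuffled surrogate subsample yields a surrogate MSE;
    the mean of the paired differences is tested two-tailed by randomly
    flipping the signs of the ``M`` differences (add-one rule).
    """
    if (train.subject_ids is not None and test.subject_ids is not None
            and len(np.intersect1d(train.subject_ids, test.subject_ids))):
        raise ValueError("train and test cohorts share subjects")
    if train.labels != test.labels:
        raise ValueError("train and test designs must share predictor labels")
    rng = np.random.default_rng(seed)
    w = np.where(train.penalty_exempt, 0.0, train.penalty_weights)
    beta, mu, sd, ym = _cv_lasso_train(train.X, train.y, w, K, epsilon, cv_folds, rng)
    pred_all = ((test.X - mu) / sd) @ beta + ym
    n_te = test.n
    n_take = int(round(test_frac * n_te))
    mse_true = np.empty(M)
    mse_surr = np.empty(M)
    for m in range(M):
        idx = rng.choice(n_te, size=n_take, replace=False)
        mse_true[m] = ((pred_all[idx] - test.y[idx]) ** 2).mean()
        y_shuf = rng.permutation(test.y)
        mse_surr[m] = ((pred_all[idx] - y_shuf[idx]) ** 2).mean()
    d = mse_true - mse_surr
    obs = d.mean()
    signs = rng.choice((-1.0, 1.0), size=(n_perm, M))
    null = (signs * d).mean(axis=1)
    p = (1 + np.count_nonzero(np.abs(null) >= abs(obs))) / (n_perm + 1)
    return TransferResult(mse_true=mse_true, mse_surrogate=mse_surr,
                          mean_difference=float(obs), p_value=float(p))


# ---------------------------------------------------------------------------
# leave-one-group-out cross-validation

@dataclass
class LogoResult:
    pooled_r: float
    per_study_r: pd.DataFrame
    predicted: np.ndarray
    observed: np.ndarray
    study: np.ndarray


def logo_crossvalidation(design: DesignMatrix, predictors: list,
                         include_covariates: bool = True,
                         pooling: str = "pooled") -> LogoResult:
    """Leave-one-study-out OLS with a fixed predictor set.

    The predictor set must be chosen beforehand (re-selecting inside the
    folds would leak the left-out study). For each study, OLS (with
    intercept; optionally age/sex) is fit on the remaining studies and the
    left-out study is predicted; generalisation is the Pearson correlation
    between pooled out-of-fold predictions and observations ("pooled"), or
    between per-study means ("study_means").
    """
    studies = np.unique(design.groups)
    if len(studies) < 3:
        raise ValueError("LOGO needs >= 3 studies")
    missing = [p for p in predictors if p not in design.labels]
    if missing:
        raise ValueError(f"predictors not in design: {missing}")
    cols = [design.labels.index(p) for p in predictors]
    if include_covariates:
        cols += [i for i, ex in enumerate(design.penalty_exempt) if ex and i not in cols]
    Xp = design.X[:, cols]
    preds = np.empty(design.n)
    for g in studies:
        te = design.groups == g
        tr = ~te
        Xtr = np.column_stack([np.ones(tr.sum()), Xp[tr]])
        beta, *_ = np.linalg.lstsq(Xtr, design.y[tr], rcond=None)
        preds[te] = np.column_stack([np.ones(te.sum()), Xp[te]]) @ beta
    rows = []
    for g in studies:
        m = design.groups == g
        if m.sum() >= 3 and np.std(preds[m]) > 0 and np.std(design.y[m]) > 0:
            r = float(np.corrcoef(preds[m], design.y[m])[0, 1])
        else:
            r = np.nan
        rows.append((g, r, int(m.sum())))
    if pooling == "pooled":
        pooled = float(np.corrcoef(preds, design.y)[0, 1])
    elif pooling == "study_means":
        mp = np.array([preds[design.groups == g].mean() for g in studies])
        mo = np.array([design.y[design.groups == g].mean() for g in studies])
        pooled = float(np.corrcoef(mp, mo)[0, 1])
    else:
        raise ValueError("pooling must be 'pooled' or 'study_means'")
    return LogoResult(
        pooled_r=pooled,
        per_study_r=pd.DataFrame(rows, columns=["study", "r", "n"]),
        predicted=preds,
        observed=design.y.copy(),
        study=design.groups.copy(),
    )


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> dict:
    """Fisher-z test for two independent Pearson correlations."""
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    z = (z1 - z2) / se
    return {"z": float(z), "p_value": float(2 * stats.norm.sf(abs(z)))}


def compare_correlations_dependent(pred_a, pred_b, observed, n_boot: int = 2000,
                                   seed=0) -> dict:
    """Percentile-bootstrap comparison of two dependent prediction
    correlations (same subjects, e.g. two modalities' predictions of the same
    learning scores): resamples subjects with replacement and reports the
    bootstrap distribution of r_a - r_b."""
    pred_a = np.asarray(pred_a, dtype=float)
    pred_b = np.asarray(pred_b, dtype=float)
    observed = np.asarray(observed, dtype=float)
    n = len(observed)
    if not len(pred_a) == len(pred_b) == n:
        raise ValueError("all three vectors must share the subjects")
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        o = observed[idx]
        if o.std() == 0 or pred_a[idx].std() == 0 or pred_b[idx].std() == 0:
            diffs[b] = 0.0
            continue
        diffs[b] = (np.corrcoef(pred_a[idx], o)[0, 1]
                    - np.corrcoef(pred_b[idx], o)[0, 1])
    observed_diff = (np.corrcoef(pred_a, observed)[0, 1]
                     - np.corrcoef(pred_b, observed)[0, 1])
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    # two-sided bootstrap p: how far 0 sits in the resampled distribution
    p = 2 * min((diffs <= 0).mean(), (diffs >= 0).mean())
    return {"difference": float(observed_diff), "ci": (float(lo), float(hi)),
            "p_value": float(min(1.0, p + 1.0 / n_boot))}


# ---------------------------------------------------------------------------
# task-window FC regression

def _window_fc(ts: np.ndarray, events: pd.DataFrame, tr: float, edges: list,
               node_idx: dict, window: tuple) -> dict:
    """Condition-wise Pearson FC from volumes inside BOLD-peak windows."""
    n_vol = ts.shape[1]
    vol_times = np.arange(n_vol) * tr
    out = {}
    for cond in ("CS+", "CS-"):
        sel = np.zeros(n_vol, dtype=bool)
        for _, ev in events[events.trial_type == cond].iterrows():
            m = (vol_times >= ev.onset + window[0]) & (vol_times <= ev.onset + window[1])
            if not m.any():
                raise ValueError(
                    f"empty peak window for trial at onset {ev.onset:.1f} s"
                )
            sel |= m
        if sel.sum() < 2:
            raise ValueError(f"fewer than 2 volumes in {cond} windows; FC undefined")
        seg = ts[:, sel]
        for e in edges:
            a, b = e.split("-")
            va, vb = seg[node_idx[a]], seg[node_idx[b]]
            if va.std() == 0 or vb.std() == 0:
                raise ValueError(f"zero-variance window segment on edge {e}")
            out[(cond, e)] = float(np.corrcoef(va, vb)[0, 1])
    return out


@dataclass
class TaskFCResult:
    f_statistic: float
    p_value: float
    r_squared: float
    coefficients: pd.DataFrame
    random_r2: np.ndarray
    max_random_r2: float


def taskfc_regression_test(timeseries: dict, events: pd.DataFrame | dict,
                           selected_edges: list, scores: pd.DataFrame,
                           covariates: pd.DataFrame, repetition_time: float,
                           edge_set, peak_window: tuple = (4.0, 8.0),
                           n_random_sets: int = 100, seed=0) -> TaskFCResult:
    """Does task-based condition-difference FC on the selected edges predict
    learning better than pseudo-random edge sets?

    Per subject and edge, FC is the Pearson correlation over the volumes
    falling in ``[onset + w1, onset + w2]`` of each trial (concatenated per
    condition); the predictor is FC(CS+) - FC(CS-). An OLS of the learning
    score on the selected-edge predictors plus covariates yields the model
    F, p, and R^2; the same regression on ``n_random_sets`` equal-size edge
    sets drawn from the non-selected catalogue gives the comparison
    distribution (max random R^2 reported).
    """
    import statsmodels.api as sm

    min_trials = 10
    ev0 = events if isinstance(events, pd.DataFrame) else next(iter(events.values()))
    for cond in ("CS+", "CS-"):
        if (ev0.trial_type == cond).sum() < min_trials:
            raise ValueError(f"need >= {min_trials} trials per condition")
    from .network import NODES

    node_idx = {n: i for i, n in enumerate(NODES)}
    all_edges = edge_set.undirected_labels
    bad = [e for e in selected_edges if e not in all_edges]
    if bad:
        raise ValueError(f"unknown edges {bad}")
    rng = np.random.default_rng(seed)
    sc = scores.set_index("subject_id")
    cov = covariates.set_index("subject_id")
    sids = [s for s in timeseries if s in sc.index and s in cov.index]
    fc_rows = {}
    for sid in sids:
        ev = events if isinstance(events, pd.DataFrame) else events[sid]
        fc_rows[sid] = _window_fc(timeseries[sid], ev, repetition_time,
                                  all_edges, node_idx, peak_window)

    def model_r2(edges):
        X = np.array(
            [[fc_rows[s][("CS+", e)] - fc_rows[s][("CS-", e)] for e in edges]
             for s in sids]
        )
        X = np.column_stack([X, cov.loc[sids, ["age", "sex"]].to_numpy()])
        y = sc.loc[sids, "z_score"].to_numpy()
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        return fit

    fit = model_r2(selected_edges)
    others = [e for e in all_edges if e not in selected_edges]
    if len(others) < len(selected_edges):
        raise ValueError("not enough non-selected edges for random comparison sets")
    random_r2 = np.empty(n_random_sets)
    for i in range(n_random_sets):
        pick = list(rng.choice(others, size=len(selected_edges), replace=False))
        random_r2[i] = model_r2(pick).rsquared
    coef = pd.DataFrame(
        {
            "predictor": list(selected_edges) + ["age", "sex"],
            "coef": fit.params[1:],
            "p": fit.pvalues[1:],
        }
    )
    return TaskFCResult(
        f_statistic=float(fit.fvalue),
        p_value=float(fit.f_pvalue),
        r_squared=float(fit.rsquared),
        coefficients=coef,
        random_r2=random_r2,
        max_random_r2=float(random_r2.max()),
    )


# ---------------------------------------------------------------------------
# multivariate-normal simulation comparison

@dataclass
class MvnSimResult:
    r2_selected: np.ndarray
    r2_random: np.ndarray
    t_statistic: float
    p_value: float
    r2_noise: np.ndarray | None = None


def mvn_simulation_comparison(design: DesignMatrix, selected: list, D: int = 100,
                              n_per_dataset: int = 40, seed=0,
                              bootstrap_mode: str = "none",
                              n_noise_edges: int = 0) -> MvnSimResult:
    """Simulate new datasets and compare selected vs pseudo-random predictors.

    ``D`` datasets of ``n_per_dataset`` observations are drawn from a
    multivariate normal with the reference cohort's estimated mean and
    covariance of [outcome, predictors, covariates]; to acknowledge that a
    future study's moments differ from the sample estimates, each dataset
    draws its own population moments with their sampling error: means and
    scales are jittered by their standard errors and the covariance is a
    fresh Wishart draw with the reference degrees of freedom. Without the
    covariance perturbation the simulated population would inherit the
    reference sample's spurious outcome-predictor correlations as exact
    truths, and the paired comparison would reject on null data. Per dataset,
    OLS R^2 is computed for (a) the selected predictors and (b) an
    equal-count pseudo-random set from the same modality excluding the
    selected ones (fresh draw per dataset), optionally (c) pure-noise
    baseline columns standing in for ventricle connectivity. The paired
    t-test compares R^2(a) - R^2(b) across datasets.

    ``bootstrap_mode``: "with_replacement" / "without_replacement" replace
    the MVN draws with row resampling of the reference data.
    """
    if bootstrap_mode not in ("none", "with_replacement", "without_replacement"):
        raise ValueError("unknown bootstrap_mode")
    missing = [e for e in selected if e not in design.labels]
    if missing:
        raise ValueError(f"selected predictors missing: {missing}")
    pen_labels = [lab for lab, ex in zip(design.labels, design.penalty_exempt) if not ex]
    others = [e for e in pen_labels if e not in selected]
    if len(others) < len(selected):
        raise ValueError("fewer non-selected edges than needed")
    rng = np.random.default_rng(seed)
    data = np.column_stack([design.y, design.X])
    names = ["__y__"] + list(design.labels)
    mu = data.mean(axis=0)
    cov = np.cov(data, rowvar=False)
    n_ref = data.shape[0]
    se_mu = data.std(axis=0, ddof=1) / np.sqrt(n_ref)
    se_sd = data.std(axis=0, ddof=1) / np.sqrt(2 * (n_ref - 1))
    sd_ref = data.std(axis=0, ddof=1)

    cov_cols = [names.index(lab)
                for lab, ex in zip(design.labels, design.penalty_exempt) if ex]

    def ols_r2(mat, cols):
        X = np.column_stack([np.ones(mat.shape[0])] +
                            [mat[:, c] for c in cols] +
                            [mat[:, c] for c in cov_cols])
        y = mat[:, 0]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ss_tot = ((y - y.mean()) ** 2).sum()
        return 1 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0

    r2_sel = np.empty(D)
    r2_rnd = np.empty(D)
    r2_noise = np.empty(D) if n_noise_edges > 0 else None
    sel_cols = [names.index(e) for e in selected]
    df_wishart = max(n_ref - 1, data.shape[1] + 2)
    w, V = np.linalg.eigh(cov)
    Lref = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    for d in range(D):
        if bootstrap_mode == "none":
            # per-dataset population covariance: Wishart draw around the
            # reference estimate, W = S^{1/2} (Z'Z / df) S^{1/2}
            Z = rng.standard_normal((df_wishart, data.shape[1]))
            Zc = Z - Z.mean(axis=0)
            cov_d = Lref @ (Zc.T @ Zc / df_wishart) @ Lref.T
            wd, Vd = np.linalg.eigh(cov_d)
            Ld = Vd @ np.diag(np.sqrt(np.clip(wd, 0, None)))
            zmat = rng.standard_normal((n_per_dataset, data.shape[1])) @ Ld.T
            mu_d = mu + se_mu * rng.standard_normal(data.shape[1])
            scale_d = 1.0 + (se_sd / sd_ref) * rng.standard_normal(data.shape[1])
            mat = mu_d + zmat * scale_d
        elif bootstrap_mode == "with_replacement":
            mat = data[rng.integers(0, n_ref, n_per_dataset)]
        else:
            if n_per_dataset > n_ref:
                raise ValueError("without-replacement bootstrap needs n <= reference n")
            mat = data[rng.choice(n_ref, n_per_dataset, replace=False)]
        r2_sel[d] = ols_r2(mat, sel_cols)
        pick = rng.choice(len(others), size=len(selected), replace=False)
        r2_rnd[d] = ols_r2(mat, [names.index(others[i]) for i in pick])
        if r2_noise is not None:
            noise = rng.standard_normal((mat.shape[0], n_noise_edges))
            ext = np.column_stack([mat, noise])
            r2_noise[d] = ols_r2(ext, list(range(mat.shape[1],
                                                 mat.shape[1] + n_noise_edges)))
    t, p = stats.ttest_rel(r2_sel, r2_rnd)
    return MvnSimResult(r2_selected=r2_sel, r2_random=r2_rnd,
                        t_statistic=float(t), p_value=float(p), r2_noise=r2_noise)


# ---------------------------------------------------------------------------
# reliability

def cronbach_alpha(measurements) -> float:
    """Cronbach's alpha over an observations x items matrix.

    ``alpha = k/(k-1) * (1 - sum of item variances / variance of item sum)``
    for k items (columns). For test-retest reliability of a connectivity
    protocol, the repeated scanning sessions are the items and the measured
    quantities (ROIs or edges) are the observations.
    """
    X = np.asarray(measurements, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 sessions and >= 2 items")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1 - item_var / total_var))
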