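"""Subject-level learning, extinction, and renewal scores.

Trial-level measurements (skin-conductance response amplitudes, or binary
behavioural choices) are converted into one standardized number per subject
and phase:

* SCR branch — a theory-free quadratic polynomial regression of amplitude on
  trial number, CS type, and their interaction is fit per subject; the
  per-CS score sums the successive differences of the fitted values (which
  telescopes to last-minus-first fitted value), and the learning score is
  the CS+ minus CS- difference.
* Behavioural branch — a multilevel logistic regression (random intercept
  and random trial slope per subject) yields per-subject success
  probabilities; the expected number of correct responses over the standard
  8-trial block summarizes learning (8 = perfect, 4 = chance for a binary
  choice). Renewal is summarized by whether (and how often) the subject
  repeats their dominant acquisition-phase response during renewal.

Raw scores are standardized within each study x experiment cell so that
every cell has mean 0 and unit variance, putting heterogeneous paradigms on
a common scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "PolyScores",
    "LogisticLearningParams",
    "polynomial_learning_score",
    "hierarchical_logistic_scores",
    "expected_success_score",
    "renewal_response_prob",
    "standardize_scores",
    "condition_permutation_test",
    "score_cohort",
]

STANDARD_BLOCK = 8  # unique trial types per experiment in the behavioural task
CHANCE_P = 0.5  # two-alternative binary response


@dataclass
class PolyScores:
    """Polynomial learning scores for one subject x phase."""

    cs_plus: float
    cs_minus: float
    learning: float  # cs_plus - cs_minus
    coefficients: np.ndarray
    fitted: pd.DataFrame  # cs_type, trial, fitted


def polynomial_learning_score(trials: pd.DataFrame, index_mode: str = "within_cs") -> PolyScores:
    """Quadratic learning score for one subject and phase.

    Fits ``amplitude ~ (1 + t + t^2) * CS`` by ordinary least squares over
    all trials of both CS types, then scores each CS type by the sum of
    successive fitted-value differences (telescoping to last minus first),
    and returns the CS+ minus CS- difference as the learning score.

    ``index_mode``: "within_cs" numbers trials 1..n within each CS type (the
    default); "global" uses the trial column as a shared running index.
    """
    required = {"cs_type", "trial", "amplitude"}
    if not required <= set(trials.columns):
        raise ValueError(f"trials must have columns {sorted(required)}")
    if index_mode not in ("within_cs", "global"):
        raise ValueError("index_mode must be 'within_cs' or 'global'")
    cs_types = set(trials.cs_type)
    if cs_types != {"CS+", "CS-"}:
        raise ValueError(
            f"both CS types required for polynomial scoring, got {sorted(cs_types)}"
        )
    df = trials.sort_values(["cs_type", "trial"]).copy()
    if index_mode == "within_cs":
        t = df.groupby("cs_type").cumcount().to_numpy() + 1.0
    else:
        t = df.trial.to_numpy().astype(float)
    cs = (df.cs_type == "CS+").to_numpy().astype(float)
    X = np.column_stack([np.ones_like(t), t, t**2, cs, t * cs, t**2 * cs])
    y = df.amplitude.to_numpy()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient polynomial design (rank {rank} < 6); need >= 3 "
            "distinct trial indices for each CS type"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    df["fitted"] = fitted
    scores = {}
    for name in ("CS+", "CS-"):
        f = df.loc[df.cs_type == name].sort_values("trial").fitted.to_numpy()
        scores[name] = float(np.diff(f).sum())  # telescopes to f[-1] - f[0]
    return PolyScores(
        cs_plus=scores["CS+"],
        cs_minus=scores["CS-"],
        learning=scores["CS+"] - scores["CS-"],
        coefficients=beta,
        fitted=df[["cs_type", "trial", "fitted"]].reset_index(drop=True),
    )


@dataclass
class LogisticLearningParams:
    """Per-subject parameters of the multilevel logistic learning model."""

    params: pd.DataFrame  # subject_id, b0, b1, separation_flag
    fixed_intercept: float
    fixed_slope: float
    probabilities: pd.DataFrame  # subject_id, trial, p

    def subject_probabilities(self, subject_id) -> np.ndarray:
        p = self.probabilities
        return p.loc[p.subject_id == subject_id].sort_values("trial").p.to_numpy()


def hierarchical_logistic_scores(trials: pd.DataFrame) -> LogisticLearningParams:
    """Multilevel logistic regression of response on trial number.

    Model: ``logit p_it = (b0 + u0_i) + (b1 + u1_i) t`` with subject random
    intercepts and random trial slopes, estimated by penalized approximate
    (variational Gaussian) posterior inference with the trial predictor
    standardized internally for numerical stability; coefficients are
    back-transformed to the raw trial scale.

    Subjects with all-0 or all-1 responses (complete separation) are handled
    by the shrinkage built into the random-effect prior and flagged, never
    raised.
    """
    required = {"subject_id", "trial", "response"}
    if not required <= set(trials.columns):
        raise ValueError(f"trials must have columns {sorted(required)}")
    df = trials.dropna(subset=["response"]).copy()
    subjects = np.sort(df.subject_id.unique())
    if len(subjects) < 2:
        raise ValueError("multilevel model needs >= 2 subjects")
    y = df.response.to_numpy().astype(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("responses must be binary 0/1")

    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    t = df.trial.to_numpy().astype(float)
    mu_t, sd_t = t.mean(), t.std()
    if sd_t == 0:
        raise ValueError("trial number has no variation")
    ts = (t - mu_t) / sd_t
    sub_idx = pd.Categorical(df.subject_id, categories=subjects).codes
    n, k = len(df), len(subjects)
    exog = np.column_stack([np.ones(n), ts])
    vc = sp.hstack(
        [
            sp.csr_matrix((np.ones(n), (np.arange(n), sub_idx)), shape=(n, k)),
            sp.csr_matrix((ts, (np.arange(n), sub_idx)), shape=(n, k)),
        ]
    ).tocsr()
    ident = np.array([0] * k + [1] * k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = BinomialBayesMixedGLM(y, exog, vc, ident)
        fit = model.fit_vb()
    fe0_s, fe1_s = fit.fe_mean
    u0_s, u1_s = fit.vc_mean[:k], fit.vc_mean[k:]
    # back-transform from the standardized-trial scale
    b1 = (fe1_s + u1_s) / sd_t
    b0 = (fe0_s + u0_s) - b1 * mu_t
    fixed_slope = fe1_s / sd_t
    fixed_intercept = fe0_s - fixed_slope * mu_t

    grp = df.groupby("subject_id").response
    all_same = (grp.mean().isin((0.0, 1.0))).reindex(subjects).to_numpy()
    params = pd.DataFrame(
        {"subject_id": subjects, "b0": b0, "b1": b1, "separation_flag": all_same}
    )
    trial_grid = np.sort(df.trial.unique())
    eps = 1e-12
    probs = []
    for i, sid in enumerate(subjects):
        p = 1.0 / (1.0 + np.exp(-(b0[i] + b1[i] * trial_grid)))
        probs.append(
            pd.DataFrame(
                {"subject_id": sid, "trial": trial_grid, "p": np.clip(p, eps, 1 - eps)}
            )
        )
    return LogisticLearningParams(
        params=params,
        fixed_intercept=float(fixed_intercept),
        fixed_slope=float(fixed_slope),
        probabilities=pd.concat(probs, ignore_index=True),
    )


def expected_success_score(p) -> float:
    """Expected number of correct responses over the standard 8-trial block.

    ``score = sum_t p_t`` for the 8 per-trial success probabilities; 8 means
    certain success on every trial, 4 is the chance anchor for a binary
    choice (all p_t = 0.5). Linear and monotone in every probability.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (STANDARD_BLOCK,):
        raise ValueError(f"expected exactly {STANDARD_BLOCK} probabilities, got {p.shape}")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in (0, 1]")
    return float(p.sum())


def renewal_response_prob(acquisition: pd.DataFrame, renewal: pd.DataFrame):
    """Renewal-response summary for one subject.

    A renewal response is a renewal-phase response equal to the subject's
    dominant (majority) acquisition-phase response for that stimulus; ties in
    the acquisition majority yield no renewal credit for that stimulus.
    Returns ``(any_renewal, proportion)``; both are NaN when no renewal
    trials with a defined dominant response exist.
    """
    for df, name in ((acquisition, "acquisition"), (renewal, "renewal")):
        if not {"stimulus", "response"} <= set(df.columns):
            raise ValueError(f"{name} table needs stimulus and response columns")
    if len(renewal) == 0:
        return float("nan"), float("nan")
    dominant = {}
    for stim, grp in acquisition.groupby("stimulus"):
        mean = grp.response.mean()
        if mean > 0.5:
            dominant[stim] = 1
        elif mean < 0.5:
            dominant[stim] = 0
    scored = renewal[renewal.stimulus.isin(dominant)]
    if len(scored) == 0:
        return float("nan"), float("nan")
    matches = np.array([r == dominant[s] for s, r in zip(scored.stimulus, scored.response)])
    return float(matches.any()), float(matches.mean())


def standardize_scores(scores: pd.DataFrame, group_cols=("study_id", "experiment"),
                       value_col: str = "raw_score") -> pd.DataFrame:
    """Z-score raw learning scores within each study x experiment cell.

    After standardization every cell has mean 0 and unit (population) sd,
    removing between-site level and scale differences while preserving the
    ordering of individuals within a cell. Idempotent.
    """
    group_cols = list(group_cols)
    out = scores.copy()
    for key, grp in out.groupby(group_cols):
        if len(grp) < 2:
            raise ValueError(f"standardization cell {key} has < 2 subjects")
        sd = grp[value_col].std(ddof=0)
        if sd == 0:
            raise ValueError(f"standardization cell {key} has zero variance")
        out.loc[grp.index, "z_score"] = (grp[value_col] - grp[value_col].mean()) / sd
    return out


def condition_permutation_test(cs_plus, cs_minus, n_perm: int = 10000, seed=0) -> dict:
    """Paired sign-flip permutation test of the CS+ vs CS- score difference.

    Statistic: mean paired difference. The null swaps CS labels within
    subject, i.e. flips the sign of each pair difference; two-sided p-value
    with the add-one convention ``(1 + #{|null| >= |obs|}) / (n_perm + 1)``.
    """
    d = np.asarray(cs_plus, dtype=float) - np.asarray(cs_minus, dtype=float)
    if len(d) < 5:
        warnings.warn("fewer than 5 pairs: permutation p-value is coarse", stacklevel=2)
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    rng = np.random.default_rng(seed)
    obs = d.mean()
    signs = rng.choice((-1.0, 1.0), size=(n_perm, len(d)))
    null = (signs * d).mean(axis=1)
    p = (1 + np.count_nonzero(np.abs(null) >= abs(obs))) / (n_perm + 1)
    return {"statistic": float(obs), "p_value": float(p), "n_perm": n_perm}


def score_cohort(cohort, phase: str = "acquisition") -> pd.DataFrame:
    """Standardized learning scores for every subject of a cohort.

    SCR studies are scored with the polynomial learning score; behavioural
    studies with the expected-success score (acquisition/extinction) or the
    renewal-response proportion (renewal). Scores are standardized per
    study x experiment.
    """
    rows = []
    for design in cohort.designs:
        if phase not in design.phases:
            continue
        sub = cohort.subjects[cohort.subjects.study_id == design.study_id]
        tri = cohort.trials[cohort.trials.subject_id.isin(sub.subject_id)]
        if design.measurement == "SCR":
            for sid, grp in tri[tri.phase == phase].groupby("subject_id"):
                res = polynomial_learning_score(grp)
                rows.append((sid, design.study_id, design.experiment, res.learning, "SCR"))
        else:
            if phase == "renewal":
                acq = tri[tri.phase == "acquisition"]
                ren = tri[tri.phase == "renewal"]
                for sid in sub.subject_id:
                    _, prop = renewal_response_prob(
                        acq[acq.subject_id == sid], ren[ren.subject_id == sid]
                    )
                    rows.append((sid, design.study_id, design.experiment, prop,
                                 "behavioural"))
            else:
                fit = hierarchical_logistic_scores(tri[tri.phase == phase])
                for sid in fit.params.subject_id:
                    p = fit.subject_probabilities(sid)[:STANDARD_BLOCK]
                    rows.append(
                        (sid, design.study_id, design.experiment,
                         expected_success_score(p), "behavioural")
                    )
    scores = pd.DataFrame(
        rows, columns=["subject_id", "study_id", "experiment", "raw_score", "branch"]
    )
    scores["phase"] = phase
    return standardize_scores(scores)
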