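"""Synthetic multi-study cohort generator.

Emulates the data layout of a multi-site fear/predictive-learning consortium:
per-subject ROI time series (stationary AR(1) Gaussian processes with a
target cross-correlation structure), directed effective-connectivity (EC)
coupling matrices with posterior variances, structural-connectivity (SC)
streamline counts, trial-level learning data (skin-conductance amplitudes or
binary behavioural responses), and demographic covariates — across several
studies grouped into two paradigm families (fear learning, FL; predictive
learning, PL).

Linear edge -> learning-score effects can be planted (:func:`plant_outcome`)
so that downstream selection and validation procedures can be tested against
known ground truth.

Randomness: one global integer seed; every operation derives independent
substreams via ``numpy.random.SeedSequence.spawn`` in a fixed, documented
order (covariates, connectivity, time series, trials per study, then outcome
planting), so any fixed seed reproduces the cohort bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import EdgeSet, default_edge_set, edge_label, split_node

__all__ = [
    "StudyDesign",
    "PlantedEffect",
    "Cohort",
    "default_study_roster",
    "gen_cohort",
    "gen_timeseries",
    "gen_connectivity",
    "gen_trial_data",
    "gen_task_events",
    "plant_outcome",
]

PHASES = ("acquisition", "extinction", "renewal")


class CohortConfigError(ValueError):
    """Raised for inconsistent study designs or generator parameters."""


@dataclass(frozen=True)
class StudyDesign:
    """Design of one study in the cohort.

    Parameters
    ----------
    study_id : str
        Label, e.g. ``"S1"``.
    paradigm : {"FL", "PL"}
        Fear learning or predictive learning family.
    measurement : {"SCR", "behavioural"}
        Trial-level dependent variable: skin-conductance response amplitudes
        or binary choices.
    n_subjects : int
    phases : tuple of str
        Subset of (acquisition, extinction, renewal).
    n_trials_per_cs : int
        Trials per CS type (or per stimulus) in each phase.
    repetition_time : float
        fMRI sampling interval in seconds.
    n_volumes : int
        Resting-state volumes per subject.
    experiment : str
        Experiment label within the study (standardization cell is
        study x experiment).
    """

    study_id: str
    paradigm: str
    measurement: str
    n_subjects: int
    phases: tuple = ("acquisition", "extinction")
    n_trials_per_cs: int = 8
    repetition_time: float = 2.0
    n_volumes: int = 190
    experiment: str = "E1"

    def __post_init__(self):
        if self.paradigm not in ("FL", "PL"):
            raise CohortConfigError(f"paradigm must be FL or PL, got {self.paradigm!r}")
        if self.measurement not in ("SCR", "behavioural"):
            raise CohortConfigError(
                f"measurement must be SCR or behavioural, got {self.measurement!r}"
            )
        if self.n_subjects < 1:
            raise CohortConfigError("n_subjects must be >= 1")
        if self.repetition_time <= 0:
            raise CohortConfigError("repetition_time must be > 0")
        unknown = set(self.phases) - set(PHASES)
        if unknown:
            raise CohortConfigError(f"unknown phases {sorted(unknown)}")
        if "renewal" in self.phases and self.n_trials_per_cs < 2:
            raise CohortConfigError(
                f"study {self.study_id}: renewal phase requires >= 2 trials per CS"
            )
        if self.measurement == "SCR" and self.n_trials_per_cs < 3:
            raise CohortConfigError(
                f"study {self.study_id}: polynomial (quadratic) scoring requires "
                f">= 3 trials per CS, got {self.n_trials_per_cs}"
            )

    @property
    def has_renewal(self) -> bool:
        return "renewal" in self.phases


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth linear edge -> learning effect.

    ``latent_i = sum_e beta_e * x_ie + gamma_age * age_i + gamma_sex * sex_i + eps_i``

    If ``target_r2`` is set, ``noise_sd`` is solved so the population R^2 of
    the oracle regression matches it.
    """

    modality: str = "FC"
    effect_edges: tuple = ()
    coefficients: tuple = ()
    covariate_effects: tuple = (0.0, 0.0)  # (age, sex)
    noise_sd: float = 1.0
    target_r2: float | None = None
    phase: str = "acquisition"

    def __post_init__(self):
        if self.modality not in ("FC", "EC", "SC"):
            raise CohortConfigError(f"unknown modality {self.modality!r}")
        if len(self.effect_edges) != len(self.coefficients):
            raise CohortConfigError("effect_edges and coefficients must align")
        if self.noise_sd < 0:
            raise CohortConfigError("noise_sd must be >= 0")
        if self.target_r2 is not None and not (0 <= self.target_r2 < 1):
            raise CohortConfigError("target_r2 must lie in [0, 1)")


@dataclass
class Cohort:
    """Per-subject multimodal bundle for one or more studies.

    Attributes
    ----------
    subjects : DataFrame
        subject_id, study_id, experiment, paradigm, measurement, age, sex,
        plus ``latent_<phase>`` ground-truth learning columns.
    connectivity : DataFrame (long)
        subject_id, modality (FC/EC/SC), source, target, edge, value,
        posterior_var (EC only, NaN otherwise).
    trials : DataFrame
        subject_id, phase, cs_type, trial (1-based within phase x cs_type),
        stimulus, amplitude (SCR) / response (behavioural).
    timeseries : dict subject_id -> ndarray (10 regions, n_volumes)
    designs : list of StudyDesign
    edge_set : EdgeSet
    manifest : dict  — seed and generator parameters.
    """

    subjects: pd.DataFrame
    connectivity: pd.DataFrame
    trials: pd.DataFrame
    timeseries: dict
    designs: list
    edge_set: EdgeSet
    manifest: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def study(self, study_id: str) -> "Cohort":
        """Subset the cohort to one study (shallow views of the tables)."""
        subj = self.subjects[self.subjects.study_id == study_id]
        ids = set(subj.subject_id)
        return Cohort(
            subjects=subj.reset_index(drop=True),
            connectivity=self.connectivity[
                self.connectivity.subject_id.isin(ids)
            ].reset_index(drop=True),
            trials=self.trials[self.trials.subject_id.isin(ids)].reset_index(drop=True),
            timeseries={k: v for k, v in self.timeseries.items() if k in ids},
            designs=[d for d in self.designs if d.study_id == study_id],
            edge_set=self.edge_set,
            manifest=self.manifest,
        )


def default_study_roster() -> list[StudyDesign]:
    """Six studies: five FL studies with SCR learning indices and one larger
    PL study with binary behavioural responses. Renewal is measured in one FL
    study and in the PL study."""
    roster = []
    for sid in ("S1", "S2", "S3", "S5", "S6"):
        phases = ("acquisition", "extinction", "renewal") if sid == "S3" else (
            "acquisition",
            "extinction",
        )
        roster.append(
            StudyDesign(study_id=sid, paradigm="FL", measurement="SCR",
                        n_subjects=60, phases=phases)
        )
    roster.append(
        StudyDesign(study_id="S4", paradigm="PL", measurement="behavioural",
                    n_subjects=180, phases=("acquisition", "extinction", "renewal"),
                    n_trials_per_cs=24)  # 8 unique trial types x 3 presentations
    )
    return roster


# ---------------------------------------------------------------------------
# time series

def _target_matrix(target_edge_corr: dict, edge_set: EdgeSet, nodes: tuple) -> np.ndarray:
    C = np.eye(len(nodes))
    idx = {n: i for i, n in enumerate(nodes)}
    for edge, r in target_edge_corr.items():
        if isinstance(edge, str):
            a, b = edge.split("->") if "->" in edge else edge.split("-")
        else:
            a, b = edge
        if not -1 < r < 1:
            raise CohortConfigError(f"target correlation for {edge} must lie in (-1, 1)")
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = r
    return C


def gen_timeseries(
    n_subjects: int,
    target_edge_corr: dict,
    ar_coefficient: float = 0.4,
    n_volumes: int = 190,
    seed=0,
    edge_set: EdgeSet | None = None,
    nodes: tuple | None = None,
) -> dict:
    """Stationary AR(1) Gaussian ROI series with target cross-correlations.

    Each subject's 10 x n_volumes matrix follows
    ``z_t = phi z_{t-1} + sqrt(1 - phi^2) L eps_t`` with ``L L' = C`` the
    target correlation matrix, so the stationary covariance equals ``C``
    while each series has lag-1 autocorrelation ``phi``. Rows are demeaned.

    Raises
    ------
    CohortConfigError
        If the implied 10x10 matrix is not positive definite (the message
        suggests the nearest-PD eigenvalue-clipped alternative; no silent
        repair is performed) or ``ar_coefficient`` is outside [0, 1).
    """
    if not 0 <= ar_coefficient < 1:
        raise CohortConfigError("ar_coefficient must lie in [0, 1)")
    if nodes is None:
        from .network import NODES

        nodes = NODES
    edge_set = edge_set or default_edge_set()
    C = _target_matrix(target_edge_corr, edge_set, nodes)
    w = np.linalg.eigvalsh(C)
    if w.min() <= 1e-10:
        clipped = _nearest_pd(C)
        raise CohortConfigError(
            "target correlation matrix is not positive definite "
            f"(min eigenvalue {w.min():.3g}); nearest PD matrix has "
            f"max entry-wise change {np.abs(clipped - C).max():.3g} — "
            "adjust targets rather than relying on silent repair"
        )
    rng = np.random.default_rng(seed)
    out = {}
    L = np.linalg.cholesky(C)
    phi = ar_coefficient
    innov_scale = math.sqrt(1 - phi * phi)
    for i in range(n_subjects):
        eps = rng.standard_normal((n_volumes, len(nodes))) @ L.T
        z = np.empty_like(eps)
        z[0] = rng.standard_normal(len(nodes)) @ L.T
        for t in range(1, n_volumes):
            z[t] = phi * z[t - 1] + innov_scale * eps[t]
        ts = z.T
        out[i] = ts - ts.mean(axis=1, keepdims=True)
    return out


def _nearest_pd(C: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    w = np.clip(w, floor, None)
    M = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(M))
    return M / np.outer(d, d)


def _ar1_from_corr(C: np.ndarray, phi: float, n_volumes: int, rng) -> np.ndarray:
    L = np.linalg.cholesky(C)
    eps = rng.standard_normal((n_volumes, C.shape[0])) @ L.T
    z = np.empty_like(eps)
    z[0] = rng.standard_normal(C.shape[0]) @ L.T
    s = math.sqrt(1 - phi * phi)
    for t in range(1, n_volumes):
        z[t] = phi * z[t - 1] + s * eps[t]
    ts = z.T
    return ts - ts.mean(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# connectivity

def default_fc_template(edge_set: EdgeSet) -> dict:
    """Qualitative resting-state coupling template: strong HIP-AMY, then
    HIP-PFC and AMY-PFC, weak cerebellar edges."""
    strong = {
        frozenset(("AMY", "HIP")): 0.50,
        frozenset(("HIP", "PFC")): 0.40,
        frozenset(("AMY", "PFC")): 0.30,
        frozenset(("ACC", "PFC")): 0.25,
    }
    tmpl = {}
    for a, b in edge_set.undirected:
        ra, rb = split_node(a)[0], split_node(b)[0]
        key = frozenset((ra, rb))
        if "CEB" in key:
            tmpl[edge_label(a, b)] = 0.15
        else:
            tmpl[edge_label(a, b)] = strong.get(key, 0.20)
    return tmpl


def default_ec_template(edge_set: EdgeSet) -> dict:
    """Directed coupling means: mostly inhibitory (negative), except positive
    bidirectional HIP<->AMY."""
    tmpl = {}
    for a, b in edge_set.directed:
        ra, rb = split_node(a)[0], split_node(b)[0]
        if {ra, rb} == {"AMY", "HIP"}:
            tmpl[edge_label(a, b, directed=True)] = 0.3
        else:
            tmpl[edge_label(a, b, directed=True)] = -0.2
    return tmpl


def default_sc_template(edge_set: EdgeSet) -> dict:
    """Skewed streamline-count means: HIP-AMY disproportionately largest,
    then ACC-PFC and AMY-PFC."""
    strong = {
        frozenset(("AMY", "HIP")): 800.0,
        frozenset(("ACC", "PFC")): 400.0,
        frozenset(("AMY", "PFC")): 300.0,
    }
    tmpl = {}
    for a, b in edge_set.undirected:
        key = frozenset((split_node(a)[0], split_node(b)[0]))
        tmpl[edge_label(a, b)] = strong.get(key, 100.0)
    return tmpl


def gen_connectivity(
    n_subjects: int,
    ec_mean_matrix: dict | None = None,
    ec_between_subject_sd: float = 0.15,
    ec_posterior_var_range: tuple = (0.01, 0.1),
    sc_mean_counts: dict | None = None,
    sc_dispersion: float = 2.0,
    seed=0,
    edge_set: EdgeSet | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-subject EC matrices (+ posterior variances) and SC counts.

    EC values are Gaussian around a signed mean template (negative
    off-diagonal couplings except positive HIP<->AMY by default) with
    between-subject sd ``ec_between_subject_sd``; per-connection posterior
    variances are uniform in ``ec_posterior_var_range``. SC counts are
    negative-binomial around a skewed mean template with dispersion (size)
    ``sc_dispersion``; ``var = mu + mu^2 / dispersion``, so the
    ``dispersion -> inf`` limit is Poisson.

    Returns (ec_long, sc_long) DataFrames.
    """
    edge_set = edge_set or default_edge_set()
    if sc_dispersion <= 0:
        raise CohortConfigError("sc_dispersion must be > 0")
    lo, hi = ec_posterior_var_range
    if lo <= 0 or hi < lo:
        raise CohortConfigError("ec_posterior_var_range must be positive and ordered")
    ec_mean = ec_mean_matrix or default_ec_template(edge_set)
    sc_mean = sc_mean_counts or default_sc_template(edge_set)
    if any(v < 0 for v in sc_mean.values()):
        raise CohortConfigError("sc_mean_counts must be >= 0")
    rng = np.random.default_rng(seed)

    ec_labels = edge_set.directed_labels
    mu = np.array([ec_mean[e] for e in ec_labels])
    vals = mu + ec_between_subject_sd * rng.standard_normal((n_subjects, len(ec_labels)))
    pvar = rng.uniform(lo, hi, size=(n_subjects, len(ec_labels)))
    ec = pd.DataFrame(
        {
            "subject_id": np.repeat(np.arange(n_subjects), len(ec_labels)),
            "edge": np.tile(ec_labels, n_subjects),
            "value": vals.ravel(),
            "posterior_var": pvar.ravel(),
        }
    )

    sc_labels = edge_set.undirected_labels
    mu_sc = np.array([sc_mean[e] for e in sc_labels])
    if sc_dispersion > 1e6:  # numerically Poisson
        counts = rng.poisson(np.broadcast_to(mu_sc, (n_subjects, len(sc_labels))))
    else:
        r = sc_dispersion
        p = r / (r + mu_sc)
        counts = rng.negative_binomial(r, np.broadcast_to(p, (n_subjects, len(sc_labels))))
    sc = pd.DataFrame(
        {
            "subject_id": np.repeat(np.arange(n_subjects), len(sc_labels)),
            "edge": np.tile(sc_labels, n_subjects),
            "value": counts.ravel().astype(float),
        }
    )
    return ec, sc


# ---------------------------------------------------------------------------
# trial data

def _phase_template(phase: str, t: np.ndarray, n_trials: int) -> np.ndarray:
    """Linear learning-curve template f_phase(t): increasing during
    acquisition, decreasing during extinction and renewal. Lies inside the
    quadratic model space so polynomial scores are analytic."""
    if phase == "acquisition":
        return (t - 1).astype(float)
    return (n_trials - t).astype(float)


def gen_trial_data(
    design: StudyDesign,
    learning_rate_distribution: tuple = (0.5, 0.15),
    seed=0,
    noise_sd: float = 0.2,
    baseline: float = 0.5,
    behav_intercept: tuple = (0.0, 0.5),
    behav_slope: tuple | None = None,
    renewal_logit: tuple = (-1.0, 0.8),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate trial tables and latent per-subject learning rates.

    SCR branch: ``amplitude(t, CS) = baseline + g_i * f_phase(t) * 1[CS+] + eps``
    with ``g_i ~ N(mean, sd)`` from ``learning_rate_distribution`` and
    Gaussian noise ``eps``. Behavioural branch: per-subject logistic learning
    ``response_t ~ Bernoulli(sigmoid(b0_i + b1_i * t))`` with ``(b0_i, b1_i)``
    bivariate normal; renewal-phase responses are Bernoulli at a per-subject
    renewal propensity ``sigmoid(r_i)``.

    Returns (trials, latent) where ``latent`` has one row per subject with
    ``g_<phase>`` (or ``b1_<phase>``) ground-truth rates.
    """
    if noise_sd <= 0:
        raise CohortConfigError("noise_sd must be > 0")
    g_mean, g_sd = learning_rate_distribution
    if not np.isfinite(g_sd) or g_sd < 0:
        raise CohortConfigError("learning-rate distribution must have finite variance")
    rng = np.random.default_rng(seed)
    n, T = design.n_subjects, design.n_trials_per_cs
    rows = []
    latent = {"subject_id": np.arange(n)}
    if design.measurement == "SCR":
        for phase in design.phases:
            g = rng.normal(g_mean, g_sd, n)
            latent[f"g_{phase}"] = g
            t = np.arange(1, T + 1)
            f = _phase_template(phase, t, T)
            for cs, csname in ((1, "CS+"), (0, "CS-")):
                amp = (
                    baseline
                    + np.outer(g, f) * cs
                    + rng.normal(0, noise_sd, (n, T))
                )
                for ti in range(T):
                    rows.append(
                        pd.DataFrame(
                            {
                                "subject_id": np.arange(n),
                                "phase": phase,
                                "cs_type": csname,
                                "trial": ti + 1,
                                "stimulus": ti + 1,
                                "amplitude": amp[:, ti],
                            }
                        )
                    )
        trials = pd.concat(rows, ignore_index=True)
        trials["response"] = np.nan
    else:
        b0_mean, b0_sd = behav_intercept
        b1_mean, b1_sd = behav_slope if behav_slope is not None else (g_mean, g_sd)
        r_mean, r_sd = renewal_logit
        for phase in design.phases:
            t = np.arange(1, T + 1)
            if phase == "renewal":
                r = rng.normal(r_mean, r_sd, n)
                latent["r_renewal"] = r
                p = 1 / (1 + np.exp(-r))[:, None] * np.ones((1, T))
            else:
                b0 = rng.normal(b0_mean, b0_sd, n)
                sgn = 1.0 if phase == "acquisition" else -1.0
                b1 = sgn * rng.normal(b1_mean, b1_sd, n)
                latent[f"b0_{phase}"] = b0
                latent[f"b1_{phase}"] = b1
                p = 1 / (1 + np.exp(-(b0[:, None] + b1[:, None] * t[None, :])))
            resp = (rng.random((n, T)) < p).astype(int)
            for ti in range(T):
                rows.append(
                    pd.DataFrame(
                        {
                            "subject_id": np.arange(n),
                            "phase": phase,
                            "cs_type": "CS+",
                            "trial": ti + 1,
                            "stimulus": ti + 1,
                            "response": resp[:, ti],
                        }
                    )
                )
        trials = pd.concat(rows, ignore_index=True)
        trials["amplitude"] = np.nan
    return trials, pd.DataFrame(latent)


# ---------------------------------------------------------------------------
# task events

def gen_task_events(
    design: StudyDesign,
    n_trials_per_condition: int = 20,
    iti_range: tuple = (4.0, 8.0),
    duration: float = 4.0,
    coupling_plus: dict | None = None,
    coupling_minus: dict | None = None,
    hrf_lag: tuple = (4.0, 8.0),
    seed=0,
    edge_set: EdgeSet | None = None,
    n_subjects: int | None = None,
    schedule: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Event table (onset/duration/trial_type) plus task time series whose
    edge coupling depends on the condition inside the expected BOLD-peak
    window ``[onset + hrf_lag[0], onset + hrf_lag[1]]``.

    Volumes inside CS+ peak windows are drawn with edge correlations
    ``coupling_plus``, CS- windows with ``coupling_minus``, all other volumes
    uncorrelated baseline noise. Passing ``schedule`` (an events table from a
    previous call) reuses its timing so several generator calls share one
    trial schedule.
    """
    if n_trials_per_condition <= 0:
        raise CohortConfigError("n_trials_per_condition must be > 0")
    if iti_range[0] <= 0 or iti_range[1] < iti_range[0]:
        raise CohortConfigError("iti_range must be positive and ordered")
    edge_set = edge_set or default_edge_set()
    rng = np.random.default_rng(seed)
    n_sub = n_subjects if n_subjects is not None else design.n_subjects
    tr = design.repetition_time

    if schedule is not None:
        onsets = schedule.onset.to_numpy(dtype=float)
        types = schedule.trial_type.to_numpy()
        duration = float(schedule.duration.iloc[0])
        t0 = float(onsets.max()) + max(duration, hrf_lag[1]) + iti_range[0]
    else:
        n_trials = 2 * n_trials_per_condition
        types = np.array(
            ["CS+"] * n_trials_per_condition + ["CS-"] * n_trials_per_condition
        )
        rng.shuffle(types)
        onsets = np.empty(n_trials)
        t0 = float(iti_range[0])
        window_len = hrf_lag[1]  # peak window closes before the next trial opens
        for i in range(len(onsets)):
            onsets[i] = t0
            t0 += max(duration, window_len) + rng.uniform(*iti_range)
    total_time = t0 + hrf_lag[1]
    n_volumes = int(math.ceil(total_time / tr)) + 1
    if (onsets + hrf_lag[1]).max() > n_volumes * tr:
        raise CohortConfigError("events do not fit within the scan duration")
    # overlapping peak windows would make the planted coupling ill-defined
    order = np.argsort(onsets)
    starts, ends = onsets[order] + hrf_lag[0], onsets[order] + hrf_lag[1]
    if np.any(starts[1:] < ends[:-1]):
        raise CohortConfigError("peak windows overlap; increase the ITI range")

    events = pd.DataFrame({"onset": onsets, "duration": duration, "trial_type": types})

    from .network import NODES

    C_plus = _target_matrix(coupling_plus or {}, edge_set, NODES)
    C_minus = _target_matrix(coupling_minus or {}, edge_set, NODES)
    for name, C in (("coupling_plus", C_plus), ("coupling_minus", C_minus)):
        if np.linalg.eigvalsh(C).min() <= 1e-10:
            raise CohortConfigError(f"{name} matrix is not positive definite")
    L_plus, L_minus = np.linalg.cholesky(C_plus), np.linalg.cholesky(C_minus)

    vol_times = np.arange(n_volumes) * tr
    masks = []
    for _, ev in events.iterrows():
        sel = (vol_times >= ev.onset + hrf_lag[0]) & (vol_times <= ev.onset + hrf_lag[1])
        masks.append((ev.trial_type, sel))
    timeseries = {}
    p = len(NODES)
    for s in range(n_sub):
        ts = rng.standard_normal((p, n_volumes))
        for trial_type, sel in masks:
            k = int(sel.sum())
            L = L_plus if trial_type == "CS+" else L_minus
            ts[:, sel] = (rng.standard_normal((k, p)) @ L.T).T
        timeseries[s] = ts - ts.mean(axis=1, keepdims=True)
    return events, timeseries


# ---------------------------------------------------------------------------
# outcome planting

def plant_outcome(
    cohort: Cohort,
    effect: PlantedEffect,
    seed=0,
    measurement_link: float = 0.9,
) -> Cohort:
    """Overwrite latent learning with a planted linear function of edges.

    ``latent_i = sum_e beta_e x_ie + gamma_age age_i + gamma_sex sex_i + eps_i``.
    If ``effect.target_r2`` is set, the noise sd is solved so the population
    R^2 of the oracle regression equals it. Trial-generating learning rates
    for ``effect.phase`` are then re-linked so that measured scores correlate
    with the latent outcome with strength ``measurement_link`` (rho).
    """
    conn = cohort.connectivity
    sub = cohort.subjects.sort_values("subject_id").reset_index(drop=True)
    cmod = conn[conn.modality == effect.modality]
    wide = cmod.pivot_table(index="subject_id", columns="edge", values="value")
    missing = [e for e in effect.effect_edges if e not in wide.columns]
    if missing:
        raise CohortConfigError(
            f"effect edges {missing} absent from the {effect.modality} catalogue"
        )
    wide = wide.loc[sub.subject_id]
    rng = np.random.default_rng(seed)
    signal = np.zeros(len(sub))
    for e, b in zip(effect.effect_edges, effect.coefficients):
        x = wide[e].to_numpy()
        sd = x.std()
        signal += b * (x - x.mean()) / (sd if sd > 0 else 1.0)
    g_age, g_sex = effect.covariate_effects
    signal += g_age * (sub.age - sub.age.mean()).to_numpy()
    signal += g_sex * (sub.sex - sub.sex.mean()).to_numpy()
    if effect.target_r2 is not None:
        var_sig = signal.var()
        if effect.target_r2 == 0 or var_sig == 0:
            noise_sd = 1.0 if var_sig == 0 else effect.noise_sd
        else:
            noise_sd = math.sqrt(var_sig * (1 - effect.target_r2) / effect.target_r2)
    else:
        noise_sd = effect.noise_sd
    latent = signal + (noise_sd * rng.standard_normal(len(sub)) if noise_sd > 0 else 0.0)

    sub = sub.copy()
    sub[f"latent_{effect.phase}"] = latent
    new_cohort = replace(cohort, subjects=sub)
    _relink_trials(new_cohort, effect.phase, latent, rng, measurement_link)
    return new_cohort


def _relink_trials(cohort: Cohort, phase: str, latent: np.ndarray, rng,
                   rho: float) -> None:
    """Regenerate the phase's trial measurements so measured learning rates
    correlate (strength rho) with the planted latent outcome. Operates
    in-place on ``cohort.trials``."""
    sd = latent.std()
    z = (latent - latent.mean()) / (sd if sd > 0 else 1.0)
    sub = cohort.subjects
    trials = cohort.trials
    for design in cohort.designs:
        ids = sub.loc[sub.study_id == design.study_id, "subject_id"].to_numpy()
        if phase not in design.phases or len(ids) == 0:
            continue
        pos = sub.set_index("subject_id").index.get_indexer(ids)
        zi = z[pos]
        u = rng.standard_normal(len(ids))
        mix = rho * zi + math.sqrt(max(0.0, 1 - rho * rho)) * u
        T = design.n_trials_per_cs
        t = np.arange(1, T + 1)
        if design.measurement == "SCR":
            g = 0.5 + 0.15 * mix
            f = _phase_template(phase, t, T)
            for cs, csname in ((1, "CS+"), (0, "CS-")):
                amp = 0.5 + np.outer(g, f) * cs + rng.normal(0, 0.2, (len(ids), T))
                m = (
                    (trials.phase == phase)
                    & (trials.cs_type == csname)
                    & trials.subject_id.isin(ids)
                )
                block = trials.loc[m]
                row = _row_index(block.subject_id.to_numpy(), ids)
                col = block.trial.to_numpy() - 1
                trials.loc[block.index, "amplitude"] = amp[row, col]
        else:
            if phase == "renewal":
                r = -1.0 + 0.8 * mix
                p = 1 / (1 + np.exp(-r))[:, None] * np.ones((1, T))
            else:
                sgn = 1.0 if phase == "acquisition" else -1.0
                b1 = sgn * (0.3 + 0.15 * mix)
                b0 = rng.normal(0, 0.5, len(ids))
                p = 1 / (1 + np.exp(-(b0[:, None] + b1[:, None] * t[None, :])))
            resp = (rng.random((len(ids), T)) < p).astype(int)
            m = (trials.phase == phase) & trials.subject_id.isin(ids)
            block = trials.loc[m]
            row = _row_index(block.subject_id.to_numpy(), ids)
            col = block.trial.to_numpy() - 1
            trials.loc[block.index, "response"] = resp[row, col]


def _row_index(values: np.ndarray, ids: np.ndarray) -> np.ndarray:
    lookup = {v: i for i, v in enumerate(ids)}
    return np.array([lookup[v] for v in values])


# ---------------------------------------------------------------------------
# orchestrator

def gen_cohort(
    designs: list,
    effect: PlantedEffect | None = None,
    seed: int = 0,
    edge_set: EdgeSet | None = None,
    fc_subject_sd: float = 0.15,
    ar_coefficient: float = 0.4,
    trial_kwargs: dict | None = None,
    connectivity_kwargs: dict | None = None,
    generate_timeseries: bool = True,
) -> Cohort:
    """Generate a full multi-study cohort from a single seed.

    Per study, independent substreams are derived (in order: covariates,
    connectivity, time series, trials); a final substream drives outcome
    planting. Subject FC edge values are drawn around the qualitative
    coupling template on the Fisher-z scale (sd ``fc_subject_sd``); each
    subject's ROI time series is simulated from their own correlation matrix,
    so estimated FC tracks the cohort's latent FC table.
    """
    if not designs:
        raise CohortConfigError("at least one StudyDesign required")
    ids = [d.study_id for d in designs]
    if len(set(ids)) != len(ids):
        raise CohortConfigError("duplicate study_id in designs")
    edge_set = edge_set or default_edge_set()
    root = np.random.SeedSequence(seed)
    study_seeds = root.spawn(len(designs) + 1)
    fc_template = default_fc_template(edge_set)
    und_labels = edge_set.undirected_labels
    z_template = np.arctanh(np.array([fc_template[e] for e in und_labels]))

    subj_frames, conn_frames, trial_frames = [], [], []
    timeseries: dict = {}
    offset = 0
    from .network import NODES

    node_idx = {n: i for i, n in enumerate(NODES)}
    for design, sseq in zip(designs, study_seeds[:-1]):
        s_cov, s_conn, s_ts, s_tr = sseq.spawn(4)
        n = design.n_subjects
        rng_cov = np.random.default_rng(s_cov)
        sub_ids = np.arange(offset, offset + n)
        subj = pd.DataFrame(
            {
                "subject_id": sub_ids,
                "study_id": design.study_id,
                "experiment": design.experiment,
                "paradigm": design.paradigm,
                "measurement": design.measurement,
                "age": rng_cov.uniform(20, 30, n),
                "sex": rng_cov.integers(0, 2, n),
            }
        )

        rng_conn = np.random.default_rng(s_conn)
        # latent subject-level FC on the Fisher-z scale
        z = z_template[None, :] + fc_subject_sd * rng_conn.standard_normal(
            (n, len(und_labels))
        )
        r = np.tanh(z)
        fc = pd.DataFrame(
            {
                "subject_id": np.repeat(sub_ids, len(und_labels)),
                "edge": np.tile(und_labels, n),
                "value": r.ravel(),
            }
        )
        fc["modality"] = "FC"
        ec, sc = gen_connectivity(
            n, seed=rng_conn.integers(2**31), edge_set=edge_set,
            **(connectivity_kwargs or {}),
        )
        ec["subject_id"] = ec.subject_id.map(dict(enumerate(sub_ids)))
        sc["subject_id"] = sc.subject_id.map(dict(enumerate(sub_ids)))
        ec["modality"], sc["modality"] = "EC", "SC"
        conn_frames.extend([fc, ec, sc])

        if generate_timeseries:
            rng_ts = np.random.default_rng(s_ts)
            for i, sid in enumerate(sub_ids):
                C = np.eye(len(NODES))
                for j, lab in enumerate(und_labels):
                    a, b = lab.split("-")
                    C[node_idx[a], node_idx[b]] = C[node_idx[b], node_idx[a]] = r[i, j]
                if np.linalg.eigvalsh(C).min() <= 1e-8:
                    C = _nearest_pd(C)
                timeseries[sid] = _ar1_from_corr(
                    C, ar_coefficient, design.n_volumes, rng_ts
                )

        trials, latent = gen_trial_data(
            design, seed=s_tr, **(trial_kwargs or {})
        )
        trials["subject_id"] = trials.subject_id.map(dict(enumerate(sub_ids)))
        for phase in design.phases:
            col = f"g_{phase}" if design.measurement == "SCR" else (
                "r_renewal" if phase == "renewal" else f"b1_{phase}"
            )
            subj[f"latent_{phase}"] = latent[col].to_numpy()
        subj_frames.append(subj)
        trial_frames.append(trials)
        offset += n

    subjects = pd.concat(subj_frames, ignore_index=True)
    connectivity = pd.concat(conn_frames, ignore_index=True)
    connectivity["source"] = [
        e.split("->")[0] if "->" in e else e.split("-")[0] for e in connectivity.edge
    ]
    connectivity["target"] = [
        e.split("->")[1] if "->" in e else e.split("-")[1] for e in connectivity.edge
    ]
    if "posterior_var" not in connectivity:
        connectivity["posterior_var"] = np.nan
    trials = pd.concat(trial_frames, ignore_index=True)
    cohort = Cohort(
        subjects=subjects,
        connectivity=connectivity[
            ["subject_id", "modality", "source", "target", "edge", "value", "posterior_var"]
        ],
        trials=trials,
        timeseries=timeseries,
        designs=list(designs),
        edge_set=edge_set,
        manifest={
            "seed": int(seed),
            "n_studies": len(designs),
            "fc_subject_sd": fc_subject_sd,
            "ar_coefficient": ar_coefficient,
            "substream_order": "per study: covariates, connectivity, timeseries, "
                               "trials; then planting",
        },
    )
    if effect is not None:
        cohort = plant_outcome(cohort, effect, seed=study_seeds[-1])
    return cohort
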