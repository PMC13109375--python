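"""Cohort readers and writers.

A cohort on disk is a directory of tab-delimited UTF-8 tables with header
rows plus a JSON manifest:

    subjects.tsv       subject_id, study_id, experiment, paradigm,
                       measurement, age, sex, latent_* columns
    connectivity.tsv   subject_id, modality, source, target, edge, value,
                       posterior_var (long format)
    trials.tsv         subject_id, phase, cs_type, trial, stimulus,
                       amplitude, response
    events.tsv         onset, duration, trial_type (BIDS-events style,
                       seconds; optional)
    timeseries/sub-<id>.tsv   regions x volumes matrix, row labels = nodes
    manifest.json      seed, generator parameters, study designs

Schema violations are reported with table, row, and column coordinates.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import NODES, EdgeSet, parse_edge
from .synthgen import Cohort, StudyDesign

__all__ = ["write_cohort", "load_cohort_tables", "SchemaError"]


class SchemaError(ValueError):
    pass


SUBJECT_COLS = ["subject_id", "study_id", "experiment", "paradigm", "measurement",
                "age", "sex"]
CONNECTIVITY_COLS = ["subject_id", "modality", "source", "target", "edge", "value",
                     "posterior_var"]
TRIAL_COLS = ["subject_id", "phase", "cs_type", "trial", "stimulus"]


def write_cohort(cohort: Cohort, directory) -> Path:
    """Serialize a cohort to a directory of TSV tables + manifest.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cohort.subjects.to_csv(d / "subjects.tsv", sep="\t", index=False)
    cohort.connectivity.to_csv(d / "connectivity.tsv", sep="\t", index=False)
    cohort.trials.to_csv(d / "trials.tsv", sep="\t", index=False)
    tsdir = d / "timeseries"
    tsdir.mkdir(exist_ok=True)
    for sid, ts in cohort.timeseries.items():
        pd.DataFrame(ts, index=NODES).to_csv(tsdir / f"sub-{sid}.tsv", sep="\t",
                                             header=False)
    manifest = dict(cohort.manifest)
    manifest["designs"] = [dataclasses.asdict(ds) for ds in cohort.designs]
    manifest["edges"] = cohort.edge_set.undirected_labels
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return d


def _require_columns(df: pd.DataFrame, cols, table: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required columns {missing}")


def load_cohort_tables(directory) -> Cohort:
    """Load and schema-validate a cohort directory written by write_cohort."""
    d = Path(directory)
    mf_path = d / "manifest.json"
    if not mf_path.exists():
        raise SchemaError("manifest.json not found")
    manifest = json.loads(mf_path.read_text())
    designs = [
        StudyDesign(**{**ds, "phases": tuple(ds["phases"])})
        for ds in manifest.pop("designs", [])
    ]
    subjects = pd.read_csv(d / "subjects.tsv", sep="\t")
    _require_columns(subjects, SUBJECT_COLS, "subjects.tsv")
    connectivity = pd.read_csv(d / "connectivity.tsv", sep="\t")
    _require_columns(connectivity, CONNECTIVITY_COLS[:6], "connectivity.tsv")
    for i, e in enumerate(connectivity.edge):
        try:
            parse_edge(e)
        except ValueError as err:
            raise SchemaError(f"connectivity.tsv row {i}: {err}") from None
    sc = connectivity[connectivity.modality == "SC"]
    neg = sc.index[sc.value < 0]
    if len(neg):
        raise SchemaError(
            f"connectivity.tsv row {neg[0]}: negative SC streamline count"
        )
    ec = connectivity[connectivity.modality == "EC"]
    if "posterior_var" in connectivity.columns:
        bad = ec.index[~(ec.posterior_var > 0)]
        if len(bad):
            raise SchemaError(
                f"connectivity.tsv row {bad[0]}: EC posterior variance must be > 0"
            )
    trials = pd.read_csv(d / "trials.tsv", sep="\t")
    _require_columns(trials, TRIAL_COLS, "trials.tsv")
    for (sid, phase, cs), grp in trials.groupby(["subject_id", "phase", "cs_type"]):
        t = np.sort(grp.trial.to_numpy())
        if not np.array_equal(t, np.arange(1, len(t) + 1)):
            raise SchemaError(
                f"trials.tsv: subject {sid} {phase}/{cs}: trial indices not "
                f"contiguous from 1"
            )
    ev_path = d / "events.tsv"
    if ev_path.exists():
        events = pd.read_csv(ev_path, sep="\t")
        _require_columns(events, ["onset", "duration", "trial_type"], "events.tsv")
    timeseries = {}
    tsdir = d / "timeseries"
    if tsdir.exists():
        for f in sorted(tsdir.glob("sub-*.tsv")):
            sid = f.stem.removeprefix("sub-")
            sid = int(sid) if sid.isdigit() else sid
            mat = pd.read_csv(f, sep="\t", header=None, index_col=0)
            if mat.shape[0] != len(NODES):
                raise SchemaError(
                    f"{f.name}: expected {len(NODES)} region rows, got {mat.shape[0]}"
                )
            unknown = [r for r in mat.index if r not in NODES]
            if unknown:
                raise SchemaError(f"{f.name}: unknown region labels {unknown}")
            timeseries[sid] = mat.loc[list(NODES)].to_numpy(dtype=float)
    edges = manifest.pop("edges", None)
    if edges:
        und = tuple(tuple(e.split("-")) for e in edges)
        edge_set = EdgeSet(undirected=und)
    else:
        from .network import default_edge_set

        edge_set = default_edge_set()
    return Cohort(
        subjects=subjects,
        connectivity=connectivity,
        trials=trials,
        timeseries=timeseries,
        designs=designs,
        edge_set=edge_set,
        manifest=manifest,
    )
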