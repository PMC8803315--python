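"""Readers/writers for the artifact's on-disk formats and the pipeline driver.

Sessions are stored as three CSV files (``trials.csv``, ``events.csv`` in
long format with columns ``time_s,event_label,trial_index``, and
``motion.csv``), spikes as a two-column CSV (``unit_id,time_s``), and LFP /
node time series as HDF5 arrays with ``fs_hz`` / node-name attributes.
Schema violations are reported with the offending column or row number.
Outputs are written atomically (temp file + rename).
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import behavior, connectivity, ephys, lfp as lfp_mod, synthetic
from .config import RunConfig, stage_seeds
from .synthetic import KNOWN_EVENT_LABELS, SessionLog

log = logging.getLogger("impulsekit")

__all__ = [
    "SchemaError",
    "write_session", "read_session",
    "write_spikes", "read_spikes",
    "write_lfp", "read_lfp",
    "write_node_timeseries", "read_node_timeseries",
    "run_pipeline",
]


class SchemaError(ValueError):
    """A file does not conform to the expected schema."""


def _atomic_write_df(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        df.to_csv(tmp, index=False)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------

def write_session(session: SessionLog, directory) -> None:
    d = Path(directory)
    _atomic_write_df(session.trials, d / "trials.csv")
    _atomic_write_df(session.events, d / "events.csv")
    _atomic_write_df(session.motion, d / "motion.csv")
    meta = {"animal_id": session.animal_id, "duration_s": session.duration_s,
            "motion_fs_hz": session.motion_fs_hz}
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    os.close(fd)
    Path(tmp).write_text(json.dumps(meta, sort_keys=True))
    os.replace(tmp, d / "session.json")


def read_session(directory) -> SessionLog:
    d = Path(directory)
    trials = pd.read_csv(d / "trials.csv")
    events = pd.read_csv(d / "events.csv")
    motion = pd.read_csv(d / "motion.csv")
    meta = json.loads((d / "session.json").read_text())
    _require_columns(trials, ["index", "trial_type", "precue_duration_s",
                              "cue_onset_s", "outcome", "response_latency_s",
                              "n_precue_pokes", "lick_count"], "trials.csv")
    _require_columns(events, ["time_s", "event_label", "trial_index"],
                     "events.csv")
    _require_columns(motion, ["time_s", "motion"], "motion.csv")
    t = events["time_s"].to_numpy()
    bad = np.flatnonzero(np.diff(t) < 0)
    if len(bad):
        raise SchemaError(f"events.csv: times out of order at row {bad[0] + 1}")
    unknown = ~events["event_label"].isin(KNOWN_EVENT_LABELS)
    if unknown.any():
        row = int(np.flatnonzero(unknown)[0])
        raise SchemaError(
            f"events.csv: unknown event label "
            f"{events['event_label'].iloc[row]!r} at row {row}")
    bad_outcome = ~trials["outcome"].isin(synthetic.TRIAL_OUTCOMES)
    if bad_outcome.any():
        row = int(np.flatnonzero(bad_outcome)[0])
        raise SchemaError(f"trials.csv: unknown outcome at row {row}")
    return SessionLog(animal_id=meta["animal_id"], trials=trials,
                      events=events, motion=motion,
                      duration_s=float(meta["duration_s"]),
                      motion_fs_hz=float(meta["motion_fs_hz"]))


# ---------------------------------------------------------------------------
# Spikes
# ---------------------------------------------------------------------------

def write_spikes(trains, path) -> None:
    rows = [{"unit_id": tr.unit_id, "time_s": t}
            for tr in trains for t in tr.spike_times_s]
    df = pd.DataFrame(rows, columns=["unit_id", "time_s"])
    _atomic_write_df(df, Path(path))


def read_spikes(path, span) -> list:
    df = pd.read_csv(path)
    _require_columns(df, ["unit_id", "time_s"], "spikes csv")
    out = []
    for uid, sub in df.groupby("unit_id", sort=True):
        times = np.sort(sub["time_s"].to_numpy(dtype=float))
        out.append(ephys.SpikeTrain(unit_id=str(uid), spike_times_s=times,
                                    span=tuple(span)))
    return out


# ---------------------------------------------------------------------------
# HDF5 arrays
# ---------------------------------------------------------------------------

def write_lfp(records, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        data = np.stack([r.samples for r in records])
        ds = fh.create_dataset("lfp", data=data)
        ds.attrs["fs_hz"] = records[0].fs_hz
        ds.attrs["channel_ids"] = [r.channel_id for r in records]


def read_lfp(path) -> list:
    with h5py.File(path, "r") as fh:
        ds = fh["lfp"]
        fs = float(ds.attrs["fs_hz"])
        ids = [c.decode() if isinstance(c, bytes) else str(c)
               for c in ds.attrs["channel_ids"]]
        return [lfp_mod.LFPRecord(channel_id=cid, samples=np.array(row),
                                  fs_hz=fs) for cid, row in zip(ids, ds[...])]


def write_node_timeseries(data: synthetic.NodeTimeseriesSet, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        fh.attrs["node_names"] = data.node_names
        fh.attrs["treatments"] = data.treatments
        for (animal, treatment), arr in data.series.items():
            g = fh.require_group(animal)
            g.attrs["group"] = data.groups[animal]
            g.create_dataset(treatment, data=arr)


def read_node_timeseries(path) -> synthetic.NodeTimeseriesSet:
    with h5py.File(path, "r") as fh:
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in fh.attrs["node_names"]]
        treatments = [t.decode() if isinstance(t, bytes) else str(t)
                      for t in fh.attrs["treatments"]]
        series, groups = {}, {}
        for animal in fh:
            g = fh[animal]
            groups[animal] = str(g.attrs["group"])
            for treatment in g:
                series[(animal, treatment)] = np.array(g[treatment])
    return synthetic.NodeTimeseriesSet(series=series, node_names=names,
                                       groups=groups, treatments=treatments)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o).__name__)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run simulate -> behavior -> ephys -> lfp -> connectivity end to end.

    Every stage logs its parameters and derived seed; outputs are written
    under ``out_dir`` and a machine-readable ``summary.json`` (sorted keys,
    byte-identical for identical config + seed) is produced and returned as
    a dict.  Any stage failure propagates with the stage named in the log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {k: int(v.generate_state(1)[0] % (2 ** 31))
             for k, v in stage_seeds(config.seed).items()}
    a = config.analysis
    summary: dict = {"seed": config.seed, "stage_seeds": seeds}

    log.info("stage=cohort seed=%d n_animals=%d", seeds["cohort"],
             config.n_animals)
    cohort = synthetic.simulate_cohort(config.n_animals, seed=seeds["cohort"])

    log.info("stage=sessions seed=%d", seeds["sessions"])
    sessions = [synthetic.simulate_session(agent, seed=seeds["sessions"] + i)
                for i, agent in enumerate(cohort)]
    metrics_rows = []
    for agent, session in zip(cohort, sessions):
        write_session(session, out / "sessions" / agent.animal_id)
        m = behavior.compute_session_metrics(session)
        metrics_rows.append({"animal_id": agent.animal_id,
                             "precue_response_rate": m.precue_response_rate,
                             "pct_correct_go": m.pct_correct_go,
                             "pct_ng_fa": m.pct_ng_fa,
                             "n_trials": m.n_trials,
                             "total_licks": m.total_licks,
                             "distance": m.distance})
    metrics = pd.DataFrame(metrics_rows)
    _atomic_write_df(metrics, out / "behavior_metrics.csv")
    split = behavior.assign_trait_groups(metrics, method=a.split_method)
    split_df = pd.DataFrame([{"animal_id": s.animal_id,
                              "compound_score": s.compound_score,
                              "group": s.group} for s in split])
    _atomic_write_df(split_df, out / "trait_groups.csv")
    summary["behavior"] = {
        "n_animals": len(cohort),
        "mean_precue_rate": float(metrics["precue_response_rate"].mean()),
        "mean_pct_correct_go": float(metrics["pct_correct_go"].mean()),
        "mean_pct_ng_fa": float(metrics["pct_ng_fa"].mean()),
        "groups": {s.animal_id: s.group for s in split},
    }

    # --- ephys on the first session -------------------------------------
    log.info("stage=spikes seed=%d n_units=%d", seeds["spikes"], config.n_units)
    session = sessions[0]
    units = []
    for i in range(config.n_units):
        kind = i % 3
        coupling = ()
        if kind == 1:
            coupling = (("precue_poke", 2.0, 0.0, 1.0),)
        elif kind == 2:
            coupling = (("precue_poke", 0.3, 0.0, 1.0),)
        units.append(synthetic.UnitSpec(unit_id=f"u{i:02d}",
                                        baseline_rate_hz=10.0,
                                        couplings=coupling))
    trains = synthetic.simulate_spike_trains(session, units,
                                             seed=seeds["spikes"])
    write_spikes(trains, out / "spikes.csv")
    events = session.event_times("precue_poke")
    labels = {}
    resp_rows = []
    for train in trains:
        z = ephys.bin_and_zscore(train, bin_width_s=a.bin_width_s,
                                 kernel_s=a.kernel_s)
        mat = ephys.build_peri_event_matrix(z, events, window=a.peri_window,
                                            event_label="precue_poke")
        resp = ephys.classify_unit_response(mat, n_iter=a.cluster_n_iter,
                                            bin_alpha=a.bin_alpha,
                                            alpha=a.alpha,
                                            seed=seeds["analysis"])
        labels[train.unit_id] = resp.label
        resp_rows.append({
            "unit_id": train.unit_id, "label": resp.label,
            "clusters": "; ".join(
                f"[{c.start_bin},{c.end_bin}) mass={c.mass:.2f} "
                f"p={c.p_corrected:.4f}" for c in resp.clusters)})
    _atomic_write_df(pd.DataFrame(resp_rows), out / "unit_responses.csv")
    pop = ephys.population_count_test(
        trains, events, span=(0.0, session.duration_s),
        n_iter=a.population_n_iter, cluster_n_iter=a.cluster_n_iter,
        seed=seeds["analysis"], event_label="precue_poke",
        criterion_q=a.criterion_q)
    summary["ephys"] = {
        "labels": labels,
        "population": {"observed_count": pop.observed_count,
                       "n_units": pop.n_units, "passed": pop.passed,
                       "p_value": round(pop.p_value, 6)},
    }

    # --- lfp -------------------------------------------------------------
    log.info("stage=lfp seed=%d n_channels=%d", seeds["lfp"],
             config.n_lfp_channels)
    spec = synthetic.LFPSpec(
        fs_hz=a.lfp_fs_hz,
        event_modulations=(synthetic.EventModulation(
            "precue_poke", "beta", -0.5, 2.0),))
    records = synthetic.simulate_lfp(session, spec, config.n_lfp_channels,
                                     seed=seeds["lfp"])
    write_lfp(records, out / "lfp.h5")
    bands = lfp_mod.BandSet({k: tuple(v) for k, v in a.band_edges.items()})
    sgram = lfp_mod.event_spectrogram_z(records[0], events,
                                        window=a.lfp_window)
    tc = lfp_mod.band_timecourse(sgram, bands, bin_s=a.lfp_bin_s)
    tc_df = pd.DataFrame(tc.values, index=tc.band_names,
                         columns=[f"{c:.1f}" for c in tc.bin_centers])
    tc_df.insert(0, "band", tc.band_names)
    _atomic_write_df(tc_df, out / "band_timecourse.csv")
    pre_bin = int(np.argmin(np.abs(tc.bin_centers - (-a.lfp_bin_s / 2))))
    summary["lfp"] = {
        "n_events": sgram.n_events,
        "pre_event_z": {b: round(float(tc.values[i, pre_bin]), 4)
                        for i, b in enumerate(tc.band_names)},
    }

    # --- connectivity ----------------------------------------------------
    log.info("stage=nodes seed=%d n_nodes=%d", seeds["nodes"], config.n_nodes)
    netspec = synthetic.NetworkSpec(n_nodes=config.n_nodes,
                                    group_effect=(0, -0.15),
                                    interaction_effect=(1, -0.15),
                                    interaction_treatment=config.treatments[-1])
    nodes = synthetic.simulate_node_timeseries(cohort, netspec,
                                               treatments=config.treatments,
                                               seed=seeds["nodes"])
    write_node_timeseries(nodes, out / "nodes.h5")
    veh = config.treatments[0]
    mats = {g: [] for g in ("HI", "LI")}
    for (animal, tr), arr in nodes.series.items():
        if tr == veh and nodes.groups[animal] in mats:
            mats[nodes.groups[animal]].append(
                connectivity.node_correlation_matrix(arr, nodes.node_names))
    scores = connectivity.group_difference_node_scores(mats["HI"], mats["LI"])
    _atomic_write_df(scores, out / "group_diff_scores.csv")
    strengths = connectivity.node_strength_table(nodes)
    inter = connectivity.interaction_node_scores(strengths)
    _atomic_write_df(inter, out / "interaction_scores.csv")
    top_g = scores.loc[scores["rank"] == 1].iloc[0]
    top_i = inter.loc[inter["rank"] == 1].iloc[0]
    summary["connectivity"] = {
        "group_top_node": str(top_g["node"]),
        "group_top_t": round(float(top_g["statistic"]), 4),
        "interaction_top_node": str(top_i["node"]),
        "interaction_top_F": round(float(top_i["statistic"]), 4),
    }

    text = json.dumps(summary, sort_keys=True, indent=2, default=_json_default)
    fd, tmp = tempfile.mkstemp(dir=out, suffix=".tmp")
    os.close(fd)
    Path(tmp).write_text(text)
    os.replace(tmp, out / "summary.json")
    return summary
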