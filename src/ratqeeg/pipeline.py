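"""End-to-end study orchestration.

One :class:`StudyConfig` drives the whole analysis: simulate (or load)
recordings, filter, carve epochs, select artifact-free inactivity
segments, compute band powers and lagged coherences, normalise to each
subject's baseline, run the mixed repeated-measures statistics and the
global-connectivity inference, and write every intermediate table as a
deterministically formatted CSV.  Re-running with an identical config and
seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as _behavior
from . import connectivity as _conn
from . import preprocess as _pre
from . import signal_io as _io
from . import spectral as _spec
from . import stats as _stats
from . import synthetic_data as _syn
from .montage import default_layout

__all__ = ["StudyConfig", "StudyResult", "run_study", "load_config"]


@dataclass
class GroupSpec:
    name: str
    n: int = 8
    power_gain: float = 1.0
    coupling_gain: float = 1.0


@dataclass
class StudyConfig:
    """Study-level configuration (YAML-serialisable).

    Exactly one of ``groups`` (simulation) or ``manifest_path`` (recorded
    data) must be provided.
    """

    seed: int = 0
    output_dir: str = "study_out"
    groups: list = field(default_factory=list)          # list[GroupSpec]
    manifest_path: str | None = None
    epoch_s: float | None = 60.0   # compressed epochs; None -> full-length study
    alpha: float = 0.05
    selection: _pre.SelectionCriteria = field(
        default_factory=lambda: _pre.SelectionCriteria(target_total_s=50.0)
    )
    coherence_floor: float = _conn.COHERENCE_FLOOR
    save_recordings: bool = False
    make_maps: bool = False
    map_resolution: float = 1.0
    activity: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if bool(self.groups) == bool(self.manifest_path):
            raise ValueError("provide exactly one of simulation groups or a manifest")


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    groups = [GroupSpec(**g) for g in raw.pop("groups", [])]
    sel = raw.pop("selection", None)
    cfg = StudyConfig(groups=groups, **raw)
    if sel:
        cfg.selection = _pre.SelectionCriteria(**sel)
    return cfg


def _subject_seed(global_seed: int, subject_id: str) -> int:
    """Stable per-subject seed: adding subjects never shifts other streams."""
    h = zlib.crc32(subject_id.encode()) & 0x7FFFFFFF
    return int((global_seed * 2654435761 + h) % (2**31 - 1))


def _simulation_config(cfg: StudyConfig, spec: GroupSpec, subject_id: str):
    kwargs = {}
    if cfg.epoch_s is not None:
        sched = _syn.compressed_schedule(cfg.epoch_s)
        kwargs.update(
            epoch_schedule=sched,
            duration=max(e for _, e in sched.values()),
            admin_time=cfg.epoch_s,
        )
    if cfg.activity:
        dur = kwargs.get("duration", 5400.0)
        rng = np.random.default_rng(_subject_seed(cfg.seed, subject_id) ^ 0xA5A5)
        t, sched = 0.0, []
        while t < dur:
            t += rng.uniform(20.0, 60.0)
            a0, a1 = t, min(dur, t + rng.uniform(5.0, 15.0))
            if a1 > a0:
                sched.append((a0, a1))
            t = a1
        kwargs["activity_schedule"] = sched
    sim = _syn.default_config(seed=_subject_seed(cfg.seed, subject_id), **kwargs)
    if spec.power_gain != 1.0 or spec.coupling_gain != 1.0:
        sim.drug_effect = _syn.psilocin_like_effect(
            power_gain=spec.power_gain, coupling_gain=spec.coupling_gain
        )
    return sim


@dataclass
class StudyResult:
    tables: dict
    anova: dict            # band -> AnovaResult for mean power
    gfc_inference: object  # stats.GFCInference
    output_dir: Path
    selection_report: pd.DataFrame


class StageError(RuntimeError):
    def __init__(self, stage: str, subject: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed for subject {subject!r}: {exc}")
        self.stage, self.subject = stage, subject


def _epoch_manifest(cfg: StudyConfig) -> _io.StudyManifest:
    if cfg.epoch_s is None:
        return _io.StudyManifest()
    e = cfg.epoch_s
    return _io.StudyManifest(
        baseline_window=(0.0, e),
        post_windows={"E1": (0.0, e), "E2": (e, 2 * e), "E3": (2 * e, 3 * e)},
    )


def run_study(cfg: StudyConfig, layout=None) -> StudyResult:
    layout = layout or default_layout()
    scheme = _spec.default_bands()
    manifest = _epoch_manifest(cfg)
    out_dir = Path(cfg.output_dir)

    subjects = []  # (subject_id, group, recording-producer)
    if cfg.groups:
        for spec in cfg.groups:
            for i in range(spec.n):
                sid = f"{spec.name}_{i + 1:02d}"
                subjects.append((sid, spec.name, spec))
    else:
        man = _load_manifest(cfg.manifest_path)
        manifest = man
        for entry in man.subjects:
            subjects.append((entry.subject_id, entry.group, entry))

    power_rows, coh_tables, behav_rows, sel_rows = [], {}, [], []
    groups_by_subject = {}
    epoch_names = manifest.epoch_names

    for sid, group, src in subjects:
        groups_by_subject[sid] = group
        try:
            if isinstance(src, GroupSpec):
                sim = _simulation_config(cfg, src, sid)
                rec, truth = _syn.generate_recording(sim, layout)
                rec.subject_id, rec.group = sid, group
                if cfg.save_recordings:
                    _io.write_recording(out_dir / "recordings" / f"{sid}.edf", rec, truth)
            else:
                rec = _io.read_recording(src.path, layout)
                rec.subject_id, rec.group = sid, group
        except Exception as exc:  # noqa: BLE001 - rewrap with context
            raise StageError("acquire", sid, exc) from exc

        try:
            rec = _pre.bandpass_fir(rec)
            epochs = _pre.extract_epochs(rec, manifest)
        except Exception as exc:
            raise StageError("preprocess", sid, exc) from exc

        if cfg.activity:
            behav_rows.append(_behavior.summarize_recording(rec, manifest, sid))

        for epoch_name in epoch_names:
            ep = epochs.get(epoch_name)
            if ep is None:
                sel_rows.append({"subject": sid, "epoch": epoch_name, "total_s": 0.0,
                                 "accepted": False, "reason": "epoch missing"})
                continue
            segs = _pre.select_segments(ep, cfg.selection, source_epoch=epoch_name)
            sel_rows.append({"subject": sid, "epoch": epoch_name,
                             "total_s": segs.total_s, "accepted": segs.accepted,
                             "reason": segs.reason})
            if not segs.accepted:
                continue
            try:
                bins = _spec.power_spectrum(ep.data, ep.sfreq, segments=segs.segments)
                power_rows.append(
                    _spec.power_table(bins, layout.labels, sid, epoch_name, scheme)
                )
                coh_tables[(sid, epoch_name)] = _conn.coherence_table(
                    ep.data, ep.sfreq, layout, sid, epoch_name,
                    segments=segs.segments, scheme=scheme,
                )
            except Exception as exc:
                raise StageError("spectra", sid, exc) from exc

    power = pd.concat(power_rows, ignore_index=True) if power_rows else pd.DataFrame()
    selection_report = pd.DataFrame(sel_rows)

    # --- mean power, baseline-normalised, per-band ANOVA -------------------
    anova_by_band, anova_frames, posthoc_frames = {}, [], []
    mean_rows = []
    if len(power):
        for (sid, epoch_name), sub in power.groupby(["subject", "epoch"], sort=False):
            bp = sub[list(scheme.names)].to_numpy()
            mp = _spec.mean_power(bp, n_channels_expected=layout.n_channels, axis=0)
            row = {"subject": sid, "epoch": epoch_name}
            row.update(dict(zip(scheme.names, mp)))
            mean_rows.append(row)
    mean_power_df = pd.DataFrame(mean_rows)

    post_epochs = [e for e in epoch_names if e != "baseline"]
    if len(mean_power_df):
        base = mean_power_df[mean_power_df.epoch == "baseline"].set_index("subject")
        for band in scheme.names:
            rows = []
            for _, r in mean_power_df[mean_power_df.epoch != "baseline"].iterrows():
                sid = r["subject"]
                if sid not in base.index:
                    continue
                rows.append({
                    "subject": sid, "group": groups_by_subject[sid],
                    "time": r["epoch"],
                    "value": float(_stats.boxcox_ratio(r[band], base.loc[sid, band])),
                })
            design = pd.DataFrame(rows)
            design["time"] = pd.Categorical(design["time"], categories=post_epochs,
                                            ordered=True)
            complete = design.groupby("subject").size() == len(post_epochs)
            full = complete[complete].index
            per_group = design[design.subject.isin(full)].groupby("group")[
                "subject"
            ].nunique()
            if len(per_group) < 2 or (per_group < 2).any():
                continue
            res = _stats.rm_anova(design, alpha=cfg.alpha)
            res.posthoc = _stats.bonferroni_posthoc(design, res)
            anova_by_band[band] = (res, design)
            frame = res.to_frame()
            frame.insert(0, "band", band)
            anova_frames.append(frame)
            if len(res.posthoc):
                ph = res.posthoc.copy()
                ph.insert(0, "band", band)
                posthoc_frames.append(ph)

    # --- connectivity: change, GFC, inference, KDE -------------------------
    gfc_rows, change_frames = [], []
    for sid in dict.fromkeys(s for s, _ in coh_tables):
        base_tab = coh_tables.get((sid, "baseline"))
        if base_tab is None:
            continue
        for epoch_name in post_epochs:
            tab = coh_tables.get((sid, epoch_name))
            if tab is None:
                continue
            ch = _conn.coherence_change(tab, base_tab, floor=cfg.coherence_floor)
            change_frames.append(ch)
            g = _conn.gfc(ch)
            if g.defined:
                gfc_rows.append({"subject": sid, "group": groups_by_subject[sid],
                                 "time": epoch_name, "value": g.gfc})
    gfc_design = pd.DataFrame(gfc_rows)
    gfc_inf = None
    if len(gfc_design):
        complete = gfc_design.groupby("subject").size() == len(post_epochs)
        full_subjects = complete[complete].index
        per_group = gfc_design[gfc_design.subject.isin(full_subjects)].groupby(
            "group"
        )["subject"].nunique()
        gfc_ok = len(per_group) >= 2 and (per_group >= 2).all()
    else:
        gfc_ok = False
    if gfc_ok:
        gfc_design["time"] = pd.Categorical(gfc_design["time"],
                                            categories=post_epochs, ordered=True)
        gfc_inf = _stats.gfc_inference(gfc_design, alpha=cfg.alpha)

    changes = (pd.concat(change_frames, ignore_index=True)
               if change_frames else pd.DataFrame())
    kde_frames = []
    if len(changes):
        changes = changes.merge(
            pd.Series(groups_by_subject, name="group"), left_on="subject",
            right_index=True,
        )
        for grp, sub in changes.groupby("group", sort=True):
            samples = sub["change"].dropna().to_numpy()
            if len(samples) >= 10:
                grid, dens = _conn.kde_distribution(samples)
                kde_frames.append(pd.DataFrame(
                    {"group": grp, "change": grid, "density": dens}
                ))

    # --- behaviour ---------------------------------------------------------
    behav = pd.concat(behav_rows, ignore_index=True) if behav_rows else pd.DataFrame()
    behav_anova_frame = pd.DataFrame()
    if len(behav) and len(set(groups_by_subject.values())) >= 2:
        try:
            b_res = _behavior.behavior_anova(behav, groups_by_subject)
            behav_anova_frame = b_res.to_frame()
        except ValueError:
            pass

    tables = {
        "band_power": power,
        "mean_power": mean_power_df,
        "anova_mean_power": (pd.concat(anova_frames, ignore_index=True)
                             if anova_frames else pd.DataFrame()),
        "posthoc_mean_power": (pd.concat(posthoc_frames, ignore_index=True)
                               if posthoc_frames else pd.DataFrame()),
        "coherence": (pd.concat(coh_tables.values(), ignore_index=True)
                      if coh_tables else pd.DataFrame()),
        "coherence_change": changes,
        "gfc": gfc_design,
        "gfc_anova": gfc_inf.anova.to_frame() if gfc_inf else pd.DataFrame(),
        "gfc_posthoc": gfc_inf.posthoc if gfc_inf else pd.DataFrame(),
        "kde": (pd.concat(kde_frames, ignore_index=True)
                if kde_frames else pd.DataFrame()),
        "behavior": behav,
        "behavior_anova": behav_anova_frame,
        "selection_report": selection_report,
    }
    if gfc_inf is not None:
        tables["gfc_decision"] = pd.DataFrame([{"branch": gfc_inf.branch}])

    _io.write_results(tables, out_dir)

    if cfg.make_maps and anova_by_band:
        _write_maps(cfg, power, groups_by_subject, layout, scheme, out_dir,
                    post_epochs)

    run_manifest = {
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "n_subjects": len(subjects),
        "epochs": epoch_names,
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True)

    return StudyResult(tables=tables, anova={b: r for b, (r, _) in anova_by_band.items()},
                       gfc_inference=gfc_inf, output_dir=out_dir,
                       selection_report=selection_report)


def _config_dict(cfg: StudyConfig) -> dict:
    d = asdict(cfg)
    return d


def _write_maps(cfg, power, groups_by_subject, layout, scheme, out_dir, post_epochs):
    from . import topomap as _topo

    maps_dir = out_dir / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    spec = _topo.GridSpec(resolution=cfg.map_resolution)
    base = power[power.epoch == "baseline"].set_index(["subject", "channel"])
    for band in scheme.names:
        subj_ids, groups, mats = [], [], []
        for sid in dict.fromkeys(power["subject"]):
            rows = []
            ok = True
            for epoch_name in post_epochs:
                sub = power[(power.subject == sid) & (power.epoch == epoch_name)]
                if len(sub) != layout.n_channels:
                    ok = False
                    break
                vals = []
                for ch in layout.labels:
                    try:
                        b = base.loc[(sid, ch), band]
                        v = sub.loc[sub.channel == ch, band].iloc[0]
                        vals.append(float(np.log(v / b)))
                    except KeyError:
                        ok = False
                        break
                if not ok:
                    break
                rows.append(vals)
            if ok and len(rows) == len(post_epochs):
                subj_ids.append(sid)
                groups.append(groups_by_subject[sid])
                mats.append(rows)
        if len(set(groups)) < 2:
            continue
        arr = np.asarray(mats)  # (n_subj, n_times, n_ch)
        topo = _topo.pointwise_significance(arr, groups, layout, grid_spec=spec,
                                            band=band)
        _topo.plot_topomap(topo, maps_dir / f"power_{band}.png")
        pd.DataFrame(topo.values, index=topo.anterior, columns=topo.lateral).to_csv(
            maps_dir / f"power_{band}_grid.csv"
        )


def _load_manifest(path) -> _io.StudyManifest:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    subjects = [_io.SubjectEntry(**s) for s in raw.get("subjects", [])]
    kwargs = {}
    if "baseline_window" in raw:
        kwargs["baseline_window"] = tuple(raw["baseline_window"])
    if "post_windows" in raw:
        kwargs["post_windows"] = {k: tuple(v) for k, v in raw["post_windows"].items()}
    return _io.StudyManifest(subjects=subjects, **kwargs)
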