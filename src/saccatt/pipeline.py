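"""End-to-end orchestration: simulate → detect → classify → ERP/TFR →
stats → ERP-image, with a provenance manifest.

The pipeline streams one participant at a time (simulating or loading,
then reducing to per-participant summaries) so the full 23 × 1,200-trial
experiment never has to sit in memory at once.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import defaults, __version__
from .erp_core import EegEpochs, baseline_correct, contra_ipsi, n2pc_amplitude
from .erp_image import alignment_statistic, build_erp_image
from .gaze_io import mask_blinks
from .group_stats import paired_tests, rm_anova, trim_rts
from .perm_cluster import permutation_test
from .saccade_detect import DetectParams, detect_all
from .saccade_dynamics import saccade_rate
from .spectral_lat import lateralization_index, stft_power
from .synthgen import CLASSES, SimConfig, load_participant, simulate_participant

log = logging.getLogger(__name__)

ALL_STAGES = ("detect", "erp", "stats", "behavior", "tfr", "erpimage", "rates")


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    detect: DetectParams = field(default_factory=DetectParams)
    class_window_ms: tuple[float, float] = defaults.CLASS_WINDOW_MS
    n2pc_window_ms: tuple[float, float] = defaults.N2PC_WINDOW_MS
    baseline_window_ms: tuple[float, float] = defaults.BASELINE_WINDOW_MS
    n_permutations: int = defaults.N_PERMUTATIONS
    cluster_alpha: float = defaults.CLUSTER_ALPHA
    stages: tuple[str, ...] = ALL_STAGES
    data_dir: str | None = None  # load instead of simulate when set
    erp_image_max_rows: int = 4000
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        lo, hi = self.sim.epoch_window
        for name in ("class_window_ms", "n2pc_window_ms", "baseline_window_ms"):
            w = getattr(self, name)
            if not (lo <= w[0] < w[1] <= hi):
                raise ValueError(f"{name} {w} outside epoch window {self.sim.epoch_window}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _participant_summary(cfg: RunConfig, participant: int) -> dict:
    """Simulate/load one participant and reduce to per-participant results."""
    if cfg.data_dir is not None:
        data = load_participant(Path(cfg.data_dir) / f"p{participant:02d}")
    else:
        data, _, _ = simulate_participant(cfg.sim, participant)

    masked = []
    for ep in data.gaze_epochs:
        x, y = mask_blinks(ep.x_deg, ep.y_deg, rate_hz=ep.rate_hz)
        ep2 = type(ep)(time_ms=ep.time_ms, x_deg=x, y_deg=y, trial_id=ep.trial_id,
                       task=ep.task, cued_side=ep.cued_side)
        masked.append(ep2)

    events, per_trial = detect_all(masked, cfg.detect)
    from .trial_classes import classify_trials

    classes = classify_trials(per_trial, masked, cfg.class_window_ms)
    classes.insert(0, "participant", participant)

    out: dict = {"participant": participant, "classes": classes, "events": events}

    eeg = baseline_correct(data.eeg, cfg.baseline_window_ms)
    meta = data.meta.merge(classes[["trial_id", "class", "first_saccade_onset_ms"]],
                           left_on="trial", right_on="trial_id")

    if "erp" in cfg.stages:
        waves, amps = {}, {}
        for cls in CLASSES + ("all",):
            sel = np.ones(len(meta), dtype=bool) if cls == "all" \
                else (meta["class"] == cls).to_numpy()
            if sel.sum() == 0 or len(set(meta.loc[sel, "cued_side"])) < 2:
                log.warning("participant %d: class %s unusable for ERP", participant, cls)
                continue
            sub = EegEpochs(data=eeg.data[sel], ch_names=eeg.ch_names, sfreq=eeg.sfreq,
                            times_ms=eeg.times_ms, metadata=meta.loc[sel].reset_index(drop=True))
            w = contra_ipsi(sub)
            waves[cls] = w
            amps[cls] = n2pc_amplitude(w, cfg.n2pc_window_ms)
        out["waves"] = waves
        out["n2pc_amps"] = amps

    if "tfr" in cfg.stages:
        power = stft_power(EegEpochs(
            data=eeg.data[:, [eeg.ch_index("PO7"), eeg.ch_index("PO8")], :],
            ch_names=["PO7", "PO8"], sfreq=eeg.sfreq, times_ms=eeg.times_ms))
        out["tfr_lat"] = lateralization_index(power, meta)

    if "erpimage" in cfg.stages:
        sel = (meta["class"] == "toward").to_numpy()
        rows_idx = np.flatnonzero(sel)
        img_meta = meta.loc[sel, ["cued_side", "first_saccade_onset_ms"]].copy()
        chans = [eeg.ch_index(c) for c in ("PO7", "PO8", "Oz", "HEOG")]
        out["image_rows"] = eeg.data[rows_idx][:, chans, :].astype(np.float32)
        out["image_meta"] = img_meta.reset_index(drop=True)

    behav = data.meta.merge(classes[["trial_id", "class"]], left_on="trial",
                            right_on="trial_id")
    behav = behav[behav["class"] != "excluded"]
    behav.insert(0, "participant", participant)
    out["behavior"] = behav[["participant", "class", "rt_ms", "correct"]]
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages for all participants; return a results
    dict and, when ``cfg.out_dir`` is set, write tables + manifest."""
    n_participants = cfg.sim.n_participants
    summaries = [_participant_summary(cfg, p) for p in range(n_participants)]

    results: dict = {"config_hash": _config_hash(cfg)}
    class_table = pd.concat([s["classes"] for s in summaries], ignore_index=True)
    results["class_table"] = class_table

    from .trial_classes import class_proportions, summarize_proportions

    props = class_proportions(class_table, by="participant")
    results["class_proportions"] = props
    results["class_proportions_summary"] = summarize_proportions(props)

    if "rates" in cfg.stages:
        all_events = []
        for s in summaries:
            ev = s["events"].copy()
            side = dict(zip(s["classes"]["trial_id"], s["classes"]["cued_side"]))
            ev["participant"] = s["participant"]
            ev["cued_side"] = ev["trial_id"].map(side)
            all_events.append(ev)
        events = pd.concat(all_events, ignore_index=True)
        toward = (events["direction"] < 0) == (events["cued_side"] == "left")
        events["label"] = np.where(toward, "toward", "away")
        n_trials = int(class_table.shape[0])
        results["rate_curves"] = saccade_rate(events, n_trials,
                                              epoch_window=cfg.sim.epoch_window)
        results["events"] = events

    if "erp" in cfg.stages:
        amp_rows = []
        for s in summaries:
            row = {"participant": s["participant"]}
            row.update(s.get("n2pc_amps", {}))
            amp_rows.append(row)
        amp_table = pd.DataFrame(amp_rows).set_index("participant")
        results["n2pc_amplitudes"] = amp_table

        if "stats" in cfg.stages:
            complete = amp_table[list(CLASSES)].dropna()
            if len(complete) >= 3:
                results["anova"] = rm_anova(complete)
                one_sample = paired_tests(complete, [(c,) for c in CLASSES],
                                          m_corrections=1)
                pairwise = paired_tests(
                    complete,
                    [("toward", "none"), ("toward", "away"), ("none", "away")],
                    m_corrections=3)
                results["t_tests"] = {"one_sample": one_sample, "pairwise": pairwise}
            cluster_res = {}
            for cls in CLASSES:
                stack = [s["waves"][cls].diff for s in summaries if cls in s.get("waves", {})]
                if len(stack) >= 2:
                    cluster_res[cls] = permutation_test(
                        np.asarray(stack), n_perm=cfg.n_permutations,
                        seed=np.random.default_rng(cfg.seed), alpha=cfg.cluster_alpha)
            results["clusters"] = cluster_res

    if "behavior" in cfg.stages:
        behav = pd.concat([s["behavior"] for s in summaries], ignore_index=True)
        trimmed, summary = trim_rts(behav)
        results["behavior_trimmed"] = trimmed
        results["behavior_summary"] = summary

    if "tfr" in cfg.stages:
        maps = [s["tfr_lat"] for s in summaries if "tfr_lat" in s]
        if maps:
            L = np.nanmean([m.L for m in maps], axis=0)
            ref = maps[0]
            from .spectral_lat import TfrLateralization

            grand = TfrLateralization(L=L, freqs_hz=ref.freqs_hz, times_ms=ref.times_ms)
            results["tfr_lateralization"] = grand
            results["alpha_summary"] = grand.alpha_summary()

    if "erpimage" in cfg.stages:
        rows = np.concatenate([s["image_rows"] for s in summaries], axis=0)
        img_meta = pd.concat([s["image_meta"] for s in summaries], ignore_index=True)
        if rows.shape[0] > cfg.erp_image_max_rows:
            pick = np.linspace(0, rows.shape[0] - 1, cfg.erp_image_max_rows).astype(int)
            rows, img_meta = rows[pick], img_meta.iloc[pick].reset_index(drop=True)
        pooled = EegEpochs(data=rows, ch_names=["PO7", "PO8", "Oz", "HEOG"],
                           sfreq=cfg.sim.eeg_rate, times_ms=cfg.sim.eeg_times(),
                           metadata=img_meta)
        table = img_meta.copy()
        table["class"] = "toward"
        table["row"] = np.arange(len(table))
        images, align = {}, {}
        for derivation in ("HEOG", "Oz", "N2pc-diff"):
            img = build_erp_image(pooled, table, derivation, "toward")
            images[derivation] = img
            align[derivation] = alignment_statistic(img, seed=cfg.seed)
        results["erp_images"] = images
        results["alignment"] = align

    if cfg.out_dir is not None:
        _write_report(cfg, results)
    return results


def _write_report(cfg: RunConfig, results: dict) -> None:
    out = Path(cfg.out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def save_csv(name: str, df: pd.DataFrame) -> None:
        path = out / "tables" / f"{name}.csv"
        df.to_csv(path, index=True)
        written[str(path.relative_to(out))] = hashlib.sha256(path.read_bytes()).hexdigest()

    for key in ("class_table", "class_proportions", "class_proportions_summary",
                "n2pc_amplitudes", "behavior_summary"):
        if key in results:
            save_csv(key, results[key])

    stats_payload: dict = {}
    if "anova" in results:
        stats_payload["anova"] = asdict(results["anova"])
    if "t_tests" in results:
        stats_payload["t_tests"] = {
            kind: [asdict(t) for t in tests]
            for kind, tests in results["t_tests"].items()
        }
    if "clusters" in results:
        stats_payload["clusters"] = {
            cls: {
                "n_permutations": r.n_permutations,
                "clusters": [
                    {"start": c.start, "stop": c.stop, "mass": c.mass,
                     "sign": c.sign, "p": c.p_value, "p_str": c.p_str}
                    for c in r.clusters
                ],
            }
            for cls, r in results["clusters"].items()
        }
    if "alignment" in results:
        stats_payload["alignment"] = {
            k: {"rho": a.rho, "ci": [a.ci_low, a.ci_high], "n_rows": a.n_rows}
            for k, a in results["alignment"].items()
        }
    if "alpha_summary" in results:
        stats_payload["alpha_lateralization_percent"] = results["alpha_summary"]
    stats_path = out / "stats.json"
    stats_path.write_text(json.dumps(stats_payload, indent=1, default=float))
    written["stats.json"] = hashlib.sha256(stats_path.read_bytes()).hexdigest()

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": cfg.seed,
        "config_hash": results["config_hash"],
        "config": cfg.to_dict(),
        "files": written,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def make_fixtures(size: str = "tiny", out_dir: str | Path | None = None):
    """Packaged test dataset: 'tiny' = 3 participants × 60 trials/task."""
    if size == "tiny":
        cfg = SimConfig(n_participants=3, trials_per_task=60, seed=7)
    elif size == "default":
        cfg = SimConfig(seed=7)
    else:
        raise ValueError(f"unknown fixture size {size!r}")
    from .synthgen import generate_experiment

    return generate_experiment(cfg, out_dir)
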