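"""End-to-end study orchestration: synthesis, per-subject analysis, group stats.

``make_demo_study`` writes a fully synthetic multi-genotype study to disk
(EDF signals, tab-delimited event tables and ground truth, a YAML config);
``run_study`` consumes a config, analyses every subject blind to any
injected effects, and emits per-subject metric tables, group statistics and
a machine-readable summary plus a run log with every resolved parameter.

Cohorts are paired across genotypes by common random numbers: subject i of
every genotype shares one base seed, so background-noise realizations are
identical and injected effects are isolated from simulation noise at
feasible group sizes. The analysis path never sees the injected effects.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evoked as ev
from . import sigio, spectra, spindles, staging, stats, synthgen
from .exceptions import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "StudyReport",
    "EFFECT_PRESETS",
    "load_config",
    "make_demo_study",
    "build_subject_session",
    "effective_parameters",
    "run_study",
    "analyze_sleep",
    "analyze_assr",
    "analyze_mmn",
    "subject_seed",
]

GENOTYPES = ("WT", "Het", "KO")

#: Genotype effect presets encoding the mutant contrasts used for demos:
#: gene dose-dependent gamma/spindle increases with reduced 50 Hz
#: entrainment ("grin2a_like"), and spindle/NREM/P3a reductions
#: ("akap11_like"). Entrainment scalings act on amplitude, so a 30% power
#: reduction corresponds to sqrt(0.7).
EFFECT_PRESETS: dict[str, dict[str, synthgen.EffectConfig]] = {
    "null": {g: synthgen.EffectConfig() for g in GENOTYPES},
    "grin2a_like": {
        "WT": synthgen.EffectConfig(),
        "Het": synthgen.EffectConfig(
            gamma_power=1.1, spindle_rate=1.25, assr_gain=float(np.sqrt(0.7))
        ),
        "KO": synthgen.EffectConfig(
            gamma_power=1.2, spindle_rate=1.4, assr_gain=float(np.sqrt(0.7))
        ),
    },
    "akap11_like": {
        "WT": synthgen.EffectConfig(),
        "Het": synthgen.EffectConfig(spindle_rate=0.75),
        "KO": synthgen.EffectConfig(
            gamma_power=1.1, spindle_rate=0.375, p3a_amplitude=0.3,
            nrem_fraction=0.9,
        ),
    },
}

DEFAULT_PARAMS: dict = {
    "staging": {"theta_delta_rem": 1.5, "emg_separation_ratio": 2.0,
                "epoch_len_s": 10.0},
    "spectra": {"window_s": 4.0, "overlap_s": 2.0, "fit_range": [0.5, 50.0]},
    "spindles": {"freqs": [9.0, 11.0, 13.0, 15.0], "threshold_hi": 3.0,
                 "threshold_lo": 1.5},
    "evoked": {"reject_uv": 400.0, "assr_freqs": [10.0, 20.0, 30.0, 40.0, 50.0]},
}


@dataclass
class RunConfig:
    subjects: list[dict]
    out_dir: Path
    seed: int = 0
    params: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_PARAMS)))
    reference_genotype: str = "WT"
    base_dir: Path = Path(".")

    def resolve(self, rel: str | None) -> Path | None:
        return None if rel is None else (self.base_dir / rel)

    def validate(self) -> None:
        if not self.subjects:
            raise ParameterError("empty subject manifest")
        for sub in self.subjects:
            if sub.get("genotype") not in GENOTYPES:
                raise ParameterError(
                    f"subject {sub.get('id')}: genotype {sub.get('genotype')!r} "
                    f"not in {GENOTYPES}"
                )
            for key in ("sleep_edf", "assr_edf", "assr_events", "mmn_edf",
                        "mmn_events"):
                rel = sub.get(key)
                if rel is not None and not (self.base_dir / rel).exists():
                    raise ParameterError(
                        f"subject {sub.get('id')}: missing file {rel}"
                    )


@dataclass
class StudyReport:
    subject_metrics: pd.DataFrame
    group_stats: pd.DataFrame
    summary: dict
    failures: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    cfg = RunConfig(
        subjects=raw.get("subjects", []),
        out_dir=Path(raw.get("out_dir", path.parent / "results")),
        seed=int(raw.get("seed", 0)),
        params={**json.loads(json.dumps(DEFAULT_PARAMS)), **raw.get("params", {})},
        reference_genotype=raw.get("reference_genotype", "WT"),
        base_dir=path.parent,
    )
    return cfg


def subject_seed(master_seed: int, index: int) -> int:
    """Deterministic per-subject base seed, shared across genotypes (CRN)."""
    return int(
        np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0]
        % (2**31)
    )


# ---------------------------------------------------------------------------
# per-subject analyses (blind to any injected effect)


def analyze_sleep(
    rec: sigio.Recording,
    params: dict | None = None,
    spindle_freqs: tuple[float, ...] | None = None,
) -> tuple[dict, staging.Hypnogram]:
    """Stage a sleep session and compute sleep, spectral and spindle metrics."""
    p = {**json.loads(json.dumps(DEFAULT_PARAMS)), **(params or {})}
    fs = rec.fs
    eeg, emg = rec.get("EEG"), rec.get("EMG")
    epoch_len = p["staging"]["epoch_len_s"]
    grid = sigio.epoch_grid(rec, epoch_len)
    feats = staging.epoch_features(eeg, emg, fs, grid,
                                   p["spectra"]["window_s"], p["spectra"]["overlap_s"])
    light = (np.arange(len(grid)) * epoch_len) < synthgen.LIGHT_CYCLE_S
    hyp = staging.classify_stages(
        feats,
        epoch_len_s=epoch_len,
        theta_delta_rem=p["staging"]["theta_delta_rem"],
        emg_separation_ratio=p["staging"]["emg_separation_ratio"],
        light_mask=light,
    )
    metrics = staging.sleep_metrics(hyp).as_dict()
    out = {
        "pct_nrem": metrics["pct_nrem"],
        "pct_rem": metrics["pct_rem"],
        "pct_wake": metrics["pct_wake"],
        "sleep_onset_score": metrics["sleep_onset_score"],
        "nrem_bout_len_s": metrics["mean_bout_s_nrem"],
        "transitions_per_hour": metrics["transitions_per_hour"],
    }

    # NREM spectral profile: per-epoch Welch spectra averaged over the stage.
    nrem_idx = np.flatnonzero(hyp.labels == "NREM")
    specs = [
        spectra.welch_psd(eeg[grid[k][0]:grid[k][1]], fs,
                          p["spectra"]["window_s"], p["spectra"]["overlap_s"])
        for k in nrem_idx
    ]
    if specs:
        spec = spectra.average_spectra(specs)
        for band in spectra.BANDS:
            out[f"bp_{band}"] = spectra.band_power(spec, band)
        out["spectral_entropy"] = spectra.spectral_entropy(spec)
        fit = spectra.fit_aperiodic(spec, tuple(p["spectra"]["fit_range"]))
        out["aperiodic_exponent"] = fit.exponent
        out["aperiodic_offset"] = fit.offset

    freqs = spindle_freqs if spindle_freqs is not None else p["spindles"]["freqs"]
    for f in freqs:
        events = spindles.detect_spindles(
            eeg, fs, hyp, f,
            threshold_hi=p["spindles"]["threshold_hi"],
            threshold_lo=p["spindles"]["threshold_lo"],
        )
        out[f"spindle_density_{f:g}"] = spindles.spindle_density(events, hyp)
    return out, hyp


def analyze_assr(
    rec: sigio.Recording, events: pd.DataFrame, params: dict | None = None
) -> dict:
    """Evoked/baseline power ratios at each stimulation frequency."""
    p = {**json.loads(json.dumps(DEFAULT_PARAMS)), **(params or {})}
    epochs = ev.epoch_events(
        rec, events, t_min=-0.5, t_max=1.0, baseline_window=None,
        reject_uv=p["evoked"]["reject_uv"],
    )
    out = {}
    present = (
        set(np.unique(epochs.stim_freq_hz)) if epochs.stim_freq_hz is not None else set()
    )
    for f in p["evoked"]["assr_freqs"]:
        if present and f not in present:
            continue
        out[f"assr_ratio_{f:g}"] = ev.assr_power_ratio(epochs, f)
    return out


def analyze_mmn(
    rec: sigio.Recording, events: pd.DataFrame, params: dict | None = None
) -> dict:
    """Condition ERPs, deviant-minus-standard difference, and P1/N1/P3a peaks."""
    p = {**json.loads(json.dumps(DEFAULT_PARAMS)), **(params or {})}
    epochs = ev.epoch_events(
        rec, events, t_min=-0.1, t_max=0.4, baseline_window=(-0.05, 0.0),
        reject_uv=p["evoked"]["reject_uv"],
    )
    erp_std = ev.average_erp(epochs, "standard")
    erp_dev = ev.average_erp(epochs, "deviant")
    erp_diff = ev.erp_difference(erp_std, erp_dev)
    out = {}
    for cond, erp in (("std", erp_std), ("dev", erp_dev), ("diff", erp_diff)):
        peaks = ev.find_erp_peaks(erp)
        for comp in ("P1", "N1", "P3a"):
            out[f"erp_{cond}_{comp}_amp"] = (
                peaks.amplitude(comp) if peaks.found(comp) else np.nan
            )
    return out


# ---------------------------------------------------------------------------
# demo-study synthesis


def effective_parameters(eff: synthgen.EffectConfig, assr_excess: float = 3.0):
    """Resolve an effect configuration into concrete generator parameters.

    Returns (stage_params, spindle_params, deviant_components, assr_gains):
    the gamma effect is applied per stage on the model band power, the
    spindle effect by thinning against the wild-type base rates, the P3a
    effect on the deviant component amplitude, and the entrainment effect on
    the per-frequency gains calibrated for a wild-type power-ratio excess of
    ``assr_excess``.
    """
    stage_params = {
        name: synthgen.apply_gamma_power_scale(sp, eff.gamma_power)
        for name, sp in synthgen.DEFAULT_STAGE_PARAMS.items()
    }
    spindle_params = synthgen.DEFAULT_SPINDLE_PARAMS.scaled(eff.spindle_rate)
    deviant = tuple(
        dataclasses.replace(c, amplitude_uv=c.amplitude_uv * eff.p3a_amplitude)
        if c.name == "P3a"
        else c
        for c in synthgen.DEFAULT_DEVIANT_COMPONENTS
    )
    wake = synthgen.DEFAULT_STAGE_PARAMS["WAKE"]
    gains = {
        f: synthgen.gain_for_power_excess(wake, f, assr_excess) * eff.assr_gain
        for f in DEFAULT_PARAMS["evoked"]["assr_freqs"]
    }
    return stage_params, spindle_params, deviant, gains


def build_subject_session(
    kind: str,
    eff: synthgen.EffectConfig,
    base_seed: int,
    meta: dict | None = None,
    sleep_duration_s: float = 3600.0,
    target_nrem_fraction: float = 0.55,
    hypnogram_fraction_tol: float = 0.005,
    n_trains_per_freq: int = 60,
    assr_excess: float = 3.0,
    stim_freqs: tuple[float, ...] | None = None,
    n_standard: int = 900,
    n_deviant: int = 100,
    fs: float = 1000.0,
) -> tuple[sigio.Recording, dict]:
    """Synthesize one subject session of a given kind with injected effects.

    ``kind`` is ``sleep``, ``assr`` or ``mmn``. Returns the recording plus a
    dict of ground truth / event tables. Subjects paired across genotypes
    (same ``base_seed``) share their noise realization.
    """
    stage_params, spindle_params, deviant, gains = effective_parameters(
        eff, assr_excess
    )
    if kind == "sleep":
        hyp = synthgen.generate_hypnogram(
            sleep_duration_s,
            target_nrem_fraction=target_nrem_fraction * eff.nrem_fraction,
            seed=base_seed,
            fraction_tol=hypnogram_fraction_tol,
            max_tries=200,
        )
        rec, truth = synthgen.synthesize_session(
            hyp, stage_params, spindle_params, fs=fs, seed=base_seed, meta=meta
        )
        return rec, {"hypnogram": hyp, "spindle_truth": truth}
    if kind == "assr":
        if stim_freqs is not None:
            gains = {f: gains[f] for f in stim_freqs}
        rec, events = synthgen.generate_assr_session(
            stim_freqs=tuple(gains),
            n_trains_per_freq=n_trains_per_freq,
            entrainment_gain=gains,
            fs=fs,
            seed=base_seed + 1,
            meta=meta,
        )
        return rec, {"events": events}
    if kind == "mmn":
        rec, events = synthgen.generate_mmn_session(
            n_standard=n_standard,
            n_deviant=n_deviant,
            components_deviant=deviant,
            fs=fs,
            seed=base_seed + 2,
            meta=meta,
        )
        return rec, {"events": events}
    raise ParameterError(f"unknown session kind {kind!r}")


def make_demo_study(
    effect_preset: str | dict[str, synthgen.EffectConfig],
    n_per_group: int = 12,
    seed: int = 0,
    out_dir: str | Path = "demo_study",
    session_kinds: tuple[str, ...] = ("sleep", "assr", "mmn"),
    sleep_duration_s: float = 3600.0,
    target_nrem_fraction: float = 0.55,
    hypnogram_fraction_tol: float = 0.005,
    n_trains_per_freq: int = 60,
    assr_excess: float = 3.0,
    n_standard: int = 900,
    n_deviant: int = 100,
    fs: float = 1000.0,
) -> RunConfig:
    """Write a synthetic multi-genotype study to disk and return its config.

    ``effect_preset`` is a preset name (``null``, ``grin2a_like``,
    ``akap11_like``) or a mapping genotype -> :class:`EffectConfig`. The
    baseline 50 Hz entrainment gain is chosen so the wild-type power ratio
    is ~ ``1 + assr_excess`` at every stimulation frequency.
    """
    if isinstance(effect_preset, str):
        if effect_preset not in EFFECT_PRESETS:
            raise ParameterError(
                f"unknown preset {effect_preset!r}; choose from {list(EFFECT_PRESETS)}"
            )
        effects = EFFECT_PRESETS[effect_preset]
    else:
        effects = dict(effect_preset)
    out_dir = Path(out_dir)
    (out_dir / "data").mkdir(parents=True, exist_ok=True)

    sizes = dict(
        sleep_duration_s=sleep_duration_s,
        target_nrem_fraction=target_nrem_fraction,
        hypnogram_fraction_tol=hypnogram_fraction_tol,
        n_trains_per_freq=n_trains_per_freq,
        assr_excess=assr_excess,
        n_standard=n_standard,
        n_deviant=n_deviant,
        fs=fs,
    )
    subjects = []
    for genotype, eff in effects.items():
        for i in range(n_per_group):
            sid = f"{genotype}_{i:02d}"
            base = subject_seed(seed, i)
            meta = {"subject_id": sid, "genotype": genotype, "age_label": "3mo"}
            entry: dict = {"id": sid, "genotype": genotype}
            if "sleep" in session_kinds:
                rec, aux = build_subject_session("sleep", eff, base, meta, **sizes)
                entry["sleep_edf"] = f"data/{sid}_sleep.edf"
                sigio.write_edf(rec, out_dir / entry["sleep_edf"])
                staging.write_hypnogram(
                    aux["hypnogram"], out_dir / f"data/{sid}_truth_hypnogram.tsv"
                )
                spindles.events_to_frame(aux["spindle_truth"]).to_csv(
                    out_dir / f"data/{sid}_truth_spindles.tsv", sep="\t", index=False
                )
            if "assr" in session_kinds:
                rec, aux = build_subject_session("assr", eff, base, meta, **sizes)
                entry["assr_edf"] = f"data/{sid}_assr.edf"
                entry["assr_events"] = f"data/{sid}_assr_events.tsv"
                sigio.write_edf(rec, out_dir / entry["assr_edf"])
                sigio.write_events(aux["events"], out_dir / entry["assr_events"])
            if "mmn" in session_kinds:
                rec, aux = build_subject_session("mmn", eff, base, meta, **sizes)
                entry["mmn_edf"] = f"data/{sid}_mmn.edf"
                entry["mmn_events"] = f"data/{sid}_mmn_events.tsv"
                sigio.write_edf(rec, out_dir / entry["mmn_edf"])
                sigio.write_events(aux["events"], out_dir / entry["mmn_events"])
            subjects.append(entry)

    cfg = RunConfig(
        subjects=subjects, out_dir=out_dir / "results", seed=seed,
        base_dir=out_dir,
    )
    raw = {
        "seed": seed,
        "out_dir": str(cfg.out_dir),
        "subjects": subjects,
        "params": cfg.params,
        "reference_genotype": cfg.reference_genotype,
    }
    (out_dir / "config.yaml").write_text(yaml.safe_dump(raw, sort_keys=False))
    return cfg


# ---------------------------------------------------------------------------
# study runner


def run_study(config: RunConfig) -> StudyReport:
    """Run every subject through the applicable analyses and compare genotypes.

    Subject failures are recorded and the run continues; ``StudyReport.ok``
    is False when any subject failed.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows: list[dict] = []
    failures: list[dict] = []
    statuses: dict[str, str] = {}
    for sub in config.subjects:
        sid = sub["id"]
        try:
            metrics: dict = {}
            if sub.get("sleep_edf"):
                rec = sigio.read_edf(config.resolve(sub["sleep_edf"]))
                sleep_metrics_d, hyp = analyze_sleep(rec, config.params)
                metrics.update(sleep_metrics_d)
                staging.write_hypnogram(hyp, out_dir / f"{sid}_hypnogram.tsv")
            if sub.get("assr_edf"):
                rec = sigio.read_edf(config.resolve(sub["assr_edf"]))
                events = sigio.read_events(
                    config.resolve(sub["assr_events"]), rec.duration_s
                )
                metrics.update(analyze_assr(rec, events, config.params))
            if sub.get("mmn_edf"):
                rec = sigio.read_edf(config.resolve(sub["mmn_edf"]))
                events = sigio.read_events(
                    config.resolve(sub["mmn_events"]), rec.duration_s
                )
                metrics.update(analyze_mmn(rec, events, config.params))
            for name, value in metrics.items():
                rows.append(
                    dict(subject_id=sid, genotype=sub["genotype"],
                         metric=name, value=value)
                )
            statuses[sid] = "ok"
        except Exception as exc:  # noqa: BLE001 - per-subject fault isolation
            logger.error("subject %s failed: %s", sid, exc)
            failures.append(
                dict(subject_id=sid, error=str(exc),
                     traceback=traceback.format_exc())
            )
            statuses[sid] = f"failed: {exc}"

    subject_metrics = pd.DataFrame(
        rows, columns=["subject_id", "genotype", "metric", "value"]
    )
    if not subject_metrics.empty:
        clean = subject_metrics.dropna(subset=["value"])
        group_stats = stats.group_stats_table(clean, config.reference_genotype)
        means = (
            clean.groupby(["metric", "genotype"])["value"].mean().unstack().round(6)
        )
        summary_means = {
            m: {g: (None if pd.isna(v) else float(v)) for g, v in row.items()}
            for m, row in means.iterrows()
        }
    else:
        group_stats = pd.DataFrame()
        summary_means = {}

    summary = {
        "seed": config.seed,
        "n_subjects": len(config.subjects),
        "n_failed": len(failures),
        "group_means": summary_means,
    }
    subject_metrics.to_csv(out_dir / "subject_metrics.tsv", sep="\t", index=False)
    group_stats.to_csv(out_dir / "group_stats.tsv", sep="\t", index=False)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out_dir / "run_log.json").write_text(
        json.dumps(
            {"seed": config.seed, "params": config.params,
             "reference_genotype": config.reference_genotype,
             "subject_status": statuses},
            indent=2, sort_keys=True,
        )
    )
    return StudyReport(subject_metrics, group_stats, summary, failures)
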