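"""End-to-end orchestration: simulate -> preprocess -> CSD -> SNR -> statistics.

A single global seed is expanded into named, independent substreams (subject
sampling, per-subject schedules, per-subject EEG noise, ratings, bootstrap),
so changing e.g. the bootstrap settings never perturbs the generated data.
All stage outputs are CSV/JSON in the run directory plus a manifest with
versions, seeds and checksums; rerunning an identical config reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contrasts import contrast_weights
from .csd import CSDConfig, csd_transform
from .design import PHASES, ScheduleConfig, make_schedule
from .edf import write_edf
from .montage import make_montage, write_sfp
from .preprocess import average_conditions, detect_artifacts, interpolate_channels, lowpass_filter
from .simulate import RatingParams, SignalParams, synthesize_epochs, synthesize_ratings
from .spectral import snr_rows
from .stats_bayes import (
    bayes_comparison,
    bootstrap_bf,
    correlate_with_covariate,
    phase_differences,
    tuning_index_table,
)
from .stats_lmm import fit_lmm, lmm_table
from .subjects import AccentuationParams, SpaiParams, sample_subjects
from .tables import write_csv

logger = logging.getLogger(__name__)

_STREAMS = ("subjects", "schedules", "epochs", "ratings", "bootstrap")


@dataclass
class PreprocessConfig:
    k_iqr: float = 3.0
    max_bad_channels: int = 20
    exclude_reinforced: bool = False
    lowpass_hz: float = 40.0


@dataclass
class SpectralConfig:
    window_ms: tuple[float, float] = (500.0, 3000.0)
    freq: float = 12.0


@dataclass
class BayesConfig:
    rscale_fixed: float = 0.5
    rscale_random: float = 1.0
    contrasts: tuple[str, ...] = ("lateral_inhibition", "quadratic", "linear")


@dataclass
class BootstrapConfig:
    b: int = 100_000
    repeats: int = 100


@dataclass
class MontageConfig:
    n_channels: int = 129
    cluster_size: int = 8


@dataclass
class RunConfig:
    seed: int = 0
    n_subjects: int = 67
    n_per_condition: int = 15
    pattern: str | None = "lateral_inhibition"
    spai: SpaiParams = field(default_factory=SpaiParams)
    accentuation: AccentuationParams = field(default_factory=AccentuationParams)
    signal: SignalParams = field(default_factory=SignalParams)
    ratings: RatingParams = field(default_factory=RatingParams)
    montage: MontageConfig = field(default_factory=MontageConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    csd: CSDConfig = field(default_factory=CSDConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    bayes: BayesConfig = field(default_factory=BayesConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    write_edf_files: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {
            "spai": SpaiParams, "accentuation": AccentuationParams,
            "signal": SignalParams, "ratings": RatingParams,
            "montage": MontageConfig, "preprocess": PreprocessConfig,
            "csd": CSDConfig, "spectral": SpectralConfig,
            "bayes": BayesConfig, "bootstrap": BootstrapConfig,
        }
        kwargs: dict = {}
        for key, val in d.items():
            if key in sub and isinstance(val, dict):
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        cfg = cls(**kwargs)
        if isinstance(cfg.spectral.window_ms, list):
            cfg.spectral.window_ms = tuple(cfg.spectral.window_ms)
        if isinstance(cfg.bayes.contrasts, list):
            cfg.bayes.contrasts = tuple(cfg.bayes.contrasts)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)


def _seed_streams(seed: int) -> dict[str, np.random.SeedSequence]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STREAMS))
    return dict(zip(_STREAMS, children))


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0])


def simulate_subject_snr(cfg: RunConfig, profile, schedule, montage, epoch_seed: int,
                         edf_dir: Path | None = None) -> tuple[pd.DataFrame, dict]:
    """One subject through EEG synthesis, preprocessing, CSD and the 12 Hz SNR."""
    pattern = contrast_weights(cfg.pattern) if cfg.pattern else None
    epochs = synthesize_epochs(profile, schedule, montage, cfg.signal, pattern,
                               seed=epoch_seed)
    if edf_dir is not None:
        for phase in PHASES:
            sel = (epochs.trial_meta["phase"] == phase).to_numpy()
            if not sel.any():
                continue
            sub = type(epochs)(epochs.data[sel], epochs.fs, epochs.t0_ms,
                               epochs.trial_meta[sel], list(epochs.channels))
            write_edf(sub, edf_dir / f"{profile.subject_id}_{phase}.edf")
    epochs = lowpass_filter(epochs, cfg.preprocess.lowpass_hz)
    report = detect_artifacts(epochs, cfg.preprocess.k_iqr, cfg.preprocess.max_bad_channels)
    epochs = interpolate_channels(epochs, report, montage)
    avg = average_conditions(epochs, report,
                             exclude_reinforced=cfg.preprocess.exclude_reinforced,
                             subject_id=profile.subject_id)
    avg = csd_transform(avg, montage, cfg.csd)
    rows = snr_rows(avg, montage, profile.spai, cfg.spectral.window_ms, cfg.spectral.freq)
    info = {"subject_id": profile.subject_id, "n_rejected": report.n_rejected,
            "n_trials": epochs.n_trials}
    return rows, info


def analyze_tables(snr: pd.DataFrame, ratings: pd.DataFrame | None,
                   cfg: RunConfig) -> dict:
    """Statistics stages 5-6 on long tables (synthetic or user-supplied)."""
    out: dict = {}
    lmm_frames = {}
    for phase in PHASES:
        fits = {}
        sub = snr[snr["phase"] == phase]
        if len(sub):
            fits["ssvep_snr"] = fit_lmm(sub)
        if ratings is not None:
            rsub = ratings[ratings["phase"] == phase]
            for scale in rsub["scale"].unique():
                ssub = rsub[rsub["scale"] == scale]
                fits[scale] = fit_lmm(ssub, response="value")
        if fits:
            lmm_frames[phase] = lmm_table(fits)
    out["lmm"] = lmm_frames

    gen = snr[snr["phase"] == "generalization"]
    if len(gen):
        comparison = bayes_comparison(
            gen, contrasts=cfg.bayes.contrasts,
            rscale_fixed=cfg.bayes.rscale_fixed, rscale_random=cfg.bayes.rscale_random,
        )
        out["bayes"] = comparison
        melted = comparison.melt(id_vars="model")
        bf_rows = melted[melted["variable"].str.startswith("bf_")]
        best = bf_rows.loc[bf_rows["value"].idxmax()]
        out["winning"] = {"model": str(best["model"]),
                          "contrast": str(best["variable"][3:]),
                          "bf": float(best["value"])}
        indices = tuning_index_table(snr, cfg.bayes.contrasts)
        out["tuning_indices"] = indices
        corr_rows = []
        for name, grp in indices.groupby("contrast", sort=False):
            res = correlate_with_covariate(grp["index"].to_numpy(), grp["spai"].to_numpy())
            corr_rows.append((name, res.r, res.df, res.p, res.bf_rho))
        out["correlations"] = pd.DataFrame(
            corr_rows, columns=["contrast", "r", "df", "p", "bf_rho"])

    phases_present = set(snr["phase"])
    if {"habituation", "acquisition"} <= phases_present:
        hab = phase_differences(snr, "habituation")
        acq = phase_differences(snr, "acquisition")
        boot_seed = _seed_int(_seed_streams(cfg.seed)["bootstrap"])
        res = bootstrap_bf(hab, acq, b=cfg.bootstrap.b, repeats=cfg.bootstrap.repeats,
                           seed=boot_seed)
        out["bootstrap"] = {"bf": res.bf, "se": res.se, "se_pct": res.se_pct,
                            "b": res.b, "repeats": res.repeats}
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages and write the report into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams = _seed_streams(config.seed)

    profiles = sample_subjects(config.n_subjects, config.spai, config.accentuation,
                               seed=_seed_int(streams["subjects"]))
    montage = make_montage(config.montage.n_channels, config.montage.cluster_size)
    write_sfp(montage, out / "montage.sfp")

    sched_cfg = ScheduleConfig()
    for spec in sched_cfg.phases:
        spec.n_per_condition = config.n_per_condition

    schedule_seeds = streams["schedules"].spawn(config.n_subjects)
    epoch_seeds = streams["epochs"].spawn(config.n_subjects)
    edf_dir = out / "edf" if config.write_edf_files else None
    if edf_dir is not None:
        edf_dir.mkdir(exist_ok=True)

    snr_parts, sched_parts, infos = [], [], []
    for i, prof in enumerate(profiles):
        schedule = make_schedule(sched_cfg, seed=_seed_int(schedule_seeds[i]))
        sched_df = schedule.to_frame()
        sched_df.insert(0, "subject_id", prof.subject_id)
        sched_parts.append(sched_df)
        rows, info = simulate_subject_snr(config, prof, schedule, montage,
                                          _seed_int(epoch_seeds[i]), edf_dir)
        snr_parts.append(rows)
        infos.append(info)
        logger.info("subject %s: %d/%d trials rejected", prof.subject_id,
                    info["n_rejected"], info["n_trials"])

    snr = pd.concat(snr_parts, ignore_index=True)
    ratings = synthesize_ratings(profiles, config.ratings,
                                 seed=_seed_int(streams["ratings"]))

    subj_df = pd.DataFrame(
        [(p.subject_id, p.spai, p.accentuation, p.cs_assignment) for p in profiles],
        columns=["subject_id", "spai", "accentuation", "cs_assignment"],
    )
    files = {
        "snr": write_csv(snr, out / "snr.csv"),
        "ratings": write_csv(ratings, out / "ratings.csv"),
        "subjects": write_csv(subj_df, out / "subjects.csv"),
        "schedules": write_csv(pd.concat(sched_parts, ignore_index=True),
                               out / "schedules.csv"),
    }

    results = analyze_tables(snr, ratings, config)
    for phase, frame in results["lmm"].items():
        files[f"lmm_{phase}"] = write_csv(frame, out / f"lmm_{phase}.csv")
    if "bayes" in results:
        files["bayes"] = write_csv(results["bayes"], out / "bayes_model_comparison.csv")
        files["tuning"] = write_csv(results["tuning_indices"], out / "tuning_indices.csv")
        files["correlations"] = write_csv(results["correlations"], out / "correlations.csv")
    if "bootstrap" in results:
        (out / "bootstrap_bf.json").write_text(
            json.dumps(results["bootstrap"], indent=2) + "\n")

    config.to_yaml(out / "config.yaml")
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "rejections": infos,
        "checksums": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in files.items()
        },
    }
    if "winning" in results:
        manifest["winning"] = results["winning"]
    if "bootstrap" in results:
        manifest["bootstrap_bf"] = results["bootstrap"]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    results["manifest"] = manifest
    results["files"] = {k: str(v) for k, v in files.items()}
    results["snr"] = snr
    return results
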