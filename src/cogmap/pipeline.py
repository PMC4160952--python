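"""End-to-end orchestration: synthetic cohort -> analyses -> report.

``run_experiment`` simulates a cohort with planted spatial codes and runs
the enabled analyses (label adaptation, distance modulation, decoding, RSA,
cross-decoding), writing tidy TSV tables plus a JSON report stamped with
the configuration hash and master seed. A thin ``click`` CLI exposes the
stages as subcommands. A single master seed expands into independent
per-stage streams through ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import environment as env
from . import adaptation as adapt_mod
from . import mvpa, rsa, synthgen, texture
from .sequence import pair_count_spread

__all__ = ["RunConfig", "Report", "run_experiment", "validate_stimulus_set", "cli"]

log = logging.getLogger("cogmap")


@dataclass
class RunConfig:
    """Configuration of a full synthetic experiment."""

    room_config: str | None = None  # packaged reference room when None
    n_subjects: int = 16
    n_runs: int = 4
    trials_per_run: int = 176
    n_voxels: int = 216
    master_seed: int = 0
    out_dir: str = "cogmap_out"
    # planted effects
    repeat_suppression: float = 0.3
    slope_place: float = 0.05
    slope_view: float = 0.05
    slope_heading: float = 0.0
    noise_sigma: float = 1.0
    noise_rho: float = 0.3
    drift_amplitude: float = 0.5
    tuning_widths: tuple[float, float, float] = (0.8, 0.8, 60.0)
    location_code_weight: float = 0.0
    use_texture: bool = True
    # analysis toggles
    run_adaptation: bool = True
    run_distance: bool = True
    run_decoding: bool = True
    run_rsa: bool = True
    run_crossdecoding: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.room_config and not Path(cfg.room_config).exists():
            raise FileNotFoundError(cfg.room_config)
        return cfg

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class Report:
    tables: dict[str, pd.DataFrame]
    config_hash: str
    master_seed: int
    timings: dict[str, float] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary = {"config_hash": self.config_hash, "seed": self.master_seed, "timings": self.timings}
        for name, df in self.tables.items():
            df = df.copy()
            df["config_hash"] = self.config_hash
            df["seed"] = self.master_seed
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        (out / "report.json").write_text(json.dumps(summary, indent=2))


def _stage_seeds(master_seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(master_seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31 - 1)) for n, c in zip(names, children)}


def validate_stimulus_set(room_config: str | None = None) -> pd.DataFrame:
    """Check all stimulus-set invariants and report design diagnostics.

    Verifies the printed exemplar anchors (P1->V6 heads south and shares
    landmarks L4 and L5 with P6->V8, which heads east), the uniqueness and
    coverage invariants, and reports the heading-change collinearity with
    place and view change over all ordered pairs of distinct conditions.
    """
    room, stimuli = env.load_room(room_config)
    checks = []

    def check(name, ok, detail=""):
        checks.append({"check": name, "passed": bool(ok), "detail": detail})

    s16 = stimuli[stimuli.condition_of("P1", "V6")]
    s68 = stimuli[stimuli.condition_of("P6", "V8")]
    check("P1V6 heads south", s16.heading == "S", s16.label)
    check("P6V8 heads east", s68.heading == "E", s68.label)
    shared = s16.visible_landmarks & s68.visible_landmarks
    check("P1V6/P6V8 share exactly L4+L5", shared == {"L4", "L5"}, ",".join(sorted(shared)))
    for snap in stimuli:
        if snap.heading != env.heading_of(snap.place_id, snap.view_id, room):
            check("heading consistency", False, snap.label)
            break
    else:
        check("heading consistency", True)
    H = stimuli.pairwise("heading")
    P = stimuli.pairwise("place")
    V = stimuli.pairwise("view")
    off = ~np.eye(len(stimuli), dtype=bool)
    rhp = float(np.corrcoef(H[off], P[off])[0, 1])
    rhv = float(np.corrcoef(H[off], V[off])[0, 1])
    check("heading/place collinearity", True, f"r={rhp:.3f}")
    check("heading/view collinearity", True, f"r={rhv:.3f}")
    return pd.DataFrame(checks)


def run_experiment(config: RunConfig) -> Report:
    """Simulate a cohort and run every enabled analysis stage."""
    t0 = time.time()
    timings: dict[str, float] = {}
    room, stimuli = env.load_room(config.room_config)
    seeds = _stage_seeds(config.master_seed, ["texture", "cohort", "decode"])

    tex_table = None
    if config.use_texture:
        tex_table = texture.condition_texture_table(stimuli, room, seed=seeds["texture"])
        timings["texture"] = time.time() - t0
        log.info("texture table in %.1fs", timings["texture"])

    t1 = time.time()
    dataset = synthgen.make_cohort(
        n_subjects=config.n_subjects,
        n_runs=config.n_runs,
        trials_per_run=config.trials_per_run,
        room=room,
        stimuli=stimuli,
        texture_table=tex_table,
        adapt=synthgen.AdaptationSpec(
            repeat_suppression=config.repeat_suppression,
            slope_place=config.slope_place,
            slope_view=config.slope_view,
            slope_heading=config.slope_heading,
        ),
        noise=synthgen.NoiseSpec(
            sigma=config.noise_sigma,
            rho=config.noise_rho,
            drift_amplitude=config.drift_amplitude,
        ),
        n_voxels=config.n_voxels,
        tuning_widths=config.tuning_widths,
        location_code_weight=config.location_code_weight,
        seed=seeds["cohort"],
    )
    timings["simulate"] = time.time() - t1
    log.info("cohort simulated in %.1fs", timings["simulate"])

    tables: dict[str, pd.DataFrame] = {"stimulus_checks": validate_stimulus_set(config.room_config)}
    spreads = [
        pair_count_spread(
            [t.condition_id for run in s.sequence.runs for t in run if t.kind == "target"],
            stimuli.n_conditions,
        )
        for s in dataset.subjects
    ]
    tables["sequence_balance"] = pd.DataFrame(
        {"subject": range(len(spreads)), "pair_count_spread": spreads}
    )

    def stage(name, enabled, fn):
        if not enabled:
            return
        t = time.time()
        try:
            fn()
        except Exception as exc:  # pragma: no cover - abort with stage context
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = time.time() - t
        log.info("stage %s in %.1fs", name, timings[name])

    def do_adaptation():
        fits = [adapt_mod.fit_label_model(s) for s in dataset.subjects]
        res = adapt_mod.adaptation_contrasts(fits)
        tables["adaptation_contrasts"] = res.group
        tables["adaptation_subjects"] = res.subject_contrasts

    def do_distance():
        for model in ("place_view", "heading"):
            fits = [adapt_mod.fit_distance_model(s, model=model) for s in dataset.subjects]
            res = adapt_mod.distance_modulation(fits, model=model)
            tables[f"distance_{model}"] = res.group

    patterns_cache: list[mvpa.PatternEstimate] = []

    def get_patterns():
        if not patterns_cache:
            patterns_cache.extend(mvpa.estimate_condition_patterns(s) for s in dataset.subjects)
        return patterns_cache

    def do_decoding():
        rows = []
        for grouping in ("place", "view", "heading"):
            accs = [
                mvpa.pairwise_decode(p, grouping, stimuli, seed=seeds["decode"]).mean_accuracy
                for p in get_patterns()
            ]
            from .glm import group_test

            t, p = group_test(np.array(accs) - 0.5, "one_sample", tail="greater")
            rows.append(
                {"grouping": grouping, "mean_accuracy": float(np.mean(accs)), "t": t, "p": p}
            )
        matched = [
            mvpa.matched_view_place_decode(pat, stimuli).mean_accuracy for pat in get_patterns()
        ]
        rows.append(
            {
                "grouping": "place_matched_view",
                "mean_accuracy": float(np.mean(matched)),
                "t": np.nan,
                "p": np.nan,
            }
        )
        tables["decoding"] = pd.DataFrame(rows)

    def do_rsa():
        predictors = rsa.model_rdms(stimuli, room, tex_table)
        for model in ("place_view", "heading"):
            fits = [
                rsa.rsa_regression(rsa.neural_rdm(p), predictors, model=model)
                for p in get_patterns()
            ]
            tables[f"rsa_{model}"] = rsa.group_rsa(fits)

    def do_cross():
        rows = []
        for pat in get_patterns():
            res = mvpa.cross_decode(pat, stimuli)
            for direction, r in res.items():
                rows.append({"direction": direction, "accuracy": r.mean_accuracy})
        t_lmk, _ = mvpa.landmark_confound_check(stimuli)
        df = pd.DataFrame(rows).groupby("direction", as_index=False)["accuracy"].mean()
        df["landmark_confound_t"] = t_lmk
        tables["cross_decoding"] = df

    stage("adaptation", config.run_adaptation, do_adaptation)
    stage("distance", config.run_distance, do_distance)
    stage("decoding", config.run_decoding, do_decoding)
    stage("rsa", config.run_rsa, do_rsa)
    stage("crossdecoding", config.run_crossdecoding, do_cross)

    report = Report(tables=tables, config_hash=config.hash(), master_seed=config.master_seed, timings=timings)
    report.write(config.out_dir)
    return report


def _load_config(config_path: str | None, seed: int | None, out_dir: str | None, **overrides) -> RunConfig:
    cfg = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    if seed is not None:
        cfg.master_seed = seed
    if out_dir is not None:
        cfg.out_dir = out_dir
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@click.group()
@click.option("-v", "--verbose", is_flag=True)
def cli(verbose: bool) -> None:
    """Carry-over fMRI analysis pipeline on synthetic spatial codes."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        stream=sys.stderr,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


_shared = [
    click.option("--config", "config_path", type=click.Path(exists=True), default=None),
    click.option("--seed", type=int, default=None),
    click.option("--out-dir", type=str, default=None),
]


def _with_shared(fn):
    for opt in reversed(_shared):
        fn = opt(fn)
    return fn


def _single_stage(stage_flag: str):
    toggles = {t: False for t in
               ("run_adaptation", "run_distance", "run_decoding", "run_rsa", "run_crossdecoding")}
    toggles[stage_flag] = True
    return toggles


@cli.command()
@_with_shared
def simulate(config_path, seed, out_dir):
    """Simulate a synthetic cohort and write volumes + events."""
    cfg = _load_config(config_path, seed, out_dir, **_single_stage("run_adaptation"))
    room, stimuli = env.load_room(cfg.room_config)
    seeds = _stage_seeds(cfg.master_seed, ["texture", "cohort", "decode"])
    dataset = synthgen.make_cohort(
        n_subjects=cfg.n_subjects, n_runs=cfg.n_runs, trials_per_run=cfg.trials_per_run,
        room=room, stimuli=stimuli, n_voxels=cfg.n_voxels, seed=seeds["cohort"],
    )
    dataset.to_bids(cfg.out_dir)
    click.echo(f"wrote {cfg.n_subjects} subjects to {cfg.out_dir}")


def _run_stage(config_path, seed, out_dir, stage_flag):
    cfg = _load_config(config_path, seed, out_dir, **_single_stage(stage_flag))
    report = run_experiment(cfg)
    click.echo(f"report in {cfg.out_dir} (hash {report.config_hash})")


@cli.command()
@_with_shared
def adapt(config_path, seed, out_dir):
    """Label-based repetition adaptation analysis."""
    _run_stage(config_path, seed, out_dir, "run_adaptation")


@cli.command()
@_with_shared
def decode(config_path, seed, out_dir):
    """Pairwise SVM-RFE decoding of place, view and heading."""
    _run_stage(config_path, seed, out_dir, "run_decoding")


@cli.command(name="rsa")
@_with_shared
def rsa_cmd(config_path, seed, out_dir):
    """RDM-regression representational similarity analysis."""
    _run_stage(config_path, seed, out_dir, "run_rsa")


@cli.command()
@_with_shared
def crossdecode(config_path, seed, out_dir):
    """Place/view cross-decoding plus the landmark confound check."""
    _run_stage(config_path, seed, out_dir, "run_crossdecoding")


@cli.command()
@_with_shared
def report(config_path, seed, out_dir):
    """Run every enabled stage and write the full report."""
    cfg = _load_config(config_path, seed, out_dir)
    rep = run_experiment(cfg)
    click.echo(f"report in {cfg.out_dir} (hash {rep.config_hash})")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
def validate(config_path):
    """Validate the room/stimulus configuration."""
    df = validate_stimulus_set(config_path)
    click.echo(df.to_string(index=False))
    if not df["passed"].all():
        raise SystemExit(1)
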