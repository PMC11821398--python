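"""End-to-end orchestration of the full study flow.

Stages, in order:

1. ``fixtures``   — build (or load) observed pure-oil tables and the
   real-world-style mixture table;
2. ``preprocess`` — replicate averaging + validation of the observed
   tables;
3. ``fit``        — per-class Gaussian fits;
4. ``kld``        — generator comparison grid (Monte-Carlo vs
   independent-marginal baseline) across the configured sizes;
5. ``corpus``     — 7-class mixture training corpus;
6. ``split``      — stratified 80/20 train/test split;
7. ``rf`` / ``nn``— hyperparameter-tuned classifiers;
8. ``evaluate``   — reports on the simulated test set and on the
   real-world-style mixtures.

Every stage's seed is derived deterministically from one master seed,
every artifact is persisted under the output directory, and a manifest
lists all of it.  Rerunning with the same config and master seed
reproduces the Random-Forest outputs byte-for-byte; the network follows
the same contract through its own derived seed.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .classify import (
    NNSearchSpace,
    RFSearchSpace,
    split_train_test,
    train_neural_network,
    tune_random_forest,
)
from .data import average_replicates, validate_table
from .divergence import DEFAULT_EPSILON, compare_generators
from .evaluate import evaluate_model
from .fixtures import FixtureBundle, GroundTruthSpec, make_fixture_bundle, save_bundle
from .generators import (
    baseline_independent_sample,
    fit_class_distribution,
    mc_sample,
    save_sim_dataset,
)
from .mixtures import CO_LABEL, SO_LABEL, MixtureDesign, build_training_corpus

STAGES = (
    "fixtures", "preprocess", "fit", "kld", "corpus", "split", "rf", "nn",
    "evaluate",
)


def derive_stage_seed(master_seed: int, stage_name: str) -> int:
    """Stable per-stage seed: first 4 bytes of SHA-256(master:stage), < 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage_name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Declarative description of one full run."""

    outdir: Path
    master_seed: int = 0
    fixture_spec: GroundTruthSpec = field(default_factory=GroundTruthSpec)
    mc_sizes: tuple[int, ...] = (1_000, 10_000)
    design: MixtureDesign = field(default_factory=MixtureDesign)
    rf_space: RFSearchSpace = field(default_factory=RFSearchSpace)
    nn_space: NNSearchSpace = field(default_factory=NNSearchSpace)
    epsilon: float = DEFAULT_EPSILON
    train_fraction: float = 0.8
    skip_nn: bool = False

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if any(s < 1 for s in self.mc_sizes):
            raise ValueError("mc sizes must be >= 1")

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "master_seed": self.master_seed,
                "mc_sizes": list(self.mc_sizes),
                "ratios": list(self.design.ratios),
                "n_per_class": self.design.n_per_class,
                "epsilon": self.epsilon,
                "train_fraction": self.train_fraction,
                "rf_space": {
                    f: list(getattr(self.rf_space, f)) if isinstance(getattr(self.rf_space, f), tuple) else getattr(self.rf_space, f)
                    for f in (*RFSearchSpace._FIELDS, "cv_folds")
                },
                "nn_space": {
                    "n_hidden_layers": list(self.nn_space.n_hidden_layers),
                    "hidden_dim": list(self.nn_space.hidden_dim),
                    "batch_size": list(self.nn_space.batch_size),
                    "n_trials": self.nn_space.n_trials,
                    "epoch_budget": self.nn_space.epoch_budget,
                },
                "fixture_seed": self.fixture_spec.seed,
                "rho": self.fixture_spec.rho,
                "cv": self.fixture_spec.cv,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stage_seeds: dict[str, int]
    artifacts: dict[str, str]
    notes: dict[str, str] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "version": self.version,
                    "stage_seeds": self.stage_seeds,
                    "artifacts": self.artifacts,
                    "notes": self.notes,
                },
                indent=1,
                sort_keys=True,
            )
        )


def run_pipeline(
    config: PipelineConfig, bundle: Optional[FixtureBundle] = None
) -> RunManifest:
    """Execute the full flow and persist every intermediate artifact.

    ``bundle`` may inject pre-built fixtures (e.g. loaded from disk);
    by default the fixture stage generates them from the config's spec.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: derive_stage_seed(config.master_seed, s) for s in STAGES}
    artifacts: dict[str, str] = {}
    notes: dict[str, str] = {}

    def _register(name: str, path: Path) -> Path:
        artifacts[name] = str(path.relative_to(out))
        return path

    manifest = RunManifest(config.config_hash(), __version__, seeds, artifacts, notes)
    stage = "fixtures"
    try:
        # 1. fixtures
        if bundle is None:
            spec = GroundTruthSpec(
                schema=config.fixture_spec.schema,
                ranges=config.fixture_spec.ranges,
                rho=config.fixture_spec.rho,
                cv=config.fixture_spec.cv,
                sd_floor=config.fixture_spec.sd_floor,
                seed=seeds["fixtures"],
            )
            bundle = make_fixture_bundle(spec)
        fx_dir = out / "fixtures"
        save_bundle(bundle, fx_dir)
        for key in ("observed_co", "observed_so", "real_world_mixtures"):
            _register(key, fx_dir / f"{key}.csv")
        _register("fixture_manifest", fx_dir / "manifest.json")

        # 2. preprocess
        stage = "preprocess"
        obs = {}
        for label, table in ((CO_LABEL, bundle.observed_co), (SO_LABEL, bundle.observed_so)):
            averaged = average_replicates(table)
            report = validate_table(averaged)
            notes[f"validate_{label}"] = (
                "ok" if report.passed else f"{len(report.issues)} issue(s)"
            )
            obs[label] = averaged

        # 3. fit
        stage = "fit"
        dists = {label: fit_class_distribution(t, label) for label, t in obs.items()}
        for label, d in dists.items():
            d.to_json(_register(f"dist_{label}", out / f"dist_{label}.json"))

        # 4. kld generator comparison
        stage = "kld"
        grid = compare_generators(
            obs,
            {"mc": mc_sample, "independent-marginal": baseline_independent_sample},
            config.mc_sizes,
            epsilon=config.epsilon,
            seed=seeds["kld"],
        )
        grid.to_csv(_register("kld_grid", out / "kld_grid.csv"), index=False)

        # 5. mixture corpus
        stage = "corpus"
        corpus = build_training_corpus(
            dists[CO_LABEL], dists[SO_LABEL], config.design, seeds["corpus"]
        )
        corpus_dir = out / "corpus"
        corpus_dir.mkdir(exist_ok=True)
        for ds in corpus:
            fname = f"class_{ds.label.replace(':', '_')}.csv"
            save_sim_dataset(
                ds, _register(f"corpus_{ds.label}", corpus_dir / fname),
                list(bundle.schema.feature_names),
            )

        # 6. split
        stage = "split"
        split = split_train_test(corpus, config.train_fraction, seeds["split"])
        ratio_map = config.design.ratio_percent_of()

        # 7-8. train + evaluate
        stage = "rf"
        rf = tune_random_forest(split, config.rf_space, seeds["rf"])
        rf.search_trace.to_csv(_register("rf_trace", out / "rf_trace.csv"), index=False)
        with open(_register("rf_model", out / "rf_model.pkl"), "wb") as fh:
            pickle.dump(rf, fh)

        stage = "evaluate"
        evaluate_model(rf, split.X_test, split.y_test, ratio_map).save(
            _register("rf_report_sim", out / "rf_report_sim.json")
        )
        rw = bundle.real_world_mixtures
        evaluate_model(rf, rw.matrix(), rw.labels(), ratio_map).save(
            _register("rf_report_real", out / "rf_report_real.json")
        )

        if not config.skip_nn:
            stage = "nn"
            nn = train_neural_network(split, config.nn_space, seeds["nn"])
            nn.search_trace.to_csv(
                _register("nn_trace", out / "nn_trace.csv"), index=False
            )
            with open(_register("nn_model", out / "nn_model.pkl"), "wb") as fh:
                pickle.dump(nn, fh)
            stage = "evaluate"
            evaluate_model(nn, split.X_test, split.y_test, ratio_map).save(
                _register("nn_report_sim", out / "nn_report_sim.json")
            )
            evaluate_model(nn, rw.matrix(), rw.labels(), ratio_map).save(
                _register("nn_report_real", out / "nn_report_real.json")
            )
    except Exception as e:
        notes["failed_stage"] = stage
        notes["error"] = repr(e)
        manifest.save(out / "manifest.json")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {e}") from e

    manifest.save(out / "manifest.json")
    artifacts["manifest"] = "manifest.json"
    return manifest
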