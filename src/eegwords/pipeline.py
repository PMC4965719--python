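"""End-to-end orchestration: configs, training runs, and experiments.

A single flat, typed key-value config (section-prefixed keys, YAML on
disk) drives every stage; one global seed deterministically derives the
per-module seeds, so a whole run is reproducible byte for byte in
single-threaded mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import detector as det
from .cbow import CBOWConfig, CBOWModel, train_cbow
from .records import EEGRecord, parse_annotations, read_record, write_annotations, write_record
from .sae import SAEConfig, SAEModel, train_sae
from .segmentation import (
    LABEL_SEIZURE,
    FragmentPool,
    label_pool,
    normalize_pool,
    segment_record,
)
from .simulate import SimConfig, simulate_cohort
from .translation import EEGSentence, translate

DEFAULTS: dict = {
    "seed": 0,
    "segmentation.window_s": 3.0,
    "segmentation.step_s": 1.0,
    "segmentation.overlap_threshold": 0.5,
    "segmentation.channels": "all",
    "sae.hidden_dims": [400, 250],
    "sae.rho": 0.05,
    "sae.beta": 3.0,
    "sae.learning_rate": 0.1,
    "sae.epochs": 30,
    "sae.batch_size": 32,
    "cbow.d": 26,
    "cbow.k": 2,
    "cbow.epochs": 10,
    "cbow.learning_rate": 0.025,
    "cbow.min_count": 1,
    "cbow.integration": "average",
    "translation.mode": "sample",
    "detector.kernel": "rbf",
    "detector.C": 1.0,
    "detector.test_fraction": 0.2,
    "detector.balance": True,
    "sim.fs": 256.0,
    "sim.n_channels": 23,
    "sim.duration_s": 3600.0,
    "sim.n_seizures": 1,
    "sim.seizure_len_min_s": 30.0,
    "sim.seizure_len_max_s": 100.0,
    "sim.seizure_freq": 3.0,
    "sim.seizure_gain": 6.0,
    "sim.noise_sd": 8.0,
    "sim.seizure_noise_frac": 1.0,
    "sim.subject_jitter_sd": 0.25,
    "sim.n_subjects": 4,
}


@dataclass
class PipelineConfig:
    """Resolved flat configuration for one run."""

    values: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.values) - set(DEFAULTS)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(DEFAULTS)
        merged.update(self.values)
        self.values = merged

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        return cls(values=loaded)

    def __getitem__(self, key):
        return self.values[key]

    def seeds(self) -> dict[str, int]:
        """Derive per-module seeds from the global seed, all below 2**31."""
        ss = np.random.SeedSequence(int(self.values["seed"]))
        names = ["sim", "sae", "translate", "cbow", "split", "balance"]
        state = ss.generate_state(len(names))
        return {n: int(s % (2**31)) for n, s in zip(names, state)}

    def sim_config(self) -> SimConfig:
        v = self.values
        return SimConfig(
            fs=float(v["sim.fs"]),
            n_channels=int(v["sim.n_channels"]),
            duration_s=float(v["sim.duration_s"]),
            n_seizures=int(v["sim.n_seizures"]),
            seizure_len_range_s=(float(v["sim.seizure_len_min_s"]),
                                 float(v["sim.seizure_len_max_s"])),
            seizure_freq=float(v["sim.seizure_freq"]),
            seizure_gain=float(v["sim.seizure_gain"]),
            seizure_noise_frac=float(v["sim.seizure_noise_frac"]),
            noise_sd=float(v["sim.noise_sd"]),
            subject_jitter_sd=float(v["sim.subject_jitter_sd"]),
            seed=self.seeds()["sim"],
        )

    def sae_config(self, fs: float) -> SAEConfig:
        v = self.values
        return SAEConfig(
            input_dim=int(round(v["segmentation.window_s"] * fs)),
            hidden_dims=list(v["sae.hidden_dims"]),
            rho=float(v["sae.rho"]),
            beta=float(v["sae.beta"]),
            learning_rate=float(v["sae.learning_rate"]),
            epochs=int(v["sae.epochs"]),
            batch_size=int(v["sae.batch_size"]),
            seed=self.seeds()["sae"],
        )

    def cbow_config(self) -> CBOWConfig:
        v = self.values
        return CBOWConfig(
            d=int(v["cbow.d"]),
            k=int(v["cbow.k"]),
            epochs=int(v["cbow.epochs"]),
            learning_rate=float(v["cbow.learning_rate"]),
            min_count=int(v["cbow.min_count"]),
            integration=str(v["cbow.integration"]),
            seed=self.seeds()["cbow"],
        )

    def echo(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.values, sort_keys=True))


# ---------------------------------------------------------------------------
# Dataset on disk: <stem>.csv/.edf next to <stem>.annotations.csv

def save_dataset(records: list[EEGRecord], out_dir, format: str = "csv") -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in records:
        stem = rec.subject_id or f"record{len(paths)+1:02d}"
        path = out_dir / f"{stem}.{format}"
        write_record(rec, path, format=format)
        write_annotations(rec.annotations, out_dir / f"{stem}.annotations.csv")
        paths.append(path)
    return paths


def load_dataset(data_dir) -> list[EEGRecord]:
    data_dir = Path(data_dir)
    records = []
    for path in sorted(list(data_dir.glob("*.csv")) + list(data_dir.glob("*.edf"))):
        if path.name.endswith(".annotations.csv"):
            continue
        fmt = "edf" if path.suffix == ".edf" else "csv"
        rec = read_record(path, format=fmt)
        if not rec.subject_id:
            rec.subject_id = path.stem
        ann_path = data_dir / f"{path.stem}.annotations.csv"
        if ann_path.exists():
            rec.annotations = parse_annotations(ann_path.read_text(), "interval_csv")
            rec.validate_annotations()
        records.append(rec)
    if not records:
        raise FileNotFoundError(f"no .csv/.edf records found in {data_dir}")
    return records


# ---------------------------------------------------------------------------
# Stages

def build_pool(records: list[EEGRecord], cfg: PipelineConfig) -> FragmentPool:
    """Segment, label and normalize every record into one combined pool."""
    v = cfg.values
    channels = None if v["segmentation.channels"] == "all" else list(v["segmentation.channels"])
    pools = [
        segment_record(rec, v["segmentation.window_s"], v["segmentation.step_s"], channels)
        for rec in records
    ]
    anns = {rec.subject_id: rec.annotations for rec in records}
    frags = []
    for pool in pools:
        label_pool(pool, anns, v["segmentation.overlap_threshold"])
        frags.extend(pool.fragments)
    combined = FragmentPool(
        fragments=frags, window_s=v["segmentation.window_s"], step_s=v["segmentation.step_s"]
    )
    return normalize_pool(combined)


@dataclass
class TrainedModels:
    sae: SAEModel
    cbow: CBOWModel
    detector: det.DetectionModel
    sentences: list[EEGSentence]
    config: PipelineConfig


def fit_feature_models(
    pool: FragmentPool, cfg: PipelineConfig, fs: float
) -> tuple[SAEModel, CBOWModel, list[EEGSentence]]:
    """Unsupervised half of the pipeline: dictionary, translation, contexts."""
    seeds = cfg.seeds()
    sae_model, _ = train_sae(pool, cfg.sae_config(fs))
    rng = np.random.default_rng(seeds["translate"])
    sentences = translate(pool, sae_model, rng=rng, mode=cfg["translation.mode"])
    cbow_model = train_cbow(sentences, cfg.cbow_config(),
                            vocab_size=sae_model.config.n_words)
    return sae_model, cbow_model, sentences


def stratified_split(labels: list[str], test_fraction: float, seed: int):
    """Random fragment-level split keeping both classes in each side."""
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(labels))
    y = [1 if l == LABEL_SEIZURE else 0 for l in labels]
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed % (2**31), stratify=y
    )
    return sorted(train_idx.tolist()), sorted(test_idx.tolist())


def run_experiment(records: list[EEGRecord], cfg: PipelineConfig) -> dict:
    """Full comparison run on labeled records.

    Learns the dictionary and embeddings on the whole pool (both are
    unsupervised), trains the SVM on a random stratified fragment split,
    balances the test split to ~50-50, and scores the fused features
    against downsampling and PCA baselines at the same dimensionality.
    Returns a plain dict of error rates, AUCs and sizes.
    """
    seeds = cfg.seeds()
    fs = records[0].fs
    pool = build_pool(records, cfg)
    sae_model, cbow_model, sentences = fit_feature_models(pool, cfg, fs)
    features = det.assemble_features(pool, sae_model, cbow_model, sentences)

    labels = pool.labels()
    train_idx, test_idx = stratified_split(
        labels, cfg["detector.test_fraction"], seeds["split"]
    )
    if cfg["detector.balance"]:
        test_labels = [labels[i] for i in test_idx]
        keep = det.balance_indices(test_labels, seeds["balance"])
        test_idx = [test_idx[i] for i in keep]

    def fit_eval(feat_list):
        train_feats = [feat_list[i] for i in train_idx]
        test_feats = [feat_list[i] for i in test_idx]
        model = det.train_detector(train_feats, kernel=cfg["detector.kernel"],
                                   C=cfg["detector.C"])
        _, scores = det.predict(model, test_feats)
        report = det.evaluate(scores, [f.label for f in test_feats])
        return model, report

    detector_model, report = fit_eval(features)
    target_dim = len(features[0].values)
    results = {
        "n_fragments": len(pool),
        "n_train": len(train_idx),
        "n_test": len(test_idx),
        "n_test_seizure": sum(labels[i] == LABEL_SEIZURE for i in test_idx),
        "feature_dim": target_dim,
        "context": {"error_rate": report.error_rate, "auc": report.auc},
    }
    for method in ("downsample", "pca"):
        base = det.baseline_features(pool, method=method, target_dim=target_dim,
                                     fit_indices=train_idx)
        _, base_report = fit_eval(base)
        results[method] = {
            "error_rate": base_report.error_rate, "auc": base_report.auc
        }
    results["_models"] = TrainedModels(
        sae=sae_model, cbow=cbow_model, detector=detector_model,
        sentences=sentences, config=cfg,
    )
    results["_report"] = report
    return results


# ---------------------------------------------------------------------------
# Model persistence for the CLI

def save_models(models: TrainedModels, model_dir) -> None:
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    models.sae.save(model_dir / "sae.model")
    models.cbow.save(model_dir / "cbow.model")
    import pickle

    with open(model_dir / "detector.model", "wb") as fh:
        pickle.dump(models.detector, fh, protocol=4)
    models.config.echo(model_dir / "config.yaml")


def load_models(model_dir) -> TrainedModels:
    model_dir = Path(model_dir)
    import pickle

    with open(model_dir / "detector.model", "rb") as fh:
        detector_model = pickle.load(fh)
    return TrainedModels(
        sae=SAEModel.load(model_dir / "sae.model"),
        cbow=CBOWModel.load(model_dir / "cbow.model"),
        detector=detector_model,
        sentences=[],
        config=PipelineConfig.from_file(model_dir / "config.yaml"),
    )


def detect_record(models: TrainedModels, record: EEGRecord) -> list[dict]:
    """Per-fragment labels and scores for one record (argmax translation,
    so the output is a pure function of the models and the record)."""
    cfg = models.config
    expected = models.sae.config.input_dim
    got = int(round(cfg["segmentation.window_s"] * record.fs))
    if got != expected:
        raise ValueError(
            f"record at fs={record.fs} gives {got}-sample windows but the "
            f"model expects {expected}"
        )
    pool = build_pool([record], cfg)
    if len(pool) == 0:
        return []
    sentences = translate(pool, models.sae, mode="argmax")
    features = det.assemble_features(pool, models.sae, models.cbow, sentences)
    labels, scores = det.predict(models.detector, features)
    return [
        {"start_s": frag.start_s, "label": lab, "score": float(sc)}
        for frag, lab, sc in zip(pool, labels, scores)
    ]


def make_cohort(cfg: PipelineConfig) -> list[EEGRecord]:
    return simulate_cohort(int(cfg["sim.n_subjects"]), cfg.sim_config())


def report_to_json(results: dict) -> str:
    clean = {k: v for k, v in results.items() if not k.startswith("_")}
    return json.dumps(clean, indent=2, sort_keys=True)
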