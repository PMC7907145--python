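"""End-to-end pipeline: cohort -> prep -> features -> images -> CV / stats.

Every stage logs record counts in/out; the results bundle is returned as a
plain dict and also written under ``output_dir`` as JSON plus a delimited
comparison table (method x feature accuracy rows).
"""

from __future__ import annotations

import csv
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from eegtopo.classify.baselines import baseline_fit
from eegtopo.classify.crossval import crossvalidate, kfold_indices
from eegtopo.classify.network import LstmSpec, build_model
from eegtopo.cli_io.config import PipelineConfig
from eegtopo.cli_io.io import read_cohort, write_cohort
from eegtopo.features import feature_frames
from eegtopo.groupstats import t_map
from eegtopo.signal_prep import remove_channels, segment_trials, sliding_windows
from eegtopo.synth_eeg import SynthConfig, generate_cohort
from eegtopo.topomap import IdentityNormalizer, Montage, default_montage, make_sequence

__all__ = ["run_pipeline", "extract_dataset", "load_or_simulate"]

log = logging.getLogger("eegtopo.pipeline")


def load_or_simulate(cfg: PipelineConfig):
    if cfg.input_dir is not None:
        recordings = read_cohort(cfg.input_dir)
        log.info("loaded %d recordings from %s", len(recordings), cfg.input_dir)
    else:
        synth_kwargs = dict(cfg.synth)
        synth_kwargs.setdefault("n_subjects_per_class", 5)
        synth_kwargs.setdefault("seed", cfg.seed)
        if "channel_labels" in synth_kwargs:
            synth_kwargs["channel_labels"] = tuple(synth_kwargs["channel_labels"])
        recordings = generate_cohort(SynthConfig(**synth_kwargs))
        log.info("simulated %d recordings", len(recordings))
    return recordings


def _resolve_montage(cfg: PipelineConfig, channel_labels: List[str]) -> Montage:
    from eegtopo.topomap import aep_project

    if cfg.montage_file is not None:
        montage = aep_project(Montage.from_json(cfg.montage_file)).subset(channel_labels)
        return aep_project(montage)
    return default_montage(tuple(channel_labels))


def extract_dataset(cfg: PipelineConfig, recordings):
    """Per-trial raw image sequences, labels, subject ids, and feature vectors.

    Returns (images (n, T, g, g, 3) unnormalized, labels, subject_ids,
    flat feature matrix for the baselines, montage).
    """
    recordings = [remove_channels(r, cfg.drop_channels) for r in recordings]
    montage = _resolve_montage(cfg, recordings[0].channel_labels)
    identity = IdentityNormalizer()
    images, labels, subjects, flats = [], [], [], []
    t0 = time.time()
    n_trials = 0
    for rec in recordings:
        if rec.channel_labels != montage.labels:
            montage = _resolve_montage(cfg, rec.channel_labels)
        trials = segment_trials(rec, cfg.trial_length, cfg.max_trials)
        n_trials += len(trials)
        for trial in trials:
            windows = sliding_windows(trial, cfg.window, cfg.step)
            frames = feature_frames(
                windows, cfg.bands, cfg.feature, cfg.fuzzyen, fs=rec.sampling_rate
            )
            seq = make_sequence(
                frames,
                montage,
                identity,
                trial_ref=f"{rec.subject_id}/t{trial.trial_index}",
                label=rec.label,
            )
            images.append(seq.as_array())
            labels.append(rec.label)
            subjects.append(rec.subject_id)
            flats.append(np.concatenate([f.values.ravel() for f in frames]))
    log.info(
        "extracted %d trials x %d frames from %d recordings in %.1fs",
        n_trials,
        images[0].shape[0] if images else 0,
        len(recordings),
        time.time() - t0,
    )
    return (
        np.stack(images).astype(np.float32),
        np.asarray(labels),
        np.asarray(subjects),
        np.vstack(flats),
        montage,
    )


def _subject_folds(subjects: np.ndarray, k: int, rng: np.random.Generator) -> List[np.ndarray]:
    unique = np.array(sorted(set(subjects.tolist())))
    groups = kfold_indices(len(unique), k, rng)
    return [
        np.sort(np.nonzero(np.isin(subjects, unique[g]))[0]) for g in groups
    ]


def _stat_inputs(flats: np.ndarray, labels: np.ndarray, subjects: np.ndarray, n_channels: int):
    """Subject-mean per-channel features (averaged over windows and bands)."""
    per_trial = flats.reshape(len(flats), -1, n_channels, 3).mean(axis=(1, 3))
    rows_a, rows_b = [], []
    for subject in sorted(set(subjects.tolist())):
        mask = subjects == subject
        mean = per_trial[mask].mean(axis=0)
        (rows_b if labels[mask][0] == 1 else rows_a).append(mean)
    return np.vstack(rows_a), np.vstack(rows_b)


def run_pipeline(cfg: PipelineConfig) -> Dict:
    """Run the configured stages; returns (and writes) the results bundle."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recordings = load_or_simulate(cfg)
    if cfg.input_dir is None:
        write_cohort(recordings, out_dir / "cohort")
    images, labels, subjects, flats, montage = extract_dataset(cfg, recordings)
    results: Dict = {
        "n_trials": int(len(images)),
        "n_channels": int(montage.n_channels),
        "feature": cfg.feature,
        "model": cfg.model,
    }

    folds = None
    if cfg.cv_level == "subject":
        folds = _subject_folds(subjects, cfg.cv_k, np.random.default_rng(cfg.seed))

    if cfg.model != "none":
        n_frames = images.shape[1]
        def factory(seed: int):
            return build_model(
                cfg.model,
                LstmSpec(cfg.lstm_hidden),
                n_frames=n_frames,
                image_size=images.shape[2],
                dropout=cfg.train.dropout,
                seed=seed,
            )

        fold_results, summary = crossvalidate(
            images,
            labels,
            factory,
            cfg.train,
            k=cfg.cv_k,
            seed=cfg.seed,
            train_subsample=cfg.train_subsample,
            folds=folds,
        )
        results["folds"] = [f.to_dict() for f in fold_results]
        results["summary"] = summary
        log.info("CV mean test accuracy: %.4f", summary["mean_test_accuracy"])

    if cfg.baselines:
        results["baselines"] = {}
        for method in cfg.baselines:
            _, acc = baseline_fit(flats, labels, method, seed=cfg.seed, cv=cfg.cv_k)
            results["baselines"][method] = acc
            log.info("baseline %s accuracy: %.4f", method, acc)

    group_a, group_b = _stat_inputs(flats, labels, subjects, montage.n_channels)
    if len(group_a) >= 2 and len(group_b) >= 2:
        stat = t_map(group_a, group_b, cfg.stats_alpha, channel_labels=montage.labels)
        results["statmap"] = stat.to_dict()

    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(results, fh, indent=1)
    _write_comparison(results, cfg, out_dir / "comparison.tsv")
    return results


def _write_comparison(results: Dict, cfg: PipelineConfig, path: Path) -> None:
    """Delimited method x feature accuracy table (one feature per run)."""
    rows = []
    for method, acc in results.get("baselines", {}).items():
        rows.append((method, cfg.feature, "", f"{100 * acc:.2f}"))
    if "summary" in results:
        rows.append(
            (
                f"cnn-lstm {cfg.model}",
                cfg.feature,
                f"{100 * results['summary']['mean_val_accuracy']:.2f}",
                f"{100 * results['summary']['mean_test_accuracy']:.2f}",
            )
        )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["method", "feature", "validation_accuracy_pct", "test_accuracy_pct"])
        writer.writerows(rows)
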