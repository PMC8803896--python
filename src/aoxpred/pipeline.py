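"""End-to-end pipeline orchestration.

Stage order (the default): sequence hygiene -> random undersampling of
the majority class -> feature encoding (188D + CKSAAP, default gap 3)
-> MRMD ranking and prefix selection -> random-forest training and
pooled stratified CV.  A flag moves selection before sampling for
ablation.  Every stage's seed and configuration land in a config
snapshot so a run is fully reproducible from its artifacts directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

from . import classify_eval, mrmd
from .feature_matrix import FeatureMatrix
from .features_cksaap import encode_dataset, encode_sequences
from .sampling import SamplingConfig, random_undersample
from .sequence_io import LabeledDataset, read_fasta, validate_sequence

logger = logging.getLogger("aoxpred")


@dataclass(frozen=True)
class FeatureSpec:
    """Which encoders to run: the 188D block and/or CKSAAP gaps."""

    include_188d: bool = True
    ks: tuple[int, ...] = (3,)
    transition_denominator: str = "L"

    @classmethod
    def parse(cls, text: str) -> "FeatureSpec":
        """Parse '188d', 'cksaap:K', or 'combined:K[,K...]' ('g' = 'k')."""
        text = text.strip().lower()
        if text == "188d":
            return cls(True, ())
        kind, _, arg = text.partition(":")
        if kind in ("cksaap", "combined"):
            if not arg:
                raise ValueError(f"{kind} needs a gap list, e.g. {kind}:3")
            ks = tuple(sorted(int(t) for t in arg.split(",")))
            return cls(kind == "combined", ks)
        raise ValueError(f"unknown feature spec {text!r}")

    @property
    def min_length(self) -> int:
        """Shortest sequence every selected encoder accepts."""
        return max(self.ks) + 2 if self.ks else 1

    def label(self) -> str:
        if not self.ks:
            return "188d"
        kind = "combined" if self.include_188d else "cksaap"
        return f"{kind}:{','.join(map(str, self.ks))}"


@dataclass
class PipelineConfig:
    """Defaults follow the pipeline's chosen configuration:
    188D + CKSAAP(k=3), 1:1 random undersampling, 5-fold CV."""

    features: str = "combined:3"
    transition_denominator: str = "L"
    mrmd_method: str = "mean"
    mrmd_step: int | None = None
    select: bool = True
    sampling_ratio: float = 1.0
    n_trees: int = 100
    folds: int = 5
    threshold: float = 0.5
    seed: int = 0
    sample_before_select: bool = True  # False = ablation order

    def feature_spec(self) -> FeatureSpec:
        spec = FeatureSpec.parse(self.features)
        return FeatureSpec(spec.include_188d, spec.ks, self.transition_denominator)


def clean_dataset(data: LabeledDataset, min_length: int) -> LabeledDataset:
    """Drop sequences failing validation (nonstandard residues / too short)."""
    keep = []
    for i, seq in enumerate(data.sequences):
        verdict = validate_sequence(seq, min_length)
        if verdict:
            keep.append(i)
        else:
            logger.warning("excluding %s: %s", seq.id, verdict.reason)
    if len(keep) < len(data):
        logger.info("hygiene: kept %d of %d sequences", len(keep), len(data))
    return data.subset(keep)


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                logger.info("stage %s: done in %.2fs", stage, dt)
            else:
                logger.error("stage %s: FAILED after %.2fs", stage, dt)
            return False

    return _Timer()


def run_pipeline(
    config: PipelineConfig,
    positive_fasta: str | Path,
    negative_fasta: str | Path,
    out_dir: str | Path,
) -> dict[str, Any]:
    """Run hygiene -> undersample -> encode -> select -> train/CV.

    Writes features.csv, ranking.csv, selection.json, model.joblib,
    metrics.json, and a config.json snapshot to out_dir; returns the
    metrics report dict plus artifact paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fspec = config.feature_spec()

    with _timed("load"):
        data = LabeledDataset.from_fasta_pair(positive_fasta, negative_fasta)
        data = clean_dataset(data, fspec.min_length)

    if config.sample_before_select:
        with _timed("undersample"):
            data = random_undersample(
                data, SamplingConfig(config.sampling_ratio, config.seed)
            )

    with _timed("encode"):
        matrix = encode_dataset(
            data,
            ks=fspec.ks,
            transition_denominator=fspec.transition_denominator,  # type: ignore[arg-type]
            include_188d=fspec.include_188d,
        )
        matrix.to_csv(out_dir / "features.csv")

    selection_info: dict[str, Any] | None = None
    if config.select:
        with _timed("select"):
            ranking = mrmd.rank_features(matrix, config.mrmd_method)  # type: ignore[arg-type]
            # The selection CV uses its own fold seed so the metrics
            # reported below are not computed on the folds that chose
            # the subset (reduces optimistic selection bias).
            selection = mrmd.select_subset(
                ranking,
                matrix,
                folds=config.folds,
                seed=config.seed + 1,
                step=config.mrmd_step,
                n_trees=config.n_trees,
            )
            ranking.to_csv(out_dir / "ranking.csv")
            selection_info = {
                "distance_method": config.mrmd_method,
                "sizes": selection.sizes,
                "accuracies": selection.accuracies,
                "chosen_size": selection.chosen_size,
                "chosen_features": selection.chosen_features,
                "seed": config.seed + 1,
            }
            (out_dir / "selection.json").write_text(
                json.dumps(selection_info, indent=2) + "\n"
            )
            matrix = matrix.subset_features(selection.chosen_features)

    if not config.sample_before_select:
        with _timed("undersample"):
            matrix = random_undersample(
                matrix, SamplingConfig(config.sampling_ratio, config.seed)
            )

    with _timed("train"):
        provenance = {
            "features": fspec.label(),
            "transition_denominator": fspec.transition_denominator,
            "selected_features": None
            if selection_info is None
            else selection_info["chosen_features"],
            "sampling_ratio": config.sampling_ratio,
            "seed": config.seed,
        }
        model = classify_eval.train(
            matrix,
            n_trees=config.n_trees,
            seed=config.seed,
            threshold=config.threshold,
            provenance=provenance,
        )
        model.save(out_dir / "model.joblib")

    with _timed("cross-validate"):
        report = classify_eval.cross_validate(
            matrix,
            folds=config.folds,
            n_trees=config.n_trees,
            seed=config.seed,
            threshold=config.threshold,
        )
        report.to_json(out_dir / "metrics.json", config=asdict(config))

    (out_dir / "config.json").write_text(json.dumps(asdict(config), indent=2) + "\n")

    return {
        "metrics": report.to_dict(),
        "selection": selection_info,
        "artifacts": {
            name: str(out_dir / fname)
            for name, fname in [
                ("features", "features.csv"),
                ("ranking", "ranking.csv"),
                ("selection", "selection.json"),
                ("model", "model.joblib"),
                ("metrics", "metrics.json"),
                ("config", "config.json"),
            ]
            if (out_dir / fname).exists()
        },
    }


def predict_fasta(
    model: classify_eval.TrainedModel, fasta: str | Path
):
    """Score a screening FASTA with a trained model (ranked report).

    Sequences are encoded with the model's stored feature configuration
    and restricted to its selected feature subset.
    """
    fspec = FeatureSpec.parse(model.provenance.get("features", "combined:3"))
    fspec = FeatureSpec(
        fspec.include_188d,
        fspec.ks,
        model.provenance.get("transition_denominator", "L"),
    )
    seqs = read_fasta(fasta)
    cleaned = []
    for s in seqs:
        verdict = validate_sequence(s, fspec.min_length)
        if verdict:
            cleaned.append(s)
        else:
            logger.warning("excluding %s: %s", s.id, verdict.reason)
    matrix = encode_sequences(
        cleaned,
        ks=fspec.ks,
        transition_denominator=fspec.transition_denominator,  # type: ignore[arg-type]
        include_188d=fspec.include_188d,
    )
    if model.provenance.get("selected_features"):
        matrix = matrix.subset_features(model.provenance["selected_features"])
    return classify_eval.predict_score(model, matrix)
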