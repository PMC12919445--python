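"""Run configuration schema, validation, and stage dispatch.

A single YAML file (with CLI overrides) drives every stage. Desk-scale
schedules are the default; ``preset: paper`` switches to the full published
schedule (pretraining 300 epochs / warm-up 10 / batch 96; fine-tuning 400 /
100 / 64), which is intended for GPU-scale hardware and not for the test
suite. Every run writes a manifest (config snapshot, content hashes of
inputs, seeds, metrics) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "load_config", "run"]


class ConfigError(ValueError):
    pass


class OptimizerConfig(BaseModel):
    lr: float
    weight_decay: float = 0.05


class ScheduleConfig(BaseModel):
    epochs: int
    warmup_epochs: int
    batch_size: int


class ModelConfig(BaseModel):
    d_model: int = 128
    n_heads: int = 4
    n_blocks: int = 4
    rope_base: float = 2048.0
    dropout: float = 0.1
    mlp_ratio: int = 4
    n_decoder_blocks: int = 1
    site_hidden: int = 256
    d_atom: int = 64
    max_residues: int = 2048
    use_plm: bool = False
    plm_dim_antigen: int = 480
    plm_dim_antibody: int = 512


class MaskingConfig(BaseModel):
    mask_fraction: float = 0.5
    zero_fill_prob: float = 0.2
    random_fill_prob: float = 0.8


class AugmentConfig(BaseModel):
    enabled: bool = True
    coord_noise_sigma: float = 0.1
    normal_noise_sigma: float = 0.05
    rotate: bool = True
    residue_feature_noise_sigma: float = 0.02


class SynthConfig(BaseModel):
    n_complexes: int = 30
    antigen_residues: tuple[int, int] = (40, 70)
    antibody_residues: tuple[int, int] = (25, 45)
    atoms_per_residue: tuple[int, int] = (4, 14)
    contact_fraction: float = 0.12
    val_fraction: float = 0.15
    test_fraction: float = 0.15


class LossConfig(BaseModel):
    lambda_aa: float = 1.0
    lambda_sol: float = 1.0
    lambda_pssm: float = 1.0
    label_smoothing: float = 0.1


_DESK = {"pretrain": ScheduleConfig(epochs=20, warmup_epochs=2, batch_size=4),
         "finetune": ScheduleConfig(epochs=40, warmup_epochs=10, batch_size=4)}
_PAPER = {"pretrain": ScheduleConfig(epochs=300, warmup_epochs=10, batch_size=96),
          "finetune": ScheduleConfig(epochs=400, warmup_epochs=100, batch_size=64)}


class RunConfig(BaseModel):
    stage: Literal["preprocess", "synth", "pretrain", "finetune", "predict",
                   "evaluate"]
    preset: Literal["desk", "paper"] = "desk"
    seed: int = 0
    paths: dict[str, str] = Field(default_factory=dict)
    optimizer: OptimizerConfig = Field(
        default_factory=lambda: OptimizerConfig(lr=1e-4))
    pretrain_schedule: ScheduleConfig | None = None
    finetune_schedule: ScheduleConfig | None = None
    model: ModelConfig = Field(default_factory=ModelConfig)
    masking: MaskingConfig = Field(default_factory=MaskingConfig)
    augmentation: AugmentConfig = Field(default_factory=AugmentConfig)
    synth: SynthConfig = Field(default_factory=SynthConfig)
    loss: LossConfig = Field(default_factory=LossConfig)
    threshold: float = 0.5
    antigen_chains: list[str] = Field(default_factory=lambda: ["A"])
    antibody_chains: list[str] = Field(default_factory=lambda: ["H"])

    def schedule(self, stage: str) -> ScheduleConfig:
        explicit = getattr(self, f"{stage}_schedule")
        if explicit is not None:
            return explicit
        return (_PAPER if self.preset == "paper" else _DESK)[stage]


def _format_validation_error(err: ValidationError) -> str:
    lines = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"])
        lines.append(f"{loc}: {e['msg']}")
    return "invalid configuration: " + "; ".join(lines)


def load_config(source: str | Path | dict, overrides: dict | None = None
                ) -> RunConfig:
    """Load and validate a config from YAML or a dict, applying dotted-key
    overrides (e.g. ``{"optimizer.lr": 3e-4}``)."""
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text()) or {}
    else:
        data = dict(source)
    for key, value in (overrides or {}).items():
        node = data
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    try:
        return RunConfig(**data)
    except ValidationError as err:
        raise ConfigError(_format_validation_error(err)) from None


# -------------------------------------------------------------------- dispatch

def _hash_path(path: Path) -> str:
    h = hashlib.sha256()
    if path.is_file():
        h.update(path.read_bytes())
    elif path.is_dir():
        for f in sorted(path.rglob("*")):
            if f.is_file():
                h.update(f.name.encode())
                h.update(f.read_bytes())
    return h.hexdigest()[:16]


def _write_manifest(outdir: Path, config: RunConfig, metrics: dict) -> None:
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "inputs": {name: _hash_path(Path(p)) for name, p in config.paths.items()
                   if Path(p).exists()},
        "seed": config.seed,
        "metrics": metrics,
    }
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))


def _model_configs(cfg: RunConfig):
    from .encoder import EncoderConfig
    from .finetune import DecoderConfig
    from .rhem import RhemConfig

    rhem = RhemConfig(atom_mlp_widths=(11, 32, cfg.model.d_atom),
                      d_model=cfg.model.d_model, dropout=cfg.model.dropout,
                      max_residues=cfg.model.max_residues,
                      use_plm=cfg.model.use_plm,
                      plm_dim=cfg.model.plm_dim_antigen)
    enc = EncoderConfig(n_blocks=cfg.model.n_blocks, d_model=cfg.model.d_model,
                        n_heads=cfg.model.n_heads, rope_base=cfg.model.rope_base,
                        mlp_ratio=cfg.model.mlp_ratio, dropout=cfg.model.dropout)
    dec = DecoderConfig(n_heads=cfg.model.n_heads, d_model=cfg.model.d_model,
                        dropout=cfg.model.dropout,
                        n_decoder_blocks=cfg.model.n_decoder_blocks,
                        mlp_ratio=cfg.model.mlp_ratio,
                        site_hidden=cfg.model.site_hidden)
    return rhem, enc, dec


def _augmentation(cfg: RunConfig):
    from .augmentation import AugmentationConfig

    a = cfg.augmentation
    return AugmentationConfig(coord_noise_sigma=a.coord_noise_sigma,
                              normal_noise_sigma=a.normal_noise_sigma,
                              rotate=a.rotate,
                              residue_feature_noise_sigma=a.residue_feature_noise_sigma)


def _run_synth(cfg: RunConfig) -> dict:
    from .dataset import save_dataset
    from .synthetic import SyntheticSpec, generate_dataset

    s = cfg.synth
    spec = SyntheticSpec(n_complexes=s.n_complexes,
                         antigen_residues=tuple(s.antigen_residues),
                         antibody_residues=tuple(s.antibody_residues),
                         atoms_per_residue=tuple(s.atoms_per_residue),
                         contact_fraction=s.contact_fraction,
                         rng_seed=cfg.seed)
    samples = generate_dataset(spec)
    n = len(samples)
    n_val = max(1, int(round(s.val_fraction * n)))
    n_test = max(1, int(round(s.test_fraction * n)))
    ids = [x.complex_id for x in samples]
    splits = {"train": ids[:n - n_val - n_test],
              "val": ids[n - n_val - n_test:n - n_test],
              "test": ids[n - n_test:]}
    outdir = Path(cfg.paths.get("out", "synth_dataset"))
    save_dataset(outdir, samples, splits,
                 metadata={"pssm": "substitute (BLOSUM62 profile)",
                           "seed": cfg.seed})
    return {"n_complexes": n,
            "epitope_fraction": float(np.mean(
                [x.labels.labels.mean() for x in samples]))}


def _run_preprocess(cfg: RunConfig) -> dict:
    from .dataset import build_sample, save_sample
    from .features import FeatureOptions
    from .structure_io import parse_pdb

    pdb = Path(cfg.paths["pdb"])
    complex = parse_pdb(pdb, cfg.antigen_chains, cfg.antibody_chains)
    options = FeatureOptions(
        antigen_pssm=cfg.paths.get("antigen_pssm"),
        antibody_pssm=cfg.paths.get("antibody_pssm"),
        antigen_plm=cfg.paths.get("antigen_plm"),
        antibody_plm=cfg.paths.get("antibody_plm"))
    sample = build_sample(complex, options)
    outdir = Path(cfg.paths.get("out", complex.complex_id))
    save_sample(outdir, sample,
                metadata={"pssm": ("psiblast" if options.antigen_pssm
                                   else "substitute (BLOSUM62 profile)")})
    return {"n_antigen_residues": sample.n_antigen_residues,
            "n_epitope_residues": int(sample.labels.labels.sum())}


def _run_pretrain(cfg: RunConfig) -> dict:
    from .checkpoint import save_checkpoint
    from .dataset import load_dataset
    from .pretrain import (MaskingSpec, PretrainConfig, PretrainLossWeights,
                           PretrainModel, run_pretraining)

    data = load_dataset(cfg.paths["dataset"], split="train")
    sched = cfg.schedule("pretrain")
    rhem_cfg, enc_cfg, _ = _model_configs(cfg)
    model = PretrainModel(rhem_cfg, enc_cfg, np.random.default_rng(cfg.seed),
                          head_dropout=cfg.model.dropout)
    pcfg = PretrainConfig(
        epochs=sched.epochs, warmup_epochs=sched.warmup_epochs,
        batch_size=sched.batch_size, lr=cfg.optimizer.lr,
        weight_decay=cfg.optimizer.weight_decay,
        masking=MaskingSpec(cfg.masking.mask_fraction,
                            cfg.masking.zero_fill_prob,
                            cfg.masking.random_fill_prob),
        loss_weights=PretrainLossWeights(cfg.loss.lambda_aa, cfg.loss.lambda_sol,
                                         cfg.loss.lambda_pssm),
        augmentation=_augmentation(cfg), augment=cfg.augmentation.enabled,
        seed=cfg.seed)
    log: list[dict] = []
    model = run_pretraining(data, pcfg, model=model, log=log)
    outdir = Path(cfg.paths.get("out", "pretrain_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    save_checkpoint(outdir / "pretrain.npz", model, meta={"stage": "pretrain"})
    with (outdir / "loss_log.jsonl").open("w") as fh:
        for row in log:
            fh.write(json.dumps(row) + "\n")
    return {"final_loss": log[-1]["loss"] if log else None,
            "n_steps": len(log)}


def _run_finetune(cfg: RunConfig) -> dict:
    from .checkpoint import load_checkpoint, save_checkpoint
    from .dataset import load_dataset
    from .evaluation import build_report, optimize_threshold
    from .finetune import FinetuneConfig, predict, run_finetuning
    from .pretrain import chain_inputs_from_features

    train = load_dataset(cfg.paths["dataset"], split="train")
    try:
        val = load_dataset(cfg.paths["dataset"], split="val")
    except KeyError:
        val = []
    sched = cfg.schedule("finetune")
    rhem_cfg, enc_cfg, dec_cfg = _model_configs(cfg)
    pretrained = None
    if "pretrain_checkpoint" in cfg.paths:
        pretrained, _ = load_checkpoint(cfg.paths["pretrain_checkpoint"])
    fcfg = FinetuneConfig(
        epochs=sched.epochs, warmup_epochs=sched.warmup_epochs,
        batch_size=sched.batch_size, lr=cfg.optimizer.lr,
        weight_decay=cfg.optimizer.weight_decay,
        label_smoothing=cfg.loss.label_smoothing,
        augmentation=_augmentation(cfg), augment=cfg.augmentation.enabled,
        from_scratch=pretrained is None, seed=cfg.seed)
    model = run_finetuning(train, pretrained, fcfg, rhem_cfg, enc_cfg, dec_cfg)
    threshold = cfg.threshold
    metrics: dict = {}
    if val:
        probs, labels = [], []
        for sample in val:
            ag = chain_inputs_from_features(sample.antigen_atoms,
                                            sample.antigen_starts,
                                            sample.antigen_residues,
                                            sample.antigen_plm)
            ab = chain_inputs_from_features(sample.antibody_atoms,
                                            sample.antibody_starts,
                                            sample.antibody_residues,
                                            sample.antibody_plm)
            probs.append(predict(ag, ab, model).probabilities)
            labels.append(sample.labels.labels)
        threshold = optimize_threshold(np.concatenate(probs),
                                       np.concatenate(labels))
        report = build_report(probs, labels, threshold,
                              [s.complex_id for s in val])
        metrics["validation"] = {k: v for k, v in report.to_dict().items()
                                 if k != "per_complex"}
    outdir = Path(cfg.paths.get("out", "finetune_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    save_checkpoint(outdir / "finetune.npz", model,
                    meta={"stage": "finetune", "threshold": threshold})
    metrics["threshold"] = threshold
    return metrics


def _build_finetune_model(cfg: RunConfig, state: dict):
    from .finetune import EpitopeModel

    rhem_cfg, enc_cfg, dec_cfg = _model_configs(cfg)
    model = EpitopeModel(rhem_cfg, enc_cfg, dec_cfg,
                         np.random.default_rng(cfg.seed))
    model.load_state_dict(state)
    return model


def _run_predict(cfg: RunConfig) -> dict:
    import pandas as pd

    from .checkpoint import load_checkpoint
    from .dataset import build_sample
    from .features import FeatureOptions
    from .finetune import predict
    from .pretrain import chain_inputs_from_features
    from .structure_io import parse_pdb

    state, meta = load_checkpoint(cfg.paths["checkpoint"])
    model = _build_finetune_model(cfg, state)
    complex = parse_pdb(cfg.paths["pdb"], cfg.antigen_chains, cfg.antibody_chains)
    options = FeatureOptions(antigen_plm=cfg.paths.get("antigen_plm"),
                             antibody_plm=cfg.paths.get("antibody_plm"))
    sample = build_sample(complex, options)
    ag = chain_inputs_from_features(sample.antigen_atoms, sample.antigen_starts,
                                    sample.antigen_residues, sample.antigen_plm)
    ab = chain_inputs_from_features(sample.antibody_atoms, sample.antibody_starts,
                                    sample.antibody_residues, sample.antibody_plm)
    threshold = meta.get("threshold", cfg.threshold)
    pred = predict(ag, ab, model, threshold)
    outdir = Path(cfg.paths.get("out", "prediction"))
    outdir.mkdir(parents=True, exist_ok=True)
    chain = complex.antigen
    table = pd.DataFrame({
        "chain_id": chain.chain_ids,
        "residue_index": np.arange(chain.n_residues),
        "residue_name": chain.residue_names,
        "probability": pred.probabilities,
        "call": pred.calls,
    })
    table.to_csv(outdir / "predictions.tsv", sep="\t", index=False,
                 float_format="%.4f")
    if pred.attention is not None:
        n_heads = pred.attention.shape[0]
        with (outdir / "attention.tsv").open("w") as fh:
            fh.write(f"# heads={n_heads} R_A={pred.attention.shape[1]} "
                     f"R_B={pred.attention.shape[2]}\n")
            np.savetxt(fh, pred.attention.reshape(-1, pred.attention.shape[2]),
                       fmt="%.5g", delimiter="\t")
    return {"n_predicted": int(len(pred.probabilities)),
            "n_called": int(pred.calls.sum()), "threshold": threshold}


def _run_evaluate(cfg: RunConfig) -> dict:
    from .evaluation import build_report, optimize_threshold

    preds = np.loadtxt(cfg.paths["pred"], ndmin=1)
    labels = np.loadtxt(cfg.paths["labels"], dtype=np.int64, ndmin=1)
    if "val_pred" in cfg.paths:
        val_p = np.loadtxt(cfg.paths["val_pred"], ndmin=1)
        val_l = np.loadtxt(cfg.paths["val_labels"], dtype=np.int64, ndmin=1)
        threshold = optimize_threshold(val_p, val_l)
    else:
        threshold = cfg.threshold
    report = build_report([preds], [labels], threshold)
    outdir = Path(cfg.paths.get("out", "evaluation"))
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
    return {k: v for k, v in report.to_dict().items() if k != "per_complex"}


_STAGES = {"synth": _run_synth, "preprocess": _run_preprocess,
           "pretrain": _run_pretrain, "finetune": _run_finetune,
           "predict": _run_predict, "evaluate": _run_evaluate}


def run(config: RunConfig) -> dict:
    """Dispatch a validated config to its stage; returns the metrics dict
    and writes a manifest into the stage's output directory."""
    metrics = _STAGES[config.stage](config)
    outdir = Path(config.paths.get("out", f"{config.stage}_run"))
    _write_manifest(outdir, config, metrics)
    return metrics
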