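"""Configuration, cross-validation folds, and run orchestration.

A run is driven by one YAML config validated against a flat schema (unknown
keys rejected before any compute).  ``run_train`` trains one model per
requested fold on a fixture-style dataset directory, writing checkpoints,
JSON-lines loss logs and a manifest carrying the config hash and seed;
``run_generate`` synthesizes one image per supplied condition vector from a
checkpoint; ``run_evaluate`` scores generated against real images.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .denoiser import ConditionalDenoiser, DenoiserConfig
from .model import ConditionalDiffusionModel
from .schedule import make_schedule
from . import metrics as _metrics

__all__ = ["RunConfig", "FoldPlan", "make_folds", "run_train",
           "run_generate", "run_evaluate"]


class ConfigError(ValueError):
    pass


_SCHEMA = {
    # diffusion
    "diffusion.T": int,
    "diffusion.beta_start": float,
    "diffusion.beta_end": float,
    "diffusion.sigma_mode": str,
    "diffusion.schedule": str,
    # denoiser
    "denoiser.base_channels": int,
    "denoiser.depth": int,
    "denoiser.time_embed_dim": int,
    # conditioning
    "cond.tokens": int,
    "cond.heads": int,
    "cond.gate_init": float,
    "cond.extension": str,
    # omics
    "omics.fraction": float,
    "omics.rank": int,
    "omics.seed": int,
    # training
    "train.epochs": int,
    "train.batch_size": int,
    "train.lr": float,
    "train.folds": int,
    "train.max_folds": int,
    # run
    "run.seed": int,
    "run.out_dir": str,
}

_DEFAULTS = {
    "diffusion.T": 50,
    "diffusion.beta_start": 1e-4,
    "diffusion.beta_end": 0.02,
    "diffusion.sigma_mode": "beta",
    "diffusion.schedule": "linear",
    "denoiser.base_channels": 16,
    "denoiser.depth": 2,
    "denoiser.time_embed_dim": 32,
    "cond.tokens": 4,
    "cond.heads": 1,
    "cond.gate_init": 0.0,
    "cond.extension": "dense",
    "omics.fraction": 0.10,
    "omics.rank": 17,
    "omics.seed": 0,
    "train.epochs": 2,
    "train.batch_size": 16,
    "train.lr": 2e-3,
    "train.folds": 15,
    "train.max_folds": 1,
    "run.seed": 0,
    "run.out_dir": "runs/default",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated flat key/value run configuration."""

    values: dict

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(_DEFAULTS)
        for key, val in raw.items():
            want = _SCHEMA[key]
            try:
                merged[key] = want(val)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"bad value for {key}: {val!r}") from exc
        return cls(merged)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def __getitem__(self, key):
        return self.values[key]

    @property
    def hash(self) -> str:
        blob = json.dumps(self.values, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class FoldPlan:
    """k disjoint test folds covering all ids; sizes differ by at most 1."""

    k: int
    folds: tuple  # tuple of tuples of ids
    seed: int

    def train_ids(self, fold: int) -> list:
        test = set(self.folds[fold])
        return [i for f in self.folds for i in f if i not in test]

    def test_ids(self, fold: int) -> list:
        return list(self.folds[fold])


def make_folds(ids, k: int, seed: int = 0) -> FoldPlan:
    """Seeded shuffle followed by contiguous partition into k folds of size
    ceil(N/k) or floor(N/k)."""
    ids = list(ids)
    n = len(ids)
    if k > n:
        raise ConfigError(f"cannot make {k} folds from {n} ids")
    if k < 2:
        raise ConfigError("need k >= 2: a single fold leaves no training set")
    rng = np.random.default_rng(seed)
    shuffled = [ids[i] for i in rng.permutation(n)]
    parts = np.array_split(np.arange(n), k)
    return FoldPlan(
        k=k,
        folds=tuple(tuple(shuffled[i] for i in part) for part in parts),
        seed=seed,
    )


# -- dataset directory layout ---------------------------------------------


def load_dataset(data_dir) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a fixture-style dataset: ``factors.tsv`` (patients x R) and
    ``images.npy`` (N, n, n) in [0, 1], rows aligned."""
    data_dir = Path(data_dir)
    factors = pd.read_csv(data_dir / "factors.tsv", sep="\t", index_col=0)
    images = np.load(data_dir / "images.npy")
    if images.shape[0] != factors.shape[0]:
        raise ConfigError("factors.tsv and images.npy disagree on N")
    return factors, images


def _write_manifest(out_dir: Path, config: RunConfig, extra: dict) -> None:
    manifest = {"config": config.values, "config_hash": config.hash, **extra}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _build_model(images, conditions, config: RunConfig) -> ConditionalDiffusionModel:
    sch = make_schedule(
        config["diffusion.schedule"], T=config["diffusion.T"],
        beta_start=config["diffusion.beta_start"],
        beta_end=config["diffusion.beta_end"],
        sigma_mode=config["diffusion.sigma_mode"],
    )
    n = images.shape[1]
    depth = config["denoiser.depth"]
    dcfg = DenoiserConfig(
        image_size=n, cond_dim=conditions.shape[1],
        base_channels=config["denoiser.base_channels"], depth=depth,
        channel_mults=tuple(2**i for i in range(depth)),
        time_embed_dim=config["denoiser.time_embed_dim"],
        n_cond_tokens=config["cond.tokens"],
        n_heads=config["cond.heads"],
        gate_init=config["cond.gate_init"],
        extension=config["cond.extension"],
    )
    return ConditionalDiffusionModel(images, conditions, schedule=sch, config=dcfg)


def run_train(config: RunConfig, data_dir, out_dir) -> dict:
    """Cross-validated training: per-fold checkpoint + loss log + manifest.

    ``train.max_folds`` caps how many folds are actually trained (desk-scale
    runs train one fold of the full plan).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    factors, images = load_dataset(data_dir)
    plan = make_folds(list(factors.index), config["train.folds"],
                      seed=config["run.seed"] + 1)
    summary = {"folds": []}
    for fold in range(min(plan.k, config["train.max_folds"])):
        train_ids = plan.train_ids(fold)
        pos = [factors.index.get_loc(i) for i in train_ids]
        model = _build_model(images[pos], factors.to_numpy(float)[pos], config)
        log_path = out_dir / f"fold{fold}_loss.jsonl"
        with open(log_path, "w") as log:
            res = model.fit(
                epochs=config["train.epochs"],
                batch_size=config["train.batch_size"],
                lr=config["train.lr"], seed=config["run.seed"],
                callback=lambda e, l: log.write(
                    json.dumps({"epoch": e + 1, "loss": l}) + "\n"
                ),
            )
        ckpt = out_dir / f"fold{fold}_checkpoint.npz"
        res.save(ckpt)
        summary["folds"].append({
            "fold": fold,
            "n_train": len(train_ids),
            "n_test": len(plan.test_ids(fold)),
            "final_loss": float(res.loss_history[-1]),
            "checkpoint": ckpt.name,
        })
    _write_manifest(out_dir, config, {"stage": "train", **summary})
    return summary


def run_generate(config: RunConfig, checkpoint, factors_tsv, out_dir) -> Path:
    """Sample one image per condition vector in ``factors_tsv``; writes an
    images.npy stack plus per-patient PNGs and a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    checkpoint = Path(checkpoint)
    if not checkpoint.exists():
        raise FileNotFoundError(
            f"checkpoint {checkpoint} not found — run training first"
        )
    denoiser, extra = ConditionalDenoiser.load(checkpoint)
    sch_meta = extra["schedule"]
    sch = make_schedule("linear", T=sch_meta["T"],
                        beta_start=sch_meta["beta_start"],
                        beta_end=sch_meta["beta_end"],
                        sigma_mode=sch_meta["sigma_mode"])
    factors = pd.read_csv(factors_tsv, sep="\t", index_col=0)
    n = denoiser.config.image_size
    from . import diffusion
    from .image_prep import Projection2D, save_png
    from .model import _to_unit_range

    rng = np.random.default_rng(
        np.random.SeedSequence([config["run.seed"], 4])
    )
    out = diffusion.sample(
        factors.to_numpy(float), denoiser, sch, rng, (n, n),
        n_images=factors.shape[0],
    )
    imgs = _to_unit_range(out)
    np.save(out_dir / "images.npy", imgs)
    for pid, img in zip(factors.index, imgs):
        save_png(Projection2D(img, (0.0, 1.0)), out_dir / f"{pid}.png")
    _write_manifest(out_dir, config,
                    {"stage": "generate", "n_images": int(imgs.shape[0])})
    return out_dir / "images.npy"


def run_evaluate(config: RunConfig, real_npy, gen_npy, report_path,
                 extractor: str = "pixels", ssim_mode: str = "global") -> dict:
    """Score generated against real images; writes a JSON metrics report."""
    real = np.load(real_npy)
    gen = np.load(gen_npy)
    real_e = _metrics.embed_images(real, extractor)
    gen_e = _metrics.embed_images(gen, extractor)
    n_batches = max(2, min(4, gen.shape[0] // 2))
    splits = [s for s in np.array_split(np.arange(gen.shape[0]), n_batches)
              if len(s) >= 2]
    report = _metrics.MetricsReport(
        fid=_metrics.fid(real_e, gen_e),
        fid_std=(_metrics.fid_std(real_e, [
            _metrics.embed_images(gen[s], extractor) for s in splits
        ]) if len(splits) >= 2 else None),
        mse=float(np.mean([_metrics.mse(a, b) for a, b in zip(real, gen)])),
        ssim=float(np.mean([
            _metrics.ssim(a, b, L=1.0, mode=ssim_mode)
            for a, b in zip(real, gen)
        ])),
        meta={"extractor": extractor, "ssim_mode": ssim_mode,
              "config_hash": config.hash, "seed": config["run.seed"]},
    )
    payload = report.to_dict()
    Path(report_path).write_text(json.dumps(payload, indent=2))
    return payload
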