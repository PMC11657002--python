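"""End-to-end orchestration of the three training stages plus evaluation.

A run executes, under one self-describing directory:

1. data preparation (phantom generation or preprocessed slices),
2. Stage 1 — tumor-presence classifier,
3. Stage 2 — occlusion-saliency heatmaps -> localization seeds (with the
   healthy-image all-negative override),
4. Stage 3 — joint training of the superpixel generator and clusterer
   against the combined compactness + seed objective,
5. threshold selection on the validation cohort and test-set evaluation.

Every stage writes its artifacts to fixed filenames and is skipped on rerun
when those files already exist, so deleting a stage's outputs re-runs only
that stage and everything after it stays reproducible from the recorded
config and seed.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nn
from .classifier import ClassifierConfig, TrainedClassifier, predict_batch, train_classifier
from .data import MultimodalSlice, load_slices, save_slices
from .inference import predict_heatmap, select_threshold
from .losses import LossConfig, seed_loss, soft_cluster, spixel_loss
from .metrics import dice, evaluate_cohort
from .models import (
    SuperpixelClusterer,
    SuperpixelGenerator,
    count_effective_superpixels,
    load_models,
    save_models,
)
from .phantom import PhantomConfig, generate_phantom, phantom_difficulty_suite
from .rise import generate_masks, load_seed_maps, save_seed_maps, seeds_for_dataset

_SEED_MOD = 2**31


@dataclass
class SuperpixelTrainConfig:
    n_superpixels: int = 64
    base_channels: int = 16
    clusterer_backbone: str = "resnet-small"
    epochs: int = 100
    batch_size: int = 32
    lr: float = 5e-4
    lr_halve_every: int = 25
    weight_decay: float = 0.1
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    rng_seed: int = 0


@dataclass
class RiseConfig:
    n_masks: int = 4000
    cell_grid: int = 8
    keep_prob: float = 0.5
    seed_quantile: float = 0.2
    batch_size: int = 128


@dataclass
class RunConfig:
    out_dir: str = "runs/latest"
    rng_seed: int = 0
    # data: either a named phantom difficulty or a prepared slice directory
    phantom_suite: str = "easy"
    n_train: int = 256
    n_val: int = 32
    n_test: int = 64
    image_size: tuple[int, int] = (32, 32)
    prepared_data: str | None = None  # directory with train/ val/ test/
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    rise: RiseConfig = field(default_factory=RiseConfig)
    superpixel: SuperpixelTrainConfig = field(default_factory=SuperpixelTrainConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    threshold_grid_step: float = 0.1

    @classmethod
    def desk_scale(cls, out_dir: str = "runs/desk", rng_seed: int = 0) -> "RunConfig":
        """Small-backbone CPU profile used by tests and examples."""
        return cls(
            out_dir=out_dir,
            rng_seed=rng_seed,
            classifier=ClassifierConfig(backbone="vgg-small", epochs=16,
                                        lr_init=1e-3, weight_decay=0.01,
                                        rng_seed=rng_seed),
            rise=RiseConfig(n_masks=512),
            superpixel=SuperpixelTrainConfig(base_channels=8, epochs=15,
                                             lr=1e-3, weight_decay=0.01,
                                             rng_seed=rng_seed),
        )

    @classmethod
    def paper_scale(cls, out_dir: str = "runs/full", rng_seed: int = 0) -> "RunConfig":
        """Full-size profile (128×128 inputs, VGG-16/ResNet-18); GPU-recommended
        scale of compute, provided for completeness."""
        return cls(
            out_dir=out_dir,
            rng_seed=rng_seed,
            image_size=(128, 128),
            classifier=ClassifierConfig(backbone="vgg16-bn", rng_seed=rng_seed),
            rise=RiseConfig(n_masks=4000),
            superpixel=SuperpixelTrainConfig(base_channels=32,
                                             clusterer_backbone="resnet18",
                                             rng_seed=rng_seed),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["classifier"] = ClassifierConfig(**{
            **raw.get("classifier", {}),
            "adam_betas": tuple(raw.get("classifier", {}).get("adam_betas", (0.9, 0.999))),
        })
        raw["rise"] = RiseConfig(**raw.get("rise", {}))
        sp = raw.get("superpixel", {})
        sp["adam_betas"] = tuple(sp.get("adam_betas", (0.9, 0.999)))
        raw["superpixel"] = SuperpixelTrainConfig(**sp)
        raw["loss"] = LossConfig(**raw.get("loss", {}))
        raw["image_size"] = tuple(raw["image_size"])
        return cls(**raw)


def _sub_seed(base: int, offset: int) -> int:
    return int((base + offset * 9973) % _SEED_MOD)


def _log(msg: str) -> None:
    print(f"[spixseg] {msg}", file=sys.stderr, flush=True)


def prepare_phantom_cohorts(config: RunConfig) -> dict[str, list[MultimodalSlice]]:
    """Generate disjoint train/val/test phantom cohorts from the run seed."""
    suite = phantom_difficulty_suite(image_size=config.image_size)
    base = suite[config.phantom_suite]
    cohorts = {}
    for name, n, offset in (("train", config.n_train, 1),
                            ("val", config.n_val, 2),
                            ("test", config.n_test, 3)):
        cfg = PhantomConfig(**{
            **asdict(base),
            "n_images": n,
            "rng_seed": _sub_seed(config.rng_seed + base.rng_seed, offset),
        })
        cfg.image_size = tuple(cfg.image_size)
        cfg.lesion_radius_range = tuple(cfg.lesion_radius_range)
        cfg.lesion_contrast = tuple(cfg.lesion_contrast)
        cohorts[name] = generate_phantom(cfg)
    return cohorts


def train_superpixel_stage(
    train_slices: list[MultimodalSlice],
    seeds: list,
    config: SuperpixelTrainConfig | None = None,
    loss_config: LossConfig | None = None,
) -> tuple[SuperpixelGenerator, SuperpixelClusterer, pd.DataFrame]:
    """Jointly train generator and clusterer against the combined loss.

    One Adam optimizer covers the union of both networks' parameters; the
    learning rate halves every ``lr_halve_every`` epochs.  Training uses all
    images (including classifier-predicted-healthy ones, whose seeds are the
    all-negative override).
    """
    config = config or SuperpixelTrainConfig()
    loss_config = loss_config or LossConfig()
    if len(seeds) != len(train_slices):
        missing = [s.patient_id for s in train_slices[len(seeds):]] or ["<count mismatch>"]
        raise ValueError(f"missing seeds for training slices: {missing[:10]}")
    rng = np.random.default_rng(config.rng_seed)
    nn.seed(config.rng_seed)
    generator = SuperpixelGenerator(config.n_superpixels, 4, config.base_channels)
    clusterer = SuperpixelClusterer(config.n_superpixels, 4, config.clusterer_backbone)
    params = generator.parameters() + clusterer.parameters()
    opt = nn.Adam(params, lr=config.lr, betas=config.adam_betas,
                  eps=config.adam_eps, weight_decay=config.weight_decay)
    schedule = nn.StepHalving(opt, every=config.lr_halve_every)
    x_all = np.stack([s.pixels for s in train_slices])
    n = len(train_slices)
    rows = []
    for epoch in range(config.epochs):
        schedule.at_epoch(epoch)
        generator.train()
        clusterer.train()
        order = rng.permutation(n)
        tot, tot_sp, tot_seed = 0.0, 0.0, 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x = nn.Tensor(x_all[idx])
            q = generator(x)
            r = clusterer(x, q)
            l_sp = spixel_loss(x, q, loss_config.m)
            l_seed = seed_loss(soft_cluster(q, r), [seeds[i] for i in idx],
                               loss_config.eps)
            loss = l_sp + loss_config.alpha * l_seed
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"non-finite superpixel loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot += loss.item() * len(idx)
            tot_sp += l_sp.item() * len(idx)
            tot_seed += l_seed.item() * len(idx)
        rows.append({"epoch": epoch, "loss": tot / n, "spixel_loss": tot_sp / n,
                     "seed_loss": tot_seed / n, "lr": opt.lr})
        _log(f"stage3 epoch {epoch}: loss={tot / n:.4f} "
             f"(spixel={tot_sp / n:.4f}, seed={tot_seed / n:.4f})")
    generator.eval()
    clusterer.eval()
    return generator, clusterer, pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages under ``config.out_dir``; resumable per stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    (out / "versions.json").write_text(json.dumps({
        "python": sys.version.split()[0],
        "numpy": np.__version__,
    }))

    # -- data ---------------------------------------------------------------
    data_dir = out / "data"
    if config.prepared_data is not None:
        data_dir = Path(config.prepared_data)
    elif not (data_dir / "test" / "slices.npz").exists():
        _log("preparing phantom cohorts")
        cohorts = prepare_phantom_cohorts(config)
        for name, slices in cohorts.items():
            save_slices(slices, data_dir / name)
    cohorts = {name: load_slices(data_dir / name) for name in ("train", "val", "test")}

    # -- stage 1: classifier -------------------------------------------------
    clf_path = out / "classifier.npz"
    if clf_path.exists():
        clf = TrainedClassifier.load(clf_path)
    else:
        _log("stage 1: training classifier")
        cfg = config.classifier
        cfg.rng_seed = _sub_seed(config.rng_seed + cfg.rng_seed, 11)
        clf = train_classifier(cohorts["train"], cohorts["val"], cfg)
        clf.save(clf_path)
        pd.DataFrame(clf.history).to_csv(out / "classifier_history.csv", index=False)

    # -- stage 2: saliency seeds --------------------------------------------
    seeds_path = out / "seeds.npz"
    if seeds_path.exists():
        seeds = load_seed_maps(seeds_path)
    else:
        _log("stage 2: generating occlusion masks and seeds")
        masks = generate_masks(
            K=config.rise.n_masks, cell_grid=config.rise.cell_grid,
            keep_prob=config.rise.keep_prob,
            image_shape=tuple(config.image_size),
            rng_seed=_sub_seed(config.rng_seed, 23),
        )
        seeds = seeds_for_dataset(clf, cohorts["train"], masks,
                                  quantile=config.rise.seed_quantile,
                                  batch_size=config.rise.batch_size)
        save_seed_maps(seeds, seeds_path)

    # -- stage 3: superpixel models ------------------------------------------
    models_path = out / "superpixel_models.npz"
    if models_path.exists():
        generator, clusterer = load_models(
            models_path, base_channels=config.superpixel.base_channels,
            backbone=config.superpixel.clusterer_backbone,
        )
    else:
        _log("stage 3: joint superpixel training")
        sp_cfg = config.superpixel
        sp_cfg.rng_seed = _sub_seed(config.rng_seed + sp_cfg.rng_seed, 31)
        generator, clusterer, history = train_superpixel_stage(
            cohorts["train"], seeds, sp_cfg, config.loss
        )
        save_models(generator, clusterer, models_path)
        history.to_csv(out / "superpixel_history.csv", index=False)

    # -- threshold selection --------------------------------------------------
    thr_path = out / "threshold.json"
    if thr_path.exists():
        threshold = json.loads(thr_path.read_text())["threshold"]
    else:
        _log("selecting threshold on validation cohort")
        val_heat = [predict_heatmap(s, generator, clusterer) for s in cohorts["val"]]
        val_masks = [s.reference_mask for s in cohorts["val"]]
        threshold = select_threshold(val_heat, val_masks,
                                     grid_step=config.threshold_grid_step)
        thr_path.write_text(json.dumps({"threshold": threshold}))

    # -- evaluation ------------------------------------------------------------
    metrics_path = out / "metrics.csv"
    if not metrics_path.exists():
        _log("evaluating on test cohort")
        test = cohorts["test"]
        probs = predict_batch(clf, test)
        predicted = (probs >= clf.config.decision_threshold).astype(int)
        segs, effective = [], []
        for s, gate in zip(test, predicted):
            q = generator.associations(s)
            effective.append(count_effective_superpixels(q))
            if gate == 0:  # healthy override: forced-empty mask
                mask = np.zeros(s.shape, dtype=bool)
            else:
                from .inference import soft_cluster_heatmap

                mask = soft_cluster_heatmap(q, clusterer.scores(s, q)) >= threshold
            segs.append(mask)
        refs = [s.reference_mask for s in test]
        correct = [int(p) == s.label for p, s in zip(predicted, test)]
        table = evaluate_cohort(segs, refs, correct,
                                ids=[s.patient_id for s in test])
        table.to_csv(metrics_path, index=False)
        all_positive = float(np.mean([
            dice(np.ones_like(r, dtype=bool), r) for r in refs
        ]))
        summary = {
            "threshold": float(threshold),
            "classifier_test_accuracy": float(np.mean(correct)),
            "mean_test_dice": float(table[table.id == "mean_all"].dice.iloc[0]),
            "mean_test_hd95": float(table[table.id == "mean_all"].hd95.iloc[0]),
            "mean_test_u_dice": float(table[table.id == "mean_all"].u_dice.iloc[0]),
            "all_positive_baseline_dice": all_positive,
            "mean_effective_superpixels": float(np.mean(effective)),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        _log(f"summary: {summary}")
    return out
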