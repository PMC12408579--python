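"""Reproducible benchmark suite: architecture accounting, reference dataset
arithmetic, and a seeded end-to-end training benchmark on synthetic scenes.

Everything here is pure computation on top of the library API; the test
suite and the ``scripts/acceptance.py`` runner both call into this module so
they measure exactly the same quantities.

The training benchmark uses the width-reduced (desk-scale) model on seeded
128x128 synthetic scenes: large enough that detection is non-trivial (many
tiny objects per image), small enough that a full run fits in minutes on a
single CPU core.  Loss-ablation runs reuse the same data at fewer epochs to
expose the qualitative failure modes of the partial losses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .annotations import split_sizes
from .model import ModelConfig, profile
from .synthetic import SceneConfig, generate_scenes
from .train import TrainConfig, train, upsample_samples, validate
from .model import TCDNet

# Reference greenhouse-trap dataset statistics (images, annotations) per
# split, used for planning and for checking the split arithmetic.
REFERENCE_SPLITS = {
    "train": (3370, 28934),
    "val": (1124, 9407),
    "test": (1124, 9385),
}


def architecture_accounting(input_size: tuple[int, int] = (1280, 1280)) -> dict:
    """Parameter/MAC deltas of the three architecture switches.

    Returns parameter and MAC counts for the plain baseline (no PConv, no
    HA, no AFM), the deltas from enabling each switch alone, and the full
    model, all at the default stage configuration.
    """
    base = ModelConfig(input_size=input_size)

    def variant(pconv: bool, ha: bool, afm: bool) -> dict:
        cfg = replace(
            base,
            backbone=replace(base.backbone, use_pconv=pconv),
            ha=replace(base.ha, enabled=ha),
            fpn=replace(base.fpn, afm_enabled=afm),
        )
        return profile(cfg, input_size)

    baseline = variant(False, False, False)
    pconv = variant(True, False, False)
    ha = variant(False, True, False)
    afm = variant(False, False, True)
    full = variant(True, True, True)
    return {
        "baseline_params": baseline["params"],
        "baseline_macs": baseline["macs"],
        "pconv_delta_params": pconv["params"] - baseline["params"],
        "pconv_delta_macs": pconv["macs"] - baseline["macs"],
        "ha_delta_params": ha["params"] - baseline["params"],
        "ha_delta_macs": ha["macs"] - baseline["macs"],
        "afm_delta_params": afm["params"] - baseline["params"],
        "afm_delta_macs": afm["macs"] - baseline["macs"],
        "full_params": full["params"],
        "full_macs": full["macs"],
    }


def dataset_arithmetic() -> dict:
    """Totals implied by the reference per-split statistics, plus the split
    sizes our partition rule produces at the same scale and ratios."""
    n_images = sum(v[0] for v in REFERENCE_SPLITS.values())
    n_annotations = sum(v[1] for v in REFERENCE_SPLITS.values())
    sizes = split_sizes(n_images, (0.6, 0.2, 0.2))
    return {
        "total_images": n_images,
        "total_annotations": n_annotations,
        "mean_annotations_per_image": n_annotations / n_images,
        "split_images": sizes,
        "reference_split_images": tuple(v[0] for v in REFERENCE_SPLITS.values()),
    }


# --- training benchmark -------------------------------------------------

@dataclass
class BenchConfig:
    """Problem sizes of the seeded training benchmark (chosen for a
    single-CPU budget of roughly fifteen minutes).

    Scenes are generated at ``image_size`` and bilinearly upsampled by
    ``upsample`` before training, so the smallest objects sit above the
    resolution limit of the stride-4 heads (see docs/methods.md)."""
    image_size: int = 128
    upsample: int = 2
    count_max: int = 12
    n_train: int = 32
    n_val: int = 12
    epochs: int = 40
    eval_every: int = 2
    lr: float = 3e-4
    ablation_epochs: int = 20
    ablation_n_train: int = 12
    ablation_n_val: int = 6
    ll_only_epochs: int = 4


def _scene_config(bc: BenchConfig) -> SceneConfig:
    return SceneConfig(image_size=bc.image_size, count_max=bc.count_max)


def _seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent sub-seeds below 2**31 from one seed."""
    return [int(s) for s in
            np.random.default_rng(seed).integers(0, 2 ** 31, size=n)]


def _fresh_model(bc: BenchConfig, model_seed: int) -> TCDNet:
    side = bc.image_size * bc.upsample
    cfg = ModelConfig.desk_scale(input_size=(side, side))
    return TCDNet(cfg, rng=np.random.default_rng(model_seed))


def training_benchmark(seed: int, bc: BenchConfig | None = None,
                       verbose: bool = False) -> dict:
    """Train the desk-scale model on seeded scenes; report best-checkpoint
    validation detection/counting metrics."""
    bc = bc or BenchConfig()
    data_seed, model_seed, train_seed = _seeds(seed, 3)
    data = upsample_samples(
        generate_scenes(_scene_config(bc), bc.n_train + bc.n_val,
                        seed=data_seed), bc.upsample)
    train_data, val_data = data[:bc.n_train], data[bc.n_train:]
    model = _fresh_model(bc, model_seed)
    tc = TrainConfig.desk_scale(epochs=bc.epochs, eval_every=bc.eval_every,
                                lr=bc.lr, seed=train_seed)
    log, best = train(model, train_data, val_data, tc, verbose=verbose)
    model.load_state_dict(best)
    report = validate(model, val_data, tc)
    return {
        "val_f1": report["f1"],
        "val_mae": report["mae"],
        "val_precision": report["precision"],
        "val_recall": report["recall"],
        "val_rmse": report["rmse"],
        "n_val_images": report["n_images"],
        "epochs": bc.epochs,
        "n_train_images": bc.n_train,
    }


def loss_ablation_benchmark(seed: int, bc: BenchConfig | None = None,
                            verbose: bool = False) -> dict:
    """Qualitative loss ablations on a shared seeded dataset.

    * localization-only training: with nothing penalising background, the
      prediction should degenerate towards global foreground — reported as
      the mean fraction of validation pixels above the 0.5 threshold.
    * no-false-positive-term training vs. the full loss at identical
      epochs/seeds: spurious components are never suppressed, so the
      pooled validation false-positive count should be strictly higher.
    """
    from ._tensor import Tensor
    from .train import to_input

    bc = bc or BenchConfig()
    data_seed, model_seed, train_seed = _seeds(seed + 1, 3)
    data = upsample_samples(
        generate_scenes(_scene_config(bc),
                        bc.ablation_n_train + bc.ablation_n_val,
                        seed=data_seed), bc.upsample)
    train_data = data[:bc.ablation_n_train]
    val_data = data[bc.ablation_n_train:]

    def run(terms: tuple[str, ...], epochs: int) -> TCDNet:
        model = _fresh_model(bc, model_seed)
        tc = TrainConfig.desk_scale(epochs=epochs, lr=bc.lr,
                                    seed=train_seed, loss_terms=terms)
        # no validation data: train() returns the final state
        train(model, train_data, [], tc, verbose=verbose)
        return model

    ll_only = run(("localization",), bc.ll_only_epochs)
    frac = []
    for image, _ in val_data:
        pmap = ll_only(Tensor(to_input(image)))
        frac.append(float((pmap.values >= 0.5).mean()))
    foreground_fraction = float(np.mean(frac))

    full = run(("localization", "boundary", "false_positive"),
               bc.ablation_epochs)
    no_fp = run(("localization", "boundary"), bc.ablation_epochs)
    tc_eval = TrainConfig.desk_scale()
    fp_full = validate(full, val_data, tc_eval)["fp"]
    fp_no_fp_term = validate(no_fp, val_data, tc_eval)["fp"]
    return {
        "ll_only_foreground_fraction": foreground_fraction,
        "fp_full_loss": int(fp_full),
        "fp_without_fp_term": int(fp_no_fp_term),
        "ablation_epochs": bc.ablation_epochs,
    }
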