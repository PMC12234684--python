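"""Intensity-to-DOPU synthesis: dataset building, training, inference, stats.

A compact convolutional encoder-decoder is trained on paired patches of
log-scaled standard-OCT intensity (input) and measured DOPU (target), with
per-pixel binary cross-entropy treating DOPU values as Bernoulli means.
The dataset split is strictly subject-wise (8:2 by default) so no subject
contributes patches to both training and validation. The trained model then
drives the melanin pipeline with synthesized DOPU in place of measured
DOPU; paired per-subject statistics (Wilcoxon signed-rank, Pearson)
quantify original-vs-synthesized agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats

from .nn import UNet, bce_loss, mse_loss
from .polarimetry import DOPUVolume, IntensityVolume

__all__ = [
    "PatchDataset",
    "normalize_log_intensity",
    "build_patches",
    "train",
    "synthesize_dopu",
    "compare_original_synthesized",
]


@dataclass
class PatchDataset:
    x: np.ndarray                     # (N, 1, h, w) float32, normalized log-intensity
    y: np.ndarray                     # (N, 1, h, w) float32, DOPU in [0, 1]
    subject_id: np.ndarray            # (N,) str
    split: np.ndarray                 # (N,) "train" | "val"
    patch_size: int = 64
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        train_subj = set(self.subject_id[self.split == "train"])
        val_subj = set(self.subject_id[self.split == "val"])
        if train_subj & val_subj:
            raise ValueError(f"subject leakage across splits: {train_subj & val_subj}")
        if self.y.size and (self.y.min() < 0 or self.y.max() > 1):
            raise ValueError("DOPU targets must lie in [0, 1]")

    def subset(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.split == split
        return self.x[m], self.y[m]


def normalize_log_intensity(intensity: IntensityVolume) -> np.ndarray:
    """Per-volume log transform then robust affine scaling to [0, 1].

    The log view is scaled by its 1st/99th percentiles (computed over
    positive-signal voxels) so volumes of different overall brightness map
    to a common input range.
    """
    log = intensity.log_view()
    lo, hi = np.percentile(log, [1.0, 99.0])
    if hi <= lo:
        return np.zeros_like(log)
    return np.clip((log - lo) / (hi - lo), 0.0, 1.0)


def _dopu_target(dopu: DOPUVolume) -> np.ndarray:
    """DOPU with invalid voxels set to 1 (no depolarization evidence)."""
    return np.where(dopu.valid_mask, dopu.dopu, 1.0)


def build_patches(
    pairs: list[tuple[IntensityVolume, DOPUVolume, str]],
    patch_size: int = 64,
    stride: int | None = None,
    split_ratio: float = 0.8,
    seed: int = 0,
    bscan_step: int = 1,
) -> PatchDataset:
    """Tile paired B-scans into patches with a subject-wise split.

    Each B-scan is viewed as a (depth, aline) image and tiled with the given
    stride (default: non-overlapping). ``bscan_step`` subsamples B-scans to
    control dataset size. Deterministic under ``seed``.
    """
    if stride is None:
        stride = patch_size
    subjects = sorted({sid for _, _, sid in pairs})
    if len(subjects) < 5:
        raise ValueError(f"need >= 5 subjects for a subject-wise split, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(subjects))
    n_train = int(round(split_ratio * len(subjects)))
    n_train = min(max(n_train, 1), len(subjects) - 1)
    train_set = set(order[:n_train])

    xs, ys, sids = [], [], []
    for iv, dv, sid in pairs:
        x_vol = normalize_log_intensity(iv).astype(np.float32)
        y_vol = _dopu_target(dv).astype(np.float32)
        nb, na, nz = x_vol.shape
        if nz < patch_size or na < patch_size:
            raise ValueError("B-scan smaller than patch size")
        z_pos = list(range(0, nz - patch_size + 1, stride))
        a_pos = list(range(0, na - patch_size + 1, stride))
        for b in range(0, nb, bscan_step):
            xi = x_vol[b].T        # (depth, aline)
            yi = y_vol[b].T
            for z0 in z_pos:
                for a0 in a_pos:
                    xs.append(xi[z0:z0 + patch_size, a0:a0 + patch_size])
                    ys.append(yi[z0:z0 + patch_size, a0:a0 + patch_size])
                    sids.append(sid)
    x = np.stack(xs)[:, None]
    y = np.stack(ys)[:, None]
    sid_arr = np.array(sids)
    split = np.where(np.isin(sid_arr, list(train_set)), "train", "val")
    return PatchDataset(
        x=x, y=y, subject_id=sid_arr, split=split, patch_size=patch_size,
        meta={"stride": stride, "split_ratio": split_ratio, "seed": seed,
              "train_subjects": sorted(train_set),
              "val_subjects": sorted(set(subjects) - train_set)},
    )


def _eval_loss(model: UNet, x: np.ndarray, y: np.ndarray, loss: str,
               batch_size: int) -> float:
    fn = bce_loss if loss == "bce" else mse_loss
    total, n = 0.0, 0
    for i in range(0, len(x), batch_size):
        p = model.forward(x[i:i + batch_size])
        total += fn(p, y[i:i + batch_size]) * len(p)
        n += len(p)
    return total / max(n, 1)


def train(
    model: UNet,
    data: PatchDataset,
    epochs: int = 6,
    batch_size: int = 16,
    lr: float = 2e-3,
    loss: str = "bce",
    seed: int = 0,
    verbose: bool = False,
) -> tuple[UNet, list[dict]]:
    """Minimize per-pixel loss; return the best-validation checkpoint.

    Raises on divergence (NaN loss) with the step at which it occurred.
    """
    x_tr, y_tr = data.subset("train")
    x_va, y_va = data.subset("val")
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("both train and val splits must be nonempty")
    rng = np.random.default_rng(seed)
    fn = bce_loss if loss == "bce" else mse_loss
    history: list[dict] = []
    best_val = _eval_loss(model, x_va, y_va, loss, batch_size)
    best_state = model.state_dict()
    history.append({"epoch": 0, "train_loss": np.nan, "val_loss": best_val})
    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(x_tr))
        tr_losses = []
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            p, cache = model.forward(x_tr[idx], want_cache=True)
            step_loss = fn(p, y_tr[idx])
            if not np.isfinite(step_loss):
                raise RuntimeError(
                    f"training diverged (loss={step_loss}) at epoch {epoch}, "
                    f"step {i // batch_size}"
                )
            tr_losses.append(step_loss)
            grads = model.backward(p, y_tr[idx], cache, loss=loss)
            model.adam_step(grads, lr=lr)
        val = _eval_loss(model, x_va, y_va, loss, batch_size)
        history.append({"epoch": epoch, "train_loss": float(np.mean(tr_losses)),
                        "val_loss": val})
        if verbose:
            print(f"epoch {epoch}: train {np.mean(tr_losses):.4f}  val {val:.4f}")
        if val < best_val:
            best_val = val
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    model.trained = True
    return model, history


def synthesize_dopu(
    model: UNet,
    intensity: IntensityVolume,
    patch_size: int = 64,
    overlap: float = 0.5,
    batch_size: int = 64,
    intensity_floor: float | None = None,
) -> DOPUVolume:
    """Tiled inference over every B-scan with overlap averaging.

    Tiles of ``patch_size`` are laid out with the given fractional overlap
    (edge tiles snapped to the border) and predictions are averaged with
    uniform weights where tiles overlap, removing patch seams. Output is
    clipped to [0, 1]. ``intensity_floor`` (linear scale) marks voxels below
    it invalid; default: everything valid.
    """
    if not model.trained:
        raise ValueError("model has not been trained")
    x_vol = normalize_log_intensity(intensity).astype(np.float32)
    nb, na, nz = x_vol.shape
    if nz < patch_size or na < patch_size:
        raise ValueError("volume smaller than inference patch size")
    step = max(1, int(round(patch_size * (1.0 - overlap))))
    z_pos = sorted({*range(0, nz - patch_size, step), nz - patch_size})
    a_pos = sorted({*range(0, na - patch_size, step), na - patch_size})

    tiles, coords = [], []
    for b in range(nb):
        img = x_vol[b].T                  # (depth, aline)
        for z0 in z_pos:
            for a0 in a_pos:
                tiles.append(img[z0:z0 + patch_size, a0:a0 + patch_size])
                coords.append((b, z0, a0))
    tiles = np.stack(tiles)[:, None]
    preds = np.empty_like(tiles)
    for i in range(0, len(tiles), batch_size):
        preds[i:i + batch_size] = model.forward(tiles[i:i + batch_size])

    acc = np.zeros((nb, nz, na), dtype=np.float64)
    wgt = np.zeros((nb, nz, na), dtype=np.float64)
    for (b, z0, a0), p in zip(coords, preds[:, 0]):
        acc[b, z0:z0 + patch_size, a0:a0 + patch_size] += p
        wgt[b, z0:z0 + patch_size, a0:a0 + patch_size] += 1.0
    out = np.clip(acc / np.maximum(wgt, 1.0), 0.0, 1.0)
    out = out.transpose(0, 2, 1)          # back to (bscan, aline, depth)
    if intensity_floor is None:
        valid = np.ones_like(out, dtype=bool)
    else:
        valid = np.asarray(intensity.intensity) > intensity_floor
    return DOPUVolume(dopu=np.where(valid, out, 0.0), valid_mask=valid,
                      kernel_shape=(1, 1), source="synthesized")


def compare_original_synthesized(
    original: np.ndarray, synthesized: np.ndarray, label: str = "mean_thickness_um"
) -> dict:
    """Paired original-vs-synthesized statistics across subjects.

    Returns Wilcoxon signed-rank p, Pearson r and p, and descriptive means;
    with fewer than 5 pairs only descriptive statistics are reported.
    """
    a = np.asarray(original, dtype=float)
    b = np.asarray(synthesized, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired inputs must be 1-D arrays of equal length")
    out: dict = {
        "label": label,
        "n": int(len(a)),
        "mean_original": float(a.mean()),
        "mean_synthesized": float(b.mean()),
        "sd_original": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
        "sd_synthesized": float(b.std(ddof=1)) if len(b) > 1 else 0.0,
    }
    if len(a) < 5:
        warnings.warn("fewer than 5 pairs: reporting descriptive statistics only")
        return out
    diffs = a - b
    if np.allclose(diffs, 0):
        out["wilcoxon_p"] = 1.0
        out["wilcoxon_stat"] = 0.0
    else:
        method = "exact" if len(a) <= 25 else "approx"
        w = stats.wilcoxon(a, b, zero_method="wilcox", method=method)
        out["wilcoxon_p"] = float(w.pvalue)
        out["wilcoxon_stat"] = float(w.statistic)
    if np.std(a) > 0 and np.std(b) > 0:
        r = stats.pearsonr(a, b)
        out["pearson_r"] = float(r.statistic)
        out["pearson_p"] = float(r.pvalue)
    return out
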