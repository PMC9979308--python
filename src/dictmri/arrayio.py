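"""File I/O: grayscale images (PNG/TIFF/NIfTI), k-space, models, tables.

Images are always normalized to float in [0, 1] on read (by the dtype's
value range for integer rasters) and windowed back to 8-bit on PNG write.
K-space samples, patch dictionaries and network parameters persist to
compressed ``.npz`` containers with an embedded config echo.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

from .deep import ConvNetParams
from .dictionary import PatchDictionary
from .synthetic import KSpaceSample

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NIFTI_SUFFIXES)


def load_image(path: str | Path) -> np.ndarray:
    """Read a 2-D grayscale image as float in [0, 1]."""
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj).squeeze()
        if data.ndim == 3:
            data = data[..., data.shape[2] // 2]  # middle slice
        if data.ndim != 2:
            raise ValueError(f"cannot interpret {path} as a single 2-D slice")
        data = data.astype(float)
        lo, hi = float(data.min()), float(data.max())
        if 0.0 <= lo and hi <= 1.0:  # already normalized; keep values
            return data
        return (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
    img = PILImage.open(path)
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    arr = arr.astype(float)
    return np.clip(arr, 0.0, 1.0)


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] image; PNG/TIFF as 8-bit, NIfTI as float32."""
    path = Path(path)
    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if _is_nifti(path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(img.astype(np.float32), np.eye(4)), str(path))
        return
    PILImage.fromarray((img * 255).round().astype(np.uint8)).save(path)


def save_kspace(path: str | Path, sample: KSpaceSample) -> None:
    np.savez_compressed(
        path, data=sample.data, mask=sample.mask, sampling_rate=sample.sampling_rate
    )


def load_kspace(path: str | Path) -> KSpaceSample:
    with np.load(path) as z:
        return KSpaceSample(
            data=z["data"], mask=z["mask"], sampling_rate=float(z["sampling_rate"])
        )


def save_dictionary(path: str | Path, dic: PatchDictionary) -> None:
    np.savez_compressed(
        path,
        atoms=dic.atoms,
        sparsity_T=dic.sparsity_T,
        train_iters=dic.train_iters,
        seed=dic.seed,
    )


def load_dictionary(path: str | Path) -> PatchDictionary:
    with np.load(path) as z:
        return PatchDictionary(
            atoms=z["atoms"],
            sparsity_T=int(z["sparsity_T"]),
            train_iters=int(z["train_iters"]),
            seed=int(z["seed"]),
        )


def save_net(path: str | Path, net: ConvNetParams) -> None:
    config = {
        "learning_rate": net.learning_rate,
        "weight_decay": net.weight_decay,
        "seed": net.seed,
        "residual": net.residual,
        "n_layers": len(net.weights),
    }
    arrays = {f"w{i}": w for i, w in enumerate(net.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(net.biases)})
    np.savez_compressed(path, config=json.dumps(config), **arrays)


def load_net(path: str | Path) -> ConvNetParams:
    with np.load(path) as z:
        config = json.loads(str(z["config"]))
        n = config["n_layers"]
        return ConvNetParams(
            weights=[z[f"w{i}"] for i in range(n)],
            biases=[z[f"b{i}"] for i in range(n)],
            learning_rate=config["learning_rate"],
            weight_decay=config["weight_decay"],
            seed=config["seed"],
            residual=config.get("residual", False),
        )
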