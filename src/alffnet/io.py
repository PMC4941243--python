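"""NIfTI-1 input/output helpers."""

from __future__ import annotations

import numpy as np
import nibabel as nib

__all__ = ["save_volume", "load_volume"]


def save_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)
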