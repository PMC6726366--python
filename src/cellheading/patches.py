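"""Image-patch preparation: cropping, normalization, augmentation, splits.

Each annotated (cell, frame) becomes a square crop centered on the
tracked position, resized to a fixed side (128 px by default) and
min-max normalized to [0, 1].  Geometric augmentation expands the
training set six-fold (identity, two reflections, three rotations);
the direction label is transformed by the same planar isometry, since
e.g. a rotated image of a right-moving cell shows an upward-moving
cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.transform import resize

from .tracking import AnnotatedSample, DirectionLabel, Trajectory


class InvalidCenterError(ValueError):
    """Patch center lies outside the source frame."""


PATCH_SIZE = 128

# Label permutations: new_label = MAP[transform][old_label].  Quadrant
# indices are 0 UR, 1 UL, 2 LL, 3 LR in the displayed (y-down) image.
# rot90 is counterclockwise in the displayed image, so it advances the
# quadrant by one (UR -> UL -> LL -> LR -> UR).
LABEL_MAPS: dict[str, tuple[int, int, int, int]] = {
    "identity": (0, 1, 2, 3),
    "hflip": (1, 0, 3, 2),      # mirror left-right: x -> -x
    "vflip": (3, 2, 1, 0),      # mirror top-bottom: y -> -y
    "rot90": (1, 2, 3, 0),
    "rot180": (2, 3, 0, 1),
    "rot270": (3, 0, 1, 2),
}

AUGMENTATIONS = ("identity", "hflip", "vflip", "rot90", "rot180", "rot270")


def transform_patch(patch: np.ndarray, name: str) -> np.ndarray:
    if patch.shape[0] != patch.shape[1]:
        raise ValueError("augmentation requires a square patch")
    if name == "identity":
        return patch.copy()
    if name == "hflip":
        return patch[:, ::-1].copy()
    if name == "vflip":
        return patch[::-1, :].copy()
    if name.startswith("rot"):
        k = int(name[3:]) // 90
        return np.rot90(patch, k).copy()
    raise KeyError(name)


def transform_label(label: int, name: str) -> DirectionLabel:
    return DirectionLabel(LABEL_MAPS[name][int(label)])


def augment(
    patch: np.ndarray, label: int, transform_labels: bool = True
) -> list[tuple[np.ndarray, DirectionLabel]]:
    """Return the six (patch, label) variants of one training sample.

    ``transform_labels=False`` keeps the original label on every
    variant (the literal reading in which augmentation does not remap
    the annotated direction).
    """
    out = []
    for name in AUGMENTATIONS:
        lab = transform_label(label, name) if transform_labels else DirectionLabel(int(label))
        out.append((transform_patch(patch, name), lab))
    return out


def extract_patch(
    frame: np.ndarray,
    center_px: tuple[float, float],
    crop_px: int,
    out_px: int = PATCH_SIZE,
) -> np.ndarray:
    """Square crop centered on (x, y), edge-replicated, resized to out_px.

    ``center_px`` is (x, y) in pixel units; the crop window extends
    crop_px//2 pixels to each side and is padded by edge replication
    where it leaves the frame.  Resizing is bilinear.
    """
    h, w = frame.shape
    cx, cy = center_px
    if not (0 <= cx < w and 0 <= cy < h):
        raise InvalidCenterError(f"center {center_px} outside frame {w}x{h}")
    ix, iy = int(round(cx)), int(round(cy))
    half = crop_px // 2
    x0, x1 = ix - half, ix - half + crop_px
    y0, y1 = iy - half, iy - half + crop_px
    pad_x0, pad_y0 = max(0, -x0), max(0, -y0)
    pad_x1, pad_y1 = max(0, x1 - w), max(0, y1 - h)
    crop = frame[max(0, y0) : min(h, y1), max(0, x0) : min(w, x1)]
    if pad_x0 or pad_x1 or pad_y0 or pad_y1:
        crop = np.pad(crop, ((pad_y0, pad_y1), (pad_x0, pad_x1)), mode="edge")
    if crop_px == out_px:
        return crop.astype(np.float32)
    return resize(
        crop.astype(np.float64), (out_px, out_px), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    ).astype(np.float32)


def normalize_patch(patch: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; constant patches map to all zeros."""
    p = patch.astype(np.float32)
    p = p - p.min()
    m = float(p.max())
    if m > 0:
        p /= m
    return p


@dataclass
class PatchSet:
    """Patches with labels and provenance, the in-memory dataset unit."""

    patches: np.ndarray          # (N, S, S) float32 in [0, 1]
    labels: np.ndarray           # (N,) int
    cell_ids: np.ndarray         # (N,) int
    frames: np.ndarray           # (N,) int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        self.frames = np.asarray(self.frames, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.labels.size)

    def subset(self, idx: np.ndarray) -> "PatchSet":
        return PatchSet(self.patches[idx], self.labels[idx],
                        self.cell_ids[idx], self.frames[idx])

    def class_counts(self, n_classes: int = 4) -> np.ndarray:
        return np.bincount(self.labels, minlength=n_classes)


@dataclass
class DatasetSplit:
    train: PatchSet
    validation: PatchSet
    test: PatchSet

    @property
    def pool(self) -> PatchSet:
        """Train + validation, the cross-validation pool."""
        tr, va = self.train, self.validation
        return PatchSet(
            np.concatenate([tr.patches, va.patches]),
            np.concatenate([tr.labels, va.labels]),
            np.concatenate([tr.cell_ids, va.cell_ids]),
            np.concatenate([tr.frames, va.frames]),
        )


def build_patchset(
    movie: np.ndarray,
    trajs: Sequence[Trajectory],
    samples: Sequence[AnnotatedSample],
    crop_px: int,
    out_px: int = PATCH_SIZE,
) -> PatchSet:
    """Cut and normalize one patch per annotated sample from the movie."""
    by_id = {tr.cell_id: tr for tr in trajs}
    pat, lab, cid, frm = [], [], [], []
    for s in samples:
        tr = by_id[s.cell_id]
        x_um, y_um = tr.position(s.frame_index)
        center = (x_um / tr.pixel_size_um, y_um / tr.pixel_size_um)
        p = extract_patch(movie[s.frame_index], center, crop_px, out_px)
        pat.append(normalize_patch(p))
        lab.append(int(s.label))
        cid.append(s.cell_id)
        frm.append(s.frame_index)
    n = len(pat)
    shape = (n, out_px, out_px) if n else (0, out_px, out_px)
    return PatchSet(
        np.asarray(pat, dtype=np.float32).reshape(shape),
        np.asarray(lab), np.asarray(cid), np.asarray(frm),
    )


def split_dataset(
    samples: PatchSet,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    group_by_cell: bool = False,
) -> DatasetSplit:
    """Stratified random train/validation/test split.

    Stratification is by label at the patch level by default, mirroring
    per-class dataset tables; ``group_by_cell=True`` instead keeps all
    patches of one cell in a single split (no cross-split leakage of a
    cell's frames), at the cost of less exact per-class fractions.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n = len(samples)
    assign = np.empty(n, dtype=np.int64)  # 0 train, 1 val, 2 test

    if group_by_cell:
        cells = np.unique(samples.cell_ids)
        cells = cells[rng.permutation(cells.size)]
        n_tr = int(round(fractions[0] * cells.size))
        n_va = int(round((fractions[0] + fractions[1]) * cells.size)) - n_tr
        part = {c: 0 for c in cells[:n_tr]}
        part.update({c: 1 for c in cells[n_tr : n_tr + n_va]})
        part.update({c: 2 for c in cells[n_tr + n_va :]})
        assign = np.array([part[c] for c in samples.cell_ids])
    else:
        for k in np.unique(samples.labels):
            idx = np.nonzero(samples.labels == k)[0]
            idx = idx[rng.permutation(idx.size)]
            m = idx.size
            n_tr = int(m * fractions[0] + 0.5)
            n_va = int(m * (fractions[0] + fractions[1]) + 0.5) - n_tr
            assign[idx[:n_tr]] = 0
            assign[idx[n_tr : n_tr + n_va]] = 1
            assign[idx[n_tr + n_va :]] = 2

    import warnings

    counts = samples.class_counts()
    if np.any(counts == 0):
        warnings.warn("one or more direction classes are empty in this dataset")
    return DatasetSplit(
        train=samples.subset(np.nonzero(assign == 0)[0]),
        validation=samples.subset(np.nonzero(assign == 1)[0]),
        test=samples.subset(np.nonzero(assign == 2)[0]),
    )


def augment_set(train: PatchSet, transform_labels: bool = True) -> PatchSet:
    """Six-fold geometric augmentation of a training set."""
    pats, labs, cids, frms = [], [], [], []
    for name in AUGMENTATIONS:
        if name == "identity":
            pats.append(train.patches)
        elif name == "hflip":
            pats.append(train.patches[:, :, ::-1])
        elif name == "vflip":
            pats.append(train.patches[:, ::-1, :])
        else:
            k = int(name[3:]) // 90
            pats.append(np.rot90(train.patches, k, axes=(1, 2)))
        lm = np.asarray(LABEL_MAPS[name])
        labs.append(lm[train.labels] if transform_labels else train.labels)
        cids.append(train.cell_ids)
        frms.append(train.frames)
    return PatchSet(
        np.ascontiguousarray(np.concatenate(pats)),
        np.concatenate(labs), np.concatenate(cids), np.concatenate(frms),
    )
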