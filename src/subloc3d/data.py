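"""Data model and I/O for single-cell volumes, annotations and splits.

A *sample* is one cropped single cell: a two-channel 3-D intensity volume
(channel 0 = nucleus reference stain, channel 1 = tagged protein), a set of
subcellular-localization class labels inherited from its protein, and a
per-class confidence grade in {1, 2, 3} (3 = prominent signal, 1 = subtle
and weak).  Labels live at the protein level — every cell of a protein
carries the protein's full label set — which is the weak-annotation setting
this package is built to be robust to.

Train/validation/test splits are made at the protein level by default so
that no protein's cells leak across splits; a cell-level mode is provided
for datasets whose proteins map one-to-one to classes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import tifffile
from skimage.transform import resize as _sk_resize

__all__ = [
    "VolumeSample",
    "DatasetTable",
    "SplitAssignment",
    "crop_single_cells",
    "project_z",
    "split_by_protein",
    "read_annotations",
    "write_annotations",
    "read_volume",
    "write_volume",
    "normalize_volume",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS = (0.70, 0.15, 0.15)
SPLITS = ("train", "val", "test")


@dataclass
class VolumeSample:
    """One single-cell record; ``volume`` has axis order (channel, z, y, x)."""

    cell_id: str
    protein_id: str
    labels: frozenset[str]
    grades: dict[str, int]
    volume: np.ndarray | None = None
    volume_path: str | None = None
    split: str = "unassigned"
    image_id: str | None = None

    def __post_init__(self):
        self.labels = frozenset(self.labels)
        if not self.labels:
            raise ValueError(f"sample {self.cell_id}: labels must be non-empty")
        if set(self.grades) != set(self.labels):
            raise ValueError(
                f"sample {self.cell_id}: grades keys must equal labels "
                f"({sorted(self.grades)} vs {sorted(self.labels)})"
            )
        for cls, g in self.grades.items():
            if g not in (1, 2, 3):
                raise ValueError(
                    f"sample {self.cell_id}: grade for {cls!r} is {g}, "
                    "must be in {1, 2, 3}"
                )
        if self.volume is not None:
            v = np.asarray(self.volume)
            if v.ndim != 4 or v.shape[0] != 2:
                raise ValueError(
                    f"sample {self.cell_id}: volume must be (2, z, y, x), "
                    f"got shape {v.shape}"
                )
            if v.min() < 0:
                raise ValueError(f"sample {self.cell_id}: negative intensities")
            self.volume = v


@dataclass
class DatasetTable:
    samples: list[VolumeSample]
    class_vocabulary: list[str]
    protein_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.class_vocabulary)) != len(self.class_vocabulary):
            raise ValueError("class_vocabulary has duplicates")
        if not self.protein_index:
            proteins = sorted({s.protein_id for s in self.samples})
            self.protein_index = {p: i for i, p in enumerate(proteins)}
        idx = sorted(self.protein_index.values())
        if idx != list(range(len(idx))):
            raise ValueError("protein_index must be a bijection onto 0..N-1")

    @property
    def n_classes(self) -> int:
        return len(self.class_vocabulary)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_index)

    def subset(self, split: str) -> list[VolumeSample]:
        return [s for s in self.samples if s.split == split]

    def label_matrix(self, samples: list[VolumeSample] | None = None) -> np.ndarray:
        """Binary (n_samples, C) matrix in vocabulary order."""
        if samples is None:
            samples = self.samples
        y = np.zeros((len(samples), self.n_classes), dtype=np.int64)
        col = {c: j for j, c in enumerate(self.class_vocabulary)}
        for i, s in enumerate(samples):
            for c in s.labels:
                y[i, col[c]] = 1
        return y


@dataclass
class SplitAssignment:
    fractions: tuple[float, float, float]
    assignment: dict[str, str]
    seed: int

    def apply(self, table: DatasetTable) -> None:
        for s in table.samples:
            s.split = self.assignment[s.protein_id]

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["protein_id", "split"])
            for pid in sorted(self.assignment):
                writer.writerow([pid, self.assignment[pid]])

    @classmethod
    def read_csv(cls, path) -> "SplitAssignment":
        assignment: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                if row["split"] not in SPLITS + ("unassigned",):
                    raise ValueError(f"unknown split {row['split']!r}")
                assignment[row["protein_id"]] = row["split"]
        return cls(fractions=(0.0, 0.0, 0.0), assignment=assignment, seed=-1)


# -- geometry ----------------------------------------------------------------


def crop_single_cells(
    multicell_volume: np.ndarray,
    nucleus_centers: list[tuple[int, int, int]],
    crop_xy: int,
    out_xy: int = 128,
    protein_id: str = "unknown",
    labels: frozenset[str] | None = None,
    grades: dict[str, int] | None = None,
) -> list[VolumeSample]:
    """Cut one square (y, x) window per nucleus center and resize to out_xy.

    The window is half-open, ``crop_xy`` wide, centered on the nucleus
    center (0-based coordinates), keeps the full z extent and is
    zero-padded where it leaves the field of view.  When ``crop_xy ==
    out_xy`` the crop is returned without resampling.
    """
    vol = np.asarray(multicell_volume, dtype=np.float64)
    if vol.ndim != 4 or vol.shape[0] != 2:
        raise ValueError(f"multicell volume must be (2, z, y, x), got {vol.shape}")
    if crop_xy <= 0 or out_xy <= 0:
        raise ValueError("crop_xy and out_xy must be positive")
    _, nz, ny, nx = vol.shape
    if labels is None:
        labels = frozenset({"unlabeled"})
        grades = {"unlabeled": 3}
    out: list[VolumeSample] = []
    half = crop_xy // 2
    for i, (cz, cy, cx) in enumerate(nucleus_centers):
        if not (0 <= cz < nz and 0 <= cy < ny and 0 <= cx < nx):
            raise ValueError(
                f"nucleus center ({cz}, {cy}, {cx}) lies outside the volume "
                f"bounds (z<{nz}, y<{ny}, x<{nx})"
            )
        y0, x0 = cy - half, cx - half
        crop = np.zeros((2, nz, crop_xy, crop_xy), dtype=np.float64)
        ys, ye = max(y0, 0), min(y0 + crop_xy, ny)
        xs, xe = max(x0, 0), min(x0 + crop_xy, nx)
        crop[:, :, ys - y0 : ye - y0, xs - x0 : xe - x0] = vol[:, :, ys:ye, xs:xe]
        if crop_xy != out_xy:
            crop = _resize_xy(crop, out_xy)
        out.append(
            VolumeSample(
                cell_id=f"{protein_id}_cell{i}",
                protein_id=protein_id,
                labels=labels,
                grades=dict(grades),
                volume=crop,
            )
        )
    return out


def _resize_xy(vol: np.ndarray, out_xy: int) -> np.ndarray:
    """Linear resize on (y, x) only; z and channel untouched."""
    c, z, _, _ = vol.shape
    out = np.empty((c, z, out_xy, out_xy), dtype=np.float64)
    for ci in range(c):
        for zi in range(z):
            out[ci, zi] = _sk_resize(
                vol[ci, zi], (out_xy, out_xy), order=1, mode="edge",
                anti_aliasing=False, preserve_range=True,
            )
    return np.clip(out, 0.0, None)


def project_z(volume: np.ndarray, operator: str = "max") -> np.ndarray:
    """Project a (z, y, x) or (c, z, y, x) array along z.

    Maximum-intensity projection by default; ``operator="mean"`` averages.
    """
    vol = np.asarray(volume)
    ax = vol.ndim - 3
    if vol.ndim not in (3, 4):
        raise ValueError(f"expected 3-D or 4-D volume, got ndim={vol.ndim}")
    if vol.shape[ax] == 0:
        raise ValueError("z axis has zero size")
    if operator == "max":
        return vol.max(axis=ax)
    if operator == "mean":
        return vol.mean(axis=ax)
    raise ValueError(f"unknown projection operator {operator!r}")


# -- splits ------------------------------------------------------------------


def split_by_protein(
    table: DatasetTable,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
    level: str = "protein",
) -> SplitAssignment:
    """Assign proteins (or cells) to train/val/test with seeded shuffling.

    Protein-level splitting guarantees every cell of a protein shares its
    split; per-split protein counts land within one of ``fraction * N``.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    rng = np.random.default_rng(seed)
    if level == "protein":
        units = sorted(table.protein_index, key=table.protein_index.get)
    elif level == "cell":
        units = [s.cell_id for s in table.samples]
    else:
        raise ValueError(f"unknown split level {level!r}")
    n = len(units)
    n_nonzero = sum(f > 0 for f in fractions)
    if n < n_nonzero:
        raise ValueError(
            f"cannot split {n} units into {n_nonzero} non-empty parts"
        )
    order = rng.permutation(n)
    counts = np.floor(np.asarray(fractions) * n).astype(int)
    # distribute the remainder to the largest fractional parts
    rem = n - counts.sum()
    fracpart = np.asarray(fractions) * n - counts
    for j in np.argsort(-fracpart)[:rem]:
        counts[j] += 1
    bounds = np.cumsum(counts)
    assignment: dict[str, str] = {}
    for pos, ui in enumerate(order):
        part = int(np.searchsorted(bounds, pos, side="right"))
        assignment[units[ui]] = SPLITS[part]
    sa = SplitAssignment(fractions=fractions, assignment=assignment, seed=seed)
    if level == "protein":
        sa.apply(table)
    else:
        for s in table.samples:
            s.split = assignment[s.cell_id]
    return sa


def stratified_protein_split(
    table: DatasetTable,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> SplitAssignment:
    """Protein-level split stratified by label combination.

    Proteins sharing a label set are split together so every combination
    with at least three proteins is represented in train, validation and
    test.  Used by designed evaluations that must measure specific classes
    on held-out proteins; leakage-free like :func:`split_by_protein` (no
    protein crosses splits).
    """
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    rng = np.random.default_rng(seed)
    groups: dict[frozenset, list[str]] = {}
    for s in table.samples:
        groups.setdefault(s.labels, [])
        if s.protein_id not in groups[s.labels]:
            groups[s.labels].append(s.protein_id)
    assignment: dict[str, str] = {}
    for labels in sorted(groups, key=sorted):
        pids = sorted(groups[labels])
        order = rng.permutation(len(pids))
        n = len(pids)
        n_test = max(1, round(fractions[2] * n)) if n >= 3 else (1 if n == 2 else 0)
        n_val = max(1, round(fractions[1] * n)) if n >= 3 else 0
        for pos, pi in enumerate(order):
            if pos < n_test:
                part = "test"
            elif pos < n_test + n_val:
                part = "val"
            else:
                part = "train"
            assignment[pids[pi]] = part
    sa = SplitAssignment(fractions=fractions, assignment=assignment, seed=seed)
    sa.apply(table)
    return sa


# -- annotation / volume I/O --------------------------------------------------

_ANNOT_COLS = ["cell_id", "protein_id", "volume_path", "labels", "grades"]


def read_annotations(path) -> DatasetTable:
    """Read the annotation CSV (labels and grades pipe-separated, aligned)."""
    samples: list[VolumeSample] = []
    classes: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_ANNOT_COLS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"annotation file missing columns: {sorted(missing)}")
        for row in reader:
            labels = row["labels"].split("|")
            grade_strs = row["grades"].split("|")
            if len(labels) != len(grade_strs):
                raise ValueError(
                    f"cell {row['cell_id']}: {len(labels)} labels but "
                    f"{len(grade_strs)} grades"
                )
            grades = {c: int(g) for c, g in zip(labels, grade_strs)}
            samples.append(
                VolumeSample(
                    cell_id=row["cell_id"],
                    protein_id=row["protein_id"],
                    labels=frozenset(labels),
                    grades=grades,
                    volume_path=row["volume_path"] or None,
                    image_id=row.get("image_id") or None,
                    split=row.get("split") or "unassigned",
                )
            )
            classes.update(labels)
    return DatasetTable(samples=samples, class_vocabulary=sorted(classes))


def write_annotations(table: DatasetTable, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ANNOT_COLS + ["image_id", "split"])
        for s in table.samples:
            labels = sorted(s.labels)
            writer.writerow(
                [
                    s.cell_id,
                    s.protein_id,
                    s.volume_path or "",
                    "|".join(labels),
                    "|".join(str(s.grades[c]) for c in labels),
                    s.image_id or "",
                    s.split,
                ]
            )


def write_volume(volume: np.ndarray, path) -> None:
    """Write a (2, z, y, x) volume: ``.tif`` via tifffile, else ``.npz``."""
    path = str(path)
    vol = np.asarray(volume, dtype=np.float32)
    if path.endswith((".tif", ".tiff")):
        tifffile.imwrite(path, vol, metadata={"axes": "CZYX"})
    else:
        np.savez_compressed(path if path.endswith(".npz") else path + ".npz",
                            volume=vol)


def read_volume(path) -> np.ndarray:
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            axes = None
            if tf.series:
                axes = tf.series[0].axes
        arr = np.asarray(arr, dtype=np.float64)
        if axes and axes.endswith("C") and not axes.startswith("C"):
            arr = np.moveaxis(arr, -1, 0)  # channel-last -> channel-first
        return arr
    with np.load(path) as z:
        return np.asarray(z["volume"], dtype=np.float64)


def normalize_volume(volume: np.ndarray) -> np.ndarray:
    """Per-channel min-max scaling to [0, 1]; constant channels map to 0."""
    vol = np.asarray(volume, dtype=np.float64)
    out = np.empty_like(vol)
    for c in range(vol.shape[0]):
        lo, hi = vol[c].min(), vol[c].max()
        out[c] = (vol[c] - lo) / (hi - lo) if hi > lo else 0.0
    return out
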