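"""Dataset layout, 8-bit PNG serialization and stratified splits.

Each study lives in its own directory named by a 5-digit numeric ID with
three aligned image subdirectories — ``pet`` (activity slices), ``liver_mask``
and ``lesion_label`` (binary 0/255 maps) — plus a ``meta.json`` sidecar.
Activity slices are scaled to 8-bit through a fixed intensity window
recorded in the sidecar, so the scaling is invertible up to one quantization
step (window width / 255).  Without the sidecar the PNG intensities are not
quantitatively interpretable, and reading refuses to guess.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from .phantom import LesionLabelMap, OrganMask, SliceStack, Study

PET_DIR, LIVER_DIR, LESION_DIR = "pet", "liver_mask", "lesion_label"
SIDECAR = "meta.json"


class LayoutError(RuntimeError):
    """Study directory violates the expected layout."""


# --------------------------------------------------------------------------
# study round trip
# --------------------------------------------------------------------------

def _slice_name(z: int) -> str:
    return f"slice_{z:03d}.png"


def write_study(root: Path | str, study: Study,
                window: tuple[float, float] | None = None) -> Path:
    """Write one study as 8-bit PNG directories plus the metadata sidecar.

    ``window`` is the (low, high) activity interval mapped onto 0..255;
    default is (0, study max).  Values outside the window clip.
    """
    root = Path(root)
    sdir = root / study.study_id
    vox = study.stack.voxels
    if window is None:
        window = (0.0, float(vox.max()) if vox.max() > 0 else 1.0)
    lo, hi = window
    if hi <= lo:
        raise ValueError("intensity window must have high > low")
    for sub in (PET_DIR, LIVER_DIR, LESION_DIR):
        (sdir / sub).mkdir(parents=True, exist_ok=True)
    scaled = np.clip((vox - lo) / (hi - lo) * 255.0, 0, 255)
    scaled = np.rint(scaled).astype(np.uint8)
    liver = (study.liver.mask * 255).astype(np.uint8)
    lesion = (study.lesions.mask * 255).astype(np.uint8)
    for z in range(vox.shape[0]):
        name = _slice_name(z)
        Image.fromarray(scaled[z], mode="L").save(sdir / PET_DIR / name)
        Image.fromarray(liver[z], mode="L").save(sdir / LIVER_DIR / name)
        Image.fromarray(lesion[z], mode="L").save(sdir / LESION_DIR / name)
    meta = {
        "study_id": study.study_id,
        "abnormal": bool(study.abnormal),
        "n_slices": int(vox.shape[0]),
        "pixel_spacing_mm": study.stack.pixel_spacing_mm,
        "slice_thickness_mm": study.stack.slice_thickness_mm,
        "intensity_window": [float(lo), float(hi)],
    }
    (sdir / SIDECAR).write_text(json.dumps(meta, indent=2))
    return sdir


def read_study(root: Path | str, study_id: str) -> Study:
    """Read a study back; inverts the 8-bit scaling through the sidecar.

    Distinct 3D lesion ids are recovered from the binary lesion map by
    26-connected labeling (valid because lesions are non-confluent).
    """
    sdir = Path(root) / study_id
    sidecar = sdir / SIDECAR
    if not sidecar.exists():
        raise LayoutError(f"{sdir}: missing {SIDECAR}; PNG intensities "
                          "cannot be interpreted quantitatively")
    meta = json.loads(sidecar.read_text())
    names = {}
    for sub in (PET_DIR, LIVER_DIR, LESION_DIR):
        d = sdir / sub
        if not d.is_dir():
            raise LayoutError(f"{sdir}: missing image directory {sub}")
        names[sub] = sorted(p.name for p in d.glob("*.png"))
    if not (names[PET_DIR] == names[LIVER_DIR] == names[LESION_DIR]):
        raise LayoutError(f"{sdir}: slice filename sets differ between "
                          "image directories")
    if len(names[PET_DIR]) != meta["n_slices"]:
        raise LayoutError(f"{sdir}: sidecar declares {meta['n_slices']} "
                          f"slices, found {len(names[PET_DIR])}")
    lo, hi = meta["intensity_window"]
    pet, liver, lesion = [], [], []
    for name in names[PET_DIR]:
        pet.append(np.asarray(Image.open(sdir / PET_DIR / name), np.float64))
        liver.append(np.asarray(Image.open(sdir / LIVER_DIR / name)) > 127)
        lesion.append(np.asarray(Image.open(sdir / LESION_DIR / name)) > 127)
    vox = np.stack(pet) / 255.0 * (hi - lo) + lo
    lesion_bin = np.stack(lesion)
    labels, _ = ndimage.label(lesion_bin, structure=np.ones((3, 3, 3), bool))
    return Study(meta["study_id"],
                 SliceStack(np.clip(vox, 0.0, None), meta["pixel_spacing_mm"],
                            meta.get("slice_thickness_mm")),
                 OrganMask(np.stack(liver)),
                 LesionLabelMap(labels),
                 bool(meta["abnormal"]))


def write_dataset(root: Path | str, studies: Sequence[Study]) -> None:
    for st in studies:
        write_study(root, st)


def read_dataset(root: Path | str) -> list[Study]:
    root = Path(root)
    out = []
    for sdir in sorted(p for p in root.iterdir() if p.is_dir()):
        if (sdir / SIDECAR).exists():
            out.append(read_study(root, sdir.name))
    return out


# --------------------------------------------------------------------------
# splits
# --------------------------------------------------------------------------

@dataclass
class SplitManifest:
    """Assignment of study ids to train/validation/test, stratified by the
    abnormal flag."""

    assignment: dict[str, str]
    counts: dict[str, dict[str, int]]
    seed: int = 0

    def ids(self, split: str) -> list[str]:
        return sorted(k for k, v in self.assignment.items() if v == split)

    def to_json(self) -> str:
        return json.dumps({"assignment": self.assignment,
                           "counts": self.counts, "seed": self.seed},
                          indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SplitManifest":
        d = json.loads(text)
        return cls(d["assignment"], d["counts"], d.get("seed", 0))


SPLITS = ("train", "validation", "test")


def split_dataset(studies: Sequence[Study],
                  counts: dict[str, tuple[int, int]] | None = None,
                  fractions: tuple[float, float, float] | None = None,
                  seed: int = 0) -> SplitManifest:
    """Seeded stratified random split.

    ``counts`` maps each split to (n_abnormal, n_normal); alternatively
    ``fractions`` gives (train, validation, test) proportions applied within
    each stratum, remainders going to train.  The partition is always
    disjoint and exhaustive.
    """
    abn = [s.study_id for s in studies if s.abnormal]
    nrm = [s.study_id for s in studies if not s.abnormal]
    rng = np.random.default_rng(seed)
    rng.shuffle(abn)
    rng.shuffle(nrm)

    if counts is None:
        if fractions is None:
            raise ValueError("provide counts or fractions")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        counts = {}
        for pool_name, pool in (("abnormal", abn), ("normal", nrm)):
            n = len(pool)
            k_val = int(round(fractions[1] * n))
            k_test = int(round(fractions[2] * n))
            k_train = n - k_val - k_test
            for split, k in zip(SPLITS, (k_train, k_val, k_test)):
                counts.setdefault(split, [0, 0])
                counts[split][0 if pool_name == "abnormal" else 1] = k
        counts = {k: tuple(v) for k, v in counts.items()}

    need_abn = sum(counts.get(s, (0, 0))[0] for s in SPLITS)
    need_nrm = sum(counts.get(s, (0, 0))[1] for s in SPLITS)
    if need_abn > len(abn) or need_nrm > len(nrm):
        raise ValueError(
            f"requested {need_abn} abnormal / {need_nrm} normal studies, but "
            f"only {len(abn)} / {len(nrm)} are available")

    assignment: dict[str, str] = {}
    ia = inr = 0
    for split in SPLITS:
        ka, kn = counts.get(split, (0, 0))
        for sid in abn[ia:ia + ka]:
            assignment[sid] = split
        for sid in nrm[inr:inr + kn]:
            assignment[sid] = split
        ia += ka
        inr += kn
    out_counts = {split: {"abnormal": counts.get(split, (0, 0))[0],
                          "normal": counts.get(split, (0, 0))[1]}
                  for split in SPLITS}
    return SplitManifest(assignment, out_counts, seed)


def select(studies: Sequence[Study], manifest: SplitManifest,
           split: str) -> list[Study]:
    wanted = set(manifest.ids(split))
    return [s for s in studies if s.study_id in wanted]
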