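"""Clip extraction, labelling, normalisation and patient-level splits.

A recording of T frames is cut into fixed 1000-frame clips anchored at the
video END: because nystagmus tends to emerge late in a positional test,
the remainder T mod 1000 is discarded from the *beginning* of the trace,
keeping the symptom-rich tail. A clip is labelled positive when strictly
more than 1% of its frames (i.e. more than 10 of 1000) are annotated as
nystagmus. Dataset splits are drawn per patient so no subject's clips
straddle partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Clip", "SplitManifest", "CLIP_LEN", "POSITIVE_FRACTION",
    "segment_from_end", "label_clip", "normalize_clip", "patient_split",
    "frame_labels_from_annotations", "augmented_training_size",
]

CLIP_LEN = 1000
POSITIVE_FRACTION = 0.01


@dataclass
class Clip:
    """A fixed-length gaze-trace window, the detector's classification unit."""

    x: np.ndarray
    label: int | None = None
    source: str = ""
    eye: str = "left"
    start: int = 0
    end: int = 0
    normalized: bool = False

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)


@dataclass
class SplitManifest:
    """Patient -> partition assignment with the ratios and seed used."""

    assignment: dict[str, str]
    ratios: tuple[int, int, int] = (8, 1, 1)
    seed: int = 0
    partitions: tuple[str, str, str] = ("train", "val", "test")

    def members(self, partition: str) -> list[str]:
        return [p for p, part in self.assignment.items() if part == partition]

    def partition_of(self, patient: str) -> str:
        return self.assignment[patient]


def segment_from_end(trace: np.ndarray, frame_labels: np.ndarray | None = None,
                     clip_len: int = CLIP_LEN, source: str = "",
                     eye: str = "left",
                     ) -> list[tuple[Clip, np.ndarray | None]]:
    """Tile a trace into clips of ``clip_len`` frames, anchored at the end.

    The leading ``T mod clip_len`` frames are discarded; a trace shorter
    than one clip yields an empty list. Clips are returned in chronological
    order, each with its per-frame label slice (or None when no labels are
    given).
    """
    if clip_len < 1:
        raise ValueError("clip_len must be >= 1")
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if frame_labels is not None:
        frame_labels = np.asarray(frame_labels)
        if len(frame_labels) != n:
            raise ValueError("frame_labels length must match trace length")
    n_clips = n // clip_len
    offset = n - n_clips * clip_len
    out = []
    for i in range(n_clips):
        a = offset + i * clip_len
        b = a + clip_len
        lab = None if frame_labels is None else frame_labels[a:b]
        clip = Clip(x=trace[a:b], source=source, eye=eye, start=a, end=b)
        if lab is not None:
            clip.label = label_clip(lab, clip_len=clip_len)
        out.append((clip, lab))
    return out


def label_clip(frame_labels: np.ndarray,
               positive_fraction: float = POSITIVE_FRACTION,
               clip_len: int = CLIP_LEN) -> int:
    """Label a clip 1 iff strictly more than ``positive_fraction`` of its
    frames are nystagmus-positive (default: more than 10 of 1000 frames).

    The boundary is strict: a clip with exactly 1% positive frames is
    negative.
    """
    frame_labels = np.asarray(frame_labels)
    if len(frame_labels) != clip_len:
        raise ValueError(f"expected {clip_len} frame labels, "
                         f"got {len(frame_labels)}")
    return int(np.count_nonzero(frame_labels) > positive_fraction * clip_len)


def normalize_clip(clip: Clip) -> Clip:
    """Centre on the median and scale by the standard deviation.

    Removes the arbitrary pixel offset of the pupil rest position and the
    amplitude scale, so the detector sees waveform shape only. Flat clips
    map to all-zeros (the scale is regularised by 1e-6).
    """
    x = clip.x
    xn = (x - np.median(x)) / (x.std() + 1e-6)
    return Clip(x=xn, label=clip.label, source=clip.source, eye=clip.eye,
                start=clip.start, end=clip.end, normalized=True)


def patient_split(patients: list[str], ratios: tuple[int, int, int] = (8, 1, 1),
                  seed: int = 0) -> SplitManifest:
    """Randomly partition patients into train/val/test at the given ratios.

    Partition sizes are the largest-remainder rounding of the ratio shares,
    so they always sum to the number of patients (e.g. 10 patients at 8:1:1
    give exactly 8/1/1). Clips inherit their patient's partition, keeping
    the evaluation subject-independent.
    """
    patients = list(patients)
    n = len(patients)
    if n < len(ratios):
        raise ValueError(f"need at least {len(ratios)} patients, got {n}")
    shares = np.asarray(ratios, dtype=float) / sum(ratios) * n
    sizes = np.floor(shares).astype(int)
    rem = shares - sizes
    for i in np.argsort(-rem)[: n - sizes.sum()]:
        sizes[i] += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    names = ("train", "val", "test")
    assignment: dict[str, str] = {}
    pos = 0
    for name, size in zip(names, sizes):
        for j in order[pos:pos + size]:
            assignment[patients[j]] = name
        pos += size
    return SplitManifest(assignment=assignment, ratios=tuple(ratios),
                         seed=seed)


def frame_labels_from_annotations(n_frames: int,
                                  annotations: pd.DataFrame | list[tuple[int, int]],
                                  ) -> np.ndarray:
    """Expand [start, end] positive frame ranges into per-frame labels.

    Annotation ranges are 1-based inclusive (the convention of the
    annotation CSVs, columns start_frame/end_frame); internally they become
    0-based half-open.
    """
    labels = np.zeros(n_frames, dtype=np.int8)
    if isinstance(annotations, pd.DataFrame):
        pairs = zip(annotations["start_frame"], annotations["end_frame"])
    else:
        pairs = annotations
    for start, end in pairs:
        if start < 1 or end < start:
            raise ValueError(f"bad annotation range [{start}, {end}]")
        labels[start - 1:end] = 1
    return labels


def augmented_training_size(n_samples: int, variants_per_sample: int = 3,
                            ratios: tuple[int, int, int] = (8, 1, 1),
                            ) -> tuple[int, int, int]:
    """Train/val/test sample counts after an 8:1:1 split where each training
    sample additionally contributes ``variants_per_sample`` augmented copies.
    """
    shares = np.asarray(ratios, dtype=float) / sum(ratios) * n_samples
    sizes = np.floor(shares).astype(int)
    rem = shares - sizes
    for i in np.argsort(-rem)[: n_samples - sizes.sum()]:
        sizes[i] += 1
    train, val, test = (int(v) for v in sizes)
    return train * (1 + variants_per_sample), val, test
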