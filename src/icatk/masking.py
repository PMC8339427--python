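"""Dynamic backward-mask generation.

The mask shown after each stimulus is built once per test from a single
white-noise field: the noise is smoothed at four spatial scales, each smoothed
image is thresholded at its median into a high-contrast binary pattern, and
each pattern is augmented by rotation/mirroring into four variants, giving a
pool of 16 frames.  A per-trial dynamic mask is a random sequence of eight
frames drawn so that every spatial scale appears exactly twice, displayed for
250 ms in total.

The binary patterns are plain ``numpy`` arrays with values in {0, 1}; frames
can be exported as 8-bit grayscale PNGs for use in an actual test runner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "MaskFrame",
    "MaskPool",
    "MaskSequence",
    "generate_noise_frame",
    "make_scale_variants",
    "build_mask_pool",
    "draw_mask_sequence",
    "export_pool",
    "N_SCALES",
    "N_VARIANTS",
    "SEQUENCE_LENGTH",
    "SEQUENCE_DURATION_MS",
    "DEFAULT_FRAME_SIZE",
]

N_SCALES = 4
N_VARIANTS = 4
SEQUENCE_LENGTH = 8
SEQUENCE_DURATION_MS = 250.0
DEFAULT_FRAME_SIZE = 256
MIN_FRAME_SIZE = 8

#: Gaussian smoothing standard deviations (pixels) for a 256-px frame, one per
#: spatial scale; a geometric ladder, rescaled proportionally for other sizes.
BASE_SIGMAS = (1.0, 2.0, 4.0, 8.0)


@dataclass(frozen=True)
class MaskFrame:
    """One binary mask frame at a given spatial scale.

    ``variant_index`` identifies which member of the rotation/mirror set the
    frame is: 1 = rotated 90 deg, 2 = rotated 180 deg, 3 = rotated 270 deg,
    4 = horizontal mirror.  The un-transformed pattern is not part of the
    pool (4 scales x 4 variants = 16 frames).
    """

    scale_index: int
    variant_index: int
    pattern: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not 1 <= self.scale_index <= N_SCALES:
            raise ValueError(f"scale_index must be in 1..{N_SCALES}, got {self.scale_index}")
        if not 1 <= self.variant_index <= N_VARIANTS:
            raise ValueError(f"variant_index must be in 1..{N_VARIANTS}, got {self.variant_index}")
        vals = np.unique(self.pattern)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask pattern must be strictly binary (0/1)")


@dataclass(frozen=True)
class MaskPool:
    """The full pool of 16 mask frames generated from one noise field."""

    frames: tuple[MaskFrame, ...]
    seed: int
    size: int

    def __post_init__(self) -> None:
        counts = scale_histogram(self.frames)
        if sorted(counts) != list(range(1, N_SCALES + 1)) or any(
            counts[s] != N_VARIANTS for s in counts
        ):
            raise ValueError(
                f"mask pool must hold {N_VARIANTS} frames for each of "
                f"{N_SCALES} scales; got histogram {counts}"
            )

    def __len__(self) -> int:
        return len(self.frames)

    def frames_at_scale(self, scale_index: int) -> list[MaskFrame]:
        return [f for f in self.frames if f.scale_index == scale_index]


@dataclass(frozen=True)
class MaskSequence:
    """An 8-frame dynamic mask; each spatial scale appears exactly twice."""

    frames: tuple[MaskFrame, ...]
    total_duration_ms: float = SEQUENCE_DURATION_MS

    def __post_init__(self) -> None:
        if len(self.frames) != SEQUENCE_LENGTH:
            raise ValueError(f"mask sequence must hold {SEQUENCE_LENGTH} frames")
        counts = scale_histogram(self.frames)
        if any(counts.get(s, 0) != 2 for s in range(1, N_SCALES + 1)):
            raise ValueError(f"each scale must appear exactly twice; got {counts}")
        if self.total_duration_ms <= 0:
            raise ValueError("total_duration_ms must be positive")

    @property
    def frame_duration_ms(self) -> float:
        """Per-frame display time under a uniform split of the sequence."""
        return self.total_duration_ms / len(self.frames)


def scale_histogram(frames) -> dict[int, int]:
    """Count frames per spatial scale."""
    counts: dict[int, int] = {}
    for f in frames:
        counts[f.scale_index] = counts.get(f.scale_index, 0) + 1
    return counts


def generate_noise_frame(seed: int, size: int = DEFAULT_FRAME_SIZE) -> np.ndarray:
    """Draw a square white-noise image with i.i.d. uniform [0, 1) intensities."""
    if size < MIN_FRAME_SIZE:
        raise ValueError(f"frame size must be >= {MIN_FRAME_SIZE}, got {size}")
    rng = np.random.default_rng(seed)
    return rng.random((size, size))


def _binarize(filtered: np.ndarray) -> np.ndarray:
    """Threshold an image at its median into a {0,1} pattern.

    Depends only on the rank order of intensities, so the output is invariant
    under any strictly increasing intensity rescaling.  A (near-)constant
    image has no meaningful median split and is rejected.
    """
    thr = np.median(filtered)
    pattern = (filtered > thr).astype(np.uint8)
    if pattern.min() == pattern.max():
        raise ValueError("degenerate input: constant image cannot be median-thresholded")
    return pattern


def _sigma_for(scale_index: int, size: int) -> float:
    return BASE_SIGMAS[scale_index - 1] * size / DEFAULT_FRAME_SIZE


def make_scale_variants(noise: np.ndarray, scale_index: int) -> list[MaskFrame]:
    """Smooth, threshold and augment one noise field at one spatial scale.

    Returns the four rotation/mirror variants of the binary pattern; the
    un-transformed pattern itself is not returned.
    """
    if not 1 <= scale_index <= N_SCALES:
        raise ValueError(f"scale_index must be in 1..{N_SCALES}, got {scale_index}")
    filtered = ndimage.gaussian_filter(
        np.asarray(noise, dtype=float), sigma=_sigma_for(scale_index, noise.shape[0]), mode="reflect"
    )
    base = _binarize(filtered)
    transforms = (
        np.rot90(base, 1),
        np.rot90(base, 2),
        np.rot90(base, 3),
        np.fliplr(base),
    )
    return [
        MaskFrame(scale_index=scale_index, variant_index=i + 1, pattern=np.ascontiguousarray(t))
        for i, t in enumerate(transforms)
    ]


def build_mask_pool(seed: int, size: int = DEFAULT_FRAME_SIZE) -> MaskPool:
    """Build the 16-frame mask pool from a single seeded noise field."""
    noise = generate_noise_frame(seed, size)
    frames: list[MaskFrame] = []
    for scale_index in range(1, N_SCALES + 1):
        frames.extend(make_scale_variants(noise, scale_index))
    return MaskPool(frames=tuple(frames), seed=seed, size=size)


def draw_mask_sequence(pool: MaskPool, rng_seed: int) -> MaskSequence:
    """Draw a random 8-frame sequence with each spatial scale appearing twice.

    Two distinct frames are sampled per scale, then the eight frames are
    shuffled into a random display order.  Reproducible for a given seed.
    """
    if not isinstance(pool, MaskPool):
        raise TypeError("pool must be a MaskPool")
    rng = np.random.default_rng(rng_seed)
    chosen: list[MaskFrame] = []
    for scale_index in range(1, N_SCALES + 1):
        at_scale = pool.frames_at_scale(scale_index)
        idx = rng.choice(len(at_scale), size=2, replace=False)
        chosen.extend(at_scale[i] for i in idx)
    order = rng.permutation(len(chosen))
    return MaskSequence(frames=tuple(chosen[i] for i in order))


def export_pool(pool: MaskPool, directory: str | Path) -> dict:
    """Write the pool as 8-bit grayscale PNGs (0/255) plus a JSON manifest.

    Returns the manifest dictionary.
    """
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for frame in pool.frames:
        name = f"mask_s{frame.scale_index}_v{frame.variant_index}.png"
        img = Image.fromarray((frame.pattern * 255).astype(np.uint8), mode="L")
        img.save(directory / name)
        entries.append(
            {
                "scale_index": frame.scale_index,
                "variant_index": frame.variant_index,
                "file": name,
            }
        )
    manifest = {"seed": pool.seed, "size": pool.size, "frames": entries}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
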