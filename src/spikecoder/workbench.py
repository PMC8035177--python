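"""Supporting engineering: seeding, fixtures, configuration and file I/O.

Seeding discipline: every source of randomness in the package is a
``numpy.random.Generator`` obtained from :func:`substream`, which derives a
child stream from a single root seed plus a tuple of labels (module name,
trial index, pixel coordinates, ...). Streams are independent and bitwise
reproducible; there is no hidden global random state.
"""

from __future__ import annotations

import hashlib
import json
import struct
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__version__ = "0.1.0"

__all__ = [
    "substream",
    "Fixture",
    "make_fixture",
    "RunConfig",
    "load_idx",
    "save_idx",
    "read_gray_image",
    "write_gray_image",
    "save_spike_volume",
    "load_spike_volume",
    "config_hash",
    "output_header",
]


# ---------------------------------------------------------------------------
# seeding

def _key_to_int(key) -> int:
    """Stable 32-bit hash of a stream label (int or str)."""
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    raise TypeError(f"stream keys must be int or str, got {type(key)!r}")


def substream(seed: int, *keys) -> np.random.Generator:
    """Child random generator derived from ``seed`` and a label tuple."""
    entropy = [int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy)))


# ---------------------------------------------------------------------------
# fixtures

FIXTURE_KINDS = ("gradient", "checkerboard", "disk-phantom", "blob-digits")

# Nominal pixel-noise scale (gray levels) that the blob-digit ``contrast``
# parameter is expressed against: class-template peak = contrast * 25 gray.
_BLOB_NOISE_UNIT = 25.0


@dataclass(frozen=True)
class Fixture:
    """Specification of a synthetic image fixture."""

    kind: str = "gradient"
    shape: tuple = (64, 64)
    n_classes: int = 10
    n_images: int = 100
    contrast: float = 8.0
    noise: float = 20.0
    tile: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if len(self.shape) != 2 or min(self.shape) < 1:
            raise ValueError(f"invalid shape {self.shape!r}")


def _gradient(shape) -> np.ndarray:
    h, w = shape
    if w > 1:
        row = np.round(np.arange(w) * 255.0 / (w - 1))
    else:
        row = np.zeros(1)
    return np.tile(row, (h, 1)).astype(np.uint8)


def _checkerboard(shape, tile) -> np.ndarray:
    h, w = shape
    r = np.arange(h)[:, None] // tile
    c = np.arange(w)[None, :] // tile
    return np.where((r + c) % 2 == 0, 0, 255).astype(np.uint8)


def _disk_phantom(shape) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = (yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2
    radius = min(h, w) / 4.0
    img = np.where(r2 <= radius**2, 220, 30)
    return img.astype(np.uint8)


def _blob_templates(n_classes: int, shape, seed: int) -> np.ndarray:
    """Per-class templates: a few Gaussian bumps at class-specific positions.

    Templates depend only on (n_classes, shape, seed); amplitudes normalized
    to a peak of 1.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    templates = np.zeros((n_classes, h, w))
    for k in range(n_classes):
        rng = substream(seed, "blob-template", k)
        n_blobs = 3
        t = np.zeros((h, w))
        for _ in range(n_blobs):
            cy = rng.uniform(0.2 * h, 0.8 * h)
            cx = rng.uniform(0.2 * w, 0.8 * w)
            s = rng.uniform(min(h, w) / 10.0, min(h, w) / 6.0)
            t += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
        templates[k] = t / t.max()
    return templates


def make_fixture(f: Fixture):
    """Generate the images (and labels, for blob digits) of a fixture.

    Returns a uint8 ``(H, W)`` image for the deterministic kinds, or a pair
    ``(images, labels)`` with images of shape ``(n_images, H, W)`` for
    ``blob-digits``. Blob-digit classes are Gaussian-bump templates scaled to
    a peak of ``contrast * 25`` gray levels with additive pixel noise of
    standard deviation ``noise``; labels are balanced round-robin.
    """
    if f.kind == "gradient":
        return _gradient(f.shape)
    if f.kind == "checkerboard":
        return _checkerboard(f.shape, f.tile)
    if f.kind == "disk-phantom":
        return _disk_phantom(f.shape)
    # blob-digits
    if f.n_classes < 2:
        raise ValueError("blob-digits needs at least 2 classes")
    templates = _blob_templates(f.n_classes, f.shape, f.seed)
    amp = f.contrast * _BLOB_NOISE_UNIT
    labels = np.arange(f.n_images) % f.n_classes
    rng = substream(f.seed, "blob-noise")
    noise = rng.normal(0.0, f.noise, size=(f.n_images, *f.shape)) if f.noise > 0 else 0.0
    images = np.clip(amp * templates[labels] + noise, 0, 255)
    return images.astype(np.uint8), labels.astype(np.int64)


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Serializable description of a run; a run is reproducible from this + seed."""

    mode: str = "rate"
    mu_tg: float = -2.5
    sigma_tg: float = 0.8
    i_st: float = 5e-10
    n_pulses: int = 32
    n_trials: int = 16
    t_p: float = 0.010
    seed: int = 0
    device: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def config_hash(obj) -> str:
    """Short stable hash of any YAML-serializable configuration object."""
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    elif hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    blob = yaml.safe_dump(obj, sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def output_header(seed=None, config=None) -> str:
    """Comment stanza stamped at the top of every CSV the tools emit."""
    parts = [f"# spikecoder v{__version__}"]
    if config is not None:
        parts.append(f"config_hash={config_hash(config)}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts) + "\n"


# ---------------------------------------------------------------------------
# IDX (MNIST) files

_IDX_DTYPES = {0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2", 0x0C: ">i4",
               0x0D: ">f4", 0x0E: ">f8"}


def load_idx(path) -> np.ndarray:
    """Read an IDX-format array (the MNIST container format)."""
    raw = Path(path).read_bytes()
    if len(raw) < 4 or raw[0] != 0 or raw[1] != 0:
        raise ValueError(f"{path}: not an IDX file")
    dtype_code, ndim = raw[2], raw[3]
    if dtype_code not in _IDX_DTYPES:
        raise ValueError(f"{path}: unknown IDX dtype 0x{dtype_code:02x}")
    dims = struct.unpack(f">{ndim}I", raw[4 : 4 + 4 * ndim])
    data = np.frombuffer(raw, dtype=_IDX_DTYPES[dtype_code], offset=4 + 4 * ndim)
    if data.size != int(np.prod(dims)):
        raise ValueError(f"{path}: truncated IDX payload")
    return data.reshape(dims).astype(data.dtype.newbyteorder("="))


def save_idx(path, array: np.ndarray) -> None:
    """Write a uint8 array in IDX format (for tests and interop)."""
    a = np.ascontiguousarray(array, dtype=np.uint8)
    header = bytes([0, 0, 0x08, a.ndim]) + struct.pack(f">{a.ndim}I", *a.shape)
    Path(path).write_bytes(header + a.tobytes())


# ---------------------------------------------------------------------------
# grayscale images (PGM / PNG via pillow)

def read_gray_image(path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def write_gray_image(path, image: np.ndarray) -> None:
    from PIL import Image

    a = np.asarray(image)
    if a.dtype != np.uint8:
        a = np.clip(np.round(a), 0, 255).astype(np.uint8)
    Image.fromarray(a, mode="L").save(path)


# ---------------------------------------------------------------------------
# spike volumes: bit-packed binary + JSON sidecar

def save_spike_volume(prefix, spikes: np.ndarray, meta: dict) -> None:
    """Store an H x W x T binary spike tensor as packed bits + sidecar."""
    prefix = Path(prefix)
    packed = np.packbits(spikes.astype(np.uint8).ravel())
    prefix.with_suffix(".bits").write_bytes(packed.tobytes())
    sidecar = dict(meta)
    sidecar["shape"] = [int(s) for s in spikes.shape]
    sidecar["version"] = __version__
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_spike_volume(prefix):
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    shape = tuple(meta["shape"])
    n = int(np.prod(shape))
    bits = np.unpackbits(
        np.frombuffer(prefix.with_suffix(".bits").read_bytes(), dtype=np.uint8),
        count=n,
    )
    return bits.reshape(shape).astype(bool), meta
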