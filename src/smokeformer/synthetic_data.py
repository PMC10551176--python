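"""Procedural surgical-smoke dataset synthesis.

Emulates an endoscopic smoke-classification corpus: low-texture, red-dominant
tissue-like base frames (multi-octave value noise, radial vignette, a few
specular highlights) plus translucent smoke plumes rendered procedurally from
multi-octave fractal noise under a Gaussian spatial envelope, composited
additively onto the base frame and clipped at sensor saturation.

A plume is controlled by three parameters — intensity (peak luminance scale),
density (spatial extent of the envelope) and position (plume centre) — and a
seed, so every image in a built dataset is reproducible byte-for-byte.

The reference-scale configuration builds 5,000 frames at 384x192 of which 1,000
carry smoke, split 3,800 train / 1,200 test with a 4:1 smoke-free:smoke ratio
in each split.
"""

from __future__ import annotations

import csv
import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import yaml
from PIL import Image as PILImage

__all__ = [
    "SmokeParams",
    "SmokeLayer",
    "SynthConfig",
    "DatasetManifest",
    "generate_base_frame",
    "render_smoke",
    "compose",
    "build_dataset",
]

LABEL_SMOKE = "smoke"
LABEL_SMOKE_FREE = "smoke_free"

# support radius of the plume envelope in units of sigma (envelope floor)
_ENVELOPE_CUTOFF_SIGMA = 1.5
_ENVELOPE_FLOOR = float(np.exp(-0.5 * _ENVELOPE_CUTOFF_SIGMA**2))
# peak additive luminance at intensity 1 before noise modulation
_PEAK_LUMINANCE = 230.0


@dataclass(frozen=True)
class SmokeParams:
    """Parameters of one rendered smoke layer."""

    intensity: float  # peak luminance scale in [0, 1]
    density: float    # envelope extent in [0, 1]
    position: tuple[float, float]  # (row, col) plume centre, 0-based
    seed: int = 0

    def validate(self, height: int, width: int) -> None:
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError(f"intensity must be in [0, 1], got {self.intensity}")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError(f"density must be in [0, 1], got {self.density}")
        r, c = self.position
        if not (0 <= r < height and 0 <= c < width):
            raise ValueError(
                f"position {self.position} outside frame {height}x{width}"
            )


@dataclass
class SmokeLayer:
    """Additive luminance contribution of one plume."""

    values: np.ndarray        # (H, W) float, >= 0
    support_mask: np.ndarray  # (H, W) bool, True exactly where values > 0


def _check_dims(height: int, width: int) -> None:
    if height < 32 or width < 32:
        raise ValueError(f"frame dimensions must be >= 32, got {height}x{width}")


def _bilinear_upsample(grid: np.ndarray, height: int, width: int) -> np.ndarray:
    """Separable bilinear upsampling of a small lattice to (height, width)."""
    gh, gw = grid.shape
    x = np.linspace(0.0, gw - 1.0, width)
    x0 = np.minimum(x.astype(int), gw - 2)
    fx = x - x0
    rows = grid[:, x0] * (1.0 - fx) + grid[:, x0 + 1] * fx
    y = np.linspace(0.0, gh - 1.0, height)
    y0 = np.minimum(y.astype(int), gh - 2)
    fy = (y - y0)[:, None]
    return rows[y0, :] * (1.0 - fy) + rows[y0 + 1, :] * fy


def _value_noise(rng: np.random.Generator, height: int, width: int,
                 base_cells: int = 4, octaves: int = 3) -> np.ndarray:
    """Multi-octave smooth value noise, roughly zero-mean, unit-ish scale."""
    out = np.zeros((height, width))
    amp = 1.0
    cells = base_cells
    for _ in range(octaves):
        grid = rng.standard_normal((cells + 1, cells + 1))
        out += amp * _bilinear_upsample(grid, height, width)
        amp *= 0.5
        cells *= 2
    return out / 1.75  # sum of amplitudes


def _rng_for(seed: int, stream: int) -> np.random.Generator:
    if seed < 0:
        raise ValueError("seed must be non-negative")
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def generate_base_frame(seed: int, height: int, width: int) -> np.ndarray:
    """Tissue-like smoke-free base frame, (H, W, 3) uint8.

    Red-dominant smooth noise, a radial vignette darkening toward the
    corners, and 0-3 specular highlight blobs emulating non-Lambertian wet
    tissue.  Deterministic for a fixed seed.
    """
    _check_dims(height, width)
    rng = _rng_for(seed, 0)

    r = 150.0 + 26.0 * _value_noise(rng, height, width)
    g = 66.0 + 18.0 * _value_noise(rng, height, width)
    b = 44.0 + 8.0 * _value_noise(rng, height, width)

    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    d2 = ((yy - cy) / max(cy, 1.0)) ** 2 + ((xx - cx) / max(cx, 1.0)) ** 2
    vignette = 1.0 - 0.45 * d2 / 2.0

    frame = np.stack([r, g, b], axis=-1) * vignette[..., None]

    n_highlights = int(rng.integers(0, 4))
    for _ in range(n_highlights):
        hy = rng.uniform(0, height)
        hx = rng.uniform(0, width)
        sigma = rng.uniform(2.0, min(height, width) / 12.0)
        amp = rng.uniform(40.0, 90.0)
        blob = amp * np.exp(-(((yy - hy) ** 2 + (xx - hx) ** 2) / (2 * sigma**2)))
        frame += blob[..., None]

    return np.clip(frame, 0, 255).astype(np.uint8)


def render_smoke(params: SmokeParams, height: int, width: int) -> SmokeLayer:
    """Render one plume as an additive luminance layer.

    The layer is strictly positive fractal noise modulated by a Gaussian
    envelope centred at ``params.position`` whose width grows with density;
    the envelope is floored so the plume has compact support.  The peak value
    scales linearly (hence strictly monotonically) with intensity, and the
    support area grows monotonically with density for a fixed seed.
    """
    _check_dims(height, width)
    params.validate(height, width)
    if params.intensity == 0.0:
        zeros = np.zeros((height, width))
        return SmokeLayer(values=zeros, support_mask=zeros > 0)

    rng = _rng_for(params.seed, 1)
    # noise field independent of density so the support set is nested in sigma
    noise = 0.15 + 0.85 * np.clip(0.5 + 0.5 * _value_noise(rng, height, width,
                                                           base_cells=6, octaves=4), 0.0, 1.0)
    sigma = (0.08 + 0.30 * params.density) * min(height, width)
    yy, xx = np.mgrid[0:height, 0:width]
    r0, c0 = params.position
    envelope = np.exp(-(((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * sigma**2)))
    envelope = np.clip((envelope - _ENVELOPE_FLOOR) / (1.0 - _ENVELOPE_FLOOR), 0.0, None)

    values = params.intensity * _PEAK_LUMINANCE * noise * envelope
    return SmokeLayer(values=values, support_mask=values > 0)


def compose(original: np.ndarray, smoke: SmokeLayer) -> np.ndarray:
    """Additive compositing: per-channel addition of the smoke luminance,
    clipped at 255.  Pixels outside the plume support are unchanged."""
    if original.shape[:2] != smoke.values.shape:
        raise ValueError(
            f"shape mismatch: image {original.shape[:2]} vs smoke {smoke.values.shape}"
        )
    out = np.clip(original.astype(np.float64) + smoke.values[..., None], 0.0, 255.0)
    if np.issubdtype(original.dtype, np.integer):
        return np.rint(out).astype(original.dtype)
    return out.astype(original.dtype)


# ---------------------------------------------------------------------------
# dataset construction
# ---------------------------------------------------------------------------

@dataclass
class SynthConfig:
    """Settings for one built dataset.

    ``smoke_fraction`` is the share of smoke-labelled images overall and
    within each split (1/5 reproduces the 4:1 smoke-free:smoke ratio);
    ``test_fraction`` is the share of images held out as the test split.
    """

    total: int = 5000
    smoke_fraction: float = 0.2
    test_fraction: float = 0.24
    height: int = 192
    width: int = 384
    intensity_range: tuple[float, float] = (0.3, 1.0)
    density_range: tuple[float, float] = (0.3, 0.9)
    position_margin: float = 0.15  # plume centre kept this fraction away from borders
    seed: int = 0

    @classmethod
    def reference_scale(cls, seed: int = 0) -> "SynthConfig":
        """5,000 frames at 384x192, 1,000 smoke, 3,800/1,200 split."""
        return cls(seed=seed)

    @classmethod
    def reduced(cls, total: int = 500, size: int = 64, seed: int = 0,
                test_fraction: float = 0.2) -> "SynthConfig":
        return cls(total=total, test_fraction=test_fraction,
                   height=size, width=size, seed=seed)

    def counts(self) -> dict[tuple[str, str], int]:
        """Exact per-(split, label) image counts; raises if non-integer."""
        def _int(x: float, what: str) -> int:
            n = x * self.total
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"{what} does not yield an integer image count: "
                    f"{x} x {self.total} = {n}"
                )
            return int(round(n))

        n_smoke = _int(self.smoke_fraction, "smoke_fraction")
        n_test = _int(self.test_fraction, "test_fraction")
        test_smoke = self.smoke_fraction * n_test
        if abs(test_smoke - round(test_smoke)) > 1e-9:
            raise ValueError(
                f"smoke_fraction x test size is not an integer: "
                f"{self.smoke_fraction} x {n_test} = {test_smoke}"
            )
        test_smoke = int(round(test_smoke))
        n_train = self.total - n_test
        train_smoke = n_smoke - test_smoke
        return {
            ("train", LABEL_SMOKE_FREE): n_train - train_smoke,
            ("train", LABEL_SMOKE): train_smoke,
            ("test", LABEL_SMOKE_FREE): n_test - test_smoke,
            ("test", LABEL_SMOKE): test_smoke,
        }

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        for key in ("intensity_range", "density_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SynthConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class DatasetManifest:
    """Index of a built dataset: (path, label, split) per image."""

    records: list[tuple[str, str, str]] = field(default_factory=list)
    seed: int = 0
    root: str = "."

    @property
    def counts(self) -> dict[tuple[str, str], int]:
        tally: dict[tuple[str, str], int] = {}
        for _, label, split in self.records:
            tally[(split, label)] = tally.get((split, label), 0) + 1
        return tally

    def subset(self, split: str) -> "DatasetManifest":
        recs = [r for r in self.records if r[2] == split]
        return DatasetManifest(records=recs, seed=self.seed, root=self.root)

    def labels(self) -> np.ndarray:
        return np.array([1 if lab == LABEL_SMOKE else 0 for _, lab, _ in self.records])

    def paths(self) -> list[str]:
        return [os.path.join(self.root, p) for p, _, _ in self.records]

    def save(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["path", "label", "split"])
            writer.writerows(self.records)

    @classmethod
    def load(cls, path: str, seed: int = 0) -> "DatasetManifest":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if header != ["path", "label", "split"]:
                raise ValueError(f"unexpected manifest header: {header}")
            records = [(p, lab, sp) for p, lab, sp in reader]
        return cls(records=records, seed=seed, root=os.path.dirname(path) or ".")


def _sample_smoke_params(cfg: SynthConfig, rng: np.random.Generator) -> SmokeParams:
    lo_i, hi_i = cfg.intensity_range
    lo_d, hi_d = cfg.density_range
    mr = cfg.position_margin * cfg.height
    mc = cfg.position_margin * cfg.width
    return SmokeParams(
        intensity=float(rng.uniform(lo_i, hi_i)),
        density=float(rng.uniform(lo_d, hi_d)),
        position=(float(rng.uniform(mr, cfg.height - 1 - mr)),
                  float(rng.uniform(mc, cfg.width - 1 - mc))),
        seed=int(rng.integers(0, 2**31)),
    )


def synthesize_image(cfg: SynthConfig, index: int, smoky: bool) -> np.ndarray:
    """Render image ``index`` of the dataset (deterministic in cfg.seed)."""
    frame = generate_base_frame(int(np.random.SeedSequence(
        [cfg.seed, index, 2]).generate_state(1)[0] % 2**31), cfg.height, cfg.width)
    if smoky:
        rng = _rng_for(cfg.seed, 3 + index)
        params = _sample_smoke_params(cfg, rng)
        frame = compose(frame, render_smoke(params, cfg.height, cfg.width))
    return frame


def build_dataset(cfg: SynthConfig, out_dir: str,
                  progress: bool = False) -> DatasetManifest:
    """Write the full image set and its CSV manifest under ``out_dir``.

    Deterministic: the same config (including seed) reproduces every PNG and
    the manifest byte-for-byte.  Returns the manifest; the CSV is written to
    ``out_dir/manifest.csv`` and images to ``out_dir/images/``.
    """
    _check_dims(cfg.height, cfg.width)
    counts = cfg.counts()
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)

    cells = [("train", LABEL_SMOKE_FREE), ("train", LABEL_SMOKE),
             ("test", LABEL_SMOKE_FREE), ("test", LABEL_SMOKE)]
    records: list[tuple[str, str, str]] = []
    index = 0
    iterator = None
    if progress:
        try:
            from tqdm import tqdm
            # disable=None: no bar when stderr is not a terminal
            iterator = tqdm(total=cfg.total, desc="synthesizing", unit="img",
                            disable=None)
        except ImportError:
            iterator = None
    for split, label in cells:
        for _ in range(counts[(split, label)]):
            frame = synthesize_image(cfg, index, smoky=(label == LABEL_SMOKE))
            rel = os.path.join("images", f"img_{index:05d}.png")
            PILImage.fromarray(frame).save(os.path.join(out_dir, rel))
            records.append((rel, label, split))
            index += 1
            if iterator is not None:
                iterator.update(1)
    if iterator is not None:
        iterator.close()

    manifest = DatasetManifest(records=records, seed=cfg.seed, root=out_dir)
    manifest.save(os.path.join(out_dir, "manifest.csv"))
    return manifest
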