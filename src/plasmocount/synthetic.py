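"""Synthetic darkfield scenes with ground truth.

Darkfield immunoplasmonic micrographs have a characteristic structure: a
near-black background, faint diffuse clutter where cell membranes scatter
broadband light, and bright diffraction-limited spots — individual plasmonic
nanoparticles — whose scattering colour identifies the particle type. The
generator emulates exactly that structure so every pipeline stage can be
exercised against known ground truth:

* three chromatic particle classes (blue / green / yellow) with intra-class
  colour spread drawn from a per-class Gaussian HSV model;
* an isotropic Gaussian point-spread function, widened and attenuated for
  slices away from the particle's focal plane, across a small z-stack;
* diffuse low-intensity clutter blobs;
* Poisson shot noise plus Gaussian read noise, clipped to the bit depth.

Randomness comes from a single per-scene seed; placement, colour, clutter
and noise use fixed sub-streams of it so each component is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skimage import color as _skcolor

from .errors import GenerationError, InvalidInputError
from .io import RGBStack

__all__ = [
    "ClassColour",
    "ClassColourModel",
    "SceneParams",
    "default_colour_model",
    "sample_scene",
    "sample_labelled_features",
]


@dataclass(frozen=True)
class ClassColour:
    """Gaussian HSV colour model of one particle class.

    Hue is on the unit colour circle (draws wrap modulo 1); saturation and
    value draws are clipped to [0, 1]. The amplitude is the peak additive
    brightness of an in-focus spot, in pixel-value units of the target bit
    depth before the colour's V scaling.
    """

    h_mean: float
    h_sd: float = 0.02
    s_mean: float = 0.8
    s_sd: float = 0.05
    v_mean: float = 0.8
    v_sd: float = 0.1
    amp_mean: float = 30.0
    amp_sd: float = 3.0

    def __post_init__(self) -> None:
        for name in ("h_mean", "s_mean", "v_mean"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise InvalidInputError(f"{name} must lie in [0, 1]; got {val}")
        for name in ("h_sd", "s_sd", "v_sd", "amp_sd"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")


ClassColourModel = dict[str, ClassColour]


def default_colour_model(**overrides) -> ClassColourModel:
    """Three well-separated hue clusters at canonical blue/green/yellow.

    Keyword overrides are forwarded to every class (e.g. ``h_sd=0.1`` to
    create a harder, overlapping benchmark).
    """
    hues = {"blue": 0.60, "green": 0.33, "yellow": 0.12}
    return {name: ClassColour(h_mean=h, **overrides) for name, h in hues.items()}


@dataclass(frozen=True)
class SceneParams:
    """Geometry, optics, clutter and noise of one synthetic acquisition."""

    shape: tuple[int, int] = (512, 512)
    n_slices: int = 5
    counts: dict = field(default_factory=lambda: {"blue": 50, "green": 50, "yellow": 50})
    psf_sigma_px: float = 1.5
    min_separation_px: float = 10.0
    placement_margin_px: int = 8
    background_level: float = 2.0
    n_clutter: int = 15
    clutter_sigma_px: tuple[float, float] = (4.0, 8.0)
    clutter_intensity: float = 1.5
    read_noise_sd: float = 2.0
    poisson_gain: float = 1.0  # photoelectrons per pixel unit; 0 disables shot noise
    focus_sigma_slices: float = 1.2
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise InvalidInputError("particle counts must be >= 0")
        if self.n_slices < 1:
            raise InvalidInputError("n_slices must be >= 1")
        if self.bit_depth not in (8, 16):
            raise InvalidInputError("bit_depth must be 8 or 16")
        if self.psf_sigma_px <= 0:
            raise InvalidInputError("psf_sigma_px must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _substream(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _place_particles(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample integer centres at the required minimum separation."""
    n_total = int(sum(params.counts.values()))
    rows, cols = params.shape
    m = params.placement_margin_px
    if rows - 2 * m <= 0 or cols - 2 * m <= 0:
        raise GenerationError("image too small for the placement margin")
    placed: list[tuple[int, int]] = []
    max_attempts = 300 * max(n_total, 1)
    attempts = 0
    d2_min = params.min_separation_px**2
    while len(placed) < n_total and attempts < max_attempts:
        attempts += 1
        r = int(rng.integers(m, rows - m))
        c = int(rng.integers(m, cols - m))
        if all((r - pr) ** 2 + (c - pc) ** 2 >= d2_min for pr, pc in placed):
            placed.append((r, c))
    if len(placed) < n_total:
        raise GenerationError(
            f"could only place {len(placed)} of {n_total} particles at "
            f"separation {params.min_separation_px} px"
        )
    return np.array(placed, dtype=int)


def _draw_class_hsv(model: ClassColour, n: int, rng: np.random.Generator) -> np.ndarray:
    h = (rng.normal(model.h_mean, model.h_sd, n)) % 1.0
    s = np.clip(rng.normal(model.s_mean, model.s_sd, n), 0.0, 1.0)
    v = np.clip(rng.normal(model.v_mean, model.v_sd, n), 0.0, 1.0)
    return np.column_stack([h, s, v])


def _add_gaussian_blob(
    canvas: np.ndarray, r: float, c: float, sigma: float, amplitude_rgb: np.ndarray
) -> None:
    """Accumulate ``amplitude_rgb * exp(-d^2 / 2 sigma^2)`` around (r, c)."""
    rows, cols = canvas.shape[:2]
    half = int(np.ceil(4 * sigma))
    r0, r1 = max(0, int(r) - half), min(rows, int(r) + half + 1)
    c0, c1 = max(0, int(c) - half), min(cols, int(c) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1, dtype=float) - r
    cc = np.arange(c0, c1, dtype=float) - c
    g = np.exp(-(rr[:, None] ** 2 + cc[None, :] ** 2) / (2.0 * sigma**2))
    canvas[r0:r1, c0:c1] += g[..., None] * amplitude_rgb[None, None, :]


def sample_scene(
    params: SceneParams,
    colours: ClassColourModel | None = None,
) -> tuple[RGBStack, pd.DataFrame]:
    """Render one synthetic z-stack and its ground-truth particle table.

    Deterministic for a fixed ``params.seed``. The ground truth has one row
    per particle: ``particle_id, row, col, label, amplitude, focal_slice``
    plus the drawn ``h, s, v`` colour.
    """
    colours = colours if colours is not None else default_colour_model()
    unknown = set(params.counts) - set(colours)
    if unknown:
        raise InvalidInputError(f"counts refer to unknown classes: {sorted(unknown)}")

    rng_place = _substream(params.seed, 0)
    rng_colour = _substream(params.seed, 1)
    rng_clutter = _substream(params.seed, 2)
    rng_noise = _substream(params.seed, 3)

    positions = _place_particles(params, rng_place)
    rows, cols = params.shape
    max_value = (1 << params.bit_depth) - 1

    # ground truth assembly
    labels = [name for name, n in params.counts.items() for _ in range(int(n))]
    n_total = len(labels)
    records = []
    hsv_draws = np.zeros((n_total, 3))
    amps = np.zeros(n_total)
    focal = rng_colour.integers(0, params.n_slices, n_total)
    i = 0
    for name, n in params.counts.items():
        n = int(n)
        model = colours[name]
        hsv_draws[i : i + n] = _draw_class_hsv(model, n, rng_colour)
        amps[i : i + n] = np.clip(
            rng_colour.normal(model.amp_mean, model.amp_sd, n), 0.0, None
        )
        i += n
    rgb_unit = _skcolor.hsv2rgb(hsv_draws.reshape(1, -1, 3)).reshape(-1, 3)

    # static parts: background pedestal + diffuse membrane clutter
    base = np.full((rows, cols, 3), float(params.background_level))
    lo, hi = params.clutter_sigma_px
    for _ in range(params.n_clutter):
        cr = rng_clutter.uniform(0, rows)
        cc = rng_clutter.uniform(0, cols)
        csig = rng_clutter.uniform(lo, hi)
        # weak desaturated scatter typical of membranes
        tint = np.array([0.9, 0.95, 1.0]) * rng_clutter.uniform(0.5, 1.0)
        _add_gaussian_blob(base, cr, cc, csig, params.clutter_intensity * tint)

    stack = np.zeros((params.n_slices, rows, cols, 3), dtype=np.uint8 if params.bit_depth == 8 else np.uint16)
    for z in range(params.n_slices):
        canvas = base.copy()
        for p in range(n_total):
            dz = z - int(focal[p])
            atten = np.exp(-(dz**2) / (2.0 * params.focus_sigma_slices**2))
            if atten < 1e-3:
                continue
            sigma_z = params.psf_sigma_px * np.sqrt(1.0 + (dz / 1.5) ** 2)
            _add_gaussian_blob(
                canvas,
                float(positions[p, 0]),
                float(positions[p, 1]),
                sigma_z,
                amps[p] * atten * rgb_unit[p],
            )
        if params.poisson_gain > 0:
            canvas = rng_noise.poisson(canvas * params.poisson_gain) / params.poisson_gain
        canvas = canvas + rng_noise.normal(0.0, params.read_noise_sd, canvas.shape)
        stack[z] = np.clip(np.round(canvas), 0, max_value).astype(stack.dtype)

    for p in range(n_total):
        records.append(
            {
                "particle_id": p,
                "row": int(positions[p, 0]),
                "col": int(positions[p, 1]),
                "label": labels[p],
                "amplitude": float(amps[p]),
                "focal_slice": int(focal[p]),
                "h": float(hsv_draws[p, 0]),
                "s": float(hsv_draws[p, 1]),
                "v": float(hsv_draws[p, 2]),
            }
        )
    truth = pd.DataFrame(
        records,
        columns=["particle_id", "row", "col", "label", "amplitude", "focal_slice", "h", "s", "v"],
    )
    return RGBStack(data=stack, bit_depth=params.bit_depth), truth


def sample_labelled_features(
    n_per_class: int,
    colours: ClassColourModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Direct labelled draws from the colour model, bypassing rendering.

    Fast substitute for extracting features from rendered control scenes;
    useful for classifier unit tests. Deterministic per seed.
    """
    if n_per_class < 1:
        raise InvalidInputError("n_per_class must be >= 1")
    colours = colours if colours is not None else default_colour_model()
    rng = _substream(seed, 1)
    frames = []
    for name in colours:
        hsv = _draw_class_hsv(colours[name], n_per_class, rng)
        frames.append(
            pd.DataFrame(
                {"h": hsv[:, 0], "s": hsv[:, 1], "v": hsv[:, 2], "label": name}
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "detection_id", np.arange(len(out)))
    return out
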