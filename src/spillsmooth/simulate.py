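"""Dense synthetic tissue generator with known per-cell ground truth.

The generator emulates a field of small, densely packed cells imaged at a
configurable resolution:

1. A super-resolved 3D label volume is generated procedurally: seed
   points on a jittered grid (one per target cell) are turned into a
   space-filling power diagram (additively-weighted Voronoi), whose cells
   are convex, connected and size-dispersed; across z-slices the seed
   points drift slowly so the same cell occupies nearby xy positions in
   adjacent slices, emulating a 3D cell.
2. Every cell is assigned a positive/negative class per channel by an
   i.i.d. Bernoulli draw, and a mean expression drawn from an
   exp-transformed truncated normal (or fixed class means for
   deterministic channels).
3. A per-pixel mean-intensity stack is rendered (whole-cell or
   membrane-only localization, plus an offset and smooth gradient
   noise), downsampled in xy (block mean) and projected over z, and
   finally Poisson-sampled into a counts image.

A noise-free variant (no offset, no noise, no Poisson step) is emitted
alongside for studying the resolution-driven limits of mean aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .model import IntensityImage, LabelMask
from .morphology import boundary_labels
from .aggregate import cell_table_skeleton

__all__ = [
    "ChannelSpec",
    "SimulationConfig",
    "SimulatedDataset",
    "generate_label_volume",
    "assign_classes",
    "draw_cell_means",
    "render_mean_intensity",
    "downsample_mask",
    "downsample_intensity",
    "sample_counts",
    "poissonize_image",
    "simulate_dataset",
    "default_channels",
]


@dataclass(frozen=True)
class ChannelSpec:
    """Marker channel recipe.

    ``mu_neg`` / ``mu_pos`` are the (pre-exp) truncated-normal means of
    the negative and positive populations; ``sigma`` their shared sd.
    ``deterministic`` channels skip the random draw and the exponential
    transform entirely: cell means are ``mu_neg`` / ``mu_pos`` as given.
    ``localization`` puts the signal either across the whole cell or only
    on its boundary ring. ``offset`` and smooth gradient noise
    (``noise_amplitude`` × noise in [0, 1] with correlation length
    ``noise_scale_px``) are added everywhere, background included.
    """

    name: str
    mu_neg: float = 0.5
    mu_pos: float = 1.3
    sigma: float = 0.3
    deterministic: bool = False
    localization: str = "whole_cell"  # or "membrane"
    offset: float = 0.1
    noise_amplitude: float = 0.2
    noise_scale_px: float = 20.0

    def __post_init__(self):
        if self.mu_pos < self.mu_neg:
            raise ValueError("mu_pos must be >= mu_neg")
        if self.sigma < 0 or self.offset < 0 or self.noise_amplitude < 0:
            raise ValueError("sigma, offset, noise_amplitude must be >= 0")
        if self.noise_scale_px <= 0:
            raise ValueError("noise_scale_px must be > 0")
        if self.localization not in ("whole_cell", "membrane"):
            raise ValueError("localization must be 'whole_cell' or 'membrane'")


def default_channels() -> list[ChannelSpec]:
    """The two study channels: a noisy low-contrast marker ('ch0') and a
    noiseless high-contrast one ('ch5')."""
    return [
        ChannelSpec("ch0", mu_neg=0.5, mu_pos=1.3, sigma=0.3),
        ChannelSpec(
            "ch5", mu_neg=0.0, mu_pos=100.0, sigma=0.0, deterministic=True,
            offset=0.0, noise_amplitude=0.0,
        ),
    ]


@dataclass
class SimulationConfig:
    """All generator parameters.

    ``field_um`` is the physical field size; the full-resolution grid has
    ``super_res_px_per_um`` pixels per micrometer per axis. Cell geometry
    is calibrated so the median 2D footprint is ``target_median_area_um2``
    (default 31 μm², a typical small densely-packed cell of ~6 μm median
    diameter). ``xy_downsample_factor`` sets the acquisition resolution
    (factor = super_res_px_per_um gives 1 μm pixels, the IMC convention).
    """

    field_um: tuple[float, float] = (200.0, 200.0)
    super_res_px_per_um: int = 4
    n_z_slices: int = 1
    target_median_area_um2: float = 31.0
    p_positive: float = 0.5
    channels: list[ChannelSpec] = field(default_factory=default_channels)
    xy_downsample_factor: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.super_res_px_per_um < 1 or self.xy_downsample_factor < 1:
            raise ValueError("resolution factors must be >= 1")
        if self.n_z_slices < 1:
            raise ValueError("n_z_slices must be >= 1")
        if not 0.0 <= self.p_positive <= 1.0:
            raise ValueError("p_positive must be in [0, 1]")

    @property
    def grid_shape(self) -> tuple[int, int]:
        s = self.super_res_px_per_um
        return int(round(self.field_um[0] * s)), int(round(self.field_um[1] * s))

    @property
    def output_pixel_size_um(self) -> float:
        return self.xy_downsample_factor / self.super_res_px_per_um


@dataclass
class SimulatedDataset:
    """Everything one simulated acquisition produces."""

    mask: LabelMask                       # downsampled acquisition mask
    counts: dict[str, IntensityImage]     # Poisson counts per channel
    noise_free: dict[str, IntensityImage]  # clean mean-intensity per channel
    truth: pd.DataFrame                   # per-cell class + drawn mean per channel
    cells: pd.DataFrame                   # id/area/centroid skeleton
    mask_full: LabelMask                  # one full-resolution slice (geometry QC)
    config: SimulationConfig


# ---------------------------------------------------------------------------
# geometry


def _seed_points(config: SimulationConfig, rng: np.random.Generator):
    """Jittered-grid seed points (μm) and power-diagram weights."""
    h_um, w_um = config.field_um
    spacing = float(np.sqrt(config.target_median_area_um2))
    nr = max(int(round(h_um / spacing)), 1)
    nc = max(int(round(w_um / spacing)), 1)
    n = nr * nc
    if n < 10:
        raise ValueError(
            f"target area {config.target_median_area_um2} μm² yields only {n} cells "
            f"in a {h_um}×{w_um} μm field; need at least 10"
        )
    rr = (np.arange(nr) + 0.5) * (h_um / nr)
    cc = (np.arange(nc) + 0.5) * (w_um / nc)
    pts = np.stack(np.meshgrid(rr, cc, indexing="ij"), axis=-1).reshape(-1, 2)
    pts = pts + rng.uniform(-0.35 * spacing, 0.35 * spacing, size=pts.shape)
    # additive (power-diagram) weights give mild, connected size dispersion
    weights = rng.uniform(0.0, (0.45 * spacing) ** 2, size=n)
    return pts, weights


def _assign_labels(
    shape: tuple[int, int],
    pts_um: np.ndarray,
    weights: np.ndarray,
    px_um: float,
    k: int = 12,
) -> np.ndarray:
    """Label every pixel by its power-diagram cell (argmin of squared
    distance minus weight over the k Euclidean-nearest seeds)."""
    h, w = shape
    rows = (np.arange(h) + 0.5) * px_um
    cols = (np.arange(w) + 0.5) * px_um
    grid = np.stack(np.meshgrid(rows, cols, indexing="ij"), axis=-1).reshape(-1, 2)
    tree = cKDTree(pts_um)
    k = min(k, len(pts_um))
    dist, idx = tree.query(grid, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    power = dist * dist - weights[idx]
    winner = idx[np.arange(len(grid)), power.argmin(axis=1)]
    return (winner + 1).reshape(h, w).astype(np.int32)


def generate_label_volume(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Super-resolved ``(n_z, H, W)`` label volume of densely packed cells.

    Slices are correlated: the same seed points drift by a small random
    walk across z, so each cell's footprint moves smoothly through the
    stack (a proxy for a 3D cell body).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pts, weights = _seed_points(config, rng)
    shape = config.grid_shape
    px_um = 1.0 / config.super_res_px_per_um
    # per-slice random-walk sd of the seed points; ~1 μm per slice makes a
    # cell traverse a third of its diameter over a 4-slice stack, which is
    # what couples z-depth to lateral mixing after projection
    drift_sd_um = 1.0
    vol = np.empty((config.n_z_slices, *shape), dtype=np.int32)
    cur = pts.copy()
    for z in range(config.n_z_slices):
        if z > 0:
            cur = cur + rng.normal(0.0, drift_sd_um, size=cur.shape)
        vol[z] = _assign_labels(shape, cur, weights, px_um)
    return vol


# ---------------------------------------------------------------------------
# ground truth


def assign_classes(
    labels: np.ndarray,
    p_positive: float,
    rng: np.random.Generator,
    channel_names: list[str],
) -> pd.DataFrame:
    """I.i.d. Bernoulli(p_positive) class per cell per channel, independent
    across channels. Returns a truth table with one ``class_<ch>`` column
    per channel."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("label volume contains no cells")
    truth = pd.DataFrame({"cell_id": ids.astype(int)})
    for name in channel_names:
        truth[f"class_{name}"] = rng.binomial(1, p_positive, size=ids.size)
    return truth


def _truncnorm_exp_draws(
    mu: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """exp(t), t ~ Normal(mu, sigma) truncated to [0, ∞)."""
    if sigma == 0:
        return np.exp(np.maximum(mu, 0.0))
    a = (0.0 - mu) / sigma
    t = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, random_state=rng)
    return np.exp(t)


def draw_cell_means(
    truth: pd.DataFrame, spec: ChannelSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill per-cell mean expression for one channel into the truth table.

    Deterministic channels use the class means directly; otherwise the
    mean is ``exp(t)`` with ``t`` drawn from a Normal(mu_class, sigma)
    truncated to [0, ∞).
    """
    cls = truth[f"class_{spec.name}"].to_numpy()
    mu = np.where(cls == 1, spec.mu_pos, spec.mu_neg).astype(np.float64)
    if spec.deterministic:
        means = mu
    else:
        means = _truncnorm_exp_draws(mu, spec.sigma, rng)
    out = truth.copy()
    out[f"mean_{spec.name}"] = means
    return out


# ---------------------------------------------------------------------------
# rendering


def smooth_noise(
    shape: tuple[int, int], scale_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth gradient noise in [0, 1] with correlation length ~scale_px:
    a coarse Gaussian random field upsampled with cubic interpolation and
    min-max rescaled."""
    h, w = shape
    ch = max(int(np.ceil(h / scale_px)) + 3, 4)
    cw = max(int(np.ceil(w / scale_px)) + 3, 4)
    coarse = rng.normal(size=(ch, cw))
    fine = ndimage.zoom(coarse, (h / ch, w / cw), order=3, grid_mode=True, mode="nearest")
    fine = fine[:h, :w]
    lo, hi = fine.min(), fine.max()
    if hi == lo:
        return np.zeros(shape)
    return (fine - lo) / (hi - lo)


def render_mean_intensity(
    labels: np.ndarray,
    truth: pd.DataFrame,
    spec: ChannelSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-pixel mean-intensity stack for one channel.

    Whole-cell localization paints each cell with its drawn mean;
    membrane localization paints only the cell's boundary ring (interior
    and background get 0). ``offset`` plus scaled smooth noise is added
    everywhere. ``labels`` may be 2D or a (n_z, H, W) stack.
    """
    stack = labels[None] if labels.ndim == 2 else labels
    lut = np.zeros(int(stack.max()) + 1, dtype=np.float64)
    lut[truth["cell_id"].to_numpy()] = truth[f"mean_{spec.name}"].to_numpy()
    out = np.empty(stack.shape, dtype=np.float64)
    for z in range(stack.shape[0]):
        sl = stack[z]
        if spec.localization == "membrane":
            ring = boundary_labels(sl)
            vals = lut[ring]
        else:
            vals = lut[sl]
        vals = vals + spec.offset
        if spec.noise_amplitude > 0:
            if rng is None:
                raise ValueError("noise_amplitude > 0 requires an rng")
            vals = vals + spec.noise_amplitude * smooth_noise(
                sl.shape, spec.noise_scale_px, rng
            )
        out[z] = vals
    return out if labels.ndim == 3 else out[0]


# ---------------------------------------------------------------------------
# downsampling


def _check_divisible(shape: tuple[int, int], f: int) -> None:
    if shape[0] % f or shape[1] % f:
        raise ValueError(f"shape {shape} not divisible by xy factor {f}")


def downsample_mask(stack: np.ndarray, xy_factor: int) -> np.ndarray:
    """Acquisition-resolution 2D mask: nearest-neighbor in xy (the sample
    at the floor of each block center) then the per-pixel z-mode (ties →
    smallest label)."""
    st = stack[None] if stack.ndim == 2 else stack
    _check_divisible(st.shape[1:], xy_factor)
    off = (xy_factor - 1) // 2
    sub = st[:, off::xy_factor, off::xy_factor]
    if sub.shape[0] == 1:
        return sub[0].copy()
    mode = stats.mode(sub, axis=0, keepdims=False)
    return np.asarray(mode.mode)


def downsample_intensity(stack: np.ndarray, xy_factor: int) -> np.ndarray:
    """Block mean over ``xy_factor × xy_factor × n_z`` blocks; the global
    mean of the output equals the global mean of the input."""
    st = stack[None] if stack.ndim == 2 else stack
    _check_divisible(st.shape[1:], xy_factor)
    nz, h, w = st.shape
    f = xy_factor
    return st.reshape(nz, h // f, f, w // f, f).mean(axis=(0, 2, 4))


# ---------------------------------------------------------------------------
# counts


def sample_counts(mean_image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent Poisson draw per pixel with that pixel's mean."""
    mean_image = np.asarray(mean_image, dtype=np.float64)
    if np.any(mean_image < 0):
        raise ValueError("Poisson means must be nonnegative")
    return rng.poisson(mean_image).astype(np.float64)


def poissonize_image(
    image: IntensityImage, rng: np.random.Generator, pseudo: float = 0.5
) -> IntensityImage:
    """Poisson(image + pseudo) per pixel — the shot-noise step used to
    turn clean (e.g. fluorescence-derived) intensities into count-like
    images."""
    counts = rng.poisson(np.asarray(image.pixels, dtype=np.float64) + pseudo)
    return IntensityImage(
        counts.astype(np.float64),
        pixel_size_um=image.pixel_size_um,
        channel_name=image.channel_name,
    )


# ---------------------------------------------------------------------------
# orchestration


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: geometry → truth → rendering → resolution
    downsampling → Poisson counts, plus the noise-free variant (no offset,
    no noise, no Poisson step) for theoretical studies."""
    ss = np.random.SeedSequence(config.seed)
    rng_geom, rng_truth, rng_noise, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    vol = generate_label_volume(config, rng_geom)
    names = [c.name for c in config.channels]
    truth = assign_classes(vol, config.p_positive, rng_truth, names)
    for spec in config.channels:
        truth = draw_cell_means(truth, spec, rng_truth)

    f = config.xy_downsample_factor
    px_out = config.output_pixel_size_um
    mask2d = downsample_mask(vol, f)
    counts: dict[str, IntensityImage] = {}
    noise_free: dict[str, IntensityImage] = {}
    for spec in config.channels:
        mean_stack = render_mean_intensity(vol, truth, spec, rng_noise)
        mean2d = downsample_intensity(mean_stack, f)
        counts[spec.name] = IntensityImage(
            sample_counts(mean2d, rng_counts), pixel_size_um=px_out,
            channel_name=spec.name,
        )
        clean_spec = replace(spec, offset=0.0, noise_amplitude=0.0)
        clean_stack = render_mean_intensity(vol, truth, clean_spec, None)
        noise_free[spec.name] = IntensityImage(
            downsample_intensity(clean_stack, f), pixel_size_um=px_out,
            channel_name=spec.name,
        )

    mask = LabelMask(mask2d.astype(np.int64), pixel_size_um=px_out)
    cells = cell_table_skeleton(mask)
    mask_full = LabelMask(
        vol[0].astype(np.int64), pixel_size_um=1.0 / config.super_res_px_per_um
    )
    return SimulatedDataset(
        mask=mask, counts=counts, noise_free=noise_free, truth=truth,
        cells=cells, mask_full=mask_full, config=config,
    )
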