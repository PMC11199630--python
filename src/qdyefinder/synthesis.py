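"""Phantom generation: synthetic multicolour neurite volumes with ground truth.

The phantom emulates, at toy scale, a tissue volume in which each neuron
expresses a stochastic combination of N fluorescent proteins: neuron
colours are drawn from the Poisson copy-number model, skeletons are
persistent random walks (optionally branched), and the volume is rendered
as Gaussian-profile tubes over a constant background with optional
shot-like noise.  Ground-truth traces, fragment-to-neuron labels, and the
true colour vectors come back alongside the image, so every pipeline stage
can be tested end to end without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .simulation import LabelModel, simulate_cells
from .spectral import ChannelImage
from .traces import Fragment, Trace, fragment_voxel_mask, split_at_branches

__all__ = ["PhantomConfig", "Phantom", "generate_phantom", "make_hybrid_fragment"]


@dataclass
class PhantomConfig:
    """Knobs of the phantom generator (lengths in um)."""

    n_neurons: int = 10
    n_channels: int = 7
    mean_copies: float = 2.0
    shape: tuple = (24, 96, 96)          # (z, y, x) voxels
    voxel_size_um: tuple = (0.5, 0.5, 1.0)  # (x, y, z)
    n_segments: int = 30
    step_length_um: float = 2.0
    tortuosity: float = 0.25             # sd of the per-step direction kick
    radius_um: tuple = (0.4, 0.8)
    branch_probability: float = 0.15
    psf_sigma_um: tuple = (0.3, 0.3, 0.8)   # (x, y, z)
    peak_brightness: tuple = (400.0, 1200.0)
    background_level: float = 20.0
    noise_scale: float = 0.0             # 0 disables; 1 ~ Poisson-like
    colour_jitter_sd: float = 0.0        # per-fragment colour wobble
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1 or self.n_channels < 1:
            raise ValueError("need at least one neuron and one channel")
        if min(self.shape) < 4:
            raise ValueError("volume too small for a fibre step")


@dataclass
class Phantom:
    """Everything the generator knows about one synthetic volume."""

    image: ChannelImage
    traces: list
    fragments: list
    labels: dict                     # fragment_id -> neuron index
    true_colours: np.ndarray         # (n_neurons, n_channels) unit rows
    config: PhantomConfig = field(repr=False, default=None)


def _random_walk(rng, start, n_steps, step, tortuosity, bounds_um):
    """Persistent random walk: direction diffuses on the unit sphere."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    pts = [np.asarray(start, dtype=float)]
    for _ in range(n_steps):
        kick = rng.normal(scale=tortuosity, size=3)
        direction = direction + kick
        direction /= np.linalg.norm(direction)
        nxt = pts[-1] + direction * step
        # reflect off the volume faces to stay inside
        for ax in range(3):
            if nxt[ax] < 0:
                nxt[ax] = -nxt[ax]
                direction[ax] = -direction[ax]
            elif nxt[ax] > bounds_um[ax]:
                nxt[ax] = 2 * bounds_um[ax] - nxt[ax]
                direction[ax] = -direction[ax]
        pts.append(nxt)
    return np.asarray(pts)


def _neuron_trace(rng, cfg: PhantomConfig) -> Trace:
    # keep fibres (and their sphere footprint) inside the rendered volume
    margin = cfg.radius_um[1] + max(cfg.voxel_size_um)
    full = (np.array(cfg.shape)[::-1] - 1) * np.array(cfg.voxel_size_um)
    bounds = np.maximum(full - 2 * margin, 1.0)
    start = rng.uniform(0.1, 0.9, size=3) * bounds
    xyz = _random_walk(
        rng, start, cfg.n_segments, cfg.step_length_um, cfg.tortuosity, bounds
    ) + margin
    radius = rng.uniform(*cfg.radius_um, size=len(xyz))
    parent = np.arange(-1, len(xyz) - 1)
    if rng.uniform() < cfg.branch_probability and len(xyz) > 6:
        # grow a side branch from a mid point
        at = int(rng.integers(2, len(xyz) - 3))
        side = _random_walk(
            rng, xyz[at] - margin, max(cfg.n_segments // 2, 3),
            cfg.step_length_um, cfg.tortuosity, bounds,
        )[1:] + margin
        side_par = np.concatenate([[at], np.arange(len(xyz), len(xyz) + len(side) - 1)])
        xyz = np.vstack([xyz, side])
        radius = np.concatenate([radius, rng.uniform(*cfg.radius_um, size=len(side))])
        parent = np.concatenate([parent, side_par])
    node_type = np.full(len(xyz), 3)  # dendrite label; no soma in the phantom
    return Trace(xyz, radius, parent, node_type)


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Render a reproducible synthetic volume with full ground truth."""
    rng = np.random.default_rng(config.seed)
    model = LabelModel(config.n_channels, config.mean_copies)
    colours = simulate_cells(model, config.n_neurons, rng)
    brightness = rng.uniform(*config.peak_brightness, size=config.n_neurons)

    volume = np.zeros((config.n_channels,) + tuple(config.shape))
    traces, fragments, labels = [], [], {}
    occupancy = np.zeros(config.shape, dtype=bool)
    for n in range(config.n_neurons):
        trace = _neuron_trace(rng, config)
        traces.append(trace)
        frags = split_at_branches(trace, exclude_soma=True, id_prefix=f"n{n}_f")
        for f in frags:
            f.neuron_id = n
            labels[f.fragment_id] = n
            mask = fragment_voxel_mask(f, config.shape, config.voxel_size_um)
            occupancy |= mask
            colour = colours[n]
            if config.colour_jitter_sd > 0:
                jittered = np.clip(
                    colour + rng.normal(0, config.colour_jitter_sd, colour.shape),
                    0, None,
                )
                norm = np.linalg.norm(jittered)
                colour = jittered / norm if norm > 0 else colour
            amp = brightness[n] * colour
            for c in range(config.n_channels):
                volume[c][mask] += amp[c]
        fragments.extend(frags)

    if occupancy.mean() > 0.30:
        import warnings

        warnings.warn("phantom volume is overcrowded (>30% fibre voxels)",
                      stacklevel=2)

    # optical blur: separable Gaussian PSF, sigma converted to voxels
    vs = np.array(config.voxel_size_um)           # (x, y, z)
    sigma_vox = (np.array(config.psf_sigma_um) / vs)[::-1]  # (z, y, x)
    for c in range(config.n_channels):
        volume[c] = gaussian_filter(volume[c], sigma=sigma_vox)

    volume += config.background_level
    if config.noise_scale > 0:
        volume = rng.poisson(
            np.clip(volume / config.noise_scale, 0, None)
        ) * config.noise_scale
    image = ChannelImage(volume.astype(float), config.voxel_size_um)
    return Phantom(image, traces, fragments, labels, colours, config)


def make_hybrid_fragment(
    colour_a,
    colour_b,
    lengths=(15.0, 15.0),
    radius_um: float = 0.6,
    voxel_size_um=(0.5, 0.5, 1.0),
    background_level: float = 10.0,
    brightness: float = 500.0,
    psf_sigma_um=(0.3, 0.3, 0.8),
):
    """Fixture: one straight fragment whose colour flips midway.

    Emulates a mis-joined crossing — two neurites of colours A and B
    traced as a single fragment.  Returns ``(fragment, image,
    boundary_arclength_um)`` for exercising colour-change splitting.
    """
    colour_a = np.asarray(colour_a, dtype=float)
    colour_b = np.asarray(colour_b, dtype=float)
    if colour_a.shape != colour_b.shape:
        raise ValueError("colour dimension mismatch")
    total = float(sum(lengths))
    n_ch = colour_a.size
    vs = np.array(voxel_size_um)
    margin_um = 6.0
    nx = int(np.ceil((total + 2 * margin_um) / vs[0]))
    ny = int(np.ceil(2 * margin_um / vs[1]))
    nz = int(np.ceil(2 * margin_um / vs[2]))
    shape = (nz, ny, nx)

    step = 1.0  # um between samples along the x axis
    n_pts = int(np.round(total / step)) + 1
    xs = margin_um + np.linspace(0.0, total, n_pts)
    pts = np.column_stack([xs, np.full(n_pts, margin_um), np.full(n_pts, margin_um)])
    frag = Fragment("hybrid", pts, np.full(n_pts, radius_um))

    volume = np.zeros((n_ch,) + shape)
    arc = xs - xs[0]
    half_a = arc <= lengths[0]
    for part, colour in ((half_a, colour_a), (~half_a, colour_b)):
        idx = np.flatnonzero(part)
        if len(idx) < 2:
            continue
        piece = Fragment(
            "piece", pts[idx], np.full(len(idx), radius_um)
        )
        mask = fragment_voxel_mask(piece, shape, voxel_size_um)
        for c in range(n_ch):
            volume[c][mask] += brightness * colour[c]
    sigma_vox = (np.array(psf_sigma_um) / vs)[::-1]
    for c in range(n_ch):
        volume[c] = gaussian_filter(volume[c], sigma=sigma_vox)
    volume += background_level
    image = ChannelImage(volume, voxel_size_um)
    return frag, image, float(lengths[0])
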