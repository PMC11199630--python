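"""Quality control: from raw fragment intensities to reliable colour vectors.

Four screening stages precede the final colour-vector computation:

1. *Channel S/N* — a channel whose bright-fragment intensities (80th-100th
   percentile) are not clearly above background carries no label and is
   dropped, shrinking the vector dimension.
2. *Minimum length* — short pieces of a neurite wobble in colour; the
   minimum fragment length is the smallest piece length whose sub-fragments
   stay within a small distance of their parent's colour.
3. *Minimum brightness* — dim fragments have proportionally noisy colour
   vectors; the magnitude cut-off is the smallest at which fewer than 5% of
   minimum-length pieces are colour-inaccurate.
4. *Colour-change splitting* — an abrupt hue change inside one fragment
   marks a mis-joined crossing of two neurites; the fragment is cut there.

Surviving fragments get background-subtracted, per-channel max-scaled,
unit-normalized colour vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .colour_space import ColourVector, colour_distance, vector_normalize
from .traces import Fragment, subdivide_fragment

__all__ = [
    "QCConfig",
    "QCReport",
    "channel_snr",
    "determine_min_length",
    "determine_min_brightness",
    "split_colour_changes",
    "compute_colour_vectors",
    "run_qc",
]


@dataclass
class QCConfig:
    """Thresholds of the QC pipeline.

    Defaults follow the values found to work on 7-colour cortical data:
    channel S/N 2.5 over the 80-100 percentile band (a stricter 3.0 is
    sometimes used), sub-fragment accuracy d 0.1 for the length criterion,
    inaccuracy d 0.2 with a 5% tolerated fraction for the brightness
    criterion, and a colour-change split at d > 0.3.  ``min_length_um`` and
    ``min_magnitude`` may be fixed numbers or "auto" (determined from the
    data; typical outcomes are ~5 um and ~0.1).
    """

    snr_threshold: float = 2.5
    snr_percentile_range: tuple = (80.0, 100.0)
    min_length_um: object = "auto"
    sub_accuracy_d: float = 0.1
    inaccuracy_d: float = 0.2
    inaccuracy_fraction: float = 0.05
    min_magnitude: object = "auto"
    split_d: float = 0.3
    length_grid_um: tuple = (2.5, 5.0, 7.5, 10.0, 15.0, 20.0)
    length_statistic: str = "median"

    def __post_init__(self) -> None:
        for name in ("snr_threshold", "sub_accuracy_d", "inaccuracy_d",
                     "inaccuracy_fraction", "split_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.snr_percentile_range
        if not (0 <= lo < hi <= 100):
            raise ValueError("snr_percentile_range must be within [0, 100]")


@dataclass
class QCReport:
    """Per-stage bookkeeping of what was measured and dropped."""

    snr_per_channel: dict = field(default_factory=dict)
    channels_kept: list = field(default_factory=list)
    channels_dropped: list = field(default_factory=list)
    min_length_um: float = None
    length_curve: list = field(default_factory=list)
    min_magnitude: float = None
    n_input: int = 0
    n_after_length: int = 0
    n_after_brightness: int = 0
    n_after_split: int = 0
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "snr_per_channel": self.snr_per_channel,
            "channels_kept": self.channels_kept,
            "channels_dropped": self.channels_dropped,
            "min_length_um": self.min_length_um,
            "length_curve": self.length_curve,
            "min_magnitude": self.min_magnitude,
            "counts": {
                "input": self.n_input,
                "after_length_filter": self.n_after_length,
                "after_brightness_filter": self.n_after_brightness,
                "after_colour_split": self.n_after_split,
            },
            "thresholds": self.thresholds,
        }


def channel_snr(
    fragment_means: np.ndarray,
    background_medians: np.ndarray,
    config: QCConfig = None,
):
    """Screen channels by signal-to-noise over the brightest fragments.

    Per channel, S/N is the mean fragment intensity within the configured
    percentile band of that channel's distribution, divided by the
    background median.  Returns ``(snr_array, keep_mask)``.
    """
    config = config or QCConfig()
    means = np.asarray(fragment_means, dtype=float)
    bg = np.asarray(background_medians, dtype=float)
    if means.ndim != 2:
        raise ValueError("fragment_means must be (n_fragments, n_channels)")
    if len(means) < 10:
        raise ValueError("need >=10 fragments for a stable S/N estimate")
    lo, hi = config.snr_percentile_range
    snr = np.empty(means.shape[1])
    for c in range(means.shape[1]):
        col = means[:, c]
        p_lo, p_hi = np.percentile(col, [lo, hi])
        band = col[(col >= p_lo) & (col <= p_hi)]
        signal = band.mean() if band.size else col.max()
        if bg[c] <= 0:
            warnings.warn(
                f"channel {c}: background median is 0; S/N treated as inf",
                stacklevel=2,
            )
            snr[c] = np.inf if signal > 0 else 1.0
        else:
            snr[c] = signal / bg[c]
    keep = snr >= config.snr_threshold
    if not keep.any():
        raise ValueError("all channels fail the S/N screen")
    return snr, keep


def _image_background(img) -> np.ndarray:
    """Per-channel global median; a good background estimate when fibres
    occupy a small fraction of the volume."""
    return np.array(
        [float(np.nanmedian(img.voxels[c])) for c in range(img.n_channels)]
    )


def _fragment_colour(
    frag: Fragment, img, kept_channels=None, background=None
) -> ColourVector:
    """Background-subtracted colour vector of one fragment (no max scaling).

    Used by the length/brightness/split analyses, which compare colours
    *within* a fragment family where the per-channel max scaling cancels.
    """
    from .traces import sample_fragment_intensities

    if frag.raw_channel_means is None:
        sample_fragment_intensities(frag, img)
    means = frag.raw_channel_means
    if background is not None:
        means = means - background
    if kept_channels is not None:
        means = means[kept_channels]
    return vector_normalize(np.clip(means, 0.0, None))


def determine_min_length(
    fragments,
    img,
    config: QCConfig = None,
    kept_channels=None,
):
    """Smallest piece length whose sub-fragment colours track the parent.

    Every fragment is subdivided at each candidate length; the distance d
    between each sub-fragment's colour vector and its parent's is
    aggregated (median by default) per length.  Returns ``(min_length_um,
    curve)`` with the full length-vs-aggregate-d curve; the minimum length
    is the smallest grid value whose aggregate d <= ``sub_accuracy_d``.
    """
    config = config or QCConfig()
    agg = np.median if config.length_statistic == "median" else np.mean
    bg = _image_background(img)
    curve = []
    for length in sorted(config.length_grid_um):
        ds = []
        for frag in fragments:
            parent_cv = _fragment_colour(frag, img, kept_channels, bg)
            if parent_cv.magnitude == 0:
                continue
            for piece in subdivide_fragment(frag, length):
                if piece is frag:
                    continue
                piece_cv = _fragment_colour(piece, img, kept_channels, bg)
                ds.append(colour_distance(piece_cv, parent_cv))
        curve.append((length, float(agg(ds)) if ds else np.nan))
    for length, d in curve:
        if np.isfinite(d) and d <= config.sub_accuracy_d:
            return length, curve
    warnings.warn(
        "no candidate length satisfies the colour-stability criterion; "
        "using the largest grid value",
        stacklevel=2,
    )
    return max(l for l, _ in curve), curve


def determine_min_brightness(
    fragments,
    img,
    min_length_um: float,
    config: QCConfig = None,
    kept_channels=None,
):
    """Smallest magnitude cut-off with under 5% colour-inaccurate pieces.

    Pieces of length ``min_length_um`` whose colour vector sits farther
    than ``inaccuracy_d`` from their parent's are *inaccurate*.  Magnitudes
    here are relative: piece magnitudes are scaled by the brightest piece
    so the cut-off lives on the same 0-1 scale as the final colour-vector
    magnitudes.  Scanning cut-offs from dim to bright, the first value at
    which the surviving inaccurate fraction drops below
    ``inaccuracy_fraction`` is returned.
    """
    config = config or QCConfig()
    bg = _image_background(img)
    mags, inaccurate = [], []
    for frag in fragments:
        parent_cv = _fragment_colour(frag, img, kept_channels, bg)
        if parent_cv.magnitude == 0:
            continue
        for piece in subdivide_fragment(frag, min_length_um):
            piece_cv = _fragment_colour(piece, img, kept_channels, bg)
            mags.append(piece_cv.magnitude)
            inaccurate.append(
                colour_distance(piece_cv, parent_cv) > config.inaccuracy_d
            )
    if not mags:
        raise ValueError("no sub-fragments available for the brightness scan")
    mags = np.asarray(mags)
    max_mag = mags.max()
    if max_mag > 0:
        mags = mags / max_mag
    inaccurate = np.asarray(inaccurate)
    for cutoff in np.unique(np.concatenate([[0.0], mags])):
        sel = mags >= cutoff
        if not sel.any():
            break
        if inaccurate[sel].mean() < config.inaccuracy_fraction:
            return float(cutoff)
    warnings.warn(
        "brightness criterion unreachable; returning the maximum observed "
        "magnitude",
        stacklevel=2,
    )
    return float(mags.max())


def split_colour_changes(
    frag: Fragment,
    img,
    min_length_um: float,
    config: QCConfig = None,
    kept_channels=None,
):
    """Cut a fragment where adjacent pieces jump in colour.

    The fragment is viewed as consecutive ``min_length_um`` pieces; every
    boundary where adjacent piece colours differ by d > ``split_d`` becomes
    a cut.  Fragments shorter than two pieces pass through unchanged.
    """
    config = config or QCConfig()
    if frag.length < 2 * min_length_um:
        return [frag]
    pieces = subdivide_fragment(frag, min_length_um)
    if len(pieces) < 2:
        return [frag]
    bg = _image_background(img)
    colours = [_fragment_colour(p, img, kept_channels, bg) for p in pieces]
    cut_after = [
        i
        for i in range(len(pieces) - 1)
        if colour_distance(colours[i], colours[i + 1]) > config.split_d
    ]
    if not cut_after:
        return [frag]
    out, start = [], 0
    boundaries = cut_after + [len(pieces) - 1]
    for k, stop in enumerate(boundaries):
        group = pieces[start : stop + 1]
        pts = np.vstack([group[0].points] + [g.points[1:] for g in group[1:]])
        rad = np.concatenate(
            [group[0].radii] + [g.radii[1:] for g in group[1:]]
        )
        out.append(
            Fragment(
                fragment_id=f"{frag.fragment_id}s{k+1}",
                points=pts,
                radii=rad,
                neuron_id=frag.neuron_id,
                parent_fragment=frag.fragment_id,
            )
        )
        start = stop + 1
    return out


def compute_colour_vectors(
    fragments,
    background_medians: np.ndarray,
    kept_channels=None,
):
    """Final colour vectors: background-subtract, max-scale, unit-normalize.

    Per fragment the per-channel background median is subtracted from the
    raw channel means (negatives clipped to 0); each channel is then scaled
    by its maximum across all surviving fragments of the dataset — one
    shared scale, so colours stay comparable across jointly processed
    images — and the result is unit-normalized.  The pre-normalization
    Euclidean norm is kept as the fragment's magnitude.
    """
    fragments = list(fragments)
    if not fragments:
        return []
    bg = np.asarray(background_medians, dtype=float)
    if kept_channels is not None:
        bg = bg[kept_channels]
    rows = []
    for f in fragments:
        if f.raw_channel_means is None:
            raise ValueError(f"fragment {f.fragment_id} has no sampled means")
        m = np.asarray(f.raw_channel_means, dtype=float)
        if kept_channels is not None:
            m = m[kept_channels]
        rows.append(np.clip(m - bg, 0.0, None))
    mat = np.stack(rows)
    ch_max = mat.max(axis=0)
    if np.any(ch_max <= 0):
        dead = np.flatnonzero(ch_max <= 0).tolist()
        raise ValueError(
            f"channels {dead} have zero maximum across fragments; they "
            "should have been dropped by the S/N screen"
        )
    mat = mat / ch_max
    return [
        vector_normalize(row, fragment_id=f.fragment_id)
        for row, f in zip(mat, fragments)
    ]


def run_qc(fragments, img, config: QCConfig = None, trace_mask=None):
    """Run the full QC ledger; returns ``(colour_vectors, fragments, report)``.

    Stage order: channel S/N screen -> minimum-length filter -> minimum-
    brightness filter -> colour-change splitting -> colour-vector
    computation.  The returned fragment list is parallel to the vectors.
    """
    from .traces import sample_fragment_intensities

    config = config or QCConfig()
    report = QCReport(n_input=len(fragments))
    fragments = list(fragments)
    if not fragments:
        return [], [], report

    bgs = None
    for f in fragments:
        if f.raw_channel_means is None:
            _, bgs = sample_fragment_intensities(f, img, trace_mask=trace_mask)
    if bgs is None:
        from .traces import background_medians as _bgm
        mask = trace_mask if trace_mask is not None else np.zeros(
            img.shape, dtype=bool
        )
        bgs = _bgm(img, mask)

    means = np.stack([f.raw_channel_means for f in fragments])
    snr, keep = channel_snr(means, bgs, config)
    kept = np.flatnonzero(keep)
    report.snr_per_channel = {
        img.channel_labels[c]: float(snr[c]) for c in range(len(snr))
    }
    report.channels_kept = [img.channel_labels[c] for c in kept]
    report.channels_dropped = [
        img.channel_labels[c] for c in np.flatnonzero(~keep)
    ]

    if config.min_length_um == "auto":
        min_len, curve = determine_min_length(fragments, img, config, kept)
        report.length_curve = [(float(l), float(d)) for l, d in curve]
    else:
        min_len = float(config.min_length_um)
    report.min_length_um = min_len
    fragments = [f for f in fragments if f.length >= min_len]
    report.n_after_length = len(fragments)

    if config.min_magnitude == "auto":
        min_mag = determine_min_brightness(fragments, img, min_len, config, kept)
    else:
        min_mag = float(config.min_magnitude)
    report.min_magnitude = min_mag

    if fragments:
        provisional = compute_colour_vectors(fragments, bgs, kept)
        fragments = [
            f for f, v in zip(fragments, provisional) if v.magnitude >= min_mag
        ]
    report.n_after_brightness = len(fragments)

    split = []
    for f in fragments:
        split.extend(split_colour_changes(f, img, min_len, config, kept))
    for f in split:
        if f.raw_channel_means is None:
            sample_fragment_intensities(f, img, trace_mask=trace_mask)
    # splitting can leave sub-minimum pieces; they are as unreliable as any
    # other short fragment, so the length filter applies again
    split = [f for f in split if f.length >= min_len]
    report.n_after_split = len(split)

    vectors = compute_colour_vectors(split, bgs, kept) if split else []
    bright = [i for i, v in enumerate(vectors) if v.magnitude >= min_mag]
    vectors = [vectors[i] for i in bright]
    split = [split[i] for i in bright]
    report.thresholds = {
        "snr_threshold": config.snr_threshold,
        "min_length_um": min_len,
        "min_magnitude": min_mag,
        "split_d": config.split_d,
    }
    return vectors, split, report
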