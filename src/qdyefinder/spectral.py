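"""Detector linearity correction and reference-based linear unmixing.

Hybrid photon-counting detectors under-count at high photon flux, so
measured intensity x falls below the true intensity.  The correction maps
measured to true intensity with a linear-plus-exponential form

    y = a*x + b*(exp(c*x) - 1)

fitted against per-pixel linear extrapolations from a low-laser-power
calibration series.  Beyond a saturation cutoff the detector response is
uncorrectable and voxels are discarded (set to NaN).

Spectral unmixing recovers per-fluorophore abundances from N detection
channels by solving, per voxel and per excitation group, the least-squares
system M u = s against single-fluorophore reference columns.  Groups mirror
the acquisition scheme (one laser line excites a subset of fluorophores
read out on a subset of channels); cross-laser bleed-through is assumed
zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, nnls

__all__ = [
    "LinearityCoefficients",
    "ExcitationGroup",
    "SpectralReference",
    "ChannelImage",
    "correction_curve",
    "fit_linearity",
    "apply_linearity_correction",
    "build_mixing_matrix",
    "unmix",
]


@dataclass(frozen=True)
class LinearityCoefficients:
    """Coefficients (a, b, c) of the detector correction and the saturation cutoff."""

    a: float
    b: float
    c: float
    saturation_cutoff: float

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("exponential rate c must be >= 0")
        if self.saturation_cutoff <= 0:
            raise ValueError("saturation_cutoff must be > 0")


def correction_curve(x, a: float, b: float, c: float):
    """y = a*x + b*exp(c*x) - b, the measured-to-true intensity map.

    Fixes 0 (y(0) = 0) and is strictly increasing for a > 0, b, c >= 0.
    """
    x = np.asarray(x, dtype=float)
    return a * x + b * np.expm1(c * x)


@dataclass(frozen=True)
class ExcitationGroup:
    """One laser line: its detection channels, fluorophores, and mixing matrix.

    ``mixing_matrix`` has shape (n_channels_in_group, n_fluorophores); each
    column is a fluorophore's emission split across the group's channels,
    L1-normalized.
    """

    laser: str
    channel_indices: tuple
    fluorophores: tuple
    mixing_matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mixing_matrix, dtype=float)
        object.__setattr__(self, "mixing_matrix", m)
        object.__setattr__(self, "channel_indices", tuple(self.channel_indices))
        object.__setattr__(self, "fluorophores", tuple(self.fluorophores))
        if m.shape != (len(self.channel_indices), len(self.fluorophores)):
            raise ValueError("mixing matrix shape does not match group layout")
        if np.any(m < 0):
            raise ValueError("mixing matrix entries must be nonnegative")
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-8):
            raise ValueError("mixing matrix columns must be L1-normalized")


@dataclass
class SpectralReference:
    """Per-excitation-group mixing matrices plus optional linearity coefficients."""

    groups: list
    linearity: LinearityCoefficients | None = None

    def __post_init__(self) -> None:
        seen = set()
        for g in self.groups:
            for ch in g.channel_indices:
                if ch in seen:
                    raise ValueError(f"channel {ch} appears in more than one group")
                seen.add(ch)

    @property
    def fluorophores(self) -> tuple:
        return tuple(f for g in self.groups for f in g.fluorophores)

    def to_dict(self) -> dict:
        d = {
            "groups": [
                {
                    "laser": g.laser,
                    "channels": list(g.channel_indices),
                    "fluorophores": list(g.fluorophores),
                    "mixing_matrix": g.mixing_matrix.tolist(),
                }
                for g in self.groups
            ]
        }
        if self.linearity is not None:
            d["linearity"] = {
                "a": self.linearity.a,
                "b": self.linearity.b,
                "c": self.linearity.c,
                "saturation_cutoff": self.linearity.saturation_cutoff,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralReference":
        groups = [
            ExcitationGroup(
                laser=g["laser"],
                channel_indices=tuple(g["channels"]),
                fluorophores=tuple(g["fluorophores"]),
                mixing_matrix=np.asarray(g["mixing_matrix"], dtype=float),
            )
            for g in d["groups"]
        ]
        lin = None
        if "linearity" in d:
            ld = d["linearity"]
            lin = LinearityCoefficients(
                ld["a"], ld["b"], ld["c"], ld["saturation_cutoff"]
            )
        return cls(groups=groups, linearity=lin)


@dataclass
class ChannelImage:
    """N-channel 3-D volume with voxel size metadata.

    ``voxels`` has shape (n_channels, nz, ny, nx); NaN marks voxels
    discarded as saturated.  ``voxel_size_um`` is (x, y, z) in micrometres.
    """

    voxels: np.ndarray
    voxel_size_um: tuple = (1.0, 1.0, 1.0)
    channel_labels: tuple = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 4:
            raise ValueError("voxels must be (channels, z, y, x)")
        self.voxels = v
        self.voxel_size_um = tuple(float(s) for s in self.voxel_size_um)
        if not self.channel_labels:
            self.channel_labels = tuple(f"ch_{i+1}" for i in range(v.shape[0]))
        else:
            self.channel_labels = tuple(self.channel_labels)
            if len(self.channel_labels) != v.shape[0]:
                raise ValueError("channel label count does not match channels")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple:
        return self.voxels.shape[1:]


def fit_linearity(
    calibration: np.ndarray,
    powers,
    linear_range_powers,
    saturation_rel_error: float = 0.15,
    initial=(1.0, 1.0, 1e-3),
) -> LinearityCoefficients:
    """Fit detector correction coefficients from a laser-power series.

    Parameters
    ----------
    calibration : array (n_powers, n_pixels)
        Measured intensity of each pixel at each relative laser power.
    powers : sequence of n_powers floats
        Relative laser powers (linear in photon flux).
    linear_range_powers : sequence
        Subset of ``powers`` where the detector is trusted to be linear;
        per-pixel straight-line fits over this range extrapolate the
        predicted (true) intensity at every power.
    saturation_rel_error : float
        The saturation cutoff is the largest measured intensity at which
        the fitted curve's residual relative error stays below this bound.

    Returns the pooled-pixel fit of predicted = a*x + b*exp(c*x) - b.
    """
    cal = np.asarray(calibration, dtype=float)
    powers = np.asarray(powers, dtype=float)
    if cal.ndim != 2 or cal.shape[0] != powers.size:
        raise ValueError("calibration must be (n_powers, n_pixels)")
    linear_mask = np.isin(powers, np.asarray(linear_range_powers, dtype=float))
    if linear_mask.sum() < 3:
        raise ValueError("need >=3 power levels inside the linear range")

    mean_trend = cal.mean(axis=1)
    if np.polyfit(powers, mean_trend, 1)[0] <= 0 or np.ptp(mean_trend) == 0:
        raise ValueError(
            "degenerate calibration: intensity does not grow with laser power"
        )

    # per-pixel linear trend over the trusted range, through the origin.
    # Even the "linear" range carries residual nonlinearity, so after a
    # first fit the measured values are corrected and the slopes re-estimated
    # once, which removes most of the bias in (a, b, c).
    p_lin = powers[linear_mask]
    corrected = cal[linear_mask]
    a = b = c = None
    for _ in range(3):
        slopes = (p_lin @ corrected) / (p_lin @ p_lin)
        predicted = np.outer(powers, slopes)  # true intensity at every power
        x = cal.ravel()
        y = predicted.ravel()
        ok = np.isfinite(x) & np.isfinite(y)
        xf, yf = x[ok], y[ok]
        order = np.argsort(xf)
        xf, yf = xf[order], yf[order]
        try:
            (a, b, c), _ = curve_fit(
                correction_curve, xf, yf,
                p0=initial if a is None else (a, b, c), maxfev=20000,
                bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, 1.0]),
            )
        except RuntimeError as exc:  # pragma: no cover - scipy failure path
            raise ValueError(f"linearity fit failed to converge: {exc}") from exc
        corrected = correction_curve(cal[linear_mask], a, b, c)
    x, y = xf, yf

    resid = np.abs(correction_curve(x, a, b, c) - y) / np.maximum(np.abs(y), 1.0)
    bad = resid > saturation_rel_error
    cutoff = float(x[bad].min()) if bad.any() else float(x.max())
    return LinearityCoefficients(float(a), float(b), float(c), cutoff)


def apply_linearity_correction(
    img: ChannelImage, coeffs: LinearityCoefficients
) -> ChannelImage:
    """Correct every voxel; voxels above the saturation cutoff become NaN."""
    x = img.voxels
    out = correction_curve(x, coeffs.a, coeffs.b, coeffs.c)
    out[x > coeffs.saturation_cutoff] = np.nan
    return ChannelImage(out, img.voxel_size_um, img.channel_labels)


def build_mixing_matrix(
    reference_images: dict,
    group_layout,
    foreground_percentile: float = 90.0,
    linearity: LinearityCoefficients | None = None,
) -> SpectralReference:
    """Build per-group mixing matrices from single-fluorophore references.

    Parameters
    ----------
    reference_images : dict fluorophore -> ChannelImage
        One image per fluorophore, expressing only that fluorophore.
    group_layout : sequence of (laser, channel_indices, fluorophores)
        The acquisition scheme.
    foreground_percentile : float
        Voxels above this percentile of the group-summed intensity are
        foreground; the per-channel median of the rest is the background
        subtracted before averaging.

    Each fluorophore's column is its mean background-subtracted foreground
    intensity per in-group channel, L1-normalized.
    """
    groups = []
    for laser, channels, fluors in group_layout:
        channels = tuple(channels)
        cols = []
        for fluor in fluors:
            if fluor not in reference_images:
                raise ValueError(f"no reference image for fluorophore {fluor!r}")
            ref = reference_images[fluor]
            sub = ref.voxels[list(channels)]
            total = np.nansum(sub, axis=0)
            if np.nanmax(total) <= 0:
                raise ValueError(
                    f"reference for {fluor!r} has no foreground voxels"
                )
            # foreground = brightest (100 - p)% of voxels by rank, so a flat
            # background never swallows the selection
            n_fg = max(int(round(total.size * (100 - foreground_percentile) / 100)), 1)
            cut = np.partition(total.ravel(), -n_fg)[-n_fg]
            fg = total >= cut
            bg_median = np.nanmedian(sub[:, ~fg], axis=1) if (~fg).any() else 0.0
            means = np.nanmean(sub[:, fg], axis=1) - bg_median
            means = np.clip(means, 0.0, None)
            s = means.sum()
            if s <= 0:
                raise ValueError(
                    f"reference for {fluor!r} has no signal above background"
                )
            cols.append(means / s)
        m = np.column_stack(cols)
        # warn on (near-)duplicate emission profiles: unmixing will be unstable
        for i in range(m.shape[1]):
            for j in range(i + 1, m.shape[1]):
                if np.allclose(m[:, i], m[:, j], atol=1e-3):
                    warnings.warn(
                        f"fluorophores {fluors[i]!r} and {fluors[j]!r} have "
                        "near-identical emission columns; unmixing will be "
                        "rank-deficient",
                        stacklevel=2,
                    )
        groups.append(
            ExcitationGroup(
                laser=laser,
                channel_indices=channels,
                fluorophores=tuple(fluors),
                mixing_matrix=m,
            )
        )
    return SpectralReference(groups=groups, linearity=linearity)


def unmix(
    img: ChannelImage,
    ref: SpectralReference,
    method: str = "clip",
) -> ChannelImage:
    """Linear unmixing of an N-channel image into per-fluorophore images.

    Solves M u = s per voxel within each excitation group.  ``method``
    "clip" solves the unconstrained least-squares system and clips negative
    abundances to zero; "nnls" solves the nonnegative least-squares problem
    exactly (slower).  Voxels that are NaN in any of a group's channels
    propagate NaN to all of that group's fluorophores.
    """
    if method not in ("clip", "nnls"):
        raise ValueError("method must be 'clip' or 'nnls'")
    n_ch = img.n_channels
    max_ch = max(ch for g in ref.groups for ch in g.channel_indices)
    if max_ch >= n_ch:
        raise ValueError(
            f"reference expects channel {max_ch} but image has {n_ch} channels"
        )
    fluor_labels = ref.fluorophores
    out = np.empty((len(fluor_labels),) + img.shape)
    row = 0
    for g in ref.groups:
        m = g.mixing_matrix
        if np.linalg.matrix_rank(m) < m.shape[1]:
            raise ValueError(
                f"mixing matrix for laser {g.laser!r} is singular; redesign "
                "the reference set (fluorophore emissions are not separable)"
            )
        s = img.voxels[list(g.channel_indices)]
        flat = s.reshape(len(g.channel_indices), -1)
        bad = ~np.isfinite(flat).all(axis=0)
        safe = np.where(np.isfinite(flat), flat, 0.0)
        if method == "clip":
            u, *_ = np.linalg.lstsq(m, safe, rcond=None)
            np.clip(u, 0.0, None, out=u)
        else:
            u = np.empty((m.shape[1], flat.shape[1]))
            for i in range(flat.shape[1]):
                u[:, i] = nnls(m, safe[:, i])[0]
        u[:, bad] = np.nan
        k = m.shape[1]
        out[row : row + k] = u.reshape((k,) + img.shape)
        row += k
    return ChannelImage(out, img.voxel_size_um, fluor_labels)
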