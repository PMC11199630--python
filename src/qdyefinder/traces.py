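"""SWC trace handling and fragment extraction.

Automated neurite detection frequently mis-joins processes at branch points
and crossings, so traces are broken into unbranched *fragments* — the
regions of interest from which colour vectors are measured.  This module
reads and writes 7-column SWC, splits traces into fragments at branch
points (excluding somata, whose signals exceed the detectors' linear
range), samples per-channel mean intensities over a fragment's voxel
footprint, and subdivides fragments into fixed-length pieces for the
quality-control analyses.

Coordinates are micrometres in world space; SWC samples are treated as
centre points, and the voxel footprint of a fragment is the union of
spheres of the per-point radii (minimum one voxel) along its polyline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

SOMA_TYPE = 1

__all__ = [
    "Trace",
    "Fragment",
    "read_swc",
    "write_swc",
    "split_at_branches",
    "subdivide_fragment",
    "sample_fragment_intensities",
    "recenter_points",
    "polyline_length",
]


@dataclass
class Trace:
    """One SWC tree: parallel arrays of sample attributes.

    ``parent`` holds positional indices into the arrays (-1 for roots), not
    raw SWC ids; ``node_type`` keeps the SWC structure label (1 = soma).
    """

    xyz: np.ndarray          # (n, 3) in um
    radius: np.ndarray       # (n,)
    parent: np.ndarray       # (n,) int, -1 = root
    node_type: np.ndarray    # (n,) int
    ids: np.ndarray = None   # original SWC sample ids

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        n = len(self.xyz)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)
        self.node_type = np.asarray(self.node_type, dtype=int)
        if self.ids is None:
            self.ids = np.arange(1, n + 1)
        self.ids = np.asarray(self.ids, dtype=int)
        if not (len(self.radius) == len(self.parent) == len(self.node_type) == n):
            raise ValueError("trace attribute arrays have mismatched lengths")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("trace coordinates must be finite")
        if np.any(self.radius <= 0):
            raise ValueError("trace radii must be > 0")
        for i, p in enumerate(self.parent):
            if p >= i:
                raise ValueError(f"parent of sample {i} is not defined earlier")

    @property
    def n_points(self) -> int:
        return len(self.xyz)

    def children(self):
        """List of child index lists, parallel to the samples."""
        ch = [[] for _ in range(self.n_points)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def branch_points(self) -> np.ndarray:
        """Indices of samples with two or more children."""
        counts = np.zeros(self.n_points, dtype=int)
        for p in self.parent:
            if p >= 0:
                counts[p] += 1
        return np.flatnonzero(counts >= 2)


@dataclass
class Fragment:
    """An unbranched run of trace points; the colour-measurement ROI."""

    fragment_id: object
    points: np.ndarray       # (n, 3) um
    radii: np.ndarray        # (n,)
    neuron_id: object = None
    raw_channel_means: np.ndarray = None
    parent_fragment: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float)
        if len(self.points) < 2:
            raise ValueError("fragment needs at least 2 points")
        if len(self.radii) != len(self.points):
            raise ValueError("radii length mismatch")

    @property
    def length(self) -> float:
        return polyline_length(self.points)


def polyline_length(points: np.ndarray) -> float:
    """Sum of consecutive-point Euclidean distances, in um."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# SWC I/O


def read_swc(path):
    """Read a 7-column SWC file into a list of Traces (one per root).

    Lines are ``id type x y z radius parent`` with '#' comments.  A parent
    id that never appears as a sample id is a parse error reported with its
    line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                sid = int(parts[0]); stype = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                par = int(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable row") from exc
            rows.append((lineno, sid, stype, x, y, z, r, par))

    id_to_pos = {sid: i for i, (_, sid, *_rest) in enumerate(rows)}
    for lineno, sid, *_mid, par in [(r[0], r[1], r[7]) for r in rows]:
        if par != -1 and par not in id_to_pos:
            raise ValueError(
                f"{path}:{lineno}: sample {sid} references unknown parent {par}"
            )

    # group rows into connected components rooted at parent == -1
    root_of = {}
    for _, sid, _, _, _, _, _, par in rows:
        root_of[sid] = sid if par == -1 else root_of[par]
    components = {}
    for row in rows:
        components.setdefault(root_of[row[1]], []).append(row)

    traces = []
    for comp in components.values():
        local = {r[1]: i for i, r in enumerate(comp)}
        xyz = np.array([[r[3], r[4], r[5]] for r in comp])
        radius = np.array([r[6] for r in comp])
        node_type = np.array([r[2] for r in comp])
        parent = np.array([-1 if r[7] == -1 else local[r[7]] for r in comp])
        ids = np.array([r[1] for r in comp])
        traces.append(Trace(xyz, radius, parent, node_type, ids))
    return traces


def write_swc(traces, path) -> None:
    """Write traces to one SWC file with globally renumbered sample ids."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        offset = 0
        for tr in traces:
            for i in range(tr.n_points):
                sid = offset + i + 1
                par = -1 if tr.parent[i] == -1 else offset + tr.parent[i] + 1
                x, y, z = tr.xyz[i]
                fh.write(
                    f"{sid} {tr.node_type[i]} {x:.6f} {y:.6f} {z:.6f} "
                    f"{tr.radius[i]:.6f} {par}\n"
                )
            offset += tr.n_points


# ---------------------------------------------------------------------------
# fragmentation


def split_at_branches(trace: Trace, exclude_soma: bool = True, id_prefix="f"):
    """Split a trace into unbranched fragments at its branch points.

    Every non-soma edge lands in exactly one fragment; branch points are
    duplicated as endpoints of each incident fragment so no fragment has a
    branch point in its interior.  Soma-labelled samples (SWC type 1) are
    excluded by default, cutting the tree there.
    """
    children = trace.children()
    n_children = np.array([len(c) for c in children])
    soma = (trace.node_type == SOMA_TYPE) if exclude_soma else np.zeros(
        trace.n_points, dtype=bool
    )

    def is_break(i):
        # fragment boundary: root, branch point, or a soma-adjacent cut
        p = trace.parent[i]
        return p < 0 or n_children[i] >= 2 or soma[i]

    fragments = []
    counter = 0
    # walk from every boundary node down each child branch to the next boundary
    for start in range(trace.n_points):
        if soma[start]:
            continue
        if not is_break(start) and not (
            trace.parent[start] >= 0 and soma[trace.parent[start]]
        ):
            continue
        for child in children[start]:
            if soma[child]:
                continue
            run = [start, child]
            node = child
            while not is_break(node) and len(children[node]) == 1:
                nxt = children[node][0]
                if soma[nxt]:
                    break
                run.append(nxt)
                node = nxt
            if len(run) >= 2:
                counter += 1
                fragments.append(
                    Fragment(
                        fragment_id=f"{id_prefix}{counter}",
                        points=trace.xyz[run],
                        radii=trace.radius[run],
                    )
                )
    return fragments


def _resample_arclength(points, radii, cut_positions):
    """Insert interpolated samples at the given arc-length positions."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    out_pts, out_rad = [points[0]], [radii[0]]
    s_list = sorted(set(np.concatenate([cum[1:], cut_positions])))
    for s in s_list:
        i = np.searchsorted(cum, s, side="right") - 1
        i = min(i, len(seg) - 1)
        if seg[i] == 0:
            t = 0.0
        else:
            t = (s - cum[i]) / seg[i]
        out_pts.append(points[i] * (1 - t) + points[i + 1] * t)
        out_rad.append(radii[i] * (1 - t) + radii[i + 1] * t)
    return np.array(out_pts), np.array(out_rad)


def subdivide_fragment(frag: Fragment, piece_length: float):
    """Cut a fragment into consecutive pieces of the given arc length.

    The trailing remainder is kept as its own piece when it is at least
    half of ``piece_length`` and merged into the previous piece otherwise.
    Concatenating the pieces reproduces the parent polyline.
    """
    if piece_length <= 0:
        raise ValueError("piece_length must be > 0")
    total = frag.length
    if total <= piece_length:
        return [frag]
    n_full = int(np.floor(total / piece_length))
    remainder = total - n_full * piece_length
    cuts = [piece_length * k for k in range(1, n_full + 1)]
    if cuts and remainder < piece_length / 2:
        # drop the final cut: exact multiple, or short tail merged into the
        # previous full piece
        cuts = cuts[:-1]
    cut_arr = np.array(cuts)
    pts, rad = _resample_arclength(frag.points, frag.radii, cut_arr)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    boundaries = [0.0] + cuts + [cum[-1]]
    pieces = []
    for k in range(len(boundaries) - 1):
        lo, hi = boundaries[k], boundaries[k + 1]
        mask = (cum >= lo - 1e-9) & (cum <= hi + 1e-9)
        idx = np.flatnonzero(mask)
        pieces.append(
            Fragment(
                fragment_id=f"{frag.fragment_id}.{k+1}",
                points=pts[idx],
                radii=rad[idx],
                neuron_id=frag.neuron_id,
                parent_fragment=frag.fragment_id,
            )
        )
    return pieces


# ---------------------------------------------------------------------------
# intensity sampling


def _world_to_index(points_um, voxel_size_um):
    vs = np.asarray(voxel_size_um, dtype=float)  # (x, y, z)
    # array axes are (z, y, x)
    return points_um[:, ::-1] / vs[::-1]


def fragment_voxel_mask(frag: Fragment, shape, voxel_size_um) -> np.ndarray:
    """Boolean mask of the sphere-union footprint of a fragment's polyline."""
    mask = np.zeros(shape, dtype=bool)
    vs = np.asarray(voxel_size_um, dtype=float)[::-1]  # (z, y, x)
    # densely sample the polyline so consecutive spheres overlap
    pts, rads = [], []
    for i in range(len(frag.points) - 1):
        a, b = frag.points[i], frag.points[i + 1]
        ra, rb = frag.radii[i], frag.radii[i + 1]
        step = max(np.linalg.norm(b - a), 1e-9)
        n = max(int(np.ceil(step / (vs.min() / 2))), 1)
        for t in np.linspace(0.0, 1.0, n + 1):
            pts.append(a * (1 - t) + b * t)
            rads.append(ra * (1 - t) + rb * t)
    pts = np.asarray(pts)
    idx = _world_to_index(pts, voxel_size_um)
    out_of_bounds = False
    for centre, r_um in zip(idx, rads):
        r_vox = np.maximum(r_um / vs, 0.5)  # at least one voxel across
        lo = np.floor(centre - r_vox).astype(int)
        hi = np.ceil(centre + r_vox).astype(int) + 1
        if np.any(hi <= 0) or np.any(lo >= shape):
            out_of_bounds = True
            continue
        lo_c = np.clip(lo, 0, shape)
        hi_c = np.clip(hi, 0, shape)
        if np.any(lo != lo_c) or np.any(hi != hi_c):
            out_of_bounds = True
        grids = np.meshgrid(
            *[np.arange(l, h) for l, h in zip(lo_c, hi_c)], indexing="ij"
        )
        dist2 = sum(
            ((g - c) / rv) ** 2 for g, c, rv in zip(grids, centre, r_vox)
        )
        sub = tuple(slice(l, h) for l, h in zip(lo_c, hi_c))
        mask[sub] |= dist2 <= 1.0
    if out_of_bounds:
        warnings.warn(
            f"fragment {frag.fragment_id}: points outside image bounds were "
            "clipped",
            stacklevel=2,
        )
    return mask


def background_medians(img, trace_mask: np.ndarray) -> np.ndarray:
    """Per-channel median over all voxels not covered by any trace."""
    bg = ~trace_mask
    if not bg.any():
        return np.zeros(img.n_channels)
    return np.array(
        [float(np.nanmedian(img.voxels[c][bg])) for c in range(img.n_channels)]
    )


def sample_fragment_intensities(frag: Fragment, img, trace_mask=None):
    """Mean per-channel intensity over a fragment's voxel footprint.

    Returns ``(raw_channel_means, background_medians)``.  The background is
    the per-channel median over non-trace voxels (the whole image minus
    ``trace_mask`` when given, minus this fragment's own footprint
    otherwise).  NaN voxels (saturation) are excluded from the means.
    """
    mask = fragment_voxel_mask(frag, img.shape, img.voxel_size_um)
    if not mask.any():
        raise ValueError(
            f"fragment {frag.fragment_id} covers no voxels in the image"
        )
    means = np.array(
        [float(np.nanmean(img.voxels[c][mask])) for c in range(img.n_channels)]
    )
    bg = background_medians(img, trace_mask if trace_mask is not None else mask)
    frag.raw_channel_means = means
    return means, bg


def recenter_points(
    trace: Trace, img, search_radius_um: float, n_iter: int = 3
) -> Trace:
    """Snap trace points to the local intensity centre of mass.

    Automated tracing sometimes rides the edge of a neurite rather than its
    axis.  Each point is moved to the intensity-weighted centroid of the
    channel-max image within ``search_radius_um``; the centroid step is
    iterated (``n_iter`` times, stopping early once the move is below a
    tenth of a voxel) because one truncated-window step undershoots.  Total
    displacement is capped at the search radius; points in zero-signal
    neighbourhoods stay put.  Topology is unchanged.
    """
    chan_max = np.nanmax(img.voxels, axis=0)
    chan_max = np.where(np.isfinite(chan_max), chan_max, 0.0)
    vs = np.asarray(img.voxel_size_um, dtype=float)[::-1]  # (z, y, x)
    shape = np.array(img.shape)

    def centroid_step(p):
        centre = p[::-1] / vs  # (z, y, x) voxel coords
        r_vox = search_radius_um / vs
        lo = np.clip(np.floor(centre - r_vox).astype(int), 0, shape)
        hi = np.clip(np.ceil(centre + r_vox).astype(int) + 1, 0, shape)
        if np.any(lo >= hi):
            return None
        grids = np.meshgrid(
            *[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij"
        )
        dist2 = sum(((g - c) / rv) ** 2 for g, c, rv in zip(grids, centre, r_vox))
        sub = tuple(slice(l, h) for l, h in zip(lo, hi))
        w = chan_max[sub] * (dist2 <= 1.0)
        total = w.sum()
        if total <= 0:
            return None
        com = np.array([float((g * w).sum() / total) for g in grids])
        return (com * vs)[::-1]  # back to (x, y, z) um

    new_xyz = trace.xyz.copy()
    for i, start in enumerate(trace.xyz):
        p = start.copy()
        for _ in range(n_iter):
            moved = centroid_step(p)
            if moved is None:
                break
            step = np.linalg.norm(moved - p)
            p = moved
            if step < 0.1 * vs.min():
                break
        delta = p - start
        norm = np.linalg.norm(delta)
        if norm > search_radius_um:
            delta *= search_radius_um / norm
        new_xyz[i] = start + delta
    return Trace(new_xyz, trace.radius.copy(), trace.parent.copy(),
                 trace.node_type.copy(), trace.ids.copy())
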