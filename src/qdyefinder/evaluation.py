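"""Scoring clustering output against ground-truth neuron labels.

Each ground-truth neuron is matched to the cluster holding the most of its
fragments; fragments are then confusion-counted per neuron — true positive
(in the matched cluster, from the neuron), false positive (in the matched
cluster, from another neuron), false negative (elsewhere, from the
neuron), true negative (neither) — giving per-neuron precision, recall,
and F1.  The optimal Th(d) is the grid value maximizing the median
per-neuron F1.  Trace-overlap quality is summarized as "% reconstructed":
the fraction of ground-truth skeleton voxels covered by the (dilated)
predicted traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dcrawler import dcrawler

__all__ = [
    "NeuronScore",
    "match_and_score",
    "optimal_threshold",
    "percent_reconstructed",
]


@dataclass
class NeuronScore:
    """Fragment-level confusion counts and F1 for one neuron."""

    neuron_id: object
    best_cluster_id: int
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def match_and_score(labels: dict, clusters: dict):
    """Per-neuron confusion scores given fragment->neuron and fragment->cluster maps.

    The best cluster for a neuron is the one containing most of its
    fragments (ties to the lower cluster id); a cluster may be best for
    several neurons.  Both maps must cover the same fragment universe.
    """
    only_labels = set(labels) - set(clusters)
    only_clusters = set(clusters) - set(labels)
    if only_labels or only_clusters:
        raise ValueError(
            "fragment universes differ; only in labels: "
            f"{sorted(only_labels)!r}, only in clusters: "
            f"{sorted(only_clusters)!r}"
        )
    frag_ids = list(labels)
    total = len(frag_ids)
    scores = []
    neurons = sorted(set(labels.values()), key=str)
    for neuron in neurons:
        counts = {}
        for f in frag_ids:
            if labels[f] == neuron:
                c = clusters[f]
                counts[c] = counts.get(c, 0) + 1
        best = min(
            counts, key=lambda c: (-counts[c], c)
        )  # most fragments, ties to lower id
        tp = fp = fn = 0
        for f in frag_ids:
            in_cluster = clusters[f] == best
            from_neuron = labels[f] == neuron
            if in_cluster and from_neuron:
                tp += 1
            elif in_cluster:
                fp += 1
            elif from_neuron:
                fn += 1
        scores.append(
            NeuronScore(neuron, best, tp, fp, fn, total - tp - fp - fn)
        )
    return scores


def optimal_threshold(
    points,
    labels: dict,
    th_grid=None,
    order: str = "input",
):
    """Scan Th(d) values and pick the one maximizing median per-neuron F1.

    ``points`` must be ColourVectors carrying ``fragment_id``s matching the
    keys of ``labels``.  Returns ``(best_th_d, curve)`` with the full
    (th_d, median F1) curve; ties go to the smaller threshold.
    """
    if th_grid is None:
        th_grid = np.arange(0.05, 1.0 + 1e-9, 0.025)
    if len(set(labels.values())) < 2:
        raise ValueError("need at least 2 neurons to optimize Th(d)")
    pts = list(points)
    ids = [p.fragment_id for p in pts]
    if set(ids) != set(labels):
        raise ValueError("points and labels cover different fragments")
    curve = []
    for th_d in th_grid:
        cs = dcrawler(pts, float(th_d), order=order)
        cluster_map = {fid: int(c) for fid, c in zip(ids, cs.assignments)}
        scores = match_and_score(labels, cluster_map)
        curve.append((float(th_d), float(np.median([s.f1 for s in scores]))))
    best = max(curve, key=lambda t: (t[1], -t[0]))
    return best[0], curve


def _rasterize(traces, shape, voxel_size_um) -> np.ndarray:
    from .traces import Fragment, fragment_voxel_mask, split_at_branches

    mask = np.zeros(shape, dtype=bool)
    for tr in traces:
        if isinstance(tr, Fragment):
            frags = [tr]
        else:
            frags = split_at_branches(tr, exclude_soma=False)
        for f in frags:
            mask |= fragment_voxel_mask(f, shape, voxel_size_um)
    return mask


def percent_reconstructed(
    ground_truth,
    predicted,
    shape,
    voxel_size_um=(1.0, 1.0, 1.0),
    dilation_px: int = 10,
) -> float:
    """Percent of ground-truth trace voxels covered by the predictions.

    Both trace sets are rasterized on the same voxel grid; the predictions
    are dilated by ``dilation_px`` voxels to forgive small misalignments.
    Returns 100 * |GT intersect dilated(pred)| / |GT|.
    """
    from scipy.ndimage import binary_dilation

    gt_mask = _rasterize(ground_truth, shape, voxel_size_um)
    if not gt_mask.any():
        raise ValueError("ground truth rasterizes to an empty mask")
    pred_mask = _rasterize(predicted, shape, voxel_size_um)
    if dilation_px > 0 and pred_mask.any():
        pred_mask = binary_dilation(
            pred_mask, iterations=dilation_px
        )
    return float(100.0 * (gt_mask & pred_mask).sum() / gt_mask.sum())
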