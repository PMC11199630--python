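"""Stochastic-labelling simulations.

Combinatorial fluorophore labelling delivers each cell a random number of
copies of each of N fluorescent-protein vectors; copy numbers follow a
Poisson distribution with mean ``mean_copies`` per colour per cell.  The
resulting N-channel expression profile, unit-normalized, is the cell's
colour vector.  Two cells are *discriminable* when their colour vectors are
separated by more than a threshold distance Th(d), and a cell is *uniquely
labelled* when no other cell in the cohort lies within Th(d) — the
birthday-problem statistic that limits how many neurons can be told apart
even when pairwise discriminability is high.

Two sampling modes are provided.  ``"quota"`` (default) fits the Poisson
probability mass function to the cohort size — each copy number gets a
deterministic quota of cells, largest-remainder rounded — and shuffles the
assignment independently per channel.  ``"poisson"`` draws independent
Poisson counts per cell and channel.  The modes agree in distribution for
large cohorts; quota sampling pins the per-channel copy-number composition
exactly, which matters for small cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson as _poisson

__all__ = [
    "LabelModel",
    "simulate_cells",
    "percent_discriminable",
    "percent_unique",
    "discriminability_with_noise",
]


@dataclass
class LabelModel:
    """Parameters of the stochastic labelling model.

    Attributes
    ----------
    n_channels : int
        Number of spectrally distinct fluorescent proteins (1-7 typical).
    mean_copies : float
        Poisson mean, copies per colour per cell.
    max_copies : int
        Truncation of the copy-number distribution (default 50).
    noise_sd : float
        Per-channel Gaussian noise SD applied to the normalized vector in
        the neurite-noise model; 0 disables noise.
    sampling : str
        "quota" or "poisson" (see module docstring).
    """

    n_channels: int
    mean_copies: float
    max_copies: int = 50
    noise_sd: float = 0.0
    sampling: str = "quota"

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.mean_copies < 0:
            raise ValueError("mean_copies must be >= 0")
        if self.max_copies < 1:
            raise ValueError("max_copies must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sampling not in ("quota", "poisson"):
            raise ValueError("sampling must be 'quota' or 'poisson'")


def _quota_column(n_cells: int, lam: float, max_copies: int) -> np.ndarray:
    """Copy numbers for one channel with exact Poisson-pmf quotas.

    Largest-remainder rounding distributes the cohort over copy numbers
    0..max_copies so the composition matches the truncated pmf as closely
    as integers allow.
    """
    k = np.arange(max_copies + 1)
    pmf = _poisson.pmf(k, lam)
    pmf = pmf / pmf.sum()
    expected = pmf * n_cells
    counts = np.floor(expected).astype(int)
    shortfall = n_cells - counts.sum()
    if shortfall > 0:
        order = np.argsort(-(expected - counts), kind="stable")
        counts[order[:shortfall]] += 1
    return np.repeat(k, counts).astype(float)


def simulate_cells(model: LabelModel, n_cells: int, rng) -> np.ndarray:
    """Simulate colour vectors for ``n_cells`` labelled cells.

    Returns an (n_cells, n_channels) array of unit L2-normalized rows.
    Cells that draw zero copies of every colour are unlabelled — invisible
    in any experiment — and are redrawn.

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if model.mean_copies == 0:
        raise ValueError("mean_copies is 0: no labelled cells possible")
    rng = np.random.default_rng(rng)

    if model.sampling == "quota":
        # unlabelled (all-zero) cells are invisible; top the cohort up with
        # labelled rows from fresh quota draws until n_cells are collected
        col = _quota_column(n_cells, model.mean_copies, model.max_copies)
        collected = []
        n_have = 0
        for attempt in range(1000):
            draw = np.column_stack(
                [rng.permutation(col) for _ in range(model.n_channels)]
            )
            labelled = draw[draw.sum(axis=1) > 0]
            if len(labelled) == 0:
                continue
            collected.append(labelled[: n_cells - n_have])
            n_have += len(collected[-1])
            if n_have == n_cells:
                break
        else:
            raise RuntimeError("could not draw a cohort with all cells labelled")
        counts = np.vstack(collected)
    else:
        counts = np.empty((n_cells, model.n_channels))
        filled = 0
        while filled < n_cells:
            draw = rng.poisson(model.mean_copies, size=(n_cells, model.n_channels))
            draw = np.minimum(draw, model.max_copies).astype(float)
            labelled = draw[draw.sum(axis=1) > 0]
            take = min(len(labelled), n_cells - filled)
            counts[filled : filled + take] = labelled[:take]
            filled += take

    return counts / np.linalg.norm(counts, axis=1, keepdims=True)


def _pairs_beyond(vectors: np.ndarray, th_d: float, chunk: int = 512):
    """Count unordered pairs with distance > th_d, chunked over rows.

    Returns (n_beyond, n_pairs, per_cell_beyond) where per_cell_beyond[i]
    is the number of *other* cells farther than th_d from cell i.
    """
    n = len(vectors)
    per_cell = np.zeros(n, dtype=np.int64)
    sq = np.einsum("ij,ij->i", vectors, vectors)
    th2 = th_d * th_d
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        # squared distances block (start:stop) x (all)
        d2 = (
            sq[start:stop, None]
            + sq[None, :]
            - 2.0 * vectors[start:stop] @ vectors.T
        )
        np.maximum(d2, 0.0, out=d2)
        beyond = d2 > th2
        beyond[np.arange(stop - start), np.arange(start, stop)] = False
        per_cell[start:stop] = beyond.sum(axis=1)
    n_beyond = int(per_cell.sum()) // 2
    n_pairs = n * (n - 1) // 2
    return n_beyond, n_pairs, per_cell


def percent_discriminable(vectors: np.ndarray, th_d: float):
    """Percentage of unordered cell pairs separated by d > Th(d).

    Returns ``(percent, per_cell_mean, per_cell_sd)`` where the per-cell
    statistics summarize each cell's fraction of discriminable partners.
    """
    vectors = np.asarray(vectors, dtype=float)
    n = len(vectors)
    if n < 2:
        raise ValueError("need at least 2 vectors")
    n_beyond, n_pairs, per_cell = _pairs_beyond(vectors, th_d)
    frac = per_cell / (n - 1)
    return (
        100.0 * n_beyond / n_pairs,
        float(100.0 * frac.mean()),
        float(100.0 * frac.std()),
    )


def percent_unique(
    model: LabelModel,
    n_cells: int,
    th_d: float,
    n_sims: int = 200,
    rng=None,
):
    """Monte-Carlo percent of uniquely labelled cells.

    Per simulation, a cell is unique when no other cell's colour vector
    lies within Th(d).  Returns (mean %, SD %) over ``n_sims`` cohorts.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    rng = np.random.default_rng(rng)
    results = np.empty(n_sims)
    for s in range(n_sims):
        v = simulate_cells(model, n_cells, rng)
        _, _, per_cell = _pairs_beyond(v, th_d)
        results[s] = 100.0 * (per_cell == n_cells - 1).mean()
    return float(results.mean()), float(results.std())


def discriminability_with_noise(model: LabelModel, n_cells: int, rng=None):
    """Neurite-noise model: derive Th(d) from noise, then score discriminability.

    Each cell's noisy replicate is its normalized vector plus per-channel
    Gaussian(0, noise_sd), clipped at 0 and re-normalized — emulating the
    fluctuation of a neurite's colour around its cell's true colour.
    Th(d) is set to the 95th percentile of noisy-to-true distances (so the
    threshold covers 95% of noisy neurites), and percent discriminable is
    computed on the true vectors at that threshold.

    Returns ``(th_d, percent_discriminable)``.
    """
    if model.noise_sd <= 0:
        raise ValueError("noise_sd must be > 0 for the noise model")
    rng = np.random.default_rng(rng)
    v = simulate_cells(model, n_cells, rng)
    noisy = np.clip(v + rng.normal(0.0, model.noise_sd, v.shape), 0.0, None)
    norms = np.linalg.norm(noisy, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    noisy /= norms
    d_noise = np.linalg.norm(noisy - v, axis=1)
    th_d = float(np.percentile(d_noise, 95))
    pct, _, _ = percent_discriminable(v, th_d)
    return th_d, pct
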