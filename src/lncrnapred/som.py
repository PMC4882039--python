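"""Self-organizing-map subsampling of representative training sets.

A rectangular Kohonen grid (default 8 x 8) is trained per class by online
competitive learning: the winner is the neuron minimizing the squared
Euclidean distance to the presented sample, and all weights move toward the
sample scaled by a learning rate and a Gaussian neighborhood of the winner,
both decaying over training.  After training, each sample maps to its winning
neuron, and a target of L training samples is allocated across neurons in
proportion to occupancy with ceiling rounding:

    O_i = ceil(w_i / N * L),  capped at w_i,

then drawn uniformly without replacement within each neuron.  The ceiling
makes the drawn total land in [L, L + number of non-empty neurons] — which is
why targeting 2000 samples per class yields set sizes slightly above 2000.

Inputs are expected z-scored (see :func:`select_training_set`) so that
large-scale features such as Length do not dominate the distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError


@dataclass
class SOMGrid:
    """Trained map: weight matrix (rows*cols, m) plus its learning schedule."""

    rows: int
    cols: int
    weights: np.ndarray
    eta_start: float
    eta_end: float
    sigma_start: float
    sigma_end: float
    iterations: int
    rng_seed: int

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    def grid_coords(self) -> np.ndarray:
        r, c = np.divmod(np.arange(self.n_neurons), self.cols)
        return np.stack([r, c], axis=1).astype(float)


@dataclass
class SampleAllocation:
    """Per-neuron quotas and the drawn sample indices/ids."""

    neuron_counts: np.ndarray
    pool_size: int
    target: int
    per_neuron_quota: np.ndarray
    selected_indices: np.ndarray
    selected_ids: list


def _validate_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ConfigurationError("X must be a non-empty 2-D matrix")
    return X


def som_fit(
    X,
    rows: int = 8,
    cols: int = 8,
    epochs: int = 10,
    seed: int = 0,
    eta: tuple[float, float] = (0.5, 0.01),
    sigma: tuple[float, float] | None = None,
) -> SOMGrid:
    """Train the map by online competitive learning.

    Weights initialize uniformly at random within each feature's observed
    [min, max].  The learning rate decays linearly from eta[0] to eta[1] and
    the Gaussian neighborhood width from max(rows, cols)/2 to 1 over
    epochs * n_samples iterations; samples are presented in a fresh random
    order each epoch.  Fully reproducible given the seed.
    """
    X = _validate_matrix(X)
    if epochs < 1:
        raise ConfigurationError(f"epochs must be >= 1, got {epochs}")
    if rows < 1 or cols < 1:
        raise ConfigurationError("grid must have at least one neuron")
    n, m = X.shape
    rng = np.random.default_rng(seed)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    k = rows * cols
    weights = rng.uniform(lo, hi, size=(k, m))
    sigma_start, sigma_end = sigma if sigma is not None else (max(rows, cols) / 2.0, 1.0)
    eta_start, eta_end = eta
    total = epochs * n
    grid = SOMGrid(
        rows=rows, cols=cols, weights=weights,
        eta_start=eta_start, eta_end=eta_end,
        sigma_start=sigma_start, sigma_end=sigma_end,
        iterations=total, rng_seed=seed,
    )
    coords = grid.grid_coords()
    t = 0
    denom = max(total - 1, 1)
    for _ in range(epochs):
        for i in rng.permutation(n):
            x = X[i]
            d = ((weights - x) ** 2).sum(axis=1)
            winner = int(np.argmin(d))
            frac = t / denom
            eta_t = eta_start + (eta_end - eta_start) * frac
            sigma_t = sigma_start + (sigma_end - sigma_start) * frac
            gd2 = ((coords - coords[winner]) ** 2).sum(axis=1)
            h = np.exp(-gd2 / (2.0 * sigma_t**2))
            weights += eta_t * h[:, None] * (x - weights)
            t += 1
    return grid


def som_assign(grid: SOMGrid, X) -> tuple[np.ndarray, np.ndarray]:
    """Winning neuron per sample (lowest index on ties) and occupancy counts."""
    X = _validate_matrix(X)
    if X.shape[1] != grid.weights.shape[1]:
        raise ValidationError(
            f"feature dimension {X.shape[1]} != grid dimension "
            f"{grid.weights.shape[1]}"
        )
    # squared distances via expansion; argmin returns the lowest tied index
    d = (
        (X**2).sum(axis=1)[:, None]
        - 2.0 * X @ grid.weights.T
        + (grid.weights**2).sum(axis=1)[None, :]
    )
    winners = np.argmin(d, axis=1)
    counts = np.bincount(winners, minlength=grid.n_neurons)
    return winners, counts


def allocation_quota(neuron_counts, L: int) -> np.ndarray:
    """Uncapped ceiling quotas O_i = ceil(w_i / N * L) (exact integer math)."""
    w = np.asarray(neuron_counts, dtype=np.int64)
    N = int(w.sum())
    return -((-w * L) // N)


def allocate_and_draw(
    assignments,
    neuron_counts,
    L: int,
    seed: int = 0,
    ids=None,
) -> SampleAllocation:
    """Draw O_i samples uniformly without replacement from each neuron.

    Quotas are the ceiling allocation capped at occupancy so that sampling
    without replacement stays well-defined.
    """
    assignments = np.asarray(assignments)
    w = np.asarray(neuron_counts, dtype=np.int64)
    N = int(w.sum())
    if L < 1:
        raise ConfigurationError(f"L must be >= 1, got {L}")
    if L > N:
        raise ConfigurationError(f"L = {L} exceeds pool size N = {N}")
    quota = np.minimum(allocation_quota(w, L), w)
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for i in range(len(w)):
        if quota[i] == 0:
            continue
        members = np.flatnonzero(assignments == i)
        chosen.append(np.sort(rng.choice(members, size=int(quota[i]), replace=False)))
    selected = np.concatenate(chosen) if chosen else np.empty(0, dtype=int)
    selected_ids = [ids[j] for j in selected] if ids is not None else list(selected)
    return SampleAllocation(
        neuron_counts=w,
        pool_size=N,
        target=L,
        per_neuron_quota=quota,
        selected_indices=selected,
        selected_ids=selected_ids,
    )


def standardize(X, mean=None, sd=None) -> np.ndarray:
    """Z-score columns; zero-variance columns pass through unscaled."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0) if mean is None else np.asarray(mean, dtype=float)
    s = X.std(axis=0) if sd is None else np.asarray(sd, dtype=float)
    s = np.where(s > 0, s, 1.0)
    return (X - mu) / s


def select_training_set(
    positives,
    negatives,
    L: int = 2000,
    seed: int = 0,
    rows: int = 8,
    cols: int = 8,
    epochs: int = 10,
    positive_ids=None,
    negative_ids=None,
) -> tuple[list, list]:
    """Pick L-proportional representative subsets for both classes.

    Each class gets its own map fit and allocation; features are z-scored
    with mean/SD pooled over both classes first.  Returned id-set sizes lie
    in [L, L + rows*cols].
    """
    pos = _validate_matrix(positives)
    neg = _validate_matrix(negatives)
    for name, pool in (("positive", pos), ("negative", neg)):
        if pool.shape[0] < L:
            raise ConfigurationError(
                f"{name} pool ({pool.shape[0]}) smaller than L = {L}"
            )
    stacked = np.vstack([pos, neg])
    mu, sd = stacked.mean(axis=0), stacked.std(axis=0)
    seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    out = []
    for pool, ids, fit_seed, draw_seed in (
        (pos, positive_ids, int(seeds[0]), int(seeds[1])),
        (neg, negative_ids, int(seeds[2]), int(seeds[3])),
    ):
        Z = standardize(pool, mu, sd)
        grid = som_fit(Z, rows=rows, cols=cols, epochs=epochs, seed=fit_seed)
        winners, counts = som_assign(grid, Z)
        alloc = allocate_and_draw(winners, counts, L, seed=draw_seed, ids=ids)
        out.append(alloc.selected_ids)
    return out[0], out[1]
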