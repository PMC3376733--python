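"""Vectorised without-replacement subset sampling shared by the Monte Carlo
positional tests."""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np

# Cap on chunk size (elements of the uniform matrix) so trials x universe
# never allocates more than ~160 MB at float64.
_CHUNK_ELEMENTS = 20_000_000


def subset_means(
    values: np.ndarray, k: int, n_trials: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of ``n_trials`` random size-``k`` subsets of ``values``, drawn
    without replacement, one independent subset per trial.

    Implemented by ranking a uniform matrix per trial (argpartition of the
    k smallest uniforms is a uniformly random k-subset), chunked to bound
    memory.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if not 1 <= k <= n:
        raise ValueError(f"subset size {k} not in [1, {n}]")
    if k == n:
        return np.full(n_trials, values.mean())
    out = np.empty(n_trials)
    chunk = max(1, _CHUNK_ELEMENTS // n)
    done = 0
    while done < n_trials:
        t = min(chunk, n_trials - done)
        u = rng.random((t, n))
        idx = np.argpartition(u, k - 1, axis=1)[:, :k]
        out[done : done + t] = values[idx].mean(axis=1)
        done += t
    return out


def exact_subset_means(values: np.ndarray, k: int, cap: int = 100_000) -> np.ndarray:
    """Means of every size-``k`` subset of ``values``; refuses when
    C(n, k) exceeds ``cap``."""
    values = np.asarray(values, dtype=float)
    n = values.size
    n_subsets = comb(n, k)
    if n_subsets > cap:
        raise ValueError(
            f"C({n}, {k}) = {n_subsets} exceeds the enumeration cap {cap}"
        )
    idx = np.fromiter(
        (i for combo in combinations(range(n), k) for i in combo),
        dtype=np.intp,
        count=n_subsets * k,
    ).reshape(n_subsets, k)
    return values[idx].mean(axis=1)
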