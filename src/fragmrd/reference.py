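"""Per-fragment-length score table built from tumour vs non-tumour pools.

The score of a fragment length L is the log2 ratio of its probability in
tumour-derived cfDNA to its probability in non-tumour cfDNA, estimated by
repeated subsampling: each bootstrap iteration draws ``n_sample`` fragments
from each pool, forms the two empirical densities, takes ``log2`` of their
ratio clipped to ``[-cap, +cap]`` (the cap is also assigned outright when one
density is zero), and zeroes lengths whose combined sampled count is at or
below ``min_count``. The final table averages the iteration scores, which
smooths sampling noise in sparsely covered length bins.
"""

from __future__ import annotations

import dataclasses
import uuid
from typing import Iterable, Mapping

import numpy as np

from .fragio import FragmentPool


@dataclasses.dataclass
class FragmentScoreTable:
    """Lookup table mapping fragment length (bp) to a per-fragment score.

    ``scores[L]`` is the score of length L; lengths outside the built support
    score 0. ``meta`` records the build parameters for provenance and caching.
    """

    scores: np.ndarray
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)

    @property
    def cap(self) -> float:
        return float(self.meta.get("cap", np.abs(self.scores).max(initial=0.0)))

    @property
    def table_id(self) -> str:
        return str(self.meta.get("table_id", "unkeyed"))

    def score_of(self, lengths: Iterable[int] | np.ndarray) -> np.ndarray:
        """Vectorised lookup; lengths beyond the table score 0."""
        arr = np.asarray(lengths, dtype=np.int64)
        out = np.zeros(arr.shape, dtype=float)
        ok = (arr >= 0) & (arr < self.scores.size)
        out[ok] = self.scores[arr[ok]]
        return out

    def aligned(self, size: int) -> np.ndarray:
        """Score vector zero-padded or truncated-safe to ``size`` bins."""
        if self.scores.size >= size:
            return self.scores[:size]
        out = np.zeros(size, dtype=float)
        out[: self.scores.size] = self.scores
        return out


def empirical_density(sample: Iterable[int], support: range | None = None) -> dict[int, float]:
    """Empirical probability of each fragment length in ``sample``.

    ``support`` restricts the returned mapping (zero-probability lengths in
    the support are included); by default only observed lengths are returned.
    """
    arr = np.asarray(list(sample), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("cannot compute a density from an empty sample")
    if arr.min() < 0:
        raise ValueError("lengths must be non-negative")
    counts = np.bincount(arr)
    dens = counts / arr.size
    if support is None:
        return {int(L): float(dens[L]) for L in np.flatnonzero(counts)}
    return {int(L): float(dens[L]) if L < dens.size else 0.0 for L in support}


def _draw_counts(
    pool: FragmentPool, n_sample: int, size: int, rng: np.random.Generator, replace: bool
) -> np.ndarray:
    """Counts of ``n_sample`` fragments drawn from the pool histogram."""
    counts = pool.padded(size)
    if replace:
        return rng.multinomial(n_sample, counts / counts.sum())
    if n_sample > counts.sum():
        raise ValueError(
            f"cannot draw {n_sample} fragments without replacement from a pool of {counts.sum()}"
        )
    return rng.multivariate_hypergeometric(counts, n_sample)


def bootstrap_iteration_scores(
    tumour_pool: FragmentPool,
    nontumour_pool: FragmentPool,
    n_sample: int = 10_000,
    cap: float = 5.0,
    min_count: int = 20,
    rng: np.random.Generator | None = None,
    replace: bool = True,
) -> np.ndarray:
    """One bootstrap iteration's score vector.

    Draws ``n_sample`` fragments from each pool; per length the score is
    ``log2(d_tumour / d_nontumour)`` clipped to ``[-cap, cap]`` (``+cap`` /
    ``-cap`` when exactly one density is zero) and forced to 0 wherever the
    combined sampled count is ``<= min_count``.
    """
    if n_sample <= 0:
        raise ValueError("n_sample must be positive")
    rng = np.random.default_rng(rng)
    size = max(tumour_pool.counts.size, nontumour_pool.counts.size)
    t = _draw_counts(tumour_pool, n_sample, size, rng, replace)
    nt = _draw_counts(nontumour_pool, n_sample, size, rng, replace)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.log2((t / n_sample) / (nt / n_sample))
    s[(t > 0) & (nt == 0)] = cap
    s[(t == 0) & (nt > 0)] = -cap
    s[(t == 0) & (nt == 0)] = 0.0
    s = np.clip(s, -cap, cap)
    s[(t + nt) <= min_count] = 0.0
    return s


def build_score_table(
    tumour_pool: FragmentPool,
    nontumour_pool: FragmentPool,
    n_boot: int = 1000,
    n_sample: int = 10_000,
    cap: float = 5.0,
    min_count: int = 20,
    seed: int | np.random.Generator | None = None,
    replace: bool = True,
    aggregate: str = "mean",
) -> FragmentScoreTable:
    """Build the per-length score table as the mean of ``n_boot`` iterations.

    Deterministic given ``seed``: a single RNG stream is consumed sequentially
    by the iterations. ``aggregate`` may be ``"mean"`` (default) or
    ``"median"``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    rng = np.random.default_rng(seed)
    size = max(tumour_pool.counts.size, nontumour_pool.counts.size)
    if aggregate == "mean":
        acc = np.zeros(size, dtype=float)
        for _ in range(n_boot):
            acc += bootstrap_iteration_scores(
                tumour_pool, nontumour_pool, n_sample, cap, min_count, rng, replace
            )
        scores = acc / n_boot
    else:
        stack = np.empty((n_boot, size), dtype=float)
        for i in range(n_boot):
            stack[i] = bootstrap_iteration_scores(
                tumour_pool, nontumour_pool, n_sample, cap, min_count, rng, replace
            )
        scores = np.median(stack, axis=0)
    meta: Mapping = {
        "table_id": uuid.uuid4().hex,
        "n_boot": n_boot,
        "n_sample": n_sample,
        "cap": cap,
        "min_count": min_count,
        "seed": seed if isinstance(seed, int) else None,
        "replace": replace,
        "aggregate": aggregate,
        "tumour_sample_id": tumour_pool.sample_id,
        "tumour_total": tumour_pool.total,
        "nontumour_sample_id": nontumour_pool.sample_id,
        "nontumour_total": nontumour_pool.total,
    }
    return FragmentScoreTable(scores=scores, meta=dict(meta))
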