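"""Patient-level (FS) and variant-level (VFS) fragmentation scores.

The patient FS is the mean per-fragment score over one million fragments
sampled (with replacement) from the patient's plasma pool; a patient is
MRD-positive on the FS axis when their score exceeds the control mean plus
two standard deviations. The VFS averages the same per-fragment score over
the reads supporting a single variant and compares it against a read-count-
dependent null threshold derived from non-malignant cfDNA, classifying the
variant as tumour-derived or blood-derived (CHIP-like); variants with fewer
than ``min_reads`` supporting reads are left indeterminate.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Sequence

import numpy as np

from .fragio import FragmentPool, SupportingFragments
from .reference import FragmentScoreTable

TUMOUR = "tumour"
BLOOD = "blood"
INDETERMINATE = "indeterminate"


@dataclasses.dataclass
class PatientFS:
    patient_id: str
    fs: float
    n_sampled: int
    seed: int | None = None


@dataclasses.dataclass
class VariantFS:
    key: tuple
    vfs: float  # NaN when no supporting fragments
    n_reads: int
    classification: str | None = None


# ---------------------------------------------------------------------------
# patient-level score
# ---------------------------------------------------------------------------


def patient_fs(
    pool: FragmentPool,
    table: FragmentScoreTable,
    n_sample: int = 1_000_000,
    seed: int | np.random.Generator | None = None,
    replace: bool = True,
) -> PatientFS:
    """Mean per-fragment score over ``n_sample`` fragments drawn from ``pool``.

    Sampling is with replacement by default (so pools smaller than
    ``n_sample`` behave uniformly); the draw is realised as a multinomial over
    the pool's length histogram, which is distributionally identical to
    drawing fragments one by one.
    """
    if pool.total == 0:
        raise ValueError(f"fragment pool {pool.sample_id!r} is empty")
    if n_sample <= 0:
        raise ValueError("n_sample must be positive")
    rng = np.random.default_rng(seed)
    counts = pool.counts
    if replace:
        draw = rng.multinomial(n_sample, counts / counts.sum())
    else:
        if n_sample > counts.sum():
            raise ValueError("n_sample exceeds pool size for without-replacement sampling")
        draw = rng.multivariate_hypergeometric(counts, n_sample)
    s = table.aligned(counts.size)
    fs = float(draw @ s) / n_sample
    return PatientFS(
        patient_id=pool.sample_id,
        fs=fs,
        n_sampled=n_sample,
        seed=seed if isinstance(seed, int) else None,
    )


def expected_fs(pool: FragmentPool, table: FragmentScoreTable) -> float:
    """Closed-form expectation of the patient FS: sum_L p(L) * s(L)."""
    p = pool.probabilities()
    return float(p @ table.aligned(p.size))


def fs_threshold(control_fs: Sequence[float]) -> float:
    """MRD-positivity threshold: control mean + 2 * sample SD (n-1)."""
    vals = np.asarray(list(control_fs), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 control FS values for mean + 2 SD")
    return float(vals.mean() + 2.0 * vals.std(ddof=1))


def fs_call(fs: float, threshold: float) -> bool:
    """MRD-positive iff the FS strictly exceeds the threshold."""
    return bool(fs > threshold)


def fs_replicates(
    pool: FragmentPool,
    table: FragmentScoreTable,
    n_replicates: int = 10,
    n_sample: int = 1_000_000,
    seed: int | None = None,
) -> dict:
    """Repeated-subsampling reproducibility of the patient FS.

    Draws ``n_replicates`` independent subsamples of ``n_sample`` fragments,
    computes the FS of each, and reports both the t-based 95% confidence
    interval of the mean and the replicate min-max range.
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    values = np.array(
        [patient_fs(pool, table, n_sample=n_sample, seed=rng).fs for _ in range(n_replicates)]
    )
    sd = values.std(ddof=1)
    half = stats.t.ppf(0.975, df=n_replicates - 1) * sd / np.sqrt(n_replicates)
    return {
        "values": values,
        "mean": float(values.mean()),
        "sd": float(sd),
        "ci_low": float(values.mean() - half),
        "ci_high": float(values.mean() + half),
        "ci_width": float(2 * half),
        "range_width": float(values.max() - values.min()),
    }


# ---------------------------------------------------------------------------
# variant-level score
# ---------------------------------------------------------------------------


def variant_fs(
    support: Sequence[SupportingFragments], table: FragmentScoreTable
) -> VariantFS:
    """Average per-fragment score over a variant's supporting reads.

    ``support`` holds the records for one variant (pre- and postoperative
    plasma records are merged so more fragments contribute). With no
    supporting fragments the VFS is NaN and the variant is indeterminate.
    """
    if not support:
        raise ValueError("no supporting-fragment records given")
    keys = {r.key for r in support}
    if len(keys) > 1:
        raise ValueError(f"supporting records span multiple variants: {sorted(keys)}")
    lengths = [L for r in support for L in r.lengths]
    if not lengths:
        return VariantFS(key=support[0].key, vfs=float("nan"), n_reads=0,
                         classification=INDETERMINATE)
    scores = table.score_of(np.asarray(lengths))
    return VariantFS(key=support[0].key, vfs=float(scores.mean()), n_reads=len(lengths))


def vfs_null_threshold(
    nonmalignant_pool: FragmentPool,
    table: FragmentScoreTable,
    n: int,
    n_iter: int = 1000,
    rng: int | np.random.Generator | None = None,
) -> float:
    """Null VFS threshold for a variant supported by ``n`` reads.

    ``n`` fragments are drawn from the pooled non-malignant cfDNA ``n_iter``
    times; the threshold is the mean + 2 SD of the resulting VFS values.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2 to estimate an SD")
    rng = np.random.default_rng(rng)
    p = nonmalignant_pool.probabilities()
    s = table.aligned(p.size)
    draws = rng.multinomial(n, p, size=n_iter)
    vfs_vals = (draws @ s) / n
    return float(vfs_vals.mean() + 2.0 * vfs_vals.std(ddof=1))


class VfsThresholds:
    """Cached read-count-dependent VFS null thresholds for one score table.

    The cache key includes the score table's build id, so a rebuilt table
    never reuses stale thresholds. Each read count ``n`` gets its own RNG
    stream derived from ``(seed, n)``, making thresholds independent of the
    order in which they are requested.
    """

    def __init__(
        self,
        nonmalignant_pool: FragmentPool,
        table: FragmentScoreTable,
        n_iter: int = 1000,
        seed: int = 0,
    ) -> None:
        self.pool = nonmalignant_pool
        self.table = table
        self.n_iter = n_iter
        self.seed = seed
        self._cache: dict[tuple[str, int], float] = {}

    def __call__(self, n: int) -> float:
        key = (self.table.table_id, int(n))
        if key not in self._cache:
            rng = np.random.default_rng([self.seed, int(n)])
            self._cache[key] = vfs_null_threshold(
                self.pool, self.table, n, n_iter=self.n_iter, rng=rng
            )
        return self._cache[key]


def classify_variant(
    record: VariantFS,
    threshold_fn: Callable[[int], float],
    min_reads: int = 8,
) -> VariantFS:
    """Classify a variant as tumour- or blood-derived from its VFS.

    Variants with fewer than ``min_reads`` supporting reads are
    indeterminate; otherwise tumour when the VFS strictly exceeds the null
    threshold for that read count, blood otherwise.
    """
    if record.n_reads < min_reads:
        label = INDETERMINATE
    elif record.vfs > threshold_fn(record.n_reads):
        label = TUMOUR
    else:
        label = BLOOD
    return dataclasses.replace(record, classification=label)


def vfs_performance_score(
    classifications: Sequence[str], truth: Sequence[str]
) -> int:
    """+1 per correct, -1 per wrong, 0 per indeterminate classification."""
    if len(classifications) != len(truth):
        raise ValueError(
            f"length mismatch: {len(classifications)} classifications vs {len(truth)} truths"
        )
    score = 0
    for c, t in zip(classifications, truth):
        if c == INDETERMINATE:
            continue
        score += 1 if c == t else -1
    return score
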