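"""Compartment-based variant classification and the variant-tracking MRD call.

Variants seen across a patient's four compartments (tumour tissue, blood
cell pellet, pre- and postoperative plasma) are triaged by where the
upstream caller detected them: blood-cell-pellet variants are germline (if
also in tissue) or CHIP (if not) and are excluded; tissue- or preoperative-
plasma variants are trackable; variants seen only postoperatively are
uninformative. MRD is then called when at least ``k`` trackable variants
have postoperative support of at least ``r`` reads, with ``(r, k)`` chosen
by an exhaustive grid search for the highest concordance with recurrence.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np

from .fragio import PatientRecord, VariantObservation

GERMLINE = "germline"
CHIP = "chip"
TRACKABLE = "trackable"
UNINFORMATIVE = "uninformative"

READ_CUTOFF_RANGE = (1, 8)
MIN_VARIANTS_RANGE = (1, 6)


@dataclasses.dataclass(frozen=True)
class VariantClass:
    key: tuple
    label: str


@dataclasses.dataclass(frozen=True)
class VariantCallParams:
    """Grid-searched thresholds: ``read_cutoff`` r and ``min_variants`` k."""

    read_cutoff: int
    min_variants: int

    def __post_init__(self) -> None:
        if not (READ_CUTOFF_RANGE[0] <= self.read_cutoff <= READ_CUTOFF_RANGE[1]):
            raise ValueError(f"read_cutoff must lie in {READ_CUTOFF_RANGE}")
        if not (MIN_VARIANTS_RANGE[0] <= self.min_variants <= MIN_VARIANTS_RANGE[1]):
            raise ValueError(f"min_variants must lie in {MIN_VARIANTS_RANGE}")


def classify_baseline_variants(
    observations: Sequence[VariantObservation],
) -> list[VariantClass]:
    """Label each variant of one patient by its compartment pattern.

    "Detected" means reported by the upstream caller (``pipeline_called``) in
    that compartment; raw supporting reads alone do not promote a variant at
    baseline. Labels are mutually exclusive and exhaustive:

    * in BCP and in tissue -> germline
    * in BCP, not in tissue -> CHIP
    * else in tissue or preoperative plasma -> trackable
    * else (postoperative plasma only) -> uninformative
    """
    detected: dict[tuple, set[str]] = {}
    order: list[tuple] = []
    for o in observations:
        if o.key not in detected:
            detected[o.key] = set()
            order.append(o.key)
        if o.pipeline_called:
            detected[o.key].add(o.compartment)
    out = []
    for key in order:
        comps = detected[key]
        if "bcp" in comps:
            label = GERMLINE if "tissue" in comps else CHIP
        elif "tissue" in comps or "preop_plasma" in comps:
            label = TRACKABLE
        else:
            label = UNINFORMATIVE
        out.append(VariantClass(key=key, label=label))
    return out


def trackable_postop_support(
    patient: PatientRecord,
) -> tuple[np.ndarray, np.ndarray]:
    """Postoperative (alt_reads, pipeline_called) arrays for trackable variants.

    Trackable variants with no postoperative observation contribute
    ``alt_reads = 0, pipeline_called = False``.
    """
    labels = {vc.key: vc.label for vc in classify_baseline_variants(patient.observations)}
    postop = {o.key: o for o in patient.observations if o.compartment == "postop_plasma"}
    reads, called = [], []
    for key, label in labels.items():
        if label != TRACKABLE:
            continue
        o = postop.get(key)
        reads.append(o.alt_reads if o else 0)
        called.append(o.pipeline_called if o else False)
    return np.asarray(reads, dtype=np.int64), np.asarray(called, dtype=bool)


def count_detected_variants(
    postop_alt_reads: Iterable[int],
    read_cutoff: int,
    pipeline_called: Iterable[bool] | None = None,
    count_pipeline_called: bool = True,
) -> int:
    """Number of trackable variants detected in postoperative plasma.

    A variant counts when its raw supporting reads reach ``read_cutoff``;
    pipeline-called variants count regardless of the cutoff (the caller has
    already accepted them) unless ``count_pipeline_called`` is disabled.
    """
    if read_cutoff < 1:
        raise ValueError("read_cutoff must be >= 1")
    reads = np.asarray(list(postop_alt_reads), dtype=np.int64)
    hit = reads >= read_cutoff
    if pipeline_called is not None and count_pipeline_called:
        hit |= np.asarray(list(pipeline_called), dtype=bool)
    return int(hit.sum())


def variant_mrd_call(detected: int, min_variants: int) -> bool:
    """MRD-positive iff at least ``min_variants`` trackable variants detected."""
    if min_variants < 1:
        raise ValueError("min_variants must be >= 1")
    return bool(detected >= min_variants)


def _count_matrix(
    patients_support: Sequence[tuple[np.ndarray, np.ndarray]],
    r_values: np.ndarray,
    count_pipeline_called: bool = True,
) -> np.ndarray:
    """counts[i, j] = detected variants of patient i at read cutoff r_values[j]."""
    counts = np.zeros((len(patients_support), r_values.size), dtype=np.int64)
    for i, (reads, called) in enumerate(patients_support):
        if reads.size == 0:
            continue
        hit = reads[:, None] >= r_values[None, :]
        if count_pipeline_called:
            hit |= called[:, None]
        counts[i] = hit.sum(axis=0)
    return counts


def optimize_cutoffs(
    patients_support: Sequence[tuple[np.ndarray, np.ndarray]],
    recurrence: Sequence[bool],
    r_range: tuple[int, int] = READ_CUTOFF_RANGE,
    k_range: tuple[int, int] = MIN_VARIANTS_RANGE,
    count_pipeline_called: bool = True,
    return_grid: bool = False,
):
    """Exhaustive grid search of ``(read_cutoff, min_variants)``.

    ``patients_support`` holds one ``(alt_reads, pipeline_called)`` pair per
    training patient (see :func:`trackable_postop_support`); concordance is
    plain accuracy against the recurrence labels. Ties break deterministically:
    highest accuracy, then larger r (stringent on raw read support, the
    channel through which sequencing noise creates false positives), then
    smaller k (patients with few trackable variants stay detectable). With
    degenerate labels (all identical) the default ``(1, 1)`` is returned with
    a warning.
    """
    y = np.asarray(list(recurrence), dtype=bool)
    if len(patients_support) != y.size:
        raise ValueError("patients_support and recurrence must align")
    r_values = np.arange(r_range[0], r_range[1] + 1)
    k_values = np.arange(k_range[0], k_range[1] + 1)
    if y.size == 0 or y.all() or not y.any():
        warnings.warn(
            "degenerate recurrence labels (all identical); returning default cutoffs (1, 1)",
            stacklevel=2,
        )
        params = VariantCallParams(1, 1)
        if return_grid:
            return params, np.full((r_values.size, k_values.size), np.nan)
        return params

    counts = _count_matrix(patients_support, r_values, count_pipeline_called)
    # calls[i, j, l] = counts[i, j] >= k_values[l]
    calls = counts[:, :, None] >= k_values[None, None, :]
    acc = (calls == y[:, None, None]).mean(axis=0)  # (n_r, n_k)

    best = acc.max()
    # tie-break: larger r first, then smaller k
    best_r_idx = max(
        (j for j in range(r_values.size) if np.isclose(acc[j].max(), best)),
    )
    best_k_idx = min(
        (l for l in range(k_values.size) if np.isclose(acc[best_r_idx, l], best)),
    )
    params = VariantCallParams(int(r_values[best_r_idx]), int(k_values[best_k_idx]))
    if return_grid:
        return params, acc
    return params
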