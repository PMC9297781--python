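"""Synthetic cfDNA cohorts with known ground truth.

Fragment lengths follow discrete truncated-normal mixtures of mono- and
dinucleosomal components; tumour-derived fragments are shifted shorter
(mono ~145 bp, di ~300 bp) than non-tumour cfDNA (mono ~167 bp, di ~334 bp).
A patient's plasma is a two-component mixture governed by a tumour fraction.
Variants are laid out with the compartment structure the tumour-informed
workflow assumes: germline variants appear in blood cell pellet and tissue,
CHIP variants in the pellet only, trackable variants in tissue/preoperative
plasma, with postoperative support scaled by the postoperative tumour
fraction. Recurrence labels, follow-up times and hidden origin labels are
emitted so every classifier in the package can be scored against generator
truth.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fragio import (
    DEFAULT_LENGTH_CAP,
    FragmentPool,
    PatientRecord,
    SupportingFragments,
    VariantObservation,
    merge_pools,
    write_cohort_metadata,
    write_fragment_table,
    write_supporting_fragments,
    write_variant_table,
)


@dataclasses.dataclass(frozen=True)
class FragmentLengthProfile:
    """Discrete truncated-normal mixture over fragment lengths.

    ``components`` is a sequence of ``(mode_bp, spread_bp, weight)`` tuples;
    weights must be non-negative and sum to 1. A spread of 0 collapses the
    component to a point mass at its mode.
    """

    components: tuple[tuple[float, float, float], ...]
    length_cap: int = DEFAULT_LENGTH_CAP

    def __post_init__(self) -> None:
        w = np.array([c[2] for c in self.components], dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("component weights must be >= 0 and sum to 1")
        if any(c[0] <= 0 for c in self.components):
            raise ValueError("component modes must be positive")

    def pmf(self) -> np.ndarray:
        """Probability of each integer length on [0, length_cap] (0 at L=0)."""
        L = np.arange(self.length_cap + 1, dtype=float)
        p = np.zeros_like(L)
        for mode, spread, weight in self.components:
            if spread == 0:
                comp = np.zeros_like(L)
                m = int(round(mode))
                if not (1 <= m <= self.length_cap):
                    raise ValueError(f"point-mass mode {mode} outside [1, {self.length_cap}]")
                comp[m] = 1.0
            else:
                comp = np.exp(-0.5 * ((L - mode) / spread) ** 2)
                comp[0] = 0.0
                comp /= comp.sum()
            p += weight * comp
        p[0] = 0.0
        return p / p.sum()


NONTUMOUR_PROFILE = FragmentLengthProfile(((167.0, 10.0, 0.8), (334.0, 25.0, 0.2)))
TUMOUR_PROFILE = FragmentLengthProfile(((145.0, 12.0, 0.85), (300.0, 30.0, 0.15)))


def sample_fragment_pool(
    profile: FragmentLengthProfile,
    n: int,
    seed: int | np.random.Generator | None = None,
    sample_id: str = "synthetic",
    source_label: str = "nonmalignant",
) -> FragmentPool:
    """Draw ``n`` fragment lengths iid from ``profile`` (as a histogram)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, profile.pmf())
    return FragmentPool(sample_id=sample_id, counts=counts, source_label=source_label)


@dataclasses.dataclass
class PatientSample:
    """A mixed patient pool with hidden per-origin histograms."""

    pool: FragmentPool
    tumour_counts: np.ndarray
    nontumour_counts: np.ndarray

    @property
    def true_tumour_fraction(self) -> float:
        total = self.tumour_counts.sum() + self.nontumour_counts.sum()
        return float(self.tumour_counts.sum() / total) if total else 0.0


def sample_patient(
    tumour_fraction: float,
    n_fragments: int,
    seed: int | np.random.Generator | None = None,
    sample_id: str = "patient",
    source_label: str = "patient_postop",
    tumour_profile: FragmentLengthProfile = TUMOUR_PROFILE,
    nontumour_profile: FragmentLengthProfile = NONTUMOUR_PROFILE,
) -> PatientSample:
    """Mix tumour and non-tumour fragments at the given tumour fraction.

    Each fragment is tumour-origin with probability ``tumour_fraction``;
    origin histograms are retained as hidden truth.
    """
    if not 0.0 <= tumour_fraction <= 1.0:
        raise ValueError("tumour_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_t = int(rng.binomial(n_fragments, tumour_fraction))
    size = max(tumour_profile.length_cap, nontumour_profile.length_cap) + 1
    t_counts = np.zeros(size, dtype=np.int64)
    nt_counts = np.zeros(size, dtype=np.int64)
    if n_t:
        t_counts[: tumour_profile.length_cap + 1] = rng.multinomial(n_t, tumour_profile.pmf())
    if n_fragments - n_t:
        nt_counts[: nontumour_profile.length_cap + 1] = rng.multinomial(
            n_fragments - n_t, nontumour_profile.pmf()
        )
    pool = FragmentPool(sample_id=sample_id, counts=t_counts + nt_counts,
                        source_label=source_label)
    return PatientSample(pool=pool, tumour_counts=t_counts, nontumour_counts=nt_counts)


@dataclasses.dataclass
class SyntheticCohortConfig:
    """Study conditions for a synthetic MRD cohort.

    Defaults mirror the structure of a 36-patient surgical cohort with 14
    recurrences and 15 non-malignant controls; recurrent patients retain a
    postoperative tumour fraction of a few percent while non-recurrent
    patients carry none (plus optional contamination).
    """

    n_patients: int = 36
    n_recurrent: int = 14
    n_controls: int = 15
    recurrent_postop_tf: tuple[float, float] = (0.05, 0.15)
    nonrecurrent_postop_tf: float = 0.0
    preop_tf: tuple[float, float] = (0.02, 0.10)
    n_fragments_patient: int = 2_000_000
    n_fragments_control: int = 2_000_000
    n_trackable_mean: float = 8.0
    n_chip_mean: float = 5.0
    n_germline_mean: float = 3.0
    depth_mean: float = 5000.0
    postop_noise_af: float = 1e-4
    pipeline_call_min_reads: int = 25
    max_support_per_variant: int = 200
    tumour_profile: FragmentLengthProfile = TUMOUR_PROFILE
    nontumour_profile: FragmentLengthProfile = NONTUMOUR_PROFILE
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_recurrent <= self.n_patients:
            raise ValueError("n_recurrent must lie in [0, n_patients]")
        for lo, hi in (self.recurrent_postop_tf, self.preop_tf):
            if not (0 <= lo <= hi <= 1):
                raise ValueError("tumour-fraction ranges must satisfy 0 <= lo <= hi <= 1")
        if not 0 <= self.nonrecurrent_postop_tf <= 1:
            raise ValueError("nonrecurrent_postop_tf must lie in [0, 1]")


@dataclasses.dataclass
class SyntheticCohort:
    """Generated cohort plus the hidden truth used by test oracles."""

    patients: list[PatientRecord]
    controls: list[FragmentPool]
    metadata: pd.DataFrame
    truth: pd.DataFrame  # per patient: postop_tf, preop_tf
    variant_truth: pd.DataFrame  # per (patient, variant): origin label
    config: SyntheticCohortConfig


def _sample_variant_positions(rng: np.random.Generator, n: int, used: set) -> list[tuple]:
    keys = []
    while len(keys) < n:
        key = (f"chr{rng.integers(1, 23)}", int(rng.integers(1, 2_000_000)),
               "ACGT"[rng.integers(4)], "ACGT"[rng.integers(4)])
        if key[2] != key[3] and key not in used:
            used.add(key)
            keys.append(key)
    return keys


def sample_cohort(config: SyntheticCohortConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort (patients, controls, variants, truth)."""
    cfg = config or SyntheticCohortConfig()
    rng = np.random.default_rng(cfg.seed)
    t_pmf = cfg.tumour_profile.pmf()
    nt_pmf = cfg.nontumour_profile.pmf()
    size = max(t_pmf.size, nt_pmf.size)

    controls = [
        sample_fragment_pool(
            cfg.nontumour_profile, cfg.n_fragments_control, seed=rng,
            sample_id=f"C{i + 1:02d}", source_label="nonmalignant",
        )
        for i in range(cfg.n_controls)
    ]

    recurrence = np.zeros(cfg.n_patients, dtype=bool)
    recurrence[rng.permutation(cfg.n_patients)[: cfg.n_recurrent]] = True

    patients: list[PatientRecord] = []
    truth_rows, vtruth_rows = [], []
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:02d}"
        rec = bool(recurrence[i])
        preop_tf = float(rng.uniform(*cfg.preop_tf))
        postop_tf = (
            float(rng.uniform(*cfg.recurrent_postop_tf)) if rec else cfg.nonrecurrent_postop_tf
        )
        preop = sample_patient(
            preop_tf, cfg.n_fragments_patient, seed=rng, sample_id=f"{pid}.preop",
            source_label="patient_preop",
            tumour_profile=cfg.tumour_profile, nontumour_profile=cfg.nontumour_profile,
        ).pool
        postop = sample_patient(
            postop_tf, cfg.n_fragments_patient, seed=rng, sample_id=f"{pid}.postop",
            source_label="patient_postop",
            tumour_profile=cfg.tumour_profile, nontumour_profile=cfg.nontumour_profile,
        ).pool

        n_track = max(3, int(rng.poisson(cfg.n_trackable_mean)))
        n_chip = int(rng.poisson(cfg.n_chip_mean))
        n_germ = int(rng.poisson(cfg.n_germline_mean))
        used: set = set()
        track_keys = _sample_variant_positions(rng, n_track, used)
        chip_keys = _sample_variant_positions(rng, n_chip, used)
        germ_keys = _sample_variant_positions(rng, n_germ, used)

        observations: list[VariantObservation] = []
        support: list[SupportingFragments] = []
        tumour_ref_counts = np.zeros(size, dtype=np.int64)

        def _obs(key, comp, af, called_if=None):
            depth = max(1, int(rng.poisson(cfg.depth_mean)))
            alt = int(rng.binomial(depth, min(af, 1.0)))
            called = alt >= (called_if if called_if is not None else cfg.pipeline_call_min_reads)
            observations.append(
                VariantObservation(
                    patient_id=pid, compartment=comp, chrom=key[0], pos=key[1],
                    ref=key[2], alt=key[3], alt_reads=alt, depth=depth,
                    pipeline_called=called,
                )
            )
            return alt

        def _support(key, comp, n_frags, pmf):
            kept = min(n_frags, cfg.max_support_per_variant)
            if kept == 0:
                return None
            hist = rng.multinomial(kept, pmf)
            lengths = np.repeat(np.arange(hist.size), hist).tolist()
            rec_ = SupportingFragments(
                patient_id=pid, compartment=comp, chrom=key[0], pos=key[1],
                ref=key[2], alt=key[3], lengths=lengths,
            )
            support.append(rec_)
            return hist

        for key in germ_keys:
            for comp in ("bcp", "tissue", "preop_plasma", "postop_plasma"):
                _obs(key, comp, 0.5)
            vtruth_rows.append((pid, *key, "germline"))
        for key in chip_keys:
            chip_af = float(rng.uniform(0.005, 0.05))
            _obs(key, "bcp", chip_af, called_if=1)
            for comp in ("preop_plasma", "postop_plasma"):
                alt = _obs(key, comp, chip_af, called_if=1)
                _support(key, comp, alt, nt_pmf)
            vtruth_rows.append((pid, *key, "blood"))
        for key in track_keys:
            _obs(key, "tissue", float(rng.uniform(0.2, 0.5)), called_if=1)
            pre_alt = _obs(key, "preop_plasma", preop_tf / 2, called_if=1)
            pre_hist = _support(key, "preop_plasma", pre_alt, t_pmf)
            if pre_hist is not None:
                tumour_ref_counts[: pre_hist.size] += pre_hist
            post_af = postop_tf / 2 if postop_tf > 0 else cfg.postop_noise_af
            post_alt = _obs(key, "postop_plasma", post_af)
            if postop_tf > 0:
                _support(key, "postop_plasma", post_alt, t_pmf)
            elif post_alt:
                _support(key, "postop_plasma", post_alt, nt_pmf)
            vtruth_rows.append((pid, *key, "tumour"))

        followup = float(rng.uniform(6, 24)) if rec else float(rng.uniform(20, 36))
        adjuvant = str(rng.choice(["none", "partial", "completed"], p=[0.6, 0.2, 0.2]))
        patients.append(
            PatientRecord(
                patient_id=pid, recurrence=rec, followup_months=followup,
                adjuvant_status=adjuvant, preop=preop, postop=postop,
                tumour_fragments=FragmentPool(
                    sample_id=f"{pid}.tumour", counts=tumour_ref_counts,
                    source_label="tumour_reference",
                ),
                observations=observations, support=support,
            )
        )
        truth_rows.append((pid, rec, preop_tf, postop_tf))

    metadata = pd.DataFrame(
        [
            (p.patient_id, p.recurrence, p.followup_months, p.adjuvant_status, "patient")
            for p in patients
        ]
        + [(c.sample_id, False, 0.0, "none", "control") for c in controls],
        columns=["patient_id", "recurrence", "followup_months", "adjuvant_status", "group"],
    )
    truth = pd.DataFrame(truth_rows, columns=["patient_id", "recurrence", "preop_tf", "postop_tf"])
    variant_truth = pd.DataFrame(
        vtruth_rows, columns=["patient_id", "chrom", "pos", "ref", "alt", "origin"]
    )
    return SyntheticCohort(
        patients=patients, controls=controls, metadata=metadata,
        truth=truth, variant_truth=variant_truth, config=cfg,
    )


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> None:
    """Write a cohort to the TSV layout understood by :func:`fragmrd.fragio.read_cohort`.

    Truth tables go to ``truth_patients.tsv`` / ``truth_variants.tsv`` so the
    blinded inputs and the oracle stay separable.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pools: list[FragmentPool] = []
    for p in cohort.patients:
        for pool in (p.preop, p.postop, p.tumour_fragments):
            if pool is not None:
                pools.append(pool)
    pools.extend(cohort.controls)
    write_fragment_table(pools, directory / "fragments.tsv")
    write_variant_table(
        [o for p in cohort.patients for o in p.observations], directory / "variants.tsv"
    )
    write_supporting_fragments(
        [s for p in cohort.patients for s in p.support], directory / "support.tsv"
    )
    write_cohort_metadata(cohort.metadata, directory / "metadata.tsv")
    cohort.truth.to_csv(directory / "truth_patients.tsv", sep="\t", index=False)
    cohort.variant_truth.to_csv(directory / "truth_variants.tsv", sep="\t", index=False)


def pooled_controls(controls: Sequence[FragmentPool]) -> FragmentPool:
    """All control fragments merged into one non-malignant reference pool."""
    return merge_pools(controls, sample_id="controls.pooled", source_label="nonmalignant")


def write_fragment_alignment(pool: FragmentPool, path: str | Path, read_length: int = 50) -> None:
    """Write a SAM file whose proper pairs reproduce ``pool``.

    Each fragment becomes one read pair with template length +/- L on a
    single synthetic contig; useful as a round-trip fixture for
    :func:`fragmrd.fragio.read_fragment_lengths_from_alignment`.
    """
    import pysam

    path = Path(path)
    max_len = int(pool.length_cap)
    n = pool.total
    ref_len = 1000 + 2 * n + max_len + read_length
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": "synthetic_contig", "LN": ref_len}],
    }
    lengths = pool.lengths()
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        pos = 100
        for i, L in enumerate(lengths):
            L = int(L)
            rlen = min(read_length, L)
            for first in (True, False):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"frag{i}"
                a.reference_id = 0
                a.mapping_quality = 60
                a.cigarstring = f"{rlen}M"
                a.query_sequence = "A" * rlen
                a.query_qualities = pysam.qualitystring_to_array("I" * rlen)
                if first:
                    a.flag = 99  # paired, proper, mate reverse, first in pair
                    a.reference_start = pos
                    a.next_reference_start = pos + L - rlen
                    a.template_length = L
                else:
                    a.flag = 147  # paired, proper, reverse, second in pair
                    a.reference_start = pos + L - rlen
                    a.next_reference_start = pos
                    a.template_length = -L
                out.write(a)
            pos += 2
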