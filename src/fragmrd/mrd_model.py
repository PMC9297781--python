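"""Combined fragmentation-score + variant-tracking MRD classifier.

The classifier couples the two independent ctDNA read-outs: the patient-level
fragmentation score (FS) with its control-derived threshold, and the
tumour-informed variant count with its grid-searched cutoffs. Training picks
the combination logic — both read-outs positive (AND) or either positive
(OR) — that best fits recurrence in the training data. Performance is
assessed with 20-times-repeated 10-fold cross-validation in which the score
table, control threshold and variant cutoffs are all refitted per fold from
the training 90% only; the final per-patient call is the majority over the
20 repeats (positive when called positive at least 11 of 20 times).
"""

from __future__ import annotations

import dataclasses
import zlib
from typing import Sequence

import numpy as np

from .fragio import FragmentPool, PatientRecord
from .reference import FragmentScoreTable, build_score_table
from .scoring import fs_call, fs_threshold, patient_fs
from .synthetic import pooled_controls
from .variants import (
    VariantCallParams,
    count_detected_variants,
    optimize_cutoffs,
    trackable_postop_support,
    variant_mrd_call,
)

AND = "AND"
OR = "OR"


def _combine(fs_pos: bool, var_pos: bool, logic: str) -> bool:
    if logic == AND:
        return fs_pos and var_pos
    if logic == OR:
        return fs_pos or var_pos
    raise ValueError(f"unknown combination logic {logic!r}")


def _patient_seed(model_seed: int, patient_id: str) -> int:
    """Stable per-(model, patient) seed so predictions are deterministic."""
    return zlib.crc32(f"{model_seed}:{patient_id}".encode()) & 0x7FFFFFFF


@dataclasses.dataclass
class FittedModel:
    """Everything fitted on one training set."""

    table: FragmentScoreTable
    fs_thr: float
    control_fs: np.ndarray
    params: VariantCallParams
    logic: str
    seed: int
    train_ids: list[str]
    table_train_ids: list[str]  # patients whose tumour-tagged fragments built the table
    train_accuracy: dict[str, float] = dataclasses.field(default_factory=dict)
    fs_n_sample: int = 1_000_000

    def summary(self) -> dict:
        return {
            "table_id": self.table.table_id,
            "fs_threshold": self.fs_thr,
            "read_cutoff": self.params.read_cutoff,
            "min_variants": self.params.min_variants,
            "logic": self.logic,
            "train_ids": self.train_ids,
            "table_train_ids": self.table_train_ids,
            "train_accuracy": self.train_accuracy,
        }


def _support_cache(patients: Sequence[PatientRecord]) -> dict[str, tuple]:
    return {p.patient_id: trackable_postop_support(p) for p in patients}


def fit_combined_model(
    training_patients: Sequence[PatientRecord],
    controls: Sequence[FragmentPool],
    seed: int = 0,
    n_boot: int = 100,
    n_sample: int = 10_000,
    cap: float = 5.0,
    min_count: int = 20,
    fs_n_sample: int = 1_000_000,
    support_cache: dict[str, tuple] | None = None,
    fs_overrides: dict[str, FragmentPool] | None = None,
) -> FittedModel:
    """Fit score table, FS threshold, variant cutoffs and logic on training data.

    The tumour side of the score table pools only the training patients'
    mutation-carrying fragments; control FS values and their mean + 2 SD
    threshold are then recomputed under that table, variant cutoffs are
    grid-searched, and the AND/OR logic with the higher training accuracy is
    selected (tie -> AND, the specificity-first choice).

    ``fs_overrides`` maps patient ids to replacement postoperative pools and
    exists for the permuted-FS negative control.
    """
    if not training_patients:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)

    tumour_pools = [
        p.tumour_fragments for p in training_patients
        if p.tumour_fragments is not None and p.tumour_fragments.total > 0
    ]
    if not tumour_pools:
        raise ValueError("no tumour-tagged fragments in the training set")
    table_train_ids = [
        p.patient_id for p in training_patients
        if p.tumour_fragments is not None and p.tumour_fragments.total > 0
    ]
    size = max(p.counts.size for p in tumour_pools)
    tumour_counts = np.zeros(size, dtype=np.int64)
    for p in tumour_pools:
        tumour_counts[: p.counts.size] += p.counts
    tumour_pool = FragmentPool("train.tumour_reference", tumour_counts, "tumour_reference")
    nontumour_pool = pooled_controls(controls)

    table = build_score_table(
        tumour_pool, nontumour_pool, n_boot=n_boot, n_sample=n_sample,
        cap=cap, min_count=min_count, seed=rng,
    )
    control_fs = np.array(
        [patient_fs(c, table, n_sample=fs_n_sample, seed=rng).fs for c in controls]
    )
    fs_thr = fs_threshold(control_fs)

    y = np.array([p.recurrence for p in training_patients], dtype=bool)
    cache = support_cache or _support_cache(training_patients)
    support = [cache[p.patient_id] for p in training_patients]
    params = optimize_cutoffs(support, y)

    def _postop(p: PatientRecord) -> FragmentPool:
        pool = (fs_overrides or {}).get(p.patient_id, p.postop)
        if pool is None:
            raise ValueError(f"patient {p.patient_id} has no postoperative fragment pool")
        return pool

    fs_calls = np.array(
        [
            fs_call(
                patient_fs(
                    _postop(p), table, n_sample=fs_n_sample,
                    seed=_patient_seed(seed, p.patient_id),
                ).fs,
                fs_thr,
            )
            for p in training_patients
        ]
    )
    var_calls = np.array(
        [
            variant_mrd_call(
                count_detected_variants(reads, params.read_cutoff, called),
                params.min_variants,
            )
            for reads, called in support
        ]
    )
    acc = {
        "fs": float((fs_calls == y).mean()),
        "variant": float((var_calls == y).mean()),
        AND: float(((fs_calls & var_calls) == y).mean()),
        OR: float(((fs_calls | var_calls) == y).mean()),
    }
    logic = AND if acc[AND] >= acc[OR] else OR
    acc["combined"] = acc[logic]

    return FittedModel(
        table=table, fs_thr=fs_thr, control_fs=control_fs, params=params,
        logic=logic, seed=seed, train_ids=[p.patient_id for p in training_patients],
        table_train_ids=table_train_ids, train_accuracy=acc, fs_n_sample=fs_n_sample,
    )


def predict(
    model: FittedModel,
    patient: PatientRecord,
    modality: str = "combined",
    support: tuple | None = None,
    fs_pool: FragmentPool | None = None,
) -> bool:
    """Apply a fitted model to one patient.

    ``modality`` selects the combined call (fitted logic), or the FS-only /
    variant-only component. Deterministic given the fitted model and patient.
    """
    pool = fs_pool if fs_pool is not None else patient.postop
    if pool is None:
        raise ValueError(f"patient {patient.patient_id} has no postoperative fragment pool")
    fs = patient_fs(
        pool, model.table, n_sample=model.fs_n_sample,
        seed=_patient_seed(model.seed, patient.patient_id),
    ).fs
    fs_pos = fs_call(fs, model.fs_thr)
    reads, called = support if support is not None else trackable_postop_support(patient)
    var_pos = variant_mrd_call(
        count_detected_variants(reads, model.params.read_cutoff, called),
        model.params.min_variants,
    )
    if modality == "fs":
        return fs_pos
    if modality == "variant":
        return var_pos
    if modality == "combined":
        return _combine(fs_pos, var_pos, model.logic)
    raise ValueError(f"unknown modality {modality!r}")


MODALITIES = ("combined", "fs", "variant")


@dataclasses.dataclass
class FoldFit:
    repeat: int
    fold: int
    train_ids: list[str]
    test_ids: list[str]
    table_train_ids: list[str]
    fs_threshold: float
    params: VariantCallParams
    logic: str
    train_accuracy: dict[str, float]


@dataclasses.dataclass
class CVResult:
    """Per-patient positive-call counts over the repeated cross-validation."""

    patient_ids: list[str]
    positive_counts: dict[str, np.ndarray]  # modality -> counts out of n_repeats
    n_repeats: int
    n_folds: int
    folds: list[FoldFit]

    def positive_prob(self, modality: str = "combined") -> np.ndarray:
        return self.positive_counts[modality] / self.n_repeats


def majority_call(cv: CVResult, modality: str = "combined") -> np.ndarray:
    """Final per-patient call: positive when positive in a strict majority of
    repeats (>= 11 of 20)."""
    need = cv.n_repeats // 2 + 1
    return cv.positive_counts[modality] >= need


def run_ttfcv(
    cohort: Sequence[PatientRecord],
    controls: Sequence[FragmentPool],
    n_repeats: int = 20,
    n_folds: int = 10,
    seed: int = 0,
    n_boot: int = 100,
    fs_n_sample: int = 1_000_000,
    fs_overrides: dict[str, FragmentPool] | None = None,
) -> CVResult:
    """Twenty-times-repeated 10-fold cross-validation with per-fold refits.

    Each repeat re-partitions the cohort at random into ``n_folds`` folds as
    evenly as possible (3 or 4 patients per fold for a 36-patient cohort);
    each fold is held out once while the score table, thresholds, cutoffs and
    logic are refitted on the rest. The repeat RNG is seeded ``seed + repeat``
    so runs are reproducible. Positive calls are accumulated per patient for
    the combined model and both single-modality components.
    """
    N = len(cohort)
    if n_folds > N:
        raise ValueError(f"n_folds ({n_folds}) exceeds cohort size ({N})")
    patient_ids = [p.patient_id for p in cohort]
    cache = _support_cache(cohort)
    counts = {m: np.zeros(N, dtype=np.int64) for m in MODALITIES}
    folds_out: list[FoldFit] = []

    for rep in range(n_repeats):
        rng = np.random.default_rng(seed + rep)
        perm = rng.permutation(N)
        folds = np.array_split(perm, n_folds)
        for fold_idx, test_idx in enumerate(folds):
            test_set = set(int(i) for i in test_idx)
            train = [cohort[i] for i in range(N) if i not in test_set]
            fold_seed = int(rng.integers(0, 2**31 - 1))
            model = fit_combined_model(
                train, controls, seed=fold_seed, n_boot=n_boot,
                fs_n_sample=fs_n_sample, support_cache=cache,
                fs_overrides=fs_overrides,
            )
            for i in test_idx:
                p = cohort[int(i)]
                fs_pool = (fs_overrides or {}).get(p.patient_id, p.postop)
                for m in MODALITIES:
                    if predict(model, p, modality=m, support=cache[p.patient_id],
                               fs_pool=fs_pool):
                        counts[m][int(i)] += 1
            folds_out.append(
                FoldFit(
                    repeat=rep, fold=fold_idx,
                    train_ids=model.train_ids,
                    test_ids=[patient_ids[int(i)] for i in test_idx],
                    table_train_ids=model.table_train_ids,
                    fs_threshold=model.fs_thr, params=model.params,
                    logic=model.logic, train_accuracy=model.train_accuracy,
                )
            )
    return CVResult(
        patient_ids=patient_ids, positive_counts=counts,
        n_repeats=n_repeats, n_folds=n_folds, folds=folds_out,
    )


def shuffle_fs_control(
    cohort: Sequence[PatientRecord], seed: int = 0
) -> dict[str, FragmentPool]:
    """Permute the postoperative pools (hence the FS) among patients.

    Returns an ``fs_overrides`` mapping for :func:`run_ttfcv`: each patient's
    FS is computed from a randomly chosen other patient's plasma while the
    variant data stay untouched — the negative control showing the FS signal
    is patient-specific.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 patients to shuffle FS assignments")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(cohort))
    overrides: dict[str, FragmentPool] = {}
    for i, p in enumerate(cohort):
        donor = cohort[int(perm[i])]
        if donor.postop is None:
            raise ValueError(f"patient {donor.patient_id} has no postoperative pool")
        overrides[p.patient_id] = donor.postop
    return overrides


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class EvaluationReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    npv: float | None
    ppv: float | None
    accuracy_ci: tuple[float, float]
    sensitivity_ci: tuple[float, float] | None
    specificity_ci: tuple[float, float] | None
    npv_ci: tuple[float, float] | None
    logrank_chi2: float | None
    logrank_p: float | None
    km_curves: dict | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("km_curves")
        return d


def _exact_ci(k: int, n: int) -> tuple[float, float] | None:
    from scipy.stats import binomtest

    if n == 0:
        return None
    ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    return (float(ci.low), float(ci.high))


def evaluate(
    calls: Sequence[bool],
    recurrence: Sequence[bool],
    followup_months: Sequence[float],
    km_curves: bool = False,
) -> EvaluationReport:
    """Confusion-matrix metrics with exact binomial CIs plus a two-group
    log-rank test (recurrence as event, follow-up as time) and optional
    Kaplan-Meier curves per predicted group."""
    calls = np.asarray(list(calls), dtype=bool)
    y = np.asarray(list(recurrence), dtype=bool)
    t = np.asarray(list(followup_months), dtype=float)
    if not (calls.size == y.size == t.size):
        raise ValueError("calls, recurrence and followup_months must align")

    tp = int((calls & y).sum())
    fp = int((calls & ~y).sum())
    tn = int((~calls & ~y).sum())
    fn = int((~calls & y).sum())
    n = calls.size

    def _rate(num: int, den: int) -> float | None:
        return num / den if den else None

    sens, spec = _rate(tp, tp + fn), _rate(tn, tn + fp)
    npv, ppv = _rate(tn, tn + fn), _rate(tp, tp + fp)

    logrank_chi2 = logrank_p = None
    km = None
    if calls.any() and (~calls).any():
        from lifelines.statistics import logrank_test

        res = logrank_test(t[calls], t[~calls], event_observed_A=y[calls],
                           event_observed_B=y[~calls])
        logrank_chi2 = float(res.test_statistic)
        logrank_p = float(res.p_value)
        if km_curves:
            from lifelines import KaplanMeierFitter

            km = {}
            for name, mask in (("mrd_positive", calls), ("mrd_negative", ~calls)):
                kmf = KaplanMeierFitter()
                kmf.fit(t[mask], event_observed=y[mask], label=name)
                km[name] = kmf.survival_function_

    return EvaluationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / n,
        sensitivity=sens, specificity=spec, npv=npv, ppv=ppv,
        accuracy_ci=_exact_ci(tp + tn, n),
        sensitivity_ci=_exact_ci(tp, tp + fn),
        specificity_ci=_exact_ci(tn, tn + fp),
        npv_ci=_exact_ci(tn, tn + fn),
        logrank_chi2=logrank_chi2, logrank_p=logrank_p, km_curves=km,
    )


def rank_sum_test(a: Sequence[float], b: Sequence[float]):
    """Wilcoxon rank-sum comparison of two groups (e.g. FS distributions)."""
    from scipy.stats import ranksums

    return ranksums(np.asarray(list(a), float), np.asarray(list(b), float))


def paired_t_test(a: Sequence[float], b: Sequence[float]):
    """Paired t-test (e.g. preoperative vs postoperative FS of the same patients)."""
    from scipy.stats import ttest_rel

    return ttest_rel(np.asarray(list(a), float), np.asarray(list(b), float))
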