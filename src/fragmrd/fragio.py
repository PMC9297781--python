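"""I/O and core containers for cfDNA fragment and variant data.

Fragment pools are stored as length histograms (``counts[L]`` = number of
fragments of length ``L`` bp), which is lossless for a multiset of integer
lengths and turns every downstream "randomly sample n fragments" step into a
cheap multinomial draw over at most a few hundred length bins.

On-disk formats are plain tab-separated text (UTF-8, ``#`` comments allowed):

* fragment table      ``sample_id  length  count``
* variant table       ``patient_id  compartment  chrom  pos  ref  alt  alt_reads  depth  pipeline_called``
* supporting-fragment ``patient_id  compartment  chrom  pos  ref  alt  fragment_length``
* cohort metadata     ``patient_id  recurrence  followup_months  adjuvant_status  group``
* score table         ``length  score`` (+ a ``.meta.json`` sidecar of build metadata)

Fragment lengths can also be harvested directly from paired-end alignment
files (SAM/BAM) via pysam.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCE_LABELS = ("tumour_reference", "nonmalignant", "patient_preop", "patient_postop")
COMPARTMENTS = ("tissue", "bcp", "preop_plasma", "postop_plasma")
DEFAULT_LENGTH_CAP = 600


class ParseError(ValueError):
    """An on-disk table violates its schema."""


class AlignmentError(IOError):
    """An alignment file cannot be used for fragment-length extraction."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FragmentPool:
    """A sample's multiset of cfDNA fragment lengths, stored as a histogram.

    Parameters
    ----------
    sample_id : str
        Identifier of the sample the fragments came from.
    counts : ndarray of int
        ``counts[L]`` is the number of fragments of length ``L`` bp.
        ``counts[0]`` must be zero (lengths are >= 1).
    source_label : str
        Provenance, one of :data:`SOURCE_LABELS`.
    """

    sample_id: str
    counts: np.ndarray
    source_label: str = "nonmalignant"

    def __post_init__(self) -> None:
        if self.source_label not in SOURCE_LABELS:
            raise ValueError(
                f"source_label {self.source_label!r} not in {SOURCE_LABELS}"
            )
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be a 1-D histogram indexed by length")
        if counts.size == 0:
            counts = np.zeros(1, dtype=np.int64)
        if np.any(counts < 0):
            raise ValueError("histogram counts must be non-negative")
        counts = counts.astype(np.int64)
        if counts[0] != 0:
            raise ValueError("fragment lengths must be >= 1 bp (counts[0] != 0)")
        self.counts = counts

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_lengths(
        cls,
        sample_id: str,
        lengths: Iterable[int],
        source_label: str = "nonmalignant",
        length_cap: int | None = None,
    ) -> "FragmentPool":
        """Build a pool from an explicit list of fragment lengths (bp)."""
        arr = np.asarray(list(lengths), dtype=np.int64)
        if arr.size and arr.min() < 1:
            raise ValueError("all fragment lengths must be >= 1 bp")
        cap = int(length_cap) if length_cap is not None else DEFAULT_LENGTH_CAP
        if arr.size:
            cap = max(cap, int(arr.max()))
        counts = np.bincount(arr, minlength=cap + 1) if arr.size else np.zeros(cap + 1, dtype=np.int64)
        return cls(sample_id=sample_id, counts=counts, source_label=source_label)

    # -- queries ------------------------------------------------------------

    @property
    def total(self) -> int:
        """Total fragment count (O(1) from the histogram)."""
        return int(self.counts.sum())

    @property
    def length_cap(self) -> int:
        return self.counts.size - 1

    def probabilities(self) -> np.ndarray:
        """Empirical length distribution; errors on an empty pool."""
        total = self.total
        if total == 0:
            raise ValueError(f"fragment pool {self.sample_id!r} is empty")
        return self.counts / total

    def lengths(self) -> np.ndarray:
        """Expand the histogram back into a (sorted) array of lengths."""
        return np.repeat(np.arange(self.counts.size), self.counts)

    def padded(self, size: int) -> np.ndarray:
        """Histogram zero-padded (or identical) to at least ``size`` bins."""
        if self.counts.size >= size:
            return self.counts
        out = np.zeros(size, dtype=np.int64)
        out[: self.counts.size] = self.counts
        return out


def merge_pools(
    pools: Sequence[FragmentPool], sample_id: str, source_label: str
) -> FragmentPool:
    """Pool several fragment pools into one histogram."""
    if not pools:
        raise ValueError("no pools to merge")
    size = max(p.counts.size for p in pools)
    counts = np.zeros(size, dtype=np.int64)
    for p in pools:
        counts[: p.counts.size] += p.counts
    return FragmentPool(sample_id=sample_id, counts=counts, source_label=source_label)


@dataclasses.dataclass(frozen=True)
class VariantObservation:
    """One variant observed in one compartment of one patient.

    ``pipeline_called`` distinguishes variants reported by the upstream caller
    from variants that merely have supporting raw reads in the alignment.
    """

    patient_id: str
    compartment: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: int
    depth: int
    pipeline_called: bool

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r}; allowed: {COMPARTMENTS}"
            )
        if self.pos < 1:
            raise ValueError("pos must be 1-based (>= 1)")
        if self.alt_reads < 0:
            raise ValueError("alt_reads must be >= 0")
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads ({self.alt_reads}) exceeds depth ({self.depth}) "
                f"for {self.patient_id} {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """(chrom, pos, ref, alt) — identifies the variant."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclasses.dataclass
class SupportingFragments:
    """Lengths of the alt-allele-carrying fragments for one variant/compartment."""

    patient_id: str
    compartment: str
    chrom: str
    pos: int
    ref: str
    alt: str
    lengths: list[int]

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def n_fragments(self) -> int:
        return len(self.lengths)


@dataclasses.dataclass
class PatientRecord:
    """Everything the MRD model needs for one patient.

    ``tumour_fragments`` holds the lengths of mutation-carrying (hence
    tumour-derived) plasma fragments; pooled over the training patients these
    form the tumour side of the score-table reference.
    """

    patient_id: str
    recurrence: bool
    followup_months: float
    adjuvant_status: str = "none"
    preop: FragmentPool | None = None
    postop: FragmentPool | None = None
    tumour_fragments: FragmentPool | None = None
    observations: list[VariantObservation] = dataclasses.field(default_factory=list)
    support: list[SupportingFragments] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.followup_months < 0:
            raise ValueError("followup_months must be >= 0")


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(columns))
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing} (found {list(df.columns)})")
    return df


def _to_int(df: pd.DataFrame, col: str, path: Path | str) -> np.ndarray:
    """Strict integer conversion with the offending line number on failure."""
    raw = df[col]
    num = pd.to_numeric(raw, errors="coerce")
    bad = num.isna() | (num != num.round())
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: one for the header line, one for 1-based numbering
        raise ParseError(f"{path} line {i + 2}: non-integer {col!r} value {raw.iloc[i]!r}")
    return num.astype(np.int64).to_numpy()


_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _to_bool(df: pd.DataFrame, col: str, path: Path | str) -> np.ndarray:
    vals = df[col].astype(str).str.strip().str.lower()
    bad = ~vals.isin(_BOOL_MAP)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"{path} line {i + 2}: non-boolean {col!r} value {df[col].iloc[i]!r}")
    return vals.map(_BOOL_MAP).to_numpy(dtype=bool)


# ---------------------------------------------------------------------------
# fragment tables
# ---------------------------------------------------------------------------

_FRAGMENT_COLS = ("sample_id", "length", "count")


def read_fragment_tables(
    path: str | Path, source_labels: dict[str, str] | None = None
) -> dict[str, FragmentPool]:
    """Read a fragment table possibly holding several samples.

    Returns a dict ``sample_id -> FragmentPool`` in order of first appearance.
    Counts on repeated ``(sample_id, length)`` rows are summed.
    """
    path = Path(path)
    df = _read_tsv(path, _FRAGMENT_COLS)
    if df.empty:
        logger.warning("%s: fragment table has no data rows", path)
        return {}
    lengths = _to_int(df, "length", path)
    counts = _to_int(df, "count", path)
    if (lengths < 1).any():
        i = int(np.flatnonzero(lengths < 1)[0])
        raise ParseError(f"{path} line {i + 2}: fragment length must be >= 1")
    if (counts < 0).any():
        i = int(np.flatnonzero(counts < 0)[0])
        raise ParseError(f"{path} line {i + 2}: negative count")
    pools: dict[str, FragmentPool] = {}
    for sid in df["sample_id"].drop_duplicates():
        mask = (df["sample_id"] == sid).to_numpy()
        size = max(DEFAULT_LENGTH_CAP, int(lengths[mask].max())) + 1
        hist = np.zeros(size, dtype=np.int64)
        np.add.at(hist, lengths[mask], counts[mask])
        label = (source_labels or {}).get(sid, "nonmalignant")
        pools[str(sid)] = FragmentPool(sample_id=str(sid), counts=hist, source_label=label)
    return pools


def read_fragment_table(path: str | Path, source_label: str = "nonmalignant") -> FragmentPool:
    """Read a single-sample fragment table into a :class:`FragmentPool`."""
    path = Path(path)
    pools = read_fragment_tables(path)
    if not pools:
        logger.warning("%s: empty fragment table, returning empty pool", path)
        return FragmentPool(sample_id=path.stem, counts=np.zeros(DEFAULT_LENGTH_CAP + 1),
                            source_label=source_label)
    if len(pools) > 1:
        raise ParseError(
            f"{path}: expected one sample, found {sorted(pools)}; use read_fragment_tables"
        )
    (pool,) = pools.values()
    pool.source_label = source_label
    return pool


def write_fragment_table(pools: FragmentPool | Sequence[FragmentPool], path: str | Path) -> None:
    """Write one or more pools to a fragment-table TSV (zero-count bins skipped)."""
    if isinstance(pools, FragmentPool):
        pools = [pools]
    rows = []
    for pool in pools:
        nz = np.flatnonzero(pool.counts)
        for length in nz:
            rows.append((pool.sample_id, int(length), int(pool.counts[length])))
    df = pd.DataFrame(rows, columns=list(_FRAGMENT_COLS))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

_VARIANT_COLS = (
    "patient_id", "compartment", "chrom", "pos", "ref", "alt",
    "alt_reads", "depth", "pipeline_called",
)


def read_variant_table(path: str | Path) -> list[VariantObservation]:
    """Read a variant observation table; validates compartments and counts."""
    path = Path(path)
    df = _read_tsv(path, _VARIANT_COLS)
    if df.empty:
        return []
    pos = _to_int(df, "pos", path)
    alt_reads = _to_int(df, "alt_reads", path)
    depth = _to_int(df, "depth", path)
    called = _to_bool(df, "pipeline_called", path)
    out: list[VariantObservation] = []
    for i in range(len(df)):
        comp = df["compartment"].iloc[i]
        if comp not in COMPARTMENTS:
            raise ParseError(
                f"{path} line {i + 2}: unknown compartment {comp!r}; allowed: {COMPARTMENTS}"
            )
        try:
            out.append(
                VariantObservation(
                    patient_id=str(df["patient_id"].iloc[i]),
                    compartment=comp,
                    chrom=str(df["chrom"].iloc[i]),
                    pos=int(pos[i]),
                    ref=str(df["ref"].iloc[i]),
                    alt=str(df["alt"].iloc[i]),
                    alt_reads=int(alt_reads[i]),
                    depth=int(depth[i]),
                    pipeline_called=bool(called[i]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path} line {i + 2}: {exc}") from exc
    return out


def write_variant_table(observations: Sequence[VariantObservation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (o.patient_id, o.compartment, o.chrom, o.pos, o.ref, o.alt,
             o.alt_reads, o.depth, o.pipeline_called)
            for o in observations
        ],
        columns=list(_VARIANT_COLS),
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# supporting-fragment tables
# ---------------------------------------------------------------------------

_SUPPORT_COLS = ("patient_id", "compartment", "chrom", "pos", "ref", "alt", "fragment_length")


def read_supporting_fragments(path: str | Path) -> list[SupportingFragments]:
    """Read per-variant supporting fragment lengths, grouped per
    (patient, compartment, variant) in order of first appearance."""
    path = Path(path)
    df = _read_tsv(path, _SUPPORT_COLS)
    if df.empty:
        return []
    pos = _to_int(df, "pos", path)
    flen = _to_int(df, "fragment_length", path)
    if (flen < 1).any():
        i = int(np.flatnonzero(flen < 1)[0])
        raise ParseError(f"{path} line {i + 2}: fragment_length must be >= 1")
    groups: dict[tuple, SupportingFragments] = {}
    for i in range(len(df)):
        comp = df["compartment"].iloc[i]
        if comp not in COMPARTMENTS:
            raise ParseError(
                f"{path} line {i + 2}: unknown compartment {comp!r}; allowed: {COMPARTMENTS}"
            )
        gkey = (
            str(df["patient_id"].iloc[i]), comp, str(df["chrom"].iloc[i]),
            int(pos[i]), str(df["ref"].iloc[i]), str(df["alt"].iloc[i]),
        )
        if gkey not in groups:
            groups[gkey] = SupportingFragments(*gkey, lengths=[])
        groups[gkey].lengths.append(int(flen[i]))
    return list(groups.values())


def write_supporting_fragments(records: Sequence[SupportingFragments], path: str | Path) -> None:
    rows = []
    for r in records:
        for length in r.lengths:
            rows.append((r.patient_id, r.compartment, r.chrom, r.pos, r.ref, r.alt, length))
    pd.DataFrame(rows, columns=list(_SUPPORT_COLS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort metadata
# ---------------------------------------------------------------------------

_META_COLS = ("patient_id", "recurrence", "followup_months", "adjuvant_status", "group")


def read_cohort_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _read_tsv(path, _META_COLS)
    if df.empty:
        return pd.DataFrame(columns=list(_META_COLS))
    df = df.copy()
    df["recurrence"] = _to_bool(df, "recurrence", path)
    fm = pd.to_numeric(df["followup_months"], errors="coerce")
    if fm.isna().any() or (fm < 0).any():
        i = int(np.flatnonzero((fm.isna() | (fm < 0)).to_numpy())[0])
        raise ParseError(f"{path} line {i + 2}: invalid followup_months")
    df["followup_months"] = fm.astype(float)
    return df


def write_cohort_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(_META_COLS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------


def write_score_table(table, path: str | Path) -> None:
    """Write a score table TSV plus a ``.meta.json`` sidecar of build metadata."""
    path = Path(path)
    scores = np.asarray(table.scores, dtype=float)
    df = pd.DataFrame({"length": np.arange(scores.size), "score": scores})
    df = df[df["length"] >= 1]
    df.to_csv(path, sep="\t", index=False)
    sidecar = path.with_name(path.name + ".meta.json")
    sidecar.write_text(json.dumps(table.meta, indent=2, default=str))


def read_score_table(path: str | Path):
    """Read a score table TSV (and its metadata sidecar, if present)."""
    from .reference import FragmentScoreTable  # local import to avoid a cycle

    path = Path(path)
    df = _read_tsv(path, ("length", "score"))
    lengths = _to_int(df, "length", path)
    vals = pd.to_numeric(df["score"], errors="coerce")
    if vals.isna().any():
        i = int(np.flatnonzero(vals.isna().to_numpy())[0])
        raise ParseError(f"{path} line {i + 2}: non-numeric score")
    size = max(DEFAULT_LENGTH_CAP, int(lengths.max()) if lengths.size else 0) + 1
    scores = np.zeros(size, dtype=float)
    scores[lengths] = vals.to_numpy(dtype=float)
    sidecar = path.with_name(path.name + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return FragmentScoreTable(scores=scores, meta=meta)


# ---------------------------------------------------------------------------
# alignment extraction
# ---------------------------------------------------------------------------


def read_fragment_lengths_from_alignment(
    path: str | Path,
    sample_id: str | None = None,
    source_label: str = "nonmalignant",
    min_mapq: int = 20,
    length_cap: int = DEFAULT_LENGTH_CAP,
) -> FragmentPool:
    """Harvest fragment lengths from a deduplicated paired-end alignment file.

    One length per unique fragment: the absolute template length of the
    first-in-pair, properly-paired read. Duplicate-flagged, secondary,
    supplementary and unmapped records are ignored, as are template lengths
    of 0 or above ``length_cap``. Single-end data is a fatal error.
    """
    import pysam

    path = Path(path)
    if not path.exists():
        raise AlignmentError(f"alignment file not found: {path}")
    try:
        af = pysam.AlignmentFile(str(path), check_sq=False)
    except (OSError, ValueError) as exc:
        raise AlignmentError(f"cannot open alignment file {path}: {exc}") from exc
    counts = np.zeros(length_cap + 1, dtype=np.int64)
    saw_any = False
    with af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            saw_any = True
            if not read.is_paired:
                raise AlignmentError(
                    f"{path}: single-end read {read.query_name!r}; fragment-length "
                    "extraction needs paired-end data"
                )
            if (
                read.is_duplicate
                or read.is_secondary
                or read.is_supplementary
                or not read.is_proper_pair
                or not read.is_read1
                or read.mapping_quality < min_mapq
            ):
                continue
            tlen = abs(read.template_length)
            if tlen < 1 or tlen > length_cap:
                continue
            counts[tlen] += 1
    if not saw_any:
        logger.warning("%s: no mapped reads found", path)
    return FragmentPool(
        sample_id=sample_id or path.stem, counts=counts, source_label=source_label
    )


# ---------------------------------------------------------------------------
# cohort directory
# ---------------------------------------------------------------------------


def read_cohort(directory: str | Path):
    """Load a cohort directory written by :func:`fragmrd.synthetic.write_cohort`.

    Expects ``metadata.tsv``, ``fragments.tsv``, ``variants.tsv`` and
    ``support.tsv``. Patient fragment samples are named ``<pid>.preop``,
    ``<pid>.postop`` and ``<pid>.tumour``; control samples carry their own id
    and ``group == "control"`` in the metadata.

    Returns ``(patients, controls, metadata)``.
    """
    directory = Path(directory)
    meta = read_cohort_metadata(directory / "metadata.tsv")
    pools = read_fragment_tables(directory / "fragments.tsv")
    observations = read_variant_table(directory / "variants.tsv")
    support = read_supporting_fragments(directory / "support.tsv")

    obs_by_pid: dict[str, list[VariantObservation]] = {}
    for o in observations:
        obs_by_pid.setdefault(o.patient_id, []).append(o)
    sup_by_pid: dict[str, list[SupportingFragments]] = {}
    for s in support:
        sup_by_pid.setdefault(s.patient_id, []).append(s)

    patients: list[PatientRecord] = []
    controls: list[FragmentPool] = []
    for _, row in meta.iterrows():
        pid = str(row["patient_id"])
        if str(row["group"]) == "control":
            pool = pools.get(pid)
            if pool is not None:
                pool.source_label = "nonmalignant"
                controls.append(pool)
            continue

        def _grab(suffix: str, label: str) -> FragmentPool | None:
            pool = pools.get(f"{pid}.{suffix}")
            if pool is not None:
                pool.source_label = label
            return pool

        patients.append(
            PatientRecord(
                patient_id=pid,
                recurrence=bool(row["recurrence"]),
                followup_months=float(row["followup_months"]),
                adjuvant_status=str(row["adjuvant_status"]),
                preop=_grab("preop", "patient_preop"),
                postop=_grab("postop", "patient_postop"),
                tumour_fragments=_grab("tumour", "tumour_reference"),
                observations=obs_by_pid.get(pid, []),
                support=sup_by_pid.get(pid, []),
            )
        )
    return patients, controls, meta
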