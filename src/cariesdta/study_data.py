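"""Study-level 2x2 accuracy data: types, CSV I/O, eligibility and deduplication.

The universal input is one 2x2 table (TP/FP/FN/TN counts of tooth sites or
surfaces) per study x technology (x optional dataset label and positivity
threshold).  Counts refer to sites/surfaces, not patients; no clustering
adjustment is applied.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import (
    DataFormatError,
    DataValidationError,
    DuplicateKeyError,
    UnknownTechnologyError,
)

#: The five technology categories of the source reviews.  Users may extend the
#: registry (e.g. to split analog/digital imaging) by passing their own set.
DEFAULT_TECHNOLOGIES = frozenset(
    {"fluorescence", "visual", "imaging", "electrical", "transillumination_oct"}
)

UNIT = "tooth sites or surfaces"

_REQUIRED_COLUMNS = ("study_id", "technology", "tp", "fp", "fn", "tn")
_OPTIONAL_COLUMNS = ("dataset_label", "threshold", "setting", "reference_standard")


@dataclass(frozen=True)
class ArmRecord:
    """One 2x2 accuracy table for a study x technology (x dataset, threshold).

    ``n_diseased = tp + fn`` sites positive on the reference standard,
    ``n_sound = tn + fp`` sites negative.  Both margins must be >= 1.
    """

    study_id: str
    technology: str
    tp: int
    fp: int
    fn: int
    tn: int
    dataset_label: str = ""
    threshold: str | None = None
    setting: str | None = None
    reference_standard: str | None = None
    covariates: tuple = ()

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise DataValidationError(
                    f"count {name}={value!r} for {self.study_id}/{self.technology} "
                    "must be a non-negative integer"
                )
            if value < 0:
                raise DataValidationError(
                    f"count {name}={value} for {self.study_id}/{self.technology} is negative"
                )
        if not self.study_id:
            raise DataValidationError("study_id must be non-empty")
        if not self.technology:
            raise DataValidationError("technology must be non-empty")
        if self.tp + self.fn < 1:
            raise DataValidationError(
                f"{self.study_id}/{self.technology}: diseased margin tp+fn must be >= 1"
            )
        if self.tn + self.fp < 1:
            raise DataValidationError(
                f"{self.study_id}/{self.technology}: sound margin tn+fp must be >= 1"
            )

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_sound(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def key(self) -> tuple:
        return (self.study_id, self.technology, self.dataset_label, self.threshold)


@dataclass
class StudyTable:
    """Ordered collection of :class:`ArmRecord` with table-level invariants."""

    arms: list[ArmRecord]
    unit: str = UNIT
    dropped_datasets: list[tuple] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for arm in self.arms:
            if arm.key in seen:
                raise DuplicateKeyError(f"duplicate arm key {arm.key}")
            seen.add(arm.key)

    def __len__(self) -> int:
        return len(self.arms)

    def __iter__(self):
        return iter(self.arms)

    @property
    def study_ids(self) -> list[str]:
        out: list[str] = []
        for arm in self.arms:
            if arm.study_id not in out:
                out.append(arm.study_id)
        return out

    @property
    def technologies(self) -> list[str]:
        out: list[str] = []
        for arm in self.arms:
            if arm.technology not in out:
                out.append(arm.technology)
        return out

    def technologies_of(self, study_id: str) -> set[str]:
        return {a.technology for a in self.arms if a.study_id == study_id}

    @property
    def total_sites(self) -> int:
        return sum(a.total for a in self.arms)

    @property
    def prevalence(self) -> float:
        """Site-level prevalence Sigma(tp+fn) / Sigma(tp+fp+fn+tn)."""
        total = self.total_sites
        if total == 0:
            return float("nan")
        return sum(a.n_diseased for a in self.arms) / total

    def restrict(self, technologies) -> "StudyTable":
        keep = set(technologies)
        return StudyTable([a for a in self.arms if a.technology in keep])

    def for_study(self, study_id: str) -> list[ArmRecord]:
        return [a for a in self.arms if a.study_id == study_id]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.arms:
            rows.append(
                {
                    "study_id": a.study_id,
                    "technology": a.technology,
                    "dataset_label": a.dataset_label,
                    "threshold": "" if a.threshold is None else a.threshold,
                    "tp": a.tp,
                    "fp": a.fp,
                    "fn": a.fn,
                    "tn": a.tn,
                    "setting": "" if a.setting is None else a.setting,
                    "reference_standard": ""
                    if a.reference_standard is None
                    else a.reference_standard,
                }
            )
        return pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS[:2]) + [
            "dataset_label", "threshold", "tp", "fp", "fn", "tn",
            "setting", "reference_standard",
        ])

    def fingerprint(self) -> str:
        """Stable content hash, used to tie posterior draws to their data."""
        import hashlib

        payload = self.to_frame().to_csv(index=False).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class NetworkSummary:
    """Direct-comparison structure of a multi-technology table."""

    studies_per_technology: dict
    technologies_per_study: dict
    pair_counts: dict  # (tech_a, tech_b) sorted tuple -> number of studies with both


def _to_int(value, row_idx: int, column: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise DataValidationError(
            f"row {row_idx}: column {column!r} value {value!r} is not a number"
        ) from None
    if f != int(f):
        raise DataValidationError(
            f"row {row_idx}: column {column!r} value {value!r} is not an integer"
        )
    if f < 0:
        raise DataValidationError(
            f"row {row_idx}: column {column!r} value {value!r} is negative"
        )
    return int(f)


def table_from_frame(df: pd.DataFrame, registry=DEFAULT_TECHNOLOGIES) -> StudyTable:
    """Validate a data frame against the CSV schema and build a StudyTable."""
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise DataFormatError(f"missing required column {col!r}")
    arms = []
    for idx, row in enumerate(df.itertuples(index=False)):
        record = row._asdict()
        tech = str(record["technology"])
        if registry is not None and tech not in registry:
            raise UnknownTechnologyError(
                f"row {idx}: technology {tech!r} not in registry "
                f"{sorted(registry)}; register it explicitly to accept it"
            )

        def _opt(name):
            v = record.get(name)
            if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
                return None
            return str(v)

        try:
            arm = ArmRecord(
                study_id=str(record["study_id"]),
                technology=tech,
                tp=_to_int(record["tp"], idx, "tp"),
                fp=_to_int(record["fp"], idx, "fp"),
                fn=_to_int(record["fn"], idx, "fn"),
                tn=_to_int(record["tn"], idx, "tn"),
                dataset_label=_opt("dataset_label") or "",
                threshold=_opt("threshold"),
                setting=_opt("setting"),
                reference_standard=_opt("reference_standard"),
            )
        except DataValidationError as err:
            raise DataValidationError(f"row {idx}: {err}") from None
        arms.append(arm)
    return StudyTable(arms)


def read_study_table(path, registry=DEFAULT_TECHNOLOGIES) -> StudyTable:
    """Read study-level 2x2 data from CSV (comma-separated, UTF-8, header row).

    Required columns: study_id, technology, tp, fp, fn, tn.  Optional:
    dataset_label, threshold (stored as string; device scales differ),
    setting, reference_standard.  Unknown technologies are rejected unless
    present in ``registry`` (pass ``None`` to accept anything).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return table_from_frame(df, registry=registry)


def write_study_table(table: StudyTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def select_largest_dataset(table: StudyTable) -> StudyTable:
    """Keep one dataset per study x technology: the largest total site count.

    When a study contributes several data sets for the same technology (e.g.
    analog and digital radiographs), only the one with the largest volume of
    data enters analysis.  Ties break to the lexicographically smallest
    dataset_label (then threshold) so the rule is deterministic and auditable.
    The dropped arm keys are recorded on ``dropped_datasets``.
    """
    best: dict[tuple, ArmRecord] = {}
    order: list[tuple] = []
    for arm in table.arms:
        k = (arm.study_id, arm.technology)
        if k not in best:
            best[k] = arm
            order.append(k)
            continue
        incumbent = best[k]
        cand_rank = (-arm.total, arm.dataset_label, str(arm.threshold))
        inc_rank = (-incumbent.total, incumbent.dataset_label, str(incumbent.threshold))
        if cand_rank < inc_rank:
            best[k] = arm
    kept = {id(best[k]) for k in order}
    dropped = [a.key for a in table.arms if id(a) not in kept]
    return StudyTable([best[k] for k in order], dropped_datasets=dropped)


def filter_for_analysis(
    table: StudyTable, min_tests: int, required=None
) -> StudyTable:
    """Apply the eligibility rule for one of the two analyses.

    Retains studies whose technology set has size >= ``min_tests`` (2 for the
    network analysis, 3 for the fully within-person analysis) and, when
    ``required`` is given, contains all required technologies; arms of
    retained studies are then restricted to the required set.
    """
    if min_tests < 2:
        raise ValueError("min_tests must be >= 2")
    required_set = set(required) if required is not None else None
    arms = []
    for sid in table.study_ids:
        techs = table.technologies_of(sid)
        if len(techs) < min_tests:
            continue
        if required_set is not None and not required_set <= techs:
            continue
        for arm in table.for_study(sid):
            if required_set is None or arm.technology in required_set:
                arms.append(arm)
    if not arms:
        warnings.warn("eligibility filter returned an empty table", stacklevel=2)
    return StudyTable(arms)


def network_summary(table: StudyTable) -> NetworkSummary:
    """Per-technology study counts and pairwise direct-comparison counts."""
    techs = sorted(table.technologies)
    per_study = {sid: table.technologies_of(sid) for sid in table.study_ids}
    per_tech = {
        t: sum(1 for s in per_study.values() if t in s) for t in techs
    }
    pairs = {}
    for i, a in enumerate(techs):
        for b in techs[i + 1 :]:
            pairs[(a, b)] = sum(1 for s in per_study.values() if a in s and b in s)
    return NetworkSummary(
        studies_per_technology=per_tech,
        technologies_per_study=per_study,
        pair_counts=pairs,
    )
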