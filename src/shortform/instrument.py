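"""Instrument model: items, cutoffs, dichotomization and risk labelling.

The instrument is a semistructured psychosis-risk interview with 60 items
grouped into four positive-symptom scales (unusual thought content,
non-bizarre ideas, perceptual abnormalities, disorganized speech).  Each
item carries a 0-6 severity rating and a 0-6 frequency/duration rating.
Per-item cutoffs convert the ordinal pair into a binary risk indicator;
a participant is at clinical high risk (CHR-P) if *any* item is positive,
and crosses the psychosis threshold if any item reaches psychosis-level
severity.

The cutoff table shipped here (severity 3-5, frequency >= 3, psychosis
severity 6) is a documented stand-in configuration: all downstream logic
is cutoff-agnostic and reads the thresholds from :class:`ItemDefinition`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

SCALES = (
    "unusual_thought_content",
    "non_bizarre_ideas",
    "perceptual_abnormalities",
    "disorganized_speech",
)

#: default item count per scale (sums to 60)
DEFAULT_SCALE_COUNTS = {
    "unusual_thought_content": 13,
    "non_bizarre_ideas": 11,
    "perceptual_abnormalities": 22,
    "disorganized_speech": 14,
}

_SCALE_PREFIX = {
    "unusual_thought_content": "utc",
    "non_bizarre_ideas": "nbi",
    "perceptual_abnormalities": "pa",
    "disorganized_speech": "ds",
}

NOT_AT_RISK = "not_at_risk"
CHR_P = "chr_p"
PSYCHOSIS = "psychosis"


class InstrumentError(ValueError):
    """Raised for invalid instrument definitions or out-of-range responses."""


@dataclass(frozen=True)
class ItemDefinition:
    """One interview item and its dichotomization cutoffs.

    Parameters
    ----------
    item_id
        Unique identifier, e.g. ``"utc_03"``.
    scale
        One of :data:`SCALES`.
    severity_positive_range
        Inclusive ``(low, high)`` severity interval counting as risk-positive.
    frequency_min
        Minimum frequency rating required for a positive indicator.
    psychosis_severity_min
        Severity at or above which the item feeds the psychosis-threshold
        label instead of the risk indicator.  ``None`` disables the
        psychosis criterion for this item.
    """

    item_id: str
    scale: str
    severity_positive_range: tuple[int, int] = (3, 5)
    frequency_min: int = 3
    psychosis_severity_min: Optional[int] = 6

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise InstrumentError(f"unknown scale {self.scale!r} for item {self.item_id!r}")
        lo, hi = self.severity_positive_range
        if not (0 <= lo <= hi <= 6):
            raise InstrumentError(
                f"item {self.item_id!r}: severity_positive_range {self.severity_positive_range} "
                "must satisfy 0 <= low <= high <= 6"
            )
        if not 0 <= self.frequency_min <= 6:
            raise InstrumentError(f"item {self.item_id!r}: frequency_min must be in [0, 6]")
        if self.psychosis_severity_min is not None and self.psychosis_severity_min <= hi:
            raise InstrumentError(
                f"item {self.item_id!r}: psychosis_severity_min must exceed the "
                "upper bound of severity_positive_range"
            )


@dataclass
class Instrument:
    """Ordered collection of :class:`ItemDefinition` making up the interview."""

    items: list[ItemDefinition]

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InstrumentError(f"duplicate item ids: {dup}")
        if not self.items:
            raise InstrumentError("instrument has no items")

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def scale_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in SCALES}
        for it in self.items:
            counts[it.scale] += 1
        return counts

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, item_id: str) -> ItemDefinition:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    @classmethod
    def default(cls) -> "Instrument":
        """The standard 60-item, four-scale layout with stand-in cutoffs."""
        items = []
        for scale in SCALES:
            prefix = _SCALE_PREFIX[scale]
            for k in range(1, DEFAULT_SCALE_COUNTS[scale] + 1):
                items.append(ItemDefinition(item_id=f"{prefix}_{k:02d}", scale=scale))
        return cls(items=items)

    # ------------------------------------------------------------------ I/O
    def to_yaml(self, path) -> None:
        payload = {
            "items": [
                {
                    "item_id": it.item_id,
                    "scale": it.scale,
                    "severity_positive_range": list(it.severity_positive_range),
                    "frequency_min": it.frequency_min,
                    "psychosis_severity_min": it.psychosis_severity_min,
                }
                for it in self.items
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Instrument":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        items = [
            ItemDefinition(
                item_id=d["item_id"],
                scale=d["scale"],
                severity_positive_range=tuple(d.get("severity_positive_range", (3, 5))),
                frequency_min=d.get("frequency_min", 3),
                psychosis_severity_min=d.get("psychosis_severity_min", 6),
            )
            for d in payload["items"]
        ]
        return cls(items=items)


@dataclass
class ResponseRecord:
    """Raw per-participant interview ratings plus demographics."""

    participant_id: str
    severity: dict[str, int]
    frequency: dict[str, int]
    sex: str = "female"
    ethnicity_white: bool = True
    age_years: float = 24.0
    distress: Optional[dict[str, int]] = None

    def validate(self, instrument: Instrument) -> None:
        if self.sex not in ("female", "male"):
            raise InstrumentError(f"participant {self.participant_id!r}: sex must be 'female' or 'male'")
        for it in instrument.items:
            for name, table, hi in (("severity", self.severity, 6), ("frequency", self.frequency, 6)):
                if it.item_id not in table:
                    raise InstrumentError(
                        f"participant {self.participant_id!r}: missing {name} for item {it.item_id!r}"
                    )
                v = table[it.item_id]
                if not (isinstance(v, (int, np.integer)) and 0 <= v <= hi):
                    raise InstrumentError(
                        f"participant {self.participant_id!r}: {name} {v!r} out of range "
                        f"[0, {hi}] for item {it.item_id!r}"
                    )
            if self.distress is not None and it.item_id in self.distress:
                d = self.distress[it.item_id]
                if not 0 <= d <= 100:
                    raise InstrumentError(
                        f"participant {self.participant_id!r}: distress {d!r} out of range "
                        f"[0, 100] for item {it.item_id!r}"
                    )


def dichotomize_item(severity: int, frequency: int, item: ItemDefinition) -> int:
    """Binary risk indicator for one (severity, frequency) rating pair.

    Returns 1 iff severity lies inside the item's positive range *and*
    frequency reaches the item's minimum.  Severity at or above the
    psychosis threshold returns 0 here; it contributes to the
    psychosis-threshold label via :func:`full_scale_status` instead.
    """
    for name, v in (("severity", severity), ("frequency", frequency)):
        if not (isinstance(v, (int, np.integer)) and 0 <= v <= 6):
            raise InstrumentError(f"item {item.item_id!r}: {name} {v!r} out of range [0, 6]")
    lo, hi = item.severity_positive_range
    return int(lo <= severity <= hi and frequency >= item.frequency_min)


def _is_psychosis_level(
    severity: int, frequency: int, item: ItemDefinition, require_frequency: bool = True
) -> bool:
    if item.psychosis_severity_min is None:
        return False
    if severity < item.psychosis_severity_min:
        return False
    return frequency >= item.frequency_min if require_frequency else True


def full_scale_status(
    record: ResponseRecord,
    instrument: Instrument,
    psychosis_requires_frequency: bool = True,
) -> str:
    """Full-scale risk label: ``psychosis`` > ``chr_p`` > ``not_at_risk``.

    A single positive item suffices for CHR-P status (the any-item rule);
    any psychosis-level item overrides it.
    """
    record.validate(instrument)
    any_positive = False
    for it in instrument.items:
        sev = record.severity[it.item_id]
        freq = record.frequency[it.item_id]
        if _is_psychosis_level(sev, freq, it, psychosis_requires_frequency):
            return PSYCHOSIS
        if dichotomize_item(sev, freq, it):
            any_positive = True
    return CHR_P if any_positive else NOT_AT_RISK


@dataclass
class CohortDataset:
    """A cohort of interview records plus derived binary matrix and labels.

    ``binary_matrix`` (participants x items, values in {0,1}) and
    ``risk_labels`` are filled by :func:`dichotomize_cohort`.
    ``provenance`` carries generator ground truth for synthetic cohorts.
    """

    instrument: Instrument
    records: list[ResponseRecord]
    binary_matrix: Optional[pd.DataFrame] = None
    risk_labels: Optional[dict[str, str]] = None
    provenance: dict = field(default_factory=dict)

    @property
    def participant_ids(self) -> list[str]:
        return [r.participant_id for r in self.records]

    def severity_frame(self) -> pd.DataFrame:
        cols = self.instrument.item_ids
        data = [[r.severity[c] for c in cols] for r in self.records]
        return pd.DataFrame(data, index=self.participant_ids, columns=cols, dtype=int)

    def frequency_frame(self) -> pd.DataFrame:
        cols = self.instrument.item_ids
        data = [[r.frequency[c] for c in cols] for r in self.records]
        return pd.DataFrame(data, index=self.participant_ids, columns=cols, dtype=int)

    def demographics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sex": [r.sex for r in self.records],
                "ethnicity_white": [r.ethnicity_white for r in self.records],
                "age": [r.age_years for r in self.records],
            },
            index=self.participant_ids,
        )

    def analysis_set(self) -> tuple[pd.DataFrame, pd.Series]:
        """Binary item matrix and 0/1 CHR-P outcome, psychosis cases excluded.

        The binary analysis contrasts CHR-P status against not-at-risk;
        participants already past the psychosis threshold are out of scope
        for that contrast and are dropped here.
        """
        if self.binary_matrix is None or self.risk_labels is None:
            raise InstrumentError("cohort not scored; call dichotomize_cohort first")
        keep = [pid for pid in self.participant_ids if self.risk_labels[pid] != PSYCHOSIS]
        X = self.binary_matrix.loc[keep]
        y = pd.Series(
            [1 if self.risk_labels[pid] == CHR_P else 0 for pid in keep],
            index=keep,
            name="chr_p",
            dtype=int,
        )
        return X, y

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        """Write the wide CSV layout: demographics then <item>_sev/<item>_freq."""
        rows = []
        for r in self.records:
            row = {
                "participant_id": r.participant_id,
                "sex": r.sex,
                "ethnicity_white": int(r.ethnicity_white),
                "age": r.age_years,
            }
            for it in self.instrument.items:
                row[f"{it.item_id}_sev"] = r.severity[it.item_id]
                row[f"{it.item_id}_freq"] = r.frequency[it.item_id]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, instrument: Instrument) -> "CohortDataset":
        df = pd.read_csv(path, dtype={"participant_id": str})
        records = []
        for _, row in df.iterrows():
            severity = {it.item_id: int(row[f"{it.item_id}_sev"]) for it in instrument.items}
            frequency = {it.item_id: int(row[f"{it.item_id}_freq"]) for it in instrument.items}
            records.append(
                ResponseRecord(
                    participant_id=str(row["participant_id"]),
                    severity=severity,
                    frequency=frequency,
                    sex=str(row["sex"]),
                    ethnicity_white=bool(int(row["ethnicity_white"])),
                    age_years=float(row["age"]),
                )
            )
        return cls(instrument=instrument, records=records)


def dichotomize_cohort(
    dataset: CohortDataset, psychosis_requires_frequency: bool = True
) -> CohortDataset:
    """Score a cohort in place: fill ``binary_matrix`` and ``risk_labels``.

    Vectorized over items; equivalent to applying :func:`dichotomize_item`
    and :func:`full_scale_status` record by record.
    """
    if not dataset.records:
        raise InstrumentError("empty cohort")
    for r in dataset.records:
        r.validate(dataset.instrument)
    sev = dataset.severity_frame().to_numpy()
    freq = dataset.frequency_frame().to_numpy()
    n, p = sev.shape
    binary = np.zeros((n, p), dtype=int)
    psych_any = np.zeros(n, dtype=bool)
    for j, it in enumerate(dataset.instrument.items):
        lo, hi = it.severity_positive_range
        binary[:, j] = (
            (sev[:, j] >= lo) & (sev[:, j] <= hi) & (freq[:, j] >= it.frequency_min)
        ).astype(int)
        if it.psychosis_severity_min is not None:
            hit = sev[:, j] >= it.psychosis_severity_min
            if psychosis_requires_frequency:
                hit &= freq[:, j] >= it.frequency_min
            psych_any |= hit
    pids = dataset.participant_ids
    dataset.binary_matrix = pd.DataFrame(
        binary, index=pids, columns=dataset.instrument.item_ids
    )
    labels = {}
    row_any = binary.sum(axis=1) > 0
    for i, pid in enumerate(pids):
        if psych_any[i]:
            labels[pid] = PSYCHOSIS
        elif row_any[i]:
            labels[pid] = CHR_P
        else:
            labels[pid] = NOT_AT_RISK
    dataset.risk_labels = labels
    return dataset


def drop_zero_variance(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove constant columns (all-0 or all-1) from a binary item matrix.

    Returns the reduced matrix and the removed item ids.  Idempotent.
    """
    if matrix.shape[1] == 0:
        raise InstrumentError("matrix has no columns")
    constant = [c for c in matrix.columns if matrix[c].nunique(dropna=False) <= 1]
    if len(constant) == matrix.shape[1]:
        raise InstrumentError("all columns are zero-variance; nothing to model")
    return matrix.drop(columns=constant), constant
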