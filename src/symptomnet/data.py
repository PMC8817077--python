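"""Questionnaire data model: item metadata, response matrices, coding.

The pipeline's sole empirical input is a subjects x items matrix of ordinal
scores.  Items carry metadata (scale membership, admissible score range,
reverse-scoring flag) that controls validation and coding.  Scoring rules are
always driven by metadata, never inferred from item text.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Scale",
    "CombineMethod",
    "ItemMeta",
    "CompositeSpec",
    "ResponseMatrix",
    "load_responses",
    "write_responses",
    "load_item_meta",
    "save_item_meta",
    "complete_cases",
    "reverse_score",
]


class Scale(str, enum.Enum):
    """Instrument an item belongs to."""

    DS2 = "DS2"
    PHQ9 = "PHQ9"
    COMPOSITE = "COMPOSITE"


class CombineMethod(str, enum.Enum):
    """How redundant items are merged into a composite node."""

    LATENT_SCORE = "LATENT_SCORE"
    MEAN = "MEAN"


@dataclass(frozen=True)
class ItemMeta:
    """Metadata for one questionnaire item.

    ``min_score``/``max_score`` bound admissible ordinal responses; they are
    ``None`` for continuous composite columns created after redundancy
    reduction.  ``reverse`` marks positively worded items that must be
    reverse-scored (x -> min + max - x) before any correlation is computed.
    """

    code: str
    scale: Scale = Scale.DS2
    min_score: Optional[int] = 0
    max_score: Optional[int] = 4
    reverse: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("item code must be non-empty")
        if self.min_score is not None and self.max_score is not None:
            if not self.min_score < self.max_score:
                raise ValueError(
                    f"item {self.code!r}: min_score must be < max_score"
                )

    @property
    def is_ordinal(self) -> bool:
        return self.min_score is not None and self.max_score is not None

    @property
    def n_categories(self) -> int:
        if not self.is_ordinal:
            raise ValueError(f"item {self.code!r} is not ordinal")
        return self.max_score - self.min_score + 1


@dataclass(frozen=True)
class CompositeSpec:
    """Specification for merging >= 2 redundant items into one node."""

    new_code: str
    member_codes: tuple[str, ...]
    method: CombineMethod = CombineMethod.LATENT_SCORE

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_codes", tuple(self.member_codes))
        object.__setattr__(self, "method", CombineMethod(self.method))
        if len(self.member_codes) < 2:
            raise ValueError(
                f"composite {self.new_code!r} needs >= 2 member items"
            )
        if len(set(self.member_codes)) != len(self.member_codes):
            raise ValueError(
                f"composite {self.new_code!r} has duplicate members"
            )


def _check_meta_codes(item_meta: Sequence[ItemMeta]) -> None:
    codes = [m.code for m in item_meta]
    if len(set(codes)) != len(codes):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        raise ValueError(f"duplicate item codes in metadata: {dupes}")


@dataclass
class ResponseMatrix:
    """Subjects x items matrix of questionnaire responses.

    ``values`` is a float array so that missing responses (NaN) can be
    carried before complete-case filtering; after filtering, ordinal columns
    hold integers exactly.  Column order always matches ``item_meta`` order.
    """

    values: np.ndarray
    item_meta: tuple[ItemMeta, ...]
    subject_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.item_meta = tuple(self.item_meta)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if self.values.shape[1] != len(self.item_meta):
            raise ValueError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.item_meta)} item metadata entries"
            )
        _check_meta_codes(self.item_meta)
        if self.subject_ids is not None:
            self.subject_ids = np.asarray(self.subject_ids)
            if len(self.subject_ids) != self.values.shape[0]:
                raise ValueError("subject_ids length mismatch")
        self._validate_ranges()

    def _validate_ranges(self) -> None:
        for j, meta in enumerate(self.item_meta):
            if not meta.is_ordinal:
                continue
            col = self.values[:, j]
            ok = np.isnan(col) | (
                (col >= meta.min_score) & (col <= meta.max_score)
            )
            if not ok.all():
                row = int(np.flatnonzero(~ok)[0])
                raise ValueError(
                    f"value {col[row]:g} out of range "
                    f"[{meta.min_score}, {meta.max_score}] at row {row}, "
                    f"item {meta.code!r}"
                )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(m.code for m in self.item_meta)

    def meta_for(self, code: str) -> ItemMeta:
        for m in self.item_meta:
            if m.code == code:
                return m
        raise KeyError(code)

    def to_frame(self) -> pd.DataFrame:
        index = (
            self.subject_ids
            if self.subject_ids is not None
            else np.arange(self.n_subjects)
        )
        return pd.DataFrame(self.values, columns=list(self.codes), index=index)


# ---------------------------------------------------------------------------
# IO

_NA_VALUES = ["", "NA", "NaN", "nan"]


def load_responses(path: str | Path, meta: Sequence[ItemMeta]) -> ResponseMatrix:
    """Read a response CSV whose header is a superset of ``meta`` codes.

    Columns are reordered to metadata order; empty cells and ``NA`` are
    treated as missing.  Out-of-range values and absent columns are fatal.
    A ``subject_id`` column, if present, is used as row identifiers.
    """
    meta = tuple(meta)
    _check_meta_codes(meta)
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)
    missing = [m.code for m in meta if m.code not in df.columns]
    if missing:
        raise ValueError(f"input {path} lacks required columns: {missing}")
    subject_ids = (
        df["subject_id"].to_numpy() if "subject_id" in df.columns else None
    )
    values = df[[m.code for m in meta]].to_numpy(dtype=float)
    return ResponseMatrix(values, meta, subject_ids=subject_ids)


def write_responses(m: ResponseMatrix, path: str | Path) -> None:
    """Write a response matrix as CSV (integers written without decimals)."""
    df = m.to_frame()
    all_integral = np.all(
        np.isnan(m.values) | (np.mod(m.values, 1) == 0)
    )
    if all_integral:
        df = df.astype("Int64")
    if m.subject_ids is not None:
        df.insert(0, "subject_id", m.subject_ids)
        df.to_csv(path, index=False)
    else:
        df.to_csv(path, index=False)


def _meta_to_dicts(meta: Sequence[ItemMeta]) -> list[dict]:
    return [
        {
            "code": m.code,
            "scale": m.scale.value,
            "min_score": m.min_score,
            "max_score": m.max_score,
            "reverse": m.reverse,
            "label": m.label,
        }
        for m in meta
    ]


def save_item_meta(meta: Sequence[ItemMeta], path: str | Path) -> None:
    path = Path(path)
    records = _meta_to_dicts(meta)
    if path.suffix == ".json":
        path.write_text(json.dumps(records, indent=2))
    else:
        path.write_text(yaml.safe_dump(records, sort_keys=False))


def load_item_meta(path: str | Path) -> tuple[ItemMeta, ...]:
    """Load item metadata from a YAML or JSON sidecar file."""
    path = Path(path)
    text = path.read_text()
    records = (
        json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    )
    return tuple(
        ItemMeta(
            code=r["code"],
            scale=Scale(r.get("scale", "DS2")),
            min_score=r.get("min_score"),
            max_score=r.get("max_score"),
            reverse=bool(r.get("reverse", False)),
            label=r.get("label", ""),
        )
        for r in records
    )


# ---------------------------------------------------------------------------
# Coding


def complete_cases(m: ResponseMatrix) -> tuple[ResponseMatrix, int]:
    """Keep only rows without any missing item; return (filtered, n removed)."""
    keep = ~np.isnan(m.values).any(axis=1)
    removed = int((~keep).sum())
    if not keep.any():
        raise ValueError("no complete cases remain after filtering")
    sub_ids = m.subject_ids[keep] if m.subject_ids is not None else None
    return ResponseMatrix(m.values[keep], m.item_meta, subject_ids=sub_ids), removed


def reverse_score(m: ResponseMatrix) -> ResponseMatrix:
    """Reverse-score items flagged ``reverse=True``: x -> min + max - x.

    The returned matrix has all reverse flags cleared, so applying the
    operation again is a no-op (the value map itself is an involution).
    """
    values = m.values.copy()
    new_meta = []
    for j, meta in enumerate(m.item_meta):
        if meta.reverse:
            if not meta.is_ordinal:
                raise ValueError(
                    f"cannot reverse-score non-ordinal item {meta.code!r}"
                )
            values[:, j] = meta.min_score + meta.max_score - values[:, j]
            new_meta.append(replace(meta, reverse=False))
        else:
            new_meta.append(meta)
    return ResponseMatrix(values, tuple(new_meta), subject_ids=m.subject_ids)
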