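"""Diagnostic code map and complexity weight table.

Raw diagnosis codes are aggregated into diagnostic groups, each carrying a
chronicity class (chronic, acute, neoplastic, or pregnancy-related) and an
organ system. A separate weight table maps each diagnostic group to a
non-negative complexity weight; the weighted sum of a patient's active
groups is the morbidity index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

CHRONICITY_CLASSES = frozenset({"chronic", "acute", "neoplastic", "pregnancy"})

#: chronicity classes whose groups, once diagnosed, stay active indefinitely
PERSISTENT_CLASSES = frozenset({"chronic", "neoplastic", "pregnancy"})


class CodeMapError(ValueError):
    """Raised when a code map or weight table violates its invariants."""


@dataclass(frozen=True)
class GroupInfo:
    """Attributes of one diagnostic group."""

    group_id: str
    chronicity: str
    organ_system: str


class CodeMap:
    """Mapping from raw diagnosis codes to diagnostic groups.

    Each raw code maps to exactly one group; each group has exactly one
    chronicity class and one organ system.
    """

    def __init__(self, entries: Mapping[str, GroupInfo]):
        groups: dict[str, GroupInfo] = {}
        for code, info in entries.items():
            if info.chronicity not in CHRONICITY_CLASSES:
                raise CodeMapError(
                    f"unknown chronicity {info.chronicity!r} for code {code!r}"
                )
            seen = groups.get(info.group_id)
            if seen is not None and seen != info:
                raise CodeMapError(
                    f"group {info.group_id!r} has conflicting attributes: "
                    f"{seen} vs {info}"
                )
            groups[info.group_id] = info
        self._entries = dict(entries)
        self._groups = groups

    @property
    def entries(self) -> dict[str, GroupInfo]:
        return dict(self._entries)

    @property
    def groups(self) -> dict[str, GroupInfo]:
        """group_id -> GroupInfo for every group in the map."""
        return dict(self._groups)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __eq__(self, other) -> bool:
        return isinstance(other, CodeMap) and self._entries == other._entries

    def group_of(self, code: str) -> str:
        return self._entries[code].group_id

    def info(self, code: str) -> GroupInfo:
        return self._entries[code]

    def group_info(self, group_id: str) -> GroupInfo:
        return self._groups[group_id]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "code": code,
                "group_id": info.group_id,
                "chronicity": info.chronicity,
                "organ_system": info.organ_system,
            }
            for code, info in sorted(self._entries.items())
        ]
        return pd.DataFrame(rows, columns=["code", "group_id", "chronicity", "organ_system"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CodeMap":
        required = {"code", "group_id", "chronicity", "organ_system"}
        missing = required - set(frame.columns)
        if missing:
            raise CodeMapError(f"code map missing columns: {sorted(missing)}")
        dup = frame["code"][frame["code"].duplicated()]
        if len(dup):
            raise CodeMapError(
                f"duplicate codes in code map: {sorted(dup.unique().tolist())}"
            )
        entries = {
            str(r.code): GroupInfo(str(r.group_id), str(r.chronicity), str(r.organ_system))
            for r in frame.itertuples()
        }
        return cls(entries)


class MissingWeightError(KeyError):
    """A diagnostic group has no weight and no default was configured."""


class WeightTable:
    """group_id -> non-negative complexity weight, with optional default."""

    def __init__(self, weights: Mapping[str, float], default: float | None = None):
        for g, w in weights.items():
            if w < 0:
                raise CodeMapError(f"negative weight {w} for group {g!r}")
        if default is not None and default < 0:
            raise CodeMapError(f"negative default weight {default}")
        self._weights = {str(g): float(w) for g, w in weights.items()}
        self.default = default

    def weight(self, group_id: str) -> float:
        try:
            return self._weights[group_id]
        except KeyError:
            if self.default is not None:
                return self.default
            raise MissingWeightError(
                f"no weight for group {group_id!r} and no default configured"
            ) from None

    def __len__(self) -> int:
        return len(self._weights)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WeightTable)
            and self._weights == other._weights
            and self.default == other.default
        )

    def as_dict(self) -> dict[str, float]:
        return dict(self._weights)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self._weights.items())
        return pd.DataFrame(rows, columns=["group_id", "weight"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, default: float | None = None) -> "WeightTable":
        required = {"group_id", "weight"}
        missing = required - set(frame.columns)
        if missing:
            raise CodeMapError(f"weight table missing columns: {sorted(missing)}")
        dup = frame["group_id"][frame["group_id"].duplicated()]
        if len(dup):
            raise CodeMapError(
                f"duplicate groups in weight table: {sorted(dup.unique().tolist())}"
            )
        return cls(dict(zip(frame["group_id"].astype(str), frame["weight"].astype(float))), default)


def load_codemap(path) -> CodeMap:
    """Read ``codemap.csv`` (code, group_id, chronicity, organ_system)."""
    return CodeMap.from_frame(pd.read_csv(path, dtype=str))


def write_codemap(codemap: CodeMap, path) -> None:
    codemap.to_frame().to_csv(path, index=False)


def load_weights(path, default: float | None = None) -> WeightTable:
    """Read ``weights.csv`` (group_id, weight)."""
    return WeightTable.from_frame(pd.read_csv(path), default=default)


def write_weights(weights: WeightTable, path) -> None:
    weights.to_frame().to_csv(path, index=False)


def map_events(events: pd.DataFrame, codemap: CodeMap) -> tuple[pd.DataFrame, int]:
    """Attach group_id/chronicity/organ_system to diagnosis events.

    Events whose code has no entry in the map are dropped; the count of
    dropped rows is returned and logged, never silently ignored.
    """
    frame = codemap.to_frame()
    merged = events.merge(frame, on="code", how="left")
    unmapped = merged["group_id"].isna()
    n_dropped = int(unmapped.sum())
    if n_dropped:
        logger.warning("dropping %d events with unmapped diagnosis codes", n_dropped)
    mapped = merged.loc[~unmapped].copy()
    mapped["onset_date"] = pd.to_datetime(mapped["onset_date"])
    return mapped, n_dropped


def codemap_from_specs(specs: Iterable) -> CodeMap:
    """Build a CodeMap from condition specifications (one raw code per group)."""
    entries = {}
    for s in specs:
        entries[f"{s.group_id}-01"] = GroupInfo(s.group_id, s.chronicity, s.organ_system)
    return CodeMap(entries)
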