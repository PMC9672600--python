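"""Readers and writers for the package's on-disk formats.

Points CSV: header ``id,x,y,hot,<attr1>,<attr2>,...``; UTF-8.  The protected
schema is inferred from the observed category labels (sorted lexically, so
inference is deterministic) unless a hint is supplied.

Hot-spot list JSON: an array ordered by rank, each entry carrying explicit
member ids so downstream population unions are exact and independent of any
distance recomputation:
``[{"rank": 1, "center": [x, y], "radius": r, "score": s, "member_ids": [...]}, ...]``

Result JSON: the selected candidates with raw and (when available)
normalized N-F coordinates, plus the run parameters, for reproducibility.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .exceptions import (
    EmptyInputError,
    FormatError,
    UnknownIdError,
    ValidationError,
)
from .measures import Candidate, NFPoint
from .model import (
    Hotspot,
    PointDataset,
    PointRecord,
    ProtectedSchema,
    RankedHotspotList,
)
from .search import ResultSet

__all__ = [
    "read_point_dataset",
    "write_point_dataset",
    "read_ranked_hotspots",
    "write_ranked_hotspots",
    "write_result_set",
    "read_result_set",
]

RESERVED_COLUMNS = ("id", "x", "y", "hot")
FORMAT_VERSION = 1


def read_point_dataset(
    path: str | Path,
    schema_hint: ProtectedSchema | None = None,
    coordinate_system: str = "planar",
) -> PointDataset:
    """Parse and validate a points CSV; infer the schema when no hint given."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in RESERVED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    attr_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    if schema_hint is not None:
        missing = [a for a in schema_hint.attributes if a not in attr_cols]
        if missing:
            raise FormatError(f"{path.name}: missing attribute column(s) {missing}")
        schema = schema_hint
    else:
        if not attr_cols:
            raise FormatError(f"{path.name}: no protected attribute columns found")
        schema = ProtectedSchema(
            attributes=tuple(attr_cols),
            levels={a: tuple(sorted(df[a].unique())) for a in attr_cols},
        )

    records = []
    for _, row in df.iterrows():
        if row["hot"] not in ("0", "1"):
            raise ValidationError(
                f"{path.name}: non-binary hot value {row['hot']!r} at id {row['id']!r}"
            )
        try:
            x, y = float(row["x"]), float(row["y"])
        except ValueError as exc:
            raise FormatError(
                f"{path.name}: bad coordinate at id {row['id']!r}: {exc}"
            ) from exc
        records.append(
            PointRecord(
                id=row["id"],
                x=x,
                y=y,
                hot=int(row["hot"]),
                protected={a: row[a] for a in schema.attributes},
            )
        )
    return PointDataset(
        records=records, schema=schema, coordinate_system=coordinate_system
    )


def write_point_dataset(dataset: PointDataset, path: str | Path) -> None:
    path = Path(path)
    attrs = dataset.schema.attributes
    rows = [
        {
            "id": r.id,
            "x": repr(r.x),
            "y": repr(r.y),
            "hot": r.hot,
            **{a: r.protected[a] for a in attrs},
        }
        for r in dataset.records
    ]
    pd.DataFrame(rows, columns=list(RESERVED_COLUMNS) + list(attrs)).to_csv(
        path, index=False
    )


def read_ranked_hotspots(path: str | Path, dataset: PointDataset) -> RankedHotspotList:
    """Load an externally produced ranked hot-spot list.

    Entries are renumbered 1..m in file order; entries whose member set
    duplicates an earlier (better-ranked) one are dropped.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise FormatError(f"{path.name}: expected a JSON array of hot spots")
    if not raw:
        raise EmptyInputError(f"{path.name}: hot spot array is empty")
    hotspots: list[Hotspot] = []
    seen: set[frozenset[str]] = set()
    for entry in raw:
        try:
            member_ids = frozenset(entry["member_ids"])
            center = tuple(float(v) for v in entry.get("center", (0.0, 0.0)))
            radius = float(entry.get("radius", 0.0))
            score = float(entry.get("score", 0.0))
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path.name}: malformed hot spot entry: {exc}") from exc
        for id_ in member_ids:
            if id_ not in dataset:
                raise UnknownIdError(
                    f"{path.name}: hot spot references unknown id {id_!r}"
                )
        if member_ids in seen:
            continue
        seen.add(member_ids)
        hotspots.append(
            Hotspot(
                rank=len(hotspots) + 1,
                center=(center[0], center[1]),
                radius=radius,
                member_ids=member_ids,
                score=score,
            )
        )
    return RankedHotspotList(hotspots=hotspots)


def write_ranked_hotspots(S: RankedHotspotList, path: str | Path) -> None:
    payload = [
        {
            "rank": h.rank,
            "center": [h.center[0], h.center[1]],
            "radius": h.radius,
            "score": h.score,
            "member_ids": sorted(h.member_ids),
        }
        for h in S.hotspots
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def write_result_set(result: ResultSet, path: str | Path) -> None:
    """Serialize a result set with its parameters and tool version."""
    if len(result) == 0:
        raise EmptyInputError("refusing to write an empty result set")
    payload: dict[str, Any] = {
        "format_version": FORMAT_VERSION,
        "tool_version": __version__,
        "provenance": result.provenance,
        "parameters": result.config,
        "warnings": result.warnings,
        "candidates": [
            {
                "hotspot_ranks": list(c.ranks),
                "member_union": sorted(c.member_union),
                "N": c.nf.N,
                "F": c.nf.F,
                "normN": c.nf.normN,
                "normF": c.nf.normF,
            }
            for c in result.candidates
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_result_set(path: str | Path) -> ResultSet:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    try:
        cands = [
            Candidate(
                ranks=tuple(entry["hotspot_ranks"]),
                member_union=frozenset(entry["member_union"]),
                nf=NFPoint(
                    N=entry["N"],
                    F=entry["F"],
                    normN=entry.get("normN"),
                    normF=entry.get("normF"),
                ),
            )
            for entry in payload["candidates"]
        ]
        return ResultSet(
            candidates=cands,
            provenance=payload.get("provenance", "unknown"),
            config=payload.get("parameters", {}),
            warnings=payload.get("warnings", []),
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path.name}: malformed result file: {exc}") from exc
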