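"""Readers and writers for the tabular formats the pipeline exchanges.

Bibliographic exports are CSV/TSV with a header row and a configurable
column mapping; interaction networks are labelled matrices (first column =
plant labels, header = pollinator labels) in the Web-of-Life dialect with
an optional JSON metadata sidecar per network.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import SourceRecord, GenusYearCounts
from .networks import InteractionNetwork

DEFAULT_COLUMN_MAP = {
    "record_id": "id",
    "source": "source",
    "doi": "doi",
    "title": "title",
    "abstract": "abstract",
    "year": "year",
    "doc_type": "doc_type",
    "language": "language",
    "country_text": "countries",
}


def read_records_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str = ",",
) -> list[SourceRecord]:
    """Read bibliographic records from a delimited UTF-8 file."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        year_raw = row.get(cmap["year"], "")
        year = int(float(year_raw)) if year_raw not in ("", None) else None
        records.append(
            SourceRecord(
                record_id=row[cmap["record_id"]],
                source=row[cmap["source"]].strip().lower(),
                doi=row.get(cmap["doi"]) or None,
                title=row.get(cmap["title"], ""),
                abstract=row.get(cmap["abstract"], ""),
                year=year,
                doc_type=row.get(cmap["doc_type"], ""),
                language=row.get(cmap["language"], ""),
                country_text=row.get(cmap["country_text"], ""),
            )
        )
    return records


def write_records_csv(records: Sequence[SourceRecord], path: str | Path) -> None:
    rows = [
        {
            "id": r.record_id,
            "source": r.source,
            "doi": r.doi or "",
            "title": r.title,
            "abstract": r.abstract,
            "year": "" if r.year is None else r.year,
            "doc_type": r.doc_type,
            "language": r.language,
            "countries": r.country_text,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_counts_csv(counts: GenusYearCounts, path: str | Path) -> None:
    counts.to_frame().to_csv(path, index=False)


def write_cooccurrence_csv(counts: GenusYearCounts, path: str | Path) -> None:
    counts.cooccurrence_frame().to_csv(path, index=False)


def read_network_csv(path: str | Path, metadata: Mapping | None = None) -> InteractionNetwork:
    """Read a labelled interaction matrix (plants on rows, header = pollinators).

    ``metadata`` (or a ``<stem>.meta.json`` sidecar next to the file) may
    provide ``network_id``, ``region`` and ``weighted``.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta = {}
    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    if metadata:
        meta.update(metadata)
    return InteractionNetwork(
        matrix=df.to_numpy(dtype=float),
        column_labels=[str(c) for c in df.columns],
        row_labels=[str(i) for i in df.index],
        network_id=str(meta.get("network_id", path.stem)),
        region=meta.get("region"),
        weighted=bool(meta.get("weighted", True)),
    )


def write_network_csv(network: InteractionNetwork, path: str | Path) -> None:
    path = Path(path)
    rows = network.row_labels or [f"plant{i}" for i in range(network.matrix.shape[0])]
    pd.DataFrame(network.matrix, index=rows, columns=network.column_labels).to_csv(path)
    sidecar = path.with_suffix(".meta.json")
    sidecar.write_text(
        json.dumps(
            {
                "network_id": network.network_id,
                "region": network.region,
                "weighted": network.weighted,
            },
            indent=2,
        )
    )


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
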