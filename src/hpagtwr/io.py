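"""File I/O: panel CSV, corpus JSONL, reports, GeoJSON coefficient export.

All formats are plain text. The corpus dialect is JSON Lines with one
``{"city_id": ..., "year": ..., "text": ...}`` object per line; blank lines
are skipped with a logged warning. Malformed rows are reported with their
line numbers rather than silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .errors import ParseError
from .gtwr import CityPanel, GTWRFit
from .scoring import DocumentRecord, tokenize

__all__ = [
    "read_panel", "write_panel", "read_corpus", "write_corpus",
    "write_report", "write_coefficients_geojson", "file_sha256",
]

logger = logging.getLogger(__name__)


def read_panel(path: str | Path, covariates: Sequence[str] | None = None
               ) -> CityPanel:
    """Read a panel CSV (columns city_id, u, v, t, y, covariates...).

    When ``covariates`` is omitted every extra column is treated as one.
    """
    df = pd.read_csv(path)
    missing = [c for c in CityPanel.REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: panel CSV missing columns {missing}")
    if covariates is None:
        covariates = [c for c in df.columns if c not in CityPanel.REQUIRED]
    else:
        absent = [c for c in covariates if c not in df.columns]
        if absent:
            raise ParseError(f"{path}: covariate columns {absent} not found")
    return CityPanel(data=df, covariates=list(covariates))


def write_panel(panel: CityPanel | pd.DataFrame, path: str | Path) -> None:
    df = panel.data if isinstance(panel, CityPanel) else panel
    df.to_csv(path, index=False)


def read_corpus(path: str | Path,
                segmenter: Callable[[str], list[str]] | None = None
                ) -> tuple[list[DocumentRecord], int]:
    """Read a JSONL corpus; returns ``(documents, n_blank_skipped)``."""
    docs: list[DocumentRecord] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                skipped += 1
                continue
            try:
                rec = json.loads(line)
                docs.append(DocumentRecord(
                    city_id=int(rec["city_id"]), year=int(rec["year"]),
                    tokens=tokenize(rec["text"], segmenter)))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed corpus record "
                                 f"({exc})") from exc
    if skipped:
        logger.warning("%s: skipped %d blank line(s)", path, skipped)
    return docs, skipped


def write_corpus(documents: Iterable[DocumentRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in documents:
            fh.write(json.dumps({"city_id": doc.city_id, "year": doc.year,
                                 "text": " ".join(doc.tokens)},
                                ensure_ascii=False) + "\n")


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n",
                          encoding="utf-8")


def write_coefficients_geojson(fit: GTWRFit, path: str | Path) -> None:
    """Export local coefficients as a GeoJSON FeatureCollection of points
    (synthetic planar km coordinates, no CRS claimed)."""
    feats = []
    table = fit.local_table()
    for _, row in table.iterrows():
        props = {k: (float(v) if k != "city_id" else int(v))
                 for k, v in row.items() if k not in ("u", "v")}
        feats.append({"type": "Feature",
                      "geometry": {"type": "Point",
                                   "coordinates": [float(row["u"]),
                                                   float(row["v"])]},
                      "properties": props})
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}) + "\n",
        encoding="utf-8")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
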