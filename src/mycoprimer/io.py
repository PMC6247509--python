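"""Tabular I/O shared across the toolkit.

Primer lists travel as TSV (name, sequence, orientation, optional reference
position).  All output tables are long-format TSV whose header comment
records the tool version, a config hash and the seed; percentages are kept as
fractions internally and rendered with one decimal, matching the style of the
published tables.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .oligo import Oligo, round_tm
from .pcr import CoverageReport


def read_primer_tsv(path: str | Path) -> list[Oligo]:
    """Columns: name, sequence, orientation[, ref_position]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"name", "sequence", "orientation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"primer TSV {path} lacks columns: {sorted(missing)}")
    primers = []
    for row in df.itertuples(index=False):
        pos = getattr(row, "ref_position", None)
        ref_position = int(pos) if pos is not None and str(pos) not in ("", "nan") else None
        primers.append(
            Oligo(
                name=row.name, sequence=row.sequence,
                orientation=row.orientation, ref_position=ref_position,
            )
        )
    return primers


def write_primer_props_tsv(
    primers: Sequence[Oligo], path: str | Path, header_meta: dict | None = None
) -> None:
    rows = []
    for p in primers:
        try:
            std = p.standard_name()
        except ValueError:
            std = ""
        rows.append(
            {
                "name": p.name, "sequence": p.sequence,
                "orientation": p.orientation, "length": p.length,
                "gc": round(p.gc, 3),
                "tm_basic": round_tm(p.tm_basic),
                "tm_salt": round_tm(p.tm_salt),
                "standard_name": std,
            }
        )
    write_tsv(pd.DataFrame(rows), path, header_meta)


def pct(fraction: float) -> float:
    """Rendered percentage with one decimal."""
    return round(100.0 * fraction, 1)


def coverage_report_rows(report: CoverageReport) -> list[dict]:
    rows = []
    for level in report.mismatch_levels:
        matched, denom = report.fungal[level]
        rows.append(
            {
                "query": report.query_label, "group": "Fungi", "level": level,
                "matched": matched, "denominator": denom,
                "percent": pct(matched / denom if denom else 0.0),
            }
        )
        for (g, lv), (m, d) in sorted(report.groups.items()):
            if lv == level:
                rows.append(
                    {
                        "query": report.query_label, "group": g, "level": level,
                        "matched": m, "denominator": d,
                        "percent": pct(m / d if d else 0.0),
                    }
                )
        m, d = report.coamp[level]
        rows.append(
            {
                "query": report.query_label, "group": "non-fungal eukaryotes",
                "level": level, "matched": m, "denominator": d,
                "percent": pct(m / d if d else 0.0),
            }
        )
        for (g, lv), (m, d) in sorted(report.outgroups.items()):
            if lv == level:
                rows.append(
                    {
                        "query": report.query_label, "group": g, "level": level,
                        "matched": m, "denominator": d,
                        "percent": pct(m / d if d else 0.0),
                    }
                )
    return rows


def write_coverage_tsv(
    reports: Iterable[CoverageReport], path: str | Path,
    header_meta: dict | None = None,
) -> None:
    rows = [row for rep in reports for row in coverage_report_rows(rep)]
    write_tsv(pd.DataFrame(rows), path, header_meta)


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tsv(
    df: pd.DataFrame, path: str | Path, header_meta: dict | None = None
) -> None:
    path = Path(path)
    meta = {"tool": f"mycoprimer {__version__}"}
    meta.update(header_meta or {})
    header = "# " + " ".join(f"{k}={v}" for k, v in meta.items())
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
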