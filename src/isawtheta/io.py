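"""Plain-text interchange formats.

* CoefficientTable TSV — '#'-prefixed header lines (n_steps, generator,
  prefix_depth), then ``m<TAB>r2<TAB>count`` rows sorted by (m, r2), counts
  in plain decimal so arbitrary-precision integers round-trip exactly.
* PolyPair JSON — coefficients as decimal strings for the same reason.
* CrossingSeries CSV — ``parity,N,t_star,correction`` rows.
* Scan report TSV — ``omega, T_I, T_II, mean, error`` columns.
"""

from __future__ import annotations

import json
from pathlib import Path

from .crossing import CrossingSeries
from .extrapolate import ScanRow
from .observables import PolyPair
from .walk_enum import CoefficientTable

__all__ = [
    "write_table_tsv",
    "read_table_tsv",
    "write_poly_json",
    "read_poly_json",
    "write_series_csv",
    "read_series_csv",
    "write_scan_tsv",
]


def write_table_tsv(table: CoefficientTable, path) -> None:
    lines = [f"# n_steps\t{table.n_steps}"]
    for key in ("generator", "prefix_depth", "weight"):
        if key in table.metadata:
            lines.append(f"# {key}\t{table.metadata[key]}")
    for (m, r2), c in sorted(table.counts.items()):
        lines.append(f"{m}\t{r2}\t{c}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_table_tsv(path) -> CoefficientTable:
    n_steps = None
    meta = {}
    counts: dict[tuple[int, int], int] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) >= 2:
                key, val = parts[0], parts[1]
                if key == "n_steps":
                    n_steps = int(val)
                else:
                    meta[key] = val
            continue
        m, r2, c = line.split("\t")
        counts[(int(m), int(r2))] = int(c)
    if n_steps is None:
        raise ValueError(f"{path}: missing '# n_steps' header")
    return CoefficientTable(n_steps=n_steps, counts=counts, metadata=meta)


def write_poly_json(poly: PolyPair, path) -> None:
    payload = {
        "n_steps": poly.n_steps,
        "z_coeffs": [str(c) for c in poly.z_coeffs],
        "r2_coeffs": [str(c) for c in poly.r2_coeffs],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_poly_json(path) -> PolyPair:
    payload = json.loads(Path(path).read_text())
    return PolyPair(
        n_steps=int(payload["n_steps"]),
        z_coeffs=tuple(int(c) for c in payload["z_coeffs"]),
        r2_coeffs=tuple(int(c) for c in payload["r2_coeffs"]),
    )


def write_series_csv(series_list, path) -> None:
    lines = ["parity,N,t_star,correction"]
    for s in series_list:
        for n, t in s.points:
            lines.append(f"{s.parity},{n},{t!r},{s.correction}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_series_csv(path) -> list[CrossingSeries]:
    rows = Path(path).read_text().splitlines()
    if not rows or rows[0] != "parity,N,t_star,correction":
        raise ValueError(f"{path}: not a crossing-series CSV")
    grouped: dict[tuple[str, str], list[tuple[int, float]]] = {}
    for row in rows[1:]:
        if not row.strip():
            continue
        parity, n, t, corr = row.split(",")
        grouped.setdefault((parity, corr), []).append((int(n), float(t)))
    return [
        CrossingSeries(parity=parity, points=sorted(pts), correction=corr)
        for (parity, corr), pts in grouped.items()
    ]


def write_scan_tsv(rows: list[ScanRow], path) -> None:
    lines = ["omega\tT_I\tT_II\tmean\terror"]
    for r in rows:
        lines.append(
            f"{r.omega:.4f}\t{r.t_odd:.4f}\t{r.t_even:.4f}"
            f"\t{r.mean:.4f}\t{r.combined_error:.5f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
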