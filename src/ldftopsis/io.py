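"""Reading and writing decision panels and pipeline traces.

JSON is the canonical interchange format::

    {
      "alternatives": ["A1", ...],
      "criteria": [{"label": "G1", "sense": "benefit"}, ...],
      "experts": [ [[mem, nonmem], ...], ... ],     # one n x m grid per expert
      "agg_weights": [...]                           # optional
    }

A cell is either a pair ``[mem, nonmem]`` (lifted with the configured default
reference parameters) or a quadruple ``[mem, nonmem, ref_mem, ref_nonmem]``.
The CSV dialect is a convenience: one file per expert, first column the
alternative label, header ``label:sense`` per criterion, and cells written as
``"mem,nonmem"`` or ``"mem,nonmem|ref_mem,ref_nonmem"``.  Writers emit full
precision so read/write round-trips are lossless; report rounding happens
only in the CLI renderer.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import IO, Sequence

from .ldfn import LDFN, ConstraintError, from_pair, make_ldfn
from .topsis import (
    DecisionMatrix,
    ExpertPanel,
    PipelineConfig,
    TopsisTrace,
)


class PanelFormatError(ValueError):
    """Malformed panel document; the message carries cell coordinates."""


def _parse_cell(raw, config: PipelineConfig, where: str) -> LDFN:
    try:
        values = [float(x) for x in raw]
    except (TypeError, ValueError) as exc:
        raise PanelFormatError(f"cell {where}: not a numeric sequence: {raw!r}") from exc
    try:
        if len(values) == 2:
            return from_pair(values[0], values[1], config.default_refs, config.q)
        if len(values) == 4:
            return make_ldfn(*values, config.q)
    except ConstraintError as exc:
        raise PanelFormatError(f"cell {where}: {exc}") from exc
    raise PanelFormatError(
        f"cell {where}: expected 2 or 4 components, got {len(values)}"
    )


def _panel_from_dict(doc: dict, config: PipelineConfig) -> ExpertPanel:
    for key in ("alternatives", "criteria", "experts"):
        if key not in doc:
            raise PanelFormatError(f"panel document missing {key!r}")
    alternatives = tuple(str(a) for a in doc["alternatives"])
    criteria = []
    for j, c in enumerate(doc["criteria"]):
        if not isinstance(c, dict) or "label" not in c or "sense" not in c:
            raise PanelFormatError(
                f"criterion {j + 1}: expected {{label, sense}}, got {c!r}"
            )
        if c["sense"] not in ("benefit", "cost"):
            raise PanelFormatError(
                f"criterion {c['label']!r}: sense must be benefit or cost, "
                f"got {c['sense']!r}"
            )
        criteria.append((str(c["label"]), c["sense"]))
    criteria = tuple(criteria)

    matrices = []
    for k, grid in enumerate(doc["experts"], start=1):
        if len(grid) != len(alternatives):
            raise PanelFormatError(
                f"expert {k}: {len(grid)} rows, expected {len(alternatives)}"
            )
        rows = []
        for i, row in enumerate(grid):
            if len(row) != len(criteria):
                raise PanelFormatError(
                    f"expert {k} row {alternatives[i]!r}: {len(row)} cells, "
                    f"expected {len(criteria)}"
                )
            rows.append(tuple(
                _parse_cell(
                    cell, config,
                    f"(expert {k}, {alternatives[i]}, {criteria[j][0]})",
                )
                for j, cell in enumerate(row)
            ))
        matrices.append(DecisionMatrix(alternatives, criteria, tuple(rows)))
    agg = doc.get("agg_weights")
    return ExpertPanel(tuple(matrices), tuple(agg) if agg is not None else None)


def _split_pair(text: str, where: str) -> list[float]:
    try:
        return [float(x) for x in text.split(",")]
    except ValueError as exc:
        raise PanelFormatError(f"cell {where}: unparseable {text!r}") from exc


def _matrix_from_csv(path: Path, config: PipelineConfig) -> DecisionMatrix:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 3:
        raise PanelFormatError(f"{path}: need a header and >= 2 alternative rows")
    header = rows[0][1:]
    criteria = []
    for j, item in enumerate(header):
        label, _, sense = item.partition(":")
        sense = sense or "benefit"
        if sense not in ("benefit", "cost"):
            raise PanelFormatError(f"{path}: column {j + 1} sense {sense!r} invalid")
        criteria.append((label, sense))
    alternatives, grid = [], []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(criteria) + 1:
            raise PanelFormatError(f"{path} line {i}: wrong number of columns")
        alternatives.append(row[0])
        cells = []
        for j, text in enumerate(row[1:]):
            where = f"({path.name}, {row[0]}, {criteria[j][0]})"
            if "|" in text:
                grades, refs = text.split("|", 1)
                values = _split_pair(grades, where) + _split_pair(refs, where)
            else:
                values = _split_pair(text, where)
            cells.append(_parse_cell(values, config, where))
        grid.append(tuple(cells))
    return DecisionMatrix(tuple(alternatives), tuple(criteria), tuple(grid))


def read_panel(
    source: str | Path | Sequence[str | Path] | IO[str],
    config: PipelineConfig | None = None,
) -> ExpertPanel:
    """Read an ExpertPanel from a JSON path/stream or a list of per-expert
    CSV paths.  Pair cells are lifted with ``config.default_refs``."""
    config = config or PipelineConfig()
    if isinstance(source, (list, tuple)):
        matrices = tuple(_matrix_from_csv(Path(p), config) for p in source)
        return ExpertPanel(matrices)
    if hasattr(source, "read"):
        return _panel_from_dict(json.load(source), config)
    path = Path(source)
    if path.suffix.lower() == ".csv":
        return ExpertPanel((_matrix_from_csv(path, config),))
    with open(path) as fh:
        return _panel_from_dict(json.load(fh), config)


def panel_to_dict(panel: ExpertPanel) -> dict:
    first = panel.matrices[0]
    doc = {
        "alternatives": list(first.alternatives),
        "criteria": [{"label": c, "sense": s} for c, s in first.criteria],
        "experts": [
            [[list(cell.as_tuple()) for cell in row] for row in mat.cells]
            for mat in panel.matrices
        ],
    }
    if panel.agg_weights is not None:
        doc["agg_weights"] = list(panel.agg_weights)
    return doc


def write_panel(panel: ExpertPanel, target: str | Path | IO[str]) -> None:
    """Write a panel as canonical JSON (always quadruple cells, full
    precision)."""
    doc = panel_to_dict(panel)
    if hasattr(target, "write"):
        json.dump(doc, target, indent=2)
    else:
        with open(target, "w") as fh:
            json.dump(doc, fh, indent=2)


def _matrix_to_lists(mat: DecisionMatrix | None):
    if mat is None:
        return None
    return [[list(cell.as_tuple()) for cell in row] for row in mat.cells]


def trace_to_dict(trace: TopsisTrace) -> dict:
    """Serialize every intermediate of a pipeline run as a named section."""
    first = trace.panel.matrices[0]
    cfg = trace.config
    return {
        "config": {
            "family": cfg.family, "lam": cfg.lam, "upsilon": cfg.upsilon,
            "q": cfg.q, "default_refs": list(cfg.default_refs),
            "strict_eq13": cfg.strict_eq13,
            "collective_phase3": cfg.collective_phase3,
        },
        "alternatives": list(first.alternatives),
        "criteria": [{"label": c, "sense": s} for c, s in first.criteria],
        "normalized": [_matrix_to_lists(m) for m in trace.normalized],
        "gdis": _matrix_to_lists(trace.gdis),
        "gris": _matrix_to_lists(trace.gris),
        "glis": _matrix_to_lists(trace.glis),
        "dgdis": trace.dgdis,
        "dgris": trace.dgris,
        "dglis": trace.dglis,
        "closeness_indices": trace.closeness_indices,
        "expert_weights": trace.expert_weights,
        "rgdis": _matrix_to_lists(trace.rgdis),
        "criterion_entropies": trace.criterion_entropies,
        "criterion_weights": trace.criterion_weights,
        "weighted_matrices": [_matrix_to_lists(m) for m in trace.weighted_matrices],
        "pis": [[list(c.as_tuple()) for c in row] for row in trace.pis],
        "nis": [[list(c.as_tuple()) for c in row] for row in trace.nis],
        "dis_plus": trace.dis_plus,
        "dis_minus": trace.dis_minus,
        "rci": trace.rci,
        "final_closeness": trace.final_closeness,
        "ranking": trace.ranking,
    }


def write_trace(trace: TopsisTrace, target: str | Path | IO[str]) -> None:
    """Write a full pipeline trace as JSON."""
    doc = trace_to_dict(trace)
    if hasattr(target, "write"):
        json.dump(doc, target, indent=2, sort_keys=True)
    else:
        with open(target, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
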