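"""Phase-space sweeps over the external parameter triplet (Nc, Np, Br).

Each grid cell runs the four-seed minimization of
:func:`bundlemech.minimize.enumerate_minima`; the cell is coloured by every
label whose minimum lies within 1% of the lowest energy (two labels = a
bistable, two-colour cell).  Cells are cached by a content hash of the full
parameter set, so interrupted or variant sweeps only recompute what changed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .minimize import MERGE_RTOL, enumerate_minima
from .model import ModelParams

__all__ = [
    "PhaseTable",
    "run_sweep",
    "write_phase_table",
    "read_phase_table",
    "default_grid",
    "internal_onset",
]

log = logging.getLogger(__name__)


def default_grid():
    """The survey grid: Nc in [0.5, 10] (20 steps), Np in [0, 0.4]
    (9 steps), Br in [1, 1e4] (7 log-spaced layers)."""
    return (
        np.linspace(0.5, 10.0, 20),
        np.linspace(0.0, 0.4, 9),
        np.logspace(0.0, 4.0, 7),
    )


@dataclass
class PhaseTable:
    """Rows of classified minima per (Nc, Np, Br) cell."""

    rows: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            rec = {"Nc": row["Nc"], "Np": row["Np"], "Br": row["Br"]}
            for k in (0, 1):
                rec[f"label{k + 1}"] = (
                    row["labels"][k] if k < len(row["labels"]) else ""
                )
                rec[f"energy{k + 1}"] = (
                    row["energies"][k] if k < len(row["energies"]) else np.nan
                )
            recs.append(rec)
        cols = ["Nc", "Np", "Br", "label1", "energy1", "label2", "energy2"]
        return pd.DataFrame(recs, columns=cols)

    def cell(self, Nc: float, Np: float, Br: float) -> dict | None:
        for row in self.rows:
            if (math.isclose(row["Nc"], Nc) and math.isclose(row["Np"], Np)
                    and math.isclose(row["Br"], Br)):
                return row
        return None

    def layer(self, Br: float) -> list[dict]:
        return [r for r in self.rows if math.isclose(r["Br"], Br)]


def _cell_minima(params: ModelParams, seed: int) -> dict:
    results = enumerate_minima(params, seed=seed)
    best = results[0][0].energy.total
    labels, energies = [], []
    for res, label in results:
        scale = max(abs(best), abs(res.energy.total), 1e-12)
        if abs(res.energy.total - best) < MERGE_RTOL * scale:
            if label not in labels:
                labels.append(label)
                energies.append(res.energy.total)
    return {"labels": labels, "energies": energies}


def run_sweep(base_params: ModelParams, Nc_values, Np_values, Br_values,
              seed: int = 0, cache_dir=None) -> PhaseTable:
    """Classify the energy minima on a (Nc, Np, Br) grid.

    Deterministic for fixed ``seed``.  Cell-level failures are recorded in
    the row (label "failed") rather than aborting the sweep.  With
    ``cache_dir`` set, finished cells are stored as JSON keyed by the
    parameter hash and reused on re-runs.
    """
    Nc_values = np.atleast_1d(np.asarray(Nc_values, dtype=float))
    Np_values = np.atleast_1d(np.asarray(Np_values, dtype=float))
    Br_values = np.atleast_1d(np.asarray(Br_values, dtype=float))
    if not (Nc_values.size and Np_values.size and Br_values.size):
        raise ValueError("grid must be non-empty along every axis")
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)

    table = PhaseTable()
    for Br in Br_values:
        for Np in Np_values:
            for Nc in Nc_values:
                params = base_params.replace(Nc=float(Nc), Np=float(Np),
                                             B_r=float(Br))
                key = f"{params.content_hash()}_{seed}"
                entry = None
                if cache is not None and (cache / f"{key}.json").exists():
                    entry = json.loads((cache / f"{key}.json").read_text())
                if entry is None:
                    try:
                        entry = _cell_minima(params, seed)
                    except Exception as exc:  # record, keep sweeping
                        log.error("cell (%.3g, %.3g, %.3g) failed: %s",
                                  Nc, Np, Br, exc)
                        entry = {"labels": ["failed"], "energies": [np.nan]}
                    if cache is not None:
                        (cache / f"{key}.json").write_text(json.dumps(entry))
                row = {"Nc": float(Nc), "Np": float(Np), "Br": float(Br)}
                row.update(entry)
                table.rows.append(row)
                log.info("cell (%.3g, %.3g, %.3g): %s",
                         Nc, Np, Br, entry["labels"])
    return table


def internal_onset(table: PhaseTable, Br: float, Np: float = 0.0) -> float:
    """Smallest Nc at which an internal minimum appears in a (Br, Np) row.

    Returns inf when no cell of the row carries the internal label.
    """
    onsets = [
        r["Nc"] for r in table.layer(Br)
        if math.isclose(r["Np"], Np) and "internal" in r["labels"]
    ]
    return min(onsets) if onsets else math.inf


def write_phase_table(table: PhaseTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_phase_table(path) -> PhaseTable:
    """Read a phase-table CSV back; malformed rows raise with a line number."""
    df = pd.read_csv(path)
    expected = ["Nc", "Np", "Br", "label1", "energy1", "label2", "energy2"]
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    table = PhaseTable()
    for lineno, rec in enumerate(df.to_dict("records"), start=2):
        try:
            labels = [rec["label1"]]
            energies = [float(rec["energy1"])]
            if isinstance(rec["label2"], str) and rec["label2"]:
                labels.append(rec["label2"])
                energies.append(float(rec["energy2"]))
            table.rows.append(
                {
                    "Nc": float(rec["Nc"]),
                    "Np": float(rec["Np"]),
                    "Br": float(rec["Br"]),
                    "labels": labels,
                    "energies": energies,
                }
            )
        except (TypeError, ValueError, KeyError) as exc:
            raise ValueError(f"{path}: malformed row at line {lineno}: {exc}")
    return table
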