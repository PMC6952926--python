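"""Manifest-driven batch analysis: curves in, per-curve and per-cell tables out."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import StageError
from .forcecurve import ForceCurve, read_force_curve
from .indentation import IndentConfig, analyze_indentation_cycle
from .scfs import SCFSConfig, analyze_retraction, summarize_cells
from .simulate import PopulationDataset


def _iter_curves(
    manifest: pd.DataFrame, curves: Optional[Sequence[ForceCurve]] = None
):
    for i, row in manifest.iterrows():
        if curves is not None:
            yield row, curves[i]
        else:
            yield row, read_force_curve(row["path"])


def analyze_indent_manifest(
    manifest: pd.DataFrame,
    curves: Optional[Sequence[ForceCurve]] = None,
    config: Optional[IndentConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyze every indentation cycle of a manifest.

    Returns (per-curve table, per-cell table).  ``curves`` may supply the
    in-memory objects of a :class:`PopulationDataset`; otherwise each row's
    ``path`` is read.  Curves whose analysis fails are recorded with the
    failing stage in the ``error`` column and excluded from per-cell means.
    """
    rows = []
    for row, curve in _iter_curves(manifest, curves):
        rec = {"cell_id": row["cell_id"], "group": row["group"],
               "repeat": row.get("repeat", 0)}
        try:
            res = analyze_indentation_cycle(curve, config)
            rec.update(
                E_Pa=res.young.E_Pa,
                eta=res.plasticity.eta,
                A1_J=res.plasticity.A1_J,
                A2_J=res.plasticity.A2_J,
                z0_m=res.contact.z0_m,
                r_squared=res.young.r_squared,
                qc=";".join(sorted(res.qc_flags)),
                error="",
            )
        except StageError as exc:
            rec.update(E_Pa=np.nan, eta=np.nan, A1_J=np.nan, A2_J=np.nan,
                       z0_m=np.nan, r_squared=np.nan, qc="", error=exc.stage)
        rows.append(rec)
    per_curve = pd.DataFrame(rows)
    ok = per_curve[per_curve["error"] == ""]
    per_cell = (
        ok.groupby(["cell_id", "group"], as_index=False)
        .agg(E_Pa=("E_Pa", "mean"), eta=("eta", "mean"),
             n_repeats=("E_Pa", "size"))
    )
    return per_curve, per_cell


def analyze_scfs_manifest(
    manifest: pd.DataFrame,
    curves: Optional[Sequence[ForceCurve]] = None,
    config: Optional[SCFSConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyze every SCFS retraction of a manifest; see indent counterpart."""
    rows = []
    for row, curve in _iter_curves(manifest, curves):
        rec = {"cell_id": row["cell_id"], "group": row["group"],
               "repeat": row.get("repeat", 0)}
        try:
            res = analyze_retraction(curve, config)
            n_rup = sum(ev.label == "rupture" for ev in res.events)
            rec.update(
                work_J=res.work_J,
                n_steps=len(res.events),
                n_ruptures=n_rup,
                rupture_ratio=res.rupture_ratio
                if res.rupture_ratio is not None
                else np.nan,
                error="",
            )
        except StageError as exc:
            rec.update(work_J=np.nan, n_steps=0, n_ruptures=0,
                       rupture_ratio=np.nan, error=exc.stage)
        rows.append(rec)
    per_curve = pd.DataFrame(rows)
    ok = per_curve[per_curve["error"] == ""].copy()
    per_cell = summarize_cells(ok.rename(columns={"group": "group"}))
    return per_curve, per_cell


def analyze_population(
    dataset: PopulationDataset,
    mode: str = "indent",
    config=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper running the matching manifest analysis in memory."""
    if mode == "indent":
        return analyze_indent_manifest(dataset.manifest, dataset.curves, config)
    return analyze_scfs_manifest(dataset.manifest, dataset.curves, config)
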