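"""Ligand-based virtual screening with a fitted or published model.

The pipeline computes the model's descriptors on every library entry,
predicts pIC50, ranks (descending activity, ties by id), applies a hit
threshold and optionally annotates each entry with its leverage
relative to the training descriptor block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import Molecule, SurfaceParams, parse_structures
from .descriptors import DescriptorMatrix, MODEL_DESCRIPTOR_DEFS, compute_matrix
from .model import LinearModel
from .validation import leverage_analysis

log = logging.getLogger(__name__)


@dataclass
class HitTable:
    """Ranked screening result.

    ``entries`` has one row per scored compound (library_id index,
    columns predicted_pic50 and rank, plus leverage/in_domain after AD
    annotation); ``hits`` is the slice at or above the threshold.
    """

    entries: pd.DataFrame
    threshold_pic50: float
    n_screened: int
    n_failed: int
    failed_ids: list[str]

    @property
    def hits(self) -> pd.DataFrame:
        return self.entries[self.entries["predicted_pic50"] >= self.threshold_pic50]

    @property
    def n_hits(self) -> int:
        return int(len(self.hits))

    def to_csv(self, path: str | Path) -> None:
        self.entries.to_csv(path, index_label="library_id")

    def summary(self) -> dict:
        return {
            "screened": self.n_screened,
            "scored": int(len(self.entries)),
            "failed": self.n_failed,
            "hits": self.n_hits,
            "threshold_pic50": self.threshold_pic50,
        }


def score_descriptors(
    matrix: DescriptorMatrix, model: LinearModel, threshold_pic50: float = 8.0
) -> HitTable:
    """Rank a precomputed descriptor matrix under a model."""
    pred = model.predict(matrix.data)
    entries = pd.DataFrame(
        {"predicted_pic50": pred}, index=matrix.data.index.astype(str)
    )
    entries = entries.sort_values(
        by="predicted_pic50", ascending=False, kind="mergesort"
    )
    # deterministic tie-break on library id
    entries = entries.iloc[
        np.lexsort((entries.index.to_numpy(), -entries["predicted_pic50"].to_numpy()))
    ]
    entries["rank"] = np.arange(1, len(entries) + 1)
    return HitTable(
        entries=entries,
        threshold_pic50=threshold_pic50,
        n_screened=len(entries),
        n_failed=0,
        failed_ids=[],
    )


def screen(
    library: str | Path | Sequence[Molecule],
    model: LinearModel,
    threshold_pic50: float = 8.0,
    *,
    surface_params: SurfaceParams | None = None,
    embed_seed: int = 42,
) -> HitTable:
    """Score a compound library and return the ranked hit table.

    ``library`` is a SMILES/SDF path or an iterable of prepared
    molecules.  Entries that fail parsing or descriptor computation are
    counted and listed, never silently dropped.
    """
    parse_failures: list[str] = []
    if isinstance(library, (str, Path)):
        mols, failures = parse_structures(library, embed_seed=embed_seed)
        parse_failures = [f.record_id for f in failures]
    else:
        mols = list(library)
    if not mols and not parse_failures:
        raise ValueError("empty screening library")
    matrix, desc_failures = compute_matrix(
        mols, MODEL_DESCRIPTOR_DEFS, params=surface_params
    )
    table = score_descriptors(matrix, model, threshold_pic50)
    failed = parse_failures + desc_failures
    table.n_screened = len(mols) + len(parse_failures)
    table.n_failed = len(failed)
    table.failed_ids = failed
    for fid in failed:
        log.warning("library entry %s failed and was excluded from ranking", fid)
    return table


def annotate_ad(
    table: HitTable, X_train: DescriptorMatrix | pd.DataFrame, model: LinearModel,
    library_matrix: DescriptorMatrix | None = None,
) -> HitTable:
    """Attach leverage and applicability-domain flags to scored entries.

    Requires the library descriptor matrix used for scoring (or a
    matrix covering the same ids) together with the training block that
    defines h* = 3(p+1)/n_train.
    """
    if library_matrix is None:
        raise ValueError("library_matrix with the entries' descriptors is required")
    lib = library_matrix.data.loc[[str(i) for i in table.entries.index]]
    report = leverage_analysis(model, X_train, lib)
    table.entries = table.entries.assign(
        leverage=report.leverages, in_domain=report.in_domain
    )
    return table


def screen_with_ad(
    library: str | Path | Sequence[Molecule],
    model: LinearModel,
    X_train: DescriptorMatrix | pd.DataFrame,
    threshold_pic50: float = 8.0,
    *,
    surface_params: SurfaceParams | None = None,
    embed_seed: int = 42,
) -> HitTable:
    """Screen a library and annotate every scored entry with leverage."""
    parse_failures: list[str] = []
    if isinstance(library, (str, Path)):
        mols, failures = parse_structures(library, embed_seed=embed_seed)
        parse_failures = [f.record_id for f in failures]
    else:
        mols = list(library)
    matrix, desc_failures = compute_matrix(
        mols, MODEL_DESCRIPTOR_DEFS, params=surface_params
    )
    table = score_descriptors(matrix, model, threshold_pic50)
    table.n_screened = len(mols) + len(parse_failures)
    table.failed_ids = parse_failures + desc_failures
    table.n_failed = len(table.failed_ids)
    return annotate_ad(table, X_train, model, library_matrix=matrix)
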