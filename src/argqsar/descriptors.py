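"""Molecular descriptors, the descriptor matrix, and objective feature
selection.

The six model descriptors are all built from two primitives:

* graph pair counts — the number of unordered atom pairs, one from a
  source category and one from a target category, separated by an exact
  shortest-path distance in bonds (``fringNdon3B``, ``fsp2OC9B``,
  ``fHringC2B``, ``fringCC3B``);
* geometry — the surface-area ratio ``rsa`` = MSA/SASA and the count of
  lipophilic hydrogens within 3 Å of the centre of mass
  (``com_lipohyd_3A``).

``ofs_prune`` implements activity-blind (objective) feature selection:
constant, near-constant and highly intercorrelated columns are removed
before any model is fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import (
    Molecule,
    SurfaceParams,
    bond_distance_matrix,
    center_of_mass,
    surface_areas,
)

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Atom categories

ATOM_CATEGORIES: dict[str, Callable] = {
    "carbon": lambda a: a.element == "C",
    "hydrogen": lambda a: a.element == "H",
    "nitrogen": lambda a: a.element == "N",
    "oxygen": lambda a: a.element == "O",
    "ring-carbon": lambda a: a.is_ring_carbon,
    "ring-nitrogen": lambda a: a.is_ring_nitrogen,
    "donor": lambda a: a.is_donor,
    "sp2-oxygen": lambda a: a.is_sp2_oxygen,
    "lipophilic-hydrogen": lambda a: a.is_lipophilic_hydrogen,
}


def category_members(mol: Molecule, category: str) -> list[int]:
    try:
        pred = ATOM_CATEGORIES[category]
    except KeyError:
        raise ValueError(f"unknown atom category {category!r}") from None
    return [a.index for a in mol.atoms if pred(a)]


# ---------------------------------------------------------------------------
# Descriptor definitions


@dataclass(frozen=True)
class DescriptorDef:
    """Declarative definition of one descriptor.

    kind
        ``ratio`` (surface-area ratio), ``com_shell_count`` (atoms of
        ``source_type`` within ``distance`` Å of the centre of mass) or
        ``pair_count_at_distance`` (graph pair count at exactly
        ``distance`` bonds).
    exclusion
        Optional rule name; ``"other_oxygen_same_distance"`` drops a
        carbon that also sits at the same bond distance from a second
        oxygen atom (the published reading of the fsp2OC9B count).
    """

    name: str
    kind: str
    source_type: str | None = None
    target_type: str | None = None
    distance: float | None = None
    exclusion: str | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.kind in ("com_shell_count", "pair_count_at_distance"):
            if self.distance is None or self.distance <= 0:
                raise ValueError(f"{self.name}: distance must be positive")


MODEL_DESCRIPTOR_DEFS: tuple[DescriptorDef, ...] = (
    DescriptorDef(
        "rsa", "ratio", notes="molecular surface area / solvent-accessible area"
    ),
    DescriptorDef(
        "com_lipohyd_3A",
        "com_shell_count",
        source_type="lipophilic-hydrogen",
        distance=3.0,
        notes="lipophilic hydrogens (|q| <= 0.2) within 3 Å of the centre of mass",
    ),
    DescriptorDef(
        "fringNdon3B",
        "pair_count_at_distance",
        source_type="ring-nitrogen",
        target_type="donor",
        distance=3,
        notes="donor atoms exactly 3 bonds from a ring nitrogen",
    ),
    DescriptorDef(
        "fsp2OC9B",
        "pair_count_at_distance",
        source_type="sp2-oxygen",
        target_type="carbon",
        distance=9,
        exclusion="other_oxygen_same_distance",
        notes="carbons exactly 9 bonds from an sp2 oxygen",
    ),
    DescriptorDef(
        "fHringC2B",
        "pair_count_at_distance",
        source_type="hydrogen",
        target_type="ring-carbon",
        distance=2,
        notes="ring carbons exactly 2 bonds from a hydrogen",
    ),
    DescriptorDef(
        "fringCC3B",
        "pair_count_at_distance",
        source_type="ring-carbon",
        target_type="carbon",
        distance=3,
        notes="carbons exactly 3 bonds from a ring carbon",
    ),
)

MODEL_DESCRIPTOR_NAMES: tuple[str, ...] = tuple(d.name for d in MODEL_DESCRIPTOR_DEFS)


def extended_pool() -> list[DescriptorDef]:
    """A generalized pool of same-family descriptors.

    Covers pair counts over category/distance combinations plus
    centre-of-mass shell counts; this emulates a large automatic
    descriptor catalogue at a size the feature-selection machinery can
    exercise.
    """
    defs: list[DescriptorDef] = [d for d in MODEL_DESCRIPTOR_DEFS]
    sources = ["ring-carbon", "ring-nitrogen", "sp2-oxygen", "donor", "hydrogen"]
    targets = ["carbon", "hydrogen", "donor", "ring-carbon"]
    seen = {d.name for d in defs}
    for s in sources:
        for t in targets:
            if s == t:
                continue
            for k in range(2, 10):
                name = f"f[{s}][{t}]{k}B"
                if name in seen:
                    continue
                defs.append(
                    DescriptorDef(
                        name, "pair_count_at_distance",
                        source_type=s, target_type=t, distance=k,
                    )
                )
                seen.add(name)
    for cat in ("lipophilic-hydrogen", "donor", "carbon"):
        for r in (2.0, 3.0, 4.0):
            name = f"com[{cat}]{r:g}A"
            if name not in seen:
                defs.append(
                    DescriptorDef(name, "com_shell_count", source_type=cat, distance=r)
                )
                seen.add(name)
    return defs


# ---------------------------------------------------------------------------
# Descriptor primitives


def rsa(msa: float, sasa: float) -> float:
    """Ratio of molecular (van der Waals) to solvent-accessible surface
    area."""
    if sasa <= 0:
        raise ValueError("sasa must be positive")
    if msa < 0:
        raise ValueError("msa must be non-negative")
    return msa / sasa


def rsa_of(mol: Molecule, params: SurfaceParams | None = None) -> float:
    msa, sasa = surface_areas(mol, params)
    return rsa(msa, sasa)


def com_shell_count(mol: Molecule, category: str, radius: float) -> int:
    """Atoms of a category within ``radius`` Å of the centre of mass."""
    members = category_members(mol, category)
    if not members:
        return 0
    com = center_of_mass(mol)
    coords = mol.coords[members]
    return int(np.count_nonzero(np.linalg.norm(coords - com, axis=1) <= radius))


def com_lipohyd_3A(mol: Molecule) -> int:
    """Lipophilic hydrogens (|q| <= 0.200) within 3 Å of the centre of
    mass."""
    return com_shell_count(mol, "lipophilic-hydrogen", 3.0)


def pair_count_at_distance(
    mol: Molecule,
    source: str,
    target: str,
    k: int,
    *,
    dist_matrix: np.ndarray | None = None,
    exclusion: str | None = None,
    counting_mode: str = "pairs",
) -> int:
    """Count qualifying (source-category, target-category) atom pairs at
    an exact shortest-path distance of ``k`` bonds.

    ``counting_mode="pairs"`` counts each unordered pair once (the
    default reading of "frequency of occurrence");
    ``counting_mode="targets"`` counts distinct target atoms that see at
    least one source at distance k.
    """
    if dist_matrix is None:
        dist_matrix = bond_distance_matrix(mol)
    src = set(category_members(mol, source))
    tgt = set(category_members(mol, target))
    if not src or not tgt:
        return 0

    def excluded(t_idx: int, s_idx: int) -> bool:
        if exclusion is None:
            return False
        if exclusion == "other_oxygen_same_distance":
            for o in category_members(mol, "oxygen"):
                if o != s_idx and dist_matrix[o, t_idx] == k:
                    return True
            return False
        raise ValueError(f"unknown exclusion rule {exclusion!r}")

    if counting_mode == "pairs":
        count = 0
        n = mol.n_atoms
        for a in range(n):
            for b in range(a + 1, n):
                if dist_matrix[a, b] != k:
                    continue
                if (a in src and b in tgt and not excluded(b, a)) or (
                    b in src and a in tgt and not excluded(a, b)
                ):
                    count += 1
        return count
    if counting_mode == "targets":
        hit = set()
        for t in tgt:
            for s in src:
                if s != t and dist_matrix[s, t] == k and not excluded(t, s):
                    hit.add(t)
                    break
        return len(hit)
    raise ValueError(f"unknown counting_mode {counting_mode!r}")


def fringNdon3B(mol: Molecule, dist_matrix: np.ndarray | None = None) -> int:
    return pair_count_at_distance(
        mol, "ring-nitrogen", "donor", 3, dist_matrix=dist_matrix
    )


def fsp2OC9B(
    mol: Molecule,
    dist_matrix: np.ndarray | None = None,
    apply_exclusion: bool = True,
) -> int:
    return pair_count_at_distance(
        mol,
        "sp2-oxygen",
        "carbon",
        9,
        dist_matrix=dist_matrix,
        exclusion="other_oxygen_same_distance" if apply_exclusion else None,
    )


def fHringC2B(mol: Molecule, dist_matrix: np.ndarray | None = None) -> int:
    return pair_count_at_distance(
        mol, "hydrogen", "ring-carbon", 2, dist_matrix=dist_matrix
    )


def fringCC3B(mol: Molecule, dist_matrix: np.ndarray | None = None) -> int:
    return pair_count_at_distance(
        mol, "ring-carbon", "carbon", 3, dist_matrix=dist_matrix
    )


def evaluate_descriptor(
    mol: Molecule,
    ddef: DescriptorDef,
    *,
    params: SurfaceParams | None = None,
    dist_matrix: np.ndarray | None = None,
) -> float:
    if ddef.kind == "ratio":
        return rsa_of(mol, params)
    if ddef.kind == "com_shell_count":
        return float(com_shell_count(mol, ddef.source_type, ddef.distance))
    if ddef.kind == "pair_count_at_distance":
        return float(
            pair_count_at_distance(
                mol,
                ddef.source_type,
                ddef.target_type,
                int(ddef.distance),
                dist_matrix=dist_matrix,
                exclusion=ddef.exclusion,
            )
        )
    raise ValueError(f"unknown descriptor kind {ddef.kind!r}")


# ---------------------------------------------------------------------------
# Descriptor matrix


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors, with optional pIC50 activity."""

    data: pd.DataFrame
    activity: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.activity is not None:
            self.activity = self.activity.reindex(self.data.index)
            if self.activity.isna().any():
                missing = list(self.activity[self.activity.isna()].index)
                raise ValueError(f"activity missing for compounds {missing}")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, names: Sequence[str]) -> "DescriptorMatrix":
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"descriptors not in matrix: {missing}")
        return DescriptorMatrix(self.data[list(names)].copy(), self.activity)

    def to_csv(self, path: str | Path) -> None:
        df = self.data.copy()
        if self.activity is not None:
            df["pIC50"] = self.activity
        df.to_csv(path, index_label="compound_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorMatrix":
        df = pd.read_csv(path, index_col="compound_id")
        activity = None
        if "pIC50" in df.columns:
            activity = df.pop("pIC50")
        return cls(df, activity)


def compute_matrix(
    mols: Sequence[Molecule],
    defs: Sequence[DescriptorDef] = MODEL_DESCRIPTOR_DEFS,
    *,
    params: SurfaceParams | None = None,
) -> tuple[DescriptorMatrix, list[str]]:
    """Descriptor matrix over a set of prepared molecules.

    Molecules whose descriptor computation fails are excluded from the
    matrix and returned as a list of ids (never silently dropped).
    """
    rows: dict[str, list[float]] = {}
    activities: dict[str, float] = {}
    failed: list[str] = []
    for mol in mols:
        try:
            dm = bond_distance_matrix(mol)
            rows[mol.id] = [
                evaluate_descriptor(mol, d, params=params, dist_matrix=dm)
                for d in defs
            ]
            if mol.pic50 is not None:
                activities[mol.id] = mol.pic50
        except Exception as exc:  # noqa: BLE001 - per-molecule isolation
            log.warning("descriptor computation failed for %s: %s", mol.id, exc)
            failed.append(mol.id)
    if not rows:
        raise ValueError("descriptor computation failed for every molecule")
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[d.name for d in defs]
    )
    activity = (
        pd.Series(activities).reindex(df.index)
        if len(activities) == len(rows)
        else None
    )
    return DescriptorMatrix(df, activity), failed


# ---------------------------------------------------------------------------
# Objective feature selection


def ofs_prune(
    m: DescriptorMatrix,
    corr_cutoff: float = 0.90,
    near_constant_frac: float = 0.95,
) -> DescriptorMatrix:
    """Activity-blind pruning: drop constant columns, near-constant
    columns (>= ``near_constant_frac`` identical values) and, from each
    pair with |Pearson r| > ``corr_cutoff``, all but one column.

    Of a correlated pair the column more correlated with activity is
    kept when activity is available, otherwise the earlier column.
    Idempotent: pruning an already-pruned matrix changes nothing.
    """
    if len(m.data) < 2:
        raise ValueError("need at least 2 compounds to prune")
    df = m.data.copy()
    keep = []
    for col in df.columns:
        top_frac = df[col].value_counts(normalize=True).iloc[0]
        if df[col].nunique() <= 1 or top_frac >= near_constant_frac:
            continue
        keep.append(col)
    df = df[keep]
    if df.shape[1] == 0:
        raise ValueError("all descriptor columns pruned as (near-)constant")

    corr = df.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    cols = list(df.columns)
    if m.activity is not None:
        y = m.activity.to_numpy(dtype=float)
        act_corr = {
            c: abs(np.corrcoef(df[c].to_numpy(dtype=float), y)[0, 1]) for c in cols
        }
    else:
        act_corr = None

    alive = np.ones(len(cols), dtype=bool)
    while True:
        masked = np.where(np.outer(alive, alive), corr, 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= corr_cutoff:
            break
        a, b = min(i, j), max(i, j)
        if act_corr is not None and act_corr[cols[b]] > act_corr[cols[a]]:
            alive[a] = False
        else:
            alive[b] = False
    survivors = [c for c, ok in zip(cols, alive) if ok]
    if not survivors:
        raise ValueError("all descriptor columns pruned")
    return DescriptorMatrix(df[survivors].copy(), m.activity)


def correlation_matrix(
    m: DescriptorMatrix, names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation matrix over (a subset of) descriptors."""
    df = m.data if names is None else m.subset(names).data
    if len(df) < 3:
        raise ValueError("need at least 3 compounds")
    std = df.std(ddof=0)
    zero_var = list(std[std == 0].index)
    if zero_var:
        raise ValueError(f"zero-variance descriptor columns: {zero_var}")
    return df.corr()
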