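"""JUMP-MOA-style plate maps.

A JUMP-MOA plate is a 384-well positive-control layout carrying 90 compounds
drawn from 47 mechanism-of-action (MOA) classes, with 4 replicate wells per
compound; most MOA classes contribute a pair of compounds, which is what makes
MOA-matching statistics computable from a single plate.  This module models,
generates, reads, writes and validates such layouts.  Compound identities are
synthetic (``C001`` ...): only the census structure matters downstream.
"""

from __future__ import annotations

import dataclasses
import re
import string
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PlateError",
    "LayoutError",
    "PlateMapError",
    "PlateMap",
    "CONTROL_COMPOUND",
    "PLATEMAP_COLUMNS",
    "well_label",
    "parse_well",
    "all_wells",
    "generate_jumpmoa_layout",
    "read_platemap",
    "write_platemap",
]

CONTROL_COMPOUND = "DMSO"
ROLE_TREATMENT = "treatment"
ROLE_CONTROL = "negative_control"
PLATEMAP_COLUMNS = ("well_position", "compound_id", "moa", "concentration_uM", "role")

_WELL_RE = re.compile(r"^([A-Z])(\d{2})$")


class PlateError(ValueError):
    """Base class for plate-layout errors."""


class LayoutError(PlateError):
    """Requested layout cannot be realized on the plate."""


class PlateMapError(PlateError):
    """A plate-map file or table violates the plate-map contract.

    Carries the full list of violations so callers can report every problem
    in a file at once.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


def well_label(row: int, col: int) -> str:
    """Canonical well label for 0-based ``row`` and ``col`` (e.g. (0, 0) -> "A01")."""
    return f"{string.ascii_uppercase[row]}{col + 1:02d}"


def parse_well(label: str, plate_dims: tuple[int, int] = (16, 24)) -> tuple[int, int]:
    """Parse a well label into 0-based (row, col); raises PlateError if invalid."""
    m = _WELL_RE.match(str(label).strip().upper())
    if m is None:
        raise PlateError(f"unparseable well address {label!r}")
    row = string.ascii_uppercase.index(m.group(1))
    col = int(m.group(2)) - 1
    n_rows, n_cols = plate_dims
    if row >= n_rows or not (0 <= col < n_cols):
        raise PlateError(
            f"well address {label!r} outside the {n_rows}x{n_cols} plate"
        )
    return row, col


def all_wells(plate_dims: tuple[int, int] = (16, 24)) -> list[str]:
    """All well labels in row-major order (A01, A02, ..., P24 for 16x24)."""
    n_rows, n_cols = plate_dims
    return [well_label(r, c) for r in range(n_rows) for c in range(n_cols)]


@dataclasses.dataclass
class PlateMap:
    """Per-well assignment of compound, MOA class and role.

    Parameters
    ----------
    plate_id : str
        Identifier propagated into ``Metadata_Plate`` of simulated tables.
    wells : pandas.DataFrame
        Indexed by well label, with columns ``compound_id``, ``moa``,
        ``concentration_uM``, ``role``.  Negative-control wells carry the
        control sentinel compound and a missing MOA.
    plate_dims : (n_rows, n_cols)
    """

    plate_id: str
    wells: pd.DataFrame
    plate_dims: tuple[int, int] = (16, 24)

    def __post_init__(self) -> None:
        violations = []
        missing = [c for c in PLATEMAP_COLUMNS[1:] if c not in self.wells.columns]
        if missing:
            violations.append(f"missing columns: {missing}")
        dup = self.wells.index[self.wells.index.duplicated()].unique().tolist()
        if dup:
            violations.append(f"duplicate wells: {dup}")
        for w in self.wells.index:
            try:
                parse_well(w, self.plate_dims)
            except PlateError as exc:
                violations.append(str(exc))
        if violations:
            raise PlateMapError(violations)

    # -- census -----------------------------------------------------------
    @property
    def treatments(self) -> pd.DataFrame:
        return self.wells[self.wells["role"] == ROLE_TREATMENT]

    @property
    def controls(self) -> pd.DataFrame:
        return self.wells[self.wells["role"] == ROLE_CONTROL]

    @property
    def compounds(self) -> list[str]:
        return sorted(self.treatments["compound_id"].unique())

    @property
    def moa_classes(self) -> list[str]:
        return sorted(self.treatments["moa"].dropna().unique())

    def replicate_wells(self) -> dict[str, list[str]]:
        """compound -> sorted list of its treatment wells."""
        grp = self.treatments.groupby("compound_id").groups
        return {c: sorted(ix) for c, ix in grp.items()}

    def moa_compounds(self) -> dict[str, list[str]]:
        """MOA class -> sorted list of distinct compounds annotated with it."""
        grp = self.treatments.groupby("moa")["compound_id"].unique()
        return {m: sorted(v) for m, v in grp.items()}

    def compound_moa(self) -> dict[str, str]:
        return (
            self.treatments.drop_duplicates("compound_id")
            .set_index("compound_id")["moa"]
            .to_dict()
        )

    # -- validation -------------------------------------------------------
    def validate(
        self,
        n_compounds: int | None = None,
        n_moa: int | None = None,
        replicates: int | None = None,
    ) -> None:
        """Check census invariants; raises PlateMapError listing all violations."""
        violations = []
        counts = self.treatments["compound_id"].value_counts()
        if replicates is not None:
            bad = counts[counts != replicates]
            if len(bad):
                violations.append(
                    f"compounds without exactly {replicates} wells: "
                    f"{bad.to_dict()}"
                )
        if n_compounds is not None and len(counts) != n_compounds:
            violations.append(
                f"expected {n_compounds} compounds, found {len(counts)}"
            )
        if n_moa is not None and len(self.moa_classes) != n_moa:
            violations.append(
                f"expected {n_moa} MOA classes, found {len(self.moa_classes)}"
            )
        if self.treatments["moa"].isna().any():
            violations.append("treatment wells with missing MOA")
        if self.controls["moa"].notna().any():
            violations.append("negative-control wells must have no MOA")
        if violations:
            raise PlateMapError(violations)

    def equals(self, other: "PlateMap") -> bool:
        return (
            self.plate_id == other.plate_id
            and self.plate_dims == other.plate_dims
            and self.wells.sort_index().equals(other.wells.sort_index())
        )


def _default_multiplicity(n_compounds: int, n_moa: int) -> dict[int, int]:
    # x classes of 2 compounds + y singletons with 2x + y = n_compounds,
    # x + y = n_moa; for the defaults (90, 47) this is 43 pairs + 4 singletons.
    pairs = n_compounds - n_moa
    singles = 2 * n_moa - n_compounds
    if pairs < 0 or singles < 0:
        raise LayoutError(
            f"cannot build a pair/singleton split for {n_compounds} compounds "
            f"over {n_moa} MOA classes; pass moa_multiplicity explicitly"
        )
    out: dict[int, int] = {}
    if pairs:
        out[2] = pairs
    if singles:
        out[1] = singles
    return out


def generate_jumpmoa_layout(
    n_compounds: int = 90,
    n_moa: int = 47,
    replicates: int = 4,
    moa_multiplicity: Mapping[int, int] | None = None,
    seed: int = 0,
    plate_dims: tuple[int, int] = (16, 24),
    concentration_um: float = 3.0,
    plate_id: str | None = None,
) -> PlateMap:
    """Generate a randomized JUMP-MOA-style layout.

    ``moa_multiplicity`` maps MOA-class size (compounds per class) to the number
    of classes of that size; the default splits the compounds into 2-compound
    classes plus singletons (43 + 4 for the 90/47 defaults).  Treatment wells
    are placed by a seeded random permutation of the plate; the leftover wells
    become negative controls (control sentinel compound, no MOA, 0 uM).

    Deterministic for a fixed seed.
    """
    n_rows, n_cols = plate_dims
    plate_size = n_rows * n_cols
    n_treatment = n_compounds * replicates
    if n_treatment > plate_size:
        raise LayoutError(
            f"{n_compounds} compounds x {replicates} replicates = {n_treatment} "
            f"wells exceed the {plate_size}-well plate"
        )
    if moa_multiplicity is None:
        moa_multiplicity = _default_multiplicity(n_compounds, n_moa)
    total_compounds = sum(size * count for size, count in moa_multiplicity.items())
    total_moa = sum(moa_multiplicity.values())
    if total_compounds != n_compounds or total_moa != n_moa:
        raise LayoutError(
            f"moa_multiplicity covers {total_compounds} compounds / {total_moa} "
            f"classes, expected {n_compounds} / {n_moa}"
        )

    width = max(3, len(str(n_compounds)))
    moa_width = max(3, len(str(n_moa)))
    compounds, moas = [], []
    c_idx = m_idx = 0
    for size in sorted(moa_multiplicity, reverse=True):
        for _ in range(moa_multiplicity[size]):
            m_idx += 1
            moa = f"MOA{m_idx:0{moa_width}d}"
            for _ in range(size):
                c_idx += 1
                compounds.append(f"C{c_idx:0{width}d}")
                moas.append(moa)

    rng = np.random.default_rng(seed)
    wells = all_wells(plate_dims)
    perm = rng.permutation(plate_size)
    records = []
    slot = 0
    for comp, moa in zip(compounds, moas):
        for _ in range(replicates):
            records.append(
                (wells[perm[slot]], comp, moa, concentration_um, ROLE_TREATMENT)
            )
            slot += 1
    # leftover positions, in permutation order, become negative controls
    for p in perm[slot:]:
        records.append((wells[p], CONTROL_COMPOUND, np.nan, 0.0, ROLE_CONTROL))

    df = (
        pd.DataFrame(records, columns=list(PLATEMAP_COLUMNS))
        .set_index("well_position")
        .sort_index()
    )
    if plate_id is None:
        plate_id = f"JUMPMOA-sim-{seed}"
    pm = PlateMap(plate_id=plate_id, wells=df, plate_dims=plate_dims)
    pm.validate(n_compounds=n_compounds, n_moa=n_moa, replicates=replicates)
    return pm


def write_platemap(platemap: PlateMap, path: str | Path) -> Path:
    """Write a plate map as UTF-8 CSV with the canonical header."""
    path = Path(path)
    platemap.wells.reset_index().to_csv(path, index=False)
    return path


def read_platemap(
    path: str | Path,
    plate_id: str | None = None,
    plate_dims: tuple[int, int] = (16, 24),
) -> PlateMap:
    """Read and validate a plate-map CSV; reports all violations at once."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"compound_id": str, "moa": str, "role": str})
    violations = []
    missing = [c for c in PLATEMAP_COLUMNS if c not in df.columns]
    if missing:
        raise PlateMapError([f"missing columns: {missing}"])
    dup = df["well_position"][df["well_position"].duplicated()].unique().tolist()
    if dup:
        violations.append(f"duplicate wells: {dup}")
    for i, w in enumerate(df["well_position"]):
        try:
            parse_well(w, plate_dims)
        except PlateError as exc:
            violations.append(f"row {i}: {exc}")
    if violations:
        raise PlateMapError(violations)
    wells = df.set_index("well_position")
    wells["concentration_uM"] = wells["concentration_uM"].astype(float)
    if plate_id is None:
        plate_id = path.stem
    return PlateMap(plate_id=plate_id, wells=wells, plate_dims=plate_dims)
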