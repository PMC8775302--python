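"""Domain types and tabular I/O for covered-codend haul data.

A selectivity experiment with the (dual) covered-codend method yields, per
haul and 1-cm length class, the number of fish measured in the codend (CD),
the codend cover (CC) and — when the gear carries a square mesh panel (SMP) —
the panel cover (PC).  Fish are measured to the nearest centimetre below, so
a length-class label is the lower bound of a 1-cm bin: a fish recorded as
27 belongs to [27, 28) cm.  When the catch is subsampled, each compartment
carries a subsampling factor ``q`` in (0, 1] (ratio of length-measured to
total fish); counts are raised by ``1/q`` before pooling.

The canonical CSV schema is::

    haul_id, length_cm, n_CD, n_CC, [n_PC], q_CD, q_CC, [q_PC]

PC columns are present only for gears with an SMP.  Duplicate
(haul, length) rows are summed, which tolerates concatenated field sheets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COMPARTMENTS",
    "CSV_COLUMNS",
    "SchemaError",
    "ValidationError",
    "HaulRecord",
    "SelectivityDataset",
    "GearDesignLabel",
    "ALL_DESIGNS",
    "read_dataset",
    "write_dataset",
    "apply_length_filters",
    "raise_counts",
    "pool_over_hauls",
]

#: Compartments of the dual-cover design, in canonical order.
COMPARTMENTS = ("CD", "CC", "PC")

CSV_COLUMNS = ("haul_id", "length_cm", "n_CD", "n_CC", "n_PC", "q_CD", "q_CC", "q_PC")


class ValidationError(ValueError):
    """Raised when haul data violate a structural invariant."""


class SchemaError(ValidationError):
    """Raised when an input table lacks required columns."""


@dataclass(frozen=True, eq=False)
class HaulRecord:
    """One haul's measured counts per compartment and 1-cm length class.

    Parameters
    ----------
    haul_id:
        Identifier of the haul (the between-haul bootstrap resampling unit).
    lengths:
        Sorted, unique integer lower bounds of the 1-cm length classes.
    counts:
        Mapping compartment -> array of measured counts aligned with
        ``lengths``.  ``CD`` and ``CC`` are required; ``PC`` is present only
        for gears with an SMP.
    q:
        Mapping compartment -> subsampling factor in (0, 1].
    """

    haul_id: str
    lengths: np.ndarray
    counts: dict[str, np.ndarray]
    q: dict[str, float]

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=int)
        if lengths.ndim != 1:
            raise ValidationError("lengths must be one-dimensional")
        if lengths.size and lengths.min() < 0:
            raise ValidationError("length-class labels must be >= 0")
        if np.any(np.diff(lengths) <= 0):
            raise ValidationError("lengths must be sorted and unique")
        object.__setattr__(self, "lengths", lengths)

        comps = set(self.counts)
        if not {"CD", "CC"} <= comps:
            raise ValidationError(f"haul {self.haul_id!r}: CD and CC counts required")
        if not comps <= set(COMPARTMENTS):
            raise ValidationError(f"haul {self.haul_id!r}: unknown compartments {comps - set(COMPARTMENTS)}")
        clean: dict[str, np.ndarray] = {}
        for comp, arr in self.counts.items():
            a = np.asarray(arr, dtype=float)
            if a.shape != lengths.shape:
                raise ValidationError(f"haul {self.haul_id!r}: {comp} counts misaligned with lengths")
            if not np.all(np.isfinite(a)) or np.any(a < 0):
                raise ValidationError(f"haul {self.haul_id!r}: negative or non-finite {comp} count")
            clean[comp] = a
        object.__setattr__(self, "counts", clean)

        if set(self.q) != comps:
            raise ValidationError(f"haul {self.haul_id!r}: q must be given for exactly the compartments present")
        for comp, qv in self.q.items():
            qv = float(qv)
            if not (0.0 < qv <= 1.0):
                raise ValidationError(f"haul {self.haul_id!r}: q_{comp}={qv} outside (0, 1]")

    @property
    def has_pc(self) -> bool:
        return "PC" in self.counts

    @property
    def compartments(self) -> tuple[str, ...]:
        return tuple(c for c in COMPARTMENTS if c in self.counts)

    def raised(self, comp: str) -> np.ndarray:
        """Counts raised by the compartment's subsampling factor."""
        return self.counts[comp] / self.q[comp]

    def total_measured(self, comp: str) -> float:
        return float(self.counts[comp].sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaulRecord):
            return NotImplemented
        return (
            self.haul_id == other.haul_id
            and np.array_equal(self.lengths, other.lengths)
            and set(self.counts) == set(other.counts)
            and all(np.array_equal(self.counts[c], other.counts[c]) for c in self.counts)
            and all(self.q[c] == other.q[c] for c in self.counts)
        )


@dataclass(frozen=True, eq=False)
class SelectivityDataset:
    """An ordered collection of hauls for one gear design and species."""

    hauls: tuple[HaulRecord, ...]
    gear_label: str | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        hauls = tuple(self.hauls)
        if not hauls:
            raise ValidationError("a dataset needs at least one haul")
        pc = hauls[0].has_pc
        if any(h.has_pc != pc for h in hauls):
            raise ValidationError("all hauls must share the compartment scheme (with/without PC)")
        if len({h.haul_id for h in hauls}) != len(hauls):
            raise ValidationError("duplicate haul_id in dataset")
        object.__setattr__(self, "hauls", hauls)

    @property
    def has_pc(self) -> bool:
        return self.hauls[0].has_pc

    @property
    def n_hauls(self) -> int:
        return len(self.hauls)

    @property
    def compartments(self) -> tuple[str, ...]:
        return self.hauls[0].compartments

    def length_grid(self) -> np.ndarray:
        """Sorted union of length classes present across hauls."""
        return np.unique(np.concatenate([h.lengths for h in self.hauls]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SelectivityDataset):
            return NotImplemented
        return (
            self.gear_label == other.gear_label
            and self.species == other.species
            and len(self.hauls) == len(other.hauls)
            and all(a == b for a, b in zip(self.hauls, other.hauls))
        )


# ---------------------------------------------------------------------------
# Gear design labels

_SMP_CODES = ("SMP_TS", "SMP_TL", "SMP_BS", "SMP_BL", "NONE")
_CODEND_CODES = ("CD_D", "CD_S")


@dataclass(frozen=True, order=True)
class GearDesignLabel:
    """A gear design: one SMP option combined with one codend option.

    SMP options are a small/large panel (S/L) at the top/bottom of the
    extension piece (T/B), or no panel at all; codends are diamond-mesh
    (CD_D) or square-mesh (CD_S).  The full cross gives ten designs.
    """

    smp: str
    codend: str

    def __post_init__(self) -> None:
        if self.smp not in _SMP_CODES:
            raise ValidationError(f"unknown SMP code {self.smp!r}")
        if self.codend not in _CODEND_CODES:
            raise ValidationError(f"unknown codend code {self.codend!r}")

    @property
    def smp_present(self) -> bool:
        return self.smp != "NONE"

    @property
    def smp_position(self) -> str | None:
        """'T' (top) or 'B' (bottom), None without an SMP."""
        return self.smp[4] if self.smp_present else None

    @property
    def smp_size(self) -> str | None:
        """'S' (small) or 'L' (large), None without an SMP."""
        return self.smp[5] if self.smp_present else None

    def __str__(self) -> str:
        return f"{self.smp}+{self.codend}" if self.smp_present else self.codend

    @classmethod
    def parse(cls, text: str) -> "GearDesignLabel":
        text = text.strip()
        if "+" in text:
            smp, codend = (part.strip() for part in text.split("+", 1))
        else:
            smp, codend = "NONE", text
        return cls(smp=smp, codend=codend)


#: The ten valid SMP x codend combinations.
ALL_DESIGNS = tuple(
    GearDesignLabel(smp=s, codend=c) for c in _CODEND_CODES for s in _SMP_CODES
)


# ---------------------------------------------------------------------------
# Operations


def raise_counts(haul: HaulRecord) -> pd.DataFrame:
    """Measured counts divided by their compartment's subsampling factor.

    Returns a frame indexed by ``length_cm`` with one column per compartment
    present.  Exact (no-op) when q = 1.
    """
    data = {comp: haul.raised(comp) for comp in haul.compartments}
    return pd.DataFrame(data, index=pd.Index(haul.lengths, name="length_cm"))


def pool_over_hauls(ds: SelectivityDataset) -> pd.DataFrame:
    """Sum of raised counts across hauls, per compartment and length class."""
    grid = ds.length_grid()
    out = pd.DataFrame(0.0, index=pd.Index(grid, name="length_cm"), columns=list(ds.compartments))
    for haul in ds.hauls:
        idx = np.searchsorted(grid, haul.lengths)
        for comp in haul.compartments:
            out.iloc[idx, out.columns.get_loc(comp)] += haul.raised(comp)
    return out


def apply_length_filters(
    ds: SelectivityDataset, min_pc_cm: float = 20, min_cc_cm: float = 15
) -> SelectivityDataset:
    """Drop cover counts from length classes too small to trust.

    Cover meshes can themselves release the smallest fish, biasing the
    escape counts downwards; only PC counts strictly above ``min_pc_cm`` and
    CC counts strictly above ``min_cc_cm`` are kept.  CD counts are never
    touched.  The input dataset is not modified.  Idempotent.
    """
    if min_pc_cm < 0 or min_cc_cm < 0:
        raise ValidationError("filter thresholds must be >= 0")
    new_hauls = []
    for haul in ds.hauls:
        counts = {comp: arr.copy() for comp, arr in haul.counts.items()}
        counts["CC"][haul.lengths <= min_cc_cm] = 0.0
        if "PC" in counts:
            counts["PC"][haul.lengths <= min_pc_cm] = 0.0
        keep = np.zeros(haul.lengths.shape, dtype=bool)
        for arr in counts.values():
            keep |= arr > 0
        new_hauls.append(
            HaulRecord(
                haul_id=haul.haul_id,
                lengths=haul.lengths[keep],
                counts={c: a[keep] for c, a in counts.items()},
                q=dict(haul.q),
            )
        )
    return SelectivityDataset(hauls=tuple(new_hauls), gear_label=ds.gear_label, species=ds.species)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_dataset(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    gear_label: str | None = None,
    species: str | None = None,
) -> SelectivityDataset:
    """Read a haul-level length-frequency CSV into a validated dataset.

    ``schema`` optionally maps canonical column names (``haul_id``,
    ``length_cm``, ``n_CD`` ...) to the names actually used in the file.
    Rows with identical (haul, length) are summed.  Negative counts or a
    subsampling factor outside (0, 1] raise :class:`ValidationError` with
    the offending row index.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    _require_columns(df, ("haul_id", "length_cm", "n_CD", "n_CC", "q_CD", "q_CC"), path)
    has_pc = "n_PC" in df.columns
    if has_pc and "q_PC" not in df.columns:
        raise SchemaError(f"{path}: n_PC present but q_PC missing")

    count_cols = ["n_CD", "n_CC"] + (["n_PC"] if has_pc else [])
    q_cols = ["q_CD", "q_CC"] + (["q_PC"] if has_pc else [])
    for col in count_cols:
        bad = df.index[(df[col] < 0) | ~np.isfinite(df[col])]
        if len(bad):
            raise ValidationError(f"{path}: negative or non-finite {col} at row {bad[0]}")
    for col in q_cols:
        bad = df.index[(df[col] <= 0) | (df[col] > 1) | ~np.isfinite(df[col])]
        if len(bad):
            raise ValidationError(f"{path}: {col} outside (0, 1] at row {bad[0]}")

    hauls = []
    for haul_id, grp in df.groupby("haul_id", sort=True):
        q: dict[str, float] = {}
        for comp in ("CD", "CC") + (("PC",) if has_pc else ()):
            col = f"q_{comp}"
            vals = grp[col].unique()
            if len(vals) > 1:
                raise ValidationError(f"{path}: haul {haul_id!r} has conflicting {col} values {vals}")
            q[comp] = float(vals[0])
        summed = grp.groupby("length_cm", sort=True)[count_cols].sum()
        counts = {"CD": summed["n_CD"].to_numpy(), "CC": summed["n_CC"].to_numpy()}
        if has_pc:
            counts["PC"] = summed["n_PC"].to_numpy()
        hauls.append(
            HaulRecord(
                haul_id=str(haul_id),
                lengths=summed.index.to_numpy(dtype=int),
                counts=counts,
                q=q,
            )
        )
    return SelectivityDataset(hauls=tuple(hauls), gear_label=gear_label, species=species)


def write_dataset(ds: SelectivityDataset, path: str | Path) -> None:
    """Write a dataset to the canonical CSV schema (round-trips with read)."""
    rows = []
    for haul in ds.hauls:
        for i, length in enumerate(haul.lengths):
            row: dict[str, object] = {"haul_id": haul.haul_id, "length_cm": int(length)}
            for comp in haul.compartments:
                row[f"n_{comp}"] = haul.counts[comp][i]
                row[f"q_{comp}"] = haul.q[comp]
            rows.append(row)
    cols = [c for c in CSV_COLUMNS if ds.has_pc or not c.endswith("PC")]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
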