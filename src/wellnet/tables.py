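"""Feature-table containers, standard-format I/O, and the plate-level growth filter.

A cultivation array produces one feature table per 96-well plate: rows are
wells, columns are Zotus (zero-radius OTUs), entries are read counts. A plate
is admitted to network inference only if more than ``min_grow_frac`` of its
wells show microbial growth ("effective plate"). Growth is scored from the
table itself: a well grew iff its total read count reaches ``min_reads`` —
an in-silico proxy for the visual scoring used at the bench.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

__all__ = [
    "PlateDesign",
    "PlateTable",
    "WellGrowth",
    "FormatError",
    "well_ids",
    "read_plate_table",
    "write_plate_table",
    "detect_growth",
    "effective_plates",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
]

SAMPLE_TYPES = ("plants", "roots", "sediments")
MEDIA = ("R2A", "TSB")
REPLICATES = ("A", "B", "C")
DILUTION_LEVELS = tuple(range(1, 8))  # 10^-1 .. 10^-7


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the documented format."""


@dataclass(frozen=True)
class PlateDesign:
    """One plate of the cultivation design.

    The full design is 3 sample types x 7 ten-fold dilutions x 3 replicates
    x 2 media = 126 plates of 96 wells (12,096 wells). ``dilution_level`` d
    means the inoculum was diluted 10^-d before dispensing
    ``inoculum_volume_ul`` into each well of ``well_volume_ul`` broth.
    """

    sample_type: str
    medium: str
    dilution_level: int
    replicate: str
    n_wells: int = 96
    inoculum_volume_ul: float = 1.0
    well_volume_ul: float = 150.0

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample_type {self.sample_type!r}; expected one of {SAMPLE_TYPES}")
        if self.medium not in MEDIA:
            raise ValueError(f"unknown medium {self.medium!r}; expected one of {MEDIA}")
        if self.dilution_level not in DILUTION_LEVELS:
            raise ValueError(f"dilution_level must be in 1..7, got {self.dilution_level}")
        if self.replicate not in REPLICATES:
            raise ValueError(f"replicate must be one of {REPLICATES}, got {self.replicate!r}")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        if self.inoculum_volume_ul <= 0 or self.well_volume_ul <= 0:
            raise ValueError("volumes must be positive")

    @property
    def plate_id(self) -> str:
        return f"{self.sample_type}-{self.medium}-d{self.dilution_level}-{self.replicate}"

    @property
    def group(self) -> tuple[str, str]:
        """Grouping key used for pair prevalence: (sample_type, medium)."""
        return (self.sample_type, self.medium)

    def to_dict(self) -> dict:
        return {
            "sample_type": self.sample_type,
            "medium": self.medium,
            "dilution_level": self.dilution_level,
            "replicate": self.replicate,
            "n_wells": self.n_wells,
            "inoculum_volume_ul": self.inoculum_volume_ul,
            "well_volume_ul": self.well_volume_ul,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlateDesign":
        return cls(**d)


def full_design(n_wells: int = 96) -> list[PlateDesign]:
    """Enumerate every plate of the declared cultivation design."""
    return [
        PlateDesign(sample_type=s, medium=m, dilution_level=d, replicate=r, n_wells=n_wells)
        for s in SAMPLE_TYPES
        for m in MEDIA
        for d in DILUTION_LEVELS
        for r in REPLICATES
    ]


def well_ids(n_wells: int) -> tuple[str, ...]:
    """Stable well labels: row-major A1..H12 for 96 wells, 12 per row otherwise.

    Rows beyond Z continue AA, AB, ... so any plate size gets unique ids.
    """
    letters = string.ascii_uppercase

    def row_label(i: int) -> str:
        label = ""
        i += 1
        while i > 0:
            i, rem = divmod(i - 1, 26)
            label = letters[rem] + label
        return label

    ids = []
    for i in range(n_wells):
        row, col = divmod(i, 12)
        ids.append(f"{row_label(row)}{col + 1}")
    return tuple(ids)


@dataclass(frozen=True)
class PlateTable:
    """One plate's wells x Zotus count matrix plus its design metadata."""

    plate_id: str
    design: PlateDesign | None
    wells: tuple[str, ...]
    zotu_ids: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.wells), len(self.zotu_ids)):
            raise ValueError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(self.wells)} wells x {len(self.zotu_ids)} zotus"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if len(set(self.wells)) != len(self.wells):
            raise ValueError("duplicate well ids")
        if len(set(self.zotu_ids)) != len(self.zotu_ids):
            raise ValueError("duplicate zotu ids")
        object.__setattr__(self, "wells", tuple(self.wells))
        object.__setattr__(self, "zotu_ids", tuple(self.zotu_ids))
        object.__setattr__(self, "counts", counts)

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.wells), columns=list(self.zotu_ids))

    def subset(
        self,
        wells: Sequence[str] | None = None,
        zotu_ids: Sequence[str] | None = None,
    ) -> "PlateTable":
        """Restrict to the given wells and/or Zotus (order preserved as given)."""
        wsel = list(self.wells) if wells is None else list(wells)
        zsel = list(self.zotu_ids) if zotu_ids is None else list(zotu_ids)
        widx = [self.wells.index(w) for w in wsel]
        zidx = [self.zotu_ids.index(z) for z in zsel]
        return PlateTable(
            plate_id=self.plate_id,
            design=self.design,
            wells=tuple(wsel),
            zotu_ids=tuple(zsel),
            counts=self.counts[np.ix_(widx, zidx)] if widx and zidx
            else np.zeros((len(widx), len(zidx)), dtype=self.counts.dtype),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlateTable):
            return NotImplemented
        return (
            self.plate_id == other.plate_id
            and self.design == other.design
            and self.wells == other.wells
            and self.zotu_ids == other.zotu_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class WellGrowth:
    well_id: str
    total_reads: int
    grew: bool


def write_plate_table(plate: PlateTable, path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Write the count matrix as TSV (first column ``well``) plus a JSON design sidecar."""
    path = Path(path)
    df = plate.to_frame()
    df.index.name = "well"
    df.to_csv(path, sep="\t")
    if sidecar_path is not None:
        sidecar = {
            "plate_id": plate.plate_id,
            "design": plate.design.to_dict() if plate.design is not None else None,
        }
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=2) + "\n")


def read_plate_table(path: str | Path, sidecar_path: str | Path | None = None) -> PlateTable:
    """Read a plate feature table written by :func:`write_plate_table`.

    Round-trips bit-exactly. Malformed input (ragged rows, negative or
    non-integer counts, duplicate ids, no wells) raises :class:`FormatError`
    naming the offending row/column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no wells")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate well ids {dupes}")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate zotu ids")
    counts = np.zeros(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, (well, raw) in enumerate(df[col].items()):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                raise FormatError(f"{path}: missing value at well {well}, zotu {col} (ragged row?)")
            text = str(raw).strip().replace("−", "-")  # tolerate unicode minus
            try:
                value = int(text)
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer count {raw!r} at well {well}, zotu {col}") from exc
            if value < 0:
                raise FormatError(f"{path}: negative count {value} at well {well}, zotu {col}")
            counts[i, j] = value

    plate_id = path.stem
    design = None
    if sidecar_path is not None:
        sidecar = json.loads(Path(sidecar_path).read_text())
        plate_id = sidecar.get("plate_id", plate_id)
        if sidecar.get("design") is not None:
            design = PlateDesign.from_dict(sidecar["design"])
    return PlateTable(
        plate_id=plate_id,
        design=design,
        wells=tuple(str(w) for w in df.index),
        zotu_ids=tuple(str(c) for c in df.columns),
        counts=counts,
    )


def detect_growth(plate: PlateTable, min_reads: int = 100) -> list[WellGrowth]:
    """Score each well as grown iff its total read count is >= ``min_reads``."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    totals = plate.counts.sum(axis=1)
    return [
        WellGrowth(well_id=w, total_reads=int(t), grew=bool(t >= min_reads))
        for w, t in zip(plate.wells, totals)
    ]


def effective_plates(
    plates: Iterable[PlateTable],
    min_reads: int = 100,
    min_grow_frac: float = 0.30,
) -> list[PlateTable]:
    """Keep plates in which strictly more than ``min_grow_frac`` of wells grew.

    The denominator is the plate's declared well count. The boundary is
    strict: 29/96 (0.3021) passes at 0.30, 28/96 (0.2917) does not.
    """
    if not 0 <= min_grow_frac <= 1:
        raise ValueError("min_grow_frac must be in [0, 1]")
    kept = []
    for plate in plates:
        grown = sum(g.grew for g in detect_growth(plate, min_reads=min_reads))
        if grown / plate.n_wells > min_grow_frac:
            kept.append(plate)
    return kept


# ---------------------------------------------------------------------------
# sequence / tree file helpers

def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: uppercase sequence}, order-preserving."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"{path}: no sequences")
    return records


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [BioSeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_newick(path: str | Path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")


def write_newick(tree, path: str | Path) -> None:
    tree.write(str(path), format="newick")
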