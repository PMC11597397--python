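"""Domain types and tabular I/O for growth-layer radiocarbon data.

The central objects are :class:`RadiocarbonSample` (one pMC measurement from
one dentine growth layer group, GLG), :class:`Specimen` (a tusk or embedded
tooth with its ordered layer series and life-history metadata) and
:class:`Dataset` (a collection of specimens).  Layer indexing follows the
convention of the source chronologies: index 0 is the prenatal tip (present
only when the neonatal line survives), postnatal layers count upward from 1;
tusk series whose tip is broken off start at the first preserved GLG.

A transcription of the published narwhal dataset (46 radiocarbon samples from
three erupted tusks and eight embedded teeth, with 36 paired stable-isotope
measurements) ships with the package and is returned by
:func:`bundled_narwhal_dataset`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Union

__all__ = [
    "Species",
    "Sex",
    "SpecimenType",
    "NeonatalLine",
    "RadiocarbonSample",
    "Specimen",
    "Dataset",
    "ParseError",
    "read_samples",
    "write_samples",
    "bundled_narwhal_dataset",
]

YEAR_MIN, YEAR_MAX = 1800.0, 2100.0


class Species(str, Enum):
    NARWHAL = "narwhal"
    BELUGA = "beluga"
    HUMPBACK = "humpback"
    FIN_WHALE = "fin_whale"
    OTHER = "other"


class Sex(str, Enum):
    MALE = "M"
    FEMALE = "F"
    UNKNOWN = "unknown"


class SpecimenType(str, Enum):
    TUSK = "tusk"
    TOOTH = "tooth"


class NeonatalLine(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNCERTAIN = "uncertain"


class ParseError(ValueError):
    """Malformed cell or duplicate row in a samples CSV; names row and column."""


@dataclass(frozen=True)
class RadiocarbonSample:
    """One growth-layer measurement.

    Parameters
    ----------
    specimen_id : str
        Identifier of the tusk/tooth the layer belongs to.
    species : Species
    layer_index : int
        GLG index; 0 denotes the prenatal tip, >= 1 postnatal layers.
    year : float or None
        Calendar year (AD) the layer was deposited, if known.
    pmc : float
        Percent modern carbon (%).
    pmc_sd : float
        1-sigma measurement standard deviation of ``pmc`` (%).
    d13c, d13c_sd : float, optional
        delta-13C (per mil vs VPDB) and its 1-sigma s.d.
    d15n, d15n_sd : float, optional
        delta-15N (per mil vs AIR) and its 1-sigma s.d.
    lab_id : str, optional
        AMS laboratory identifier of the measurement.
    """

    specimen_id: str
    species: Species
    layer_index: int
    year: Optional[float]
    pmc: float
    pmc_sd: float
    d13c: Optional[float] = None
    d13c_sd: Optional[float] = None
    d15n: Optional[float] = None
    d15n_sd: Optional[float] = None
    lab_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.pmc > 0):
            raise ValueError(f"pmc must be > 0, got {self.pmc}")
        if not (self.pmc_sd > 0):
            raise ValueError(f"pmc_sd must be > 0, got {self.pmc_sd}")
        if self.layer_index < 0:
            raise ValueError(f"layer_index must be >= 0, got {self.layer_index}")
        if self.year is not None and not (YEAR_MIN <= self.year <= YEAR_MAX):
            raise ValueError(
                f"year {self.year} outside plausible range [{YEAR_MIN}, {YEAR_MAX}]"
            )

    @property
    def has_isotopes(self) -> bool:
        return self.d13c is not None and self.d15n is not None


@dataclass(frozen=True)
class Specimen:
    """A tusk or embedded tooth with its ordered layer samples.

    ``layers_missing`` is the interval [lo, hi] of GLGs estimated lost from a
    worn/broken tip; ``layers_counted`` the number of GLGs counted on the
    sectioned specimen.  Samples are kept sorted by layer index; repeated
    indices are allowed (one layer measured more than once).
    """

    specimen_id: str
    species: Species
    sex: Sex = Sex.UNKNOWN
    specimen_type: SpecimenType = SpecimenType.TOOTH
    year_of_death: Optional[float] = None
    layers_counted: Optional[int] = None
    layers_missing: tuple[int, int] = (0, 0)
    neonatal_line: NeonatalLine = NeonatalLine.UNCERTAIN
    samples: tuple[RadiocarbonSample, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.layers_missing
        if not (0 <= lo <= hi):
            raise ValueError(f"layers_missing interval invalid: [{lo}, {hi}]")
        idx = [s.layer_index for s in self.samples]
        if idx != sorted(idx):
            object.__setattr__(
                self,
                "samples",
                tuple(sorted(self.samples, key=lambda s: s.layer_index)),
            )
        for s in self.samples:
            if s.specimen_id != self.specimen_id:
                raise ValueError(
                    f"sample specimen_id {s.specimen_id!r} != {self.specimen_id!r}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_at(self, layer_index: int) -> RadiocarbonSample:
        """First sample with the given layer index (raises KeyError if none)."""
        for s in self.samples:
            if s.layer_index == layer_index:
                return s
        raise KeyError(f"specimen {self.specimen_id}: no sample at layer {layer_index}")

    @property
    def tip_sample(self) -> RadiocarbonSample:
        return self.samples[0]

    @property
    def base_sample(self) -> RadiocarbonSample:
        return self.samples[-1]


@dataclass(frozen=True)
class Dataset:
    """An ordered collection of specimens with unique ids."""

    specimens: tuple[Specimen, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [sp.specimen_id for sp in self.specimens]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen ids: {dup}")

    def __len__(self) -> int:
        return len(self.specimens)

    def __iter__(self) -> Iterator[Specimen]:
        return iter(self.specimens)

    def get(self, specimen_id: str) -> Specimen:
        for sp in self.specimens:
            if sp.specimen_id == specimen_id:
                return sp
        raise KeyError(f"no specimen {specimen_id!r}")

    def samples(self) -> Iterator[RadiocarbonSample]:
        for sp in self.specimens:
            yield from sp.samples

    @property
    def n_samples(self) -> int:
        return sum(sp.n_samples for sp in self.specimens)

    def radiocarbon_points(self) -> list[tuple[float, float, float]]:
        """(year, pmc, pmc_sd) triples for all samples with a known year."""
        return [
            (s.year, s.pmc, s.pmc_sd) for s in self.samples() if s.year is not None
        ]

    def to_dataframe(self):
        """Flat per-sample table as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame([_sample_row(sp, s) for sp in self for s in sp.samples])


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = [
    "specimen_id",
    "species",
    "sex",
    "specimen_type",
    "year_of_death",
    "layer_index",
    "year",
    "pmc",
    "pmc_sd",
    "d13c",
    "d13c_sd",
    "d15n",
    "d15n_sd",
    "lab_id",
]

META_COLUMNS = [
    "specimen_id",
    "species",
    "sex",
    "specimen_type",
    "year_of_death",
    "layers_counted",
    "layers_missing_lo",
    "layers_missing_hi",
    "neonatal_line",
]

_ASCII_FIXES = str.maketrans({"−": "-", "–": "-", "±": "+-"})


def _clean(cell: Optional[str]) -> str:
    return (cell or "").translate(_ASCII_FIXES).strip()


def _parse_float(cell: str, row: int, col: str) -> Optional[float]:
    cell = _clean(cell)
    if cell in ("", "-", "unknown", "NA", "nan"):
        return None
    try:
        v = float(cell)
    except ValueError as exc:
        raise ParseError(f"row {row}, column {col!r}: cannot parse {cell!r}") from exc
    if math.isnan(v):
        return None
    return v


def _parse_int(cell: str, row: int, col: str) -> Optional[int]:
    v = _parse_float(cell, row, col)
    if v is None:
        return None
    if v != int(v):
        raise ParseError(f"row {row}, column {col!r}: expected integer, got {cell!r}")
    return int(v)


def _parse_enum(enum_cls, cell: str, default, row: int, col: str):
    cell = _clean(cell)
    if cell == "":
        return default
    try:
        return enum_cls(cell)
    except ValueError as exc:
        valid = [e.value for e in enum_cls]
        raise ParseError(
            f"row {row}, column {col!r}: {cell!r} not one of {valid}"
        ) from exc


def read_samples(
    path: Union[str, Path],
    meta_path: Union[str, Path, None] = None,
) -> Dataset:
    """Read a per-sample CSV (and optional per-specimen metadata CSV).

    The sample CSV must carry the canonical header (``SAMPLE_COLUMNS``);
    empty cells are missing values and an empty ``year`` means the deposition
    year is unknown.  Unicode minus and plus-minus signs are normalised on
    ingest.  Rows that are exact duplicates in (specimen, layer, lab, pmc)
    are rejected; repeated measurements of one layer with distinct values are
    legitimate and kept.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in SAMPLE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        rows = list(reader)

    meta: dict[str, dict] = {}
    if meta_path is not None:
        meta = _read_metadata(Path(meta_path))

    by_specimen: dict[str, list[RadiocarbonSample]] = {}
    specimen_info: dict[str, dict] = {}
    seen: set[tuple] = set()
    for i, row in enumerate(rows, start=2):  # 1-based, header is row 1
        sid = _clean(row["specimen_id"])
        if sid == "":
            raise ParseError(f"row {i}, column 'specimen_id': empty")
        species = _parse_enum(Species, row["species"], Species.OTHER, i, "species")
        pmc = _parse_float(row["pmc"], i, "pmc")
        pmc_sd = _parse_float(row["pmc_sd"], i, "pmc_sd")
        if pmc is None or pmc_sd is None:
            raise ParseError(f"row {i}: pmc and pmc_sd are required")
        layer = _parse_int(row["layer_index"], i, "layer_index")
        if layer is None:
            raise ParseError(f"row {i}, column 'layer_index': empty")
        lab = _clean(row["lab_id"]) or None
        key = (sid, layer, lab, pmc)
        if key in seen:
            raise ParseError(
                f"row {i}: duplicate measurement (specimen {sid}, layer {layer}, "
                f"lab {lab}, pmc {pmc})"
            )
        seen.add(key)
        sample = RadiocarbonSample(
            specimen_id=sid,
            species=species,
            layer_index=layer,
            year=_parse_float(row["year"], i, "year"),
            pmc=pmc,
            pmc_sd=pmc_sd,
            d13c=_parse_float(row["d13c"], i, "d13c"),
            d13c_sd=_parse_float(row["d13c_sd"], i, "d13c_sd"),
            d15n=_parse_float(row["d15n"], i, "d15n"),
            d15n_sd=_parse_float(row["d15n_sd"], i, "d15n_sd"),
            lab_id=lab,
        )
        by_specimen.setdefault(sid, []).append(sample)
        specimen_info.setdefault(
            sid,
            {
                "species": species,
                "sex": _parse_enum(Sex, row["sex"], Sex.UNKNOWN, i, "sex"),
                "specimen_type": _parse_enum(
                    SpecimenType, row["specimen_type"], SpecimenType.TOOTH, i,
                    "specimen_type",
                ),
                "year_of_death": _parse_float(row["year_of_death"], i, "year_of_death"),
            },
        )

    specimens = []
    for sid, samples in by_specimen.items():
        info = dict(specimen_info[sid])
        info.update(meta.get(sid, {}))
        specimens.append(Specimen(specimen_id=sid, samples=tuple(samples), **info))
    return Dataset(specimens=tuple(specimens), provenance=str(path))


def _read_metadata(path: Path) -> dict[str, dict]:
    meta: dict[str, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in META_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        for i, row in enumerate(reader, start=2):
            sid = _clean(row["specimen_id"])
            lo = _parse_int(row["layers_missing_lo"], i, "layers_missing_lo") or 0
            hi = _parse_int(row["layers_missing_hi"], i, "layers_missing_hi") or 0
            meta[sid] = {
                "species": _parse_enum(Species, row["species"], Species.OTHER, i, "species"),
                "sex": _parse_enum(Sex, row["sex"], Sex.UNKNOWN, i, "sex"),
                "specimen_type": _parse_enum(
                    SpecimenType, row["specimen_type"], SpecimenType.TOOTH, i,
                    "specimen_type",
                ),
                "year_of_death": _parse_float(row["year_of_death"], i, "year_of_death"),
                "layers_counted": _parse_int(row["layers_counted"], i, "layers_counted"),
                "layers_missing": (lo, hi),
                "neonatal_line": _parse_enum(
                    NeonatalLine, row["neonatal_line"], NeonatalLine.UNCERTAIN, i,
                    "neonatal_line",
                ),
            }
    return meta


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, Enum):
        return v.value
    if isinstance(v, float) and v == int(v) and abs(v) < 1e9:
        return str(int(v))
    return str(v)


def _sample_row(sp: Specimen, s: RadiocarbonSample) -> dict:
    return {
        "specimen_id": s.specimen_id,
        "species": s.species.value,
        "sex": sp.sex.value,
        "specimen_type": sp.specimen_type.value,
        "year_of_death": sp.year_of_death,
        "layer_index": s.layer_index,
        "year": s.year,
        "pmc": s.pmc,
        "pmc_sd": s.pmc_sd,
        "d13c": s.d13c,
        "d13c_sd": s.d13c_sd,
        "d15n": s.d15n,
        "d15n_sd": s.d15n_sd,
        "lab_id": s.lab_id,
    }


def write_samples(
    ds: Dataset,
    path: Union[str, Path],
    meta_path: Union[str, Path, None] = None,
) -> None:
    """Write a Dataset to the canonical per-sample CSV.

    When ``meta_path`` is given, per-specimen metadata (layer counts,
    missing-tip interval, neonatal line) is written alongside so that
    ``read_samples(path, meta_path)`` round-trips exactly.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=SAMPLE_COLUMNS)
        writer.writeheader()
        for sp in ds:
            for s in sp.samples:
                writer.writerow({k: _fmt(v) for k, v in _sample_row(sp, s).items()})
    if meta_path is not None:
        with open(meta_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=META_COLUMNS)
            writer.writeheader()
            for sp in ds:
                writer.writerow(
                    {
                        "specimen_id": sp.specimen_id,
                        "species": _fmt(sp.species),
                        "sex": _fmt(sp.sex),
                        "specimen_type": _fmt(sp.specimen_type),
                        "year_of_death": _fmt(sp.year_of_death),
                        "layers_counted": _fmt(sp.layers_counted),
                        "layers_missing_lo": sp.layers_missing[0],
                        "layers_missing_hi": sp.layers_missing[1],
                        "neonatal_line": _fmt(sp.neonatal_line),
                    }
                )


def bundled_narwhal_dataset() -> Dataset:
    """The packaged narwhal dataset: 46 radiocarbon samples from 11 specimens.

    Three erupted tusks (nos. 4076, 956, 953) sampled along their length and
    eight embedded teeth sampled at the prenatal tip (layer 0) and postnatal
    base, with specimen metadata (GLG counts, missing-tip estimates, neonatal
    line) attached.  Layer deposition years are the source chronology's
    estimates and are treated as known when fitting.
    """
    data_dir = resources.files("bombpulse") / "data"
    with resources.as_file(data_dir / "narwhal_table2.csv") as p2, resources.as_file(
        data_dir / "narwhal_table1_meta.csv"
    ) as p1:
        ds = read_samples(p2, meta_path=p1)
    return replace(ds, provenance="bundled narwhal growth-layer dataset")
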