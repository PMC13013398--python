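"""Reading, validation and editing of phenotype files.

The raw data are plain tab/comma-separated text with one trait record per
animal.  Editing retains only contemporary groups (CGs) with at least
``min_cg_size`` records and sires with at least ``min_progeny`` recorded
progeny; because dropping a CG can demote a sire and dropping a sire's
progeny can shrink a CG, the two filters are iterated to a fixed point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

from .pedigree import _norm_id

REQUIRED_COLUMNS = ("animal", "sire", "dam", "cg", "cow_age", "value")


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class PhenotypeRecord:
    """One trait measurement with its animal, parents, CG and cow-age covariate."""

    animal: object
    sire: object  # None = unknown
    dam: object
    cg: object
    cow_age: float
    value: float


@dataclass(frozen=True)
class RowError:
    line: int
    message: str


@dataclass
class ReadResult:
    records: list
    row_errors: list

    def __iter__(self):
        return iter(self.records)


@dataclass
class EditReport:
    n_input: int
    n_retained: int
    n_dropped_cg: int
    n_dropped_sire: int
    n_passes: int

    def __post_init__(self):
        if self.n_retained + self.n_dropped_cg + self.n_dropped_sire != self.n_input:
            raise ValueError("edit report does not account for every input record")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def read_phenotypes(path) -> ReadResult:
    """Parse a phenotype TSV/CSV with header (animal, sire, dam, cg, cow_age, value).

    Malformed rows are collected as :class:`RowError` with their line numbers;
    a missing required column is a hard error.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines()]
    if not lines or not lines[0].strip():
        raise DataError(f"{path}: empty file, expected a header line")
    sep = "\t" if "\t" in lines[0] else ","
    header = [h.strip().lower() for h in lines[0].split(sep)]
    for col in REQUIRED_COLUMNS:
        if col not in header:
            raise DataError(f"{path}: required column {col!r} missing from header")
    pos = {col: header.index(col) for col in REQUIRED_COLUMNS}
    records: list[PhenotypeRecord] = []
    errors: list[RowError] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) < len(header):
            errors.append(RowError(ln, f"expected {len(header)} fields, got {len(parts)}"))
            continue
        try:
            cow_age = float(parts[pos["cow_age"]])
            value = float(parts[pos["value"]])
        except ValueError:
            errors.append(RowError(ln, "non-numeric cow_age or value"))
            continue
        if not (cow_age > 0):
            errors.append(RowError(ln, f"cow_age must be > 0, got {cow_age}"))
            continue
        cg = parts[pos["cg"]]
        if not cg or cg.upper() == "NA":
            errors.append(RowError(ln, "empty contemporary group id"))
            continue
        animal = _norm_id(parts[pos["animal"]])
        if animal is None:
            errors.append(RowError(ln, "missing animal id"))
            continue
        records.append(
            PhenotypeRecord(
                animal=animal,
                sire=_norm_id(parts[pos["sire"]]),
                dam=_norm_id(parts[pos["dam"]]),
                cg=_norm_id(cg),
                cow_age=cow_age,
                value=value,
            )
        )
    return ReadResult(records=records, row_errors=errors)


def write_phenotypes(records: Iterable[PhenotypeRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("animal\tsire\tdam\tcg\tcow_age\tvalue\n")
        for r in records:
            fh.write(
                f"{r.animal}\t{r.sire if r.sire is not None else 0}\t"
                f"{r.dam if r.dam is not None else 0}\t{r.cg}\t"
                f"{r.cow_age:.6g}\t{r.value:.10g}\n"
            )


def apply_edits(
    records: Sequence[PhenotypeRecord],
    min_cg_size: int = 5,
    min_progeny: int = 3,
) -> tuple[list, EditReport]:
    """Iterate the CG-size and sire-progeny filters to a fixed point.

    Records whose animal has an unknown sire are exempt from the progeny
    filter (the rule governs sires).  Returns the retained records in input
    order and an :class:`EditReport`; an empty survivor set is not an error.
    """
    if min_cg_size < 1 or min_progeny < 1:
        raise ValueError("min_cg_size and min_progeny must be >= 1")
    kept = list(records)
    n_input = len(kept)
    n_dropped_cg = 0
    n_dropped_sire = 0
    n_passes = 0
    while True:
        n_passes += 1
        changed = False
        cg_counts: dict = {}
        for r in kept:
            cg_counts[r.cg] = cg_counts.get(r.cg, 0) + 1
        survivors = [r for r in kept if cg_counts[r.cg] >= min_cg_size]
        n_dropped_cg += len(kept) - len(survivors)
        changed |= len(survivors) != len(kept)
        kept = survivors

        sire_counts: dict = {}
        for r in kept:
            if r.sire is not None:
                sire_counts[r.sire] = sire_counts.get(r.sire, 0) + 1
        survivors = [
            r for r in kept if r.sire is None or sire_counts[r.sire] >= min_progeny
        ]
        n_dropped_sire += len(kept) - len(survivors)
        changed |= len(survivors) != len(kept)
        kept = survivors
        if not changed:
            break
    report = EditReport(
        n_input=n_input,
        n_retained=len(kept),
        n_dropped_cg=n_dropped_cg,
        n_dropped_sire=n_dropped_sire,
        n_passes=n_passes,
    )
    return kept, report
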