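"""Data model and I/O for per-cell tables, core metadata and patient clinical tables.

The pipeline operates on three tidy tables held in a :class:`Cohort`:

``cells``
    one row per segmented cell: ``cell_id``, ``core_id``, planar position
    ``x_um``/``y_um`` in micrometers (origin at the core bounding-box corner,
    y increasing downward, image convention), ``compartment`` (``tumor`` or
    ``stroma``) and six boolean marker channels ``ck, cd8, cd68, foxp3, pd1,
    pdl1``.  At most one of the four lineage markers {CK, CD8, CD68, FOXP3}
    may be positive on a cell; PD-1/PD-L1 are functional markers and may
    co-occur with any lineage.

``cores``
    one row per tissue-microarray core: ``core_id``, ``patient_id``,
    ``diameter_mm`` (default 1.2) and ``area_mm2`` (default the disc area).

``patients``
    one row per patient: FIGO stage (IA/IB/II), grade (G1/G2), LVSI,
    adjuvant radiotherapy, molecular statuses (tri-state yes/no/unknown),
    relapse indicator + type, and follow-up in months.

Source exports use heterogeneous headers and value encodings, so reading is
mediated by a *dialect*: a small mapping from source column names / value
spellings to the canonical schema.  Two dialects ship built in
(``canonical`` and ``inform_like``); custom ones load from YAML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

# --------------------------------------------------------------------------
# canonical schema
# --------------------------------------------------------------------------

LINEAGE_MARKERS = ("ck", "cd8", "cd68", "foxp3")
FUNCTIONAL_MARKERS = ("pd1", "pdl1")
MARKERS = LINEAGE_MARKERS + FUNCTIONAL_MARKERS

CELL_COLUMNS = ("cell_id", "core_id", "x_um", "y_um", "compartment") + MARKERS
CORE_COLUMNS = ("core_id", "patient_id", "diameter_mm", "area_mm2")
PATIENT_COLUMNS = (
    "patient_id",
    "figo_stage",
    "grade",
    "lvsi",
    "adjuvant_rt",
    "mmrp_deficient",
    "pole_mutated",
    "ctnnb1_mutated",
    "relapse",
    "relapse_type",
    "followup_months",
)

FIGO_STAGES = ("IA", "IB", "II")
GRADES = ("G1", "G2")
ADJUVANT_RT = ("none", "EBRT", "VBT", "both", "unknown")
TRISTATE = ("yes", "no", "unknown")
RELAPSE_TYPES = ("distant", "node", "local", "none")
COMPARTMENTS = ("tumor", "stroma")

DEFAULT_CORE_DIAMETER_MM = 1.2


def core_area_mm2(diameter_mm: float = DEFAULT_CORE_DIAMETER_MM) -> float:
    """Area of a circular core of the given diameter (mm^2)."""
    return math.pi * (diameter_mm / 2.0) ** 2


# --------------------------------------------------------------------------
# dialects
# --------------------------------------------------------------------------

_TRUE_TOKENS = {"1", "true", "t", "yes", "y", "+", "pos", "positive"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n", "-", "−", "neg", "negative", ""}


@dataclass
class Dialect:
    """Maps source header names and value spellings onto the canonical schema.

    ``column_aliases`` maps canonical column -> accepted source headers
    (matched case-insensitively; the canonical name is always accepted).
    ``compartment_aliases`` maps source compartment spellings -> canonical.
    ``delimiter`` is the field separator of the source files.
    """

    name: str = "canonical"
    delimiter: str = "\t"
    column_aliases: dict[str, list[str]] = field(default_factory=dict)
    compartment_aliases: dict[str, str] = field(default_factory=dict)

    def resolve_columns(self, header: list[str], wanted: tuple[str, ...]) -> dict[str, str]:
        """Map each canonical column in ``wanted`` to the source header name.

        Raises ``ValueError`` naming the first mandatory column that cannot
        be found.
        """
        lower = {h.strip().lower(): h for h in header}
        out: dict[str, str] = {}
        for canon in wanted:
            candidates = [canon] + self.column_aliases.get(canon, [])
            hit = next((lower[c.lower()] for c in candidates if c.lower() in lower), None)
            if hit is None:
                raise ValueError(f"missing mandatory column: {canon!r} (dialect {self.name!r})")
            out[canon] = hit
        return out

    def parse_compartment(self, value: str) -> str:
        v = str(value).strip()
        v = self.compartment_aliases.get(v, self.compartment_aliases.get(v.lower(), v))
        v = v.lower()
        if v not in COMPARTMENTS:
            raise ValueError(f"unrecognized compartment {value!r}")
        return v

    @staticmethod
    def parse_bool(value) -> bool:
        if isinstance(value, (bool, np.bool_)):
            return bool(value)
        v = str(value).strip().lower()
        if v in _TRUE_TOKENS:
            return True
        if v in _FALSE_TOKENS:
            return False
        raise ValueError(f"unparseable boolean {value!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Dialect":
        spec = yaml.safe_load(Path(path).read_text())
        return cls(
            name=spec.get("name", Path(path).stem),
            delimiter=spec.get("delimiter", "\t"),
            column_aliases=spec.get("column_aliases", {}),
            compartment_aliases=spec.get("compartment_aliases", {}),
        )


CANONICAL_DIALECT = Dialect()

# Approximates the header style of inForm-like per-cell exports.
INFORM_LIKE_DIALECT = Dialect(
    name="inform_like",
    delimiter="\t",
    column_aliases={
        "cell_id": ["Cell ID"],
        "core_id": ["Sample Name", "Annotation ID"],
        "x_um": ["Cell X Position"],
        "y_um": ["Cell Y Position"],
        "compartment": ["Tissue Category"],
        "ck": ["Phenotype CK", "CK positive"],
        "cd8": ["Phenotype CD8", "CD8 positive"],
        "cd68": ["Phenotype CD68", "CD68 positive"],
        "foxp3": ["Phenotype FOXP3", "FOXP3 positive"],
        "pd1": ["Phenotype PD1", "PD-1 positive"],
        "pdl1": ["Phenotype PDL1", "PD-L1 positive"],
    },
    compartment_aliases={"Tumour": "tumor", "Tumor": "tumor", "Stroma": "stroma"},
)

DIALECTS = {"canonical": CANONICAL_DIALECT, "inform_like": INFORM_LIKE_DIALECT}


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class Cohort:
    """The three cohort tables; the unit every pipeline stage consumes."""

    cells: pd.DataFrame
    cores: pd.DataFrame
    patients: pd.DataFrame

    def copy(self) -> "Cohort":
        return Cohort(self.cells.copy(), self.cores.copy(), self.patients.copy())


@dataclass
class ReadResult:
    """Parsed rows plus row-level rejection diagnostics."""

    cells: pd.DataFrame
    n_rejected: int
    rejections: list[str]


@dataclass
class ValidationReport:
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


# --------------------------------------------------------------------------
# reading
# --------------------------------------------------------------------------


def read_cell_table(path: str | Path, dialect: Dialect | str = "canonical") -> ReadResult:
    """Read a per-cell table, mapping headers/values through ``dialect``.

    Rows whose coordinates or marker calls cannot be parsed are rejected
    (counted and reported in the result), never silently coerced.  A missing
    mandatory column is a hard error naming the column.
    """
    dialect = DIALECTS[dialect] if isinstance(dialect, str) else dialect
    raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    colmap = dialect.resolve_columns(list(raw.columns), CELL_COLUMNS)

    rows: list[dict] = []
    rejections: list[str] = []
    for i, row in enumerate(raw.itertuples(index=False)):
        src = dict(zip(raw.columns, row))
        try:
            rec = {
                "cell_id": src[colmap["cell_id"]],
                "core_id": src[colmap["core_id"]],
                "x_um": float(src[colmap["x_um"]]),
                "y_um": float(src[colmap["y_um"]]),
                "compartment": dialect.parse_compartment(src[colmap["compartment"]]),
            }
            if not (math.isfinite(rec["x_um"]) and math.isfinite(rec["y_um"])):
                raise ValueError("non-finite coordinate")
            if rec["x_um"] < 0 or rec["y_um"] < 0:
                raise ValueError("negative coordinate")
            for m in MARKERS:
                rec[m] = Dialect.parse_bool(src[colmap[m]])
        except (ValueError, TypeError) as exc:
            rejections.append(f"row {i}: {exc}")
            continue
        rows.append(rec)

    cells = pd.DataFrame(rows, columns=CELL_COLUMNS)
    for m in MARKERS:
        cells[m] = cells[m].astype(bool) if len(cells) else cells[m].astype(bool)
    return ReadResult(cells=cells, n_rejected=len(rejections), rejections=rejections)


def read_core_table(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    cores = pd.read_csv(path, sep=delimiter, dtype={"core_id": str, "patient_id": str})
    if "diameter_mm" not in cores:
        cores["diameter_mm"] = DEFAULT_CORE_DIAMETER_MM
    if "area_mm2" not in cores:
        cores["area_mm2"] = cores["diameter_mm"].map(core_area_mm2)
    return cores[list(CORE_COLUMNS)]


def read_patient_table(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    patients = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    patients["lvsi"] = patients["lvsi"].map(Dialect.parse_bool)
    patients["relapse"] = patients["relapse"].map(Dialect.parse_bool)
    patients["followup_months"] = patients["followup_months"].astype(float)
    return patients[list(PATIENT_COLUMNS)]


def read_cohort(directory: str | Path, dialect: Dialect | str = "canonical") -> Cohort:
    """Load a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    dia = DIALECTS[dialect] if isinstance(dialect, str) else dialect
    res = read_cell_table(directory / "cells.tsv", dia)
    if res.n_rejected:
        raise ValueError(f"{res.n_rejected} unparseable cell rows: {res.rejections[:5]}")
    return Cohort(
        cells=res.cells,
        cores=read_core_table(directory / "cores.tsv", dia.delimiter),
        patients=read_patient_table(directory / "patients.tsv", dia.delimiter),
    )


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------


def validate_cohort(cohort: Cohort, max_cores_per_patient: int = 2) -> ValidationReport:
    """Check every cohort invariant; returns a report, never raises.

    Hard violations (any entry in the report) must stop downstream stages;
    callers gate on ``report.ok``.
    """
    v: list[str] = []
    cells, cores, patients = cohort.cells, cohort.cores, cohort.patients

    known_cores = set(cores["core_id"])
    orphans = set(cells["core_id"]) - known_cores
    for cid in sorted(orphans):
        v.append(f"cell references unknown core_id {cid!r}")

    known_patients = set(patients["patient_id"])
    for cid, pid in zip(cores["core_id"], cores["patient_id"]):
        if pid not in known_patients:
            v.append(f"core {cid!r} references unknown patient_id {pid!r}")

    counts = cores.groupby("patient_id").size()
    for pid, n in counts[counts > max_cores_per_patient].items():
        v.append(f"patient {pid!r} has {n} cores (max {max_cores_per_patient})")

    if len(cells):
        lineage_n = cells[list(LINEAGE_MARKERS)].sum(axis=1)
        for cell_id in cells.loc[lineage_n > 1, "cell_id"]:
            v.append(f"cell {cell_id!r} is positive for more than one lineage marker")

        bad_coord = ~(
            np.isfinite(cells["x_um"]) & np.isfinite(cells["y_um"])
            & (cells["x_um"] >= 0) & (cells["y_um"] >= 0)
        )
        for cell_id in cells.loc[bad_coord, "cell_id"]:
            v.append(f"cell {cell_id!r} has invalid coordinates")

        # coordinates must fall inside the stated core bounding box
        area = cores.set_index("core_id")["diameter_mm"] * 1000.0  # box side in um
        side = cells["core_id"].map(area)
        outside = (cells["x_um"] > side) | (cells["y_um"] > side)
        outside &= side.notna()
        for cell_id in cells.loc[outside, "cell_id"]:
            v.append(f"cell {cell_id!r} lies outside its core bounding box")

    if (cores["area_mm2"] <= 0).any():
        v.append("core with non-positive area_mm2")

    bad_fu = patients["followup_months"] < 0
    for pid in patients.loc[bad_fu, "patient_id"]:
        v.append(f"patient {pid!r} has negative follow-up")
    incon = (~patients["relapse"]) & (patients["relapse_type"] != "none")
    for pid in patients.loc[incon, "patient_id"]:
        v.append(f"patient {pid!r} has relapse=false but relapse_type != none")

    return ValidationReport(violations=v)


def resolve_lineage_conflicts(cells: pd.DataFrame, mode: str = "error") -> pd.DataFrame:
    """Handle cells positive for >1 lineage marker.

    ``mode='error'`` (default) raises; ``mode='priority'`` keeps the highest
    priority lineage CK > CD8 > CD68 > FOXP3 and clears the rest.
    """
    lineage_n = cells[list(LINEAGE_MARKERS)].sum(axis=1)
    conflicted = lineage_n > 1
    if not conflicted.any():
        return cells
    if mode == "error":
        n = int(conflicted.sum())
        raise ValueError(f"{n} cells are positive for more than one lineage marker")
    if mode != "priority":
        raise ValueError(f"unknown lineage-conflict mode {mode!r}")
    out = cells.copy()
    claimed = np.zeros(len(out), dtype=bool)
    for m in LINEAGE_MARKERS:  # priority order
        col = out[m].to_numpy(copy=True)
        col &= ~(claimed & conflicted.to_numpy())
        out[m] = col
        claimed |= col
    return out


# --------------------------------------------------------------------------
# writing
# --------------------------------------------------------------------------


def write_cohort(cohort: Cohort, directory: str | Path, delimiter: str = "\t") -> dict[str, Path]:
    """Write the three cohort tables so that :func:`read_cohort` round-trips.

    Coordinates are serialized with enough digits (repr) to round-trip at
    well over 6 significant figures; booleans as literal ``true``/``false``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    cells = cohort.cells.copy()
    for m in MARKERS:
        cells[m] = cells[m].map({True: "true", False: "false"})
    paths = {
        "cells": directory / "cells.tsv",
        "cores": directory / "cores.tsv",
        "patients": directory / "patients.tsv",
    }
    cells.to_csv(paths["cells"], sep=delimiter, index=False, float_format="%.10g")
    cohort.cores.to_csv(paths["cores"], sep=delimiter, index=False, float_format="%.10g")
    patients = cohort.patients.copy()
    patients["lvsi"] = patients["lvsi"].map({True: "true", False: "false"})
    patients["relapse"] = patients["relapse"].map({True: "true", False: "false"})
    patients.to_csv(paths["patients"], sep=delimiter, index=False, float_format="%.10g")
    return paths
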