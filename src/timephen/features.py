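"""Per-core feature extraction: population densities, marker fractions, gradients.

The unit of analysis is the cell density (cells/mm2) of an immune population
within a compartment scope (tumor, stroma, or whole core), plus conditional
marker fractions (e.g. the proportion of CD8+ T-cells expressing PD-1) and
tumor-minus-stroma expression gradients in percentage points.

Compartment areas are not part of per-cell exports; by default they are
estimated as (compartment cell count / total cell count) x core area, with a
supplied-area override.  Whole-core density therefore always equals
(tumor count + stroma count) / core area regardless of the split.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cell_data import Cohort

# canonical population predicates over the cell table
POPULATION_PREDICATES = {
    "ck": lambda c: c["ck"],
    "cd8": lambda c: c["cd8"],
    "cd68": lambda c: c["cd68"],
    "foxp3": lambda c: c["foxp3"],
    "ck_pdl1": lambda c: c["ck"] & c["pdl1"],
    "cd8_pd1": lambda c: c["cd8"] & c["pd1"],
    "cd68_pdl1": lambda c: c["cd68"] & c["pdl1"],
}

FEATURE_POPULATIONS = tuple(POPULATION_PREDICATES)
SCOPES = ("tumor", "stroma", "whole")

#: variables used for immune-phenotype clustering: per-compartment densities
#: of all canonical populations (fractions are reported but excluded, which
#: avoids imputing undefined denominators).
CLUSTER_VARIABLES = tuple(
    f"density_{pop}_{scope}" for pop in FEATURE_POPULATIONS for scope in ("tumor", "stroma")
)

FRACTION_VARIABLES = (
    "frac_pd1_cd8_tumor",
    "frac_pd1_cd8_stroma",
    "frac_pdl1_cd68_tumor",
    "frac_pdl1_cd68_stroma",
    "frac_pdl1_ck",
)

GRADIENT_VARIABLES = ("gradient_pd1_cd8", "gradient_pdl1_cd68")


def compartment_areas(cells: pd.DataFrame, core_area_mm2: float) -> dict[str, float]:
    """Estimate tumor/stroma areas from cell-count proportions."""
    n = len(cells)
    if n == 0:
        return {"tumor": 0.0, "stroma": 0.0, "whole": core_area_mm2}
    n_tumor = int((cells["compartment"] == "tumor").sum())
    return {
        "tumor": core_area_mm2 * n_tumor / n,
        "stroma": core_area_mm2 * (n - n_tumor) / n,
        "whole": core_area_mm2,
    }


def population_density(cells: pd.DataFrame, predicate, scope: str, area_mm2: float) -> float:
    """Count of predicate-matching cells in ``scope`` divided by its area.

    Zero area with a nonzero count is a hard error; zero area with zero
    count is density 0 by convention.
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}")
    sub = cells if scope == "whole" else cells[cells["compartment"] == scope]
    count = int(predicate(sub).sum()) if len(sub) else 0
    if area_mm2 <= 0:
        if count:
            raise ValueError(f"zero {scope} area with {count} matching cells")
        return 0.0
    return count / area_mm2


def marker_fraction(cells: pd.DataFrame, base_predicate, marker: str, scope: str) -> float:
    """(# base & marker cells in scope) / (# base cells in scope); NaN if no base cells."""
    sub = cells if scope == "whole" else cells[cells["compartment"] == scope]
    if len(sub) == 0:
        return float("nan")
    base = base_predicate(sub)
    denom = int(base.sum())
    if denom == 0:
        return float("nan")
    return int((base & sub[marker]).sum()) / denom


def compartment_gradient(fraction_tumor: float, fraction_stroma: float) -> float:
    """100 x (tumor fraction - stroma fraction); positive means higher in tumor."""
    if np.isnan(fraction_tumor) or np.isnan(fraction_stroma):
        return float("nan")
    return 100.0 * (fraction_tumor - fraction_stroma)


def overall_median_density(whole_core_densities) -> float:
    """Median whole-core density over the cores of a cluster (midpoint on even n)."""
    arr = np.asarray(list(whole_core_densities), dtype=float)
    if arr.size == 0:
        raise ValueError("empty cluster")
    return float(np.median(arr))


def build_feature_matrix(cohort: Cohort) -> tuple[pd.DataFrame, list[dict]]:
    """One row per core over the canonical variable list.

    Returns ``(features, manifest)``: features indexed by ``core_id`` with
    density, fraction and gradient columns; manifest is a JSON-able list of
    variable definitions (stable across runs).  Cores without cells get a
    zero density row with a warning; undefined fractions stay missing.
    """
    cells = cohort.cells
    cores = cohort.cores.set_index("core_id")
    core_ids = list(cores.index)

    flags = pd.DataFrame(
        {pop: pred(cells).to_numpy() for pop, pred in POPULATION_PREDICATES.items()}
    )
    flags["core_id"] = cells["core_id"].to_numpy()
    flags["compartment"] = cells["compartment"].to_numpy()
    flags["n"] = 1

    by_comp = flags.groupby(["core_id", "compartment"], sort=False).sum(numeric_only=True)
    counts = {
        scope: by_comp.xs(scope, level="compartment").reindex(core_ids).fillna(0)
        if scope in by_comp.index.get_level_values("compartment")
        else pd.DataFrame(0, index=core_ids, columns=list(FEATURE_POPULATIONS) + ["n"])
        for scope in ("tumor", "stroma")
    }
    whole = counts["tumor"] + counts["stroma"]

    area = cores["area_mm2"]
    total_n = whole["n"].replace(0, np.nan)
    scope_area = {
        "tumor": area * counts["tumor"]["n"] / total_n,
        "stroma": area * counts["stroma"]["n"] / total_n,
        "whole": area,
    }

    out = pd.DataFrame(index=pd.Index(core_ids, name="core_id"))
    for pop in FEATURE_POPULATIONS:
        for scope in SCOPES:
            cnt = (whole if scope == "whole" else counts[scope])[pop]
            a = scope_area[scope]
            dens = cnt / a
            # zero-area scopes with zero count are density 0 by convention
            dens = dens.where(~((cnt == 0) & ((a == 0) | a.isna())), 0.0)
            bad = (cnt > 0) & ((a <= 0) | a.isna())
            if bad.any():
                raise ValueError("zero scope area with nonzero count")
            out[f"density_{pop}_{scope}"] = dens.astype(float).fillna(0.0)

    def _frac(num_pop, den_pop, scope):
        table = whole if scope == "whole" else counts[scope]
        den = table[den_pop].replace(0, np.nan)
        return (table[num_pop] / den).astype(float)

    out["frac_pd1_cd8_tumor"] = _frac("cd8_pd1", "cd8", "tumor")
    out["frac_pd1_cd8_stroma"] = _frac("cd8_pd1", "cd8", "stroma")
    out["frac_pdl1_cd68_tumor"] = _frac("cd68_pdl1", "cd68", "tumor")
    out["frac_pdl1_cd68_stroma"] = _frac("cd68_pdl1", "cd68", "stroma")
    out["frac_pdl1_ck"] = _frac("ck_pdl1", "ck", "whole")
    out["gradient_pd1_cd8"] = 100.0 * (out["frac_pd1_cd8_tumor"] - out["frac_pd1_cd8_stroma"])
    out["gradient_pdl1_cd68"] = 100.0 * (
        out["frac_pdl1_cd68_tumor"] - out["frac_pdl1_cd68_stroma"]
    )

    empty = whole["n"] == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} cores contain no cells; density rows set to 0")

    manifest = []
    for pop in FEATURE_POPULATIONS:
        for scope in SCOPES:
            manifest.append(
                {
                    "name": f"density_{pop}_{scope}",
                    "kind": "density",
                    "population": pop,
                    "scope": scope,
                    "units": "cells/mm2",
                }
            )
    for name in FRACTION_VARIABLES:
        manifest.append({"name": name, "kind": "fraction", "units": "proportion"})
    for name in GRADIENT_VARIABLES:
        manifest.append({"name": name, "kind": "gradient", "units": "percentage points"})
    return out, manifest


def cluster_omd_table(features: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster overall median whole-core density for every population.

    ``assignments`` must carry ``core_id`` and a cluster column
    (``cluster_index`` or ``semantic_name``).
    """
    key = "cluster_index" if "cluster_index" in assignments else "semantic_name"
    joined = features.join(assignments.set_index("core_id")[key], how="inner")
    rows = {}
    for cluster, grp in joined.groupby(key):
        rows[cluster] = {
            pop: overall_median_density(grp[f"density_{pop}_whole"])
            for pop in FEATURE_POPULATIONS
        }
    table = pd.DataFrame(rows).T
    table.index.name = key
    return table
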