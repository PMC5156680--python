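"""Saturation-mutagenesis ΔΔG aggregation, empirical correction and classification.

In-silico saturation mutagenesis produces one predicted ΔΔG (kcal/mol,
positive = destabilizing) per mutation, per ensemble conformer, per
independent run.  This module pools those records into a position x
substitution scan matrix, applies the empirical linear correction that maps
predictor-scale ΔΔG onto the experimental scale, estimates mutant unfolding
free energies, and classifies mutations against the 1.6 kcal/mol threshold
(twice the typical 0.8 kcal/mol prediction error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "DdgRecord",
    "CorrectionParams",
    "ScanMatrix",
    "DdgClassification",
    "CompletenessError",
    "invert_calibration",
    "correct_ddg",
    "unfolding_dg",
    "classify_mutation",
    "categorize_effects",
    "aggregate_scan",
    "hotspot_positions",
    "prediction_error_threshold",
    "read_ddg_table",
    "write_ddg_table",
    "parse_foldx_dif",
]

#: One-letter codes of the twenty standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Typical prediction error of the empirical energy function, kcal/mol.
DEFAULT_PREDICTION_ERROR = 0.8


def prediction_error_threshold(prediction_error: float = DEFAULT_PREDICTION_ERROR) -> float:
    """Neutral/deleterious threshold: twice the predictor's typical error."""
    return 2.0 * prediction_error


class CompletenessError(ValueError):
    """A scan is missing (position, substitution) cells."""


@dataclass(frozen=True)
class DdgRecord:
    """One raw scan record: a mutation evaluated on one conformer in one run.

    ``chain`` is None for a monomer (stability) scan; dimer (binding) scans
    carry the mutated chain so the two chain copies are separate cells.
    """

    wt: str
    position: int
    mutant: str
    ddg: float
    conformer: int = 1
    run: int = 1
    chain: str | None = None

    def __post_init__(self) -> None:
        if self.wt not in AMINO_ACIDS or self.mutant not in AMINO_ACIDS:
            raise ValueError(f"unknown amino-acid code in {self.wt}{self.position}{self.mutant}")
        if self.wt == self.mutant:
            raise ValueError(f"wild type and mutant identical at position {self.position}")
        if not math.isfinite(self.ddg):
            raise ValueError(f"non-finite ddg for {self.wt}{self.position}{self.mutant}")

    @property
    def label(self) -> str:
        site = f"{self.wt}{self.position}{self.mutant}"
        return site if self.chain is None else f"{site}:{self.chain}"


@dataclass
class CorrectionParams:
    """Linear correction mapping predictor ΔΔG to the experimental scale.

    ``m`` and ``b`` come from inverting the published calibration of the
    predictor against experimental unfolding data
    (predicted = -0.078 + 1.14 * experimental, hence m = 1/1.14 = 0.877 and
    b = 0.078/1.14 = 0.068).  ``dgu_wt`` is the reference wild-type
    unfolding free energy (5 kcal/mol, a mid-range value for small helical
    domains, used when no experimental value exists).
    """

    m: float = 0.877
    b: float = 0.068
    dgu_wt: float = 5.0

    def __post_init__(self) -> None:
        if not self.m > 0:
            raise ValueError("slope m must be > 0")


def invert_calibration(slope: float = 1.14, intercept: float = -0.078,
                       dgu_wt: float = 5.0) -> CorrectionParams:
    """Derive correction parameters by inverting predicted = intercept + slope*experimental.

    experimental = (predicted - intercept)/slope, so m = 1/slope and
    b = -intercept/slope.
    """
    return CorrectionParams(m=1.0 / slope, b=-intercept / slope, dgu_wt=dgu_wt)


def correct_ddg(ddg: float | np.ndarray, params: CorrectionParams | None = None):
    """Experimental-scale ΔΔG: m * ddg + b (affine, order-preserving)."""
    params = params or CorrectionParams()
    return params.m * np.asarray(ddg, dtype=float) + params.b


def unfolding_dg(ddg: float | np.ndarray, params: CorrectionParams | None = None,
                 subtractive: bool = False):
    """Estimated mutant unfolding free energy.

    The default form adds the corrected ΔΔG to the wild-type reference:
    dgu_wt + m*ddg + b.  ``subtractive=True`` selects the thermodynamically
    conventional alternative dgu_wt - (m*ddg + b), in which a destabilizing
    (positive) ΔΔG lowers the mutant's unfolding free energy; the two forms
    are never switched silently.
    """
    params = params or CorrectionParams()
    corrected = correct_ddg(ddg, params)
    return params.dgu_wt - corrected if subtractive else params.dgu_wt + corrected


def classify_mutation(mean_ddg: float, threshold: float | None = None,
                      inclusive: bool = False) -> str:
    """'deleterious' when the mean ΔΔG exceeds the threshold, else 'neutral'.

    The boundary is strict by default (exactly-threshold is neutral);
    ``inclusive=True`` flips that convention.
    """
    if threshold is None:
        threshold = prediction_error_threshold()
    if not math.isfinite(mean_ddg):
        raise ValueError("mean_ddg must be finite")
    hit = mean_ddg >= threshold if inclusive else mean_ddg > threshold
    return "deleterious" if hit else "neutral"


@dataclass
class DdgClassification:
    mutation: str
    stability_ddg: float
    binding_ddg: float
    category: str  # neutral | stability-only | binding-only | both
    threshold: float


def categorize_effects(stability_ddg: float, binding_ddg: float,
                       threshold: float | None = None,
                       mutation: str = "") -> DdgClassification:
    """Four-way stability/binding category from the two threshold tests."""
    if threshold is None:
        threshold = prediction_error_threshold()
    s = classify_mutation(stability_ddg, threshold) == "deleterious"
    b = classify_mutation(binding_ddg, threshold) == "deleterious"
    category = {(False, False): "neutral", (True, False): "stability-only",
                (False, True): "binding-only", (True, True): "both"}[(s, b)]
    return DdgClassification(mutation, stability_ddg, binding_ddg, category, threshold)


@dataclass
class ScanMatrix:
    """Aggregated scan: one row per (chain, position, substitution) cell.

    ``cells`` columns: chain (empty string for monomer scans), position, wt,
    mutant, mean, sd, n_records.  ``scope`` is "stability" for monomer scans
    and "binding" for dimer scans.
    """

    cells: pd.DataFrame
    scope: str = "stability"

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def positions(self) -> list[tuple[str, int]]:
        return sorted({(r.chain, r.position) for r in self.cells.itertuples()})

    def pivot(self, value: str = "mean") -> pd.DataFrame:
        """Position x substitution matrix suitable for heatmap plotting."""
        return self.cells.pivot_table(index=["chain", "position"], columns="mutant",
                                      values=value)

    def cell(self, position: int, mutant: str, chain: str = "") -> pd.Series:
        sel = self.cells[(self.cells.position == position)
                         & (self.cells.mutant == mutant)
                         & (self.cells.chain == chain)]
        if len(sel) != 1:
            raise KeyError(f"no unique cell for {chain or 'monomer'}/{position}{mutant}")
        return sel.iloc[0]


def aggregate_scan(records: Iterable[DdgRecord], scope: str = "stability",
                   require_complete: bool = True) -> ScanMatrix:
    """Pool raw records into per-cell means and sample standard deviations.

    All conformer x run records of a cell are pooled into one arithmetic
    mean (runs are not averaged hierarchically first — identical for
    balanced designs).  With ``require_complete`` every scanned position
    must carry all 19 substitutions of its wild type; gaps raise a
    :class:`CompletenessError` listing them.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to aggregate")
    df = pd.DataFrame(
        {
            "chain": [r.chain or "" for r in records],
            "position": [r.position for r in records],
            "wt": [r.wt for r in records],
            "mutant": [r.mutant for r in records],
            "ddg": [r.ddg for r in records],
        }
    )
    wt_check = df.groupby(["chain", "position"])["wt"].nunique()
    bad = wt_check[wt_check > 1]
    if len(bad):
        raise ValueError(f"conflicting wild-type codes at positions {list(bad.index)}")

    grouped = df.groupby(["chain", "position", "wt", "mutant"], sort=True)["ddg"]
    cells = grouped.agg(mean="mean", sd=lambda x: x.std(ddof=1), n_records="count")
    cells = cells.reset_index()
    cells["sd"] = cells["sd"].fillna(0.0)

    if require_complete:
        gaps = []
        for (chain, pos, wt), sub in cells.groupby(["chain", "position", "wt"]):
            expected = set(AMINO_ACIDS) - {wt}
            missing = expected - set(sub["mutant"])
            if missing:
                gaps.append((chain or "monomer", pos, sorted(missing)))
        if gaps:
            raise CompletenessError(f"incomplete scan, missing substitutions: {gaps}")
    return ScanMatrix(cells=cells, scope=scope)


def hotspot_positions(matrix: ScanMatrix, threshold: float | None = None,
                      min_fraction: float = 0.5) -> pd.DataFrame:
    """Positions where at least ``min_fraction`` of the 19 substitutions are deleterious.

    Returns a DataFrame (chain, position, wt, deleterious_fraction) sorted
    by descending fraction then position; requires a complete matrix.
    """
    if threshold is None:
        threshold = prediction_error_threshold()
    rows = []
    for (chain, pos, wt), sub in matrix.cells.groupby(["chain", "position", "wt"]):
        if len(sub) != len(AMINO_ACIDS) - 1:
            raise CompletenessError(
                f"position {chain or 'monomer'}/{pos} has {len(sub)} of 19 substitutions"
            )
        frac = float((sub["mean"] > threshold).mean())
        rows.append((chain, pos, wt, frac))
    out = pd.DataFrame(rows, columns=["chain", "position", "wt", "deleterious_fraction"])
    out = out[out["deleterious_fraction"] >= min_fraction]
    return out.sort_values(["deleterious_fraction", "chain", "position"],
                           ascending=[False, True, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["wt", "position", "mutant", "chain", "conformer", "run", "ddg"]


def read_ddg_table(path: str | Path) -> list[DdgRecord]:
    """Read the canonical tab-separated record table (one record per row)."""
    df = pd.read_csv(path, sep="\t", dtype={"wt": str, "mutant": str})
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for row in df.itertuples():
        chain = None if pd.isna(row.chain) or row.chain == "" else str(row.chain)
        records.append(
            DdgRecord(wt=row.wt, position=int(row.position), mutant=row.mutant,
                      ddg=float(row.ddg), conformer=int(row.conformer),
                      run=int(row.run), chain=chain)
        )
    return records


def write_ddg_table(records: Iterable[DdgRecord], path: str | Path) -> None:
    rows = [(r.wt, r.position, r.mutant, r.chain or "", r.conformer, r.run, r.ddg)
            for r in records]
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def parse_foldx_dif(path: str | Path, mutations: Sequence[tuple[str, int, str]],
                    conformer: int = 1, run: int = 1,
                    chain: str | None = None) -> list[DdgRecord]:
    """Thin parser for a "Dif"-style predictor output file.

    Such files list one mutant structure per data row, whitespace-separated,
    with the mutant file name first and the total energy difference second;
    rows appear in the order of the submitted mutation list, which the
    caller supplies as (wt, position, mutant) triples.  The canonical
    tab-separated record table is preferred whenever available.
    """
    values = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) >= 2 and parts[0].lower().endswith(".pdb"):
            try:
                values.append(float(parts[1]))
            except ValueError:
                continue
    if len(values) != len(mutations):
        raise ValueError(
            f"{path}: found {len(values)} energy rows for {len(mutations)} mutations"
        )
    return [
        DdgRecord(wt=wt, position=pos, mutant=mut, ddg=v,
                  conformer=conformer, run=run, chain=chain)
        for (wt, pos, mut), v in zip(mutations, values)
    ]
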