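"""Cross-validation of conformational ensembles against NMR observables.

Implements the chi-square-like agreement statistic between per-frame
predicted chemical shifts and experimental values, signed NOE distance
differences under linear or r^-6 ensemble averaging, restraint
categorization (short/long range, intermolecular), subspace overlap of two
ensembles' essential dynamics (RMSIP), and the histidine tautomer call from
the CD2 carbon shift.

The chi-square statistic for a group of s shifts over n frames is

    chi2 = 1/(s-1) * sum_j ( (mean_i delta_ij - delta_exp_j)^2 / delta_exp_j )

with the frame mean taken first; the per-shift experimental value appears
both in the squared deviation and in the denominator (the only reading
under which the sum is well formed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .ensemble import ConformationalEnsemble, ResidueId

__all__ = [
    "ShiftRecord",
    "PredictedShiftSeries",
    "NoeRestraint",
    "Chi2Report",
    "chi2_shifts",
    "running_chi2",
    "noe_differences",
    "categorize_restraint",
    "rmsip",
    "his_tautomer",
    "read_shift_table",
    "read_predicted_shifts",
    "read_noe_table",
    "write_noe_table",
]

NE2_TAUTOMER = "NE2-H"
ND1_TAUTOMER = "ND1-H"

#: Residue-separation beyond which a same-chain NOE counts as long range.
LONG_RANGE_SEPARATION = 4


@dataclass(frozen=True)
class ShiftRecord:
    """An experimental chemical shift for one atom (ppm)."""

    residue: ResidueId
    atom: str
    shift: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.shift) or self.shift == 0:
            raise ValueError(
                f"experimental shift for {self.residue}/{self.atom} must be finite "
                f"and non-zero (it appears in a denominator), got {self.shift}"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.residue.chain, self.residue.resnum, self.atom)


@dataclass
class PredictedShiftSeries:
    """Per-frame predicted shifts for one atom (ppm)."""

    residue: ResidueId
    atom: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValueError("predicted series needs at least one frame")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.residue.chain, self.residue.resnum, self.atom)


@dataclass(frozen=True)
class NoeRestraint:
    """An NOE-derived target distance between two atoms (nm)."""

    residue_a: ResidueId
    atom_a: str
    residue_b: ResidueId
    atom_b: str
    distance_exp: float
    category: str | None = None  # short | long | intermolecular

    def __post_init__(self) -> None:
        if (self.residue_a, self.atom_a) == (self.residue_b, self.atom_b):
            raise ValueError("restraint atoms must be distinct")
        if not self.distance_exp > 0:
            raise ValueError("experimental distance must be > 0")


@dataclass
class Chi2Report:
    """Chi-square per atom-type group and pooled over all shifts."""

    per_group: dict[str, float]
    s_per_group: dict[str, int]
    overall: float
    s_total: int


# ---------------------------------------------------------------------------
# Chemical shifts
# ---------------------------------------------------------------------------

def _match_series(predicted: Sequence[PredictedShiftSeries],
                  experimental: Sequence[ShiftRecord]):
    exp_by_key = {r.key: r for r in experimental}
    pairs = []
    unmatched = [p for p in predicted if p.key not in exp_by_key]
    if unmatched:
        labels = [f"{p.residue}/{p.atom}" for p in unmatched]
        raise ValueError(f"predicted series without experimental match: {labels}")
    for p in predicted:
        pairs.append((p, exp_by_key[p.key]))
    return pairs


def _chi2_from_pairs(pairs, n_frames: int | None = None) -> float:
    s = len(pairs)
    if s < 2:
        raise ValueError(f"chi2 needs at least 2 shifts per group, got {s}")
    total = 0.0
    for pred, exp in pairs:
        values = pred.values if n_frames is None else pred.values[:n_frames]
        if len(values) == 0:
            raise ValueError("window extends to zero frames")
        frame_mean = float(np.mean(values))
        total += (frame_mean - exp.shift) ** 2 / exp.shift
    return total / (s - 1)


def chi2_shifts(predicted: Sequence[PredictedShiftSeries],
                experimental: Sequence[ShiftRecord],
                group_by_atom_type: bool = True) -> Chi2Report:
    """Chi-square agreement between frame-mean predictions and experiment.

    Every predicted series must match an experimental record on
    (chain, residue number, atom name).  With ``group_by_atom_type`` the
    statistic is reported once per atom name (the backbone atom types of
    the usual convergence panels) in addition to the pooled value.
    """
    pairs = _match_series(predicted, experimental)
    per_group: dict[str, float] = {}
    s_per_group: dict[str, int] = {}
    if group_by_atom_type:
        atoms = sorted({p.atom for p, _ in pairs})
        for atom in atoms:
            group = [pe for pe in pairs if pe[0].atom == atom]
            s_per_group[atom] = len(group)
            per_group[atom] = _chi2_from_pairs(group)
    return Chi2Report(
        per_group=per_group,
        s_per_group=s_per_group,
        overall=_chi2_from_pairs(pairs),
        s_total=len(pairs),
    )


def running_chi2(predicted: Sequence[PredictedShiftSeries],
                 experimental: Sequence[ShiftRecord],
                 window_ends: Sequence[int]) -> pd.DataFrame:
    """Pooled chi-square recomputed over growing frame windows.

    ``window_ends`` are increasing frame counts; each entry yields the
    statistic using only frames up to that end.  A flattening curve is the
    signature of converged predictions.
    """
    ends = list(window_ends)
    if ends != sorted(ends) or len(set(ends)) != len(ends):
        raise ValueError("window ends must be strictly increasing")
    n_min = min(len(p.values) for p in predicted)
    if ends and ends[-1] > n_min:
        raise ValueError(f"window end {ends[-1]} beyond frame count {n_min}")
    pairs = _match_series(predicted, experimental)
    rows = [(end, _chi2_from_pairs(pairs, n_frames=end)) for end in ends]
    return pd.DataFrame(rows, columns=["window_end", "chi2"])


# ---------------------------------------------------------------------------
# NOE distances
# ---------------------------------------------------------------------------

def categorize_restraint(restraint: NoeRestraint) -> str:
    """short / long / intermolecular under the >4-residue separation rule.

    Atoms on different chains are intermolecular; same-chain pairs more than
    four residues apart in sequence are long range, otherwise short range.
    """
    if restraint.residue_a.chain != restraint.residue_b.chain:
        return "intermolecular"
    sep = abs(restraint.residue_a.resnum - restraint.residue_b.resnum)
    return "long" if sep > LONG_RANGE_SEPARATION else "short"


def noe_differences(ensemble: ConformationalEnsemble,
                    restraints: Sequence[NoeRestraint],
                    averaging: Literal["linear", "r6"] = "linear") -> pd.DataFrame:
    """Signed per-restraint difference between ensemble-average and target distance.

    ``linear`` averaging takes the arithmetic mean of the per-frame
    distances; ``r6`` the spectroscopic (mean d^-6)^(-1/6), which never
    exceeds the linear mean.  The result has one row per restraint with its
    category, averaged distance and difference (averaged - experimental,
    both nm); positive differences mean the ensemble is more open than the
    restraint demands.
    """
    rows = []
    for k, r in enumerate(restraints):
        try:
            ia = ensemble.atom_index(r.residue_a, r.atom_a)
            ib = ensemble.atom_index(r.residue_b, r.atom_b)
        except KeyError as exc:
            raise KeyError(f"restraint #{k} ({r.residue_a}/{r.atom_a} - "
                           f"{r.residue_b}/{r.atom_b}): {exc}") from None
        d = np.linalg.norm(ensemble.coords[:, ia, :] - ensemble.coords[:, ib, :], axis=1)
        if averaging == "linear":
            d_avg = float(np.mean(d))
        elif averaging == "r6":
            d_avg = float(np.mean(d ** -6.0) ** (-1.0 / 6.0))
        else:
            raise ValueError(f"unknown averaging mode {averaging!r}")
        rows.append((
            r.residue_a.chain, r.residue_a.resnum, r.atom_a,
            r.residue_b.chain, r.residue_b.resnum, r.atom_b,
            r.category or categorize_restraint(r),
            r.distance_exp, d_avg, d_avg - r.distance_exp,
        ))
    return pd.DataFrame(rows, columns=[
        "chain_a", "res_a", "atom_a", "chain_b", "res_b", "atom_b",
        "category", "distance_exp", "distance_avg", "difference",
    ])


# ---------------------------------------------------------------------------
# Essential-dynamics overlap
# ---------------------------------------------------------------------------

def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotation matrix minimizing ||P R - Q|| for centered point sets."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def _superposed_ca(ensemble: ConformationalEnsemble) -> tuple[list, np.ndarray]:
    """Cα identities and frames least-squares fit to the ensemble mean structure."""
    ca_idx = [i for i, n in enumerate(ensemble.atom_names) if n == "CA"]
    if not ca_idx:
        raise ValueError("ensemble has no CA atoms")
    ids = [(ensemble.residues[ensemble.atom_residue_index[i]].chain,
            ensemble.residues[ensemble.atom_residue_index[i]].resnum) for i in ca_idx]
    X = ensemble.coords[:, ca_idx, :].copy()
    X -= X.mean(axis=1, keepdims=True)
    ref = X[0]
    # two passes: fit to frame 0, then refit to the resulting mean structure
    for _ in range(2):
        aligned = np.stack([frame @ _kabsch(frame, ref) for frame in X])
        ref = aligned.mean(axis=0)
        ref -= ref.mean(axis=0)
    return ids, aligned


def _top_modes(aligned: np.ndarray, n_modes: int) -> np.ndarray:
    """Leading eigenvectors (columns) of the Cα fluctuation covariance matrix."""
    f = aligned.shape[0]
    flat = aligned.reshape(f, -1)
    flat = flat - flat.mean(axis=0)
    cov = flat.T @ flat / f
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evecs[:, order[:n_modes]]


def rmsip(ensemble_a: ConformationalEnsemble, ensemble_b: ConformationalEnsemble,
          n_modes: int = 20) -> float:
    """Root mean square inner product of the two ensembles' leading Cα subspaces.

    Each ensemble's frames are superposed onto their mean structure, the
    covariance matrix of Cα fluctuations is diagonalized, and the overlap
    of the first ``n_modes`` principal components is

        RMSIP = sqrt( 1/n_modes * sum_ij (v_i . w_j)^2 )  in [0, 1],

    1 for identical subspaces.  Both ensembles must share the Cα atom set
    and have at least ``n_modes`` frames.
    """
    ids_a, Xa = _superposed_ca(ensemble_a)
    ids_b, Xb = _superposed_ca(ensemble_b)
    if ids_a != ids_b:
        raise ValueError("ensembles have mismatched CA atom sets")
    for name, ens in (("first", ensemble_a), ("second", ensemble_b)):
        if ens.n_frames < n_modes:
            raise ValueError(f"{name} ensemble has {ens.n_frames} frames < n_modes={n_modes}")
    V = _top_modes(Xa, n_modes)
    W = _top_modes(Xb, n_modes)
    inner = V.T @ W
    return float(np.sqrt(np.sum(inner ** 2) / n_modes))


# ---------------------------------------------------------------------------
# Tautomer rule
# ---------------------------------------------------------------------------

def his_tautomer(cd2_shift: float) -> str:
    """Histidine tautomer from the CD2 carbon chemical shift.

    A CD2 shift strictly below 122 ppm indicates the Nε2-H tautomer,
    otherwise Nδ1-H (the boundary value itself falls on the Nδ1-H side).
    """
    if not math.isfinite(cd2_shift):
        raise ValueError("shift must be finite")
    return NE2_TAUTOMER if cd2_shift < 122.0 else ND1_TAUTOMER


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_shift_table(path: str | Path) -> list[ShiftRecord]:
    """Experimental shifts: tab-separated chain, resnum, resname, atom, shift."""
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "atom": str, "resname": str})
    return [
        ShiftRecord(ResidueId(r.chain, int(r.resnum), r.resname), r.atom, float(r.shift))
        for r in df.itertuples()
    ]


def read_predicted_shifts(path: str | Path) -> list[PredictedShiftSeries]:
    """Predicted shifts, long format: frame, chain, resnum, resname, atom, shift."""
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "atom": str, "resname": str})
    out = []
    for (chain, resnum, resname, atom), sub in df.groupby(
            ["chain", "resnum", "resname", "atom"], sort=True):
        sub = sub.sort_values("frame")
        out.append(PredictedShiftSeries(
            ResidueId(chain, int(resnum), resname), atom,
            sub["shift"].to_numpy(dtype=float)))
    return out


_NOE_COLUMNS = ["chain_a", "res_a", "resname_a", "atom_a",
                "chain_b", "res_b", "resname_b", "atom_b", "distance_nm"]


def read_noe_table(path: str | Path) -> list[NoeRestraint]:
    df = pd.read_csv(path, sep="\t", dtype={"chain_a": str, "chain_b": str,
                                            "atom_a": str, "atom_b": str})
    restraints = []
    for r in df.itertuples():
        restraint = NoeRestraint(
            ResidueId(r.chain_a, int(r.res_a), r.resname_a), r.atom_a,
            ResidueId(r.chain_b, int(r.res_b), r.resname_b), r.atom_b,
            float(r.distance_nm))
        restraints.append(NoeRestraint(
            restraint.residue_a, restraint.atom_a,
            restraint.residue_b, restraint.atom_b,
            restraint.distance_exp, categorize_restraint(restraint)))
    return restraints


def write_noe_table(restraints: Iterable[NoeRestraint], path: str | Path) -> None:
    rows = [(r.residue_a.chain, r.residue_a.resnum, r.residue_a.resname, r.atom_a,
             r.residue_b.chain, r.residue_b.resnum, r.residue_b.resname, r.atom_b,
             r.distance_exp) for r in restraints]
    pd.DataFrame(rows, columns=_NOE_COLUMNS).to_csv(path, sep="\t", index=False)
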