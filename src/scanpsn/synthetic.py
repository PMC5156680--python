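"""Synthetic inputs with known ground truth for every analysis stage.

Each generator is a pure function of its arguments and seed, and emits the
same in-memory objects (and file formats, through the I/O helpers) that the
analysis modules consume:

* toy two-chain ensembles whose residue pairs make contact in an exactly
  planted fraction of frames;
* saturation-scan record sets around planted per-cell means with planted
  hotspot positions;
* chemical-shift data as truth plus per-frame Gaussian noise;
* NOE restraint sets drawn from true ensemble-average distances;
* predictor score tables with planted consensus classes;
* negative-binomially distributed paired tumor/normal count matrices with
  planted fold changes and change correlations.

Geometry is deliberately minimal — backbone plus a single side-chain
pseudo-atom per residue — so center-of-mass and contact logic are exercised
without rotamer realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import PairedCountMatrix, PredictorThresholds
from .ddg import AMINO_ACIDS, DdgRecord
from .ensemble import ConformationalEnsemble, MassTable, ResidueId
from .nmr import (NoeRestraint, PredictedShiftSeries, ShiftRecord,
                  categorize_restraint)

__all__ = [
    "ContactSpec",
    "ScanTruth",
    "CountsTruth",
    "make_dimer_ensemble",
    "make_scan_truth",
    "make_ddg_scan",
    "make_shift_data",
    "make_noe_set",
    "make_predictor_table",
    "make_paired_counts",
]


# ---------------------------------------------------------------------------
# Ensembles with planted contact persistence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactSpec:
    """A planted contact: (chain, resnum) pair, persistence, two distances.

    The pair sits at ``contact_distance`` (below the intended cutoff) in a
    ``persistence`` fraction of frames and at ``separated_distance`` (above
    it) otherwise.
    """

    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    persistence: float
    contact_distance: float = 0.45
    separated_distance: float = 0.65

    def __post_init__(self) -> None:
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must lie in [0, 1]")
        if not self.contact_distance < self.separated_distance:
            raise ValueError("contact distance must be below separated distance")
        if self.residue_a == self.residue_b:
            raise ValueError("contact pair must involve two residues")


# Local atom offsets (nm) around the side-chain pseudo-atom position: a tiny
# rigid residue whose single CB atom IS the side-chain center of mass.
_RESIDUE_ATOMS = [
    ("N", "N", (-0.15, 0.10, 0.0)),
    ("CA", "C", (-0.10, 0.00, 0.0)),
    ("C", "C", (-0.15, -0.10, 0.0)),
    ("O", "O", (-0.20, -0.15, 0.0)),
    ("CB", "C", (0.0, 0.0, 0.0)),
]


def make_dimer_ensemble(
    n_frames: int,
    residues_per_chain: int,
    contact_specs: Sequence[ContactSpec] = (),
    coordinate_noise_sd: float = 0.0,
    seed: int = 0,
    resname: str = "ALA",
) -> ConformationalEnsemble:
    """A two-chain toy ensemble with exactly planted contact persistences.

    Chains A and B carry ``residues_per_chain`` identical residues each.
    Residues not named in a spec are spread far apart (2 nm spacing, chains
    6 nm apart) so no accidental contacts arise; each spec pair is parked in
    its own region and its second residue toggled between the contact and
    separated distance.  The contacting frame subset is a deterministic
    seeded permutation prefix of round(persistence * n_frames) frames, so
    small-ensemble persistence is exact.  Isotropic Gaussian noise of the
    given sd (nm) is then added to every atom.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)

    residues = [ResidueId(chain, i + 1, resname)
                for chain in ("A", "B") for i in range(residues_per_chain)]
    index_of = {(r.chain, r.resnum): k for k, r in enumerate(residues)}

    seen_pairs: set[frozenset] = set()
    moved: set[tuple[str, int]] = set()
    for spec in contact_specs:
        for key in (spec.residue_a, spec.residue_b):
            if key not in index_of:
                raise ValueError(f"contact spec references unknown residue {key}")
        pair = frozenset((spec.residue_a, spec.residue_b))
        if pair in seen_pairs:
            raise ValueError(f"conflicting specs for pair {sorted(pair)}")
        seen_pairs.add(pair)
        if spec.residue_b in moved:
            raise ValueError(f"residue {spec.residue_b} moved by more than one spec")
        moved.add(spec.residue_b)

    # Base side-chain positions: far-apart grid.
    base = np.zeros((len(residues), 3))
    for k, r in enumerate(residues):
        base[k] = ((r.resnum - 1) * 2.0, 0.0 if r.chain == "A" else -6.0, 0.0)
    # Park each spec pair in its own lane well away from the grid.
    anchor_of_spec = {}
    for s, spec in enumerate(contact_specs):
        anchor = np.array([s * 5.0, 10.0, 0.0])
        base[index_of[spec.residue_a]] = anchor
        anchor_of_spec[s] = anchor

    contact_frames: list[np.ndarray] = []
    for spec in contact_specs:
        n_contact = int(round(spec.persistence * n_frames))
        contact_frames.append(rng.permutation(n_frames)[:n_contact])

    coords = np.zeros((n_frames, len(residues) * len(_RESIDUE_ATOMS), 3))
    atom_names, atom_elements, atom_residue_index = [], [], []
    for k, r in enumerate(residues):
        for name, elem, _ in _RESIDUE_ATOMS:
            atom_names.append(name)
            atom_elements.append(elem)
            atom_residue_index.append(k)

    offsets = np.array([off for _, _, off in _RESIDUE_ATOMS])
    for f in range(n_frames):
        centers = base.copy()
        for s, spec in enumerate(contact_specs):
            d = (spec.contact_distance if f in contact_frames[s]
                 else spec.separated_distance)
            centers[index_of[spec.residue_b]] = anchor_of_spec[s] + np.array([d, 0.0, 0.0])
        coords[f] = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 3)

    if coordinate_noise_sd > 0:
        coords += rng.normal(0.0, coordinate_noise_sd, size=coords.shape)

    return ConformationalEnsemble(
        coords=coords,
        residues=residues,
        atom_names=atom_names,
        atom_elements=atom_elements,
        atom_residue_index=np.asarray(atom_residue_index),
        masses=MassTable(),
    )


# ---------------------------------------------------------------------------
# Saturation-scan records
# ---------------------------------------------------------------------------

@dataclass
class ScanTruth:
    """Planted per-cell mean ΔΔG values and the hotspot position list."""

    true_means: dict[tuple[str, int, str, str], float]  # (chain, pos, wt, mutant)
    hotspots: list[tuple[str, int]]

    def cells(self):
        return sorted(self.true_means)


def make_scan_truth(
    positions: Sequence[int],
    hotspots: Sequence[int] = (),
    chains: Sequence[str | None] = (None,),
    seed: int = 0,
    wt_sequence: dict[int, str] | None = None,
    neutral_range: tuple[float, float] = (-0.5, 0.9),
    hotspot_range: tuple[float, float] = (2.2, 4.0),
    hotspot_fraction: float = 1.0,
) -> ScanTruth:
    """Plant per-cell true means: hotspot positions intolerant to substitutions.

    Neutral cells draw uniform means comfortably below the 1.6 kcal/mol
    threshold; in hotspot positions a ``hotspot_fraction`` share of the 19
    substitutions draws means comfortably above it (margin >= 0.5 kcal/mol
    on each side by default).
    """
    rng = np.random.default_rng(seed)
    hotspots = list(hotspots)
    unknown = set(hotspots) - set(positions)
    if unknown:
        raise ValueError(f"hotspots outside scanned positions: {sorted(unknown)}")
    wt_sequence = wt_sequence or {
        pos: AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))] for pos in positions
    }
    true_means: dict[tuple[str, int, str, str], float] = {}
    hotspot_keys: list[tuple[str, int]] = []
    for chain in chains:
        ckey = chain or ""
        for pos in positions:
            wt = wt_sequence[pos]
            substitutions = [aa for aa in AMINO_ACIDS if aa != wt]
            if pos in hotspots:
                hotspot_keys.append((ckey, pos))
                n_hot = int(round(hotspot_fraction * len(substitutions)))
                hot_subs = set(rng.choice(substitutions, size=n_hot, replace=False))
            else:
                hot_subs = set()
            for mut in substitutions:
                lo, hi = hotspot_range if mut in hot_subs else neutral_range
                true_means[(ckey, pos, wt, mut)] = float(rng.uniform(lo, hi))
    return ScanTruth(true_means=true_means, hotspots=hotspot_keys)


def make_ddg_scan(
    truth: ScanTruth,
    records_per_cell: int = 100,
    noise_sd: float = 0.2,
    seed: int = 0,
    n_conformers: int = 20,
) -> list[DdgRecord]:
    """Gaussian records around the planted cell means, cycling conformer/run labels."""
    if records_per_cell < 1:
        raise ValueError("records_per_cell must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for (chain, pos, wt, mut) in truth.cells():
        mean = truth.true_means[(chain, pos, wt, mut)]
        values = mean + (rng.normal(0.0, noise_sd, records_per_cell)
                         if noise_sd > 0 else np.zeros(records_per_cell))
        for j, v in enumerate(values):
            records.append(DdgRecord(
                wt=wt, position=pos, mutant=mut, ddg=float(v),
                conformer=(j % n_conformers) + 1, run=(j // n_conformers) + 1,
                chain=chain or None))
    return records


# ---------------------------------------------------------------------------
# Shifts and NOEs
# ---------------------------------------------------------------------------

def make_shift_data(
    truth: pd.DataFrame,
    n_frames: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[ShiftRecord], list[PredictedShiftSeries]]:
    """Experimental records equal to truth; predictions = truth + frame noise.

    ``truth`` columns: chain, resnum, resname, atom, shift (all shifts
    non-zero).
    """
    rng = np.random.default_rng(seed)
    experimental, predicted = [], []
    for row in truth.itertuples():
        rid = ResidueId(str(row.chain), int(row.resnum), str(row.resname))
        experimental.append(ShiftRecord(rid, str(row.atom), float(row.shift)))
        noise = rng.normal(0.0, noise_sd, n_frames) if noise_sd > 0 else np.zeros(n_frames)
        predicted.append(PredictedShiftSeries(rid, str(row.atom), float(row.shift) + noise))
    return experimental, predicted


def make_noe_set(
    ensemble: ConformationalEnsemble,
    counts: tuple[int, int, int],
    jitter: float = 0.0,
    seed: int = 0,
    atom_name: str = "CB",
) -> list[NoeRestraint]:
    """Restraints sampled from true ensemble-average distances, by category.

    ``counts`` requests (long, short, intermolecular) restraints exactly;
    candidate pairs are same-atom-name pairs categorized by the standard
    separation rule.  Target distances are the linear ensemble averages
    plus Gaussian jitter (nm, clipped positive).
    """
    n_long, n_short, n_inter = counts
    rng = np.random.default_rng(seed)
    atoms = [(i, ensemble.residues[ensemble.atom_residue_index[i]])
             for i, name in enumerate(ensemble.atom_names) if name == atom_name]
    if not atoms:
        raise ValueError(f"no atoms named {atom_name!r} in ensemble")

    candidates: dict[str, list[tuple[int, ResidueId, int, ResidueId]]] = {
        "long": [], "short": [], "intermolecular": []}
    for a in range(len(atoms)):
        ia, ra = atoms[a]
        for b in range(a + 1, len(atoms)):
            ib, rb = atoms[b]
            probe = NoeRestraint(ra, atom_name, rb, atom_name, 1.0)
            candidates[categorize_restraint(probe)].append((ia, ra, ib, rb))

    restraints: list[NoeRestraint] = []
    for category, wanted in (("long", n_long), ("short", n_short),
                             ("intermolecular", n_inter)):
        pool = candidates[category]
        if wanted > len(pool):
            raise ValueError(
                f"requested {wanted} {category} restraints but only "
                f"{len(pool)} eligible pairs exist")
        chosen = rng.choice(len(pool), size=wanted, replace=False)
        for c in chosen:
            ia, ra, ib, rb = pool[int(c)]
            d = float(np.mean(np.linalg.norm(
                ensemble.coords[:, ia, :] - ensemble.coords[:, ib, :], axis=1)))
            if jitter > 0:
                d = max(0.01, d + float(rng.normal(0.0, jitter)))
            restraints.append(NoeRestraint(ra, atom_name, rb, atom_name, d, category))
    return restraints


# ---------------------------------------------------------------------------
# Predictor score tables
# ---------------------------------------------------------------------------

_NEUTRAL_GRADE_CLASSES = ("C0", "C15", "C25", "C35")

#: Score ranges on each side of every method's cutoff.
_SCORE_RANGES = {
    "provean": {"deleterious": (-8.0, -2.6), "neutral": (-2.4, 2.0)},
    "mutation_assessor": {"deleterious": (2.1, 4.5), "neutral": (-1.0, 1.9)},
    "polyphen2": {"deleterious": (0.55, 1.0), "neutral": (0.0, 0.45)},
    "ponp2": {"deleterious": (0.55, 1.0), "neutral": (0.0, 0.45)},
    "snap2": {"deleterious": (-100.0, -1.0), "neutral": (1.0, 100.0)},
    "mutpred": {"deleterious": (0.8, 1.0), "neutral": (0.0, 0.7)},
}


def make_predictor_table(
    mutations: Sequence[str],
    classes: Sequence[str],
    seed: int = 0,
) -> pd.DataFrame:
    """Score table with planted consensus classes per mutation.

    ``classes[i]`` is one of ``deleterious-consensus`` (every method votes
    deleterious), ``neutral-consensus`` (every method votes neutral) or
    ``mixed`` (methods straddle the cutoffs: at least one vote on each
    side).  Scores are drawn uniformly on the appropriate side of each
    method's published cutoff.
    """
    if len(mutations) != len(classes):
        raise ValueError("mutations and classes must align")
    rng = np.random.default_rng(seed)
    methods = list(_SCORE_RANGES) + ["align_gvgd"]
    rows = []
    for mut, cls in zip(mutations, classes):
        if cls not in ("deleterious-consensus", "neutral-consensus", "mixed"):
            raise ValueError(f"unknown class {cls!r} for mutation {mut}")
        if cls == "mixed":
            sides = ["deleterious", "neutral"] + [
                ("deleterious" if rng.random() < 0.5 else "neutral")
                for _ in range(len(methods) - 2)]
            rng.shuffle(sides)
            side_of = dict(zip(methods, sides))
        else:
            side = "deleterious" if cls == "deleterious-consensus" else "neutral"
            side_of = {m: side for m in methods}
        row: dict[str, object] = {"mutation": mut}
        for method in _SCORE_RANGES:
            lo, hi = _SCORE_RANGES[method][side_of[method]]
            row[method] = float(rng.uniform(lo, hi))
        grade_pool = (sorted(PredictorThresholds().damaging_classes)
                      if side_of["align_gvgd"] == "deleterious"
                      else _NEUTRAL_GRADE_CLASSES)
        row["align_gvgd"] = str(grade_pool[rng.integers(len(grade_pool))])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Paired tumor/normal counts
# ---------------------------------------------------------------------------

@dataclass
class CountsTruth:
    """Planted structure of a paired tumor/normal count matrix.

    baseline_means : per-gene normal-condition expected counts (> 0).
    log2_fold_changes : per-gene mean tumor shift in log2 units.
    dispersion : negative-binomial dispersion (var = mu + dispersion*mu^2).
    change_sd : per-patient sd of the tumor log2 change around its mean.
    change_correlation : per-gene loading on a shared per-patient latent
        factor; two genes with loadings rho_g, rho_h have change
        correlation ~= sqrt(rho_g * rho_h).
    """

    genes: list[str]
    baseline_means: np.ndarray
    log2_fold_changes: np.ndarray
    n_patients: int = 50
    dispersion: float = 0.01
    change_sd: float | np.ndarray = 0.3
    change_correlation: float | np.ndarray = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.baseline_means = np.asarray(self.baseline_means, dtype=float)
        self.log2_fold_changes = np.asarray(self.log2_fold_changes, dtype=float)
        if not np.all(self.baseline_means > 0):
            raise ValueError("baseline means must be > 0")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0")
        rho = np.broadcast_to(np.asarray(self.change_correlation, dtype=float),
                              self.baseline_means.shape)
        if np.any(np.abs(rho) > 1):
            raise ValueError("|change correlation| must be <= 1")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def make_paired_counts(truth: CountsTruth) -> PairedCountMatrix:
    """Negative-binomial paired counts with planted fold changes and correlations.

    Normal samples draw around the baseline means; tumor samples around
    baseline * 2^delta where the per-patient change delta carries the
    planted fold change, a shared latent factor (imposing the change
    correlations) and independent per-gene noise.
    """
    rng = np.random.default_rng(truth.seed)
    g = len(truth.genes)
    n = truth.n_patients
    sd = np.broadcast_to(np.asarray(truth.change_sd, dtype=float), (g,))
    rho = np.broadcast_to(np.asarray(truth.change_correlation, dtype=float), (g,))

    z = rng.normal(size=n)  # shared latent factor per patient
    eps = rng.normal(size=(g, n))
    loading = np.sign(rho) * np.sqrt(np.abs(rho))
    delta = (truth.log2_fold_changes[:, None]
             + sd[:, None] * (loading[:, None] * z[None, :]
                              + np.sqrt(1.0 - np.abs(rho))[:, None] * eps))

    tumor_mean = truth.baseline_means[:, None] * 2.0 ** delta
    normal_mean = np.broadcast_to(truth.baseline_means[:, None], (g, n))
    tumor = _nb_draw(rng, tumor_mean, truth.dispersion)
    normal = _nb_draw(rng, normal_mean, truth.dispersion)

    samples = [f"T{p:03d}" for p in range(n)] + [f"N{p:03d}" for p in range(n)]
    counts = pd.DataFrame(np.hstack([tumor, normal]), index=truth.genes, columns=samples)
    metadata = pd.DataFrame(
        {
            "condition": ["tumor"] * n + ["normal"] * n,
            "patient": [f"P{p:03d}" for p in range(n)] * 2,
        },
        index=samples,
    )
    return PairedCountMatrix(counts, metadata)
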