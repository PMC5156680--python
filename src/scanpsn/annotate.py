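"""Lightweight annotation computations.

Three unrelated but equally small pieces of bookkeeping live here:

* consensus calls over heterogeneous sequence-based variant-effect
  predictors, each with its published deleteriousness cutoff;
* the docking-energy filter that retains predicted complexes below a
  favorable-interaction threshold;
* node and edge values for a paired tumor/normal expression network —
  absolute log2 median differences per gene and Pearson correlations of
  per-patient expression changes per gene pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PredictorThresholds",
    "MutationCall",
    "PairedCountMatrix",
    "consensus_classify",
    "filter_docking",
    "node_value",
    "edge_value",
    "build_annotation_network",
    "write_annotation_graphml",
    "read_annotation_graphml",
]

#: Deleterious classes of the substitution-grade classifier.
DAMAGING_GRADE_CLASSES = frozenset({"C45", "C55", "C65"})

DOCKING_ENERGY_CUTOFF = -2.39  # kcal/mol, favorable-interaction threshold


@dataclass
class PredictorThresholds:
    """Per-method deleteriousness rules.

    Numeric rules are (direction, cut) pairs meaning "deleterious when
    score <direction> cut"; the grade-class method is deleterious when its
    class label falls in ``damaging_classes``.  The snap2 direction follows
    the printed rule (< 0 deleterious) and is configurable because the
    tool's own convention is the opposite.
    """

    numeric_rules: dict[str, tuple[str, float]] = field(default_factory=lambda: {
        "provean": ("<", -2.5),
        "mutation_assessor": (">", 2.0),
        "polyphen2": (">", 0.5),
        "ponp2": (">", 0.5),
        "snap2": ("<", 0.0),
        "mutpred": (">", 0.75),
    })
    damaging_classes: frozenset = DAMAGING_GRADE_CLASSES
    class_method: str = "align_gvgd"

    @property
    def methods(self) -> list[str]:
        return list(self.numeric_rules) + [self.class_method]

    def verdict(self, method: str, value) -> str:
        """'deleterious' | 'neutral' | 'missing' for one method's score."""
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return "missing"
        if method == self.class_method:
            return "deleterious" if str(value) in self.damaging_classes else "neutral"
        try:
            direction, cut = self.numeric_rules[method]
        except KeyError:
            raise KeyError(f"unknown predictor method {method!r}") from None
        value = float(value)
        hit = value < cut if direction == "<" else value > cut
        return "deleterious" if hit else "neutral"


@dataclass
class MutationCall:
    mutation: str
    verdicts: dict[str, str]
    consensus_count: int
    n_scored: int  # non-missing methods
    complete_consensus: bool


def consensus_classify(scores: pd.DataFrame,
                       thresholds: PredictorThresholds | None = None) -> list[MutationCall]:
    """Apply every method's published cutoff and count deleterious verdicts.

    ``scores`` needs a ``mutation`` column plus one column per method;
    missing scores (NaN/None) are excluded from the consensus denominator.
    ``complete_consensus`` is True when every scored method votes
    deleterious (and at least one method is scored).
    """
    thresholds = thresholds or PredictorThresholds()
    method_cols = [c for c in scores.columns if c != "mutation"]
    unknown = set(method_cols) - set(thresholds.methods)
    if unknown:
        raise KeyError(f"unknown predictor method columns: {sorted(unknown)}")
    calls = []
    for _, row in scores.iterrows():
        verdicts = {m: thresholds.verdict(m, row[m]) for m in method_cols}
        scored = [v for v in verdicts.values() if v != "missing"]
        count = sum(v == "deleterious" for v in scored)
        calls.append(MutationCall(
            mutation=str(row["mutation"]),
            verdicts=verdicts,
            consensus_count=count,
            n_scored=len(scored),
            complete_consensus=bool(scored) and count == len(scored),
        ))
    return calls


def filter_docking(energies: pd.DataFrame,
                   cutoff: float = DOCKING_ENERGY_CUTOFF) -> pd.DataFrame:
    """Retain complexes with docking energy strictly below the cutoff.

    ``energies`` has columns ``complex`` and ``energy`` (kcal/mol); a value
    exactly at the cutoff is dropped ("lower than" is strict).
    """
    if not np.all(np.isfinite(energies["energy"])):
        raise ValueError("docking energies must be finite")
    return energies[energies["energy"] < cutoff].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Paired expression values
# ---------------------------------------------------------------------------

class PairedCountMatrix:
    """Gene x sample counts with tumor/normal condition and patient pairing.

    ``counts`` is a genes-by-samples DataFrame of non-negative counts;
    ``metadata`` is indexed by sample name with columns ``condition``
    ("tumor" or "normal") and ``patient``.  Paired operations use only
    patients contributing exactly one tumor and one normal sample.
    """

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame):
        if not set(metadata.index) >= set(counts.columns):
            missing = sorted(set(counts.columns) - set(metadata.index))
            raise ValueError(f"samples without metadata: {missing}")
        bad = set(metadata["condition"]) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.metadata = metadata.loc[list(counts.columns)]

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def samples(self, condition: str) -> list[str]:
        return list(self.metadata.index[self.metadata["condition"] == condition])

    def paired_patients(self) -> list[str]:
        """Patients with exactly one tumor and one normal sample."""
        tab = self.metadata.groupby("patient")["condition"].value_counts().unstack(fill_value=0)
        ok = tab[(tab.get("tumor", 0) == 1) & (tab.get("normal", 0) == 1)]
        return list(ok.index)

    def paired_log_changes(self, gene: str) -> pd.Series:
        """Per-patient log2(tumor+1) - log2(normal+1) for one gene."""
        if gene not in self.counts.index:
            raise KeyError(f"gene {gene!r} not in matrix")
        patients = self.paired_patients()
        meta = self.metadata
        deltas = {}
        for p in patients:
            t = meta.index[(meta["patient"] == p) & (meta["condition"] == "tumor")][0]
            n = meta.index[(meta["patient"] == p) & (meta["condition"] == "normal")][0]
            deltas[p] = (np.log2(self.counts.at[gene, t] + 1.0)
                         - np.log2(self.counts.at[gene, n] + 1.0))
        return pd.Series(deltas, name=gene)


def node_value(counts: PairedCountMatrix, gene: str) -> float:
    """|median log2(tumor+1) - median log2(normal+1)| for one gene."""
    if gene not in counts.counts.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    tumor = counts.samples("tumor")
    normal = counts.samples("normal")
    if not tumor or not normal:
        raise ValueError("need at least one sample in each condition")
    log_t = np.log2(counts.counts.loc[gene, tumor].to_numpy(dtype=float) + 1.0)
    log_n = np.log2(counts.counts.loc[gene, normal].to_numpy(dtype=float) + 1.0)
    return float(abs(np.median(log_t) - np.median(log_n)))


def edge_value(counts: PairedCountMatrix, gene_a: str, gene_b: str,
               mode: Literal["paired_change", "tumor_only"] = "paired_change") -> float:
    """Pearson correlation between two genes' expression values.

    The default ``paired_change`` mode correlates per-patient
    log2(tumor+1) - log2(normal+1) change vectors — the correlation of
    expression *changes*.  ``tumor_only`` correlates log2(count+1) across
    tumor samples instead.  A zero-variance input yields NaN with a warning
    (undefined, never silently 0).
    """
    if mode == "paired_change":
        x = counts.paired_log_changes(gene_a).to_numpy()
        y = counts.paired_log_changes(gene_b).to_numpy()
        if len(x) < 3:
            raise ValueError(f"paired mode needs >= 3 paired patients, got {len(x)}")
    elif mode == "tumor_only":
        tumor = counts.samples("tumor")
        if len(tumor) < 3:
            raise ValueError(f"tumor_only mode needs >= 3 tumor samples, got {len(tumor)}")
        for gene in (gene_a, gene_b):
            if gene not in counts.counts.index:
                raise KeyError(f"gene {gene!r} not in matrix")
        x = np.log2(counts.counts.loc[gene_a, tumor].to_numpy(dtype=float) + 1.0)
        y = np.log2(counts.counts.loc[gene_b, tumor].to_numpy(dtype=float) + 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn(f"zero variance for pair ({gene_a}, {gene_b}); correlation undefined")
        return float("nan")
    r, _ = stats.pearsonr(x, y)
    return float(r)


# ---------------------------------------------------------------------------
# Annotated network export
# ---------------------------------------------------------------------------

def build_annotation_network(
    edges: Iterable[tuple[str, str]],
    node_values: dict[str, float],
    edge_values: dict[tuple[str, str], float],
) -> nx.Graph:
    """Assemble the annotated expression network.

    Node attribute ``abs_log2_median_diff`` comes from ``node_values``;
    edge attribute ``pearson_r`` from ``edge_values`` (keys in either
    order).  Every edge endpoint must carry a node value.
    """
    g = nx.Graph()
    for gene in sorted(node_values):
        g.add_node(gene, abs_log2_median_diff=float(node_values[gene]))
    for a, b in edges:
        for endpoint in (a, b):
            if endpoint not in node_values:
                raise KeyError(f"edge endpoint {endpoint!r} has no node value")
        r = edge_values.get((a, b), edge_values.get((b, a)))
        if r is None:
            raise KeyError(f"no edge value for pair ({a}, {b})")
        g.add_edge(a, b, pearson_r=float(r))
    return g


def write_annotation_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def read_annotation_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
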