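"""Evaluation harness: top-model accuracy, recall, McNemar tests, marker hits.

A criterion *correctly learns* a generating model when the top-ranked DDAG's
parent set equals the generating parent set exactly.  *Recall* relaxes this
to #(S intersect T) / #S for generating SNPs S and top-model SNPs T, so a
larger model containing the interacting pair still earns full recall.
Paired criteria are compared with the McNemar chi-square test on their
per-dataset correctness indicators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import DDAG
from .search import RankedModels, score_models
from .simulate import SimulationDesign, sample_dataset

__all__ = [
    "ExperimentSummary",
    "MarkerHitReport",
    "top_model_correct",
    "recall",
    "mcnemar",
    "accuracy_experiment",
    "marker_hit_report",
]


def top_model_correct(ranked: RankedModels, truth: DDAG) -> bool:
    """True iff the rank-1 parent set equals the generating parent set exactly."""
    if not ranked.entries:
        raise ValueError("ranking is empty")
    return ranked.entries[0][0].parent_set == truth.parent_set


def recall(truth_set: Iterable[int], top_set: Iterable[int]) -> float:
    """#(S intersect T) / #S for generating SNPs S and top-model SNPs T."""
    s, t = set(truth_set), set(top_set)
    if not s:
        raise ValueError("the generating SNP set must be nonempty")
    return len(s & t) / len(s)


def mcnemar(b: int, c: int, corrected: bool = True) -> tuple[float, float]:
    """McNemar chi-square test from the two discordant-pair counts.

    ``b`` = datasets where method A was correct and B wrong; ``c`` the
    reverse.  Returns (statistic, p) with p from the chi-square distribution
    on 1 degree of freedom.  The continuity correction is applied by default.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    if b + c == 0:
        raise ValueError("McNemar test undefined with no discordant pairs")
    if corrected:
        stat = (abs(b - c) - 1) ** 2 / (b + c) if abs(b - c) > 1 else 0.0
    else:
        stat = (b - c) ** 2 / (b + c)
    return float(stat), float(chi2.sf(stat, df=1))


@dataclass
class ExperimentSummary:
    """Per-(criterion, sample size) accuracy and recall, plus McNemar results.

    ``rows`` has columns criterion_id, sample_size, correct_count, total,
    mean_recall, recall_sum.  ``correctness`` holds the per-dataset boolean
    indicator for each criterion (datasets in design order), from which
    ``mcnemar_vs_best`` compares every criterion against the one with the
    highest overall correct count.
    """

    rows: pd.DataFrame
    correctness: pd.DataFrame
    mcnemar_vs_best: pd.DataFrame

    @property
    def best_criterion(self) -> str:
        totals = self.correctness.sum(axis=0)
        return str(totals.index[int(np.argmax(totals.to_numpy()))])


def accuracy_experiment(designs: Sequence[SimulationDesign],
                        criteria: Sequence[str],
                        kmin: int = 1, kmax: int = 4,
                        corrected: bool = True) -> ExperimentSummary:
    """Run the full simulated-data comparison across criteria.

    For every design the dataset is sampled, every DDAG with kmin..kmax
    parents is scored under every criterion (sharing sufficient statistics),
    and the top model is checked against the generating pair.  Deterministic
    given the design seeds.
    """
    if not designs or not criteria:
        raise ValueError("need at least one design and one criterion")
    correct: dict[str, list[bool]] = {}
    rec: dict[str, list[float]] = {}
    sizes: list[int] = []
    cids: list[str] | None = None
    for design in designs:
        sim = sample_dataset(design)
        sizes.append(design.n_cases + design.n_controls)
        ranked = score_models(sim.dataset, list(criteria), kmin, kmax)
        if cids is None:
            cids = list(ranked)
            for cid in cids:
                correct[cid], rec[cid] = [], []
        truth = sim.truth
        for cid in cids:
            top = ranked[cid].entries[0][0]
            correct[cid].append(top.parent_set == truth.parent_set)
            rec[cid].append(recall(truth.parent_set, top.parent_set))

    sizes_arr = np.array(sizes)
    records = []
    for cid in cids:
        c = np.array(correct[cid])
        r = np.array(rec[cid])
        for size in sorted(set(sizes)):
            mask = sizes_arr == size
            records.append({
                "criterion_id": cid,
                "sample_size": size,
                "correct_count": int(c[mask].sum()),
                "total": int(mask.sum()),
                "mean_recall": float(r[mask].mean()),
                "recall_sum": float(r[mask].sum()),
            })
    rows = pd.DataFrame.from_records(records)
    correctness = pd.DataFrame({cid: correct[cid] for cid in cids})

    totals = correctness.sum(axis=0)
    best = str(totals.index[int(np.argmax(totals.to_numpy()))])
    mc_records = []
    for cid in cids:
        if cid == best:
            stat, p = np.nan, np.nan
        else:
            b = int((correctness[best] & ~correctness[cid]).sum())
            cc = int((~correctness[best] & correctness[cid]).sum())
            if b + cc == 0:
                stat, p = np.nan, np.nan
            else:
                stat, p = mcnemar(b, cc, corrected=corrected)
        mc_records.append({"criterion_id": cid, "versus": best,
                           "statistic": stat, "p_value": p})
    return ExperimentSummary(rows, correctness, pd.DataFrame.from_records(mc_records))


@dataclass(frozen=True)
class MarkerHitReport:
    """How often a marker set appears among the top-ranked models."""

    models_with_hit: int
    distinct_markers: int
    flags: tuple[bool, ...]


def marker_hit_report(ranked: RankedModels, marker_set: Iterable[int],
                      top_n: int = 25) -> MarkerHitReport:
    """Count top-n models intersecting a marker set and the distinct markers seen."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    markers = set(marker_set)
    flags, seen = [], set()
    for ddag, _ in ranked.entries[:top_n]:
        hit = markers & set(ddag.parent_set)
        flags.append(bool(hit))
        seen |= hit
    return MarkerHitReport(sum(flags), len(seen), tuple(flags))
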