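"""Per-8mer bin enrichment, weighted expression score, and classification.

The expression score of an 8mer is the RPM-weighted average of the GFP-bin
weights, ``S = sum_b w_b * rpm_b / sum_b rpm_b`` with default weights
(-2, -1, 0, +1, +2) over the five bins ordered from lowest to highest GFP
intensity. S is therefore bounded by the extreme weights ([-2, +2]), is
invariant to rescaling all bin RPMs, and can only increase when read mass
moves from a lower- to a higher-weight bin. Scores above +1 are called
activating, below -1 repressive (strict comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from utrscreen.counts import CountTable
from utrscreen.simulate import (
    ACTIVATING,
    BACKGROUND_STRINGENT,
    DEFAULT_GFP_BINS,
    GFP_ALL,
    NEUTRAL,
    REPRESSIVE,
)

DEFAULT_WEIGHTS: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0)
DEFAULT_BIN_LABELS: tuple[str, ...] = tuple(b[0] for b in DEFAULT_GFP_BINS)

THRESHOLD_ACTIVATING = 1.0
THRESHOLD_REPRESSIVE = -1.0


class UndefinedScoreError(ValueError):
    """All-zero bin RPMs: the weighted average is undefined."""


@dataclass(frozen=True)
class ScoreRecord:
    """One 8mer's enrichment profile, expression score, rank, and class."""

    motif: str
    enrichment: dict[str, float]
    score: float
    rank: int
    label: str


def robust_background_set(
    bg_counts: CountTable,
    min_count: int = 1,
    population: str = BACKGROUND_STRINGENT,
    require_all_replicates: bool = True,
) -> set[str]:
    """8mers robustly present in the stringent background population.

    A motif qualifies when its raw count is at least ``min_count`` in every
    replicate of ``population`` (or in any replicate when
    ``require_all_replicates`` is off). This set is the analysis universe:
    only motifs that were demonstrably in the experiment can be scored.
    """
    reps = bg_counts.replicates(population)
    if not reps:
        raise ValueError(
            f"stringent background population {population!r} missing from table"
        )
    if min_count <= 0:
        return set(bg_counts.df[bg_counts.df["population"] == population]["motif"])
    sets = [
        set(counts[counts >= min_count].index)
        for counts in (bg_counts.counts_for(population, r) for r in reps)
    ]
    return set.intersection(*sets) if require_all_replicates else set.union(*sets)


def replicate_concordance(
    table: CountTable, population: str
) -> float:
    """Pearson correlation of per-motif raw counts between two replicates."""
    reps = table.replicates(population)
    if len(reps) < 2:
        raise ValueError(f"population {population!r} needs >=2 replicates")
    a = table.counts_for(population, reps[0])
    b = table.counts_for(population, reps[1])
    joined = pd.concat([a, b], axis=1).fillna(0)
    r, _ = stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
    return float(r)


def bin_enrichment(
    rpm_by_bin: Mapping[str, float],
    rpm_background: float,
    pseudocount: float = 0.0,
) -> dict[str, float]:
    """Per-bin enrichment: each bin's RPM divided by the background RPM.

    The background is the 8mer's RPM in the GFP-ALL / dsRed middle-50 %
    population. A pseudocount (default 0) guards against a zero background
    if the gate is reconfigured.
    """
    denom = rpm_background + pseudocount
    if denom <= 0:
        raise ValueError("background RPM must be positive (use a pseudocount?)")
    return {b: (rpm + pseudocount) / denom for b, rpm in rpm_by_bin.items()}


def expression_score(
    rpm_by_bin: Sequence[float],
    weights: Sequence[float] = DEFAULT_WEIGHTS,
) -> float:
    """Weighted-average expression score S = sum(w*rpm) / sum(rpm).

    Raises
    ------
    UndefinedScoreError
        If every bin RPM is zero.
    """
    rpm = np.asarray(rpm_by_bin, float)
    w = np.asarray(weights, float)
    if rpm.shape != w.shape:
        raise ValueError("rpm vector and weights must have equal length")
    if (rpm < 0).any():
        raise ValueError("bin RPMs must be non-negative")
    total = rpm.sum()
    if total == 0:
        raise UndefinedScoreError("all-zero bin RPMs: score undefined")
    return float(np.dot(w, rpm) / total)


def classify(
    score: float,
    threshold_activating: float = THRESHOLD_ACTIVATING,
    threshold_repressive: float = THRESHOLD_REPRESSIVE,
) -> str:
    """Call activating (S > +1), repressive (S < -1), else neutral; bounds strict."""
    if score > threshold_activating:
        return ACTIVATING
    if score < threshold_repressive:
        return REPRESSIVE
    return NEUTRAL


def rank_scores(records: Sequence[ScoreRecord]) -> list[ScoreRecord]:
    """Order records descending by score, ties broken lexicographically by motif."""
    ordered = sorted(records, key=lambda rec: (-rec.score, rec.motif))
    return [
        ScoreRecord(r.motif, r.enrichment, r.score, i + 1, r.label)
        for i, r in enumerate(ordered)
    ]


def score_screen(
    table: CountTable,
    bin_labels: Sequence[str] = DEFAULT_BIN_LABELS,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    background_population: str = GFP_ALL,
    stringent_population: str = BACKGROUND_STRINGENT,
    min_count: int = 1,
    aggregate: str = "sum",
    threshold_activating: float = THRESHOLD_ACTIVATING,
    threshold_repressive: float = THRESHOLD_REPRESSIVE,
) -> pd.DataFrame:
    """Full scoring pass over a raw count table.

    Restricts to the robust background set (motifs with raw count >=
    ``min_count`` in every stringent-background replicate), collapses
    replicates (``aggregate``: 'sum' or 'mean'), RPM-normalizes per library,
    then computes per-bin enrichment against ``background_population``, the
    weighted expression score, rank, and class for each motif. Motifs whose
    five bin RPMs are all zero are dropped with a warning column rather than
    scored.

    Returns a frame indexed by motif with columns ``enrichment_<bin>`` per
    bin, ``score``, ``rank``, and ``label``.
    """
    if len(bin_labels) != len(weights):
        raise ValueError("bin_labels and weights must have equal length")
    universe = robust_background_set(
        table, min_count=min_count, population=stringent_population
    )
    rpm = table.aggregate_replicates(mode=aggregate).with_rpm().rpm_matrix()
    missing = [
        p for p in (*bin_labels, background_population) if p not in rpm.columns
    ]
    if missing:
        raise ValueError(f"populations missing from count table: {missing}")
    rpm = rpm.loc[rpm.index.isin(universe)]

    bins = rpm[list(bin_labels)]
    scored = bins.sum(axis=1) > 0
    bins = bins.loc[scored]
    w = np.asarray(weights, float)
    scores = (bins.to_numpy() @ w) / bins.sum(axis=1).to_numpy()

    bg = rpm.loc[scored, background_population]
    out = pd.DataFrame(index=bins.index)
    for label in bin_labels:
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"enrichment_{label}"] = np.where(
                bg > 0, bins[label] / bg, np.nan
            )
    out["score"] = scores
    # descending score, ties broken lexicographically: stable sort after sorting by motif
    out = out.sort_index().sort_values("score", ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    out["label"] = [
        classify(s, threshold_activating, threshold_repressive) for s in out["score"]
    ]
    return out


def threshold_sweep(
    scores: pd.Series, thresholds: Sequence[float]
) -> pd.DataFrame:
    """Activating/repressive call counts over a grid of symmetric cutoffs."""
    rows = []
    for t in thresholds:
        rows.append(
            {
                "threshold": t,
                "n_activating": int((scores > t).sum()),
                "n_repressive": int((scores < -t).sum()),
            }
        )
    return pd.DataFrame(rows)
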