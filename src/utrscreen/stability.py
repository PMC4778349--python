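"""RNA/DNA abundance ratios, stability classification, and decay half-lives."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from utrscreen.counts import CountTable

STABILIZING = "stabilizing"
DESTABILIZING = "destabilizing"
NEUTRAL = "neutral"

DEFAULT_CUTOFFS = (-0.5, 0.5)


def rna_dna_ratio(
    rna_table: CountTable,
    dna_table: CountTable,
    motifs: set[str] | None = None,
    population: str | None = None,
) -> pd.DataFrame:
    """Per-motif log2(RNA RPM / DNA RPM) with stability classification.

    Both tables are replicate-summed and RPM-normalized here; ``motifs``
    (typically the robust background set) restricts the analysis universe.
    Motifs with zero RPM in either library are dropped with a warning — the
    log ratio is undefined for them.

    Returns a frame indexed by motif with columns ``dna_rpm``, ``rna_rpm``,
    ``log2_ratio``, and ``label``.
    """
    def _rpm(table: CountTable) -> pd.Series:
        df = table.df
        if population is not None:
            df = df[df["population"] == population]
            table = CountTable(df)
        mat = table.aggregate_replicates("sum").with_rpm().rpm_matrix()
        if mat.shape[1] != 1:
            raise ValueError("expected a single population per table; pass population=")
        return mat.iloc[:, 0]

    dna = _rpm(dna_table)
    rna = _rpm(rna_table)
    joined = pd.concat({"dna_rpm": dna, "rna_rpm": rna}, axis=1).fillna(0.0)
    if motifs is not None:
        joined = joined.loc[joined.index.isin(motifs)]
    zero = (joined["dna_rpm"] <= 0) | (joined["rna_rpm"] <= 0)
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} motifs with zero RPM in DNA or RNA library"
        )
        joined = joined.loc[~zero]
    joined["log2_ratio"] = np.log2(joined["rna_rpm"] / joined["dna_rpm"])
    joined["label"] = [classify_stability(r) for r in joined["log2_ratio"]]
    return joined


def classify_stability(
    log2_ratio: float, cutoffs: tuple[float, float] = DEFAULT_CUTOFFS
) -> str:
    """Stabilizing if ratio > upper cutoff, destabilizing if < lower; bounds strict."""
    lower, upper = cutoffs
    if lower >= upper:
        raise ValueError("cutoffs must be (lower, upper) with lower < upper")
    if log2_ratio > upper:
        return STABILIZING
    if log2_ratio < lower:
        return DESTABILIZING
    return NEUTRAL


@dataclass(frozen=True)
class HalfLifeFit:
    """First-order decay fit: rate k (1/h), half-life ln2/k (h), and errors.

    ``non_decaying`` flags a non-positive estimated rate, in which case the
    half-life is NaN.
    """

    half_life: float
    rate: float
    rate_stderr: float
    half_life_stderr: float
    r_squared: float
    non_decaying: bool


def fit_half_life(
    timepoints: Sequence[float], abundance: Sequence[float]
) -> HalfLifeFit:
    """Estimate a transcript half-life from a decay time course.

    Fits first-order decay by ordinary least squares on log abundance,
    ``ln(abundance) = -k * t + c``, giving ``t_half = ln2 / k``. The
    half-life standard error follows by first-order error propagation,
    ``se(t_half) = ln2 * se(k) / k^2``. Replicates are handled by passing
    all (t, abundance) points together. Requires >= 3 points and strictly
    positive abundances.
    """
    t = np.asarray(timepoints, float)
    a = np.asarray(abundance, float)
    if t.shape != a.shape:
        raise ValueError("timepoints and abundance must have equal length")
    if len(t) < 3:
        raise ValueError("need at least 3 timepoints to fit a decay rate")
    if (a <= 0).any():
        raise ValueError("abundances must be strictly positive (log undefined)")
    if np.allclose(t, t[0]):
        raise ValueError("timepoints must vary")
    res = stats.linregress(t, np.log(a))
    k = -res.slope
    if k <= 0:
        return HalfLifeFit(
            half_life=math.nan,
            rate=k,
            rate_stderr=res.stderr,
            half_life_stderr=math.nan,
            r_squared=res.rvalue**2,
            non_decaying=True,
        )
    return HalfLifeFit(
        half_life=math.log(2) / k,
        rate=k,
        rate_stderr=res.stderr,
        half_life_stderr=math.log(2) * res.stderr / k**2,
        r_squared=res.rvalue**2,
        non_decaying=False,
    )


def abundance_from_ct(
    ct_target: Sequence[float], ct_reference: Sequence[float]
) -> np.ndarray:
    """qPCR preprocessing: 2^-(Ct_target - Ct_reference), normalized to the
    first timepoint so abundance(0) = 1. The reference gene plays the role
    of the loading control (e.g. GAPDH)."""
    dct = np.asarray(ct_target, float) - np.asarray(ct_reference, float)
    rel = 2.0 ** (-dct)
    return rel / rel[0]


def fit_half_life_table(decay: pd.DataFrame) -> HalfLifeFit:
    """Fit one half-life from a tidy decay table.

    Accepts columns (time_h, abundance) with optional ``replicate``, or
    (time_h, ct_target, ct_ref) for raw qPCR input (converted per replicate
    via :func:`abundance_from_ct`). Replicate points are pooled into one fit.
    """
    if "abundance" in decay.columns:
        return fit_half_life(decay["time_h"], decay["abundance"])
    if {"ct_target", "ct_ref"} <= set(decay.columns):
        parts = []
        groups = (
            decay.groupby("replicate")
            if "replicate" in decay.columns
            else [(0, decay)]
        )
        for _, grp in groups:
            grp = grp.sort_values("time_h")
            ab = abundance_from_ct(grp["ct_target"], grp["ct_ref"])
            parts.append(pd.DataFrame({"time_h": grp["time_h"].to_numpy(), "abundance": ab}))
        pooled = pd.concat(parts, ignore_index=True)
        return fit_half_life(pooled["time_h"], pooled["abundance"])
    raise ValueError("decay table needs 'abundance' or ('ct_target', 'ct_ref') columns")


def score_ratio_correlation(
    scores: Mapping[str, float] | pd.Series,
    ratios: Mapping[str, float] | pd.Series,
    discordance_quantile: float = 0.25,
) -> tuple[float, float, dict[str, list[str]]]:
    """Correlate expression scores with log2(RNA/DNA) ratios over shared motifs.

    Returns (Pearson r, two-sided p, discordant sets). The discordant sets —
    motifs in the top score quantile but bottom ratio quantile and vice
    versa — are the candidates whose protein-level effect is not explained
    by RNA abundance (putative translational regulators).
    """
    s = pd.Series(scores, dtype=float)
    rho = pd.Series(ratios, dtype=float)
    shared = s.index.intersection(rho.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared motifs")
    s, rho = s.loc[shared], rho.loc[shared]
    r, p = stats.pearsonr(s, rho)
    q = discordance_quantile
    s_hi, s_lo = s.quantile(1 - q), s.quantile(q)
    r_hi, r_lo = rho.quantile(1 - q), rho.quantile(q)
    discordant = {
        "high_score_low_ratio": sorted(shared[(s >= s_hi) & (rho <= r_lo)]),
        "low_score_high_ratio": sorted(shared[(s <= s_lo) & (rho >= r_hi)]),
    }
    return float(r), float(p), discordant
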