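"""Motif-category enrichment, reverse-complement analysis, and conservation.

Category enrichment asks whether a motif category (prior hits, miRNA target
sites, RBP motifs, conserved 8mers, ...) is over-represented among the
activating or repressive calls: with b = |category ∩ calls|, n = |category|,
B = |calls|, N = |universe|, fold = (b/n)/(B/N), significance by a two-sided
Fisher exact test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from utrscreen.simulate import RNA_ALPHABET, rna

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def fisher_two_sided(b: int, n: int, B: int, N: int, convention: str = "minlike") -> float:
    """Exact two-sided Fisher p-value for the 2x2 membership table.

    The null is hypergeometric: drawing B calls from a universe of N motifs
    of which n are in the category, observing b in the overlap. The default
    'minlike' convention sums the probabilities of all outcomes no more
    likely than the observed one (the convention of R's fisher.test and
    scipy); 'doubling' doubles the smaller tail instead.
    """
    if not (0 <= n <= N and 0 <= B <= N):
        raise ValueError("need 0 <= n <= N and 0 <= B <= N")
    if not (max(0, n + B - N) <= b <= min(n, B)):
        raise ValueError(f"b={b} outside the support for (n={n}, B={B}, N={N})")
    support = np.arange(max(0, n + B - N), min(n, B) + 1)
    pmf = sps.hypergeom.pmf(support, N, n, B)
    p_obs = pmf[b - support[0]]
    if convention == "minlike":
        # relative tolerance guards against ties broken by float rounding
        p = pmf[pmf <= p_obs * (1 + 1e-7)].sum()
    elif convention == "doubling":
        lower = pmf[support <= b].sum()
        upper = pmf[support >= b].sum()
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown convention: {convention!r}")
    return float(min(p, 1.0))


@dataclass(frozen=True)
class CategoryEnrichmentResult:
    """Fold enrichment of a category within a call set, with Fisher p-value."""

    category: str
    direction: str
    b: int
    n: int
    B: int
    N: int
    fold: float
    p: float


def category_enrichment(
    category: set[str],
    calls: set[str],
    universe: set[str],
    category_name: str = "category",
    direction: str = "activating",
    convention: str = "minlike",
) -> CategoryEnrichmentResult:
    """Test over-representation of ``category`` within ``calls``.

    Both sets are intersected with ``universe`` (motifs outside it are
    dropped with a warning): categories must be judged against motifs that
    could have been called.
    """
    dropped = (category | calls) - universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} motifs outside the screened universe dropped"
        )
    category = category & universe
    calls = calls & universe
    b = len(category & calls)
    n = len(category)
    B = len(calls)
    N = len(universe)
    fold = (b / n) / (B / N) if n > 0 and B > 0 else math.nan
    p = fisher_two_sided(b, n, B, N, convention=convention)
    return CategoryEnrichmentResult(category_name, direction, b, n, B, N, fold, p)


def read_motif_list(path: str | Path) -> set[str]:
    """Load a category list: plain text, one 8mer per line, RNA alphabet."""
    motifs = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            motifs.add(rna(line))
    return motifs


def reverse_complement(motif: str) -> str:
    """RNA-alphabet reverse complement (an involution)."""
    m = rna(motif)
    if any(c not in RNA_ALPHABET for c in m):
        raise ValueError(f"not an RNA motif: {motif!r}")
    return m.translate(_COMPLEMENT)[::-1]


def revcomp_score_correlation(
    scores: Mapping[str, float] | pd.Series,
) -> tuple[float, float, int]:
    """Pearson correlation of scores across reverse-complement motif pairs.

    Each unordered pair with both members scored contributes once, with the
    lexicographically smaller motif's score on the first axis. Returns
    (r, p, n_pairs); with no complete pairs the correlation is undefined
    (NaN) and a warning is issued. Self-complementary palindromes (e.g.
    ACGUACGU) form no pair and are excluded.
    """
    s = pd.Series(scores, dtype=float)
    xs, ys = [], []
    for motif in s.index:
        mate = reverse_complement(motif)
        if motif < mate and mate in s.index:
            xs.append(s[motif])
            ys.append(s[mate])
    if len(xs) < 2:
        warnings.warn("no (or too few) complete reverse-complement pairs; r undefined")
        return math.nan, math.nan, len(xs)
    r, p = sps.pearsonr(xs, ys)
    return float(r), float(p), len(xs)


# ---------------------------------------------------------------------------
# Conservation against multi-species alignments
# ---------------------------------------------------------------------------

GAP_CHARS = set("-.")


def _check_block(rows: Sequence[str]) -> list[str]:
    if len(rows) < 2:
        raise ValueError("alignment block needs at least 2 rows")
    rows = [r.upper().replace("U", "T") for r in rows]
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows must have equal aligned length")
    return rows


def conserved_instance_count(
    alignment: Sequence[str], motif: str, reference_row: int = 0
) -> int:
    """Count conserved occurrences of an 8mer in one alignment block.

    An occurrence is conserved when the motif occupies ``len(motif)``
    consecutive alignment columns in the reference row and every row is
    identical (and gap-free) over those columns. Overlapping occurrences
    all count. Rows and motif may be RNA or DNA; comparison is in DNA sense.
    """
    rows = _check_block(alignment)
    target = motif.upper().replace("U", "T")
    k = len(target)
    ref = rows[reference_row]
    count = 0
    for i in range(len(ref) - k + 1):
        if ref[i : i + k] != target:
            continue
        if all(r[i : i + k] == target for r in rows):
            count += 1
    return count


def count_conserved(
    alignments: Iterable[Sequence[str]], motif: str
) -> int:
    """Total conserved occurrences of ``motif`` across alignment blocks."""
    return sum(conserved_instance_count(block, motif) for block in alignments)


@dataclass(frozen=True)
class ConservationResult:
    """Observed conserved count vs the mean over composition-matched shuffles."""

    motif: str
    conserved_count: int
    shuffled_mean: float
    signal: float  # observed / shuffled mean; NaN when the shuffled mean is 0
    n_shuffles: int


def shuffle_motif(motif: str, rng: np.random.Generator, max_tries: int = 1000) -> str:
    """Composition-preserving shuffle; avoids returning the original unless
    the motif has no distinct permutation (e.g. a homopolymer)."""
    letters = list(motif)
    if len(set(letters)) == 1:
        return motif
    for _ in range(max_tries):
        shuffled = "".join(rng.permutation(letters))
        if shuffled != motif:
            return shuffled
    return "".join(rng.permutation(letters))


def conservation_signal(
    motif: str,
    alignments: Sequence[Sequence[str]],
    n_shuffles: int = 50,
    seed: int = 0,
) -> ConservationResult:
    """Judge a motif's conserved count against shuffled control 8mers.

    Controls preserve the motif's nucleotide multiset; the signal is the
    observed count divided by the mean count over ``n_shuffles`` controls.
    A zero shuffled mean leaves the signal undefined (NaN) with a warning.
    Deterministic given the seed.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    rng = np.random.default_rng(seed)
    alignments = list(alignments)
    observed = count_conserved(alignments, motif)
    shuffled = [
        count_conserved(alignments, shuffle_motif(motif, rng))
        for _ in range(n_shuffles)
    ]
    mean = float(np.mean(shuffled))
    if mean == 0:
        if observed:
            warnings.warn(
                f"shuffled controls of {motif} never conserved; signal unbounded"
            )
            signal = math.inf
        else:
            signal = 0.0
    else:
        signal = observed / mean
    return ConservationResult(motif, observed, mean, signal, n_shuffles)


def read_alignment_fasta(path: str | Path) -> list[str]:
    """Read one aligned multi-FASTA block (e.g. 4 species rows) as strings."""
    from Bio import SeqIO

    rows = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    return _check_block(rows)


def enrichment_table(
    categories: Mapping[str, set[str]],
    calls_by_direction: Mapping[str, set[str]],
    universe: set[str],
    convention: str = "minlike",
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Run every category against every call direction; tidy result frame."""
    rows = []
    n_tests = len(categories) * len(calls_by_direction)
    for name, cat in categories.items():
        for direction, calls in calls_by_direction.items():
            res = category_enrichment(
                cat, calls, universe, name, direction, convention=convention
            )
            p = min(1.0, res.p * n_tests) if bonferroni else res.p
            rows.append(
                {
                    "category": name,
                    "direction": direction,
                    "b": res.b,
                    "n": res.n,
                    "B": res.B,
                    "N": res.N,
                    "fold": res.fold,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
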