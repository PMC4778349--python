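"""Synthetic reporter screens with known ground truth.

Generates libraries of 8mers with specified expression/stability effects,
simulates reporter-bearing cells, applies FACS-style dsRed/GFP percentile
gating into the screen's populations, and emits sequencing counts or full
amplicon FASTQ files — so the whole downstream pipeline can be exercised and
validated without any external data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from utrscreen.counts import CountTable

RNA_ALPHABET = "ACGU"
MOTIF_LENGTH = 8
MAX_LIBRARY = 4**MOTIF_LENGTH  # 65,536 possible 8mers

ACTIVATING = "activating"
REPRESSIVE = "repressive"
NEUTRAL = "neutral"

#: Population label for all GFP+ cells within the dsRed middle-50 % gate.
GFP_ALL = "GFP-ALL"
#: Population label for the stringent background: dsRed middle-25 % GFP+ cells.
BACKGROUND_STRINGENT = "BG25"

#: Default GFP percentile bins with their score weights, lowest to highest.
DEFAULT_GFP_BINS: tuple[tuple[str, tuple[float, float], float], ...] = (
    ("0-10", (0.0, 10.0), -2.0),
    ("20-30", (20.0, 30.0), -1.0),
    ("40-60", (40.0, 60.0), 0.0),
    ("70-80", (70.0, 80.0), 1.0),
    ("90-100", (90.0, 100.0), 2.0),
)


class ImpossibleLibraryError(ValueError):
    """More unique 8mers requested than exist over the 4-letter alphabet."""


class EmptyPopulationError(ValueError):
    """A simulated cell population ended up with no cells."""


def _int_to_motif(idx: int) -> str:
    chars = []
    for _ in range(MOTIF_LENGTH):
        chars.append(RNA_ALPHABET[idx & 3])
        idx >>= 2
    return "".join(reversed(chars))


def rna(seq: str) -> str:
    """Normalize a sequence to the RNA alphabet (T→U, uppercase)."""
    return seq.upper().replace("T", "U")


def dna(seq: str) -> str:
    """Normalize a sequence to the DNA alphabet (U→T, uppercase)."""
    return seq.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthTable:
    """Per-8mer latent regulatory effects driving the simulator.

    ``expression_effect`` is the shift in mean log-GFP in units of the
    population standard deviation; ``stability_effect`` is the shift in log2
    per-cell reporter mRNA abundance. ``true_class`` must be consistent with
    the sign of ``expression_effect`` under ``class_threshold``.
    """

    motif: np.ndarray
    expression_effect: np.ndarray
    stability_effect: np.ndarray
    true_class: np.ndarray
    class_threshold: float = 0.0

    def __post_init__(self) -> None:
        motifs = [str(m) for m in self.motif]
        if len(set(motifs)) != len(motifs):
            raise ValueError("motifs must be unique")
        for m in motifs:
            if len(m) != MOTIF_LENGTH or any(c not in RNA_ALPHABET for c in m):
                raise ValueError(f"invalid motif {m!r}: need 8 letters of ACGU")
        eff = np.asarray(self.expression_effect, float)
        cls = np.asarray(self.true_class)
        thr = self.class_threshold
        expected = np.where(
            eff > thr, ACTIVATING, np.where(eff < -thr, REPRESSIVE, NEUTRAL)
        )
        if not (cls == expected).all():
            bad = np.asarray(motifs)[cls != expected]
            raise ValueError(
                f"true_class inconsistent with expression_effect sign for {bad[:5]}"
            )

    def __len__(self) -> int:
        return len(self.motif)

    def effect_of(self, motif: str) -> float:
        i = np.nonzero(self.motif == motif)[0]
        if not len(i):
            raise KeyError(motif)
        return float(self.expression_effect[i[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motif": self.motif,
                "expression_effect": self.expression_effect,
                "stability_effect": self.stability_effect,
                "true_class": self.true_class,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, class_threshold: float = 0.0) -> "TruthTable":
        return cls(
            motif=df["motif"].to_numpy(dtype=object),
            expression_effect=df["expression_effect"].to_numpy(float),
            stability_effect=df["stability_effect"].to_numpy(float),
            true_class=df["true_class"].to_numpy(dtype=object),
            class_threshold=class_threshold,
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def generate_truth(
    n_motifs: int,
    class_fractions: tuple[float, float, float] = (0.12, 0.09, 0.79),
    effect_magnitude: float = 1.5,
    stability_magnitude: float = 0.0,
    seed: int = 0,
) -> TruthTable:
    """Draw a library of unique 8mers with assigned regulatory classes.

    Parameters
    ----------
    n_motifs
        Library size; at most 4^8 = 65,536.
    class_fractions
        (activating, repressive, neutral) fractions, summing to 1. Class
        counts are the rounded fractions; neutral takes the remainder.
    effect_magnitude
        |expression effect| (in SD units) given to every non-neutral motif;
        neutral motifs have effect exactly 0.
    stability_magnitude
        |log2 stability effect| given to non-neutral motifs with the same
        sign as their expression effect (0 disables stability effects).
    """
    if n_motifs <= 0:
        raise ValueError("n_motifs must be positive")
    if n_motifs > MAX_LIBRARY:
        raise ImpossibleLibraryError(
            f"cannot draw {n_motifs} unique 8mers; only {MAX_LIBRARY} exist"
        )
    fracs = np.asarray(class_fractions, float)
    if fracs.min() < 0 or fracs.max() > 1 or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("class_fractions must lie in [0,1] and sum to 1")
    if effect_magnitude <= 0:
        raise ValueError("effect_magnitude must be positive")

    rng = np.random.default_rng(seed)
    codes = rng.choice(MAX_LIBRARY, size=n_motifs, replace=False)
    motifs = np.array([_int_to_motif(int(c)) for c in codes], dtype=object)

    n_act = int(round(n_motifs * fracs[0]))
    n_rep = int(round(n_motifs * fracs[1]))
    if n_act + n_rep > n_motifs:  # rounding overflow at extreme fractions
        n_rep = n_motifs - n_act
    expr = np.zeros(n_motifs)
    expr[:n_act] = effect_magnitude
    expr[n_act : n_act + n_rep] = -effect_magnitude
    order = rng.permutation(n_motifs)
    expr = expr[order]
    stab = np.sign(expr) * stability_magnitude
    cls = np.where(expr > 0, ACTIVATING, np.where(expr < 0, REPRESSIVE, NEUTRAL))
    return TruthTable(
        motif=motifs,
        expression_effect=expr,
        stability_effect=stab,
        true_class=cls.astype(object),
    )


# ---------------------------------------------------------------------------
# Cells and gating
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellPopulation:
    """Per-cell reporter identities and fluorescence intensities."""

    motif: np.ndarray
    gfp: np.ndarray
    dsred: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.motif)
        if len(self.gfp) != n or len(self.dsred) != n:
            raise ValueError("per-cell arrays must have equal length")
        if n and (np.min(self.gfp) <= 0 or np.min(self.dsred) <= 0):
            raise ValueError("fluorescence intensities must be strictly positive")

    def __len__(self) -> int:
        return len(self.motif)

    def subset(self, index: np.ndarray) -> "CellPopulation":
        return CellPopulation(self.motif[index], self.gfp[index], self.dsred[index])

    def motif_counts(self) -> pd.Series:
        return pd.Series(self.motif).value_counts()


def simulate_cells(
    truth: TruthTable,
    mean_integrations: float = 8.0,
    noise_sd: float = 1.0,
    baseline_log_gfp: float = 7.0,
    seed: int = 0,
) -> CellPopulation:
    """Simulate single-copy reporter integrations as a pooled cell population.

    Per-motif cell counts are Poisson with mean ``mean_integrations``
    (independent rare integration events). log-GFP per cell is
    ``baseline + expression_effect * noise_sd + Normal(0, noise_sd)`` — a
    lognormal intensity with additive log-scale effects, so effects are
    expressed in population-SD units. dsRed is lognormal and independent of
    the motif.
    """
    if len(truth) == 0:
        raise ValueError("truth table is empty")
    if mean_integrations <= 0 or noise_sd <= 0:
        raise ValueError("mean_integrations and noise_sd must be positive")
    rng = np.random.default_rng(seed)
    n_cells_per_motif = rng.poisson(mean_integrations, size=len(truth))
    total = int(n_cells_per_motif.sum())
    if total == 0:
        raise EmptyPopulationError("no cells: every motif drew zero integrations")
    motif = np.repeat(truth.motif, n_cells_per_motif)
    shift = np.repeat(truth.expression_effect * noise_sd, n_cells_per_motif)
    log_gfp = baseline_log_gfp + shift + rng.normal(0.0, noise_sd, size=total)
    dsred = np.exp(rng.normal(baseline_log_gfp, 0.5, size=total))
    return CellPopulation(motif=motif, gfp=np.exp(log_gfp), dsred=dsred)


@dataclass(frozen=True)
class SortScheme:
    """FACS gating layout: dsRed windows, GFP percentile bins, replicates.

    ``sort_depth`` selects the replicate resampling rule: ``None`` (default)
    sorts each gate exhaustively, so replicate cell subsets are identical and
    replicate variation arises downstream at sequencing; a positive integer
    bootstrap-resamples that many cells per gate independently per replicate,
    modelling a finite sorted sample.
    """

    dsred_window: tuple[float, float] = (25.0, 75.0)
    dsred_stringent_window: tuple[float, float] = (37.5, 62.5)
    gfp_bins: tuple[tuple[str, tuple[float, float], float], ...] = DEFAULT_GFP_BINS
    replicates: int = 2
    sort_depth: int | None = None

    def __post_init__(self) -> None:
        for lo, hi in (self.dsred_window, self.dsred_stringent_window):
            if not (0 <= lo < hi <= 100):
                raise ValueError("dsRed windows must be increasing within [0, 100]")
        prev_hi = -1.0
        prev_w = -np.inf
        for label, (lo, hi), w in self.gfp_bins:
            if not (0 <= lo < hi <= 100):
                raise ValueError(f"bin {label}: interval must be within [0, 100]")
            if lo < prev_hi:
                raise ValueError(f"bin {label}: GFP intervals overlap")
            if w <= prev_w:
                raise ValueError("bin weights must be strictly increasing")
            prev_hi, prev_w = hi, w
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    @property
    def bin_labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.gfp_bins)

    @property
    def bin_weights(self) -> dict[str, float]:
        return {label: w for label, _, w in self.gfp_bins}


def _percentile_window(values: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = np.percentile(values, window)
    mask = (values >= lo) & (values <= hi) if window[1] == 100 else (
        (values >= lo) & (values < hi)
    )
    return mask


def gate_and_sort(
    cells: CellPopulation,
    scheme: SortScheme = SortScheme(),
    seed: int = 0,
) -> dict[str, dict[int, CellPopulation]]:
    """Gate cells on dsRed, bin on GFP percentiles, and sort replicates.

    The dsRed window is applied first; GFP percentiles are computed within
    the dsRed-gated set. Returns ``{population_label: {replicate: cells}}``
    covering the five GFP bins, ``GFP-ALL`` (all GFP+ cells in the dsRed
    middle-50 %), and ``BG25`` (the stringent dsRed middle-25 % background).
    Bins are mutually exclusive within a replicate. Empty gates trigger an
    explicit warning, never silent omission.
    """
    if len(cells) < 100:
        raise ValueError("need at least 100 cells for meaningful percentiles")
    rng = np.random.default_rng(seed)

    gated = cells.subset(_percentile_window(cells.dsred, scheme.dsred_window))
    stringent = cells.subset(
        _percentile_window(cells.dsred, scheme.dsred_stringent_window)
    )

    gates: dict[str, CellPopulation] = {GFP_ALL: gated, BACKGROUND_STRINGENT: stringent}
    for label, window, _ in scheme.gfp_bins:
        gates[label] = gated.subset(_percentile_window(gated.gfp, window))

    out: dict[str, dict[int, CellPopulation]] = {}
    for label, pop in gates.items():
        if len(pop) == 0:
            warnings.warn(f"empty gate: population {label!r} has no cells")
        reps: dict[int, CellPopulation] = {}
        for r in range(1, scheme.replicates + 1):
            if scheme.sort_depth is None or len(pop) == 0:
                reps[r] = pop
            else:
                idx = rng.integers(0, len(pop), size=scheme.sort_depth)
                reps[r] = pop.subset(idx)
        out[label] = reps
    return out


# ---------------------------------------------------------------------------
# Sequencing
# ---------------------------------------------------------------------------


def sequence_counts(
    populations: Mapping[str, Mapping[int, CellPopulation]],
    depth: int,
    seed: int = 0,
    concentration: float | None = None,
) -> CountTable:
    """Draw per-library sequencing counts from sorted populations.

    Each (population, replicate) library receives ``depth`` reads sampled
    multinomially from the population's motif frequencies. A finite
    ``concentration`` switches to Dirichlet-multinomial sampling (smaller =
    more overdispersed, modelling PCR jackpotting); the default is exact
    multinomial. This is the count-level equivalent of :func:`emit_fastq`
    with a zero corruption rate.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, int, int]] = []
    for label in populations:
        for rep in sorted(populations[label]):
            pop = populations[label][rep]
            if len(pop) == 0:
                continue
            vc = pop.motif_counts()
            p = vc.to_numpy(float) / len(pop)
            if concentration is not None and np.isfinite(concentration):
                p = rng.dirichlet(p * concentration)
            counts = rng.multinomial(depth, p)
            rows.extend(
                (m, label, rep, int(c)) for m, c in zip(vc.index, counts) if c > 0
            )
    return CountTable.from_records(rows)


@dataclass(frozen=True)
class ReadLayout:
    """Amplicon read structure: barcode, fixed flanks, variable 8mer, filler.

    A read is ``barcode + upstream_flank + motif(DNA) + downstream_flank +
    filler`` padded to ``read_length``. ``min_phred`` is the strict lower
    bound on base quality in the barcode and motif (Q <= min_phred fails).
    """

    barcode_length: int = 6
    upstream_flank: str = "CATAC"
    motif_length: int = MOTIF_LENGTH
    downstream_flank: str = "ATA"
    read_length: int = 50
    min_phred: int = 20

    def __post_init__(self) -> None:
        if (
            self.barcode_length
            + len(self.upstream_flank)
            + self.motif_length
            + len(self.downstream_flank)
            > self.read_length
        ):
            raise ValueError("amplicon structure does not fit within read_length")

    @property
    def motif_start(self) -> int:
        return self.barcode_length + len(self.upstream_flank)

    @property
    def motif_end(self) -> int:
        return self.motif_start + self.motif_length


def default_barcodes(labels: Sequence[tuple[str, int]], length: int = 6) -> dict[str, tuple[str, int]]:
    """Assign distinct fixed-length (hence prefix-free) barcodes to libraries."""
    pool = ("".join(p) for p in itertools.product("ACGT", repeat=length))
    return {next(pool): (label, rep) for label, rep in labels}


@dataclass(frozen=True)
class EmitResult:
    """FASTQ emission output: file path, barcode map, and intended truth counts."""

    fastq_path: Path
    barcode_map: dict[str, tuple[str, int]]
    truth_counts: CountTable


HIGH_Q = "I"  # Phred 40
LOW_Q = "#"  # Phred 2, below any sensible threshold


def emit_fastq(
    populations: Mapping[str, Mapping[int, CellPopulation]],
    layout: ReadLayout,
    depth: int,
    error_rate: float = 0.0,
    seed: int = 0,
    out_path: str | Path = "reads.fastq",
    barcode_map: Mapping[str, tuple[str, int]] | None = None,
    concentration: float | None = None,
) -> EmitResult:
    """Write amplicon FASTQ reads for every sorted (population, replicate).

    Reads are sampled per library as in :func:`sequence_counts`; motifs are
    emitted in the DNA alphabet. A fraction ``error_rate`` of reads is
    corrupted to exercise the filters: a low-quality base in the barcode or
    8mer, or a substitution in one flank, chosen uniformly. The returned
    ``truth_counts`` are the exact per-motif read counts emitted (before
    corruption), the oracle for round-trip tests.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    keys = [
        (label, rep)
        for label in populations
        for rep in sorted(populations[label])
        if len(populations[label][rep]) > 0
    ]
    if barcode_map is None:
        barcode_map = default_barcodes(keys, layout.barcode_length)
    by_key = {v: k for k, v in barcode_map.items()}

    filler_len = layout.read_length - layout.motif_end - len(layout.downstream_flank)
    bases = np.array(list("ACGT"), dtype="S1")
    rows: list[tuple[str, str, int, int]] = []
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        read_no = 0
        clean_qual = HIGH_Q * layout.read_length
        for label, rep in keys:
            pop = populations[label][rep]
            vc = pop.motif_counts()
            p = vc.to_numpy(float) / len(pop)
            if concentration is not None and np.isfinite(concentration):
                p = rng.dirichlet(p * concentration)
            counts = rng.multinomial(depth, p)
            barcode = by_key[(label, rep)]
            # one filler string per read, drawn in a single vectorized batch
            fillers = (
                bases[rng.integers(0, 4, size=(depth, filler_len))]
                .view(f"S{filler_len}")
                .ravel()
            )
            corrupt_flags = (
                rng.random(depth) < error_rate
                if error_rate
                else np.zeros(depth, dtype=bool)
            )
            i = 0
            for m, c in zip(vc.index, counts):
                if c == 0:
                    continue
                rows.append((m, label, rep, int(c)))
                prefix = (
                    barcode
                    + layout.upstream_flank
                    + dna(m)
                    + layout.downstream_flank
                )
                for _ in range(int(c)):
                    read_no += 1
                    seq = prefix + fillers[i].decode()
                    qual = clean_qual
                    if corrupt_flags[i]:
                        seq, qual = _corrupt(seq, qual, layout, rng)
                    i += 1
                    fh.write(f"@sim_{read_no} {label} rep{rep}\n{seq}\n+\n{qual}\n")
    return EmitResult(
        fastq_path=out_path,
        barcode_map=dict(barcode_map),
        truth_counts=CountTable.from_records(rows),
    )


def _corrupt(
    seq: str, qual: str, layout: ReadLayout, rng: np.random.Generator
) -> tuple[str, str]:
    """Damage one read so that it fails exactly one filter."""
    mode = rng.integers(0, 3)
    if mode == 0:  # low quality somewhere in barcode + motif
        region = list(range(layout.barcode_length)) + list(
            range(layout.motif_start, layout.motif_end)
        )
        i = int(rng.choice(region))
        qual = qual[:i] + LOW_Q + qual[i + 1 :]
    elif mode == 1:  # break upstream flank
        i = layout.barcode_length + int(rng.integers(0, len(layout.upstream_flank)))
        seq = seq[:i] + _other_base(seq[i], rng) + seq[i + 1 :]
    else:  # break downstream flank
        i = layout.motif_end + int(rng.integers(0, len(layout.downstream_flank)))
        seq = seq[:i] + _other_base(seq[i], rng) + seq[i + 1 :]
    return seq, qual


def _other_base(base: str, rng: np.random.Generator) -> str:
    return str(rng.choice([b for b in "ACGT" if b != base]))


# ---------------------------------------------------------------------------
# RNA stage
# ---------------------------------------------------------------------------


def simulate_rna(
    truth: TruthTable,
    dna_counts: Mapping[str, int],
    depth: int | None = None,
    seed: int = 0,
) -> dict[str, int]:
    """Sample cDNA library counts given genomic-DNA counts and stability effects.

    Expected RNA abundance per motif is ``dna_count * 2**stability_effect``;
    a multinomial draw of ``depth`` reads (default: same depth as the DNA
    library) yields RNA counts, so motifs with zero stability effect have an
    RNA/DNA RPM ratio of ~1.
    """
    motifs = [m for m in dna_counts if dna_counts[m] > 0]
    if not motifs:
        raise ValueError("no motifs with positive DNA counts")
    effects = {m: e for m, e in zip(truth.motif, truth.stability_effect)}
    weights = np.array(
        [dna_counts[m] * 2.0 ** effects.get(m, 0.0) for m in motifs], float
    )
    if depth is None:
        depth = int(sum(dna_counts.values()))
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, weights / weights.sum())
    return {m: int(c) for m, c in zip(motifs, counts)}


def replace_scheme(scheme: SortScheme, **kwargs) -> SortScheme:
    """Convenience wrapper for dataclasses.replace on a SortScheme."""
    return replace(scheme, **kwargs)
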