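"""End-to-end orchestration: simulate -> count -> score -> stability -> enrich.

A run is fully described by a :class:`RunConfig` (serializable to YAML) and
a global seed; all stage randomness is derived from that seed via spawned
child generators, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

import utrscreen
from utrscreen import scoring, stability
from utrscreen.counts import CountTable
from utrscreen.enrichment import enrichment_table
from utrscreen.simulate import (
    BACKGROUND_STRINGENT,
    ReadLayout,
    SortScheme,
    emit_fastq,
    gate_and_sort,
    generate_truth,
    sequence_counts,
    simulate_cells,
    simulate_rna,
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Declarative description of one screen simulation + analysis run."""

    seed: int = 0
    # simulation
    n_motifs: int = 1000
    class_fractions: tuple[float, float, float] = (0.12, 0.09, 0.79)
    effect_magnitude: float = 1.5
    stability_magnitude: float = 0.55
    mean_integrations: float = 50.0
    noise_sd: float = 1.0
    depth: int = 200_000
    rna_depth: int | None = None
    error_rate: float = 0.0
    emit_reads: bool = False  # write/parse FASTQ instead of count-level sampling
    # gating
    dsred_window: tuple[float, float] = (25.0, 75.0)
    dsred_stringent_window: tuple[float, float] = (37.5, 62.5)
    replicates: int = 2
    # scoring
    weights: tuple[float, ...] = scoring.DEFAULT_WEIGHTS
    threshold_activating: float = 1.0
    threshold_repressive: float = -1.0
    min_count: int = 1
    aggregate: str = "sum"
    # stability
    stability_cutoffs: tuple[float, float] = (-0.5, 0.5)

    def scheme(self) -> SortScheme:
        return SortScheme(
            dsred_window=tuple(self.dsred_window),
            dsred_stringent_window=tuple(self.dsred_stringent_window),
            replicates=self.replicates,
        )

    def layout(self) -> ReadLayout:
        return ReadLayout()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("class_fractions", "dsred_window", "dsred_stringent_window",
                    "weights", "stability_cutoffs"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


@dataclass
class RunReport:
    """Audit record of one run: stage counts, calls, concordance, config echo."""

    version: str
    config: dict
    n_motifs: int
    n_cells: int
    population_sizes: dict[str, int]
    filter_stats: dict[str, int] | None
    n_scored: int
    n_activating: int
    n_repressive: int
    n_stability_records: int
    n_stabilizing: int
    n_destabilizing: int
    replicate_concordance: dict[str, float]
    score_ratio_pearson_r: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunReport:
    """Execute all stages in dependency order, writing TSV outputs to ``outdir``.

    Outputs: ``truth.tsv``, ``counts.tsv``, ``scores.tsv``, ``stability.tsv``,
    ``enrichment.tsv``, ``report.json``, and (with ``emit_reads``)
    ``reads.fastq`` + ``barcodes.tsv`` + ``filter_stats.tsv``. Idempotent
    given identical config; a stage failure aborts with the stage named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 6)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    truth = stage(
        "generate_truth",
        generate_truth,
        config.n_motifs,
        config.class_fractions,
        config.effect_magnitude,
        stability_magnitude=config.stability_magnitude,
        seed=seeds[0],
    )
    truth.to_tsv(outdir / "truth.tsv")

    cells = stage(
        "simulate_cells",
        simulate_cells,
        truth,
        mean_integrations=config.mean_integrations,
        noise_sd=config.noise_sd,
        seed=seeds[1],
    )
    populations = stage("gate_and_sort", gate_and_sort, cells, config.scheme(), seeds[2])

    filter_stats = None
    if config.emit_reads:
        layout = config.layout()
        emitted = stage(
            "emit_fastq",
            emit_fastq,
            populations,
            layout,
            config.depth,
            error_rate=config.error_rate,
            seed=seeds[3],
            out_path=outdir / "reads.fastq",
        )
        with open(outdir / "barcodes.tsv", "w") as fh:
            fh.write("barcode\tpopulation\treplicate\n")
            for bc, (pop, rep) in emitted.barcode_map.items():
                fh.write(f"{bc}\t{pop}\t{rep}\n")
        from utrscreen import readproc

        stream, stats = readproc.parse_and_filter(
            emitted.fastq_path, layout, emitted.barcode_map
        )
        table = stage("count_motifs", readproc.count_motifs, stream)
        stats.check()
        filter_stats = stats.to_dict()
        pd.DataFrame([filter_stats]).to_csv(
            outdir / "filter_stats.tsv", sep="\t", index=False
        )
    else:
        table = stage(
            "sequence_counts", sequence_counts, populations, config.depth, seeds[3]
        )
    table.to_tsv(outdir / "counts.tsv")

    scores = stage(
        "score_screen",
        scoring.score_screen,
        table,
        weights=config.weights,
        min_count=config.min_count,
        aggregate=config.aggregate,
        threshold_activating=config.threshold_activating,
        threshold_repressive=config.threshold_repressive,
    )
    scores.to_csv(outdir / "scores.tsv", sep="\t")

    universe = scoring.robust_background_set(table, min_count=config.min_count)
    bg = table.df[table.df["population"] == BACKGROUND_STRINGENT]
    dna_counts = bg.groupby("motif")["count"].sum().to_dict()
    rna_counts = stage(
        "simulate_rna",
        simulate_rna,
        truth,
        dna_counts,
        depth=config.rna_depth,
        seed=seeds[4],
    )
    dna_table = CountTable.from_records(
        [(m, "DNA", 0, c) for m, c in dna_counts.items()]
    )
    rna_table = CountTable.from_records(
        [(m, "RNA", 0, c) for m, c in rna_counts.items()]
    )
    stab = stage(
        "rna_dna_ratio", stability.rna_dna_ratio, rna_table, dna_table, motifs=universe
    )
    stab["label"] = [
        stability.classify_stability(r, tuple(config.stability_cutoffs))
        for r in stab["log2_ratio"]
    ]
    stab.to_csv(outdir / "stability.tsv", sep="\t")

    calls = {
        "activating": set(scores.index[scores["label"] == "activating"]),
        "repressive": set(scores.index[scores["label"] == "repressive"]),
    }
    categories = {
        "true_activating": set(truth.motif[truth.true_class == "activating"]),
        "true_repressive": set(truth.motif[truth.true_class == "repressive"]),
    }
    enrich = stage(
        "category_enrichment",
        enrichment_table,
        categories,
        calls,
        set(scores.index),
    )
    enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    concordance = {}
    for pop in table.populations():
        reps = table.replicates(pop)
        if len(reps) >= 2:
            concordance[pop] = scoring.replicate_concordance(table, pop)

    shared = scores.index.intersection(stab.index)
    if len(shared) >= 3:
        r, _, _ = stability.score_ratio_correlation(
            scores.loc[shared, "score"], stab.loc[shared, "log2_ratio"]
        )
    else:
        r = math.nan

    report = RunReport(
        version=utrscreen.__version__,
        config=config.to_dict(),
        n_motifs=len(truth),
        n_cells=len(cells),
        population_sizes={
            label: len(reps[min(reps)]) for label, reps in populations.items()
        },
        filter_stats=filter_stats,
        n_scored=len(scores),
        n_activating=int((scores["label"] == "activating").sum()),
        n_repressive=int((scores["label"] == "repressive").sum()),
        n_stability_records=len(stab),
        n_stabilizing=int((stab["label"] == "stabilizing").sum()),
        n_destabilizing=int((stab["label"] == "destabilizing").sum()),
        replicate_concordance=concordance,
        score_ratio_pearson_r=float(r),
    )
    report.to_json(outdir / "report.json")
    config.to_yaml(outdir / "config.yaml")
    return report


# ---------------------------------------------------------------------------
# Reporter-table utility
# ---------------------------------------------------------------------------


def geometric_mean(values: Sequence[float]) -> float:
    """Geometric mean of strictly positive values."""
    arr = np.asarray(values, float)
    if len(arr) == 0:
        raise ValueError("empty measurement set")
    if (arr <= 0).any():
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def relative_expression_report(
    measurements: Mapping[str, Sequence[float]],
    reference_motifs: Sequence[str] = ("UUCCGUUA", "UAAUGCCC"),
) -> pd.DataFrame:
    """Normalize per-motif reporter measurements to two no-effect controls.

    Each motif's geometric mean is divided by the geometric mean of the
    pooled reference measurements. Spread is reported two ways, since the
    literal "33 % of the spread" convention is ambiguous: the central 68 %
    interval of the normalized values, and a band of ±33 % of the normalized
    range around the relative mean — both labeled explicitly.
    """
    missing = [m for m in reference_motifs if m not in measurements]
    if missing:
        raise ValueError(f"reference motifs missing from measurements: {missing}")
    pooled = [v for m in reference_motifs for v in measurements[m]]
    ref_gm = geometric_mean(pooled)
    rows = []
    for motif, values in measurements.items():
        arr = np.asarray(values, float)
        if (arr <= 0).any():
            raise ValueError(f"non-positive measurement for {motif!r}")
        rel = arr / ref_gm
        lo68, hi68 = np.percentile(rel, [16, 84])
        band = 0.33 * (rel.max() - rel.min())
        gm = geometric_mean(arr) / ref_gm
        rows.append(
            {
                "motif": motif,
                "relative_geometric_mean": gm,
                "central68_low": lo68,
                "central68_high": hi68,
                "range33_low": gm - band,
                "range33_high": gm + band,
                "n": len(arr),
            }
        )
    return pd.DataFrame(rows).set_index("motif")


def significance_stars(p: float) -> str:
    """Star convention: * p<0.05, ** p<0.005, *** p<0.0005."""
    if p < 0.0005:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return ""
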