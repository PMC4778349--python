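"""Amplicon FASTQ -> RPM-normalized 8mer count tables.

A read passes the filters iff (i) its barcode matches a known library
exactly, (ii) every base of the barcode and the variable 8mer has Phred
quality strictly greater than the threshold, and (iii) the fixed flanks
match exactly at their expected positions. Failures are attributed to the
first failing check, in that order (barcode, quality, upstream flank,
downstream flank); this ordering is part of the contract and is tested.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from utrscreen.counts import CountTable
from utrscreen.simulate import ReadLayout, rna

PHRED_OFFSET = 33


class FastqParseError(ValueError):
    """Malformed FASTQ input, annotated with the approximate record number."""


@dataclass
class ReadFilterStats:
    """Per-file read accounting with first-failure attribution."""

    total_reads: int = 0
    fail_barcode: int = 0
    fail_quality: int = 0
    fail_upstream_flank: int = 0
    fail_downstream_flank: int = 0
    passed: int = 0

    def check(self) -> None:
        failed = (
            self.fail_barcode
            + self.fail_quality
            + self.fail_upstream_flank
            + self.fail_downstream_flank
        )
        assert self.total_reads == self.passed + failed

    def to_dict(self) -> dict[str, int]:
        return {
            "total_reads": self.total_reads,
            "fail_barcode": self.fail_barcode,
            "fail_quality": self.fail_quality,
            "fail_upstream_flank": self.fail_upstream_flank,
            "fail_downstream_flank": self.fail_downstream_flank,
            "passed": self.passed,
        }


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_barcode_map(path: str | Path) -> dict[str, tuple[str, int]]:
    """Load a barcode map TSV with columns (barcode, population, replicate)."""
    out: dict[str, tuple[str, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("barcode\t"):
                continue
            barcode, population, replicate = line.split("\t")
            out[barcode] = (population, int(replicate))
    _check_prefix_free(out)
    return out


def _check_prefix_free(barcode_map: Mapping[str, tuple[str, int]]) -> None:
    codes = sorted(barcode_map)
    for a, b in zip(codes, codes[1:]):
        if b.startswith(a):
            raise ValueError(f"barcode set is not prefix-free: {a!r} prefixes {b!r}")


def parse_and_filter(
    fastq: str | Path,
    layout: ReadLayout,
    barcode_map: Mapping[str, tuple[str, int]],
    stats: ReadFilterStats | None = None,
) -> tuple[Iterator[tuple[str, int, str]], ReadFilterStats]:
    """Stream passing reads of a FASTQ file as (population, replicate, motif).

    Motifs are returned in the RNA alphabet. The returned stats object is
    filled in as the stream is consumed and is only final once the stream is
    exhausted. Unknown barcodes are counted (``fail_barcode``), not fatal;
    malformed FASTQ raises :class:`FastqParseError`.
    """
    _check_prefix_free(barcode_map)
    if stats is None:
        stats = ReadFilterStats()
    lengths = sorted({len(b) for b in barcode_map})

    def stream() -> Iterator[tuple[str, int, str]]:
        min_q = chr(layout.min_phred + PHRED_OFFSET)  # pass requires qual > this
        with _open_maybe_gzip(fastq) as handle:
            try:
                for _title, seq, qual in FastqGeneralIterator(handle):
                    stats.total_reads += 1
                    seq = seq.upper()

                    library = None
                    for blen in lengths:
                        library = barcode_map.get(seq[:blen])
                        if library is not None:
                            barcode_len = blen
                            break
                    if library is None:
                        stats.fail_barcode += 1
                        continue

                    m_start = barcode_len + len(layout.upstream_flank)
                    m_end = m_start + layout.motif_length
                    d_end = m_end + len(layout.downstream_flank)
                    if len(seq) < layout.read_length or len(qual) != len(seq):
                        stats.fail_quality += 1
                        continue
                    # strict Phred > min_phred over barcode and 8mer; N fails too
                    region = seq[:barcode_len] + seq[m_start:m_end]
                    qregion = qual[:barcode_len] + qual[m_start:m_end]
                    if "N" in region or any(q <= min_q for q in qregion):
                        stats.fail_quality += 1
                        continue
                    if seq[barcode_len:m_start] != layout.upstream_flank:
                        stats.fail_upstream_flank += 1
                        continue
                    if seq[m_end:d_end] != layout.downstream_flank:
                        stats.fail_downstream_flank += 1
                        continue
                    stats.passed += 1
                    pop, rep = library
                    yield pop, rep, rna(seq[m_start:m_end])
            except ValueError as exc:  # Biopython's malformed-record error
                raise FastqParseError(
                    f"malformed FASTQ near record {stats.total_reads + 1} "
                    f"(line ~{4 * stats.total_reads + 1}): {exc}"
                ) from exc

    return stream(), stats


def count_motifs(
    stream: Iterable[tuple[str, int, str]],
    whitelist: set[str] | None = None,
    other_label: str = "__other__",
) -> CountTable:
    """Tally parsed (population, replicate, motif) records into a count table.

    With a whitelist, non-whitelist motifs are tallied under ``other_label``
    so they can still contribute to library totals (the default RPM
    denominator uses all passing reads).
    """
    tallies: dict[tuple[str, str, int], int] = {}
    for pop, rep, motif in stream:
        if whitelist is not None and motif not in whitelist:
            motif = other_label
        key = (motif, pop, rep)
        tallies[key] = tallies.get(key, 0) + 1
    return CountTable.from_records(
        [(m, p, r, c) for (m, p, r), c in sorted(tallies.items())]
    )


def normalize_rpm(table: CountTable) -> CountTable:
    """RPM-normalize each (population, replicate) library; see CountTable.with_rpm."""
    return table.with_rpm()


def count_fastq(
    fastq: str | Path,
    layout: ReadLayout,
    barcode_map: Mapping[str, tuple[str, int]],
    whitelist: set[str] | None = None,
) -> tuple[CountTable, ReadFilterStats]:
    """Convenience: parse, filter, count, and RPM-normalize one FASTQ file."""
    stream, stats = parse_and_filter(fastq, layout, barcode_map)
    table = count_motifs(stream, whitelist=whitelist)
    stats.check()
    return table.with_rpm(), stats
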