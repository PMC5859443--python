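"""Per-cytosine methylation counts and sliding-window pooling.

Reads strand-resolved cytosine reports (Bismark ``CX_report`` style:
chromosome, 1-based position, strand, methylated count, unmethylated
count, context), builds sliding genomic bins (default 300 bp sliding by
200 bp), and pools counts per bin, per context, over both strands.

Because consecutive bins overlap, a cytosine contributes to every bin
containing it; pooled bins must therefore never be summed across bins.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

log = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")

#: columns of the long-format pooled-bin table used throughout the package
BIN_COLUMNS = ["chrom", "start", "end", "context", "library", "n_meth", "n_unmeth"]


@dataclass(frozen=True)
class CytosineSiteCount:
    """Methylated / unmethylated call counts for one cytosine."""

    chrom: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class BinningConfig:
    """Sliding-window geometry: ``bin_size`` bp windows every ``step`` bp."""

    bin_size: int = 300
    step: int = 200

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.bin_size):
            raise ValueError("need 0 < step <= bin_size")


@dataclass
class MethylationBin:
    """Pooled counts of one context in one window, per library."""

    interval: GenomicInterval
    context: str
    counts: dict[str, tuple[int, int]]  # library -> (n_meth, n_unmeth)


class CytosineReportError(ValueError):
    """Malformed cytosine-report line."""


def _open_maybe_gzip(path) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_cytosine_report(path) -> Iterator[CytosineSiteCount]:
    """Stream per-cytosine records from a (possibly gzipped) report.

    Expected tab-separated columns: chrom, pos, strand, count-methylated,
    count-unmethylated, context [, trinucleotide].  The trinucleotide
    column, if present, is ignored.  Zero-coverage sites are yielded
    unchanged; coverage filtering is the DMR caller's job.
    """
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise CytosineReportError(
                    f"{path}: line {lineno}: expected >= 6 tab-separated "
                    f"fields, got {len(fields)}"
                )
            chrom, pos, strand, n_meth, n_unmeth, context = fields[:6]
            try:
                rec = CytosineSiteCount(
                    chrom, int(pos), strand, context, int(n_meth), int(n_unmeth)
                )
            except ValueError as exc:
                raise CytosineReportError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
            yield rec


def read_cytosine_report_df(path) -> pd.DataFrame:
    """Read a full cytosine report into a DataFrame (fast bulk path)."""
    df = pd.read_csv(
        str(path),
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3, 4, 5],
        names=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"],
        dtype={"chrom": str, "pos": np.int64, "strand": str,
               "n_meth": np.int64, "n_unmeth": np.int64, "context": str},
    )
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise CytosineReportError(
            f"{path}: unknown context value(s) "
            f"{sorted(df.loc[bad, 'context'].unique())}"
        )
    return df


def sites_to_frame(sites: Iterable[CytosineSiteCount]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.chrom, s.pos, s.strand, s.n_meth, s.n_unmeth, s.context) for s in sites],
        columns=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"],
    )


def make_bins(
    chrom_lengths: Mapping[str, int], config: BinningConfig = BinningConfig()
) -> list[GenomicInterval]:
    """Enumerate sliding windows anchored at position 1 of each chromosome.

    Windows start at 1, 1+step, 1+2*step, ...; the last window is
    truncated at the chromosome end.  Enumeration stops once a window
    reaches the chromosome end, so every position is covered and no
    window is fully contained in its predecessor.
    """
    bins: list[GenomicInterval] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if length < 1:
            raise ValueError(f"chromosome {chrom} has length {length} < 1")
        start = 1
        while start <= length:
            end = min(start + config.bin_size - 1, length)
            bins.append(GenomicInterval(chrom, start, end))
            if end >= length:
                break
            start += config.step
    return bins


def _n_bin_starts(length: int, bin_size: int, step: int) -> int:
    # starts 1, 1+step, ...; enumeration stops at the first window
    # reaching the chromosome end (same rule as make_bins)
    if length <= bin_size:
        return 1
    return -(-(length - bin_size) // step) + 1


def pool_counts_frame(
    sites: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    library: str,
    config: BinningConfig = BinningConfig(),
    contexts: Iterable[str] = CONTEXTS,
) -> pd.DataFrame:
    """Pool one library's site counts into sliding bins, per context.

    A site lands in every window containing its position (consecutive
    windows overlap by ``bin_size - step`` bp); both strands are pooled.
    Sites on chromosomes absent from ``chrom_lengths`` are skipped with
    a warning.  Returns a long-format frame with BIN_COLUMNS; bins with
    zero calls are retained (the DMR caller's coverage filter removes
    them explicitly).
    """
    unknown = set(sites["chrom"].unique()) - set(chrom_lengths)
    if unknown:
        log.warning("skipping sites on unknown chromosome(s): %s", sorted(unknown))
        sites = sites[sites["chrom"].isin(chrom_lengths)]

    bs, step = config.bin_size, config.step
    max_back = (bs - 1) // step  # how many earlier windows can still contain a site
    records = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        nbins = _n_bin_starts(length, bs, step)
        starts = 1 + step * np.arange(nbins, dtype=np.int64)
        ends = np.minimum(starts + bs - 1, length)
        on_chrom = sites[sites["chrom"] == chrom]
        for context in contexts:
            sub = on_chrom[on_chrom["context"] == context]
            meth = np.zeros(nbins, dtype=np.int64)
            unmeth = np.zeros(nbins, dtype=np.int64)
            if len(sub):
                pos = sub["pos"].to_numpy()
                nm = sub["n_meth"].to_numpy()
                nu = sub["n_unmeth"].to_numpy()
                j_last = (pos - 1) // step  # window index whose start is closest below pos
                for back in range(max_back + 1):
                    j = j_last - back
                    ok = (j >= 0) & (j < nbins) & (pos <= 1 + j * step + bs - 1)
                    np.add.at(meth, j[ok], nm[ok])
                    np.add.at(unmeth, j[ok], nu[ok])
            records.append(pd.DataFrame({
                "chrom": chrom, "start": starts, "end": ends,
                "context": context, "library": library,
                "n_meth": meth, "n_unmeth": unmeth,
            }))
    if not records:
        return pd.DataFrame(columns=BIN_COLUMNS)
    return pd.concat(records, ignore_index=True)[BIN_COLUMNS]


def pool_counts(
    sites: Iterable[CytosineSiteCount],
    chrom_lengths: Mapping[str, int],
    library: str,
    config: BinningConfig = BinningConfig(),
    context: str | None = None,
) -> list[MethylationBin]:
    """Record-level pooling API; see :func:`pool_counts_frame`.

    If ``context`` is given, only that context is pooled and returned.
    """
    contexts = CONTEXTS if context is None else (context,)
    frame = pool_counts_frame(
        sites_to_frame(sites), chrom_lengths, library, config, contexts
    )
    out = []
    for row in frame.itertuples():
        out.append(MethylationBin(
            GenomicInterval(row.chrom, row.start, row.end),
            row.context,
            {library: (int(row.n_meth), int(row.n_unmeth))},
        ))
    return out


def write_pooled_bins(frame: pd.DataFrame, path) -> None:
    """Write the long-format pooled-bin table as TSV."""
    frame[BIN_COLUMNS].to_csv(str(path), sep="\t", index=False)


def read_pooled_bins(path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t", dtype={"chrom": str, "library": str})
    missing = set(BIN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing pooled-bin columns {sorted(missing)}")
    return df[BIN_COLUMNS]
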