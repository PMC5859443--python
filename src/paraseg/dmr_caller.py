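"""Differential-methylation calling on pooled sliding bins.

Pipeline per introgression line vs the recurrent parent, per context:
coverage-filter the bins, test each bin with a binomial regression of
methylated proportion on genotype, Benjamini-Hochberg-correct the
p-values, require a minimum absolute methylation difference (averaged
over replicates), merge overlapping flagged bins into DMRs, drop DMRs
inside introgressed segments, then intersect DMR sets across lines.

The default per-bin test is the likelihood-ratio test of the genotype
term.  With genotype as the only covariate the binomial-GLM profile
likelihood depends on the counts only through their per-genotype pooled
totals, so the LRT has a closed form (the two-proportion G-test) which
is evaluated vectorised over all bins; it is well defined even under
complete separation (0% vs 100%), where Wald is not.  A Wald flavour
fitted with statsmodels is available per bin and falls back to adding a
0.5 pseudo-count per cell when groups are completely separated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.special import xlogy
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, merge_overlapping
from .methylation_data import BIN_COLUMNS

log = logging.getLogger(__name__)

BIN_KEY = ["chrom", "start", "end", "context"]

#: Introgressed segments excluded from the genome-wide screen
#: (donor-genotype DNA differs in sequence, not only methylation).
DEFAULT_EXCLUSIONS = (
    GenomicInterval("ch01", 1, 86_000_000),
    GenomicInterval("ch02", 44_000_000, 54_000_000),
    GenomicInterval("ch08", 61_000_000, 65_866_657),
)


@dataclass(frozen=True)
class BinFilterConfig:
    """Coverage filter: drop a bin if, in any library, its total call
    count is below ``min_counts`` or above that library's per-context
    ``coverage_percentile``."""

    min_counts: int = 10
    coverage_percentile: float = 99.0

    def __post_init__(self) -> None:
        if self.min_counts < 0:
            raise ValueError("min_counts must be >= 0")
        if not (0 < self.coverage_percentile <= 100):
            raise ValueError("coverage_percentile must be in (0, 100]")


@dataclass(frozen=True)
class DmrThresholds:
    """FDR cutoff and per-context minimum absolute methylation difference."""

    fdr: float = 0.05
    min_diff: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.25, "CHG": 0.20, "CHH": 0.10}
    )

    def __post_init__(self) -> None:
        if not (0 < self.fdr <= 1):
            raise ValueError("fdr must be in (0, 1]")
        for ctx, d in self.min_diff.items():
            if not (0 < d <= 1):
                raise ValueError(f"min_diff[{ctx}] must be in (0, 1]")


@dataclass
class BinTestResult:
    """Differential test of one bin (reference vs alternative genotype)."""

    interval: GenomicInterval
    context: str
    p_value: float
    mean_prop_ref: float
    mean_prop_alt: float
    q_value: float | None = None

    @property
    def diff(self) -> float:
        return self.mean_prop_alt - self.mean_prop_ref

    @property
    def direction(self) -> str:
        return "hyper" if self.diff >= 0 else "hypo"


@dataclass
class DMR:
    """Merged run of overlapping differential bins of one context and
    direction; ``mean_meth`` holds the per-genotype mean methylation
    averaged over member bins."""

    interval: GenomicInterval
    context: str
    direction: str
    n_bins: int
    mean_meth: dict[str, float]


@dataclass
class SharedDMR:
    """Consensus interval supported by >= 1 DMR from every required line."""

    interval: GenomicInterval
    context: str
    direction: str
    support: dict[str, list[GenomicInterval]]


# ---------------------------------------------------------------------------
# coverage filtering


def filter_bins(bins: pd.DataFrame, config: BinFilterConfig = BinFilterConfig()) -> pd.DataFrame:
    """Apply the per-library coverage filter to a long-format bin table.

    Percentiles are computed per library and per context over ALL bins
    before any removal.  Removal is strict: a bin with total exactly
    ``min_counts`` in every library is retained ("fewer than" rule), and
    a total exactly at the percentile is retained.
    """
    if bins.empty:
        log.info("filter_bins: empty input")
        return bins.copy()
    df = bins.copy()
    df["total"] = df["n_meth"] + df["n_unmeth"]
    totals = df.pivot_table(
        index=BIN_KEY, columns="library", values="total", fill_value=0, aggfunc="sum"
    )
    keep = pd.Series(True, index=totals.index)
    contexts = totals.index.get_level_values("context")
    for lib in totals.columns:
        col = totals[lib].to_numpy(dtype=float)
        keep &= totals[lib] >= config.min_counts
        for ctx in np.unique(contexts):
            mask = contexts == ctx
            cutoff = np.percentile(col[mask], config.coverage_percentile)
            keep &= ~(pd.Series(mask, index=totals.index) & (totals[lib] > cutoff))
    kept_keys = totals.index[keep]
    out = bins.set_index(BIN_KEY).loc[kept_keys].reset_index()
    return out[BIN_COLUMNS]


# ---------------------------------------------------------------------------
# per-bin differential test


def _binom_ll(m: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Maximised binomial log-likelihood of pooled counts (m, u)."""
    return xlogy(m, m) + xlogy(u, u) - xlogy(m + u, m + u)


def lrt_p_values(
    m_ref: np.ndarray, u_ref: np.ndarray, m_alt: np.ndarray, u_alt: np.ndarray
) -> np.ndarray:
    """Vectorised likelihood-ratio test of a genotype effect on the
    methylated proportion, from per-genotype pooled counts.

    Returns NaN where a genotype has zero total calls.
    """
    m_ref, u_ref, m_alt, u_alt = (
        np.asarray(a, dtype=float) for a in (m_ref, u_ref, m_alt, u_alt)
    )
    lr = 2.0 * (
        _binom_ll(m_ref, u_ref)
        + _binom_ll(m_alt, u_alt)
        - _binom_ll(m_ref + m_alt, u_ref + u_alt)
    )
    p = chi2.sf(np.clip(lr, 0.0, None), df=1)
    p = np.where((m_ref + u_ref == 0) | (m_alt + u_alt == 0), np.nan, p)
    return p


def _wald_p_value(counts_ref: Sequence[tuple[int, int]],
                  counts_alt: Sequence[tuple[int, int]]) -> float:
    """Wald p-value of the genotype coefficient from a statsmodels
    binomial GLM; 0.5 pseudo-counts per cell on complete separation."""
    import statsmodels.api as sm

    def _fit(ref, alt):
        import warnings

        endog = np.array(list(ref) + list(alt), dtype=float)
        genotype = np.array([0.0] * len(ref) + [1.0] * len(alt))
        exog = sm.add_constant(genotype)
        with warnings.catch_warnings():
            # one library per genotype leaves zero residual df; expected
            warnings.simplefilter("ignore")
            res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        return float(res.pvalues[1])

    pr = sum(m for m, _ in counts_ref) / max(sum(m + u for m, u in counts_ref), 1)
    pa = sum(m for m, _ in counts_alt) / max(sum(m + u for m, u in counts_alt), 1)
    separated = {pr, pa} <= {0.0, 1.0} and pr != pa
    if separated:
        counts_ref = [(m + 0.5, u + 0.5) for m, u in counts_ref]
        counts_alt = [(m + 0.5, u + 0.5) for m, u in counts_alt]
    return _fit(counts_ref, counts_alt)


def test_bin(
    counts: Mapping[str, tuple[int, int]],
    genotypes: Mapping[str, str],
    ref_genotype: str,
    alt_genotype: str,
    interval: GenomicInterval | None = None,
    context: str = "CG",
    method: str = "lrt",
) -> BinTestResult:
    """Test one bin for differential methylation between two genotypes.

    ``counts`` maps library id to (n_meth, n_unmeth); ``genotypes`` maps
    library id to its genotype label.  The effect size is the unweighted
    mean of replicate proportions per genotype; the p-value pools
    replicates (weighted by their totals) through the regression.
    """
    ref = [counts[lib] for lib, g in genotypes.items() if g == ref_genotype]
    alt = [counts[lib] for lib, g in genotypes.items() if g == alt_genotype]
    if not ref or not alt:
        raise ValueError("need >= 1 library per genotype")

    def _mean_prop(group):
        props = [m / (m + u) for m, u in group if (m + u) > 0]
        return float(np.mean(props)) if props else float("nan")

    if method == "lrt":
        p = float(lrt_p_values(
            np.array([sum(m for m, _ in ref)]), np.array([sum(u for _, u in ref)]),
            np.array([sum(m for m, _ in alt)]), np.array([sum(u for _, u in alt)]),
        )[0])
    elif method == "wald":
        p = _wald_p_value(ref, alt)
    else:
        raise ValueError(f"unknown test method {method!r}")
    return BinTestResult(
        interval=interval or GenomicInterval("?", 1, 1),
        context=context,
        p_value=p,
        mean_prop_ref=_mean_prop(ref),
        mean_prop_alt=_mean_prop(alt),
    )


def test_bins(
    bins: pd.DataFrame,
    design: Mapping[str, str],
    ref_genotype: str,
    alt_genotype: str,
) -> pd.DataFrame:
    """Vectorised per-bin LRT over a long-format bin table.

    ``design`` maps library -> genotype.  Returns one row per bin with
    p_value, per-genotype mean replicate proportions, diff and direction.
    Bins with zero total calls in a genotype get p_value NaN (they
    should have been removed by :func:`filter_bins`).
    """
    ref_libs = [lib for lib, g in design.items() if g == ref_genotype]
    alt_libs = [lib for lib, g in design.items() if g == alt_genotype]
    if not ref_libs or not alt_libs:
        raise ValueError("need >= 1 library per genotype in the design")
    df = bins[bins["library"].isin(ref_libs + alt_libs)]
    meth = df.pivot_table(index=BIN_KEY, columns="library", values="n_meth",
                          fill_value=0, aggfunc="sum")
    unmeth = df.pivot_table(index=BIN_KEY, columns="library", values="n_unmeth",
                            fill_value=0, aggfunc="sum")
    m_ref = meth[ref_libs].sum(axis=1).to_numpy()
    u_ref = unmeth[ref_libs].sum(axis=1).to_numpy()
    m_alt = meth[alt_libs].sum(axis=1).to_numpy()
    u_alt = unmeth[alt_libs].sum(axis=1).to_numpy()
    p = lrt_p_values(m_ref, u_ref, m_alt, u_alt)

    def _mean_prop(libs):
        m = meth[libs].to_numpy(dtype=float)
        t = m + unmeth[libs].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            props = np.where(t > 0, m / t, np.nan)
        return np.nanmean(props, axis=1)

    with np.errstate(invalid="ignore"):
        prop_ref = _mean_prop(ref_libs)
        prop_alt = _mean_prop(alt_libs)
    out = meth.index.to_frame(index=False)
    out["p_value"] = p
    out["mean_prop_ref"] = prop_ref
    out["mean_prop_alt"] = prop_alt
    out["diff"] = prop_alt - prop_ref
    out["direction"] = np.where(out["diff"] >= 0, "hyper", "hypo")
    return out


# ---------------------------------------------------------------------------
# FDR, thresholds, merging


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_differential_bins(
    results: pd.DataFrame, thresholds: DmrThresholds = DmrThresholds()
) -> pd.DataFrame:
    """Attach BH q-values (per context) and flag differential bins.

    A bin is flagged iff q <= fdr and |diff| >= min_diff[context]
    (both comparisons inclusive).  Rows with NaN p-values are never
    flagged.  Returns the input with ``q_value`` and boolean ``flagged``
    columns added.
    """
    out = results.copy()
    out["q_value"] = np.nan
    for ctx, idx in out.groupby("context").groups.items():
        p = out.loc[idx, "p_value"].to_numpy()
        ok = ~np.isnan(p)
        q = np.full(p.shape, np.nan)
        if ok.any():
            q[ok] = adjust_bh(p[ok])
        out.loc[idx, "q_value"] = q
    min_diff = out["context"].map(dict(thresholds.min_diff)).to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        out["flagged"] = (
            (out["q_value"].to_numpy() <= thresholds.fdr)
            & (np.abs(out["diff"].to_numpy()) >= min_diff)
        )
    out["flagged"] = out["flagged"].fillna(False)
    return out


def merge_bins_to_dmrs(flagged: pd.DataFrame,
                       ref_genotype: str = "ref",
                       alt_genotype: str = "alt") -> list[DMR]:
    """Merge overlapping flagged bins into DMRs.

    Bins are grouped by (context, direction) first; only intervals
    sharing >= 1 bp merge (transitive closure), so adjacent-but-disjoint
    bins stay separate.  Idempotent on already-merged output.
    """
    dmrs: list[DMR] = []
    if flagged.empty:
        return dmrs
    df = flagged[flagged.get("flagged", pd.Series(True, index=flagged.index))]
    for (ctx, direction), grp in df.groupby(["context", "direction"], sort=True):
        grp = grp.sort_values(["chrom", "start"])
        current: list[pd.Series] = []

        def _emit(rows):
            iv = GenomicInterval(rows[0]["chrom"],
                                 int(min(r["start"] for r in rows)),
                                 int(max(r["end"] for r in rows)))
            dmrs.append(DMR(
                interval=iv, context=ctx, direction=direction,
                n_bins=int(sum(r.get("n_bins", 1) for r in rows)),
                mean_meth={
                    ref_genotype: float(np.mean([r["mean_prop_ref"] for r in rows])),
                    alt_genotype: float(np.mean([r["mean_prop_alt"] for r in rows])),
                },
            ))

        cur_chrom, cur_end = None, -1
        for _, row in grp.iterrows():
            if current and row["chrom"] == cur_chrom and row["start"] <= cur_end:
                current.append(row)
                cur_end = max(cur_end, int(row["end"]))
            else:
                if current:
                    _emit(current)
                current = [row]
                cur_chrom, cur_end = row["chrom"], int(row["end"])
        if current:
            _emit(current)
    dmrs.sort(key=lambda d: (d.context, d.direction, d.interval))
    return dmrs


def dmrs_to_frame(dmrs: Iterable[DMR]) -> pd.DataFrame:
    rows = []
    for d in dmrs:
        row = {
            "chrom": d.interval.chrom, "start": d.interval.start,
            "end": d.interval.end, "context": d.context,
            "direction": d.direction, "n_bins": d.n_bins,
        }
        for g, v in d.mean_meth.items():
            row[f"mean_meth_{g}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exclusion, sharing, annotation


def exclude_regions(items, exclusions: Sequence[GenomicInterval] = DEFAULT_EXCLUSIONS,
                    allow: Sequence[GenomicInterval] = ()):
    """Remove bins/DMRs overlapping an excluded interval by >= 1 bp.

    Accepts either a long/results DataFrame (with chrom/start/end
    columns) or a list of DMR objects.  Items overlapping an ``allow``
    interval are kept regardless (manual allow-list for candidates that
    merit follow-up despite lying in an excluded segment).
    """
    def _excluded(iv: GenomicInterval) -> bool:
        if any(iv.overlaps(a) for a in allow):
            return False
        return any(iv.overlaps(e) for e in exclusions)

    if isinstance(items, pd.DataFrame):
        if items.empty:
            return items.copy()
        drop = np.zeros(len(items), dtype=bool)
        chrom = items["chrom"].to_numpy()
        start = items["start"].to_numpy()
        end = items["end"].to_numpy()
        for e in exclusions:
            drop |= (chrom == e.chrom) & (start <= e.end) & (end >= e.start)
        for a in allow:
            drop &= ~((chrom == a.chrom) & (start <= a.end) & (end >= a.start))
        return items[~drop]
    return [d for d in items if not _excluded(d.interval if isinstance(d, DMR) else d)]


def shared_dmrs(
    dmr_sets: Mapping[str, Sequence[DMR]],
    required_lines: Sequence[str] | None = None,
) -> list[SharedDMR]:
    """Consensus regions differential in every required line.

    All per-line DMR intervals of one (context, direction) are pooled
    and union-merged; a merged consensus interval is reported iff it
    overlaps >= 1 DMR from every required line, with the contributing
    intervals listed per line.  The result is independent of the order
    in which lines are supplied.
    """
    required = list(required_lines) if required_lines is not None else sorted(dmr_sets)
    missing = [ln for ln in required if ln not in dmr_sets]
    if missing:
        raise ValueError(f"required line(s) missing from dmr_sets: {missing}")
    groups = {(d.context, d.direction) for ds in dmr_sets.values() for d in ds}
    out: list[SharedDMR] = []
    for ctx, direction in sorted(groups):
        per_line = {
            ln: [d.interval for d in dmr_sets[ln]
                 if d.context == ctx and d.direction == direction]
            for ln in required
        }
        consensus = merge_overlapping(iv for ivs in per_line.values() for iv in ivs)
        for cons in consensus:
            support = {ln: [iv for iv in ivs if cons.overlaps(iv)]
                       for ln, ivs in per_line.items()}
            if all(support[ln] for ln in required):
                out.append(SharedDMR(cons, ctx, direction, support))
    return out


def all_context_dmrs(
    shared_by_context: Mapping[str, Sequence[SharedDMR]],
    direction: str,
    contexts: Sequence[str] = ("CG", "CHG", "CHH"),
) -> list[GenomicInterval]:
    """Consensus regions covered by a shared DMR of every context.

    Same union-consensus rule as :func:`shared_dmrs`, applied across
    contexts instead of lines.
    """
    per_ctx = {
        ctx: [s.interval for s in shared_by_context.get(ctx, [])
              if s.direction == direction]
        for ctx in contexts
    }
    consensus = merge_overlapping(iv for ivs in per_ctx.values() for iv in ivs)
    return [
        cons for cons in consensus
        if all(any(cons.overlaps(iv) for iv in per_ctx[ctx]) for ctx in contexts)
    ]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+', '-' or '.'


def read_gff3_genes(path, feature_types: Sequence[str] = ("gene",)) -> list[GeneRecord]:
    """Extract gene spans from a GFF3 file (columns: seqid, source,
    type, start, end, score, strand, phase, attributes)."""
    genes: list[GeneRecord] = []
    with open(str(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            seqid, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype not in feature_types:
                continue
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            genes.append(GeneRecord(gene_id or f"{seqid}:{start}-{end}",
                                    seqid, int(start), int(end), strand))
    return genes


def promoter_window(gene: GeneRecord, promoter_bp: int = 2000) -> GenomicInterval | None:
    """Strand-aware window upstream of the transcription start."""
    if gene.strand == "+":
        start = max(1, gene.start - promoter_bp)
        if start > gene.start - 1:
            return None
        return GenomicInterval(gene.chrom, start, gene.start - 1)
    if gene.strand == "-":
        return GenomicInterval(gene.chrom, gene.end + 1, gene.end + promoter_bp)
    log.warning("gene %s has no strand; promoter window skipped", gene.gene_id)
    return None


def annotate_dmrs(
    dmrs: Sequence[DMR] | Sequence[GenomicInterval],
    genes: Sequence[GeneRecord] = (),
    promoter_bp: int = 2000,
    loci: Mapping[str, GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Associate DMRs with genes (transcribed span or 2-kb promoter) and
    with arbitrary loci (plain overlap).

    Returns one row per association: dmr, feature id, relation in
    {gene_body, promoter, locus}.  A DMR overlapping both the body and
    the promoter of the same gene is reported once as gene_body.
    """
    trees: dict[str, IntervalTree] = {}

    def _insert(iv: GenomicInterval, payload):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1, payload)

    for g in genes:
        _insert(GenomicInterval(g.chrom, g.start, g.end), (g.gene_id, "gene_body"))
        pw = promoter_window(g, promoter_bp)
        if pw is not None:
            _insert(pw, (g.gene_id, "promoter"))
    for name, iv in (loci or {}).items():
        _insert(iv, (name, "locus"))

    rank = {"gene_body": 0, "promoter": 1, "locus": 2}
    rows = []
    for d in dmrs:
        iv = d.interval if isinstance(d, DMR) else d
        hits: dict[str, str] = {}
        for hit in trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end + 1):
            fid, relation = hit.data
            if fid not in hits or rank[relation] < rank[hits[fid]]:
                hits[fid] = relation
        for fid in sorted(hits):
            rows.append({"dmr": str(iv), "feature": fid, "relation": hits[fid]})
    return pd.DataFrame(rows, columns=["dmr", "feature", "relation"])
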