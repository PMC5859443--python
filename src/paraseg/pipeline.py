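"""End-to-end orchestration: the genome-wide DMR screen and the
segregation study, driven by a single config, with a manifest that
makes every run reproducible (config hash + input hashes + versions).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .dmr_caller import (
    DMR,
    BinFilterConfig,
    DmrThresholds,
    SharedDMR,
    all_context_dmrs,
    annotate_dmrs,
    call_differential_bins,
    dmrs_to_frame,
    exclude_regions,
    filter_bins,
    merge_bins_to_dmrs,
    read_gff3_genes,
    shared_dmrs,
    test_bins,
)
from .intervals import GenomicInterval, to_bed_fields
from .mcrbc import (
    ClassConfig,
    calls_to_frame,
    call_plant,
    read_ct_table,
    summarize_family,
)
from .methylation_data import (
    BinningConfig,
    pool_counts_frame,
    read_cytosine_report_df,
)
from .segregation import (
    SegregationObservation,
    screen_f1,
    test_bc1,
    test_f2,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a DMR screen run."""

    reports: Mapping[str, str]  # library id -> cytosine-report path
    design: Mapping[str, str]  # library id -> genotype
    ref_genotype: str
    chrom_lengths: Mapping[str, int]
    out_dir: str = "paraseg_out"
    contexts: Sequence[str] = ("CG", "CHG", "CHH")
    binning: BinningConfig = field(default_factory=BinningConfig)
    bin_filter: BinFilterConfig = field(default_factory=BinFilterConfig)
    thresholds: DmrThresholds = field(default_factory=DmrThresholds)
    exclusions: Sequence[GenomicInterval] = ()
    allow: Sequence[GenomicInterval] = ()
    gff: str | None = None
    loci_bed: str | None = None
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(str(path)) as fh:
            raw = yaml.safe_load(fh)
        kwargs = dict(raw)
        if "binning" in raw:
            kwargs["binning"] = BinningConfig(**raw["binning"])
        if "bin_filter" in raw:
            kwargs["bin_filter"] = BinFilterConfig(**raw["bin_filter"])
        if "thresholds" in raw:
            kwargs["thresholds"] = DmrThresholds(
                fdr=raw["thresholds"].get("fdr", 0.05),
                min_diff=raw["thresholds"].get(
                    "min_diff", {"CG": 0.25, "CHG": 0.20, "CHH": 0.10}
                ),
            )
        for key in ("exclusions", "allow"):
            if key in raw:
                kwargs[key] = [GenomicInterval.parse(s) for s in raw[key]]
        return cls(**kwargs)

    def validate(self) -> None:
        genotypes = set(self.design.values())
        if self.ref_genotype not in genotypes:
            raise ValueError(f"reference genotype {self.ref_genotype!r} not in design")
        if len(genotypes) < 2:
            raise ValueError("need >= 2 genotypes with >= 1 library each")
        missing = [p for p in self.reports.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")
        undeclared = set(self.reports) - set(self.design)
        if undeclared:
            raise ValueError(f"libraries without genotype in design: {sorted(undeclared)}")


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(str(path), "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, config_repr: dict, input_paths: Mapping[str, str]) -> None:
    import numpy, scipy, statsmodels  # versions for provenance

    manifest = {
        "paraseg_version": __version__,
        "config": config_repr,
        "config_sha256": hashlib.sha256(
            json.dumps(config_repr, sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {name: _sha256_file(p) for name, p in input_paths.items()},
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _config_repr(config: RunConfig) -> dict:
    return {
        "reports": dict(config.reports),
        "design": dict(config.design),
        "ref_genotype": config.ref_genotype,
        "chrom_lengths": dict(config.chrom_lengths),
        "contexts": list(config.contexts),
        "binning": {"bin_size": config.binning.bin_size, "step": config.binning.step},
        "bin_filter": {
            "min_counts": config.bin_filter.min_counts,
            "coverage_percentile": config.bin_filter.coverage_percentile,
        },
        "thresholds": {
            "fdr": config.thresholds.fdr,
            "min_diff": dict(config.thresholds.min_diff),
        },
        "exclusions": [str(e) for e in config.exclusions],
        "allow": [str(a) for a in config.allow],
        "gff": config.gff,
        "loci_bed": config.loci_bed,
        "seed": config.seed,
    }


def screen_from_tables(
    tables: Mapping[str, pd.DataFrame],
    design: Mapping[str, str],
    ref_genotype: str,
    chrom_lengths: Mapping[str, int],
    contexts: Sequence[str] = ("CG", "CHG", "CHH"),
    binning: BinningConfig = BinningConfig(),
    bin_filter: BinFilterConfig = BinFilterConfig(),
    thresholds: DmrThresholds = DmrThresholds(),
    exclusions: Sequence[GenomicInterval] = (),
    allow: Sequence[GenomicInterval] = (),
) -> dict:
    """Run pool -> filter -> test -> BH -> threshold -> exclude -> merge
    -> share on in-memory per-cytosine tables.

    Returns a dict with per-line flagged-bin frames and DMR lists, the
    shared DMRs per (context, direction), and the all-context regions.
    """
    long_bins = pd.concat(
        [
            pool_counts_frame(df, chrom_lengths, lib, binning, contexts)
            for lib, df in sorted(tables.items())
        ],
        ignore_index=True,
    )
    kept = filter_bins(long_bins, bin_filter)
    alt_genotypes = sorted(set(design.values()) - {ref_genotype})
    per_line_results: dict[str, pd.DataFrame] = {}
    per_line_dmrs: dict[str, list[DMR]] = {}
    for alt in alt_genotypes:
        res = test_bins(kept, design, ref_genotype, alt)
        res = call_differential_bins(res, thresholds)
        res = exclude_regions(res, exclusions, allow)
        per_line_results[alt] = res
        per_line_dmrs[alt] = merge_bins_to_dmrs(
            res[res["flagged"]], ref_genotype, alt
        )
    shared = shared_dmrs(per_line_dmrs, alt_genotypes) if alt_genotypes else []
    shared_by_ctx: dict[str, list[SharedDMR]] = {}
    for s in shared:
        shared_by_ctx.setdefault(s.context, []).append(s)
    all_ctx = {
        direction: all_context_dmrs(shared_by_ctx, direction, list(contexts))
        for direction in ("hyper", "hypo")
    }
    return {
        "bins": kept,
        "results": per_line_results,
        "dmrs": per_line_dmrs,
        "shared": shared,
        "all_context": all_ctx,
    }


def run_dmr_screen(config: RunConfig) -> dict:
    """File-based screen: read cytosine reports, run the full pipeline,
    write TSV/BED outputs and a reproducibility manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = {
        lib: read_cytosine_report_df(path) for lib, path in config.reports.items()
    }
    result = screen_from_tables(
        tables,
        config.design,
        config.ref_genotype,
        config.chrom_lengths,
        config.contexts,
        config.binning,
        config.bin_filter,
        config.thresholds,
        config.exclusions,
        config.allow,
    )
    for alt, res in result["results"].items():
        res.to_csv(out_dir / f"bins_{alt}_vs_{config.ref_genotype}.tsv",
                   sep="\t", index=False)
    for alt, dmrs in result["dmrs"].items():
        frame = dmrs_to_frame(dmrs)
        frame.to_csv(out_dir / f"dmrs_{alt}.tsv", sep="\t", index=False)
        with open(out_dir / f"dmrs_{alt}.bed", "w") as fh:
            for d in dmrs:
                chrom, start0, end = to_bed_fields(d.interval)
                fh.write(f"{chrom}\t{start0}\t{end}\t"
                         f"{d.context}_{d.direction}\t{d.n_bins}\t.\n")
    shared_rows = []
    for s in result["shared"]:
        shared_rows.append({
            "chrom": s.interval.chrom, "start": s.interval.start,
            "end": s.interval.end, "context": s.context,
            "direction": s.direction,
            "n_lines": len(s.support),
            "support": ";".join(
                f"{ln}:" + ",".join(str(iv) for iv in ivs)
                for ln, ivs in sorted(s.support.items())
            ),
        })
    pd.DataFrame(shared_rows).to_csv(out_dir / "shared_dmrs.tsv", sep="\t", index=False)
    ac_rows = [
        {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "direction": direction}
        for direction, ivs in result["all_context"].items()
        for iv in ivs
    ]
    pd.DataFrame(ac_rows).to_csv(out_dir / "all_context_dmrs.tsv", sep="\t", index=False)

    if config.gff:
        genes = read_gff3_genes(config.gff)
        loci = None
        if config.loci_bed:
            loci = {}
            with open(config.loci_bed) as fh:
                for i, line in enumerate(fh):
                    f = line.split("\t")
                    name = f[3].strip() if len(f) > 3 else f"locus{i + 1}"
                    loci[name] = GenomicInterval(f[0], int(f[1]) + 1, int(f[2]))
        ann = annotate_dmrs(
            [s.interval for s in result["shared"]], genes, loci=loci
        )
        ann.to_csv(out_dir / "shared_dmr_annotation.tsv", sep="\t", index=False)
        result["annotation"] = ann

    _write_manifest(out_dir, _config_repr(config), config.reports)
    return result


# ---------------------------------------------------------------------------
# truth evaluation for synthetic screens


def evaluate_screen(result: dict, truth_dmrs, contexts=("CG", "CHG", "CHH")) -> dict:
    """Score a screen against implanted truth.

    sensitivity: fraction of truth regions overlapped by a shared DMR
    of the same context.  fdp: flagged bins (across lines) that overlap
    no truth region of their context, over all flagged bins.
    """
    shared = result["shared"]
    n_hit = 0
    truth = [t for t in truth_dmrs if t.context in contexts]
    for t in truth:
        if any(s.context == t.context and s.interval.overlaps(t.interval)
               for s in shared):
            n_hit += 1
    sensitivity = n_hit / len(truth) if truth else float("nan")

    n_flagged = 0
    n_false = 0
    for res in result["results"].values():
        flagged = res[res["flagged"]]
        for row in flagged.itertuples():
            n_flagged += 1
            iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
            if not any(t.context == row.context and t.interval.overlaps(iv)
                       for t in truth):
                n_false += 1
    fdp = n_false / n_flagged if n_flagged else 0.0
    return {"sensitivity": sensitivity, "fdp": fdp,
            "n_truth": len(truth), "n_flagged_bins": n_flagged}


# ---------------------------------------------------------------------------
# segregation study


def run_segregation_study(
    ct_path,
    pedigree_path,
    out_dir=None,
    class_cfg: ClassConfig = ClassConfig(),
    alpha: float = 0.05,
    efficiency: float = 2.0,
) -> dict:
    """Per-plant McrBC calls -> family class tables -> binomial tests.

    The pedigree TSV needs columns sample, parent, generation (F1, F2,
    BC1, or parental line names for controls).  For each amplicon, F2
    plants are tested for a deficit of the low class (p0 = 1/4, lower
    tail), BC1 plants for an excess of the high class (p0 = 1/2, upper
    tail); F1 plants are summarised descriptively.
    """
    ped = pd.read_csv(str(pedigree_path), sep="\t", dtype=str)
    need = {"sample", "parent", "generation"}
    if ped.empty or not need <= set(ped.columns):
        raise ValueError(
            f"pedigree {pedigree_path} must be non-empty with columns {sorted(need)}"
        )
    generation = dict(zip(ped["sample"], ped["generation"]))
    parent = dict(zip(ped["sample"], ped["parent"]))
    measurements = read_ct_table(ct_path, efficiency=efficiency)

    calls_by_amplicon: dict[str, list] = {}
    for m in measurements:
        calls_by_amplicon.setdefault(m.amplicon, []).append(call_plant(m, class_cfg))

    reports = []
    call_frames = []
    family_tables = {}
    f1_screens = {}
    for amplicon, calls in sorted(calls_by_amplicon.items()):
        orphans = sorted({c.sample for c in calls} - set(generation))
        if orphans:
            raise ValueError(f"samples missing from pedigree: {orphans}")
        frame = calls_to_frame(calls)
        frame.insert(0, "amplicon", amplicon)
        frame["generation"] = frame["sample"].map(generation)
        frame["parent"] = frame["sample"].map(parent)
        call_frames.append(frame)

        f2_calls = [c for c in calls if generation[c.sample] == "F2"]
        if f2_calls:
            family_tables[amplicon] = summarize_family(
                f2_calls, {c.sample: parent[c.sample] for c in f2_calls}
            )
            n_low = sum(c.level == "low" for c in f2_calls)
            rep = test_f2(SegregationObservation("F2", len(f2_calls), n_low, "low"),
                          alpha=alpha)
            reports.append((amplicon, "F2", rep))
        bc1_calls = [c for c in calls if generation[c.sample] == "BC1"]
        if bc1_calls:
            n_high = sum(c.level == "high" for c in bc1_calls)
            rep = test_bc1(SegregationObservation("BC1", len(bc1_calls), n_high, "high"),
                           alpha=alpha)
            reports.append((amplicon, "BC1", rep))
        f1_calls = [c for c in calls if generation[c.sample] == "F1"]
        if f1_calls:
            f1_screens[amplicon] = screen_f1(f1_calls, class_cfg)

    calls_frame = pd.concat(call_frames, ignore_index=True) if call_frames else pd.DataFrame()
    report_frame = pd.DataFrame([
        {
            "amplicon": amp, "generation": gen,
            "n_total": r.observation.n_total,
            "n_in_class": r.observation.n_in_class,
            "tested_class": r.observation.tested_class,
            "p0": r.null.p0, "tail": r.null.tail,
            "p_value": r.p_value, "alpha": r.alpha, "flagged": r.flagged,
            "note": r.note,
        }
        for amp, gen, r in reports
    ])
    out = {
        "calls": calls_frame,
        "tests": report_frame,
        "families": family_tables,
        "f1_screens": f1_screens,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        calls_frame.to_csv(out_dir / "plant_calls.tsv", sep="\t", index=False)
        report_frame.to_csv(out_dir / "segregation_tests.tsv", sep="\t", index=False)
        for amplicon, table in family_tables.items():
            table.to_csv(out_dir / f"family_classes_{amplicon}.tsv", sep="\t")
    return out
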