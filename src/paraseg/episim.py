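"""Stochastic simulation of epiallele inheritance and synthetic methylomes.

The locus model is a diploid with two epialleles, unmethylated (u) and
methylated (m), giving four epigenetic configurations {uu, um, mu, mm}.
Methylated alleles carry a provenance: *naive* alleles inherited their
methylation, *converted* alleles gained it through a paramutation-like
interaction with a methylated homologue.  Per organismal generation,
each plant undergoes one stochastic soma step:

1. in an epi-heterozygote, the unmethylated allele is converted (u -> m,
   marked converted) with probability ``pi_primary`` if the methylated
   partner is naive, or ``pi_secondary`` if it is itself converted
   (secondary paramutation is typically weaker);
2. each allele then flips spontaneously: u -> m with ``eps_gain``,
   m -> u with ``eps_loss`` (reversion erases provenance).

Two conversion timings are provided, because segregation data usually
cannot distinguish them: ``somatic`` (default) applies paramutation in
the soma before measurement, ``meiotic`` applies it only in the
reproductive lineage, so a measured heterozygote still reads 50% while
its gametes already carry the converted allele.

Readout emulates McrBC-qPCR: fraction = (methylated alleles)/2 plus
clamped Gaussian noise.

The module also generates per-cytosine bisulfite count tables with
implanted differentially methylated regions, so the genome-wide screen
can be exercised end-to-end on data of known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .intervals import GenomicInterval, to_bed_fields
from .mcrbc import ClassConfig, classify_level

# allele codes
U, MN, MC = 0, 1, 2  # unmethylated, methylated-naive, methylated-converted
_ALLELE_LABEL = {U: "u", MN: "m", MC: "m*"}  # '*' marks converted provenance


@dataclass(frozen=True)
class EpialleleState:
    methylation: str  # 'u' | 'm'
    provenance: str = "naive"  # 'naive' | 'converted'

    def __post_init__(self) -> None:
        if self.methylation not in {"u", "m"}:
            raise ValueError("methylation must be 'u' or 'm'")
        if self.provenance not in {"naive", "converted"}:
            raise ValueError("provenance must be 'naive' or 'converted'")
        if self.provenance == "converted" and self.methylation != "m":
            raise ValueError("only a methylated allele can be converted")

    @property
    def code(self) -> int:
        if self.methylation == "u":
            return U
        return MC if self.provenance == "converted" else MN

    @classmethod
    def from_code(cls, code: int) -> "EpialleleState":
        if code == U:
            return cls("u")
        return cls("m", "converted" if code == MC else "naive")


@dataclass(frozen=True)
class DiploidEpigenotype:
    allele_1: EpialleleState
    allele_2: EpialleleState

    @property
    def n_meth(self) -> int:
        return (self.allele_1.methylation == "m") + (self.allele_2.methylation == "m")

    @property
    def label(self) -> str:
        return _ALLELE_LABEL[self.allele_1.code] + _ALLELE_LABEL[self.allele_2.code]

    @classmethod
    def from_string(cls, s: str) -> "DiploidEpigenotype":
        """Parse labels like 'um', 'mm', 'um*' ('*' = converted)."""
        alleles = []
        i = 0
        while i < len(s):
            meth = s[i]
            conv = i + 1 < len(s) and s[i + 1] == "*"
            alleles.append(EpialleleState(meth, "converted" if conv else "naive"))
            i += 2 if conv else 1
        if len(alleles) != 2:
            raise ValueError(f"cannot parse diploid epigenotype {s!r}")
        return cls(alleles[0], alleles[1])


UU = DiploidEpigenotype(EpialleleState("u"), EpialleleState("u"))
MM = DiploidEpigenotype(EpialleleState("m"), EpialleleState("m"))
UM = DiploidEpigenotype(EpialleleState("u"), EpialleleState("m"))


@dataclass(frozen=True)
class EpiModelParams:
    """Per-generation transition probabilities and readout noise."""

    eps_gain: float = 0.0
    eps_loss: float = 0.0
    pi_primary: float = 0.0
    pi_secondary: float = 0.0
    sigma: float = 0.0
    timing: str = "somatic"  # 'somatic' | 'meiotic'

    def __post_init__(self) -> None:
        for name in ("eps_gain", "eps_loss", "pi_primary", "pi_secondary"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.timing not in {"somatic", "meiotic"}:
            raise ValueError("timing must be 'somatic' or 'meiotic'")


@dataclass(frozen=True)
class CrossDesign:
    """A crossing scheme from two founder plants.

    ``design`` is one of F1, F2 (selfed F1), or BC<k> (k successive
    backcrosses of the hybrid lineage to founder_b, the recurrent
    parent).  ``n_intermediate`` sizes the unmeasured generations.
    """

    design: str
    founder_a: DiploidEpigenotype = MM
    founder_b: DiploidEpigenotype = UU
    n_offspring: int = 100
    n_intermediate: int = 50

    def __post_init__(self) -> None:
        if self.design not in {"F1", "F2"} and not (
            self.design.startswith("BC") and self.design[2:].isdigit()
        ):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_offspring < 0:
            raise ValueError("n_offspring must be >= 0")


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# vectorised population dynamics


def _paramutation_step(a1, a2, params: EpiModelParams, rng) -> tuple[np.ndarray, np.ndarray]:
    a1, a2 = a1.copy(), a2.copy()
    for target, partner in ((a1, a2), (a2, a1)):
        het = (target == U) & (partner != U)
        pi = np.where(partner == MN, params.pi_primary, params.pi_secondary)
        convert = het & (rng.random(target.shape) < pi)
        target[convert] = MC
    return a1, a2


def _epimutation_step(alleles, params: EpiModelParams, rng) -> np.ndarray:
    out = alleles.copy()
    r = rng.random(alleles.shape)
    out[(alleles == U) & (r < params.eps_gain)] = MN
    out[(alleles != U) & (r < params.eps_loss)] = U
    return out


def _advance_pop(a1, a2, params, rng, paramutation: bool) -> tuple[np.ndarray, np.ndarray]:
    if paramutation:
        a1, a2 = _paramutation_step(a1, a2, params, rng)
    return _epimutation_step(a1, params, rng), _epimutation_step(a2, params, rng)


def advance_soma(
    g: DiploidEpigenotype, params: EpiModelParams, rng
) -> DiploidEpigenotype:
    """One soma step of a single plant: paramutation in heterozygotes,
    then independent spontaneous epimutation of each allele."""
    rng = _as_rng(rng)
    a1 = np.array([g.allele_1.code])
    a2 = np.array([g.allele_2.code])
    a1, a2 = _advance_pop(a1, a2, params, rng, paramutation=True)
    return DiploidEpigenotype(
        EpialleleState.from_code(int(a1[0])), EpialleleState.from_code(int(a2[0]))
    )


def _gametes(a1, a2, idx, rng) -> np.ndarray:
    """One gamete per entry of idx, drawn uniformly from the two alleles
    of plant idx[i]."""
    pick_first = rng.random(idx.shape) < 0.5
    return np.where(pick_first, a1[idx], a2[idx])


def _pre_gamete(a1, a2, params, rng):
    """Alleles of the gamete-producing lineage: in meiotic timing,
    paramutation acts here rather than in the soma."""
    if params.timing == "meiotic":
        return _paramutation_step(a1, a2, params, rng)
    return a1, a2


def simulate_cross_arrays(
    design: CrossDesign, params: EpiModelParams, rng
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run a crossing design; returns (allele_1, allele_2, fraction)
    arrays of the measured generation.

    Each generation is created from parental gametes and advanced
    through exactly one soma step before being measured or reproducing.
    In meiotic timing the measured generation's soma step omits
    paramutation (conversion happens only en route to the next
    generation).
    """
    rng = _as_rng(rng)
    n = design.n_offspring
    if n == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy(), np.empty(0, dtype=float)

    birth_paramutation = params.timing == "somatic"

    def founder_pop(g: DiploidEpigenotype):
        a1 = np.array([g.allele_1.code], dtype=np.int64)
        a2 = np.array([g.allele_2.code], dtype=np.int64)
        return _advance_pop(a1, a2, params, rng, paramutation=birth_paramutation)

    pa1, pa2 = founder_pop(design.founder_a)
    pb1, pb2 = founder_pop(design.founder_b)

    n_backcrosses = int(design.design[2:]) if design.design.startswith("BC") else 0
    n_f1 = n if design.design == "F1" else design.n_intermediate

    # F1
    ga1, ga2 = _pre_gamete(pa1, pa2, params, rng)
    gb1, gb2 = _pre_gamete(pb1, pb2, params, rng)
    ia = rng.integers(0, len(pa1), size=n_f1)
    ib = rng.integers(0, len(pb1), size=n_f1)
    c1 = _gametes(ga1, ga2, ia, rng)
    c2 = _gametes(gb1, gb2, ib, rng)
    c1, c2 = _advance_pop(c1, c2, params, rng, paramutation=birth_paramutation)

    if design.design == "F2":
        s1, s2 = _pre_gamete(c1, c2, params, rng)
        parent = rng.integers(0, n_f1, size=n)  # selfing: both gametes, same plant
        c1n = _gametes(s1, s2, parent, rng)
        c2n = _gametes(s1, s2, parent, rng)
        c1, c2 = _advance_pop(c1n, c2n, params, rng, paramutation=birth_paramutation)
    elif n_backcrosses:
        for k in range(n_backcrosses):
            n_gen = n if k == n_backcrosses - 1 else design.n_intermediate
            s1, s2 = _pre_gamete(c1, c2, params, rng)
            r1, r2 = _pre_gamete(pb1, pb2, params, rng)
            ih = rng.integers(0, len(s1), size=n_gen)
            ir = rng.integers(0, len(r1), size=n_gen)
            c1n = _gametes(s1, s2, ih, rng)
            c2n = _gametes(r1, r2, ir, rng)
            c1, c2 = _advance_pop(c1n, c2n, params, rng, paramutation=birth_paramutation)

    frac = measure_population(c1, c2, params.sigma, rng)
    return c1, c2, frac


def measure_population(a1, a2, sigma: float, rng) -> np.ndarray:
    """McrBC-like readout: methylated-allele fraction plus clamped
    Gaussian noise."""
    rng = _as_rng(rng)
    frac = ((a1 != U).astype(float) + (a2 != U)) / 2.0
    if sigma > 0:
        frac = frac + rng.normal(0.0, sigma, size=frac.shape)
    return np.clip(frac, 0.0, 1.0)


def measure_plant(g: DiploidEpigenotype, sigma: float, rng) -> float:
    """Readout of a single plant; see :func:`measure_population`."""
    rng = _as_rng(rng)
    return float(measure_population(
        np.array([g.allele_1.code]), np.array([g.allele_2.code]), sigma, rng
    )[0])


def simulate_cross(
    design: CrossDesign,
    params: EpiModelParams,
    rng=None,
    class_cfg: ClassConfig = ClassConfig(),
    family: str = "fam1",
) -> pd.DataFrame:
    """Simulate a crossing design and return one row per measured plant
    (id, generation, family, epigenotype, n_meth, fraction, level)."""
    a1, a2, frac = simulate_cross_arrays(design, params, _as_rng(rng))
    labels = [_ALLELE_LABEL[int(x)] + _ALLELE_LABEL[int(y)] for x, y in zip(a1, a2)]
    return pd.DataFrame({
        "id": [f"{design.design}_{i + 1}" for i in range(len(a1))],
        "generation": design.design,
        "family": family,
        "epigenotype": labels,
        "n_meth": ((a1 != U).astype(int) + (a2 != U)).astype(int),
        "fraction": frac,
        "level": [classify_level(f, class_cfg) for f in frac],
    })


# ---------------------------------------------------------------------------
# exact class probabilities (9-state enumeration) and grid-search fitting


def _allele_epi_matrix(params: EpiModelParams) -> np.ndarray:
    eg, el = params.eps_gain, params.eps_loss
    E = np.zeros((3, 3))
    E[U, U], E[U, MN] = 1 - eg, eg
    E[MN, U], E[MN, MN] = el, 1 - el
    E[MC, U], E[MC, MC] = el, 1 - el
    return E


def _paramutation_matrix(params: EpiModelParams) -> np.ndarray:
    P = np.eye(9)
    for a1 in range(3):
        for a2 in range(3):
            s = 3 * a1 + a2
            if a1 == U and a2 != U:
                pi = params.pi_primary if a2 == MN else params.pi_secondary
                P[s, s] = 1 - pi
                P[s, 3 * MC + a2] = pi
            elif a2 == U and a1 != U:
                pi = params.pi_primary if a1 == MN else params.pi_secondary
                P[s, s] = 1 - pi
                P[s, 3 * a1 + MC] = pi
    return P


def _gamete_dist_per_state() -> np.ndarray:
    G = np.zeros((9, 3))
    for a1 in range(3):
        for a2 in range(3):
            G[3 * a1 + a2, a1] += 0.5
            G[3 * a1 + a2, a2] += 0.5
    return G


def cross_state_distribution(
    design: CrossDesign, params: EpiModelParams
) -> np.ndarray:
    """Exact marginal distribution over the 9 ordered diploid states of
    the measured generation (allele codes u / m-naive / m-converted).

    For F2 selfing, the joint two-gametes-from-one-plant structure is
    respected; backcross generations take one gamete from the hybrid
    lineage and one from the recurrent parent.
    """
    P = _paramutation_matrix(params)
    K = np.kron(_allele_epi_matrix(params), _allele_epi_matrix(params))
    G = _gamete_dist_per_state()
    birth = P @ K if params.timing == "somatic" else K
    pre_gamete = np.eye(9) if params.timing == "somatic" else P

    def delta(g: DiploidEpigenotype):
        d = np.zeros(9)
        d[3 * g.allele_1.code + g.allele_2.code] = 1.0
        return d

    da = delta(design.founder_a) @ birth @ pre_gamete
    db = delta(design.founder_b) @ birth @ pre_gamete
    f1 = np.outer(da @ G, db @ G).reshape(9) @ birth

    if design.design == "F1":
        return f1
    if design.design == "F2":
        pre = f1 @ pre_gamete
        joint = np.zeros(9)
        for s in range(9):  # both gametes from the same (stochastic) parent state
            joint += pre[s] * np.outer(G[s], G[s]).reshape(9)
        return joint @ birth
    n_backcrosses = int(design.design[2:])
    dist = f1
    for _ in range(n_backcrosses):
        gh = (dist @ pre_gamete) @ G
        gr = db @ G
        dist = np.outer(gh, gr).reshape(9) @ birth
    return dist


def class_probabilities(
    design: CrossDesign,
    params: EpiModelParams,
    class_cfg: ClassConfig = ClassConfig(),
) -> dict[str, float]:
    """Exact low/intermediate/high class probabilities of the measured
    generation's noisy readout."""
    dist = cross_state_distribution(design, params)
    fracs = np.array([((s // 3 != U) + (s % 3 != U)) / 2.0 for s in range(9)])
    probs = {"low": 0.0, "intermediate": 0.0, "high": 0.0}
    for s in range(9):
        f = fracs[s]
        if params.sigma == 0:
            probs[classify_level(f, class_cfg)] += dist[s]
        else:
            # clamping to [0,1] never moves a readout across an interior boundary
            p_low = norm.cdf((class_cfg.low_max - f) / params.sigma)
            p_int = norm.cdf((class_cfg.intermediate_max - f) / params.sigma) - p_low
            probs["low"] += dist[s] * p_low
            probs["intermediate"] += dist[s] * p_int
            probs["high"] += dist[s] * (1.0 - p_low - p_int)
    return probs


@dataclass
class EstimationResult:
    pi_primary: float
    eps_loss: float
    log_likelihood: float
    surface: pd.DataFrame  # columns pi_primary, eps_loss, log_likelihood


def estimate_params(
    class_counts: Mapping[str, Sequence[int]],
    design: CrossDesign,
    base_params: EpiModelParams,
    pi_grid: Sequence[float] | None = None,
    eps_loss_grid: Sequence[float] = (0.0,),
    class_cfg: ClassConfig = ClassConfig(),
) -> EstimationResult:
    """Maximum-likelihood grid search for (pi_primary, eps_loss).

    ``class_counts`` maps a generation name (F1/F2/BC1...) to observed
    (low, intermediate, high) counts; each generation's counts enter a
    multinomial log-likelihood under the exact class probabilities of
    the corresponding design.  Ties on the grid resolve to the smallest
    parameter values (scan order).
    """
    if not class_counts:
        raise ValueError("need >= 1 observed generation")
    if pi_grid is None:
        pi_grid = np.linspace(0.0, 1.0, 51)
    rows = []
    best = None
    for pi in pi_grid:
        for el in eps_loss_grid:
            params = replace(base_params, pi_primary=float(pi), eps_loss=float(el))
            ll = 0.0
            for gen, counts in class_counts.items():
                probs = class_probabilities(
                    replace(design, design=gen), params, class_cfg
                )
                pvec = np.array([probs["low"], probs["intermediate"], probs["high"]])
                cvec = np.asarray(counts, dtype=float)
                observed = cvec > 0
                with np.errstate(divide="ignore"):
                    log_p = np.log(np.where(pvec > 0, pvec, 1.0))
                log_p[observed & (pvec == 0)] = -np.inf
                ll += float((cvec[observed] * log_p[observed]).sum())
            rows.append((float(pi), float(el), ll))
            if best is None or ll > best[2]:
                best = (float(pi), float(el), ll)
    surface = pd.DataFrame(rows, columns=["pi_primary", "eps_loss", "log_likelihood"])
    return EstimationResult(*best, surface=surface)


# ---------------------------------------------------------------------------
# synthetic bisulfite methylomes with implanted DMRs


@dataclass(frozen=True)
class TruthDMR:
    interval: GenomicInterval
    context: str
    levels: Mapping[str, float]  # genotype -> methylation level inside the region


@dataclass
class BisulfiteSimSpec:
    """Specification of a synthetic per-cytosine bisulfite data set.

    Defaults emulate a leaf methylome screen at modest scale: negative-
    binomial coverage around 20x, euchromatin-like baseline methylation
    per context, and shared hyper-DMRs implanted identically in all
    introgression-line genotypes.
    """

    chrom_lengths: Mapping[str, int]
    libraries: Mapping[str, str]  # library id -> genotype
    truth_dmrs: Sequence[TruthDMR] = ()
    site_density: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.03, "CHG": 0.03, "CHH": 0.10}
    )
    baseline: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.30, "CHG": 0.20, "CHH": 0.08}
    )
    coverage_mean: float = 20.0
    coverage_dispersion: float = 10.0  # negative-binomial size; larger = tighter
    seed: int | None = None

    def validate(self) -> None:
        for level in self.baseline.values():
            if not (0.0 <= level <= 1.0):
                raise ValueError("baseline levels must be in [0, 1]")
        for t in self.truth_dmrs:
            if t.interval.chrom not in self.chrom_lengths:
                raise ValueError(f"truth DMR on unknown chromosome {t.interval.chrom}")
            if t.interval.end > self.chrom_lengths[t.interval.chrom]:
                raise ValueError(f"truth DMR {t.interval} exceeds chromosome bounds")
            for lvl in t.levels.values():
                if not (0.0 <= lvl <= 1.0):
                    raise ValueError("truth DMR levels must be in [0, 1]")
        by_ctx: dict[str, list[GenomicInterval]] = {}
        for t in self.truth_dmrs:
            by_ctx.setdefault(t.context, []).append(t.interval)
        for ctx, ivs in by_ctx.items():
            ivs = sorted(ivs)
            for a, b in zip(ivs, ivs[1:]):
                if a.overlaps(b):
                    raise ValueError(
                        f"overlapping truth DMRs in context {ctx}: {a} and {b}"
                    )


def simulate_methylomes(spec: BisulfiteSimSpec) -> dict[str, pd.DataFrame]:
    """Draw per-cytosine count tables for every library.

    Site positions and contexts are shared across libraries (one
    genome); coverage is negative-binomial per site and library;
    methylated counts are binomial at the baseline level, overridden by
    the genotype's truth-DMR level inside implanted regions.
    Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    # shared site map
    chrom_sites: dict[str, pd.DataFrame] = {}
    for chrom in sorted(spec.chrom_lengths):
        length = spec.chrom_lengths[chrom]
        parts = []
        for ctx in sorted(spec.site_density):
            n_sites = int(round(spec.site_density[ctx] * length))
            n_sites = min(n_sites, length)
            pos = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1
            parts.append(pd.DataFrame({
                "pos": pos,
                "strand": np.where(rng.random(n_sites) < 0.5, "+", "-"),
                "context": ctx,
            }))
        sites = pd.concat(parts, ignore_index=True).sort_values(
            "pos", kind="mergesort", ignore_index=True
        )
        chrom_sites[chrom] = sites

    genotypes = sorted(set(spec.libraries.values()))
    # per-chromosome, per-genotype level vectors
    levels: dict[str, dict[str, np.ndarray]] = {}
    for chrom, sites in chrom_sites.items():
        base = sites["context"].map(dict(spec.baseline)).to_numpy(dtype=float)
        per_geno = {g: base.copy() for g in genotypes}
        pos = sites["pos"].to_numpy()
        ctx = sites["context"].to_numpy()
        for t in spec.truth_dmrs:
            if t.interval.chrom != chrom:
                continue
            inside = (pos >= t.interval.start) & (pos <= t.interval.end) & (ctx == t.context)
            for g in genotypes:
                if g in t.levels:
                    per_geno[g][inside] = t.levels[g]
        levels[chrom] = per_geno

    r = spec.coverage_dispersion
    nb_p = r / (r + spec.coverage_mean) if spec.coverage_mean > 0 else 1.0
    out: dict[str, pd.DataFrame] = {}
    for lib in sorted(spec.libraries):
        geno = spec.libraries[lib]
        frames = []
        for chrom in sorted(chrom_sites):
            sites = chrom_sites[chrom]
            n_sites = len(sites)
            if spec.coverage_mean > 0:
                cov = rng.negative_binomial(r, nb_p, size=n_sites)
            else:
                cov = np.zeros(n_sites, dtype=np.int64)
            n_meth = rng.binomial(cov, levels[chrom][geno])
            frames.append(pd.DataFrame({
                "chrom": chrom,
                "pos": sites["pos"].to_numpy(),
                "strand": sites["strand"].to_numpy(),
                "n_meth": n_meth,
                "n_unmeth": cov - n_meth,
                "context": sites["context"].to_numpy(),
            }))
        out[lib] = pd.concat(frames, ignore_index=True)
    return out


def generate_cytosine_reports(spec: BisulfiteSimSpec, out_dir) -> dict[str, Path]:
    """Write one cytosine-report TSV per library plus a truth BED.

    Returns a mapping of output name -> path ('truth' for the BED).
    Byte-identical across runs with the same spec and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = simulate_methylomes(spec)
    paths: dict[str, Path] = {}
    for lib, df in tables.items():
        path = out_dir / f"{lib}.cytosine_report.txt"
        df.to_csv(path, sep="\t", header=False, index=False)
        paths[lib] = path
    truth_path = out_dir / "truth_dmrs.bed"
    with open(truth_path, "w") as fh:
        for t in spec.truth_dmrs:
            chrom, start0, end = to_bed_fields(t.interval)
            name = t.context + ":" + ",".join(
                f"{g}={t.levels[g]:g}" for g in sorted(t.levels)
            )
            fh.write(f"{chrom}\t{start0}\t{end}\t{name}\n")
    paths["truth"] = truth_path
    return paths


def make_screen_spec(
    n_chroms: int = 5,
    chrom_length: int = 1_000_000,
    n_dmrs_per_context: int = 20,
    dmr_width: int = 900,
    effects: Mapping[str, float] | None = None,
    genotypes: Sequence[str] = ("M82", "IL1", "IL2", "IL8"),
    n_replicates: int = 2,
    coverage_mean: float = 20.0,
    seed: int | None = None,
) -> BisulfiteSimSpec:
    """Standard synthetic screen: one recurrent-parent genotype plus
    introgression lines, with hyper-DMRs implanted identically in every
    line (the shared-DMR truth the screen should recover).

    Effect sizes default to CG +0.40, CHG +0.35, CHH +0.25 over the
    per-context baselines — comfortably above the caller's decision
    thresholds, as implanted truth must be for recovery to be a
    property of the caller rather than of sampling noise at the cutoff.
    """
    if effects is None:
        effects = {"CG": 0.40, "CHG": 0.35, "CHH": 0.25}
    spec = BisulfiteSimSpec(
        chrom_lengths={f"chr{i + 1:02d}": chrom_length for i in range(n_chroms)},
        libraries={
            f"{g}_{r + 1}": g for g in genotypes for r in range(n_replicates)
        },
        coverage_mean=coverage_mean,
        seed=seed,
    )
    ref, alts = genotypes[0], list(genotypes[1:])
    chroms = sorted(spec.chrom_lengths)
    truth: list[TruthDMR] = []
    contexts = sorted(effects)
    # lay truth regions on a fixed grid, one context per slot, spaced so
    # adjacent regions can never fall into the same sliding window
    n_slots = n_dmrs_per_context * len(contexts)
    per_chrom = -(-n_slots // len(chroms))
    margin = 10_000
    spacing = max(dmr_width + 2_000, (chrom_length - 2 * margin) // per_chrom)
    slot = 0
    for ctx in contexts:
        for _ in range(n_dmrs_per_context):
            chrom = chroms[slot % len(chroms)]
            start = margin + (slot // len(chroms)) * spacing
            slot += 1
            if start + dmr_width - 1 > chrom_length:
                raise ValueError("genome too small for requested truth DMRs")
            iv = GenomicInterval(chrom, start, start + dmr_width - 1)
            base = spec.baseline[ctx]
            lvl = min(1.0, base + effects[ctx])
            truth.append(TruthDMR(iv, ctx, {ref: base, **{a: lvl for a in alts}}))
    spec.truth_dmrs = tuple(truth)
    return spec
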