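"""McrBC-qPCR methylation quantification.

McrBC cleaves methylated DNA, so amplification of a digested aliquot is
delayed relative to a mock-digested aliquot in proportion to the
fraction of intact (unmethylated) template molecules.  With
amplification efficiency E per cycle, the surviving unmethylated
fraction is u = E^-(Ct_digested - Ct_mock) and the methylated fraction
is 1 - u, clamped to [0, 1].  This is the standard reading of the
digestion/qPCR principle; the assay itself does not prescribe a unique
arithmetic.

Plants are then classified into low (<= 1/3), intermediate (<= 2/3) and
high (> 2/3) methylation levels, and families summarised as
parent x level contingency tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

LEVELS = ("low", "intermediate", "high")


@dataclass(frozen=True)
class McrBCMeasurement:
    """One digested/mock Ct pair for one sample and amplicon.

    ``ct_digested`` may be NaN for reactions with no amplification in
    the digested aliquot (fully methylated template): these are treated
    as fraction 1.0 and flagged censored.
    """

    sample: str
    amplicon: str
    ct_digested: float
    ct_mock: float
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError("efficiency must be in (1, 2]")
        if not math.isnan(self.ct_mock) and self.ct_mock <= 0:
            raise ValueError("Ct values must be positive")
        if not math.isnan(self.ct_digested) and self.ct_digested <= 0:
            raise ValueError("Ct values must be positive")


@dataclass(frozen=True)
class ClassConfig:
    """Level boundaries on the methylated fraction (inclusive upper)."""

    low_max: float = 1 / 3
    intermediate_max: float = 2 / 3

    def __post_init__(self) -> None:
        if not (0 < self.low_max < self.intermediate_max < 1):
            raise ValueError("need 0 < low_max < intermediate_max < 1")


@dataclass(frozen=True)
class PlantMethylationCall:
    sample: str
    fraction_methylated: float
    level: str
    censored: bool = False


def fraction_methylated(m: McrBCMeasurement) -> tuple[float, bool]:
    """Methylated-molecule fraction from a Ct pair.

    Returns (fraction, censored).  Negative delta-Ct (digested amplifies
    earlier than mock, within noise) clamps to 0; a missing digested Ct
    means complete digestion and returns (1.0, True).
    """
    if math.isnan(m.ct_digested):
        return 1.0, True
    delta_ct = m.ct_digested - m.ct_mock
    unmeth = m.efficiency ** (-delta_ct)
    return min(1.0, max(0.0, 1.0 - unmeth)), False


def classify_level(fraction: float, cfg: ClassConfig = ClassConfig()) -> str:
    """Map a fraction in [0, 1] to low / intermediate / high."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if fraction <= cfg.low_max:
        return "low"
    if fraction <= cfg.intermediate_max:
        return "intermediate"
    return "high"


def call_plant(m: McrBCMeasurement, cfg: ClassConfig = ClassConfig()) -> PlantMethylationCall:
    frac, censored = fraction_methylated(m)
    return PlantMethylationCall(m.sample, frac, classify_level(frac, cfg), censored)


def read_ct_table(path, efficiency: float = 2.0) -> list[McrBCMeasurement]:
    """Read a Ct table TSV (columns: sample, amplicon, treatment, ct)
    with treatment in {digested, mock}; technical-replicate Ct values
    are averaged before pairing."""
    df = pd.read_csv(str(path), sep="\t", dtype={"sample": str, "amplicon": str})
    need = {"sample", "amplicon", "treatment", "ct"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: Ct table needs columns {sorted(need)}")
    bad = ~df["treatment"].isin(["digested", "mock"])
    if bad.any():
        raise ValueError(f"{path}: treatment must be 'digested' or 'mock'")
    mean_ct = df.groupby(["sample", "amplicon", "treatment"])["ct"].mean().unstack()
    out = []
    for (sample, amplicon), row in mean_ct.iterrows():
        out.append(McrBCMeasurement(
            sample, amplicon,
            ct_digested=float(row.get("digested", float("nan"))),
            ct_mock=float(row.get("mock", float("nan"))),
            efficiency=efficiency,
        ))
    return out


def calls_to_frame(calls: Iterable[PlantMethylationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.sample, c.fraction_methylated, c.level, c.censored) for c in calls],
        columns=["sample", "fraction_methylated", "level", "censored"],
    )


def summarize_family(
    calls: Iterable[PlantMethylationCall], pedigree: Mapping[str, str]
) -> pd.DataFrame:
    """Parent x level contingency table of progeny methylation classes.

    ``pedigree`` maps sample id -> parent id; every called sample must
    appear in it.  Row sums equal family sizes (counts are conserved).
    """
    calls = list(calls)
    orphans = sorted({c.sample for c in calls} - set(pedigree))
    if orphans:
        raise ValueError(f"samples missing from pedigree: {orphans}")
    table = pd.DataFrame(0, index=sorted({pedigree[c.sample] for c in calls}),
                         columns=list(LEVELS))
    for c in calls:
        table.loc[pedigree[c.sample], c.level] += 1
    table.index.name = "parent"
    return table
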