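import numpy as np
import pandas as pd
import pytest

from paraseg.episim import make_screen_spec, simulate_methylomes
from paraseg.pipeline import screen_from_tables


@pytest.fixture(scope="session")
def small_screen():
    """A small synthetic screen (2 x 200 kb, 4 implanted DMRs per
    context, 4 genotypes x 2 replicates) plus its pipeline result."""
    spec = make_screen_spec(
        n_chroms=2, chrom_length=200_000, n_dmrs_per_context=4, seed=11
    )
    tables = simulate_methylomes(spec)
    result = screen_from_tables(tables, spec.libraries, "M82", spec.chrom_lengths)
    return spec, tables, result


@pytest.fixture()
def toy_report(tmp_path):
    """Six-line cytosine report covering all contexts and both strands."""
    lines = [
        ("ch08", 54487325, "+", 3, 1, "CG"),
        ("ch08", 54487326, "-", 2, 2, "CG"),
        ("ch08", 54487330, "+", 0, 0, "CHH"),
        ("ch08", 54487340, "-", 5, 0, "CHG"),
        ("ch01", 100, "+", 1, 9, "CG"),
        ("ch01", 301, "+", 4, 4, "CHH"),
    ]
    path = tmp_path / "toy.cytosine_report.txt"
    with open(path, "w") as fh:
        for rec in lines:
            fh.write("\t".join(str(x) for x in rec) + "\n")
    return path, lines


def long_bins_frame(rows):
    """rows: (chrom, start, end, context, library, n_meth, n_unmeth)."""
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "context", "library", "n_meth", "n_unmeth"],
    )
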