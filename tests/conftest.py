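import numpy as np
import pandas as pd
import pytest

from pleioqtl.ldpanel import GenotypePanel
from pleioqtl.sumstats import SumStatTable, VariantKey, table_from_records


@pytest.fixture
def toy_variants():
    return [VariantKey("1", 1000 + 100 * j, "A", "G", rsid=f"rs{j}")
            for j in range(4)]


@pytest.fixture
def toy_panel(toy_variants):
    """6 samples x 4 variants, hand-chosen dosage columns.

    col0 and col1 are the derived LD fixture; col2 duplicates col0; col3 is
    col0 recoded as 2 - g.
    """
    g0 = [0, 0, 1, 1, 2, 2]
    g1 = [0, 1, 1, 1, 1, 2]
    dos = np.column_stack([g0, g1, g0, [2 - x for x in g0]]).astype(float)
    return GenotypePanel(dos, toy_variants, [f"s{i}" for i in range(6)])


def make_table(rows, **kwargs) -> SumStatTable:
    """Build a SumStatTable from (chrom, pos, ea, oa, beta, se, p, n, maf) tuples."""
    recs = []
    for i, (chrom, pos, ea, oa, beta, se, p, n, maf) in enumerate(rows):
        recs.append({"rsid": f"v{i}", "chrom": chrom, "pos": pos,
                     "effect_allele": ea, "other_allele": oa,
                     "beta": beta, "se": se, "p": p, "n": n, "maf": maf})
    return table_from_records(recs, **kwargs)


@pytest.fixture
def three_row_tsv(tmp_path):
    path = tmp_path / "sumstats.tsv"
    path.write_text(
        "rsid\tchr\tpos\tea\toa\tbeta\tse\tp\tn\tmaf\n"
        "rs1\t1\t100\tA\tG\t0.5\t0.1\t5e-7\t1000\t0.25\n"
        "rs2\tchr2\t200\tC\tT\t-0.2\t0.05\t0.01\t1000\t0.4\n"
        "rs3\tX\t300\tAT\tA\t0.0\t0.2\t1.0\t500\t0.1\n"
    )
    return path
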