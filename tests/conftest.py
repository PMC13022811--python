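"""Shared fixtures: simulated call matrices and toy VCF builders."""

from __future__ import annotations

import numpy as np
import pytest

from svbayes import make_case, simulate

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000000>
##contig=<ID=chr2,length=10000000>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##FILTER=<ID=LowQual,Description="Low quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def make_vcf(path, records):
    """Write a plain-text VCF; records are (chrom, pos, svtype, end, svlen,
    qual, filter) tuples."""
    lines = [VCF_HEADER]
    for chrom, pos, svtype, end, svlen, qual, filt in records:
        info = f"SVTYPE={svtype};END={end};SVLEN={svlen}"
        q = "." if qual is None else f"{qual:g}"
        lines.append(f"{chrom}\t{pos}\t.\tN\t<{svtype}>\t{q}\t{filt}\t{info}\n")
    path.write_text("".join(lines))
    return path


@pytest.fixture
def toy_vcf_factory(tmp_path):
    def _make(name, records):
        return make_vcf(tmp_path / name, records)

    return _make


@pytest.fixture(scope="session")
def case1_small():
    """A small Case-1 call matrix with truth (n = 300), for fast model tests."""
    cfg = make_case(1, seed=20260929)
    cfg.n = 300
    return simulate(cfg)


@pytest.fixture(scope="session")
def case1_full():
    """One full-size Case-1 replicate (n = 2000)."""
    return simulate(make_case(1, seed=4242))
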