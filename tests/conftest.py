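"""Shared fixtures: toy VCFs, small panels, and the session ABC reference table."""

import numpy as np
import pandas as pd
import pytest

from clineselect.io_formats import GeneticMap, HaplotypeMatrix
from clineselect.locus_simulator import gravel_demography
from clineselect.synthetic_data import ClineScenario, generate_cline_panel


VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr2,length=300000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_toy_vcf(path, records, samples=("s1", "s2", "s3")):
    """Write a minimal phased VCF.

    ``records`` rows: (pos, ref, alt, aa, [gt strings per sample]).
    """
    lines = [VCF_HEADER.format(samples="\t".join(samples)).rstrip("\n")]
    for pos, ref, alt, aa, gts in records:
        info = f"AA={aa}" if aa is not None else "."
        lines.append("\t".join(
            ["chr2", str(pos), ".", ref, alt, ".", "PASS", info, "GT"] + list(gts)))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def toy_vcf(tmp_path):
    """Five SNPs: one unpolarized (AA=.), one AA=ALT (flipped), plus an indel
    and a multiallelic record that must be dropped."""
    records = [
        (100, "A", "G", "A", ("0|1", "1|1", "0|0")),
        (200, "C", "T", "C", ("0|0", "0|1", "1|1")),
        (300, "G", "A", "A", ("0|1", "0|0", "1|0")),   # AA == ALT -> flip
        (400, "T", "C", ".", ("0|0", "0|1", "0|0")),   # unpolarized -> drop
        (450, "T", "TA", "T", ("0|0", "0|1", "0|0")),  # indel -> drop
        (500, "A", "C", "A", ("1|1", "0|0", "0|1")),
        (600, "G", "T", "G", ("0|0", "1|1", "0|0")),
    ]
    return write_toy_vcf(tmp_path / "toy.vcf", records)


@pytest.fixture
def flat_map():
    return GeneticMap([1.0, 200_000.0], [1.0, 1.0])


@pytest.fixture
def small_panel():
    sc = ClineScenario(n_pops=10, n_individuals=25, beta_lat=1.0,
                       drift_fst=0.03, n_background_snps=3000, seed=11)
    records, metas = generate_cline_panel(sc)
    return sc, records, metas


def random_matrix(rng, n_hap=12, n_sites=20, pops=("A", "B")):
    alleles = rng.integers(0, 2, (n_hap, n_sites)).astype(np.int8)
    positions = np.sort(rng.choice(np.arange(1, 10_000), n_sites, replace=False))
    ids = np.array([f"i{k // 2}" for k in range(n_hap)], dtype=object)
    pop = np.array([pops[k % len(pops)] for k in range(n_hap)], dtype=object)
    return HaplotypeMatrix(alleles, positions, ids, pop)


# ---------------------------------------------------------------------------
# Session-scoped ABC reference tables (built once; used by the validation and
# acceptance layers).  Sizes are the desk-scale study conditions documented in
# docs/methods.md.
# ---------------------------------------------------------------------------

ABC_SEED = 1234
ABC_Q = 100.0


@pytest.fixture(scope="session")
def abc_reference():
    from clineselect.abc_inference import simulate_reference

    dem = gravel_demography("EUR")
    parts = [
        simulate_reference(["SDN", "SSV"], 2000, dem, seed=ABC_SEED, rescale_q=ABC_Q),
        simulate_reference(["NTR"], 3000, dem, seed=ABC_SEED + 1, rescale_q=ABC_Q),
    ]
    return pd.concat(parts, ignore_index=True)


@pytest.fixture(scope="session")
def halted_reference(abc_reference):
    from clineselect.abc_inference import simulate_reference

    dem = gravel_demography("EUR")
    halted = simulate_reference(["SSV_halted"], 500, dem, seed=ABC_SEED + 2,
                                rescale_q=ABC_Q)
    ssv = abc_reference[abc_reference["model"] == "SSV"].head(500)
    return pd.concat([ssv, halted], ignore_index=True)
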