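import numpy as np
import pytest

from um_landscape.driver_analysis import load_packaged_driver_table
from um_landscape.synth import synthetic_signature_matrix


@pytest.fixture(scope="session")
def um_cohort():
    """Driver table of the 28-sample cohort, as packaged."""
    return load_packaged_driver_table()


@pytest.fixture(scope="session")
def sig5():
    """Deterministic 5-column synthetic signature matrix."""
    return synthetic_signature_matrix(5)


@pytest.fixture(scope="session")
def sig3():
    """Deterministic 3-column synthetic signature matrix."""
    return synthetic_signature_matrix(3, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20151214)


def make_vcf(path, records, extra_info=""):
    """Write a small tumor/normal VCF (samples TUMOR, NORMAL).

    ``records`` is a list of dicts with keys chrom, pos, ref, alt, t_ref,
    t_alt, n_ref, n_alt, pl_wt, clr and optional info (a raw INFO string
    like 'DB;COSMIC' or 'WARN=tri_allelic').
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CLR,Number=1,Type=Float,Description="Constrained log likelihood ratio">',
        '##INFO=<ID=DB,Number=0,Type=Flag,Description="In dbSNP">',
        '##INFO=<ID=COSMIC,Number=0,Type=Flag,Description="In COSMIC">',
        '##INFO=<ID=REPEAT,Number=0,Type=Flag,Description="Short-motif repeat region">',
        '##INFO=<ID=WARN,Number=.,Type=String,Description="Caller quality warnings">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred genotype likelihoods">',
        "##contig=<ID=chr1,length=100000000>",
        "##contig=<ID=chr2,length=100000000>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL",
    ]
    for rec in records:
        info = f"CLR={rec['clr']}"
        if rec.get("info"):
            info += ";" + rec["info"]
        pl_wt = int(rec["pl_wt"])
        lines.append(
            f"{rec['chrom']}\t{rec['pos']}\t.\t{rec['ref']}\t{rec['alt']}\t"
            f"100\tPASS\t{info}\tGT:AD:PL\t"
            f"0/1:{rec['t_ref']},{rec['t_alt']}:{pl_wt},0,200\t"
            f"0/0:{rec['n_ref']},{rec['n_alt']}:0,60,600"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
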