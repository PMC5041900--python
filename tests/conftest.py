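import pytest

from ithkit.design import CohortDesign, SampleMeta
from ithkit.simulate import simulate_cohort
from ithkit.variants import VariantCall


@pytest.fixture(scope="session")
def small_design() -> CohortDesign:
    return CohortDesign(n_patients=3, n_cores=250, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return simulate_cohort(small_design)


def make_meta(n_patients=2, n_neph=3, with_normal=True, cohort="sunitinib"):
    out = []
    for i in range(n_patients):
        pid = f"SU{i + 1:02d}"
        resp = "good" if i % 2 == 0 else "poor"
        if with_normal:
            out.append(SampleMeta(f"{pid}_N", pid, "normal", "na", cohort, resp))
        out.append(SampleMeta(f"{pid}_Bx", pid, "biopsy", "pre", cohort, resp))
        for k in range(n_neph):
            out.append(SampleMeta(f"{pid}_Nx{k + 1}", pid, "nephrectomy", "post", cohort, resp))
    return out


def make_call(
    sample_id="SU01_Bx",
    patient_id="SU01",
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    gq=99.0,
    depth=500,
    vaf=0.5,
    flank="ACGTACGTACGTACGTACGTA",
    flank_offset=10,
    consequence="missense_variant",
    sift=None,
    polyphen=None,
    gene=None,
    genotype=(0, 1),
):
    alt_depth = int(round(depth * vaf))
    return VariantCall(
        patient_id=patient_id,
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        genotype=genotype,
        gq=gq,
        allele_depths=(depth - alt_depth, alt_depth),
        flank_seq=flank,
        flank_offset=flank_offset,
        consequence=consequence,
        sift=sift,
        polyphen=polyphen,
        gene=gene,
    )
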