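import numpy as np
import pytest
from hypothesis import settings

from malines.io import ALT_HOM, HET, MISSING, REF_HOM, GenomeRef, GenotypeCall, GroupConfig, VariantSite

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_call(line, gclass, dp=10, gq=60, alt_index=None):
    if gclass in (HET, ALT_HOM) and alt_index is None:
        alt_index = 0
    return GenotypeCall(line_id=line, gclass=gclass, dp=dp, gq=gq, alt_index=alt_index)


def make_site(pos, calls, contig="chr1", ref="A", alts=("G",)):
    return VariantSite(contig=contig, pos=pos, ref=ref, alts=tuple(alts), calls=tuple(calls))


def uniform_site(pos, line_ids, focal=None, focal_dp=10, focal_gq=50, other_dp=10,
                 ref="A", alts=("G",), het_lines=(), missing_lines=()):
    """A site where everyone is ref-hom except an optional focal alt-hom."""
    calls = []
    for line in line_ids:
        if line == focal:
            calls.append(make_call(line, ALT_HOM, dp=focal_dp, gq=focal_gq))
        elif line in het_lines:
            calls.append(make_call(line, HET, dp=other_dp))
        elif line in missing_lines:
            calls.append(make_call(line, MISSING, dp=0, gq=0))
        else:
            calls.append(make_call(line, REF_HOM, dp=other_dp))
    return make_site(pos, calls, ref=ref, alts=alts)


@pytest.fixture
def lines20():
    return [f"L{i:02d}" for i in range(1, 21)]


@pytest.fixture
def group20(lines20):
    return GroupConfig(group_name="g", line_ids=lines20, generations=100)


@pytest.fixture
def tiny_genome():
    return GenomeRef({"c1": "ACGTACGTTTAAGGCC", "c2": "GGGGCCCCAAAATTTT"})


def random_sites(rng, line_ids, n_sites, contig_length=2000):
    """Random genotype matrices exercising every filter criterion branch."""
    positions = sorted(rng.choice(np.arange(1, contig_length + 1),
                                  size=n_sites, replace=False))
    alleles = [("A", ("G",)), ("C", ("T", "A")), ("A", ("AGG",)), ("ATT", ("A",))]
    sites = []
    for pos in positions:
        ref, alts = alleles[rng.integers(len(alleles))]
        calls = []
        for line in line_ids:
            u = rng.random()
            if u < 0.70:
                gclass, alt_index = REF_HOM, None
            elif u < 0.85:
                gclass, alt_index = ALT_HOM, int(rng.integers(len(alts)))
            elif u < 0.93:
                gclass, alt_index = HET, int(rng.integers(len(alts)))
            else:
                gclass, alt_index = MISSING, None
            calls.append(GenotypeCall(line_id=line, gclass=gclass,
                                      dp=int(rng.integers(0, 13)),
                                      gq=int(rng.integers(0, 61)),
                                      alt_index=alt_index))
        sites.append(make_site(int(pos), calls, ref=ref, alts=alts))
    return sites
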