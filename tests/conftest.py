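import itertools

import pytest
from hypothesis import HealthCheck, settings

from palmshell import LocusCall, MultiLocusGenotype, builtin_panel
from palmshell.synthetic import retest_fixture

settings.register_profile(
    "palmshell",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("palmshell")


@pytest.fixture(scope="session")
def panel():
    return builtin_panel()


@pytest.fixture
def retest_cohort():
    return retest_fixture()


def mutant_allele(variant):
    """A loss-of-function allele for a site: the catalogued mutant, or an
    arbitrary novel nucleotide for sites without one (sh_MPOB3)."""
    if variant.known_mutant_alleles:
        return sorted(variant.known_mutant_alleles)[0]
    return "G" if variant.wildtype_allele != "G" else "A"


def make_genotype(panel, mutant_counts=None, sample_id="S1"):
    """Unphased genotype with the given per-site mutant-allele count
    (0 = wt/wt, 1 = het, 2 = hom mutant); unnamed sites are wildtype."""
    mutant_counts = mutant_counts or {}
    calls = {}
    for v in panel:
        n = mutant_counts.get(v.id, 0)
        mut = mutant_allele(v)
        pair = [v.wildtype_allele] * (2 - n) + [mut] * n
        calls[v.id] = LocusCall(v.id, pair[0], pair[1])
    return MultiLocusGenotype(sample_id, calls)


def all_zygosity_states(panel):
    """All 3^len(panel) unphased per-site states {wt/wt, wt/mut, mut/mut}."""
    for combo in itertools.product((0, 1, 2), repeat=len(panel)):
        yield dict(zip(panel.ids, combo))
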