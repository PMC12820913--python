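import pytest
from hypothesis import settings

from hlako.fixtures import FamilyConfig, generate_family
from hlako.offtarget import ScoringParams

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return ScoringParams()


@pytest.fixture(scope="session")
def pam_family():
    """Two-allele family: the derived allele differs by one PAM-break SNP."""
    return generate_family(FamilyConfig(seed=11, n_pam_snps=1))


@pytest.fixture(scope="session")
def pam_family_db(pam_family):
    return pam_family.load_db()


def make_imgt_fasta(records):
    """records: iterable of (accession, name, seq) -> IMGT-dialect FASTA text."""
    parts = []
    for accession, name, seq in records:
        wrapped = "\n".join(seq[i : i + 60] for i in range(0, len(seq), 60))
        parts.append(f">HLA:{accession} {name} {len(seq)} bp\n{wrapped}\n")
    return "".join(parts)
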