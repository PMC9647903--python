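import dataclasses

import pytest
from hypothesis import settings

from krabzfp._codons import PREFERRED_CODON
from krabzfp.annotation import annotate_table
from krabzfp.io import GeneRecord
from krabzfp.simulate import FamilyConfig, generate_family

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def reverse_translate(protein: str) -> str:
    """Deterministic reverse translation for handcrafted fixtures."""
    return "".join(PREFERRED_CODON[aa] for aa in protein)


def make_record(gene_id: str, protein: str, cds: str | None = None, **kw) -> GeneRecord:
    defaults = dict(species="synthetic", chromosome="chr1", start=1_000,
                    end=1_000 + 3 * len(protein) - 1, strand="+")
    defaults.update(kw)
    return GeneRecord(gene_id=gene_id, protein_seq=protein,
                      cds_seq=cds if cds is not None else reverse_translate(protein),
                      **defaults)


@pytest.fixture(scope="session")
def zero_noise_config():
    return FamilyConfig(seed=42, linker_mutation_rate=0.0,
                        synonymous_wobble_rate=0.0)


@pytest.fixture(scope="session")
def zero_noise_bundle(zero_noise_config):
    return generate_family(zero_noise_config)


@pytest.fixture(scope="session")
def zero_noise_annotations(zero_noise_bundle):
    return annotate_table(zero_noise_bundle.table)


@pytest.fixture(scope="session")
def default_bundle():
    return generate_family(FamilyConfig())


@pytest.fixture(scope="session")
def default_annotations(default_bundle):
    return annotate_table(default_bundle.table)


@pytest.fixture()
def noisy_config():
    return dataclasses.replace(
        FamilyConfig(), linker_mutation_rate=0.05, synonymous_wobble_rate=0.2
    )
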