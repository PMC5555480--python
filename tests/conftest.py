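import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from tebench.fixtures import FixtureSpec, make_toy_reference


@pytest.fixture(scope="session")
def toy_universe():
    """One small deterministic universe shared across the suite."""
    spec = FixtureSpec(n_chroms=1, chrom_len=100_000, n_trna=8, n_families=4, seed=7)
    genome, trnas, library, te_ann, hierarchy = make_toy_reference(spec)
    return {
        "spec": spec,
        "genome": genome,
        "trnas": trnas,
        "library": library,
        "te_annotation": te_ann,
        "hierarchy": hierarchy,
        "chrom_lengths": {c.name: len(c.seq) for c in genome},
    }


@pytest.fixture(scope="session")
def big_truth_set():
    """>=500 single-insertion truths for parameter-recovery statistics."""
    from tebench.genome_sim import generate_truth_set

    spec = FixtureSpec(
        n_chroms=1, chrom_len=400_000, n_trna=250, n_families=4,
        n_reference_copies=0, seed=11,
    )
    genome, trnas, library, _ann, _h = make_toy_reference(spec)
    truths = generate_truth_set(
        {c.name: len(c.seq) for c in genome}, trnas, list(library)
    )
    return {
        "truths": truths,
        "chrom_lengths": {c.name: len(c.seq) for c in genome},
        "families": list(library),
    }
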