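import numpy as np
import pytest

import hybridzone as hz
from hybridzone.genotypes import GenotypeMatrix


def stack_classes(freq_a, freq_b, spec, seed=0, loci=None):
    """Build a GenotypeMatrix from (pop, class, n) tuples with one shared rng."""
    rng = np.random.default_rng(seed)
    parts = [hz.simulate_class_genotypes(freq_a, freq_b, cls, n, rng,
                                         pop=pop, loci=loci)
             for pop, cls, n in spec]
    return GenotypeMatrix(
        ids=sum((p.ids for p in parts), []),
        pops=sum((p.pops for p in parts), []),
        loci=parts[0].loci,
        genotypes=np.vstack([p.genotypes for p in parts]))


@pytest.fixture(scope="session")
def diagnostic_freqs():
    """100 direction-randomised fully diagnostic loci."""
    model = hz.SpeciesPairModel(n_loci=100, prop_fixed_diff=1.0, seed=11)
    freqs = hz.draw_parental_freqs(model)
    return freqs["freqA"].to_numpy(), freqs["freqB"].to_numpy()


@pytest.fixture(scope="session")
def six_class_panel(diagnostic_freqs):
    """20 individuals per genealogical class at 100 diagnostic loci."""
    fa, fb = diagnostic_freqs
    return stack_classes(fa, fb, [(cls, cls, 20) for cls in hz.CLASSES],
                         seed=42)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small on-disk fixture bundle shared across I/O tests."""
    outdir = tmp_path_factory.mktemp("bundle") / "fixture"
    config = hz.FixtureConfig(
        model=hz.SpeciesPairModel(n_loci=400, prop_fixed_diff=0.4, seed=9),
        n_panel_loci=50)
    truth = hz.generate_fixture_bundle(config, outdir)
    return outdir, config, truth


@pytest.fixture(scope="session")
def two_clade_alignment():
    model = hz.SpeciesPairModel(mt_length=300, mt_interclade_steps=25,
                                mt_intraclade_mutations=1.0, seed=5)
    aln_df, truth = hz.simulate_mtdna_alignment(
        model, {"P1": 10, "P2": 10}, {"P1": "A", "P2": "B"})
    aln = hz.SequenceAlignment(list(aln_df["id"]),
                               list(aln_df["population"]),
                               list(aln_df["sequence"]))
    return aln, truth, model
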