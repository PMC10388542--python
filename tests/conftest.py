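import numpy as np
import pytest

import chlorotype as ct


@pytest.fixture(scope="session")
def demo_spec():
    return ct.demo_spec(42)


@pytest.fixture(scope="session")
def genome_pair(demo_spec):
    """The default desk-scale S/N template pair with its truth record."""
    return ct.generate_genome_pair(demo_spec)


@pytest.fixture(scope="session")
def canonical_pair(genome_pair):
    s, n, truth = genome_pair
    cs = ct.canonical_rotation(s, ct.detect_structure(s))
    cn = ct.canonical_rotation(n, ct.detect_structure(n))
    return cs, cn, truth


@pytest.fixture(scope="session")
def demo_variants(canonical_pair):
    cs, cn, _ = canonical_pair
    aln = ct.align_genomes(cs, cn)
    return ct.call_variants(aln, annotation=cs.features)


@pytest.fixture(scope="session")
def demo_markers(canonical_pair, demo_variants):
    """Marker definitions built from the published primer pairs."""
    from chlorotype.synth import CP01_FWD, CP01_REV, CP02_FWD, CP02_REV

    cs, cn, _ = canonical_pair
    cands = ct.select_marker_candidates(demo_variants, cs, cn)
    by_ct = {"S": cs, "N": cn}
    primers = {"cp_01": (CP01_FWD, CP01_REV), "cp_02": (CP02_FWD, CP02_REV)}
    defs = []
    for cand in cands:
        fwd, rev = primers[cand.name]
        ct.use_published_primers(cand, fwd, rev, by_ct)
        defs.append(ct.to_definition(cand))
    return defs


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, length, gc=0.4):
    bases = np.array(list("ACGT"))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(bases, size=length, p=p))
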