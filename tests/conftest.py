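"""Shared fixtures: one fully simulated study at the default conditions."""

from types import SimpleNamespace

import numpy as np
import pytest

from mirnaforge import GenomeIndex
from mirnaforge import discovery as dv
from mirnaforge import preprocess as pp
from mirnaforge import synthetic_data as sd


@pytest.fixture(scope="session")
def default_run():
    """Default study: 100 kb genome, 30 planted loci, 6 libraries, seed 1."""
    cfg = sd.SimConfig(rng_seed=1)
    rng = np.random.default_rng(1)
    genome, truth = sd.generate_genome(cfg, rng)
    refs = sd.make_reference_sets(rng)
    reads = sd.simulate_reads(genome, truth, cfg, rng, references=refs)
    tags, stats = pp.run_preprocess(reads.libraries, references=refs)
    clean = pp.clean_tags(tags)
    index = GenomeIndex({"chr1": genome}, k=18)
    loci = dv.call_loci(clean, index)
    return SimpleNamespace(cfg=cfg, genome=genome, truth=truth, refs=refs,
                           reads=reads, tags=tags, stats=stats, clean=clean,
                           index=index, loci=loci,
                           accepted=[l for l in loci if l.accepted])


def match_truth(locus, truth, tol=3):
    """The planted locus a called locus corresponds to, or None."""
    mg = locus.mature_genomic()
    for rec in truth:
        if locus.strand == rec.strand and abs(mg[0] - rec.mature_start) <= tol \
                and abs(mg[1] - rec.mature_end) <= tol:
            return rec
    return None
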