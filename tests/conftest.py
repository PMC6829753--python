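"""Shared fixtures: a compact synthetic genome and the 16-sample cohort.

Session-scoped so the cohort is simulated once for the whole suite.
"""

import numpy as np
import pandas as pd
import pytest

from methylscape.genome import generate_genome
from methylscape.pipeline import small_genome_config
from methylscape.simulate import simulate_cohort
from methylscape.states import default_design

SEED = 1


@pytest.fixture(scope="session")
def genome_small():
    return generate_genome(small_genome_config(), seed=SEED)


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def cohort(genome_small, design):
    """(tables, manifest) for the default 16-sample design on the small genome."""
    return simulate_cohort(genome_small, design, SEED)


@pytest.fixture(scope="session")
def sample_states(design):
    return {s.name: s.state for s in design.samples}


def make_sites(chrom, positions, levels_, depth=20, context="CG", strand="+",
               seed=0, exact=False):
    """Construct a site table with the given per-site levels.

    With ``exact`` the counts realize the level exactly (meth = level*depth);
    otherwise counts are binomial draws at the given depth.
    """
    rng = np.random.default_rng(seed)
    positions = np.asarray(positions, dtype=np.int64)
    levels_ = np.asarray(levels_, dtype=float)
    total = np.full(len(positions), depth, dtype=np.int64)
    if exact:
        meth = np.round(levels_ * depth).astype(np.int64)
    else:
        meth = rng.binomial(total, levels_)
    return pd.DataFrame({"chrom": chrom, "pos": positions,
                         "strand": strand, "context": context,
                         "meth": meth, "total": total})
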