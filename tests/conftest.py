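"""Shared fixtures: ideal-geometry structures and synthetic datasets.

Everything is generated programmatically at test time with fixed seeds;
the heavier labelled datasets are session-scoped because descriptor
computation dominates their cost.
"""

import warnings

import numpy as np
import pytest

from cleavecrf import dataset as ds_mod
from cleavecrf import synthetic
from cleavecrf.encoding import EncodedInstance, POSITIONS


@pytest.fixture(scope="session")
def helix_structure():
    """20-residue ideal alpha-helix."""
    return synthetic.build_backbone([("helix", 20)], seed=1)


@pytest.fixture(scope="session")
def mixed_structure():
    """30-residue helix/coil/strand chain used for brute-force oracles."""
    return synthetic.build_backbone(
        [("helix", 10), ("coil", 8), ("strand", 6), ("coil", 6)], seed=2
    )


def _assemble(signal_mode: str, seed: int, n_substrates: int = 40, tmpdir=None):
    spec = synthetic.FixtureSpec(
        n_substrates=n_substrates, signal_mode=signal_mode, seed=seed
    )
    synthetic.generate_dataset(spec, tmpdir)
    records, structures, negpos = synthetic.load_generated(tmpdir)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ds_mod.build_cleavage_dataset(
            records, structures, seed=seed, negative_positions=negpos
        )


@pytest.fixture(scope="session")
def both_signal_dataset(tmp_path_factory):
    """40 substrates with a planted P4–P1 motif at coil-centred sites."""
    return _assemble("both", seed=7,
                     tmpdir=tmp_path_factory.mktemp("fix_both"))


@pytest.fixture(scope="session")
def structure_only_dataset(tmp_path_factory):
    """40 substrates whose cleavage signal is purely structural."""
    return _assemble("structure_only", seed=11,
                     tmpdir=tmp_path_factory.mktemp("fix_struct"))


def random_instance(rng: np.random.Generator, n_attrs: int = 12) -> EncodedInstance:
    """A random length-8 observation chain over a small attribute pool."""
    positions = []
    for pos in POSITIONS:
        k = int(rng.integers(1, 4))
        attrs = [f"f{int(a)}[{pos}]" for a in rng.choice(n_attrs, size=k,
                                                         replace=False)]
        positions.append(attrs)
    return EncodedInstance(positions=positions)
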