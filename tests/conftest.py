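import numpy as np
import pytest

from solidhub import simulate


@pytest.fixture
def smt_mixture():
    """A planted bound/free localization mixture with its ground truth."""
    locs, truth = simulate.gen_smt_localizations(
        n_bound=20, n_free=20, d_free=0.5, sigma_loc=3.0, n_frames=40, seed=11
    )
    return locs, truth


@pytest.fixture
def genome_fixture():
    seqs, peaks, contacts, truth = simulate.gen_genome_fixture(
        seq_len=200_000, n_motifs=6, n_peaks=12, n_contacts=80,
        strong_fraction=0.25, resolution=5000, seed=7,
    )
    return seqs, peaks, contacts, truth


def loc_key(p):
    return (p.frame, p.x, p.y, p.channel, p.cell_id)


def truth_class_of_trajectory(traj, locs, truth):
    """Planted class ('condensate'/'free') of a linked trajectory, via its
    first localization's ground-truth label."""
    index = {loc_key(p): i for i, p in enumerate(locs)}
    i = index[loc_key(traj.points[0])]
    return "condensate" if truth.label[i] == "bound" else "free"
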