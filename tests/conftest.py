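import numpy as np
import pytest

from yeastfish import presets
from yeastfish.simcounts import simulate_counts
from yeastfish.simimages import NOISELESS, NoiseConfig, render_field, sample_scene

CHANNEL_MAP = {"CLB1": "Cy3"}


@pytest.fixture(scope="session")
def noiseless_field():
    """One noiseless rendered field (~25 cells) with ground truth."""
    genes = [presets.study_gene("CLB1")]
    table = simulate_counts(genes, n_cells=25, seed=11)
    scene = sample_scene(table, CHANNEL_MAP, shape=(450, 450), seed=12)
    return render_field(
        scene, noise=NOISELESS, seed=13, shape=(450, 450), channel_map=CHANNEL_MAP
    )


@pytest.fixture(scope="session")
def noisy_field():
    """A field with realistic camera noise (shot + read)."""
    genes = [presets.study_gene("CLN1")]
    table = simulate_counts(genes, n_cells=20, seed=21)
    scene = sample_scene(table, {"CLN1": "Cy3"}, shape=(420, 420), seed=22)
    return render_field(
        scene,
        noise=NoiseConfig(background=100.0, read_noise_sd=2.0),
        seed=23,
        shape=(420, 420),
        channel_map={"CLN1": "Cy3"},
    )


def truth_counts_per_label(field):
    """Ground-truth spot count per mask label of a rendered field."""
    obj = field.truth_objects
    label_of = {
        (row.cell_id, row.role == "bud"): int(row.label) for row in obj.itertuples()
    }
    counts = {int(l): 0 for l in obj["label"]}
    for row in field.truth_spots.itertuples():
        counts[label_of[(row.cell_id, bool(row.in_bud))]] += 1
    return counts


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
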