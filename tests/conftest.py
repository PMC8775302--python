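import numpy as np
import pytest

from trawlselect.data_model import HaulRecord, SelectivityDataset


def make_haul(haul_id, lengths, cd, cc, pc=None, q_cd=1.0, q_cc=1.0, q_pc=1.0):
    counts = {"CD": np.asarray(cd, dtype=float), "CC": np.asarray(cc, dtype=float)}
    q = {"CD": q_cd, "CC": q_cc}
    if pc is not None:
        counts["PC"] = np.asarray(pc, dtype=float)
        q["PC"] = q_pc
    return HaulRecord(haul_id=haul_id, lengths=np.asarray(lengths, dtype=int), counts=counts, q=q)


def random_dataset(rng, n_hauls=3, with_pc=True, n_classes=8, base_length=18, max_count=60):
    """A small random but identifiable covered-codend dataset."""
    hauls = []
    lengths = np.arange(base_length, base_length + n_classes)
    for j in range(n_hauls):
        cd = rng.integers(1, max_count, size=n_classes)
        cc = rng.integers(1, max_count, size=n_classes)
        pc = rng.integers(1, max_count, size=n_classes) if with_pc else None
        q_choices = (1.0, 0.5, 0.25)
        hauls.append(
            make_haul(
                f"h{j}", lengths, cd, cc, pc,
                q_cd=float(rng.choice(q_choices)),
                q_cc=float(rng.choice(q_choices)),
                q_pc=float(rng.choice(q_choices)),
            )
        )
    return SelectivityDataset(hauls=tuple(hauls), gear_label="toy", species="toy")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def toy_smp_dataset(rng):
    return random_dataset(rng, n_hauls=2, with_pc=True)


@pytest.fixture(scope="session")
def sim_dataset_small():
    from trawlselect.synthetic_data import DEFAULT_TRUTH, SimulationConfig, simulate_dataset

    return simulate_dataset(SimulationConfig(n_hauls=3, fish_per_haul=300, seed=77), DEFAULT_TRUTH)
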