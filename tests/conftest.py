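import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from envphylo.alphabet import AA_INDEX, AA_ORDER, N_AA

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: residues plus placeholder characters for randomized sequences
NOISY_ALPHABET = list(AA_ORDER) + ["X", "B", "U", "-"]


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)


def random_sequence(rng, length, noisy=False):
    pool = NOISY_ALPHABET if noisy else list(AA_ORDER)
    return "".join(rng.choice(pool, size=length))


def random_proteome(rng, n_seqs, max_len, noisy=False):
    return [
        random_sequence(rng, int(rng.integers(1, max_len + 1)), noisy=noisy)
        for _ in range(n_seqs)
    ]


def brute_force_environments(sequences, radius):
    """Independent O(L·r) oracle: naive double loop over every window."""
    offsets = list(range(-radius, 0)) + list(range(1, radius + 1))
    counts = np.zeros((N_AA, N_AA, 2 * radius), dtype=np.int64)
    for seq in sequences:
        for p, ch in enumerate(seq):
            target = AA_INDEX.get(ch, -1)
            if target < 0:
                continue
            for col, off in enumerate(offsets):
                q = p + off
                if 0 <= q < len(seq):
                    nb = AA_INDEX.get(seq[q], -1)
                    if nb >= 0:
                        counts[target, nb, col] += 1
    return counts
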