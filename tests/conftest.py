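import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_runs(times, max_isi, min_spikes):
    """Oracle for burst detection: split the spike sequence at every
    inter-spike gap >= max_isi and keep segments long enough.

    Formulated as gap-splitting (rather than run extension) so it is an
    independent path to the same definition.
    """
    times = list(times)
    n = len(times)
    if n == 0:
        return []
    cuts = [0] + [k + 1 for k in range(n - 1)
                  if times[k + 1] - times[k] >= max_isi] + [n]
    return [(i, j - 1) for i, j in zip(cuts[:-1], cuts[1:])
            if j - i >= min_spikes]


def brute_force_bursts(times, max_isi=0.100, min_spikes=5):
    return [(times[i], times[j], j - i + 1)
            for i, j in brute_force_runs(times, max_isi, min_spikes)]


def brute_force_network_bursts(trains, n_electrodes, max_isi=0.100,
                               min_spikes=50, min_fraction=0.35):
    tagged = sorted([(t, e) for e, tr in enumerate(trains) for t in tr])
    times = [t for t, _ in tagged]
    elecs = [e for _, e in tagged]
    out = []
    for i, j in brute_force_runs(times, max_isi, min_spikes):
        members = set(elecs[i:j + 1])
        if len(members) / n_electrodes >= min_fraction:
            out.append((times[i], times[j], j - i + 1, frozenset(members)))
    return out


def brute_force_di(values):
    """Oracle for the distribution index: plain-python mean absolute
    deviation of the mean-normalized profile."""
    m = sum(values) / len(values)
    z = [v / m for v in values]
    return sum(abs(v - 1.0) for v in z) / len(z)
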