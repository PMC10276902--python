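import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from admixwave.signal_prep import GridSignal, RecombinationMap

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_noise_signals(rng, lengths, resolution=1.0):
    """White-noise grid signals keyed c0, c1, ... with the given lengths."""
    return {
        f"c{i}": GridSignal(f"c{i}", resolution, rng.normal(size=L))
        for i, L in enumerate(lengths)
    }


def make_block_map(name, n_blocks, mb=20e6, lo=0.3, hi=3.0):
    """Recombination map alternating low/high-rate blocks of ``mb`` bp
    (default 10x contrast, the order seen between human chromosome arms and
    centromeric regions).  Low-rate blocks carry a 10x higher density of
    selected loci per Morgan, so genome-wide selection couples ancestry to
    recombination at the block scale."""
    rates = np.array([lo if i % 2 == 0 else hi for i in range(n_blocks)])
    starts = np.arange(n_blocks) * mb
    return RecombinationMap(name, starts, starts + mb, rates, units="cM_per_Mb")


def make_hetero_map(name, n_seg, seed, mb_per_seg=10e6, lo=0.2, hi=3.0):
    """Piecewise-constant recombination map with broad-scale rate variation
    (cM/Mb), the setting in which polygenic selection couples ancestry to
    recombination."""
    r = np.random.default_rng(seed)
    rates = r.uniform(lo, hi, n_seg)
    starts = np.arange(n_seg) * mb_per_seg
    return RecombinationMap(name, starts, starts + mb_per_seg, rates, units="cM_per_Mb")
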