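import logging

import numpy as np
import pytest

from crmscan import GenomicInterval, PWM

logging.getLogger("crmscan").setLevel(logging.WARNING)

BASES = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_genome(rng, n_chroms=2, min_len=50, max_len=400, alphabet=BASES):
    return {f"chr{i + 1}": "".join(
        rng.choice(list(alphabet), size=int(rng.integers(min_len, max_len + 1))))
        for i in range(n_chroms)}


def random_pwm(rng, width=None, pwm_id="m1", kind="probability"):
    width = width or int(rng.integers(4, 13))
    if kind == "probability":
        m = rng.random((4, width))
        m = m / m.sum(axis=0)
    else:
        m = rng.random((4, width)) * 5
    return PWM(id=pwm_id, matrix=m)


def random_intervals(rng, n, chroms=("chr1", "chr2", "chr3"), max_pos=1000,
                     max_len=120):
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len + 1))
        out.append(GenomicInterval(chrom, start, start + length, name=f"iv{i}"))
    return out
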