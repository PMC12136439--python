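import numpy as np
import pytest

import cyclorder as co


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def tiny_tsv(tmp_path):
    """A 4x3 TSV fixture with samples as rows."""
    path = tmp_path / "tiny.tsv"
    path.write_text(
        "id\tg1\tg2\tg3\n"
        "s1\t1.0\t4.0\t0.5\n"
        "s2\t2.0\t3.0\t0.25\n"
        "s3\t3.0\t2.0\t0.75\n"
        "s4\t4.0\t1.0\t1.0\n"
    )
    return path


@pytest.fixture
def noiseless_cycle():
    """20 samples equally spaced on the cycle, 10 sinusoidal features with
    known peak phases plus 10 flat features; no noise."""
    n, p_r, p_a = 20, 10, 10
    t = np.arange(n) / n
    phases = np.linspace(0.0, 0.9, p_r)
    X = np.zeros((n, p_r + p_a))
    X[:, :p_r] = np.cos(2 * np.pi * (t[:, None] - phases[None, :]))
    return X, t, phases


@pytest.fixture
def small_rhythmic():
    """Small noisy rhythmic dataset for fast end-to-end checks."""
    return co.generate(N=80, p=240, r=0.2, snr=3.0, seed=42)
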