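import numpy as np
import pytest

from ovitherm import ppt, synth


@pytest.fixture(scope="session")
def calib():
    return synth.synthetic_calibration()  # exact 0.25 mm/px


@pytest.fixture(scope="session")
def front_phantom():
    return synth.EggPhantom(chamber_a_mm=6.0, chamber_b_mm=8.0, noise_sd=1.0, seed=7)


@pytest.fixture(scope="session")
def front_seq_truth(front_phantom):
    return synth.generate_sequence(front_phantom, view="front")


@pytest.fixture(scope="session")
def front_images(front_seq_truth):
    seq, truth = front_seq_truth
    return ppt.extract_pt_frame(seq), ppt.phase_image(seq), truth


@pytest.fixture(scope="session")
def lateral_seq_truth(front_phantom):
    return synth.generate_sequence(front_phantom, view="lateral")


def dft_oracle(signal):
    """Direct O(N^2) DFT summation, the independent reference for compute_dft."""
    s = np.asarray(signal, dtype=np.float64)
    n = s.size
    ks = np.arange(n // 2 + 1)
    coeffs = np.array(
        [np.sum(s * np.exp(-2j * np.pi * k * np.arange(n) / n)) for k in ks]
    )
    return coeffs


@pytest.fixture(scope="session")
def oracle():
    return dft_oracle
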