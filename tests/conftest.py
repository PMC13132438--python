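import numpy as np
import pytest

from pneumabio.nlp_idsa import load_dictionary
from pneumabio.synthdata import EcgSimParams, PageRenderSpec, gen_ecg_signal, render_ecg_page


@pytest.fixture(scope="session")
def dictionary():
    return load_dictionary()


@pytest.fixture(scope="session")
def rendered_page():
    """A 10 s, 60 bpm rhythm-strip page at 5 px/mm with its manifest."""
    sim = gen_ecg_signal(EcgSimParams(mean_hr=60, rmssd_target=20, duration=10, seed=7))
    page, manifest = render_ecg_page({"II-rhythm": sim}, PageRenderSpec(px_per_mm=5))
    return sim, page, manifest


def make_flat_trace(duration_s=10.0, fs=500.0, value_mv=0.0):
    from pneumabio.synthdata.ecg import SimulatedEcg

    n = int(round(duration_s * fs))
    return SimulatedEcg(
        samples=np.full(n, value_mv),
        fs=fs,
        r_peak_times_ms=np.empty(0),
        rr_ms=np.empty(0),
        params=None,
    )
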