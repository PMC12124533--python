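import numpy as np
import pytest

from scentpipe.gcms_io import RawChromatogram, SampleMeta


@pytest.fixture(scope="session")
def synthetic_records_small():
    """Binned chromatograms + metadata from the standard biased generator
    (desk-scale grid, 4 sources), shared across tests for speed."""
    from scentpipe.preprocess import round_mz
    from scentpipe.synthetic_data import SimConfig, generate_dataset

    cfg = SimConfig(n_per_cell=5, n_timesteps=600, n_mz=32, seed=42)
    dataset, truth = generate_dataset(cfg)
    records = [(round_mz(c), m) for c, m in dataset.records]
    return records, truth


@pytest.fixture(scope="session")
def synthetic_feature_matrix(synthetic_records_small):
    from scentpipe.batch_correct import build_feature_matrix
    from scentpipe.preprocess import segment_time

    records, _ = synthetic_records_small
    return build_feature_matrix(records, segment_time(41.0, 1.5))


@pytest.fixture
def tiny_chrom() -> RawChromatogram:
    """3 timesteps x 2 channels with non-integer m/z."""
    return RawChromatogram(
        times=np.array([0.0, 1.0, 2.0]),
        mz_raw=np.array([23.6, 23.7]),
        intensity=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
    )


@pytest.fixture
def meta_factory():
    def make(sid="S1", source="SiteA", risk="Control"):
        return SampleMeta(sample_id=sid, source=source, risk=risk)

    return make


def gaussian_chrom(
    n_t=600,
    n_mz=8,
    t_total=41.0,
    peaks=(),
    baseline=0.0,
    drift=None,
    noise_sd=0.0,
    seed=0,
):
    """Hand-built chromatogram: sum of (rt, width, channel, amplitude) peaks
    plus optional constant baseline, per-timestep drift array, and noise."""
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, t_total, n_t)
    inten = np.full((n_t, n_mz), float(baseline))
    for rt, width, chan, amp in peaks:
        inten[:, chan] += amp * np.exp(-0.5 * ((times - rt) / width) ** 2)
    if drift is not None:
        inten += np.asarray(drift)[:, None]
    if noise_sd:
        inten += np.abs(rng.normal(0, noise_sd, inten.shape))
    return RawChromatogram(
        times=times, mz_raw=50.0 + np.arange(n_mz, dtype=float),
        intensity=np.maximum(inten, 0.0),
    )
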