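"""Synthetic GC-MS dataset generator with known ground truth.

The clinical chromatograms behind this pipeline are not publicly deposited,
so every downstream stage is exercised on simulated data that carries the
statistical structure the pipeline assumes:

* Gaussian peaks in retention time, each with a sparse m/z fragment
  fingerprint (separable time x m/z shape);
* class-dependent amplitude multipliers on designated signature peaks
  (the "scent character" the classifier is supposed to find);
* an internal-standard (Mirex) peak near 29.6 min, occasionally dropped
  out to emulate undetectable internal standard;
* per-sample multiplicative batch factors drawn from a per-source gamma
  prior and additive shifts from a per-source normal prior;
* source-specific persistent per-channel "stripe" artifacts (steady
  signals at fixed m/z values lasting many minutes);
* slow polynomial baseline drift and a truncated-normal noise floor.

The default grid is desk-scale (1000 timesteps x 64 channels over a
41-minute run); the full-scale 7300 x 480 grid is available through
:class:`SimConfig`.  Every draw is reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gcms_io import RISK_LEVELS, Dataset, RawChromatogram, SampleMeta

__all__ = [
    "Peak",
    "SimConfig",
    "default_peak_library",
    "generate_dataset",
    "summarize_bias",
    "make_image_classification_fixture",
]


@dataclass(frozen=True)
class Peak:
    """One chromatographic peak: Gaussian in time, sparse m/z fingerprint."""

    rt: float                      # retention time, minutes
    width: float                   # Gaussian sigma, minutes
    fingerprint: tuple[tuple[int, float], ...]  # (channel index, weight), weights sum to 1
    amplitude: float               # base apex amplitude, ion counts
    signature: bool = False        # carries the class signal if True


def default_peak_library(
    n_mz: int, n_peaks: int = 12, n_signature: int = 3, t_total: float = 41.0,
    seed: int = 20240531,
) -> tuple[Peak, ...]:
    """A reproducible library of peaks spread over the run.

    The first ``n_signature`` peaks are class-signature peaks.  The library
    seed is independent of the dataset seed so that two datasets drawn with
    different seeds share the same underlying chemistry.
    """
    rng = np.random.default_rng(seed)
    peaks = []
    # keep the internal-standard elution region (29.0-30.2 min on a 41-min
    # run) free of analyte peaks, as an assay would by design
    quiet = (29.0 / 41.0 * t_total, 30.2 / 41.0 * t_total)
    rts = rng.uniform(0.06 * t_total, 0.92 * t_total, n_peaks)
    for _ in range(100):
        inside = (rts > quiet[0]) & (rts < quiet[1])
        if not inside.any():
            break
        rts[inside] = rng.uniform(0.06 * t_total, 0.92 * t_total, inside.sum())
    rts = np.sort(rts)
    for i, rt in enumerate(rts):
        n_frag = int(rng.integers(3, 6))
        chans = rng.choice(n_mz, size=n_frag, replace=False)
        w = rng.dirichlet(np.ones(n_frag) * 2.0)
        amp = float(rng.uniform(800, 3000))
        peaks.append(
            Peak(
                rt=float(rt),
                width=float(rng.uniform(0.10, 0.22)),
                fingerprint=tuple((int(c), float(x)) for c, x in zip(chans, w)),
                amplitude=amp,
                signature=(i < n_signature),
            )
        )
    return tuple(peaks)


def _default_stripes(n_sources: int, n_mz: int) -> dict[int, tuple]:
    """Source-specific persistent channel artifacts (steady m/z signals)."""
    stripes: dict[int, tuple] = {}
    for s in range(n_sources):
        chans = [(4 + 2 * s) % n_mz, (n_mz // 2 + 3 * s) % n_mz]
        stripes[s] = tuple((c, 150.0, 4.0, 36.0) for c in chans)
    return stripes


@dataclass
class SimConfig:
    """Generator configuration.  Defaults are the standard study conditions.

    ``batch_mult_prior[s]`` is the (shape, rate) of the gamma prior on the
    per-sample multiplicative factor of source ``s``; ``batch_add_prior[s]``
    the (mean, sd) of the normal prior on its additive shift (ion counts
    added to every cell).  ``class_effect`` multiplies the amplitude of
    signature peaks per risk class.  ``cell_counts`` optionally overrides
    the per-(source index, risk) sample count for unbalanced designs.
    """

    n_per_cell: int = 5
    n_sources: int = 4
    t_total: float = 41.0
    n_timesteps: int = 1000
    n_mz: int = 64
    mz_start: float = 50.0
    peaks: tuple[Peak, ...] | None = None   # default: default_peak_library
    class_effect: dict[str, float] = field(
        default_factory=lambda: {"Control": 1.0, "LowRisk": 1.8, "HighRisk": 2.8}
    )
    amplitude_jitter_sd: float = 0.15       # lognormal sd on per-sample peak amplitudes
    batch_mult_prior: tuple[tuple[float, float], ...] | None = None
    batch_add_prior: tuple[tuple[float, float], ...] | None = None
    stripes: dict[int, tuple] | None = None  # source -> ((channel, amp, t_lo, t_hi), ...)
    drift_scale: float = 30.0               # max drift amplitude over the run, counts
    noise_mean: float = 20.0
    noise_sd: float = 5.0
    mirex_rt: float = 29.6
    mirex_width: float = 0.05
    mirex_amplitude: float = 20000.0  # internal standard is spiked to tower over the background
    mirex_channel: int | None = None        # default: n_mz - 5
    mirex_dropout: float = 0.05
    cell_counts: dict[tuple[int, str], int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        if self.peaks is None:
            self.peaks = default_peak_library(
                self.n_mz, t_total=self.t_total
            )
        if not self.peaks:
            raise ValueError("peak library must not be empty")
        if self.batch_mult_prior is None:
            means = (0.6, 1.0, 1.6, 2.4, 3.2, 4.0)
            self.batch_mult_prior = tuple(
                (50.0, 50.0 / means[s % len(means)]) for s in range(self.n_sources)
            )
        if self.batch_add_prior is None:
            self.batch_add_prior = tuple(
                (30.0 * s, 5.0) for s in range(self.n_sources)
            )
        if self.stripes is None:
            self.stripes = _default_stripes(self.n_sources, self.n_mz)
        if self.mirex_channel is None:
            self.mirex_channel = self.n_mz - 5
        for p in self.peaks:
            if p.amplitude < 0 or not (0 <= p.rt <= self.t_total):
                raise ValueError("peak amplitudes must be >= 0 and rt within the run")

    @property
    def source_names(self) -> tuple[str, ...]:
        return tuple(f"Site{chr(ord('A') + s)}" for s in range(self.n_sources))


def _peak_surface(cfg: SimConfig, times: np.ndarray, risk: str,
                  amp_jitter: np.ndarray) -> np.ndarray:
    """Sum of Gaussian x fingerprint peaks with class multipliers applied."""
    surface = np.zeros((times.size, cfg.n_mz))
    for p, jit in zip(cfg.peaks, amp_jitter):
        mult = cfg.class_effect[risk] if p.signature else 1.0
        profile = np.exp(-0.5 * ((times - p.rt) / p.width) ** 2)
        col = np.zeros(cfg.n_mz)
        for chan, w in p.fingerprint:
            col[chan] += w
        surface += (p.amplitude * mult * jit) * np.outer(profile, col)
    return surface


def generate_dataset(cfg: SimConfig) -> tuple[Dataset, pd.DataFrame]:
    """Draw a full dataset plus its ground-truth table.

    Each chromatogram is ``(peak surface + Mirex) * mult_factor +
    add_shift + stripes + drift + noise``, clipped at zero.  The ground
    truth records every drawn nuisance parameter per sample.
    """
    rng = np.random.default_rng(cfg.seed)
    times = np.linspace(0.0, cfg.t_total, cfg.n_timesteps)
    mz_raw = cfg.mz_start + np.arange(cfg.n_mz, dtype=float)
    records = []
    truth_rows = []
    counter = 0
    for s, source in enumerate(cfg.source_names):
        shape, rate = cfg.batch_mult_prior[s]
        add_mu, add_sd = cfg.batch_add_prior[s]
        for risk in RISK_LEVELS:
            n = (cfg.cell_counts or {}).get((s, risk), cfg.n_per_cell)
            for _ in range(n):
                counter += 1
                sid = f"SYN{counter:04d}"
                amp_jitter = rng.lognormal(0.0, cfg.amplitude_jitter_sd, len(cfg.peaks))
                surface = _peak_surface(cfg, times, risk, amp_jitter)
                mirex_present = rng.random() >= cfg.mirex_dropout
                if mirex_present:
                    profile = np.exp(
                        -0.5 * ((times - cfg.mirex_rt) / cfg.mirex_width) ** 2
                    )
                    surface[:, cfg.mirex_channel] += cfg.mirex_amplitude * profile
                factor = rng.gamma(shape, 1.0 / rate)
                shift = rng.normal(add_mu, add_sd)
                mat = surface * factor + shift
                for chan, amp, t_lo, t_hi in cfg.stripes.get(s, ()):
                    mat[(times >= t_lo) & (times <= t_hi), chan] += amp
                drift_coef = rng.uniform(-cfg.drift_scale, cfg.drift_scale, 2)
                x = times / cfg.t_total
                drift = drift_coef[0] * x + drift_coef[1] * x**2
                mat += drift[:, None]
                if cfg.noise_sd > 0 or cfg.noise_mean > 0:
                    noise = np.maximum(
                        rng.normal(cfg.noise_mean, cfg.noise_sd, mat.shape), 0.0
                    )
                    mat += noise
                mat = np.maximum(mat, 0.0)
                chrom = RawChromatogram(times=times, mz_raw=mz_raw, intensity=mat)
                meta = SampleMeta(sample_id=sid, source=source, risk=risk)
                records.append((chrom, meta))
                truth_rows.append(
                    {
                        "sample_id": sid,
                        "source": source,
                        "risk": risk,
                        "mult_factor": factor,
                        "add_shift": shift,
                        "drift_lin": drift_coef[0],
                        "drift_quad": drift_coef[1],
                        "mirex_present": mirex_present,
                    }
                )
    dataset = Dataset(records=records, sources=cfg.source_names)
    return dataset, pd.DataFrame(truth_rows)


def summarize_bias(d: Dataset, gt: pd.DataFrame) -> pd.DataFrame:
    """Per-source mean TIC and mean drawn nuisance parameters."""
    if len(d) != len(gt):
        raise ValueError(f"dataset has {len(d)} records but truth has {len(gt)} rows")
    rows = []
    tics = {m.sample_id: float(c.intensity.sum(axis=1).mean()) for c, m in d.records}
    for source, grp in gt.groupby("source", sort=False):
        rows.append(
            {
                "source": source,
                "n": len(grp),
                "mean_tic": float(np.mean([tics[s] for s in grp["sample_id"]])),
                "mean_mult_factor": float(grp["mult_factor"].mean()),
                "mean_add_shift": float(grp["add_shift"].mean()),
                "mirex_dropout_rate": float(1.0 - grp["mirex_present"].mean()),
            }
        )
    return pd.DataFrame(rows)


def make_image_classification_fixture(
    n_per_source: int = 50,
    n_sources: int = 4,
    seed: int = 0,
    class_source_correlation: float = 0.0,
    image_mode: str = "heatmap",
    n_timesteps: int = 400,
    n_mz: int = 32,
):
    """Images + labels for adversarial-training experiments.

    Generates a small-grid synthetic dataset with strong source artifacts,
    encodes each sample as a 256x256 RGB heatmap, and returns
    ``(images uint8 [N,256,256,3], risks, sources)``.

    ``class_source_correlation`` = 0 gives a balanced (source x class)
    design; rho > 0 skews each source's class mix toward one dominant class
    with probability ``rho + (1 - rho)/3`` — the class-correlated-bias
    regime in which a classifier can cheat by reading the source.
    """
    from .imaging import to_heatmap_image, to_peak_projection_image
    from .preprocess import round_mz

    rng = np.random.default_rng(seed)
    lib = default_peak_library(n_mz, n_peaks=8, n_signature=3)
    counts: dict[tuple[int, str], int] = {}
    for s in range(n_sources):
        if class_source_correlation <= 0:
            base = n_per_source // 3
            rem = n_per_source - 3 * base
            per = [base + (1 if i < rem else 0) for i in range(3)]
        else:
            rho = class_source_correlation
            dominant = s % 3
            p = np.full(3, (1.0 - rho) / 3.0)
            p[dominant] += rho
            per = rng.multinomial(n_per_source, p)
        for i, risk in enumerate(RISK_LEVELS):
            counts[(s, risk)] = int(per[i])
    cfg = SimConfig(
        n_sources=n_sources,
        n_timesteps=n_timesteps,
        n_mz=n_mz,
        peaks=lib,
        cell_counts=counts,
        seed=int(rng.integers(2**31 - 1)),
        mirex_channel=n_mz - 3,
    )
    dataset, _ = generate_dataset(cfg)
    encode = to_heatmap_image if image_mode == "heatmap" else to_peak_projection_image
    images, risks, sources = [], [], []
    for chrom, meta in dataset.records:
        img = encode(round_mz(chrom))
        images.append(img.pixels)
        risks.append(meta.risk)
        sources.append(meta.source)
    return np.stack(images), np.array(risks), np.array(sources)
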