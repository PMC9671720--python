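"""Synthetic 1D proton spectra with known ground truth.

The generator realizes the intensity model that absolute-intensity
quantification assumes: every signal's integral equals

    A = IG * NS * g(RG) * n_H * c

where IG is the intensity-gain factor (intensity per scan, per RG unit,
per proton, per mM), NS the number of scans, g(RG) the true — possibly
nonlinear — amplifier response at nominal receiver gain RG, n_H the
proton count of the signal and c the analyte concentration in mM.
Lineshapes are Lorentzian; noise is additive white Gaussian in the
frequency domain with standard deviation ``noise_sigma * g(RG) * sqrt(NS)``
per point, matching per-scan co-addition statistics.

Spectra are built directly in the frequency domain so that simulator
correctness does not depend on the processing module it is used to test;
:func:`simulate_fid` provides the matching time-domain signal for
exercising the full FT → phase → baseline path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import AcquisitionMeta, Fid, Spectrum, ppm_axis


@dataclass
class SignalSpec:
    """One NMR signal: position, width, proton count and multiplet pattern.

    ``multiplet`` lists (offset_hz, relative_weight) components; weights
    must sum to 1 so the total integral stays n_H-proportional.
    """

    center_ppm: float
    linewidth_hz: float
    n_protons: int
    multiplet: list = field(default_factory=lambda: [(0.0, 1.0)])
    label: str = ""

    def __post_init__(self) -> None:
        if self.linewidth_hz <= 0:
            raise ValueError(f"linewidth_hz must be > 0, got {self.linewidth_hz}")
        if self.n_protons < 1:
            raise ValueError(f"n_protons must be >= 1, got {self.n_protons}")
        total = sum(w for _, w in self.multiplet)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"multiplet weights must sum to 1, got {total}")
        if not self.label:
            self.label = f"s{self.center_ppm:g}ppm"


@dataclass
class GainModel:
    """True amplifier response g(RG) over the instrument's nominal RG steps.

    ``deviation[i]`` is the multiplicative factor g(RG)/RG for step i —
    unity for a perfectly linear receiver. Real amplifiers deviate by a
    few percent, which is exactly what RG linearization estimates.
    """

    nominal_rg_values: Sequence[float]
    deviation: Sequence[float]

    def __post_init__(self) -> None:
        self.nominal_rg_values = [float(r) for r in self.nominal_rg_values]
        self.deviation = [float(d) for d in self.deviation]
        if len(self.nominal_rg_values) != len(self.deviation):
            raise ValueError("nominal_rg_values and deviation must have equal length")
        if any(r <= 0 for r in self.nominal_rg_values):
            raise ValueError("all nominal RG values must be > 0")
        if any(not (0.85 <= d <= 1.15) for d in self.deviation):
            raise ValueError("deviation factors must lie in [0.85, 1.15]")

    def gain(self, rg: float) -> float:
        """True gain g(rg) at a nominal step; unknown steps are an error."""
        for r, d in zip(self.nominal_rg_values, self.deviation):
            if np.isclose(r, rg):
                return r * d
        raise ValueError(
            f"RG step {rg} is not in the gain model "
            f"(known steps: {self.nominal_rg_values})"
        )

    @classmethod
    def identity(cls, rg_values: Iterable[float]) -> "GainModel":
        rgs = list(rg_values)
        return cls(nominal_rg_values=rgs, deviation=[1.0] * len(rgs))

    @classmethod
    def from_linearization_table(cls, table: pd.DataFrame) -> "GainModel":
        """Gain model whose per-step deviations equal the ratio
        linearized/original of a measured RG-linearization ladder —
        a realistic test bed for the linearization estimator."""
        rgs = table["rg_original"].to_numpy(dtype=float)
        dev = table["rg_linearized"].to_numpy(dtype=float) / rgs
        return cls(nominal_rg_values=list(rgs), deviation=list(dev))


@dataclass
class SimConfig:
    """Conditions for one simulated experiment.

    ``ig_true`` is in intensity per (scan x RG unit x mM x proton);
    ``noise_sigma`` is the per-point frequency-domain noise standard
    deviation before scaling by ``g(rg) * sqrt(ns)``.
    """

    ig_true: float = 1650.0
    ns: int = 16
    rg: float = 90.5
    concentration_mM: float = 50.0
    noise_sigma: float = 0.0
    sweep_ppm: float = 14.0
    n_points: int = 16384
    center_ppm: float = 5.0
    spectrometer_freq_MHz: float = 400.0
    d1_s: float = 16.0
    temperature_K: float = 298.15
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ig_true <= 0:
            raise ValueError(f"ig_true must be > 0, got {self.ig_true}")
        if self.ns < 1:
            raise ValueError(f"ns must be >= 1, got {self.ns}")
        if self.n_points < 2 or (self.n_points & (self.n_points - 1)):
            raise ValueError(f"n_points must be a power of two, got {self.n_points}")

    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta(
            ns=self.ns, rg=self.rg, d1_s=self.d1_s,
            temperature_K=self.temperature_K, sweep_ppm=self.sweep_ppm,
            n_points=self.n_points,
            spectrometer_freq_MHz=self.spectrometer_freq_MHz,
            center_ppm=self.center_ppm,
        )


def _check_signals_in_window(signals: Sequence[SignalSpec], cfg: SimConfig) -> None:
    if not signals:
        raise ValueError("signal list is empty")
    lo = cfg.center_ppm - cfg.sweep_ppm / 2.0
    hi = cfg.center_ppm + cfg.sweep_ppm / 2.0
    for s in signals:
        for off_hz, _ in s.multiplet:
            c = s.center_ppm + off_hz / cfg.spectrometer_freq_MHz
            if not (lo < c < hi):
                raise ValueError(
                    f"signal {s.label!r} component at {c:.3f} ppm lies outside "
                    f"the sweep window [{lo:.3f}, {hi:.3f}] ppm"
                )


def lorentzian(ppm: np.ndarray, center_ppm: float, linewidth_hz: float,
               area: float, sfo_MHz: float) -> np.ndarray:
    """Absorption Lorentzian with the given integral in intensity*ppm units."""
    hw = 0.5 * linewidth_hz / sfo_MHz  # half width at half max, ppm
    return area / np.pi * hw / ((ppm - center_ppm) ** 2 + hw ** 2)


def lorentzian_truncated_area(center_ppm: float, linewidth_hz: float,
                              area: float, sfo_MHz: float,
                              ppm_low: float, ppm_high: float) -> float:
    """Analytic integral of :func:`lorentzian` over [ppm_low, ppm_high]."""
    hw = 0.5 * linewidth_hz / sfo_MHz
    return area / np.pi * (
        np.arctan((ppm_high - center_ppm) / hw)
        - np.arctan((ppm_low - center_ppm) / hw)
    )


def signal_area(spec: SignalSpec, cfg: SimConfig, gain: GainModel) -> float:
    """Model integral of one signal: IG * NS * g(RG) * n_H * c."""
    return (cfg.ig_true * cfg.ns * gain.gain(cfg.rg)
            * spec.n_protons * cfg.concentration_mM)


def simulate_spectrum(signals: Sequence[SignalSpec], cfg: SimConfig,
                      gain: GainModel) -> Spectrum:
    """Simulate a processed absorption-mode spectrum in the frequency domain.

    Noiseless region integrals equal the intensity model to quadrature
    accuracy (the only bias is the analytic Lorentzian tail mass outside
    the region). Noise is Gaussian per point, std
    ``noise_sigma * g(rg) * sqrt(ns)``, seeded by ``cfg.seed``.
    """
    _check_signals_in_window(signals, cfg)
    g = gain.gain(cfg.rg)
    meta = cfg.meta()
    ppm = ppm_axis(meta)
    y = np.zeros_like(ppm)
    for s in signals:
        total = signal_area(s, cfg, gain)
        for off_hz, w in s.multiplet:
            c = s.center_ppm + off_hz / cfg.spectrometer_freq_MHz
            y += lorentzian(ppm, c, s.linewidth_hz, w * total,
                            cfg.spectrometer_freq_MHz)
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        y = y + rng.normal(0.0, cfg.noise_sigma * g * np.sqrt(cfg.ns), size=y.shape)
    return Spectrum(meta=meta, ppm=ppm, data=y.astype(np.complex128),
                    provenance=[f"simulate(seed={cfg.seed})"])


def simulate_fid(signals: Sequence[SignalSpec], cfg: SimConfig,
                 gain: GainModel) -> Fid:
    """Simulate the time-domain signal matching :func:`simulate_spectrum`.

    Each Lorentzian component becomes a decaying complex exponential with
    R2 = pi * linewidth_hz; amplitudes are chosen so the Fourier-transformed
    absorption spectrum carries the same model integrals. Time-domain noise
    is scaled so the frequency-domain noise floor matches ``noise_sigma *
    g(rg) * sqrt(ns)`` under the processing module's FT normalization.
    """
    _check_signals_in_window(signals, cfg)
    g = gain.gain(cfg.rg)
    sfo = cfg.spectrometer_freq_MHz
    sw_hz = cfg.sweep_ppm * sfo
    dt = 1.0 / sw_hz
    t = np.arange(cfg.n_points) * dt
    x = np.zeros(cfg.n_points, dtype=np.complex128)
    for s in signals:
        total = signal_area(s, cfg, gain)
        r2 = np.pi * s.linewidth_hz
        for off_hz, w in s.multiplet:
            c = s.center_ppm + off_hz / sfo
            f0 = (c - cfg.center_ppm) * sfo
            # amplitude 2*area*sfo gives unit-consistent ppm-axis integrals
            x += 2.0 * w * total * sfo * np.exp((2j * np.pi * f0 - r2) * t)
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        sigma_f = cfg.noise_sigma * g * np.sqrt(cfg.ns)
        sigma_t = sigma_f / (dt * np.sqrt(cfg.n_points))
        x = x + rng.normal(0.0, sigma_t, cfg.n_points) \
              + 1j * rng.normal(0.0, sigma_t, cfg.n_points)
    return Fid(meta=cfg.meta(), data=x, source=f"simulate_fid(seed={cfg.seed})")


def noise_sigma_for_snr(signals: Sequence[SignalSpec], cfg: SimConfig,
                        gain: GainModel, target_snr: float) -> float:
    """Per-point ``noise_sigma`` putting the weakest signal at ``target_snr``.

    Uses the convention SNR = peak height / (2 * noise std in the
    spectrum). Peak height of a Lorentzian is area / (pi * half-width).
    """
    if target_snr <= 0:
        raise ValueError("target_snr must be > 0")
    g = gain.gain(cfg.rg)
    heights = []
    for s in signals:
        total = signal_area(s, cfg, gain)
        hw = 0.5 * s.linewidth_hz / cfg.spectrometer_freq_MHz
        heights.append(max(w for _, w in s.multiplet) * total / (np.pi * hw))
    noise_std = min(heights) / (2.0 * target_snr)
    return noise_std / (g * np.sqrt(cfg.ns))


# ---------------------------------------------------------------------------
# Study designs and calibration sets
# ---------------------------------------------------------------------------

#: Default signal set: five well-separated singlets, 1 Hz wide at 400 MHz,
#: with varied proton counts — isolated signals are the method's stated
#: applicability condition.
def example_signals() -> list:
    return [
        SignalSpec(8.6, 1.0, 1, label="H1"),
        SignalSpec(6.8, 1.0, 1, label="H2"),
        SignalSpec(5.0, 1.0, 2, label="H3"),
        SignalSpec(3.2, 1.0, 3, label="H4"),
        SignalSpec(1.4, 1.0, 1, label="H5"),
    ]


#: Half-width (ppm) of the integration region around each example signal.
#: ±0.6 ppm keeps the analytic Lorentzian tail loss at 0.13% for 1 Hz lines.
EXAMPLE_REGION_HALFWIDTH_PPM = 0.6

#: ppm interval containing no signal, for noise estimation.
EXAMPLE_NOISE_REGION = (-1.8, -0.8)


def example_regions():
    """Integration regions matching :func:`example_signals`."""
    from .integrate import IntegrationRegion
    return [
        IntegrationRegion(label=s.label,
                          ppm_high=s.center_ppm + EXAMPLE_REGION_HALFWIDTH_PPM,
                          ppm_low=s.center_ppm - EXAMPLE_REGION_HALFWIDTH_PPM,
                          n_protons=s.n_protons)
        for s in example_signals()
    ]


def default_calibration_design() -> pd.DataFrame:
    """The emulated study design: five concentrations spanning ~5–110 mM,
    each measured at four (NS, RG) settings in duplicate.

    Concentrations are the prepared quinine samples of the bundled study;
    each sample's RG settings span from the lowest instrument step up to
    the highest step its concentration allowed (stronger samples saturate
    the receiver earlier), as a real auto-receiver-gain routine produces.
    """
    from .datasets import load_quinine_samples, load_rg_linearization
    samples = load_quinine_samples()
    ladder = load_rg_linearization()["rg_original"].to_numpy(dtype=float)
    ns_values = [2, 8, 32, 64]
    rows = []
    for _, srow in samples.iterrows():
        allowed = ladder[ladder <= srow["highest_rg"] + 1e-9]
        idx = np.unique(np.linspace(0, len(allowed) - 1, 4).round().astype(int))
        rgs = allowed[idx]
        while len(rgs) < 4:  # degenerate (very short ladder): reuse steps
            rgs = np.append(rgs, rgs[-1])
        for ns, rg in zip(ns_values, rgs):
            rows.append({"sample_id": str(int(srow["sample_id"])),
                         "concentration_mM": float(srow["concentration_mM"]),
                         "ns": int(ns), "rg": float(rg)})
    return pd.DataFrame(rows)


def default_gain_model(identity: bool = False) -> GainModel:
    """Gain model over the bundled instrument RG ladder.

    With ``identity=False`` the per-step deviations reproduce the measured
    linearization ratios (0.92–0.97), i.e. a realistically nonlinear
    receiver; with ``identity=True`` the receiver is perfectly linear.
    """
    from .datasets import load_rg_linearization
    table = load_rg_linearization()
    if identity:
        return GainModel.identity(table["rg_original"].to_numpy(dtype=float))
    return GainModel.from_linearization_table(table)


def simulate_calibration_set(
    design: pd.DataFrame | Sequence[tuple],
    signals: Sequence[SignalSpec],
    gain: GainModel,
    ig_true: float = 1650.0,
    noise_sigma: float | None = 0.0,
    seed: int | None = 0,
    replicates: int = 2,
    target_snr: float | None = None,
    **cfg_kwargs,
):
    """Simulate a full calibration set with its ground-truth manifest.

    ``design`` is a DataFrame with columns sample_id, concentration_mM,
    ns, rg (or a sequence of (concentration_mM, ns, rg) tuples). Each row
    is simulated ``replicates`` times with independent, deterministic child
    seeds. If ``target_snr`` is given, each spectrum's noise is set so its
    weakest signal sits at that signal-to-noise ratio.

    Returns ``(spectra, manifest)``; the manifest records sample_id,
    replicate, concentration_mM, ns, rg, the true gain g(rg), and the seed
    of every spectrum.
    """
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame(
            [{"sample_id": str(i + 1), "concentration_mM": c, "ns": ns, "rg": rg}
             for i, (c, ns, rg) in enumerate(design)]
        )
    if design.empty:
        raise ValueError("calibration design is empty")
    if not list(signals):
        raise ValueError("signal list is empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in ss.spawn(len(design) * replicates)]
    spectra, manifest_rows = [], []
    k = 0
    for _, row in design.iterrows():
        for rep in range(1, replicates + 1):
            cfg = SimConfig(ig_true=ig_true, ns=int(row["ns"]),
                            rg=float(row["rg"]),
                            concentration_mM=float(row["concentration_mM"]),
                            noise_sigma=0.0, seed=child_seeds[k], **cfg_kwargs)
            if target_snr is not None:
                cfg.noise_sigma = noise_sigma_for_snr(signals, cfg, gain, target_snr)
            elif noise_sigma:
                cfg.noise_sigma = noise_sigma
            spectra.append(simulate_spectrum(signals, cfg, gain))
            manifest_rows.append({
                "sample_id": str(row["sample_id"]), "replicate": rep,
                "concentration_mM": cfg.concentration_mM, "ns": cfg.ns,
                "rg": cfg.rg, "g_of_rg": gain.gain(cfg.rg),
                "seed": child_seeds[k],
            })
            k += 1
    return spectra, pd.DataFrame(manifest_rows)
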