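"""Absolute integrals over named ppm regions.

Regions are defined once (on a reference experiment) and applied
unchanged to every spectrum in a set, which is what makes absolute
intensities comparable across experiments. Quadrature is the trapezoidal
rule on the spectrum's own grid; region bounds follow a half-open tie
rule — a grid point exactly on ``ppm_low`` belongs to the region, one
exactly on ``ppm_high`` does not.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .io import AcquisitionMeta, Spectrum


@dataclass
class IntegrationRegion:
    """A named ppm interval with the proton count of the signal inside it."""

    label: str
    ppm_high: float
    ppm_low: float
    n_protons: int

    def __post_init__(self) -> None:
        if self.ppm_high <= self.ppm_low:
            raise ValueError(
                f"region {self.label!r}: ppm_high ({self.ppm_high}) must exceed "
                f"ppm_low ({self.ppm_low})"
            )
        if self.n_protons < 1:
            raise ValueError(f"region {self.label!r}: n_protons must be >= 1")


@dataclass
class SignalIntegral:
    """Absolute integral of one region in one spectrum."""

    label: str
    absolute_intensity: float
    snr: float
    meta: AcquisitionMeta
    n_protons: int = 1

    def __post_init__(self) -> None:
        if self.snr < 0:
            raise ValueError("snr must be >= 0")


def check_region_set(regions: Sequence[IntegrationRegion]) -> None:
    """Enforce unique labels; warn (not error) on overlapping intervals —
    overlapped signals are excluded by the user's region choice, not by
    the library."""
    labels = [r.label for r in regions]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate region labels: {', '.join(dupes)}")
    rs = sorted(regions, key=lambda r: r.ppm_low)
    for a, b in zip(rs, rs[1:]):
        if b.ppm_low < a.ppm_high:
            warnings.warn(
                f"regions {a.label!r} and {b.label!r} overlap "
                f"({a.ppm_low}-{a.ppm_high} vs {b.ppm_low}-{b.ppm_high} ppm)",
                UserWarning,
            )


def _region_mask(ppm: np.ndarray, low: float, high: float) -> np.ndarray:
    return (ppm >= low) & (ppm < high)


def integrate_regions(
    spectrum: Spectrum,
    regions: Sequence[IntegrationRegion],
    noise_region: Optional[Tuple[float, float]] = None,
) -> list:
    """Trapezoidal integrals (intensity*ppm) of each region, with SNR.

    SNR is peak height in the region over twice the standard deviation of
    the real part inside ``noise_region`` (a signal-free (high, low) ppm
    pair); without a noise region, SNR is reported as 0 for empty signals
    and infinity otherwise (unknown noise floor).
    """
    check_region_set(regions)
    ppm = spectrum.ppm
    y = spectrum.data.real
    lo_axis, hi_axis = ppm[-1], ppm[0]

    noise_std = None
    if noise_region is not None:
        nlo, nhi = sorted(noise_region)
        m = _region_mask(ppm, nlo, nhi)
        if not m.any():
            raise ValueError(f"noise region ({nlo}, {nhi}) contains no grid points")
        noise_std = float(np.std(y[m]))

    out = []
    for r in regions:
        if r.ppm_low < lo_axis or r.ppm_high > hi_axis:
            raise ValueError(
                f"region {r.label!r} [{r.ppm_low}, {r.ppm_high}] ppm lies outside "
                f"the spectrum axis [{lo_axis:.4f}, {hi_axis:.4f}] ppm"
            )
        m = _region_mask(ppm, r.ppm_low, r.ppm_high)
        # axis is stored descending; integrate on the ascending view
        integral = float(np.trapezoid(y[m][::-1], ppm[m][::-1]))
        peak = float(np.max(y[m])) if m.any() else 0.0
        if noise_std and noise_std > 0:
            snr = max(peak, 0.0) / (2.0 * noise_std)
        else:
            snr = 0.0 if peak <= 0 else np.inf
        out.append(SignalIntegral(label=r.label, absolute_intensity=integral,
                                  snr=snr, meta=spectrum.meta,
                                  n_protons=r.n_protons))
    return out


def check_snr(integrals: Sequence[SignalIntegral], threshold: float = 200.0) -> list:
    """Warnings for signals whose SNR falls below ``threshold`` (default
    200:1, the working limit for reliable absolute-intensity work)."""
    if threshold <= 0:
        raise ValueError(f"snr threshold must be > 0, got {threshold}")
    return [
        f"signal {s.label!r}: SNR {s.snr:.1f} below threshold {threshold:.0f}"
        for s in integrals if s.snr < threshold
    ]


# ---------------------------------------------------------------------------
# Region-set and integral-table serialization (CSV)
# ---------------------------------------------------------------------------

def read_regions_csv(path: Union[str, os.PathLike]) -> list:
    df = pd.read_csv(path)
    required = {"label", "ppm_high", "ppm_low", "n_protons"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"region file {path} missing columns: {sorted(missing)}")
    regions = [IntegrationRegion(label=str(r.label), ppm_high=float(r.ppm_high),
                                 ppm_low=float(r.ppm_low), n_protons=int(r.n_protons))
               for r in df.itertuples()]
    check_region_set(regions)
    return regions


def write_regions_csv(regions: Sequence[IntegrationRegion],
                      path: Union[str, os.PathLike]) -> None:
    pd.DataFrame([{"label": r.label, "ppm_high": r.ppm_high,
                   "ppm_low": r.ppm_low, "n_protons": r.n_protons}
                  for r in regions]).to_csv(path, index=False)


def integrals_to_frame(integrals: Sequence[SignalIntegral], **extra) -> pd.DataFrame:
    """Flatten integrals into a table (one row per signal) with acquisition
    columns; ``extra`` columns (e.g. sample_id) are broadcast to all rows."""
    rows = []
    for s in integrals:
        rows.append({"label": s.label, "intensity": s.absolute_intensity,
                     "snr": s.snr, "ns": s.meta.ns, "rg": s.meta.rg,
                     "n_protons": s.n_protons, **extra})
    return pd.DataFrame(rows)
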