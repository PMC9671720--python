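"""Reading and writing of 1D NMR data and acquisition metadata.

Two on-disk dialects are supported:

* a Bruker-style experiment directory (plain-text ``acqus`` parameter file
  plus a binary ``fid``), restricted to the handful of parameters a
  quantification pipeline needs;
* an internal ``.fnmr`` format — a YAML text header paired with a raw
  little-endian float64 binary — designed for lossless, bit-exact round
  trips in tests and between pipeline stages.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import yaml

INTERNAL_FORMAT_VERSION = "fnmr-1"

#: Parameter keys required in the Bruker-style ``acqus`` file. ``TD`` counts
#: real+imaginary points, i.e. twice the number of complex observe points.
BRUKER_REQUIRED_KEYS = ("NS", "RG", "D1", "TE", "SW", "TD", "SFO1")


class SpectraIOError(Exception):
    """Raised for malformed or incomplete NMR data files."""


@dataclass
class AcquisitionMeta:
    """Acquisition parameters relevant to intensity-based quantification.

    Parameters
    ----------
    ns : int
        Number of co-added scans. Signal grows linearly with ``ns``, noise
        as ``sqrt(ns)``.
    rg : float
        Nominal receiver gain (instrument units).
    d1_s : float
        Inter-scan relaxation delay in seconds. For quantitative integrals
        it must be several times the longest T1 in the sample.
    temperature_K : float
        Sample temperature in Kelvin.
    sweep_ppm : float
        Spectral width in ppm.
    n_points : int
        Number of complex observe points.
    spectrometer_freq_MHz : float
        Proton carrier frequency in MHz (1 ppm == this many Hz).
    center_ppm : float
        Chemical shift at the center of the spectral window.
    """

    ns: int
    rg: float
    d1_s: float
    temperature_K: float
    sweep_ppm: float
    n_points: int
    spectrometer_freq_MHz: float
    center_ppm: float = 5.0

    def __post_init__(self) -> None:
        if self.ns < 1:
            raise ValueError(f"ns must be >= 1, got {self.ns}")
        if self.rg <= 0:
            raise ValueError(f"rg must be > 0, got {self.rg}")
        if self.d1_s < 0:
            raise ValueError(f"d1_s must be >= 0, got {self.d1_s}")
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        if self.sweep_ppm <= 0:
            raise ValueError(f"sweep_ppm must be > 0, got {self.sweep_ppm}")
        if self.spectrometer_freq_MHz <= 0:
            raise ValueError("spectrometer_freq_MHz must be > 0")

    def to_dict(self) -> dict:
        return {
            "ns": int(self.ns),
            "rg": float(self.rg),
            "d1_s": float(self.d1_s),
            "temperature_K": float(self.temperature_K),
            "sweep_ppm": float(self.sweep_ppm),
            "n_points": int(self.n_points),
            "spectrometer_freq_MHz": float(self.spectrometer_freq_MHz),
            "center_ppm": float(self.center_ppm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        return cls(**d)


@dataclass
class Fid:
    """A free induction decay: complex time-domain samples plus metadata."""

    meta: AcquisitionMeta
    data: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 1:
            raise ValueError("Fid data must be one-dimensional")
        if len(self.data) != self.meta.n_points:
            raise ValueError(
                f"Fid length {len(self.data)} != meta.n_points {self.meta.n_points}"
            )

    @property
    def dwell_s(self) -> float:
        """Dwell time (seconds per complex point)."""
        return 1.0 / (self.meta.sweep_ppm * self.meta.spectrometer_freq_MHz)


@dataclass
class Spectrum:
    """A 1D frequency-domain spectrum on a descending ppm axis.

    ``data`` stays complex through phasing; quantification uses the real
    (absorption-mode) part. ``provenance`` is an append-only record of the
    processing steps that produced the object.
    """

    meta: AcquisitionMeta
    ppm: np.ndarray
    data: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=np.float64)
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.ppm.shape != self.data.shape:
            raise ValueError("ppm and data must have the same length")
        if len(self.ppm) > 1 and not np.all(np.diff(self.ppm) < 0):
            raise ValueError("ppm axis must be strictly decreasing")

    @property
    def real(self) -> np.ndarray:
        """Absorption-mode intensities."""
        return self.data.real

    def with_step(self, step: str, data: np.ndarray | None = None) -> "Spectrum":
        """Return a copy with ``step`` appended to the provenance."""
        return Spectrum(
            meta=self.meta,
            ppm=self.ppm.copy(),
            data=(self.data if data is None else data).copy(),
            provenance=list(self.provenance) + [step],
        )


def ppm_axis(meta: AcquisitionMeta, n: int | None = None) -> np.ndarray:
    """Descending ppm axis for a spectral window described by ``meta``."""
    n = meta.n_points if n is None else n
    sw_hz = meta.sweep_ppm * meta.spectrometer_freq_MHz
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=1.0 / sw_hz))
    return (meta.center_ppm + freqs / meta.spectrometer_freq_MHz)[::-1]


# ---------------------------------------------------------------------------
# Bruker-style directory dialect
# ---------------------------------------------------------------------------

def _parse_acqus(path: str) -> dict:
    params: dict = {}
    with open(path, "r") as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("##$"):
                continue
            key, _, value = line[3:].partition("=")
            params[key.strip()] = value.strip()
    return params


def read_bruker_dir(path: Union[str, os.PathLike]) -> Fid:
    """Read an FID from a Bruker-style experiment directory.

    The directory must contain an ``acqus`` parameter file and a binary
    ``fid``. Only the parameter subset needed for quantification is parsed
    (see :data:`BRUKER_REQUIRED_KEYS`); ``BYTORDA`` selects byte order
    (0 little, 1 big) and ``DTYPA`` the encoding (0 int32, 2 float64).
    Missing required keys are an error — NS and RG are never defaulted.
    """
    path = os.fspath(path)
    acqus = os.path.join(path, "acqus")
    fid_path = os.path.join(path, "fid")
    if not os.path.isfile(acqus):
        raise SpectraIOError(f"no acqus parameter file in {path}")
    if not os.path.isfile(fid_path):
        raise SpectraIOError(f"no fid binary in {path}")

    params = _parse_acqus(acqus)
    missing = [k for k in BRUKER_REQUIRED_KEYS if k not in params]
    if missing:
        raise SpectraIOError(
            f"acqus in {path} is missing required keys: {', '.join(missing)}"
        )

    td = int(params["TD"])
    if td % 2:
        raise SpectraIOError(f"TD must be even (real+imag pairs), got {td}")
    n_complex = td // 2

    byte_order = "<" if int(params.get("BYTORDA", 0)) == 0 else ">"
    dtypa = int(params.get("DTYPA", 0))
    if dtypa == 0:
        dtype = np.dtype(byte_order + "i4")
    elif dtypa == 2:
        dtype = np.dtype(byte_order + "f8")
    else:
        raise SpectraIOError(f"unsupported DTYPA={dtypa} (supported: 0, 2)")

    raw = np.fromfile(fid_path, dtype=dtype)
    if len(raw) != td:
        raise SpectraIOError(
            f"truncated fid in {path}: expected {td} values "
            f"({td * dtype.itemsize} bytes), found {len(raw)}"
        )
    data = raw.astype(np.float64).view()
    complex_data = data[0::2] + 1j * data[1::2]

    meta = AcquisitionMeta(
        ns=int(params["NS"]),
        rg=float(params["RG"]),
        d1_s=float(params["D1"]),
        temperature_K=float(params["TE"]),
        sweep_ppm=float(params["SW"]),
        n_points=n_complex,
        spectrometer_freq_MHz=float(params["SFO1"]),
        center_ppm=float(params.get("O1P", 5.0)),
    )
    return Fid(meta=meta, data=complex_data, source=path)


def write_bruker_dir(fid: Fid, path: Union[str, os.PathLike],
                     dtypa: int = 2, big_endian: bool = False) -> None:
    """Write an FID as a Bruker-style directory (used to build fixtures)."""
    path = os.fspath(path)
    os.makedirs(path, exist_ok=True)
    m = fid.meta
    lines = [
        "##TITLE= faintnmr bruker-subset dialect",
        f"##$NS= {m.ns}",
        f"##$RG= {m.rg}",
        f"##$D1= {m.d1_s}",
        f"##$TE= {m.temperature_K}",
        f"##$SW= {m.sweep_ppm}",
        f"##$TD= {2 * m.n_points}",
        f"##$SFO1= {m.spectrometer_freq_MHz}",
        f"##$O1P= {m.center_ppm}",
        f"##$BYTORDA= {1 if big_endian else 0}",
        f"##$DTYPA= {dtypa}",
        "##END=",
    ]
    with open(os.path.join(path, "acqus"), "w") as fh:
        fh.write("\n".join(lines) + "\n")

    interleaved = np.empty(2 * m.n_points, dtype=np.float64)
    interleaved[0::2] = fid.data.real
    interleaved[1::2] = fid.data.imag
    byte_order = ">" if big_endian else "<"
    if dtypa == 0:
        out = np.round(interleaved).astype(byte_order + "i4")
    elif dtypa == 2:
        out = interleaved.astype(byte_order + "f8")
    else:
        raise SpectraIOError(f"unsupported DTYPA={dtypa} (supported: 0, 2)")
    out.tofile(os.path.join(path, "fid"))


# ---------------------------------------------------------------------------
# Internal .fnmr format: YAML header + raw little-endian float64 binary
# ---------------------------------------------------------------------------

def write_internal(obj: Union[Fid, Spectrum], path: Union[str, os.PathLike]) -> None:
    """Write a :class:`Fid` or :class:`Spectrum` as a header/binary pair.

    ``path`` receives the text header; the float64 payload goes to
    ``path + '.dat'``. Complex data is stored interleaved (re, im); a
    spectrum's ppm axis precedes its intensities.
    """
    path = os.fspath(path)
    if isinstance(obj, Fid):
        kind = "fid"
        payload = np.empty(2 * len(obj.data), dtype="<f8")
        payload[0::2] = obj.data.real
        payload[1::2] = obj.data.imag
        extra = {"source": obj.source}
    elif isinstance(obj, Spectrum):
        kind = "spectrum"
        n = len(obj.data)
        payload = np.empty(3 * n, dtype="<f8")
        payload[:n] = obj.ppm
        payload[n::2] = obj.data.real
        payload[n + 1::2] = obj.data.imag
        extra = {"provenance": list(obj.provenance), "n_spectrum": n}
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")

    header = {
        "version": INTERNAL_FORMAT_VERSION,
        "kind": kind,
        "meta": obj.meta.to_dict(),
        "n_values": int(len(payload)),
        **extra,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(header, fh, sort_keys=True)
    payload.tofile(path + ".dat")


def read_internal(path: Union[str, os.PathLike]) -> Union[Fid, Spectrum]:
    """Read a ``.fnmr`` header/binary pair written by :func:`write_internal`."""
    path = os.fspath(path)
    with open(path, "r") as fh:
        header = yaml.safe_load(fh)
    version = header.get("version")
    if version != INTERNAL_FORMAT_VERSION:
        raise SpectraIOError(
            f"internal format version mismatch in {path}: "
            f"found {version!r}, expected {INTERNAL_FORMAT_VERSION!r}"
        )
    payload = np.fromfile(path + ".dat", dtype="<f8")
    if len(payload) != header["n_values"]:
        raise SpectraIOError(
            f"truncated payload for {path}: expected {header['n_values']} "
            f"values, found {len(payload)}"
        )
    meta = AcquisitionMeta.from_dict(header["meta"])
    if header["kind"] == "fid":
        data = payload[0::2] + 1j * payload[1::2]
        return Fid(meta=meta, data=data, source=header.get("source", ""))
    if header["kind"] == "spectrum":
        n = int(header["n_spectrum"])
        ppm = payload[:n]
        data = payload[n::2] + 1j * payload[n + 1::2]
        return Spectrum(meta=meta, ppm=ppm, data=data,
                        provenance=list(header.get("provenance", [])))
    raise SpectraIOError(f"unknown kind {header['kind']!r} in {path}")


def file_digest(path: Union[str, os.PathLike]) -> str:
    """SHA-256 hex digest of a file (used in run logs)."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Metadata checks for quantitative use
# ---------------------------------------------------------------------------

def validate_for_quantification(
    meta: Union[AcquisitionMeta, Sequence[AcquisitionMeta]],
    t1_max_s: float,
) -> list:
    """Check acquisition metadata against quantification requirements.

    Returns a list of human-readable warnings (never raises on bad
    experimental settings). Two checks are applied:

    * incomplete relaxation: the inter-scan delay should satisfy
      ``d1_s >= 5 * t1_max_s`` so that magnetization recovers to within
      ~0.7% between scans;
    * temperature consistency: signal positions and intensities shift with
      temperature, so a quantified set should be acquired isothermally.
    """
    if t1_max_s <= 0:
        raise ValueError(f"t1_max_s must be > 0, got {t1_max_s}")
    metas = [meta] if isinstance(meta, AcquisitionMeta) else list(meta)
    warnings_out = []
    for i, m in enumerate(metas):
        if m.d1_s < 5.0 * t1_max_s:
            warnings_out.append(
                f"experiment {i}: inter-scan delay D1={m.d1_s} s is below "
                f"5*T1max={5.0 * t1_max_s:.2f} s; integrals will be biased by "
                "incomplete relaxation"
            )
    temps = {round(m.temperature_K, 6) for m in metas}
    if len(temps) > 1:
        warnings_out.append(
            "temperature varies across the set "
            f"({sorted(temps)} K); not recommended for quantification"
        )
    return warnings_out
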