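"""Reference-free quantification from absolute intensities.

The method rests on one proportionality: the absolute integral I of an
isolated signal is

    I = IG * NS * RG * n_H * c

with NS the number of scans, RG the receiver gain, n_H the signal's
proton count and c the molar concentration (mM). Dividing I by
``NS * RG * c * n_H`` over a set of samples of known concentration yields
a scatter of *normalized increments* whose central value is the
spectrometer's Intensity-Gain (IG) factor. Once IG is fixed, any new
sample's concentration follows directly from a single absolute integral —
no internal or external reference material is needed.

Real receiver amplifiers are not perfectly linear in their nominal RG
setting. The calibration residuals expose this: the mean normalized
increment at each RG step, relative to the global IG, estimates the
step's true relative gain. Replacing each nominal RG by this *linearized*
RG removes the amplifier bias from back-calculated concentrations.

:class:`FaintCalibrator` packages calibration and prediction in
scikit-learn estimator style (``fit`` / ``predict`` / ``get_params``);
the module-level functions are thin wrappers over it.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .integrate import SignalIntegral, integrals_to_frame

OBSERVATION_COLUMNS = ("label", "intensity", "ns", "rg",
                       "concentration_mM", "n_protons")


@dataclass
class SampleInfo:
    """Identity and preparation data of one sample.

    Concentration comes either from a direct value
    (``known_concentration_mM``) or from the weighed preparation:
    weight (mg), molecular weight (g/mol) and solvent volume (ml).
    """

    sample_id: str
    weight_mg: Optional[float] = None
    molecular_weight: Optional[float] = None
    volume_ml: Optional[float] = None
    known_concentration_mM: Optional[float] = None

    @property
    def concentration_mM(self) -> float:
        if self.known_concentration_mM is not None:
            return float(self.known_concentration_mM)
        return weight_to_concentration(self)


def weight_to_concentration(info: Union[SampleInfo, None] = None, *,
                            weight_mg: float | None = None,
                            molecular_weight: float | None = None,
                            volume_ml: float | None = None) -> float:
    """Concentration (mM) of a weighed sample.

    c = (weight_mg / MW) / volume_ml * 1000 — millimoles of analyte per
    liter of solvent.
    """
    if info is not None:
        weight_mg = info.weight_mg
        molecular_weight = info.molecular_weight
        volume_ml = info.volume_ml
    for name, v in (("weight_mg", weight_mg),
                    ("molecular_weight", molecular_weight),
                    ("volume_ml", volume_ml)):
        if v is None or v <= 0:
            raise ValueError(f"{name} must be a positive number, got {v}")
    return (weight_mg / molecular_weight) / volume_ml * 1000.0


def normalized_increment(intensity: float, ns: float, rg: float,
                         concentration_mM: float, n_protons: float) -> float:
    """Per-scan, per-RG-unit, per-proton, per-mM intensity increment:
    I / (NS * RG * c * n_H). Its central value over a calibration set is
    the IG factor."""
    for name, v in (("intensity", intensity), ("ns", ns), ("rg", rg),
                    ("concentration_mM", concentration_mM),
                    ("n_protons", n_protons)):
        if v is None or v <= 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    return intensity / (ns * rg * concentration_mM * n_protons)


@dataclass
class IGCalibration:
    """A fitted IG factor with its underlying observations.

    ``observations`` has one row per (signal x experiment) with columns
    label, ns, rg, concentration_mM, n_protons, normalized_increment;
    ``dispersion`` is the standard deviation of the increments.
    """

    ig: float
    observations: pd.DataFrame
    dispersion: float

    def __post_init__(self) -> None:
        if self.ig <= 0:
            raise ValueError("ig must be > 0")

    def to_json(self, path: Union[str, os.PathLike]) -> None:
        payload = {"ig": self.ig, "dispersion": self.dispersion,
                   "n_obs": int(len(self.observations)), "version": 1}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


@dataclass
class RGLinearization:
    """Lookup table mapping nominal RG steps to linearized values.

    Queries at tabulated steps return the table value exactly; between
    steps, linear interpolation; outside the table an error, unless
    ``allow_extrapolate`` extends the nearest edge's correction factor.
    """

    table: pd.DataFrame  # columns rg_original, rg_linearized
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        t = self.table.sort_values("rg_original").reset_index(drop=True)
        orig = t["rg_original"].to_numpy(dtype=float)
        lin = t["rg_linearized"].to_numpy(dtype=float)
        if len(orig) < 1:
            raise ValueError("linearization table is empty")
        if np.any(np.diff(orig) <= 0):
            raise ValueError("rg_original values must be strictly increasing")
        if np.any(lin <= 0):
            raise ValueError("all rg_linearized values must be > 0")
        self.table = t

    def apply(self, rg: float, allow_extrapolate: bool = False) -> float:
        orig = self.table["rg_original"].to_numpy(dtype=float)
        lin = self.table["rg_linearized"].to_numpy(dtype=float)
        exact = np.isclose(orig, rg)
        if exact.any():
            return float(lin[exact][0])
        if rg < orig[0] or rg > orig[-1]:
            if not allow_extrapolate:
                raise ValueError(
                    f"RG {rg} outside linearization table range "
                    f"[{orig[0]}, {orig[-1]}]; pass allow_extrapolate=True to "
                    "apply the nearest edge's correction factor"
                )
            edge = 0 if rg < orig[0] else -1
            return float(rg * lin[edge] / orig[edge])
        return float(np.interp(rg, orig, lin))

    def to_csv(self, path: Union[str, os.PathLike]) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, os.PathLike]) -> "RGLinearization":
        return cls(table=pd.read_csv(path))


@dataclass
class QuantResult:
    """Back-calculated concentration of one sample.

    ``per_signal`` maps each signal label to its individual concentration
    estimates (one per experiment); ``bc_mM``/``sigma_mM`` are the mean and
    sample standard deviation of the pooled estimates.
    """

    sample_id: str
    per_signal: dict
    bc_mM: float
    sigma_mM: float
    linearized: bool
    n_estimates: int

    def __post_init__(self) -> None:
        if self.sigma_mM < 0:
            raise ValueError("sigma_mM must be >= 0")


class FaintCalibrator(BaseEstimator):
    """Absolute-intensity quantification calibrator (sklearn-style).

    Parameters
    ----------
    central : {"mean", "median"}
        Central estimate of the normalized increments used as the IG
        factor. The default mean matches the method's definition; the
        median is a robust alternative for contaminated calibrations.
    linearize : bool
        If True, fit a per-RG-step linearization from the calibration
        residuals (requires >= 2 distinct RG values) and use linearized
        RG values in :meth:`predict`.
    allow_extrapolate : bool
        Permit RG queries outside the fitted linearization table, using
        the nearest edge's correction factor.

    Attributes
    ----------
    ig_ : float
        Fitted Intensity-Gain factor (intensity per scan, per RG unit,
        per proton, per mM).
    dispersion_ : float
        Standard deviation of the normalized increments.
    observations_ : pandas.DataFrame
        One row per (signal x experiment) with the normalized increment.
    linearization_ : RGLinearization or None
        Fitted RG lookup table (only when ``linearize=True``).
    """

    def __init__(self, central: str = "mean", linearize: bool = False,
                 allow_extrapolate: bool = False):
        self.central = central
        self.linearize = linearize
        self.allow_extrapolate = allow_extrapolate

    # -- fitting ------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "FaintCalibrator":
        """Fit the IG factor (and optionally the RG linearization).

        ``X`` is an observation table with columns label, intensity, ns,
        rg, concentration_mM, n_protons — one row per signal per
        calibration experiment (see :func:`observations_from_integrals`).
        """
        if self.central not in ("mean", "median"):
            raise ValueError(f"central must be 'mean' or 'median', got {self.central!r}")
        X = pd.DataFrame(X)
        missing = set(OBSERVATION_COLUMNS) - set(X.columns)
        if missing:
            raise ValueError(f"observation table missing columns: {sorted(missing)}")
        if len(X) < 1:
            raise ValueError("no calibration observations")
        obs = X.copy()
        obs["normalized_increment"] = [
            normalized_increment(r.intensity, r.ns, r.rg,
                                 r.concentration_mM, r.n_protons)
            for r in obs.itertuples()
        ]
        inc = obs["normalized_increment"].to_numpy(dtype=float)
        self.ig_ = float(np.mean(inc) if self.central == "mean" else np.median(inc))
        # population std: dispersion describes the scatter of the increments
        self.dispersion_ = float(np.std(inc))
        self.observations_ = obs
        self.linearization_ = self._fit_linearization(obs) if self.linearize else None
        return self

    def _fit_linearization(self, obs: pd.DataFrame) -> RGLinearization:
        grouped = obs.groupby("rg")["normalized_increment"].mean().sort_index()
        if len(grouped) < 2:
            raise ValueError(
                "linearization needs observations at >= 2 distinct RG values; "
                f"got {len(grouped)}"
            )
        rg_orig = grouped.index.to_numpy(dtype=float)
        correction = grouped.to_numpy(dtype=float) / self.ig_
        table = pd.DataFrame({"rg_original": rg_orig,
                              "rg_linearized": rg_orig * correction})
        return RGLinearization(table=table)

    # -- prediction ---------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "ig_"):
            raise ValueError("FaintCalibrator is not fitted; call fit() first")

    def effective_rg(self, rg: float) -> float:
        """Nominal or linearized RG, per the ``linearize`` parameter."""
        self._check_fitted()
        if self.linearize and self.linearization_ is not None:
            return self.linearization_.apply(rg, self.allow_extrapolate)
        return float(rg)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Concentration (mM) per observation row.

        ``X`` needs columns intensity, ns, rg, n_protons. Each estimate is
        c = I / (IG * NS * RG_eff * n_H).
        """
        self._check_fitted()
        X = pd.DataFrame(X)
        missing = {"intensity", "ns", "rg", "n_protons"} - set(X.columns)
        if missing:
            raise ValueError(f"prediction table missing columns: {sorted(missing)}")
        out = np.empty(len(X), dtype=float)
        for i, r in enumerate(X.itertuples()):
            rg_eff = self.effective_rg(float(r.rg))
            out[i] = r.intensity / (self.ig_ * r.ns * rg_eff * r.n_protons)
        return out

    def calibration_(self) -> IGCalibration:
        """The fitted calibration as a plain result object."""
        self._check_fitted()
        return IGCalibration(ig=self.ig_, observations=self.observations_,
                             dispersion=self.dispersion_)


# ---------------------------------------------------------------------------
# Functional surface over the estimator
# ---------------------------------------------------------------------------

def observations_from_integrals(
    integrals: Mapping[str, Sequence[SignalIntegral]],
    samples: Sequence[SampleInfo],
) -> pd.DataFrame:
    """Join per-sample integrals with sample concentrations into the
    observation table the calibrator consumes."""
    by_id = {s.sample_id: s for s in samples}
    frames = []
    for sample_id, ints in integrals.items():
        if sample_id not in by_id:
            raise ValueError(f"no SampleInfo for sample {sample_id!r}")
        c = by_id[sample_id].concentration_mM
        frames.append(integrals_to_frame(ints, sample_id=sample_id,
                                         concentration_mM=c))
    if not frames:
        raise ValueError("no calibration observations")
    return pd.concat(frames, ignore_index=True)


def calibrate_ig(integrals: Mapping[str, Sequence[SignalIntegral]],
                 samples: Sequence[SampleInfo],
                 central: str = "mean") -> IGCalibration:
    """Fit the IG factor from integrals of known-concentration samples."""
    obs = observations_from_integrals(integrals, samples)
    cal = FaintCalibrator(central=central).fit(obs)
    return cal.calibration_()


def estimate_linearization(cal: IGCalibration) -> RGLinearization:
    """Estimate per-RG-step linearized values from calibration residuals.

    For each distinct RG step, the mean normalized increment relative to
    the global IG gives a multiplicative correction f(RG); the linearized
    value is ``RG * f(RG)``. No smoothing is applied across steps (the
    measured corrections need not be monotone)."""
    est = FaintCalibrator()
    est.ig_ = cal.ig
    est.dispersion_ = cal.dispersion
    est.observations_ = cal.observations
    return est._fit_linearization(cal.observations)


def apply_linearization(lin: RGLinearization, rg: float,
                        allow_extrapolate: bool = False) -> float:
    """Linearized RG for a nominal value (table lookup / interpolation)."""
    return lin.apply(rg, allow_extrapolate)


def back_calculate(
    integrals: Mapping[str, Sequence[SignalIntegral]],
    cal: IGCalibration,
    lin: Optional[RGLinearization] = None,
    pooling: str = "flat",
    allow_extrapolate: bool = False,
) -> list:
    """Back-calculate one concentration per sample from its integrals.

    Every (signal x experiment) yields an estimate
    c = I / (IG * NS * RG_eff * n_H); with ``pooling='flat'`` (default)
    all estimates of a sample are pooled equally into the mean bc_mM and
    sample standard deviation sigma_mM, with ``pooling='per_signal'``
    signals are first averaged individually and the per-signal means are
    then pooled.
    """
    if pooling not in ("flat", "per_signal"):
        raise ValueError(f"pooling must be 'flat' or 'per_signal', got {pooling!r}")
    est = FaintCalibrator(linearize=lin is not None,
                          allow_extrapolate=allow_extrapolate)
    est.ig_ = cal.ig
    est.dispersion_ = cal.dispersion
    est.observations_ = cal.observations
    est.linearization_ = lin

    results = []
    for sample_id, ints in integrals.items():
        for s in ints:
            if s.n_protons is None or s.n_protons < 1:
                raise ValueError(
                    f"signal {s.label!r} of sample {sample_id!r} has no valid "
                    "proton count"
                )
        frame = integrals_to_frame(ints)
        estimates = est.predict(frame)
        per_signal: dict = {}
        for label, c in zip(frame["label"], estimates):
            per_signal.setdefault(label, []).append(float(c))
        if pooling == "flat":
            pool = np.asarray(estimates, dtype=float)
        else:
            pool = np.array([np.mean(v) for v in per_signal.values()])
        bc = float(np.mean(pool))
        sigma = float(np.std(pool, ddof=1)) if len(pool) > 1 else 0.0
        results.append(QuantResult(sample_id=sample_id, per_signal=per_signal,
                                   bc_mM=bc, sigma_mM=sigma,
                                   linearized=lin is not None,
                                   n_estimates=int(len(pool))))
    return results


def quant_results_to_frame(results: Sequence[QuantResult]) -> pd.DataFrame:
    """Tabular quantification report (concentrations rounded to 0.01 mM)."""
    return pd.DataFrame([{
        "sample_id": r.sample_id,
        "bc_mM": round(r.bc_mM, 2),
        "sigma_mM": round(r.sigma_mM, 2),
        "linearized": r.linearized,
        "n_estimates": r.n_estimates,
    } for r in results])
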