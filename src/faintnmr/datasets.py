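"""Bundled example data: a published quinine qNMR study.

The measurements ship as small CSV tables: prepared quinine samples
(weights, concentrations, available receiver-gain range), the manually
linearized receiver-gain ladder of the spectrometer used, and the
back-calculated concentrations obtained with and without that
linearization. The raw spectra behind these tables are deposited on
Zenodo (:data:`ZENODO_DOI`); fetching them is an optional, out-of-band
compatibility check — nothing in this package requires network access.
"""

from importlib import resources

import pandas as pd

#: DOI of the public raw-data deposit (FIDs, processed spectra, integrals)
#: for the bundled quinine study. Optional; not used by any code path.
ZENODO_DOI = "10.5281/zenodo.7221753"

#: Molecular weight of quinine (C20H24N2O2), g/mol.
QUININE_MW = 324.42


def _read(name: str) -> pd.DataFrame:
    with resources.files("faintnmr.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_quinine_samples() -> pd.DataFrame:
    """Prepared quinine samples: weights (mg), MW, solvent volume (ml),
    resulting concentrations (mM), and the receiver-gain range the
    instrument allowed for each sample."""
    return _read("quinine_samples.csv")


def load_rg_linearization() -> pd.DataFrame:
    """Receiver-gain linearization ladder: nominal instrument RG steps and
    their manually linearized equivalents."""
    return _read("rg_linearization.csv")


def load_quinine_backcalc() -> pd.DataFrame:
    """Back-calculated quinine concentrations (mM) per sample, with and
    without RG linearization, each with its standard deviation."""
    return _read("quinine_backcalc.csv")
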