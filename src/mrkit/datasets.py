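"""Packaged data: the published serum-testosterone instruments and fixtures.

Two exposure instruments ship with the package, as published for the
REDUCE cohort (3225 men of European descent):

* ``jmjd1c`` — a single genome-wide significant variant (rs10822184);
* ``shbg`` — the 20-variant instrument produced by stepwise LD pruning of
  the sex-hormone-binding-globulin locus.

The original per-outcome disease GWAS are external consortium data and are
not redistributable here. In their place, ``data/synthetic_outcomes/``
holds SYNTHETIC single-variant outcome tables for the JMJD1C locus,
derived by inverting the published ratio estimates
(beta_y = estimate * beta_x, se_y = se * |beta_x|); they reproduce the
published JMJD1C rows exactly and exist for worked examples and tests,
not as real GWAS data.

``reported_results.tsv`` carries the published per-outcome IVW results
(odds ratio, log-odds estimate, SE, p-value, printed CI bounds where
available, and the MR-Egger intercept column for the SHBG locus) for
consistency checks against this package's arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .sumstats import read_associations
from .types import VariantAssociation

_OUTCOMES = (
    "alzheimers",
    "bipolar",
    "schizophrenia",
    "depression",
    "rheumatoid_arthritis",
    "gout",
    "type2_diabetes",
)


def _data_path(*parts):
    return resources.files("mrkit").joinpath("data", *parts)


def load_exposure_instrument(locus: str) -> list:
    """The published exposure instrument for ``"jmjd1c"`` or ``"shbg"``."""
    locus = locus.lower()
    if locus not in {"jmjd1c", "shbg"}:
        raise ValueError(f"unknown locus {locus!r}; expected 'jmjd1c' or 'shbg'")
    with resources.as_file(_data_path(f"{locus}_exposure.tsv")) as path:
        return read_associations(path)


def available_outcomes() -> tuple:
    """Outcome labels with a packaged synthetic JMJD1C fixture."""
    return _OUTCOMES


def load_synthetic_outcome(outcome: str) -> list:
    """A synthetic single-variant outcome table for the JMJD1C locus.

    Derived by inverting the published ratio estimate; see the module
    docstring. ``outcome`` is one of :func:`available_outcomes`.
    """
    if outcome not in _OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; one of {_OUTCOMES}")
    with resources.as_file(
        _data_path("synthetic_outcomes", f"jmjd1c_{outcome}.tsv")
    ) as path:
        return read_associations(path)


def load_reported_results() -> pd.DataFrame:
    """Published per-outcome IVW results as printed (both loci).

    Columns: locus, outcome, odds_ratio, estimate, se, pvalue (string, may
    be ``<0.001``), ci_low/ci_high (blank where no CI was printed),
    egger_intercept, egger_intercept_pvalue (SHBG rows only).
    """
    with resources.as_file(_data_path("reported_results.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype={"pvalue": str})
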