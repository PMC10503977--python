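"""Packaged reference tables for the MAO-B chalcone inhibitor study.

These CSV files transcribe, verbatim, the printed tables of the study this
package reanalyses: 25 unsaturated ketone (chalcone-type) MAO-B inhibitors
with four MOE descriptors, activities, train/test flags, multicollinearity
statistics, Y-randomization runs, physicochemical properties with
drug-likeness verdicts, and docking binding affinities.

The tables are not mutually harmonised — a few activities are printed with
slightly different last digits in different tables (e.g. compound 10b:
7.7959 in the activity table, 7.7958 in the descriptor and affinity
tables), the activity table contains compound 12a but not 9b while the
property/affinity tables contain 9b but not 12a.  Each loader returns its
own table exactly as printed; pick the table that matches the analysis
stage you are reproducing.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .datasets import CompoundRecord, QSARDataset, load_table

__all__ = [
    "DESCRIPTOR_NAMES",
    "fixture_path",
    "load_fixture",
    "load_activity_table",
    "load_vif_table",
    "load_correlation_table",
    "load_descriptor_table",
    "load_randomization_table",
    "load_property_table",
    "load_affinity_table",
]

#: The four selected MOE descriptors, in model-equation order.
DESCRIPTOR_NAMES = ["BCUT_SMR_2", "logP(o/w)", "SlogP_VSA4", "vsurf_IW3"]

_FILES = {
    "table1": "table1.csv",
    "table2": "table2.csv",
    "table3": "table3.csv",
    "table4": "table4.csv",
    "tableS1": "tableS1.csv",
    "tableS2": "tableS2.csv",
    "tableS4": "tableS4.csv",
}


def fixture_path(name: str):
    """Path-like handle to a packaged fixture CSV (``table1`` ... ``tableS4``)."""
    try:
        fname = _FILES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FILES)}")
    return resources.files("qsarkit.data").joinpath(fname)


def load_fixture(name: str) -> pd.DataFrame:
    """Raw DataFrame view of any packaged fixture table."""
    with resources.as_file(fixture_path(name)) as p:
        return pd.read_csv(p)


def load_activity_table() -> pd.DataFrame:
    """Compound ids and experimental pIC50 for all 25 compounds (Table 1 analogue)."""
    return load_fixture("table1")


def load_vif_table() -> pd.DataFrame:
    """Printed tolerance, VIF, coefficient p-value and activity correlation per descriptor."""
    return load_fixture("table2")


def load_correlation_table() -> pd.DataFrame:
    """Printed descriptor/activity Pearson correlation matrix, indexed by variable."""
    return load_fixture("table3").set_index("variable")


def load_descriptor_table(*, with_predictions: bool = False):
    """The modelling dataset: descriptors, activities and the 20/5 train/test split.

    Parameters
    ----------
    with_predictions : bool
        If True, also return the raw DataFrame whose ``pIC50_pred`` /
        ``pIC50_loo`` columns hold the study's printed fitted and
        leave-one-out predictions (useful as regression anchors).

    Returns
    -------
    QSARDataset, or (QSARDataset, DataFrame)
    """
    with resources.as_file(fixture_path("table4")) as p:
        ds = load_table(
            p,
            activity_column="pIC50_obs",
            descriptor_columns=[n for n in pd.read_csv(p).columns
                                if n not in ("compound", "pIC50_obs",
                                             "pIC50_pred", "pIC50_loo", "split")],
        )
    if with_predictions:
        return ds, load_fixture("table4")
    return ds


def load_randomization_table() -> pd.DataFrame:
    """The study's printed Y-randomization runs: R, R² and Q² for the original
    model and 20 response-scrambled refits."""
    return load_fixture("tableS1")


def load_property_table() -> pd.DataFrame:
    """Physicochemical properties plus printed drug-likeness verdicts.

    Columns MW/LogP/HBA/HBD/TPSA are rule-engine inputs; the verdict columns
    (lipinski, ghose, veber, egan, muegge, bioavailability_score) are the
    printed expectations.  The Ghose verdicts depend on WLOGP, which the
    source tables do not print, so those nine failures are expectations
    only — the rule engine reports the WLOGP conditions as not evaluable
    unless a WLOGP value is supplied.
    """
    return load_fixture("tableS2")


def load_affinity_table() -> QSARDataset:
    """Activities and docking binding affinities (kcal/mol) for 25 compounds."""
    df = load_fixture("tableS4")
    records = [
        CompoundRecord(
            id=str(r.compound),
            activity=float(r.pIC50),
            binding_affinity=float(r.binding_affinity),
        )
        for r in df.itertuples()
    ]
    return QSARDataset(records, [])
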