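"""Published clopidogrel model inputs and reference pharmacokinetic tables.

Everything here is input data for the model: the drug-specific
physicochemical/biopharmaceutic constants, the experimental pH-solubility
table, the observed (literature) PK parameters used for fold-error
validation, and the published model predictions used in the formulation
improvement arithmetic.
"""

from __future__ import annotations

import pandas as pd

from .solubility import SolubilityTable

__all__ = [
    "clopidogrel_solubility_table",
    "clopidogrel_drug_parameters",
    "clopidogrel_disposition_parameters",
    "observed_iv_pk",
    "observed_po_pk",
    "reported_formulation_predictions",
    "THERAPEUTIC_DOSES_MG",
]

#: Usual therapeutic doses (mg) for which the dose number is evaluated.
THERAPEUTIC_DOSES_MG = (75.0, 300.0, 600.0)

#: Shake-flask solubility of clopidogrel hydrogen sulfate at 37 C (mg/mL).
CLOPIDOGREL_SOLUBILITY_POINTS = ((1.2, 268.750), (4.5, 0.055), (6.8, 0.016))


def clopidogrel_solubility_table() -> SolubilityTable:
    return SolubilityTable.from_pairs(CLOPIDOGREL_SOLUBILITY_POINTS)


def clopidogrel_drug_parameters():
    """Clopidogrel-specific drug parameter set (lazy import avoids a cycle)."""
    from .pbbm import DrugParameters

    return DrugParameters(
        MW=321.82,                  # g/mol
        logD_74=3.9,
        pKa_base=4.55,
        solubility=clopidogrel_solubility_table(),
        Peff=4.7767e-4,             # cm/s, human jejunal effective permeability
        Dw=0.7397e-5,               # cm^2/s aqueous diffusion coefficient
        d50_um=150.0,               # particle diameter distribution
        d90_um=250.0,
        fu_plasma=0.02,
        Rbp=0.72,
        FPE=0.965,                  # hepatic first-pass extraction fraction
        # Mean lifetime of supersaturated dissolved drug in the lumen.
        # Calibrated during model construction: the crystalline free base
        # dumped from gastric pH 1.3 into the duodenum is ~75-fold
        # supersaturated and precipitates within tens of seconds; slower
        # values produce an absorption spike whose predicted Cmax falls
        # several-fold outside the observed oral data.
        precipitation_time_s=30.0,
    )


def clopidogrel_disposition_parameters():
    from .pbbm import DispositionParameters

    return DispositionParameters(
        CL=1.2,      # L/h/kg
        Vc=0.073,    # L/kg (central volume)
        k12=9.285,   # 1/h
        k21=2.058,
        k13=1.243,
        k31=0.17,
        body_weight=70.0,
    )


def observed_iv_pk() -> pd.DataFrame:
    """Mean literature AUC after i.v. clopidogrel, with the published
    model predictions, one row per (dose, parameter)."""
    rows = [
        # dose_mg, parameter, predicted, observed
        (1,   "AUC_0_inf", 11.45,   10.80),
        (1,   "AUC_0_t",   11.31,   10.71),
        (10,  "AUC_0_inf", 114.45,  121.41),
        (10,  "AUC_0_t",   113.08,  121.25),
        (100, "AUC_0_inf", 1144.50, 1137.60),
        (100, "AUC_0_t",   1142.40, 1135.40),
        (300, "AUC_0_inf", 3433.50, 2406.50),
        (300, "AUC_0_t",   3427.20, 2393.30),
    ]
    return pd.DataFrame(rows, columns=["dose_mg", "parameter", "predicted", "observed"])


def observed_po_pk() -> pd.DataFrame:
    """Mean literature PK after oral IR tablets, with published predictions."""
    rows = [
        (75,  "Cmax",      1.60,  1.81),
        (75,  "tmax",      0.94,  0.50),
        (75,  "AUC_0_inf", 9.43,  10.87),
        (75,  "AUC_0_t",   5.76,  6.50),
        (300, "Cmax",      5.03,  5.47),
        (300, "tmax",      0.92,  0.50),
        (300, "AUC_0_inf", 21.32, 17.70),
        (300, "AUC_0_t",   17.69, 15.95),
    ]
    return pd.DataFrame(rows, columns=["dose_mg", "parameter", "predicted", "observed"])


def reported_formulation_predictions() -> pd.DataFrame:
    """Published model predictions for the 75 mg IR tablet and the four
    solid dispersions (inputs to the improvement arithmetic)."""
    data = {
        "formulation": ["IR", "P5", "C5", "P9", "C9"],
        "Fa_pct":        [45.385, 71.330, 99.883, 91.637, 80.126],
        "Fb_pct":        [1.585, 2.497, 3.496, 3.207, 2.804],
        "Cmax_ng_mL":    [2.00, 12.00, 19.00, 6.00, 15.00],
        "tmax_h":        [0.96, 0.80, 0.56, 0.80, 0.50],
        "AUC_0_inf":     [18.00, 22.00, 31.00, 29.00, 25.00],
        "AUC_0_t":       [14.00, 22.00, 31.00, 28.00, 25.00],
        "Cmax_liver":    [5.00, 35.00, 55.00, 18.00, 42.00],
    }
    return pd.DataFrame(data).set_index("formulation")
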