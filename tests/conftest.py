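"""Shared fixtures: published HRMS reference rows and parent formulas.

The REFERENCE_ROWS constant mirrors the published sodium-adduct reference data for monensin A/B
and its twelve transformation products: (simulation method, compound id,
retention time s, printed calc. m/z, printed sodiated formula, printed
transformation shorthand, intensity class).
"""

import pytest

from tpscreen.chemcore import Formula

REFERENCE_ROWS = [
    ("Std", "MON A", 162, 693.4184, "C_36_H_62_O_11_Na", "-", "s"),
    ("Std", "MON B", 120, 679.4028, "C_35_H_60_O_11_Na", "-", "w"),
    ("EC-GC", "TP 1", 92, 619.3817, "C_33_H_56_O_9_Na", "-CO2 -2x CH2", "w"),
    ("EC-GC", "TP 2", 102, 665.4235, "C_35_H_62_O_10_Na",
     "-CO2 -2H +H2O", "w"),
    ("EC-GC, RLM", "TP 3", 109, 633.3973, "C_34_H_58_O_9_Na",
     "-CO2 -CH2", "s"),
    ("EC-GC", "TP 4", 132, 647.4130, "C_35_H_60_O_9_Na", "-CO2 -2H", "ms"),
    ("EC-GC", "TP 5", 133, 679.4392, "C_36_H_64_O_10_Na",
     "-CO2 -2H +OCH3 +H", "s"),
    ("EC-GC", "TP 6", 144, 679.4392, "C_36_H_64_O_10_Na",
     "-CO2 -2H +OCH3 +H", "ms"),
    ("EC-MD", "TP 7", 107, 707.4341, "C_37_H_64_O_11_Na", "+CH2", "vw"),
    # printed m/z of this row misses the electron-mass correction; see
    # test_acceptance.py::test_tp8_printed_value_is_uncorrected
    ("RLM", "TP 8", 79, 665.3877, "C_34_H_58_O_11_Na", "-2 CH2", "vw"),
    ("RLM", "TP 9", 95, 679.4028, "C_35_H_60_O_11_Na", "-CH2", "w"),
    ("Hyd", "TP 10", 75, 693.4184, "C_36_H_62_O_11_Na", "diastereomer", "s"),
    ("Hyd", "TP 11", 99, 693.4184, "C_36_H_62_O_11_Na", "ring cleavage",
     "ms"),
    ("Hyd", "TP 12", 86, 675.4079, "C_36_H_60_O_10_Na", "-H2O", "s"),
]

#: compound id -> parent assignment from the study's MS/MS evidence
#: (TP1 and TP8 derive from monensin B, all others from monensin A).
PARENT_OF = {
    "TP 1": "C35H60O11", "TP 8": "C35H60O11",
    **{f"TP {i}": "C36H62O11" for i in (2, 3, 4, 5, 6, 7, 9, 10, 11, 12)},
}


@pytest.fixture(scope="session")
def mon_a():
    return Formula.parse("C36H62O11")


@pytest.fixture(scope="session")
def mon_b():
    return Formula.parse("C35H60O11")


@pytest.fixture(scope="session")
def reference_rows():
    return REFERENCE_ROWS
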