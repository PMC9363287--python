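"""Built-in model descriptions for the biomarker panel.

The measurement structure groups the 13 serum markers into three
first-order factors (inflammation, oxidative stress, fibrosis) plus a
single-indicator myocardium factor; the structural model adds a
second-order inflammation/oxidative-stress factor, the observed
selenium/age quotient as exogenous input and directed paths onto
fibrosis and myocardium.
"""

INFLAMMATION = ("tnfr1", "tnfr2", "opg", "opn")
OXIDATIVE_STRESS = ("copeptin", "mrproadm")
FIBROSIS = ("endostatin", "galectin3", "timp1", "cathepsin_s", "gdf15",
            "mmp1")
MYOCARDIUM = ("ntprobnp",)

FACTOR_INDICATORS = {
    "inflammation": INFLAMMATION,
    "oxidative_stress": OXIDATIVE_STRESS,
    "fibrosis": FIBROSIS,
    "myocardium": MYOCARDIUM,
}

BIOMARKERS = INFLAMMATION + OXIDATIVE_STRESS + FIBROSIS + MYOCARDIUM


def cfa_model_text(include_myocardium: bool = False) -> str:
    """Three correlated first-order factors over 12 indicators (the
    single-indicator myocardium marker is excluded by default)."""
    lines = [
        "factor inflammation: " + " ".join(INFLAMMATION),
        "factor oxidative_stress: " + " ".join(OXIDATIVE_STRESS),
        "factor fibrosis: " + " ".join(FIBROSIS),
    ]
    if include_myocardium:
        lines.append("factor myocardium: ntprobnp fix_error=0")
    return "\n".join(lines) + "\n"


def structural_model_text() -> str:
    """Full second-order structural model: selenium/age quotient ->
    combined inflammation/oxidative-stress factor -> fibrosis and
    myocardium."""
    return "\n".join([
        "factor inflammation: " + " ".join(INFLAMMATION),
        "factor oxidative_stress: " + " ".join(OXIDATIVE_STRESS),
        "factor fibrosis: " + " ".join(FIBROSIS),
        "factor myocardium: ntprobnp fix_error=0",
        "second_order infl_ox: inflammation oxidative_stress",
        "observed_exogenous sel_age",
        "path sel_age -> infl_ox",
        "path infl_ox -> fibrosis",
        "path infl_ox -> myocardium",
    ]) + "\n"
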