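import pandas as pd
import pytest

import neodose as nd

#: ground-truth label fields mapped to the classification the review
#: procedure should produce; the independent oracle for classifier tests
_SITE_REASON = {
    "initial": "initial_dose_incorrect",
    "stale": "stale_dose_after_criteria_change",
    "pborder": "pborder_vs_eorder",
    "kardex": "kardex_not_updated",
    "pbmac": "pbmac_vs_emac",
}


def expected_from_labels(labels: pd.DataFrame) -> pd.DataFrame:
    """Translate simulator ground-truth labels into expected review verdicts."""
    rows = []
    for _, lab in labels.iterrows():
        if lab.injected_error == "none":
            rows.append(("no_error", "not_applicable", "none", "none"))
        elif lab.intercepted_by == "warning":
            rows.append(
                ("intercepted_by_warning", "prescription",
                 "initial_dose_incorrect", lab.subtype)
            )
        elif lab.intercepted_by == "provider":
            rows.append(
                ("intercepted_by_provider", "prescription",
                 _SITE_REASON[lab.injection_site], lab.subtype)
            )
        else:
            stage = "prescription" if lab.injected_error == "prescription" else "transcription"
            rows.append(
                ("nonintercepted", stage, _SITE_REASON[lab.injection_site], lab.subtype)
            )
    return pd.DataFrame(
        rows, columns=["interception", "stage", "reason", "subtype"]
    ).assign(ordered_medication_id=labels["ordered_medication_id"].values)


@pytest.fixture(scope="session")
def kb():
    return nd.load_kb()


@pytest.fixture(scope="session")
def poe_dataset():
    return nd.simulate_period(nd.default_config("POE", seed=11))


@pytest.fixture(scope="session")
def noe_dataset():
    return nd.simulate_period(nd.default_config("NOE", seed=12))


@pytest.fixture(scope="session")
def poe_classified(poe_dataset):
    return nd.classify_dataset(poe_dataset)


@pytest.fixture(scope="session")
def noe_classified(noe_dataset):
    return nd.classify_dataset(noe_dataset)


def null_config(mode: str, seed: int = 0, **overrides) -> nd.SimulationConfig:
    """A configuration injecting no errors anywhere in the chain."""
    return nd.default_config(
        mode,
        seed=seed,
        p_initial_prescription_error=0.0,
        p_stale_dose_error=0.0,
        p_transcription_error_per_hop=0.0,
        p_kardex_error=0.0,
        p_pbmac_error=0.0,
        **overrides,
    )


def make_chain_row(
    true=(10.0, 12), hand=None, eorder=None, kardex=None, pbmac=None, emac=None,
    line_id="L1",
):
    """A documentation-chain row for classifier unit tests; unspecified hops
    copy the electronic order."""
    eorder = eorder or true
    kardex = kardex or eorder
    pbmac = pbmac or kardex
    emac = emac or eorder
    row = {"ordered_medication_id": line_id}
    for prefix, pair in (
        ("true", true), ("hand", hand), ("eorder", eorder),
        ("kardex", kardex), ("pbmac", pbmac), ("emac", emac), ("admin", pbmac),
    ):
        row[f"{prefix}_dose"] = pair[0] if pair else float("nan")
        row[f"{prefix}_interval"] = pair[1] if pair else float("nan")
    return pd.Series(row)
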