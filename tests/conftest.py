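import pytest

from edflow.model import calibrate_service_times, load_default_config

# Table rows used throughout the suite: (mean, sd) minutes per subprocess.
OBSERVED_MOMENTS = {
    "registration": (14.0, 1.9),
    "triage": (17.0, 3.7),
    "assessment": (14.2, 4.5),
    "referral_to_medicine": (175.3, 38.1),
    "decision_to_admit": (525.5, 93.5),
    "room_allocation": (163.6, 28.8),
    "physical_transfer": (66.4, 12.2),
}

TOTAL_PET_MIN = 976.0

# Printed scenario means (minutes) from the published comparison table.
PRINTED_SCENARIO_MEANS = {
    "0": 976, "1": 970, "2": 965, "3": 967, "4": 907, "5": 781,
    "6": 712, "7": 947, "8": 952, "9": 849, "10": 586,
}


@pytest.fixture()
def default_config():
    return load_default_config()


@pytest.fixture(scope="session")
def calibrated_config():
    """Queueing-mode config with service multipliers fitted once per session."""
    cfg, report = calibrate_service_times(
        load_default_config(),
        tol=3.0,
        horizon_days=60.0,
        warmup_days=7.0,
        replications=3,
        master_seed=777,
    )
    assert all(entry["converged"] for entry in report.values())
    return cfg
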