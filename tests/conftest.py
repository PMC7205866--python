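import numpy as np
import pandas as pd
import pytest

from senescreen.simulate import ScreenSimConfig, simulate_screen


@pytest.fixture(scope="session")
def screen_data():
    """One default synthetic screen shared across tests (fixed seed)."""
    return simulate_screen(ScreenSimConfig(seed=1))


def make_plate(values_by_channel, plate_id="P1", n_controls=2):
    """Small handcrafted plate: first ``n_controls`` wells are non-targeting
    controls, the rest SMARTpool sample wells, one gene per sample well."""
    n = len(next(iter(values_by_channel.values())))
    rows = []
    for i in range(n):
        cls = "control_nontargeting" if i < n_controls else "smartpool"
        rows.append(
            dict(
                plate_id=plate_id,
                well=f"A{i + 1:02d}" if i < 24 else f"B{i - 23:02d}",
                reagent_id=f"r{i}",
                gene=None if i < n_controls else f"G{i:03d}",
                reagent_class=cls,
                duplex_index=None,
                seed_seq=None,
            )
        )
    plate = pd.DataFrame(rows)
    for ch, vals in values_by_channel.items():
        plate[ch] = np.asarray(vals, dtype=float)
    return plate


@pytest.fixture
def flat_plate():
    """Plate whose wells all share the control value on every channel except
    a configurable cell-count vector; EdU/area carry mild structure so MAD
    is non-zero."""

    def build(cell_counts, n_controls=2):
        n = len(cell_counts)
        base = np.linspace(90.0, 110.0, n)
        return make_plate(
            {
                "cell_count": cell_counts,
                "edu_intensity": base,
                "nuclear_area": base + 50.0,
            },
            n_controls=n_controls,
        )

    return build
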