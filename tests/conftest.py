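import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def occurrence_frame():
    """Small occurrence table with coordinate strings of varied precision."""
    rows = [
        ("Xerichthys sp001", 46.1, -99.4, "46.1", "-99.4"),
        ("Xerichthys sp002", 46.0, -99.4, "46", "-99.4"),
        ("Xerichthys sp003", 46.0, -99.432, "46", "-99.432"),
        ("Xerichthys sp004", 46.0, -99.4321, "46", "-99.4321"),
        ("Xerichthys sp005", 12.345, 100.1, "12.345", "100.1"),
        ("Xerichthys sp006", 0.0, 0.0, "abc", "0.0"),
    ]
    df = pd.DataFrame(rows, columns=["species", "lat", "lon",
                                     "lat_text", "lon_text"])
    df["date"] = "2000-06-15"
    df["source"] = "test"
    return df
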