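import numpy as np
import pandas as pd
import pytest

from panelroc import MarkerTable, SyntheticSpec, generate_two_class_table


@pytest.fixture
def tiny_table() -> MarkerTable:
    """4 samples x 3 markers, hand-written, labeled."""
    signals = pd.DataFrame(
        {
            "A": [5.0, 6.0, 1.0, 2.0],
            "B": [7.0, 4.0, 3.0, 0.5],
            "C": [2.0, 2.5, 2.0, 2.5],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="ID"),
    )
    classes = pd.Series(["case", "case", "ctrl", "ctrl"], index=signals.index)
    return MarkerTable(signals=signals, classes=classes,
                       case_label="case", control_label="ctrl")


@pytest.fixture
def labeled_csv(tmp_path):
    path = tmp_path / "table.csv"
    path.write_text(
        "ID,Class,M1,M2,M3,M4,M5\n"
        "p1,Disease,500,120,88,30,2\n"
        "p2,Disease,450,300,10,5,1\n"
        "p3,Ctrl,100,110,90,20,3\n"
        "p4,Ctrl,90,100,70,10,2\n"
    )
    return path


def random_table(rng: np.random.Generator, n_samples: int, n_markers: int) -> MarkerTable:
    """Random labeled table with integer-ish signals (ties on purpose)."""
    signals = pd.DataFrame(
        rng.integers(0, 12, size=(n_samples, n_markers)).astype(float),
        index=pd.Index([f"s{i}" for i in range(n_samples)], name="ID"),
        columns=[f"m{j}" for j in range(n_markers)],
    )
    n_case = max(1, n_samples // 2)
    classes = pd.Series(
        ["case"] * n_case + ["ctrl"] * (n_samples - n_case), index=signals.index
    )
    return MarkerTable(signals=signals, classes=classes,
                       case_label="case", control_label="ctrl")


@pytest.fixture
def planted_table():
    spec = SyntheticSpec(seed=7, effect_mode="complementary",
                         n_case=200, n_control=200)
    return generate_two_class_table(spec)
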