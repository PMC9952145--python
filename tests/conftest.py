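"""Shared fixtures: small synthetic cohorts and tabular stand-ins.

Everything is generated programmatically at session scope so the expensive
signal synthesis runs once per test session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ppgscreen import features, preprocess, synthgen
from ppgscreen.mlpipe import DEMOGRAPHIC_COLS, MEAN_COLS, VAR_COLS


@pytest.fixture(scope="session")
def healthy_morph() -> synthgen.BeatMorphology:
    return synthgen.BeatMorphology(
        systolic_amp=1.0,
        systolic_center=0.18,
        systolic_width=0.06,
        diastolic_amp=0.45,
        diastolic_center=0.44,
        diastolic_width=0.09,
        beat_period=0.85,
    )


@pytest.fixture(scope="session")
def systolic_only_morph() -> synthgen.BeatMorphology:
    return synthgen.BeatMorphology(
        systolic_amp=1.0,
        systolic_center=0.20,
        systolic_width=0.07,
        diastolic_amp=0.0,
        diastolic_center=0.50,
        diastolic_width=0.09,
        beat_period=0.90,
    )


@pytest.fixture(scope="session")
def small_cohort() -> synthgen.Cohort:
    """Noise-free two-subjects-per-class cohort, 30 s at 120 Hz."""
    cfg = synthgen.noise_free(
        synthgen.GeneratorConfig(
            n_per_class={k: 2 for k in synthgen.CLASS_LABELS},
            duration=30.0,
            seed=3,
        )
    )
    return synthgen.generate_cohort(cfg)


@pytest.fixture(scope="session")
def healthy_beats(small_cohort) -> list[preprocess.Beat]:
    """Segmented beats of the first healthy subject of the small cohort."""
    subject = small_cohort.subjects[0]
    filtered = preprocess.filter_record(subject.record)
    return preprocess.segment_beats(filtered)


def make_subject_table(
    n_per_class: dict[str, int], seed: int = 0, shift: float = 3.0
) -> pd.DataFrame:
    """A schema-complete subject-features table with class-shifted Gaussians.

    Stands in for a full signal-extraction run in tests that exercise only
    the tabular machinery (selection, CV, cascade).
    """
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for ci, (label, n) in enumerate(n_per_class.items()):
        for _ in range(n):
            row = {"subject_id": f"T{sid:04d}", "label": label}
            sid += 1
            for j, col in enumerate(MEAN_COLS + VAR_COLS + DEMOGRAPHIC_COLS):
                # the first few columns carry the class signal
                mu = shift * ci if j < 4 else 0.0
                row[col] = rng.normal(mu, 1.0)
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture()
def two_class_table() -> pd.DataFrame:
    return make_subject_table({"Healthy": 30, "ACS": 30}, seed=5)
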