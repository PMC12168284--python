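"""Shared fixtures: small synthetic cohorts and toy tables."""

import numpy as np
import pandas as pd
import pytest

import plaquestab as ps


@pytest.fixture(scope="session")
def cohort():
    """Default-condition cohort: group-specific drift SDs and anterior
    offsets with 25 subjects per group (the package's study conditions)."""
    cfg = ps.SimulationConfig(n_subjects_per_group=25, seed=1)
    return ps.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = ps.SimulationConfig(n_subjects_per_group=5, seed=7)
    return ps.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def phase_cohort():
    return ps.simulate_phase_cohort(n_teeth=60, seed=4)


@pytest.fixture()
def toy_table():
    """2 samples × 3 taxa toy count table."""
    return ps.FeatureTable(
        pd.DataFrame(
            [[5, 0, 3], [1, 2, 4]],
            index=["s1", "s2"],
            columns=["t1", "t2", "t3"],
        )
    )


def random_table(rng: np.random.Generator, n_samples: int = 5, n_taxa: int = 8):
    counts = rng.integers(0, 50, size=(n_samples, n_taxa))
    return ps.FeatureTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"t{j}" for j in range(n_taxa)],
        )
    )


def metadata_row(sample_id, subject, visit, fdi=11, hiv="HUU", tooth="H",
                 mouth="CF", dentition="permanent", **over):
    row = {
        "sample_id": sample_id,
        "subject_id": subject,
        "visit": visit,
        "hiv_status": hiv,
        "fdi_code": fdi,
        "dentition": dentition,
        "tooth_health": tooth,
        "mouth_health": mouth,
        "combined_health": f"{tooth}-{mouth}",
        "position": "anterior" if fdi % 10 <= 3 else "posterior",
        "jaw": "maxillary" if fdi // 10 in (1, 2, 5, 6) else "mandibular",
        "sex": "F",
        "age_years": 7.0,
        "cd4_count": 900,
        "collection_day": (visit - 1) * 180,
    }
    row.update(over)
    return row


def make_metadata(rows):
    return ps.SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))
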