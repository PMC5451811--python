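import numpy as np
import pandas as pd
import pytest

from fossilhab import (
    HabitatParams,
    SimulationConfig,
    Timescale,
    GeologicalStage,
)


@pytest.fixture
def write_csv(tmp_path):
    """Write a DataFrame (or list of dicts) to a temp CSV and return the path."""

    def _write(rows, name="table.csv", sep=","):
        df = pd.DataFrame(rows)
        path = tmp_path / name
        df.to_csv(path, sep=sep, index=False)
        return str(path)

    return _write


def occ_row(**kw):
    """One generic-dialect occurrence row with sensible defaults."""
    row = {
        "occurrence_id": "o1",
        "species_name": "Genus alpha",
        "taxon_group": "Urodela",
        "early_stage": "A",
        "late_stage": "A",
        "lithology": "claystone",
        "paleo_lng": 10.0,
        "paleo_lat": 20.0,
        "reference_id": "r1",
        "is_lagerstatte": False,
        "specimen_score": "",
        "source_db": "synthetic",
    }
    row.update(kw)
    return row


@pytest.fixture
def simple_stages():
    """Four contiguous 10-My stages, oldest (A) to youngest (D)."""
    return Timescale(
        [
            GeologicalStage("A", 0, 330.0, 320.0),
            GeologicalStage("B", 1, 320.0, 310.0),
            GeologicalStage("C", 2, 310.0, 300.0),
            GeologicalStage("D", 3, 300.0, 290.0),
        ]
    )


def two_habitat_config(
    seed, lentic_mean=3.0, lotic_mean=6.0, n_per_side=200, preservation=0.5
):
    """Lentic-vs-lotic simulation: one stagnant and one medium-velocity pool."""
    weights = {"other": 1.0}
    scores = (0.2, 0.2, 0.2, 0.2, 0.2)
    return SimulationConfig(
        seed=seed,
        habitats={
            "stagnant": HabitatParams(n_per_side, lentic_mean, preservation, weights, scores),
            "medium-velocity": HabitatParams(
                n_per_side, lotic_mean, preservation, weights, scores
            ),
        },
    )
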