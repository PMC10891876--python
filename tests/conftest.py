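"""Shared fixtures: registries, configs and small synthetic experiments."""

from __future__ import annotations

import numpy as np
import pytest

from cyanopept.classify import ClassifierConfig
from cyanopept.network import NetworkParams
from cyanopept.registry import default_registry
from cyanopept.synth import GeneratorConfig, StrainSpec, simulate_experiment


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def clf_config():
    return ClassifierConfig()


@pytest.fixture()
def net_params():
    return NetworkParams()


def two_strain_specs() -> list[StrainSpec]:
    """Compact two-strain design used by deconvolution/recovery tests."""
    return [
        StrainSpec(
            "strainA",
            {
                "cyanopeptolin": {"Thr": 4, "Lxx": 3},
                "microcystin": {None: 4},
                "anabaenopeptin": {"exo-Arg": 2, "exo-Trp": 2},
            },
            decoy_count=2,
        ),
        StrainSpec(
            "strainB",
            {
                "aeruginosin": {"Hpla-Phe": 3, "Hpla-Tyr": 2},
                "microviridin": {None: 4},
                "anabaenopeptin": {"exo-Apa": 2, "exo-Ahppa": 2},
            },
            decoy_count=2,
            chlorination_fraction=0.5,
        ),
    ]


@pytest.fixture(scope="session")
def clean_experiment():
    """Noise-free two-strain experiment with ESI redundancy and a blank."""
    config = GeneratorConfig(
        seed=11,
        ppm_sigma=0.0,
        noise_peaks_per_spectrum=0,
        adduct_prob=0.4,
        isotopologue_prob=0.5,
        n_media_features=3,
    )
    table, spectra, truth = simulate_experiment(two_strain_specs(), config)
    return table, spectra, truth, config
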