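"""Shared configuration for the analysis scripts.

The study emulates a chromatin-tracing experiment: 3,000 chromosome copies
of a freely-jointed 50-kb-resolution chain carrying three co-burst gene
pairs with a planted short-range coupling, plus live-cell allele tracks at
the TFF1 mobility.  Every script reads/writes under results/.
"""

from pathlib import Path

import numpy as np

from chromaburst import synthetic
from chromaburst.datatypes import CouplingFunction

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
DATA = RESULTS / "data"

SEED = 0
OMEGA_TRUE = CouplingFunction(np.array([0.3, 0.3, 0, 0, 0, 0, 0.0]))


def study_config(localization_sigma: float = 100.0) -> synthetic.SyntheticConfig:
    return synthetic.coburst_study_config(
        n_chromosomes=3000,
        omega_true=OMEGA_TRUE,
        localization_sigma=localization_sigma,
        rng_seed=SEED,
    )


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
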