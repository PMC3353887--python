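import numpy as np
import pandas as pd
import pytest

from orthotox.synthetic_data import SimConfig


@pytest.fixture
def small_sim() -> SimConfig:
    """A screen-in-miniature: fast enough for per-test use."""
    return SimConfig(n_yeast_genes=300, n_human_genes=300, planted_module_size=15,
                     n_core_all_agent=4, seed=11)


def make_survival_frame(
    lines: dict[str, dict[str, float]],
    agents=("MMS",),
    doses=(0.0, 1.0, 2.0),
    decay=1.1,
    n_replicates=3,
    cv=0.0,
    seeded=1000,
    pe=0.5,
    rng=None,
) -> pd.DataFrame:
    """Hand-rolled colony table independent of the package's generator.

    ``lines`` maps line name -> {"role": ..., <agent>: log2 shift}. Latent
    survival is exp2(-decay*dose + shift) at dose > 0, times log-normal
    noise of the given CV.
    """
    rng = rng or np.random.default_rng(0)
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    rows = []
    for line, spec in lines.items():
        role = spec.get("role", "test")
        for agent in agents:
            shift = float(spec.get(agent, 0.0))
            for dose in doses:
                latent = 2.0 ** (-decay * dose + (shift if dose > 0 else 0.0))
                for rep in range(1, n_replicates + 1):
                    noise = float(np.exp(rng.normal(0, sigma))) if sigma else 1.0
                    rel = min(latent * noise, 1.0)
                    colonies = max(int(round(seeded * pe * rel)), 0)
                    rows.append((line, agent, dose, rep, colonies, seeded, role))
    return pd.DataFrame(rows, columns=["line", "agent", "dose", "replicate",
                                       "colonies", "cells_seeded", "role"])
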