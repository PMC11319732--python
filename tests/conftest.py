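import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_landscape():
    """Small noise-free landscape with a planted 7-mer motif."""
    from epibind.synthetic import SyntheticLandscape

    return SyntheticLandscape(
        motif="PLEEVLN",
        match_energy=(0.6,) * 7,
        composition_coeffs={"W": 0.1},
        gain=1.0,
        noise_sigma=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_table():
    """Prepared binding table from a small noise-free abundant landscape."""
    from dataclasses import replace

    from epibind import pipeline

    preset = replace(
        pipeline.ABUNDANT,
        n_peptides=2500,
        n_spiked=250,
        spike_mutations=(0, 1, 1, 2, 2, 3, 3, 4),
        landscape=replace(pipeline.ABUNDANT.landscape, noise_sigma=0.0),
    )
    return pipeline.prepare_table(preset, 3)


class OracleEnsemble:
    """Ensemble stand-in whose predictions come from a supplied function
    of the peptide string (synthetic: bypasses network training so ranking
    and scan mechanics can be tested against exact expectations)."""

    def __init__(self, fn, n_conc=4, shifting=False):
        from epibind.model import ModelConfig

        self.fn = fn
        self.config = ModelConfig(shifting=shifting)
        self.models = [self]
        self.concentrations = (0.125, 0.5, 2.0, 8.0)
        self.n_conc = n_conc

    def _values(self, sequences):
        return np.array([self.fn(s) for s in sequences], dtype=float)

    composition_model = None

    def predict(self, sequences, add_composition_back=True):
        return self._values(sequences)

    def forward_tokens(self, tokens, group):
        return self.predict_tokens(tokens, group)

    def predict_tokens(self, tokens, group, sequences=None, add_composition_back=True):
        from epibind import encoding

        if sequences is None:
            texts = ["".join(encoding.TOKENS[i] for i in row) for row in tokens]
            sequences = []
            for t in texts:
                sequences.append(t[t.index("(") + 1 : t.index(")")])
            seen = {}
            uniq = []
            for g, s in zip(group, sequences):
                if g not in seen:
                    seen[g] = s
                    uniq.append(s)
            sequences = uniq
        return self._values(sequences)


@pytest.fixture
def oracle_ensemble_factory():
    return OracleEnsemble
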