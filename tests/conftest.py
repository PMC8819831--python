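import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def random_dot_bracket(rng, length, p=(0.3, 0.3, 0.4)):
    """Random valid dot-bracket: random symbols repaired to a balanced string."""
    raw = rng.choice(list("()."), size=length, p=p)
    keep = [True] * length
    stack = []
    for i, ch in enumerate(raw):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if stack:
                stack.pop()
            else:
                keep[i] = False
    for i in stack:
        keep[i] = False
    return "".join(ch if k else "." for ch, k in zip(raw, keep))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_split():
    """A small synthetic dataset shared by cheap tests."""
    from mircleave import SynthConfig, generate_dataset

    return generate_dataset(SynthConfig(n_records=60, seed=5))


@pytest.fixture(scope="session")
def tiny_model(small_split):
    """A tiny briefly trained model (not accurate; structurally valid)."""
    from mircleave import ModelConfig
    from mircleave.workflows import train_replicates

    cfg = ModelConfig(
        input_mode="seq_bprna",
        embedding_dim=8,
        dropout=0.0,
        lstm1_units=12,
        lstm2_units=0,
        learning_rate=3e-3,
        epsilon_exp=-7.0,
        max_epochs=2,
        patience=5,
        seed=3,
    )
    models, _ = train_replicates(
        small_split.train, small_split.validation, cfg, n_replicates=1, seed=3
    )
    return models[0]
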