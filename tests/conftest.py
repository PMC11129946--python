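import numpy as np
import pandas as pd
import pytest

from apf2 import (
    Direction,
    LabeledVariantSet,
    ScoreTable,
    Strictness,
    VariantKey,
    default_config,
    simulate_labeled_scores,
)


@pytest.fixture(scope="session")
def study_data():
    """Simulated combined fitting set at study-condition defaults."""
    cfg = default_config(seed=11)
    table, labels = simulate_labeled_scores(cfg)
    return cfg, table, labels


@pytest.fixture
def tiny_table():
    """Four variants, two algorithms, one missing cell."""
    variants = [
        VariantKey(gene="CYP2C9", protein_change=f"p.A{i}V") for i in range(4)
    ]
    scores = pd.DataFrame(
        {
            "SIFT": [0.01, 0.05, 0.8, np.nan],
            "CADD": [25.0, 15.0, 3.0, 30.0],
        },
        index=pd.Index([v.id for v in variants], name="variant"),
    )
    return ScoreTable(variants, scores)


@pytest.fixture
def tiny_labels(tiny_table):
    return LabeledVariantSet(
        list(tiny_table.variants),
        ["deleterious", "deleterious", "neutral", "neutral"],
    )


# ---------------------------------------------------------------------------
# Independent oracles (kept free of the implementation paths they check)
# ---------------------------------------------------------------------------


def deleterious_calls_oracle(scores, threshold, direction, strictness):
    """Literal translation of a printed cutoff operator."""
    s = np.asarray(scores, dtype=float)
    if direction is Direction.DELETERIOUS_IF_HIGH:
        return s >= threshold if strictness is Strictness.NON_STRICT else s > threshold
    return s <= threshold if strictness is Strictness.NON_STRICT else s < threshold


def youden_oracle(scores, truth, threshold, direction, strictness):
    """J = SEN + SPE - 1 at one cutoff, by direct counting."""
    calls = deleterious_calls_oracle(scores, threshold, direction, strictness)
    truth = np.asarray(truth, dtype=bool)
    sen = calls[truth].mean()
    spe = (~calls[~truth]).mean()
    return sen + spe - 1


def exhaustive_best_threshold(scores, truth, direction, strictness, candidates):
    """Scan every candidate; return (best_J, set of argmax candidates)."""
    js = np.array(
        [youden_oracle(scores, truth, t, direction, strictness) for t in candidates]
    )
    best = js.max()
    return best, np.asarray(candidates)[js >= best - 1e-12]


def concordance_auc_oracle(scores, truth, direction):
    """Pairwise Mann-Whitney concordance, ties counting one half."""
    s = np.asarray(scores, dtype=float)
    if direction is Direction.DELETERIOUS_IF_LOW:
        s = -s
    truth = np.asarray(truth, dtype=bool)
    d, n = s[truth], s[~truth]
    diff = d[:, None] - n[None, :]
    return ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size
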