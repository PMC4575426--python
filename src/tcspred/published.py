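"""Published benchmark scores consumed as data.

The T set is a small experimentally characterised benchmark of 21
*Caulobacter crescentus* HK-RR pairs (16 interacting, 5 non-interacting)
for which two published predictors -- a Bayesian network-reconstruction
approach and an SVM meta-predictor -- reported per-pair scores.  Those printed
scores are bundled here so the evaluation stack (AUC, head-to-head
comparison) can be exercised against real published numbers without any
external download; the scores are inputs, never recomputed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_t_set_scores() -> pd.DataFrame:
    """Per-pair published scores on the C. crescentus T set.

    Columns: ``hk_id, rr_id, label, bayesian, meta`` with scores in
    [0, 1]; labels are ``interacting`` / ``non-interacting``.
    """
    with resources.files("tcspred.data").joinpath("t_set_scores.csv").open() as fh:
        df = pd.read_csv(fh)
    df["y"] = (df["label"] == "interacting").astype(int)
    return df


def head_to_head(df: pd.DataFrame) -> dict[str, int]:
    """Count, pair by pair, which predictor is closer to the truth: for
    an interacting pair the higher score wins, for a non-interacting pair
    the lower one; equal scores tie."""
    meta = bayes = tie = 0
    for _, row in df.iterrows():
        a, b = row["meta"], row["bayesian"]
        better = (a > b) if row["y"] == 1 else (a < b)
        if a == b:
            tie += 1
        elif better:
            meta += 1
        else:
            bayes += 1
    return {"meta": meta, "bayesian": bayes, "tie": tie}
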