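"""Shared test helpers: synthetic coherence tensors and feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from nclnet.coherence import CoherenceTensor, plan_windows
from nclnet.netfeatures import FEATURE_COLUMNS
from nclnet.preprocess import BAND_BY_NAME


def make_tensor(values: np.ndarray, band_name: str = "beta", subject_id: str = "bird0"):
    """Wrap raw (trials, windows, n, n) values in a CoherenceTensor."""
    n_windows = values.shape[1]
    # synthetic plan: first half pre, second half post
    plan = plan_windows(
        256 + (n_windows - 1) * 128, 256, 128, event_sample=(256 + (n_windows - 1) * 128) // 2
    )
    assert plan.n_windows == n_windows
    return CoherenceTensor(
        subject_id=subject_id,
        band=BAND_BY_NAME[band_name],
        values=values,
        window_plan=plan,
    )


def make_feature_table(
    n_subjects: int = 1,
    n_trials: int = 60,
    n_windows_per_condition: int = 7,
    band: str = "beta",
    seed: int = 0,
    post_kbar_shift: float = 0.0,
) -> pd.DataFrame:
    """Random tidy feature table with the pipeline's schema."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for t in range(n_trials):
            for w in range(2 * n_windows_per_condition):
                condition = "pre" if w < n_windows_per_condition else "post"
                shift = post_kbar_shift if condition == "post" else 0.0
                rows.append(
                    (
                        f"bird{s}",
                        band,
                        t,
                        w,
                        condition,
                        rng.normal(5.0 + shift, 1.0),
                        rng.normal(0.3, 0.05),
                    )
                )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
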