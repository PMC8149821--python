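"""Group-comparison convenience statistics."""

from __future__ import annotations

import numpy as np
from scipy.stats import mannwhitneyu


def compare_groups(values_a, values_b) -> float:
    """Two-sided Mann-Whitney rank-sum p-value.

    Thin wrapper over the standard implementation: exact for small
    tie-free samples, normal approximation with tie correction otherwise.
    No multiple-testing correction is applied.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    return float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
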