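"""Background-subtracted signal quantification and downstream summary tests.

Band and image signals are quantified from two nested boxes drawn around the
feature: an inner box S containing mainly the feature and a larger box L
containing the feature plus surrounding background.  With I and N the total
pixel intensity and pixel count of a box, the signal over background is

    I_S - N_S * (I_L - I_S) / (N_L - N_S)

i.e. the inner total minus the inner area scaled by the per-pixel intensity
of the surrounding ring.  A constant per-pixel background is removed exactly
by this estimator, for any box sizes with N_L > N_S.

Group comparisons use the two-sided Wilcoxon rank-sum test on per-subject
intensities (medians reported, with the percent change of medians) and the
two-sided Fisher exact test on 2x2 bi-/mono-orientation counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class BoxMeasurement:
    """Totals of the inner (S) and larger (L) quantification boxes."""

    i_s: float
    n_s: int
    i_l: float
    n_l: int

    def validate(self) -> None:
        if self.n_s <= 0:
            raise ValueError(f"inner box pixel count must be > 0, got {self.n_s}")
        if self.n_l <= self.n_s:
            raise ValueError(
                f"larger box must contain more pixels than the inner box "
                f"(N_L={self.n_l}, N_S={self.n_s})"
            )
        if self.i_s < 0 or self.i_l < 0:
            raise ValueError("box intensities must be >= 0")
        if self.i_l < self.i_s:
            raise ValueError(f"I_L ({self.i_l}) must be >= I_S ({self.i_s})")


def background_subtract(box: BoxMeasurement) -> float:
    """Signal over background: ``I_S - N_S * (I_L - I_S) / (N_L - N_S)``.

    May be negative when the ring is brighter per pixel than the inner box;
    the value is returned as-is (callers may flag it).
    """
    box.validate()
    ring_per_pixel = (box.i_l - box.i_s) / (box.n_l - box.n_s)
    return box.i_s - box.n_s * ring_per_pixel


def normalize_pulldown(
    bands: pd.DataFrame, reference_label: str
) -> pd.DataFrame:
    """Normalise band signals to a reference band within each experiment.

    ``bands`` needs columns ``label``, ``signal`` and ``experiment``; each
    band's background-subtracted signal is divided by the reference band's
    signal from the same experiment.  A missing or non-positive reference
    is an error.
    """
    out = bands.copy()
    out["normalized"] = np.nan
    for experiment, group in bands.groupby("experiment"):
        ref = group.loc[group["label"] == reference_label, "signal"]
        if ref.empty:
            raise ValueError(f"reference {reference_label!r} missing in experiment {experiment!r}")
        ref_value = float(ref.iloc[0])
        if ref_value <= 0:
            raise ValueError(
                f"reference signal must be > 0, got {ref_value} in experiment {experiment!r}"
            )
        out.loc[group.index, "normalized"] = group["signal"] / ref_value
    return out


def compare_intensities(
    group_a: np.ndarray | list[float], group_b: np.ndarray | list[float]
) -> tuple[float, float, float, float]:
    """Median comparison of two intensity groups with a rank-sum test.

    Returns ``(median_a, median_b, percent_change, p)`` where
    ``percent_change = 100 * (median_a - median_b) / median_a`` (a positive
    value is the percent reduction of B relative to A).  The two-sided
    Wilcoxon rank-sum p-value is exact for small tie-free samples and
    normal-approximated with tie correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    median_a, median_b = float(np.median(a)), float(np.median(b))
    if median_a == 0:
        raise ValueError("median of group A is 0; percent change undefined")
    percent_change = 100.0 * (median_a - median_b) / median_a
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)
    return median_a, median_b, percent_change, p


def biorientation_test(counts: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Mono-orientation frequencies per genotype and a Fisher exact p-value.

    ``counts`` is a 2x2 frame indexed by genotype with columns
    ``bioriented`` and ``monooriented``.  Returns per-genotype totals and
    mono frequencies plus the two-sided Fisher p.
    """
    if set(counts.columns) != {"bioriented", "monooriented"} or len(counts) != 2:
        raise ValueError("counts must be 2 genotypes x [bioriented, monooriented]")
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("each genotype needs at least one oocyte")
    freq = counts["monooriented"] / totals
    table = counts[["bioriented", "monooriented"]].to_numpy()
    p = float(stats.fisher_exact(table).pvalue)
    summary = pd.DataFrame(
        {
            "n": totals,
            "n_monooriented": counts["monooriented"],
            "mono_frequency": freq,
        }
    )
    return summary, p
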