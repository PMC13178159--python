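"""Published cohort-level descriptive statistics used as pooling inputs.

These are the printed per-cohort descriptives (mean (SD) or %) of the four
Framingham Heart Study cohorts in the motivating DHA / APOE-ε4 analysis —
Offspring (n=1201), Generation 3 (n=778), Omni 1 (n=135), Omni 2 (n=44) —
together with the printed all-cohorts column.  They serve two purposes:
calibrating the synthetic generator, and exercising exact pooling on real
published numbers (the pooled column is recomputable from the cohort rows).

Values are stored as printed, i.e. rounded; ``half_ulp`` captures each
entry's print precision so error propagation through the pooled weighted
mean can be bounded honestly (a pooled value recomputed from rounded
inputs can differ from the printed pooled value by up to the propagated
input rounding plus half a ULP of the output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pooling import pool_summaries
from .summary import SummarySet

COHORT_LABELS = ("Offspring", "Gen3", "Omni1", "Omni2")
COHORT_SIZES = (1201, 778, 135, 44)
POOLED_N = 2158


def _half_ulp(text: str) -> float:
    """Half of the last printed decimal place of a number-as-printed."""
    if "." in text:
        return 0.5 * 10.0 ** -(len(text.split(".")[1]))
    return 0.5


@dataclass
class MeanSdRow:
    """A 'mean (SD)' descriptive row: four cohort entries plus pooled."""

    name: str
    cohort_means: tuple[str, ...]
    cohort_sds: tuple[str, ...]
    pooled_mean: str
    pooled_sd: str

    def summary_sets(self) -> list[SummarySet]:
        return [
            SummarySet(
                [self.name], [float(m)], [[float(sd) ** 2]], n, cohort_label=lab
            )
            for m, sd, n, lab in zip(
                self.cohort_means, self.cohort_sds, COHORT_SIZES, COHORT_LABELS
            )
        ]

    def pooled(self) -> tuple[float, float]:
        s = pool_summaries(self.summary_sets()).summary
        return float(s.means[0]), float(np.sqrt(s.cov[0, 0]))

    def tolerance_mean(self) -> float:
        """Propagated input rounding + half a ULP of the printed pooled mean."""
        w = np.array(COHORT_SIZES) / POOLED_N
        return float(
            w @ [_half_ulp(m) for m in self.cohort_means]
        ) + _half_ulp(self.pooled_mean)


@dataclass
class PercentRow:
    """A percent descriptive row (Bernoulli variable, printed as %)."""

    name: str
    cohort_pcts: tuple[str, ...]
    pooled_pct: str

    def pooled(self) -> float:
        w = np.array(COHORT_SIZES, dtype=float)
        return float(w @ [float(p) for p in self.cohort_pcts] / w.sum())

    def tolerance(self) -> float:
        w = np.array(COHORT_SIZES) / POOLED_N
        return float(
            w @ [_half_ulp(p) for p in self.cohort_pcts]
        ) + _half_ulp(self.pooled_pct)


MEAN_SD_ROWS = [
    MeanSdRow("age", ("61.5", "55.0", "58.8", "57.4"),
              ("4.8", "4.1", "5.4", "5.5"), "58.9", "5.5"),
    MeanSdRow("bmi", ("28.4", "28.9", "28.7", "26.4"),
              ("5.5", "6.0", "5.3", "4.4"), "28.6", "5.7"),
    MeanSdRow("alcohol_drinks_per_week", ("5.1", "5.5", "2.7", "2.7"),
              ("7.3", "7.9", "5.1", "4.0"), "5.0", "7.4"),
    MeanSdRow("exercise_met_hours", ("268.7", "265.4", "257.5", "258.9"),
              ("97.1", "113.8", "92.6", "100.6"), "266.6", "103.2"),
    MeanSdRow("dha_pct_total_fa", ("4.8", "4.4", "5.2", "5.1"),
              ("1.4", "1.3", "1.4", "1.0"), "4.7", "1.4"),
    MeanSdRow("trails_b_minus_a_min", ("0.9", "0.7", "1.3", "0.9"),
              ("0.9", "0.5", "1.3", "0.7"), "0.8", "0.8"),
    MeanSdRow("years_fa_to_tmt", ("0.2", "1.6", "-0.2", "2.4"),
              ("1.5", "1.0", "1.1", "1.1"), "0.8", "1.5"),
]

PERCENT_ROWS = [
    PercentRow("sex_female", ("55", "51.8", "64.4", "47.7"), "54.3"),
    PercentRow("apoe4_carrier", ("27.6", "26.2", "21.5", "13.6"), "26.5"),
    PercentRow("cholesterol_medication", ("41", "28.3", "43", "29.5"), "36.3"),
    PercentRow("hypertension_medication", ("41.7", "27.5", "45.2", "34.1"), "36.7"),
    PercentRow("diabetes", ("10.2", "10.4", "20", "15.9"), "11"),
    PercentRow("cardiovascular_disease", ("9.3", "4.2", "9.6", "4.5"), "7.4"),
]
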