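"""Reference fall-risk labeling from clinical scores.

Tinetti: scores below the cutoff (default 21) mean high risk; the best of
up to three TUG trials at or above the cutoff (default 13.5 s) means high
risk. When the two instruments disagree the resolution rule assumes risk
(high wins).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

LOW, HIGH = "low", "high"


@dataclass(frozen=True)
class LabelingConfig:
    tinetti_cutoff: int = 21
    tug_cutoff: float = 13.5
    resolution: str = "high_wins"

    def __post_init__(self):
        if self.tinetti_cutoff <= 0 or self.tug_cutoff <= 0:
            raise ValueError("cutoffs must be > 0")
        if self.resolution != "high_wins":
            raise ValueError(f"unknown resolution rule {self.resolution!r}")


@dataclass(frozen=True)
class RiskLabel:
    value: str    # "low" | "high"
    source: str   # "tinetti" | "tug" | "resolved"


def tinetti_label(score: int, config: LabelingConfig = LabelingConfig()) -> RiskLabel:
    """High risk iff the Tinetti score is strictly below the cutoff."""
    if not 0 <= score <= 28:
        raise ValueError(f"Tinetti score {score} out of range 0..28")
    return RiskLabel(HIGH if score < config.tinetti_cutoff else LOW, "tinetti")


def tug_label(trials, config: LabelingConfig = LabelingConfig()) -> RiskLabel:
    """High risk iff the fastest TUG trial is at or above the cutoff."""
    trials = [float(t) for t in (trials if hasattr(trials, "__len__") else [trials])]
    if not 1 <= len(trials) <= 3:
        raise ValueError("between 1 and 3 TUG trials required")
    if any(t <= 0 for t in trials):
        raise ValueError("TUG times must be > 0")
    return RiskLabel(HIGH if min(trials) >= config.tug_cutoff else LOW, "tug")


def resolve(tinetti: RiskLabel, tug: RiskLabel) -> RiskLabel:
    """Combine the two instrument labels: high if either is high."""
    value = HIGH if HIGH in (tinetti.value, tug.value) else LOW
    source = "resolved" if tinetti.value != tug.value else "tinetti"
    return RiskLabel(value, source)


def label_subject(profile, config: LabelingConfig = LabelingConfig(),
                  use_fall_history: bool = False) -> RiskLabel:
    """Label one subject profile; optionally let a documented fall history
    force high risk (off by default)."""
    label = resolve(tinetti_label(profile.tinetti_score, config),
                    tug_label(profile.tug_trials, config))
    if use_fall_history and getattr(profile, "fell_before", False) and label.value == LOW:
        return RiskLabel(HIGH, "resolved")
    return label


def label_cohort(profiles, config: LabelingConfig = LabelingConfig(),
                 use_fall_history: bool = False) -> pd.DataFrame:
    """Labels for every subject: DataFrame with columns label, source."""
    rows = {}
    for p in profiles:
        try:
            lab = label_subject(p, config, use_fall_history)
            rows[p.subject_id] = {"label": lab.value, "source": lab.source}
        except (ValueError, TypeError):
            rows[p.subject_id] = {"label": "missing", "source": "missing"}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df


def tug_cutoff_sweep(profiles, lo: float, hi: float, step: float = 0.1,
                     config: LabelingConfig = LabelingConfig()) -> bool:
    """True iff every TUG cutoff in [lo, hi] (grid of `step`) yields the same
    cohort labeling as `config` does."""
    import numpy as np
    ref = label_cohort(profiles, config)["label"]
    for cutoff in np.arange(lo, hi + step / 2, step):
        alt = LabelingConfig(tinetti_cutoff=config.tinetti_cutoff,
                             tug_cutoff=float(cutoff))
        if not label_cohort(profiles, alt)["label"].equals(ref):
            return False
    return True
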