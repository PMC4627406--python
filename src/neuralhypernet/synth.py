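"""Synthetic pulmonary-embolism cohorts.

The generator emulates the statistical structure the downstream pipeline
assumes, without any access to the clinical data: a table of 28 columns
(one row per patient), a binary final diagnosis with an exactly enforced
prevalence, continuous and boolean indicators whose probability of falling
in the risk range depends on the diagnosis through a per-variable log-odds
shift, and missing-not-at-random (MNAR) masking — an entry's chance of being
missing is inflated when its own realized value lies in the non-risk range,
mimicking clinicians not recording unremarkable findings.

Continuous indicators are drawn from class-conditional normals whose means
are placed so that the probability mass beyond the variable's risk threshold
equals the configured crossing probability; count indicators (numbers of
predictive/risk factors) are zero-inflated Poisson; symptom flags are
Bernoulli.  Default missingness rates follow the per-variable pattern of the
clinical cohort (about 24 % of entries missing overall, ranging from none on
the diagnosis to ~86 % on pulmonary artery pressure).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .schema import (
    ALL_COLUMNS,
    BOOLEAN_VARIABLES,
    ID_COLUMN,
    LABEL_COLUMN,
    MISSING_SENTINEL,
)

__all__ = ["SyntheticConfig", "generate_cohort", "write_cohort", "read_cohort"]

#: Per-variable missingness rates patterned on the clinical cohort.
DEFAULT_MISSING_RATES: dict[str, float] = {
    "Age": 0.0007,
    "N_F_Pred": 0.0664,
    "N_F_Risk": 0.0755,
    "Previous DVT": 0.3427,
    "Palpitations": 0.1371,
    "Cough": 0.1287,
    "dDimer": 0.0776,
    "PAS": 0.1133,
    "PAD": 0.3818,
    "FC": 0.0406,
    "PAPS": 0.8580,
    "WBC": 0.0266,
    "Cancer at diagnosis": 0.4685,
    "Troponin": 0.3993,
    "Shockindex": 0.1189,
    "Cancer": 0.4671,
    "RVD": 0.6028,
    "Wells score": 0.3580,
    "Revised Geneva score": 0.0,
    "Wicki score": 0.4650,
    "Dyspnea": 0.1301,
    "Chest pain": 0.1287,
    "PCO2": 0.1692,
    "PO2": 0.1664,
    "PH": 0.4035,
    "Hemoptysis": 0.3427,
}

#: Baseline probability that a variable's value lies in its risk range
#: (the vertex descriptor) for a patient without pulmonary embolism.
BASELINE_CROSSING: dict[str, float] = {
    "Age": 0.50,
    "N_F_Pred": 0.45,
    "N_F_Risk": 0.45,
    "Previous DVT": 0.15,
    "Palpitations": 0.25,
    "Cough": 0.30,
    "dDimer": 0.55,
    "FC": 0.25,
    "WBC": 0.30,
    "Cancer at diagnosis": 0.15,
    "Shockindex": 0.20,
    "Cancer": 0.15,
    "RVD": 0.20,
    "Dyspnea": 0.50,
    "Chest pain": 0.35,
    "PCO2": 0.25,
    "PO2": 0.55,
    "PH": 0.30,
    "Hemoptysis": 0.08,
}

#: Default log-odds shift of the risk-range probability for a positive
#: diagnosis; the classic presentation of pulmonary embolism (elevated
#: d-dimer, dyspnea, tachycardia, prior deep-vein thrombosis...).
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "dDimer": 2.0,
    "Dyspnea": 1.0,
    "Previous DVT": 1.0,
    "FC": 0.8,
    "Age": 0.6,
    "Shockindex": 0.8,
    "RVD": 0.8,
    "Hemoptysis": 0.8,
    "Chest pain": 0.5,
}

# (risk threshold on the latent value, latent standard deviation, integer?)
# The threshold is the point the class-conditional normal mean is anchored
# to; for integer-valued indicators it sits at the half-step so rounding
# preserves the configured crossing probability.
_CONTINUOUS: dict[str, tuple[float, float, bool]] = {
    "Age": (64.5, 12.0, True),
    "dDimer": (230.0, 150.0, False),
    "FC": (99.5, 15.0, True),
    "WBC": (9999.5, 2500.0, True),
    "Shockindex": (0.9, 0.18, False),
    "PCO2": (45.0, 3.5, False),
    "PO2": (60.0, 12.0, False),
    "PH": (7.42, 0.05, False),
}

_COUNT_VARIABLES = ("N_F_Pred", "N_F_Risk")

#: The canonical presentation of pulmonary embolism: the descriptor polarity
#: each variable takes when a positive patient presents "typically" (elderly,
#: elevated d-dimer, tachycardic and dyspneic, without cough, chest pain,
#: hemoptysis, palpitations, shock or a previous DVT, oxygen tension kept
#: above 60 mmHg).  Co-presentation is what makes these descriptors pairwise
#: share large patient sets and form a stable high-dimensional backcloth.
PRESENTATION_POLARITY: dict[str, int] = {
    "Age": 1,
    "Cough": 0,
    "Shockindex": 0,
    "PO2": 1,
    "Previous DVT": 0,
    "Palpitations": 0,
    "dDimer": 1,
    "FC": 1,
    "Dyspnea": 1,
    "Chest pain": 0,
    "Hemoptysis": 0,
}

# Discarded columns carry no planted effect; plausible marginals only.
_NUISANCE_NORMALS: dict[str, tuple[float, float, bool]] = {
    "PAS": (125.0, 20.0, True),
    "PAD": (75.0, 12.0, True),
    "PAPS": (35.0, 12.0, True),
    "Wells score": (4.0, 2.5, False),
    "Revised Geneva score": (8.0, 4.0, True),
    "Wicki score": (6.0, 3.0, True),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Parameters
    ----------
    n_patients : int
        Cohort size (the clinical cohort held 1427 patients).
    prevalence : float
        Fraction of positive final diagnoses, enforced as an exact rounded
        count (0.58 in the clinical cohort after CT-angiography).
    missing_rates : dict
        Variable name -> probability that an entry is masked.  Defaults to
        the clinical cohort's per-variable pattern.
    effect_sizes : dict
        Variable name -> log-odds shift of the risk-range probability given
        a positive diagnosis.
    mnar_boost : float
        Multiplier (>= 1) on a variable's missing rate when its realized
        value lies in the non-risk range.
    presentation_rate : float
        Probability that a positive patient exhibits the canonical
        co-presentation (all :data:`PRESENTATION_POLARITY` polarities at
        once, before masking).  This correlation is what carves a stable
        mid-q backcloth out of the complex.
    presentation_rate_negative : float
        Same, for patients whose embolism is ruled out.  The cohort is
        emergency-room pre-screened — negatives were admitted because they
        too looked like PE — so their rate is high as well; equal rates make
        the backcloth carry no label signal at all.
    seed : int
        Seed for the single random generator; generation is bit-reproducible.
    """

    n_patients: int = 1427
    prevalence: float = 0.58
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES)
    )
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    mnar_boost: float = 1.5
    presentation_rate: float = 0.75
    presentation_rate_negative: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 1:
            raise ValueError(f"n_patients must be a positive integer, got {self.n_patients!r}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must lie in [0, 1], got {self.prevalence!r}")
        for name, rate in self.missing_rates.items():
            if name not in ALL_COLUMNS or name in (ID_COLUMN, LABEL_COLUMN):
                raise ValueError(f"missing_rates: unknown or unmaskable variable {name!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing_rates[{name!r}] must lie in [0, 1], got {rate!r}")
        for name in self.effect_sizes:
            if name not in BASELINE_CROSSING:
                raise ValueError(f"effect_sizes: unknown variable {name!r}")
        if self.mnar_boost < 1.0:
            raise ValueError(f"mnar_boost must be >= 1, got {self.mnar_boost!r}")
        if not 0.0 <= self.presentation_rate <= 1.0:
            raise ValueError(
                f"presentation_rate must lie in [0, 1], got {self.presentation_rate!r}"
            )
        if not 0.0 <= self.presentation_rate_negative <= 1.0:
            raise ValueError(
                f"presentation_rate_negative must lie in [0, 1], "
                f"got {self.presentation_rate_negative!r}"
            )
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


def _crossing_probability(variable: str, labels: np.ndarray, effects: dict[str, float]) -> np.ndarray:
    p0 = BASELINE_CROSSING[variable]
    beta = effects.get(variable, 0.0)
    return expit(logit(p0) + beta * labels)


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Draw one cohort table under *config*.

    Returns a DataFrame with the 28 canonical columns; masked entries are
    ``NaN`` floats (serialized as the literal string ``NaN``).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    n_pos = int(round(config.prevalence * n))
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    cols: dict[str, np.ndarray] = {}
    cols[ID_COLUMN] = np.array([f"P{i + 1:04d}" for i in range(n)], dtype=object)

    for variable in BOOLEAN_VARIABLES + _COUNT_VARIABLES:
        p = _crossing_probability(variable, labels, config.effect_sizes)
        crossed = rng.random(n) < p
        if variable in _COUNT_VARIABLES:
            cols[variable] = np.where(crossed, 1 + rng.poisson(0.7, size=n), 0).astype(float)
        else:
            cols[variable] = crossed.astype(float)

    for variable, (threshold, sigma, integer) in _CONTINUOUS.items():
        p = _crossing_probability(variable, labels, config.effect_sizes)
        # mean chosen so P(value > threshold) = p for each patient's class
        mean = threshold - sigma * norm.ppf(1.0 - p)
        values = rng.normal(mean, sigma)
        cols[variable] = np.round(values) if integer else values

    for variable, (mean, sigma, integer) in _NUISANCE_NORMALS.items():
        values = rng.normal(mean, sigma, size=n)
        cols[variable] = np.clip(np.round(values) if integer else values, 0.0, None)

    cols["Troponin"] = np.abs(rng.normal(0.05, 0.08, size=n))
    cols[LABEL_COLUMN] = labels.astype(float)

    if config.presentation_rate > 0.0 or config.presentation_rate_negative > 0.0:
        rate = np.where(labels == 1, config.presentation_rate, config.presentation_rate_negative)
        typical = rng.random(n) < rate
        for variable, polarity in PRESENTATION_POLARITY.items():
            values = cols[variable]
            if variable in _CONTINUOUS:
                threshold, _, integer = _CONTINUOUS[variable]
                above = values > threshold
                # reflect wrong-side values across the threshold so the
                # conditional shape is preserved
                wrong = typical & (above != bool(polarity))
                values = np.where(wrong, 2.0 * threshold - values, values)
                cols[variable] = np.round(values) if integer else values
            else:
                cols[variable] = np.where(typical, float(polarity), values)

    df = pd.DataFrame({c: cols[c] for c in ALL_COLUMNS})

    from .thresholds import load_threshold_map  # deferred: avoids import cycle

    tmap = load_threshold_map()
    for variable, rate in config.missing_rates.items():
        if rate == 0.0:
            continue
        p_miss = np.full(n, rate)
        if config.mnar_boost > 1.0 and variable in tmap:
            # MNAR: unremarkable (non-risk) values go unrecorded more often,
            # with the per-variable marginal rate preserved.
            anti = tmap[variable][0]
            in_nonrisk = df[variable].map(lambda v: bool(anti.contains(v))).to_numpy()
            f = in_nonrisk.mean()
            p_risk = rate / (f * config.mnar_boost + (1.0 - f))
            p_miss = np.clip(
                np.where(in_nonrisk, p_risk * config.mnar_boost, p_risk), 0.0, 1.0
            )
        mask = rng.random(n) < p_miss
        df.loc[mask, variable] = np.nan

    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Serialize with the literal ``NaN`` sentinel for missing entries."""
    cohort.to_csv(path, index=False, na_rep=MISSING_SENTINEL)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=[MISSING_SENTINEL], keep_default_na=False)
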