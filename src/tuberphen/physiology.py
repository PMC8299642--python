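"""Leaf water status, gravimetric watering, and group-comparison statistics.

Small, exactly specified utilities used throughout a pot drought trial:
relative water content / leaf water deficit from the fresh-turgid-dry weight
triplet, the water mass to add to a pot to hold a target fraction of field
capacity, and the one-way ANOVA + Tukey HSD compact-letter display used to
annotate condition comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "LeafWaterSample",
    "WaterRegime",
    "PotState",
    "rwc_lwd",
    "watering_amount",
    "osmotic_potential_full_turgor",
    "anova_tukey_letters",
    "GroupStats",
]


@dataclass(frozen=True)
class LeafWaterSample:
    """Weight triplet (grams) of one leaf sample.

    Requires ``dry <= fresh <= turgid`` and ``turgid > dry`` so that the
    relative water content (fresh - dry) / (turgid - dry) is well defined.
    """

    fresh_weight: float
    turgid_weight: float
    dry_weight: float

    def __post_init__(self) -> None:
        f, t, d = self.fresh_weight, self.turgid_weight, self.dry_weight
        if not (d <= f <= t):
            raise ValueError(
                f"weights must satisfy dry <= fresh <= turgid, got "
                f"dry={d}, fresh={f}, turgid={t}"
            )
        if t <= d:
            raise ValueError("turgid weight must exceed dry weight")


@dataclass(frozen=True)
class WaterRegime:
    """Watering target as a fraction of soil field capacity.

    The trial ran three regimes: Control at 0.70, mild water deficit (MWD)
    at 0.40 and severe water deficit (SWD) at 0.20 of field capacity.
    """

    condition: str
    target_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 < self.target_fraction <= 1.0):
            raise ValueError(
                f"target_fraction must be in (0, 1], got {self.target_fraction}"
            )


#: The three regimes of the study design, keyed by condition label.
STANDARD_REGIMES: Mapping[str, WaterRegime] = {
    "Control": WaterRegime("Control", 0.70),
    "MWD": WaterRegime("MWD", 0.40),
    "SWD": WaterRegime("SWD", 0.20),
}


@dataclass(frozen=True)
class PotState:
    """Mass bookkeeping (grams) for one pot on one weighing."""

    tare: float
    dry_soil_mass: float
    water_mass_at_field_capacity: float
    current_total_mass: float

    def __post_init__(self) -> None:
        for name in ("tare", "dry_soil_mass", "water_mass_at_field_capacity",
                     "current_total_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.current_total_mass < self.tare + self.dry_soil_mass:
            raise ValueError(
                "current_total_mass below tare + dry soil: negative water content"
            )


def rwc_lwd(sample: LeafWaterSample) -> tuple[float, float]:
    """Relative water content and leaf water deficit of one sample.

    RWC = (fresh - dry) / (turgid - dry); LWD = 1 - RWC. Both are fractions
    in [0, 1] and sum to 1 exactly.
    """
    rwc = (sample.fresh_weight - sample.dry_weight) / (
        sample.turgid_weight - sample.dry_weight
    )
    return rwc, 1.0 - rwc


def watering_amount(pot: PotState, regime: WaterRegime) -> float:
    """Grams of water to add to bring a pot to its regime target.

    The target total mass is tare + dry soil + fraction x water mass at field
    capacity. Water is only ever added, never removed, so the return value is
    clamped at zero when the pot is at or above target.
    """
    target_total = (
        pot.tare
        + pot.dry_soil_mass
        + regime.target_fraction * pot.water_mass_at_field_capacity
    )
    return max(0.0, target_total - pot.current_total_mass)


def osmotic_potential_full_turgor(psi_pi_at_rwc: float, rwc: float) -> float:
    """Osmotic potential rescaled to full turgor by Van't Hoff dilution.

    psi_pi(full turgor) = psi_pi(RWC) x RWC: solutes measured in sap at the
    sampled hydration are diluted to the water volume the tissue would hold
    fully turgid. This linear dilution correction assumes ideal osmotic
    behaviour and no solute gain or loss on rehydration.
    """
    if not (0.0 < rwc <= 1.0):
        raise ValueError(f"rwc must be in (0, 1], got {rwc}")
    if psi_pi_at_rwc > 0:
        raise ValueError("osmotic potential must be <= 0 MPa")
    return psi_pi_at_rwc * rwc


@dataclass
class GroupStats:
    """Per-group summary with compact letter display."""

    table: pd.DataFrame  # columns: group, n, mean, se, letters
    anova_f: float | None
    anova_p: float | None
    letters_suppressed: bool = False


def _compact_letters(groups: Sequence[str],
                     nonsig: set[frozenset[str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Two groups share a letter iff their pair is in ``nonsig`` (not
    significantly different). Groups are processed in the given order; letter
    sets are greedily built then absorbed (a letter contained in another is
    dropped) and renamed alphabetically.
    """
    letter_sets: list[set[str]] = [set(groups)]
    for a_i, a in enumerate(groups):
        for b in groups[a_i + 1:]:
            if frozenset((a, b)) in nonsig:
                continue
            # a and b are significantly different: split every set holding both
            new_sets: list[set[str]] = []
            for s in letter_sets:
                if a in s and b in s:
                    new_sets.append(s - {a})
                    new_sets.append(s - {b})
                else:
                    new_sets.append(s)
            # absorb: drop sets contained in another
            letter_sets = [
                s for i, s in enumerate(new_sets)
                if s and not any(s < t or (s == t and i > j)
                                 for j, t in enumerate(new_sets))
            ]
    # assign letters in order of each group's first appearance
    letter_sets.sort(key=lambda s: min(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def anova_tukey_letters(groups: Mapping[str, Sequence[float]],
                        alpha: float = 0.05) -> GroupStats:
    """One-way ANOVA followed by Tukey HSD, summarised as letter groups.

    Groups sharing a letter are not significantly different at ``alpha``.
    Letters are suppressed (set to empty, flagged) when any group has fewer
    than two observations, or when there are fewer than two groups. A fully
    degenerate design (zero variance everywhere, identical means) is treated
    as "no difference": every group gets the same letter.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = list(groups)
    arrays = {g: np.asarray(groups[g], dtype=float) for g in names}
    rows = [
        {"group": g, "n": a.size,
         "mean": float(a.mean()) if a.size else np.nan,
         "se": float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else np.nan}
        for g, a in arrays.items()
    ]
    table = pd.DataFrame(rows)

    if any(a.size < 2 for a in arrays.values()):
        table["letters"] = ""
        return GroupStats(table, None, None, letters_suppressed=True)

    values = np.concatenate([arrays[g] for g in names])
    labels = np.concatenate([[g] * arrays[g].size for g in names])

    pooled_var = np.concatenate(
        [arrays[g] - arrays[g].mean() for g in names]
    ).var()
    means = np.array([arrays[g].mean() for g in names])
    if pooled_var == 0.0:
        # no within-group variance: identical means are indistinguishable,
        # any mean difference is taken as significant
        nonsig = {
            frozenset((a, b))
            for i, a in enumerate(names) for b in names[i + 1:]
            if means[i] == arrays[b].mean()
        }
        table["letters"] = table["group"].map(_compact_letters(names, nonsig))
        return GroupStats(table, None, None)

    from scipy import stats

    f_stat, p_val = stats.f_oneway(*(arrays[g] for g in names))
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    res = pd.DataFrame(tukey.summary().data[1:],
                       columns=tukey.summary().data[0])
    nonsig = {
        frozenset((str(r["group1"]), str(r["group2"])))
        for _, r in res.iterrows() if not r["reject"]
    }
    table["letters"] = table["group"].map(_compact_letters(names, nonsig))
    return GroupStats(table, float(f_stat), float(p_val))
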