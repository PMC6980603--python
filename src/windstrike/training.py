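"""Presence / pseudo-absence training tables from carcass-search records.

A turbine is a presence if the target species was ever detected beneath
it; a pseudo-absence if only birds of other families were detected; and
excluded when its only detections belong to the target's own taxonomic
family (those carry the same collision signal without being the target)
or when it was never controlled.  Record multiplicity is ignored: only
the turbine coordinate carries information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import CLASS_ORDER, TARGET_FAMILY, TARGET_SPECIES

PRESENCE = "presence"
PSEUDO_ABSENCE = "pseudo_absence"
EXCLUDED = "excluded"


@dataclass
class TrainingSet:
    """Per-turbine feature rows with a binary presence label."""

    table: pd.DataFrame
    feature_names: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        missing = [c for c in ("turbine_id", "label", *self.feature_names) if c not in self.table.columns]
        if missing:
            raise ValueError(f"training table missing columns: {missing}")
        if self.table["turbine_id"].duplicated().any():
            raise ValueError("a turbine appears more than once in the training set")
        if self.table[list(self.feature_names)].isna().any().any():
            raise ValueError("training features contain missing values")

    @property
    def X(self) -> np.ndarray:
        return self.table[list(self.feature_names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.table["label"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, mask) -> "TrainingSet":
        return TrainingSet(self.table.loc[mask].reset_index(drop=True), self.feature_names)

    def drop_features(self, names) -> "TrainingSet":
        keep = tuple(n for n in self.feature_names if n not in set(names))
        return TrainingSet(self.table, keep)


def label_turbines(
    carcasses: pd.DataFrame,
    target_species: str = TARGET_SPECIES,
    excluded_family: str = TARGET_FAMILY,
) -> dict[str, str]:
    """Classify each controlled turbine as presence/pseudo-absence/excluded.

    Presence wins when both target and other-family records exist at one
    turbine.  Turbines without any record do not appear in the result
    (uncontrolled).  Raises if the excluded family never occurs in the
    records, which almost always indicates a misspelled family name.
    """
    families = set(carcasses["family"])
    if excluded_family not in families:
        raise ValueError(
            f"unknown family {excluded_family!r}: not present in carcass records"
        )
    target_fams = set(carcasses.loc[carcasses["species"] == target_species, "family"])
    if target_fams and target_fams != {excluded_family}:
        raise ValueError(
            f"target species {target_species!r} recorded under families "
            f"{sorted(target_fams)}, expected {excluded_family!r}"
        )
    labels: dict[str, str] = {}
    for tid, group in carcasses.groupby("turbine_id", sort=True):
        if (group["species"] == target_species).any():
            labels[str(tid)] = PRESENCE
        elif (group["family"] == excluded_family).any():
            labels[str(tid)] = EXCLUDED
        else:
            labels[str(tid)] = PSEUDO_ABSENCE
    return labels


def downsample_balance(
    labeled: pd.DataFrame, target_ratio: float = 1.0, seed: int = 0
) -> pd.DataFrame:
    """Randomly subsample the majority label towards target_ratio.

    labeled must carry a binary ``label`` column (1 = presence).  With
    the default 1:1 ratio the output label counts differ by at most one.
    Deterministic for a fixed seed; sampling is without replacement.
    """
    n_pos = int((labeled["label"] == 1).sum())
    n_neg = int((labeled["label"] == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both presence and pseudo-absence labels are required")
    rng = np.random.default_rng(seed)
    if n_pos >= n_neg:
        majority, n_major, n_minor = 1, n_pos, n_neg
    else:
        majority, n_major, n_minor = 0, n_neg, n_pos
    n_keep = min(n_major, int(round(n_minor * target_ratio)))
    major_idx = labeled.index[labeled["label"] == majority].to_numpy()
    keep = rng.choice(major_idx, size=n_keep, replace=False)
    mask = (labeled["label"] != majority) | labeled.index.isin(keep)
    return labeled.loc[mask].reset_index(drop=True)


def assemble(
    labels: dict[str, str],
    delv_features: pd.DataFrame,
    feature_names: tuple[str, ...] = CLASS_ORDER,
) -> pd.DataFrame:
    """Join labels with DELV feature rows into a labelled table.

    delv_features must have a ``turbine_id`` column plus one column per
    feature.  Excluded turbines are dropped; every retained turbine must
    have a feature row.  Returns a plain DataFrame suitable for
    :func:`downsample_balance` and :class:`TrainingSet`.
    """
    usable = {t: l for t, l in labels.items() if l in (PRESENCE, PSEUDO_ABSENCE)}
    if not usable:
        raise ValueError("no presence or pseudo-absence turbines to assemble")
    feats = delv_features.set_index("turbine_id")
    missing = [t for t in usable if t not in feats.index]
    if missing:
        raise ValueError(f"missing DELV feature rows for turbines: {missing[:5]}")
    tids = sorted(usable)
    out = feats.loc[tids, list(feature_names)].reset_index()
    out["label"] = [1 if usable[t] == PRESENCE else 0 for t in tids]
    return out
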