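import numpy as np
import pytest

import windstrike as ws
from windstrike.brt import BRTConfig, boost, predict, relative_influence, roc_auc
from windstrike.delv import build_delv_stack, sample_delv
from windstrike.training import TrainingSet, downsample_balance

DRIVER_CLASSES = frozenset({"FW", "GF", "GS", "B"})

#: scaled-down boosting configuration used for the replicated recovery
#: experiments (fixed tree count keeps each replicate fast)
RECOVERY_CONFIG = dict(tc=5, lr=0.05, bf=0.5, min_node=10)
RECOVERY_NT = 300


def make_synthetic_training(seed: int, n_train: int = 400, n_test: int = 400):
    """Balanced training and independent holdout sets from the standard
    synthetic conditions.

    Generates a 20 km x 20 km landscape, 2200 turbines, collision
    outcomes under the default four-driver risk surface, balances
    presences against pseudo-absences 1:1 and draws disjoint
    label-stratified training (n_train rows) and holdout (n_test rows)
    subsets.  Returns (train, holdout, stack, risk_spec).
    """
    lc = ws.LandscapeConfig(seed=seed)
    layers = ws.generate_landscape(lc)
    stack = build_delv_stack(layers, lc.grid)
    turbines = ws.generate_turbines(2200, lc.grid, seed=seed + 1000)
    risk = ws.default_risk_spec()
    sim = ws.simulate_collisions(turbines, stack, risk, seed=seed + 2000)
    feats = sample_delv(stack, sim)
    feats["label"] = sim["outcome"].to_numpy()
    balanced = downsample_balance(feats, 1.0, seed=seed + 3000)
    rng = np.random.default_rng(seed + 4000)
    train_idx, test_idx = [], []
    for label in (0, 1):
        idx = balanced.index[balanced["label"] == label].to_numpy()
        pick = rng.choice(idx, size=min(idx.size, (n_train + n_test) // 2), replace=False)
        train_idx.append(pick[: n_train // 2])
        test_idx.append(pick[n_train // 2 :])
    train = TrainingSet(
        balanced.loc[np.sort(np.concatenate(train_idx))].reset_index(drop=True)
    )
    holdout = TrainingSet(
        balanced.loc[np.sort(np.concatenate(test_idx))].reset_index(drop=True)
    )
    return train, holdout, stack, risk


def permute_labels(training: TrainingSet, seed: int) -> TrainingSet:
    table = training.table.copy()
    table["label"] = np.random.default_rng(seed).permutation(table["label"].to_numpy())
    return TrainingSet(table)


@pytest.fixture(scope="session")
def small_stack():
    """6 km x 6 km landscape with its DELV stack (fast shared fixture)."""
    lc = ws.LandscapeConfig(extent=(6000.0, 6000.0), seed=11)
    layers = ws.generate_landscape(lc)
    return lc, layers, build_delv_stack(layers, lc.grid)


@pytest.fixture(scope="session")
def recovery_replicates():
    """Ten seeded replicates of the driver-recovery experiment.

    Each replicate holds the fitted model, its influence ranking, the
    AUC on the independent balanced holdout, and the holdout AUC of a
    label-permuted null fit.
    """
    replicates = []
    for seed in range(10):
        train, test, stack, risk = make_synthetic_training(seed)
        cfg = BRTConfig(seed=seed, **RECOVERY_CONFIG)
        model = boost(train, cfg, RECOVERY_NT)
        influence = relative_influence(model)
        auc = roc_auc(test.y, predict(model, test.X))

        null_train = permute_labels(train, seed + 6000)
        null_test = permute_labels(test, seed + 7000)
        null_model = boost(null_train, cfg, RECOVERY_NT)
        null_auc = roc_auc(null_test.y, predict(null_model, null_test.X))

        replicates.append(
            {
                "seed": seed,
                "model": model,
                "influence": influence,
                "auc": auc,
                "null_auc": null_auc,
                "risk": risk,
                "train": train,
                "test": test,
            }
        )
    return replicates
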