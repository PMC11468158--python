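"""Desk-scale synthetic benchmark: directional reproduction suite.

Runs the full pipeline on the synthetic stimulus set at reduced problem
sizes chosen to finish on one CPU in a few minutes, and returns the
quantities on which the qualitative claims rest:

* model ordering — median accuracy of V1S, V1C, LGN and V1L under the
  lesion-analysis condition (scale down to 50%, rotation +/-45 deg,
  blurred-scene background): simple and complex models comparable, both
  above LGN, the linear-RF model worst;
* rotation degradation — V1S median accuracy across rotation ranges 0, 45
  and 180 deg on a mid-gray background (non-increasing);
* consistency lesions — keep-only / remove subsets of units whose readout
  weight sign recurs in >= 9 of the 10 full-model runs, retrained;
* channel lesions — each single frequency-channel knockout, plus keeping
  only the lowest-frequency channel F0, retrained.

Problem sizes (the benchmark's study conditions, fixed here): 200 synthetic
images per class (the scaled-down element), the protocol's own 1,500
resampled presentations per class and 10 training epochs, 10 runs per
condition, and a 6-variant precomputed augmentation pool standing in for
per-presentation composition (see the methods note). All randomness descends
from one master seed.
"""

from __future__ import annotations


from . import lesions as ls
from . import models as md
from . import protocol as pr
from . import stimuli as st
from .rng import substream

__all__ = ["BENCHMARK_SIZES", "HARD_CONDITION", "run_benchmark"]

BENCHMARK_SIZES = {
    "n_images_per_class": 200,
    "n_train_per_class": 1500,  # the protocol's resampled presentations per class
    "n_test_per_class": 1500,
    "n_runs": 10,
    "epochs": 10,
    "cache_augmentations": 6,
    "consistency_threshold": 9,  # of 10 runs
}

# the lesion-analysis condition: scale down to 50%, rotation +/-45 deg,
# blurred-scene background
HARD_CONDITION = {"scale_min": 0.5, "rot_max": 45.0,
                  "background": st.BackgroundKind.BLURRED_SCENE}
ROTATION_LEVELS = (0.0, 45.0, 180.0)


def _condition(n: dict, **kw) -> pr.Condition:
    return pr.Condition(n_train_per_class=n["n_train_per_class"],
                        n_test_per_class=n["n_test_per_class"],
                        n_runs=n["n_runs"], **kw)


def run_benchmark(seed: int, sizes: dict | None = None,
                  verbose: bool = False) -> dict:
    """Run the full directional suite; returns a flat dict of measurements.

    Accuracies are fractions in [0, 1]; the caller converts to percent
    where needed. Deterministic given ``seed``.
    """
    n = dict(BENCHMARK_SIZES)
    if sizes:
        n.update(sizes)
    cfg = pr.TrainConfig(epochs=n["epochs"])
    stimset = pr.StimulusSet.synthetic(n["n_images_per_class"],
                                       seed=int(substream(seed, "stimset").integers(2**31)))

    def say(msg):
        if verbose:
            print(msg, flush=True)

    out: dict = {"seed": seed, "sizes": n}
    hard = _condition(n, **HARD_CONDITION)

    # --- model ordering under combined variation ---------------------------
    hard_results: dict[str, pr.ConditionResult] = {}
    pools: dict[str, pr.FeaturePool] = {}
    for variant in ("V1S", "V1C", "LGN", "V1L"):
        model = md.make_model(variant)
        pool = pr.FeaturePool.build(
            model, stimset, hard,
            seed=int(substream(seed, "pool", variant).integers(2**31)),
            K=n["cache_augmentations"])
        res = pr.run_condition(model, hard, stimset, master_seed=seed,
                               cfg=cfg, pool=pool)
        hard_results[variant] = res
        pools[variant] = pool
        out[f"median_accuracy_{variant}"] = res.median_accuracy
        say(f"{variant}: median {res.median_accuracy:.3f}")

    # --- rotation degradation (V1S, mid-gray, full scale) ------------------
    v1s = md.make_model("V1S")
    for rot in ROTATION_LEVELS:
        cond = _condition(n, scale_min=1.0, rot_max=rot,
                          background=st.BackgroundKind.MID_GRAY)
        res = pr.run_condition(v1s, cond, stimset, master_seed=seed, cfg=cfg,
                               cache_augmentations=n["cache_augmentations"])
        out[f"median_accuracy_rot{int(rot)}"] = res.median_accuracy
        say(f"rot {rot}: median {res.median_accuracy:.3f}")

    # --- consistency lesions (from the full V1S hard-condition runs) -------
    full = hard_results["V1S"]
    out["full_model_iqr"] = full.iqr
    table = ls.weight_sign_consistency(full.runs)
    thr = n["consistency_threshold"]
    for action in ("keep_only", "remove"):
        lm = ls.apply_consistency_subset(v1s, table, thr, action)
        res = pr.run_condition(lm, hard, stimset, master_seed=seed, cfg=cfg,
                               pool=pools["V1S"].masked(lm.unit_mask))
        out[f"median_accuracy_cs_{action}"] = res.median_accuracy
        if action == "keep_only":
            out["cs_keep_only_iqr"] = res.iqr
            out["cs_keep_only_n_units"] = lm.n_units
        say(f"cs {action}: median {res.median_accuracy:.3f} ({lm.n_units} units)")

    # --- channel lesions ----------------------------------------------------
    for ch in range(4):
        lm = ls.drop_channels(v1s, [ch])
        res = pr.run_condition(lm, hard, stimset, master_seed=seed, cfg=cfg,
                               pool=pools["V1S"].masked(lm.unit_mask))
        out[f"median_accuracy_dropF{ch}"] = res.median_accuracy
        say(f"drop F{ch}: median {res.median_accuracy:.3f}")
    lm = ls.keep_channels(v1s, [0])
    res = pr.run_condition(lm, hard, stimset, master_seed=seed, cfg=cfg,
                           pool=pools["V1S"].masked(lm.unit_mask))
    out["median_accuracy_keep_onlyF0"] = res.median_accuracy
    say(f"keep only F0: median {res.median_accuracy:.3f}")
    return out
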