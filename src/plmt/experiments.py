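"""Desk-scale study: the four pipeline modes on the synthetic binary task.

Reproduces, at workstation scale, the comparison the full-scale method is
built around: supervised-only training on the labeled 10%, plain mean
teacher, plain pseudo-label self-training, and the combined pipeline
(mean-teacher Stage A, pseudo-labels, Stage C with both unsupervised
losses). Stage A runs are shared where the pipelines coincide (the
supervised model doubles as self-training's pseudo-labeler; the
mean-teacher model doubles as the combined pipeline's), so one suite costs
four training stages per seed.

Problem sizes are chosen for a single CPU: 50 cases of 4 slices at 32x32
(200 slices; 40 train cases of which 4 labeled at the 10% fraction, 10
test cases), the light backbone profile, 3+3 batches and a schedule long
enough (1500 iterations) for the ramped unsupervised terms to act after
the supervised term has converged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import TEST_PROFILE, ArchSpec
from .data_io import make_split
from .losses import LossWeights, adaptive_weights
from .metrics import evaluate
from .synthetic_data import SynthSpec, generate
from .training import (TrainConfig, generate_pseudo_labels, train_stage_a,
                       train_stage_c)

#: study conditions for the desk-scale comparison
STUDY_ITER_MAX = 1500
STUDY_BATCH = 3
STUDY_NOISE_STD = 0.8
STUDY_LABELED_FRACTION = 0.1


@dataclass
class ModeComparison:
    """Per-seed and mean test Dice of the four modes."""

    per_seed: dict = field(default_factory=dict)  # mode -> list of dice
    alpha_final: list = field(default_factory=list)
    n_train_slices: int = 0
    n_labeled_slices: int = 0

    def mean(self, mode: str) -> float:
        return float(np.mean(self.per_seed[mode]))

    @property
    def gain_over_supervised(self) -> float:
        return self.mean("plmt") - self.mean("supervised")

    @property
    def gain_over_best_single(self) -> float:
        return self.mean("plmt") - max(self.mean("mt"),
                                       self.mean("self-training"))


def run_mode_suite(seed: int, iter_max: int = STUDY_ITER_MAX,
                   arch: ArchSpec = TEST_PROFILE,
                   noise_std: float = STUDY_NOISE_STD) -> dict:
    """All four modes for one seed; returns mode -> mean test Dice."""
    spec = SynthSpec(seed=seed, noise_std=noise_std)
    split = make_split(generate(spec), STUDY_LABELED_FRACTION, seed=seed)
    cfg = TrainConfig(iter_max=iter_max, labeled_batch=STUDY_BATCH,
                      unlabeled_batch=STUDY_BATCH, log_every=max(1, iter_max // 4),
                      seed=seed)
    out: dict = {"_n_train": len(split.labeled) + len(split.unlabeled),
                 "_n_labeled": len(split.labeled)}
    sup, _ = train_stage_a(cfg, split, arch, supervised_only=True)
    out["supervised"] = evaluate(sup, split.test).mean_dice
    mt, _ = train_stage_a(cfg, split, arch, weights=LossWeights())
    out["mt"] = evaluate(mt, split.test).mean_dice
    pairs_sup = generate_pseudo_labels(sup.freeze(), split.unlabeled)
    st, _, _ = train_stage_c(cfg, split.labeled, pairs_sup, arch,
                             variant="self-training")
    out["self-training"] = evaluate(st, split.test).mean_dice
    pairs_mt = generate_pseudo_labels(mt.freeze(), split.unlabeled)
    plmt, w, _ = train_stage_c(cfg, split.labeled, pairs_mt, arch,
                               weights=LossWeights(), variant="plmt")
    out["plmt"] = evaluate(plmt, split.test).mean_dice
    alpha, _ = adaptive_weights(w.z.item())
    out["_alpha"] = float(alpha)
    return out


def compare_modes(base_seed: int, n_seeds: int = 3,
                  iter_max: int = STUDY_ITER_MAX) -> ModeComparison:
    """Run the suite over ``n_seeds`` derived seeds and aggregate."""
    ss = np.random.SeedSequence(base_seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_seeds)]
    comp = ModeComparison(per_seed={m: [] for m in
                                    ("supervised", "mt", "self-training", "plmt")})
    for s in seeds:
        res = run_mode_suite(s, iter_max=iter_max)
        for m in comp.per_seed:
            comp.per_seed[m].append(res[m])
        comp.alpha_final.append(res["_alpha"])
        comp.n_train_slices = res["_n_train"]
        comp.n_labeled_slices = res["_n_labeled"]
    return comp
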