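"""Three-stage semi-supervised training pipeline.

Stage A trains a mean-teacher pair on the labeled + unlabeled streams: the
student sees Gaussian-perturbed unlabeled inputs, the teacher clean copies,
and the teacher's parameters track the student's by exponential moving
average. Stage B freezes the Stage-A student and writes one hard pixelwise
argmax pseudo-label per unlabeled image — no confidence threshold, no pixel
exclusion. Stage C re-trains a fresh student-teacher pair from scratch
under supervised + consistency + pseudo-label losses with the trainable
convex weights (alpha, beta) and temperature K; the pseudo-labels stay
fixed throughout.

Batches draw from independent infinite shuffled cyclers over D^L and D^U,
so the small labeled set is revisited many times per pass over the
unlabeled set. One optimizer step is one iteration; the learning rate
follows the poly schedule lr0 * (1 - t/t_max)^power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from .backbone import (ArchSpec, ConfigurationError, InputError, ModelState,
                       build_model)
from .data_io import DatasetSplit, augment
from .losses import (LossBreakdown, LossWeights, consistency_loss,
                     pseudo_loss, stage_a_total, stage_c_total,
                     supervised_loss, warmup_weight)
from .metrics import MetricReport, evaluate
from .nn import SGD

MODES = ("plmt", "mt", "self-training", "supervised")


class StateError(ValueError):
    """Model states are incompatible (e.g. incongruent parameter shapes)."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule and batch composition.

    Defaults follow the reference configuration for full-scale runs
    (36,000 iterations, 12+12 batches, SGD momentum 0.9, weight decay
    0.001, initial lr 0.1 with poly decay, Gaussian warm-up on the
    unsupervised weight); desk-scale experiments shrink ``iter_max`` and
    the batch sizes.
    """

    iter_max: int = 36000
    labeled_batch: int = 12
    unlabeled_batch: int = 12
    lr0: float = 0.1
    poly_power: float = 0.9
    momentum: float = 0.9
    weight_decay: float = 0.001
    ema_decay: float = 0.99
    student_noise_std: float = 0.1
    seed: int = 0
    log_every: int = 50

    def __post_init__(self):
        if self.iter_max < 0:
            raise ConfigurationError("iter_max must be non-negative")
        if not 0.0 <= self.ema_decay <= 1.0:
            raise ConfigurationError("ema_decay must lie in [0, 1]")
        if self.student_noise_std < 0:
            raise ConfigurationError("student_noise_std must be non-negative")
        if self.labeled_batch < 1:
            raise ConfigurationError("labeled_batch must be >= 1")


@dataclass
class PseudoPair:
    """An unlabeled image with its fixed Stage-B hard pseudo-label."""

    image: np.ndarray
    pseudo: np.ndarray  # integer mask, argmax of the frozen model's output
    source_case: str


def ema_update(teacher: ModelState, student: ModelState, decay: float) -> ModelState:
    """teacher <- decay * teacher + (1 - decay) * student, elementwise.

    Applies to every parameter and buffer; the student is untouched.
    """
    if not 0.0 <= decay <= 1.0:
        raise ConfigurationError(f"decay must lie in [0, 1], got {decay}")
    t_params = dict(teacher.net.named_parameters())
    s_params = dict(student.net.named_parameters())
    if set(t_params) != set(s_params):
        raise StateError("parameter collections differ between teacher and student")
    for name, tp in t_params.items():
        sp = s_params[name]
        if tp.data.shape != sp.data.shape:
            raise StateError(f"shape mismatch for {name}")
        tp.data *= decay
        tp.data += (1.0 - decay) * sp.data
    s_bufs = dict(student.net.named_buffers())
    for name, tval in teacher.net.named_buffers():
        obj, attr = teacher.net._locate_buffer(name)
        setattr(obj, attr, decay * tval + (1.0 - decay) * s_bufs[name])
    return teacher


def perturb_input(images: np.ndarray, std: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Add zero-mean Gaussian noise; std = 0 returns the input unchanged."""
    if std < 0:
        raise ConfigurationError("noise std must be non-negative")
    if std == 0:
        return images
    return images + rng.normal(0.0, std, size=images.shape).astype(np.float32)


def poly_lr(t: int, t_max: int, lr0: float, power: float) -> float:
    """Poly decay lr0 * (1 - t/t_max)^power, floored at zero."""
    if t_max <= 0:
        raise ConfigurationError("t_max must be positive")
    frac = max(0.0, 1.0 - t / t_max)
    return lr0 * frac ** power


def _cycler(n: int, rng: np.random.Generator):
    """Infinite shuffled index stream over range(n)."""
    while True:
        for i in rng.permutation(n):
            yield int(i)


def _take_batch(cycler, k: int) -> list:
    return [next(cycler) for _ in range(k)]


class _LossLog:
    def __init__(self, path=None):
        self.records: list[tuple[int, LossBreakdown]] = []
        self._fh = open(path, "w") if path else None
        if self._fh:
            self._fh.write(LossBreakdown.log_header() + "\n")

    def add(self, iteration: int, breakdown: LossBreakdown) -> None:
        self.records.append((iteration, breakdown))
        if self._fh:
            self._fh.write(breakdown.log_line(iteration) + "\n")

    def close(self) -> None:
        if self._fh:
            self._fh.close()


def _seed_streams(seed: int, stage: int):
    """Independent RNG streams per purpose, so e.g. the labeled batch order
    is identical whether or not the unlabeled stream is consumed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stage,))
    names = ("init", "labeled", "unlabeled", "noise", "aug_l", "aug_u")
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _init_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2 ** 31))


def _stack_labeled(items, idxs, rng_aug):
    imgs, masks = [], []
    for i in idxs:
        img, m = augment(items[i].image, items[i].mask, rng_aug)
        imgs.append(img)
        masks.append(m)
    return (np.asarray(imgs, dtype=np.float32)[:, None],
            np.asarray(masks, dtype=np.int64))


def train_stage_a(config: TrainConfig, data: DatasetSplit, arch: ArchSpec,
                  supervised_only: bool = False,
                  weights: LossWeights | None = None,
                  log_path=None) -> tuple[ModelState, list]:
    """Stage A: mean-teacher training (or its supervised-only degeneration).

    Returns the final student parameters (the pseudo-labeler-to-be) and the
    logged loss records. With an empty unlabeled set the run falls back to
    supervised-only with a warning, since the consistency term is undefined.
    """
    w = weights or LossWeights()
    if not data.labeled:
        raise InputError("Stage A requires a non-empty labeled set")
    if not supervised_only and not data.unlabeled:
        warnings.warn("unlabeled set is empty; falling back to supervised-only")
        supervised_only = True
    rngs = _seed_streams(config.seed, stage=0)
    student = build_model(arch, _init_seed(rngs["init"]), role="student")
    teacher = student.clone(role="teacher")
    teacher.net.set_requires_grad(False)
    opt = SGD(student.net.parameters(), momentum=config.momentum,
              weight_decay=config.weight_decay)
    lab_cycle = _cycler(len(data.labeled), rngs["labeled"])
    unl_cycle = (None if supervised_only
                 else _cycler(len(data.unlabeled), rngs["unlabeled"]))
    log = _LossLog(log_path)
    try:
        for t in range(config.iter_max):
            xl, yl = _stack_labeled(data.labeled,
                                    _take_batch(lab_cycle, config.labeled_batch),
                                    rngs["aug_l"])
            sup = supervised_loss(student.net(Tensor(xl), train=True), yl)
            ramp = warmup_weight(t, config.iter_max)
            if supervised_only:
                breakdown = LossBreakdown(sup=sup.item(), con=None, pse=None,
                                          ramp=ramp, alpha=None, beta=None,
                                          total=sup)
            else:
                idxs = _take_batch(unl_cycle, config.unlabeled_batch)
                xu = np.asarray([augment(data.unlabeled[i].image, None,
                                         rngs["aug_u"])[0]
                                 for i in idxs], dtype=np.float32)[:, None]
                xs = perturb_input(xu, config.student_noise_std, rngs["noise"])
                s_out = student.net(Tensor(xs), train=True)
                t_out = teacher.net(Tensor(xu), train=True)
                con = consistency_loss(s_out, t_out)
                breakdown = stage_a_total(sup, con, w, ramp)
            breakdown.total.backward()
            opt.step(poly_lr(t, config.iter_max, config.lr0, config.poly_power))
            opt.zero_grad()
            ema_update(teacher, student, config.ema_decay)
            if (t + 1) % config.log_every == 0 or t + 1 == config.iter_max:
                log.add(t + 1, breakdown)
        student.iteration = config.iter_max
        return student, log.records
    finally:
        log.close()


def generate_pseudo_labels(frozen: ModelState, unlabeled,
                           batch_size: int = 8) -> list[PseudoPair]:
    """Stage B: one hard pseudo-label per unlabeled image.

    The pseudo-label is the pixelwise class argmax of the frozen Stage-A
    model's probability output. Every image gets a pair — no confidence
    filtering, no pixel exclusion — and the mapping is deterministic.
    """
    if frozen.role != "frozen":
        raise StateError(f"pseudo-labeler must have role 'frozen', got {frozen.role!r}")
    items = list(unlabeled)
    pairs: list[PseudoPair] = []
    for start in range(0, len(items), batch_size):
        chunk = items[start:start + batch_size]
        x = np.asarray([it.image for it in chunk], dtype=np.float32)[:, None]
        probs = frozen.net(Tensor(x), train=False).data
        hard = probs.argmax(axis=1)
        for it, mask in zip(chunk, hard):
            pairs.append(PseudoPair(image=it.image, pseudo=mask.astype(np.int64),
                                    source_case=it.case_id))
    return pairs


def train_stage_c(config: TrainConfig, labeled, pseudo: list[PseudoPair],
                  arch: ArchSpec, weights: LossWeights | None = None,
                  variant: str = "plmt",
                  log_path=None) -> tuple[ModelState, LossWeights, list]:
    """Stage C: re-train from scratch under the combined loss.

    ``variant='plmt'`` uses the full total with an EMA teacher and the
    trainable convex weights; ``variant='self-training'`` drops the
    consistency term and the teacher entirely (plain pseudo-label
    self-training: total = sup + lambda_C * ramp * pse). Pseudo-labels are
    fixed inputs and are never regenerated.
    """
    if variant not in ("plmt", "self-training"):
        raise ConfigurationError(f"unknown Stage C variant {variant!r}")
    if not pseudo:
        raise InputError("Stage C requires a non-empty pseudo-label set")
    if not labeled:
        raise InputError("Stage C requires a non-empty labeled set")
    w = weights or LossWeights()
    rngs = _seed_streams(config.seed, stage=2)
    student = build_model(arch, _init_seed(rngs["init"]), role="student")
    teacher = student.clone(role="teacher")
    teacher.net.set_requires_grad(False)
    params = student.net.parameters()
    if variant == "plmt":
        w.z.requires_grad = True
        opt = SGD(params + [w.z], momentum=config.momentum,
                  weight_decay=config.weight_decay, no_decay=(w.z,))
    else:
        opt = SGD(params, momentum=config.momentum,
                  weight_decay=config.weight_decay)
    lab_cycle = _cycler(len(labeled), rngs["labeled"])
    pse_cycle = _cycler(len(pseudo), rngs["unlabeled"])
    log = _LossLog(log_path)
    try:
        for t in range(config.iter_max):
            xl, yl = _stack_labeled(labeled,
                                    _take_batch(lab_cycle, config.labeled_batch),
                                    rngs["aug_l"])
            sup = supervised_loss(student.net(Tensor(xl), train=True), yl)
            idxs = _take_batch(pse_cycle, config.unlabeled_batch)
            xu, yp = [], []
            for i in idxs:
                img, m = augment(pseudo[i].image, pseudo[i].pseudo, rngs["aug_u"])
                xu.append(img)
                yp.append(m)
            xu = np.asarray(xu, dtype=np.float32)[:, None]
            yp = np.asarray(yp, dtype=np.int64)
            xs = perturb_input(xu, config.student_noise_std, rngs["noise"])
            s_out = student.net(Tensor(xs), train=True)
            pse = pseudo_loss(s_out, yp)
            ramp = warmup_weight(t, config.iter_max)
            if variant == "plmt":
                t_out = teacher.net(Tensor(xu), train=True)
                con = consistency_loss(s_out, t_out)
                breakdown = stage_c_total(sup, con, pse, w, ramp)
            else:
                total = sup + (w.lambda_c * ramp) * pse
                breakdown = LossBreakdown(sup=sup.item(), con=None,
                                          pse=pse.item(), ramp=ramp,
                                          alpha=None, beta=None, total=total)
            breakdown.total.backward()
            opt.step(poly_lr(t, config.iter_max, config.lr0, config.poly_power))
            opt.zero_grad()
            if variant == "plmt":
                ema_update(teacher, student, config.ema_decay)
            if (t + 1) % config.log_every == 0 or t + 1 == config.iter_max:
                log.add(t + 1, breakdown)
        student.iteration = config.iter_max
        return student, w, log.records
    finally:
        log.close()


@dataclass
class PipelineResult:
    model: ModelState
    report: MetricReport
    stage_a: ModelState | None = None
    pseudo: list | None = None
    weights: LossWeights | None = None
    logs: dict | None = None


def run_pipeline(config: TrainConfig, data: DatasetSplit, arch: ArchSpec,
                 mode: str = "plmt", weights: LossWeights | None = None,
                 out_dir=None) -> PipelineResult:
    """Compose the stages for one of the four pipeline modes.

    ``plmt``: mean-teacher Stage A -> pseudo-labels -> full Stage C.
    ``mt``: mean-teacher Stage A only. ``self-training``: supervised Stage
    A -> pseudo-labels -> Stage C without consistency or EMA teacher.
    ``supervised``: labeled data only. All modes end with evaluation on the
    test split; checkpoints and logs are written when ``out_dir`` is given.
    """
    if mode not in MODES:
        raise ConfigurationError(f"mode must be one of {MODES}, got {mode!r}")
    from pathlib import Path

    from .backbone import save_checkpoint

    w = weights or LossWeights()
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def _p(name):
        return (out / name) if out else None

    logs = {}
    sup_only = mode in ("supervised", "self-training")
    theta_a, logs["stage_a"] = train_stage_a(
        config, data, arch, supervised_only=sup_only, weights=w,
        log_path=_p("stage_a_loss.tsv"))
    if out:
        save_checkpoint(theta_a, out / "stage_a.ckpt")
    model = theta_a
    pseudo = None
    if mode in ("plmt", "self-training"):
        frozen = theta_a.freeze()
        pseudo = generate_pseudo_labels(frozen, data.unlabeled)
        if out:
            np.savez(out / "pseudo_labels.npz",
                     **{f"pair{i:05d}": p.pseudo for i, p in enumerate(pseudo)})
        variant = "plmt" if mode == "plmt" else "self-training"
        model, w, logs["stage_c"] = train_stage_c(
            config, data.labeled, pseudo, arch, weights=w, variant=variant,
            log_path=_p("stage_c_loss.tsv"))
        if out:
            save_checkpoint(model, out / "stage_c.ckpt")
    report = evaluate(model, data.test)
    if out:
        (out / "metrics.tsv").write_text(report.to_table() + "\n")
    return PipelineResult(model=model, report=report, stage_a=theta_a,
                          pseudo=pseudo, weights=w, logs=logs)
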