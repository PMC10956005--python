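"""Multi-stage training strategy and inference.

Training proceeds in up to three stages over the four generative functions:

* S1 — every trainable role is optimised independently against its own
  supervised intra-domain L1 term;
* S2 — inter-domain consistency: the image- and acquisition-domain maps of
  each direction are trained alternately, the partner frozen while the
  other is updated;
* S3 — cycle fine-tuning: only the image-domain map of each direction is
  updated, all other functions frozen.

At test time only the image-domain map of the requested direction runs; for
accelerated MRI its output additionally passes through data consistency
with the measured k-space.  Every stage re-initialises its Adam optimiser
and draws all randomness (data order) from the plan seed, so two runs with
the same plan are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import autodiff as ad
from . import hierarchy as hi
from . import metrics as me
from .generators import (
    ROLES,
    DataConsistencyGenerator,
    GeneratorSet,
    ImageUNet,
    build_acquisition_generator,
    build_image_generator,
)
from .operators import SamplingMask, TransformSpec, n_detectors_for

__all__ = [
    "StagePlan",
    "TrainState",
    "build_generator_set",
    "run_stage1",
    "run_stage2",
    "run_stage3",
    "run_plan",
    "infer",
    "ablation_plans",
    "ABLATION_PRESETS",
    "save_checkpoint",
    "load_checkpoint",
]

_STAGE_ORDER = ("S1", "S2", "S3")

# Stage-subset rows of the ablation design, plus the single-domain variant.
ABLATION_PRESETS = ("S1", "S1+S2", "S1+S3", "S2+S3", "S1+S2+S3", "image_only")


@dataclass
class StagePlan:
    """Everything a training run needs besides the data."""

    stages_enabled: tuple = ("S1", "S2", "S3")
    weights: hi.LossWeights = field(default_factory=hi.LossWeights)
    lr_per_stage: tuple = (0.005, 0.002, 0.002)
    epochs_per_stage: tuple = (4, 4, 4)
    alternation_granularity: str = "per_epoch"
    seed: int = 0
    batch_size: int = 4
    optimizer: str = "adam"
    image_arch: str = "runet"
    base_filters: int = 8
    depth: int = 2
    acq_kind: str = "fcn"
    dual_domain: bool = True
    weight_sharing: bool = False
    audit_freeze: bool = False

    def __post_init__(self):
        bad = [s for s in self.stages_enabled if s not in _STAGE_ORDER]
        if bad:
            raise ValueError(f"unknown stages {bad}")
        # stages always execute in S1 -> S2 -> S3 order among those enabled
        self.stages_enabled = tuple(
            s for s in _STAGE_ORDER if s in self.stages_enabled
        )
        if self.alternation_granularity not in ("per_epoch", "per_batch"):
            raise ValueError("alternation_granularity must be per_epoch or per_batch")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")

    def stage_lr(self, stage: str) -> float:
        return self.lr_per_stage[_STAGE_ORDER.index(stage)]

    def stage_epochs(self, stage: str) -> int:
        return int(self.epochs_per_stage[_STAGE_ORDER.index(stage)])


@dataclass
class TrainState:
    """Loss curves, checksums and audit results accumulated over stages."""

    checksums: dict = field(default_factory=dict)
    loss_log: list = field(default_factory=list)
    epochs_run: dict = field(default_factory=dict)
    updates: int = 0
    audit_violations: int = 0

    def log(self, stage, term, epoch, value):
        self.loss_log.append(
            {"stage": stage, "term": term, "epoch": int(epoch), "value": float(value)}
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "checksums": self.checksums,
                "epochs_run": self.epochs_run,
                "updates": self.updates,
                "audit_violations": self.audit_violations,
                "loss_log": self.loss_log,
            }
        )


def _trainable(gs: GeneratorSet, role: str) -> bool:
    g = gs.role(role)
    return g is not None and len(g.parameters()) > 0


def build_generator_set(task: str, spec: TransformSpec, plan: StagePlan) -> GeneratorSet:
    """Construct the task's generator roles from the plan's backbone choices."""
    rng = np.random.default_rng(plan.seed)
    seeds = [int(s) for s in rng.integers(0, 2**31, size=4)]
    if task == "mri":
        rows, cols = spec.image_shape
        g_t_i = build_image_generator(
            plan.image_arch, plan.base_filters, (2, 2), plan.depth, seeds[0]
        )
        if plan.weight_sharing:
            g_t_a: object = g_t_i  # one module serves both domains
            sharing = {"G_t_A": "G_t_I"}
        else:
            g_t_a = build_acquisition_generator("fcn", (2, rows, cols), seed=seeds[1])
            sharing = {}
        return GeneratorSet(
            G_t_I=g_t_i, G_t_A=g_t_a, G_s_A=DataConsistencyGenerator(), weight_sharing=sharing
        )
    na, nd = spec.n_angles, n_detectors_for(spec.image_shape)
    gs = GeneratorSet(
        G_s_I=build_image_generator(
            plan.image_arch, plan.base_filters, (1, 1), plan.depth, seeds[0]
        ),
        G_t_I=build_image_generator(
            plan.image_arch, plan.base_filters, (1, 1), plan.depth, seeds[1]
        ),
    )
    if plan.dual_domain:
        gs.G_s_A = build_acquisition_generator(plan.acq_kind, (1, na, nd), seed=seeds[2])
        gs.G_t_A = build_acquisition_generator(plan.acq_kind, (1, na, nd), seed=seeds[3])
    return gs


def _bind_sample(gs: GeneratorSet, pair) -> None:
    """Attach per-sample measurements to data-consistency roles (MRI)."""
    if isinstance(gs.G_s_A, DataConsistencyGenerator) and "mask" in pair.provenance:
        mask = SamplingMask(
            pair.provenance["mask"],
            acceleration=pair.provenance.get("accel", 1.0),
            n_center=pair.provenance.get("n_center", 1),
        )
        # the loss graph carries k-space in acquisition-normalized units
        gs.G_s_A.bind(mask, pair.provenance["k_measured"] / pair.transform.acq_norm)


def _batches(n: int, batch_size: int, rng) -> list:
    order = rng.permutation(n)
    return [order[i : i + batch_size] for i in range(0, n, batch_size)]


def _optim(gs: GeneratorSet, roles, lr) -> ad.Adam:
    params, seen = [], set()
    for r in roles:
        for p in gs.require(r).parameters():
            if id(p) not in seen:
                seen.add(id(p))
                params.append(p)
    return ad.Adam(params, lr=lr)


def _audit_step(gs, frozen_roles, opt, state, plan):
    if not plan.audit_freeze:
        opt.step()
        return
    before = {r: gs.require(r).checksum() for r in frozen_roles if gs.role(r) is not None}
    opt.step()
    for r, chk in before.items():
        if gs.require(r).checksum() != chk:
            state.audit_violations += 1


def _mean_loss(build_one, idxs, samples) -> ad.Tensor:
    terms = [build_one(samples[i]) for i in idxs]
    return ad.weighted_sum(terms, [1.0 / len(terms)] * len(terms))


def run_stage1(
    gs: GeneratorSet, data, plan: StagePlan, state: Optional[TrainState] = None
) -> TrainState:
    """Independent supervised training of every trainable role (intra-domain)."""
    state = state or TrainState()
    samples = list(data)
    if not samples:
        raise ValueError("stage 1 requires a non-empty dataset")
    rng = np.random.default_rng((plan.seed, 1))
    roles = [r for r in ROLES if _trainable(gs, r)]
    # tied roles must not be stepped twice in one pass
    tied = set(gs.weight_sharing)
    roles = [r for r in roles if r not in tied]
    opts = {r: _optim(gs, [r], plan.stage_lr("S1")) for r in roles}
    lw = plan.weights
    for epoch in range(plan.stage_epochs("S1")):
        sums = {r: 0.0 for r in roles}
        for idxs in _batches(len(samples), plan.batch_size, rng):
            for r in roles:
                gs.set_frozen(set(ROLES) - {r})

                def one(s, _r=r):
                    _bind_sample(gs, s)
                    return hi.loss_stage1(gs, s, s.transform, lw, roles=(_r,))[_r]

                loss = _mean_loss(one, idxs, samples)
                opts[r].zero_grad()
                loss.backward()
                _audit_step(gs, set(ROLES) - {r}, opts[r], state, plan)
                state.updates += 1
                sums[r] += loss.data * len(idxs)
        for r in roles:
            state.log("S1", r, epoch, sums[r] / len(samples))
    gs.set_frozen(set())
    state.epochs_run["S1"] = plan.stage_epochs("S1")
    state.checksums = gs.checksums()
    return state


def _stage2_phases(gs: GeneratorSet, plan: StagePlan):
    """(term name, loss builder, updated role, which output) per alternation."""
    lw = plan.weights
    phases = []
    if _trainable(gs, "G_t_I") and gs.role("G_t_A") is not None:
        phases.append(("eq2", hi.loss_stage2_t, "G_t_I", 0))
        if _trainable(gs, "G_t_A"):
            phases.append(("eq3", hi.loss_stage2_t, "G_t_A", 1))
    if (
        lw.weight_or_none("lambda3") is not None
        and _trainable(gs, "G_s_I")
        and gs.role("G_s_A") is not None
    ):
        phases.append(("eq4", hi.loss_stage2_s, "G_s_I", 0))
        if _trainable(gs, "G_s_A"):
            phases.append(("eq5", hi.loss_stage2_s, "G_s_A", 1))
    return phases


def run_stage2(
    gs: GeneratorSet, data, plan: StagePlan, state: Optional[TrainState] = None
) -> TrainState:
    """Alternating inter-domain optimisation with cross-partner freezing."""
    state = state or TrainState()
    samples = list(data)
    if not samples:
        raise ValueError("stage 2 requires a non-empty dataset")
    phases = _stage2_phases(gs, plan)
    if not phases:
        raise ValueError(
            "stage 2 needs generators in both domains; this plan has a single domain"
        )
    rng = np.random.default_rng((plan.seed, 2))
    opts = {role: _optim(gs, [role], plan.stage_lr("S2")) for _, _, role, _ in phases}
    lw = plan.weights

    def phase_loss(loss_fn, pick, idxs):
        def one(s):
            _bind_sample(gs, s)
            return loss_fn(gs, s, s.transform, lw)[pick]

        return _mean_loss(one, idxs, samples)

    for epoch in range(plan.stage_epochs("S2")):
        sums = {name: 0.0 for name, *_ in phases}
        if plan.alternation_granularity == "per_epoch":
            for name, loss_fn, role, pick in phases:
                gs.set_frozen(set(ROLES) - {role})
                for idxs in _batches(len(samples), plan.batch_size, rng):
                    loss = phase_loss(loss_fn, pick, idxs)
                    opts[role].zero_grad()
                    loss.backward()
                    _audit_step(gs, set(ROLES) - {role}, opts[role], state, plan)
                    state.updates += 1
                    sums[name] += loss.data * len(idxs)
        else:  # per_batch: cycle through the phases within each batch
            for idxs in _batches(len(samples), plan.batch_size, rng):
                for name, loss_fn, role, pick in phases:
                    gs.set_frozen(set(ROLES) - {role})
                    loss = phase_loss(loss_fn, pick, idxs)
                    opts[role].zero_grad()
                    loss.backward()
                    _audit_step(gs, set(ROLES) - {role}, opts[role], state, plan)
                    state.updates += 1
                    sums[name] += loss.data * len(idxs)
        for name, *_ in phases:
            state.log("S2", name, epoch, sums[name] / len(samples))
    gs.set_frozen(set())
    state.epochs_run["S2"] = plan.stage_epochs("S2")
    state.checksums = gs.checksums()
    return state


def _stage3_phases(gs: GeneratorSet, plan: StagePlan):
    lw = plan.weights
    phases = []
    if _trainable(gs, "G_t_I"):
        phases.append(("eq6", hi.loss_stage3_t, "G_t_I"))
    if _trainable(gs, "G_s_I"):
        phases.append(("eq7", hi.loss_stage3_s, "G_s_I"))
    return phases


def run_stage3(
    gs: GeneratorSet, data, plan: StagePlan, state: Optional[TrainState] = None
) -> TrainState:
    """Cycle-consistency fine-tuning of the image-domain maps only."""
    state = state or TrainState()
    samples = list(data)
    if not samples:
        raise ValueError("stage 3 requires a non-empty dataset")
    phases = _stage3_phases(gs, plan)
    rng = np.random.default_rng((plan.seed, 3))
    opts = {role: _optim(gs, [role], plan.stage_lr("S3")) for _, _, role in phases}
    lw = plan.weights
    for epoch in range(plan.stage_epochs("S3")):
        sums = {name: 0.0 for name, *_ in phases}
        for name, loss_fn, role in phases:
            gs.set_frozen(set(ROLES) - {role})
            for idxs in _batches(len(samples), plan.batch_size, rng):

                def one(s, _fn=loss_fn):
                    _bind_sample(gs, s)
                    return _fn(gs, s, s.transform, lw)

                loss = _mean_loss(one, idxs, samples)
                opts[role].zero_grad()
                loss.backward()
                _audit_step(gs, set(ROLES) - {role}, opts[role], state, plan)
                state.updates += 1
                sums[name] += loss.data * len(idxs)
        for name, *_ in phases:
            state.log("S3", name, epoch, sums[name] / len(samples))
    gs.set_frozen(set())
    state.epochs_run["S3"] = plan.stage_epochs("S3")
    state.checksums = gs.checksums()
    return state


def infer(gs: GeneratorSet, x: np.ndarray, direction: str, spec: TransformSpec, dc=None):
    """Single image-domain forward pass; data consistency for masked Fourier.

    ``dc`` is an optional (SamplingMask, measured k-space) pair; when given
    (the MRI test-time rule) the network output is carried to k-space, the
    sampled lines are replaced by the measurements, and the magnitude of the
    inverse transform is returned.
    """
    role = {"s_to_t": "G_t_I", "t_to_s": "G_s_I"}.get(direction)
    if role is None:
        raise ValueError(f"unknown direction {direction!r}")
    g = gs.role(role)
    if g is None or (len(g.parameters()) == 0 and not isinstance(g, ImageUNet)):
        raise ValueError(f"direction {direction} has no trained image generator")
    t = hi.image_tensor(x, spec)
    out = g(t)
    if spec.kind == "fourier" and dc is not None:
        mask, measured = dc
        pred = out.data[0] + 1j * out.data[1]
        k = np.fft.fftshift(np.fft.fft2(pred))
        grid = mask.as_grid(spec.image_shape)
        kv = k * (1 - grid) + np.asarray(measured) * grid
        img = np.fft.ifft2(np.fft.ifftshift(kv))
        return np.abs(img)
    if out.data.shape[0] == 2:
        return np.hypot(out.data[0], out.data[1])
    return out.data[0]


def _evaluate(gs: GeneratorSet, samples, direction="s_to_t") -> me.MetricsReport:
    pairs = []
    for s in samples:
        dc = None
        if s.transform.kind == "fourier" and "mask" in s.provenance:
            dc = (
                SamplingMask(
                    s.provenance["mask"],
                    acceleration=s.provenance.get("accel", 1.0),
                    n_center=s.provenance.get("n_center", 1),
                ),
                s.provenance["k_measured"],
            )
        pred = infer(gs, s.x_s, direction, s.transform, dc=dc)
        pairs.append((pred, np.abs(s.x_t)))
    return me.evaluate_pairs(pairs, data_range=1.0)


_RUNNERS = {"S1": run_stage1, "S2": run_stage2, "S3": run_stage3}


def run_plan(dataset: dict, plan: StagePlan, task: str):
    """Execute the enabled stages in order and evaluate on the test split.

    Returns (GeneratorSet, TrainState, MetricsReport).
    """
    train = dataset["train"]
    if not train:
        raise ValueError("empty training split")
    spec = train[0].transform
    gs = build_generator_set(task, spec, plan)
    state = TrainState()
    for stage in plan.stages_enabled:
        state = _RUNNERS[stage](gs, train, plan, state)
    report = _evaluate(gs, dataset["test"])
    return gs, state, report


def _updates_per_epoch(stage: str, task: str, dual: bool) -> int:
    """Role-update passes per epoch (unit: full passes over the data)."""
    if task == "mri":
        return {"S1": 2, "S2": 2, "S3": 1}[stage]
    if not dual:
        return {"S1": 2, "S2": 0, "S3": 2}[stage]
    return {"S1": 4, "S2": 4, "S3": 2}[stage]


def ablation_plans(base: StagePlan, task: str) -> dict:
    """Matched-budget plans for every ablation preset.

    Each preset's epochs are scaled so its total role-update count matches
    the full dual-domain S1+S2+S3 plan, keeping comparisons compute-fair.
    """
    full_cost = sum(
        base.stage_epochs(s) * _updates_per_epoch(s, task, True) for s in _STAGE_ORDER
    )
    plans = {}
    for preset in ABLATION_PRESETS:
        dual = preset != "image_only"
        stages = tuple(preset.split("+")) if dual else ("S1", "S3")
        cost = sum(
            base.stage_epochs(s) * _updates_per_epoch(s, task, dual) for s in stages
        )
        if cost == 0:
            continue
        factor = full_cost / cost
        epochs = tuple(
            max(1, round(base.stage_epochs(s) * factor)) if s in stages else 0
            for s in _STAGE_ORDER
        )
        weights = base.weights
        if not dual:
            # single-domain variant: drop the cross-domain cycle terms
            weights = replace(
                weights, inactive=frozenset(weights.inactive | {"xi2", "xi4"})
            )
        plans[preset] = replace(
            base,
            stages_enabled=stages,
            epochs_per_stage=epochs,
            dual_domain=dual,
            weights=weights,
        )
    return plans


def save_checkpoint(gs: GeneratorSet, path, config: Optional[dict] = None) -> None:
    """Single-file archive of all role weights plus a config hash."""
    arrays = {}
    for r in gs.active_roles():
        for k, v in gs.require(r).state_dict().items():
            arrays[f"{r}__{k}"] = v
    cfg = json.dumps(config or {}, sort_keys=True)
    arrays["__config_hash__"] = np.frombuffer(
        hashlib.sha256(cfg.encode()).digest(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(gs: GeneratorSet, path) -> None:
    """Load weights by role name into an already-built GeneratorSet."""
    with np.load(path) as f:
        for key in f.files:
            if key == "__config_hash__":
                continue
            role, _, pname = key.partition("__")
            g = gs.role(role)
            if g is not None and pname in g._params:
                g._params[pname].data = np.array(f[key], dtype=np.float64)
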